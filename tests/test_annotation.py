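import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import binom_two_sided_exact
from tescope.annotation import (
    GENOMIC_BASELINE,
    assign_age,
    chromosome_enrichment,
    class_composition,
    cluster_size_diagnostics,
    family_enrichment,
    spearman_exact,
    summarize_direction,
)
from tescope.ingest import TELocus


def _results(up: int, down: int, cell_type="EX"):
    return pd.DataFrame(
        {
            "feature_id": [f"f{i}" for i in range(up + down)],
            "cell_type": cell_type,
            "log2fc": [3.0] * up + [-3.0] * down,
        }
    )


class TestDirectionSummary:
    def test_overall_percentages(self):
        # 428 up / 80 down of 508: 84.3% vs 15.7%
        out = summarize_direction(_results(428, 80), by="overall")
        assert out.loc[0, "up"] == 428 and out.loc[0, "n"] == 508
        assert out.loc[0, "up_pct"] == 84.3
        assert out.loc[0, "down_pct"] == 15.7

    def test_per_cell_type(self):
        df = pd.concat([_results(303, 16, "EX"), _results(107, 58, "ODC")])
        out = summarize_direction(df, by="cell_type").set_index("group")
        assert out.loc["EX", "up_pct"] == 95.0  # 303/319
        assert out.loc["ODC", "up_pct"] == 64.8  # 107/165

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        df = _results(int(rng.integers(1, 300)), int(rng.integers(1, 300)))
        out = summarize_direction(df)
        assert abs(out.loc[0, "up_pct"] + out.loc[0, "down_pct"] - 100.0) <= 0.1

    def test_zero_log2fc_excluded_and_counted(self):
        df = _results(2, 1)
        df.loc[len(df)] = ["fz", "EX", 0.0]
        out = summarize_direction(df)
        assert out.loc[0, "zero"] == 1 and out.loc[0, "n"] == 3

    def test_empty_input(self):
        out = summarize_direction(_results(0, 0))
        assert out.empty or out.loc[0, "n"] == 0


def _locus(i, cls="SINE", fam="Alu", sub="AluY", chrom="chr1"):
    return TELocus(chrom, 100 * i + 1, 100 * i + 50, sub, fam, cls)


class TestClassComposition:
    def test_study_scale_percentages(self):
        loci = (
            [_locus(i, "SINE") for i in range(319)]
            + [_locus(1000 + i, "LINE", "L1", "L1PA4") for i in range(134)]
            + [_locus(2000 + i, "LTR", "ERV", "HERVK") for i in range(37)]
            + [_locus(3000 + i, "DNA", "DNA", "MER20") for i in range(18)]
        )
        out = class_composition(loci).set_index("te_class")
        assert out.loc["SINE", "pct"] == 62.8
        assert out.loc["LINE", "pct"] == 26.4
        assert out.loc["LTR", "pct"] == 7.3
        assert out.loc["DNA", "pct"] == 3.5
        assert abs(out["pct"].sum() - 100.0) <= 0.1

    def test_single_and_empty(self):
        out = class_composition([_locus(0, "LINE", "L1", "L1PA4")])
        assert out.loc[0, "pct"] == 100.0
        assert class_composition([]).empty


class TestAgeClasses:
    @pytest.mark.parametrize(
        "sub,age",
        [
            ("L1HS", "Young"), ("L1PA2", "Young"), ("L1PA4", "Young"), ("L1PA8", "Young"),
            ("L1PA9", "Old"), ("L1PA17", "Old"), ("L1PB1", "Old"),
            ("L1M5", "Very Old"), ("L2a", "Ancient"), ("L3", "Ancient"),
            ("AluYa5", "Young"), ("AluSx", "Old"), ("AluJb", "Ancient"), ("MIRb", "Ancient"),
            ("HERVK-int", "unclassified"), ("MER20", "unclassified"),
        ],
    )
    def test_assignments(self, sub, age):
        assert assign_age(sub) == age


class TestFamilyEnrichment:
    def test_alu_fold_at_study_scale(self):
        # 300 Alu of 508 vs 45% baseline -> 1.31-fold enrichment
        table, chi2_stat, chi2_p = family_enrichment({"Alu": 300, "L1": 110, "L2": 24,
                                                      "MIR": 19, "ERV": 37, "DNA": 18})
        row = table.set_index("family").loc["Alu"]
        assert row["fold"] == 1.31
        assert row["p_value"] < 1e-6
        assert row["direction"] == "enriched"

    def test_proportional_observed_gives_unit_folds(self):
        n = 1000
        obs = {f: int(round(n * pi)) for f, pi in GENOMIC_BASELINE.items()}
        table, chi2_stat, _ = family_enrichment(obs)
        assert np.allclose(table["fold_exact"], 1.0, atol=0.01)
        assert chi2_stat < 0.5

    def test_binomial_p_matches_enumeration_oracle(self):
        # spot value: k=8, n=10, pi=0.5 -> two-sided exact p = 0.109375
        table, *_ = family_enrichment({"Alu": 8, "L1": 2}, {"Alu": 0.5, "L1": 0.5})
        assert table.set_index("family").loc["Alu", "p_value"] == pytest.approx(0.109375)
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(1, 21))
            k = int(rng.integers(0, n + 1))
            pi = float(rng.uniform(0.05, 0.95))
            table, *_ = family_enrichment(
                {"Alu": k, "L1": n - k}, {"Alu": pi, "L1": 1 - pi}
            )
            got = table.set_index("family").loc["Alu", "p_value"]
            assert got == pytest.approx(binom_two_sided_exact(k, n, pi), abs=1e-10)

    def test_unknown_family_pooled_into_other(self):
        table, *_ = family_enrichment({"Alu": 5, "SVA": 5})
        assert table.set_index("family").loc["other", "observed"] == 5


class TestChromosomeEnrichment:
    def test_two_chromosome_example(self):
        genome = {"chr1": 10_000_000, "chr2": 10_000_000}
        loci = [_locus(i, chrom="chr1") for i in range(16)] + [
            _locus(i, chrom="chr2") for i in range(4)
        ]
        out = chromosome_enrichment(loci, genome).set_index("chrom")
        assert out.loc["chr1", "fold"] == pytest.approx(1.6)
        assert out.loc["chr2", "fold"] == pytest.approx(0.4)
        assert bool(out.loc["chr1", "enriched"]) and not bool(out.loc["chr2", "enriched"])
        assert out["expected"].sum() == pytest.approx(20, abs=1e-9)

    def test_uniform_density_unflagged(self):
        genome = {"chr1": 10_000_000, "chr2": 20_000_000}
        loci = [_locus(i, chrom="chr1") for i in range(10)] + [
            _locus(i, chrom="chr2") for i in range(20)
        ]
        out = chromosome_enrichment(loci, genome)
        assert np.allclose(out["fold"], 1.0)
        assert not out["enriched"].any()

    def test_single_chromosome(self):
        out = chromosome_enrichment([_locus(0)], {"chr1": 1_000_000})
        assert out.loc[0, "fold"] == pytest.approx(1.0)


class TestClusterSizeDiagnostics:
    def _summary(self):
        return pd.DataFrame(
            {
                "cell_type": ["EX", "ODC", "INH", "MG", "ASC"],
                "n_cells": [6000, 37052, 3000, 1500, 5000],
                "n_de_tes": [319, 165, 16, 5, 3],
                "mean_abs_log2fc": [4.5, 3.5, 4.8, 5.0, 4.2],
            }
        )

    def test_rate_per_1000(self):
        diag = cluster_size_diagnostics(self._summary())
        tab = diag.table.set_index("cell_type")
        # 165 DE TEs over 37,052 cells -> 4.5 per 1,000 cells
        assert tab.loc["ODC", "rate_per_1000"] == pytest.approx(4.45, abs=0.02)
        assert tab.loc["EX", "rate_per_1000"] == pytest.approx(1000 * 319 / 6000)

    def test_zero_de_cell_type_retained(self):
        s = self._summary()
        s.loc[len(s)] = ["OPC", 2740, 0, np.nan]
        diag = cluster_size_diagnostics(s)
        assert diag.table.set_index("cell_type").loc["OPC", "rate_per_1000"] == 0.0

    def test_perfect_monotone_rho(self):
        s = pd.DataFrame(
            {
                "cell_type": list("abcde"),
                "n_cells": [100, 200, 300, 400, 500],
                "n_de_tes": [1, 2, 3, 4, 5],
                "mean_abs_log2fc": [2.0, 2.5, 3.0, 3.5, 4.0],
            }
        )
        diag = cluster_size_diagnostics(s)
        assert diag.spearman_rho == pytest.approx(1.0)

    def test_too_few_cell_types_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            cluster_size_diagnostics(self._summary().head(2))


class TestSpearmanExact:
    def test_exact_p_matches_direct_enumeration(self):
        from itertools import permutations

        rng = np.random.default_rng(2)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        rho, p = spearman_exact(x, y)
        rho_ref = stats.spearmanr(x, y).statistic
        assert rho == pytest.approx(rho_ref)
        count = 0
        total = 0
        yr = stats.rankdata(y)
        for perm in permutations(range(6)):
            r = stats.spearmanr(stats.rankdata(x), yr[list(perm)]).statistic
            count += abs(r) >= abs(rho_ref) - 1e-12
            total += 1
        assert p == pytest.approx(count / total)

    def test_constant_input_flagged(self):
        rho, p = spearman_exact([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_large_n_uses_asymptotic(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = spearman_exact(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
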