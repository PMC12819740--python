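import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import brute_force_pairs, fisher_two_sided_exact, hypergeom_sf_exact
from tescope.ingest import TELocus
from tescope.proximity import (
    DEFAULT_WINDOWS,
    GenomicFeatureAssigner,
    WindowMetrics,
    ad_gene_proximity,
    find_pairs,
    hypergeom_enrichment,
    select_window,
    te_derived_gene_test,
    window_metrics,
)


def _genes(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    df["strand"] = "+"
    df["tss"] = df["start"]
    return df


class TestFindPairs:
    def test_gap_distance(self):
        te = TELocus("chr1", 1000, 1300, "AluY", "Alu", "SINE")
        genes = _genes([("g1", "chr1", 1500, 3000)])
        out = find_pairs([te], genes, 250_000)
        assert len(out) == 1
        assert out.loc[0, "distance"] == 200

    def test_overlap_gives_zero(self):
        te = TELocus("chr1", 2000, 2100, "AluY", "Alu", "SINE")  # intronic TE
        out = find_pairs([te], _genes([("g1", "chr1", 1500, 3000)]), 50_000)
        assert out.loc[0, "distance"] == 0

    def test_beyond_window_excluded(self):
        te = TELocus("chr1", 0, 100, "AluY", "Alu", "SINE")
        out = find_pairs([te], _genes([("g1", "chr1", 300_101, 400_000)]), 250_000)
        assert out.empty

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            n_te, n_g = rng.integers(1, 60, size=2)
            tes = []
            for i in range(n_te):
                s = int(rng.integers(0, 900_000))
                tes.append(TELocus(f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(100, 5000)),
                                   "AluY", "Alu", "SINE"))
            genes = _genes([
                (f"g{j}", f"chr{rng.integers(1, 3)}", s := int(rng.integers(0, 900_000)),
                 s + int(rng.integers(500, 50_000)))
                for j in range(n_g)
            ])
            window = int(rng.choice([5_000, 50_000, 200_000]))
            got = find_pairs(tes, genes, window)
            expected = brute_force_pairs(
                [(t.chrom, t.start, t.end) for t in tes],
                list(genes[["chrom", "start", "end"]].itertuples(index=False)),
                window,
            )
            got_set = {(r.te_id, r.gene_id, r.distance) for r in got.itertuples()}
            exp_set = {(tes[i].name, f"g{j}", d) for i, j, d in expected}
            assert got_set == exp_set


class TestWindowNesting:
    def test_monotone_metrics_on_simulated_bundle(self, planted_bundle):
        loci = planted_bundle.te_loci[:60]
        pairs = {w: find_pairs(loci, planted_bundle.gene_models, w) for w in DEFAULT_WINDOWS}
        keys = {
            w: {(r.te_id, r.gene_id) for r in pairs[w].itertuples()} for w in DEFAULT_WINDOWS
        }
        metrics = window_metrics(
            pairs, [t.name for t in loci], planted_bundle.gene_sets,
            set(planted_bundle.gene_models["gene_id"]),
        )
        for w1, w2 in zip(DEFAULT_WINDOWS, DEFAULT_WINDOWS[1:]):
            assert keys[w1] <= keys[w2]  # pair nesting
        iso = [m.isolation_pct for m in metrics]
        med = [m.median_genes_per_te for m in metrics]
        assert all(a >= b for a, b in zip(iso, iso[1:]))  # isolation non-increasing
        assert all(a <= b for a, b in zip(med, med[1:]))  # coverage non-decreasing


class TestWindowMetrics:
    def test_toy_isolation_and_median(self):
        tes = [
            TELocus("chr1", 1000, 1100, "AluY", "Alu", "SINE"),
            TELocus("chr2", 1000, 1100, "AluY", "Alu", "SINE"),
        ]
        genes = _genes([("g1", "chr1", 2000, 3000), ("g2", "chr1", 4000, 5000),
                        ("g3", "chr2", 900_000, 950_000)])
        pairs = {10_000: find_pairs(tes, genes, 10_000)}
        with pytest.warns(UserWarning, match="empty gene-set"):
            m = window_metrics(pairs, [t.name for t in tes], {}, set(genes["gene_id"]))[0]
        assert m.isolation_pct == 50.0  # TE2 has no gene within 10 kb
        assert m.median_genes_per_te == 1.0  # counts {2, 0}

    def test_all_genes_beyond_windows(self):
        tes = [TELocus("chr1", 0, 100, "AluY", "Alu", "SINE")]
        genes = _genes([("g1", "chr2", 0, 1000)])
        pairs = {w: find_pairs(tes, genes, w) for w in DEFAULT_WINDOWS}
        with pytest.warns(UserWarning, match="empty gene-set"):
            for m in window_metrics(pairs, [t.name for t in tes], {}, {"g1"}):
                assert m.isolation_pct == 100.0

    def test_enriched_set_detected(self):
        proximal = {f"g{i}" for i in range(10)}
        background = {f"g{i}" for i in range(100)}
        enr = hypergeom_enrichment(proximal, {"hit": sorted(proximal)}, background)
        assert enr.loc[0, "q_value"] < 0.05

    def test_hypergeom_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            M = int(rng.integers(10, 51))
            n = int(rng.integers(1, M + 1))
            N = int(rng.integers(1, M + 1))
            k = int(rng.integers(0, min(n, N) + 1))
            got = stats.hypergeom.sf(k - 1, M, n, N)
            assert got == pytest.approx(hypergeom_sf_exact(k, M, n, N), abs=1e-10)


class TestSelectWindow:
    def test_dominant_window_selected(self):
        metrics = [
            WindowMetrics(50_000, 40.0, 2.0, 1),
            WindowMetrics(250_000, 5.0, 6.0, 12),   # best on all three terms
            WindowMetrics(500_000, 10.0, 15.0, 6),
        ]
        selected, table = select_window(metrics)
        assert selected == 250_000
        assert table["composite"].idxmax() == 1

    def test_tie_takes_smaller_window(self):
        metrics = [WindowMetrics(50_000, 10.0, 5.0, 3), WindowMetrics(250_000, 10.0, 5.0, 3)]
        selected, table = select_window(metrics)
        assert selected == 50_000
        # constant metrics neutralized at 0.5
        assert np.allclose(table["specificity_score"], 0.5)

    def test_study_scale_metric_table_selects_250kb(self):
        # study-scale window sensitivity: 18.3% vs 3.3% isolation, 2 vs 6
        # genes/TE, 0 vs 14 significant sets at 50 kb vs 250 kb; the
        # larger windows continue the trend
        metrics = [
            WindowMetrics(50_000, 18.3, 2.0, 0),
            WindowMetrics(250_000, 3.3, 6.0, 14),
            WindowMetrics(500_000, 2.0, 12.0, 9),
            WindowMetrics(1_000_000, 1.0, 21.0, 5),
        ]
        selected, _ = select_window(metrics)
        assert selected == 250_000


class TestAdGeneProximity:
    def test_cumulative_tiers(self):
        te = TELocus("chr1", 100_000, 100_300, "AluY", "Alu", "SINE")
        genes = _genes([
            ("near", "chr1", 140_000, 150_000),    # 39.7 kb -> 50 kb tier
            ("mid", "chr1", 320_000, 330_000),     # ~220 kb -> 250 kb tier
            ("far", "chr1", 900_000, 910_000),     # ~800 kb -> 1 Mb tier
        ])
        pairs = {w: find_pairs([te], genes, w) for w in DEFAULT_WINDOWS}
        out = ad_gene_proximity(pairs, ["near", "mid", "far"])
        assert out.tier_counts[50_000] == 1
        assert out.tier_counts[250_000] == 1
        assert out.tier_counts[500_000] == 0
        assert out.tier_counts[1_000_000] == 1

    def test_ranking_by_distinct_te_count(self):
        tes = [TELocus("chr1", s, s + 100, "AluY", "Alu", "SINE") for s in (1000, 3000, 5000)]
        genes = _genes([("a", "chr1", 10_000, 12_000), ("b", "chr1", 500_000, 502_000)])
        pairs = {50_000: find_pairs(tes, genes, 50_000), 1_000_000: find_pairs(tes, genes, 1_000_000)}
        out = ad_gene_proximity(pairs, ["a", "b"], tally_window=1_000_000)
        top = out.top_genes.set_index("gene_id")["n_tes"]
        assert top["a"] == 3 and top["b"] == 3
        out50 = ad_gene_proximity(pairs, ["a", "b"], tally_window=50_000)
        assert out50.top_genes.set_index("gene_id")["n_tes"]["a"] == 3

    def test_no_ad_genes_in_windows(self):
        te = TELocus("chr1", 0, 100, "AluY", "Alu", "SINE")
        pairs = {w: find_pairs([te], _genes([("g", "chr1", 10, 20)]), w) for w in (50_000,)}
        out = ad_gene_proximity(pairs, ["absent"])
        assert out.tier_counts.sum() == 0
        assert out.family_counts.empty


class TestTeDerivedGeneTest:
    def test_study_scale_depletion(self):
        proximal = [f"g{i}" for i in range(2326)]
        catalog = proximal[:12] + ["x1", "x2"]
        res = te_derived_gene_test(proximal, catalog)
        assert res.proportion_pct == 0.52  # 12 / 2,326
        assert res.direction == "depleted"
        assert res.p_value < 1e-6

    def test_null_proportion(self):
        proximal = [f"g{i}" for i in range(1000)]
        catalog = proximal[:30]  # exactly 3%
        res = te_derived_gene_test(proximal, catalog)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.01)
        assert res.p_value > 0.5

    def test_fisher_matches_enumeration(self):
        got = stats.fisher_exact([[1, 9], [3, 7]], alternative="two-sided")[1]
        assert got == pytest.approx(fisher_two_sided_exact([[1, 9], [3, 7]]), abs=1e-10)
        rng = np.random.default_rng(6)
        for _ in range(20):
            t = [[int(rng.integers(0, 12)), int(rng.integers(0, 12))],
                 [int(rng.integers(0, 12)), int(rng.integers(0, 12))]]
            if sum(t[0]) == 0 or sum(t[1]) == 0:
                continue
            got = stats.fisher_exact(t, alternative="two-sided")[1]
            assert got == pytest.approx(fisher_two_sided_exact(t), abs=1e-9)

    def test_empty_proximal_rejected(self):
        with pytest.raises(ValueError, match="proximal"):
            te_derived_gene_test([], ["g1"])


class TestGenomicFeatureAssignment:
    @pytest.fixture()
    def assigner(self):
        genes = _genes([("g1", "chr1", 10_000, 30_000)])
        exons = pd.DataFrame({"chrom": ["chr1"], "start": [12_000], "end": [12_500]})
        enhancers = pd.DataFrame({"chrom": ["chr1"], "start": [20_000], "end": [21_000]})
        return GenomicFeatureAssigner(genes, exons, enhancers)

    def _te(self, start, end):
        return TELocus("chr1", start, end, "AluY", "Alu", "SINE")

    def test_promoter_upstream_of_tss(self, assigner):
        assert assigner.assign(self._te(8_900, 9_100)) == "promoter"  # 1 kb upstream

    def test_enhancer_beats_intron(self, assigner):
        assert assigner.assign(self._te(20_300, 20_500)) == "enhancer"

    def test_exon_and_intron(self, assigner):
        assert assigner.assign(self._te(12_100, 12_300)) == "exon"
        assert assigner.assign(self._te(15_000, 15_200)) == "intron"

    def test_intergenic(self, assigner):
        assert assigner.assign(self._te(5_000_000, 5_000_200)) == "intergenic"

    def test_total_and_counts_sum(self, assigner):
        tes = [self._te(s, s + 100) for s in range(0, 100_000, 7_000)]
        out = assigner.assign_all(tes)
        assert len(out) == len(tes)
        assert out["feature"].isin(
            ["promoter", "enhancer", "exon", "intron", "intergenic"]
        ).all()
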