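"""Class/family/age annotation and enrichment for differentially expressed TEs.

Covers: direction summaries (up vs down), class composition, subfamily
age classes (evolutionary age from RepeatMasker-style subfamily names),
family enrichment against a genomic baseline composition (chi-square
goodness of fit plus per-family exact binomial tests with BH
correction), chromosome-level enrichment normalized for chromosome
size, and cluster-size bias diagnostics.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .pseudobulk import bh_adjust

__all__ = [
    "GENOMIC_BASELINE",
    "assign_age",
    "summarize_direction",
    "class_composition",
    "family_enrichment",
    "chromosome_enrichment",
    "cluster_size_diagnostics",
    "BiasDiagnostics",
    "spearman_exact",
]

#: genome-wide TE family composition used as the enrichment baseline
GENOMIC_BASELINE = {
    "Alu": 0.45,
    "L1": 0.17,
    "L2": 0.08,
    "MIR": 0.05,
    "ERV": 0.08,
    "DNA": 0.03,
    "other": 0.14,
}

AGE_CLASSES = ("Young", "Old", "Very Old", "Ancient", "unclassified")

_L1PA = re.compile(r"^L1PA(\d+)")


def assign_age(subfamily: str) -> str:
    """Evolutionary age class of a TE subfamily.

    LINE-1: Young (<6 Mya) = L1HS, L1PA2-L1PA8; Old (6-40 Mya) =
    L1PA9-L1PA17, L1PB*; Very Old (40-80 Mya) = L1M*; Ancient (>80 Mya)
    = L2*, L3*.  SINE: Young (<25 Mya) = AluY*; Old (25-50 Mya) =
    AluS*; Ancient (>50 Mya) = AluJ*, MIR*.  Anything else is
    "unclassified".  Total and deterministic.
    """
    s = subfamily
    if s.startswith("L1HS"):
        return "Young"
    m = _L1PA.match(s)
    if m:
        n = int(m.group(1))
        if 2 <= n <= 8:
            return "Young"
        if 9 <= n <= 17:
            return "Old"
        return "unclassified"
    if s.startswith("L1PB"):
        return "Old"
    if s.startswith("L1M"):
        return "Very Old"
    if s.startswith(("L2", "L3")):
        return "Ancient"
    if s.startswith("AluY"):
        return "Young"
    if s.startswith("AluS"):
        return "Old"
    if s.startswith(("AluJ", "MIR")):
        return "Ancient"
    return "unclassified"


def summarize_direction(results: pd.DataFrame, by: str = "overall") -> pd.DataFrame:
    """Up/down counts and one-decimal percentages from signed log2FC.

    ``by`` is ``"overall"`` or ``"cell_type"``.  Features with exactly
    zero log2FC are excluded from the percentages and counted in a
    ``zero`` column.
    """
    if by not in ("overall", "cell_type"):
        raise ValueError("by must be 'overall' or 'cell_type'")
    df = results.copy()
    df["_group"] = "all" if by == "overall" else df["cell_type"]
    rows = []
    for group, g in df.groupby("_group", sort=True):
        lfc = g["log2fc"].to_numpy()
        up = int((lfc > 0).sum())
        down = int((lfc < 0).sum())
        zero = int((lfc == 0).sum())
        n = up + down
        rows.append(
            {
                "group": group,
                "n": n,
                "up": up,
                "down": down,
                "zero": zero,
                "up_pct": round(100.0 * up / n, 1) if n else np.nan,
                "down_pct": round(100.0 * down / n, 1) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def class_composition(te_loci) -> pd.DataFrame:
    """Counts and one-decimal percentages per TE class."""
    classes = [t.te_class for t in te_loci]
    if not classes:
        return pd.DataFrame(columns=["te_class", "count", "pct"])
    counts = pd.Series(classes).value_counts()
    total = int(counts.sum())
    out = pd.DataFrame(
        {"te_class": counts.index, "count": counts.to_numpy()}
    )
    out["pct"] = (100.0 * out["count"] / total).round(1)
    return out.reset_index(drop=True)


def family_enrichment(
    observed: dict[str, int], baseline: dict[str, float] | None = None
) -> tuple[pd.DataFrame, float, float]:
    """Per-family fold enrichment vs a genomic baseline, plus overall GOF.

    Families observed but absent from the baseline are pooled into
    ``other``.  Per-family tests are two-sided exact binomial
    (minlike convention: sum of probabilities of all outcomes no more
    likely than the observed one), BH-corrected across families; the
    overall deviation is a chi-square goodness-of-fit over the baseline
    families.

    Returns ``(table, chi2_statistic, chi2_p)``; folds are reported to
    two decimals in the ``fold`` column (exact values in ``fold_exact``).
    """
    if baseline is None:
        baseline = GENOMIC_BASELINE
    total_pi = sum(baseline.values())
    if abs(total_pi - 1.0) > 1e-9:
        raise ValueError(f"baseline proportions sum to {total_pi}, not 1")
    obs = dict.fromkeys(baseline, 0)
    for fam, k in observed.items():
        obs[fam if fam in baseline else "other"] = obs.get(
            fam if fam in baseline else "other", 0
        ) + int(k)
    n = sum(obs.values())
    if n < 1:
        raise ValueError("no observations")
    rows = []
    for fam, pi in baseline.items():
        k = obs[fam]
        expected = n * pi
        if pi == 0:
            fold = np.inf if k > 0 else np.nan
            p = np.nan
        else:
            fold = (k / n) / pi
            p = stats.binomtest(k, n, pi, alternative="two-sided").pvalue
        rows.append(
            {
                "family": fam,
                "observed": k,
                "expected": expected,
                "fold_exact": fold,
                "fold": round(fold, 2) if np.isfinite(fold) else fold,
                "p_value": p,
                "direction": "enriched" if fold > 1 else "depleted",
            }
        )
    table = pd.DataFrame(rows)
    finite = table["p_value"].notna()
    table["q_value"] = np.nan
    if finite.any():
        table.loc[finite, "q_value"] = bh_adjust(table.loc[finite, "p_value"].to_numpy())
    chi2_stat, chi2_p = stats.chisquare(
        table["observed"], f_exp=[n * baseline[f] for f in table["family"]]
    )
    return table, float(chi2_stat), float(chi2_p)


def chromosome_enrichment(
    te_loci, genome: dict[str, int], fold_threshold: float = 1.5
) -> pd.DataFrame:
    """Observed vs size-expected TE counts per chromosome.

    ``expected_c = N * L_c / sum(L)``; a chromosome is flagged enriched
    when observed/expected exceeds ``fold_threshold``.  Expected counts
    sum to N exactly (up to float tolerance).
    """
    chroms = [t.chrom for t in te_loci]
    unknown = set(chroms) - set(genome)
    if unknown:
        raise ValueError(f"loci on chromosomes absent from genome table: {sorted(unknown)}")
    n = len(chroms)
    total_len = float(sum(genome.values()))
    counts = pd.Series(chroms).value_counts()
    rows = []
    for chrom, length in genome.items():
        observed = int(counts.get(chrom, 0))
        expected = n * length / total_len
        fold = observed / expected if expected > 0 else np.nan
        rows.append(
            {
                "chrom": chrom,
                "length": length,
                "observed": observed,
                "expected": expected,
                "fold": fold,
                "enriched": bool(fold > fold_threshold) if np.isfinite(fold) else False,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cluster-size diagnostics
# ---------------------------------------------------------------------------

@dataclass
class BiasDiagnostics:
    """Cluster-size bias diagnostics across cell types."""

    table: pd.DataFrame  # cell_type, n_cells, n_de_tes, rate_per_1000, mean_abs_log2fc
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    pearson_p: float


def spearman_exact(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rho with an exact permutation two-sided p for small n.

    All ``n!`` pairings are enumerated when ``n <= exact_max_n`` (the
    study regime is n = 7 cell types); the asymptotic p from
    ``scipy.stats.spearmanr`` is used otherwise.  Constant input yields
    ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        return np.nan, np.nan
    rho, p_asym = stats.spearmanr(x, y)
    if n > exact_max_n:
        return float(rho), float(p_asym)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    num = ry_c @ rx_c
    den = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rhos = num / den
    p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return float(rho), p


def cluster_size_diagnostics(summary: pd.DataFrame) -> BiasDiagnostics:
    """Rate-normalized DE counts and size-bias correlations.

    ``summary`` needs columns ``cell_type, n_cells, n_de_tes,
    mean_abs_log2fc``; requires >= 3 cell types.  Computes the rank
    correlation of cluster size with the number of DE TEs and the
    product-moment correlation of cluster size with mean effect size;
    cell types with zero DE TEs are retained with rate 0.
    """
    if len(summary) < 3:
        raise ValueError("need >= 3 cell types for diagnostics")
    tab = summary.copy()
    tab["rate_per_1000"] = 1000.0 * tab["n_de_tes"] / tab["n_cells"]
    rho, p_rho = spearman_exact(tab["n_cells"], tab["n_de_tes"])
    eff = tab.dropna(subset=["mean_abs_log2fc"])
    if len(eff) >= 3 and eff["mean_abs_log2fc"].nunique() > 1 and eff["n_cells"].nunique() > 1:
        r, p_r = stats.pearsonr(eff["n_cells"], eff["mean_abs_log2fc"])
    else:
        warnings.warn("effect-size correlation undefined (constant input)", stacklevel=2)
        r, p_r = np.nan, np.nan
    return BiasDiagnostics(tab, float(rho), float(p_rho), float(r), float(p_r))
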