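"""Chromatin-accessibility integration and weighted regulatory scoring.

For each robust DE TE, ATAC peaks are intersected with the TE interval
and collected within a proximity window; accessibility metrics (mean,
variance, cell-type specificity tau) feed a weighted composite score
over TE-gene pairs:

    composite = 0.3 * s_dist + 0.3 * s_acc + 0.2 * s_eff + 0.2 * s_corr

with distance decayed linearly over the selected window, accessibility
and effect size min-max normalized over the scored set, and only
positive expression correlation contributing (regulatory support is
directional).  Pairs are then tiered Very High / High / Medium / Low
around peak overlap and the set-wise median composite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .ingest import TELocus

__all__ = [
    "AccessibilityProfile",
    "ScoreWeights",
    "accessibility_profile",
    "accessibility_profiles",
    "tau_specificity",
    "score_pairs",
    "classify_confidence",
    "pseudobulk_correlation",
]


@dataclass(frozen=True)
class ScoreWeights:
    """Component weights for the composite regulatory score (sum to 1)."""

    distance: float = 0.3
    accessibility: float = 0.3
    effect: float = 0.2
    correlation: float = 0.2

    def __post_init__(self):
        vals = (self.distance, self.accessibility, self.effect, self.correlation)
        if any(v < 0 for v in vals):
            raise ValueError("weights must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(vals)}")


@dataclass
class AccessibilityProfile:
    """Per-TE accessibility metrics from the ATAC peak matrix."""

    te_id: str
    overlaps_peak: bool
    n_peaks_within_window: int
    mean_accessibility: float
    peak_variance: float
    tau: float
    flagged: bool = False  # no peak within the window


def tau_specificity(x) -> float:
    """Cell-type specificity tau = sum(1 - x_i/max x) / (n - 1).

    0 for a uniform profile, 1 when the signal sits in a single cell
    type.  All-zero input returns 0.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return 0.0
    mx = x.max()
    if mx <= 0:
        return 0.0
    return float(np.sum(1.0 - x / mx) / (len(x) - 1))


def _peak_tree(peaks: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, p in enumerate(peaks.itertuples()):
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, i)
    return trees


def accessibility_profile(
    te: TELocus,
    peaks: pd.DataFrame,
    peak_matrix: pd.DataFrame,
    window: int = 250_000,
    _trees=None,
) -> AccessibilityProfile:
    """Accessibility metrics for one TE.

    ``peaks`` is a BED-like frame (row order matches ``peak_matrix``
    rows); ``peak_matrix`` holds non-negative accessibility per peak x
    cell type.  Metrics aggregate the peaks overlapping the TE or lying
    within ``window`` bp; when none exist all metrics are 0 and the
    profile is flagged.
    """
    trees = _trees if _trees is not None else _peak_tree(peaks)
    tree = trees.get(te.chrom)
    overlap_ids: list[int] = []
    window_ids: list[int] = []
    if tree is not None:
        overlap_ids = sorted(iv.data for iv in tree.overlap(te.start, te.end))
        window_ids = sorted(
            iv.data for iv in tree.overlap(max(0, te.start - window), te.end + window)
        )
    if not window_ids:
        return AccessibilityProfile(te.name, False, 0, 0.0, 0.0, 0.0, flagged=True)
    sub = peak_matrix.iloc[window_ids].to_numpy(dtype=float)
    per_ct = sub.mean(axis=0)  # mean accessibility per cell type
    return AccessibilityProfile(
        te_id=te.name,
        overlaps_peak=bool(overlap_ids),
        n_peaks_within_window=len(window_ids),
        mean_accessibility=float(sub.mean()),
        peak_variance=float(sub.mean(axis=1).var()),
        tau=tau_specificity(per_ct),
    )


def accessibility_profiles(
    te_loci: list[TELocus], peaks: pd.DataFrame, peak_matrix: pd.DataFrame,
    window: int = 250_000,
) -> dict[str, AccessibilityProfile]:
    trees = _peak_tree(peaks)
    return {
        te.name: accessibility_profile(te, peaks, peak_matrix, window, _trees=trees)
        for te in te_loci
    }


def pseudobulk_correlation(expr_by_unit: pd.DataFrame, te_id: str, gene_id: str) -> float:
    """Pearson correlation of TE and gene expression across sample x cell-type units.

    ``expr_by_unit`` is features x units (columns are pseudobulk units,
    e.g. normalized log counts per sample within a cell type).  Returns
    0 when either profile is constant.
    """
    x = expr_by_unit.loc[te_id].to_numpy(dtype=float)
    y = expr_by_unit.loc[gene_id].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _minmax_context(values: np.ndarray, label: str) -> tuple[float, float]:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi - lo < 1e-12:
        warnings.warn(f"degenerate min-max context for {label}; component set to 0.5",
                      stacklevel=3)
    return lo, hi


def score_pairs(
    pairs: pd.DataFrame,
    profiles: dict[str, AccessibilityProfile],
    de_results: pd.DataFrame,
    correlations: dict[tuple[str, str], float],
    weights: ScoreWeights = ScoreWeights(),
    window: int = 250_000,
) -> tuple[pd.DataFrame, dict]:
    """Composite regulatory score for every TE-gene pair.

    Components: ``s_dist = 1 - min(d, W)/W``; ``s_acc`` and ``s_eff``
    min-max normalized over the scored set (constant context -> 0.5,
    warned); ``s_corr = max(r, 0)``.  The normalization context is
    returned as a manifest dict.  ``de_results`` must carry one row per
    scored TE (``feature_id``, ``log2fc``).
    """
    if pairs.empty:
        return pairs.assign(composite=[]), {}
    lfc = de_results.set_index("feature_id")["log2fc"]
    acc = np.array([profiles[t].mean_accessibility for t in pairs["te_id"]])
    eff = np.array([abs(lfc[t]) for t in pairs["te_id"]])
    acc_lo, acc_hi = _minmax_context(acc, "accessibility")
    eff_lo, eff_hi = _minmax_context(eff, "effect size")

    def mm(v, lo, hi):
        if hi - lo < 1e-12:
            return np.full(len(v), 0.5)
        return (v - lo) / (hi - lo)

    d = pairs["distance"].to_numpy(dtype=float)
    s_dist = 1.0 - np.minimum(d, window) / window
    s_acc = mm(acc, acc_lo, acc_hi)
    s_eff = mm(eff, eff_lo, eff_hi)
    r = np.array([correlations.get((t, g), 0.0) for t, g in zip(pairs["te_id"], pairs["gene_id"])])
    s_corr = np.maximum(r, 0.0)
    composite = (
        weights.distance * s_dist
        + weights.accessibility * s_acc
        + weights.effect * s_eff
        + weights.correlation * s_corr
    )
    out = pairs.copy()
    out["s_dist"] = s_dist
    out["s_acc"] = s_acc
    out["s_eff"] = s_eff
    out["s_corr"] = s_corr
    out["composite"] = composite
    out["overlaps_peak"] = [profiles[t].overlaps_peak for t in pairs["te_id"]]
    manifest = {
        "window": window,
        "weights": {
            "distance": weights.distance,
            "accessibility": weights.accessibility,
            "effect": weights.effect,
            "correlation": weights.correlation,
        },
        "accessibility_minmax": [acc_lo, acc_hi],
        "effect_minmax": [eff_lo, eff_hi],
    }
    return out, manifest


TIERS = ("Very High", "High", "Medium", "Low")


def classify_confidence(
    scores: pd.DataFrame, corr_support_threshold: float = 0.3
) -> pd.DataFrame:
    """Assign high-confidence flags and confidence tiers.

    ``high_confidence`` = peak overlap AND composite above the set-wise
    median.  Tiers: Very High = high confidence with correlation
    support (``s_corr >=`` threshold); High = high confidence without;
    Medium = exactly one of peak overlap / above-median; Low = neither.
    Every pair gets exactly one tier; order of rows is irrelevant.
    """
    out = scores.copy()
    median = float(out["composite"].median())
    above = out["composite"] > median
    peak = out["overlaps_peak"].astype(bool)
    out["high_confidence"] = peak & above
    tier = np.where(
        out["high_confidence"],
        np.where(out["s_corr"] >= corr_support_threshold, "Very High", "High"),
        np.where(peak ^ above, "Medium", "Low"),
    )
    out["tier"] = tier
    out.attrs["median_composite"] = median
    return out
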