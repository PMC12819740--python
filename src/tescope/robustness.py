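"""Balanced-downsampling sensitivity analysis for pseudobulk DE.

With unbalanced group sizes (e.g. 11 AD vs 7 control) the larger
condition is repeatedly subsampled to the size of the smaller one and
the DE test repeated; a feature is "highly robust" only if it is
significant in the full data set AND in every balanced iteration
(100% detection rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .pseudobulk import PseudobulkMatrix, call_robust_candidates, nb_lrt

__all__ = [
    "DownsamplePlan",
    "make_plans",
    "classify_robust",
    "run_robustness",
    "select_robust_tes",
]


@dataclass(frozen=True)
class DownsamplePlan:
    """One balanced iteration: which case samples are retained."""

    iteration: int
    retained_cases: tuple
    seed: int


def make_plans(case_ids, control_ids, k: int = 10, seed: int = 0) -> list[DownsamplePlan]:
    """Draw ``k`` pairwise-distinct uniform subsets of the case samples.

    Each subset has exactly ``len(control_ids)`` cases (all controls are
    always retained).  Distinctness is enforced by rejection-resampling;
    the draw is deterministic under ``seed``.
    """
    case_ids = list(case_ids)
    n_keep = len(list(control_ids))
    if len(case_ids) < n_keep:
        raise ValueError("fewer case samples than control samples")
    n_subsets = comb(len(case_ids), n_keep)
    if k > n_subsets:
        raise ValueError(
            f"requested {k} distinct subsets but only C({len(case_ids)},{n_keep})"
            f" = {n_subsets} exist"
        )
    rng = np.random.default_rng(seed)
    seen: set[tuple] = set()
    plans: list[DownsamplePlan] = []
    while len(plans) < k:
        subset = tuple(sorted(rng.choice(len(case_ids), size=n_keep, replace=False)))
        if subset in seen:
            continue
        seen.add(subset)
        plans.append(
            DownsamplePlan(
                iteration=len(plans) + 1,
                retained_cases=tuple(case_ids[i] for i in subset),
                seed=seed,
            )
        )
    return plans


def classify_robust(
    full: pd.DataFrame,
    per_iteration: list[pd.DataFrame],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Count per-iteration detections and apply the strict robustness rule.

    ``highly_robust`` iff significant in the full run and detected
    (FDR < threshold) in all K iterations.  A feature absent from an
    iteration's results counts as not detected there.
    """
    k = len(per_iteration)
    detection = pd.Series(0, index=pd.Index(full["feature_id"]), dtype=int)
    for it in per_iteration:
        sig = it.loc[(it["fdr"] < fdr_threshold).fillna(False), "feature_id"]
        hits = detection.index.isin(set(sig))
        detection[hits] += 1
    significant_full = (full["fdr"] < fdr_threshold).fillna(False).to_numpy()
    out = pd.DataFrame(
        {
            "feature_id": full["feature_id"].to_numpy(),
            "cell_type": full["cell_type"].to_numpy(),
            "significant_full": significant_full,
            "detection_count": detection.loc[full["feature_id"]].to_numpy(),
            "k": k,
        }
    )
    out["highly_robust"] = out["significant_full"] & (out["detection_count"] == k)
    return out


def run_robustness(
    pb: PseudobulkMatrix,
    k: int = 10,
    seed: int = 0,
    fdr_threshold: float = 0.05,
    **de_kwargs,
) -> tuple[pd.DataFrame, list[pd.DataFrame], pd.DataFrame]:
    """Full-data DE plus ``k`` balanced-downsampling DE runs.

    Returns ``(full_results, per_iteration_results, robustness_records)``.
    If the groups are already balanced the downsampling step is the
    identity and a single iteration is run.
    """
    case = [s for s, c in zip(pb.sample_ids, pb.condition) if c == "AD"]
    control = [s for s, c in zip(pb.sample_ids, pb.condition) if c == "control"]
    k_eff = min(k, comb(len(case), len(control)))
    plans = make_plans(case, control, k=k_eff, seed=seed)
    full = nb_lrt(pb, fdr_threshold=fdr_threshold, **de_kwargs)
    per_iteration = []
    for plan in plans:
        keep = list(plan.retained_cases) + control
        per_iteration.append(
            nb_lrt(pb.subset_samples(keep), fdr_threshold=fdr_threshold, **de_kwargs)
        )
    records = classify_robust(full, per_iteration, fdr_threshold=fdr_threshold)
    return full, per_iteration, records


def select_robust_tes(
    full: pd.DataFrame,
    records: pd.DataFrame,
    lfc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Robust DE feature set: highly robust, then |log2FC| filter on full-data estimates.

    The effect-size filter is applied after robustness classification,
    using the full-data log2FC; this ordering is recorded in the output
    metadata of the pipeline.
    """
    robust_ids = set(records.loc[records["highly_robust"], "feature_id"])
    cand = call_robust_candidates(full, fdr_threshold, lfc_threshold)
    out = cand[cand["feature_id"].isin(robust_ids)].copy()
    det = records.set_index("feature_id")["detection_count"]
    out["detection_count"] = det.loc[out["feature_id"]].to_numpy()
    return out
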