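"""Pseudobulk negative-binomial differential expression (AD vs control).

Counts are summed per biological sample within one cell type, so
replication is at the sample level.  Each feature is tested with a
negative-binomial log-linear model

    log mu_s = b0 + b1 * [sample s is AD] + log(library size of s)

and a likelihood-ratio test of ``b1 = 0`` against chi-square(1); the
log2 fold change is ``b1 / ln 2``.  Dispersion is estimated per feature
by profile maximum likelihood and shrunk toward the common (all-feature)
dispersion with a fixed weight.  Benjamini-Hochberg correction is
applied across tested features within the cell type.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PseudobulkMatrix",
    "aggregate_pseudobulk",
    "nb_lrt",
    "call_robust_candidates",
    "fit_nb_glm",
    "bh_adjust",
]

LN2 = math.log(2.0)


@dataclass
class PseudobulkMatrix:
    """Features x samples summed counts for one cell type."""

    counts: np.ndarray  # dense int, features x samples
    feature_ids: pd.Index
    sample_ids: pd.Index
    condition: np.ndarray  # "AD" | "control" per sample
    cell_type: str
    n_cells: np.ndarray = field(default=None)  # cells aggregated per sample
    lib_size: np.ndarray = field(default=None)  # library override (e.g. gene+TE
    # totals when only TE features are carried); defaults to column sums

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.feature_ids = pd.Index(self.feature_ids)
        self.sample_ids = pd.Index(self.sample_ids)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape mismatch")
        if self.n_cells is None:
            self.n_cells = np.zeros(len(self.sample_ids), dtype=int)

    @property
    def library_size(self) -> np.ndarray:
        if self.lib_size is not None:
            return self.lib_size
        return self.counts.sum(axis=0)

    def n_per_condition(self) -> dict[str, int]:
        vals, counts = np.unique(self.condition, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset_samples(self, keep_ids) -> "PseudobulkMatrix":
        keep = self.sample_ids.isin(list(keep_ids))
        return PseudobulkMatrix(
            self.counts[:, keep],
            self.feature_ids,
            self.sample_ids[keep],
            self.condition[keep],
            self.cell_type,
            self.n_cells[keep],
            None if self.lib_size is None else self.lib_size[keep],
        )

    def subset_features(self, mask) -> "PseudobulkMatrix":
        """Restrict to a feature subset, preserving the full library sizes."""
        mask = np.asarray(mask)
        return PseudobulkMatrix(
            self.counts[mask],
            self.feature_ids[mask],
            self.sample_ids,
            self.condition,
            self.cell_type,
            self.n_cells,
            self.library_size.copy(),
        )


def aggregate_pseudobulk(matrix, cell_meta: pd.DataFrame, cell_type: str) -> PseudobulkMatrix:
    """Sum counts per sample over the cells of one cell type.

    Samples contributing zero cells of the type are excluded (and
    reported via a warning).  Total counts are conserved exactly:
    the matrix total equals the sum over contributing cells.
    """
    meta = cell_meta.set_index("cell_id").loc[matrix.cell_ids]
    sel = (meta["cell_type"] == cell_type).to_numpy()
    if not sel.any():
        raise ValueError(f"no cells of type {cell_type!r}")
    sub = matrix.counts[:, sel]
    samples = meta.loc[sel, "sample_id"].to_numpy()
    sample_ids = pd.Index(pd.unique(samples))
    # sample -> condition map (each sample has exactly one condition)
    cond_map = meta.drop_duplicates("sample_id").set_index("sample_id")["condition"]
    indicator = np.zeros((sub.shape[1], len(sample_ids)), dtype=np.int64)
    col = sample_ids.get_indexer(samples)
    indicator[np.arange(sub.shape[1]), col] = 1
    counts = np.asarray(sub @ indicator)
    n_cells = indicator.sum(axis=0)
    all_samples = cell_meta["sample_id"].unique()
    absent = sorted(set(all_samples) - set(sample_ids))
    if absent:
        warnings.warn(
            f"cell type {cell_type!r}: samples without cells excluded: {absent}",
            stacklevel=2,
        )
    pb = PseudobulkMatrix(
        counts,
        matrix.feature_ids,
        sample_ids,
        cond_map.loc[sample_ids].to_numpy(dtype=object),
        cell_type,
        n_cells,
    )
    per_cond = pb.n_per_condition()
    if min(per_cond.get("AD", 0), per_cond.get("control", 0)) < 2:
        warnings.warn(
            f"cell type {cell_type!r}: fewer than 2 samples per condition "
            f"({per_cond}); differential testing will be skipped",
            stacklevel=2,
        )
    return pb


# ---------------------------------------------------------------------------
# NB GLM machinery
# ---------------------------------------------------------------------------

def _nb_loglik(y, mu, alpha):
    """NB2 log-likelihood; Poisson in the alpha -> 0 limit."""
    mu = np.maximum(mu, 1e-12)
    if alpha <= 0:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _solve_wls(X, w, z):
    """Weighted LS solve, written so that negating a covariate column
    negates its coefficient bit-exactly (needed for exact condition-swap
    antisymmetry of the DE test)."""
    p = X.shape[1]
    if p == 1:
        sw = float(np.sum(w))
        if sw <= 0:
            raise np.linalg.LinAlgError("singular")
        return np.array([float(np.sum(w * z)) / sw])
    if p == 2:
        x = X[:, 1]
        a = float(np.sum(w))
        b = float(np.sum(w * x))
        c = float(np.sum(w * x * x))
        u = float(np.sum(w * z))
        v = float(np.sum(w * x * z))
        det = a * c - b * b
        if det <= 0:
            raise np.linalg.LinAlgError("singular")
        return np.array([(c * u - b * v) / det, (a * v - b * u) / det])
    XtW = X.T * w
    return np.linalg.solve(XtW @ X, XtW @ z)


def fit_nb_glm(y, X, offset, alpha, max_iter=100, tol=1e-8):
    """Fit an NB (or Poisson when ``alpha == 0``) log-linear GLM by IRLS.

    Returns ``(beta, mu, loglik, converged)``.  The working response
    uses the canonical log link; iteration stops when the deviance-scale
    change in log-likelihood drops below ``tol`` (absolute).  The first
    column of ``X`` must be the intercept.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    offset = np.asarray(offset, dtype=float)
    beta = np.zeros(X.shape[1])
    beta[0] = float(np.mean(np.log(y + 0.5) - offset))
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)  # IRLS weight for log link, NB2 variance
        z = (eta - offset) + (y - mu) / mu
        try:
            beta_new = _solve_wls(X, w, z)
        except np.linalg.LinAlgError:
            return beta, mu, _nb_loglik(y, mu, alpha), False
        beta = beta_new
        mu = np.exp(np.clip(X @ beta + offset, -30.0, 30.0))
        ll = _nb_loglik(y, mu, alpha)
        if 2.0 * abs(ll - ll_old) < tol:  # deviance-scale absolute change
            converged = True
            break
        ll_old = ll
    return beta, mu, _nb_loglik(y, mu, alpha), converged


def _profile_alpha_ml(y, X, offset, alpha0, n_outer=3):
    """Per-feature dispersion by alternating IRLS fit / 1-D Cox-Reid ML.

    The profile likelihood in alpha is adjusted by the Cox-Reid term
    ``-0.5 log det(X' W X)`` to correct the downward bias from the
    fitted mean parameters (small-sample regime of pseudobulk designs).
    """
    alpha = max(alpha0, 1e-4)
    for _ in range(n_outer):
        _, mu, _, _ = fit_nb_glm(y, X, offset, alpha)

        def neg_apl(log_a, _mu=mu):
            a = math.exp(log_a)
            w = _mu / (1.0 + a * _mu)
            XtWX = (X.T * w) @ X
            sign, logdet = np.linalg.slogdet(XtWX)
            cr = 0.5 * logdet if sign > 0 else 0.0
            return -(_nb_loglik(y, _mu, a) - cr)

        res = minimize_scalar(neg_apl, bounds=(math.log(1e-6), math.log(50.0)),
                              method="bounded", options={"xatol": 1e-6})
        alpha = math.exp(res.x)
    return alpha


def _moment_alpha(y, mu):
    denom = float(np.sum(mu**2))
    if denom <= 0:
        return 0.0
    return max(0.0, float(np.sum((y - mu) ** 2 - mu)) / denom)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def nb_lrt(
    pb: PseudobulkMatrix,
    dispersion: float | None = None,
    shrink_weight: float = 0.3,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 2.0,
    min_nonzero_per_condition: int = 2,
) -> pd.DataFrame:
    """Negative-binomial LRT for every testable feature of a pseudobulk matrix.

    Parameters
    ----------
    dispersion
        Fixed NB dispersion (alpha) shared across features; ``0`` gives a
        Poisson GLM.  ``None`` (default) estimates a per-feature
        dispersion by profile ML, shrunk toward the common dispersion by
        ``shrink_weight``.
    min_nonzero_per_condition
        Testability filter: a feature must have nonzero pseudobulk
        counts in at least this many samples of each condition;
        untestable features get NA p-values and are excluded from the
        BH correction.

    Returns a DataFrame with one row per feature: ``feature_id,
    cell_type, log2fc, p_value, fdr, significant, passes_effect, tested,
    converged``.
    """
    per_cond = pb.n_per_condition()
    if min(per_cond.get("AD", 0), per_cond.get("control", 0)) < 2:
        raise ValueError(
            f"need >= 2 samples per condition to test, got {per_cond}"
        )
    y_all = pb.counts.astype(float)
    lib = pb.library_size.astype(float)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    offset = np.log(lib)
    is_ad = pb.condition == "AD"
    n_s = len(is_ad)
    n_ad = int(is_ad.sum())
    # centered, exactly swap-antisymmetric condition covariate; the
    # condition coefficient (hence log2FC) is unchanged by centering
    x_cond = np.where(is_ad, (n_s - n_ad) / n_s, -(n_ad / n_s))
    X_full = np.column_stack([np.ones(n_s), x_cond])
    X_null = X_full[:, :1]
    is_ad = is_ad.astype(float)

    nz = y_all > 0
    testable = (nz[:, is_ad == 1].sum(axis=1) >= min_nonzero_per_condition) & (
        nz[:, is_ad == 0].sum(axis=1) >= min_nonzero_per_condition
    )

    n_feat = y_all.shape[0]
    log2fc = np.full(n_feat, np.nan)
    pvals = np.full(n_feat, np.nan)
    converged = np.zeros(n_feat, dtype=bool)

    idx = np.flatnonzero(testable)

    # dispersion: per-feature ML shrunk toward the common dispersion
    if dispersion is None:
        alpha_mom = np.empty(len(idx))
        mus = {}
        for j, i in enumerate(idx):
            _, mu, _, _ = fit_nb_glm(y_all[i], X_full, offset, 0.0)
            mus[i] = mu
            alpha_mom[j] = _moment_alpha(y_all[i], mu)
        alpha_common = float(np.mean(alpha_mom)) if len(idx) else 0.0
        alphas = {
            i: (1.0 - shrink_weight) * _profile_alpha_ml(y_all[i], X_full, offset, a0)
            + shrink_weight * alpha_common
            for i, a0 in zip(idx, alpha_mom)
        }
    else:
        alphas = {i: float(dispersion) for i in idx}

    for i in idx:
        y = y_all[i]
        a = alphas[i]
        beta_f, _, ll_full, conv_f = fit_nb_glm(y, X_full, offset, a)
        _, _, ll_null, conv_n = fit_nb_glm(y, X_null, offset, a)
        converged[i] = conv_f and conv_n
        if not converged[i]:
            continue  # reported with NA p, excluded from BH
        stat = max(0.0, 2.0 * (ll_full - ll_null))
        pvals[i] = float(chi2.sf(stat, df=1))
        log2fc[i] = beta_f[1] / LN2

    fdr = np.full(n_feat, np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        fdr[ok] = bh_adjust(pvals[ok])

    out = pd.DataFrame(
        {
            "feature_id": pb.feature_ids,
            "cell_type": pb.cell_type,
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "tested": ok,
            "converged": converged,
        }
    )
    out["significant"] = out["fdr"] < fdr_threshold
    out["passes_effect"] = out["log2fc"].abs() >= lfc_threshold
    n_failed = int(testable.sum() - ok.sum())
    if n_failed:
        warnings.warn(f"{n_failed} feature fits did not converge", stacklevel=2)
    return out


def call_robust_candidates(
    results: pd.DataFrame, fdr_threshold: float = 0.05, lfc_threshold: float = 2.0
) -> pd.DataFrame:
    """Features passing both FDR < threshold and |log2FC| >= threshold."""
    keep = (results["fdr"] < fdr_threshold) & (results["log2fc"].abs() >= lfc_threshold)
    return results[keep.fillna(False)].copy()
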