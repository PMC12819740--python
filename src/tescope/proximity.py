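"""TE-gene proximity at multiple genomic windows, window selection,
over-representation of proximal genes, AD-risk-gene tiers, TE-derived
gene testing and genomic feature assignment.

Distances are interval-gap distances between the TE interval and the
gene-body interval (0 on overlap); strand is ignored.  A TSS-anchored
distance mode is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .ingest import TELocus
from .pseudobulk import bh_adjust

__all__ = [
    "DEFAULT_WINDOWS",
    "find_pairs",
    "WindowMetrics",
    "window_metrics",
    "select_window",
    "ad_gene_proximity",
    "ADGeneProximity",
    "te_derived_gene_test",
    "TEDerivedGeneResult",
    "GenomicFeatureAssigner",
    "hypergeom_enrichment",
]

#: default proximity windows (bp): 50 kb, 250 kb, 500 kb, 1 Mb
DEFAULT_WINDOWS = (50_000, 250_000, 500_000, 1_000_000)


def _interval_gap(a_start, a_end, b_start, b_end):
    """Gap in bp between two half-open intervals; 0 on overlap/adjacency."""
    return np.maximum(0, np.maximum(b_start - a_end, a_start - b_end))


def find_pairs(
    te_loci: list[TELocus],
    gene_models: pd.DataFrame,
    window: int,
    anchor: str = "body",
) -> pd.DataFrame:
    """All TE-gene pairs with interval gap <= ``window``.

    ``gene_models`` needs columns ``gene_id, chrom, start, end`` (and
    ``tss`` when ``anchor="tss"``).  Returns a DataFrame with columns
    ``te_id, gene_id, distance, window, te_family, te_class``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    by_chrom = {c: g for c, g in gene_models.groupby("chrom")}
    for te in te_loci:
        genes = by_chrom.get(te.chrom)
        if genes is None:
            continue
        if anchor == "tss":
            gstart = genes["tss"].to_numpy()
            gend = gstart + 1
        else:
            gstart = genes["start"].to_numpy()
            gend = genes["end"].to_numpy()
        d = _interval_gap(te.start, te.end, gstart, gend)
        hit = d <= window
        for gid, dist in zip(genes.loc[hit, "gene_id"], d[hit]):
            rows.append(
                {
                    "te_id": te.name,
                    "gene_id": gid,
                    "distance": int(dist),
                    "window": int(window),
                    "te_family": te.family,
                    "te_class": te.te_class,
                }
            )
    return pd.DataFrame(
        rows, columns=["te_id", "gene_id", "distance", "window", "te_family", "te_class"]
    )


# ---------------------------------------------------------------------------
# window metrics and the normalized selection matrix
# ---------------------------------------------------------------------------

@dataclass
class WindowMetrics:
    """Per-window specificity / coverage / functional-signal metrics."""

    window: int
    isolation_pct: float  # % of TEs with zero genes in the window
    median_genes_per_te: float
    n_significant_gene_sets: int


def hypergeom_enrichment(
    query: set[str], gene_sets: dict[str, list[str]], background: set[str]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each set.

    Population = ``background``; draws = ``query & background``.  BH
    correction across sets.
    """
    background = set(background)
    query = set(query) & background
    m = len(background)
    n_draw = len(query)
    rows = []
    for name, members in gene_sets.items():
        in_bg = set(members) & background
        k = len(query & in_bg)
        p = stats.hypergeom.sf(k - 1, m, len(in_bg), n_draw) if in_bg else 1.0
        rows.append({"gene_set": name, "set_size": len(in_bg), "overlap": k, "p_value": p})
    out = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p_value"])
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out


def window_metrics(
    pairs_by_window: dict[int, pd.DataFrame],
    te_ids: list[str],
    gene_sets: dict[str, list[str]],
    background: set[str],
    alpha: float = 0.05,
) -> list[WindowMetrics]:
    """Isolation %, median genes/TE and significant gene sets per window.

    The median counts every TE, including isolated ones (zero genes);
    gene-set over-representation uses the union of proximal genes at
    that window against ``background``.
    """
    if not gene_sets:
        warnings.warn("empty gene-set collection; functional signal is 0", stacklevel=2)
    out = []
    n_te = len(te_ids)
    for window in sorted(pairs_by_window):
        pairs = pairs_by_window[window]
        per_te = pairs.groupby("te_id")["gene_id"].nunique()
        counts = pd.Series(0, index=pd.Index(te_ids), dtype=float)
        counts[per_te.index] = per_te
        isolation = 100.0 * float((counts == 0).sum()) / n_te if n_te else np.nan
        proximal = set(pairs["gene_id"])
        if gene_sets:
            enr = hypergeom_enrichment(proximal, gene_sets, background)
            n_sig = int((enr["q_value"] < alpha).sum())
        else:
            n_sig = 0
        out.append(
            WindowMetrics(
                window=int(window),
                isolation_pct=isolation,
                median_genes_per_te=float(counts.median()),
                n_significant_gene_sets=n_sig,
            )
        )
    return out


def _minmax(values: np.ndarray) -> np.ndarray:
    """Min-max to [0,1]; a constant metric maps to 0.5 everywhere (neutral)."""
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi - lo < 1e-12:
        return np.full(len(values), 0.5)
    return (values - lo) / (hi - lo)


def select_window(
    metrics: list[WindowMetrics], weights=(1.0, 1.0, 1.0)
) -> tuple[int, pd.DataFrame]:
    """Pick the window maximizing the normalized selection matrix composite.

    Per window the composite is the weighted mean of three min-max
    normalized terms: specificity is rewarded (1 - minmax(isolation)),
    functional signal is rewarded (minmax(significant sets)), and
    excessive coverage is penalized (1 - minmax(median genes/TE)).
    Ties go to the smaller window.
    """
    if len(metrics) < 2:
        raise ValueError("need >= 2 windows to select")
    metrics = sorted(metrics, key=lambda m: m.window)
    iso = np.array([m.isolation_pct for m in metrics], dtype=float)
    sig = np.array([m.n_significant_gene_sets for m in metrics], dtype=float)
    med = np.array([m.median_genes_per_te for m in metrics], dtype=float)
    terms = np.column_stack([1.0 - _minmax(iso), _minmax(sig), 1.0 - _minmax(med)])
    w = np.asarray(weights, dtype=float)
    composite = terms @ w / w.sum()
    table = pd.DataFrame(
        {
            "window": [m.window for m in metrics],
            "isolation_pct": iso,
            "n_significant_gene_sets": sig.astype(int),
            "median_genes_per_te": med,
            "specificity_score": terms[:, 0],
            "functional_score": terms[:, 1],
            "coverage_score": terms[:, 2],
            "composite": composite,
        }
    )
    best = int(np.argmax(composite))  # argmax takes the first (smallest window) on ties
    return int(metrics[best].window), table


# ---------------------------------------------------------------------------
# AD risk genes and TE-derived genes
# ---------------------------------------------------------------------------

@dataclass
class ADGeneProximity:
    """AD risk genes near DE TEs, by cumulative window tier."""

    tier_counts: pd.Series  # window -> # of AD genes first appearing at that window
    family_counts: pd.Series  # TE family -> # of AD-gene pairs (at tally window)
    top_genes: pd.DataFrame  # gene_id, n_tes (distinct proximal TEs), ranked
    tally_window: int


def ad_gene_proximity(
    pairs_by_window: dict[int, pd.DataFrame],
    ad_genes: list[str],
    tally_window: int | None = None,
) -> ADGeneProximity:
    """Cumulative-tier counts of AD risk genes plus family/per-gene tallies.

    A gene is counted in the tier of the smallest window where it first
    pairs with any TE (it is not re-counted at larger windows).  Family
    counts and the per-gene distinct-TE ranking are computed at
    ``tally_window`` (default: the largest window).
    """
    if not ad_genes:
        raise ValueError("ad_genes is empty")
    ad = set(ad_genes)
    windows = sorted(pairs_by_window)
    seen: set[str] = set()
    tiers = {}
    for w in windows:
        genes_here = set(pairs_by_window[w]["gene_id"]) & ad
        tiers[w] = len(genes_here - seen)
        seen |= genes_here
    if tally_window is None:
        tally_window = windows[-1]
    tally = pairs_by_window[tally_window]
    ad_pairs = tally[tally["gene_id"].isin(ad)]
    family_counts = ad_pairs["te_family"].value_counts()
    top = (
        ad_pairs.groupby("gene_id")["te_id"]
        .nunique()
        .sort_values(ascending=False)
        .rename("n_tes")
        .reset_index()
    )
    return ADGeneProximity(
        tier_counts=pd.Series(tiers, name="n_new_ad_genes"),
        family_counts=family_counts,
        top_genes=top,
        tally_window=int(tally_window),
    )


@dataclass
class TEDerivedGeneResult:
    """Fisher test of TE-derived-gene content among proximal genes."""

    n_proximal: int
    n_te_derived: int
    proportion_pct: float  # to two decimals
    odds_ratio: float
    p_value: float
    direction: str  # depleted | enriched


def te_derived_gene_test(
    proximal_genes,
    catalog,
    genome_rate: float = 0.03,
    genome_size: int = 20_000,
) -> TEDerivedGeneResult:
    """Compare the TE-derived fraction of proximal genes to the genome rate.

    Two-sided Fisher's exact test on the 2x2 table
    ``[[k, n-k], [expected TE-derived in genome, remainder]]`` with the
    genome-wide expectation ``genome_rate * genome_size``.
    """
    catalog = set(catalog)
    if not catalog:
        raise ValueError("TE-derived gene catalog is empty")
    proximal = set(proximal_genes)
    n = len(proximal)
    if n == 0:
        raise ValueError("no proximal genes (undefined proportion)")
    k = len(proximal & catalog)
    exp_td = int(round(genome_rate * genome_size))
    table = [[k, n - k], [exp_td, genome_size - exp_td]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    pct = round(100.0 * k / n, 2)
    return TEDerivedGeneResult(
        n_proximal=n,
        n_te_derived=k,
        proportion_pct=pct,
        odds_ratio=float(odds),
        p_value=float(p),
        direction="depleted" if pct < 100.0 * genome_rate else "enriched",
    )


# ---------------------------------------------------------------------------
# genomic feature assignment
# ---------------------------------------------------------------------------

FEATURE_PRECEDENCE = ("promoter", "enhancer", "exon", "intron", "intergenic")


class GenomicFeatureAssigner:
    """Classify TE midpoints into promoter/enhancer/exon/intron/intergenic.

    Promoters span TSS -2,000/+500 bp (strand-aware, both spans
    configurable); precedence on overlap is promoter > enhancer > exon
    > intron > intergenic.  Assignment is total and deterministic.
    """

    def __init__(
        self,
        gene_models: pd.DataFrame,
        exons: pd.DataFrame,
        enhancers: pd.DataFrame,
        promoter_upstream: int = 2_000,
        promoter_downstream: int = 500,
    ):
        self._trees: dict[str, dict[str, IntervalTree]] = {}

        def add(category: str, chrom: str, start: int, end: int):
            if end <= start:
                return
            self._trees.setdefault(chrom, {}).setdefault(category, IntervalTree()).addi(
                start, end
            )

        for g in gene_models.itertuples():
            if g.strand == "-":
                p_start, p_end = g.tss - promoter_downstream, g.tss + promoter_upstream
            else:
                p_start, p_end = g.tss - promoter_upstream, g.tss + promoter_downstream
            add("promoter", g.chrom, max(0, p_start), p_end)
            add("gene_body", g.chrom, g.start, g.end)
        for e in exons.itertuples():
            add("exon", e.chrom, e.start, e.end)
        for e in enhancers.itertuples():
            add("enhancer", e.chrom, e.start, e.end)

    def assign(self, te: TELocus) -> str:
        mid = te.midpoint
        trees = self._trees.get(te.chrom, {})

        def hit(category: str) -> bool:
            tree = trees.get(category)
            return bool(tree is not None and tree.overlap(mid, mid + 1))

        if hit("promoter"):
            return "promoter"
        if hit("enhancer"):
            return "enhancer"
        if hit("exon"):
            return "exon"
        if hit("gene_body"):
            return "intron"
        return "intergenic"

    def assign_all(self, te_loci: list[TELocus]) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "te_id": [t.name for t in te_loci],
                "feature": [self.assign(t) for t in te_loci],
            }
        )
        return out
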