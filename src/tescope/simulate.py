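"""Synthetic snRNA-seq + snATAC-seq inputs with planted TE dysregulation.

Generates, from a single seed, every input the pipeline consumes: a
sparse gene+TE count matrix with locus-encoded TE feature names, cell
metadata (sample, AD/control condition, cell type), interval tracks
(TE BED, gene models with TSS and exons, enhancers, ATAC peaks), an
ATAC accessibility matrix, and the flat gene lists/collections.

The statistical structure mirrors what the analysis assumes: counts are
negative binomial around per-cell-type baseline means (log-normal
feature means, shared dispersion), TE features contribute a configured
fraction of each cell's transcripts (default 12%, the 10-15% regime of
cortical snRNA-seq), the TE family mix follows the genomic baseline
(45% Alu, 17% L1, 8% L2, 5% MIR, 8% ERV, 3% DNA, 14% other), and
planted case-condition effects multiply the targeted TE's mean in the
targeted cell type by 2**log2FC.  Planted regulatory TEs get an
overlapping ATAC peak with elevated signal and a coupled (same
direction, attenuated) effect on their nearest gene, giving the scoring
stage positive controls.

Not simulated: reads/BAMs, UMI collapsing, ambient RNA, doublets, batch
effects.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy.io import mmread, mmwrite

from .ingest import ExpressionMatrix, TELocus, parse_te_name

__all__ = [
    "SimulationConfig",
    "PlantedEffect",
    "SyntheticBundle",
    "generate_dataset",
    "plant_ad_scenario",
    "write_bundle",
    "read_bundle",
    "DEFAULT_FAMILY_MIX",
    "DEFAULT_CELL_TYPES",
]

DEFAULT_FAMILY_MIX = {
    "Alu": 0.45,
    "L1": 0.17,
    "L2": 0.08,
    "MIR": 0.05,
    "ERV": 0.08,
    "DNA": 0.03,
    "other": 0.14,
}

#: subfamily pools per family (RepeatMasker-style names)
SUBFAMILIES = {
    "Alu": ["AluYa5", "AluYb8", "AluY", "AluSx", "AluSz", "AluSg", "AluJb", "AluJo"],
    "L1": ["L1HS", "L1PA3", "L1PA4", "L1PA7", "L1PA11", "L1PA13", "L1PB1", "L1M5", "L1MA4"],
    "L2": ["L2a", "L2b", "L2c"],
    "MIR": ["MIR", "MIRb", "MIRc"],
    "ERV": ["HERVK-int", "LTR7", "MLT1A", "THE1B"],
    "DNA": ["MER20", "Charlie1a", "Tigger1"],
    "other": ["SVA_A", "SVA_B", "UCON2"],
}

FAMILY_CLASS = {
    "Alu": "SINE",
    "MIR": "SINE",
    "L1": "LINE",
    "L2": "LINE",
    "ERV": "LTR",
    "DNA": "DNA",
    "other": "other",
}

#: cell types with per-sample cell-count ranges (scaled-down desk defaults)
DEFAULT_CELL_TYPES = (
    ("ASC", (15, 30)),
    ("EX", (40, 70)),
    ("INH", (10, 25)),
    ("MG", (8, 20)),
    ("ODC", (50, 90)),
    ("OPC", (8, 18)),
    ("PER.END", (3, 8)),
)

DEFAULT_GENOME = (("chr1", 10_000_000), ("chr2", 10_000_000),
                  ("chr3", 10_000_000), ("chr4", 10_000_000))


@dataclass(frozen=True)
class PlantedEffect:
    """A case-condition multiplicative effect on one TE in one cell type."""

    te_index: int
    cell_type: str
    log2fc: float


@dataclass
class SimulationConfig:
    seed: int = 0
    n_samples_case: int = 11
    n_samples_control: int = 7
    cell_types: tuple = DEFAULT_CELL_TYPES
    n_genes: int = 600
    n_te_loci: int = 400
    family_mix: dict = field(default_factory=lambda: dict(DEFAULT_FAMILY_MIX))
    target_te_fraction: float = 0.12
    planted_effects: tuple = ()
    nb_dispersion: float = 0.15
    genome: tuple = DEFAULT_GENOME
    # secondary knobs
    mean_log_sigma: float = 1.0
    cell_scale_sigma: float = 0.3
    celltype_factor_sigma: float = 0.4
    te_length_range: tuple = (150, 6_000)
    gene_length_range: tuple = (2_000, 100_000)
    n_atac_peaks: int = 300
    planted_peak_fraction: float = 0.6
    n_ad_genes: int = 40
    te_derived_fraction: float = 0.03
    n_gene_sets: int = 20
    n_enriched_sets: int = 3
    gene_coupling_scale: float = 0.5
    coupling_window: int = 250_000

    def validate(self) -> None:
        if abs(sum(self.family_mix.values()) - 1.0) > 1e-9:
            raise ValueError("family_mix must sum to 1")
        if not 0.0 < self.target_te_fraction < 0.5:
            raise ValueError("target_te_fraction must be in (0, 0.5)")
        for name, n in [("n_genes", self.n_genes), ("n_te_loci", self.n_te_loci),
                        ("n_samples_case", self.n_samples_case),
                        ("n_samples_control", self.n_samples_control)]:
            if n <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        min_chrom = min(length for _, length in self.genome)
        if self.te_length_range[1] >= min_chrom or self.gene_length_range[1] >= min_chrom:
            raise ValueError(
                "impossible geometry: feature length range exceeds chromosome length"
            )
        ct_names = {name for name, _ in self.cell_types}
        for eff in self.planted_effects:
            if not 0 <= eff.te_index < self.n_te_loci:
                raise ValueError(f"planted te_index {eff.te_index} out of range")
            if abs(eff.log2fc) > 10:
                raise ValueError(f"|log2fc| > 10 for planted effect {eff}")
            if eff.cell_type not in ct_names:
                raise ValueError(f"planted effect on unknown cell type {eff.cell_type!r}")


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, generated from one seed."""

    config: SimulationConfig
    matrix: ExpressionMatrix
    cell_meta: pd.DataFrame
    te_loci: list
    gene_models: pd.DataFrame
    exons: pd.DataFrame
    enhancers: pd.DataFrame
    atac_peaks: pd.DataFrame
    atac_matrix: pd.DataFrame
    ad_genes: list
    te_derived_genes: list
    gene_sets: dict
    genome: dict
    planted_effects: tuple = ()
    planted_pairs: tuple = ()  # (te_id, gene_id) coupled positives
    planted_peak_te_ids: tuple = ()


def _random_intervals(rng, genome: dict, n: int, length_range) -> pd.DataFrame:
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    which = rng.choice(len(chroms), size=n, p=probs)
    sizes = rng.integers(length_range[0], length_range[1] + 1, size=n)
    starts = np.array(
        [rng.integers(0, genome[chroms[w]] - s) for w, s in zip(which, sizes)]
    )
    return pd.DataFrame(
        {
            "chrom": [chroms[w] for w in which],
            "start": starts,
            "end": starts + sizes,
        }
    )


def _nearest_gene(te: TELocus, gene_models: pd.DataFrame, window: int):
    genes = gene_models[gene_models["chrom"] == te.chrom]
    if genes.empty:
        return None
    gap = np.maximum(
        0, np.maximum(genes["start"].to_numpy() - te.end, te.start - genes["end"].to_numpy())
    )
    i = int(np.argmin(gap))
    if gap[i] > window:
        return None
    return genes.iloc[i]["gene_id"]


def generate_dataset(config: SimulationConfig) -> SyntheticBundle:
    """Generate a complete synthetic bundle; bit-identical under one seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = dict(config.genome)

    # --- TE loci ----------------------------------------------------------
    fams = list(config.family_mix)
    fam_draw = rng.choice(len(fams), size=config.n_te_loci,
                          p=np.array([config.family_mix[f] for f in fams]))
    coords = _random_intervals(rng, genome, config.n_te_loci, config.te_length_range)
    te_loci: list[TELocus] = []
    seen_names: set[str] = set()
    for i in range(config.n_te_loci):
        fam = fams[fam_draw[i]]
        sub = SUBFAMILIES[fam][rng.integers(0, len(SUBFAMILIES[fam]))]
        strand = "+" if rng.random() < 0.5 else "-"
        row = coords.iloc[i]
        start, end = int(row.start), int(row.end)
        while True:  # locus names double as feature ids and must be unique
            locus = TELocus(row.chrom, start, end, sub, fam, FAMILY_CLASS[fam], strand)
            if locus.name not in seen_names:
                break
            start += 1
            end += 1
        seen_names.add(locus.name)
        te_loci.append(locus)

    # --- gene models ------------------------------------------------------
    gene_ids = [f"GENE{i:04d}" for i in range(config.n_genes)]
    gcoords = _random_intervals(rng, genome, config.n_genes, config.gene_length_range)
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    gene_models = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": gcoords["chrom"],
            "start": gcoords["start"].astype(int),
            "end": gcoords["end"].astype(int),
            "strand": strands,
        }
    )
    gene_models["tss"] = np.where(
        gene_models["strand"] == "+", gene_models["start"], gene_models["end"]
    ).astype(int)

    exon_rows = []
    for g in gene_models.itertuples():
        n_ex = int(rng.integers(2, 9))
        length = g.end - g.start
        for _ in range(n_ex):
            size = int(rng.integers(100, 501))
            if size >= length:
                size = max(1, length - 1)
            off = int(rng.integers(0, length - size))
            exon_rows.append(
                {"chrom": g.chrom, "start": g.start + off, "end": g.start + off + size,
                 "name": g.gene_id}
            )
    exons = pd.DataFrame(exon_rows)

    enhancers = _random_intervals(rng, genome, config.n_genes // 3, (200, 2_000))
    enhancers["name"] = [f"ENH{i:04d}" for i in range(len(enhancers))]

    # --- expression means -------------------------------------------------
    ct_names = [name for name, _ in config.cell_types]
    n_feat = config.n_genes + config.n_te_loci
    base = rng.lognormal(0.7, config.mean_log_sigma, size=n_feat)
    # TE features scaled so dataset-wide mean TE fraction hits the target
    gene_sum = base[: config.n_genes].sum()
    te_sum = base[config.n_genes:].sum()
    f = config.target_te_fraction
    base[config.n_genes:] *= (f / (1.0 - f)) * gene_sum / te_sum
    ct_factor = rng.lognormal(0.0, config.celltype_factor_sigma, size=(n_feat, len(ct_names)))
    mean_matrix = base[:, None] * ct_factor  # features x cell types

    # --- planted effects (TE + coupled nearest-gene) ----------------------
    feature_ids = gene_ids + [t.name for t in te_loci]
    effect_mult = {}  # (feature_row, ct_index) -> multiplier on AD means
    planted_pairs = []
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    for eff in config.planted_effects:
        ct_i = ct_names.index(eff.cell_type)
        row = config.n_genes + eff.te_index
        effect_mult[(row, ct_i)] = effect_mult.get((row, ct_i), 1.0) * 2.0**eff.log2fc
        if config.gene_coupling_scale > 0:
            gid = _nearest_gene(te_loci[eff.te_index], gene_models, config.coupling_window)
            if gid is not None:
                gmult = 2.0 ** (eff.log2fc * config.gene_coupling_scale)
                key = (gene_row[gid], ct_i)
                effect_mult[key] = effect_mult.get(key, 1.0) * gmult
                planted_pairs.append((te_loci[eff.te_index].name, gid))

    # --- cells and counts -------------------------------------------------
    sample_ids = [f"S{i + 1:02d}" for i in range(config.n_samples_case + config.n_samples_control)]
    conditions = ["AD"] * config.n_samples_case + ["control"] * config.n_samples_control
    meta_rows = []
    cell_counter = 0
    for sid, cond in zip(sample_ids, conditions):
        for ct, (lo, hi) in config.cell_types:
            n_cells = int(rng.integers(lo, hi + 1))
            for _ in range(n_cells):
                meta_rows.append(
                    {"cell_id": f"CELL{cell_counter:06d}", "sample_id": sid,
                     "condition": cond, "cell_type": ct}
                )
                cell_counter += 1
    cell_meta = pd.DataFrame(meta_rows)

    counts = np.zeros((n_feat, len(cell_meta)), dtype=np.int64)
    scale = rng.lognormal(0.0, config.cell_scale_sigma, size=len(cell_meta))
    alpha = config.nb_dispersion
    ct_index = {c: i for i, c in enumerate(ct_names)}
    groups = cell_meta.groupby(["cell_type", "condition"], sort=True).indices
    for (ct, cond), cells in sorted(groups.items()):
        mu_vec = mean_matrix[:, ct_index[ct]].copy()
        if cond == "AD":
            for (row, ci), mult in sorted(effect_mult.items()):
                if ci == ct_index[ct]:
                    mu_vec[row] *= mult
        mu = mu_vec[:, None] * scale[cells][None, :]
        if alpha > 0:
            r = 1.0 / alpha
            counts[:, cells] = rng.negative_binomial(r, r / (r + mu))
        else:
            counts[:, cells] = rng.poisson(mu)
    matrix = ExpressionMatrix.from_counts(
        sp.csr_matrix(counts), feature_ids, cell_meta["cell_id"]
    )

    # --- ATAC peaks and accessibility ------------------------------------
    peaks = _random_intervals(rng, genome, config.n_atac_peaks, (300, 1_500))
    planted_rows = sorted({config.n_genes + e.te_index for e in config.planted_effects})
    planted_peak_te_ids = []
    extra = []
    for row in planted_rows:
        if rng.random() >= config.planted_peak_fraction:
            continue
        te = te_loci[row - config.n_genes]
        mid = te.midpoint
        start = max(0, mid - int(rng.integers(100, 500)))
        end = min(genome[te.chrom], mid + int(rng.integers(100, 500)))
        extra.append({"chrom": te.chrom, "start": start, "end": end})
        planted_peak_te_ids.append(te.name)
    if extra:
        peaks = pd.concat([peaks, pd.DataFrame(extra)], ignore_index=True)
    peaks = peaks.reset_index(drop=True)
    peaks["name"] = [f"PEAK{i:05d}" for i in range(len(peaks))]
    acc = rng.gamma(2.0, 1.0, size=(len(peaks), len(ct_names)))
    if extra:  # planted peaks carry elevated accessibility
        acc[config.n_atac_peaks:, :] += rng.gamma(20.0, 1.0,
                                                  size=(len(extra), len(ct_names)))
    atac_matrix = pd.DataFrame(acc, columns=ct_names, index=peaks["name"])

    # --- flat lists and gene sets -----------------------------------------
    coupled_genes = [g for _, g in planted_pairs]
    pool = [g for g in gene_ids if g not in set(coupled_genes)]
    n_coupled = min(len(set(coupled_genes)), config.n_ad_genes // 2)
    ad_genes = sorted(set(coupled_genes))[:n_coupled] + list(
        rng.choice(pool, size=config.n_ad_genes - n_coupled, replace=False)
    )
    te_derived = sorted(
        rng.choice(gene_ids, size=max(1, int(round(config.te_derived_fraction * config.n_genes))),
                   replace=False)
    )
    gene_sets = {}
    for i in range(config.n_gene_sets):
        size = int(rng.integers(10, 41))
        gene_sets[f"SET{i:03d}"] = sorted(rng.choice(gene_ids, size=size, replace=False))
    near_planted = sorted(
        {
            g.gene_id
            for row in planted_rows
            for g in gene_models.itertuples()
            if g.chrom == te_loci[row - config.n_genes].chrom
            and max(0, max(g.start - te_loci[row - config.n_genes].end,
                           te_loci[row - config.n_genes].start - g.end))
            <= config.coupling_window
        }
    )
    for i in range(config.n_enriched_sets):
        if not near_planted:
            break
        size = min(len(near_planted), int(rng.integers(10, 31)))
        gene_sets[f"ENRICHED{i:02d}"] = sorted(
            rng.choice(near_planted, size=size, replace=False)
        )

    te_bed = pd.DataFrame(
        {
            "chrom": [t.chrom for t in te_loci],
            "start": [t.start for t in te_loci],
            "end": [t.end for t in te_loci],
            "name": [t.name for t in te_loci],
            "score": 0,
            "strand": [t.strand for t in te_loci],
        }
    )

    return SyntheticBundle(
        config=config,
        matrix=matrix,
        cell_meta=cell_meta,
        te_loci=te_loci,
        gene_models=gene_models,
        exons=exons,
        enhancers=enhancers,
        atac_peaks=peaks,
        atac_matrix=atac_matrix,
        ad_genes=list(ad_genes),
        te_derived_genes=list(te_derived),
        gene_sets=gene_sets,
        genome=genome,
        planted_effects=tuple(config.planted_effects),
        planted_pairs=tuple(planted_pairs),
        planted_peak_te_ids=tuple(planted_peak_te_ids),
    )


def plant_ad_scenario(
    config: SimulationConfig,
    n_effects: int,
    population_a: str = "EX",
    population_b: str = "ODC",
) -> SimulationConfig:
    """Plant effects reproducing the AD direction structure at reduced scale.

    ~63% of effects land in ``population_a`` (>= 90% upregulated, the
    excitatory-neuron-like pattern), ~32% in ``population_b`` (~65%
    upregulated, the oligodendrocyte-like balanced pattern) and the
    remainder are scattered over the other cell types (~70% up).
    Direction counts are deterministic quotas, magnitudes are drawn
    uniformly from the strong-effect regime |log2FC| in [2.0, 6.2];
    the assignment is a pure function of ``config.seed``.
    """
    if n_effects == 0:
        return config
    ct_names = [name for name, _ in config.cell_types]
    for pop in (population_a, population_b):
        if pop not in ct_names:
            raise ValueError(f"cell type {pop!r} not in config.cell_types")
    if n_effects > config.n_te_loci:
        raise ValueError("more effects than TE loci")
    rng = np.random.default_rng(config.seed + 1_000_003)
    n_a = round(0.63 * n_effects)
    n_b = round(0.32 * n_effects)
    n_rest = n_effects - n_a - n_b
    others = [c for c in ct_names if c not in (population_a, population_b)] or [population_a]
    te_idx = rng.choice(config.n_te_loci, size=n_effects, replace=False)
    effects = []
    blocks = [
        (population_a, n_a, 0.95),
        (population_b, n_b, 0.65),
        (None, n_rest, 0.70),
    ]
    pos = 0
    for pop, n_block, up_frac in blocks:
        n_up = math.ceil(up_frac * n_block) if pop == population_a else round(up_frac * n_block)
        signs = np.array([1.0] * n_up + [-1.0] * (n_block - n_up))
        rng.shuffle(signs)
        for s in signs:
            ct = pop if pop is not None else others[int(rng.integers(0, len(others)))]
            mag = rng.uniform(2.0, 6.2)
            effects.append(PlantedEffect(int(te_idx[pos]), ct, float(s * mag)))
            pos += 1
    return replace(config, planted_effects=tuple(effects))


# ---------------------------------------------------------------------------
# bundle writers / readers (MTX + TSV + BED6 + JSON + YAML)
# ---------------------------------------------------------------------------

def _write_bed(df: pd.DataFrame, path: Path, strand_col: bool = False) -> None:
    cols = ["chrom", "start", "end"]
    out = df.copy()
    if "name" not in out:
        out["name"] = [f"iv{i}" for i in range(len(out))]
    out["score"] = out.get("score", 0)
    if strand_col and "strand" not in out:
        out["strand"] = "."
    cols += ["name", "score"] + (["strand"] if strand_col or "strand" in out else [])
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bundle(bundle: SyntheticBundle, outdir) -> Path:
    """Serialize a bundle to flat files (MTX/TSV/BED6/JSON/YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(outdir / "matrix.mtx", bundle.matrix.counts.astype(np.int64))
    pd.DataFrame(
        {"feature_id": bundle.matrix.feature_ids, "kind": bundle.matrix.kind}
    ).to_csv(outdir / "features.tsv", sep="\t", index=False)
    pd.Series(bundle.matrix.cell_ids).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    bundle.cell_meta.to_csv(outdir / "cell_metadata.tsv", sep="\t", index=False)
    te_bed = pd.DataFrame(
        {
            "chrom": [t.chrom for t in bundle.te_loci],
            "start": [t.start for t in bundle.te_loci],
            "end": [t.end for t in bundle.te_loci],
            "name": [t.name for t in bundle.te_loci],
            "score": 0,
            "strand": [t.strand for t in bundle.te_loci],
        }
    )
    te_bed.to_csv(outdir / "te_loci.bed", sep="\t", header=False, index=False)
    bundle.gene_models.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    _write_bed(bundle.exons, outdir / "exons.bed")
    _write_bed(bundle.enhancers, outdir / "enhancers.bed")
    _write_bed(bundle.atac_peaks, outdir / "atac_peaks.bed")
    bundle.atac_matrix.to_csv(outdir / "atac_matrix.tsv", sep="\t",
                              index_label="peak", float_format="%.6g")
    (outdir / "ad_genes.txt").write_text("\n".join(bundle.ad_genes) + "\n")
    (outdir / "te_derived_genes.txt").write_text("\n".join(bundle.te_derived_genes) + "\n")
    (outdir / "gene_sets.json").write_text(json.dumps(bundle.gene_sets, indent=1, sort_keys=True))
    (outdir / "genome.tsv").write_text(
        "".join(f"{c}\t{l}\n" for c, l in bundle.genome.items())
    )
    cfg = asdict(bundle.config)
    cfg["planted_effects"] = [asdict(e) for e in bundle.config.planted_effects]
    cfg["cell_types"] = [[n, list(r)] for n, r in bundle.config.cell_types]
    cfg["genome"] = [[c, l] for c, l in bundle.config.genome]
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    (outdir / "planted.json").write_text(
        json.dumps(
            {
                "effects": [asdict(e) for e in bundle.planted_effects],
                "pairs": [list(p) for p in bundle.planted_pairs],
                "peak_te_ids": list(bundle.planted_peak_te_ids),
            },
            indent=1,
        )
    )
    return outdir


def load_config(path) -> SimulationConfig:
    """Read a SimulationConfig back from its YAML form."""
    raw = yaml.safe_load(Path(path).read_text())
    raw["planted_effects"] = tuple(PlantedEffect(**e) for e in raw.get("planted_effects", []))
    raw["cell_types"] = tuple((n, tuple(r)) for n, r in raw["cell_types"])
    raw["genome"] = tuple((c, l) for c, l in raw["genome"])
    for key in ("te_length_range", "gene_length_range"):  # YAML turns tuples into lists
        raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)


def read_bundle(path) -> SyntheticBundle:
    """Read a serialized bundle directory back into memory."""
    path = Path(path)
    config = load_config(path / "config.yaml")
    counts = sp.csr_matrix(mmread(path / "matrix.mtx"))
    features = pd.read_csv(path / "features.tsv", sep="\t")
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
    matrix = ExpressionMatrix(
        counts, pd.Index(features["feature_id"]),
        features["kind"].to_numpy(dtype=object), pd.Index(barcodes),
    )
    cell_meta = pd.read_csv(path / "cell_metadata.tsv", sep="\t")
    te_bed = pd.read_csv(path / "te_loci.bed", sep="\t", header=None,
                         names=["chrom", "start", "end", "name", "score", "strand"])
    te_loci = [parse_te_name(n) for n in te_bed["name"]]
    gene_models = pd.read_csv(path / "genes.tsv", sep="\t")
    bed_cols = ["chrom", "start", "end", "name", "score"]
    exons = pd.read_csv(path / "exons.bed", sep="\t", header=None, names=bed_cols)
    enhancers = pd.read_csv(path / "enhancers.bed", sep="\t", header=None, names=bed_cols)
    peaks = pd.read_csv(path / "atac_peaks.bed", sep="\t", header=None, names=bed_cols)
    atac_matrix = pd.read_csv(path / "atac_matrix.tsv", sep="\t", index_col="peak")
    genome = {}
    for line in (path / "genome.tsv").read_text().splitlines():
        c, l = line.split("\t")
        genome[c] = int(l)
    planted = json.loads((path / "planted.json").read_text())
    with open(path / "ad_genes.txt") as fh:
        ad_genes = [x.strip() for x in fh if x.strip()]
    with open(path / "te_derived_genes.txt") as fh:
        te_derived = [x.strip() for x in fh if x.strip()]
    gene_sets = json.loads((path / "gene_sets.json").read_text())
    return SyntheticBundle(
        config=config,
        matrix=matrix,
        cell_meta=cell_meta,
        te_loci=te_loci,
        gene_models=gene_models,
        exons=exons,
        enhancers=enhancers,
        atac_peaks=peaks,
        atac_matrix=atac_matrix,
        ad_genes=ad_genes,
        te_derived_genes=te_derived,
        gene_sets=gene_sets,
        genome=genome,
        planted_effects=tuple(PlantedEffect(**e) for e in planted["effects"]),
        planted_pairs=tuple(tuple(p) for p in planted["pairs"]),
        planted_peak_te_ids=tuple(planted["peak_te_ids"]),
    )
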