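"""End-to-end orchestration: simulate -> ingest -> DE -> robustness ->
annotation -> proximity -> ATAC scoring, driven by one YAML config and
one root seed.

Every stage reads its inputs from the run directory and writes TSV/JSON
outputs there, so stages are independently re-runnable; a run manifest
records the config hash, seeds, thresholds and per-stage row counts.
Output tables are pure functions of config + seed (byte-identical on
re-run); only the manifest carries timestamps.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import atac as atac_mod
from . import proximity as prox
from .ingest import filter_low_expression, parse_te_name, te_fraction_per_cell
from .pseudobulk import aggregate_pseudobulk
from .robustness import run_robustness, select_robust_tes
from .simulate import (
    PlantedEffect,
    SimulationConfig,
    generate_dataset,
    plant_ad_scenario,
    read_bundle,
    write_bundle,
)

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "load_pipeline_config", "STAGES"]

STAGES = ("simulate", "de", "robust", "annotate", "proximity", "atac")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"n_effects": 40, "config": {}},
    "input_dir": None,  # use an existing bundle instead of simulating
    "min_cells": 10,
    "de": {"fdr": 0.05, "lfc": 2.0, "shrink_weight": 0.3},
    "robustness": {"k": 10},
    "windows": [50_000, 250_000, 500_000, 1_000_000],
    "selected_window": "auto",
    "promoter": {"upstream": 2_000, "downstream": 500},
    "atac": {"window": 250_000,
             "weights": {"distance": 0.3, "accessibility": 0.3,
                         "effect": 0.2, "correlation": 0.2},
             "corr_threshold": 0.3},
    "te_derived": {"genome_rate": 0.03, "genome_size": 20_000},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_pipeline_config(path=None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ValueError("pipeline config must be a YAML mapping")
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


class Pipeline:
    """Stage-wise runner over a run directory."""

    def __init__(self, config: dict, outdir):
        self.cfg = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(config["seed"])
        self.manifest: dict = {
            "config_hash": _config_hash(config),
            "seed": self.seed,
            "thresholds": {"fdr": config["de"]["fdr"], "lfc": config["de"]["lfc"]},
            "stages": {},
        }
        self._bundle = None

    # -- helpers ----------------------------------------------------------
    def _record(self, stage: str, **info):
        self.manifest["stages"][stage] = {**info, "timestamp": time.time()}

    @property
    def bundle(self):
        if self._bundle is None:
            src = self.cfg.get("input_dir") or self.outdir / "bundle"
            self._bundle = read_bundle(src)
        return self._bundle

    def _filtered_matrix(self):
        return filter_low_expression(self.bundle.matrix, self.cfg["min_cells"])

    # -- stages -----------------------------------------------------------
    def stage_simulate(self):
        sim_cfg = self.cfg["simulate"]
        overrides = dict(sim_cfg.get("config") or {})
        if "planted_effects" in overrides:
            overrides["planted_effects"] = tuple(
                PlantedEffect(**e) for e in overrides["planted_effects"]
            )
        if "cell_types" in overrides:
            overrides["cell_types"] = tuple(
                (n, tuple(r)) for n, r in overrides["cell_types"]
            )
        if "genome" in overrides:
            overrides["genome"] = tuple((c, l) for c, l in overrides["genome"])
        config = SimulationConfig(seed=self.seed, **overrides)
        n_effects = int(sim_cfg.get("n_effects", 0))
        if n_effects and not config.planted_effects:
            config = plant_ad_scenario(config, n_effects)
        self._bundle = generate_dataset(config)
        write_bundle(self._bundle, self.outdir / "bundle")
        frac = te_fraction_per_cell(self._bundle.matrix)
        self._record(
            "simulate",
            n_cells=int(self._bundle.matrix.n_cells),
            n_features=int(self._bundle.matrix.n_features),
            n_planted=len(self._bundle.planted_effects),
            mean_te_fraction_pct=float(frac.mean()),
        )

    def stage_de(self):
        matrix = self._filtered_matrix()
        de_cfg = self.cfg["de"]
        k = int(self.cfg["robustness"]["k"])
        fulls, records = [], []
        cell_types = sorted(self.bundle.cell_meta["cell_type"].unique())
        for i, ct in enumerate(cell_types):
            # aggregate genes+TEs so offsets reflect total library sizes,
            # then test the TE features
            pb_all = aggregate_pseudobulk(matrix, self.bundle.cell_meta, ct)
            pb = pb_all.subset_features(matrix.kind == "TE")
            per_cond = pb.n_per_condition()
            if min(per_cond.get("AD", 0), per_cond.get("control", 0)) < 2:
                warnings.warn(f"skipping cell type {ct}: {per_cond}", stacklevel=2)
                continue
            ct_seed = (self.seed + 7919 * (i + 1)) % (2**31)
            full, _, rec = run_robustness(
                pb, k=k, seed=ct_seed,
                fdr_threshold=de_cfg["fdr"],
                shrink_weight=de_cfg["shrink_weight"],
                lfc_threshold=de_cfg["lfc"],
            )
            fulls.append(full)
            records.append(rec)
        full_df = pd.concat(fulls, ignore_index=True)
        rec_df = pd.concat(records, ignore_index=True)
        robust = pd.concat(
            [
                select_robust_tes(f, r, de_cfg["lfc"], de_cfg["fdr"])
                for f, r in zip(fulls, records)
            ],
            ignore_index=True,
        )
        _write_tsv(full_df, self.outdir / "de_results.tsv")
        _write_tsv(rec_df, self.outdir / "robustness.tsv")
        _write_tsv(robust, self.outdir / "robust_tes.tsv")
        self._record(
            "de",
            n_tested=int(full_df["tested"].sum()),
            n_cell_types=len(fulls),
            n_robust_records=len(robust),
            n_unique_robust_ids=int(robust["feature_id"].nunique()),
            effect_filter_order="|log2FC| filter applied after robustness, full-data estimates",
        )

    def _robust(self) -> pd.DataFrame:
        return pd.read_csv(self.outdir / "robust_tes.tsv", sep="\t")

    def stage_annotate(self):
        robust = self._robust()
        loci = [parse_te_name(f) for f in robust["feature_id"].unique()]
        direction = ann.summarize_direction(robust, by="overall")
        direction_ct = ann.summarize_direction(robust, by="cell_type")
        comp = ann.class_composition(loci)
        fam_counts = pd.Series([t.family for t in loci]).value_counts().to_dict()
        if fam_counts:
            fam_table, chi2_stat, chi2_p = ann.family_enrichment(fam_counts)
        else:
            fam_table, chi2_stat, chi2_p = pd.DataFrame(), np.nan, np.nan
        chrom = ann.chromosome_enrichment(loci, self.bundle.genome) if loci else pd.DataFrame()
        ages = pd.DataFrame(
            {"te_id": [t.name for t in loci],
             "subfamily": [t.subfamily for t in loci],
             "age_class": [ann.assign_age(t.subfamily) for t in loci]}
        )
        cells = self.bundle.cell_meta.groupby("cell_type").size()
        per_ct = (
            robust.groupby("cell_type")
            .agg(n_de_tes=("feature_id", "nunique"), mean_abs_log2fc=("log2fc", lambda s: s.abs().mean()))
            .reindex(cells.index)
        )
        per_ct["n_de_tes"] = per_ct["n_de_tes"].fillna(0).astype(int)
        summary = per_ct.reset_index().assign(n_cells=cells.to_numpy())
        diag = ann.cluster_size_diagnostics(summary)
        _write_tsv(direction, self.outdir / "direction_overall.tsv")
        _write_tsv(direction_ct, self.outdir / "direction_by_cell_type.tsv")
        _write_tsv(comp, self.outdir / "class_composition.tsv")
        _write_tsv(fam_table, self.outdir / "family_enrichment.tsv")
        _write_tsv(chrom, self.outdir / "chromosome_enrichment.tsv")
        _write_tsv(ages, self.outdir / "age_classes.tsv")
        _write_tsv(diag.table, self.outdir / "cluster_size_diagnostics.tsv")
        (self.outdir / "annotation_stats.json").write_text(
            json.dumps(
                {
                    "chi2_statistic": chi2_stat,
                    "chi2_p": chi2_p,
                    "spearman_rho": diag.spearman_rho,
                    "spearman_p": diag.spearman_p,
                    "pearson_r": diag.pearson_r,
                    "pearson_p": diag.pearson_p,
                    "young_fraction": float((ages["age_class"] == "Young").mean())
                    if len(ages) else float("nan"),
                },
                indent=1, allow_nan=True,
            )
        )
        self._record("annotate", n_robust_loci=len(loci))

    def stage_proximity(self):
        robust = self._robust()
        loci = [parse_te_name(f) for f in robust["feature_id"].unique()]
        windows = [int(w) for w in self.cfg["windows"]]
        pairs_by_window = {
            w: prox.find_pairs(loci, self.bundle.gene_models, w) for w in windows
        }
        background = set(self.bundle.gene_models["gene_id"])
        metrics = prox.window_metrics(
            pairs_by_window, [t.name for t in loci], self.bundle.gene_sets, background
        )
        if self.cfg["selected_window"] == "auto" and len(metrics) >= 2:
            selected, sel_table = prox.select_window(metrics)
        else:
            selected = (
                int(self.cfg["selected_window"])
                if self.cfg["selected_window"] != "auto"
                else windows[0]
            )
            _, sel_table = (selected, pd.DataFrame()) if len(metrics) < 2 else prox.select_window(metrics)
        for w, pairs in pairs_by_window.items():
            _write_tsv(pairs, self.outdir / f"pairs_{w}.tsv")
        _write_tsv(sel_table, self.outdir / "window_selection.tsv")
        sel_pairs = pairs_by_window[selected]
        adp = prox.ad_gene_proximity(pairs_by_window, self.bundle.ad_genes,
                                     tally_window=selected)
        td = prox.te_derived_gene_test(
            set(sel_pairs["gene_id"]), self.bundle.te_derived_genes,
            **self.cfg["te_derived"],
        ) if len(sel_pairs) else None
        assigner = prox.GenomicFeatureAssigner(
            self.bundle.gene_models, self.bundle.exons, self.bundle.enhancers,
            promoter_upstream=self.cfg["promoter"]["upstream"],
            promoter_downstream=self.cfg["promoter"]["downstream"],
        )
        _write_tsv(assigner.assign_all(loci), self.outdir / "genomic_features.tsv")
        result = {
            "selected_window": selected,
            "n_pairs": int(len(sel_pairs)),
            "n_unique_genes": int(sel_pairs["gene_id"].nunique()),
            "median_distance_bp": float(sel_pairs["distance"].median())
            if len(sel_pairs) else float("nan"),
            "ad_gene_tiers": {int(k): int(v) for k, v in adp.tier_counts.items()},
            "ad_family_counts": {k: int(v) for k, v in adp.family_counts.items()},
            "te_derived": None if td is None else asdict(td),
        }
        (self.outdir / "proximity_summary.json").write_text(
            json.dumps(result, indent=1, allow_nan=True)
        )
        _write_tsv(adp.top_genes, self.outdir / "ad_top_genes.tsv")
        self._record("proximity", selected_window=selected, n_pairs=result["n_pairs"])

    def stage_atac(self):
        robust = self._robust()
        summary = json.loads((self.outdir / "proximity_summary.json").read_text())
        window = int(summary["selected_window"])
        pairs = pd.read_csv(self.outdir / f"pairs_{window}.tsv", sep="\t")
        if pairs.empty:
            (self.outdir / "atac_scores.tsv").write_text("")
            self._record("atac", n_scored=0)
            return
        loci = [parse_te_name(f) for f in robust["feature_id"].unique()]
        profiles = atac_mod.accessibility_profiles(
            loci, self.bundle.atac_peaks, self.bundle.atac_matrix,
            window=self.cfg["atac"]["window"],
        )
        # pseudobulk units (sample x cell type), library-normalized log counts
        expr = self._pseudobulk_units()
        corrs = {
            (t, g): atac_mod.pseudobulk_correlation(expr, t, g)
            for t, g in zip(pairs["te_id"], pairs["gene_id"])
            if t in expr.index and g in expr.index
        }
        # per-TE best (most significant) full-data effect across cell types
        de_best = (
            robust.assign(a=robust["log2fc"].abs())
            .sort_values("a", ascending=False)
            .drop_duplicates("feature_id")[["feature_id", "log2fc"]]
        )
        weights = atac_mod.ScoreWeights(**self.cfg["atac"]["weights"])
        scores, manifest = atac_mod.score_pairs(
            pairs, profiles, de_best, corrs, weights, window=window
        )
        scores = atac_mod.classify_confidence(
            scores, self.cfg["atac"]["corr_threshold"]
        )
        _write_tsv(scores, self.outdir / "atac_scores.tsv")
        manifest["median_composite"] = scores.attrs["median_composite"]
        manifest["corr_threshold"] = self.cfg["atac"]["corr_threshold"]
        (self.outdir / "scoring_manifest.json").write_text(json.dumps(manifest, indent=1))
        self._record("atac", n_scored=len(scores),
                     n_high_confidence=int(scores["high_confidence"].sum()))

    def _pseudobulk_units(self) -> pd.DataFrame:
        """Features x (sample, cell type) normalized log1p pseudobulk expression."""
        matrix = self.bundle.matrix
        meta = self.bundle.cell_meta.set_index("cell_id").loc[matrix.cell_ids]
        unit = meta["sample_id"].astype(str) + "|" + meta["cell_type"].astype(str)
        units = pd.Index(pd.unique(unit))
        indicator = np.zeros((matrix.n_cells, len(units)))
        indicator[np.arange(matrix.n_cells), units.get_indexer(unit)] = 1
        counts = np.asarray(matrix.counts @ indicator)
        lib = counts.sum(axis=0)
        lib[lib == 0] = 1.0
        cpm = counts / lib * 1e4
        return pd.DataFrame(np.log1p(cpm), index=matrix.feature_ids, columns=units)

    def write_manifest(self):
        (self.outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, allow_nan=True)
        )


def run_pipeline(
    config: dict | str | Path | None = None,
    outdir="tescope_run",
    seed: int | None = None,
    stages=STAGES,
) -> Path:
    """Run the requested stages in order and write a run manifest.

    ``config`` may be a YAML path, a dict of overrides over
    :data:`DEFAULT_CONFIG`, or None.  ``seed`` overrides the config
    seed.  Any stage failure aborts with a stage-named error.
    """
    if isinstance(config, (str, Path)):
        cfg = load_pipeline_config(config)
    else:
        cfg = load_pipeline_config(None, config)
    if seed is not None:
        cfg["seed"] = int(seed)
    pipe = Pipeline(cfg, outdir)
    wanted = [s for s in STAGES if s in set(stages)]
    if cfg.get("input_dir") and "simulate" in wanted:
        wanted.remove("simulate")
    runners = {
        "simulate": pipe.stage_simulate,
        "de": pipe.stage_de,
        "robust": pipe.stage_de,  # robustness is computed jointly with DE
        "annotate": pipe.stage_annotate,
        "proximity": pipe.stage_proximity,
        "atac": pipe.stage_atac,
    }
    done = set()
    for stage in wanted:
        runner = runners[stage]
        if runner in done:
            continue
        try:
            runner()
        except Exception as exc:
            pipe.manifest["failed_stage"] = stage
            pipe.write_manifest()
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        done.add(runner)
    pipe.write_manifest()
    return pipe.outdir
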