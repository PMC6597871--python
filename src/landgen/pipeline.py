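"""Pipeline orchestration: config validation, stage ordering, artifacts.

``run_pipeline`` executes the analysis stages in dependency order —
filter -> diversity -> relatedness -> resistance -> IBR model selection ->
genome scans — writing one CSV/JSON artifact per stage into a run
directory together with a log of the seeds and options used.  Stage
outputs are cached by a hash of the configuration and input paths;
rerunning with unchanged inputs reuses them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    FilterSpec, apply_locus_filters, assign_clusters, build_pair_table,
    build_resistance_surface, diversity_metrics, fit_mlpe,
    all_subsets_selection, geographic_distance_matrix, latent_factor_scan,
    intersect_candidates, ld_prune, pairwise_circuit_resistance, read_vcf,
    read_ascii_grid, residual_serial_autocorrelation, spatial_autocorrelogram,
    yang_relatedness, fst_outlier_scan, env_variable_select,
)
from .popgen import summaries_to_frame

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "vcf", "metadata", "qmatrix", "rasters", "environment",
    "filters", "resistance", "ibr", "scan", "autocorrelogram", "seed",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    vcf: str
    metadata: str
    rasters: dict = field(default_factory=dict)  # name -> {path, mode}
    qmatrix: str | None = None
    environment: str | None = None
    filters: dict = field(default_factory=dict)
    resistance: dict = field(default_factory=dict)  # neighborhood, averaging
    ibr: dict = field(default_factory=dict)  # nested, method, collinearity_rmax
    scan: dict = field(default_factory=dict)  # k, q, env_var
    autocorrelogram: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for req in ("vcf", "metadata"):
            if req not in raw:
                raise ValueError(f"configuration missing required key {req!r}")
        cfg = cls(**raw)
        for name, spec in cfg.rasters.items():
            if "path" not in spec:
                raise ValueError(f"raster {name!r} missing 'path'")
            if not Path(spec["path"]).exists():
                raise ValueError(f"raster path does not exist: {spec['path']}")
        for p in (cfg.vcf, cfg.metadata):
            if not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _stage_done(run_dir: Path, stage: str, digest: str) -> bool:
    marker = run_dir / f".{stage}.done"
    return marker.exists() and marker.read_text().strip() == digest


def _mark_stage(run_dir: Path, stage: str, digest: str) -> None:
    (run_dir / f".{stage}.done").write_text(digest)


def run_pipeline(config: PipelineConfig, run_dir) -> Path:
    """Run every stage, writing artifacts into ``run_dir``.

    Stage failures raise with the stage name attached.  Completed stages
    are skipped on rerun when the configuration hash is unchanged.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    log_path = run_dir / "pipeline.log"
    handler = logging.FileHandler(log_path)
    logging.getLogger("landgen").addHandler(handler)
    try:
        return _run_stages(config, run_dir, digest)
    finally:
        logging.getLogger("landgen").removeHandler(handler)


def _run_stages(config: PipelineConfig, run_dir: Path, digest: str) -> Path:
    stage = "filter"
    try:
        gt = read_vcf(config.vcf, config.metadata)
        spec = FilterSpec(**config.filters)
        gt, report = apply_locus_filters(gt, spec)
        gt = ld_prune(gt, spec.ld_r2_max)
        if config.qmatrix:
            gt = assign_clusters(gt, pd.read_csv(config.qmatrix))
        (run_dir / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))

        stage = "diversity"
        if not _stage_done(run_dir, stage, digest):
            by_cluster = "cluster" in gt.samples.columns
            summaries = diversity_metrics(gt, by_cluster=by_cluster, seed=config.seed)
            summaries_to_frame(summaries).to_csv(run_dir / "diversity.csv", index=False)
            _mark_stage(run_dir, stage, digest)

        stage = "relatedness"
        rel = yang_relatedness(gt)
        if not _stage_done(run_dir, stage, digest):
            rel.to_frame().to_csv(run_dir / "relatedness.csv")
            ac_opts = dict(config.autocorrelogram)
            if ac_opts.pop("enabled", True):
                ac = spatial_autocorrelogram(rel, gt.samples, seed=config.seed, **ac_opts)
                ac.to_frame().to_csv(run_dir / "autocorrelogram.csv", index=False)
            _mark_stage(run_dir, stage, digest)

        stage = "resistance"
        distances = {}
        res_opts = config.resistance
        for name, spec_r in config.rasters.items():
            grid = read_ascii_grid(spec_r["path"])
            surface = build_resistance_surface(
                grid, mode=spec_r.get("mode", "raw"), points=gt.samples,
                provenance=name)
            rd = pairwise_circuit_resistance(
                surface, gt.samples,
                neighborhood=res_opts.get("neighborhood", 8),
                averaging=res_opts.get("averaging", "conductance"))
            rd.to_frame().to_csv(run_dir / f"resistance_{name}.csv")
            distances[name] = rd
        _mark_stage(run_dir, stage, digest)

        stage = "ibr"
        if distances:
            pairs = build_pair_table(rel, distances, gt.samples)
            ibr_opts = config.ibr
            nested = ibr_opts.get("nested", True)
            table = all_subsets_selection(
                pairs, collinearity_rmax=ibr_opts.get("collinearity_rmax", 0.6),
                nested=False)
            best_terms = table.iloc[0]["predictors"]
            best_fit = table.iloc[0]["_fit"]
            out = table.drop(columns=["_fit"])
            out.to_csv(run_dir / "ibr_selection.csv", index=False)
            preds = [] if best_terms == "(intercept)" else [
                t.strip() for t in best_terms.split("+")]
            refit = fit_mlpe(pairs, preds, nested=nested,
                             method=ibr_opts.get("method", "ml"))
            refit.summary().to_csv(run_dir / "ibr_best_fit.csv", index=False)
            diag = {
                "best_model": best_terms,
                "mlpe_serial_autocorr": residual_serial_autocorrelation(
                    best_fit, pairs, preds),
                "nmlpe_serial_autocorr": residual_serial_autocorrelation(
                    refit, pairs, preds) if nested else None,
                "rho": refit.rho,
            }
            (run_dir / "ibr_diagnostics.json").write_text(json.dumps(diag, indent=2))
        _mark_stage(run_dir, stage, digest)

        stage = "scan"
        scan_opts = config.scan
        if config.environment:
            env = pd.read_csv(config.environment)
            env = env.set_index(env["sample_id"].astype(str)).loc[
                gt.samples["id"].astype(str)]
            env_num = env.drop(columns=["sample_id"])
            n_axes = min(int(scan_opts.get("n_axes", 4)), env_num.shape[1])
            chosen = (env_variable_select(env_num, n_axes)["selected"]
                      if env_num.shape[1] > n_axes else list(env_num.columns))
            k = int(scan_opts.get("k", 1))
            q = float(scan_opts.get("q", 0.05))
            results = {}
            for var in chosen:
                scans = [latent_factor_scan(gt, env_num[var].to_numpy(float),
                                            k=max(kk, 0), q=q)
                         for kk in (k - 1, k, k + 1) if 0 <= kk < gt.n_samples - 2]
                cand = sorted(intersect_candidates(scans)) if len(scans) >= 2 else \
                    sorted(scans[0].flagged_loci)
                results[var] = {"n_candidates": len(cand), "candidates": cand}
                scans[min(len(scans) - 1, 1)].table.to_csv(
                    run_dir / f"scan_{var}.csv", index=False)
            (run_dir / "scan_candidates.json").write_text(json.dumps(results, indent=2))
        if "cluster" in gt.samples.columns and gt.samples["cluster"].nunique() >= 2:
            outl = fst_outlier_scan(gt)
            outl.table.to_csv(run_dir / "fst_outliers.csv", index=False)
        _mark_stage(run_dir, stage, digest)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (run_dir / "run_info.json").write_text(json.dumps({
        "config_digest": digest, "seed": config.seed,
    }, indent=2))
    return run_dir
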