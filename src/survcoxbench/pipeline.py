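"""End-to-end orchestration: dataset -> QC -> benchmark -> partition ->
optional permutation control and gene-number sweep, written to a run
directory with a manifest that allows an exact re-run.

All stochastic stages derive their seeds from one master seed with a fixed
counter scheme (stage name -> offset), so two runs with the same config are
identical apart from timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .datasets import (
    classify_censoring,
    load_clinical,
    load_dataset,
    load_expression_matrix,
    merge_dataset,
    qc_filter_genes,
    save_dataset,
    standardize,
)
from .cox.mixed import MixedCox
from .cox.penalized import PenalizedConfig
from .evaluation import gene_number_sweep, permutation_validation, run_mccv
from .simulate import SimulationConfig, simulate_dataset
from .variance import estimate_partition, jackknife_ci

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("survcoxbench")

# fixed offsets added to the master seed, one per stochastic stage
SEED_OFFSETS = {"mccv": 1, "permutation": 2, "sweep": 3, "jackknife": 4, "tuning": 5}


@dataclass
class RunConfig:
    """Validated pipeline configuration; every field has a default and
    unknown keys are rejected."""

    out_dir: str = "svb_run"
    dataset_path: str | None = None
    expr_path: str | None = None
    clin_path: str | None = None
    simulation: dict | None = None
    models: tuple = ("cox_clinical", "coxlasso", "coxenet", "coxlmm")
    n_rep: int = 100
    train_frac: float = 0.8
    seed: int = 0
    alpha_enet: float = 0.5
    alpha_lasso: float = 1.0
    n_lambda: int = 100
    n_subsample: int = 20
    stratify_splits: bool = False
    fold_standardize: bool = False
    qc_max_zero_frac: float = 0.5
    qc_var_quantile: float = 0.2
    censoring_n_min: int = 175
    censoring_frac_threshold: float = 0.15
    censoring_criterion: str = "event_fraction_ge"
    run_partition: bool = True
    partition_level: float = 0.95
    partition_max_delete: int | None = 100
    partition_jackknife: bool = False
    run_permutation: bool = False
    run_sweep: bool = False
    sweep_grid: tuple = (100, 300, 1000, 3000, 5000, "all")
    sweep_n_rep: int = 20
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def _obtain_dataset(config: RunConfig, out: Path):
    """Simulate, load a container, or ingest raw TSVs; returns
    (standardized dataset, qc report or None, provenance dict)."""
    qc_report = None
    if config.simulation is not None:
        sim = SimulationConfig.from_dict({"seed": config.seed, **config.simulation})
        ds, truth = simulate_dataset(sim)
        provenance = {"source": "simulation", "config": sim.to_dict(),
                      "pce_true": truth.pce_true, "pge_true": truth.pge_true,
                      "censoring_realized": truth.censoring_realized}
    elif config.dataset_path:
        ds = load_dataset(config.dataset_path)
        provenance = {"source": "container", "path": str(config.dataset_path)}
    elif config.expr_path and config.clin_path:
        expr = load_expression_matrix(config.expr_path)
        clin = load_clinical(config.clin_path)
        ds = merge_dataset(expr, clin)
        ds, qc_report = qc_filter_genes(ds, config.qc_max_zero_frac, config.qc_var_quantile)
        provenance = {"source": "tsv", "expr": str(config.expr_path),
                      "clin": str(config.clin_path), "n_merged": ds.n}
    else:
        raise ValueError("config must provide simulation, dataset_path, or expr+clin paths")
    if not ds.standardized:
        ds = standardize(ds)
    save_dataset(ds, out / "dataset.npz")
    if qc_report is not None:
        (out / "qc.json").write_text(json.dumps(qc_report.__dict__, indent=2))
    return ds, qc_report, provenance


def _penalized_configs(config: RunConfig) -> dict:
    shared = dict(n_lambda=config.n_lambda, n_subsample=config.n_subsample)
    return {
        "coxlasso": PenalizedConfig(alpha=config.alpha_lasso, **shared),
        "coxenet": PenalizedConfig(alpha=config.alpha_enet, **shared),
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    manifest: dict = {"version": __version__, "config": config.to_dict(), "stages": {}}
    try:
        ds, qc_report, provenance = _obtain_dataset(config, out)
        manifest["provenance"] = provenance
        cls = classify_censoring(ds, config.censoring_n_min,
                                 config.censoring_frac_threshold, config.censoring_criterion)
        manifest["censoring_class"] = cls.__dict__
        log.info("dataset: n=%d p=%d m=%d (%s)", ds.n, ds.p, ds.m, cls.label)

        summary: dict = {}
        mccv_seed = config.seed + SEED_OFFSETS["mccv"]
        model_configs = _penalized_configs(config)
        log.info("MCCV: %d replicates, models=%s, seed=%d", config.n_rep, config.models, mccv_seed)
        mccv = run_mccv(ds, config.models, config.n_rep, config.train_frac,
                        seed=mccv_seed, stratify=config.stratify_splits,
                        fold_standardize=config.fold_standardize,
                        model_configs=model_configs)
        mccv.table.to_csv(out / "mccv.csv", index=False)
        summary["mccv_mean_cindex"] = mccv.model_means().to_dict()
        summary["mccv_sd_cindex"] = mccv.summary()["sd_cindex"].to_dict()
        summary["pairwise_gains"] = {
            m2: row.to_dict() for m2, row in mccv.pairwise_gains().iterrows()
        }
        manifest["stages"]["mccv"] = {"seed": mccv_seed, "rows": len(mccv.table)}

        if config.run_partition:
            jk_seed = config.seed + SEED_OFFSETS["jackknife"]
            if config.partition_jackknife:
                part = jackknife_ci(ds, level=config.partition_level,
                                    max_delete=config.partition_max_delete, seed=jk_seed)
            else:
                part = estimate_partition(ds, MixedCox(ds).fit())
            part_json = {
                "pce": part.pce, "pge": part.pge, "pve": part.pve,
                "v_c": part.v_c, "v_g": part.v_g,
                "residual_constant": part.residual_constant,
                "ci_pce": part.ci_pce, "ci_pge": part.ci_pge,
                "level": part.level, "n_jackknife": part.n_jackknife,
            }
            (out / "partition.json").write_text(json.dumps(part_json, indent=2))
            summary["partition"] = {"pce": part.pce, "pge": part.pge, "pve": part.pve}
            manifest["stages"]["partition"] = {"seed": jk_seed,
                                               "jackknife": config.partition_jackknife}

        if config.run_permutation:
            perm_seed = config.seed + SEED_OFFSETS["permutation"]
            perm = permutation_validation(ds, config.models, config.n_rep,
                                          config.train_frac, seed=perm_seed,
                                          model_configs=model_configs)
            perm.permuted.table.to_csv(out / "mccv_permuted.csv", index=False)
            summary["permuted_mean_cindex"] = perm.permuted.model_means().to_dict()
            manifest["stages"]["permutation"] = {"seed": perm_seed}

        if config.run_sweep:
            sweep_seed = config.seed + SEED_OFFSETS["sweep"]
            sweep = gene_number_sweep(ds, config.sweep_grid, n_rep=config.sweep_n_rep,
                                      train_frac=config.train_frac, seed=sweep_seed)
            sweep.table.to_csv(out / "sweep.csv", index=False)
            summary["sweep_mean_cindex"] = {
                f"{scheme}:{k}": v
                for (k, scheme), v in sweep.summary().stack().items()
            }
            manifest["stages"]["sweep"] = {"seed": sweep_seed}

        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
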