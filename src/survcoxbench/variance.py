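"""Partition of survival variation on the log-hazard scale.

Within the mixed-effects Cox framework the log relative hazard for subject i
is X_i'a + G_i'b plus an extreme-value residual. The proportion of survival
variation explained by the clinical covariates (PCE) and by the transcriptome
(PGE) are

    PCE = v_c / (v_c + v_g + c_res)
    PGE = v_g / (v_c + v_g + c_res)
    PVE = PCE + PGE

where v_c is the sample variance of the fitted clinical predictor X a, v_g
is the model-based per-sample genetic variance m * sigma_b_hat^2, and c_res
is the residual log-hazard variance, by convention pi^2/6 (the variance of a
standard Gumbel residual, the usual choice when partitioning variance under
proportional hazards). Confidence intervals come from a delete-one-sample
jackknife with normal-theory limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import SurvivalDataset, standardize
from .simulate import RESIDUAL_LOGHAZARD_VARIANCE

__all__ = [
    "VariancePartition",
    "estimate_partition",
    "jackknife_ci",
    "jackknife_se",
]


@dataclass
class VariancePartition:
    """PCE/PGE/PVE point estimates, optionally with jackknife CIs."""

    pce: float
    pge: float
    pve: float
    v_c: float
    v_g: float
    residual_constant: float
    ci_pce: tuple[float, float] | None = None
    ci_pge: tuple[float, float] | None = None
    se_pce: float | None = None
    se_pge: float | None = None
    level: float | None = None
    n_jackknife: int = 0
    replicates: pd.DataFrame | None = None

    def __post_init__(self):
        assert self.pce >= 0 and self.pge >= 0
        assert abs(self.pve - (self.pce + self.pge)) < 1e-10
        assert self.pve <= 1 + 1e-12

    def summary(self) -> pd.DataFrame:
        rows = {
            "PCE": [self.pce, *(self.ci_pce or (np.nan, np.nan))],
            "PGE": [self.pge, *(self.ci_pge or (np.nan, np.nan))],
            "PVE": [self.pve, np.nan, np.nan],
        }
        return pd.DataFrame(rows, index=["estimate", "ci_low", "ci_high"]).T


def estimate_partition(
    ds: SurvivalDataset,
    fit,
    residual_constant: float = RESIDUAL_LOGHAZARD_VARIANCE,
    v_g_source: str = "model",
) -> VariancePartition:
    """Point estimates of PCE/PGE/PVE from a converged mixed-model fit.

    ``v_g_source`` chooses the genetic-variance estimate: ``"model"`` uses
    m * sigma_b_hat^2 (default; the posterior-mode predictor's empirical
    variance is shrunken), ``"empirical"`` uses var(G b_mode) for
    sensitivity checks.
    """
    if not getattr(fit, "converged", False):
        raise ValueError("variance partition requires a converged mixed-model fit")
    v_c = float(np.var(ds.X @ fit.a, ddof=1)) if ds.p else 0.0
    if v_g_source == "model":
        v_g = float(fit.genetic_variance)
    elif v_g_source == "empirical":
        v_g = float(np.var(ds.G @ fit.b_mode, ddof=1))
    else:
        raise ValueError(f"unknown v_g_source {v_g_source!r}")
    denom = v_c + v_g + residual_constant
    return VariancePartition(
        pce=v_c / denom, pge=v_g / denom, pve=(v_c + v_g) / denom,
        v_c=v_c, v_g=v_g, residual_constant=residual_constant,
    )


def jackknife_se(stat_fn, n: int, max_delete: int | None = None, seed: int = 0):
    """Delete-one jackknife standard error of a (possibly vector) statistic.

    ``stat_fn(keep_idx)`` evaluates the statistic on the subsample indexed by
    ``keep_idx``. With ``max_delete`` < n, a seeded random subset of d
    deletions is used and the usual (n-1)/n sum is rescaled to (n-1)/d —
    unbiased for the full-jackknife variance under random deletion choice.

    Returns (replicates (d, k) array, se (k,) array, deleted indices).
    Failures of single refits are skipped; more than 10% failures raise.
    """
    all_idx = np.arange(n)
    if max_delete is not None and max_delete < n:
        rng = np.random.default_rng(seed)
        deleted = np.sort(rng.choice(n, size=max_delete, replace=False))
    else:
        deleted = all_idx
    reps, kept_deleted = [], []
    n_fail = 0
    for i in deleted:
        try:
            reps.append(np.atleast_1d(np.asarray(stat_fn(np.delete(all_idx, i)), dtype=float)))
            kept_deleted.append(i)
        except Exception as exc:  # noqa: BLE001 — refit failures are counted
            n_fail += 1
            warnings.warn(f"jackknife refit without sample {i} failed: {exc}")
    if n_fail > 0.1 * len(deleted):
        raise RuntimeError(f"{n_fail}/{len(deleted)} jackknife refits failed")
    reps = np.vstack(reps)
    d = reps.shape[0]
    se = np.sqrt((n - 1) / d * ((reps - reps.mean(axis=0)) ** 2).sum(axis=0))
    return reps, se, np.asarray(kept_deleted)


def jackknife_ci(
    ds: SurvivalDataset,
    level: float = 0.95,
    max_delete: int | None = 100,
    seed: int = 0,
    residual_constant: float = RESIDUAL_LOGHAZARD_VARIANCE,
    v_g_source: str = "model",
    ties: str = "efron",
    fit=None,
) -> VariancePartition:
    """Variance partition with jackknife confidence intervals.

    Each delete-one replicate re-standardizes the reduced dataset and refits
    the full mixed model (variance component included); the CI is the normal
    approximation around the full-sample point estimate.
    """
    from scipy import stats

    from .cox.mixed import MixedCox

    if ds.n < 30:
        raise ValueError("jackknife CI needs n >= 30")
    if fit is None:
        fit = MixedCox(ds, ties=ties).fit()
    point = estimate_partition(ds, fit, residual_constant, v_g_source)

    def stat(keep_idx):
        sub = standardize(ds.subset(keep_idx))
        f = MixedCox(sub, ties=ties).fit()
        part = estimate_partition(sub, f, residual_constant, v_g_source)
        return [part.pce, part.pge]

    reps, se, deleted = jackknife_se(stat, ds.n, max_delete=max_delete, seed=seed)
    z = stats.norm.ppf(0.5 + level / 2)
    replicates = pd.DataFrame(
        {"deleted_sample": [ds.sample_ids[i] for i in deleted],
         "pce": reps[:, 0], "pge": reps[:, 1]}
    )
    return VariancePartition(
        pce=point.pce, pge=point.pge, pve=point.pve,
        v_c=point.v_c, v_g=point.v_g, residual_constant=residual_constant,
        ci_pce=(point.pce - z * se[0], point.pce + z * se[0]),
        ci_pge=(point.pge - z * se[1], point.pge + z * se[1]),
        se_pce=float(se[0]), se_pge=float(se[1]),
        level=level, n_jackknife=len(deleted), replicates=replicates,
    )
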