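"""Model comparison harness: Harrell's C-index, Monte Carlo cross-validation
(MCCV), relative prediction gain, the permuted-expression control, and the
gene-number sweep.

The benchmark design follows the comparison protocol: repeated random 80/20
train/test splits (100 by default); every model — clinical-only Cox, lasso
Cox, elastic-net Cox, mixed-effects Cox — is fitted on the training part
(penalized-model tuning runs entirely inside the training fold) and scored by
Harrell's C-index on the held-out part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import SurvivalDataset, standardize
from .cox.clinical import CoxPH, univariate_gene_pvalues
from .cox.mixed import MixedCox
from .cox.penalized import CoxElasticNet, PenalizedConfig

__all__ = [
    "c_index",
    "prediction_gain",
    "MCCVResult",
    "SweepResult",
    "PermutationResult",
    "run_mccv",
    "permutation_validation",
    "gene_number_sweep",
    "MODEL_NAMES",
]

MODEL_NAMES = ("cox_clinical", "coxlasso", "coxenet", "coxlmm")


# -----------------------------------------------------------------------------
# C-index and prediction gain
# -----------------------------------------------------------------------------

def c_index(times, status, scores) -> float:
    """Harrell's concordance index.

    A pair (i, j) is permissible when the member with the strictly smaller
    time had an observed event; pairs with tied times are not compared. A
    permissible pair is concordant when the shorter-surviving member has the
    strictly higher risk score; score ties contribute 1/2. Returns
    concordant / (concordant + discordant).
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if not (len(times) == len(status) == len(scores)):
        raise ValueError("times, status, scores must have equal length")
    order = np.argsort(times, kind="stable")
    t, d, s = times[order], status[order], scores[order]
    n = len(t)
    concordant = 0.0
    permissible = 0
    for i in range(n):
        if d[i] != 1:
            continue
        j0 = np.searchsorted(t, t[i], side="right")  # strictly later times
        if j0 >= n:
            continue
        later = s[j0:]
        permissible += n - j0
        concordant += np.count_nonzero(s[i] > later) + 0.5 * np.count_nonzero(s[i] == later)
    if permissible == 0:
        raise ValueError("no permissible pairs (no events before any other time)")
    return concordant / permissible


def prediction_gain(c_m2: float, c_m1: float) -> float:
    """Relative prediction gain (C_M2 - C_M1) / C_M1 of model M2 over M1."""
    if c_m1 <= 0:
        raise ValueError("reference C-index must be positive")
    return (c_m2 - c_m1) / c_m1


# -----------------------------------------------------------------------------
# model registry
# -----------------------------------------------------------------------------

def _fit_model(name: str, train: SurvivalDataset, tune_seed: int, configs: dict):
    cfg = configs.get(name)
    if name == "cox_clinical":
        return CoxPH(train).fit()
    if name == "coxlasso":
        pc = cfg or PenalizedConfig(alpha=1.0)
        return CoxElasticNet(train, config=pc).fit(seed=tune_seed)
    if name == "coxenet":
        pc = cfg or PenalizedConfig(alpha=0.5)
        return CoxElasticNet(train, config=pc).fit(seed=tune_seed)
    if name == "coxlmm":
        return MixedCox(train).fit()
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def _score(fit, ds: SurvivalDataset, test_idx) -> float:
    eta = ds.X[test_idx] @ fit.a + ds.G[test_idx] @ fit.b
    return c_index(ds.times[test_idx], ds.status[test_idx], eta)


# -----------------------------------------------------------------------------
# MCCV
# -----------------------------------------------------------------------------

@dataclass
class MCCVResult:
    """Per-replicate, per-model test C-indexes plus summaries."""

    table: pd.DataFrame
    models: tuple
    n_rep: int
    seed: int

    def model_means(self) -> pd.Series:
        return self.table.groupby("model", sort=False)["cindex"].mean()

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby("model", sort=False)["cindex"]
        return pd.DataFrame({"mean_cindex": g.mean(), "sd_cindex": g.std()})

    def pairwise_gains(self) -> pd.DataFrame:
        """Mean relative gain of the row model over the column model."""
        means = self.model_means()
        out = pd.DataFrame(index=means.index, columns=means.index, dtype=float)
        for m2 in means.index:
            for m1 in means.index:
                out.loc[m2, m1] = prediction_gain(means[m2], means[m1])
        return out


def _draw_split(rng, ds, n_train, stratify, max_redraw=10):
    n_redrawn = 0
    for _ in range(max_redraw + 1):
        if stratify:
            ev, ce = np.flatnonzero(ds.status == 1), np.flatnonzero(ds.status == 0)
            tr = np.concatenate([
                rng.permutation(ev)[: int(round(len(ev) * n_train / ds.n))],
                rng.permutation(ce)[: n_train - int(round(len(ev) * n_train / ds.n))],
            ])
            te = np.setdiff1d(np.arange(ds.n), tr)
        else:
            perm = rng.permutation(ds.n)
            tr, te = perm[:n_train], perm[n_train:]
        if ds.status[te].sum() >= 2 and ds.status[tr].sum() >= 2:
            return np.sort(tr), np.sort(te), n_redrawn
        n_redrawn += 1
    raise RuntimeError(f"could not draw a usable split after {max_redraw} redraws")


def run_mccv(
    ds: SurvivalDataset,
    models=MODEL_NAMES,
    n_rep: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
    stratify: bool = False,
    fold_standardize: bool = False,
    model_configs: dict | None = None,
    progress: bool = False,
) -> MCCVResult:
    """Monte Carlo cross-validation of the requested models.

    One shared random split per replicate; each model is fitted on the
    training part (tuning included) and scored by C-index on the test part.
    Fully reproducible given ``seed``. Splits with fewer than 2 train or test
    events are redrawn (at most 10 times).
    """
    if ds.n < 50:
        raise ValueError("MCCV needs at least 50 samples")
    model_configs = model_configs or {}
    n_train = int(round(train_frac * ds.n))
    master = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(master.spawn(n_rep)):
        rng = np.random.default_rng(child)
        tune_seed = int(child.generate_state(1)[0] % (2**31))
        tr, te, n_redrawn = _draw_split(rng, ds, n_train, stratify)
        train = ds.subset(tr)
        score_ds = ds
        if fold_standardize:
            train = standardize(train)
            Xte, Gte = train.standardizer.apply(ds.X[te], ds.G[te])
            score_ds = ds.replace(X=ds.X.copy(), G=ds.G.copy())
            score_ds.X[te], score_ds.G[te] = Xte, Gte
        for name in models:
            fit = _fit_model(name, train, tune_seed, model_configs)
            ci = _score(fit, score_ds, te)
            rows.append({"replicate": rep, "model": name, "cindex": ci,
                         "n_train": len(tr), "n_test": len(te),
                         "n_redrawn": n_redrawn, "seed": tune_seed})
        if progress:
            print(f"[mccv] replicate {rep + 1}/{n_rep} done")
    return MCCVResult(pd.DataFrame(rows), tuple(models), n_rep, seed)


# -----------------------------------------------------------------------------
# permutation control
# -----------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """MCCV on the original data next to MCCV on expression-permuted data."""

    original: MCCVResult
    permuted: MCCVResult
    permutation_seed: int

    def summary(self) -> pd.DataFrame:
        a = self.original.summary().add_suffix("_original")
        b = self.permuted.summary().add_suffix("_permuted")
        return a.join(b)


def permute_expressions(ds: SurvivalDataset, seed: int) -> SurvivalDataset:
    """Shuffle the sample-to-expression-row assignment (rows of G jointly),
    leaving covariates and survival untouched; gene-gene correlation is
    preserved while any gene-outcome association is broken."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n)
    return ds.replace(G=ds.G[perm])


def permutation_validation(
    ds: SurvivalDataset,
    models=("cox_clinical", "coxlmm"),
    n_rep: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
    **mccv_kwargs,
) -> PermutationResult:
    """Run the MCCV benchmark on the original and on an expression-permuted
    copy of the dataset, with identical splits."""
    original = run_mccv(ds, models, n_rep, train_frac, seed, **mccv_kwargs)
    permuted_ds = permute_expressions(ds, seed)
    permuted = run_mccv(permuted_ds, models, n_rep, train_frac, seed, **mccv_kwargs)
    return PermutationResult(original, permuted, seed)


# -----------------------------------------------------------------------------
# gene-number sweep
# -----------------------------------------------------------------------------

DEFAULT_SWEEP_GRID = (100, 300, 1000, 3000, 5000, "all")


@dataclass
class SweepResult:
    """Test C-index of the mixed model by gene count and selection scheme."""

    table: pd.DataFrame
    grid: tuple
    schemes: tuple
    n_rep: int
    seed: int

    def summary(self) -> pd.DataFrame:
        return self.table.pivot_table(index="n_genes", columns="scheme",
                                      values="cindex", aggfunc="mean")


def gene_number_sweep(
    ds: SurvivalDataset,
    grid=DEFAULT_SWEEP_GRID,
    schemes=("ranked", "random"),
    n_rep: int = 20,
    train_frac: float = 0.8,
    seed: int = 0,
    progress: bool = False,
) -> SweepResult:
    """Mixed-model prediction accuracy as a function of the number of genes.

    Per replicate: one 80/20 split; the ``ranked`` scheme keeps the genes
    with the smallest univariate Cox p-values *computed on the training
    fold*, the ``random`` scheme keeps a seeded random subset. Grid entries
    above m are clipped with a warning; "all" means every gene.
    """
    counts = []
    for gcount in grid:
        k = ds.m if gcount == "all" else int(gcount)
        if k > ds.m:
            warnings.warn(f"sweep grid value {gcount} exceeds m={ds.m}; clipped")
            k = ds.m
        counts.append(k)
    counts = sorted(set(counts))
    for scheme in schemes:
        if scheme not in ("ranked", "random"):
            raise ValueError(f"unknown selection scheme {scheme!r}")

    n_train = int(round(train_frac * ds.n))
    master = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(master.spawn(n_rep)):
        rng = np.random.default_rng(child)
        tr, te, _ = _draw_split(rng, ds, n_train, stratify=False)
        train = ds.subset(tr)
        pvals = univariate_gene_pvalues(train) if "ranked" in schemes else None
        for scheme in schemes:
            if scheme == "ranked":
                rank = np.argsort(pvals, kind="stable")
            else:
                rank = rng.permutation(ds.m)
            for k in counts:
                sel = np.sort(rank[:k])
                fit = MixedCox(train.subset(np.arange(len(tr)), genes=sel)).fit()
                eta = ds.X[te] @ fit.a + ds.G[np.ix_(te, sel)] @ fit.b_mode
                rows.append({"replicate": rep, "scheme": scheme, "n_genes": k,
                             "cindex": c_index(ds.times[te], ds.status[te], eta)})
        if progress:
            print(f"[sweep] replicate {rep + 1}/{n_rep} done")
    return SweepResult(pd.DataFrame(rows), tuple(counts), tuple(schemes), n_rep, seed)
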