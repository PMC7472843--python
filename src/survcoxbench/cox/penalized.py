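"""Lasso and elastic-net Cox models via IRLS + cyclic coordinate descent.

The penalized objective, in glmnet's scaling, is

    Q(a, b) = (1/n) * pl(X a + G b)
              - lambda * sum_j [ alpha*|b_j| + (1-alpha)/2 * b_j^2 ]

with clinical effects ``a`` unpenalized by default (they are the benchmark
and are always kept in the model). ``alpha`` = 1 gives the lasso
("coxlasso"); ``alpha`` = 0.5 the elastic net used for "coxenet".

The tuning parameter is chosen by a subsampling strategy: repeated random
80/20 splits of the training data, scoring every lambda on the held-out part
by C-index (default) or partial-likelihood deviance, and picking the lambda
with the best mean held-out score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..datasets import SurvivalDataset
from ._cd import cd_solve
from .clinical import predict_risk, fit_cox
from .likelihood import PartialLikelihood

__all__ = [
    "PenalizedConfig",
    "CoxElasticNet",
    "PenalizedCoxResults",
    "compute_lambda_path",
    "fit_coxenet",
    "fit_coxlasso",
    "select_lambda",
    "penalized_objective",
]


@dataclass
class PenalizedConfig:
    """Settings for the elastic-net path and its subsampling-based tuning."""

    alpha: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    lambda_grid: np.ndarray | None = None
    tuning: str = "subsample_cindex"  # or "subsample_deviance"
    n_subsample: int = 20
    subsample_train_frac: float = 0.8
    penalize_clinical: bool = False
    ties: str = "efron"
    max_outer: int = 100
    cd_tol: float = 1e-6
    max_sweeps: int = 2000
    path_sweep_budget: int = 500

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.tuning not in ("subsample_cindex", "subsample_deviance"):
            raise ValueError(f"unknown tuning criterion {self.tuning!r}")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if np.any(np.diff(grid) >= 0) or np.any(grid <= 0):
                raise ValueError("lambda_grid must be strictly decreasing and positive")
            self.lambda_grid = grid


def penalized_objective(ds: SurvivalDataset, a, b, lambda_, alpha,
                        penalize_clinical=False, ties="efron") -> float:
    """The elastic-net Cox objective Q(a, b) being maximized (see module
    docstring); exposed for optimality probes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pl = PartialLikelihood(ds.times, ds.status, ties)
    eta = ds.X @ a + ds.G @ b
    pen = alpha * np.abs(b).sum() + 0.5 * (1 - alpha) * (b**2).sum()
    if penalize_clinical:
        pen += alpha * np.abs(a).sum() + 0.5 * (1 - alpha) * (a**2).sum()
    return pl.loglik(eta) / ds.n - lambda_ * pen


class PenalizedCoxResults:
    """Fitted elastic-net Cox model at one lambda."""

    def __init__(self, model, a, b, loglik, lambda_, converged, n_iter):
        self.model = model
        self.a = a
        self.b = b
        self.params = np.concatenate([a, b])
        self.loglik = float(loglik)
        self.lambda_ = float(lambda_)
        self.alpha = model.config.alpha
        self.ties_method = model.config.ties
        self.converged = bool(converged)
        self.n_iter = int(n_iter)

    @property
    def n_nonzero_genes(self) -> int:
        return int(np.count_nonzero(self.b))

    @property
    def active_genes(self) -> list[str]:
        return [self.model.ds.gene_ids[j] for j in np.flatnonzero(self.b)]

    def predict_risk(self, X_new, G_new=None, standardizer=None):
        return predict_risk(self, X_new, G_new, standardizer)

    def summary(self):
        import pandas as pd

        act = np.flatnonzero(self.b)
        rows = {name: coef for name, coef in zip(self.model.ds.clinical_names, self.a)}
        rows.update({self.model.ds.gene_ids[j]: self.b[j] for j in act})
        return pd.DataFrame({"coef": pd.Series(rows)}).assign(
            penalized=[False] * len(self.a) + [True] * len(act)
        )


class CoxElasticNet:
    """Elastic-net penalized Cox model (lasso when alpha=1).

    Parameters
    ----------
    ds : standardized SurvivalDataset
    alpha : elastic-net mixing; overrides ``config.alpha`` when given.
    config : PenalizedConfig
    """

    def __init__(self, ds: SurvivalDataset, alpha: float | None = None,
                 config: PenalizedConfig | None = None):
        if not (ds.standardized or ds.metadata.get("standardized_parent")):
            warnings.warn("penalized Cox expects a standardized dataset")
        self.ds = ds
        self.config = config or PenalizedConfig()
        if alpha is not None:
            self.config = PenalizedConfig(**{**self.config.__dict__, "alpha": alpha})
        self._W = np.ascontiguousarray(np.hstack([ds.X, ds.G]))
        self._pen = np.concatenate([
            np.full(ds.p, self.config.penalize_clinical, dtype=bool),
            np.ones(ds.m, dtype=bool),
        ])
        self._pl = PartialLikelihood(ds.times, ds.status, self.config.ties)
        self._null_fit = None

    # -- path construction ----------------------------------------------------
    def null_fit(self):
        """Clinical-only fit defining the start of the path."""
        if self._null_fit is None:
            self._null_fit = fit_cox(self.ds, use_genes=False, ties=self.config.ties)
        return self._null_fit

    def lambda_max(self) -> float:
        """Smallest lambda at which all penalized coefficients are zero:
        the max absolute gradient of (1/n)pl over penalized coordinates at
        the null (clinical-only) fit, divided by alpha."""
        cfg = self.config
        if cfg.penalize_clinical:
            eta = np.zeros(self.ds.n)
        else:
            eta = self.ds.X @ self.null_fit().a
        _, grad_eta = self._pl.loglik_grad(eta)
        g = self._W[:, self._pen].T @ grad_eta / self.ds.n
        gmax = np.max(np.abs(g))
        if gmax <= 0:
            raise ValueError("all-zero penalized gradient: no signal and no path")
        return float(gmax / cfg.alpha)

    def lambda_path(self) -> np.ndarray:
        cfg = self.config
        if cfg.lambda_grid is not None:
            return cfg.lambda_grid
        lmax = self.lambda_max()
        return np.geomspace(lmax, lmax * cfg.lambda_min_ratio, cfg.n_lambda)

    # -- single-lambda fit ----------------------------------------------------
    def _irls_fit(self, lambda_: float, beta0: np.ndarray | None = None,
                  sweep_budget: int | None = None):
        """Returns (beta, converged, n_outer, diverged). Divergence means the
        linear predictor ran away (separation at a too-small lambda); the
        last stable iterate is returned. ``sweep_budget`` caps the total
        coordinate-descent sweeps across outer iterations (used by warm-
        started path fits, where solutions deep in the saturated region need
        not be polished)."""
        cfg = self.config
        W, pen, pl = self._W, self._pen, self._pl
        beta = np.zeros(W.shape[1]) if beta0 is None else beta0.copy()
        n_outer = 0
        converged = False
        diverged = False

        def _objective(e, b):
            pen_val = cfg.alpha * np.abs(b[pen]).sum() + 0.5 * (1 - cfg.alpha) * (b[pen] ** 2).sum()
            return pl.loglik(e) / self.ds.n - lambda_ * pen_val

        obj = None
        sweeps_used = 0
        for n_outer in range(1, cfg.max_outer + 1):
            eta = W @ beta
            if not np.isfinite(eta).all() or np.max(np.abs(eta - eta.mean())) > 30:
                diverged = True
                beta = beta_old  # noqa: F821 — divergence cannot happen at iter 1
                break
            grad, w = pl.weights(eta)
            wsafe = np.maximum(w, 1e-10)
            z = eta + grad / wsafe
            beta_old = beta.copy()
            sweeps_used += cd_solve(W, wsafe, z, beta, pen, lambda_, cfg.alpha,
                                    cfg.cd_tol, cfg.max_sweeps)
            if not np.isfinite(beta).all() or np.max(np.abs(beta)) > 1e3:
                diverged = True
                beta = beta_old
                break
            if np.max(np.abs(beta - beta_old)) < cfg.cd_tol:
                converged = True
                break
            if sweep_budget is not None:
                if sweeps_used >= sweep_budget:
                    break
                # near saturation the objective flattens long before the
                # coefficients settle; within a budgeted path fit, stop once
                # improvement is negligible
                new_obj = _objective(W @ beta, beta)
                if obj is not None and abs(new_obj - obj) < 1e-9 * (1 + abs(new_obj)):
                    converged = True
                    break
                obj = new_obj
        return beta, converged, n_outer, diverged

    def fit(self, lambda_: float | None = None, seed: int | None = None,
            beta0: np.ndarray | None = None) -> PenalizedCoxResults:
        """Fit at a given lambda, or — when ``lambda_`` is None — at the
        lambda chosen by the subsampling tuner (requires ``seed``)."""
        if lambda_ is None:
            lambda_, _ = self.select_lambda(seed=0 if seed is None else seed)
        if lambda_ < 0:
            raise ValueError("lambda must be nonnegative")
        beta, converged, n_outer, diverged = self._irls_fit(float(lambda_), beta0)
        p = self.ds.p
        ll = self._pl.loglik(self._W @ beta)
        if diverged:
            warnings.warn("penalized fit diverged (separation at small lambda); "
                          "returning the last stable iterate")
        elif not converged:
            warnings.warn("coordinate-descent outer loop hit iteration cap")
        return PenalizedCoxResults(self, beta[:p], beta[p:], ll, lambda_, converged, n_outer)

    # -- path + tuning ---------------------------------------------------------
    def fit_path(self, lambdas: np.ndarray | None = None, dev_ratio_cap: float = 0.99):
        """Warm-started fits down the lambda grid.

        Returns (lambdas, coefs) with coefs of shape (n_lambda, p + m). The
        path stops early once the fraction of null (clinical-only) deviance
        explained exceeds ``dev_ratio_cap`` or the fit diverges (separation);
        remaining rows repeat the last stable solution.
        """
        lambdas = self.lambda_path() if lambdas is None else np.asarray(lambdas, float)
        q = self._W.shape[1]
        coefs = np.zeros((len(lambdas), q))
        beta = np.zeros(q)
        ll_null = self.null_fit().loglik if not self.config.penalize_clinical \
            else self._pl.loglik(np.zeros(self.ds.n))
        for i, lam in enumerate(lambdas):
            beta, _, _, diverged = self._irls_fit(float(lam), beta,
                                                  sweep_budget=self.config.path_sweep_budget)
            coefs[i:] = beta  # repeated if the loop stops below
            if diverged:
                break
            if ll_null < 0:
                frac_dev = (self._pl.loglik(self._W @ beta) - ll_null) / (0.0 - ll_null)
                if frac_dev > dev_ratio_cap:
                    break
        return lambdas, coefs

    def select_lambda(self, seed: int):
        """Subsampling tuner: ``n_subsample`` random splits, score the path on
        each held-out part, return (lambda_opt, diagnostics DataFrame)."""
        import pandas as pd

        from ..evaluation import c_index

        cfg = self.config
        ds = self.ds
        if ds.n < 40:
            raise ValueError("subsampling tuner needs at least 40 samples")
        lambdas = self.lambda_path()
        rng = np.random.default_rng(seed)
        scores = np.full((cfg.n_subsample, len(lambdas)), np.nan)
        n_train = int(round(cfg.subsample_train_frac * ds.n))
        n_redrawn = 0
        for rep in range(cfg.n_subsample):
            for _attempt in range(11):
                perm = rng.permutation(ds.n)
                tr, te = perm[:n_train], perm[n_train:]
                if ds.status[te].sum() >= 2:
                    break
                n_redrawn += 1
            else:
                raise RuntimeError("could not draw a test fold with >= 2 events")
            sub = CoxElasticNet(ds.subset(tr), config=cfg)
            _, coefs = sub.fit_path(lambdas)
            W_te = np.hstack([ds.X[te], ds.G[te]])
            etas = W_te @ coefs.T
            for i in range(len(lambdas)):
                if cfg.tuning == "subsample_cindex":
                    scores[rep, i] = c_index(ds.times[te], ds.status[te], etas[:, i])
                else:
                    pl_te = PartialLikelihood(ds.times[te], ds.status[te], cfg.ties)
                    scores[rep, i] = -(-2.0 * pl_te.loglik(etas[:, i]))  # -deviance
        mean = scores.mean(axis=0)
        sd = scores.std(axis=0, ddof=1)
        best = int(np.argmax(mean))
        diagnostics = pd.DataFrame({"lambda": lambdas, "mean_score": mean, "sd_score": sd})
        diagnostics.attrs["criterion"] = cfg.tuning
        diagnostics.attrs["n_redrawn"] = n_redrawn
        return float(lambdas[best]), diagnostics


# -- functional wrappers -------------------------------------------------------

def compute_lambda_path(ds: SurvivalDataset, config: PenalizedConfig | None = None):
    return CoxElasticNet(ds, config=config).lambda_path()


def fit_coxenet(ds: SurvivalDataset, lambda_: float | None = None,
                config: PenalizedConfig | None = None, seed: int | None = None):
    """Elastic-net Cox fit (alpha = 0.5 by default)."""
    return CoxElasticNet(ds, config=config).fit(lambda_, seed=seed)


def fit_coxlasso(ds: SurvivalDataset, lambda_: float | None = None,
                 config: PenalizedConfig | None = None, seed: int | None = None):
    """Lasso Cox fit (alpha = 1)."""
    cfg = config or PenalizedConfig(alpha=1.0)
    return CoxElasticNet(ds, config=cfg).fit(lambda_, seed=seed)


def select_lambda(ds: SurvivalDataset, config: PenalizedConfig | None = None, seed: int = 0):
    return CoxElasticNet(ds, config=config).select_lambda(seed)
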