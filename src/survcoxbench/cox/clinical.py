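"""Unpenalized Cox proportional-hazards model and univariate gene screening.

The clinical-only Cox model ``h(t|X) = h0(t) exp(X'a)`` is the benchmark all
gene-expression models are compared against. Fitting is safeguarded
Newton-Raphson on the log partial likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..datasets import SurvivalDataset, Standardizer
from .likelihood import PartialLikelihood, breslow_cumulative_hazard, fit_newton

__all__ = [
    "BaselineHazard",
    "CoxPH",
    "CoxPHResults",
    "fit_cox",
    "predict_risk",
    "univariate_gene_pvalues",
]


@dataclass
class BaselineHazard:
    """Breslow cumulative baseline hazard: a nondecreasing step function over
    the distinct event times."""

    event_times: np.ndarray
    cumulative_hazard: np.ndarray

    def __post_init__(self):
        assert np.all(np.diff(self.event_times) > 0)
        assert np.all(np.diff(self.cumulative_hazard) >= 0)
        assert self.cumulative_hazard[0] >= 0

    def at(self, t):
        """H0(t), right-continuous step interpolation."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="right")
        H = np.concatenate(([0.0], self.cumulative_hazard))
        return H[idx]


def predict_risk(fit, X_new, G_new=None, standardizer: Standardizer | None = None):
    """Linear-predictor risk scores X a + G b on the training scale.

    If a :class:`Standardizer` learned on the training data is given, raw
    new rows are centered/scaled with the *training* means and scales first.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    b = np.asarray(fit.b, dtype=float)
    if G_new is None:
        if b.size and np.any(b != 0):
            raise ValueError("fit has nonzero gene effects but G_new not supplied")
        G_new = np.zeros((X_new.shape[0], b.size))
    G_new = np.atleast_2d(np.asarray(G_new, dtype=float))
    if standardizer is not None:
        X_new, G_new = standardizer.apply(X_new, G_new)
    a = np.asarray(fit.a, dtype=float)
    if X_new.shape[1] != a.size:
        raise ValueError(f"X_new has {X_new.shape[1]} columns, fit expects {a.size}")
    if G_new.shape[1] != b.size:
        raise ValueError(f"G_new has {G_new.shape[1]} columns, fit expects {b.size}")
    return X_new @ a + (G_new @ b if b.size else 0.0)


class CoxPHResults:
    """Fitted unpenalized Cox model.

    Attributes mirror the shared fit contract: ``a`` clinical effects, ``b``
    gene effects (zeros unless genes were included in the design), ``loglik``
    the maximized log partial likelihood.
    """

    def __init__(self, model, beta, loglik, neg_hessian, converged, n_iter, message=""):
        self.model = model
        p = model.ds.p
        self.a = beta[:p]
        self.b = beta[p:] if model.use_genes else np.zeros(model.ds.m)
        self.params = beta
        self.loglik = float(loglik)
        self.ties_method = model.ties
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.message = message
        self.lambda_ = 0.0
        self.alpha = 0.0
        self._neg_hessian = neg_hessian

    @property
    def cov_params(self):
        return np.linalg.inv(self._neg_hessian)

    @property
    def bse(self):
        return np.sqrt(np.diag(self.cov_params))

    @property
    def zvalues(self):
        return self.params / self.bse

    @property
    def pvalues(self):
        return 2 * stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self, level: float = 0.95):
        z = stats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def baseline_hazard(self) -> BaselineHazard:
        if not self.converged:
            raise RuntimeError("baseline hazard requires a converged fit")
        ds = self.model.ds
        eta = self.predict_risk(ds.X, ds.G if self.model.use_genes else None)
        t, H = breslow_cumulative_hazard(eta, ds.times, ds.status)
        return BaselineHazard(t, H)

    def predict_risk(self, X_new, G_new=None, standardizer=None):
        return predict_risk(self, X_new, G_new, standardizer)

    def summary(self):
        import pandas as pd

        names = list(self.model.ds.clinical_names)
        if self.model.use_genes:
            names += list(self.model.ds.gene_ids)
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "exp(coef)": np.exp(self.params),
                "se(coef)": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
                "ci95_low": ci[:, 0],
                "ci95_high": ci[:, 1],
            },
            index=names,
        )


class CoxPH:
    """Cox proportional-hazards model on clinical covariates (optionally with
    a small set of gene columns in the design, for oracle comparisons).

    Parameters
    ----------
    ds : SurvivalDataset
    use_genes : include ``ds.G`` columns as ordinary covariates.
    ties : {"efron", "breslow"}
    """

    def __init__(self, ds: SurvivalDataset, use_genes: bool = False, ties: str = "efron"):
        if ds.n_events == 0:
            raise ValueError("no events in dataset; Cox model cannot be fitted")
        q = ds.p + (ds.m if use_genes else 0)
        if ds.n <= q:
            raise ValueError(f"need n > number of covariates ({ds.n} <= {q})")
        self.ds = ds
        self.use_genes = use_genes
        self.ties = ties

    @property
    def design(self):
        return np.hstack([self.ds.X, self.ds.G]) if self.use_genes else self.ds.X

    def fit(self, tol: float = 1e-8, max_iter: int = 50) -> CoxPHResults:
        res = fit_newton(self.design, self.ds.times, self.ds.status, ties=self.ties,
                         tol=tol, max_iter=max_iter)
        if not res.converged:
            warnings.warn(f"Cox fit did not converge: {res.message or 'iteration cap reached'}")
        return CoxPHResults(self, res.beta, res.loglik, res.neg_hessian,
                            res.converged, res.n_iter, res.message)


def fit_cox(ds: SurvivalDataset, use_genes: bool = False, ties: str = "efron") -> CoxPHResults:
    """Functional wrapper around :class:`CoxPH`."""
    return CoxPH(ds, use_genes=use_genes, ties=ties).fit()


def univariate_gene_pvalues(
    ds: SurvivalDataset,
    ties: str = "efron",
    adjust_clinical: bool = False,
    max_iter: int = 25,
    tol: float = 1e-6,
):
    """Wald p-value of each gene from a Cox model with that gene as the only
    covariate (marginal screening).

    All m single-gene Newton iterations run simultaneously on (n, m) arrays;
    genes whose fit degenerates (zero curvature, divergence) get p = 1 and a
    warning. With ``adjust_clinical`` the screening model additionally
    contains the clinical covariates (slower, per-gene loop).
    """
    if not (ds.standardized or ds.metadata.get("standardized_parent")):
        warnings.warn("screening on unstandardized expressions")
    if adjust_clinical:
        return _adjusted_gene_pvalues(ds, ties, max_iter, tol)

    pl = PartialLikelihood(ds.times, ds.status, ties)
    Gs = ds.G[pl.order]                       # (n, m) sorted by time
    d = pl.d_sorted[:, None]
    ev = pl.is_event_sorted
    n, m = Gs.shape
    beta = np.zeros(m)
    degenerate = np.zeros(m, dtype=bool)

    tied = pl.event_groups[pl.d_g[pl.event_groups] > 1]
    single = pl.event_groups[pl.d_g[pl.event_groups] == 1]
    for _ in range(max_iter):
        es = np.exp(np.clip(Gs * beta, -200, 200))
        gsum = np.add.reduceat(es, pl.starts, axis=0)
        S = np.cumsum(gsum[::-1], axis=0)[::-1]            # (G, m)
        c = np.zeros_like(S)
        e = np.zeros_like(S)
        c[single] = e[single] = 1.0 / S[single]
        if tied.size:
            T = np.add.reduceat(es * ev[:, None], pl.starts, axis=0)
            for g in tied:
                dg = int(pl.d_g[g])
                frac = (np.arange(dg) / dg)[:, None]
                denom = S[g][None, :] - frac * T[g][None, :]
                c[g] = (1.0 / denom).sum(axis=0)
                e[g] = ((1.0 - frac) / denom).sum(axis=0)
        cumc = np.cumsum(c, axis=0)
        A = cumc[pl.grp]
        A[ev] += e[pl.grp[ev]] - c[pl.grp[ev]]
        resid = d - es * A
        grad = (resid * Gs).sum(axis=0)                    # (m,)
        # projected scalar curvature: sum q w^2 - sum_groups m_g^2
        q_w = (es * A) * Gs**2
        P = np.add.reduceat(es * Gs, pl.starts, axis=0)
        M_R = np.cumsum(P[::-1], axis=0)[::-1]
        negH = q_w.sum(axis=0) - ((M_R[single] / S[single]) ** 2).sum(axis=0)
        if tied.size:
            M_T = np.add.reduceat(es * Gs * ev[:, None], pl.starts, axis=0)
            for g in tied:
                dg = int(pl.d_g[g])
                frac = (np.arange(dg) / dg)[:, None]
                denom = S[g][None, :] - frac * T[g][None, :]
                mg = (M_R[g][None, :] - frac * M_T[g][None, :]) / denom
                negH -= (mg**2).sum(axis=0)
        bad = ~np.isfinite(negH) | (negH <= 1e-12)
        degenerate |= bad
        if np.max(np.abs(np.where(bad, 0.0, grad))) < tol:
            break
        step = np.where(bad, 0.0, grad / np.where(bad, 1.0, negH))
        step = np.clip(step, -1.0, 1.0)
        beta = np.clip(beta + step, -50, 50)

    se = np.where(degenerate, np.inf, 1.0 / np.sqrt(np.maximum(negH, 1e-300)))
    z = np.where(degenerate, 0.0, beta / se)
    pvals = 2 * stats.norm.sf(np.abs(z))
    pvals[degenerate] = 1.0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} degenerate univariate gene fits; p set to 1")
    return pvals


def _adjusted_gene_pvalues(ds, ties, max_iter, tol):
    pvals = np.ones(ds.m)
    n_bad = 0
    for j in range(ds.m):
        W = np.hstack([ds.X, ds.G[:, [j]]])
        res = fit_newton(W, ds.times, ds.status, ties=ties, max_iter=max_iter, tol=tol)
        try:
            se = np.sqrt(np.linalg.inv(res.neg_hessian)[-1, -1])
            if res.converged and np.isfinite(se) and se > 0:
                pvals[j] = 2 * stats.norm.sf(abs(res.beta[-1]) / se)
            else:
                n_bad += 1
        except np.linalg.LinAlgError:
            n_bad += 1
    if n_bad:
        warnings.warn(f"{n_bad} degenerate adjusted gene fits; p set to 1")
    return pvals
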