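"""Mixed-effects Cox model: every gene carries a random effect
b_j ~ N(0, sigma_b^2), integrated out by Laplace approximation.

Fitting maximizes the Laplace-approximated integrated log partial likelihood
over the variance component. Because m >> n, the model is fitted in a
low-rank reparameterization: with b ~ N(0, sigma_b^2 I_m), the per-sample
genetic predictor g = G b is N(0, sigma_b^2 G G'). Writing the kernel
K = G G' = U L U' (rank r <= n), set Z = U L^{1/2}; then g = Z z with
z ~ N(0, sigma_b^2 I_r), and the minimal-norm gene effects are recovered as
b = G' U L^{-1/2} z. The prior components of b orthogonal to the rows of G
never touch the likelihood and integrate out exactly, so the m-dimensional
integral reduces to an r-dimensional one with no approximation beyond
Laplace itself.

The interpretable variance scale is the per-sample genetic variance
m * sigma_b^2 (the variance of G'b for one subject with standardized,
uncorrelated expressions); the 1-D outer optimization runs on its log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from ..datasets import SurvivalDataset
from .clinical import predict_risk, fit_cox
from .likelihood import fit_newton

__all__ = [
    "MixedCox",
    "MixedCoxResults",
    "fit_coxlmm",
    "penalized_mode",
    "laplace_marginal_loglik",
]

GENETIC_VARIANCE_BOUNDS = (1e-8, 1e3)  # on the per-sample scale m * sigma_b^2


class MixedCoxResults:
    """Fitted mixed-effects Cox model.

    Attributes
    ----------
    a : clinical fixed effects.
    b_mode : posterior-mode (BLUP-like) gene effects, length m.
    sigma2_b : per-gene variance component.
    genetic_variance : per-sample scale, m * sigma2_b.
    laplace_loglik : Laplace-approximated integrated log partial likelihood
        at the optimum.
    at_boundary : the variance optimum hit a search bound (effectively zero
        or runaway genetic variance).
    """

    def __init__(self, model, a, b_mode, sigma2_b, laplace_loglik,
                 n_iter_outer, converged, at_boundary):
        self.model = model
        self.a = a
        self.b = b_mode          # shared fit contract
        self.b_mode = b_mode
        self.sigma2_b = float(sigma2_b)
        self.genetic_variance = float(sigma2_b * model.ds.m)
        self.laplace_loglik = float(laplace_loglik)
        self.n_iter_outer = int(n_iter_outer)
        self.converged = bool(converged)
        self.at_boundary = bool(at_boundary)

    def predict_risk(self, X_new, G_new=None, standardizer=None):
        return predict_risk(self, X_new, G_new, standardizer)

    def variance_partition(self, **kwargs):
        from ..variance import estimate_partition

        return estimate_partition(self.model.ds, self, **kwargs)

    def summary(self):
        import pandas as pd

        rows = {
            "sigma2_b (per gene)": self.sigma2_b,
            "genetic variance (per sample)": self.genetic_variance,
            "laplace loglik": self.laplace_loglik,
            "outer iterations": self.n_iter_outer,
            "converged": self.converged,
            "variance at search boundary": self.at_boundary,
        }
        clin = pd.Series(dict(zip(self.model.ds.clinical_names, self.a)), name="coef")
        return pd.concat([clin, pd.Series(rows, name="coef")])


class MixedCox:
    """Mixed-effects Cox model ("coxlmm") with random gene effects.

    Parameters
    ----------
    ds : standardized SurvivalDataset with at least 10 events.
    ties : {"efron", "breslow"}
    rank_tol : relative eigenvalue cutoff for the kernel's numerical rank.
    """

    def __init__(self, ds: SurvivalDataset, ties: str = "efron", rank_tol: float = 1e-10):
        if not (ds.standardized or ds.metadata.get("standardized_parent")):
            warnings.warn("mixed Cox expects a standardized dataset")
        self.ds = ds
        self.ties = ties
        K = ds.G @ ds.G.T
        evals, evecs = np.linalg.eigh(K)
        keep = evals > rank_tol * max(evals.max(), 1.0)
        self._evals = evals[keep]             # (r,)
        self._evecs = evecs[:, keep]          # (n, r)
        self.rank = int(keep.sum())
        self._Z = self._evecs * np.sqrt(self._evals)   # (n, r)
        self._W = np.hstack([ds.X, self._Z])
        self._warm = None

    # -- inner problem ---------------------------------------------------------
    def penalized_mode(self, sigma2_b: float, warm=True):
        """Joint maximizer of pl(Xa + Gb) - b'b/(2 sigma2_b) over (a, b),
        computed in the low-rank space.

        Returns (a, b_mode, inner_loglik, newton_result) where inner_loglik
        is the unpenalized log partial likelihood at the mode.
        """
        if sigma2_b < 0:
            raise ValueError("sigma2_b must be nonnegative")
        ds, p, r = self.ds, self.ds.p, self.rank
        if sigma2_b == 0:
            base = fit_cox(ds, ties=self.ties)
            return base.a, np.zeros(ds.m), base.loglik, None
        ridge = np.concatenate([np.zeros(p), np.full(r, 1.0 / sigma2_b)])
        beta0 = self._warm if (warm and self._warm is not None) else None
        res = fit_newton(self._W, ds.times, ds.status, ties=self.ties,
                         ridge=ridge, beta0=beta0, coef_cap=1e6)
        if warm:
            self._warm = res.beta.copy()
        a, z = res.beta[:p], res.beta[p:]
        b_mode = ds.G.T @ (self._evecs @ (z / np.sqrt(self._evals)))
        return a, b_mode, res.loglik, res

    def laplace_marginal_loglik(self, sigma2_b: float, warm=True) -> float:
        """Laplace approximation to the log integrated partial likelihood:
        penalized objective at the mode minus half the log-determinant of
        the scaled curvature in the random-effect space."""
        if sigma2_b == 0:
            return fit_cox(self.ds, ties=self.ties).loglik
        a, _, _, res = self.penalized_mode(sigma2_b, warm=warm)
        p, r = self.ds.p, self.rank
        z = res.beta[p:]
        # res.neg_hessian already includes the ridge: H_zz + I/sigma2
        Hzz = res.neg_hessian[p:, p:]
        sign, logdet = np.linalg.slogdet(Hzz)
        if sign <= 0:
            raise FloatingPointError("non-positive-definite curvature in Laplace correction")
        return (res.loglik - float(z @ z) / (2 * sigma2_b)
                - 0.5 * r * np.log(sigma2_b) - 0.5 * logdet)

    # -- outer optimization ----------------------------------------------------
    def fit(self, xatol: float = 1e-4) -> MixedCoxResults:
        """Maximize the Laplace marginal over log genetic variance (Brent,
        bounded), then assemble the fit at the optimum."""
        ds = self.ds
        if ds.n_events < 10:
            raise ValueError("mixed Cox fit needs at least 10 events")
        m = ds.m
        lo, hi = np.log(GENETIC_VARIANCE_BOUNDS[0]), np.log(GENETIC_VARIANCE_BOUNDS[1])
        self._warm = None
        n_eval = 0

        def neg_laplace(logv):
            nonlocal n_eval
            n_eval += 1
            return -self.laplace_marginal_loglik(np.exp(logv) / m)

        opt = minimize_scalar(neg_laplace, bounds=(lo, hi), method="bounded",
                              options={"xatol": xatol})
        logv = float(opt.x)
        at_boundary = logv - lo < 10 * xatol or hi - logv < 10 * xatol
        if at_boundary:
            # compare against the effective-zero end before accepting
            if neg_laplace(lo) <= opt.fun:
                logv = lo
        sigma2_b = np.exp(logv) / m
        a, b_mode, _, res = self.penalized_mode(sigma2_b, warm=False)
        converged = bool(opt.success and (res is None or res.converged))
        if not converged:
            warnings.warn("mixed Cox fit did not fully converge")
        return MixedCoxResults(self, a, b_mode, sigma2_b, -float(opt.fun),
                               n_iter_outer=n_eval, converged=converged,
                               at_boundary=at_boundary)


# -- functional wrappers -------------------------------------------------------

def penalized_mode(ds: SurvivalDataset, sigma2_b: float, ties: str = "efron"):
    a, b_mode, ll, _ = MixedCox(ds, ties=ties).penalized_mode(sigma2_b)
    return a, b_mode, ll


def laplace_marginal_loglik(ds: SurvivalDataset, sigma2_b: float, ties: str = "efron") -> float:
    return MixedCox(ds, ties=ties).laplace_marginal_loglik(sigma2_b)


def fit_coxlmm(ds: SurvivalDataset, ties: str = "efron") -> MixedCoxResults:
    return MixedCox(ds, ties=ties).fit()
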