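"""Cox partial-likelihood machinery shared by all models.

Everything here works on the linear-predictor (eta) scale so the same code
serves the clinical-only Newton fit, the coordinate-descent elastic net
(which needs the eta-gradient and the diagonal of the negative Hessian), and
the mixed model (which needs the negative Hessian projected into a low-rank
design ``W``).

Ties are handled by either the Breslow or the Efron correction. With tied
event times of multiplicity d at one time, Breslow uses the full risk-set
denominator d times, while Efron steps the tied events' own contribution out
of the denominator in fractions l/d, l = 0..d-1. The two coincide when no
event times are tied.
"""

from __future__ import annotations

import numpy as np

__all__ = ["PartialLikelihood", "NewtonResult", "fit_newton", "breslow_cumulative_hazard"]


class PartialLikelihood:
    """Precomputed sort/tie structure for one (times, status) sample.

    Parameters
    ----------
    times, status : arrays of length n
    ties : {"efron", "breslow"}
    """

    def __init__(self, times, status, ties: str = "efron"):
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown ties method {ties!r}")
        self.ties = ties
        times = np.asarray(times, dtype=float)
        status = np.asarray(status)
        if times.shape != status.shape:
            raise ValueError("times and status must have equal length")
        if status.sum() == 0:
            raise ValueError("no events observed; partial likelihood undefined")
        self.n = len(times)
        self.order = np.argsort(times, kind="stable")
        self.t_sorted = times[self.order]
        self.d_sorted = status[self.order].astype(float)
        # group boundaries over tied times
        change = np.flatnonzero(np.diff(self.t_sorted) > 0) + 1
        self.starts = np.concatenate(([0], change))                    # (G,)
        self.ends = np.concatenate((change, [self.n]))                 # (G,)
        self.G = len(self.starts)
        self.grp = np.repeat(np.arange(self.G), self.ends - self.starts)  # sorted sample -> group
        self.d_g = np.add.reduceat(self.d_sorted, self.starts)         # events per group
        self.event_groups = np.flatnonzero(self.d_g > 0)
        self.is_event_sorted = self.d_sorted > 0
        self.n_events = int(self.d_sorted.sum())

    # -- helpers --------------------------------------------------------------
    def _sorted_exp(self, eta):
        eta = np.asarray(eta, dtype=float)
        if not np.isfinite(eta).all():
            raise ValueError("non-finite linear predictors")
        es = np.exp(eta[self.order])
        # suffix sums at group starts: S_g = sum over risk set R_g
        group_sums = np.add.reduceat(es, self.starts)
        S = np.cumsum(group_sums[::-1])[::-1]
        return eta, es, S

    def _tied_sums(self, es):
        """Per-group sum of exp(eta) over the tied *events* of the group."""
        return np.add.reduceat(es * self.is_event_sorted, self.starts)

    # -- values ---------------------------------------------------------------
    def loglik(self, eta) -> float:
        eta, es, S = self._sorted_exp(eta)
        ll = float(eta[self.order][self.is_event_sorted].sum())
        if self.ties == "breslow":
            g = self.event_groups
            ll -= float((self.d_g[g] * np.log(S[g])).sum())
        else:
            # groups with a single event coincide with Breslow; loop only
            # over genuinely tied groups
            single = self.event_groups[self.d_g[self.event_groups] == 1]
            ll -= float(np.log(S[single]).sum())
            tied = self.event_groups[self.d_g[self.event_groups] > 1]
            if tied.size:
                T = self._tied_sums(es)
                for g in tied:
                    d = int(self.d_g[g])
                    l = np.arange(d)
                    ll -= float(np.log(S[g] - (l / d) * T[g]).sum())
        return ll

    def _group_coefs(self, es, S):
        """Per-group risk-set coefficients for gradient and diagonal Hessian.

        Returns (c, e, b, f): for each group g,
          c_g = sum_l 1/denom         (weight for plain risk-set members)
          e_g = sum_l (1-l/d)/denom   (weight for the group's tied events)
          b_g = sum_l 1/denom^2
          f_g = sum_l (1-l/d)^2/denom^2
        """
        c = np.zeros(self.G)
        e = np.zeros(self.G)
        b = np.zeros(self.G)
        f = np.zeros(self.G)
        if self.ties == "breslow":
            g = self.event_groups
            c[g] = e[g] = self.d_g[g] / S[g]
            b[g] = f[g] = self.d_g[g] / S[g] ** 2
        else:
            single = self.event_groups[self.d_g[self.event_groups] == 1]
            c[single] = e[single] = 1.0 / S[single]
            b[single] = f[single] = 1.0 / S[single] ** 2
            tied = self.event_groups[self.d_g[self.event_groups] > 1]
            if tied.size:
                T = self._tied_sums(es)
                for g in tied:
                    d = int(self.d_g[g])
                    frac = np.arange(d) / d
                    denom = S[g] - frac * T[g]
                    c[g] = (1.0 / denom).sum()
                    e[g] = ((1.0 - frac) / denom).sum()
                    b[g] = (1.0 / denom**2).sum()
                    f[g] = ((1.0 - frac) ** 2 / denom**2).sum()
        return c, e, b, f

    def loglik_grad(self, eta):
        """Log partial likelihood and its gradient with respect to eta
        (original sample order)."""
        eta, es, S = self._sorted_exp(eta)
        c, e, b, f = self._group_coefs(es, S)
        cumc = np.cumsum(c)
        A = cumc[self.grp].copy()
        ev = self.is_event_sorted
        A[ev] += e[self.grp[ev]] - c[self.grp[ev]]
        g_sorted = self.d_sorted - es * A
        grad = np.empty(self.n)
        grad[self.order] = g_sorted
        return self.loglik(eta), grad

    def weights(self, eta):
        """(gradient wrt eta, diagonal of the negative Hessian wrt eta), both
        in original order — the IRLS quantities for coordinate descent."""
        eta, es, S = self._sorted_exp(eta)
        c, e, b, f = self._group_coefs(es, S)
        cumc, cumb = np.cumsum(c), np.cumsum(b)
        A = cumc[self.grp].copy()
        B = cumb[self.grp].copy()
        ev = self.is_event_sorted
        gev = self.grp[ev]
        A[ev] += e[gev] - c[gev]
        B[ev] += f[gev] - b[gev]
        g_sorted = self.d_sorted - es * A
        w_sorted = es * A - es**2 * B
        grad = np.empty(self.n)
        w = np.empty(self.n)
        grad[self.order] = g_sorted
        w[self.order] = np.maximum(w_sorted, 0.0)
        return grad, w

    def loglik_grad_hess(self, eta, W):
        """Value, gradient and negative Hessian of the log partial likelihood
        as a function of beta where eta = W @ beta.

        Returns (loglik, grad (q,), neg_hessian (q, q)). The full n x n
        Hessian is never materialized; the projection is accumulated from
        per-risk-set rank-one terms, so cost scales with events x q^2.
        """
        W = np.asarray(W, dtype=float)
        eta, es, S = self._sorted_exp(eta)
        c, e, b, f = self._group_coefs(es, S)
        cumc = np.cumsum(c)
        A = cumc[self.grp].copy()
        ev = self.is_event_sorted
        A[ev] += e[self.grp[ev]] - c[self.grp[ev]]
        g_sorted = self.d_sorted - es * A
        grad_eta = np.empty(self.n)
        grad_eta[self.order] = g_sorted
        grad = W.T @ grad_eta

        Ws = W[self.order]
        P = Ws * es[:, None]                                     # (n, q)
        group_P = np.add.reduceat(P, self.starts, axis=0)        # (G, q)
        M_R = np.cumsum(group_P[::-1], axis=0)[::-1]             # suffix sums
        q_sorted = es * A
        H = (Ws * q_sorted[:, None]).T @ Ws
        if self.ties == "breslow":
            g = self.event_groups
            Mn = M_R[g] / S[g, None] * np.sqrt(self.d_g[g])[:, None]
            H -= Mn.T @ Mn
        else:
            single = self.event_groups[self.d_g[self.event_groups] == 1]
            Mn = M_R[single] / S[single, None]
            H -= Mn.T @ Mn
            tied = self.event_groups[self.d_g[self.event_groups] > 1]
            if tied.size:
                T = self._tied_sums(es)
                M_T = np.add.reduceat(P * ev[:, None], self.starts, axis=0)
                for g in tied:
                    d = int(self.d_g[g])
                    for l in range(d):
                        denom = S[g] - (l / d) * T[g]
                        m = (M_R[g] - (l / d) * M_T[g]) / denom
                        H -= np.outer(m, m)
        return self.loglik(eta), grad, H


class NewtonResult:
    """Raw output of the safeguarded Newton maximizer."""

    def __init__(self, beta, loglik, grad, neg_hessian, converged, n_iter, message=""):
        self.beta = beta
        self.loglik = loglik
        self.grad = grad
        self.neg_hessian = neg_hessian
        self.converged = converged
        self.n_iter = n_iter
        self.message = message


def _solve_pd(H, g):
    """Solve H x = g for symmetric positive-definite H, adding jitter on
    failure (near-singular curvature from separation or collinearity)."""
    from scipy.linalg import cho_factor, cho_solve

    jitter = 0.0
    for _ in range(6):
        try:
            cf = cho_factor(H + jitter * np.eye(H.shape[0]), lower=True)
            return cho_solve(cf, g)
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-8 * max(np.trace(H) / H.shape[0], 1.0))
    return np.linalg.lstsq(H, g, rcond=None)[0]


def fit_newton(
    W,
    times,
    status,
    ties: str = "efron",
    ridge=None,
    beta0=None,
    tol: float = 1e-8,
    max_iter: int = 50,
    coef_cap: float = 50.0,
) -> NewtonResult:
    """Maximize ``pl(W beta) - 0.5 * sum_j ridge_j beta_j^2`` by safeguarded
    Newton-Raphson with step-halving.

    ``ridge`` is an optional per-coordinate quadratic penalty (used by the
    mixed model's penalized mode); convergence is max-norm of the penalized
    gradient below ``tol``. Coefficients exceeding ``coef_cap`` in absolute
    value flag monotone-likelihood divergence.
    """
    W = np.asarray(W, dtype=float)
    n, q = W.shape
    pl = PartialLikelihood(times, status, ties)
    beta = np.zeros(q) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    r = np.zeros(q) if ridge is None else np.asarray(ridge, dtype=float)

    def objective(b):
        return pl.loglik(W @ b) - 0.5 * float(r @ b**2)

    ll, grad, H = pl.loglik_grad_hess(W @ beta, W)
    obj = ll - 0.5 * float(r @ beta**2)
    grad = grad - r * beta
    Hp = H + np.diag(r) if ridge is not None else H
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            it -= 1
            break
        step = _solve_pd(Hp, grad)
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            cand_obj = objective(cand)
            if np.isfinite(cand_obj) and cand_obj > obj - 1e-12:
                break
            alpha /= 2.0
        else:
            message = "step-halving failed to improve the objective"
            break
        beta = cand
        obj = cand_obj
        ll, grad, H = pl.loglik_grad_hess(W @ beta, W)
        grad = grad - r * beta
        Hp = H + np.diag(r) if ridge is not None else H
        if np.max(np.abs(beta)) > coef_cap:
            message = "coefficient cap exceeded: likely monotone likelihood"
            break
    else:
        it = max_iter
    if not converged and np.max(np.abs(grad)) < tol:
        converged = True
    return NewtonResult(beta, pl.loglik(W @ beta), grad, Hp, converged, it, message)


def breslow_cumulative_hazard(eta, times, status):
    """Breslow step estimator of the cumulative baseline hazard.

    Returns (event_times, cumulative_hazard): at each distinct event time,
    H0 increments by d_g / sum_{risk set} exp(eta).
    """
    pl = PartialLikelihood(times, status, "breslow")
    _, es, S = pl._sorted_exp(np.asarray(eta, dtype=float))
    g = pl.event_groups
    increments = pl.d_g[g] / S[g]
    return pl.t_sorted[pl.starts[g]], np.cumsum(increments)
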