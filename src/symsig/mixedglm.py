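"""Logistic mixed-effects regression via the Laplace approximation.

Fits Bernoulli responses with logit link, fixed effects X b, and independent
gaussian random-effect blocks u_k ~ N(0, tau_k^2 I) (variance-components
parameterisation: crossed random intercepts and slopes, no correlations):

    y_i ~ Bernoulli( logistic( x_i' b + z_i' u ) ).

For fixed tau the mode (b_hat, u_hat) of the penalised log-likelihood is
found by damped Newton iterations (penalised IRLS); the marginal likelihood
is then approximated by Laplace's method,

    l(tau) ~= l_cond(b_hat, u_hat) - u_hat' D^-1 u_hat / 2
              - log det(Z' W Z D + I) / 2,

and maximised over log tau with Nelder-Mead.  This is the approximation
strategy standard GLMM software uses.  Fixed-effect standard errors come
from the b-block of the inverse joint Hessian at the mode; p-values are Wald
(normal).  Everything is deterministic given the data.

Random-effect design blocks are stored sparse (indicator-times-covariate
columns have one nonzero per row), which keeps each Newton step linear in
the number of observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, sparse, stats

from .errors import NumericalError

_LOGTAU_BOUNDS = (-6.0, 3.0)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log p(y | eta) = y*eta - log(1 + exp(eta)), computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


@dataclass
class LogisticMixedResult:
    """Converged fit: fixed effects with Wald inference plus RE variances."""

    beta: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    tau: np.ndarray  # random-effect SDs per block
    u: np.ndarray
    loglik: float
    converged: bool
    n_obs: int


class LogisticMixedModel:
    """Bernoulli GLMM with independent variance-component blocks.

    Parameters
    ----------
    y : binary response (n,)
    X : fixed-effects design (n, p), including the intercept column
    z_blocks : list of (name, Z_k) random-effect design blocks; each column of
        Z_k gets an i.i.d. N(0, tau_k^2) coefficient.  May be empty, in which
        case the model is plain logistic regression.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, z_blocks: list[tuple[str, np.ndarray]]):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.names = [n for n, _ in z_blocks]
        self._block_sizes = [np.asarray(Z).shape[1] for _, Z in z_blocks]
        self.Zs = [sparse.csr_matrix(np.asarray(Z, dtype=float)) for _, Z in z_blocks]
        self.Z = sparse.hstack(self.Zs, format="csr") if self.Zs else sparse.csr_matrix((len(self.y), 0))
        n, self.p = self.X.shape
        self.q = self.Z.shape[1]
        if len(self.y) != n:
            raise ValueError("y and X have incompatible shapes")
        self._w_cache: np.ndarray | None = None  # warm start across outer evaluations

    def _dinv(self, tau: np.ndarray) -> np.ndarray:
        return np.repeat(1.0 / np.maximum(tau, 1e-8) ** 2, self._block_sizes)

    def _eta(self, w: np.ndarray) -> np.ndarray:
        return self.X @ w[: self.p] + (self.Z @ w[self.p :] if self.q else 0.0)

    def _hessian(self, wt: np.ndarray, pen: np.ndarray) -> np.ndarray:
        """Joint negative Hessian [[X'WX, X'WZ], [Z'WX, Z'WZ]] + diag(pen)."""
        H = np.empty((self.p + self.q, self.p + self.q))
        XW = self.X * wt[:, None]
        H[: self.p, : self.p] = XW.T @ self.X
        if self.q:
            XWZ = self.Z.T.dot(XW).T  # (p, q)
            H[: self.p, self.p :] = XWZ
            H[self.p :, : self.p] = XWZ.T
            WZ = self.Z.multiply(wt[:, None])
            H[self.p :, self.p :] = (self.Z.T @ WZ).toarray()
        H[np.diag_indices_from(H)] += pen
        return H

    def _inner_mode(
        self, tau: np.ndarray, w0: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """Penalised Newton for (beta, u) at fixed tau.

        Returns (w, H, penalised loglik) at the mode, where w = [beta, u] and
        H is the negative joint Hessian there.
        """
        dinv = self._dinv(tau)
        pen = np.concatenate([np.zeros(self.p), dinv])
        w = np.zeros(self.p + self.q) if w0 is None else w0.copy()

        def objective(w: np.ndarray) -> float:
            return _bernoulli_loglik(self.y, self._eta(w)) - 0.5 * float((pen * w * w).sum())

        f = objective(w)
        H = None
        for _ in range(100):
            eta = self._eta(w)
            mu = _sigmoid(eta)
            resid = self.y - mu
            g = np.concatenate([self.X.T @ resid, self.Z.T @ resid if self.q else np.zeros(0)])
            g -= pen * w
            wt = np.maximum(mu * (1 - mu), 1e-10)
            H = self._hessian(wt, pen)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError as exc:
                raise NumericalError(f"singular Hessian in penalised IRLS: {exc}") from exc
            # damped Newton: halve until the objective improves
            t = 1.0
            f_new = f
            for _ in range(30):
                w_new = w + t * step
                f_new = objective(w_new)
                if f_new >= f - 1e-12:
                    break
                t /= 2.0
            if not np.isfinite(f_new):
                raise NumericalError("divergent penalised IRLS")
            done = abs(f_new - f) < 1e-10 * (1 + abs(f)) and float(np.abs(g).max()) < 1e-6
            w, f = w_new, f_new
            if done:
                break
        return w, H, f

    def _laplace_negll(self, log_tau: np.ndarray) -> float:
        tau = np.exp(np.clip(log_tau, *_LOGTAU_BOUNDS))
        w, H, _ = self._inner_mode(tau, self._w_cache)
        self._w_cache = w
        u = w[self.p :]
        dinv = self._dinv(tau)
        # log det(Z'WZ D + I) = log det(H_uu) + log det(D), H_uu = Z'WZ + D^-1
        H_uu = H[self.p :, self.p :]
        sign, logdet_huu = np.linalg.slogdet(H_uu)
        if sign <= 0:
            return np.inf
        logdet = logdet_huu - float(np.log(dinv).sum())
        ll = (
            _bernoulli_loglik(self.y, self._eta(w))
            - 0.5 * float(dinv @ (u * u))
            - 0.5 * logdet
        )
        return -ll

    def fit(self, start_log_tau: np.ndarray | None = None) -> LogisticMixedResult:
        if self.q == 0:
            w, H, _ = self._inner_mode(np.zeros(0))
            tau = np.zeros(0)
            ll = _bernoulli_loglik(self.y, self.X @ w)
            outer_ok = True
        else:
            x0 = (
                np.zeros(len(self.Zs))  # log tau = 0, i.e. unit SDs
                if start_log_tau is None
                else np.clip(np.asarray(start_log_tau, dtype=float), *_LOGTAU_BOUNDS)
            )
            self._w_cache = None
            res = optimize.minimize(
                self._laplace_negll,
                x0,
                method="Nelder-Mead",
                options={"xatol": 2e-3, "fatol": 1e-6, "maxiter": 400},
            )
            log_tau = np.clip(res.x, *_LOGTAU_BOUNDS)
            tau = np.exp(log_tau)
            ll = -self._laplace_negll(log_tau)
            w, H, _ = self._inner_mode(tau, self._w_cache)
            outer_ok = bool(res.success) and np.isfinite(ll)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"singular joint Hessian at the optimum: {exc}") from exc
        beta = w[: self.p]
        se = np.sqrt(np.maximum(np.diag(cov)[: self.p], 0.0))
        if not (np.isfinite(se).all() and (se > 0).all()):
            raise NumericalError("non-finite or zero fixed-effect standard errors")
        z = beta / se
        pvals = 2 * stats.norm.sf(np.abs(z))
        return LogisticMixedResult(
            beta=beta,
            se=se,
            zvalues=z,
            pvalues=pvals,
            tau=tau,
            u=w[self.p :],
            loglik=ll,
            converged=outer_ok,
            n_obs=len(self.y),
        )

    def simulate(
        self, beta: np.ndarray, tau: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw a parametric-bootstrap response vector from (beta, tau)."""
        eta = self.X @ np.asarray(beta, dtype=float)
        for t, Z in zip(tau, self.Zs):
            eta = eta + Z @ rng.normal(scale=max(float(t), 0.0), size=Z.shape[1])
        return (rng.random(len(self.y)) < _sigmoid(eta)).astype(float)
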