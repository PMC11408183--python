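"""Zero-inflated Poisson GLMM engine (Laplace approximation).

Model
-----
Counts ``y_i`` follow a zero-inflated Poisson mixture:

    P(y_i = 0)     = pi_i + (1 - pi_i) * exp(-lam_i)
    P(y_i = k > 0) = (1 - pi_i) * lam_i^k * exp(-lam_i) / k!

with a log link on the count (conditional) mean and a logit link on
the structural-zero probability:

    log lam_i  = x_i' beta + z_i' b,   b ~ N(0, D)
    logit pi_i = x_zi' gamma

``b`` stacks independent Gaussian random intercepts, one block per
grouping factor (e.g. subject, song owner, subject x owner pair), with
one variance per factor; the zero-inflation part contains fixed
effects only. Random effects are integrated out by the Laplace
approximation: with ``g(b)`` the joint log density of (y, b),

    log L(theta) ~= g(b_hat) + (q/2) log 2pi - 0.5 log det H,

where ``b_hat`` maximizes ``g`` (found by damped Newton with a line
search, so ``g`` never decreases across iterations) and
``H = -g''(b_hat) = Z' W Z + D^{-1}`` is sparse. The marginal
likelihood is maximized over ``theta = (beta, gamma, log sd)`` by
L-BFGS-B with finite-difference gradients and warm-started inner
modes; with no random effects the Laplace correction vanishes and the
objective is the exact ZIP log-likelihood. Wald standard errors come
from the numerical Hessian of the approximate marginal
log-likelihood at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve, lu_factor
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.special import expit, gammaln

_ETA_CLIP = 30.0
_LOGSD_BOUNDS = (-7.0, 3.0)
#: below this random-effect dimension, dense Cholesky beats sparse LU
_DENSE_Q = 500


def zip_log_pmf(y: np.ndarray, lam: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Elementwise log P(y) under the zero-inflated Poisson mixture."""
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    pi = np.broadcast_to(np.asarray(pi, dtype=float), y.shape)
    out = np.where(
        y == 0,
        np.log(pi + (1.0 - pi) * np.exp(-lam)),
        np.log1p(-pi) + y * np.log(np.maximum(lam, 1e-300)) - lam - gammaln(y + 1.0),
    )
    return out


def _zip_terms(y, eta, zeta):
    """Log-likelihood and first/second derivatives w.r.t. eta.

    Returns (ll_i, d1_i, w_i) with w_i = -d2 ll_i / d eta_i^2 clamped
    to be positive (Newton weights).
    """
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    lam = np.exp(eta)
    if zeta is None:
        ll = y * eta - lam - gammaln(y + 1.0)
        d1 = y - lam
        w = lam.copy()
        return ll, d1, w
    # clip keeps pi away from exactly 0/1, so log1p(-pi) stays finite
    pi = expit(np.clip(zeta, -_ETA_CLIP, _ETA_CLIP))
    zero = y == 0
    ll = np.empty_like(lam)
    d1 = np.empty_like(lam)
    w = np.empty_like(lam)
    # positive counts: Poisson terms plus log(1 - pi)
    pos = ~zero
    ll[pos] = (np.log1p(-pi[pos]) + y[pos] * eta[pos] - lam[pos]
               - gammaln(y[pos] + 1.0))
    d1[pos] = y[pos] - lam[pos]
    w[pos] = lam[pos]
    # zeros: mixture of structural and sampling zeros
    lz, pz = lam[zero], pi[zero]
    u = (1.0 - pz) * np.exp(-lz)
    p0 = pz + u
    a = u / p0  # P(sampling zero | y=0)
    ll[zero] = np.log(p0)
    d1[zero] = -a * lz
    # true negative second derivative; can itself be negative (the y=0
    # mixture term is locally convex for moderate eta) — callers clip
    # for Newton steps but must use the true value in the Laplace logdet
    w[zero] = a * lz - (lz ** 2) * a * (1.0 - a)
    return ll, d1, w


@dataclass
class RandomStructure:
    """Sparse random-intercept design: one indicator block per factor."""

    factor_names: list[str]
    Z: sparse.csr_matrix | None          # n_obs x q
    block_slices: list[slice]            # columns of Z per factor
    n_levels: list[int]

    @property
    def q(self) -> int:
        return 0 if self.Z is None else self.Z.shape[1]

    @classmethod
    def build(cls, codes: dict[str, np.ndarray]) -> "RandomStructure":
        """``codes`` maps factor name -> integer level codes per observation."""
        names, blocks, slices, levels = [], [], [], []
        start = 0
        for name, code in codes.items():
            n_lev = int(code.max()) + 1 if len(code) else 0
            n = len(code)
            block = sparse.csr_matrix(
                (np.ones(n), (np.arange(n), code)), shape=(n, n_lev))
            names.append(name)
            blocks.append(block)
            slices.append(slice(start, start + n_lev))
            levels.append(n_lev)
            start += n_lev
        Z = sparse.hstack(blocks, format="csr") if blocks else None
        return cls(factor_names=names, Z=Z, block_slices=slices, n_levels=levels)

    def prior_precision(self, sds: np.ndarray) -> np.ndarray:
        """Per-column 1/sigma^2, expanding one sd per factor."""
        prec = np.empty(self.q)
        for sl, sd in zip(self.block_slices, sds):
            prec[sl] = 1.0 / (sd ** 2)
        return prec

    def expand_sds(self, sds: np.ndarray) -> np.ndarray:
        out = np.empty(self.q)
        for sl, sd in zip(self.block_slices, sds):
            out[sl] = sd
        return out


@dataclass
class ZipGlmmProblem:
    """One dataset + design, ready for repeated likelihood evaluation."""

    y: np.ndarray
    X: np.ndarray                     # conditional fixed-effect design
    Xz: np.ndarray | None             # zero-inflation design (None = no ZI)
    rand: RandomStructure
    _b_cache: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_beta(self) -> int:
        return self.X.shape[1]

    @property
    def n_gamma(self) -> int:
        return 0 if self.Xz is None else self.Xz.shape[1]

    @property
    def n_sd(self) -> int:
        return len(self.rand.factor_names)

    @property
    def n_params(self) -> int:
        return self.n_beta + self.n_gamma + self.n_sd

    def unpack(self, theta: np.ndarray):
        p, pz = self.n_beta, self.n_gamma
        beta = theta[:p]
        gamma = theta[p:p + pz] if pz else None
        log_sd = theta[p + pz:]
        return beta, gamma, log_sd

    def pack(self, beta, gamma, log_sd) -> np.ndarray:
        parts = [np.atleast_1d(beta)]
        if gamma is not None:
            parts.append(np.atleast_1d(gamma))
        parts.append(np.atleast_1d(log_sd))
        return np.concatenate(parts) if parts else np.empty(0)

    # ---- inner problem: mode of the joint density over b ----

    def _joint(self, b, eta_fixed, zeta, prec, log_sds):
        """g(b) = log p(y | b) + log p(b)."""
        eta = eta_fixed if b is None else eta_fixed + self.rand.Z @ b
        ll, d1, w = _zip_terms(self.y, eta, zeta)
        g = ll.sum()
        if b is not None:
            g += -0.5 * np.sum(prec * b ** 2) - np.sum(np.log(log_sds)) \
                 - 0.5 * self.rand.q * np.log(2 * np.pi)
        return g, d1, w

    def _inner_mode(self, eta_fixed, zeta, prec, sds_expanded,
                    tol: float = 1e-9, max_iter: int = 100):
        """Damped Newton for b_hat; warm-started across calls."""
        q = self.rand.q
        b = (self._b_cache.copy() if self._b_cache is not None
             and len(self._b_cache) == q else np.zeros(q))
        Z = self.rand.Z
        dense = q <= _DENSE_Q
        g, d1, w = self._joint(b, eta_fixed, zeta, prec, sds_expanded)
        for _ in range(max_iter):
            grad = Z.T @ d1 - prec * b
            if np.max(np.abs(grad)) < tol:
                break
            # clipped weights: keep the Newton system positive definite
            H_newton = self._curvature(np.clip(w, 1e-10, None), prec, dense)
            if dense:
                step = cho_solve(cho_factor(H_newton, lower=True), grad)
            else:
                step = splu(H_newton).solve(grad)
            # line search: g must not decrease
            t = 1.0
            for _ in range(30):
                b_new = b + t * step
                g_new, d1_new, w_new = self._joint(
                    b_new, eta_fixed, zeta, prec, sds_expanded)
                if g_new >= g - 1e-12:
                    break
                t *= 0.5
            if g_new < g - 1e-8:  # no improving step found
                break
            b, g, d1, w = b_new, g_new, d1_new, w_new
        self._b_cache = b.copy()
        # true curvature at the mode for the Laplace determinant
        return b, g, self._curvature(w, prec, dense)

    def _curvature(self, w, prec, dense: bool):
        """Z' diag(w) Z + D^-1, dense or sparse CSC."""
        Z = self.rand.Z
        H = Z.T @ Z.multiply(w[:, None])
        if dense:
            return H.toarray() + np.diag(prec)
        return H.tocsc() + sparse.diags(prec, format="csc")

    @staticmethod
    def _logdet(H) -> float:
        """log |det H| for the (normally PD) curvature at the mode."""
        if sparse.issparse(H):
            return float(np.sum(np.log(np.abs(splu(H).U.diagonal()))))
        try:
            c, _ = cho_factor(H, lower=True)
            return float(2.0 * np.sum(np.log(np.diag(c))))
        except np.linalg.LinAlgError:
            lu, _ = lu_factor(H)
            return float(np.sum(np.log(np.abs(np.diag(lu)))))

    # ---- marginal (Laplace) negative log-likelihood ----

    def nll(self, theta: np.ndarray) -> float:
        beta, gamma, log_sd = self.unpack(theta)
        eta_fixed = self.X @ beta
        zeta = None if self.Xz is None else self.Xz @ gamma
        if self.rand.q == 0:
            ll, _, _ = _zip_terms(self.y, eta_fixed, zeta)
            return -ll.sum()
        sds = np.exp(log_sd)
        prec = self.rand.prior_precision(sds)
        sds_expanded = self.rand.expand_sds(sds)
        try:
            b_hat, g_hat, H = self._inner_mode(eta_fixed, zeta, prec,
                                               sds_expanded)
            logdet = self._logdet(H)
        except np.linalg.LinAlgError:
            # numerically indefinite inner system at an extreme theta
            # proposed by the outer optimizer: penalize and back away
            self._b_cache = None
            return 1e10
        logL = g_hat + 0.5 * self.rand.q * np.log(2 * np.pi) - 0.5 * logdet
        if not np.isfinite(logL):
            return 1e10
        return -logL

    def fit(self, theta0: np.ndarray | None = None, maxiter: int = 300):
        """Maximize the (Laplace) marginal likelihood; returns raw results."""
        if theta0 is None:
            theta0 = self.default_start()
        self._b_cache = None
        bounds = ([(None, None)] * (self.n_beta + self.n_gamma)
                  + [_LOGSD_BOUNDS] * self.n_sd)
        res = minimize(self.nll, theta0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7,
                                "eps": 1e-6})
        return res

    def default_start(self) -> np.ndarray:
        """Moment-based starting values: Poisson-ish beta, zero-rate gamma."""
        y = self.y
        mean_pos = y[y > 0].mean() if (y > 0).any() else 0.5
        beta0 = np.zeros(self.n_beta)
        beta0[0] = np.log(max(mean_pos, 0.1))
        parts = [beta0]
        if self.Xz is not None:
            frac_zero = np.clip((y == 0).mean(), 0.02, 0.98)
            gamma0 = np.zeros(self.n_gamma)
            gamma0[0] = np.log(frac_zero / (1 - frac_zero))
            parts.append(gamma0)
        parts.append(np.full(self.n_sd, np.log(0.3)))
        return np.concatenate(parts)

    def hessian(self, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
        """Central-difference Hessian of the negative log-likelihood."""
        d = len(theta)
        h = rel_step * np.maximum(1.0, np.abs(theta))
        H = np.empty((d, d))
        f0 = self.nll(theta)
        fp = np.empty(d)
        fm = np.empty(d)
        for i in range(d):
            e = np.zeros(d)
            e[i] = h[i]
            fp[i] = self.nll(theta + e)
            fm[i] = self.nll(theta - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(d):
            for j in range(i + 1, d):
                e_i = np.zeros(d); e_i[i] = h[i]
                e_j = np.zeros(d); e_j[j] = h[j]
                fpp = self.nll(theta + e_i + e_j)
                fmm = self.nll(theta - e_i - e_j)
                H[i, j] = H[j, i] = (
                    (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm)
                    / (2 * h[i] * h[j]))
        return H
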