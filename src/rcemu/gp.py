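"""Gaussian-process regression with an explicit linear mean basis.

This is universal kriging with the basis coefficients and the covariance
amplitude profiled out of the marginal likelihood.  The data model for one
scalar output y at inputs x (scaled to the unit box) is

    y ~ N(f, (nu sigma)^2),     f | beta, sigma, theta ~ N(H^T beta, sigma^2 A)

with H the (q x n) matrix of basis vectors h(x_i) = (1, x_i1, .., x_im)^T
and A the ARD squared-exponential kernel matrix

    k(x_i, x_j) = exp(-1/2 sum_k ((x_ik - x_jk)/theta_k)^2).

Writing A_y = A + nu^2 I, the generalized-least-squares profile gives

    beta_hat   = (H A_y^-1 H^T)^-1 H A_y^-1 y
    sigma2_hat = (y - H^T beta_hat)^T A_y^-1 (y - H^T beta_hat) / (n - q)
    L = -1/2 ( log|A_y| + log|H A_y^-1 H^T| + (n - q) log(2 pi sigma2_hat) )

maximized over (log theta, log nu) by multistart L-BFGS-B.  Predictions at
X* follow the universal-kriging mean and covariance, including the
basis-coefficient uncertainty term:

    M = H*^T beta_hat + A*^T A_y^-1 (y - H^T beta_hat)
    V = sigma2_hat ( A** - A*^T A_y^-1 A*
        + (H* - H A_y^-1 A*)^T (H A_y^-1 H^T)^-1 (H* - H A_y^-1 A*) )

The nugget nu is *relative*: the observation variance is (nu sigma)^2, so it
scales with the process amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial.distance import cdist
from scipy.optimize import minimize

__all__ = [
    "GPHyperparams",
    "GaussianProcess",
    "GPFitError",
    "kernel",
    "kernel_matrix",
    "profiled_coefficients",
    "log_marginal_likelihood",
]

_JITTER0 = 1e-10
_JITTER_MAX = 1e-6


class GPFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class GPHyperparams:
    """ARD lengthscales (in unit-box coordinates) and relative nugget."""

    lengthscales: np.ndarray
    nugget: float

    def __post_init__(self):
        ls = np.asarray(self.lengthscales, dtype=float)
        object.__setattr__(self, "lengthscales", ls)
        if not (np.isfinite(ls).all() and (ls > 0).all()):
            raise ValueError("lengthscales must be finite and positive")
        if not (np.isfinite(self.nugget) and self.nugget >= 0):
            raise ValueError("nugget must be finite and >= 0")


def kernel(xi, xj, hyper: GPHyperparams) -> float:
    """Squared-exponential ARD kernel between two points."""
    xi = np.asarray(xi, float)
    xj = np.asarray(xj, float)
    z = (xi - xj) / hyper.lengthscales
    return float(np.exp(-0.5 * np.dot(z, z)))


def kernel_matrix(X1: np.ndarray, X2: np.ndarray, lengthscales: np.ndarray) -> np.ndarray:
    """Kernel cross-matrix, shape (n1, n2).

    Squared distances via cdist (explicit coordinate differences): the
    inner-product expansion loses up to ~10 decimal digits to cancellation
    when lengthscales are small relative to the point spread.
    """
    sq = cdist(X1 / lengthscales, X2 / lengthscales, metric="sqeuclidean")
    return np.exp(-0.5 * sq)


def _basis(X: np.ndarray) -> np.ndarray:
    """Linear basis H, shape (q, n) with q = m + 1: rows (1, x_1, .., x_m)."""
    return np.vstack([np.ones(X.shape[0]), X.T])


@dataclass
class _Factorization:
    cho: tuple                    # Cholesky of A_y (+ jitter)
    H: np.ndarray                 # (q, n)
    G_cho: tuple                  # Cholesky of G = H A_y^-1 H^T
    beta_hat: np.ndarray
    sigma2_hat: float
    alpha: np.ndarray             # A_y^-1 (y - H^T beta_hat)
    AyiHT: np.ndarray             # A_y^-1 H^T, (n, q)
    logdet_Ay: float
    logdet_G: float
    jitter: float


def _factorize(X, y, hyper: GPHyperparams) -> _Factorization:
    n = X.shape[0]
    H = _basis(X)
    q = H.shape[0]
    if n <= q:
        raise GPFitError(f"need n > q = {q} training points, got n = {n}")
    A = kernel_matrix(X, X, hyper.lengthscales)
    Ay = A + (hyper.nugget**2) * np.eye(n)
    jitter = _JITTER0
    while True:
        try:
            cho = cho_factor(Ay + jitter * np.eye(n), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter *= 10.0
            if jitter > _JITTER_MAX:
                raise
    AyiHT = cho_solve(cho, H.T)
    G = H @ AyiHT
    G = 0.5 * (G + G.T)
    try:
        G_cho = cho_factor(G, lower=True)
    except np.linalg.LinAlgError as err:
        raise GPFitError(
            "singular basis Gram matrix H A_y^-1 H^T; the training design may be "
            "degenerate (e.g. collinear inputs)") from err
    Ayiy = cho_solve(cho, y)
    beta_hat = cho_solve(G_cho, H @ Ayiy)
    resid = y - H.T @ beta_hat
    alpha = cho_solve(cho, resid)
    sigma2_hat = float(resid @ alpha) / (n - q)
    logdet_Ay = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    logdet_G = 2.0 * float(np.sum(np.log(np.diag(G_cho[0]))))
    return _Factorization(cho=cho, H=H, G_cho=G_cho, beta_hat=beta_hat,
                          sigma2_hat=sigma2_hat, alpha=alpha, AyiHT=AyiHT,
                          logdet_Ay=logdet_Ay, logdet_G=logdet_G, jitter=jitter)


def profiled_coefficients(X, y, hyper: GPHyperparams):
    """Profiled GLS coefficients (beta_hat, sigma2_hat) at fixed hyperparameters."""
    f = _factorize(np.asarray(X, float), np.asarray(y, float), hyper)
    return f.beta_hat, f.sigma2_hat


def log_marginal_likelihood(X, y, hyper: GPHyperparams) -> float:
    """Profiled marginal log likelihood at fixed hyperparameters."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    f = _factorize(X, y, hyper)
    n, q = X.shape[0], f.H.shape[0]
    s2 = max(f.sigma2_hat, 1e-300)
    return -0.5 * (f.logdet_Ay + f.logdet_G + (n - q) * np.log(2.0 * np.pi * s2))


@dataclass
class GaussianProcess:
    """A fitted scalar emulator: training data, hyperparameters, cached factors.

    Construct, then call :meth:`fit` (hyperparameter optimization) or
    :meth:`set_hyperparams` (fixed hyperparameters), then :meth:`predict`.
    """

    X: np.ndarray
    y: np.ndarray
    hyper: GPHyperparams | None = None
    _fact: _Factorization | None = field(default=None, repr=False)
    optimizer_trace: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y lengths differ")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite training data")
        d = np.sum((self.X[:, None, :] - self.X[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.min(d) < 1e-24:
            raise ValueError("duplicate training inputs (within 1e-12 after scaling)")
        if self.hyper is not None:
            self._fact = _factorize(self.X, self.y, self.hyper)

    # -- fitting -----------------------------------------------------------

    def set_hyperparams(self, hyper: GPHyperparams) -> "GaussianProcess":
        self.hyper = hyper
        self._fact = _factorize(self.X, self.y, hyper)
        return self

    def fit(self, seed: int = 0, n_starts: int = 8,
            ls_start_range=(0.05, 5.0), nu_starts=(1e-4, 1e-2, 1e-1),
            ls_bounds=(1e-2, 1e2), nu_bounds=(1e-8, 10.0)) -> "GaussianProcess":
        """Maximize the profiled marginal likelihood over (log theta, log nu).

        Multistart gradient-based local search; deterministic given ``seed``.
        """
        m = self.X.shape[1]
        rng = np.random.default_rng(seed)

        def objective(z):
            try:
                h = GPHyperparams(np.exp(z[:m]), np.exp(z[m]))
                return -log_marginal_likelihood(self.X, self.y, h)
            except (np.linalg.LinAlgError, GPFitError, FloatingPointError):
                return 1e12

        bounds = [(np.log(ls_bounds[0]), np.log(ls_bounds[1]))] * m
        bounds.append((np.log(nu_bounds[0]), np.log(nu_bounds[1])))
        best = None
        self.optimizer_trace = []
        for s in range(n_starts):
            ls0 = np.exp(rng.uniform(np.log(ls_start_range[0]),
                                     np.log(ls_start_range[1]), size=m))
            nu0 = nu_starts[s % len(nu_starts)]
            z0 = np.log(np.concatenate([ls0, [nu0]]))
            res = minimize(objective, z0, method="L-BFGS-B", bounds=bounds)
            self.optimizer_trace.append((float(res.fun), res.x.copy()))
            if np.isfinite(res.fun) and res.fun < 1e11 and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise GPFitError("all hyperparameter starts were rejected")
        self.set_hyperparams(GPHyperparams(np.exp(best.x[:m]), float(np.exp(best.x[m]))))
        return self

    # -- cached profiled quantities ---------------------------------------

    @property
    def beta_hat(self) -> np.ndarray:
        return self._fact.beta_hat

    @property
    def sigma2_hat(self) -> float:
        return self._fact.sigma2_hat

    @property
    def log_marginal_likelihood_(self) -> float:
        n, q = self.X.shape[0], self._fact.H.shape[0]
        s2 = max(self._fact.sigma2_hat, 1e-300)
        return -0.5 * (self._fact.logdet_Ay + self._fact.logdet_G
                       + (n - q) * np.log(2.0 * np.pi * s2))

    # -- prediction --------------------------------------------------------

    def predict(self, Xstar: np.ndarray, full_cov: bool = False):
        """Posterior mean and variance of the latent f at new inputs.

        Returns ``(mean, var)`` with ``var`` the pointwise variance, or the
        full covariance matrix when ``full_cov`` is True.  Small negative
        variances (above -1e-8) from roundoff are clipped to zero.
        """
        if self._fact is None:
            raise GPFitError("call fit() or set_hyperparams() first")
        f = self._fact
        Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
        Astar = kernel_matrix(self.X, Xstar, self.hyper.lengthscales)   # (n, N)
        Hstar = _basis(Xstar)                                           # (q, N)
        mean = Hstar.T @ f.beta_hat + Astar.T @ f.alpha
        AyiAstar = cho_solve(f.cho, Astar)                              # (n, N)
        R = Hstar - f.H @ AyiAstar                                      # (q, N)
        Lg = f.G_cho[0]
        W = solve_triangular(Lg, R, lower=f.G_cho[1])                   # (q, N)
        if full_cov:
            Ass = kernel_matrix(Xstar, Xstar, self.hyper.lengthscales)
            cov = f.sigma2_hat * (Ass - Astar.T @ AyiAstar + W.T @ W)
            cov = 0.5 * (cov + cov.T)
            d = np.diag(cov).copy()
            d[(d < 0) & (d > -1e-8)] = 0.0
            np.fill_diagonal(cov, d)
            return mean, cov
        var = f.sigma2_hat * (1.0 - np.sum(Astar * AyiAstar, axis=0)
                              + np.sum(W * W, axis=0))
        var[(var < 0) & (var > -1e-8)] = 0.0
        return mean, var

    def loo_standardized_residuals(self) -> np.ndarray:
        """Leave-one-out residuals standardized by the predictive sd.

        Each point is left out in turn and predicted with the *fixed* fitted
        hyperparameters; approximately N(0, 1) under a well-specified model.
        """
        n = self.X.shape[0]
        out = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            sub = GaussianProcess(self.X[keep], self.y[keep], hyper=self.hyper)
            mu, var = sub.predict(self.X[i:i + 1])
            nu2 = (self.hyper.nugget ** 2) * sub.sigma2_hat
            out[i] = (self.y[i] - mu[0]) / np.sqrt(var[0] + nu2)
        return out

    def summary(self) -> str:
        f = self._fact
        ls = ", ".join(f"{v:.4g}" for v in self.hyper.lengthscales)
        return (
            f"GaussianProcess(n={self.X.shape[0]}, m={self.X.shape[1]})\n"
            f"  lengthscales : [{ls}]\n"
            f"  nugget nu    : {self.hyper.nugget:.4g}\n"
            f"  sigma2_hat   : {f.sigma2_hat:.6g}\n"
            f"  beta_hat     : {np.array2string(f.beta_hat, precision=4)}\n"
            f"  log marg lik : {self.log_marginal_likelihood_:.4f}\n"
            f"  jitter used  : {f.jitter:.1g}"
        )
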