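"""Bayesian calibration of mMS parameters to noisy restitution measurements.

Three measurement channels are supported, each contributing an additive log
likelihood:

* CV(S2) and APD(S2) points: homoscedastic normal errors around the RCE
  curve posterior, Y ~ N(M(x, S2_Y), V(x, S2_Y) + sigma_Y^2 I), where the
  RCE covariance V is low-rank (Psi diag(V_c) Psi^T) and sigma_Y is the
  per-channel noise scale (CV in m/s, APD in ms — the channels have
  different units, so each carries its own scale).

* ERP brackets: an S1S2 protocol observes only the interval of width
  Delta_S2 containing ERP.  Writing Y for the bracket's lower endpoint, the
  error ERP - Y is modeled as a mixture of N Gaussians with means
  m_i = (i - 1/2) Delta_S2 / N (the centers of N regular sub-intervals of
  the bracket) and common sd s = Delta_S2 / N.  Combined with the scalar
  RCE prediction F(x) ~ N(M, V) this gives the analytic likelihood

      p(Y | x) = sum_i (1/N) Normal(Y; M - m_i, s^2 + V),

  an exact density in Y with infinite support that is nearly flat while the
  predicted ERP stays inside the bracket — exactly the behavior an interval
  observation warrants — evaluated in log space with logsumexp.

The prior over x is uniform on the design box (zero outside); the noise
scales get a log-uniform prior.  MAP is found by multistart bounded
optimization over (x, log sigma); the posterior is sampled with the
affine-invariant ensemble sampler (emcee), by default with the noise scales
fixed at their MAP values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import qmc

import emcee

from .emulator import RCE

__all__ = [
    "CurveObservations",
    "ERPBracket",
    "ERPLikelihoodSpec",
    "CalibrationProblem",
    "MAPResult",
    "MCMCResult",
    "loglik_curve",
    "loglik_erp",
    "run_ensemble",
]

SIGMA_PRIOR_BOUNDS = (1e-3, 10.0)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class CurveObservations:
    """Noisy points from one restitution curve channel ('cv' or 'apd')."""

    s2: np.ndarray
    values: np.ndarray
    channel: str
    noise_scale: float | None = None   # known sigma_Y, or None to estimate

    def __post_init__(self):
        self.s2 = np.asarray(self.s2, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.s2.shape != self.values.shape:
            raise ValueError("s2 and values must have the same shape")
        if self.channel not in ("cv", "apd"):
            raise ValueError(f"channel must be 'cv' or 'apd', got {self.channel!r}")


@dataclass(frozen=True)
class ERPBracket:
    """ERP observed only as: ERP lies in (lower, lower + width) at this S1."""

    s1: float
    lower: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("bracket width must be > 0")


@dataclass(frozen=True)
class ERPLikelihoodSpec:
    """Mixture parametrization of the ERP interval likelihood."""

    n_terms: int = 10

    def means(self, width: float) -> np.ndarray:
        i = np.arange(1, self.n_terms + 1)
        return (i - 0.5) * width / self.n_terms

    def sd(self, width: float) -> float:
        return width / self.n_terms


def _grid_indices(grid: np.ndarray, s2: np.ndarray) -> np.ndarray:
    idx = np.rint((s2 - grid[0]) / (grid[1] - grid[0])).astype(int)
    if (np.abs(grid[np.clip(idx, 0, grid.size - 1)] - s2) > 1e-9).any() \
            or (idx < 0).any() or (idx >= grid.size).any():
        raise ValueError("observation S2 values must lie on the emulator grid")
    return idx


def _mvn_logpdf_lowrank(y, mean, Psi_obs, comp_var, sigma2):
    """log N(y; mean, Psi_obs diag(comp_var) Psi_obs^T + sigma2 I)."""
    d = y.shape[0]
    cov = (Psi_obs * comp_var) @ Psi_obs.T + sigma2 * np.eye(d)
    try:
        cho = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError:
        import warnings
        warnings.warn("observation covariance factorization failed", stacklevel=2)
        return -np.inf
    r = y - mean
    alpha = cho_solve(cho, r)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    return float(-0.5 * (d * _LOG2PI + logdet + r @ alpha))


def loglik_curve(x, obs: CurveObservations, rce: RCE, sigma: float) -> float:
    """Log likelihood of noisy curve points under the RCE posterior."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    idx = _grid_indices(rce.basis.grid, obs.s2)
    means, varis = rce.predict_components(np.atleast_2d(x))
    Psi_obs = rce.basis.components[:, idx].T          # (d_obs, C)
    mean = rce.basis.mean[idx] + Psi_obs @ means[0]
    return _mvn_logpdf_lowrank(obs.values, mean, Psi_obs, varis[0], sigma**2)


def loglik_erp(x, bracket: ERPBracket, rce_erp: RCE,
               spec: ERPLikelihoodSpec | None = None) -> float:
    """Log likelihood of one ERP bracket observation (analytic mixture)."""
    spec = spec or ERPLikelihoodSpec()
    M, V = rce_erp.predict_scalar(np.asarray(x, float), bracket.s1)
    return _erp_loglik_terms(np.array([M]), np.array([V]), bracket, spec)[0]


def _erp_loglik_terms(M, V, bracket, spec):
    """Vectorized over prediction points: Eq. of the mixture, via logsumexp."""
    mi = spec.means(bracket.width)                     # (N,)
    s2_tot = spec.sd(bracket.width) ** 2 + V[:, None]  # (W, N)
    z = (bracket.lower + mi[None, :] - M[:, None])
    log_terms = -0.5 * (np.log(2.0 * np.pi * s2_tot) + z**2 / s2_tot) \
        - np.log(spec.n_terms)
    return logsumexp(log_terms, axis=1)


@dataclass
class MAPResult:
    x: np.ndarray
    sigmas: dict
    log_posterior: float
    n_starts: int

    def summary(self) -> str:
        sig = ", ".join(f"{k}={v:.4g}" for k, v in self.sigmas.items()) or "-"
        return (f"MAP estimate (best of {self.n_starts} starts)\n"
                f"  x           : {np.array2string(self.x, precision=5)}\n"
                f"  noise scales: {sig}\n"
                f"  log posterior: {self.log_posterior:.3f}")


@dataclass
class MCMCResult:
    samples: np.ndarray            # (n_kept, ndim) after burn-in and thinning
    log_prob: np.ndarray
    acceptance_fraction: float
    n_walkers: int
    n_steps: int
    burn: int
    thin: int
    warnings: list = field(default_factory=list)

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        lo = (1.0 - level) / 2.0
        return np.quantile(self.samples, [lo, 1.0 - lo], axis=0).T

    def summary(self) -> str:
        mean = self.samples.mean(axis=0)
        sd = self.samples.std(axis=0)
        ci = self.credible_interval()
        lines = [f"MCMC posterior: {self.samples.shape[0]} samples "
                 f"({self.n_walkers} walkers x {self.n_steps} steps, "
                 f"burn {self.burn}, thin {self.thin}), "
                 f"acceptance {self.acceptance_fraction:.3f}"]
        for j in range(self.samples.shape[1]):
            lines.append(f"  dim {j}: mean {mean[j]:.5g}  sd {sd[j]:.3g}  "
                         f"95% CI [{ci[j, 0]:.5g}, {ci[j, 1]:.5g}]")
        lines.extend(f"  warning: {w}" for w in self.warnings)
        return "\n".join(lines)


def run_ensemble(log_prob_batch, x0: np.ndarray, n_steps: int = 2000,
                 burn: int = 1000, thin: int = 5, seed: int = 0) -> MCMCResult:
    """Affine-invariant ensemble MCMC over a batched log-probability.

    ``log_prob_batch`` maps an (n_walkers, ndim) array to n_walkers log
    probabilities.  ``x0`` supplies the initial walker positions.
    """
    x0 = np.asarray(x0, dtype=float)
    n_walkers, ndim = x0.shape
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob_batch, vectorize=True)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(x0, n_steps, progress=False)
    samples = sampler.get_chain(discard=burn, thin=thin, flat=True)
    logp = sampler.get_log_prob(discard=burn, thin=thin, flat=True)
    acc = float(np.mean(sampler.acceptance_fraction))
    warnings_list = []
    if acc < 0.05:
        warnings_list.append(f"low acceptance fraction {acc:.3f} (< 0.05)")
    return MCMCResult(samples=samples, log_prob=logp, acceptance_fraction=acc,
                      n_walkers=n_walkers, n_steps=n_steps, burn=burn, thin=thin,
                      warnings=warnings_list)


class CalibrationProblem:
    """Posterior over mMS parameters given curve and ERP observations.

    Parameters
    ----------
    curve_obs : list of (CurveObservations, RCE) pairs, one per channel.
    erp_brackets : list of ERPBracket, scored against ``rce_erp``.
    rce_erp : the ERP(S1) emulator, or None when no brackets are used.
    spec : ERP mixture likelihood settings.
    """

    def __init__(self, curve_obs=(), erp_brackets=(), rce_erp: RCE | None = None,
                 spec: ERPLikelihoodSpec | None = None,
                 sigma_prior_bounds=SIGMA_PRIOR_BOUNDS):
        self.curve_obs = list(curve_obs)
        self.erp_brackets = list(erp_brackets)
        self.rce_erp = rce_erp
        self.spec = spec or ERPLikelihoodSpec()
        self.sigma_prior_bounds = sigma_prior_bounds
        if self.erp_brackets and rce_erp is None:
            raise ValueError("ERP brackets supplied without an ERP emulator")
        boxes = [rce.box for _, rce in self.curve_obs]
        if rce_erp is not None:
            boxes.append(rce_erp.box)
        if not boxes:
            raise ValueError("no observations supplied")
        self.box = boxes[0]
        self.channels = [obs.channel for obs, _ in self.curve_obs]
        # cache per-channel grid slices
        self._cache = []
        for obs, rce in self.curve_obs:
            idx = _grid_indices(rce.basis.grid, obs.s2)
            self._cache.append((obs, rce, idx,
                                rce.basis.components[:, idx].T,
                                rce.basis.mean[idx]))
        if self.erp_brackets:
            grid = rce_erp.basis.grid
            self._erp_idx = [int(np.argmin(np.abs(grid - b.s1))) for b in self.erp_brackets]

    # -- posterior ---------------------------------------------------------

    def log_posterior_batch(self, X: np.ndarray, sigmas: dict) -> np.ndarray:
        """Log posterior at a batch of parameter points with fixed noise scales."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        W = X.shape[0]
        out = np.zeros(W)
        inside = np.all((X >= self.box[:, 0]) & (X <= self.box[:, 1]), axis=1)
        out[~inside] = -np.inf
        if not inside.any():
            return out
        Xi = X[inside]
        tot = np.zeros(Xi.shape[0])
        for (obs, rce, idx, Psi_obs, mu0) in self._cache:
            sigma = sigmas[obs.channel]
            means, varis = rce.predict_components(Xi)
            mu = mu0 + means @ Psi_obs.T        # (Wi, d_obs)
            for w in range(Xi.shape[0]):
                tot[w] += _mvn_logpdf_lowrank(obs.values, mu[w], Psi_obs,
                                              varis[w], sigma**2)
        if self.erp_brackets:
            means, varis = self.rce_erp.predict_components(Xi)
            for b, j in zip(self.erp_brackets, self._erp_idx):
                psi = self.rce_erp.basis.components[:, j]
                M = self.rce_erp.basis.mean[j] + means @ psi
                V = np.maximum(varis @ (psi**2), 0.0)
                tot += _erp_loglik_terms(M, V, b, self.spec)
        out[inside] = tot
        return out

    def log_posterior(self, x, sigmas: dict) -> float:
        """Log posterior at one point: channel log likelihoods + log priors."""
        lp = float(self.log_posterior_batch(np.atleast_2d(x), sigmas)[0])
        lo, hi = self.sigma_prior_bounds
        for ch in self.channels:
            s = sigmas[ch]
            if not (lo <= s <= hi):
                return -np.inf
            lp += -np.log(s)       # log-uniform prior on sigma
        return lp

    # -- estimation --------------------------------------------------------

    def map_estimate(self, seed: int = 0, n_starts: int = 16) -> MAPResult:
        """Best of multistart bounded local optimizations over (x, log sigma)."""
        m = self.box.shape[0]
        n_sig = len(self.channels)
        lo, hi = self.sigma_prior_bounds

        def objective(v):
            x = v[:m]
            sigmas = {ch: float(np.exp(v[m + i])) for i, ch in enumerate(self.channels)}
            lp = self.log_posterior(x, sigmas)
            return -lp if np.isfinite(lp) else 1e12

        starts = qmc.LatinHypercube(d=m, seed=seed).random(n_starts)
        starts = self.box[:, 0] + starts * (self.box[:, 1] - self.box[:, 0])
        rng = np.random.default_rng(seed + 1)
        bounds = [tuple(r) for r in self.box] + [(np.log(lo), np.log(hi))] * n_sig
        best = None
        for s in range(n_starts):
            logsig0 = rng.uniform(np.log(1e-2), np.log(1.0), size=n_sig)
            v0 = np.concatenate([starts[s], logsig0])
            res = minimize(objective, v0, method="L-BFGS-B", bounds=bounds)
            if np.isfinite(res.fun) and res.fun < 1e11 and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise RuntimeError("all MAP starts landed at zero posterior")
        x_hat = best.x[:m]
        sigmas = {ch: float(np.exp(best.x[m + i])) for i, ch in enumerate(self.channels)}
        return MAPResult(x=x_hat, sigmas=sigmas, log_posterior=-float(best.fun),
                         n_starts=n_starts)

    def run_mcmc(self, map_result: MAPResult, n_walkers: int = 32,
                 n_steps: int = 2000, burn: int = 1000, thin: int = 5,
                 seed: int = 0, sample_noise: bool = False) -> MCMCResult:
        """Ensemble MCMC initialized at the MAP estimate plus a small jitter.

        By default the noise scales are fixed at their MAP values and only
        the model parameters are sampled; with ``sample_noise`` the log
        noise scales are appended to the state vector.
        """
        m = self.box.shape[0]
        rng = np.random.default_rng(seed)
        span = self.box[:, 1] - self.box[:, 0]
        x0 = map_result.x + 1e-4 * span * rng.standard_normal((n_walkers, m))
        x0 = np.clip(x0, self.box[:, 0] + 1e-9 * span, self.box[:, 1] - 1e-9 * span)

        if not sample_noise:
            sigmas = map_result.sigmas

            def log_prob(X):
                return self.log_posterior_batch(X, sigmas)

            z0 = x0
        else:
            lo, hi = self.sigma_prior_bounds
            logsig_map = np.array([np.log(map_result.sigmas[ch]) for ch in self.channels])
            z0 = np.hstack([x0, logsig_map + 1e-3 * rng.standard_normal((n_walkers, len(self.channels)))])

            def log_prob(Z):
                out = np.empty(Z.shape[0])
                for w in range(Z.shape[0]):
                    sig = {ch: float(np.exp(Z[w, m + i])) for i, ch in enumerate(self.channels)}
                    if any(not (lo <= s <= hi) for s in sig.values()):
                        out[w] = -np.inf
                        continue
                    out[w] = self.log_posterior(Z[w, :m], sig)
                return out

        return run_ensemble(log_prob, z0, n_steps=n_steps, burn=burn, thin=thin, seed=seed)
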