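"""Restitution-curve fitting, resampling and principal-component decomposition.

Each simulated run yields (S2, value) points at the integer coupling
intervals visited by the ERP bisection, which differ between runs.  A
three-parameter exponential-saturation form

    F(S2) = a (1 - b exp(-S2 / c))

is fitted to each run (nonlinear least squares, multistart) and evaluated on
a common grid, 160..600 ms at 1 ms steps.  The region of the grid below a
run's ERP is "virtual": the analytic form is extrapolated there because PCA
needs equal-length vectors, but no measurement is physically possible and
nothing downstream consumes predictions in that region.

PCA is performed via SVD on the mean-centered, *unscaled* curve matrix
(units are homogeneous along a curve, and the amplitude of variation is
physically meaningful).  Explained-variance ratios are stored relative to
the total dataset variance; the share of the *retained* variance attributed
to each kept component is also derived, since both normalizations are of
interest when summarizing parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.decomposition import PCA

__all__ = [
    "RestitutionFit",
    "trim_nonmonotone_head",
    "CurveGrid",
    "CurveBasis",
    "CurveFitError",
    "fit_restitution",
    "resample",
    "fit_pca",
    "project",
    "reconstruct",
]


class CurveFitError(RuntimeError):
    """Nonlinear curve fit failed to converge; carries the best fit found."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass(frozen=True)
class RestitutionFit:
    """Coefficients of F(S2) = a (1 - b exp(-S2/c)) plus the fit residual.

    For degenerate (constant) data the curve reduces to F = a with b = 0 and
    c unidentifiable (``c_identifiable`` False, c stored as NaN).
    """

    a: float
    b: float
    c: float
    residual_rms: float
    c_identifiable: bool = True

    def __call__(self, s2):
        s2 = np.asarray(s2, dtype=float)
        if not self.c_identifiable or self.b == 0.0:
            return np.full_like(s2, self.a)
        return self.a * (1.0 - self.b * np.exp(-s2 / self.c))


@dataclass(frozen=True)
class CurveGrid:
    """Uniform integer S2 (or S1) grid in ms, endpoints inclusive."""

    start: float = 160.0
    stop: float = 600.0
    step: float = 1.0

    def values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1


@dataclass
class CurveBasis:
    """PCA mean, components and variance ratios on a fixed grid."""

    grid: np.ndarray               # grid values (ms)
    mean: np.ndarray               # Phi_0, (d,)
    components: np.ndarray         # Psi_C rows Phi_1..Phi_C, (C, d), orthonormal
    explained_variance_ratio: np.ndarray  # fraction of total variance, (C,)
    n_train: int

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def retained_share(self) -> np.ndarray:
        """Share of the variance retained by the kept components."""
        total = self.explained_variance_ratio.sum()
        if total == 0.0:
            return np.zeros_like(self.explained_variance_ratio)
        return self.explained_variance_ratio / total


def _model(s2, a, b, c):
    return a * (1.0 - b * np.exp(-s2 / c))


def trim_nonmonotone_head(s2, values, min_points: int = 4):
    """Drop the descending head of a measured restitution series.

    Restitution is monotone increasing in S2, but measurements taken in the
    first few ms above ERP are contaminated by the premature front's
    acceleration phase (the conduction delay to the measurement region is
    still shrinking, so points indexed by the pacing interval sit *above*
    the points that follow).  The artifact manifests as a strictly
    descending prefix of the S2-sorted series, which is discarded — at most
    down to ``min_points`` remaining.  Clean monotone data is returned
    unchanged.
    """
    s2 = np.asarray(s2, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(s2)
    s2, values = s2[order], values[order]
    i = 0
    while i + 1 < values.size and values[i + 1] < values[i]:
        i += 1
    i = min(i, max(values.size - min_points, 0))
    return s2[i:], values[i:]


def fit_restitution(s2, values, c_starts=(100.0, 30.0, 60.0, 160.0, 300.0),
                    constant_tol: float = 1e-9, robust: bool = True,
                    anchor: float = 160.0, anchor_bounds=(-6.0, 7.0)) -> RestitutionFit:
    """Fit the exponential-saturation restitution form to (S2, value) points.

    Nonlinear least squares with multistarts over the relaxation constant c;
    by default a soft-L1 loss (scale 2% of the curve amplitude) so that
    isolated near-ERP measurement artifacts do not drag the curve.  The fit
    is parameterized as a (1 - (1-w) exp(-(S2-anchor)/c)) with w = F(anchor)/a
    the relative curve value at the start of the resampling grid; bounding w
    keeps the virtual-region extrapolation within a few curve amplitudes.
    (Near-flat noisy series — e.g. conduction pinned at the lattice limit —
    otherwise admit fits with b ~ 1e12 and small c whose extrapolation
    dominates the whole dataset's variance.)  The returned coefficients are
    in the canonical (a, b, c) form, b = (1-w) exp(anchor/c).

    Requires at least 4 points spanning at least 100 ms of S2.  Constant
    data is handled as the degenerate b = 0 curve rather than an error.
    Raises :class:`CurveFitError` if no start converges.
    """
    s2 = np.asarray(s2, dtype=float)
    values = np.asarray(values, dtype=float)
    if s2.size < 4:
        raise ValueError(f"need >= 4 points, got {s2.size}")
    if np.ptp(s2) < 100.0:
        raise ValueError(f"points must span >= 100 ms of S2, got {np.ptp(s2):.1f}")
    if not (np.isfinite(s2).all() and np.isfinite(values).all()):
        raise ValueError("non-finite input points")

    scale = max(abs(values).max(), 1.0)
    if np.ptp(values) <= constant_tol * scale:
        a = float(values.mean())
        rms = float(np.sqrt(np.mean((values - a) ** 2)))
        return RestitutionFit(a=a, b=0.0, c=float("nan"), residual_rms=rms,
                              c_identifiable=False)

    a0 = float(values.max())
    i_min = int(np.argmin(s2))

    def model_w(p):
        a, w, c = p
        return a * (1.0 - (1.0 - w) * np.exp(-(s2 - anchor) / c))

    loss = "soft_l1" if robust else "linear"
    f_scale = max(0.02 * abs(a0), 1e-8)
    lb = [1e-12, anchor_bounds[0], 1e-3]
    ub = [np.inf, anchor_bounds[1], 1e6]
    best = None
    best_sse = np.inf
    last_err = None
    for c0 in c_starts:
        b0 = (1.0 - values[i_min] / a0) * np.exp(s2[i_min] / c0)
        w0 = 1.0 - b0 * np.exp(-anchor / c0)
        p0 = [a0, float(np.clip(w0, anchor_bounds[0] + 1e-9, anchor_bounds[1] - 1e-9)), c0]
        try:
            res = least_squares(lambda p: model_w(p) - values, p0, loss=loss,
                                f_scale=f_scale, bounds=(lb, ub), max_nfev=20000)
        except (ValueError, RuntimeError) as err:  # pragma: no cover
            last_err = err
            continue
        if not res.success and not np.isfinite(res.cost):  # pragma: no cover
            continue
        sse = float(np.sum((model_w(res.x) - values) ** 2))
        if sse < best_sse:
            best_sse = sse
            best = res.x
    if best is None:
        raise CurveFitError(f"restitution fit failed: {last_err}", best_fit=None)
    rms = float(np.sqrt(best_sse / s2.size))
    a, w, c = best
    b = (1.0 - w) * np.exp(anchor / c)
    return RestitutionFit(a=float(a), b=float(b), c=float(c), residual_rms=rms)


def resample(fit: RestitutionFit, grid: CurveGrid) -> np.ndarray:
    """Evaluate a fitted curve on every grid point (including below ERP)."""
    return fit(grid.values())


def fit_pca(curves: np.ndarray, n_components: int, grid: np.ndarray | None = None):
    """Centered, unscaled PCA of a curve matrix via SVD.

    Returns ``(CurveBasis, coordinates)`` where ``coordinates`` is the
    (n, C) matrix of per-curve coefficients f_c.
    """
    curves = np.asarray(curves, dtype=float)
    n, d = curves.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(n - 1, d):
        raise ValueError(f"n_components={n_components} exceeds min(n-1, d)={min(n - 1, d)}")
    if grid is None:
        grid = np.arange(d, dtype=float)

    mean = curves.mean(axis=0)
    centered = curves - mean
    total_var = float(np.sum(centered ** 2) / (n - 1))
    # identical curves leave only rounding residue after centering
    if total_var <= 1e-24 * max(1.0, float(np.mean(curves ** 2))):
        # all curves identical: zero variance, arbitrary (orthonormal) axes
        components = np.eye(d)[:n_components]
        basis = CurveBasis(grid=np.asarray(grid, float), mean=mean,
                           components=components,
                           explained_variance_ratio=np.zeros(n_components),
                           n_train=n)
        return basis, np.zeros((n, n_components))

    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(curves)
    basis = CurveBasis(grid=np.asarray(grid, float), mean=pca.mean_,
                       components=pca.components_.copy(),
                       explained_variance_ratio=pca.explained_variance_ratio_.copy(),
                       n_train=n)
    return basis, coords


def project(curve: np.ndarray, basis: CurveBasis) -> np.ndarray:
    """Coordinates of curve(s) in the basis: Psi (curve - mean)."""
    curve = np.asarray(curve, dtype=float)
    if curve.shape[-1] != basis.mean.shape[0]:
        raise ValueError(
            f"curve length {curve.shape[-1]} does not match basis grid length {basis.mean.shape[0]}")
    return (curve - basis.mean) @ basis.components.T


def reconstruct(f: np.ndarray, basis: CurveBasis) -> np.ndarray:
    """Curve(s) from coordinates: Phi_0 + Psi^T f."""
    f = np.asarray(f, dtype=float)
    if f.shape[-1] != basis.n_components:
        raise ValueError(f"expected {basis.n_components} coordinates, got {f.shape[-1]}")
    return basis.mean + f @ basis.components
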