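"""Restitution Curve Emulators: PCA basis + independent per-coordinate GPs.

An RCE predicts a whole restitution curve from the model parameters x.  The
curve is represented by its coordinates f_c(x) in a PCA basis; each
coordinate is emulated by an independent Gaussian process, and since the
basis expansion is linear the curve posterior is itself Gaussian:

    mean(x, S2) = Phi_0(S2) + Psi_C [M_1(x), ..., M_C(x)]^T
    cov(x, S2)  = Psi_C diag[V_1(x), ..., V_C(x)] Psi_C^T

with M_c, V_c the posterior mean/variance of the c-th coordinate GP.  The
curve covariance therefore has rank at most C.  Inputs are scaled affinely
to the unit box from the design ranges before GP fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import CurveBasis, fit_pca
from .gp import GaussianProcess
from .params import ranges_array

__all__ = ["RCE", "ValidationReport", "cross_validate"]


@dataclass
class ValidationReport:
    """Per-grid-point R^2 of held-out mean predictions, averaged over folds."""

    per_grid_r2: np.ndarray
    fold_count: int
    grid: np.ndarray

    @property
    def min_r2(self) -> float:
        return float(np.min(self.per_grid_r2))

    @property
    def median_r2(self) -> float:
        return float(np.median(self.per_grid_r2))


@dataclass
class RCE:
    """A fitted restitution curve emulator.

    ``box`` holds the (m, 2) design ranges used for affine input scaling;
    component GPs live in the scaled unit box and share the training design.
    """

    basis: CurveBasis
    gps: list
    box: np.ndarray
    label: str = ""
    s1_context: float | None = None

    @classmethod
    def build(cls, design: np.ndarray, curve_matrix: np.ndarray, n_components: int,
              box: np.ndarray | None = None, grid: np.ndarray | None = None,
              seed: int = 0, label: str = "", s1_context: float | None = None,
              **fit_kwargs) -> "RCE":
        """Fit the PCA basis and one GP per retained coordinate.

        Deterministic given ``seed`` (GP c uses sub-seed seed + c).
        """
        design = np.asarray(design, dtype=float)
        curve_matrix = np.asarray(curve_matrix, dtype=float)
        if design.shape[0] != curve_matrix.shape[0]:
            raise ValueError("design and curve matrix row counts differ")
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        box = ranges_array() if box is None else np.asarray(box, dtype=float)
        basis, coords = fit_pca(curve_matrix, n_components, grid=grid)
        Xs = cls._scale_static(design, box)
        gps = []
        for c in range(n_components):
            gp = GaussianProcess(Xs, coords[:, c]).fit(seed=seed + c, **fit_kwargs)
            gps.append(gp)
        return cls(basis=basis, gps=gps, box=box, label=label, s1_context=s1_context)

    # -- input scaling -----------------------------------------------------

    @staticmethod
    def _scale_static(X, box):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - box[:, 0]) / (box[:, 1] - box[:, 0])

    def scale(self, X) -> np.ndarray:
        return self._scale_static(X, self.box)

    def in_box(self, x) -> bool:
        z = self.scale(x)
        return bool(np.all(z >= 0.0) and np.all(z <= 1.0))

    @property
    def n_components(self) -> int:
        return len(self.gps)

    # -- prediction --------------------------------------------------------

    def predict_components(self, X: np.ndarray):
        """Posterior mean and variance of every coordinate GP at X.

        Returns arrays of shape (N, C); the workhorse for batch prediction.
        """
        Z = self.scale(X)
        means = np.empty((Z.shape[0], self.n_components))
        varis = np.empty((Z.shape[0], self.n_components))
        for c, gp in enumerate(self.gps):
            means[:, c], varis[:, c] = gp.predict(Z)
        return means, varis

    def predict_curve(self, x: np.ndarray, grid_indices: np.ndarray | None = None):
        """Curve posterior (mean vector, covariance matrix) at one parameter point.

        ``grid_indices`` restricts the output to a subset of the basis grid.
        The covariance is Psi diag(V_c) Psi^T: symmetric PSD with rank <= C.
        Extrapolation outside the design box is permitted but not flagged
        here; use :meth:`in_box` to check.
        """
        means, varis = self.predict_components(np.atleast_2d(x))
        m, v = means[0], varis[0]
        Psi = self.basis.components  # (C, d)
        mu0 = self.basis.mean
        if grid_indices is not None:
            Psi = Psi[:, grid_indices]
            mu0 = mu0[grid_indices]
        mean = mu0 + Psi.T @ m
        cov = (Psi.T * v) @ Psi
        cov = 0.5 * (cov + cov.T)
        return mean, cov

    def predict_scalar(self, x: np.ndarray, grid_point: float):
        """Marginal normal (M, V) of the curve at one grid coordinate.

        An off-grid point snaps to the nearest grid point with a warning.
        """
        grid = self.basis.grid
        j = int(np.argmin(np.abs(grid - grid_point)))
        if abs(grid[j] - grid_point) > 1e-9:
            import warnings
            warnings.warn(
                f"grid point {grid_point} not on the basis grid; using nearest {grid[j]}",
                stacklevel=2)
        means, varis = self.predict_components(np.atleast_2d(x))
        psi = self.basis.components[:, j]
        M = float(self.basis.mean[j] + psi @ means[0])
        V = float(np.sum(psi**2 * varis[0]))
        return M, max(V, 0.0)

    def summary(self) -> str:
        evr = ", ".join(f"{v:.4%}" for v in self.basis.explained_variance_ratio)
        lines = [
            f"RCE(label={self.label or '-'}, C={self.n_components}, "
            f"n_train={self.basis.n_train}, grid {self.basis.grid[0]:g}..{self.basis.grid[-1]:g} ms)",
            f"  explained variance ratios: [{evr}]",
        ]
        for c, gp in enumerate(self.gps):
            ls = ", ".join(f"{v:.3g}" for v in gp.hyper.lengthscales)
            lines.append(f"  component {c + 1}: theta=[{ls}], nu={gp.hyper.nugget:.3g}, "
                         f"sigma2={gp.sigma2_hat:.4g}")
        return "\n".join(lines)


def cross_validate(design: np.ndarray, curve_matrix: np.ndarray, n_components: int,
                   k: int = 5, box: np.ndarray | None = None,
                   grid: np.ndarray | None = None, seed: int = 0,
                   **fit_kwargs) -> ValidationReport:
    """k-fold cross-validation of an RCE, scored per grid point.

    Folds are contiguous blocks after a seeded shuffle.  For each fold the
    basis and GPs are refit on the training portion only; held-out curves
    are predicted by the posterior mean, and R^2 = 1 - SSE/SST is computed
    per grid point with SST taken on the held-out fold, then averaged over
    folds.
    """
    design = np.asarray(design, dtype=float)
    curve_matrix = np.asarray(curve_matrix, dtype=float)
    n, d = curve_matrix.shape
    if n < 2 * k:
        raise ValueError(f"need n >= 2k = {2 * k} runs, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    r2 = np.zeros((k, d))
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        rce = RCE.build(design[train_idx], curve_matrix[train_idx], n_components,
                        box=box, grid=grid, seed=seed, **fit_kwargs)
        means, _ = rce.predict_components(design[test_idx])
        pred = rce.basis.mean + means @ rce.basis.components
        truth = curve_matrix[test_idx]
        sse = np.sum((pred - truth) ** 2, axis=0)
        sst = np.sum((truth - truth.mean(axis=0)) ** 2, axis=0)
        # grid points constant across the held-out fold: perfect prediction
        # scores 1, anything else scores 0 (no variance to explain)
        tiny = 1e-12 * max(1.0, float(np.mean(truth**2)))
        with np.errstate(divide="ignore", invalid="ignore"):
            r2[fi] = np.where(sst > tiny, 1.0 - sse / sst,
                              np.where(sse <= tiny, 1.0, 0.0))
    gridv = np.arange(d, dtype=float) if grid is None else np.asarray(grid, float)
    return ValidationReport(per_grid_r2=r2.mean(axis=0), fold_count=k, grid=gridv)
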