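"""Variance-based global sensitivity analysis of RCE components.

Sobol indices are estimated with Saltelli's cross-sampling scheme on a
scrambled Sobol sequence.  For m inputs and a base sample size N (a power
of two, to keep the sequence balanced), the design stacks the blocks

    A, B, AB_1..AB_m, BA_1..BA_m        -> N (2m + 2) rows

where AB_i is A with column i taken from B (and vice versa).  With f
evaluated over the whole design, the estimators are

    first-order   S1_i = mean(f_B (f_ABi - f_A)) / V
    total-effect  ST_i = mean((f_A - f_ABi)^2) / (2 V)
    second-order  S2_ij = mean(f_BAi f_ABj - f_A f_B) / V - S1_i - S1_j

with V the empirical variance of (f_A, f_B) pooled.  Small negative
estimates are ordinary Monte-Carlo behavior and are reported as-is.

Applied to an RCE, the function analyzed is the posterior *mean* of one PCA
coordinate as a function of the model parameters over the design box; the
emulator's own predictive variance is not propagated into the indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

__all__ = ["SobolResult", "saltelli_design", "sobol_indices", "analyze_rce"]


@dataclass
class SobolResult:
    """First-order, total-effect and (upper-triangular) second-order indices."""

    first_order: np.ndarray
    total_effect: np.ndarray
    second_order: np.ndarray      # (m, m), entries j>i; NaN elsewhere
    n_base: int
    undefined: bool = False       # zero output variance

    def top_total_effect(self) -> int:
        return int(np.argmax(self.total_effect))


def saltelli_design(ranges: np.ndarray, n_base: int, seed: int = 0,
                    second_order: bool = True) -> np.ndarray:
    """Saltelli cross-sampled design over a box, shape (n_base*(2m+2), m).

    ``ranges`` is (m, 2) rows of (low, high).  ``n_base`` must be a power of
    two.  Deterministic given ``seed``.  Without second-order blocks the
    design has n_base*(m+2) rows.
    """
    ranges = np.asarray(ranges, dtype=float)
    m = ranges.shape[0]
    if n_base < 2 or (n_base & (n_base - 1)) != 0:
        raise ValueError(f"n_base must be a power of 2, got {n_base}")
    eng = qmc.Sobol(d=2 * m, scramble=True, seed=seed)
    base = eng.random(n_base)
    A = base[:, :m]
    B = base[:, m:]
    blocks = [A, B]
    for i in range(m):
        AB = A.copy()
        AB[:, i] = B[:, i]
        blocks.append(AB)
    if second_order:
        for i in range(m):
            BA = B.copy()
            BA[:, i] = A[:, i]
            blocks.append(BA)
    unit = np.vstack(blocks)
    return ranges[:, 0] + unit * (ranges[:, 1] - ranges[:, 0])


def sobol_indices(f_values: np.ndarray, m: int, n_base: int,
                  second_order: bool = True) -> SobolResult:
    """Sobol index estimates from f evaluated over a Saltelli design.

    ``f_values`` must follow the block layout of :func:`saltelli_design`.
    Zero output variance yields an all-indices-undefined result.
    """
    f = np.asarray(f_values, dtype=float)
    expected = n_base * ((2 * m + 2) if second_order else (m + 2))
    if f.shape != (expected,):
        raise ValueError(f"expected {expected} evaluations, got {f.shape}")
    if not np.isfinite(f).all():
        raise ValueError("non-finite function values")
    fA = f[:n_base]
    fB = f[n_base:2 * n_base]
    fAB = [f[(2 + i) * n_base:(3 + i) * n_base] for i in range(m)]
    fBA = ([f[(2 + m + i) * n_base:(3 + m + i) * n_base] for i in range(m)]
           if second_order else None)

    pooled = np.concatenate([fA, fB])
    V = float(np.var(pooled))
    s2 = np.full((m, m), np.nan)
    if V <= 1e-300 * max(1.0, float(np.mean(pooled) ** 2)):
        return SobolResult(first_order=np.full(m, np.nan),
                           total_effect=np.full(m, np.nan),
                           second_order=s2, n_base=n_base, undefined=True)

    s1 = np.array([np.mean(fB * (fAB[i] - fA)) for i in range(m)]) / V
    st = np.array([0.5 * np.mean((fA - fAB[i]) ** 2) for i in range(m)]) / V
    if second_order:
        for i in range(m):
            for j in range(i + 1, m):
                vij = np.mean(fBA[i] * fAB[j] - fA * fB) / V
                s2[i, j] = vij - s1[i] - s1[j]
    return SobolResult(first_order=s1, total_effect=st, second_order=s2,
                       n_base=n_base)


def analyze_rce(rce, n_base: int = 2048, seed: int = 0,
                second_order: bool = True) -> list:
    """Sobol indices of each RCE coordinate's posterior mean over the design box.

    Returns one :class:`SobolResult` per PCA component, in component order.
    """
    box = rce.box
    m = box.shape[0]
    X = saltelli_design(box, n_base, seed=seed, second_order=second_order)
    means, _ = rce.predict_components(X)
    return [sobol_indices(means[:, c], m, n_base, second_order=second_order)
            for c in range(rce.n_components)]
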