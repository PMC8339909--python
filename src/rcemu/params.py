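"""Parameterizations of the modified Mitchell-Schaeffer (mMS) tissue model.

The monodomain mMS model has five free quantities once the excitation
threshold ``V_gate`` is fixed at 0.1: the tissue diffusion coefficient ``D``
and the four time constants ``tau_in``, ``tau_out``, ``tau_open``,
``tau_close``.  The *transformed* parameterization substitutes ``D`` and
``tau_close`` with two emergent quantities derived from asymptotic model
behavior,

    CV_max  = 0.5 (1 - 2 V_gate) sqrt(2 D / tau_in)        [m/s]
    APD_max = tau_close * log(1 + tau_out (1 - V_gate)^2 / (4 tau_in))  [ms]

``CV_max`` is the plane-wave conduction velocity of the fully recovered
tissue (the classical traveling-wave speed of the cubic reaction term) and
``APD_max`` is the asymptotic action potential duration at long diastolic
interval.  The transformed box {CV_max, tau_in, tau_out, tau_open, APD_max}
has the practical advantage that propagating action potentials exist
throughout a rectangular region of parameter space.

Units: lengths in mm, times in ms, so conduction velocities in mm/ms, which
is numerically identical to m/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

V_GATE = 0.1

PARAM_NAMES = ("cv_max", "tau_in", "tau_out", "tau_open", "apd_max")

#: Default design box: ranges wide enough to cover (and go slightly beyond)
#: physiologically plausible tissue behavior.
DESIGN_RANGES = {
    "cv_max": (0.1, 1.5),
    "tau_in": (0.01, 0.30),
    "tau_out": (1.0, 30.0),
    "tau_open": (65.0, 215.0),
    "apd_max": (120.0, 270.0),
}


class InvalidParameterError(ValueError):
    """Raised for non-positive or non-finite model parameters."""


@dataclass(frozen=True)
class TransformedParams:
    """One point in the 5-d transformed parameter space.

    cv_max : m/s, tau_in / tau_out / tau_open / apd_max : ms.
    """

    cv_max: float
    tau_in: float
    tau_out: float
    tau_open: float
    apd_max: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0.0:
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "TransformedParams":
        x = np.asarray(x, dtype=float)
        if x.shape != (len(PARAM_NAMES),):
            raise InvalidParameterError(f"expected {len(PARAM_NAMES)} parameters, got shape {x.shape}")
        return cls(*x)


@dataclass(frozen=True)
class PhysicalParams:
    """Native mMS parameters: diffusion in mm^2/ms, time constants in ms."""

    diffusion: float
    tau_in: float
    tau_out: float
    tau_open: float
    tau_close: float
    v_gate: float = V_GATE


def to_physical(x: TransformedParams) -> PhysicalParams:
    """Map transformed parameters to native mMS parameters.

    Inverts the asymptotic relations for CV_max and APD_max; the result
    round-trips through :func:`to_transformed` to relative error < 1e-10.
    """
    if not isinstance(x, TransformedParams):
        x = TransformedParams.from_array(np.asarray(x, dtype=float))
    one_m2vg = 1.0 - 2.0 * V_GATE
    diffusion = 2.0 * x.tau_in * (x.cv_max / one_m2vg) ** 2
    log_arg = 1.0 + x.tau_out * (1.0 - V_GATE) ** 2 / (4.0 * x.tau_in)
    tau_close = x.apd_max / math.log(log_arg)
    return PhysicalParams(
        diffusion=diffusion,
        tau_in=x.tau_in,
        tau_out=x.tau_out,
        tau_open=x.tau_open,
        tau_close=tau_close,
    )


def to_transformed(p: PhysicalParams) -> TransformedParams:
    """Map native mMS parameters to the transformed parameterization."""
    cv_max = 0.5 * (1.0 - 2.0 * p.v_gate) * math.sqrt(2.0 * p.diffusion / p.tau_in)
    apd_max = p.tau_close * math.log(1.0 + p.tau_out * (1.0 - p.v_gate) ** 2 / (4.0 * p.tau_in))
    return TransformedParams(
        cv_max=cv_max,
        tau_in=p.tau_in,
        tau_out=p.tau_out,
        tau_open=p.tau_open,
        apd_max=apd_max,
    )


def ranges_array(ranges: dict | None = None) -> np.ndarray:
    """Design box as an (m, 2) array of (low, high) rows, in PARAM_NAMES order."""
    ranges = DESIGN_RANGES if ranges is None else ranges
    return np.array([ranges[n] for n in PARAM_NAMES], dtype=float)


def center_of_box(ranges: dict | None = None) -> TransformedParams:
    r = ranges_array(ranges)
    return TransformedParams.from_array(0.5 * (r[:, 0] + r[:, 1]))
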