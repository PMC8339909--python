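"""Space-filling parameter designs and synthetic clinical-protocol data.

Everything downstream is testable without external data: a maximin Latin
hypercube supplies the simulation design, the cable simulator supplies the
training curves, and a protocol emulator turns a chosen ground-truth run
into the kind of noisy dataset an S1S2 pacing study would produce — CV and
APD points on a 10 ms S2 grid from 170 to 360 ms with Gaussian noise (sd
0.05 m/s for CV, 5 ms for APD), an extra observation at S2 = S1 for every
S2 observation (the paced beat preceding each premature beat is always
measurable, and these near-replicates pin down the noise scale), points
below the true ERP discarded (they cannot be measured), and ERP reported
only as a protocol-resolution bracket at each of several S1 intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import qmc

from .cable import CableSimulator, CaptureFailure, ProtocolError
from .calibration import CurveObservations, ERPBracket
from .curves import CurveGrid, RestitutionFit, fit_restitution, resample, trim_nonmonotone_head
from .params import TransformedParams, ranges_array

__all__ = [
    "DesignSpec",
    "MeasurementProtocol",
    "GroundTruth",
    "TrainingDataset",
    "maximin_lhs",
    "generate_observations",
    "build_training_dataset",
]


@dataclass(frozen=True)
class DesignSpec:
    """A maximin Latin-hypercube design request."""

    n_points: int
    ranges: np.ndarray = field(default_factory=ranges_array)
    n_candidate_designs: int = 200
    seed: int = 0


@dataclass(frozen=True)
class MeasurementProtocol:
    """Clinical S1S2 measurement settings for synthetic observations."""

    s2_resolution: float = 10.0
    s2_range: tuple = (170.0, 360.0)
    cv_noise_sd: float = 0.05     # m/s
    apd_noise_sd: float = 5.0     # ms
    erp_s1_list: tuple = (600.0, 500.0, 400.0)
    include_s1_equals_s2: bool = True
    seed: int = 0

    def __post_init__(self):
        span = self.s2_range[1] - self.s2_range[0]
        if abs(span / self.s2_resolution - round(span / self.s2_resolution)) > 1e-9:
            raise ValueError("s2_resolution must divide the span of s2_range")

    def s2_grid(self) -> np.ndarray:
        n = int(round((self.s2_range[1] - self.s2_range[0]) / self.s2_resolution)) + 1
        return self.s2_range[0] + self.s2_resolution * np.arange(n)


def maximin_lhs(spec: DesignSpec) -> np.ndarray:
    """Latin hypercube maximizing the minimum pairwise distance.

    Draws ``n_candidate_designs`` independent LHS candidates (all valid
    Latin hypercubes) and keeps the one whose minimum pairwise distance in
    the unit cube is largest.  Deterministic given ``spec.seed``.
    """
    if spec.n_points < 2:
        raise ValueError("n_points must be >= 2")
    ranges = np.asarray(spec.ranges, dtype=float)
    m = ranges.shape[0]
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_candidate_designs)
    best_unit = None
    best_crit = -np.inf
    for s in seeds:
        unit = qmc.LatinHypercube(d=m, seed=np.random.default_rng(s)).random(spec.n_points)
        crit = float(np.min(pdist(unit)))
        if crit > best_crit:
            best_crit = crit
            best_unit = unit
    return ranges[:, 0] + best_unit * (ranges[:, 1] - ranges[:, 0])


@dataclass
class GroundTruth:
    """Analytic ground-truth curves for one run, used to emit observations.

    ``erp`` is the continuous refractory threshold in ms.  A 1 ms-resolved
    simulated ERP value e means the threshold lies in (e, e+1]; passing
    e + 0.5 places it strictly inside any protocol-resolution bracket.
    """

    cv_fit: RestitutionFit
    apd_fit: RestitutionFit
    erp: float
    s1: float
    erp_by_s1: dict = field(default_factory=dict)   # s1 -> continuous ERP


def generate_observations(truth: GroundTruth, protocol: MeasurementProtocol):
    """Synthesize one noisy S1S2 measurement session from ground truth.

    Returns ``(cv_obs, apd_obs, erp_brackets)``.  With zero noise the
    emitted values equal the ground-truth curves at the grid points.
    """
    rng = np.random.default_rng(protocol.seed)
    grid = protocol.s2_grid()
    keep = grid > truth.erp            # sub-ERP points cannot be measured
    s2 = grid[keep]
    if protocol.include_s1_equals_s2:
        s2 = np.concatenate([s2, np.full(s2.size, truth.s1)])

    cv_vals = truth.cv_fit(s2) + protocol.cv_noise_sd * rng.standard_normal(s2.size)
    apd_vals = truth.apd_fit(s2) + protocol.apd_noise_sd * rng.standard_normal(s2.size)
    cv_obs = CurveObservations(s2=s2, values=cv_vals, channel="cv",
                               noise_scale=protocol.cv_noise_sd)
    apd_obs = CurveObservations(s2=s2, values=apd_vals, channel="apd",
                                noise_scale=protocol.apd_noise_sd)

    res = protocol.s2_resolution
    brackets = []
    for s1 in protocol.erp_s1_list:
        erp = truth.erp_by_s1.get(s1, truth.erp if s1 == truth.s1 else None)
        if erp is None:
            raise ValueError(f"no ground-truth ERP supplied for S1={s1}")
        lower = res * np.floor(erp / res)
        if not (lower < erp < lower + res):
            raise ValueError(f"true ERP {erp} not strictly inside its bracket; "
                             "pass a continuous threshold (e.g. erp + 0.5)")
        brackets.append(ERPBracket(s1=s1, lower=float(lower), width=res))
    return cv_obs, apd_obs, brackets


@dataclass
class TrainingDataset:
    """Simulated training data over a design, with the exclusion log.

    Row i of every matrix corresponds to row i of ``design`` (curve
    matrices) or ``erp_design`` (ERP matrix).  ``exclusions`` maps design
    indices to a reason string; excluded runs appear in no matrix.
    """

    design: np.ndarray                 # retained runs, (n_keep, m)
    cv_curves: np.ndarray | None       # (n_keep, d) resampled CV(S2)
    apd_curves: np.ndarray | None      # (n_keep, d) resampled APD(S2)
    grid: np.ndarray | None
    runs: list                         # RestitutionRun per retained row
    fits: list                         # (cv_fit, apd_fit) per retained row
    erp_design: np.ndarray | None      # rows with a fully defined ERP(S1) curve
    erp_matrix: np.ndarray | None      # (n_erp, len(s1_list))
    erp_s1_list: np.ndarray | None
    exclusions: dict
    n_design: int


def build_training_dataset(design: np.ndarray, simulator: CableSimulator | None = None,
                           s1_curve: float | None = 600.0,
                           erp_s1_list: Sequence[float] | None = None,
                           grid: CurveGrid = CurveGrid(),
                           erp_max: float = 350.0,
                           progress: bool = False) -> TrainingDataset:
    """Run the simulator over a design and assemble training matrices.

    With ``s1_curve`` set, each run produces CV(S2)/APD(S2) restitution
    points at that S1, fitted and resampled to ``grid``; runs whose ERP at
    ``s1_curve`` is >= ``erp_max`` are excluded (the exclusion rule that
    keeps every retained curve measurable over the S1 range of interest).
    With ``erp_s1_list`` set, each run additionally contributes an ERP(S1)
    row, excluded when ERP is undefined at any S1.  Per-run failures are
    logged and excluded, never fatal.
    """
    simulator = simulator or CableSimulator()
    design = np.atleast_2d(np.asarray(design, dtype=float))
    keep_rows, runs, fits, cv_rows, apd_rows = [], [], [], [], []
    erp_rows, erp_keep = [], []
    exclusions: dict[int, str] = {}
    gridv = grid.values()

    for i, row in enumerate(design):
        x = TransformedParams.from_array(row)
        if s1_curve is not None:
            try:
                run = simulator.s1s2_bisection(x, s1_curve)
            except (CaptureFailure, ProtocolError) as err:
                exclusions[i] = f"s1s2 at S1={s1_curve}: {err}"
                continue
            if run.erp >= erp_max:
                exclusions[i] = f"ERP(S1={s1_curve:g}) = {run.erp} >= {erp_max:g}"
                continue
            # Measurement validity: an apparent CV above the tissue's own
            # plane-wave maximum cannot be a propagated front speed (it is the
            # quasi-synchronous activation regime just above ERP); and each
            # channel's descending head near ERP is the conduction-delay
            # artifact, trimmed before fitting.
            cv = run.cv.copy()
            cv[cv > 1.1 * x.cv_max] = np.nan
            mc = np.isfinite(cv)
            ma = np.isfinite(run.apd)
            try:
                cv_fit = fit_restitution(*trim_nonmonotone_head(run.s2[mc], cv[mc]))
                apd_fit = fit_restitution(*trim_nonmonotone_head(run.s2[ma], run.apd[ma]))
            except (ValueError, RuntimeError) as err:
                exclusions[i] = f"curve fit: {err}"
                continue
            keep_rows.append(i)
            runs.append(run)
            fits.append((cv_fit, apd_fit))
            cv_rows.append(resample(cv_fit, grid))
            apd_rows.append(resample(apd_fit, grid))
        if erp_s1_list is not None:
            erps = simulator.erp_restitution(x, list(erp_s1_list))
            if erps is None:
                exclusions.setdefault(i, "ERP(S1) undefined for some S1")
            else:
                erp_rows.append(erps)
                erp_keep.append(i)
        if progress:  # pragma: no cover
            print(f"  run {i + 1}/{design.shape[0]}", end="\r", flush=True)

    has_curves = s1_curve is not None
    return TrainingDataset(
        design=design[keep_rows] if has_curves else design[erp_keep],
        cv_curves=np.array(cv_rows) if has_curves else None,
        apd_curves=np.array(apd_rows) if has_curves else None,
        grid=gridv if has_curves else None,
        runs=runs,
        fits=fits,
        erp_design=design[erp_keep] if erp_s1_list is not None else None,
        erp_matrix=np.array(erp_rows) if erp_s1_list is not None else None,
        erp_s1_list=np.asarray(erp_s1_list, dtype=float) if erp_s1_list is not None else None,
        exclusions=exclusions,
        n_design=design.shape[0],
    )
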