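# Methods

This note records the modeling choices, pinned numerical settings, and known
limitations of `rcemu`, in the order the pipeline runs.

## Tissue model and discretization

The modified Mitchell–Schaeffer (mMS) monodomain model is solved on a 1D
cable of length 24 mm with dx = 0.3 mm (81 nodes) and no-flux boundaries —
a 1D stand-in for a thin quasi-1D tissue strip with isotropic diffusion.
Working units are mm and ms, so conduction velocities in mm/ms coincide
numerically with m/s.

Time stepping is operator splitting at dt = 0.1 ms: diffusion by
Crank–Nicolson (a tridiagonal Thomas solve per step; explicit diffusion is
unstable over the design box, where D·dt/dx² reaches ≈ 2.3), then the local
reaction terms by forward Euler in 10 sub-steps of 0.01 ms.  The gate update
is a convex combination at this sub-step size, so h ∈ [0, 1] is preserved
exactly, and the conservative Neumann stencil conserves the spatial mean of
Vm under pure diffusion to solver roundoff.  When the cable is quiescent
(max |Vm| < 1e-10) and no stimulus is pending, the gate recovery
h(t) = 1 − (1−h0)e^(−t/τopen) is advanced analytically to the next event;
this changes nothing beyond the 1e-10 voltage cutoff and makes long
diastolic intervals cheap.

Verification: the zero-diffusion kernel matches a reference ODE solve
(solve_ivp, rtol 1e-10) to ~4e-5 relative APD; halving dx and dt moves
center-of-box CV and APD by well under 5%; plane-wave CV at long S2 is
within 3% of CVmax at the reference discretization.  Note that the
asymptotic APDmax parameter corresponds to the *plateau* duration (time
above the 0.7 threshold, matched within ~1–3%); the measured APD90
(0.7 up-crossing to 0.1 down-crossing) is systematically longer because it
includes the sub-plateau repolarization tail, and in tissue it also grows
with the diffusion coefficient.  The parameterization is a bijection, so
this offsets nothing downstream.

## Pacing protocol and measurements

Stimulus (not fully determined by the physiology): Jstim = 1.0 /ms on the
3 nodes at one end for 2 ms — comfortably suprathreshold over the whole
design box.  Prepacing applies 8 S1 beats; the state is saved 20 ms after
the final S1 onset (a snapshot offset long enough for the stimulus to end,
short enough that the final wave is still en route; beats 7 and 8 differ by
< 1 ms in APD at S1 = 600).  Each S2 trial reloads the snapshot.

Capture and measurement both subtract a reference run (the snapshot evolved
with no premature stimulus), so activations belonging to the final paced
beat are never attributed to the premature beat.  ERP is bisected on
integer S2 from the bracket [100, 2000] ms to 1 ms resolution: the largest
S2 whose stimulus does not propagate to the strip center.  CV is measured
between the nodes nearest 40% and 60% of strip length from 0.7-threshold
up-crossing times; APD90 at the center node from the 0.7 up-crossing to the
following 0.1 down-crossing.

Near-ERP measurement validity.  One to a few ms above ERP the premature
front crawls while the tissue ahead finishes recovering, then accelerates
sharply; the measurement region can activate quasi-synchronously.  Three
rules handle this regime: (i) CV is reported only when activation passes
the region in spatial order (a → center → b); (ii) an apparent CV above
1.1·CVmax cannot be a propagated front speed and is reported as
unmeasurable; (iii) the strictly descending head of each measured series
(restitution is monotone increasing in S2; the descending head is the
conduction-delay artifact of indexing by the pacing interval) is trimmed
before curve fitting.  Without these rules single runs dominate the PCA of
the resampled dataset.

## Curve fitting, resampling, and PCA

Each run's (S2, value) points are fitted with F(S2) = a(1 − b·e^(−S2/c)) by
multistart nonlinear least squares with a soft-L1 loss (scale 2% of the
curve amplitude).  Internally the fit is parameterized by the relative
curve value w = F(160)/a at the resampling grid start, bounded to [−6, 7]:
the same model family, but near-flat noisy series (e.g. conduction pinned
at the lattice limit at τin ≈ 0.01 ms) no longer admit b ~ 1e12 solutions
whose extrapolation below the data reaches thousands of amplitudes.  The
virtual region (grid points below a run's ERP) is extrapolation by
construction, exists only so all curves share one grid for PCA, and is
never consumed by calibration.

Curves are resampled to the 160–600 ms grid at 1 ms (441 points,
endpoints inclusive).  PCA is centered and unscaled (units are homogeneous
along a curve and amplitude is meaningful), via SVD; explained-variance
ratios are stored relative to total variance, with the share of the
retained variance derived from them.  ERP(S1) curves (S1 350–700 ms) use
the simulated values directly with no resampling; runs with ERP undefined
at any S1 (capture failure or ERP ≥ S1) are excluded from the ERP dataset.
For the S1:600 curve dataset the exclusion rule is ERP(S1:600) < 350 ms,
which keeps every retained curve measurable over the S1 range of interest.

## Gaussian-process emulators

Inputs are scaled affinely to the unit box from the design ranges
(CVmax 0.1–1.5 m/s, τin 0.01–0.30 ms, τout 1–30 ms, τopen 65–215 ms,
APDmax 120–270 ms).  Each PCA coordinate gets an independent GP with
linear mean basis h(x) = (1, x), ARD squared-exponential kernel, and a
*relative* nugget (observation variance (νσ)²).  Basis coefficients β̂ and
amplitude σ̂² are profiled out with the (n − q) divisor, and (log θ, log ν)
maximize the profiled marginal likelihood by L-BFGS-B from 8 multistarts
(θ starts log-uniform in [0.05, 5] scaled units, ν starts cycling
{1e-4, 1e-2, 1e-1}; bounds θ ∈ [1e-2, 1e2], ν ∈ [1e-8, 10]; Cholesky
jitter 1e-10 escalated ×10 to at most 1e-6).  All fits are deterministic
given a seed.  Predictions include the basis-uncertainty covariance term;
curve posteriors are Φ0 + Ψ[M_c] with covariance Ψ diag(V_c) Ψᵀ, rank ≤ C.
C = 3 for S2 curves and C = 2 for ERP(S1), both overridable.

Cross-validation uses contiguous folds of a seeded shuffle; per-grid-point
R² = 1 − SSE/SST is computed on each held-out fold (SST on the fold) and
averaged over folds.  Grid points with no variance in a fold score 1 for a
perfect prediction and 0 otherwise.

## Sensitivity analysis

Sobol indices are estimated on the posterior *mean* of each coordinate
(emulator uncertainty is not propagated into the indices).  Sampling is
Saltelli's scheme on a scrambled Sobol sequence (base size a power of two;
default 2048; blocks A, B, AB_i, BA_i), with the Saltelli-2010 first-order
and total-effect estimators and the Saltelli-2002 second-order estimator.
Small negative estimates are ordinary Monte-Carlo behavior and are
reported as-is.  The estimators reproduce the closed-form Ishigami
decomposition to within 0.02 at base size 4096.

## Calibration

CV and APD points use homoscedastic Gaussian likelihoods around the RCE
posterior, Y ~ N(M(x), V(x) + σ²I), with a separate σ per channel (the
channels have different units).  ERP is observed only as the 10 ms-wide
protocol interval containing it; writing Y for the bracket's lower edge,
the error ERP − Y is modeled as a mixture of N = 10 Gaussians with means
(i − ½)·ΔS2/N (the centers of N regular sub-intervals) and common
sd ΔS2/N, giving the analytic likelihood
p(Y|x) = Σᵢ N⁻¹·Normal(Y; M − mᵢ, s² + V): an exact density with infinite
support, evaluated with logsumexp, and nearly flat (< 0.5 log units) while
the prediction sweeps the central 80% of the bracket.  At N = 10 about 92%
of the error mass falls inside the bracket; more terms sharpen the edges.

The prior over x is uniform on the design box; noise scales get a
log-uniform prior on [1e-3, 10] channel units.  MAP is the best of 16
bounded L-BFGS-B starts (Latin-hypercube over the box) on (x, log σ).
MCMC is the affine-invariant ensemble sampler: 32 walkers initialized at
the MAP plus 1e-4-of-range jitter, 2000 iterations, burn-in 1000, thinning
5, with σ fixed at its MAP value by default (`sample_noise` includes it).
Synthetic sessions include a replicate observation at S2 = S1 for every
premature-beat observation, which is what pins the noise scales down.

## Synthetic data and study conditions

The measurement generator emulates a clinical S1S2 session: S2 grid
170–360 ms at 10 ms, Gaussian noise sd 0.05 m/s (CV) and 5 ms (APD),
points below the true ERP discarded, ERP brackets at S1 600/500/400 ms.
Simulated ground-truth ERPs are integers (1 ms bisection); the continuous
threshold is taken as ERP + 0.5 ms so brackets strictly contain it.
Designs are maximin Latin hypercubes: the best of 200 candidate LHS draws
by minimum pairwise distance (candidate count configurable; the criterion
stabilizes well before the ~10⁴ draws one would use offline).

What the generator does *not* emulate: spatial heterogeneity of tissue
parameters, measurement-location uncertainty, catheter contact artifacts,
beat-to-beat variability, and model discrepancy beyond the noise variance.
Passing the recovery tests therefore demonstrates identifiability under
the stated protocol and an exactly-specified tissue model, not robustness
to real clinical data.

## Problem sizes and reproducibility

The reduced-scale study conditions used by the test-suite ensembles are a
150-point design for the S1:600 curve dataset and a 100-point design for
ERP(S1) at 50 ms S1 spacing; the acceptance script runs the curve dataset
at the full 500-point design size.  All randomness flows from explicit
seeds; repeated runs are bit-identical.

## Known limitations

- The two-node CV estimator is undefined in the quasi-synchronous
  activation regime just above ERP (handled by the validity rules above);
  an activation-time regression over many nodes would degrade more
  gracefully but would not remove the regime itself.
- At τin near 0.01 ms the depolarization front is far narrower than dx and
  conduction is lattice-limited: CV restitution for such runs is nearly
  flat and its absolute level is discretization-dependent.
- The retained-variance split between the first two CV components is
  sensitive to how the near-ERP measurements are treated, since those
  anchor the virtual-region extrapolation; the split should be read as a
  qualitative summary rather than a sharp statistic.
- Emulators extrapolate outside the design box without error (flagged via
  `RCE.in_box`); calibration confines itself to the box by prior.
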