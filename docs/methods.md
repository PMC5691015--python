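# Methods

## The backscatter model

`ebfkit` models the dose enhancement produced by electrons backscattered
from a lead slab inside tissue. The central quantity is the electron
backscatter factor at upstream distance `t` from the Pb face,

    EBF(Em, t) = 1 + (EBF(Em) - 1) · exp(-k(Em) · t)

with the interface factor and decay coefficient

    EBF(Em) = 1 + C1 e^{-C2 Em} - C3 e^{-C4 Em}
    k(Em)   = max(0, -C5 ln(Em) + C6)

where `Em` (MeV) is the mean electron energy at the Pb surface and `t` is
in mm. The decay acts on the *enhancement* `EBF - 1`, never the full
factor: the backscatter contribution dies away with distance, but the
primary dose remains, so `EBF(Em, t) ≥ 1` everywhere and
`EBF(Em, 0) = EBF(Em)` exactly. The two exponentials encode the competing
physics: backscatter probability grows with the atomic-number contrast at
low energy but the backscattered electrons are increasingly forward-peaked
and short-ranged, so the enhancement rises with energy to a maximum near
3.5 MeV (closed form: `Em* = ln(C3 C4 / C1 C2)/(C4 - C2)`) and declines
slowly beyond. The decay coefficient falls logarithmically with energy —
faster electrons backscatter with longer residual range and reach farther
upstream.

`Em` is mapped from depth by the linear approximation
`Em = E0 (1 - z/Rp)`, with `E0 = 2.33 · R50[cm]`. Assumptions inherited by
everything downstream: central-axis point quantities only, saturation-thick
Pb (thicker slabs would not increase backscatter), and no modelling of Pb
transmission, photon contamination, off-axis behaviour, or materials other
than Pb.

### Parameters

| name | meaning | units | packaged default (95% CI) |
|------|---------|-------|---------------------------|
| C1, C3 | interface amplitudes | – | 0.936 ± 0.132, 0.602 ± 0.126 |
| C2, C4 | interface rates | 1/MeV | 0.089 ± 0.012, 0.375 ± 0.065 |
| C5 | decay slope on ln(Em) | 1/mm | 0.130 ± 0.004 |
| C6 | decay intercept | 1/mm | 0.413 ± 0.006 |

The default set is machine-specific (fitted to one vendor's electron
beams); the fitting module exists precisely so the coefficients can be
re-derived for other machines. Validated energy window: 0.2–14 MeV.
Evaluations outside it warn by default; `strict=True` turns the warning
into an error. The legacy single-exponential interface model
(`1 + 0.735 e^{-0.052 Em}`, valid 3–35 MeV) and the legacy upstream
intensity `A e^{-kt}` (constants user-supplied) are provided for
comparison only.

### Edge cases and clamps

* `z ≥ Rp` clamps `Em` to 0: no primary electrons, hence no backscatter.
  `EBF(0, t>0) = 1` (the `k → ∞` limit as `Em → 0`), while `EBF(0)` itself
  evaluates the closed form (`1 + C1 - C3`) for continuity at `t = 0`.
* `k(Em)` would turn negative above `Em = e^{C6/C5} ≈ 24` MeV (outside the
  validated window); it is clamped to 0 with a warning.
* `enhancement_range` (distance at which the enhancement falls to a target
  ε) and `peak_enhancement_energy` are closed forms, cross-checked in the
  tests against bisection and grid-search oracles to 1e-6 relative.

## Depth-dose handling

Curves are relative dose at voxel centres on a strictly increasing mm
grid, exchanged as `depth_mm,dose` CSV (written at 17 significant digits
and parsed with round-trip float precision, so file I/O is lossless).
Normalization scales the central-axis maximum to exactly 100.

**Beam quality.** R50 is the distal 50% crossing by linear interpolation.
Rp uses the standard practical-range construction: the tangent at the
steepest distal gradient extrapolated to the bremsstrahlung-tail level
(mean dose over the last 10% of the grid). The steepest point and slope are
refined by a parabolic fit to the discrete gradient, which keeps the
grid-resolution error well inside half a voxel on 1 mm grids.

**Extraction.** With/without-Pb pairs are divided voxel by voxel on
identical grids (an explicit `resample` option interpolates the *reference*
curve only — the Pb curve carries the sharp interface and is never
interpolated). Each upstream ratio is an observation at its geometric
`t = interface depth − voxel centre`; the first upstream voxel is flagged
as the interface value. Convention: the interface EBF is *attributed* to
the centre of the first upstream voxel but treated as `t = 0` in fitting
and prediction (a switch, `interface_at_t0`, selects the geometric
`t = voxel/2` instead). Prediction applies the model symmetrically, so
extraction inverts prediction exactly on noise-free data — the pipeline's
primary self-consistency oracle. Dose at and beyond the interface is set to
0 (saturation Pb; transmission out of scope), and the output is not
re-normalized.

## Staged fitting

The coefficients are estimated in the same order the model is composed,
not as a one-shot six-parameter fit (a simultaneous fit is deliberately a
non-goal; the staged route matches how the model is defined and keeps each
stage diagnosable):

1. **Interface stage (C1–C4).** Trust-region nonlinear least squares with
   positivity bounds, start `(1.0, 0.05, 0.5, 0.4)` (the magnitudes of the
   legacy model), tight tolerances (1e-14), and three perturbed restarts;
   a non-converged fit is returned flagged, never silently. At least 8
   observations spanning ≥ 5 MeV are required — two exponentials are not
   identifiable from a narrow window. Under the (+, −) positivity-bounded
   parametrization the two exponential terms are not exchangeable (swapping
   them would require negating amplitudes), so there is no label-switching
   ambiguity to resolve; the expected ordering `c2 < c4` is recorded in the
   diagnostics and warned about if violated.
2. **Per-energy decay stage.** For each interface energy, `k` is the
   negated slope of the ordinary least-squares line through
   `ln(EBF(t) − 1)` vs `t`. Points with non-positive enhancement are
   dropped with a warning, and points whose enhancement falls below 5% of
   the profile's maximum are excluded: far upstream the enhancement sinks
   into the statistical noise of the dose ratio, where the log transform
   amplifies noise without bound and keeping only the positive fluctuations
   (the negative ones being undefined in log space) would bias the slope
   flat. On noise-free data the exclusion is inert — the retained points
   lie on the exact line.
3. **Decay-model stage (C5, C6).** Ordinary least squares of the
   per-energy `k` values on `ln(Em)`.

Confidence intervals are asymptotic at the 95% level (Jacobian-based
`t`-intervals for the nonlinear stage, regression standard errors for the
linear stages); a case-resampling bootstrap is available as an option for
the interface stage. Coverage of the asymptotic intervals is verified by
simulation in the test suite (200 replicates at 1% noise; observed rates
0.91–0.97 per coefficient). The composite fit reports the RMSE of the
composed model over all input observations.

## Synthetic data

The generator provides ground-truth-known inputs with the statistical
structure of MC-scored curves: 1 mm voxel centres at `(i + ½)` mm,
independent multiplicative Gaussian noise of relative sd 0.2% per voxel per
curve (the defaults *are* the study conditions the pipeline targets), and
paired with/without-Pb runs sharing one dose scale. Seeding uses
`numpy.random.default_rng` with per-interface substreams, so identical
configurations reproduce byte-identical files.

The reference PDD shape is an analytic stand-in, not transport physics: a
Gaussian build-up (surface fraction 0.85) to the dose maximum, times a
logistic distal falloff, plus a constant 1.5% bremsstrahlung tail. The two
falloff parameters are calibrated numerically (fixed-point iteration on the
50% crossing; the tangent construction on a logistic extrapolates to
`z50 + 2w`, fixing the width) so that the beam-quality routines recover
each preset's declared R50 and Rp to within half a voxel — the round trip
is itself a test. Four presets carry plausible clinical beam parameters
(R50/Rp = 23.5/30, 36/45.5, 48.5/60.5, 63/78 mm for the 6/9/12/15 MeV
classes; E0 fixed by `2.33·R50`), chosen so the standard interface-depth
schedules (6 MeV: 3–29 mm step 1; 9: 3–45 step 2; 12: 3–60 step 3;
15: 4–76 step 4) span interface energies from roughly 0.2 to 14 MeV with
88 distinct energies. The exact per-machine values are declared stand-ins
in a packaged JSON, not reproductions of any measured beam.

What passing tests on this generator do show: the extraction, fitting and
prediction machinery is exact and self-consistent, and robust at the
stated noise level. What they do not show: fidelity of any analytic shape
to a real linac's PDD, energy-spectrum effects (the mean-energy
approximation is known to blur machine differences), photon contamination,
or detector response — validating the coefficients for a specific machine
still requires that machine's data. A 2.4% dose-noise option mimicking
film-dosimetry uncertainty exists for validation-style runs of the
deviation statistics.

## Problem sizes

The default end-to-end runs fit comfortably at desk scale: the four-preset
observation set is ~2350 observations (88 curve pairs of 55–122 voxels),
the staged fit takes well under a second, and the confidence-interval
simulation uses 200 replicates of a 60-observation interface fit. The
acceptance script's stochastic target re-runs the four-preset pipeline once
at 0.2% noise.

## Known limitations

* The composed model is empirical; coefficients transfer across machines
  only approximately, and the low-energy region (< 0.5 MeV) rests on few
  observations in any realistic schedule.
* The mean-energy depth mapping is a linear approximation derived for
  near-monoenergetic beams; its error grows near `Rp`.
* Saturation-thickness Pb is assumed; partial-thickness slabs backscatter
  less and transmit dose distally, neither of which is modelled.
* The per-energy decay fit needs ≥ 3 resolved upstream points; very
  shallow interfaces (< 3 mm) or very noisy profiles fall back to fewer
  energies in the decay-model regression.
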