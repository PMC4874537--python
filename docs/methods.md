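# Methods

This note documents the models implemented in `spinevolt`, the parameter
choices that matter, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer would want to know about.

## Signal chain for single-voxel VSD sweeps

Optical sweeps are processed in the order: artifact removal → low-pass
filtering → baseline subtraction → noise estimation → detection and fitting.

**Artifact removal.** The 0.5 ms uncaging pulse saturates the detector; the
affected samples are replaced by linear interpolation between the window
edges. This is exact for locally linear signals and happens before any
filtering so the artifact cannot ring through the filters.

**Filtering.** EPSP sweeps: 3rd-order Chebyshev type I low-pass, 0.35 kHz
cutoff, 0.5 dB passband ripple (the ripple is a package default — the odd
order makes the DC gain exactly 1), applied to the *time-reversed* sweep so
the filter's start-up transient falls at the sweep end rather than on the
EPSP onset, followed by a 2.5 ms boxcar moving average run forward. Both
passes are initialised at steady state for the first processed sample;
without that, the ~10³-count DC level of raw fluorescence produces edge
transients large enough to corrupt the baseline fit. bAP sweeps: 5th-order
Chebyshev type I at 1 kHz applied forward–backward (zero phase). A
measured chain impulse response is exposed
(`vsd.chain_impulse_response`) for filter-aware fitting (below).

**Baseline.** Photobleaching with a slow settling transient of the power
modulator is modelled as
F₀·(1 + a_on·e^(−t/τ_on))·(1 − a_bl·(1 − e^(−t/τ_bl))) and fitted by
Nelder–Mead simplex on normalised parameters with multi-starts over
time-constant decades plus jittered restarts. In the pipeline the baseline
is fitted on the averaged *uncaging* sweep itself with the response window
excluded, so the sweep's own slow noise is absorbed into the fit; fitting
on the control average and subtracting leaves that noise in place and
roughly quadruples the Monte-Carlo amplitude scatter. The control average
gets a separate fit for noise estimation.

**Noise and detection.** σ_noise is the median SD within a moving 5 ms
window on the baseline-subtracted, filtered control average (median rather
than mean so a transient occupying a few windows cannot inflate it;
configurable). The detection threshold is exactly 2.5·σ_noise. Because the
chain passes 0–350 Hz but a 5 ms window only "sees" fluctuation faster than
~100 Hz, σ_noise understates the total post-chain noise; threshold crossing
alone therefore false-triggers on slow wander. A transient counts as
detected only if additionally the *fitted* amplitude exceeds the threshold,
the fitted onset lies within [−5, +10] ms of the uncaging pulse, and the
fitted FWHM is within 0.5–80 ms. On null (zero-amplitude) synthetic cohorts
these gates reduce false positives from ~50% to ~0 while rejecting about 1
in 100 genuine transients at 4× threshold. Sub-threshold spines report
2.5·σ_noise as an upper amplitude limit.

**Transient fitting.** The alpha-like waveform K(e^(−k₂t) − e^(−k₁t)) is
fitted by least squares with the ordering k₁ > k₂ > 0 enforced through the
parameterisation (log k₂, log(k₁/k₂ − 1)); initialisation uses
k₂ = ln2/FWHM-guess, k₁ = 10k₂ and K from the observed peak; the onset is a
free parameter. The degenerate k₁ → k₂ limit K·k·t·e^(−kt) is evaluated
explicitly when |k₁−k₂| < 10⁻⁶. By default the pipeline fits
*filter-aware*: the candidate waveform is convolved with the chain impulse
response before comparison, so fitted parameters describe the unfiltered
transient. A naive fit of the filtered trace carries a ≈5% amplitude and
≈8% FWHM bias (the chain is not alpha-shape-preserving); the filter-aware
fit is exact on noiseless data. Amplitude and FWHM come from closed forms /
root finding on the fitted curve, verified against dense-grid evaluation to
10⁻⁶ relative.

## Calibration to millivolts

The dye's normalised voltage response is y(u) = s·u + (1−s)·u² on
u = v/V_AP, pinned to y(0) = 0 and y(V_AP) = 1, with small-signal fraction
s = 0.65 by default. "Sensitivity at the AP peak" is interpreted as the
secant (total ΔF/F over AP amplitude). Per spine, the peak sensitivity is
optical-bAP-peak / (somatic AP × e^(−d/λ)) with λ = 400 μm along basal
dendrites; the somatic AP amplitude defaults to 100 mV when not recorded —
this default reproduces the 5.5 mV worked detection limit. EPSP amplitudes
are converted by inverting the quadratic (numerically stable positive
root); detection limits use the small-signal linear sensitivity directly,
which is the regime they live in and matches the printed worked example
(the full quadratic inversion of the same example gives 5.36 mV).
Switching λ rescales each spine by its own e^(−d/λ) factor; amplitude
*ordering* is only guaranteed unchanged among spines at equal distance.

## FRAP and the diffusion route to R_neck

Recovery is fitted as F(t) = F∞ − (F∞ − F_b)e^(−t/τ_eq) with log-linear
initialisation and nonlinear refinement. Fits are flagged undefined when
the bleach depth is below twice the pre-bleach noise SD, when the recovery
amplitude is non-positive, or when τ exceeds 5× the monitoring window
(unmeasurable from the trace; without this guard occasional runaway fits
produce absurd resistances). Conversion uses
R_neck = R_a·τ_eq·D/Vol_head with R_a = 150 Ω·cm and D = 380 μm²/s; all
unit factors (Ω·cm → Ω·μm: 10⁴; ms → s; Ω → MΩ) live in one frozen
constants object. Hand checks: τ = 95 ms, Vol = 0.1 μm³ → 541.5 MΩ;
τ = 72 ms, Vol = 0.2 μm³ → 205.2 MΩ.

## Sub-resolution volume estimation

The PSF is an anisotropic Gaussian with FWHM 0.422, 0.526, 1.16 μm (x, y,
z), σ = FWHM/2.3548 per axis; kernels are unit-sum and convolution
conserves intensity. PSF measurement from a bead stack fits 1-D Gaussians
to the profiles through the brightest voxel and removes the bead diameter
in quadrature; more than one bright region is an error.

The dilution ratio is (max in spine ROI)/(max in dendrite ROI) on the
z-maximum projection after clipping above the 99.9th percentile and 3×3
mean smoothing. Candidate shapes are erosions/dilations (6-connected) of
the segmented head. Morphology runs on a fine isotropic working grid
(default 0.06 μm): at native anisotropy (0.029 × 0.029 × 0.3 μm) one
erosion step removes an entire 0.3 μm z-shell, which can erase a
sub-resolution head outright. Each unit-intensity candidate is blurred
with the PSF; its peak predicts the dilution ratio it would produce
against a fully resolved dendrite, and the estimate interpolates linearly
in volume between the two candidates bracketing the measured ratio (the
nearest candidate and its voxel-count volume are also reported). A 3-D
Pearson-correlation match against the observed stack is computed as a
cross-check when the stack is supplied; since all blurred candidates are
nearly Gaussian blobs the correlation criterion is weakly discriminating,
and a disagreement of more than one series step raises a flag rather than
changing the estimate. Measured performance on rendered spheres
0.05–0.5 μm³ at photon SNR 10: median |error| ≈ 10%, with a small negative
bias from partial-voxel rendering and the 3×3 smoothing of the projection.

## Passive cable model and the attenuation route to R_neck

Units are mV/ms/nA/μS/nF (so MΩ = mV/nA). Sections are cylinders with
uniform Cm = 0.75 μF/cm², Ra = 150 Ω·cm, Rm = 30,000 Ω·cm², resting
potential −70.35 mV. Dendritic sections carry a spine-membrane correction
factor F = 1.5 (Cm → F·Cm, Rm → Rm/F), standing in for spines not
explicitly modelled; the density behind this factor is a package
assumption. Compartments are ≤ 0.1 of the local DC length constant by
default (0.02 for attenuation sweeps, where site placement and distance
resolution matter); axial conductances combine half-compartment
resistances, and a spherical soma is one isopotential compartment.
Validation: an isolated sphere gives Rm/area exactly; a sealed 2 μm ×
200 μm cylinder gives R_∞·coth(L/λ) = 2.42 GΩ within 1%.

The explicit spine is a 1 μm × 1 μm cylindrical head (area π μm²) behind a
purely resistive neck: neck membrane area at realistic neck diameters
(R_neck = 200 MΩ at L = 1 μm ⇒ d = 0.0977 μm) is ≤ 0.3 μm², negligible
against the head. R_neck = 0 is handled exactly by merging the head into
its parent compartment. The synapse is a dual-exponential conductance
(rise 0.5 ms, fall 4 ms, peak G_syn, default 0.5 nS) with reversal
potential −5 mV absolute.

Integration is Crank–Nicolson; the time-varying synaptic conductance enters
as a rank-1 update on the head diagonal, handled by the Sherman–Morrison
formula so the system matrix is LU-factorised once per simulation and each
step costs one triangular solve. dt = 0.025 ms default; halving dt changes
peaks by < 0.1%, and the solver matches an adaptive LSODA reference
solution of the same equations to five digits.

The default morphology is a parameterised synthetic stand-in for a
layer-5 pyramidal cell — ten twice-bifurcating basal dendrites plus an
apical trunk with obliques and tuft — tuned once to a somatic input
resistance of ≈52 MΩ; real morphologies load from SWC. Attenuation sweeps
move the spine over basal compartments ≥ 30 μm from the soma, sampled
uniformly in arc length (117 sites by default; tests and the acceptance
script use 31 sites and a 6-point R_neck grid of 1–700 MΩ, since the
curves are smooth in distance and the quadratic fits are insensitive to
site count). Per R_neck the ratio-vs-distance cloud is summarised as
ratio(d) = c₀ + c₂·d² (a full quadratic is available); inversion evaluates
each curve at the experimental distance and interpolates linearly in
R_neck, flagging points below the zero-neck curve or above the grid.
Round-trip recovery of R_neck = 200 MΩ from held-out sites is within ±5%.

**Known limitation — G_syn sensitivity of the slope.** The attenuation
ratio is linear in R_neck (R² > 0.999). In the small-signal limit its slope
is also independent of G_syn (measured spread 0.3% over a 4× range). At
physiological conductances (0.25–1 nS here, somatic EPSPs ≈ 0.15–0.6 mV,
spine EPSPs ≈ 3–14 mV) the slope falls with G_syn by ≈ 6–11% across a 4×
range: the synaptic current g(t)(E_rev − v_head) flattens as the head
depolarises toward the −5 mV reversal, lowering the head peak (which
tracks peak current) relative to the somatic peak (which tracks filtered
charge). A passive spine cannot avoid this; voltage-gated conductances,
deliberately excluded from this core (their reported effect on inferred
R_neck is ≤ ~5–21% depending on the parameter), are the plausible
compensating factor in fuller models. Practically, an unknown G_syn within
a 4× band contributes ≲ 10% uncertainty to inferred R_neck, small against
the biological spread.

## Synthetic data: what it emulates, and what it does not

Cohorts draw EPSP amplitude from a normal truncated at 0 (13.0 ± 6.7 mV),
half-width likewise (11.7 ± 4.3 ms), optical bAP peak 21.9 ± 4.9 %ΔF/F,
distances uniform 30–110 μm, and R_neck and head volume from log-normals
(R_neck matched to mean 204 / median 161 MΩ; volume median 0.25 μm³,
σ_log = 0.5 — chosen so that τ_eq, *derived* from R_neck and volume through
the diffusion relation, lands at the reported mean ≈ 95 / median ≈ 72 ms).
Deriving τ_eq rather than sampling it keeps the FRAP arm and the
attenuation arm consistent with a single ground truth, which is what the
cross-method consistency checks exercise. Identical seed and configuration
give bit-identical outputs (salts are CRC-based, independent of process
hash randomisation).

VSD sweeps are generated at 50 kHz rather than the instrument's 5 MHz: the
0.35 kHz filter chain makes everything downstream invariant to this choice
while keeping arrays small. Shot noise is approximated as Gaussian with
SD ∝ √baseline (per-sample photon counts are high); the image generator
uses true Poisson noise, where counts are low. The per-spine noise level is
specified *operationally* as what the 5 ms-window estimator reports
post-chain, and the generator calibrates the injected white noise through a
seeded deterministic simulation of the chain; closed-loop recovery is
within a few percent. Not emulated: correlated (non-white) noise such as
mechanical drift or dye internalisation dynamics, uncaging-power drift
across trials, multi-spine crosstalk, and dendrite-to-dendrite variability
of bAP attenuation (λ is a single scalar). Passing tests therefore show the
chain is correct and well-calibrated under its stated noise model, not that
it is robust to every instrumental pathology of real recordings.

## Statistics

Cohort summaries report N, mean, SD, SE, median, min, max and a
percentile-bootstrap 95% CI of the mean (400,000 resamples by default,
seeded, computed in memory-bounded blocks; test profiles use 10,000). The
two R_neck routes are compared with the two-sample Kolmogorov–Smirnov test;
under the null, the rejection rate at α = 0.05 is calibrated (the exact
p-value is discrete at these sample sizes, so the p distribution is only
approximately uniform). With both arms drawing from one R_neck distribution
(FRAP arm n = 34 at 5% recovery noise, model arm n = 19 at 8% ratio noise),
p > 0.05 in ≈ 92% of seeded runs.

## Problem sizes

Default test and acceptance runs use: 100-trace Monte-Carlo for fit
recovery, 100 seeds for FRAP, 50 rendered scenes for volume, 31 sites ×
6 R_neck values for attenuation curves, 19/34-spine cohorts, and 40 runs
for the consistency rate. These sizes give stable medians and rates while
keeping a full run in tens of seconds; all are parameters.
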