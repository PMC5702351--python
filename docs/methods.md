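# Methods

This note documents the models, conventions and numerical choices behind
`tectumds`, and what the synthetic-data generator does and does not emulate.

## Synthetic data

**Tuning model.** A direction-selective (DS) cell responds with
`baseline + amplitude · exp(κ(cos(θ−μ) − 1))`: a von Mises shape normalized
to peak 1, so `amplitude` carries scale and `κ` carries width independently.
Orientation-selective (OS) cells use the axial variant with the angular
offset doubled (period 180°); untuned cells respond at `baseline` regardless
of direction.  Subtype concentrations are inverted from mean bandwidths via
`κ = ln2 / (1 − cos(FWHM/2))`.

**Population defaults.** The default population mirrors the emulated
interneuron sample: 177 DS cells drawn around peaks 9°/156°/257° with
bandwidths 69°/83°/125°, 8 OS and 5 untuned cells (190 total).  DS preferred
directions are wrapped-normal draws around the subtype peaks with a circular
SD of 15° — chosen once as a realistic within-subtype scatter given ~10°
histogram bins and clearly separated subtype peaks; any circular unimodal law
would serve.  Subtype membership is an equal-probability draw unless weights
are supplied (the real subtype proportions are not part of the generator's
contract).  Default `amplitude=10`, `baseline=1`: responses an order of
magnitude above the direction-independent offset, as in well-responding
cells.

**Noise and SNR.** Response-level noise is i.i.d. Gaussian.  Where a
signal-to-noise ratio is specified it is the ratio of the signal's RMS
amplitude to the noise SD: `noise_sd = std_θ(tuned response) / SNR`, the
standard deviation taken across the protocol's directions — "SNR 5" means
the tuned modulation is five times the noise.  Untuned cells receive the
population median noise SD.  Stricter readings exist: defining SNR as a
power ratio multiplies the noise by √SNR, and defining it as peak amplitude
over noise SD multiplies it by roughly 2.6 for these tuning widths; under
the latter the R² > 0.7 gate alone caps DS classification near 86% with
12-point fits.  The adopted definition is stated wherever SNR appears.

**Traces.** Each stimulus epoch contributes a transient: the fade-in /
plateau / fade-out envelope convolved with a single-exponential indicator
kernel (τ = 1.5 s — indicator kinetics are not part of the modeled claims; a
single exponential suffices to exercise the preprocessing), scaled so its
rectangle-rule integral over the epoch window equals the cell's tuned
response.  The flat `baseline`, a low-frequency drift (sum of two
incommensurate sinusoids spanning ~1.5 and ~3.7 cycles per recording) and
Gaussian frame noise are added on top.  Epochs are separated by 6 s gray
intervals; a 2 s blank epoch is inserted at a seeded random position.
One presentation per direction is the default (`n_repeats` averages several).

**Determinism.** All draws flow from `numpy` `SeedSequence`s; per-cell
streams derive from (master seed, cell index), so datasets regenerate
bit-identically.

**What the generator does not emulate.** Optics, motion artifacts, neuropil
contamination, shot-noise statistics (noise is Gaussian, not Poisson),
photobleaching beyond smooth drift, and realistic subtype proportions.
Passing tests therefore demonstrate correctness of the analysis under its
own statistical assumptions, not robustness to every failure mode of real
recordings.

## Tuning analysis

**Preprocessing.** Median filter (kernel edge 3 voxels; 1 disables) then
Gaussian smoothing (σ = 2 voxels) per frame.  Baseline correction: knots are
5 s means taken from the tail end of each inter-epoch interval — the segment
farthest from the preceding epoch, where indicator transients have decayed
most — and a natural cubic spline through the knots is subtracted (division
for ΔF/F is available).  Natural boundary conditions tame extrapolation at
the recording edges.  Empirically the correction leaves < 2.5% of a strong
drift's amplitude behind, and full trace synthesis → correction → integration
recovers the generative responses within ~6% of the peak response (~12%
under strong drift), the residual coming from kernel-tail leakage into the
knots.

**Integral responses.** Rectangle rule over the epoch window (including
fades by default; configurable) divided by the sampling rate, units
fluorescence·s.  Frames are 0-indexed and windows half-open.  The blank
epoch is excluded from the response vector but kept for QC.

**Fits.** Both models — unimodal `b + A·exp(κ(cosΔ−1))` and its period-180
variant — are fit by bounded least squares (A ≥ 0, κ ∈ [1e−3, 1e3] on a log
scale) with multi-start over initial centers at every measured direction;
best SS_res wins, near-ties resolve toward lower κ.  R² = 1 − SS_res/SS_tot.
Constant response vectors are flagged degenerate (κ = 0, R² undefined).

**Indices.** Both indices are evaluated on the better-fitting model's curve,
floored at 0.  `DSI = (R_pref − R_null)/(R_pref + R_null)` with `R_pref` the
curve's maximum and `R_null` the value 180° away.  For OSI, the response at
an *orientation* is operationalized as the response shared by its two
opposite motion directions — the minimum of the fitted curve at θ and
θ + 180° — evaluated at the preferred orientation and 90° from it.  This is
the reading under which the joint threshold gates are mutually exclusive: a
purely direction-tuned cell has no opposite-direction response, so OSI ≈ 0
even when sharply tuned (any convention that scores raw period-180 energy
assigns OSI ≈ 0.9 to a sharp DS cell, making the DS gate unsatisfiable),
while a purely axial cell has DSI = 0 exactly.  Using fitted rather than raw
responses also keeps `R_null` meaningful when 180° from the peak falls
between measured directions.

**Bandwidth.** FWHM of the baseline-subtracted fitted curve,
`2·arccos(1 − ln2/κ)`, reported as 360° when κ < ln2/2 (the curve never
reaches half maximum).  Fitted-curve FWHM is the only convention with
sub-grid precision.

**Known estimator bias.** For broad tuning (FWHM ≳ 150°) the model is weakly
identified from 12 directions — near small κ the curve is approximately
`b′ + A′κ·cosΔ`, so κ, A and b trade off — and FWHM(κ) is steep and convex
there.  At SNR 5 the scatter of κ̂ biases the *mean* fitted FWHM upward by
~7–9% for 155°-wide generative tuning (and by ~15% if the noise is √5 times
larger), while the sharp 107° subtype is essentially unbiased and median
center errors stay around 2°.  The bias is a property of maximum-likelihood
fitting at these conditions, not of the optimizer.

## Population structure

Preferred angles of DS cells are binned at 10° (the bin width is not a
measured quantity; 10° resolves the narrowest subtype while keeping counts
per bin stable) and decomposed by constrained least squares into a sum of
von Mises bumps with free center, height ≥ 0 and concentration ≥ 0.
Multi-start places initial centers on the highest bins and on rotated even
grids; `scan_components` seeds each larger fit with the smaller fit's
solution so R² is non-decreasing in component count (component count itself
is a user decision; no automatic selection is claimed).  A component's angle
bounds are center ± FWHM/2; cells in overlapping bounds go to the circularly
nearer center, cells outside all bounds stay unassigned.  Polar summaries
min-max normalize each cell's responses to [0, 1] before averaging.

## Circuit model

**Structure.** Units R1–R3 (von Mises density drives, means 24°/124°/256°),
S1–S3, P1–P4.  Excitation: R_i → S_i, R1 → P1, R2 → P3, R3 → P4, and
{R1, R2} → P2.  Inhibition: all six ordered SIN pairs (reciprocal coupling)
and S1–S3 → P2.  No SIN inhibition onto P1/P3/P4 is assumed — tuned
inhibition is modeled only where it shapes the emergent population.  Weights
are edge indicators divisively normalized per matrix; with 0° = upward,
90° = rostral-to-caudal, 180° = downward, 270° = caudal-to-rostral.

**Dynamics and solvers.** τ = 1, dt = 0.01, convergence when the largest
rate change per unit time falls below 1e−9 (max 10⁶ steps); the fixed point
is τ-invariant, so τ is cosmetic.  Explicit Euler is the reference solver;
a damped Picard iteration on the rectified fixed-point equations (r* equals
the drive exactly; s iterates; p follows in closed form) is the fast path
and agrees with Euler to ≤ 1e−8, as does a direct linear solve whenever all
rectifiers are inactive.  Tuning curves use a 1° direction grid — fine
enough that preference shifts are not quantized to the 30° stimulus spacing.
The drive is the von Mises *density*, so RGC peak height falls with
bandwidth; all steady states are positively homogeneous in the drive scale,
so units of f are immaterial to preferences, DSI and FWHM.

**Concentration calibration.** Default κs invert the printed RGC bandwidths
(107°/155°/156°).  These leave the intact P2 preference near 32°: the upward
channel's density peak is much taller than the downward channel's, and P2's
peak location is set by the relative concentration of its two drives.  A
documented refinement step therefore searches a multiplicative factor grid
(step 0.005) on R1's κ — the one-dimensional family that directly controls
the R1:R2 balance — minimizing the circular distance between the intact P2
preference and the experimentally identified 90° direction; among optimal
factors the midpoint of the longest contiguous run is chosen, keeping the
solution off knife-edge plateau boundaries where solver-level differences
could flip the argmax.  The refined circuit prefers 90°, and the 44° shift
under S1 ablation is a consequence, not a target, of this calibration.
All κs remain overridable.

**Perturbations.** `no_reciprocal_SIN` zeroes the SIN–SIN matrix.  Ablation
removes the named SIN units and every edge touching them; by default the
surviving weights keep their intact strengths — removing a population does
not strengthen the synapses that remain, and divisive normalization is part
of constructing the intact circuit, not of each perturbation.  (Under the
alternative, re-normalizing after ablation, the S1-ablation shift grows to
55° and ablating S2 after S1 *decreases* P2's amplitude and bandwidth,
inverting the expected pattern; `renormalize=True` exposes that variant.)

**Metrics.** From the unnormalized curve: amplitude = max; preferred
direction = argmax (lowest angle on ties); DSI from the responses at the
preferred direction and its opposite; FWHM by half-maximum crossing search
on the grid with linear interpolation at the crossings; tuning error =
circular distance to the observed 90° preference.

**Degenerate inputs.** Constant tuning curves, zero-amplitude fits and
all-zero histograms raise or are flagged rather than silently producing
indices; `R_pref + R_null = 0` yields NaN and the cell falls into the
untuned class.

## Problem sizes

Monte-Carlo checks run at the sizes the analysis itself uses: 200 cells per
subtype for parameter recovery, the 190-cell default population for
classification, 500 draws for mixture recovery, a 1° grid (360 steady
states) per circuit condition, and 20 random circuits for solver
cross-checks.

## Limitations

Each model unit is one functional population; population sizes and synaptic
scaling are deliberately outside the model (scaling outgoing weights would
compensate any size factor).  No plasticity, spiking, or conductances.  The
refinement step calibrates one ratio against one observed direction; the
underlying adjusted concentrations of the original calibration are not
recoverable from printed values, which is why preference targets carry
tolerances.  The OSI operationalization is one documented choice among
several possible readings of "response at preferred orientation"; it is the
one that renders the published threshold gates jointly satisfiable.
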