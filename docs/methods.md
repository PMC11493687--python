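# Methods

`erplocsim` is a desk-scale simulation study of how head-model choice —
subject-specific vs. template geometry, detailed vs. simple shell
structure, and conductivity preset — degrades EEG source localization of
ERP networks. This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic data do and do not emulate.

## Forward model: layered conducting spheres

Head models are concentric spheres. The **detailed** model has four shells
— brain, CSF, skull, scalp — and plays the role of an FEM volume-conductor
model that resolves cerebrospinal fluid. The **simple** model has three
shells — brain, skull, scalp — and plays the role of a BEM surface model,
which cannot represent CSF. Three conductivity presets are provided (S/m,
innermost first):

| preset        | shells | values                          | role |
|---------------|--------|---------------------------------|------|
| `fem_meta`    | 4      | 0.47, 1.71, 0.006, 0.41         | meta-analysis conductivities; the **generating** model |
| `fem_default` | 4      | 0.33, 1.79, 0.008, 0.43         | common software defaults; "deviant conductivities" |
| `bem_default` | 3      | 0.33, 0.006, 0.33               | classic three-layer values |

The four-shell presets collapse a nine-tissue head to four shells: the
brain shell takes the gray-matter value, the skull shell the compact-bone
value, and the CSF and scalp shells their own values. White matter, spongy
bone, eyes, blood and muscle are not representable in concentric shells
and are dropped; these four compartments dominate EEG forward physics, but
the collapse is a documented limitation. Default radii are 83/87/92/100 mm
(four-shell) and 87/92/100 mm (three-shell), conventional spherical-head
values; all radii are configurable.

The potential of a current dipole in an N-layer sphere is computed from
the classical Legendre series: with dipole eccentricity `b`, outer radius
`R`, `t = b/R`, angle cosine `c` between dipole and electrode directions,

    V = 1/(4 pi sigma_brain R^2) * sum_n f_n (2n+1)/n t^(n-1)
        [ n P_n(c) (m.r0_hat) + P_n'(c) (m.(u - c r0_hat)) ],

where the per-order factors `f_n` solve the boundary-condition system
(potential and radial-current continuity at every interface, zero normal
current at the scalp). The system is solved per order as a small batched
linear solve in unit-sphere coordinates with per-shell-scaled unknowns,
which keeps matrix entries well-conditioned for realistic radius ratios.
The series is truncated where the geometric tail `t^n (n+1)^2` falls below
1e-10 of scale (hard cap 200 terms); doubling the truncation changes
potentials by <1e-8 relative. In the equal-conductivity limit the solver
matches the homogeneous-sphere closed form (obtained by summing the series
generating functions) to better than 1e-6 relative, and it agrees with an
independent multilayer-sphere implementation at the percent level (that
implementation approximates the kernel with fitted equivalent sources).
Leadfields are average-referenced; columns come in contiguous triples per
source (x, y, z unit moments).

## Synthetic cohort and the template model

Each synthetic subject perturbs the base setup in two ways:

1. **Radius jitter** — independent lognormal factors (SD 5%) per shell,
   re-sorted to remain increasing. This perturbs shell thickness ratios
   (skull thickness in particular).
2. **Cap placement** — a random rigid rotation of the electrode cap on
   that subject's head, drawn as a Gaussian rotation vector with
   12 degrees SD per axis.

The cap rotation deserves explanation, because it is where the
subject-vs-template contrast actually lives in a spherical world. Two
candidate perturbations do *not* work: a mostly common-scale radial
perturbation changes leadfield magnitude far more than topography, and
rotating a spherically symmetric anatomy under a fixed cap is
unobservable (a full-sphere dipole grid is rotation-invariant as a point
set). What a subject-specific head model genuinely knows — and a template
model does not — is the per-channel forward mapping: where each electrode
actually sat relative to the head. Rotating the cap per subject makes the
template model's per-channel gain patterns tangentially wrong by
`r * theta`, which is the concentric-sphere analogue of the anatomical
and electrode-registration mismatch a real template (fsaverage-based)
model suffers. The SD is calibrated to the scale of that mismatch rather
than to cap slippage alone: template-model reconstructions of real ERP
data are typically displaced by 2-3 cm (they fail a 3 cm classification
radius and recover at 5 cm), and a 12-degree per-axis SD gives a relative
subject-vs-template rotation of ~19 degrees, i.e. ~2.4 cm at the source
sphere. It is a model parameter set once, not a fitted quantity.

The **template** model is the cohort mean: its radii are the exact
arithmetic mean of the subject radii and its assumed cap placement the
mean rotation vector — the role an average-anatomy (fsaverage-like) head
model with standard electrode positions plays when subject MRIs and
digitized electrodes are unavailable. Every geometry gets three leadfields
(both four-shell presets, plus its own geometry collapsed to three shells
by removing the CSF shell and extending the brain). A nearest-neighbor
angular morph maps per-dipole values between grids for group-level maps;
it conserves values (nothing is interpolated or invented) but has no
anatomical correspondence beyond angle.

## Source space and ROI networks

Dipoles sit on a Fibonacci lattice on the sphere at 0.85 x brain radius,
with the dipole count chosen so the area per dipole is `spacing^2`
(default spacing 3 mm; nearest-neighbor distances stay within 30% of
nominal). Spheres have no cortex, so a single spherical surface stands in
for gray matter; `per_dipole_volume = spacing^3` makes the volume-based
dispersion metric a pure count ratio. Simulated dipoles are radially
oriented (well-defined on a sphere; the inverse assumes nothing and
estimates free 3-component orientations).

Four-ROI networks mirror a bilateral two-region-per-hemisphere design.
ROI sites are fixed angular positions emulating occipital-pole, inferior
temporal, inferior frontal (pars opercularis analogue) and supramarginal
parcels; temporal sites lie lateral-inferior near the edge of cap
coverage, which reproduces the classic difficulty of localizing temporal
sources. Named networks (`temporo_occipital`, `fronto_parietal`,
`fronto_occipital`, `temporo_parietal`) combine the sites as
left/right-symmetric pairs. Each ROI is a 10 mm sphere of dipoles around
its center. Activity is a 5 Hz half-cycle sinusoid (100 ms lobe): ROIs
1-2 start at 100 and 110 ms post-stimulus at full amplitude, ROIs 3-4 at
120 ms at 80% amplitude. Amplitudes are arbitrary units — only ratios and
SNR matter, so no physical dipole moment is asserted.

## Epochs, noise and SNR

Each dataset has 80 epochs of 1000 ms (200 ms pre-stimulus) at 250 Hz:
40 epochs with ERP + noise, 40 with noise only. The two-condition design
lets systematic reconstruction biases cancel in the condition difference.
Noise is independent pink (1/f-power) noise per channel, shaped in the
frequency domain, added at the sensor level to all epochs (a source-space
noise option exists but is off by default; sensor noise makes the SNR
calibration exact). Fresh noise per epoch; the ERP waveform is identical
across epochs (no latency or amplitude jitter).

SNR is the ratio of the ERP component's peak amplitude to the mean
pre-stimulus peak-to-peak amplitude, in dB (`20 log10`). Because the
simulated ERP is identical across erp-condition epochs, its condition
average *is* the noiseless component; the simulator stores it, and
`measure_snr` uses its peak sensor and amplitude while measuring the
peak-to-peak from the actual noisy pre-stimulus data. This matters at the
low end of the range: a peak estimated from a noisy 40-epoch average is
extreme-value biased and floors out near -14 dB, which would make a
-20 dB target unreachable; the component-based definition is exact at all
levels. A data-only fallback (difference of condition averages) exists
and is documented as noise-floor-limited. Calibration bisects the noise
scale through the same measurement (geometric bisection; SNR is linear in
log scale), converging to +/-0.05 dB within 40 iterations.

## Inverse solution: eLORETA with pre-whitening

The noise covariance is estimated from the noise-only epochs by default
(the pre-stimulus windows of all epochs are the alternative), with
diagonal loading `loading * mean(diag)` (default 5%) guaranteeing positive
definiteness; rank deficiency with zero loading is an explicit error.
Leadfield and data are whitened with the symmetric inverse matrix square
root.

eLORETA weights solve the fixed point `W_i = [K_i^T (K W^-1 K^T +
alpha H)^+ K_i]^(1/2)` over symmetric 3x3 per-source blocks (free
orientation — the inverse must not assume the radial truth). `H` is the
average-reference centering operator for an unwhitened average-referenced
leadfield and the identity after whitening. `alpha` is a fraction of
`trace(K W^-1 K^T)/n_sensors`, recomputed each iteration, which makes the
solution invariant to covariance scale; the default 1/9 corresponds to a
conventional evoked-data SNR-of-3 prior, and the acceptance properties
hold across alpha in {1/3, 1/9, 1/25}. Pseudo-inverses use an
eigendecomposition with a 1e-12 relative eigenvalue floor (the average
reference makes the sensor-space matrix rank deficient by one). The
leadfield is rescaled to unit median column norm before iteration purely
as a numerical guard; CSD is reported in arbitrary units. Iteration stops
when the largest relative weight-block change falls below 1e-6 (default
cap 100 iterations); non-convergence is reported on the operator, never
silently. The defining zero-localization-error property — noise-free
single sources localize exactly — is verified by brute force in the tests.

Each epoch is reconstructed separately; the current source density is the
Euclidean norm of the 3-vector moment per dipole (orientation discarded),
then averaged within condition. A chunked evoked path computes the same
average at O(chunk) memory.

## Evaluation: cluster-based metrics

Scoring follows a fixed pipeline: per-dipole (ERP - noise) CSD averaged
over 100-220 ms (endpoints inclusive at sample resolution; 31 samples at
250 Hz) -> top-5% threshold (signed values, largest first; ties broken by
ascending dipole index; an all-equal input warns) -> connected components
under strict `< 5 mm` adjacency -> components with fewer than 5 dipoles
dropped. Cluster centers are unweighted centroids (amplitude-weighted
available as an option); cluster volume is member count x per-dipole
volume.

An ROI with at least one cluster center within the classification radius
(default 30 mm; 10 and 50 mm variants) is a true positive, otherwise a
false negative; clusters near no ROI are false positives. One cluster
within range of two ROIs validates both (the rule read literally; logged
when it occurs). Sensitivity = TP/(TP+FN) over ROIs; precision =
TP/(TP+FP), deliberately mixing ROI-level TPs with cluster-level FPs —
that is how the procedure defines it, and it is surfaced here rather than
"fixed". Localization error is the mean center-to-center distance of
qualifying clusters per TP ROI; spatial dispersion is (total qualifying
cluster volume - ROI volume)/ROI volume. With no TP ROIs both are
undefined and reported as NaN (never 0); precision with no clusters and
no TPs is likewise NaN. Note that the 5 mm adjacency rule requires a grid
spacing below 5 mm — on coarser grids no dipole pair is ever adjacent and
every cluster is discarded.

## Study orchestration and reduced problem sizes

The full factorial study crosses cohort x networks x SNR levels x model
variants x classification radii. Ground truth is always generated through
the subject's own detailed `fem_meta` model; reconstruction uses the
cell's variant. Per-cell seeds derive from SHA-256 over (master seed,
subject, network, SNR), so cells are independent, order-invariant and
individually reproducible; finished cells persist as CSV and are skipped
on re-runs; a failing cell is recorded with its exception, never dropped.

The default configuration mirrors the full study (18 subjects, 4
networks, SNR -20..0 dB, 6 variants, 128 sensors, 3 mm grid). The shipped
analysis and the test suite run a **reduced** study chosen once as this
package's desk-scale problem size: 6 subjects, 2 networks
(`fronto_occipital`, `temporo_occipital`), SNR -10 dB, 3 variants
(`subject_fem_meta`, `subject_fem_default`, `template_fem_meta`),
64 sensors, 4 mm grid (~4300 dipoles — the coarsest spacing compatible
with the 5 mm adjacency rule). The qualitative findings are encoded as
machine-checkable orderings per network at -10 dB: (a) median sensitivity
subject >= template; (b) median localization error subject <= template;
(c) the conductivity-preset effect within subject models no larger than
the subject-vs-template effect; plus TP monotonicity in the
classification radius. Missing variants make a property "not evaluable",
never a pass.

A caveat on (b): localization error is conditioned on TP ROIs, so a model
that recovers *more* (and harder) ROIs can show a slightly larger
conditional error — a selection effect to keep in mind when reading the
per-network medians at small cohort sizes.

## What the synthetic data do not emulate

- No cortical geometry: sources on a sphere, radial truth orientation, no
  orientation constraint mismatch between FEM and BEM pipelines.
- Anatomical variability is shell-radius scale + cap-placement rotation
  only; no local shape differences, no skull holes or sutures.
- No realistic ERP morphology (single half-sine component), no trial
  jitter, no artifacts (blinks, line noise), no real-data preprocessing.
- Quantitative distributions from real MRI-based cohorts are out of reach
  here; passing tests demonstrate the *pipeline's* metric arithmetic, the
  forward/inverse physics, and the direction of the head-model effects
  under the synthetic conditions — not the magnitudes to be expected on
  real data.

## Degenerate inputs and tie-breaks (summary)

- All-equal difference maps: top-5% falls back to index order with a
  warning. Exactly-5 mm dipole pairs are *not* adjacent (strict
  inequality). Clusters of exactly `min_size` survive.
- Noiseless epochs: SNR returns +inf (documented sentinel).
- Zero-perturbation cohorts (jitter 0 and cap rotation 0) collapse exactly:
  template radii equal the common subject radii bitwise, and every
  subject-vs-template metric difference is 0.
- A montage needs >= 8 sensors; a source grid is capped at 50k dipoles.
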