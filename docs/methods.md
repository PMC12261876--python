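# Methods

## What the package models

`preful3d` implements the analysis side of 3D phase-resolved functional lung
(PREFUL) MRI — a free-breathing, contrast-free ventilation imaging technique —
together with a synthetic cohort generator that stands in for scanner data.
The analysis chain assumes its input is what a PREFUL reconstruction
delivers: a 4D image series (one 3D volume per respiratory phase, all
registered to the end-inspiratory reference), lung parenchyma and vessel
masks, and a low-resolution navigator series that tracked breathing during
acquisition. Everything upstream of that point — k-space trajectories,
parallel-imaging/compressed-sensing reconstruction, group-oriented
registration, deep-learning segmentation — is deliberately out of scope;
the synthetic generator supplies intrinsically aligned images and exact
masks instead.

## Ventilation parameters

For each voxel x and respiratory phase p, regional ventilation is

    RVent(x, p) = S_Ref(x) / S_p(x) − S_Ref(x) / S_Exp(x),

with the end-inspiratory image as the reference phase S_Ref (it is also the
registration target). The static map is RVent at end-inspiration, which
reduces to 1 − S_Insp/S_Exp. Because parenchymal MR signal is inversely
related to local air content, RVent is positive where lung ventilates and
is identically zero at end-expiration.

From the per-phase RVent cycle we build per-voxel flow-volume loops:
volume = RVent over the cyclic phase order starting at end-expiration,
flow = the cyclic central difference of volume (so every loop closes). The
flow-volume-loop correlation metric (FVL-CM) of a voxel is the zero-lag
Pearson correlation between its concatenated (volume ‖ flow) vector and
that of the reference loop — the voxel-wise mean loop over the parenchyma —
with each sub-vector standardized before concatenation. FVL-CM is close to
1 wherever local ventilation dynamics match the global cycle.

Scalar parameters per measurement (one table row): mean and CoV of the
static RVent map; mean and CoV of the FVL-CM map; two ventilated-volume
percentages, VVP_RVent (fraction of parenchyma voxels strictly above 40% of
the in-mask 90th RVent percentile) and VVP_FVL-CM (fraction strictly above
a fixed 0.9); tidal volume (end-inspiratory minus end-expiratory lung mask
volume); and breathing frequency from the navigator. Vessel voxels are
subtracted from the parenchyma mask before all statistics.

Conventions worth noting: percentiles use linear interpolation between
order statistics; both VVP thresholds are strict (a voxel exactly at the
threshold counts as defect); map CoV uses the population (n) standard
deviation while cohort statistics use the sample (n−1) form — both are
configurable; and all parameters are invariant to a global intensity
rescaling of the images, since RVent is ratio-based.

## Gating and binning

The navigator (32×32 frames every 100 ms, or an equivalent scalar series)
is reduced to a scalar amplitude (spatial mean over the central half-field,
3-sample moving average; higher amplitude = inspiration, with an
`--invert-gating` escape hatch for opposite-polarity data). Breathing
frequency is (n_peaks − 1)/(time spanned by the peaks), with end-inspiration
peaks detected at minimum prominence 0.2 × the amplitude interquartile range
and minimum separation 1.5 s. Respiratory phase is trough-anchored — 0 at
end-expiration, 0.5 at end-inspiration, piecewise linear in time — and
samples outside the first/last extremum are dropped and flagged.

Binning sorts phased acquisitions into equal-width cyclic phase bins:
n_bins = floor(N/min_count) capped at 51 (defaults min_count = 100),
adjacent bins merged until every core count reaches the minimum, and each
bin then borrows its nearest-in-phase acquisitions from the two cyclic
neighbors, floor(0.2 × core/2) per side ("20% view sharing"). Phase-based
rather than amplitude-based binning was chosen because it resolves the
inspiratory and expiratory half-cycles that flow-volume loops need; the
borrow-20% reading of view sharing is one of two defensible readings and is
configurable.

## The synthetic cohort generator

Each subject is two ellipsoidal lungs (semiaxes ~40×50×75 mm, jittered 8%)
minus a branching vessel tree, on a 24³ grid of 8 mm voxels by default —
deliberately scaled-down lungs (~1.3 L at end-inspiration) so a full
dual-center study simulates in seconds. The end-expiratory mask removes
exactly round(tidal volume / voxel volume) outermost voxels, so
mask-derived tidal volume is exact to one voxel.

Ground truth is parameterized by specific ventilation sv(x): a Gaussian
random field smoothed to a 20 mm correlation length, mean sampled per
subject in [0.18, 0.32], relative standard deviation 0.375 ×
heterogeneity_scale, clipped at zero; optional defects are contiguous
regions with sv = 0. The forward signal model is proton-density dilution:

    S(x, p) = signal_scale / (1 + sv(x) · u_p),    u_p ∈ [0, 1],

with a raised-cosine inflation cycle u that reaches exactly 0
(end-expiration) and 1 (end-inspiration). Under this model the RVent
formula is exactly invertible — RVent_true = sv/(1+sv) — which gives every
downstream stage a closed-form oracle: a noise-free constant-sv = 0.25
phantom must yield mean RVent = 0.2, CoV 0, FVL-CM = 1, both VVPs = 100%,
to 1e-9. Noise is additive zero-mean Gaussian with σ = mean parenchymal
signal / SNR (Rician effects are second order at the SNR levels used).

Scanner profiles reduce field strength to two dials: an effective
post-reconstruction SNR and a heterogeneity multiplier on the sv field.
Defaults are SNR 500 / heterogeneity 1.0 at 1.5 T and SNR 320 / 1.3 at 3 T
— calibrated once so a default healthy subject lands in the magnitude range
typical of healthy cohorts (RVent CoV ≈ 30%, mean FVL-CM ≈ 0.98,
VVP_FVL-CM ≈ 98% at 1.5 T) and so the 3-T profile reproduces the expected
effect *directions* (higher RVent CoV, lower VVPs); no susceptibility/T2*
physics is simulated and effect magnitudes are not claimed. The SNR values
are effective ones: each reconstructed phase averages ≥100 radial
projections, so they sit far above raw-projection SNR.

Repeated measurements differ physiologically, not just in noise. Each
measurement draws, from its own named substream: a lognormal
cycle-amplitude factor (σ = 0.10; drives tidal-volume and mean-RVent repeat
variability), a lognormal breathing-frequency factor (σ = 0.08), a smooth
multiplicative regional redistribution field exp(0.12·z(x)) on sv, and a
smooth regional time-lag field (σ = 0.03 cycle fractions) that shifts each
voxel's inflation curve in time — regional ventilation timing
heterogeneity, the dominant source of scan-to-scan FVL-CM variability.
These four σ values were set so that repeat studies show
between-measurement CoVs of roughly 2–12% per parameter, VVP limits of
agreement of a few percentage points, and ventilated-map overlaps in the
low-to-mid 90s % — the repeatability regime reported for healthy volunteers.
All of it switches off when a profile is noise-free (snr = ∞), so null
designs are bit-for-bit reproducible.

The habituation scenario — a calmer second scan — is a multiplicative
perturbation of measurement 2: tidal_factor scales the cycle amplitude
(effective sv and tidal volume), frequency_factor the breathing rate. With
tidal_factor = 0.85 the true mean RVent of measurement 2 is
0.85·sv/(1+0.85·sv), a ~12% relative decrease at sv = 0.25.

All randomness flows from one root seed through named CRC32-keyed
substreams (cohort, per-subject field, per-measurement physiology, noise,
navigator), so a subject's lungs and ventilation field are identical across
scanners and repeats while noise and physiology vary.

### What the generator does not emulate

Real anatomy (lobes, diaphragm, airways), registration and segmentation
error, Rician noise, susceptibility/T2* field-strength physics, cardiac
signal modulation, irregular breathing (apnea, sighs, drift), and
inter-vendor differences. Passing tests therefore demonstrate that the
analysis chain is correct and that the statistical machinery behaves as
specified under known ground truth — not that the pipeline is robust to
real-scanner artifacts.

## Statistics

Paired comparisons use the two-sided Wilcoxon signed-rank test; zero
differences are dropped before ranking, the exact sign-flip null is
enumerated (by subset-sum convolution over midranks, equivalent to the full
2^n enumeration) for n ≤ 25, and the normal approximation with continuity
correction is used above. Agreement is summarized by Bland-Altman bias and
95% limits of agreement (bias ± 1.96 × sample sd of differences), the
median per-subject CoV (two-value sd = |x1−x2|/√2), and ICC(2,1) — two-way
random effects, absolute agreement, single measurement — computed from the
ANOVA mean squares and labeled on the Viera-Garrett scale (≤0 less than
chance, then slight/fair/moderate/substantial/almost perfect in 0.2 bands).
Effect size is paired Cohen's d (mean difference over sd of differences; an
average-variance denominator is not the default) with Sawilowsky labels
(0.01 very small … 2.0 huge, by magnitude). The single-measurement ICC form
was chosen because the clinical question is the reliability of one scan.

Regional agreement of binary ventilated-volume maps uses the matching-label
overlap 2(n_vv + n_dd)/(n_v1 + n_v2 + n_d1 + n_d2) × 100 within the shared
analysis mask. Independent cohorts are age-matched by optimal one-to-one
assignment minimizing total |Δage| (Hungarian algorithm); the unmatched
surplus of the larger cohort is reported as excluded. Field-strength biases
are also expressed as percent change relative to the reference (1.5-T)
cohort mean, with bias = reference − comparison so a positive percent
change means the comparison condition reads higher. No multiple-testing
correction is applied by default (exploratory design; a Holm adjustment is
available but off).

Degenerate inputs are handled explicitly: all-zero differences give p = 1
and d = 0; a zero-variance reference loop yields a flagged all-zero FVL-CM
map; zero-mean maps make CoV an error rather than an infinity; a
physiologically inverted mask pair returns a negative tidal volume with a
warning rather than failing.

## Study designs and problem sizes

`run_study` simulates one cohort and builds three report sections:
repeatability (measurement 1 vs 2 per scanner, parameter table plus
overlap summary), intercenter consistency (two centers at the shared field
strength, age-matched, bias + p per measurement), and field-strength
comparison (same subjects on both scanners of one center; bias, percent
change, p, Cohen's d). The default study is the full dual-center design
(24 subjects × two scanners + 26 × one scanner, two measurements each =
148 measurements) and runs in a few seconds at the default grid; the test
suite uses an n = 4 per-center fixture, and the replicate simulation
studies (habituation detection, field-strength effect directions) run 50 to
100 independent cohorts at full n. Reports carry a manifest (seed, package
version, config hash) and contain no timestamps, so identical configs
produce byte-identical report JSON.

## Known limitations

The ellipsoid phantom's VVP_RVent (~91%) sits a few points below typical
in-vivo values because its Gaussian sv field has a heavier low tail than
real healthy lungs. FVL-CM repeat variability is driven by a single
timing-lag mechanism, so its between-subject spread is narrower than in
vivo. The merge step of binning operates on the linear (non-wrapped) bin
sequence; with near-uniform phases, merges across the 0/1 boundary never
arise in practice. The exact Wilcoxon null treats ties by midranks, which
is also what the enumeration oracle does, but other software may use a
different tie policy above n = 25.
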