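# Methods

## The measurement model

`gcxquant` treats the glycocalyx index (GCXI) as an operational width: the
distance between the two points where a wall-stain intensity profile crosses
the level *b* = *c* + (1 − u)(*a* − *c*), with *a* the profile maximum, *c*
the baseline and u = 0.40 the fraction of the peak-above-baseline range
forming the measurement band ("the upper 40 %"). The baseline is the mean of
the intensities at the two inflection points flanking the peak. Two
readings of "midpoint of the two inflection points" are possible; we take
the mean of their *intensities*, because the baseline must itself be an
intensity for the band *a*–*c* to define a level. u is configurable
(`GcxiConfig.upper_fraction`).

For the two ridge families the generator renders, the index has closed
forms used throughout the tests:

- Gaussian, scale σ: inflections at ±σ, c = a·e^(−1/2),
  d = 2σ·√(−2 ln(0.6 + 0.4 e^(−1/2))) ≈ 1.17048 σ;
- raised cosine, half-width w (profile (1+cos πs/w)/2): inflections at
  ±w/2, c = a/2, d = (2w/π)·arccos 0.6 ≈ 0.59033 w.

With unequal lumen/interstitial plateaus L ≠ I the per-side crossing
targets shift by ±(I − L)/2A (A the ridge amplitude);
`scene.analytic_ridge_width` implements the general closed form, and the
rendered `GroundTruth.true_width_px` uses it, so recovery tests remain
exact for asymmetric scenes.

The statistical unit follows the study design the package models: the
vessel for GCXI (three lines averaged per artery; arteries with fewer than
three usable lines are flagged and excluded, configurable via the
`required` argument), the animal for blood endpoints.

## Numerical choices in the profile analysis

The algorithm is defined on a continuous curve; on sampled, noisy data four
choices matter. All are implemented in `gcxquant.gcxi` and verified by the
test suite.

1. **Measured curve.** Savitzky–Golay smoothing (window 7, cubic) lightly
   denoises the profile; window 1 disables smoothing entirely, and the
   analytic-oracle tests run with it disabled, where the implementation
   follows the textual definition literally (global maximum, nearest
   second-derivative zero crossings by central differences with linear
   interpolation, nearest level crossings).

2. **Derivative scale.** Differencing amplifies high-frequency noise
   quadratically, so inflection detection uses its own Savitzky–Golay
   window for the first/second derivatives. By default
   (`derivative_window=None`) the window is matched to the ridge itself:
   0.35 × a rough full width at half maximum (measured above the
   10th-percentile background on a curve smoothed at a fifth of the
   profile length), clamped to [5, n/3] samples. A fixed window cannot
   serve both a 2-µm and a 6-µm layer at the same sampling: too narrow and
   the second derivative is noise; wider than the ridge and the inflection
   estimates bias inward.

3. **Robust landmark search.** On noisy data the literal rules latch onto
   noise: the argmax wanders along the ridge's flat top, and the
   "nearest-the-peak" d² zero crossing fires on wiggles adjacent to the
   crest. The implementation therefore (i) anchors the peak at the argmax
   of the ridge-scale curve; (ii) identifies each flank as the peak's own
   descending segment, terminated only when the slope clearly reverses
   (two consecutive samples rising at half the strongest descent rate —
   this is what keeps a distal second ridge out of the measurement);
   (iii) places the inflection at the d² sign change at the flank's slope
   extremum, refined by a local straight-line fit of d² (half the
   derivative window on each side), which removes the inward bias of a
   noisy nearest-crossing scan. On clean unimodal ridges all of this
   reduces to the literal rules; the analytic oracles agree to < 0.5 %.

4. **Value evaluation.** When a ridge-scale window is active, the peak
   value, inflection intensities and level crossings are read from that
   curve. Reading values from a lightly smoothed curve at positions chosen
   on a wide curve inflates *a* and *c* under noise (a selection effect)
   and biases the width low by ~15–20 % at SNR ≈ 10.

Peak ties resolve to the smallest position. Degenerate profiles raise
typed errors (`NoPeakError`, `NoInflectionError`, `NoCrossingError`) so a
pipeline can drop a line and log the reason code rather than abort.

**Sampling-line geometry.** Lines are centred on the annotated wall
segment at arc offsets s₀ + i·50 px with s₀ = (L − 100 px)/2 (the
placement that creates the four image blocks); normals come from
central-difference tangents. The default half-length (25 px) and sample
count (101, 0.5-px steps) suit ~1 µm/px imagery; at higher magnification
the line must still span well past the layer — the bundled pipeline and
the recovery tests use 50 px (12.5 µm) at 0.25 µm/px and 40 px at
0.5 µm/px. Bilinear interpolation makes sub-pixel crossings meaningful.

## Synthetic scenes: what they emulate, and what they do not

A scene is one straight vessel of inner diameter 40 or 60 µm rendered into
a multi-channel frame: the wall channel is a symmetric ridge (Gaussian or
raised cosine; `wall_sigma_um` defaults to 4 µm, inside the 4–6 µm range
such layers present in vivo) added to a lumen/interstitial plateau; tracer
channels take the lumen amplitude inside the vessel and the leakage value
I(t) = I₀ + I_max(1 − e^(−kt)) outside, sampled at 15/30/60/90 min.
Defaults: pixel scale 1 µm/px (calibration is never universal; always
configurable), wall amplitude 100 over a plateau of 20, leakage
I₀ = 0, I_max = 100, k = 0.02 min⁻¹ — a visibly rising, unsaturated curve
over the 90-min window. Noise is Poisson first (photon, signal-dependent,
`poisson_gain` photons per intensity unit) then additive Gaussian (read
noise); the noisy recovery tests use gain 2 with SD 7, i.e. peak
SNR ≈ 10. Identical seeds give bit-identical frames.

Deliberately *not* modelled: optical PSF, motion/breathing, curvature,
vessel networks, red-cell flow, photobleaching. Passing recovery tests
therefore demonstrate the estimator's correctness and noise robustness on
resolved, straight, stationary walls — the measurement's stated domain —
not performance under motion blur or out-of-focus optics.

The cohort simulator draws per-subject endpoint values as independent
normals with the bundled published (mean, SD, n) per group, and survival
times as exponentials from per-group weekly death probabilities censored
at day 7. The published mortality narrative is internally inconsistent, so
only the three explicit percentages seed the defaults (control capped at
0.99 to keep the hazard finite) and the rest default to 0.9; these are
free parameters, not findings.

## The inference layer

ANOVA is computed from summary statistics
(SS_b = Σnᵢ(x̄ᵢ − x̄)², SS_w = Σ(nᵢ−1)sᵢ²), algebraically identical to the
raw-data decomposition; a property test checks equality to 1e−10 on random
data. Dunnett's two-sided many-to-one adjusted p is
P(max_j |T_j| ≥ |t_i|) where the T_j share the pooled error (df = N − k)
and correlate as λᵢλⱼ, λᵢ = √(nᵢ/(nᵢ+n₀)). It is evaluated by
deterministic quadrature — 128-node Gauss–Hermite over the shared control
variate × 96-node Gauss–Legendre over the χ-distributed scale mapped
through the χ² quantile function — accurate to ~1e−6 against the k = 1
closed form and within 2e−3 of scipy's raw-data Dunnett, R multcomp's
`glht`, and a seeded 10⁶-draw Monte-Carlo oracle. Equal-variance pooling
is retained even for visibly heteroscedastic endpoints because that is
the procedure the reference tables report; a one-sided mode is available.
Significance flags follow the tables: `**` for p ≤ 0.01, `*` for p ≤ 0.05.

Of the 45 published comparison marks, 43 reproduce exactly from the
printed summaries; the two 60-µm GCXI `*` calls compute to adjusted
p ≈ 0.09–0.11 under a two-sided test from rounded summaries and are not
reproducible — they are reported as found, not forced.

Kaplan–Meier estimation and the log-rank statistic are delegated to
lifelines behind `km_curve`/`logrank_test`; tests pin them to hand-computed
product-limit values, a hand hypergeometric tally (χ² = 49/17 on a
four-subject example), and a 1 000-permutation oracle.

## Problem sizes and determinism

Test and acceptance runs use desk-scale problems chosen to exercise each
property: 384–512-px frames, three σ values, 50 noisy replicates (median
reported), 10⁶ Monte-Carlo draws for the Dunnett oracle, 2 000 null
replicates for the family-wise error (compared via the exact critical
value), 10 000 subjects for the exponential-survival check. All randomness
flows through explicit integer seeds; the pipeline writes byte-identical
CSVs on re-run (floats serialized at 9 significant digits) and a run log
carrying the config hash, seeds and per-line drop reasons.

## Known limitations

- The width is an operational index, not an absolute thickness; no
  deconvolution or PSF correction is attempted.
- Auto windowing assumes one dominant ridge per profile; profiles whose
  FWHM estimate is corrupted by a second structure inside the line should
  be re-annotated or given an explicit `derivative_window`.
- At SNR well below ~10 the per-line failure rate rises and the surviving
  lines scatter widely; the per-artery mean of three lines is the smallest
  unit that should be interpreted.
- The summary-statistics Dunnett reproduces printed tables only to the
  precision of the rounding in those tables.
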