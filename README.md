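# gcxquant

Quantification of the endothelial glycocalyx and of tracer extravasation
from intravital fluorescence microscopy, with the accompanying group
statistics and a fully verifiable synthetic-scene generator.

## The problem

The endothelial glycocalyx (GCX) is a carbohydrate-rich gel layer lining the
luminal vessel wall; it regulates vascular permeability and is degraded in
hemorrhagic shock. In dorsal-skinfold-chamber mouse experiments the layer is
visualized with fluorescent lectin (FITC-WGA), which renders vessel walls as
bright intensity ridges, and vascular leakiness is tracked with labelled
tracers (TMR-DEX40, FITC-HES130) whose interstitial fluorescence rises over
time. `gcxquant` implements the quantification used in such studies:

**Glycocalyx index (GCXI).** On each of three lines drawn perpendicular to
one side of a stained arterial wall, 50 px apart, the intensity profile is
analysed as follows: the profile maximum is *a*; the two inflection points
flanking the peak are located and the mean of their intensities is the
baseline *c*; a horizontal line *b* is placed at the lower edge of the upper
40 % of the *a*–*c* range, i.e. at

&nbsp;&nbsp;&nbsp;&nbsp;*b* = *c* + 0.6 (*a* − *c*);

the distance *d* between the two profile/line intersections nearest the
peak is the GCXI of that line, and the artery's GCXI is the mean of its
three line values. For an ideal Gaussian ridge of scale σ this width is
2σ·√(−2 ln(0.6 + 0.4 e^(−1/2))) ≈ 1.17048 σ.

**Permeability.** Interstitial tracer accumulation is the mean intensity of
three randomly placed, vessel-free, pairwise-disjoint 80×80-px ROIs,
measured at 15/30/60/90 min and averaged into one value per channel per
time point.

**Inference.** Endpoints are compared across six treatment arms against a
control group with one-way ANOVA followed by Dunnett's two-sided
many-to-one test — implemented directly from summary statistics
(mean, SD, n), with the adjusted p evaluated by deterministic quadrature of
the max-|T| distribution — and seven-day survival with Kaplan–Meier curves
and the log-rank test. The published endpoint tables of the motivating
six-arm hemorrhage/resuscitation study are bundled
(`gcxquant.tables`) as reference inputs.

Because studies of this kind deposit no raw images, the package ships a
synthetic-scene generator (`gcxquant.scene`) that renders straight vessels
with a wall ridge of known analytic width, tracer leakage
I(t) = I₀ + I_max(1 − e^(−kt)), and Poisson + Gaussian noise — so every
stage of the pipeline can be verified against closed-form ground truth.

## Worked example

Render a 40-µm artery at 0.25 µm/px with a 4-µm Gaussian wall layer,
profile it along three perpendicular lines, and score the artery:

```python
from gcxquant import (VesselScene, render_frame, WallTrace,
    place_perpendicular_lines, sample_profile, analyze_profile, artery_gcxi)

scene = VesselScene(height_px=384, width_px=384, pixel_scale=0.25,
                    centerline=((192.0, 10.0), (192.0, 374.0)),
                    inner_diameter_um=40.0, wall_sigma_um=4.0)
frame, truth = render_frame(scene)
trace = WallTrace(truth.wall_trace, truth.interstitial_side)
lines = place_perpendicular_lines(trace, half_length_px=50, n_samples=201)
analyses = [analyze_profile(sample_profile(frame, "FITC-WGA", line)) for line in lines]
artery = artery_gcxi(analyses)
print(f"per-line widths (um): {[round(a.d_um, 3) for a in analyses]}")
print(f"artery GCXI: {artery.gcxi_um:.3f} um (analytic truth {truth.true_width_um:.3f} um)")
```

prints

```
per-line widths (um): [4.841, 4.841, 4.841]
artery GCXI: 4.841 um (analytic truth 4.682 um)
```

— the three noiseless lines agree exactly (the rendered vessel is straight
and uniform) and the recovered width sits within ~3 % of the closed-form
value for this ridge. Reproducing the published syndecan-1 inference from
the bundled summary table:

```python
from gcxquant import GroupSummary, dunnett_vs_control
from gcxquant.tables import ENDPOINT_SUMMARIES

summaries = [GroupSummary(g, n, m, s, "syndecan1")
             for g, (m, s, n) in ENDPOINT_SUMMARIES["syndecan1"].items()]
for c in dunnett_vs_control(summaries, control="C"):
    print(f"{c.group:7s} diff={c.mean_diff:+.2f}  t={c.t:+.2f}  p={c.p_adjusted:.4f} {c.flag}")
```

```
NS-NS   diff=+5.16  t=+3.74  p=0.0031 **
NS-ALB  diff=+0.46  t=+0.30  p=0.9986
ALB-NS  diff=+3.45  t=+2.39  p=0.0915
NS-HES  diff=-0.43  t=-0.30  p=0.9987
HES-NS  diff=+0.22  t=+0.17  p=0.9999
```

Only saline-only resuscitation (NS-NS) elevates plasma syndecan-1
significantly over control — the published call, recovered from printed
summaries alone.

A CLI wraps the same functionality (`gcxquant simulate | gcxi |
permeability | stats | survival | run`); `gcxquant run --config cfg.yaml`
executes the full synthetic pipeline and writes tidy CSVs plus a run log.

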