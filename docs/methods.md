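# Methods

## Physical model

All image arithmetic happens in optical-density (OD) space, where stains mix
linearly. For incident light `I0_c` (default pure white, 255 per channel)
and transmitted intensity `I_c`, the per-channel OD is

    OD_c = −log10(max(I_c, 1) / I0_c),  clamped at 0.

The ε = 1 grey-level guard makes saturated black pixels carry the maximal
finite OD, `log10(I0_c)` ≈ 2.41 at I0 = 255, rather than an infinity; pixels
brighter than the reference get OD 0. A pixel's OD vector is a non-negative
combination of three unit absorption directions — hematoxylin
(0.650, 0.704, 0.286), DAB (0.268, 0.570, 0.776), and a residual — collected
as rows of the stain matrix `M`. The residual is completed per channel as
`sqrt(1 − h_c² − d_c²)` (normalized), the classic ImageJ
colour-deconvolution convention; unlike a cross-product residual it is
always non-negative, and the resulting matrix has condition number ≈ 6.4.
Deconvolution applies `M⁻¹` to every pixel and clips negative concentrations
to zero *after* solving, so noise outside the stain cone cannot create
negative "expression".

All per-pixel arithmetic is floating point; quantization to 8 bits
(round-half-to-even) happens exactly twice, where a real workflow
quantizes: when the simulator writes the RGB image, and when the DAB
concentration is mapped to the inverted 8-bit scale.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `dab_od_threshold` | 0.15 OD | minimal DAB concentration counted positive; a common practice value for chromogen detection |
| `scale_od` | 1.0 OD | DAB OD mapped to 255 on the inverted scale |
| threshold window | (5, 250) | shared pass-band on the 8-bit map filtering unspecific extremes; the window is enforced to be identical across all images of a run |
| background `I0` | (255, 255, 255) | scanner white point; configurable because real scanners vary |
| `pixel_size_um` | 1.0 μm/px | typical of a 10× whole-slide export; always configurable, and every statistic carries its pixel size explicitly |
| t-test variant | pooled | the conventional spreadsheet two-sample test; Welch is available (`variant="welch"`) and reported alongside when asked |

The detection threshold and window bounds are explicit stand-ins for an
unpublished plugin color model; they are deliberate, documented defaults
rather than recovered values, and both are exposed in `RunConfig`.

"Total DAB intensity" is the sum of inverted 8-bit values over ROI ∩ mask
*after* the window; sub-threshold pixels contribute zero. The ROI area in
the length formula uses the rasterized pixel count (pixel-centre rule,
even-odd), matching what a pixel-based tool measures; the analytic polygon
area differs by O(perimeter) and both areas are recorded. Heights are data
supplied with each sample (measured in a viewer, or by the simulator), not
estimated from the image.

## The simulator

`SyntheticSlideSpec` defaults describe a small intestinal section at
1 μm/px: a 512×384 px image whose mucosa band (mean height 300 μm, ten
sampled sites jittered with SD 30 μm, linearly interpolated) is anchored at
the bottom edge; diffuse hematoxylin at 0.25 OD inside the mucosa; 8 crypts
× 3 DAB granule clusters at crypt bases. Granules are soft-edged disks
(Gaussian radial profile, σ = 4 μm, truncated at 1.2σ) with amplitude drawn
from N(0.4, 0.05) OD and the summed field capped at 0.5 OD (chromogen
saturation). Sensor noise is additive Gaussian in RGB space (SD 2 grey
levels) added after transmission, so the recorded ground-truth OD stays
exact; the image is then clipped to [0, 255] and rounded half-to-even.
Everything is reproducible from the spec's seed.

Two defaults deserve justification:

- **Amplitude cap 0.5 OD / hematoxylin 0.25 OD.** An a-priori error analysis
  of 8-bit quantization shows the worst-case post-deconvolution error grows
  with total OD (darker pixels lose more OD per grey level); keeping
  per-pixel DAB ≤ 0.5 on top of 0.25 hematoxylin bounds the recovery error
  at ≈ 0.008 OD, inside the package's stated < 0.01 OD round-trip tolerance.
  These are also physically reasonable magnitudes for well-stained tissue.
- **Truncation at 1.2σ.** The granule rim then retains ≈ 49% of the peak
  OD, so at the default amplitude the whole true support clears the 0.15
  detection threshold and the detected mask agrees with ground truth up to
  boundary/quantization pixels (Jaccard ≳ 0.98 on clean slides).

`generate_cohort` scales the NEC-like group's amplitude mean by
(1 − effect_size) and draws per-subject mucosal height means with 25%
scatter, emulating the strong between-patient height variation; patient
metadata (GA 23–40 weeks, surgery at 4–50 days, ileum-dominated tissue mix,
8 NEC vs 4 controls by default) mirrors the study design the package was
built around. Because amplitudes are truncated at zero, the realized
ground-truth NEC/control ratio at effect 0.6 is ≈ 0.41 rather than exactly
0.40.

What the simulator does **not** emulate: villus/crypt texture and branching,
extracellular DAB diffusion, stain colocalization within nuclei, scanner
color shifts, uneven illumination, or sectioning artifacts. Passing tests
therefore demonstrate that the measurement chain is *internally* correct
(it recovers what the forward model put in) — not that the stain matrix or
thresholds are optimal for any particular scanner's output.

## Validation experiments and problem sizes

The repeated-simulation experiments run on a reduced 224×160 px slide
geometry (`validation.SMALL_SLIDE_SPEC`) with unchanged stain chemistry, a
deliberate trade of field of view for replicate count:

- **Deconvolution oracle** — vectorized separation vs independent per-pixel
  3×3 `linalg.solve` on random in-cone 8×8 OD images; agreement < 1e-9.
- **Round trip** — noise-free slide → OD → deconvolution recovers the true
  concentration fields to < 0.01 OD after 8-bit quantization (< 1e-9
  before).
- **Eq. algebra** — splitting a ROI at a half-integer column conserves
  pixel counts and intensity exactly, and the union statistic equals
  (T₁+T₂)/(L₁+L₂); doubling the mean height exactly doubles expression/μm.
- **Parameter recovery** — 20 slides spanning a tenfold range of true DAB
  OD per μm, generated by sweeping granule-cluster density 1–10 per crypt
  at fixed amplitude (sweeping amplitude instead would push granules under
  the fixed 0.15 OD threshold and produce uninformative tied zeros);
  Spearman(truth, measured) ≥ 0.9, in practice ≈ 1.0.
- **Type-I calibration** — pooled t-test on two standard-normal groups of
  sizes 8 and 4, 10,000 replicates; rejection rate at α = 0.05 must lie in
  [0.04, 0.06].
- **Effect direction** — 200 simulated cohorts (8 vs 4) at effect 0.6; the
  NEC-like mean expression/μm falls below control in ≥ 95% of cohorts.

`run_validation_suite(seed, quick=True)` runs the same checks with reduced
replicate counts and correspondingly widened Monte-Carlo tolerances; the
algebraic tolerances stay fixed. Passing a deliberately wrong analysis
stain matrix makes the round-trip check fail — a packaged negative control
(the simulator always composes with the standard H-DAB basis).

## Numerical and degenerate-input choices

- Rasterization uses the pixel-centre rule with shapely's point-in-polygon;
  ROIs beyond the image are clipped with a warning, degenerate or
  self-intersecting polygons are rejected.
- Zero pooled variance with equal means returns p = 1 by convention and is
  flagged; with unequal means, p = 0 with an infinite t.
- Correlations require ≥ 3 pairs and nonzero variance; in group reports
  undefined correlations appear as NaN rather than aborting the run.
- A granule amplitude mean of exactly 0 disables the chromogen entirely
  (empty true mask), rather than drawing |N(0, σ)| noise granules.
- Unprocessable samples are excluded with a recorded reason in the run
  manifest, never dropped silently; the manifest snapshots the full
  configuration and is sufficient to re-run bit-identically.

## Known limitations

- The per-μm statistic is reported in arbitrary units; absolute values are
  not comparable across staining batches or scanners (antigen retrieval and
  staining intensity are batch-dependent), only within a run.
- NEC-like slides simulated with large effect sizes have granule amplitudes
  near or below the detection threshold, so their measured expression
  saturates toward zero — a floor effect inherent to fixed-threshold
  detection.
- The group comparison applies no multiple-testing correction and offers no
  nonparametric alternative, matching the analysis design it reproduces.
- Mucosal heights are inputs, not estimates; automatic mucosa segmentation
  is out of scope.
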