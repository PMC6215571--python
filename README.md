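# dabquant

Semiquantitative analysis of DAB-stained brightfield immunohistochemistry,
built for the question "is Paneth-cell DEFA6 expression lower in infants with
necrotizing enterocolitis (NEC) than in controls?" — but applicable to any
study that needs a reproducible, per-length-normalized readout of a brown
(DAB) chromogen inside a manually delimited mucosa region.

Intended users are researchers quantifying IHC sections exported as 8-bit RGB
TIFF/PNG with a known pixel size, who today rely on opaque point-and-click
plugin color models. dabquant replaces that step with explicit, documented
physics and ships a synthetic slide simulator with exact ground truth so the
whole chain can be validated without patient material.

## The method

Brightfield transmission follows the Beer–Lambert law per channel
*c* ∈ {R, G, B}:

    I_c = I0_c · 10^(−OD_c),      OD_c = Σ_s  a_s · M[s, c]

where `M` is the 3×3 stain matrix (unit absorption directions of
hematoxylin, DAB, and a residual) and `a_s` the per-pixel stain
concentrations. The analysis chain is:

1. **OD conversion** — `OD_c = −log10(max(I_c, 1) / I0_c)`, clamped at 0
   (the 1-grey-level guard keeps saturated black pixels finite).
2. **Color deconvolution** — per pixel, `a = OD · M⁻¹`; negative solutions
   are clipped to 0.
3. **DAB detection** — positive where the DAB concentration exceeds an OD
   threshold (default 0.15).
4. **Inverted 8-bit map** — `v = round(255 · min(a_DAB / scale_od, 1))`, so
   255 = strongest expression; a single threshold window (default 5–250),
   shared by every image of a run, removes unspecifically low/high values.
5. **Per-μm statistic** — with the ROI area `A` (μm²) and the mean mucosal
   height `h̄` (μm) over ten representative sites,

       length = A / h̄        expression/μm = Σ v (over ROI ∩ mask) / length

   plus the staining-intensity-robust alternative, the **percent DAB area**
   `100 · |mask ∩ ROI| / |ROI|`.
6. **Group statistics** — two-sided two-sample *t*-test (pooled by default,
   Welch optional) between NEC-like and control-like groups for both
   statistics, and per-group Pearson correlations against gestational age at
   birth and postconceptional age at surgery (decimal weeks).

The simulator composes slides by the same forward law: a mucosa band of
variable height, diffuse hematoxylin, and DAB granule clusters at crypt
bases (where Paneth cells sit), then records the exact DAB concentration
field as ground truth. See `docs/methods.md` for parameter choices and
limitations.

## Worked example

```python
from dabquant import (SyntheticSlideSpec, generate_slide, generate_cohort,
                      RunConfig, quantify_sample, compare_groups)

spec = SyntheticSlideSpec(seed=42)          # 512x384 px at 1 um/px
bundle = generate_slide(spec)
config = RunConfig()                        # default H-DAB matrix, window (5, 250)
res = quantify_sample(bundle.image, bundle.roi, bundle.heights, config)
print(res.expr_per_um, res.pct_area)

cohort = generate_cohort(8, 4, 0.6, spec, seed=1)   # 60% DAB reduction in NEC-like
pairs = [(rec, quantify_sample(b.image, b.roi, b.heights, config))
         for b, rec in cohort]
print(compare_groups(pairs).tests)
```

This prints, for the single slide:

```
ROI area:        148433 px = 148433 um^2
mean height:     289.93 um
mucosa length:   511.96 um
total intensity: 124937 a.u.
expression/um:   244.0383 a.u./um   (truth DAB OD/um: 0.9583)
percent area:    1.0705 %          (truth: 1.0705 %)
```

— i.e. the measured percent-positive area matches the simulator's ground
truth to four decimals — and for the 8-vs-4 cohort with a 60% simulated DAB
reduction:

```
  statistic  mean_nec  mean_control          t   df            p
expr_per_um 33.442889    239.750881 -42.290824 10.0 1.310812e-12
   pct_area  0.223062      1.134962  -9.843446 10.0 1.836553e-06
```

Both statistics are significantly lower in the NEC-like group, as designed.

The same workflow is available from the shell:

```bash
dabquant simulate --out slides/ --seed 1 --n-nec 8 --n-control 4 --effect-size 0.6
dabquant quantify --images slides/ --cohort slides/cohort.csv --out run/
dabquant compare  --results run/samples.csv --cohort slides/cohort.csv --out run/
dabquant validate --seed 1 --reps full
```

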