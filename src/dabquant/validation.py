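"""Packaged validation experiments: parameter recovery, calibration, algebra.

These experiments exercise the full analysis chain against the simulator's
ground truth and against independent brute-force oracles.  They are reused
by the test suite, the ``validate`` CLI subcommand, and the acceptance
script, so the numbers those report are always recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from .config import RunConfig
from .mucosa import ROIPolygon, quantify_sample, rasterize_roi
from .simulate import SlideBundle, SyntheticSlideSpec, generate_cohort, generate_slide
from .stains import StainMatrix, default_hdab_stain_matrix, deconvolve, rgb_to_od

__all__ = [
    "SMALL_SLIDE_SPEC",
    "deconvolution_oracle_max_error",
    "roundtrip_max_error",
    "tiling_additivity_error",
    "height_sensitivity_ratio",
    "parameter_recovery_spearman",
    "type1_error_rate",
    "effect_direction_experiment",
    "truth_ratio_experiment",
]

#: reduced slide geometry used by the repeated-simulation experiments;
#: stain chemistry and granule parameters are the package defaults.
SMALL_SLIDE_SPEC = SyntheticSlideSpec(
    width_px=224,
    height_px=160,
    mucosa_height_um=110.0,
    height_jitter_sd_um=12.0,
    n_crypts=5,
    clusters_per_crypt=3,
    granule_sigma_um=3.0,
)


def deconvolution_oracle_max_error(seed: int, n_images: int = 20, size: int = 8) -> float:
    """Whole-image stain separation vs per-pixel 3x3 linear solves.

    Random concentration triples in [0, 1] are composed into OD images; the
    vectorized inverse-matrix path is compared against an independent
    per-pixel ``numpy.linalg.solve`` on each 3x3 system.  Returns the
    largest absolute disagreement.
    """
    rng = np.random.default_rng(seed)
    stains = default_hdab_stain_matrix()
    m = stains.matrix
    worst = 0.0
    for _ in range(n_images):
        conc_true = rng.uniform(0.0, 1.0, (size, size, 3))
        od = conc_true @ m
        fast = deconvolve(od, stains)
        fast_stack = np.stack([fast.hematoxylin, fast.dab, fast.residual], axis=-1)
        slow = np.empty_like(fast_stack)
        for i in range(size):
            for j in range(size):
                slow[i, j] = np.clip(np.linalg.solve(m.T, od[i, j]), 0.0, None)
        worst = max(worst, float(np.abs(fast_stack - slow).max()))
    return worst


def roundtrip_max_error(
    seed: int,
    spec: SyntheticSlideSpec | None = None,
    analysis_stains: StainMatrix | None = None,
    quantize: bool = True,
) -> float:
    """Simulator -> rgb_to_od -> deconvolve recovery error on a noise-free slide.

    Returns the maximum absolute error (OD units) over the hematoxylin and
    DAB concentration fields.  With ``quantize=False`` the float transmission
    image is analyzed directly, isolating the algebraic round trip from the
    8-bit quantization.
    """
    if spec is None:
        spec = SyntheticSlideSpec()
    spec = replace(spec, noise_sd=0.0, seed=seed)
    bundle = generate_slide(spec)
    if analysis_stains is None:
        analysis_stains = default_hdab_stain_matrix()
    if quantize:
        od = rgb_to_od(bundle.image, background=spec.background_rgb)
    else:
        from .simulate import forward_rgb

        roi_mask = rasterize_roi(bundle.roi, bundle.image.shape)
        conc_h = np.where(roi_mask, spec.hema_od_mean, 0.0)
        float_rgb = forward_rgb(conc_h, bundle.truth.dab_concentration, background=spec.background_rgb)
        od = rgb_to_od(np.clip(float_rgb, 0, 255), background=spec.background_rgb)
    conc = deconvolve(od, analysis_stains)
    roi_mask = rasterize_roi(bundle.roi, bundle.image.shape)
    true_h = np.where(roi_mask, spec.hema_od_mean, 0.0)
    err_d = float(np.abs(conc.dab - bundle.truth.dab_concentration).max())
    err_h = float(np.abs(conc.hematoxylin - true_h).max())
    return max(err_d, err_h)


def _split_roi(roi: ROIPolygon, x_split: float) -> tuple[ROIPolygon, ROIPolygon]:
    """Split a ROI polygon along a vertical line into left/right parts."""
    from shapely.geometry import box

    poly = roi.to_shapely()
    minx, miny, maxx, maxy = poly.bounds
    left = poly.intersection(box(minx - 1, miny - 1, x_split, maxy + 1))
    right = poly.intersection(box(x_split, miny - 1, maxx + 1, maxy + 1))
    return (
        ROIPolygon(np.asarray(left.exterior.coords)),
        ROIPolygon(np.asarray(right.exterior.coords)),
    )


def tiling_additivity_error(seed: int, config: RunConfig | None = None) -> float:
    """Relative error of the tiling identity on a synthetic slide.

    The ROI is partitioned into left and right halves along a half-integer
    column (no pixel centre sits on the boundary).  Checks that pixel counts
    and total intensities add exactly and that the union per-um statistic
    equals (T1 + T2) / (L1 + L2).  Returns the worst relative discrepancy.
    """
    if config is None:
        config = RunConfig()
    bundle = generate_slide(replace(SMALL_SLIDE_SPEC, seed=seed))
    x_split = bundle.spec.width_px // 2 - 0.5
    roi_l, roi_r = _split_roi(bundle.roi, x_split)
    whole = quantify_sample(bundle.image, bundle.roi, bundle.heights, config)
    part_l = quantify_sample(bundle.image, roi_l, bundle.heights, config)
    part_r = quantify_sample(bundle.image, roi_r, bundle.heights, config)
    errs = []
    errs.append(abs(part_l.roi_area_px + part_r.roi_area_px - whole.roi_area_px) / whole.roi_area_px)
    if whole.total_intensity > 0:
        errs.append(
            abs(part_l.total_intensity + part_r.total_intensity - whole.total_intensity)
            / whole.total_intensity
        )
    pooled = (part_l.total_intensity + part_r.total_intensity) / (part_l.length_um + part_r.length_um)
    if whole.expr_per_um > 0:
        errs.append(abs(pooled - whole.expr_per_um) / whole.expr_per_um)
    return float(max(errs))


def height_sensitivity_ratio(seed: int, config: RunConfig | None = None) -> float:
    """Expression ratio after doubling the mean mucosal height at fixed staining.

    Doubling the height halves the effective length, so the per-um statistic
    must exactly double; returns the observed ratio.
    """
    if config is None:
        config = RunConfig()
    bundle = generate_slide(replace(SMALL_SLIDE_SPEC, seed=seed))
    base = quantify_sample(bundle.image, bundle.roi, bundle.heights, config)
    from .mucosa import MucosaHeights

    doubled = MucosaHeights(bundle.heights.values * 2.0)
    two = quantify_sample(bundle.image, bundle.roi, doubled, config)
    return two.expr_per_um / base.expr_per_um


def parameter_recovery_spearman(
    seed: int, n_slides: int = 20, config: RunConfig | None = None
) -> tuple[float, int]:
    """Rank agreement between true and measured DAB-per-um over a 10x sweep.

    Slides span a tenfold range of true DAB OD per um of mucosa by varying
    the granule-cluster density (1 to 10 clusters per crypt) at the default
    granule amplitude; mucosal heights vary per slide as usual.  Returns the
    Spearman correlation between ground-truth DAB OD per um and the measured
    expression per um, and the number of slides used.
    """
    if config is None:
        config = RunConfig()
    rng = np.random.default_rng(seed)
    truths, measured = [], []
    densities = [1 + (i % 10) for i in range(n_slides)]
    for dens in densities:
        spec = replace(
            SMALL_SLIDE_SPEC,
            clusters_per_crypt=dens,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        bundle = generate_slide(spec)
        res = quantify_sample(bundle.image, bundle.roi, bundle.heights, config)
        truths.append(bundle.truth.dab_od_per_um)
        measured.append(res.expr_per_um)
    rho = float(stats.spearmanr(truths, measured).statistic)
    return rho, n_slides


def type1_error_rate(
    seed: int, reps: int = 10_000, n_a: int = 8, n_b: int = 4, alpha: float = 0.05
) -> float:
    """Monte-Carlo type-I error of the pooled two-sample t-test under the null.

    Both groups are drawn from the same standard normal with the study's
    group sizes (8 vs 4 by default); returns the fraction of replicates with
    p < alpha.
    """
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((reps, n_a))
    b = rng.standard_normal((reps, n_b))
    res = stats.ttest_ind(a, b, axis=1, equal_var=True)
    return float(np.mean(res.pvalue < alpha))


def effect_direction_experiment(
    seed: int,
    n_cohorts: int = 200,
    effect_size: float = 0.6,
    n_nec: int = 8,
    n_control: int = 4,
    base_spec: SyntheticSlideSpec | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Direction check of the simulated group effect on the measured statistic.

    Simulates cohorts with the given relative DAB reduction in the NEC-like
    group, runs the full measurement chain on every slide, and reports the
    fraction of cohorts in which the NEC-like group mean expression per um
    falls below the control-like mean (plus the same fraction for percent
    DAB area).
    """
    if base_spec is None:
        base_spec = SMALL_SLIDE_SPEC
    if config is None:
        config = RunConfig()
    rng = np.random.default_rng(seed)
    below_expr = below_area = 0
    for _ in range(n_cohorts):
        cohort = generate_cohort(
            n_nec, n_control, effect_size, base_spec, seed=int(rng.integers(0, 2**31 - 1))
        )
        expr = {"NEC": [], "control": []}
        area = {"NEC": [], "control": []}
        for bundle, record in cohort:
            res = quantify_sample(bundle.image, bundle.roi, bundle.heights, config)
            expr[record.group].append(res.expr_per_um)
            area[record.group].append(res.pct_area)
        if np.mean(expr["NEC"]) < np.mean(expr["control"]):
            below_expr += 1
        if np.mean(area["NEC"]) < np.mean(area["control"]):
            below_area += 1
    return {
        "n_cohorts": n_cohorts,
        "fraction_expr_below": below_expr / n_cohorts,
        "fraction_area_below": below_area / n_cohorts,
    }


def truth_ratio_experiment(
    seed: int,
    n_cohorts: int = 50,
    effect_size: float = 0.6,
    n_nec: int = 8,
    n_control: int = 4,
    base_spec: SyntheticSlideSpec | None = None,
) -> dict:
    """Mean NEC/control ratio of ground-truth DAB OD per um across cohorts.

    With a relative reduction ``e`` the expected ratio is ``1 - e`` (up to
    the mild truncation of amplitudes at zero).
    """
    if base_spec is None:
        base_spec = SMALL_SLIDE_SPEC
    rng = np.random.default_rng(seed)
    ratios = []
    for _ in range(n_cohorts):
        cohort = generate_cohort(
            n_nec, n_control, effect_size, base_spec, seed=int(rng.integers(0, 2**31 - 1))
        )
        truth = {"NEC": [], "control": []}
        for bundle, record in cohort:
            truth[record.group].append(bundle.truth.dab_od_per_um)
        ratios.append(np.mean(truth["NEC"]) / np.mean(truth["control"]))
    return {"n_cohorts": n_cohorts, "mean_ratio": float(np.mean(ratios))}
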