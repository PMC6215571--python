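"""End-to-end analysis driver: ingest or simulate, quantify, compare, report.

``run_analysis`` applies the shared-parameter measurement chain to every
sample of a run, excludes unprocessable samples with a recorded reason
(never silently), runs the group comparison, and writes per-sample CSV,
group-report CSV and a JSON manifest that snapshots the exact configuration,
sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import CohortRecord, compare_groups
from .config import RunConfig
from .errors import DabquantError, InsufficientDataError, PipelineError
from .mucosa import MucosaHeights, ROIPolygon, quantify_sample
from .stains import RGBImage, StainMatrix
from . import validation

logger = logging.getLogger("dabquant")

__all__ = ["SampleInput", "RunManifest", "run_analysis", "run_validation_suite"]


@dataclass
class SampleInput:
    """One sample of a run: image + ROI + heights + patient record.

    ``image`` and ``roi`` may be in-memory objects or file paths (images are
    read with the config's default pixel size unless the ROI sidecar states
    one).
    """

    sample_id: str
    image: object  # RGBImage | path
    roi: object  # ROIPolygon | path to ROI JSON
    heights: MucosaHeights | None = None
    record: CohortRecord | None = None


@dataclass
class RunManifest:
    """Traceable record of one analysis run."""

    config: dict
    software_version: str
    samples: list = field(default_factory=list)
    results: list = field(default_factory=list)
    group_report: dict | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "software_version": self.software_version,
                "config": self.config,
                "samples": self.samples,
                "results": self.results,
                "group_report": self.group_report,
            },
            indent=2,
            sort_keys=True,
        )


def _load_sample(sample: SampleInput, config: RunConfig):
    from .io import read_image, read_roi

    roi, heights = sample.roi, sample.heights
    pixel_size = config.pixel_size_um
    if not isinstance(roi, ROIPolygon):
        roi, pixel_size, sidecar_heights = read_roi(roi)
        if heights is None:
            heights = sidecar_heights
    image = sample.image
    if not isinstance(image, RGBImage):
        image = read_image(image, pixel_size_um=pixel_size)
    if heights is None:
        raise PipelineError(f"sample {sample.sample_id!r} has no mucosal height measurements")
    return image, roi, heights


def run_analysis(config: RunConfig, samples: list[SampleInput], out_dir=None) -> RunManifest:
    """Quantify every sample with one shared configuration and compare groups.

    Per-sample failures are logged and the sample is excluded with a recorded
    reason.  Raises :class:`PipelineError` when no samples are given or none
    can be processed.
    """
    if not samples:
        raise PipelineError("no samples supplied")
    out = Path(out_dir) if out_dir else (Path(config.out_dir) if config.out_dir else None)
    manifest = RunManifest(config=config.snapshot(), software_version=__version__)
    usable: list[tuple[CohortRecord, object]] = []
    rows = []
    for sample in samples:
        entry = {
            "sample_id": sample.sample_id,
            "image": str(sample.image) if not isinstance(sample.image, RGBImage) else "<in-memory>",
            "roi": str(sample.roi) if not isinstance(sample.roi, ROIPolygon) else "<in-memory>",
        }
        try:
            image, roi, heights = _load_sample(sample, config)
            result = quantify_sample(image, roi, heights, config)
        except (DabquantError, OSError, ValueError) as exc:
            logger.warning("excluding sample %s: %s", sample.sample_id, exc)
            entry.update(status="excluded", reason=str(exc))
            manifest.samples.append(entry)
            continue
        entry.update(status="ok", reason=None)
        manifest.samples.append(entry)
        row = {"sample_id": sample.sample_id}
        if sample.record is not None:
            row["group"] = sample.record.group
            row["tissue"] = sample.record.tissue
        row.update(result.as_dict())
        rows.append(row)
        if sample.record is not None:
            usable.append((sample.record, result))
        logger.info("sample %s: expr/um=%.4f pct_area=%.4f", sample.sample_id, result.expr_per_um, result.pct_area)
    if not rows:
        raise PipelineError("every sample failed; nothing to report")
    manifest.results = rows

    report = None
    try:
        if usable:
            report = compare_groups(usable, variant=config.ttest_variant)
            manifest.group_report = {
                "tests": report.tests.to_dict(orient="records"),
                "correlations": report.correlations.to_dict(orient="records"),
            }
    except InsufficientDataError as exc:
        logger.warning("group comparison skipped: %s", exc)
        manifest.group_report = {"skipped": str(exc)}

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(out / "samples.csv", index=False)
        if report is not None:
            report.tests.to_csv(out / "group_report.csv", index=False)
            report.correlations.to_csv(out / "group_correlations.csv", index=False)
        (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def run_validation_suite(
    seed: int = 0,
    quick: bool = False,
    stain_matrix: StainMatrix | None = None,
) -> dict:
    """Execute the packaged validation experiments and summarize pass/fail.

    ``quick`` reduces replicate counts and correspondingly widens the
    Monte-Carlo tolerances; the algebraic checks keep their tolerances.
    ``stain_matrix`` overrides the analysis-side stain basis (the simulator
    always composes with the standard H-DAB basis), so a deliberately wrong
    matrix makes the round-trip check fail — a negative control.
    """
    config = RunConfig(stain_matrix=stain_matrix) if stain_matrix is not None else RunConfig()
    checks: dict[str, dict] = {}

    value = validation.deconvolution_oracle_max_error(seed, n_images=5 if quick else 20)
    checks["deconvolution_oracle"] = {"value": value, "threshold": 1e-9, "passed": value < 1e-9}

    value = validation.roundtrip_max_error(seed, analysis_stains=stain_matrix)
    checks["roundtrip_od_recovery"] = {"value": value, "threshold": 1e-2, "passed": value < 1e-2}

    value = validation.tiling_additivity_error(seed, config=config)
    checks["tiling_additivity"] = {"value": value, "threshold": 1e-9, "passed": value < 1e-9}

    value = validation.height_sensitivity_ratio(seed, config=config)
    checks["height_sensitivity"] = {
        "value": value,
        "threshold": "ratio == 2 +- 1e-9",
        "passed": abs(value - 2.0) < 1e-9,
    }

    rho, n_slides = validation.parameter_recovery_spearman(
        seed, n_slides=10 if quick else 20, config=config
    )
    checks["parameter_recovery"] = {"value": rho, "threshold": 0.9, "passed": rho >= 0.9}

    rate = validation.type1_error_rate(seed, reps=2_000 if quick else 10_000)
    lo, hi = (0.03, 0.07) if quick else (0.04, 0.06)
    checks["type1_calibration"] = {
        "value": rate,
        "threshold": f"[{lo}, {hi}]",
        "passed": lo <= rate <= hi,
    }

    direction = validation.effect_direction_experiment(seed, n_cohorts=20 if quick else 200)
    frac = direction["fraction_expr_below"]
    need = 0.9 if quick else 0.95
    checks["effect_direction"] = {"value": frac, "threshold": need, "passed": frac >= need}

    summary = {"seed": seed, "quick": quick, "checks": checks}
    summary["all_passed"] = all(c["passed"] for c in checks.values())
    return summary
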