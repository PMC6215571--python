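"""Reading and writing the pipeline's on-disk formats.

Slides are 8-bit RGB TIFF (PNG also accepted on read); each slide has a
JSON sidecar holding the ROI polygon (pixel coordinates), the pixel size in
um, and the ten mucosal height measurements.  Ground truth, when written by
the simulator, is a sidecar JSON plus a single-channel float TIFF of the
DAB OD field.  Cohort tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .cohort import CohortRecord, GestationalAge
from .mucosa import MucosaHeights, ROIPolygon
from .simulate import SlideBundle
from .stains import DABIntensityMap, RGBImage

__all__ = [
    "read_image",
    "write_image",
    "write_roi",
    "read_roi",
    "write_slide_bundle",
    "write_dab_map",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
]


def read_image(path, pixel_size_um: float) -> RGBImage:
    """Read an 8-bit RGB TIFF/PNG as an :class:`RGBImage`."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha if present
        arr = arr[..., :3]
    return RGBImage(pixels=np.asarray(arr, dtype=np.uint8), pixel_size_um=pixel_size_um)


def write_image(path, image: RGBImage) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels, photometric="rgb")
    else:
        iio.imwrite(path, image.pixels)


def write_roi(path, roi: ROIPolygon, pixel_size_um: float, heights: MucosaHeights | None = None) -> None:
    """Write the ROI polygon (closed, pixel coordinates) plus pixel size as JSON."""
    payload = {
        "pixel_size_um": pixel_size_um,
        "vertices": np.asarray(roi.vertices, dtype=float).tolist(),
    }
    if heights is not None:
        payload["heights_um"] = np.asarray(heights.values, dtype=float).tolist()
    Path(path).write_text(json.dumps(payload, indent=2))


def read_roi(path) -> tuple[ROIPolygon, float, MucosaHeights | None]:
    data = json.loads(Path(path).read_text())
    roi = ROIPolygon(np.asarray(data["vertices"], dtype=float))
    heights = MucosaHeights(np.asarray(data["heights_um"], dtype=float)) if "heights_um" in data else None
    return roi, float(data["pixel_size_um"]), heights


def write_dab_map(stem: Path, imap: DABIntensityMap) -> None:
    """Write the inverted map as single-channel TIFF and the mask as 0/255 PNG."""
    tifffile.imwrite(Path(f"{stem}.dab.tif"), imap.values, photometric="minisblack")
    iio.imwrite(Path(f"{stem}.mask.png"), (imap.mask.astype(np.uint8) * 255))


def write_slide_bundle(out_dir, sample_id: str, bundle: SlideBundle) -> dict:
    """Write one simulated slide: image, ROI/heights sidecar, ground truth.

    Returns the file paths written, keyed by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / f"{sample_id}.tif",
        "roi": out / f"{sample_id}.roi.json",
        "truth_field": out / f"{sample_id}.truth.tif",
        "truth": out / f"{sample_id}.truth.json",
    }
    write_image(paths["image"], bundle.image)
    write_roi(paths["roi"], bundle.roi, bundle.image.pixel_size_um, bundle.heights)
    tifffile.imwrite(
        paths["truth_field"],
        bundle.truth.dab_concentration.astype(np.float32),
        photometric="minisblack",
    )
    paths["truth"].write_text(
        json.dumps(
            {
                "total_od_in_roi": bundle.truth.total_od_in_roi,
                "length_um": bundle.truth.length_um,
                "area_fraction_pct": bundle.truth.area_fraction_pct,
                "dab_od_per_um": bundle.truth.dab_od_per_um,
                "group": bundle.spec.group,
                "seed": bundle.spec.seed,
            },
            indent=2,
        )
    )
    return {k: str(v) for k, v in paths.items()}


_COHORT_COLUMNS = [
    "patient_id",
    "group",
    "tissue",
    "ga_birth_weeks",
    "ga_birth_days",
    "birth_weight_g",
    "postnatal_age_days",
    "sex",
]


def cohort_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "group": r.group,
            "tissue": r.tissue,
            "ga_birth_weeks": r.ga_birth.weeks,
            "ga_birth_days": r.ga_birth.days,
            "birth_weight_g": r.birth_weight_g,
            "postnatal_age_days": r.postnatal_age_days,
            "sex": r.sex,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_COHORT_COLUMNS)


def write_cohort_csv(path, records: list[CohortRecord]) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path) -> list[CohortRecord]:
    df = pd.read_csv(path)
    return [
        CohortRecord(
            patient_id=str(row.patient_id),
            group=str(row.group),
            tissue=str(row.tissue),
            ga_birth=GestationalAge(int(row.ga_birth_weeks), int(row.ga_birth_days)),
            birth_weight_g=float(row.birth_weight_g),
            postnatal_age_days=int(row.postnatal_age_days),
            sex=str(row.sex),
        )
        for row in df.itertuples()
    ]
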