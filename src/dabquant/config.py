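"""Run-level configuration shared by every image of an analysis run.

The workflow requires that the same threshold window (and, for
comparability, the same stain model and detection parameters) be applied to
every image of a run; the :class:`RunConfig` object is the single place those
parameters live, and the pipeline snapshots it into the run manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .stains import StainMatrix, ThresholdWindow, default_hdab_stain_matrix

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one analysis run.

    Attributes
    ----------
    stain_matrix : "default-hdab" or a 3x3 nested list of stain vectors
        (rows: hematoxylin, DAB, residual; need not be pre-normalized).
    dab_od_threshold : minimal DAB optical density counted as positive.
    scale_od : DAB OD mapped to the top (255) of the inverted 8-bit scale.
    window_low, window_high : shared threshold window on the 8-bit map.
    pixel_size_um : default physical pixel size for images lacking one.
    background : per-channel incident-light reference (default pure white).
    ttest_variant : "pooled" (default) or "welch".
    seed : base seed for any stochastic step of the run.
    """

    stain_matrix: object = "default-hdab"
    dab_od_threshold: float = 0.15
    scale_od: float = 1.0
    window_low: int = 5
    window_high: int = 250
    pixel_size_um: float = 1.0
    background: tuple = (255.0, 255.0, 255.0)
    ttest_variant: str = "pooled"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.dab_od_threshold < 0:
            raise ValueError("dab_od_threshold must be >= 0")
        if self.scale_od <= 0:
            raise ValueError("scale_od must be > 0")
        ThresholdWindow(self.window_low, self.window_high)  # validates bounds
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.ttest_variant not in ("pooled", "welch"):
            raise ValueError(f"unknown t-test variant {self.ttest_variant!r}")
        self.resolved_stain_matrix()  # validates the matrix early

    def resolved_stain_matrix(self) -> StainMatrix:
        if isinstance(self.stain_matrix, StainMatrix):
            return self.stain_matrix
        if self.stain_matrix == "default-hdab":
            return default_hdab_stain_matrix()
        import numpy as np

        m = np.asarray(self.stain_matrix, dtype=float)
        norms = np.linalg.norm(m, axis=1, keepdims=True)
        return StainMatrix(m / norms)

    def threshold_window(self) -> ThresholdWindow:
        return ThresholdWindow(self.window_low, self.window_high)

    def snapshot(self) -> dict:
        """JSON-serializable snapshot sufficient to re-run bit-identically."""
        d = asdict(self)
        sm = self.resolved_stain_matrix()
        d["stain_matrix"] = sm.matrix.tolist()
        d["background"] = list(self.background)
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a config from YAML or JSON (YAML is a superset of JSON)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if "background" in data:
            data["background"] = tuple(data["background"])
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(self.snapshot(), indent=2))
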