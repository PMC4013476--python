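"""Run configuration, display geometry, and file I/O for the pipeline.

Display geometry defaults reproduce the experimental setup: stimuli of
256x256 pixels magnified for display to an effective pixel of 0.583 mm
viewed at 640 mm, i.e. 0.052 deg/pixel; a 3-pixel Gaussian target then has
a FWHM of 0.37 deg and the 128-pixel search region spans 6.7 deg.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import yaml

__all__ = [
    "pixel_angle",
    "PIXEL_ANGLE_DEG",
    "RunConfig",
    "config_hash",
    "save_stimulus_png",
    "save_array",
    "write_json",
    "get_logger",
]

log = logging.getLogger("freeloc")


def get_logger() -> logging.Logger:
    if not log.handlers:
        h = logging.StreamHandler()  # stderr
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(h)
        log.setLevel(logging.INFO)
    return log


def pixel_angle(pixel_mm: float, distance_mm: float) -> float:
    """Visual angle of one pixel in degrees: ``atan(pixel/distance)``."""
    if pixel_mm < 0 or distance_mm <= 0:
        raise ValueError("pixel_mm must be >= 0 and distance_mm > 0")
    return float(np.degrees(np.arctan(pixel_mm / distance_mm)))


#: Effective pixel angle of the reference display (0.583 mm at 640 mm).
PIXEL_ANGLE_DEG = pixel_angle(0.583, 640.0)


@dataclass
class RunConfig:
    """Condition grid, geometry, and simulation sizes for a pipeline run."""

    tasks: Tuple[str, ...] = ("detection", "localization", "dandl")
    betas: Tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    shape: int = 256
    pixel_mm: float = 0.583
    distance_mm: float = 640.0
    magnification: float = 2.0
    sigma_pixels: float = 3.0
    mean_level: float = 100.0
    rms_contrast: float = 0.20
    radius_px: int = 5
    n_per_point: int = 2000
    step: float = 0.01
    stop_pc: float = 0.94
    seed: int = 0
    outdir: str = "freeloc_out"

    def __post_init__(self) -> None:
        for name in ("shape", "pixel_mm", "distance_mm", "magnification",
                     "sigma_pixels", "mean_level", "radius_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def pixel_angle_deg(self) -> float:
        return pixel_angle(self.pixel_mm, self.distance_mm)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tasks"] = list(self.tasks)
        d["betas"] = list(self.betas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "tasks" in d:
            d["tasks"] = tuple(d["tasks"])
        if "betas" in d:
            d["betas"] = tuple(float(b) for b in d["betas"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of a configuration, embedded in every artifact."""
    text = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def save_stimulus_png(pixels: np.ndarray, path, scale: float = 256.0) -> None:
    """16-bit grayscale PNG preview: ``round(pixels * scale)`` clipped to
    [0, 65535] (256 counts per gray level for the default scale)."""
    from PIL import Image
    arr = np.clip(np.rint(np.asarray(pixels) * scale), 0, 65535).astype(np.uint16)
    Image.fromarray(arr).save(path)


def save_array(arr: np.ndarray, path) -> None:
    """Lossless platform-neutral array container (.npy)."""
    np.save(path, np.asarray(arr))


def write_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
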