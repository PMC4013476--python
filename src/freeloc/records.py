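"""Trial-record tables and their on-disk CSV schema.

One row per trial: ``trial_id, task, beta, contrast, present, loc_x, loc_y,
response_x, response_y, detected, correct, statistic, session, seed,
processed``.  Coordinates are 0-based with ``x = column`` and ``y = row``,
origin at the top-left pixel; location fields are empty on target-absent
trials and on "absent" responses.

A :class:`TrialSet` couples the table with the per-trial noise fields (which
classification-image estimation needs) and the generating spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .stimulus import SpectrumGrid

__all__ = ["TRIAL_COLUMNS", "TrialSet", "empty_frame"]

TRIAL_COLUMNS = [
    "trial_id", "task", "beta", "contrast", "present",
    "loc_x", "loc_y", "response_x", "response_y",
    "detected", "correct", "statistic", "session", "seed", "processed",
]


def empty_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=TRIAL_COLUMNS)


@dataclass
class TrialSet:
    """Trial records plus the per-trial noise fields and noise spectrum."""

    frame: pd.DataFrame
    noise: Optional[np.ndarray] = None  # (n_trials, shape, shape), float32
    spectrum: Optional[SpectrumGrid] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"trial frame missing columns: {missing}")
        if self.noise is not None and len(self.noise) != len(self.frame):
            raise ValueError("noise stack and frame lengths differ")

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, noise_path=None,
                 spectrum: Optional[SpectrumGrid] = None) -> "TrialSet":
        frame = pd.read_csv(path)
        noise = np.load(noise_path) if noise_path is not None else None
        return cls(frame=frame, noise=noise, spectrum=spectrum)

    def save(self, directory, stem: str = "trials") -> None:
        """Write ``<stem>.csv`` (+ ``<stem>_noise.npy`` when fields exist)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_csv(directory / f"{stem}.csv")
        if self.noise is not None:
            np.save(directory / f"{stem}_noise.npy", self.noise)
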