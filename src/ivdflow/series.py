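"""Time-series container shared by the solver, the synthetic generator and
the rheology fitters, with the CSV + JSON-sidecar on-disk format."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHANNELS = ("axial_displacement", "reaction_force")


@dataclass
class TimeSeries:
    """A sampled response history.

    ``value`` is axial displacement (mm) or reaction force (N) depending on
    ``channel``; ``t`` is seconds from the start of the measured phase.
    """

    t: np.ndarray
    value: np.ndarray
    channel: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.t.shape != self.value.shape:
            raise ValueError("t and value must have matching shapes")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("non-finite values in series")

    def __len__(self) -> int:
        return len(self.t)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame({"t_s": self.t, "value": self.value, "channel": self.channel}).to_csv(
            path, index=False, float_format="%.12g"
        )
        path.with_suffix(".json").write_text(json.dumps(self.metadata, indent=2, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeSeries":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(".json")
        metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            t=df["t_s"].to_numpy(),
            value=df["value"].to_numpy(),
            channel=str(df["channel"].iloc[0]),
            metadata=metadata,
        )
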