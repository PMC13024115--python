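"""Synthetic fixtures with known ground truth.

Stands in for raw solver output so the fitting and statistics stages can
be exercised on their own: noisy double-exponential creep/relaxation
curves (the solver's responses are deterministic; noise here exists purely
to stress the fitters) and indicator datasets with controllable
between-group effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rheology import CreepFit, IndicatorTable, RelaxFit, double_maxwell, double_voigt
from .series import TimeSeries

__all__ = ["SyntheticSpec", "EffectSpec", "gen_curve", "gen_indicator_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """A double-exponential curve with additive Gaussian noise.

    ``true_params`` follows the fit-parameter naming: double_voigt uses
    (ue, u1, tau1, u2, tau2), double_maxwell (F_inf, F1, tau1, F2, tau2).
    ``noise_sd`` is a fraction of the curve's range on the grid.
    """

    model: str  # 'double_voigt' | 'double_maxwell'
    true_params: Mapping[str, float]
    noise_sd: float = 0.0
    time_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(1.0, 108000.0, 200)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("double_voigt", "double_maxwell"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        grid = np.asarray(self.time_grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("time grid must be strictly increasing")


def gen_curve(spec: SyntheticSpec) -> TimeSeries:
    """Evaluate the model on the grid and add seeded Gaussian noise; the
    ground truth is carried in the series metadata."""
    t = np.asarray(spec.time_grid, dtype=float)
    p = dict(spec.true_params)
    if spec.model == "double_voigt":
        clean = double_voigt(t, p["ue"], p["u1"], p["tau1"], p["u2"], p["tau2"])
        channel = "axial_displacement"
    else:
        clean = double_maxwell(t, p["F_inf"], p["F1"], p["tau1"], p["F2"], p["tau2"])
        channel = "reaction_force"
    rng = np.random.default_rng(spec.seed)
    rng_range = float(np.ptp(clean)) or 1.0
    noise = rng.normal(0.0, spec.noise_sd * rng_range, size=t.shape) if spec.noise_sd else 0.0
    return TimeSeries(
        t=t,
        value=clean + noise,
        channel=channel,
        metadata={
            "synthetic": True,
            "model": spec.model,
            "true_params": p,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
            "t_hold_start_s": 0.0,
        },
    )


@dataclass(frozen=True)
class EffectSpec:
    """Gaussian indicator draws with a specified between-group shift.

    ``loc``/``scale`` map each group to the indicator location/scale;
    scalars apply to every indicator.
    """

    indicators: Sequence[str]
    n_per_group: int
    loc: Mapping[str, float]  # group -> location
    scale: Mapping[str, float]  # group -> scale (> 0)
    protocol: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need n >= 2 per group")
        if any(s <= 0 for s in self.scale.values()):
            raise ValueError("scales must be > 0")
        if set(self.loc) != set(self.scale):
            raise ValueError("loc and scale must name the same groups")


def gen_indicator_dataset(spec: EffectSpec) -> IndicatorTable:
    """Seeded per-group indicator draws shaped like the pipeline's
    indicator table (groups appear in the `condition` column)."""
    rng = np.random.default_rng(spec.seed)
    recs = []
    for group in spec.loc:
        for indicator in spec.indicators:
            draws = rng.normal(spec.loc[group], spec.scale[group], size=spec.n_per_group)
            for disc_id, v in enumerate(draws):
                recs.append(
                    dict(
                        disc_id=disc_id,
                        condition=group,
                        protocol=spec.protocol,
                        indicator=indicator,
                        value=float(v),
                    )
                )
    return IndicatorTable(pd.DataFrame.from_records(recs))
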