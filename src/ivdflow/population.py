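"""Probabilistic disc population: Latin hypercube geometry sampling.

Five geometric features of the lumbar intervertebral disc are treated as
independent Gaussian random variables (means/SDs from published lumbar
morphometry): disc height, anterior-posterior length (APL), lateral width,
nucleus pulposus (NP) volume ratio, and wedge angle.  A Latin hypercube
draws one sample per equal-probability stratum of each marginal (at the
stratum median), pairs strata across parameters by independent random
permutations, and duplicates each parameter set into a healthy and a
degenerated disc instance.

Each sampled parameter set is then reduced to the quantities the
one-dimensional column solver consumes: mid-plane ellipse area split into
NP and annulus fibrosus (AF) shares, mean height, and twenty normalized
radial stations for the AF lamellae.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "MarginalSpec",
    "GeometryParams",
    "GeometryConfig",
    "DiscDerived",
    "PopulationTable",
    "TABLE1_MARGINALS",
    "MARGINAL_NAMES",
    "sample_population",
    "derive_geometry",
    "lamella_interpolation",
]

N_LAMELLAE = 20

CONDITIONS = ("healthy", "degenerated")

MARGINAL_NAMES = (
    "disc_height",
    "apl",
    "lateral_width",
    "np_volume_ratio",
    "wedge_angle",
)


@dataclass(frozen=True)
class MarginalSpec:
    """Gaussian marginal for one geometric feature, in its native units
    (mm, degrees, or percent for the NP volume ratio)."""

    name: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"marginal {self.name!r}: sd must be >= 0, got {self.sd}")


#: Published lumbar-disc geometry distributions (NP volume ratio in percent).
TABLE1_MARGINALS: tuple[MarginalSpec, ...] = (
    MarginalSpec("disc_height", 10.21, 1.8),
    MarginalSpec("apl", 37.5, 6.21),
    MarginalSpec("lateral_width", 55.5, 6.3),
    MarginalSpec("np_volume_ratio", 39.3, 5.5),
    MarginalSpec("wedge_angle", 7.82, 6.07),
)


@dataclass(frozen=True)
class GeometryParams:
    """One sampled disc geometry.  np_volume_ratio is stored as a fraction."""

    disc_height: float  # mm
    apl: float  # mm, anterior-posterior length
    lateral_width: float  # mm
    np_volume_ratio: float  # fraction in (0, 1)
    wedge_angle: float  # degrees; metadata only for the 1D column

    def __post_init__(self) -> None:
        for name in ("disc_height", "apl", "lateral_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.np_volume_ratio < 1.0:
            raise ValueError("np_volume_ratio must lie in (0, 1)")


@dataclass(frozen=True)
class GeometryConfig:
    """Reduction constants not parameterized by the sampled population.

    The endplate thicknesses are literature-typical values; the cartilage
    endplates (CEPs) are counted inside the disc height while the bony
    endplates (BEPs) extend the axial stack beyond it.
    """

    cep_thickness: float = 0.6  # mm
    bep_thickness: float = 1.0  # mm
    n_lamellae: int = N_LAMELLAE


@dataclass(frozen=True)
class DiscDerived:
    """Areas, heights and lamella stations consumed by the column solver."""

    total_area: float  # mm^2
    np_area: float  # mm^2
    af_area: float  # mm^2
    mean_height: float  # mm, whole-disc height (CEPs included)
    lamella_fractions: tuple[float, ...]  # 20 radial stations in (0, 1)
    cep_thickness: float  # mm
    bep_thickness: float  # mm

    @property
    def core_height(self) -> float:
        """Axial extent of the soft NP/AF core between the CEPs, mm."""
        return self.mean_height - 2.0 * self.cep_thickness

    @property
    def stack_height(self) -> float:
        """Disc plus the two bony endplates, mm."""
        return self.mean_height + 2.0 * self.bep_thickness

    def __post_init__(self) -> None:
        if abs(self.np_area + self.af_area - self.total_area) > 1e-9 * self.total_area:
            raise ValueError("np_area + af_area must equal total_area")
        fr = np.asarray(self.lamella_fractions)
        if len(fr) != N_LAMELLAE or np.any(np.diff(fr) <= 0):
            raise ValueError(f"lamella_fractions must be {N_LAMELLAE} strictly increasing values")
        if self.cep_thickness <= 0 or self.bep_thickness <= 0:
            raise ValueError("endplate thicknesses must be > 0")
        if 2 * self.cep_thickness + 2 * self.bep_thickness >= self.stack_height:
            raise ValueError("endplates exceed the axial stack height")
        if self.core_height <= 0:
            raise ValueError("disc height leaves no room for the soft core")


@dataclass
class PopulationTable:
    """The sampled population: each parameter set appears under both
    conditions, so ``len(rows) == 2 * n``."""

    rows: pd.DataFrame  # columns: disc_id, condition, the five parameters
    seed: int
    marginals: tuple[MarginalSpec, ...] = field(default=TABLE1_MARGINALS)

    CSV_COLUMNS = (
        "disc_id",
        "condition",
        "disc_height_mm",
        "apl_mm",
        "lateral_width_mm",
        "np_volume_ratio",
        "wedge_angle_deg",
    )

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_parameter_sets(self) -> int:
        return self.rows["disc_id"].nunique()

    def params_for(self, disc_id: int) -> GeometryParams:
        r = self.rows[self.rows.disc_id == disc_id].iloc[0]
        return GeometryParams(
            disc_height=r.disc_height_mm,
            apl=r.apl_mm,
            lateral_width=r.lateral_width_mm,
            np_volume_ratio=r.np_volume_ratio,
            wedge_angle=r.wedge_angle_deg,
        )

    def iter_instances(self):
        """Yield (disc_id, condition, GeometryParams) per row."""
        for _, r in self.rows.iterrows():
            yield int(r.disc_id), str(r.condition), GeometryParams(
                disc_height=r.disc_height_mm,
                apl=r.apl_mm,
                lateral_width=r.lateral_width_mm,
                np_volume_ratio=r.np_volume_ratio,
                wedge_angle=r.wedge_angle_deg,
            )

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.rows.to_csv(path, index=False, float_format="%.10g")
        sidecar = {
            "seed": self.seed,
            "n": int(self.n_parameter_sets),
            "marginals": [asdict(m) for m in self.marginals],
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationTable":
        path = Path(path)
        rows = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        marginals = tuple(MarginalSpec(**m) for m in meta["marginals"])
        return cls(rows=rows, seed=meta["seed"], marginals=marginals)


# bounds used to reject nonphysical Gaussian draws, in native (tabulated) units
_TRUNCATION_BOUNDS = {
    "disc_height": (0.0, math.inf),
    "apl": (0.0, math.inf),
    "lateral_width": (0.0, math.inf),
    "np_volume_ratio": (5.0, 95.0),  # percent
    "wedge_angle": (0.0, math.inf),
}


def sample_population(
    n: int,
    marginals: Sequence[MarginalSpec] = TABLE1_MARGINALS,
    seed: int = 0,
) -> PopulationTable:
    """Latin hypercube sample of ``n`` disc geometries, duplicated into
    healthy and degenerated instances.

    Each Gaussian marginal is split into ``n`` equal-probability strata and
    sampled at the stratum median; strata are paired across parameters by
    independent random permutations.  Draws outside the physical bounds
    (non-positive lengths/angles, NP ratio outside 5-95 %) are replaced by
    rejection sampling from the full Gaussian.
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    names = [m.name for m in marginals]
    if sorted(names) != sorted(MARGINAL_NAMES):
        unknown = set(names) - set(MARGINAL_NAMES)
        missing = set(MARGINAL_NAMES) - set(names)
        raise KeyError(
            f"marginals must cover exactly {MARGINAL_NAMES}; "
            f"unknown={sorted(unknown)}, missing={sorted(missing)}"
        )

    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for m in marginals:
        u = (rng.permutation(n) + 0.5) / n
        x = norm.ppf(u, loc=m.mean, scale=m.sd)
        lo, hi = _TRUNCATION_BOUNDS[m.name]
        bad = ~((x > lo) & (x < hi))
        while np.any(bad):
            x[bad] = rng.normal(m.mean, m.sd, size=int(bad.sum()))
            bad = ~((x > lo) & (x < hi))
        cols[m.name] = x

    frames = []
    for condition in CONDITIONS:
        frames.append(
            pd.DataFrame(
                {
                    "disc_id": np.arange(n, dtype=int),
                    "condition": condition,
                    "disc_height_mm": cols["disc_height"],
                    "apl_mm": cols["apl"],
                    "lateral_width_mm": cols["lateral_width"],
                    "np_volume_ratio": cols["np_volume_ratio"] / 100.0,
                    "wedge_angle_deg": cols["wedge_angle"],
                }
            )
        )
    rows = pd.concat(frames, ignore_index=True)
    return PopulationTable(rows=rows, seed=seed, marginals=tuple(marginals))


def derive_geometry(p: GeometryParams, config: GeometryConfig = GeometryConfig()) -> DiscDerived:
    """Reduce a sampled geometry to column-solver quantities.

    The mid-plane is an ellipse with axes APL x lateral width; the NP share
    of the area equals the NP volume ratio (area ratio == volume ratio to
    first order under linear height fields).  The wedge angle is retained as
    metadata only -- a uniform column cannot express wedging.
    """
    total_area = math.pi * (p.apl / 2.0) * (p.lateral_width / 2.0)
    np_area = p.np_volume_ratio * total_area
    af_area = total_area - np_area
    if total_area <= 0 or np_area <= 0 or af_area < 0:
        raise ValueError("derived areas must be positive")
    k = config.n_lamellae
    fractions = tuple((np.arange(k) + 0.5) / k)
    return DiscDerived(
        total_area=total_area,
        np_area=np_area,
        af_area=af_area,
        mean_height=p.disc_height,
        lamella_fractions=fractions,
        cep_thickness=config.cep_thickness,
        bep_thickness=config.bep_thickness,
    )


def lamella_interpolation(fraction: float, inner_value: float, outer_value: float) -> float:
    """Linear inner->outer profile across the AF lamellae."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"lamella fraction must lie in [0, 1], got {fraction}")
    return inner_value + fraction * (outer_value - inner_value)
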