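"""Shared fixtures: the population-mean disc and its equilibrated columns.

Session-scoped because the 30 h equilibrations are the expensive part and
are reused across solver, rheology and acceptance tests.
"""

from __future__ import annotations

import pytest

from ivdflow.population import GeometryParams, derive_geometry
from ivdflow.solver import (
    ColumnSolver,
    build_column,
    equilibrate_free,
    equilibrate_preload,
)


@pytest.fixture(scope="session")
def mean_params() -> GeometryParams:
    """Disc at the population-mean geometry (NP ratio stored as fraction)."""
    return GeometryParams(
        disc_height=10.21,
        apl=37.5,
        lateral_width=55.5,
        np_volume_ratio=0.393,
        wedge_angle=7.82,
    )


@pytest.fixture(scope="session")
def mean_geometry(mean_params):
    return derive_geometry(mean_params)


@pytest.fixture(scope="session")
def models(mean_geometry):
    return {c: build_column(mean_geometry, c) for c in ("healthy", "degenerated")}


@pytest.fixture(scope="session")
def solvers(models):
    return {c: ColumnSolver(m) for c, m in models.items()}


@pytest.fixture(scope="session")
def swollen_states(solvers):
    """Post free-swelling states per condition."""
    return {c: equilibrate_free(s) for c, s in solvers.items()}


@pytest.fixture(scope="session")
def preloaded_states(solvers, swollen_states):
    """(condition, preload N) -> equilibrated state."""
    out = {}
    for c, s in solvers.items():
        for f in (20.0, 50.0):
            out[(c, f)] = equilibrate_preload(s, f, swollen_states[c])
    return out
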