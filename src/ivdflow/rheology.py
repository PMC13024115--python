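"""Rheological decomposition of creep and relaxation responses.

Creep (and swelling) displacement histories are fitted with the
five-parameter double Voigt model

    u(t) = ue + u1 (1 - exp(-t/tau1c)) + u2 (1 - exp(-t/tau2c)),

relaxation force histories with the double Maxwell model

    F(t) = F_inf + F1 exp(-t/tau1s) + F2 exp(-t/tau2s),

separating a purely elastic (residual) term from short-term and long-term
viscoelastic components.  Time is re-origined to the start of the hold
phase.  The fits use bounded nonlinear least squares with a deterministic
multi-start grid over the time constants; components are reported ordered
(tau1 <= tau2).  The engineering equilibrium time is the first crossing of
a fixed fraction (default 95 %) of the total hold-phase change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import json
import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .series import TimeSeries

__all__ = [
    "CreepFit",
    "RelaxFit",
    "IndicatorTable",
    "INDICATORS_DISPLACEMENT",
    "INDICATORS_FORCE",
    "fit_double_voigt",
    "fit_double_maxwell",
    "equilibrium_time",
    "double_voigt",
    "double_maxwell",
    "indicator_rows",
]

#: minimum number of hold-phase samples for a fit
MIN_SAMPLES = 12
#: tau2/tau1 below this is flagged weakly identified
IDENTIFIABILITY_RATIO = 3.0

INDICATORS_DISPLACEMENT = (
    "elastic_displacement",
    "short_term_displacement",
    "long_term_displacement",
    "total_displacement",
    "short_term_time",
    "long_term_time",
    "equilibrium_time",
)
INDICATORS_FORCE = (
    "residual_force",
    "short_term_force",
    "long_term_force",
    "short_term_time",
    "long_term_time",
    "equilibrium_time",
)


def double_voigt(t, ue, u1, tau1, u2, tau2):
    """Forward evaluation of the double Voigt creep model."""
    t = np.asarray(t, dtype=float)
    return ue + u1 * (1.0 - np.exp(-t / tau1)) + u2 * (1.0 - np.exp(-t / tau2))


def double_maxwell(t, F_inf, F1, tau1, F2, tau2):
    """Forward evaluation of the double Maxwell relaxation model."""
    t = np.asarray(t, dtype=float)
    return F_inf + F1 * np.exp(-t / tau1) + F2 * np.exp(-t / tau2)


@dataclass
class CreepFit:
    """Double-Voigt decomposition of a creep/swelling displacement history."""

    ue: float  # elastic displacement, mm
    u1: float  # short-term amplitude, mm
    u2: float  # long-term amplitude, mm
    tau1c: float  # short time constant, s
    tau2c: float  # long time constant, s  (tau1c <= tau2c)
    t_eq: float  # equilibrium time, s
    rmse: float  # mm
    converged: bool
    eq_fraction: float = 0.95
    weakly_identified: bool = False
    jac_cond: float = float("nan")

    @property
    def total(self) -> float:
        """ue + u1 + u2, mm."""
        return self.ue + self.u1 + self.u2

    def predict(self, t):
        return double_voigt(t, self.ue, self.u1, self.tau1c, self.u2, self.tau2c)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self) | {"total": self.total}, indent=2))


@dataclass
class RelaxFit:
    """Double-Maxwell decomposition of a relaxation force history."""

    F_inf: float  # residual force, N
    F1: float  # short-term amplitude, N
    F2: float  # long-term amplitude, N
    tau1s: float  # short time constant, s
    tau2s: float  # long time constant, s  (tau1s <= tau2s)
    t_eq: float  # equilibrium time, s
    rmse: float  # N
    converged: bool
    eq_fraction: float = 0.95
    weakly_identified: bool = False
    jac_cond: float = float("nan")

    def predict(self, t):
        return double_maxwell(t, self.F_inf, self.F1, self.tau1s, self.F2, self.tau2s)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass
class IndicatorTable:
    """Tidy indicator rows: one (disc, condition, protocol, indicator)
    value per row; only converged fits are included."""

    rows: pd.DataFrame

    COLUMNS = ("disc_id", "condition", "protocol", "indicator", "value")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"indicator table missing columns {sorted(missing)}")
        if len(self.rows):
            dup = self.rows.duplicated(subset=["disc_id", "condition", "protocol", "indicator"])
            if dup.any():
                raise ValueError("duplicate indicator rows")
            if not np.all(np.isfinite(self.rows["value"].to_numpy(dtype=float))):
                raise ValueError("non-finite indicator values")

    def __len__(self) -> int:
        return len(self.rows)

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "IndicatorTable":
        return cls(pd.read_csv(path))


def _hold_phase(ts: TimeSeries, t0: Optional[float]) -> tuple[np.ndarray, np.ndarray]:
    if t0 is None:
        t0 = float(ts.metadata.get("t_hold_start_s", 0.0))
    mask = ts.t >= t0 - 1e-12
    t = ts.t[mask] - t0
    y = ts.value[mask]
    if len(t) < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} hold-phase samples, got {len(t)}")
    return t, y


#: deterministic multi-start grid: 8 (tau1, tau2) pairs log-spaced in [10, 1e5] s
_TAU_STARTS = [(t1, t1 * r) for t1 in np.geomspace(10.0, 3.3e3, 4) for r in (5.0, 30.0)]


def _multistart_fit(t, y, kind: str):
    """Shared engine: returns (params, rmse, converged, cond)."""
    span = float(y[-1] - y[0])
    best = None
    scale_y = max(abs(span), np.max(np.abs(y)), 1e-12)

    for tau1_0, tau2_0 in _TAU_STARTS:
        if kind == "voigt":
            p0 = [max(y[0], 0.0), abs(span) / 2, tau1_0, abs(span) / 2, tau2_0]

            def model(p, tt):
                return double_voigt(tt, *p)
        else:
            p0 = [max(y[-1], 0.0), abs(span) / 2, tau1_0, abs(span) / 2, tau2_0]

            def model(p, tt):
                return double_maxwell(tt, *p)

        res = least_squares(
            lambda p: model(p, t) - y,
            p0,
            bounds=(np.zeros(5), np.full(5, np.inf)),
            method="trf",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=4000,
        )
        if best is None or res.cost < best.cost:
            best = res
        if res.cost < (1e-8 * scale_y) ** 2 * len(t):
            break  # numerically exact; later starts cannot do better

    rmse = float(np.sqrt(2 * best.cost / len(t)))
    converged = bool(best.success and np.all(np.isfinite(best.x)))
    # condition number of the Jacobian at the solution (identifiability)
    sv = np.linalg.svd(best.jac, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    return best.x, rmse, converged, cond


def fit_double_voigt(
    ts: TimeSeries, t0: Optional[float] = None, eq_fraction: float = 0.95
) -> CreepFit:
    """Fit the double Voigt model to a displacement history.

    ``t0`` is the hold-phase origin (end of the loading ramp); when omitted
    it is read from the series metadata.  Components are swapped post-fit
    so that tau1c <= tau2c.
    """
    if ts.channel != "axial_displacement":
        raise ValueError("double Voigt fits displacement series")
    t, y = _hold_phase(ts, t0)
    (ue, u1, tau1, u2, tau2), rmse, converged, cond = _multistart_fit(t, y, "voigt")
    if tau1 > tau2:
        u1, u2, tau1, tau2 = u2, u1, tau2, tau1
    t_eq = equilibrium_time(TimeSeries(t=t, value=y, channel=ts.channel), eq_fraction)
    weak = (tau2 / tau1 < IDENTIFIABILITY_RATIO) if tau1 > 0 else True
    return CreepFit(
        ue=float(ue), u1=float(u1), u2=float(u2), tau1c=float(tau1), tau2c=float(tau2),
        t_eq=float(t_eq), rmse=rmse, converged=converged, eq_fraction=eq_fraction,
        weakly_identified=bool(weak), jac_cond=cond,
    )


def fit_double_maxwell(
    ts: TimeSeries, t0: Optional[float] = None, eq_fraction: float = 0.95
) -> RelaxFit:
    """Fit the double Maxwell model to a reaction-force history."""
    if ts.channel != "reaction_force":
        raise ValueError("double Maxwell fits reaction-force series")
    t, y = _hold_phase(ts, t0)
    (F_inf, F1, tau1, F2, tau2), rmse, converged, cond = _multistart_fit(t, y, "maxwell")
    if tau1 > tau2:
        F1, F2, tau1, tau2 = F2, F1, tau2, tau1
    t_eq = equilibrium_time(TimeSeries(t=t, value=y, channel=ts.channel), eq_fraction)
    weak = (tau2 / tau1 < IDENTIFIABILITY_RATIO) if tau1 > 0 else True
    return RelaxFit(
        F_inf=float(F_inf), F1=float(F1), F2=float(F2), tau1s=float(tau1), tau2s=float(tau2),
        t_eq=float(t_eq), rmse=rmse, converged=converged, eq_fraction=eq_fraction,
        weakly_identified=bool(weak), jac_cond=cond,
    )


def equilibrium_time(ts: TimeSeries, fraction: float = 0.95) -> float:
    """First time the hold-phase response covers ``fraction`` of its total
    change, by linear interpolation between samples.

    For a monotone-in-trend series with non-monotone noise the monotone
    envelope (running extremum toward the terminal value) is crossed
    instead, with a warning.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    t, y = ts.t, ts.value
    total = y[-1] - y[0]
    if total == 0.0:
        return float(t[0])
    target = y[0] + fraction * total
    yy = y
    diffs = np.diff(y) * np.sign(total)
    if np.any(diffs < -1e-9 * abs(total)):
        warnings.warn("non-monotone series; using monotone envelope crossing")
        yy = np.maximum.accumulate(y) if total > 0 else np.minimum.accumulate(y)
    if total > 0:
        idx = np.argmax(yy >= target)
    else:
        idx = np.argmax(yy <= target)
    if idx == 0:
        return float(t[0])
    t1, t2 = t[idx - 1], t[idx]
    y1, y2 = yy[idx - 1], yy[idx]
    if y2 == y1:
        return float(t2)
    return float(t1 + (target - y1) / (y2 - y1) * (t2 - t1))


def indicator_rows(
    fit: CreepFit | RelaxFit, disc_id: int, condition: str, protocol: str
) -> list[dict]:
    """Tidy indicator rows for one converged fit (empty if not converged)."""
    if not fit.converged:
        return []
    if isinstance(fit, CreepFit):
        values = {
            "elastic_displacement": fit.ue,
            "short_term_displacement": fit.u1,
            "long_term_displacement": fit.u2,
            "total_displacement": fit.total,
            "short_term_time": fit.tau1c,
            "long_term_time": fit.tau2c,
            "equilibrium_time": fit.t_eq,
        }
    else:
        values = {
            "residual_force": fit.F_inf,
            "short_term_force": fit.F1,
            "long_term_force": fit.F2,
            "short_term_time": fit.tau1s,
            "long_term_time": fit.tau2s,
            "equilibrium_time": fit.t_eq,
        }
    return [
        {
            "disc_id": disc_id,
            "condition": condition,
            "protocol": protocol,
            "indicator": k,
            "value": v,
        }
        for k, v in values.items()
    ]
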