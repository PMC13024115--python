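"""Full-study orchestration: population -> solver -> fits -> statistics.

A study samples ``n`` disc geometries, instantiates each under healthy and
degenerated material cards, runs the seven-protocol roster (free swelling;
creep at 500/1000/1500 N; relaxation at 5/10/15 % strain) with cached
pre-equilibrations, decomposes every response with the matching rheological
model, and compares indicator distributions.  All outputs land in one
directory with a manifest tying them to the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .population import (
    GeometryConfig,
    MarginalSpec,
    PopulationTable,
    TABLE1_MARGINALS,
    derive_geometry,
    sample_population,
)
from .rheology import IndicatorTable, fit_double_maxwell, fit_double_voigt, indicator_rows
from .series import TimeSeries
from .solver import (
    ColumnConfig,
    ColumnSolver,
    ProtocolSpec,
    SolverConfig,
    build_column,
    creep_protocol,
    default_protocols,
    equilibrate_free,
    equilibrate_preload,
    relaxation_protocol,
    run_protocol,
    swelling_protocol,
)
from .stats import ComparisonResult, compare_groups

__all__ = ["StudyConfig", "StudyResult", "StudyError", "run_study", "protocol_from_label"]

log = logging.getLogger("ivdflow")


class StudyError(RuntimeError):
    """Too many per-disc failures to trust the study."""


@dataclass
class StudyConfig:
    """Everything a study run depends on; serialized into the manifest."""

    n: int = 50
    seed: int = 0
    out_dir: str = "study_out"
    conditions: tuple[str, ...] = ("healthy", "degenerated")
    protocols: tuple[str, ...] = (
        "swelling_0N",
        "creep_500N",
        "creep_1000N",
        "creep_1500N",
        "relaxation_5pct",
        "relaxation_10pct",
        "relaxation_15pct",
    )
    alpha: float = 0.05
    eq_fraction: float = 0.95
    marginal_overrides: dict = field(default_factory=dict)  # name -> (mean, sd)
    solver: SolverConfig = field(default_factory=SolverConfig)
    column: ColumnConfig = field(default_factory=ColumnConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    write_series: bool = True
    make_report: bool = True
    min_success_fraction: float = 0.9

    def marginals(self) -> tuple[MarginalSpec, ...]:
        out = []
        for m in TABLE1_MARGINALS:
            if m.name in self.marginal_overrides:
                mean, sd = self.marginal_overrides[m.name]
                out.append(MarginalSpec(m.name, mean, sd))
            else:
                out.append(m)
        return tuple(out)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, sub in (("solver", SolverConfig), ("column", ColumnConfig), ("geometry", GeometryConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        for key in ("conditions", "protocols"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def protocol_from_label(label: str) -> ProtocolSpec:
    """Inverse of ProtocolSpec.label for the standard roster."""
    if label.startswith("swelling_"):
        return swelling_protocol(float(label.removeprefix("swelling_").removesuffix("N")))
    if label.startswith("creep_"):
        return creep_protocol(float(label.removeprefix("creep_").removesuffix("N")))
    if label.startswith("relaxation_"):
        pct = float(label.removeprefix("relaxation_").removesuffix("pct"))
        return relaxation_protocol(pct / 100.0)
    raise ValueError(f"unrecognized protocol label {label!r}")


@dataclass
class StudyResult:
    config: StudyConfig
    population: PopulationTable
    indicators: IndicatorTable
    stats: ComparisonResult
    failures: list[str]
    out_dir: Path
    elapsed_s: float


def _series_filename(disc_id: int, condition: str, protocol: str) -> str:
    return f"series_{disc_id:03d}_{condition}_{protocol}.csv"


def simulate_instance(
    geom_params,
    condition: str,
    config: StudyConfig,
) -> dict[str, TimeSeries]:
    """Run the full protocol roster for one disc instance, reusing the
    free-swelling and preload equilibrations across protocols."""
    geom = derive_geometry(geom_params, config.geometry)
    model = build_column(geom, condition, config.column)
    solver = ColumnSolver(model, config.solver)
    protocols = [protocol_from_label(lbl) for lbl in config.protocols]

    s_free = None
    pre_states: dict[float, object] = {}
    out: dict[str, TimeSeries] = {}
    for proto in protocols:
        if proto.kind == "swelling" and proto.preload == 0:
            out[proto.label] = run_protocol(solver, proto)
            continue
        if s_free is None:
            s_free = equilibrate_free(solver)
        if proto.kind == "swelling":
            out[proto.label] = run_protocol(solver, proto, start_state=s_free)
            continue
        if proto.preload not in pre_states:
            pre_states[proto.preload] = equilibrate_preload(solver, proto.preload, s_free)
        out[proto.label] = run_protocol(solver, proto, start_state=pre_states[proto.preload])
    return out


def fit_series(ts: TimeSeries, eq_fraction: float = 0.95):
    """Dispatch a series to the matching rheological model."""
    if ts.channel == "axial_displacement":
        return fit_double_voigt(ts, eq_fraction=eq_fraction)
    return fit_double_maxwell(ts, eq_fraction=eq_fraction)


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the whole pipeline and write the output bundle.

    Per-disc failures are quarantined; the study aborts (after writing the
    manifest) if fewer than ``min_success_fraction`` of the instance
    protocols succeed.
    """
    t_start = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_dir = out_dir / "series"
    fits_dir = out_dir / "fits"
    chash = config.config_hash()

    log.info("study start: n=%d seed=%d hash=%s", config.n, config.seed, chash)
    population = sample_population(config.n, config.marginals(), config.seed)
    population.to_csv(out_dir / "population.csv")

    rows: list[dict] = []
    failures: list[str] = []
    attempted = 0
    for disc_id, condition, gp in population.iter_instances():
        if condition not in config.conditions:
            continue
        attempted += len(config.protocols)
        try:
            series = simulate_instance(gp, condition, config)
        except Exception as exc:  # quarantine whole instance
            failures.extend(f"{disc_id}/{condition}/{lbl}: {exc}" for lbl in config.protocols)
            log.warning("instance failed: disc %d %s: %s", disc_id, condition, exc)
            continue
        for label, ts in series.items():
            ts.metadata["disc_id"] = disc_id
            ts.metadata["config_hash"] = chash
            if config.write_series:
                series_dir.mkdir(exist_ok=True)
                ts.to_csv(series_dir / _series_filename(disc_id, condition, label))
            try:
                fit = fit_series(ts, config.eq_fraction)
                if not fit.converged:
                    raise RuntimeError("fit did not converge")
                fits_dir.mkdir(exist_ok=True)
                fit.to_json(fits_dir / f"fit_{disc_id:03d}_{condition}_{label}.json")
                rows.extend(indicator_rows(fit, disc_id, condition, label))
            except Exception as exc:
                failures.append(f"{disc_id}/{condition}/{label}: {exc}")
                log.warning("fit failed: disc %d %s %s: %s", disc_id, condition, label, exc)

    n_ok = attempted - len(failures)
    indicators = IndicatorTable(
        pd.DataFrame(rows, columns=list(IndicatorTable.COLUMNS))
        .sort_values(["protocol", "condition", "disc_id", "indicator"])
        .reset_index(drop=True)
    )
    indicators.to_csv(out_dir / "indicators.csv")
    (out_dir / "indicators.json").write_text(
        json.dumps({"config_hash": chash, "rows": len(indicators)}, indent=2)
    )

    stats = compare_groups(indicators, alpha=config.alpha) if len(indicators) else ComparisonResult([], [], config.alpha)
    stats.to_csv(out_dir / "stats.csv")

    manifest = {
        "config": config.to_dict(),
        "config_hash": chash,
        "ivdflow_version": __version__,
        "n_parameter_sets": int(population.n_parameter_sets),
        "n_instances": int(len(population)),
        "protocols_attempted": attempted,
        "protocols_succeeded": n_ok,
        "failures": failures,
        "elapsed_s": round(time.time() - t_start, 2),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    if attempted and n_ok / attempted < config.min_success_fraction:
        raise StudyError(
            f"only {n_ok}/{attempted} protocol runs succeeded "
            f"(< {config.min_success_fraction:.0%}); see manifest at {out_dir}"
        )

    if config.make_report and len(indicators):
        write_report(indicators, stats, out_dir)

    elapsed = time.time() - t_start
    log.info("study done in %.1fs: %d/%d runs ok", elapsed, n_ok, attempted)
    return StudyResult(
        config=config,
        population=population,
        indicators=indicators,
        stats=stats,
        failures=failures,
        out_dir=out_dir,
        elapsed_s=elapsed,
    )


def write_report(indicators: IndicatorTable, stats: ComparisonResult, out_dir: Path) -> None:
    """Boxplot panels (indicator by condition and protocol) plus an HTML
    index; mirrors the style of condition-comparison figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    df = indicators.rows
    pngs = []
    for kind in ("swelling", "creep", "relaxation"):
        sub = df[df.protocol.str.startswith(kind)]
        if not len(sub):
            continue
        inds = sorted(sub.indicator.unique())
        fig, axes = plt.subplots(1, len(inds), figsize=(3.2 * len(inds), 3.4), squeeze=False)
        for ax, ind in zip(axes[0], inds):
            cell = sub[sub.indicator == ind]
            protocols = sorted(cell.protocol.unique())
            data, labels, colors = [], [], []
            for proto in protocols:
                for cond in ("healthy", "degenerated"):
                    vals = cell[(cell.protocol == proto) & (cell.condition == cond)]["value"]
                    if len(vals):
                        data.append(vals.to_numpy())
                        labels.append(f"{proto.split('_', 1)[1]}\n{cond[:4]}")
                        colors.append("#4878cf" if cond == "healthy" else "#d65f5f")
            if not data:
                continue
            bp = ax.boxplot(data, patch_artist=True, tick_labels=labels)
            for patch, c in zip(bp["boxes"], colors):
                patch.set_facecolor(c)
            ax.set_title(ind.replace("_", " "), fontsize=9)
            ax.tick_params(labelsize=6)
        fig.suptitle(f"{kind} indicators by condition and level")
        fig.tight_layout()
        png = out_dir / f"report_{kind}.png"
        fig.savefig(png, dpi=110)
        plt.close(fig)
        pngs.append(png.name)

    html = ["<html><body><h1>ivdflow study report</h1>"]
    html.append(f"<p>{len(df)} indicator rows; {len(stats.rows)} contrasts "
                f"({sum(r.significant for r in stats.rows)} significant).</p>")
    html.extend(f'<img src="{p}" style="max-width:100%"><br>' for p in pngs)
    html.append("</body></html>")
    (out_dir / "report.html").write_text("\n".join(html))
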