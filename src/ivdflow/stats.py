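"""Nonparametric group comparisons with FDR control.

Healthy and degenerated indicator distributions are compared per protocol,
and load/strain levels are compared within each condition, using the
two-sided Mann-Whitney U test.  The Benjamini-Hochberg step-up procedure
controls the false discovery rate at alpha = 0.05 within each comparison
family (all cells of one table-like block).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .rheology import IndicatorTable

__all__ = [
    "StatsRow",
    "ComparisonResult",
    "mann_whitney_u",
    "bh_adjust",
    "compare_groups",
    "EXACT_PRODUCT_THRESHOLD",
]

#: exact null enumeration is used when n1*n2 <= this and there are no ties
EXACT_PRODUCT_THRESHOLD = 400


@dataclass(frozen=True)
class StatsRow:
    """One indicator x group-pair comparison."""

    indicator: str
    comparison: str  # e.g. "healthy-vs-degenerated @ creep_500N"
    family: str  # BH adjustment family the row belongs to
    U: float  # Mann-Whitney statistic for the first sample
    p_raw: float
    p_adj: float
    significant: bool
    n1: int
    n2: int


@dataclass
class ComparisonResult:
    rows: list[StatsRow]
    skipped: list[str]  # contrasts without complete data
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for x, raw p).

    The exact null distribution is enumerated for small tie-free samples
    (n1*n2 <= 400); otherwise the tie-corrected normal approximation with
    continuity correction is used -- the regime the study's n = 50 groups
    fall into.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) * len(y) <= EXACT_PRODUCT_THRESHOLD and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order.

    Zeros are floored at machine epsilon so adjusted values are never
    spuriously exactly zero.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.maximum(p, np.finfo(float).eps)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


_KINDS = ("swelling", "creep", "relaxation")


def _kind_of(protocol: str) -> str:
    for k in _KINDS:
        if protocol.startswith(k):
            return k
    return "other"


def compare_groups(
    table: IndicatorTable,
    design: Optional[dict] = None,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Run the full comparison plan on an indicator table.

    Two kinds of contrast are formed:

    * condition contrasts -- healthy vs degenerated for every
      (protocol, indicator) cell; one BH family per protocol kind;
    * load contrasts -- every pair of protocols of the same kind, within
      each condition and indicator; one BH family per protocol kind
      (a Table-5/6-like block spanning both conditions).

    ``design`` may override ``{"conditions": (a, b), "families": "per_kind"
    | "per_indicator"}``.  Contrasts with a missing or empty cell are
    skipped and listed in the result.
    """
    design = design or {}
    cond_a, cond_b = design.get("conditions", ("healthy", "degenerated"))
    family_mode = design.get("families", "per_kind")
    df = table.rows
    rows_raw: list[dict] = []
    skipped: list[str] = []

    def values(protocol, condition, indicator) -> np.ndarray:
        sel = df[
            (df.protocol == protocol) & (df.condition == condition) & (df.indicator == indicator)
        ]
        return sel["value"].to_numpy(dtype=float)

    protocols = sorted(df["protocol"].unique())
    for protocol in protocols:
        kind = _kind_of(protocol)
        for indicator in sorted(df[df.protocol == protocol]["indicator"].unique()):
            x = values(protocol, cond_a, indicator)
            y = values(protocol, cond_b, indicator)
            label = f"{cond_a}-vs-{cond_b} @ {protocol}"
            if len(x) == 0 or len(y) == 0:
                skipped.append(f"{label} [{indicator}]")
                continue
            U, p = mann_whitney_u(x, y)
            family = f"condition:{kind}" if family_mode == "per_kind" else (
                f"condition:{kind}:{indicator}"
            )
            rows_raw.append(
                dict(indicator=indicator, comparison=label, family=family,
                     U=U, p_raw=p, n1=len(x), n2=len(y))
            )

    by_kind: dict[str, list[str]] = {}
    for protocol in protocols:
        by_kind.setdefault(_kind_of(protocol), []).append(protocol)
    for kind, prots in by_kind.items():
        for pa, pb in combinations(sorted(prots), 2):
            indicators = sorted(
                set(df[df.protocol == pa]["indicator"]) & set(df[df.protocol == pb]["indicator"])
            )
            for condition in (cond_a, cond_b):
                for indicator in indicators:
                    x = values(pa, condition, indicator)
                    y = values(pb, condition, indicator)
                    label = f"{pa}-vs-{pb} within {condition}"
                    if len(x) == 0 or len(y) == 0:
                        skipped.append(f"{label} [{indicator}]")
                        continue
                    U, p = mann_whitney_u(x, y)
                    family = f"load:{kind}" if family_mode == "per_kind" else (
                        f"load:{kind}:{indicator}"
                    )
                    rows_raw.append(
                        dict(indicator=indicator, comparison=label, family=family,
                             U=U, p_raw=p, n1=len(x), n2=len(y))
                    )

    # BH within each family
    rows: list[StatsRow] = []
    fam_index: dict[str, list[int]] = {}
    for i, r in enumerate(rows_raw):
        fam_index.setdefault(r["family"], []).append(i)
    p_adj_all = np.empty(len(rows_raw))
    for fam, idx in fam_index.items():
        p_adj_all[idx] = bh_adjust([rows_raw[i]["p_raw"] for i in idx])
    for r, padj in zip(rows_raw, p_adj_all):
        rows.append(
            StatsRow(
                indicator=r["indicator"], comparison=r["comparison"], family=r["family"],
                U=r["U"], p_raw=r["p_raw"], p_adj=float(padj),
                significant=bool(padj <= alpha), n1=r["n1"], n2=r["n2"],
            )
        )
    rows.sort(key=lambda r: (r.family, r.comparison, r.indicator))
    return ComparisonResult(rows=rows, skipped=sorted(skipped), alpha=alpha)
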