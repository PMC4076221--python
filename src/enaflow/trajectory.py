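"""Time-series analysis of flow-network indices.

Covers four pieces of machinery for a multi-year sequence of networks:
exponential growth rates (endpoint compound annual rate, the default, and
a log-linear regression alternative); segmentation of an AMI series into
maximal monotone stages; and the complete decomposition of ascendency
change over a stage into the parts attributable to growth (TST) and to
development (AMI).

Complete decomposition: for a product variable ``V = x * y`` changing
from ``(x0, y0)`` to ``(x1, y1)``,

    dV = dx*y0 + dy*x0 + dx*dy

where the interaction residual ``dx*dy`` is jointly created by both
factors and is split equally between them:

    C_x = dx*y0 + dx*dy/2        C_y = dy*x0 + dx*dy/2

so that ``C_x + C_y = dV`` with no unexplained remainder.  Percent shares
``C_x/dV`` and ``C_y/dV`` always sum to 100% and either may exceed 100%
or be negative when the factors pull in opposite directions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import CurrencyNetwork, DeflatorSeries, deflate, to_extended_matrix
from .indices import IndexReport, index_report


def growth_rate_endpoint(v0: float, v1: float, span_years: float) -> float:
    """Endpoint compound annual growth rate ``(v1/v0)**(1/span) - 1``.

    This is the estimator that reproduces published exponential growth
    rates from printed start/end values; returned as a fraction
    (0.1109 for 11.09 % per year).
    """
    if v0 <= 0 or v1 <= 0:
        raise ValueError("endpoint values must be positive")
    if span_years <= 0:
        raise ValueError("span must be positive")
    return (v1 / v0) ** (1.0 / span_years) - 1.0


def growth_rate_regression(series: Sequence[tuple[float, float]]) -> float:
    """Exponential rate from least squares of log value on year.

    Uses all points, not just the endpoints; on an exact exponential
    series both estimators agree.  Returns ``exp(slope) - 1``.
    """
    if len(series) < 2:
        raise ValueError("need at least two points")
    years = np.array([y for y, _ in series], dtype=float)
    values = np.array([v for _, v in series], dtype=float)
    if np.any(values <= 0):
        raise ValueError("all values must be positive")
    slope = stats.linregress(years, np.log(values)).slope
    return math.exp(slope) - 1.0


@dataclass(frozen=True)
class Stage:
    """A maximal run of years over which AMI moves in one direction."""

    start_year: int
    end_year: int
    direction: str  # "increasing" | "decreasing" | "flat"

    def __str__(self) -> str:
        return f"{self.start_year}–{self.end_year}"


def segment_stages(ami_series: Sequence[tuple[int, float]]) -> list[Stage]:
    """Split a (year, AMI) series into maximal monotone stages.

    Consecutive stages share their boundary year.  A zero difference
    between adjacent years is merged into the preceding stage (or into
    the following one when no direction has been established yet); a
    completely constant series yields a single "flat" stage.
    """
    if len(ami_series) < 2:
        raise ValueError("need at least two points to segment")
    years = [int(y) for y, _ in ami_series]
    values = [float(v) for _, v in ami_series]
    if any(b <= a for a, b in zip(years, years[1:])):
        raise ValueError("years must be strictly increasing")
    diffs = np.diff(values)
    stages: list[Stage] = []
    start = 0
    sign = 0
    for k, d in enumerate(diffs):
        s = int(np.sign(d))
        if s == 0:
            continue
        if sign == 0:
            sign = s
        elif s != sign:
            stages.append(Stage(years[start], years[k],
                                "increasing" if sign > 0 else "decreasing"))
            start = k
            sign = s
    direction = {1: "increasing", -1: "decreasing", 0: "flat"}[sign]
    stages.append(Stage(years[start], years[-1], direction))
    return stages


@dataclass(frozen=True)
class DecompositionResult:
    """Split of a stage's ascendency change into TST and AMI contributions.

    ``contribution_x``/``contribution_y`` are the absolute contributions
    of the size factor (TST) and the organization factor (AMI);
    ``percent_x``/``percent_y`` are their shares of ``delta_v`` and are
    ``None`` when ``delta_v`` is zero (the shares are then undefined).
    """

    x0: float
    x1: float
    y0: float
    y1: float
    delta_x: float
    delta_y: float
    delta_v: float
    contribution_x: float
    contribution_y: float
    residual: float
    percent_x: float | None
    percent_y: float | None
    stage: Stage | None = None

    def to_dict(self) -> dict:
        d = {
            "x0": self.x0, "x1": self.x1, "y0": self.y0, "y1": self.y1,
            "delta_x": self.delta_x, "delta_y": self.delta_y,
            "delta_v": self.delta_v,
            "contribution_x": self.contribution_x,
            "contribution_y": self.contribution_y,
            "residual": self.residual,
            "percent_x": self.percent_x, "percent_y": self.percent_y,
        }
        if self.stage is not None:
            d["stage"] = str(self.stage)
        return d


def decompose_change(x0: float, x1: float, y0: float, y1: float,
                     stage: Stage | None = None) -> DecompositionResult:
    """Completely decompose the change in ``V = x*y`` into factor contributions.

    The interaction term is split equally, so the two contributions sum
    to the total change exactly.
    """
    for v in (x0, x1, y0, y1):
        if not math.isfinite(v):
            raise ValueError("inputs must be finite")
    dx = x1 - x0
    dy = y1 - y0
    cx = dx * y0 + dx * dy / 2.0
    cy = dy * x0 + dx * dy / 2.0
    dv = cx + cy  # completeness holds by construction; equals x1*y1 - x0*y0
    if dv != 0.0:
        px: float | None = cx / dv * 100.0
        py: float | None = cy / dv * 100.0
    else:
        px = py = None
    return DecompositionResult(x0, x1, y0, y1, dx, dy, dv, cx, cy,
                               dx * dy, px, py, stage)


@dataclass
class NetworkSeries:
    """An ordered multi-year sequence of currency networks.

    When a deflator is supplied, all per-year indices are computed on the
    constant-price networks, matching the convention that TST in the
    ascendency and capacity formulas is inflation-adjusted.
    """

    entries: list[tuple[int, CurrencyNetwork]]
    deflator: DeflatorSeries | None = None

    def __post_init__(self) -> None:
        years = [y for y, _ in self.entries]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        labels = {net.sector_labels for _, net in self.entries}
        if len(labels) > 1:
            raise ValueError("all networks must share the same sector labels")

    @property
    def years(self) -> list[int]:
        return [y for y, _ in self.entries]

    def network(self, year: int, *, constant_price: bool = True) -> CurrencyNetwork:
        for y, net in self.entries:
            if y == year:
                if constant_price and self.deflator is not None:
                    return deflate(net if net.year is not None
                                   else _with_year(net, y), self.deflator)
                return net
        raise KeyError(year)

    def index_reports(self, unit: str = "bits") -> list[IndexReport]:
        """Per-year index reports, on constant-price flows when deflatable."""
        reports = []
        for y, net in self.entries:
            if self.deflator is not None:
                net = deflate(net if net.year is not None else _with_year(net, y),
                              self.deflator)
            reports.append(index_report(to_extended_matrix(net), unit, year=y))
        return reports

    def index_frame(self, unit: str = "bits") -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.index_reports(unit)])


def _with_year(net: CurrencyNetwork, year: int) -> CurrencyNetwork:
    from dataclasses import replace
    return replace(net, year=year)


def decompose_series(series: NetworkSeries, unit: str = "bits") -> list[DecompositionResult]:
    """Decompose the ascendency change of every monotone-AMI stage.

    Stages are segmented on the per-year AMI series; each stage's change
    in ascendency is then split between TST and AMI using the values at
    the stage's boundary years.
    """
    reports = series.index_reports(unit)
    by_year = {r.year: r for r in reports}
    stages = segment_stages([(r.year, r.ami) for r in reports])
    results = []
    for st in stages:
        r0, r1 = by_year[st.start_year], by_year[st.end_year]
        results.append(decompose_change(r0.tst, r1.tst, r0.ami, r1.ami, stage=st))
    return results


def decomposition_frame(results: Sequence[DecompositionResult]) -> pd.DataFrame:
    """Stage-by-stage table with stages as columns and percent rows.

    Mirrors the usual presentation: one column per stage, rows for the
    TST (%) and AMI (%) shares of the ascendency change.
    """
    cols = {}
    for r in results:
        name = str(r.stage) if r.stage is not None else f"{r.x0:g}->{r.x1:g}"
        cols[name] = {"TST (%)": r.percent_x, "AMI (%)": r.percent_y,
                      "delta_A": r.delta_v,
                      "contribution_TST": r.contribution_x,
                      "contribution_AMI": r.contribution_y}
    return pd.DataFrame(cols)


def decomposition_to_json(results: Sequence[DecompositionResult],
                          path: str | Path | None = None) -> str:
    s = json.dumps([r.to_dict() for r in results], indent=2)
    if path is not None:
        Path(path).write_text(s + "\n")
    return s
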