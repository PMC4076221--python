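"""Information-theoretic growth-and-development indices for flow networks.

Given a supply-by-demand flow matrix ``T`` with entries ``T_ij`` (flow
from compartment ``i`` to compartment ``j``), row sums ``T_i.``, column
sums ``T_.j`` and grand total ``T..``, the joint probability that a
quantum of currency leaves ``i`` and enters ``j`` is estimated as
``p(a_i, b_j) = T_ij / T..``, with marginals ``p(a_i) = T_i. / T..`` and
``p(b_j) = T_.j / T..``.  From these:

- total system throughput  ``TST = T..``  (system size / activity; growth
  is any increase in TST);
- flow diversity  ``H = -sum p(a_i,b_j) log p(a_i,b_j)``;
- average mutual information
  ``AMI = sum p(a_i,b_j) log [ p(a_i,b_j) / (p(a_i) p(b_j)) ]``
  (network organization; development is any increase in AMI);
- ascendency ``A = TST * AMI`` (growth and development combined);
- development capacity ``C = TST * H`` (upper bound on A);
- resilience ``R = C - A`` (uncommitted, redundant flow structure).

Each flow contributes exactly one term
``t_ij = T_ij * log(T_ij * T.. / (T_i. * T_.j))`` to the sum defining
ascendency; the per-flow contribution matrix tabulates these terms with
supply-side (row) and demand-side (column) subtotals.

Logarithm base 2 gives bits (the default); natural logarithms give nats.
Cells with ``T_ij = 0`` contribute exactly 0 (the ``0 log 0 = 0``
convention), implemented by masking rather than epsilon addition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .network import ExtendedFlowMatrix

MatrixLike = Union[ExtendedFlowMatrix, np.ndarray]

#: Empirical sustainability optimum for ecosystem flow networks
#: ("window of vitality"); exposed as configurable reference constants,
#: not derived here.
REFERENCE_AC = 0.401
REFERENCE_AR = 0.67

_LOG_FUNCS = {"bits": np.log2, "nats": np.log}
_LN2 = math.log(2.0)


def _coerce(x: MatrixLike) -> np.ndarray:
    if isinstance(x, ExtendedFlowMatrix):
        return x.matrix
    return np.asarray(x, dtype=float)


def _log(unit: str):
    try:
        return _LOG_FUNCS[unit]
    except KeyError:
        raise ValueError(f"unknown information unit {unit!r}; use 'bits' or 'nats'")


def convert_information_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an information quantity between bits and nats."""
    for u in (from_unit, to_unit):
        if u not in _LOG_FUNCS:
            raise ValueError(f"unknown information unit {u!r}; use 'bits' or 'nats'")
    if from_unit == to_unit:
        return value
    return value * _LN2 if from_unit == "bits" else value / _LN2


@dataclass(frozen=True)
class FlowProbabilities:
    """Joint and marginal flow probabilities estimated from a flow matrix."""

    joint: np.ndarray
    supply_marginal: np.ndarray
    demand_marginal: np.ndarray

    @classmethod
    def from_flows(cls, x: MatrixLike) -> "FlowProbabilities":
        m = _coerce(x)
        total = m.sum()
        if total <= 0:
            raise ValueError("flow matrix has zero total; probabilities undefined")
        joint = m / total
        return cls(joint, joint.sum(axis=1), joint.sum(axis=0))


def total_system_throughput(x: MatrixLike) -> float:
    """Sum of all flows in the system (TST); measures size and activity."""
    return float(_coerce(x).sum())


def flow_diversity(x: MatrixLike, unit: str = "bits") -> float:
    """Shannon entropy H of the joint flow distribution; upper bound on AMI."""
    log = _log(unit)
    p = FlowProbabilities.from_flows(x).joint
    nz = p > 0
    return float(-(p[nz] * log(p[nz])).sum())


def average_mutual_information(x: MatrixLike, unit: str = "bits") -> float:
    """Mutual information between flow sources and destinations (AMI).

    Quantifies how much knowing the source of a flow constrains its
    destination; the convexity of the logarithm guarantees
    ``0 <= AMI <= H``.
    """
    log = _log(unit)
    prob = FlowProbabilities.from_flows(x)
    p = prob.joint
    outer = np.outer(prob.supply_marginal, prob.demand_marginal)
    nz = p > 0
    ami = float((p[nz] * log(p[nz] / outer[nz])).sum())
    # clip the tiny negative residue that rounding can leave at independence
    return max(ami, 0.0) if ami > -1e-12 else ami


def ascendency(x: MatrixLike, unit: str = "bits") -> float:
    """A = TST * AMI: the single index of combined growth and development."""
    return total_system_throughput(x) * average_mutual_information(x, unit)


def development_capacity(x: MatrixLike, unit: str = "bits") -> float:
    """C = TST * H: the upper bound on ascendency."""
    return total_system_throughput(x) * flow_diversity(x, unit)


def resilience(x: MatrixLike, unit: str = "bits") -> float:
    """R = C - A: the system's redundant, uncommitted flow structure."""
    return development_capacity(x, unit) - ascendency(x, unit)


@dataclass(frozen=True)
class IndexReport:
    """All system-level indices for one network, with unit metadata.

    Flow units are whatever the network carries (e.g. billion yuan per
    year); ``ascendency``, ``capacity`` and ``resilience`` are flow units
    times the information unit.
    """

    tst: float
    diversity: float
    ami: float
    ascendency: float
    capacity: float
    resilience: float
    ratio_ac: float
    ratio_ar: float
    unit: str
    year: int | None = None
    reference_ac: float = REFERENCE_AC
    reference_ar: float = REFERENCE_AR

    @property
    def below_reference_ac(self) -> bool:
        """Whether A/C sits below the ecosystem window-of-vitality optimum."""
        return self.ratio_ac < self.reference_ac

    @property
    def below_reference_ar(self) -> bool:
        return self.ratio_ar < self.reference_ar

    def to_dict(self) -> dict:
        d = asdict(self)
        d["below_reference_ac"] = self.below_reference_ac
        d["below_reference_ar"] = self.below_reference_ar
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    def to_series(self) -> pd.Series:
        return pd.Series(self.to_dict())


def index_report(
    x: MatrixLike,
    unit: str = "bits",
    *,
    year: int | None = None,
    reference_ac: float = REFERENCE_AC,
    reference_ar: float = REFERENCE_AR,
) -> IndexReport:
    """Assemble TST, H, AMI, A, C, R and the sustainability ratios."""
    tst = total_system_throughput(x)
    h = flow_diversity(x, unit)
    ami = average_mutual_information(x, unit)
    a = tst * ami
    c = tst * h
    r = c - a
    return IndexReport(
        tst=tst, diversity=h, ami=ami, ascendency=a, capacity=c, resilience=r,
        ratio_ac=a / c if c > 0 else float("nan"),
        ratio_ar=a / r if r > 0 else float("inf"),
        unit=unit, year=year,
        reference_ac=reference_ac, reference_ar=reference_ar,
    )


@dataclass(frozen=True)
class ContributionMatrix:
    """Per-flow contributions to ascendency with subtotals and proportions.

    ``terms[i, j] = T_ij * log(T_ij * T.. / (T_i. * T_.j))``.  Terms may be
    negative — a flow between a prolific supplier and a prolific consumer
    can be less likely than under independence — but the total, the
    supply-side subtotals and the demand-side subtotals each sum to the
    ascendency.  ``negative_count`` counts strictly negative exact terms.
    """

    terms: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    unit: str

    @property
    def total(self) -> float:
        return float(self.terms.sum())

    @property
    def supply_subtotals(self) -> np.ndarray:
        return self.terms.sum(axis=1)

    @property
    def demand_subtotals(self) -> np.ndarray:
        return self.terms.sum(axis=0)

    @property
    def supply_proportions(self) -> np.ndarray:
        """Supply-side subtotals as percent of total ascendency.

        Undefined (NaN) when total ascendency is zero.
        """
        if self.total == 0.0:
            return np.full(self.terms.shape[0], np.nan)
        return self.supply_subtotals / self.total * 100.0

    @property
    def demand_proportions(self) -> np.ndarray:
        if self.total == 0.0:
            return np.full(self.terms.shape[1], np.nan)
        return self.demand_subtotals / self.total * 100.0

    @property
    def negative_count(self) -> int:
        return int((self.terms < 0).sum())

    def to_frame(self) -> pd.DataFrame:
        """Tabulate terms with subtotal and proportion margins."""
        df = pd.DataFrame(self.terms, index=list(self.row_labels),
                          columns=list(self.col_labels))
        df["Supply sums"] = self.supply_subtotals
        df["Proportion (%)"] = self.supply_proportions
        demand_row = pd.Series(
            list(self.demand_subtotals) + [self.total, np.nan],
            index=df.columns, name="Demand sums")
        prop_row = pd.Series(
            list(self.demand_proportions) + [np.nan, np.nan],
            index=df.columns, name="Proportion (%)")
        return pd.concat([df, demand_row.to_frame().T, prop_row.to_frame().T])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format=None)

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "unit": self.unit,
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
            "terms": self.terms.tolist(),
            "supply_subtotals": self.supply_subtotals.tolist(),
            "demand_subtotals": self.demand_subtotals.tolist(),
            "supply_proportions": self.supply_proportions.tolist(),
            "demand_proportions": self.demand_proportions.tolist(),
            "negative_count": self.negative_count,
            "total": self.total,
        }
        s = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s


def contribution_matrix(x: MatrixLike, unit: str = "bits") -> ContributionMatrix:
    """Decompose ascendency into its per-flow terms.

    Cells with zero flow contribute exactly zero.  The sum of all terms
    reproduces the ascendency to floating-point precision.
    """
    log = _log(unit)
    m = _coerce(x)
    total = m.sum()
    if total <= 0:
        raise ValueError("flow matrix has zero total")
    rows = m.sum(axis=1)
    cols = m.sum(axis=0)
    terms = np.zeros_like(m)
    nz = m > 0
    terms[nz] = m[nz] * log(m[nz] * total / np.outer(rows, cols)[nz])
    if isinstance(x, ExtendedFlowMatrix):
        row_labels, col_labels = x.row_labels, x.col_labels
    else:
        row_labels = tuple(f"row{i}" for i in range(m.shape[0]))
        col_labels = tuple(f"col{j}" for j in range(m.shape[1]))
    return ContributionMatrix(terms, row_labels, col_labels, unit)
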