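"""Flow-network data model for currency networks built from input-output tables.

A currency network represents an economy as a set of sectors exchanging
currency through five categories of flow: inter-sector transactions,
inflows from outside the system (imports), outflows to other systems
(exports), value-added capital, and end use (domestic final consumption).
Sector accounting balance requires, for every sector, that total supply
(inter-sector sales + end use + outflow) equal total demand (inter-sector
purchases + inflow + value added).

All indices downstream are computed on the *extended* flow matrix, an
(n+2) x (n+2) supply-by-demand arrangement in which value added and
inflows appear as two virtual supply rows, and final demand and outflow
as two virtual demand columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("enaflow")

#: Reserved labels used by the flow-CSV dialect (extended-matrix layout).
VALUE_ADDED_LABEL = "VALUE_ADDED"
INFLOWS_LABEL = "INFLOWS"
FINAL_DEMAND_LABEL = "FINAL_DEMAND"
OUTFLOW_LABEL = "OUTFLOW"

#: Reserved labels used by the simplified I-O table CSV dialect.
IO_IMPORTS_LABEL = "IMPORTS"
IO_VALUE_ADDED_LABEL = "VALUE_ADDED"
IO_FINAL_USE_LABEL = "FINAL_USE_DOMESTIC"
IO_EXPORTS_LABEL = "EXPORTS"

#: Default relative balance tolerances: tight for synthetic (exact by
#: construction) data, loose for published tables rounded to fixed decimals.
DEFAULT_TOL_SYNTHETIC = 1e-9
DEFAULT_TOL_PUBLISHED = 1e-3


class ValidationError(ValueError):
    """Raised when a network or table violates a structural invariant."""


def _as_vector(x: Sequence[float] | np.ndarray, n: int, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (n,):
        raise ValidationError(f"{name} must have length {n}, got shape {v.shape}")
    return v


def _check_nonnegative_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    if np.any(arr < 0):
        raise ValidationError(f"{name} contains negative values")


@dataclass(frozen=True)
class CurrencyNetwork:
    """A balanced-or-not currency flow network over ``n`` sectors.

    Parameters
    ----------
    sector_labels
        Unique sector names, length ``n``.
    internal
        ``n x n`` inter-sector flow matrix; rows are selling (supply)
        sectors, columns buying (demand) sectors.  The diagonal holds
        self-supply and is a legitimate flow.
    inflow
        Inputs from outside the system (imports), per demanding sector.
    value_added
        Value-added capital, per demanding sector.
    outflow
        Outputs to other systems (exports), per supplying sector.
    end_use
        Domestic final use, per supplying sector.
    year
        Optional calendar year of the underlying table.
    price_basis
        ``"current"`` or ``("constant", base_year)``.
    """

    sector_labels: tuple[str, ...]
    internal: np.ndarray
    inflow: np.ndarray
    value_added: np.ndarray
    outflow: np.ndarray
    end_use: np.ndarray
    year: int | None = None
    price_basis: str | tuple[str, int] = "current"

    def __post_init__(self) -> None:
        labels = tuple(str(s) for s in self.sector_labels)
        n = len(labels)
        if len(set(labels)) != n:
            raise ValidationError("sector labels must be unique")
        internal = np.asarray(self.internal, dtype=float)
        if internal.shape != (n, n):
            raise ValidationError(
                f"internal matrix must be {n}x{n}, got {internal.shape}"
            )
        object.__setattr__(self, "sector_labels", labels)
        object.__setattr__(self, "internal", internal)
        for name in ("inflow", "value_added", "outflow", "end_use"):
            object.__setattr__(self, name, _as_vector(getattr(self, name), n, name))
        _check_nonnegative_finite(internal, "internal")
        for name in ("inflow", "value_added", "outflow", "end_use"):
            _check_nonnegative_finite(getattr(self, name), name)

    @property
    def n_sectors(self) -> int:
        return len(self.sector_labels)

    def supply(self) -> np.ndarray:
        """Per-sector total supply: inter-sector sales + end use + outflow."""
        return self.internal.sum(axis=1) + self.end_use + self.outflow

    def demand(self) -> np.ndarray:
        """Per-sector total demand: inter-sector purchases + inflow + value added."""
        return self.internal.sum(axis=0) + self.inflow + self.value_added

    def total_flow(self) -> float:
        """Sum of all five flow categories (equals TST of the extended matrix)."""
        return float(
            self.internal.sum()
            + self.inflow.sum()
            + self.value_added.sum()
            + self.outflow.sum()
            + self.end_use.sum()
        )


@dataclass(frozen=True)
class IOTable:
    """A simplified input-output table.

    ``intermediate`` is the inter-sector transaction block Z; ``imports``
    and ``value_added`` are the primary-input rows; ``final_use_domestic``
    and ``exports`` the final-use columns.
    """

    sector_labels: tuple[str, ...]
    intermediate: np.ndarray
    imports: np.ndarray
    value_added: np.ndarray
    final_use_domestic: np.ndarray
    exports: np.ndarray
    year: int | None = None

    def __post_init__(self) -> None:
        labels = tuple(str(s) for s in self.sector_labels)
        n = len(labels)
        if len(set(labels)) != n:
            raise ValidationError("sector labels must be unique")
        Z = np.asarray(self.intermediate, dtype=float)
        if Z.shape != (n, n):
            raise ValidationError(f"intermediate must be {n}x{n}, got {Z.shape}")
        object.__setattr__(self, "sector_labels", labels)
        object.__setattr__(self, "intermediate", Z)
        for name in ("imports", "value_added", "final_use_domestic", "exports"):
            object.__setattr__(self, name, _as_vector(getattr(self, name), n, name))

    def validate(self, *, clamp_negatives: bool = False) -> "IOTable":
        """Check non-negativity; optionally clamp negatives to zero.

        Published tables occasionally carry negative entries (inventory
        drawdowns).  Strict mode (default) rejects them; permissive mode
        clamps to zero and logs the clamped mass, since the flow-network
        indices are defined for non-negative flows only.
        """
        arrays = {
            "intermediate": self.intermediate,
            "imports": self.imports,
            "value_added": self.value_added,
            "final_use_domestic": self.final_use_domestic,
            "exports": self.exports,
        }
        clamped = 0.0
        out = {}
        for name, arr in arrays.items():
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
            neg = arr < 0
            if neg.any():
                if not clamp_negatives:
                    raise ValidationError(
                        f"{name} contains negative entries (strict mode)"
                    )
                clamped += float(-arr[neg].sum())
                arr = np.where(neg, 0.0, arr)
            out[name] = arr
        if clamped > 0:
            logger.warning(
                "clamped %.6g units of negative flow mass to zero", clamped
            )
        return IOTable(self.sector_labels, out["intermediate"], out["imports"],
                       out["value_added"], out["final_use_domestic"],
                       out["exports"], self.year)


@dataclass(frozen=True)
class ExtendedFlowMatrix:
    """The (n+2) x (n+2) supply-by-demand matrix all indices run on.

    Rows: n sectors, then value added, then inflows.  Columns: n sectors,
    then final demand, then outflow.  The 2x2 block of virtual rows by
    virtual columns is structurally zero; the grand total equals the
    network's TST.
    """

    matrix: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("extended matrix must be square")
        if m.shape[0] != len(self.row_labels) or m.shape[1] != len(self.col_labels):
            raise ValidationError("label count does not match matrix shape")
        _check_nonnegative_finite(m, "extended matrix")
        if np.any(m[-2:, -2:] != 0.0):
            raise ValidationError("virtual-by-virtual block must be zero")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))

    @property
    def n_sectors(self) -> int:
        return self.matrix.shape[0] - 2

    def total(self) -> float:
        return float(self.matrix.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.row_labels),
                            columns=list(self.col_labels))


@dataclass(frozen=True)
class DeflatorSeries:
    """Cumulative price index keyed by year; the base year is indexed 100."""

    base_year: int
    index: Mapping[int, float]

    def __post_init__(self) -> None:
        idx = dict(self.index)
        if self.base_year not in idx:
            raise ValidationError("deflator must contain its base year")
        if not np.isclose(idx[self.base_year], 100.0):
            raise ValidationError("base-year index must equal 100")
        if any(v <= 0 for v in idx.values()):
            raise ValidationError("price indices must be positive")
        object.__setattr__(self, "index", idx)

    def factor(self, year: int) -> float:
        """Multiplier converting year's current prices to base-year prices."""
        if year not in self.index:
            raise ValidationError(f"year {year} missing from deflator series")
        return 100.0 / self.index[year]


@dataclass(frozen=True)
class SectorMapping:
    """Surjective map from source sector label to aggregate label."""

    mapping: Mapping[str, str]

    def target_labels(self, source_order: Iterable[str]) -> list[str]:
        """Aggregate labels in order of first appearance along source order."""
        seen: list[str] = []
        for s in source_order:
            t = self.mapping.get(s)
            if t is not None and t not in seen:
                seen.append(t)
        return seen


@dataclass(frozen=True)
class BalanceReport:
    """Per-sector supply/demand comparison from :func:`check_balance`."""

    sector_labels: tuple[str, ...]
    supply: np.ndarray
    demand: np.ndarray
    relative_gap: np.ndarray
    tol: float

    @property
    def passed(self) -> bool:
        return bool(self.max_gap <= self.tol)

    @property
    def max_gap(self) -> float:
        return float(self.relative_gap.max()) if self.relative_gap.size else 0.0

    @property
    def failing_sectors(self) -> tuple[str, ...]:
        mask = self.relative_gap > self.tol
        return tuple(np.asarray(self.sector_labels)[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"supply": self.supply, "demand": self.demand,
             "relative_gap": self.relative_gap},
            index=list(self.sector_labels),
        )


# ---------------------------------------------------------------------------
# Construction and transformation
# ---------------------------------------------------------------------------

def from_io_table(table: IOTable, *, clamp_negatives: bool = False) -> CurrencyNetwork:
    """Convert a simplified I-O table into the five-category currency network.

    Inter-sector transactions become internal flows, imports become
    inflows, exports become outflows, and the value-added and domestic
    final-use margins become value-added capital and end use.  The result
    is balanced exactly when the table's row/column accounting identities
    hold (total output = total input per sector).
    """
    t = table.validate(clamp_negatives=clamp_negatives)
    return CurrencyNetwork(
        sector_labels=t.sector_labels,
        internal=t.intermediate,
        inflow=t.imports,
        value_added=t.value_added,
        outflow=t.exports,
        end_use=t.final_use_domestic,
        year=t.year,
    )


def to_extended_matrix(net: CurrencyNetwork) -> ExtendedFlowMatrix:
    """Arrange the five flow categories as the (n+2) x (n+2) supply-by-demand matrix."""
    n = net.n_sectors
    m = np.zeros((n + 2, n + 2))
    m[:n, :n] = net.internal
    m[:n, n] = net.end_use
    m[:n, n + 1] = net.outflow
    m[n, :n] = net.value_added
    m[n + 1, :n] = net.inflow
    row_labels = net.sector_labels + ("Value added", "Inflows")
    col_labels = net.sector_labels + ("Final demand", "Outflow")
    return ExtendedFlowMatrix(m, row_labels, col_labels)


def aggregate_sectors(net: CurrencyNetwork, mapping: SectorMapping) -> CurrencyNetwork:
    """Merge sectors into aggregates by summing all flows over mapped groups.

    Total system throughput is preserved exactly; by the data-processing
    inequality the average mutual information can only decrease.
    """
    unmapped = [s for s in net.sector_labels if s not in mapping.mapping]
    if unmapped:
        raise ValidationError(f"unmapped sector labels: {unmapped}")
    targets = mapping.target_labels(net.sector_labels)
    k = len(targets)
    pos = {t: i for i, t in enumerate(targets)}
    # 0/1 aggregation matrix S: S[i, j] = 1 if source j maps to aggregate i
    S = np.zeros((k, net.n_sectors))
    for j, s in enumerate(net.sector_labels):
        S[pos[mapping.mapping[s]], j] = 1.0
    return CurrencyNetwork(
        sector_labels=tuple(targets),
        internal=S @ net.internal @ S.T,
        inflow=S @ net.inflow,
        value_added=S @ net.value_added,
        outflow=S @ net.outflow,
        end_use=S @ net.end_use,
        year=net.year,
        price_basis=net.price_basis,
    )


def deflate(net: CurrencyNetwork, deflator: DeflatorSeries) -> CurrencyNetwork:
    """Convert all flows to constant prices of the deflator's base year.

    Every flow is multiplied by ``100 / index[year]``.  Uniform scaling
    leaves AMI and H unchanged and scales TST, A, and C by the factor.
    """
    if net.year is None:
        raise ValidationError("network has no year; cannot deflate")
    f = deflator.factor(net.year)
    return replace(
        net,
        internal=net.internal * f,
        inflow=net.inflow * f,
        value_added=net.value_added * f,
        outflow=net.outflow * f,
        end_use=net.end_use * f,
        price_basis=("constant", deflator.base_year),
    )


def check_balance(net: CurrencyNetwork, tol: float = DEFAULT_TOL_SYNTHETIC) -> BalanceReport:
    """Compare per-sector supply and demand at a relative tolerance."""
    supply = net.supply()
    demand = net.demand()
    scale = np.maximum(np.maximum(supply, demand), np.finfo(float).tiny)
    gap = np.abs(supply - demand) / scale
    return BalanceReport(net.sector_labels, supply, demand, gap, tol)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_flow_csv(net: CurrencyNetwork, path: str | Path) -> None:
    """Write a network in the flow-CSV dialect (extended-matrix layout).

    Columns are the sector labels plus ``FINAL_DEMAND`` and ``OUTFLOW``;
    rows are the sector labels plus ``VALUE_ADDED`` and ``INFLOWS``.
    Numbers are written with full ``repr`` precision so the round trip is
    lossless.
    """
    ext = to_extended_matrix(net)
    df = pd.DataFrame(
        ext.matrix,
        index=list(net.sector_labels) + [VALUE_ADDED_LABEL, INFLOWS_LABEL],
        columns=list(net.sector_labels) + [FINAL_DEMAND_LABEL, OUTFLOW_LABEL],
    )
    df.to_csv(path, float_format=None)


def read_flow_csv(
    path: str | Path,
    *,
    orientation: str = "supply-rows",
    year: int | None = None,
    strict: bool = True,
) -> CurrencyNetwork:
    """Read a network from the flow-CSV dialect.

    ``orientation="demand-rows"`` transposes the matrix on read for files
    written with rows as destinations.  In strict mode negative cells are
    rejected; otherwise they are clamped to zero with a warning.
    """
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if orientation == "demand-rows":
        df = df.T
    elif orientation != "supply-rows":
        raise ValidationError(f"unknown orientation {orientation!r}")
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
        raise ValidationError("duplicate labels in flow CSV")
    if rows[-2:] != [VALUE_ADDED_LABEL, INFLOWS_LABEL]:
        raise ValidationError(
            f"last two rows must be {VALUE_ADDED_LABEL}, {INFLOWS_LABEL}"
        )
    if cols[-2:] != [FINAL_DEMAND_LABEL, OUTFLOW_LABEL]:
        raise ValidationError(
            f"last two columns must be {FINAL_DEMAND_LABEL}, {OUTFLOW_LABEL}"
        )
    sectors_r, sectors_c = rows[:-2], cols[:-2]
    if sectors_r != sectors_c:
        raise ValidationError("sector row and column labels differ (non-square)")
    m = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValidationError("flow CSV contains non-finite or unparseable values")
    if np.any(m < 0):
        if strict:
            raise ValidationError("flow CSV contains negative values (strict mode)")
        clamped = float(-m[m < 0].sum())
        logger.warning("clamped %.6g units of negative flow mass to zero", clamped)
        m = np.clip(m, 0.0, None)
    n = len(sectors_r)
    return CurrencyNetwork(
        sector_labels=tuple(sectors_r),
        internal=m[:n, :n],
        end_use=m[:n, n],
        outflow=m[:n, n + 1],
        value_added=m[n, :n],
        inflow=m[n + 1, :n],
        year=year,
    )


def write_io_csv(table: IOTable, path: str | Path) -> None:
    """Write a simplified I-O table as CSV with labeled margin rows/columns."""
    n = len(table.sector_labels)
    m = np.zeros((n + 2, n + 2))
    m[:n, :n] = table.intermediate
    m[:n, n] = table.final_use_domestic
    m[:n, n + 1] = table.exports
    m[n, :n] = table.imports
    m[n + 1, :n] = table.value_added
    df = pd.DataFrame(
        m,
        index=list(table.sector_labels) + [IO_IMPORTS_LABEL, IO_VALUE_ADDED_LABEL],
        columns=list(table.sector_labels) + [IO_FINAL_USE_LABEL, IO_EXPORTS_LABEL],
    )
    df.to_csv(path, float_format=None)


def read_io_csv(path: str | Path, *, year: int | None = None) -> IOTable:
    """Read a simplified I-O table from the CSV dialect of :func:`write_io_csv`."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if rows[-2:] != [IO_IMPORTS_LABEL, IO_VALUE_ADDED_LABEL]:
        raise ValidationError(
            f"last two rows must be {IO_IMPORTS_LABEL}, {IO_VALUE_ADDED_LABEL}"
        )
    if cols[-2:] != [IO_FINAL_USE_LABEL, IO_EXPORTS_LABEL]:
        raise ValidationError(
            f"last two columns must be {IO_FINAL_USE_LABEL}, {IO_EXPORTS_LABEL}"
        )
    if rows[:-2] != cols[:-2]:
        raise ValidationError("sector row and column labels differ (non-square)")
    m = df.to_numpy(dtype=float)
    n = len(rows) - 2
    return IOTable(
        sector_labels=tuple(rows[:-2]),
        intermediate=m[:n, :n],
        final_use_domestic=m[:n, n],
        exports=m[:n, n + 1],
        imports=m[n, :n],
        value_added=m[n + 1, :n],
        year=year,
    )
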