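"""Synthetic balanced currency networks and in-package reference fixtures.

No raw multi-sector I-O tables are distributed with the studies this
package targets, so every pipeline stage is exercised on synthetic
networks whose statistical structure matches what those studies assume:
a small number of aggregated sectors, per-sector supply equal to demand,
a sizeable boundary (imports + value-added in, final use + exports out),
and an internal flow structure whose organization (AMI) can be dialled
between fully diffuse and fully concentrated.

Generator recipe
----------------
The internal block is a convex mixture

    B  ∝  (1 - theta) * uniform  +  theta * random permutation matrix

with a small multiplicative lognormal jitter so distinct seeds give
distinct matrices.  ``theta = 0`` gives near-independent flows (AMI of
the block close to 0); ``theta = 1`` routes each sector's sales to a
single buyer (block AMI = log2 n).  Boundary vectors are then solved so
that every sector's supply equals its demand *exactly*: each sector
draws a ``boundary_share`` fraction of its demand from inflow plus
value added (split by a drawn ratio), and the supply residual is
absorbed by end use plus outflow (again split by a drawn ratio).  The
grand total is scaled to the requested TST before any series-level
noise, making noiseless growth trajectories exactly exponential.

``calibrate_organization`` inverts the (monotone) map from ``theta`` to
the AMI of the full extended matrix by bracketed root finding, so series
can be generated to hit prescribed per-year AMI targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .indices import average_mutual_information
from .network import CurrencyNetwork, ValidationError, to_extended_matrix
from .trajectory import NetworkSeries

#: Fraction of each sector's demand met from outside the sector economy
#: (inflow + value added).  Kept moderate so the structural organization
#: floor of the extended matrix stays low (~0.05 bits) and targets down
#: to 0.1 bits remain reachable by calibration.
DEFAULT_BOUNDARY_SHARE = 0.2

#: Lognormal sigma of the per-cell jitter on the internal block; small
#: enough that a theta = 0 network stays within a few millibits of
#: independence while distinct seeds still give distinct matrices.
DEFAULT_JITTER_SIGMA = 0.05

_MAX_RETRIES = 50


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters for one synthetic balanced currency network.

    ``organization`` (theta) in [0, 1] moves the internal block from
    uniform (0) to permutation-structured (1); ``boundary_share`` in
    (0, 1) is the fraction of each sector's demand supplied by inflow
    plus value added.
    """

    n_sectors: int
    organization: float = 0.5
    target_tst: float = 1000.0
    boundary_share: float = DEFAULT_BOUNDARY_SHARE
    jitter_sigma: float = DEFAULT_JITTER_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sectors < 2:
            raise ValidationError("need at least two sectors")
        if not 0.0 <= self.organization <= 1.0:
            raise ValidationError("organization must lie in [0, 1]")
        if not 0.0 < self.boundary_share < 1.0:
            raise ValidationError("boundary_share must lie in (0, 1)")
        if self.target_tst <= 0:
            raise ValidationError("target_tst must be positive")
        if self.jitter_sigma < 0:
            raise ValidationError("jitter_sigma must be non-negative")


def generate_currency_network(params: GeneratorParams) -> CurrencyNetwork:
    """Draw one exactly balanced currency network.

    Deterministic for a fixed seed.  The grand total of all five flow
    categories equals ``target_tst`` to floating-point precision and
    every sector balances to well below 1e-9 relative.
    """
    n = params.n_sectors
    b = params.boundary_share
    rng = np.random.default_rng(params.seed)
    # internal mass follows from TST = M * (1 + b) / (1 - b)
    internal_mass = params.target_tst * (1.0 - b) / (1.0 + b)
    for _ in range(_MAX_RETRIES):
        perm = rng.permutation(n)
        P = np.zeros((n, n))
        P[np.arange(n), perm] = 1.0 / n
        U = np.full((n, n), 1.0 / n**2)
        base = (1.0 - params.organization) * U + params.organization * P
        if params.jitter_sigma > 0:
            base = base * rng.lognormal(0.0, params.jitter_sigma, size=(n, n))
        internal = base * (internal_mass / base.sum())
        split_in = rng.uniform(0.25, 0.75, size=n)
        split_out = rng.uniform(0.25, 0.75, size=n)
        demand = internal.sum(axis=0) / (1.0 - b)
        boundary_in = b * demand
        residual = demand - internal.sum(axis=1)
        if np.all(residual >= 0):
            return CurrencyNetwork(
                sector_labels=tuple(f"S{i + 1}" for i in range(n)),
                internal=internal,
                inflow=split_in * boundary_in,
                value_added=(1.0 - split_in) * boundary_in,
                end_use=split_out * residual,
                outflow=(1.0 - split_out) * residual,
            )
    raise ValidationError(
        "could not satisfy non-negativity of boundary residuals; "
        "boundary_share too small for this jitter level"
    )


def _achieved_ami(theta: float, template: GeneratorParams, unit: str = "bits") -> float:
    net = generate_currency_network(replace(template, organization=theta))
    return average_mutual_information(to_extended_matrix(net), unit)


def calibrate_organization(
    target_ami: float,
    n_sectors: int,
    seed: int,
    *,
    tol: float = 1e-3,
    **kwargs,
) -> float:
    """Find the organization level theta whose network AMI hits a target.

    AMI (bits, on the full extended matrix) is monotone in theta for a
    fixed seed, so a bracketed root find suffices; a grid fallback
    re-brackets in the rare case the root polish lands outside ``tol``.
    Raises if the target lies outside the attainable [AMI(0), AMI(1)]
    band for this seed and sector count.
    """
    template = GeneratorParams(n_sectors=n_sectors, seed=seed, **kwargs)
    lo, hi = _achieved_ami(0.0, template), _achieved_ami(1.0, template)
    if not (min(lo, hi) - tol <= target_ami <= max(lo, hi) + tol):
        raise ValidationError(
            f"target AMI {target_ami:.4f} bits outside attainable band "
            f"[{lo:.4f}, {hi:.4f}] for n={n_sectors}"
        )
    if abs(lo - target_ami) <= tol and target_ami <= lo:
        return 0.0
    if abs(hi - target_ami) <= tol and target_ami >= hi:
        return 1.0
    theta = optimize.brentq(
        lambda t: _achieved_ami(t, template) - target_ami, 0.0, 1.0, xtol=1e-8
    )
    if abs(_achieved_ami(theta, template) - target_ami) > tol:
        # grid fallback: locate the bracketing interval and re-solve
        grid = np.linspace(0.0, 1.0, 51)
        vals = np.array([_achieved_ami(t, template) for t in grid])
        k = int(np.argmin(np.abs(vals - target_ami)))
        a = grid[max(k - 1, 0)]
        c = grid[min(k + 1, len(grid) - 1)]
        theta = optimize.brentq(
            lambda t: _achieved_ami(t, template) - target_ami, a, c, xtol=1e-8
        )
    return float(theta)


@dataclass(frozen=True)
class SeriesParams:
    """Parameters for a synthetic multi-year network series.

    TST grows exponentially at ``growth_rate`` from ``initial_tst``
    (exact when ``noise_sigma`` is 0; otherwise each year's TST carries
    a multiplicative lognormal disturbance), while the per-year AMI
    tracks ``ami_targets`` (bits) via organization calibration.
    """

    years: tuple[int, ...]
    initial_tst: float
    growth_rate: float
    ami_targets: tuple[float, ...]
    noise_sigma: float = 0.0
    seed: int = 0
    n_sectors: int = 6
    boundary_share: float = DEFAULT_BOUNDARY_SHARE
    jitter_sigma: float = DEFAULT_JITTER_SIGMA

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValidationError("years must be strictly increasing")
        targets = tuple(float(a) for a in self.ami_targets)
        if len(targets) != len(years):
            raise ValidationError("need one AMI target per year")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "ami_targets", targets)


def generate_series(params: SeriesParams) -> NetworkSeries:
    """Generate a balanced network per year with prescribed TST and AMI paths.

    Per-year networks are built from independent sub-seeds drawn from the
    master seed, so the whole series is reproducible.  Because organization
    calibration and generation share each year's sub-seed, the realized AMI
    matches its target to the calibration tolerance, and uniform TST
    scaling leaves it untouched.
    """
    master = np.random.default_rng(params.seed)
    t0 = params.years[0]
    entries = []
    for year, target_ami in zip(params.years, params.ami_targets):
        sub_seed = int(master.integers(2**31))
        noise = master.lognormal(0.0, params.noise_sigma) if params.noise_sigma > 0 else 1.0
        tst = params.initial_tst * (1.0 + params.growth_rate) ** (year - t0) * noise
        theta = calibrate_organization(
            target_ami, params.n_sectors, sub_seed,
            boundary_share=params.boundary_share,
            jitter_sigma=params.jitter_sigma,
        )
        net = generate_currency_network(GeneratorParams(
            n_sectors=params.n_sectors, organization=theta, target_tst=tst,
            boundary_share=params.boundary_share,
            jitter_sigma=params.jitter_sigma, seed=sub_seed,
        ))
        entries.append((year, replace(net, year=year)))
    return NetworkSeries(entries)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContributionTableFixture:
    """A published per-flow ascendency contribution table, as printed.

    ``cells`` holds the 8x8 term matrix with IEEE signed zeros preserving
    the printed "-0.0" entries, so the printed negative-term count is
    recoverable from the sign bit without inventing magnitudes.  The
    printed margins (subtotals, proportions, total) are carried verbatim
    alongside.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    cells: np.ndarray
    printed_supply_sums: np.ndarray
    printed_supply_proportions: np.ndarray
    printed_demand_sums: np.ndarray
    printed_demand_proportions: np.ndarray
    printed_total: float
    unit: str = "billion yuan-bits / year"

    @property
    def printed_negative_count(self) -> int:
        """Count of cells printed with a minus sign, including "-0.0"."""
        return int(np.signbit(self.cells).sum())


def _load_table2() -> ContributionTableFixture:
    ref = resources.files("enaflow.fixtures") / "table2_contributions.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, index_col=0)
    cells = df.iloc[:8, :8].to_numpy(dtype=float)
    return ContributionTableFixture(
        row_labels=tuple(df.index[:8]),
        col_labels=tuple(df.columns[:8]),
        cells=cells,
        printed_supply_sums=df["Supply sums"].iloc[:8].to_numpy(dtype=float),
        printed_supply_proportions=df["Proportion (%)"].iloc[:8].to_numpy(dtype=float),
        printed_demand_sums=df.loc["Demand sums"].iloc[:8].to_numpy(dtype=float),
        printed_demand_proportions=df.loc["Proportion (%)"].iloc[:8].to_numpy(dtype=float),
        printed_total=float(df.loc["Demand sums", "Supply sums"]),
    )


def _load_macro_values() -> dict:
    ref = resources.files("enaflow.fixtures") / "macro_values.json"
    return json.loads(ref.read_text())


_FIXTURES = {
    "table2_contributions": _load_table2,
    "macro_values": _load_macro_values,
}


def load_fixture(name: str):
    """Load a packaged reference fixture by name.

    Available: ``table2_contributions`` (the printed 8x8 per-flow
    ascendency contribution table for Beijing 2010, with margins) and
    ``macro_values`` (published endpoint TST/A/C values and growth rates
    for 1985-2010).
    """
    try:
        loader = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return loader()
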