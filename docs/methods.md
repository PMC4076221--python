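# Methods

This note records the model conventions, the synthetic-data design, the
numerical choices, and the known limitations of `enaflow`.

## Flow-network model

A currency network over `n` sectors carries five categories of flow:
inter-sector transactions (an `n×n` matrix, rows = selling sector,
columns = buying sector, diagonal self-supply allowed), inflows from
outside the system (imports), outflows to other systems (exports),
value-added capital, and end use. A sector is *balanced* when its total
supply (inter-sector sales + end use + outflow) equals its total demand
(inter-sector purchases + inflow + value added); the balance check
reports per-sector relative gaps against a configurable tolerance
(default 1e-9 for synthetic data, which is balanced by construction;
1e-3 is recommended for published tables, which are rounded).

All indices are computed on the **extended matrix**: the `(n+2)×(n+2)`
supply-by-demand arrangement with value added and inflows as virtual
supply rows and final demand and outflow as virtual demand columns. The
virtual-by-virtual 2×2 block is structurally zero. The virtual rows and
columns participate fully in the probabilities and index sums — the
per-flow contribution analysis assigns terms to boundary flows, which
forces this convention.

Conversions from simplified I-O tables map the transaction block to
internal flows, imports→inflow, value added→value added, exports→outflow
and domestic final use→end use. Negative entries (e.g. inventory
drawdowns) are rejected in strict mode; permissive mode clamps them to
zero and logs the clamped mass, since the indices are defined only for
non-negative flows. The split of a table's final-use columns between end
use and outflow is taken as given by the input columns; no re-splitting
is attempted. Deflation to constant prices multiplies every flow by
`100 / index[year]` from a user-supplied cumulative price-index series
(base year = 100); it leaves AMI and H untouched and scales TST, A and C.

## Indices and numerical conventions

- `0·log 0 := 0` throughout, implemented by masking zero flows, never by
  adding an epsilon — epsilon addition would bias sparse matrices.
- Default information unit is bits (log₂); nats (ln) are supported and
  explicit conversion is provided, but values are never auto-converted.
- AMI values within one part in 10¹² of zero are clipped to zero so that
  exactly independent (outer-product) matrices report AMI = 0.
- The contribution matrix reproduces ascendency as its total to
  floating-point precision; its `negative_count` counts strictly
  negative exact values. The packaged published contribution table, by
  contrast, preserves the table's printed "−0.0" entries as IEEE signed
  zeros, so the *printed* negative count (including −0.0) is recovered
  from sign bits without inventing magnitudes for unrecoverable cells.
- A/C and A/R are compared against the configurable ecosystem
  "window-of-vitality" reference constants 0.401 and 0.67; these are
  treated as given reference points, not derived.

## Growth rates and decomposition

The default growth-rate estimator is the endpoint compound annual rate
`(v1/v0)^(1/span) − 1`, which reproduces published exponential rates
from printed endpoint values to ≤0.03 percentage points; a log-linear
least-squares estimator over all years is provided as an alternative
(they coincide on exact exponentials and on two-point series).

Stage segmentation takes maximal runs of constant sign in successive AMI
differences. Zero differences merge into the preceding stage (or the
following one when no direction is yet established; an all-constant
series is a single "flat" stage) — a tie-break that real series never
exercise but that must be defined. Stage endpoints use the boundary
years' values, not within-stage means.

The complete decomposition of `ΔA` over a stage uses
`C_TST = ΔTST·AMI₀ + ΔTST·ΔAMI/2` and
`C_AMI = ΔAMI·TST₀ + ΔTST·ΔAMI/2`; the reported `ΔV` is assembled as
`C_x + C_y`, so completeness (`C_x + C_y = ΔV`) holds exactly in
floating point as well as algebraically. When `ΔV = 0` the percent
shares are reported as undefined (`None`) rather than 0/0; absolute
contributions are still returned. When a deflator accompanies a series,
all per-year indices (hence the decomposition inputs) are computed on
constant-price flows.

## Synthetic-data generator

The generator emulates the statistical situation the pipeline is meant
for: a handful of aggregated sectors, exact per-sector balance, a
substantial boundary, and AMI in the 0.45–0.58-bit band observed for
aggregated economic networks.

Internal block: `B ∝ (1−θ)·uniform + θ·random permutation`, times a
small multiplicative lognormal jitter (σ = 0.05 by default) so distinct
seeds give distinct matrices; `θ = 0` is near-independent (block AMI a
few millibits), `θ = 1` routes each sector to a single buyer (block AMI
= log₂ n). Boundary construction makes balance exact rather than
iterative: each sector's demand is set so that a `boundary_share`
fraction (default 0.2) comes from inflow + value added (split by a ratio
drawn uniformly in [0.25, 0.75]), and the supply residual is absorbed by
end use + outflow (another drawn split). Iterative proportional fitting
was considered and rejected: residual absorption is simpler and balanced
by construction. Infeasible residuals (possible when the jitter is large
relative to the boundary share) trigger bounded redraws, then an error.

The grand total is scaled to the requested TST exactly (before any
series-level noise), so noiseless synthetic growth trajectories are
exactly exponential and rate estimators recover the generating rate to
1e-10. Series noise is a multiplicative lognormal disturbance on each
year's total.

Organization calibration inverts the θ→AMI map (AMI of the full extended
matrix, monotone in θ for a fixed seed since all random draws are reused
across θ) by bracketed root finding, with a 51-point grid fallback;
accuracy is ≤1e-3 bits across the attainable band. Two structural
effects bound that band: boundary flows add an organization floor
(≈0.05–0.07 bits at the default boundary share) and dilute the θ = 1
ceiling below log₂ n. The default boundary share of 0.2 keeps the floor
low while retaining a realistic boundary; wide-band calibration (targets
from 0.1 bits up to 0.9·log₂ n) uses a small boundary share (0.02) with
a proportionally small jitter (0.005), consistent with the fact that the
permutation limit approaches log₂ n only as the boundary vanishes.

What the generator does **not** emulate: realistic econometric structure
(sectoral correlations, gravity-like trade patterns, price dynamics),
negative inventory entries, or multi-region linkages. Passing tests on
synthetic data therefore demonstrate the correctness of the index
machinery and the decomposition algebra under balanced non-negative
flows, not the empirical behavior of any real economy.

## Problem sizes

The test suite and the acceptance script run on small instances chosen
as representative of the aggregated-sector setting: networks of 3–20
sectors (typically 6, the common aggregation level for published
national I-O comparisons), series of 11 years, property suites of
100–120 random networks and 10⁴ random decomposition tuples. The whole
suite completes in a few seconds.

## Known limitations

- Official statistical-bureau I-O spreadsheet layouts are not parsed;
  inputs must be in the documented CSV dialects.
- Only the two-factor complete decomposition is implemented.
- Other ENA suites (cycling analysis, trophic aggregation, environ
  analysis) and Monte-Carlo uncertainty on indices are out of scope.
- Deflator series must be user-supplied; no price-index data ships with
  the package.
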