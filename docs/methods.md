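# Methods

## Model overview and conventions

The world is a regular lattice of square cells of edge L = 4 m. Elevation
is an integer count of sediment slabs of thickness δ = 0.1 m, stored
relative to the sea-level datum at the start of the run; sea level is a
continuous offset in meters above that datum. The offset is never
re-quantized into the slab grid: annual rises of 0.5–2 cm are far below
one slab, so all elevation comparisons use the *effective elevation*
H·δ − offset. A cell is subaerial iff its effective elevation is strictly
positive (a cell exactly at sea level is water, which removes any
zero-area ambiguity from windowed area averages). Rows index the
alongshore direction (row 0 = north); columns index cross-shore with the
ocean at high columns, so landward migration moves material toward low
columns. The grid boundary is open: slabs transported past it leave the
system.

One simulated year runs, in order: 26 two-week aeolian events (each
followed by avalanche relaxation), the annual vegetation update, and the
annual marine step (sea-level increment, then migration, then
relaxation). The within-year ordering is a modelling choice — annual
processes act on the wind-worked surface — and is fixed so runs are
reproducible: equal (seed, config, initial state) gives bit-identical
trajectories. The wind series draws from its own RNG stream, split from
the process stream, so different scenarios run under identical winds at
the same seed.

## Vegetation

Four species with field-motivated elevation bands (m above current sea
level), erosion coefficients α, cover caps η, and growth bands [g, G]:

| species | band | α | η |
|---|---|---|---|
| *Ammophila breviligulata* | 1–5 | 0.667 | 0.80 |
| *Spartina patens* | 0.75–3 | 0.333 | 0.80 |
| *Spartina alterniflora* | −0.5–1 | 1.0 | 0.60 |
| *Morella cerifera* | ≥ 1.5 | 1.0 | 0.60 |

Annual growth adds γ·(3×3 neighbourhood cover sum) per species, with γ
drawn uniformly from [g, G] once per cell per species per year (the draw
is shared by the nine neighbourhood terms, matching the single cell index
on the rate). The neighbourhood includes the centre cell and truncates at
grid edges. Defaults are g = −0.0002, G = 0.0008 per year. Two candidate
readings of the growth-rate parameterization differ by a factor of 100;
we adopt the small one because it is the only one consistent with the
target system's observed behaviour — plant populations roughly constant
over 30 years, woody cover expanding only a few percent — whereas rates
of ±2–8 %/yr saturate every viable cell within about a decade and erase
the grass/shrub zonation that drives differential migration. Both are
plain config fields (`growth_min`/`growth_max` per species).

Crowding above the global cap M = 0.8 deducts the excess evenly from the
grasses present; the shrub is only clipped to its own cap. A grass driven
negative is floored at zero and its shortfall re-spread over the grasses
still positive (at most three rounds). Effective cover PC = Σ α_k P_k is
clipped to 1 so downstream probabilities stay valid (the raw sum can
reach 1.4 under the default caps).

Out-of-band cover decays by a factor `viability_decay` (default 0.5) per
year — the die-back rate is not empirically constrained, so it is exposed
in config — and covers below 10⁻⁴ are zeroed. Bird dispersal of the shrub
is modelled as an annual Bernoulli trial (p = 10⁻³) on every empty
subaerial cell at or above 1.5 m whenever any source exists, seeding
cover 0.01; both values are order-of-magnitude choices exposed in config.

## Aeolian transport

One wind record (speed, 8-point "blowing-from" direction) represents each
two-week period. Entrainment probability is (1 − PC)(ω − ω_L)/(ω_H − ω_L)
with ω_L = 6, ω_H = 16 m/s; travel distance is 1, 2 or 3 cells for the
6–9, 9–13, 13–16 m/s classes (diagonal distance is counted in cells, with
no √2 correction, keeping the cell-count semantics of the distance
table). Destinations follow the 50/25/25 downwind/off-diagonal rule. At
most one slab leaves a cell per event, and all pickups are decided on the
pre-event surface (synchronous update avoids sweep-order artifacts).
Deposition into water is allowed and raises the bottom; storm winds
(> 16 m/s) skip the event with a logged notice. There are no shadow-zone
or slope-dependent deposition rules.

## Avalanching

The slope angle between von Neumann neighbours is arctan(δ·ΔH / L) — the
physical height difference over one cell width. (A literal reading of the
source expression divides a slab count by L·δ, which is dimensionally
inconsistent and would make a single-slab step a 14° slope; the physical
form is used throughout.) Cells at or above θ_o = π/6 avalanche one slab
to their steepest violating neighbour (ties uniform at random) with
probability min(1, (θ′/θ_o)(1 − PC)), PC taken from the source cell.
Relaxation runs in synchronous passes on the pre-pass surface until no
violation remains or `max_passes` (default 100) is hit; with vegetation
present termination is only probabilistic, hence the cap. With PC = 0
every violation fires, each pass strictly lowers Σ H², and relaxation
provably terminates violation-free. Mass is conserved exactly (edge cells
never avalanche off-grid), and the maximum elevation never increases.
With δ = 0.1, L = 4 and θ_o = π/6 the smallest violating step is 24
slabs.

## Marine processes and sea level

Sea level (cm above the 1984 datum) follows
L(t) = a(t−1992) + b(t−1992)² + c with a = 0.45 cm/yr, c = 3.6 cm and
scenario accelerations b = 0 (historic), 0.0043 (low), 0.0105 (high),
0.0157 (highest) cm/yr²; 1984–1992 uses the linear rate through the same
anchor. The annual rise is the first difference S(t) = L(t) − L(t−1).

Recession follows R = B·S. B can be computed from an island cross-section
(shore-zone lengths, berm heights, closure depths) but is calibrated by
default from observed historical movement: B = 15 m/yr ÷ 0.45 cm/yr ≈
3333. Per row, the migration factor M_f averages PC over the subaerial
cells of a window of 2w+1 rows and all columns (truncated at edges; 0 if
the window holds no land), and

    R_i = (1 − α_f·M_f)·B·S,   α_f = 1/M_f if M_f ≥ 0.5 else 2,

so migration is exactly zero at M_f ≥ 0.5 (the boundary case joins the
zero branch) and scales linearly below. Migration is realized as a rigid
landward translation of the row's elevation and cover profiles —
island rollover under an assumed abundant sediment supply — with
fractional cells carried between years so nothing is lost to rounding;
vacated ocean-side cells become water, and plants ride the substrate
until the viability check prunes them. An erosion-only mode (ocean-side
columns drowned in place, no translation) is available in config for
users who prefer a pinned back-barrier. Translation is horizontal only:
the profile is not raised with sea level, so the low perimeter of the
island slowly drowns as the sea rises — there is no beach-profile
maintenance or shoreface evolution in this model.

The full-scale window half-width default is w = 250 rows. The desk-scale
configuration uses w = 18 on its 200-row grid: the windowed average is
meant to smooth the vegetation control over a stretch of coast short
relative to the island, and a window spanning most of the island length
would erase the along-island contrast the metric exists to measure.

## Synthetic inputs

No elevation, vegetation or wind observations are deposited for the
mid-Atlantic islands the model targets, so all experiments run on
generated inputs that emulate their structure. The default island
template (200 × 560 grid) builds an elongated north–south island on the
eastern side of the domain: a bare beach rising to a 2.8 m foredune
ridge, a 1.6 m interior platform, a 0.3 m back-barrier marsh fringe, and
about 460 columns of lagoon left open landward — enough rollover room for
30 years under the fastest scenario, which needs ~450 cells of migration
at B ≈ 3333 (a 120-column domain loses the island off its landward edge
before the run ends). The island sits on a substrate 1 m above the
surrounding sea floor (the initial sea-level offset equals that depth),
so open water has realistic depth and a stray slab blown into it does not
instantly create new land; with zero-depth water, bare shoals accrete
around the island and systematically dilute the windowed cover.

Vegetation zonation follows the species bands and the observed
along-island pattern: dune grasses on the ridge (A. breviligulata 0.6,
S. patens 0.2), sparse S. patens patches on the platform (15 % occupancy
at 0.5), marsh grass at its cap on the fringe, and a woody core —
*Morella* 0.6 plus mixed dune grass — on a 2.0 m raised interior present
only in the lower (southern) half; the upper half carries no shrub.
Heights are placed mid-band so the stands survive three decades of wind
reworking (per-cell elevations random-walk by a few decimetres over a
30-year run, and vegetation parked at a band edge dies of elevation drift
rather than of any modelled disturbance). The shrub core deliberately
sits just above its 1.5 m viability minimum: out of reach of the historic
scenario's 13 cm rise but within reach of the highest scenario's 54 cm,
reproducing the shrub die-back that accelerated-rise projections imply.
The default wind climate is Weibull (shape 2, scale 8 m/s) — 55 % of
draws inside the 6–16 m/s transport window, every distance class
exercised — with a direction vector favouring onshore E/NE/SE winds.

What the generator does not emulate: storms and overwash, tides, beach
moisture and grain size, marsh accretion, groundwater, and the detailed
hypsometry of any real island. Passing scenario experiments therefore
demonstrate the internal mechanics of the vegetation–migration coupling
at reduced scale, not a hindcast of any particular island.

## Numerical choices and degenerate inputs

* Slab counts are validated non-negative integers; cover grids are floats
  clipped to [0, η_k] with Σ_k P_k ≤ M enforced after every annual update
  (tolerance 10⁻⁹ in the in-run invariant checks, which abort the run
  naming the offending step).
* The subaerial boundary is strict (> 0); M_f windows with no subaerial
  cells return 0; regression averages exclude transects absent at either
  epoch and raise if none remain.
* Transport-distance class edges follow the half-open convention
  [6, 9), [9, 13), [13, 16]; exactly 16 m/s is still transport, above is
  storm.
* Avalanche tie-breaks add uniform noise below one slab to the integer
  height drops, which selects uniformly among tied steepest neighbours.
* Migration shifts are floored to whole cells with a per-row carry in
  meters; a shift larger than the grid width clears the row.
* Wind-table runs resample rows uniformly with replacement from the
  supplied record using the wind stream.

## Problem sizes

The default desk experiment is a 200 × 560 grid run for 30 years
(26 aeolian events + 1 vegetation + 1 marine step per year), about half a
minute per scenario on one core. The test suite's scenario experiment
runs 4 scenarios × 3 wind seeds on one frozen island; the acceptance
script runs 4 scenarios at a single user-supplied seed. The paper-scale
728 × 678 grid is the `SimulationConfig` default for users with their own
rasters.

## Known limitations

* Sparse vegetation cannot pin the surface: entrainment scales with
  1 − PC only, and a species with a small erosion coefficient (S. patens,
  α = 0.333) can never protect its own substrate even at full cover.
* Wind reworking redistributes sand onto the marsh fringe and buries it
  above its band over a decade or two; a real marsh accretes and resists
  burial. The marsh is therefore a transient feature of every long run.
* Horizontal-only rollover with no profile maintenance lets the low bare
  perimeter drown progressively under fast sea-level rise, which
  concentrates the subaerial area on high vegetated ground and damps the
  between-scenario contrast in mean regression relative to a model with
  an actively maintained beach.
* Termination of avalanche relaxation is guaranteed only for bare
  surfaces; vegetated runs rely on the pass cap (a capped pass logs a
  warning and continues).
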