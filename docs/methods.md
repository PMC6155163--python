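# Methods

This note records the modelling choices behind `shelfweb`: what is computed,
which parameters matter, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## Mass balance

The snapshot solver works on the canonical linear trophic balance
`B·PB·EE = predation + catch + BA + net export`, with one unknown per living
group (B or EE). The solve is a single linear system, so mixed configurations
(some groups with known EE, others with known B) are handled uniformly; a
singular system is reported as structurally indeterminate rather than
guessed at. Feasibility is EE ∈ [0, 1] for every living group, checked to
1e-9; residuals are verified against `1e-9 · max(1, B·PB)` per group.

Detritus is closed by definition rather than solved: its EE is
detritivory/inflow, where inflow collects unassimilated consumption
(`GS·Q`), non-predation deaths (`(1−EE)·P`) and discards; any surplus leaves
as export. Inflow must cover detritivory or the model is rejected. With more
than one detritus pool, inflow is split equally — a simplification; webs
that need routed detritus fate should collapse to one pool.

Trophic levels use the standard fractional recursion (TL = 1 for producers
and detritus; 1 + diet-weighted prey TL for consumers), solved linearly.
Diet imports are excluded and the remaining diet renormalized, which avoids
assigning an arbitrary TL to food from outside the system; a consumer
feeding entirely on imports therefore has no defined TL and is an error.

## Foraging-arena dynamics

Consumption follows the arena flow equation given in the README. Two
readings of its denominator abundance are possible; we use the predator's
abundance (P_j), the form consistent with arena theory where the predator
competes for the vulnerable prey pool. Feeding-time, mediation and handling
terms (T_i, T_j, M_ij, D_j) are carried through the operator but default to
1 and are not driven dynamically — nothing in the workflow parameterizes
them, and leaving them inert keeps the operator general without inventing
dynamics.

Vulnerability is exposed as the dimensionless multiplier k with internal
exchange rate `v = k·Q0/B0`. This anchors k to the baseline: k → 1 is pure
donor control (flow can never exceed its baseline by much), large k
approaches mass action and top-down control. The calibration inversion

    v = k·Q0/B0_i,   a = 2·v·Q0 / (P0_j · (v·B0_i − Q0))

requires k > 1 and reproduces Q0 exactly at the baseline state. The default
is k = 2 (the conventional neutral setting when fitted values are
unavailable); newly established alien groups get k = 10 so their predation
mortality can depart far from a baseline that does not yet reflect their
capacity. In the k → ∞ limit the flow behaves as `(Q0/(B0·P0))·B·P`; note
the calibrated a tends to twice that coefficient because the baseline
denominator contributes a factor 2.

Other per-group rates are derived so the balanced snapshot is an exact
equilibrium of the dynamical system: other mortality M_i absorbs the
non-predation, non-fishing losses (including any biomass accumulation
term), catchability is `catch/B0` at reference effort 1, and the detritus
export is fixed at the baseline surplus. Producers grow as
`p(B) = PB0·(1+m)/(1+m·B/B0)` with density dependence m = 1, i.e. maximum
production rate twice the baseline rate — a saturating law that keeps
producers bounded without imposing a hard carrying capacity. Consumer diet
imports scale with predator biomass (`QB·import·B`), keeping the intake
identity `Σ_i Q_ij + import = QB·B` exact at baseline.

The temperature multiplier applies to the whole consumption column of an
affected predator and to the production rate of affected producers. The
alternative — modulating prey vulnerability — is not implemented; with
predator-side forcing the response is a clean foraging-capacity limit.

Integration is fixed-step RK4 at monthly resolution (dt = 1/12 yr):
deterministic, portable, and converged — halving dt changes 10-year
trajectories by well under 0.1%. Biomass is floored at 1e-6 of baseline as
an extinction proxy (clamp events are counted and logged); a biomass below
0.1·B0 is the qualitative "near collapse" reading. Groups under biomass
forcing bypass their equation and follow the forced trajectory exactly.
Effort series are right-continuous piecewise-linear knot series, so step
policies take their post-step value at the knot.

## Environmental responses

A response is a trapezoid over the driver: 0 at or beyond the tolerance
limits (min, max), 1 on the preferable range [q10, q90], linear shoulders
between. Linear shoulders are the minimal continuous choice consistent with
the four anchors; the shape is a small frozen dataclass, so a Gaussian-tail
variant can be swapped in without touching the engine. A degenerate shoulder
(min = q10 or q90 = max) behaves as a step, with the preferable plateau
winning on the shared anchor. Missing driver values are an error — no
imputation.

## Scenarios

The eleven-scenario design table is hard-coded and audited cell-for-cell by
tests. Concrete operationalizations:

- *Regulation multipliers* — trawl 0.50, artisanal 0.85, recreational 0.80,
  purse seine 1.0 (not named by the regulations) — phased in linearly over
  the first two simulation years, then held.
- *Trawl closure* — linear ramp from 1 to 0 across the first three years,
  zero thereafter.
- *"Current level"* of SST — the mean of the final three observed years,
  damping single-year noise. Relative effort is 1.0 at the reference year by
  construction. Constant alien forcing pins each group at its final observed
  value, which the generator makes identical to the balanced B0 so the
  forcing is continuous with the snapshot.
- *Current trends* of alien biomass — least-squares slope over the final
  five observed years, extrapolated linearly and floored at zero.
- *RCP anomaly tracks* are inputs (CSV/series), never downloaded; projected
  SST = reference + anomaly. The primary-production multiplier is
  identically 1 in every scenario.

Combined scenarios are literal merges: the combination scenario's effort
series equal the regulation scenario's and its SST equals the intermediate
warming scenario's, exactly.

## Indicators

Biomass aggregates (TotalB, ForF, InvB, PredB) exclude all non-living
pools; PredB uses TL ≥ 4 and Kempton's Q uses TL ≥ 3, both with the
*baseline* trophic levels held fixed through time — diet rewiring is not
modelled, so recomputing TLs from static diets would add noise, not
information. Kempton's Q is `0.5·S / log10(B₀.₇₅S/B₀.₂₅S)` with linear
interpolation between ranked biomasses at the fractional quartile ranks; it
is undefined (NaN) below four qualifying groups or when the quartile
biomasses coincide.

Flow indicators come from an explicit flow snapshot: consumer respiration
closes the energy balance (`(1−GS)·Q − P`, and is required non-negative —
an energetically infeasible group is an error, which constrains PB/QB + GS
≤ 1); flows to detritus collect unassimilated food, other-mortality deaths
and discards; exports are landings + net export + the detritus surplus;
imports carry diet imports and producer gross production (the external
inputs of the network). TST is the sum of consumption, exports, respiration
and detritus flows. FCI uses the Leontief-inverse diagonal of the
input-proportion matrix of the internal flow network (consumption links
plus detritus routing); PL = TST/(exports + respiration). Discards are
routed to detritus and not double-counted as exports.

## Uncertainty

Monte Carlo draws B, PB and QB uniformly within the pedigree intervals
(±ci as a fraction of the point value; uniform is the convention when the
pedigree gives only an interval), re-solves EE, and rejects infeasible
draws up to 50 times before declaring the pedigree incompatible with
balance. Diet composition is not resampled — the pedigree covers rates, not
structure. Each replicate is re-calibrated and re-simulated; the 5th/95th
percentiles (linear interpolation between order statistics) form the band,
with the deterministic run as the centre (so the centre is not the median
and may exit the band). Replicates that abort are excluded and logged; more
than 20% exclusions aborts the analysis. Replicate seeds are spawned from
the master seed, so envelopes are reproducible bit-for-bit.

## Trend statistics

Spearman's rho is the Pearson correlation of average-tie ranks against
time. For n ≤ 8 the two-sided p-value is exact (full permutation null);
beyond that the t approximation is used — the two agree within 0.02 at the
boundary. Significance is p ≤ 0.05, two-sided, with no multiple-testing
correction (each scenario × indicator cell is read on its own). A constant
series has no rank ordering and returns a NaN marker. The minimum series
length is 3 (rho is well-defined there; the exact null covers the p-value).

## Synthetic generator

The generator emulates the *structure* the analysis assumes, not any real
parameterization: twelve role archetypes (producer, detritus, zooplankton,
native/alien benthic invertebrates, native forage/small-demersal fish,
earlier and new alien demersal fish, a large native demersal predator, a
demersal shark, vulnerable megafauna) with biomasses and rates in the range
typical of coastal-shelf trophic models, jittered ±15% per seed; a
lower-trophic-weighted, column-normalized diet matrix; three fleets (trawl,
artisanal, recreational — purse seine as an optional fourth) with baseline
fishing mortalities of a moderately exploited shelf and a 15% trawl discard
share; warm-shifted thermal niches for aliens (preferable range 24–34 °C
vs 18–27.5 °C native, baseline 26 °C inside both so the snapshot is a true
equilibrium); and pedigree intervals drawn in [0.1, 0.4].

A candidate web is rejected unless it balances (all EE ∈ [0, 1]), the
baseline SST sits inside every preferable range, and the calibrated system
is locally stable (all Jacobian eigenvalues with non-positive real part at
baseline). The stability screen is a generator feature that keeps property
tests deterministic; it is not a claim that real ecosystems are locally
stable. The 17-year baseline history has effort declining to the reference
level in the last years, SST warming ~0.5 °C with ±0.12 °C noise, alien
biomass rising 2–3%/yr to end exactly at the balanced B0, and smooth
anomaly tracks reaching +0.6/+1.8/+3.5 °C at year 50 for RCP2.6/4.5/8.5.

What the generator does **not** emulate: real diet structure or rate values
of any particular shelf system, multi-stanza age structure, seasonal
forcing, observation error in the histories, or spatial dynamics. Passing
tests therefore demonstrate that the machinery is correct and that the
qualitative stressor directions (effort release → predator recovery;
warming past native niches → native decline, alien rise) emerge from the
mechanisms — not that any real system's magnitudes are reproduced.

## Problem sizes

Default experiments run the 12-group web: 50-year scenarios at monthly RK4
steps, twenty seeds for the equilibrium screen, 1,000 random draws for the
operator cross-check, and 500 Monte Carlo replicates for envelopes — sizes
chosen so the whole suite re-runs comfortably on a laptop while matching
the study design where one is stated (horizon, replicate count, scenario
set).

## Known limitations

- One detritus pool is the tested configuration; multiple pools share
  inflow equally.
- Import intake scales with predator biomass; a fixed-import variant is not
  implemented.
- The indicator suite holds TLs at baseline; long simulations with strong
  compositional change would misstate TL-filtered aggregates if diets
  actually rewired.
- The trend test treats years as exchangeable under the null; indicator
  series are autocorrelated, so p-values are anti-conservative in the way
  rank-vs-time tests usually are. Signs and relative strengths are the
  robust read.
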