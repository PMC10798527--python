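# Methods

`trophos` implements the full modelling chain for a mass-balanced,
upwelling-forced shelf food-web model: data preparation, static mass
balance, network transposition, and nitrogen-currency dynamics. This
note records the model equations as implemented, the defaults and why
they were chosen, and the places where a design choice was genuinely
open.

## Mass balance

Each living functional group i satisfies the budget

    B_i (P/B)_i EE_i + I_i + BA_i
        = Σ_j B_j (C/B)_j D_ij + E_i + F_i

with biomass density B (mt km⁻² wet weight), production rate P/B and
consumption rate C/B (yr⁻¹), diet fractions D_ij (prey i in the diet of
consumer j), immigration I, biomass accumulation BA, emigration E, and
fishery removals F (landings + discards). Ecotrophic efficiency EE is
the share of production used within the system and must lie in [0, 1]
for a thermodynamically consistent web.

Each living group supplies exactly one unknown: EE where biomass was
measured, or biomass where EE was fixed a priori. Because the budget is
linear in the unknown biomasses once known-biomass predation is moved to
the constant side, the mixed problem is solved with a single linear
solve over the fixed-EE groups followed by direct EE evaluation; no
iteration is involved. EE > 1 is reported as an imbalance diagnostic
(to be addressed by rescaling survey biomass or editing the diet
matrix), never raised as an error. Detritus-pool EE is reported from the
pool budget (consumption over inflow) as a diagnostic only.

`ba_convention` selects whether BA and I sit on the production side
(default, `"as_printed"`) or among the losses (`"canonical"`); with the
default BA = I = 0 parameterization the two are identical.

## Network transposition

The balanced consumption matrix is re-expressed donor-side: A[j, i] is
the fraction of group i's production flowing to destination j,

    A_ji = D_ij c_j / Σ_j D_ij c_j,     c_j = B_j (C/B)_j

over living consumers. The expanded network closes every living column
to exactly 1 by adding landings (out of system), discards (to the
fishery-offal pool), emigration (export), and the unconsumed remainder
1 − EE_i routed to egg/detritus pools per the group's senescence fate
row.

On the intake side each consumer splits its consumption into production
(P/Q), feces (1 − AE, routed per the feces fate row), and excretion to
ammonium. The excretion share is AE − P/Q — assimilated intake minus
production — so the three shares sum to exactly 1 and the nitrogen
budget closes identically. (A closure of the form "assimilated × (1 −
P/Q)" does not conserve mass and is not used.) Consumers whose P/Q
exceeds AE are rejected at network construction: no feasible energy
budget exists for them.

## Physical scaffold

Five boxes: inner shelf (I, vertically integrated), middle and outer
shelf each split at the 15 m mixed-layer depth into surface (II, IV)
and sub-surface (III, V) layers. A daily upwelling index (CUTI-style,
m² s⁻¹ per meter of coastline) scaled by the alongshore length drives a
closed advective circuit ocean→V→III→I→II→IV→ocean (reversed under
downwelling), so volume continuity holds exactly at every box.
Nutrients enter at the oceanic boundary at monthly climatological
concentrations (deep concentrations for upwelling inflow into V,
surface concentrations for downwelling inflow into IV). Non-nutrient
tracers have reflective boundaries: inflowing water carries the
receiving box's own concentration (no net import, no dilution), while
offshore outflow exports tracer mass. Per-group retention (0 = fully
advected, 1 = resists advection) scales every advective term.

The default geometry (alongshore 830 km; zone widths 15/10/30 km; mean
thickness I: 50 m, III: 135 m, V: 625 m) is an assumption standing in
for surveyed hypsometry; any application to a real shelf should supply
measured areas and volumes via `ShelfGeometry`.

## Time dynamics

Currency is nitrogen (mmol N m⁻³). Wet weight converts at 0.1 g C per
g wet weight and Redfield C:N = 106:16 (≈1.26 mmol N m⁻² per mt km⁻²);
these are config values, and group-specific factors can replace them.

Each day, in the three surface boxes:

1. **Uptake.** Total producer uptake is Σ_p (P/B)_p B_p · r(N), capped
   at 90% of the ambient pool, where the nutrient response
   r(N) = [N/(K+N)] / [N*/(K+N*)] equals 1 at the reference
   concentration N* and is quasi-linear below the half-saturation K
   (defaults N* = 3, K = 30 mmol N m⁻³). Uptake splits between NH4 and
   NO3 with an ammonium preference weight (default 4). Uptake is
   allocated across producers by their balanced production shares —
   fixing the community composition prevents competitive exclusion
   between producers drawing on one nutrient pool.
2. **Donor-controlled flows.** Every living group passes on
   (P/B)·B per day, allocated by its expanded network column
   (consumers, fisheries, export, senescence). A nutrient-starved
   producer passes on only its realized production (outflow scaled by
   min(r, 1)), so grazing collapses with uptake while surplus uptake
   (r > 1) accumulates as bloom biomass. Consumer growth is P/Q of
   donor-supplied intake; feces and excretion follow the intake split.
3. **Detritus.** Each pool's consumers intercept their balanced share
   of the pool's *daily production* (previous-day inflow), after the
   recycling claims: the consumable share of inflow is
   1 − r_d − s_d, with r_d the pool's remineralization fraction and
   s_d the benthic sequestration fraction. Remineralization and
   sequestration additionally drain the standing pool at the same
   daily fractions, and sinking moves pelagic detritus out of the
   surface layer (to the benthic pool in box I). Recycling therefore
   competes directly with detritivores for detritus production: at
   s = 1 the benthic pathway receives nothing and obligate
   detritivores starve, while at r = s = 0 the unconsumed remainder
   accumulates without bound (pools are then only advected/exported).
4. **Nitrification** converts NH4 to NO3 in the sub-surface boxes
   (default 0.2 d⁻¹); sub-surface phytoplankton senesce to pelagic
   detritus at a slow configured rate (0.1 d⁻¹).

Integration is forward Euler at dt = 1 day (the forcing's natural
step) with non-negativity clipping; clips are counted and reported, and
all runs used in the tests and the acceptance script record zero clips.
The balanced solution is an equilibrium of this scheme when r(N) = 1,
which is what makes mass balance and dynamics mutually consistent.

Diagnostics follow the study protocol: extinction = production below 1%
of its initial value at any point; stability = per-group relative
change between the final year's mean and the mean of the year 20 years
earlier, with a 5% pass threshold; f-ratio = NO3 uptake over total
(NO3 + NH4) uptake per shelf zone (inner = box I, mid = II + III,
outer = IV + V) over the final simulated year; total primary production
is the volume-weighted mean daily uptake over the same window.

## Detritus-recycling tuning

The three recycling parameters (pelagic remineralization, benthic
remineralization, benthic sequestration) are varied in 0.1 steps over
[0, 1]³ (1331 cells), each scored with a 20-year run: zone f-ratios,
total primary production, and the extinction count. The selector takes,
among zero-extinction cells, the cell minimizing the sum of squared
zone-wise f-ratio deviations from the nearest point of a target band
(default 0.3–0.8) plus the squared relative deviation of total primary
production from a benchmark; ties break to the lexicographically
smallest triple, and an all-extinct grid falls back to the
minimal-extinction cells with a warning. The distance function is this
package's own concretization of a qualitative "closest to realistic
values" rule.

## Survey estimation

Zero-inflated, heavily skewed trawl catches are averaged with the
delta-lognormal (Pennington) minimum-variance unbiased estimator:
(m/n)·exp(ȳ)·G_m(s²/2) with the Bessel-type series G_m truncated when a
term falls below 1e-12 of the running sum; m = 1 returns x₁/n and
m = 0 returns 0. Acoustic-trawl and mid-water data use the arithmetic
mean. Conversions: counts × aL^b length-weight, volumetric→areal by
assumed occupied depth, catchability scalers, gelatinous water-content
scaling (1 − wc_gel)/(1 − wc_ref) with defaults 0.96/0.80 (crustacean
reference) and 0.75 for fish — all assumptions, visible in config.
Within a subregion, species are estimated per survey, averaged across
spatially overlapping surveys, then summed into functional groups. The
small-phytoplankton fraction uses the empirical partition
0.30821·Chl^−0.82351, clamped to [0, 1] since the raw power law exceeds
1 below ≈0.24 mg m⁻³.

## Diet and fisheries preparation

Diet sources drop unidentified material and renormalize; multiple
sources merge by sample-size weights; species combine into groups by
biomass share; broad prey labels split across member groups in
proportion to biomass among members observed at least once in that
predator's diet (falling back to all members, with a warning);
frequency-of-occurrence sources are treated like weight-based ones
after normalization (no conversion exists between the two semantics).
Pinning one prey's proportion renormalizes the others proportionally.
Zone landings redistribute to model latitude bins by interval overlap,
across the shelf by occurrence proportions, to fleets by a gear map,
with discards added from per-fleet-per-group rates; total landed weight
is conserved whenever the bins jointly cover each source zone.

## Synthetic data

The generators define the conditions under which the pipeline is
tested. Toy webs are built *flow-first*: biomasses are drawn
log-uniformly over ~5 orders of magnitude, consumption flows are
allocated layer by layer within each prey's usable production, and the
residual usable production is topped up as emigration (plankton, lower
layers) or fishery catch (upper layers), so that the solved EE of every
living group lands in the target range (default (0.2, 0.9)) by
construction. One layer-1 consumer is an obligate, non-advecting
benthic detritivore, giving the web a benthic energy pathway that
recycling parameters can sever. Upwelling forcing is a summer-peaked
sinusoid (mean 0.5, amplitude 1.0 m² s⁻¹, Gaussian noise sd 0.2) with
negative winter values; surveys are zero-inflated lognormal hauls with
the true mean recorded; diet sources perturb a Dirichlet-distributed
true diet and carry unidentified mass and broad labels.

What the synthetic webs do **not** emulate: real taxonomic structure,
ontogeny or migration, spatially heterogeneous subregion webs, observed
diet matrices, or the deposited parameter tables of any particular
shelf system. Passing tests therefore demonstrate internal consistency
of the machinery (solver correctness, conservation, stability of the
balanced state, qualitative recycling responses), not agreement with
any measured ecosystem time series.

## Numerical choices and degenerate inputs

- Diet columns are accepted within 1e-6 of 1 and renormalized exactly;
  fate rows within 1e-6, stored normalized.
- The biomass linear system is rejected as non-identifiable above a
  condition number of 1e12; negative solved biomass raises an
  infeasibility error naming the groups.
- Trophic levels solve (I − Dᵀ)TL = 1 directly; diet cycles are fine,
  and a consumer with an all-zero diet column is an error.
- Prey with zero total consumption get all-zero transpose columns, not
  errors; fleets with zero catch get NaN trophic level.
- The day-of-year forcing climatology folds Feb 29 into day 59; runs
  use a 365-day year throughout.
- In a zero-nutrient run, primary production is not exactly zero:
  consumer excretion regenerates trace ammonium that producers can take
  up. It is orders of magnitude below any nutrient-fed value.

## Known limitations

- Sub-surface boxes apply no consumer metabolism; biomass advected
  below the mixed layer is only transported and (for producers)
  senesces. Retention-0 consumers can therefore shelter mass at depth;
  benthic groups should carry retention 1.
- The dynamic transfer rule is the package's own donor-controlled
  closure (isolated in `run_simulation`); platform-specific functional
  responses can replace it without touching the network construction.
- The 150-year stability protocol and recycling-grid scoring are run
  here on 10–12-group synthetic webs; applying them to a full 90-group
  parameterization requires the corresponding deposited diet, fate, and
  catch tables as inputs.
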