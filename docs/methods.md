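# Methods

## Scope and design

The package computes a full-scale national N₂O budget in two halves: an
emission-factor (EF) inventory for the four anthropogenic sectors at
province level, and a reduced-form process model for natural forest and
grassland soils on an abstract equal-area 25-km lattice. All computation
lives in `src/n2obudget/`; the numbered scripts under `analysis/` are thin
narrative drivers over the same functions the tests exercise.

All masses are carried internally as Gg N₂O-N yr⁻¹ and converted to Gg N₂O
(× 44/28) only at the reporting surface. This keeps the soil-pathway EFs
(which are defined per kg N) and the industrial/energy EFs (defined per kg
N₂O) on one consistent basis and makes nitrogen bookkeeping exact.

## Anthropogenic inventory

Each sector emission is Σᵢ Σⱼ ADᵢⱼ(y) × EFᵢ over sources *i* and provinces
*j*. The unit layer composes arbitrary activity units (masses with SI
prefixes, TJ, head counts) with EF units (`kg N2O-N / kg N`,
`kg N2O / TJ`, `t N2O / t product`, ...) and fails loudly on mismatches.
Category taxonomy is closed: 24 anthropogenic categories (11 energy, 2
industry, 9 agriculture, 2 waste) plus natural forest/grassland, so sector
subtotals are well defined.

Sector specifics:

* **Agriculture.** Direct soil emissions apply EF₁ per N-input component
  (synthetic fertilizer, applied manure, crop residue, mineralized N,
  deposited N), stratified by climate region × land type. The shipped EF₁
  table puts upland at 0.0157 kg N₂O-N kg⁻¹ N in the humid subtropical
  east and 0.0149 in the temperate-humid northeast, 0.0065–0.0093
  elsewhere, with paddy values in 0.0052–0.0161; lookups fall back to
  tier-1 style defaults (0.01 upland, 0.004 paddy) for unconfigured
  strata. Indirect emissions follow the leaching/runoff pathway
  (Frac_leach defaults mid-range within 1.21–8.27 % paddy and 0.61–8.74 %
  upland; EF₅ = 0.0065 kg N₂O-N per kg N) and a volatilization pathway
  (Frac_GASF/Frac_GASM × EF₄). Manure N is budgeted exactly: excretion =
  headcount × (mass/1000) × rate × 365; management-system fractions must
  sum to 1; N routed to pasture or to soil application is emitted in those
  pathways only (no double counting). Pasture deposition uses EF₃ = 0.004
  (cattle/swine/poultry) and 0.003 (sheep/other); a property test verifies
  that reverting to the older defaults (0.02/0.01 with excretion rates
  1.37/1.17 instead of 0.34/0.32 for goats/sheep) strictly increases
  manure emissions, the direction that explains why updated inventories
  sit below older ones.
* **Energy.** Combustion is energy-based — activity in TJ directly or as
  mass × net calorific value — times kg N₂O TJ⁻¹; an invariance test
  checks the two routes agree. The category set is closed to the eleven
  inventory rows; fugitive emissions use native units.
* **Industry.** Adipic/nitric acid production × EF (defaults 300 and 9 kg
  N₂O t⁻¹) with abatement (1 − DF·UF) applied per plant. The abatement
  registry defaults to the two historically credited adipic plants, active
  2008–2012; continuing abatement after 2012 is a scenario switch,
  off by default, reflecting genuine uncertainty about whether the
  installed equipment kept operating.
* **Waste.** Wastewater N load = population × protein intake × 0.16 kg N
  per kg protein × co-discharge multipliers − sludge N (floored at zero
  with a logged warning), times an effluent EF (default 0.005 kg N₂O-N per
  kg N, a factor known only to within several hundred percent — hence the
  Monte Carlo layer); solid-waste composting/incineration are per-mass EF
  pathways.

Gap-filling substitutes the nearest populated year (ties toward the later
year) and flags substituted values, matching how snapshot tables borrow
neighbouring years when a sector series starts late.

## Natural soil model

An annual-step model of three soil N pools (NH₄⁺, NO₃⁻, organic N) with a
labile-C index scaling denitrification. Transformations are first-order in
substrate with a Q10 temperature response (Q10 = 2, reference 15 °C) and
WFPS responses — parabolic optimum (0.6 ± 0.35) for nitrification,
increasing (w²) for denitrification, which requires wet anaerobic soil.
The two WFPS shapes are this package's concrete choice for a mechanism the
literature models in many closely related forms.

N₂O is a fixed yield leaking from each pathway: autotrophic nitrification
(0.4 %), heterotrophic nitrification (0.4 %), nitrifier denitrification (a
second 0.2 % leak on the NH₄-oxidation flux, since it is a process of the
same organisms), and denitrifier denitrification (6 % of the NO₃ flux, the
rest leaving as N₂). Zeroing the two extra yields reproduces the simpler
two-pathway scheme bit-for-bit (tested), which mirrors the structural
difference between four-pathway and two-pathway models of record and
explains the four-pathway variant's smaller interannual variability.

Numerics: pool losses use the exact linear-decay solution
1 − exp(−Σk), partitioned among competing sinks in proportion to their
rate constants. This is unconditionally stable — an explicit Euler step
with these rate constants (up to ~5 yr⁻¹) oscillates with period 2 — and
it guarantees non-negative pools. Nitrogen is conserved to machine
precision each step: deposition − (1 − litter_frac) × uptake − gaseous
losses = Δpools. Plant uptake removes mineral N at a rate scaled by
1 + β ln(CO₂/CO₂_ref) (β = 0.6, reference 340 ppm) — the CO₂-fertilization
mechanism by which rising CO₂ lowers soil inorganic N and suppresses N₂O —
and a litter fraction (0.85) of uptake returns to the organic pool,
closing the vegetation loop so the organic pool is quasi-stationary over
the 41-yr window instead of draining.

Default rates were set so that near-steady forest columns emit
~0.08–0.12 g N₂O-N m⁻² yr⁻¹ and grassland ~0.01–0.03 under their default
forcing, which at realistic forest (~2.2 Mkm²) and grassland (~3.9 Mkm²)
extents puts national natural emissions in the few-hundred Gg N₂O range
with forests contributing ~3/4 — the documented order of magnitude for
this system. Simulations spin up by repeating the first forcing year
(30 yr in the analysis scripts) before the reported window.

Factorial attribution runs the all-driver simulation plus one run per
driver (CO₂; N deposition; climate = temperature + moisture) held at its
first-year values; a driver's contribution is the OLS slope of the
difference series × the 41-yr window, and the non-additivity of the three
contributions against the baseline trend is reported as an explicit
residual, not hidden. On the synthetic forcings the signs are stable:
N deposition positive, CO₂ negative, warming positive.

## Uncertainty

Monte Carlo propagation treats EFs as national parameters — one draw per
category per iteration, applied to every province's line items (perfect
within-category correlation), independent across categories — and activity
data as independent per-item draws. EFs default to lognormal
(strictly positive, right-skewed; draws are mean-corrected so the
expectation equals the nominal value), activity data to zero-truncated
normal. Intervals are empirical 2.5/97.5 percentiles; a test checks the
n = 10⁴ interval against closed-form lognormal quantiles to 2 %.

MCMC calibration is a random-walk Metropolis chain with diagonal Gaussian
proposals (scale 0.12 × prior SD, giving ~15–25 % acceptance on the 2-D
problems used here), Gaussian likelihood on annual fluxes with known noise
SD, 50 % burn-in. The denitrification yield and rate are strongly
anti-correlated given flux data (the flux constrains roughly their
product), so `mcmc_fit` supports pooling several chains started from
dispersed, direction-alternating prior quantiles; the recovery test uses
3 × 1500 iterations, which restores honest interval coverage (≥ 90 % over
20 simulate-then-refit repeats at 5 % observation noise) where a single
short chain under-explores the ridge. Identifiability also needs contrast
in the drivers: the synthetic calibration observations span WFPS 0.25–0.9
so the rate's saturation behaviour is visible in the data.

## Trends and reporting

Decadal percent changes are endpoint ratios between inventory years (the
convention that reproduces multi-decade growth figures quoted from
snapshot tables), not regression slopes. Linear trends are OLS on
(year, value); the accumulated change multiplies the slope by 41 — the
number of annual values in 1980–2020, kept as the published convention
even though the window spans 40 intervals. The Mann-Kendall test uses the
tie-corrected normal approximation with continuity correction and no
pre-whitening; an exhaustive test equates its S statistic with brute-force
pair counting for all small-n tie patterns. Percentages are reported to
one decimal; shares on any basis sum to 100 within rounding.

The snapshot fixture stores only sub-source line items; subtotals are
recomputed. Because the published rows were rounded independently,
recomputed subtotals can differ from printed ones by up to ~0.2 Gg, and
the printed subtotals are carried separately as reference metadata. The
printed grand totals for 1980–2010 exceed the sum of their own printed
subtotals by 0.1 Gg (rounding of unrounded internals); only the 2020
column sums cleanly, so exactness is asserted only there.

## Synthetic data: what it does and does not show

The generator reproduces the statistical *structure* of the study period:
fertilizer N rising ~3× from 12 Tg to an exact 35.4 Tg anchor in 2016 and
declining to an exact 30.6 Tg in 2020 (the only two national activity
anchors printed; everything else is shape); adipic-acid production near
zero before 1995 and growing steeply after 2005 in four producer
provinces; coal-dominated fuel use growing fastest in the 2000s;
population increments declining linearly from a 15.5 M yr⁻¹ 1980s mean to
7.5 M yr⁻¹ in the 2010s; CO₂ rising 339 → 412 ppm; N deposition rising to
2000 then plateauing; warming of 0.03 °C yr⁻¹ with interannual noise.
Provincial disaggregation uses seeded Dirichlet shares with multiplicative
lognormal noise renormalized to national totals — plausible heterogeneity,
not real provincial statistics.

Consequently, passing tests demonstrate that the engines are correct
(oracle equivalence, conservation, closed-form checks), deterministic
under seeding, and that the pipeline reproduces the qualitative dynamics
(agriculture peaking then declining after 2016; industry and energy rising
after 2005; natural emissions growing ~1.5–2 Gg yr⁻¹ with the expected
driver signs). They do not validate absolute provincial magnitudes, the
real spatial pattern, or the true full-series peak value — those require
the actual activity and forcing data, which are not redistributable here.

## Problem sizes

Default analysis sizes, chosen as a desk-scale study configuration:
31 provinces × 41 years × 24 categories (~61 k estimates); a 100 × 100
25-km lattice (~9.8 k active cells, 30-yr spin-up); 10³ Monte Carlo draws
for inventory intervals (10⁴ where checked against closed forms); MCMC
with 3 × 1500 iterations on 25 annual observations.

## Known limitations

No sub-annual dynamics, freeze–thaw pulses, crop-specific EFs, vegetation
dynamics or carbon-cycle closure; aquatic/riverine N₂O is absent (as it is
from the inventories this design follows); the abstract lattice carries no
map projection; abatement behaviour after 2012 is a scenario, not an
estimate; EF defaults for energy/industry/waste are global-style
placeholders exposed as config rather than country-calibrated values.
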