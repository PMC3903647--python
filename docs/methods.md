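# Methods

`rangemon` designs multi-species monitoring networks whose stations are
stratified across the areas where each species is predicted to *gain*,
*maintain* or *lose* climatic suitability under future scenarios, so that
later resurveys can test hypotheses about climate-driven range shifts rather
than merely track population trends. This note records the models, the
defaults and the reasoning behind the open design choices.

## Problem formulation

The planning domain is a rectangular grid with a common nodata mask; every
valid cell is a *planning unit* eligible to host one monitoring station.
For each species the inputs are continuous suitability surfaces in [0, 1]
(present climatic, future climatic per scenario, and a habitat-constrained
"full" present model) plus training occurrence cells.

**Thresholding.** A surface is reduced to presence/absence with the
10th-percentile-of-training-presence rule: the cutoff τ is the 10th
percentile (linear interpolation between order statistics) of the model
values at the training presences, so roughly the least-reliable tenth of the
records falls below it. A cell is suitable iff its value ≥ τ; the boundary
cell counts as suitable, matching the usual convention in which the
threshold-defining record stays inside the predicted range. Strictly-greater
would differ only on exact ties, which have measure zero for continuous
surfaces. τ is computed once per species per model (climatic and full
separately) and applied to present and future projections of that model
alike, because future surfaces are projections of the same fitted model.

**Change classes.** Crossing the present and future binary maps gives the
per-cell class: suitable→unsuitable = *loss*, suitable→suitable =
*maintain*, unsuitable→suitable = *gain*; the remaining (0,0) cells we call
*unsuitable* and exclude from the feature set, as they carry no hypothesis
about shift detection. Classification is done separately per scenario.

**Features and targets.** The representable features are, per species, the
three change classes per scenario plus the full-model suitable area.
Targets are status-dependent: least-concern (LC) species get 3 stations per
feature at the first network level, data-deficient (DD) species 5; the
second and third levels double and quadruple every target (6/10 and 12/20).
Because the published target table prints one G/M/L triple per species while
classification is per scenario, two readings exist; we instantiate G/M/L
features *per scenario*, each carrying the full target
(`scenario_mode: per_scenario`), which is the stricter reading — the network
supports the shift hypothesis under either scenario — and subsumes the
union-of-scenarios alternative, which remains available as
`scenario_mode: union`.

## Minimum-set solver

The optimization minimizes

    cost(S) + FPF · Σ_f max(0, T_f − r_f(S)) + β · max(0, cost(S) − C)

over station sets S, where r_f counts selected units incident to feature f,
T_f is its target, FPF is the feature penalty factor (default 100), and the
third term is active only when a cost threshold C caps the network size
(β = 10 · FPF · Σ T_f, large enough that exceeding the cap is never
profitable). Unit costs default to 1, so cost(S) = |S|. No
boundary-length/compactness term exists: for monitoring, spatially dispersed
stations give more independent data. The shortfall penalty is FPF per
missing occurrence, which coincides with the repair-cost-based penalty of
standard reserve-selection software when unit costs are 1 (our setting); the
variant is configurable.

Targets exceeding a feature's incident-unit count are capped at the
attainable maximum and reported by `coverage_report`; otherwise a scarce
stratum (gain, by construction) would make every solution equally
"infeasible" and the penalty would stop discriminating. The cap is *not*
applied when scoring comparison networks against the stratified table —
there the point is precisely to measure failure against the original
targets.

**Annealing.** Each run starts from the locked-in units plus a sparse (5%)
random subset and proposes uniform single-unit toggles; improving moves are
always accepted, worsening moves with probability exp(−ΔO/T). The published
configuration states an adaptive initial temperature but not the procedure,
so ours is documented and configurable: T₀ is the largest |ΔO| over 1,000
probe toggles from the initial state, the schedule decays geometrically to
T_final = 0.02·T₀ over the configured number of temperature decreases
(default 10,000). After annealing, a deterministic repair pass greedily adds
the unit covering the most remaining shortfall occurrences until no
attainable shortfall remains (never exceeding the cost threshold), then a
randomized trim removes units whose removal leaves every target still met.
Production defaults are 100 restarts of 1,000,000 iterations; the shipped
demo and the tests use 5 restarts of 50,000 iterations on the 60×60 grid,
where the repair pass already guarantees attainable-target feasibility and
the restarts only polish the station count. Incremental objective
bookkeeping is audited against a from-scratch recomputation every 10,000
accepted moves (tolerance 1e-9) and on every move in one test.

The *best* solution of an ensemble is the lowest objective, ties broken by
fewer stations, then earliest run — a fixed rule so reruns are reproducible.
All run seeds derive from one master seed via a seed sequence.

**Exact oracle.** For instances of ≤25 units a branch-and-bound search
(units ordered by coverage; admissible bound combining unavoidable penalty
for uncoverable shortfall with a per-unit coverage bound on the units still
needed) returns the provable optimum. It exists to audit the annealer — on
200 random instances of ≤15 units the best of 20 annealing runs must match
it in ≥95% of cases — and is never used as the production path.

**Nesting.** Level-2 networks are solved with every station of the best
level-1 solution locked in (a locked unit is never proposed for removal and
appears in every run), and level 3 likewise locks level 2. Nesting is
therefore a hard guarantee, not a statistical tendency. Station counts are
unique grid cells, not species-visits.

**Quarter rule.** Because future projections use climate only, at least a
quarter of each network's stations should lie in ground the full
(habitat-aware) model deems currently suitable. The full-model features and
their targets are the enforcement mechanism; `quarter_check` additionally
reports, per species and for the union of species' full-model areas, the
fraction of stations inside, with the pass flag on the union — the published
rule states the intent but not the accounting unit, and the union is the
reading under which the rule constrains the network as a whole.

## Occurrence-only comparison

The conventional design considers only current distributions. The
comparison network for each level is solved with one feature per species per
current model (climatic and full), targets copied from the number of the
optimized network's stations inside each area, and total size capped at the
optimized network's station count via the cost threshold. Every run of the
comparison ensemble is then scored against the original stratified table: a
feature is unmet on any positive shortfall (binary, not magnitude), and the
report aggregates the unmet fraction per run — median/min/max overall, by
class kind and by species × class, per scenario and pooled.

## Synthetic landscape

No suitability rasters are distributed with the study this pipeline
emulates, so the generator produces landscapes with the qualitative
geometry the method assumes; it is first-class, tested code.

- **Environmental field**: a planar gradient along columns plus
  Gaussian-smoothed white noise (σ = 6 cells, weight 0.25), built on a
  padded canvas so shifted windows stay coherent at the edges.
- **Species response**: a Gaussian (bell) curve around the species' niche
  optimum. A unimodal response is required here — a monotone logistic has no
  optimum and cannot produce a range that both contracts and shifts.
- **Future scenarios**: the field is translated spatially (conditions
  migrate across the grid, default 3–4 cells) and the niche response is
  raised to a contraction exponent γ ≥ 1, which keeps the optimum suitable
  while narrowing the suitable band. Translation alone cannot make loss
  extensive while keeping gain scarce on a bounded grid; the exponent
  supplies the contraction the emulated study reports. γ is
  species-specific (1.0–2.2 × a scenario base of 3.5 for the harsher and
  2.5 for the milder scenario), so some species lose far more of their
  range than others — which is what makes the *maintain* stratum scarce
  relative to current range for the sensitive species, reproducing the
  observed failure pattern of occurrence-only networks.
- **Full model**: present climatic suitability multiplied by a smoothed
  habitat indicator in [0, 1], making full-model suitability a restriction
  of climatic suitability (narrower niche for every species).
- **Community**: 7 species, 3 LC + 4 DD, niche optima staggered over
  [0.35, 0.60]; 30 training presences per species drawn without replacement
  with probability proportional to suitability (record counts per species
  are unspecified in the emulated study beyond a ≥15 floor; 30 is a
  realistic regional-atlas figure). Default grid 60×60 with 5% nodata — a
  desk-scale stand-in for the ~half-million-cell study grid.

With these defaults, per scenario, gain for ≥1 species covers roughly
5–15% of valid cells, loss for ≥1 species exceeds 40%, and per-species gain
is strictly smaller than loss — the directional calibration the analysis
assumes. What the generator does **not** emulate: spatial autocorrelation of
occurrence records, observation error in suitability, coastline/elevation
structure, and inter-species interactions. Passing tests therefore show the
*method* behaves correctly on landscapes with the assumed geometry, not that
any particular real region would yield the same numbers.

## Numerical choices and degenerate inputs

- Quantiles use numpy's linear interpolation between order statistics;
  alternative definitions shift τ by less than one order statistic.
- All-equal presence values give τ equal to that value (degenerate but
  valid); fewer than 2 presences is an error.
- An all-zero suitability surface is an error for the niche statistics
  (normalization undefined).
- Grid coordinates are 0-based (row, col), row 0 at the top, matching the
  ESRI ASCII raster order; flat cell index = row · n_cols + col.
- The cost-threshold penalty is a constant-β soft constraint; the original
  software ramps its threshold penalty over iterations with unpublished
  parameters, so a documented substitute is used and the repair pass
  enforces the cap exactly.
- Seeds: every source of randomness descends from one master seed; derived
  seeds stay below 2³¹.

## Known limitations

- Station accessibility/travel costs are not modelled (uniform unit costs).
- No power analysis: the pipeline places stations to *enable* shift
  detection but does not estimate detection probability.
- Continuous (non-binary) change metrics and ensemble thresholding across
  model replicates are out of scope.
- The exact oracle is exponential and restricted to ≤25 units by design.
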