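# Methods

## Model and conventions

A metabolic model is the standard constraint-based object: stoichiometric
matrix `S` (n metabolites × m reactions), flux bounds `lb ≤ v ≤ ub`
(mmol gDW⁻¹ h⁻¹; biomass flux in h⁻¹), and a biomass reaction with a
non-negative lower bound whose flux is read as the growth rate. The
feasible set `F = {v : Sv = 0, lb ≤ v ≤ ub}` is never materialised; all
queries are LPs solved with HiGHS (`scipy.optimize.linprog`), feasibility
and optimality tolerances at the solver's defaults (~1e-9).

Sign convention: exchanges are oriented so that their labelled direction is
positive — uptakes import at positive flux, secretion exchanges export at
positive flux. SBML input (which writes exchanges export-positive) is
re-oriented on read and the sign flips recorded for round-tripping.
Environmental bioavailability `x_env^b ≥ 0` therefore always enters as an
upper bound `0 ≤ x_env ≤ min(x_env^b, ub)`: the environment limits supply
and the model's own upper bound represents transporter capacity, which the
environment cannot relax. A toggle (`carbon_mode="equality"`) instead
forces the carbon-fixation flux to equal its bioavailable value, for users
who read fixed carbon as a commitment rather than a ceiling; the default
treats it like the nutrients.

Unbounded ("infinite") bounds are encoded internally as ±1e6. This keeps
every projection bounded; a projected coordinate whose support reaches
99 % of that cap is reported as an unbounded-projection error naming the
coordinate, since a niche extending to an artificial cap is meaningless.

Degenerate optima are canonicalised parsimoniously: after any maximisation
the reported flux vector minimises total absolute flux with the objective
pinned at its optimum (split-variable LP). Pinning uses a relative
tolerance ε_fix = 1e-6, applied wherever a flux is fixed at a previously
computed optimum (canonicalisation, bi-level steps, lifting). HiGHS is
deterministic, so repeated identical calls return bit-identical vectors.

Infeasibility is kept distinct from zero growth at the library level (a
"no growth state" exception vs a feasible optimum of 0); the grid driver
maps infeasible points to growth 0 with an `outside_niche` flag, which is
the ecological reading: the environment does not belong to the niche.

## Niche projection

The niche is the exact image of `F` under the coordinate projection onto
the p reactions of interest (p ≤ 6 supported; tested up to 4). We compute
it by support-function outer refinement rather than by any particular
multi-objective formalism, because for polytopes the support approach is
exact and directly testable:

1. **Seeding.** Support LPs along ±axes give the bounding box (and the
   unboundedness check); 8p random unit directions (fixed internal seed —
   probe directions are an implementation detail, not user randomness)
   enrich the point cloud. Every support point is the restriction of a
   feasible full flux vector.
2. **Affine rank.** SVD of the centred cloud proposes null directions;
   each is confirmed by a width check (two support LPs). Confirmed
   zero-width directions become explicit equality constraints (the affine
   hull); unconfirmed ones contribute their support points and the rank is
   re-estimated. Rank 0 and 1 niches are returned directly as a point or a
   segment. This joggle-free handling matters in practice: tightly coupled
   stoichiometry (e.g. a nutrient consumed only by biomass) makes niches
   rank-deficient, as in the TOY1 example where `EX_N = x_bio`.
3. **Refinement.** Within the affine hull, Qhull builds the hull of the
   seeds; for every facet a support LP over the full polytope checks
   whether the polytope extends beyond the facet by more than
   tol·scale (tol = 1e-6 relative, scale = bounding-box diameter). Violating
   support points are inserted and the hull rebuilt, to a fixpoint
   (200-iteration guard).

On termination every facet is supported, so vertices and halfspaces both
describe the true projection up to tolerance. Both representations are
stored; the per-grid-point LPs use the H-representation. Membership tests
use the same absolute tolerance tol·max(1, scale).

Growth extraction is `max x_bio` over the halfspaces and equalities with
`0 ≤ x_env ≤ x_env^b` on capped coordinates (uncapped coordinates default
to [0, 1e6]; uptake non-negativity reflects the uptake-positive
convention and is the intended semantics for bioavailability — models with
obligatory secretion through a coordinate of interest would need the bound
relaxed). Realised uptake is canonicalised by a secondary LP minimising
total uptake at the fixed optimum, so the reported uptake vector is the
cheapest way to sustain maximal growth.

`lift_to_full_flux` pins the reactions of interest to a niche point
(within the absolute tolerance, escalating ×10 and ×100 before failing)
and fills in the rest of the network parsimoniously — the feasibility
witness used to validate projections.

## Bi-level physiology

* **Auxiliary ranges.** Step 1: maximal growth under the environment
  (solved on the niche when one is supplied). Step 2: the target flux is
  minimised/maximised with biomass pinned at that optimum. For a single
  auxiliary dimension the projection of the growth-pinned polytope is just
  an interval, so step 2 is two LPs. Metabolites are handled sequentially
  and independently; interactions between simultaneous secretions are out
  of scope, making every aggregate an upper envelope (stated in output
  metadata). Metabolites without an exchange get an export-only exchange
  (bounds [0, 1e6]), which cannot change the optimum. The energy cost of
  making or mobilising storage is deliberately excluded.
* **Slacks.** `d_n = x_env^b,n − min uptake of n` at pinned maximal
  growth, one minimum-uptake LP per nutrient. Because realised uptake at a
  degenerate optimum is not unique, this per-nutrient minimum is the
  well-defined quantity "what the organism could spare"; the slack at the
  canonical parsimonious optimum is available by subtracting the canonical
  uptake instead, but the per-nutrient minimum is the default and the one
  used for resource constraints.
* **Resource constraints.** Min–max normalisation of each nutrient's slack
  across the declared ensemble, inverted so the smallest slack maps to
  100 % (limitation) and the largest to 0 %. A constant slack distribution
  carries no signal and is flagged uninformative rather than normalised.
  Normalisation statistics depend only on the declared ensemble scope
  (whole grid by default, per-month optionally), never on iteration order.
* **Composition ratios.** `c_M (x_M + a_M x_bio)/x_bio` with `c_M` the
  carbon atom count and `a_M` the biomass coefficient. The carbon
  coefficient multiplies the *total* component flux, including the biomass
  draw — the grouping consistent with "component produced = excess + fixed
  quota" followed by carbon scaling. Undefined at zero growth (an
  exception, not infinity).
* **Glycogen storage index.** `r_stor` = carbon-scaled maximal glycogen
  production ÷ bioavailable fixed carbon (the environmental supply, not
  realised fixation — a documented toggle away). The index is the min–max
  normalisation of `r_stor` over the ensemble; min–max was chosen for the
  normalisation (recorded in output metadata) as the simplest transform
  mapping the ensemble onto [0, 1]. Entries at or above the ensemble mean
  index are "storage"; below it, "consumption", with implied consumption
  `ṽ = v̄ − v` where `v̄` is the production corresponding to the mean
  index at that entry's fixed carbon. A degenerate ensemble (constant
  r_stor) gets index 0, storage regime, zero implied consumption.

## DOC hot spots

Per candidate metabolite: upper end of the auxiliary range × carbon atoms
(mmol C gDW⁻¹ h⁻¹). Candidates absent from the network are skipped with a
warning. Intensity = abundance × sum of per-metabolite maxima
(mmol C h⁻¹); diversity = count of metabolites whose production strictly
exceeds 5 % of the maximum over the candidate set *including* the
metabolite itself (self-exclusion would make the top producer's membership
ill-defined). Diversity is computed on carbon-scaled fluxes by default
(an unscaled toggle exists via the carbon table).

## Grid driver

The niche is projected once per model and reused at every point; per-point
work is one p-dimensional growth LP, one canonicalisation LP, one
minimum-uptake LP per nutrient, and two LPs per requested auxiliary or DOC
metabolite. Iron columns are accepted and ignored with a warning (the
models considered here cannot utilise it); any other unmapped nutrient
column is a configuration error raised before any solve. The thermal mask
is post-hoc and optional — metabolism itself has no temperature response —
flagging rows strictly below the threshold while retaining their values;
a point exactly at the threshold is kept.

## Synthetic generators

* **Quota chains.** One uptake per nutrient, a carbon-fixation source, per
  storage component a synthesis (carbon cost) and secretion pair, and a
  biomass reaction drawing nutrients, carbon and biomass-participating
  storage. The FBA optimum has the closed Liebig form
  `min_n(min(x_n, cap)/a_n, min(x_C, cap)/c_eff)`. Uptakes carry a
  transporter-capacity ceiling of 20 mmol gDW⁻¹ h⁻¹ — large relative to
  the default environment fields (nutrients O(1), fixed carbon O(10)) so
  it only binds in deliberately extreme tests, while keeping the polytope
  at a well-conditioned scale for hull construction. TOY1 is the reference
  instance: N (coeff 1), P (0.2), 5 C per biomass, glycogen (7 C, not in
  biomass).
* **Random networks.** Acyclic chains from uptakes to biomass: M0 always
  has an uptake and feeds biomass at coefficient 1, guaranteeing growth at
  unit bioavailability; remaining budget goes to random uptakes, 1:1
  conversions flowing only up the metabolite ordering (no cycles, hence
  bounded projections without loop-law machinery), secretions, and small
  extra biomass draws on producible metabolites. All bounds finite.
* **Environment grids.** Nutrient fields = base × latitudinal cosine
  gradient × hemisphere-aware seasonal modulation × longitudinal ripple ×
  (1 + Gaussian noise, sd 0.05), floored at 1e-3; fixed carbon decays
  exponentially with depth (e-folding 60 m) from a surface value of 12;
  temperature spans pole (−1 °C) to equator (28 °C) with a seasonal term;
  abundance follows the light profile. Inside a designed limitation box
  the named nutrient is rescaled to `factor × a_n × min(other quota
  ratios)` (factor 0.3), making it strictly limiting by construction; the
  label is stored per point for recovery tests. Defaults (8×8×2×4 grid)
  keep a full sweep in seconds.

What the generator does *not* emulate: ocean circulation, temperature
kinetics of uptake, co-limitation continua, or realistic covariance
between nutrients — so passing the recovery tests demonstrates that the
pipeline's limitation diagnosis is faithful to its inputs, not that those
inputs resemble any particular ocean state.

## Design choices where the design was open

* The projection algorithm is support-function refinement, chosen over
  multi-objective vertex enumeration because it is exact for polytopes,
  terminates at an explicit tolerance, and is directly checkable against
  per-direction LPs.
* Growth canonicalisation is parsimonious (minimum total absolute flux);
  plain FBA optima are degenerate and irreproducible across solvers.
* The resource-constraint orientation maps small slack to high constraint
  (100 % = limiting); the un-inverted normalisation of the slack itself is
  recoverable as `100 − RC` given the stored statistics.
* H-representation is the default for per-point LPs (V-representation is
  stored and usable); for small p the facet count stays modest and the
  H-form LP is the natural formulation.

## Known limitations

* p > 6 projections are refused; facet counts grow combinatorially.
* The DOC intensity is an upper envelope (independent maxima), not a
  simultaneous-secretion optimum.
* Ensemble statistics (RC, storage index) are only comparable across runs
  that declared the same ensemble scope.
* NetCDF input support rides on xarray's scipy backend (NetCDF3); the CSV
  path is the first-class, tested format.
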