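# metaniche

Constraint-based metabolic models predict how fast an organism can grow in
a given chemical environment, but a genome-scale flux balance problem is
too heavy to solve at every grid point of a global ocean model. `metaniche`
implements the *metabolic niche* shortcut used to couple genome-scale
models (GSMs) of marine phytoplankton to gridded biogeochemical forcing:
the feasible flux polytope

```
F = { v ∈ R^m : S v = 0,  lb ≤ v ≤ ub }
```

is projected **once** onto the handful of environmentally relevant
reactions — nutrient uptake exchanges, the carbon-fixation reaction, and
the biomass reaction — producing a small polytope *N* (the niche). Growth
at each environment then reduces to a p-dimensional linear program

```
max x_bio   s.t.   x ∈ N,   0 ≤ x_env ≤ x_env^b
```

where `x_env^b` is the per-grid-point nutrient *bioavailability* (an upper
limit on uptake, not a prescribed uptake). Because the projection is exact,
this reproduces the direct genome-scale FBA optimum to solver precision at
a tiny fraction of the cost.

On top of growth extraction the package derives the physiology and carbon
diagnostics used to interpret such couplings:

* **bi-level auxiliary fluxes** — the range of any reaction with growth
  pinned at its environmental maximum (flux variability at the optimum);
* **nutrient slacks and resource constraints** — `d_n` is the bioavailable
  amount of nutrient *n* not needed for maximal growth; min–max normalised
  and inverted over an ensemble of environments,
  `RC_n = (max d_n − d_n)/(max d_n − min d_n) × 100`, so 100 % marks a
  nutrient that limits growth outright;
* **variable biomass composition** — carbon-equivalent component ratios
  `c_M (x_M + a_M x_bio)/x_bio`;
* **glycogen storage index** — the normalised fraction of fixed carbon
  routed to glycogen, splitting environments into storage vs consumption
  regimes at the ensemble mean;
* **DOC hot spots** — carbon-scaled maximal secretion of candidate
  dissolved-organic-carbon metabolites, aggregated into an
  abundance-weighted intensity and a diversity count (metabolites above
  5 % of the top producer).

It ships synthetic generators (Liebig quota-chain toy models with
closed-form optima, random feasible networks, and environment grids with
designed limitation regions) so the whole pipeline is testable without any
external model or ocean output, plus readers for SBML-FBC models (via
cobrapy) and CSV environment tables.

## Worked example

```python
from metaniche import *

model = make_quota_chain_model(toy1_spec())       # N + 0.2 P + 5 C -> biomass
niche = project_niche(model, ["EX_N", "EX_P", "CFIX", "BIO"])
print(niche.provenance["affine_rank"])            # 2

env = {"EX_N": 2.0, "EX_P": 0.2, "CFIX": 12.0}    # bioavailability (mmol/gDW/h)
res = max_biomass_on_niche(niche, env)
print(res.growth)                                 # 1.000000
print(res.realized_uptake)                        # {'EX_N': 1.0, 'EX_P': 0.2, 'CFIX': 5.0}

print(nutrient_slack(model, env, niche=niche))    # {'EX_N': 1.0, 'EX_P': 0.0, 'CFIX': 7.0}
print(auxiliary_flux_range(model, env, "EX_GLY", niche=niche))  # (0.0, 1.0)
print(doc_metabolite_fluxes(model, env, ["GLY"], niche=niche))  # {'GLY': 7.0}
```

The niche of this toy has affine rank 2: stoichiometry forces
`EX_N = x_bio` and `EX_P = 0.2 x_bio`, so those coordinates are stored as
equality constraints of the projection. Growth is the Liebig minimum
min(2/1, 0.2/0.2, 12/5) = 1.0 h⁻¹; phosphorus is limiting (slack 0), and
the 7 units of surplus fixed carbon can all be diverted to glycogen
(7 carbon atoms per unit, hence a maximal secretion flux of 1.0 and a DOC
carbon flux of 7.0 mmol C gDW⁻¹ h⁻¹).

The same pipeline runs over gridded environments from the command line:

```
metaniche gen-synthetic --preset toy1 --seed 7 --out data/
metaniche run-grid --model data/toy1.json --env data/environment.csv \
    --map data/nutrient_map.csv --doc-list data/doc_candidates.csv \
    --thermal-min 10 --out data/run/
```

which writes one results row per grid point (growth, uptakes, slacks,
resource constraints, storage index, DOC intensity/diversity, thermal
mask). See `docs/methods.md` for the algorithms and their assumptions.

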