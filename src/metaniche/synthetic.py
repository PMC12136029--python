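"""Synthetic models and environments with known ground truth.

Two generators make every pipeline stage testable without external data:

* *quota-chain* toy models whose FBA optimum has a closed Liebig form —
  growth is the minimum over nutrients of bioavailability divided by the
  biomass stoichiometric coefficient, and over carbon of fixed carbon
  divided by the carbon cost of one biomass unit (including carbon sunk
  into storage components that participate in biomass);
* gridded environments with smooth latitudinal gradients, exponential
  light (carbon-fixation) decay with depth, seasonal modulation, noise,
  and designed nutrient-starvation boxes whose ground-truth limitation
  labels feed parameter-recovery tests.

Random feasible networks (acyclic uptake-to-biomass chains with random
side reactions) fuzz the projection and LP oracles; the chain construction
guarantees a strictly positive growth optimum at unit bioavailability and,
because every reaction is irreversible with finite bounds, a bounded flux
polytope without loop-removal machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coupling import EnvironmentGrid, EnvironmentPoint
from .model import BIG, MetabolicModel

DEFAULT_UPTAKE_CAP = 20.0  # transporter-capacity ceiling on uptakes, mmol/gDW/h


class SyntheticSpecError(ValueError):
    """A generator specification violates its invariants."""


@dataclass(frozen=True)
class StorageComponent:
    """A storage/secretion metabolite of a quota-chain model."""

    name: str
    carbon_atoms: float          # carbon per unit (scales secretions to C units)
    carbon_cost: float           # internal carbon consumed to make one unit
    biomass_coefficient: float = 0.0  # draw per unit biomass (0: not in biomass)


@dataclass(frozen=True)
class QuotaChainSpec:
    """Specification of a Liebig quota-chain toy model.

    ``nutrients`` lists (name, biomass stoichiometric coefficient) pairs;
    ``carbon_per_biomass`` is the direct carbon draw of one biomass unit.
    Uptake exchanges are capped at ``uptake_cap`` (transporter capacity).
    """

    nutrients: tuple = (("N", 1.0), ("P", 0.2))
    carbon_per_biomass: float = 5.0
    storage: tuple = (StorageComponent("GLY", 7.0, 7.0, 0.0),)
    uptake_cap: float = DEFAULT_UPTAKE_CAP
    name: str = "quota-chain"
    seed: int = 0


def toy1_spec() -> QuotaChainSpec:
    """TOY1: two nutrients (N coeff 1, P coeff 0.2), 5 C per biomass,
    glycogen storage (7 C per unit, not in biomass)."""
    return QuotaChainSpec(name="TOY1")


def make_quota_chain_model(spec: QuotaChainSpec) -> MetabolicModel:
    """Build the quota-chain model for ``spec``.

    Network: one uptake exchange per nutrient, a carbon-fixation source
    CFIX, one synthesis + one secretion reaction per storage component, and
    a biomass reaction drawing the nutrients, carbon and any
    biomass-participating storage components.
    """
    for name, coeff in spec.nutrients:
        if coeff <= 0:
            raise SyntheticSpecError(f"nutrient {name!r} has non-positive coefficient {coeff}")
    if spec.carbon_per_biomass <= 0:
        raise SyntheticSpecError("carbon_per_biomass must be positive")
    for comp in spec.storage:
        if comp.carbon_cost <= 0:
            raise SyntheticSpecError(f"storage {comp.name!r} has non-positive carbon cost")

    mets = [n for n, _ in spec.nutrients] + ["C"] + [c.name for c in spec.storage]
    met_index = {m: i for i, m in enumerate(mets)}
    rxns: list[str] = []
    cols: list[np.ndarray] = []
    lb: list[float] = []
    ub: list[float] = []
    exchanges: dict[str, str] = {}

    def add(rid, stoich, lo, hi, orientation=None):
        col = np.zeros(len(mets))
        for m, coeff in stoich.items():
            col[met_index[m]] = coeff
        rxns.append(rid)
        cols.append(col)
        lb.append(lo)
        ub.append(hi)
        if orientation:
            exchanges[rid] = orientation

    for name, _ in spec.nutrients:
        add(f"EX_{name}", {name: 1.0}, 0.0, spec.uptake_cap, "uptake")
    add("CFIX", {"C": 1.0}, 0.0, spec.uptake_cap, "uptake")
    for comp in spec.storage:
        add(f"SYN_{comp.name}", {"C": -comp.carbon_cost, comp.name: 1.0}, 0.0, BIG)
        add(f"EX_{comp.name}", {comp.name: -1.0}, 0.0, BIG, "secretion")
    bio_stoich = {n: -coeff for n, coeff in spec.nutrients}
    bio_stoich["C"] = -spec.carbon_per_biomass
    for comp in spec.storage:
        if comp.biomass_coefficient:
            bio_stoich[comp.name] = bio_stoich.get(comp.name, 0.0) - comp.biomass_coefficient
    add("BIO", bio_stoich, 0.0, BIG)

    model = MetabolicModel(
        name=spec.name,
        metabolite_ids=mets,
        reaction_ids=rxns,
        S=np.column_stack(cols),
        lb=np.array(lb),
        ub=np.array(ub),
        biomass_reaction="BIO",
        exchanges=exchanges,
        carbon_fixation_reaction="CFIX",
        carbon_coefficient={"C": 1.0, **{c.name: c.carbon_atoms for c in spec.storage}},
        biomass_coefficient={
            **{n: coeff for n, coeff in spec.nutrients},
            "C": spec.carbon_per_biomass,
            **{c.name: c.biomass_coefficient for c in spec.storage},
        },
    )
    model.validate()
    return model


def analytic_quota_growth(spec: QuotaChainSpec, bioavailability: dict[str, float]) -> float:
    """Closed-form Liebig optimum of the quota-chain model.

    ``bioavailability`` is keyed by exchange reaction id (``EX_<nutrient>``
    and ``CFIX``).  Growth is the minimum over nutrients of
    ``min(x_b, cap) / a_n`` and ``min(x_b_C, cap) / c_eff`` where ``c_eff``
    folds the carbon cost of biomass-participating storage components into
    the direct carbon draw.
    """
    branches = []
    for name, coeff in spec.nutrients:
        xb = min(float(bioavailability.get(f"EX_{name}", 0.0)), spec.uptake_cap)
        branches.append(xb / coeff)
    c_eff = spec.carbon_per_biomass + sum(
        comp.biomass_coefficient * comp.carbon_cost for comp in spec.storage
    )
    xc = min(float(bioavailability.get("CFIX", 0.0)), spec.uptake_cap)
    branches.append(xc / c_eff)
    return float(min(branches))


# ---------------------------------------------------------------------------
# random feasible networks for fuzzing


def make_random_feasible_model(n_mets: int, n_rxns: int, seed: int) -> MetabolicModel:
    """Random acyclic network with a guaranteed positive growth optimum.

    Construction: metabolite M0 has an uptake exchange and is consumed by
    the biomass reaction (coefficient 1), so unit bioavailability always
    sustains growth.  The remaining reaction budget is spent on extra
    uptakes, 1:1 conversions that only flow from lower to higher metabolite
    index (acyclicity), secretion exchanges, and extra biomass draws on
    producible metabolites with small coefficients.
    """
    if n_mets < 2 or n_rxns < n_mets:
        raise SyntheticSpecError("need n_rxns >= n_mets >= 2")
    rng = np.random.default_rng(seed)
    mets = [f"M{i}" for i in range(n_mets)]
    cols: list[np.ndarray] = []
    rxns: list[str] = []
    lb: list[float] = []
    ub: list[float] = []
    exchanges: dict[str, str] = {}

    def add(rid, stoich, lo, hi, orientation=None):
        col = np.zeros(n_mets)
        for i, coeff in stoich.items():
            col[i] = coeff
        rxns.append(rid)
        cols.append(col)
        lb.append(lo)
        ub.append(hi)
        if orientation:
            exchanges[rid] = orientation

    add("EX_M0", {0: 1.0}, 0.0, 10.0, "uptake")
    producible = {0}
    budget = n_rxns - 2  # minus EX_M0 and BIO
    for k in range(budget):
        kind = rng.choice(["uptake", "convert", "secrete"], p=[0.3, 0.55, 0.15])
        if kind == "uptake":
            i = int(rng.integers(0, n_mets))
            add(f"EX_M{i}_u{k}", {i: 1.0}, 0.0, 10.0, "uptake")
            producible.add(i)
        elif kind == "convert" and n_mets >= 2:
            src_pool = sorted(producible & set(range(n_mets - 1))) or [0]
            i = int(rng.choice(src_pool))
            j = int(rng.integers(i + 1, n_mets))
            add(f"CNV_{i}_{j}_{k}", {i: -1.0, j: 1.0}, 0.0, 10.0)
            producible.add(j)
        else:
            i = int(rng.choice(sorted(producible)))
            add(f"SEC_M{i}_{k}", {i: -1.0}, 0.0, 10.0, "secretion")

    bio = {0: -1.0}
    extras = [i for i in sorted(producible) if i != 0]
    for i in extras[: int(rng.integers(0, min(3, len(extras)) + 1))]:
        bio[i] = -float(np.round(rng.uniform(0.05, 0.5), 3))
    add("BIO", bio, 0.0, BIG)

    model = MetabolicModel(
        name=f"random-{n_mets}x{n_rxns}-s{seed}",
        metabolite_ids=mets,
        reaction_ids=rxns,
        S=np.column_stack(cols),
        lb=np.array(lb),
        ub=np.array(ub),
        biomass_reaction="BIO",
        exchanges=exchanges,
        carbon_coefficient={},
        biomass_coefficient={mets[i]: -c for i, c in bio.items()},
    )
    model.validate()
    return model


def uptake_exchange_ids(model: MetabolicModel) -> list[str]:
    """Uptake-oriented exchanges, in reaction order."""
    return [r for r in model.reaction_ids if model.exchanges.get(r) == "uptake"]


# ---------------------------------------------------------------------------
# synthetic environment grids


@dataclass(frozen=True)
class LimitationBox:
    """Region where one nutrient is forced to be growth-limiting."""

    nutrient: str
    lat_range: tuple[float, float]
    lon_range: tuple[float, float]
    factor: float = 0.3  # designed quota ratio relative to the next-scarcest resource

    def contains(self, lat: float, lon: float) -> bool:
        return (
            self.lat_range[0] <= lat <= self.lat_range[1]
            and self.lon_range[0] <= lon <= self.lon_range[1]
        )


@dataclass(frozen=True)
class SyntheticGridSpec:
    """Parameters of the synthetic environment generator.

    Field construction mimics the gridded forcing an ocean biogeochemistry
    model provides: per-nutrient bioavailable uptake fluxes with smooth
    latitudinal gradients, photosynthetic carbon fixation decaying
    exponentially with depth and modulated seasonally, a temperature field
    warm at the equator and cold at the poles, and an organism abundance
    field.  Units follow the metabolic models (mmol gDW^-1 h^-1); defaults
    are sized so that the quota-chain caps never bind outside designed
    regions.
    """

    nlat: int = 8
    nlon: int = 8
    ndepth: int = 2
    nmonth: int = 4
    nutrient_base: tuple = (("N", 2.0), ("P", 0.5))
    stoichiometry: tuple = (("N", 1.0), ("P", 0.2))  # biomass coefficients a_n
    carbon_per_biomass: float = 5.0
    carbon_surface: float = 12.0
    efold_depth_m: float = 60.0
    depth_step_m: float = 40.0
    seasonal_amplitude: float = 0.3
    gradient_amplitude: float = 0.5
    noise_sd: float = 0.05
    temp_equator: float = 28.0
    temp_pole: float = -1.0
    temp_seasonal: float = 3.0
    abundance_base: float = 1.0
    limitation_boxes: tuple = ()
    seed: int = 0


def make_environment_grid(spec: SyntheticGridSpec) -> EnvironmentGrid:
    """Generate the gridded environment described by ``spec``.

    Deterministic for a fixed seed.  Inside each limitation box the named
    nutrient is rescaled so that its quota ratio (bioavailability divided
    by biomass coefficient) is ``factor`` times the smallest competing
    ratio, making it strictly growth-limiting by construction; the designed
    label is stored per point for recovery tests.  Two boxes naming
    different nutrients may not overlap.
    """
    names = [n for n, _ in spec.nutrient_base]
    stoich = dict(spec.stoichiometry)
    missing = [n for n in names if n not in stoich]
    if missing:
        raise SyntheticSpecError(f"stoichiometry missing nutrients {missing}")
    for i, a in enumerate(spec.limitation_boxes):
        for b in spec.limitation_boxes[i + 1 :]:
            if a.nutrient != b.nutrient and _boxes_overlap(a, b):
                raise SyntheticSpecError(
                    f"limitation boxes for {a.nutrient!r} and {b.nutrient!r} overlap"
                )

    rng = np.random.default_rng(spec.seed)
    lats = np.linspace(-60.0, 60.0, spec.nlat)
    lons = np.linspace(-180.0, 180.0, spec.nlon, endpoint=False)
    depths = 5.0 + spec.depth_step_m * np.arange(spec.ndepth)
    months = 1 + (12 // spec.nmonth) * np.arange(spec.nmonth)

    points: list[EnvironmentPoint] = []
    env_id = 0
    for month in months:
        season = np.sin(2.0 * np.pi * (month - 1) / 12.0)
        for depth in depths:
            light_decay = float(np.exp(-depth / spec.efold_depth_m))
            for lat in lats:
                lat_factor = 1.0 + spec.gradient_amplitude * np.cos(np.deg2rad(lat))
                hemis = np.sign(lat) if lat != 0 else 1.0
                seasonal = 1.0 + spec.seasonal_amplitude * season * hemis
                for lon in lons:
                    lon_factor = 1.0 + 0.1 * np.sin(np.deg2rad(lon))
                    nutrients = {}
                    for name, base in spec.nutrient_base:
                        noise = rng.normal(0.0, spec.noise_sd)
                        val = base * lat_factor * seasonal * lon_factor * (1.0 + noise)
                        nutrients[name] = max(val, 1e-3)
                    cfix = max(
                        spec.carbon_surface * light_decay * max(seasonal, 0.1)
                        * (1.0 + rng.normal(0.0, spec.noise_sd)),
                        1e-3,
                    )
                    designed = None
                    for box in spec.limitation_boxes:
                        if box.contains(lat, lon):
                            ratios = [
                                nutrients[n] / stoich[n] for n in names if n != box.nutrient
                            ]
                            ratios.append(cfix / spec.carbon_per_biomass)
                            nutrients[box.nutrient] = max(
                                box.factor * stoich[box.nutrient] * min(ratios), 1e-6
                            )
                            designed = box.nutrient
                            break
                    temp = (
                        spec.temp_pole
                        + (spec.temp_equator - spec.temp_pole)
                        * float(np.cos(np.deg2rad(lat)) ** 2)
                        - 0.02 * depth
                        + spec.temp_seasonal * season * hemis
                    )
                    abundance = spec.abundance_base * light_decay * lat_factor
                    points.append(
                        EnvironmentPoint(
                            env_id=env_id,
                            lat=float(lat),
                            lon=float(lon),
                            depth=float(depth),
                            month=int(month),
                            temperature=float(temp),
                            abundance=float(abundance),
                            nutrients={k: float(v) for k, v in nutrients.items()},
                            carbon_fixed=float(cfix),
                            designed_limiting=designed,
                        )
                    )
                    env_id += 1
    return EnvironmentGrid(points=points, nutrient_columns=names)


def _boxes_overlap(a: LimitationBox, b: LimitationBox) -> bool:
    return not (
        a.lat_range[1] < b.lat_range[0]
        or b.lat_range[1] < a.lat_range[0]
        or a.lon_range[1] < b.lon_range[0]
        or b.lon_range[1] < a.lon_range[0]
    )
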