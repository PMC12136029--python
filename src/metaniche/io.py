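"""Readers and writers: SBML-FBC (via cobrapy), the toy-model JSON dialect,
niche JSON, environment CSV (optional NetCDF through xarray), DOC candidate
and nutrient-mapping CSVs, and the results table."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .coupling import EnvironmentGrid, EnvironmentPoint
from .model import BIG, MetabolicModel, orient_exchanges_uptake_positive
from .niche import NicheProjection

logger = logging.getLogger(__name__)

TOY_SCHEMA_VERSION = "1"
ENV_BASE_COLUMNS = ["lat", "lon", "depth", "month", "temperature", "abundance"]


class FormatError(ValueError):
    """A file does not conform to the expected schema."""


# ---------------------------------------------------------------------------
# toy-model JSON dialect


def write_toy_model(model: MetabolicModel, path) -> None:
    """Serialise a model to the toy JSON dialect (round-trip safe)."""
    mets = []
    for mid in model.metabolite_ids:
        mets.append(
            {
                "id": mid,
                "carbon_atoms": model.carbon_coefficient.get(mid),
                "biomass_coefficient": model.biomass_coefficient.get(mid, 0.0),
            }
        )
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        col = model.S[:, j]
        stoich = {
            model.metabolite_ids[i]: float(col[i]) for i in np.flatnonzero(col)
        }
        entry = {
            "id": rid,
            "stoichiometry": stoich,
            "lb": float(model.lb[j]),
            "ub": float(model.ub[j]),
            "is_exchange": rid in model.exchanges,
            "is_biomass": rid == model.biomass_reaction,
            "is_carbon_fixation": rid == model.carbon_fixation_reaction,
        }
        if rid in model.exchanges:
            entry["orientation"] = model.exchanges[rid]
        rxns.append(entry)
    doc = {
        "metabolites": mets,
        "reactions": rxns,
        "metadata": {
            "name": model.name,
            "version": TOY_SCHEMA_VERSION,
            "orientation": "uptake-positive",
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_toy_model(path) -> MetabolicModel:
    doc = json.loads(Path(path).read_text())
    try:
        mets = doc["metabolites"]
        rxns = doc["reactions"]
        meta = doc["metadata"]
    except KeyError as exc:
        raise FormatError(f"toy model file missing section {exc}") from None
    met_ids = [m["id"] for m in mets]
    met_index = {m: i for i, m in enumerate(met_ids)}
    biomass = [r["id"] for r in rxns if r.get("is_biomass")]
    if len(biomass) != 1:
        raise FormatError(f"toy model must have exactly one biomass reaction, found {len(biomass)}")
    cfix = [r["id"] for r in rxns if r.get("is_carbon_fixation")]
    S = np.zeros((len(met_ids), len(rxns)))
    lb = np.zeros(len(rxns))
    ub = np.zeros(len(rxns))
    exchanges = {}
    rids = []
    for j, r in enumerate(rxns):
        rids.append(r["id"])
        for mid, coeff in r["stoichiometry"].items():
            S[met_index[mid], j] = coeff
        lb[j], ub[j] = float(r["lb"]), float(r["ub"])
        if r.get("is_exchange"):
            exchanges[r["id"]] = r.get("orientation", "uptake")
    model = MetabolicModel(
        name=meta.get("name", Path(path).stem),
        metabolite_ids=met_ids,
        reaction_ids=rids,
        S=S,
        lb=lb,
        ub=ub,
        biomass_reaction=biomass[0],
        exchanges=exchanges,
        carbon_fixation_reaction=cfix[0] if cfix else None,
        carbon_coefficient={
            m["id"]: float(m["carbon_atoms"])
            for m in mets
            if m.get("carbon_atoms") is not None
        },
        biomass_coefficient={
            m["id"]: float(m.get("biomass_coefficient", 0.0)) for m in mets
        },
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# niche JSON


def write_niche(niche: NicheProjection, path) -> None:
    doc = {
        "reactions_of_interest": niche.reactions_of_interest,
        "vertices": np.asarray(niche.vertices).tolist(),
        "halfspaces": [
            {"normal": n.tolist(), "offset": float(o)} for n, o in niche.halfspaces
        ],
        "equalities": [
            {"normal": n.tolist(), "offset": float(o)} for n, o in niche.equalities
        ],
        "tolerance": niche.tolerance,
        "scale": niche.scale,
        "provenance": niche.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_niche(path) -> NicheProjection:
    doc = json.loads(Path(path).read_text())
    return NicheProjection(
        reactions_of_interest=list(doc["reactions_of_interest"]),
        vertices=np.asarray(doc["vertices"], dtype=float),
        halfspaces=[
            (np.asarray(h["normal"], dtype=float), float(h["offset"]))
            for h in doc["halfspaces"]
        ],
        equalities=[
            (np.asarray(h["normal"], dtype=float), float(h["offset"]))
            for h in doc.get("equalities", [])
        ],
        tolerance=float(doc["tolerance"]),
        scale=float(doc.get("scale", 1.0)),
        provenance=dict(doc.get("provenance", {})),
    )


# ---------------------------------------------------------------------------
# environment tables


def write_environment_csv(grid: EnvironmentGrid, path) -> None:
    rows = []
    has_truth = any(p.designed_limiting is not None for p in grid.points)
    for p in grid.points:
        row = {
            "env_id": p.env_id,
            "lat": p.lat,
            "lon": p.lon,
            "depth": p.depth,
            "month": p.month,
            "temperature": p.temperature,
            "abundance": p.abundance,
        }
        for n in grid.nutrient_columns:
            row[n] = p.nutrients[n]
        row["carbon_fixed"] = p.carbon_fixed
        if has_truth:
            row["designed_limiting"] = p.designed_limiting or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_environment_csv(path) -> EnvironmentGrid:
    df = pd.read_csv(path)
    required = set(ENV_BASE_COLUMNS) | {"carbon_fixed"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"environment CSV missing columns {sorted(missing)}")
    special = required | {"env_id", "designed_limiting"}
    nutrient_cols = [c for c in df.columns if c not in special]
    points = []
    for i, row in df.iterrows():
        designed = None
        if "designed_limiting" in df.columns:
            val = row["designed_limiting"]
            designed = None if (pd.isna(val) or val == "") else str(val)
        points.append(
            EnvironmentPoint(
                env_id=int(row["env_id"]) if "env_id" in df.columns else int(i),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                depth=float(row["depth"]),
                month=int(row["month"]),
                temperature=float(row["temperature"]),
                abundance=float(row["abundance"]),
                nutrients={n: float(row[n]) for n in nutrient_cols},
                carbon_fixed=float(row["carbon_fixed"]),
                designed_limiting=designed,
            )
        )
    grid = EnvironmentGrid(points=points, nutrient_columns=nutrient_cols)
    grid.validate()
    return grid


def read_environment_netcdf(path) -> EnvironmentGrid:
    """Read an environment grid from NetCDF (same variable names as the CSV)."""
    import xarray as xr  # optional dependency

    ds = xr.open_dataset(path)
    df = ds.to_dataframe().reset_index()
    tmp = Path(str(path) + ".csv")
    df.to_csv(tmp, index=False)
    try:
        return read_environment_csv(tmp)
    finally:
        tmp.unlink(missing_ok=True)


def read_nutrient_map(path) -> dict[str, str]:
    """CSV with columns ``column,reaction`` mapping grid columns to exchanges."""
    df = pd.read_csv(path)
    if not {"column", "reaction"} <= set(df.columns):
        raise FormatError("nutrient map CSV needs columns 'column' and 'reaction'")
    return dict(zip(df["column"].astype(str), df["reaction"].astype(str)))


def write_nutrient_map(mapping: dict[str, str], path) -> None:
    pd.DataFrame(
        {"column": list(mapping), "reaction": [mapping[k] for k in mapping]}
    ).to_csv(path, index=False)


def read_doc_candidates(path) -> dict[str, float]:
    """CSV with columns ``metabolite,carbon_atoms``."""
    df = pd.read_csv(path)
    if not {"metabolite", "carbon_atoms"} <= set(df.columns):
        raise FormatError("DOC candidate CSV needs columns 'metabolite' and 'carbon_atoms'")
    return dict(zip(df["metabolite"].astype(str), df["carbon_atoms"].astype(float)))


def write_doc_candidates(candidates: dict[str, float], path) -> None:
    pd.DataFrame(
        {"metabolite": list(candidates), "carbon_atoms": list(candidates.values())}
    ).to_csv(path, index=False)


def write_results_csv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SBML via cobrapy


def to_cobra(model: MetabolicModel):
    """Build a cobrapy model (export-negative exchange convention)."""
    import cobra

    cm = cobra.Model(model.name)
    cmets = {}
    for mid in model.metabolite_ids:
        met = cobra.Metabolite(mid, compartment="c")
        c = model.carbon_coefficient.get(mid)
        if c is not None and float(c) == int(c):
            met.formula = f"C{int(c)}" if c else ""
        cmets[mid] = met
    cm.add_metabolites(list(cmets.values()))
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        cm.add_reactions([rxn])
        col = model.S[:, j]
        flip = -1.0 if model.exchanges.get(rid) == "uptake" else 1.0
        # uptake-positive columns are negated so that SBML keeps the
        # conventional export-positive exchange orientation
        rxn.add_metabolites(
            {cmets[model.metabolite_ids[i]]: flip * float(col[i]) for i in np.flatnonzero(col)}
        )
        lo, hi = float(model.lb[j]), float(model.ub[j])
        if flip < 0:
            lo, hi = -hi, -lo
        rxn.bounds = (lo, hi)
    cm.objective = model.biomass_reaction
    return cm


def write_sbml(model: MetabolicModel, path) -> None:
    import cobra

    cobra.io.write_sbml_model(to_cobra(model), str(path))


def read_sbml(
    path,
    carbon_side_table: dict[str, float] | None = None,
    carbon_fixation_reaction: str | None = None,
) -> MetabolicModel:
    """Read an SBML L3/FBC model into a :class:`MetabolicModel`.

    Exchanges are auto-detected as boundary reactions; the FBC objective
    must name exactly one reaction (the biomass).  Carbon atom counts come
    from chemical formulae when annotated; a side-table
    (metabolite -> carbon atoms) overrides them with a logged notice.  The
    returned model is oriented uptake-positive.
    """
    import cobra
    from cobra.util.array import create_stoichiometric_matrix

    cm = cobra.io.read_sbml_model(str(path))
    objective = [
        r.id for r in cm.reactions if r.objective_coefficient not in (0, 0.0)
    ]
    if len(objective) == 0:
        candidates = [r.id for r in cm.reactions if "biomass" in r.id.lower()]
        raise FormatError(
            f"SBML file has no objective reaction; candidates: {candidates or 'none found'}"
        )
    if len(objective) > 1:
        raise FormatError(f"SBML file has {len(objective)} objective reactions: {objective}")
    biomass = objective[0]

    S = create_stoichiometric_matrix(cm)
    lb = np.array([r.lower_bound for r in cm.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cm.reactions], dtype=float)
    exchanges = {}
    for r in cm.boundary:
        # cobra writes exchanges export-positive; a negative lower bound
        # means uptake is allowed, so that is the natural orientation label
        exchanges[r.id] = "uptake" if r.lower_bound < 0 else "secretion"

    carbon = {}
    for met in cm.metabolites:
        c = met.elements.get("C") if met.formula else None
        if c:
            carbon[met.id] = float(c)
    if carbon_side_table:
        for mid, c in carbon_side_table.items():
            if mid in carbon and carbon[mid] != c:
                logger.info(
                    "carbon side-table overrides formula for %r: %s -> %s", mid, carbon[mid], c
                )
            carbon[mid] = float(c)
    if not carbon:
        logger.warning(
            "no carbon formulas in %s and no side-table: DOC operations will refuse", path
        )

    biomass_rxn = cm.reactions.get_by_id(biomass)
    biomass_coeff = {
        met.id: -float(coeff)
        for met, coeff in biomass_rxn.metabolites.items()
        if coeff < 0
    }

    model = MetabolicModel(
        name=cm.id or Path(path).stem,
        metabolite_ids=[m.id for m in cm.metabolites],
        reaction_ids=[r.id for r in cm.reactions],
        S=S,
        lb=lb,
        ub=ub,
        biomass_reaction=biomass,
        exchanges=exchanges,
        carbon_fixation_reaction=_detect_cfix(cm, carbon_fixation_reaction),
        carbon_coefficient=carbon,
        biomass_coefficient=biomass_coeff,
    )
    model.validate()
    return orient_exchanges_uptake_positive(model)


def _detect_cfix(cm, explicit: str | None) -> str | None:
    if explicit is not None:
        if explicit not in [r.id for r in cm.reactions]:
            raise FormatError(f"carbon-fixation reaction {explicit!r} not in model")
        return explicit
    for cand in ("CFIX", "RUBISC_h", "RUBISC"):
        if cand in [r.id for r in cm.reactions]:
            return cand
    return None
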