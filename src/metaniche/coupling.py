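"""Offline driver: sweep an environment grid through the niche pipeline.

The niche is projected once per model and reused at every grid point (the
efficiency rationale of the whole approach — a p-dimensional LP per point
instead of a genome-scale one).  Per point the driver extracts growth and
realised uptake, per-nutrient slacks, auxiliary flux ranges and
carbon-equivalent ratios for the requested storage components, and DOC
secretion scores.  Two ensemble passes then normalise the slacks into
resource constraints and the glycogen carbon fractions into storage
indices over a declared scope (the full grid by default, or per month).

Temperature is a pass-through: the metabolism itself carries no thermal
response, so thermal limits are applied — optionally — as a post-hoc mask
on the results, keeping the values for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doc_hotspots import doc_diversity, doc_intensity, doc_metabolite_fluxes
from .model import MetabolicModel, add_secretion_exchange, secretion_exchange_id
from .niche import NicheProjection, max_biomass_on_niche, project_niche
from .physiology import (
    UndefinedRatioError,
    auxiliary_flux_range,
    component_ratio,
    glycogen_storage_index,
    nutrient_slack,
    resource_constraint,
)

logger = logging.getLogger(__name__)

#: Environment columns ignored by default: iron is carried by ocean models
#: but not usable by the metabolic models considered here.
DEFAULT_IGNORED_NUTRIENTS = frozenset({"iron", "fe"})


class ConfigurationError(ValueError):
    """The grid/model/mapping configuration is inconsistent (raised before any solve)."""


@dataclass
class EnvironmentPoint:
    """One grid point of environmental forcing."""

    env_id: int
    lat: float
    lon: float
    depth: float
    month: int
    temperature: float
    abundance: float
    nutrients: dict[str, float]   # bioavailable uptake fluxes by column name
    carbon_fixed: float           # bioavailable carbon-fixation flux
    designed_limiting: str | None = None  # synthetic ground truth, if any

    def validate(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month {self.month} outside 1..12")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.carbon_fixed < 0 or any(v < 0 for v in self.nutrients.values()):
            raise ValueError(f"negative flux at env {self.env_id}")


@dataclass
class EnvironmentGrid:
    """A collection of environment points with a consistent nutrient schema."""

    points: list[EnvironmentPoint]
    nutrient_columns: list[str]

    def validate(self) -> None:
        for pt in self.points:
            pt.validate()
            if set(pt.nutrients) != set(self.nutrient_columns):
                raise ValueError(
                    f"env {pt.env_id} nutrient schema {sorted(pt.nutrients)} "
                    f"differs from grid schema {sorted(self.nutrient_columns)}"
                )


@dataclass
class RunOptions:
    """Knobs of the offline sweep.

    ensemble_scope:
        ``"global"`` normalises resource constraints and the glycogen index
        over the whole grid across all months; ``"per_month"`` normalises
        within each month separately.
    doc_candidates:
        metabolite -> carbon atoms for the DOC scores (None disables DOC).
    storage_metabolite:
        metabolite treated as glycogen for the storage index (None disables).
    ratio_components:
        metabolites whose carbon-equivalent per-biomass ratio is reported.
    thermal_min:
        post-hoc thermal mask threshold in deg C (None disables; points at
        exactly the threshold are kept).
    carbon_bound_mode:
        ``"upper"`` treats the fixed-carbon flux like the nutrients (the
        organism may fix less); ``"equality"`` forces it.
    """

    ensemble_scope: str = "global"
    doc_candidates: dict[str, float] | None = None
    storage_metabolite: str | None = None
    ratio_components: list[str] = field(default_factory=list)
    thermal_min: float | None = None
    carbon_bound_mode: str = "upper"
    doc_threshold_fraction: float = 0.05
    ignore_nutrients: frozenset = DEFAULT_IGNORED_NUTRIENTS
    niche_tol: float = 1.0e-6


def _resolve_mapping(
    model: MetabolicModel,
    grid: EnvironmentGrid,
    nutrient_map: dict[str, str],
    options: RunOptions,
) -> dict[str, str]:
    """Column -> exchange-reaction mapping, validated before any solve."""
    resolved: dict[str, str] = {}
    for col in grid.nutrient_columns:
        if col.lower() in options.ignore_nutrients:
            logger.warning("nutrient column %r ignored (not used by model %r)", col, model.name)
            continue
        if col not in nutrient_map:
            raise ConfigurationError(f"nutrient column {col!r} has no reaction mapping")
        rid = nutrient_map[col]
        if rid not in model.reaction_ids:
            raise ConfigurationError(f"mapped reaction {rid!r} not in model {model.name!r}")
        resolved[col] = rid
    if model.carbon_fixation_reaction is None:
        raise ConfigurationError(
            f"model {model.name!r} has no carbon-fixation reaction; cannot consume carbon_fixed"
        )
    return resolved


def run_grid(
    model: MetabolicModel,
    grid: EnvironmentGrid,
    nutrient_map: dict[str, str],
    options: RunOptions | None = None,
    niche: NicheProjection | None = None,
) -> pd.DataFrame:
    """Run the full offline pipeline over ``grid`` and return a results table.

    One row per environment point, with growth, realised uptakes, slacks,
    resource constraints, storage/ratio diagnostics and DOC scores.  The
    result is deterministic given its inputs, and independent of row order
    except for the declared ensemble normalisation scope.
    """
    options = options or RunOptions()
    grid.validate()
    mapping = _resolve_mapping(model, grid, nutrient_map, options)
    cfix_rid = model.carbon_fixation_reaction

    work_model = model
    doc_items = sorted(options.doc_candidates.items()) if options.doc_candidates else []
    storage_rid = None
    if options.storage_metabolite is not None:
        work_model = add_secretion_exchange(work_model, options.storage_metabolite)
        storage_rid = secretion_exchange_id(work_model, options.storage_metabolite)
    ratio_rids = {}
    for comp in options.ratio_components:
        work_model = add_secretion_exchange(work_model, comp)
        ratio_rids[comp] = secretion_exchange_id(work_model, comp)

    if niche is None:
        roi = list(mapping.values()) + [cfix_rid, work_model.biomass_reaction]
        niche = project_niche(work_model, roi, tol=options.niche_tol)

    rows = []
    slack_by_env: dict[int, dict[str, float]] = {}
    for pt in grid.points:
        bio = {mapping[col]: pt.nutrients[col] for col in mapping}
        bio[cfix_rid] = pt.carbon_fixed
        res = max_biomass_on_niche(niche, bio, biomass_reaction=work_model.biomass_reaction)
        row: dict = {
            "env_id": pt.env_id,
            "lat": pt.lat,
            "lon": pt.lon,
            "depth": pt.depth,
            "month": pt.month,
            "temperature": pt.temperature,
            "abundance": pt.abundance,
            "growth": res.growth,
            "outside_niche": res.outside_niche,
        }
        if pt.designed_limiting is not None or any(
            p.designed_limiting is not None for p in grid.points
        ):
            row["designed_limiting"] = pt.designed_limiting or ""
        for col, rid in mapping.items():
            row[f"bioavail_{col}"] = pt.nutrients[col]
            row[f"uptake_{col}"] = res.realized_uptake.get(rid, 0.0)
        row["bioavail_carbon"] = pt.carbon_fixed
        row["uptake_carbon"] = res.realized_uptake.get(cfix_rid, 0.0)

        if res.outside_niche or res.growth <= 0:
            slacks = {rid: bio[rid] for rid in bio}  # nothing is consumed
        else:
            slacks = nutrient_slack(work_model, bio, nutrients=list(bio), growth=res.growth)
        slack_by_env[pt.env_id] = slacks
        for col, rid in mapping.items():
            row[f"slack_{col}"] = slacks[rid]
        row["slack_carbon"] = slacks[cfix_rid]

        if storage_rid is not None:
            if res.outside_niche:
                glyc_rng = (0.0, 0.0)
            else:
                glyc_rng = auxiliary_flux_range(
                    work_model, bio, storage_rid, growth=res.growth
                )
            c_glyc = work_model.carbon_coefficient.get(options.storage_metabolite, 1.0)
            row["glycogen_flux_max"] = glyc_rng[1]
            row["glycogen_carbon_flux"] = glyc_rng[1] * c_glyc

        for comp, rid in ratio_rids.items():
            if res.outside_niche:
                row[f"ratio_{comp}"] = np.nan
                continue
            rng = auxiliary_flux_range(work_model, bio, rid, growth=res.growth)
            try:
                row[f"ratio_{comp}"] = component_ratio(work_model, res.growth, rng[1], comp)
            except UndefinedRatioError:
                row[f"ratio_{comp}"] = np.nan

        if doc_items:
            if res.outside_niche:
                per_met = {m: 0.0 for m, _ in doc_items if m in work_model.metabolite_ids}
            else:
                per_met = doc_metabolite_fluxes(
                    work_model,
                    bio,
                    [m for m, _ in doc_items],
                    carbon_atoms=dict(doc_items),
                    growth=res.growth,
                )
            for met, val in sorted(per_met.items()):
                row[f"doc_{met}"] = val
            row["doc_intensity"] = doc_intensity(per_met, pt.abundance)
            row["doc_diversity"] = doc_diversity(per_met, options.doc_threshold_fraction)
        rows.append(row)

    df = pd.DataFrame(rows)

    # ensemble pass 1: resource constraints over the declared scope
    nutrient_names = {**{col: rid for col, rid in mapping.items()}, "carbon": cfix_rid}
    for scope_key, idx in _scopes(df, options.ensemble_scope):
        scoped = {int(df.loc[i, "env_id"]): slack_by_env[int(df.loc[i, "env_id"])] for i in idx}
        rc, uninformative = resource_constraint(scoped)
        for col, rid in nutrient_names.items():
            colname = f"rc_{col}"
            if colname not in df.columns:
                df[colname] = np.nan
            if rid in uninformative:
                continue
            for i in idx:
                df.loc[i, colname] = rc[int(df.loc[i, "env_id"])].get(rid, np.nan)

    # ensemble pass 2: glycogen storage index over the same scope
    if storage_rid is not None:
        df["r_stor"] = np.nan
        df["storage_index"] = np.nan
        df["regime"] = ""
        df["implied_consumption"] = np.nan
        for scope_key, idx in _scopes(df, options.ensemble_scope):
            entries = [
                (float(df.loc[i, "glycogen_carbon_flux"]), float(df.loc[i, "bioavail_carbon"]))
                for i in idx
            ]
            for i, entry in zip(idx, glycogen_storage_index(entries)):
                df.loc[i, "r_stor"] = entry.r_stor
                df.loc[i, "storage_index"] = entry.index
                df.loc[i, "regime"] = entry.regime
                df.loc[i, "implied_consumption"] = entry.implied_consumption

    if options.thermal_min is not None:
        df = thermal_mask(df, options.thermal_min)
    else:
        df["thermal_masked"] = False
    return df


def _scopes(df: pd.DataFrame, scope: str):
    if scope == "global":
        yield "global", list(df.index)
    elif scope == "per_month":
        for month, sub in df.groupby("month"):
            yield f"month-{month}", list(sub.index)
    else:
        raise ConfigurationError(f"unknown ensemble scope {scope!r}")


def thermal_mask(results: pd.DataFrame, model_thermal_min: float) -> pd.DataFrame:
    """Flag rows colder than the organism's thermal minimum.

    Rows with ``temperature < model_thermal_min`` (strictly below: a point
    at exactly the threshold stays unmasked) get ``thermal_masked=True``.
    Values are retained for inspection; downstream consumers should treat
    masked growth and diagnostics as invalid.
    """
    out = results.copy()
    if np.isneginf(model_thermal_min):
        out["thermal_masked"] = False
    else:
        out["thermal_masked"] = out["temperature"] < model_thermal_min
    return out
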