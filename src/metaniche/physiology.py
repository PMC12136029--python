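"""Physiological diagnostics derived from the niche at a fixed optimum.

All quantities here are bi-level: growth is first maximised under the
environmental bioavailability caps, then a secondary flux question is asked
with the biomass flux pinned at that maximum — what range can an auxiliary
(e.g. storage-secretion) flux span, how little of each nutrient is actually
needed, how much fixed carbon can be diverted to glycogen.  Ensemble-level
statistics (resource constraints, the glycogen storage index) normalise
those per-environment quantities across a caller-declared ensemble of
environmental conditions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .model import (
    EPS_FIX,
    InfeasibleModelError,
    MetabolicModel,
    _effective_bounds,
    _optimize_flux,
    env_bound_overrides,
)
from .niche import NicheProjection, max_biomass_on_niche

logger = logging.getLogger(__name__)


class UndefinedRatioError(ZeroDivisionError):
    """A per-biomass ratio was requested at zero growth."""


class DegenerateEnsembleError(ValueError):
    """An ensemble statistic was requested on a constant distribution."""


def _max_growth(
    model: MetabolicModel,
    bioavailability: dict[str, float],
    niche: NicheProjection | None,
) -> float:
    """Maximal growth under the bioavailability caps.

    Uses the projected niche when one is supplied (the production path);
    otherwise answers with a direct full-model LP.  Returns 0.0 for an
    infeasible (outside-niche) condition.
    """
    if niche is not None:
        return max_biomass_on_niche(niche, _restrict_to(niche, bioavailability)).growth
    try:
        overrides = env_bound_overrides(model, bioavailability)
        lb, ub = _effective_bounds(model, overrides)
        growth, _ = _optimize_flux(model, model.biomass_reaction, "max", lb, ub)
        return growth
    except InfeasibleModelError:
        return 0.0


def _restrict_to(niche: NicheProjection, bioavailability: dict[str, float]) -> dict[str, float]:
    return {k: v for k, v in bioavailability.items() if k in niche.reactions_of_interest}


def auxiliary_flux_range(
    model: MetabolicModel,
    bioavailability: dict[str, float],
    aux_reaction: str,
    niche: NicheProjection | None = None,
    growth: float | None = None,
) -> tuple[float, float]:
    """Flux range of ``aux_reaction`` with biomass pinned at its maximum.

    Two-step bi-level procedure: (1) maximal growth under the environment
    (solved on the projected niche when supplied); (2) the auxiliary flux is
    minimised and maximised with the biomass flux held at that optimum.
    Auxiliary reactions are handled one at a time, independently, so each
    range is an envelope that ignores competition between secreted products.
    An outside-niche condition returns the empty-range convention (0, 0).
    """
    if growth is None:
        growth = _max_growth(model, bioavailability, niche)
        if niche is not None and max_biomass_on_niche(
            niche, _restrict_to(niche, bioavailability)
        ).outside_niche:
            return (0.0, 0.0)
    overrides = env_bound_overrides(model, bioavailability)
    lb, ub = _effective_bounds(model, overrides)
    jb = model.reaction_index(model.biomass_reaction)
    eps = EPS_FIX * max(1.0, abs(growth))
    lb[jb] = max(lb[jb], growth - eps)
    ub[jb] = min(ub[jb], growth + eps)
    try:
        lo, _ = _optimize_flux(model, aux_reaction, "min", lb, ub)
        hi, _ = _optimize_flux(model, aux_reaction, "max", lb, ub)
    except InfeasibleModelError:
        return (0.0, 0.0)
    return min(lo, hi), max(lo, hi)


def component_ratio(
    model: MetabolicModel,
    growth: float,
    component_flux: float,
    component: str,
) -> float:
    """Carbon-equivalent content of a biomass component per unit growth.

    The total production of metabolite M is its excess (exchange) flux plus
    the fixed draw of the biomass reaction, ``x_M + a_M * x_bio``; dividing
    by growth and scaling by the carbon atom count ``c_M`` gives
    ``c_M * (x_M + a_M * x_bio) / x_bio``, mol C per unit biomass flux.
    Undefined at zero growth (raises rather than returning infinity).
    """
    if growth <= 0:
        raise UndefinedRatioError(f"component ratio for {component!r} undefined at growth 0")
    c = model.carbon_coefficient.get(component)
    if c is None:
        raise KeyError(f"no carbon coefficient recorded for metabolite {component!r}")
    a = model.biomass_coefficient.get(component, 0.0)
    return c * (component_flux + a * growth) / growth


def nutrient_slack(
    model: MetabolicModel,
    bioavailability: dict[str, float],
    nutrients: list[str] | None = None,
    niche: NicheProjection | None = None,
    growth: float | None = None,
) -> dict[str, float]:
    """Per-nutrient divertible surplus d_n at maximal growth.

    For each nutrient n, ``d_n = x_env^b,n - min_uptake_n`` where the
    minimum uptake is taken over all flux states sustaining the maximal
    growth (one LP per nutrient).  d_n is the amount of bioavailable
    nutrient the organism can spend on anything other than growth; d_n = 0
    marks n as growth-limiting.
    """
    if nutrients is None:
        nutrients = list(bioavailability)
    if growth is None:
        growth = _max_growth(model, bioavailability, niche)
    overrides = env_bound_overrides(model, bioavailability)
    lb0, ub0 = _effective_bounds(model, overrides)
    jb = model.reaction_index(model.biomass_reaction)
    eps = EPS_FIX * max(1.0, abs(growth))
    slacks: dict[str, float] = {}
    for rid in nutrients:
        lb, ub = lb0.copy(), ub0.copy()
        lb[jb] = max(lb[jb], growth - eps)
        ub[jb] = min(ub[jb], growth + eps)
        min_uptake, _ = _optimize_flux(model, rid, "min", lb, ub)
        slacks[rid] = max(0.0, float(bioavailability[rid]) - min_uptake)
    return slacks


def resource_constraint(
    ensemble_slacks: dict,
) -> tuple[dict, set]:
    """Resource constraints RC_n in percent from an ensemble of slacks.

    ``ensemble_slacks`` maps environment id -> {nutrient -> d_n}.  Each
    nutrient's slack distribution is min-max normalised across the ensemble
    and inverted so that the smallest slack (hardest limitation) maps to
    100 % and the largest to 0 %::

        RC_n(env) = (max_E d_n - d_n(env)) / (max_E d_n - min_E d_n) * 100

    A nutrient whose slack is constant across the ensemble carries no
    limitation signal; it is returned in the ``uninformative`` set and no RC
    is emitted for it.
    """
    if not ensemble_slacks:
        return {}, set()
    env_ids = list(ensemble_slacks)
    nutrients = list(ensemble_slacks[env_ids[0]])
    stats: dict[str, tuple[float, float]] = {}
    uninformative: set[str] = set()
    for n in nutrients:
        vals = np.array([ensemble_slacks[e][n] for e in env_ids], dtype=float)
        lo, hi = float(vals.min()), float(vals.max())
        if hi - lo <= 1e-12 * max(1.0, hi):
            uninformative.add(n)
            logger.warning("slack of %r constant across ensemble; RC uninformative", n)
        else:
            stats[n] = (lo, hi)
    rc = {
        e: {
            n: (stats[n][1] - ensemble_slacks[e][n]) / (stats[n][1] - stats[n][0]) * 100.0
            for n in nutrients
            if n not in uninformative
        }
        for e in env_ids
    }
    return rc, uninformative


@dataclass
class StorageIndexEntry:
    """Glycogen storage diagnostics for one environmental condition."""

    r_stor: float           # carbon to glycogen / carbon fixed (dimensionless)
    index: float            # min-max normalised r_stor over the ensemble
    regime: str             # "storage" | "consumption"
    implied_consumption: float  # carbon-flux shortfall vs the mean-index production


def glycogen_storage_index(
    ensemble_results: list[tuple[float, float]],
) -> list[StorageIndexEntry]:
    """Glycogen storage index over an ensemble of conditions.

    Input entries are ``(glycogen_production_carbonflux, carbon_fixed)``
    with both in carbon-flux units.  For each entry
    ``r_stor = glycogen / carbon_fixed`` — the fraction of fixed carbon
    routed to glycogen.  The index is the min-max normalisation of r_stor
    over the ensemble.  Entries at or above the ensemble mean index are in
    the *storage* regime; entries below it are read as *consumption*: the
    organism is presumed to draw down glycogen stock to sustain growth, and
    the implied consumption flux is the gap between the production
    corresponding to the mean index and the actual production,
    ``v~ = v_bar - v`` with ``v_bar = r_bar * carbon_fixed``.

    A degenerate ensemble (all r_stor equal) yields index 0 and the storage
    regime everywhere, with zero implied consumption.
    """
    rs = []
    for glyc, cfix in ensemble_results:
        if cfix <= 0:
            if abs(glyc) > 0:
                raise ValueError(
                    f"glycogen production {glyc} with carbon_fixed {cfix} is inconsistent"
                )
            rs.append(0.0)
        else:
            rs.append(glyc / cfix)
    rs = np.array(rs, dtype=float)
    lo, hi = float(rs.min()), float(rs.max())
    if hi - lo <= 1e-15 * max(1.0, abs(hi)):
        indices = np.zeros_like(rs)
        r_bar = lo
    else:
        indices = (rs - lo) / (hi - lo)
        r_bar = lo + float(indices.mean()) * (hi - lo)
    mean_idx = float(indices.mean())
    out = []
    for (glyc, cfix), r, ix in zip(ensemble_results, rs, indices):
        storage = ix >= mean_idx
        if storage:
            implied = 0.0
        else:
            v_bar = r_bar * cfix
            implied = max(0.0, v_bar - glyc)
        out.append(
            StorageIndexEntry(
                r_stor=float(r),
                index=float(ix),
                regime="storage" if storage else "consumption",
                implied_consumption=float(implied),
            )
        )
    return out
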