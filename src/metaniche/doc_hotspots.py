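"""Dissolved-organic-carbon (DOC) secretion potential per grid point.

Each candidate metabolite's maximal secretion is computed independently
with growth pinned at its environmental optimum (the bi-level auxiliary
range), scaled by the metabolite's carbon content to mmol C gDW^-1 h^-1.
The intensity of DOC production at a grid point is the abundance-weighted
sum of those maxima (an upper envelope — simultaneous secretion of several
products competes for the same carbon and is not modelled); the diversity
is the count of metabolites whose production clears a fraction of the top
producer's flux.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import MetabolicModel, add_secretion_exchange, secretion_exchange_id
from .niche import NicheProjection
from .physiology import auxiliary_flux_range

logger = logging.getLogger(__name__)

DEFAULT_DIVERSITY_THRESHOLD = 0.05


@dataclass
class DOCResult:
    """Carbon-scaled secretion maxima and the derived hot-spot scores."""

    per_metabolite: dict[str, float]
    intensity: float
    diversity: int
    threshold_fraction: float = DEFAULT_DIVERSITY_THRESHOLD
    metadata: dict = field(default_factory=dict)


def doc_metabolite_fluxes(
    model: MetabolicModel,
    bioavailability: dict[str, float],
    metabolites: list[str],
    carbon_atoms: dict[str, float] | None = None,
    niche: NicheProjection | None = None,
    growth: float | None = None,
) -> dict[str, float]:
    """Maximal carbon-scaled secretion of each candidate metabolite.

    Metabolites absent from the network are skipped with a warning (the
    candidate list is compiled against what the model actually contains).
    A metabolite without a secretion route receives an export-only exchange
    on a private copy of the model; metabolites are handled sequentially
    and independently.  Carbon atom counts come from ``carbon_atoms`` when
    given, else from the model's annotation; a metabolite with neither is
    an error because the result would be unit-less.
    """
    out: dict[str, float] = {}
    for met in metabolites:
        if met not in model.metabolite_ids:
            logger.warning("DOC candidate %r not in model %r; skipped", met, model.name)
            continue
        carbon = None
        if carbon_atoms is not None:
            carbon = carbon_atoms.get(met)
        if carbon is None:
            carbon = model.carbon_coefficient.get(met)
        if carbon is None:
            raise KeyError(
                f"no carbon atom count for DOC candidate {met!r}: supply a side-table "
                "(metabolite,carbon_atoms) or annotate the model"
            )
        m = add_secretion_exchange(model, met)
        rid = secretion_exchange_id(m, met)
        _, hi = auxiliary_flux_range(m, bioavailability, rid, niche=niche, growth=growth)
        out[met] = max(0.0, hi) * float(carbon)
    return out


def doc_intensity(per_metabolite: dict[str, float], abundance: float) -> float:
    """Abundance-scaled DOC production, mmol C h^-1.

    Sums the per-metabolite carbon-scaled maxima and multiplies by the
    organism's abundance (gDW) at the grid point.
    """
    if abundance < 0:
        raise ValueError(f"abundance must be non-negative, got {abundance}")
    return float(sum(per_metabolite.values()) * abundance)


def doc_diversity(
    per_metabolite: dict[str, float],
    threshold_fraction: float = DEFAULT_DIVERSITY_THRESHOLD,
) -> int:
    """Count of metabolites produced above a fraction of the top producer.

    A metabolite counts iff its production strictly exceeds
    ``threshold_fraction * max(per_metabolite)``.  The maximum is taken over
    the full candidate set including each metabolite itself (excluding it
    would make the top producer's own membership ill-defined).  Scale
    invariant, and non-increasing in the threshold.
    """
    if not per_metabolite:
        logger.warning("empty DOC candidate map; diversity 0")
        return 0
    top = max(per_metabolite.values())
    if top <= 0:
        return 0
    cut = threshold_fraction * top
    return sum(1 for v in per_metabolite.values() if v > cut)


def doc_result(
    per_metabolite: dict[str, float],
    abundance: float,
    threshold_fraction: float = DEFAULT_DIVERSITY_THRESHOLD,
) -> DOCResult:
    """Bundle intensity and diversity for one grid point."""
    return DOCResult(
        per_metabolite=dict(per_metabolite),
        intensity=doc_intensity(per_metabolite, abundance),
        diversity=doc_diversity(per_metabolite, threshold_fraction),
        threshold_fraction=threshold_fraction,
        metadata={"aggregation": "independent per-metabolite maxima (upper envelope)"},
    )
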