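"""Constraint-based metabolic models and the exact linear-programming core.

A model is the usual flux-balance object: a stoichiometric matrix ``S``
(n metabolites x m reactions), flux bounds ``lb <= v <= ub`` and a biomass
reaction whose flux is read as the growth rate (h^-1).  The steady-state
feasible set ``F = {v : S v = 0, lb <= v <= ub}`` is never materialised;
every question about it is answered by a linear program solved with HiGHS.

Sign convention: after :func:`orient_exchanges_uptake_positive` every
exchange flagged ``"uptake"`` imports its boundary metabolite at positive
flux (column +1), and every ``"secretion"`` exchange exports it at positive
flux (column -1).  All uptakes are therefore non-negative, matching the
bioavailability reading of the environment (the organism cannot take up
more than the environment supplies, and supplies are non-negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix, eye as speye, hstack as sphstack, vstack as spvstack

logger = logging.getLogger(__name__)

#: Finite stand-in for "unbounded" fluxes.  Keeping every bound finite keeps
#: the flux polytope — and hence every niche projection — bounded.
BIG = 1.0e6

#: Relative tolerance used whenever a flux is pinned at a previously
#: computed optimum (bi-level steps, canonicalisation).
EPS_FIX = 1.0e-6

_LP_OPTIONS = {"presolve": True}


class ModelStructureError(ValueError):
    """The model violates a structural invariant (shapes, bounds, exchanges)."""


class InfeasibleModelError(RuntimeError):
    """The LP has no feasible point: a 'no growth state', distinct from growth 0."""


class UnboundedModelError(RuntimeError):
    """The LP objective is unbounded; the message names the runaway direction."""


@dataclass(frozen=True)
class FluxVector:
    """A labelled flux assignment, one value per reaction id."""

    values: dict[str, float]

    def __getitem__(self, rid: str) -> float:
        return self.values[rid]

    def get(self, rid: str, default: float = 0.0) -> float:
        return self.values.get(rid, default)

    def as_array(self, order: list[str]) -> np.ndarray:
        return np.array([self.values[r] for r in order], dtype=float)


@dataclass
class MetabolicModel:
    """Stoichiometry, bounds and annotations of a constraint-based model.

    Parameters
    ----------
    metabolite_ids, reaction_ids:
        Row / column labels of ``S``.
    S:
        Dense stoichiometric matrix, shape ``(n_metabolites, n_reactions)``.
    lb, ub:
        Per-reaction flux bounds (mmol gDW^-1 h^-1; biomass in h^-1).
    biomass_reaction:
        Reaction whose flux is the growth rate; its lower bound must be >= 0.
    exchanges:
        Map exchange reaction id -> orientation, ``"uptake"`` or
        ``"secretion"`` (which direction positive flux represents).
    carbon_fixation_reaction:
        Reaction carrying the photosynthetically fixed carbon (e.g. RuBisCO
        carboxylation in published models); constrained by the environment
        like a nutrient exchange.
    carbon_coefficient:
        Metabolite -> carbon atoms per unit (e.g. lipid 33, glycogen 7).
    biomass_coefficient:
        Metabolite -> stoichiometric coefficient ``a`` in the biomass
        reaction (0 for components absent from it).
    sign_flips:
        Reactions whose column was negated during orientation, for
        round-tripping back to the source convention.
    """

    name: str
    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    biomass_reaction: str
    exchanges: dict[str, str]
    carbon_fixation_reaction: str | None = None
    carbon_coefficient: dict[str, float] = field(default_factory=dict)
    biomass_coefficient: dict[str, float] = field(default_factory=dict)
    sign_flips: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self._rxn_index = {r: j for j, r in enumerate(self.reaction_ids)}
        self._met_index = {m: i for i, m in enumerate(self.metabolite_ids)}

    # -- structural helpers -------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rid: str) -> int:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise KeyError(f"unknown reaction {rid!r} in model {self.name!r}") from None

    def metabolite_index(self, mid: str) -> int:
        try:
            return self._met_index[mid]
        except KeyError:
            raise KeyError(f"unknown metabolite {mid!r} in model {self.name!r}") from None

    def exchange_metabolite(self, rid: str) -> str:
        """Boundary metabolite touched by an exchange (must be exactly one)."""
        col = self.S[:, self.reaction_index(rid)]
        nz = np.flatnonzero(col)
        if nz.size != 1:
            raise ModelStructureError(
                f"exchange {rid!r} touches {nz.size} metabolites; expected exactly 1"
            )
        return self.metabolite_ids[int(nz[0])]

    def exchange_for_metabolite(self, mid: str, orientation: str | None = None) -> str | None:
        """Existing exchange whose boundary metabolite is ``mid``, if any."""
        for rid, orient in self.exchanges.items():
            if orientation is not None and orient != orientation:
                continue
            if self.exchange_metabolite(rid) == mid:
                return rid
        return None

    def validate(self) -> None:
        n, m = self.S.shape
        if n != self.n_metabolites or m != self.n_reactions:
            raise ModelStructureError(
                f"S shape {self.S.shape} inconsistent with "
                f"{self.n_metabolites} metabolites x {self.n_reactions} reactions"
            )
        if self.lb.shape != (m,) or self.ub.shape != (m,):
            raise ModelStructureError("bounds length does not match reaction count")
        if np.any(self.lb > self.ub):
            bad = self.reaction_ids[int(np.argmax(self.lb > self.ub))]
            raise ModelStructureError(f"lb > ub for reaction {bad!r}")
        jb = self.reaction_index(self.biomass_reaction)
        if self.lb[jb] < 0:
            raise ModelStructureError("biomass reaction cannot have a negative lower bound")
        for rid in self.exchanges:
            self.exchange_metabolite(rid)  # raises on structural violation
        if any(c < 0 for c in self.carbon_coefficient.values()):
            raise ModelStructureError("carbon coefficients must be non-negative")

    def copy(self) -> "MetabolicModel":
        return replace(
            self,
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            exchanges=dict(self.exchanges),
            carbon_coefficient=dict(self.carbon_coefficient),
            biomass_coefficient=dict(self.biomass_coefficient),
            sign_flips=dict(self.sign_flips),
        )

    def clipped_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Bounds with infinities replaced by +-BIG (keeps LPs bounded)."""
        return np.clip(self.lb, -BIG, BIG), np.clip(self.ub, -BIG, BIG)


# ---------------------------------------------------------------------------
# orientation


def orient_exchanges_uptake_positive(model: MetabolicModel) -> MetabolicModel:
    """Return an equivalent model where every exchange's labelled direction
    carries positive sign.

    An ``"uptake"`` exchange ends with column coefficient +1-signed (positive
    flux imports the boundary metabolite); a ``"secretion"`` exchange ends
    with a negative column (positive flux exports).  Columns that need it are
    negated and their bounds swapped, which leaves the feasible set — and
    therefore the FBA optimum — unchanged.  Flipped reactions are recorded in
    ``sign_flips`` so callers can map fluxes back to the source convention.
    """
    out = model.copy()
    for rid, orientation in out.exchanges.items():
        j = out.reaction_index(rid)
        mid = out.exchange_metabolite(rid)
        coeff = out.S[out.metabolite_index(mid), j]
        wants_positive_column = orientation == "uptake"
        if (coeff > 0) != wants_positive_column:
            out.S[:, j] = -out.S[:, j]
            out.lb[j], out.ub[j] = -out.ub[j], -out.lb[j]
            out.sign_flips[rid] = -out.sign_flips.get(rid, 1)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# LP plumbing


def _effective_bounds(
    model: MetabolicModel, bound_overrides: dict[str, tuple[float, float]] | None
) -> tuple[np.ndarray, np.ndarray]:
    lb, ub = model.clipped_bounds()
    lb, ub = lb.copy(), ub.copy()
    if bound_overrides:
        for rid, (lo, hi) in bound_overrides.items():
            if lo > hi:
                raise ValueError(f"override for {rid!r} has lo {lo} > hi {hi}")
            j = model.reaction_index(rid)
            lb[j] = max(lo, -BIG)
            ub[j] = min(hi, BIG)
    return lb, ub


def _linprog(c, A_eq, b_eq, lb, ub, A_ub=None, b_ub=None):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options=_LP_OPTIONS,
    )
    return res


def _optimize_flux(
    model: MetabolicModel,
    objective_reaction: str,
    sense: str,
    lb: np.ndarray,
    ub: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Optimise one reaction's flux over the polytope; raise on infeasible/unbounded."""
    m = model.n_reactions
    c = np.zeros(m)
    j = model.reaction_index(objective_reaction)
    c[j] = -1.0 if sense == "max" else 1.0
    res = _linprog(c, csr_matrix(model.S), np.zeros(model.n_metabolites), lb, ub)
    if res.status == 2:
        raise InfeasibleModelError(
            f"model {model.name!r}: no feasible flux state under the given bounds"
        )
    if res.status == 3:
        raise UnboundedModelError(
            f"model {model.name!r}: flux through {objective_reaction!r} is unbounded "
            f"in the {sense} direction"
        )
    if res.status != 0:
        raise RuntimeError(f"LP solver failure (status {res.status}): {res.message}")
    value = -res.fun if sense == "max" else res.fun
    return float(value), res.x


def _pfba_flux(
    model: MetabolicModel,
    lb: np.ndarray,
    ub: np.ndarray,
    pinned: dict[str, float],
) -> np.ndarray:
    """Canonical flux vector: minimum total absolute flux with the pinned
    reactions held at their values (within EPS_FIX relative).

    Split formulation v = v, |v| <= w: minimise sum(w) subject to
    S v = 0, v - w <= 0, -v - w <= 0, bounds.
    """
    m = model.n_reactions
    lb, ub = lb.copy(), ub.copy()
    for rid, val in pinned.items():
        j = model.reaction_index(rid)
        eps = EPS_FIX * max(1.0, abs(val))
        lb[j] = max(lb[j], val - eps)
        ub[j] = min(ub[j], val + eps)
        if lb[j] > ub[j]:  # numerical guard
            lb[j] = ub[j] = val
    S = csr_matrix(model.S)
    Z = csr_matrix((model.n_metabolites, m))
    A_eq = sphstack([S, Z], format="csr")
    I = speye(m, format="csr")
    A_ub = spvstack([sphstack([I, -I]), sphstack([-I, -I])], format="csr")
    b_ub = np.zeros(2 * m)
    c = np.concatenate([np.zeros(m), np.ones(m)])
    lo = np.concatenate([lb, np.zeros(m)])
    hi = np.concatenate([ub, np.full(m, BIG)])
    res = _linprog(c, A_eq, np.zeros(model.n_metabolites), lo, hi, A_ub, b_ub)
    if res.status != 0:
        # fall back to the raw solution bounds if canonicalisation hits a
        # numerical corner (should not happen for well-scaled models)
        raise RuntimeError(f"canonicalisation LP failed (status {res.status}): {res.message}")
    return res.x[:m]


# ---------------------------------------------------------------------------
# public operations


def fba_max_biomass(
    model: MetabolicModel,
    bound_overrides: dict[str, tuple[float, float]] | None = None,
) -> tuple[float, FluxVector]:
    """Maximise the biomass flux (flux balance analysis).

    Returns the optimal growth rate and a canonical optimal flux vector
    (parsimonious: minimum total absolute flux at the fixed optimum, so
    repeated calls are bit-identical).  An infeasible system raises
    :class:`InfeasibleModelError` — a 'no growth state' distinct from a
    feasible optimum of zero.
    """
    lb, ub = _effective_bounds(model, bound_overrides)
    growth, _ = _optimize_flux(model, model.biomass_reaction, "max", lb, ub)
    v = _pfba_flux(model, lb, ub, {model.biomass_reaction: growth})
    return growth, FluxVector(dict(zip(model.reaction_ids, v.tolist())))


def fva_range(
    model: MetabolicModel,
    reaction: str,
    bound_overrides: dict[str, tuple[float, float]] | None = None,
) -> tuple[float, float]:
    """Plain flux variability: min and max flux of ``reaction`` over F."""
    lb, ub = _effective_bounds(model, bound_overrides)
    lo, _ = _optimize_flux(model, reaction, "min", lb, ub)
    hi, _ = _optimize_flux(model, reaction, "max", lb, ub)
    return min(lo, hi), max(lo, hi)


def fva_at_optimum(
    model: MetabolicModel,
    reaction: str,
    bound_overrides: dict[str, tuple[float, float]] | None = None,
    growth: float | None = None,
) -> tuple[float, float]:
    """Flux variability of ``reaction`` with biomass pinned at its maximum.

    This is the brute-force bi-level oracle: first maximise biomass, then
    minimise/maximise the target flux with the biomass flux held at the
    optimum within ``EPS_FIX`` relative.
    """
    lb, ub = _effective_bounds(model, bound_overrides)
    if growth is None:
        growth, _ = _optimize_flux(model, model.biomass_reaction, "max", lb, ub)
    jb = model.reaction_index(model.biomass_reaction)
    eps = EPS_FIX * max(1.0, abs(growth))
    lb[jb] = max(lb[jb], growth - eps)
    ub[jb] = min(ub[jb], growth + eps)
    lo, _ = _optimize_flux(model, reaction, "min", lb, ub)
    hi, _ = _optimize_flux(model, reaction, "max", lb, ub)
    return min(lo, hi), max(lo, hi)


def add_secretion_exchange(
    model: MetabolicModel, metabolite: str, cap: float = BIG
) -> MetabolicModel:
    """Add an export-only exchange for ``metabolite`` (bounds [0, cap]).

    The organism is allowed to produce and excrete the metabolite but never
    to take it up, so the pre-existing growth optimum cannot change (zero
    secretion is always available).  If an exchange for the metabolite
    already exists the model is returned unchanged with a logged notice,
    which also makes the operation idempotent.
    """
    model.metabolite_index(metabolite)  # raises LookupError for unknown ids
    existing = model.exchange_for_metabolite(metabolite)
    if existing is not None:
        logger.debug(
            "metabolite %r already has exchange %r; not adding a secretion reaction",
            metabolite,
            existing,
        )
        return model
    out = model.copy()
    rid = f"SEC_{metabolite}"
    col = np.zeros((out.n_metabolites, 1))
    col[out.metabolite_index(metabolite), 0] = -1.0  # positive flux exports
    out.S = np.hstack([out.S, col])
    out.lb = np.append(out.lb, 0.0)
    out.ub = np.append(out.ub, cap)
    out.reaction_ids = out.reaction_ids + [rid]
    out.exchanges = {**out.exchanges, rid: "secretion"}
    out.__post_init__()
    out.validate()
    return out


def secretion_exchange_id(model: MetabolicModel, metabolite: str) -> str:
    """Exchange reaction through which ``metabolite`` leaves the cell."""
    rid = model.exchange_for_metabolite(metabolite, orientation="secretion")
    if rid is None:
        rid = model.exchange_for_metabolite(metabolite)
    if rid is None:
        raise KeyError(f"metabolite {metabolite!r} has no exchange reaction")
    return rid


def env_bound_overrides(
    model: MetabolicModel,
    bioavailability: dict[str, float],
    carbon_mode: str = "upper",
) -> dict[str, tuple[float, float]]:
    """Translate a bioavailability vector into flux-bound overrides.

    Each entry caps the named uptake (or carbon-fixation) reaction at
    ``min(bioavailability, model upper bound)`` — the environment limits
    supply, and the model's own bound represents transporter capacity; the
    environment cannot relax the latter.  With ``carbon_mode="equality"``
    the carbon-fixation flux is forced to equal its bioavailable value
    instead of being merely capped by it.
    """
    overrides: dict[str, tuple[float, float]] = {}
    for rid, xb in bioavailability.items():
        if xb < 0:
            raise ValueError(f"negative bioavailability {xb} for {rid!r}")
        j = model.reaction_index(rid)
        hi = min(xb, float(np.clip(model.ub[j], -BIG, BIG)))
        if carbon_mode == "equality" and rid == model.carbon_fixation_reaction:
            overrides[rid] = (hi, hi)
        else:
            overrides[rid] = (0.0, hi)
    return overrides


def mass_balance_residual(model: MetabolicModel, flux: FluxVector) -> float:
    """Relative steady-state residual ||S v||_inf / max(1, ||v||_inf)."""
    v = flux.as_array(model.reaction_ids)
    return float(np.max(np.abs(model.S @ v)) / max(1.0, np.max(np.abs(v))))
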