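"""The metabolic niche: exact projection of the flux polytope onto the
reactions of interest, and growth extraction on the projected polytope.

The niche N is the image of the feasible set F under the coordinate map
that keeps only the reactions of interest (nutrient exchanges, the
carbon-fixation reaction and biomass).  Because F is a bounded polytope and
the map is linear, N is a bounded polytope of dimension p (possibly of
lower affine rank when stoichiometry couples the kept coordinates).  We
compute N by support-function outer refinement:

1.  probe F along +-axes and a handful of random directions to seed a point
    cloud of exact support points (each is the restriction of a feasible
    full flux vector);
2.  detect the affine rank of the cloud; directions of zero width become
    explicit affine-hull equality constraints;
3.  within the affine hull, build a convex hull of the seeds and, for every
    facet, solve a support LP over the full polytope; any support point that
    beats the facet offset by more than the tolerance is inserted and the
    hull rebuilt, to a fixpoint.

On termination every facet is supported by the polytope, so the hull equals
the true projection up to the stated tolerance.  Both representations are
kept: vertices (V) and facet halfspaces (H, convention normal . x <= offset
with unit normals).

Growth extraction is then a p-dimensional LP over the H-representation:
maximise the biomass coordinate subject to the niche constraints and
0 <= x_env <= x_env^b (bioavailability caps realised uptake).  An
infeasible point is 'outside the niche' and reported as zero growth with a
flag rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, QhullError

from .model import (
    BIG,
    EPS_FIX,
    FluxVector,
    MetabolicModel,
    _effective_bounds,
    _linprog,
    _pfba_flux,
)
from scipy.sparse import csr_matrix

_MAX_P = 6
_PROBE_SEED = 987654321  # fixed: probe directions are an internal detail


class UnboundedProjectionError(RuntimeError):
    """A projected coordinate is unbounded (its support reaches the BIG cap)."""


class ProjectionCapabilityError(ValueError):
    """Requested projection dimension exceeds what the algorithm supports."""


class NicheMembershipError(ValueError):
    """A point handed to a niche operation is not a member of the niche."""


class ProjectionToleranceError(RuntimeError):
    """A niche vertex failed to lift to a feasible full flux vector."""


@dataclass
class NicheGrowthResult:
    """Outcome of growth extraction at one environmental condition."""

    growth: float
    realized_uptake: dict[str, float]
    outside_niche: bool = False


@dataclass
class NicheProjection:
    """V- and H-representation of the projected flux polytope.

    ``halfspaces`` are (unit normal, offset) pairs with normal . x <= offset;
    ``equalities`` carry the affine hull of rank-deficient niches as
    normal . x = offset pairs.  ``scale`` is the bounding-box diameter used
    to convert the relative ``tolerance`` into absolute slack.
    """

    reactions_of_interest: list[str]
    vertices: np.ndarray
    halfspaces: list[tuple[np.ndarray, float]]
    equalities: list[tuple[np.ndarray, float]] = field(default_factory=list)
    tolerance: float = 1.0e-6
    scale: float = 1.0
    provenance: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return len(self.reactions_of_interest)

    @property
    def abs_tol(self) -> float:
        return self.tolerance * max(1.0, self.scale)

    def coordinate(self, rid: str) -> int:
        return self.reactions_of_interest.index(rid)

    def contains(self, point: np.ndarray, slack: float | None = None) -> bool:
        point = np.asarray(point, dtype=float)
        if point.shape != (self.p,):
            raise ValueError(f"point has dimension {point.shape}, expected ({self.p},)")
        tol = self.abs_tol if slack is None else slack
        for normal, offset in self.halfspaces:
            if float(normal @ point) - offset > tol:
                return False
        for normal, offset in self.equalities:
            if abs(float(normal @ point) - offset) > tol:
                return False
        return True


def niche_membership(niche: NicheProjection, point) -> bool:
    """True iff ``point`` satisfies every niche constraint within tolerance."""
    return niche.contains(np.asarray(point, dtype=float))


# ---------------------------------------------------------------------------
# projection construction


def _support(model, idx, lb, ub, u):
    """Exact support of the projection in direction u: max u.x over F.

    Returns (value, projected support point)."""
    c = np.zeros(model.n_reactions)
    c[idx] = -u
    res = _linprog(c, csr_matrix(model.S), np.zeros(model.n_metabolites), lb, ub)
    if res.status != 0:
        raise RuntimeError(f"support LP failed (status {res.status}): {res.message}")
    return float(-res.fun), res.x[idx]


def project_niche(
    model: MetabolicModel,
    reactions_of_interest: list[str],
    tol: float = 1.0e-6,
    max_refinements: int = 200,
) -> NicheProjection:
    """Project the flux polytope onto ``reactions_of_interest``.

    Returns the exact projection (up to ``tol`` relative to the bounding-box
    diameter) as a :class:`NicheProjection`.  Raises
    :class:`UnboundedProjectionError` naming the coordinate if a projected
    reaction's flux reaches the internal BIG cap, and
    :class:`ProjectionCapabilityError` for p > 6.
    """
    p = len(reactions_of_interest)
    if p < 1:
        raise ValueError("need at least one reaction of interest")
    if p > _MAX_P:
        raise ProjectionCapabilityError(f"projection onto p={p} > {_MAX_P} coordinates")
    idx = np.array([model.reaction_index(r) for r in reactions_of_interest])
    lb, ub = _effective_bounds(model, None)

    # 1. bounding box along the axes: also the unboundedness check
    lo_box = np.empty(p)
    hi_box = np.empty(p)
    points = []
    for i in range(p):
        e = np.zeros(p)
        e[i] = 1.0
        hi, pt_hi = _support(model, idx, lb, ub, e)
        lo_neg, pt_lo = _support(model, idx, lb, ub, -e)
        lo = -lo_neg
        if hi >= 0.99 * BIG or lo <= -0.99 * BIG:
            raise UnboundedProjectionError(
                f"projection unbounded along coordinate {reactions_of_interest[i]!r}"
            )
        lo_box[i], hi_box[i] = lo, hi
        points.extend([pt_hi, pt_lo])
    scale = float(np.max(hi_box - lo_box))
    abs_tol = tol * max(1.0, scale)

    prov = {
        "model": model.name,
        "tol": tol,
        "algorithm": "support-function outer refinement",
    }

    if scale <= abs_tol:  # the projection is a single point
        v = (lo_box + hi_box) / 2.0
        eqs = [(_unit(np.eye(p)[i]), float(v[i])) for i in range(p)]
        return NicheProjection(
            list(reactions_of_interest), np.array([v]), [], eqs, tol, max(scale, 1e-12), prov
        )

    # 2. enrich with random probe directions, then detect the affine rank
    rng = np.random.default_rng(_PROBE_SEED)
    for _ in range(4 * p):
        u = _unit(rng.standard_normal(p))
        _, pt = _support(model, idx, lb, ub, u)
        points.append(pt)
        _, pt = _support(model, idx, lb, ub, -u)
        points.append(pt)
    P = np.array(points)

    equalities: list[tuple[np.ndarray, float]] = []
    for _ in range(p + 1):
        center = P.mean(axis=0)
        _, sv, Vt = np.linalg.svd(P - center, full_matrices=True)
        sv = np.concatenate([sv, np.zeros(p - sv.size)])
        null_dirs = [Vt[i] for i in range(p) if sv[i] <= abs_tol]
        confirmed, widened = [], False
        for u in null_dirs:
            u = _unit(u)
            h_pos, pt_pos = _support(model, idx, lb, ub, u)
            h_neg, pt_neg = _support(model, idx, lb, ub, -u)
            width = h_pos + h_neg
            if width <= 10.0 * abs_tol:
                confirmed.append((u, (h_pos - h_neg) / 2.0))
            else:
                P = np.vstack([P, pt_pos, pt_neg])
                widened = True
        if not widened:
            equalities = confirmed
            break

    center = P.mean(axis=0)
    _, sv, Vt = np.linalg.svd(P - center, full_matrices=True)
    sv = np.concatenate([sv, np.zeros(p - sv.size)])
    basis = Vt[sv > abs_tol].T  # p x r, orthonormal columns spanning the affine hull
    r = basis.shape[1]
    prov["affine_rank"] = int(r)

    if r == 0:
        v = center
        eqs = [(_unit(np.eye(p)[i]), float(v[i])) for i in range(p)]
        return NicheProjection(
            list(reactions_of_interest), np.array([v]), [], eqs, tol, scale, prov
        )

    if r == 1:
        u = basis[:, 0]
        h_pos, pt_pos = _support(model, idx, lb, ub, u)
        h_neg, pt_neg = _support(model, idx, lb, ub, -u)
        verts = np.array([pt_pos, pt_neg])
        halfspaces = [(u.copy(), h_pos), (-u, h_neg)]
        return NicheProjection(
            list(reactions_of_interest), verts, halfspaces, equalities, tol, scale, prov
        )

    # 3. outer refinement of the hull within the affine hull
    Z = (P - center) @ basis
    Z = _dedup_rows(Z, abs_tol)
    hull = _hull(Z)
    for _ in range(max_refinements):
        new_pts = []
        for eq in _unique_facets(hull.equations, 1e-9):
            a, b = eq[:-1], eq[-1]  # a.z + b <= 0 inside
            u = basis @ a
            h, pt = _support(model, idx, lb, ub, u)
            z_new = (pt - center) @ basis
            if float(a @ z_new) + b > abs_tol:
                new_pts.append(z_new)
        if not new_pts:
            break
        Z = _dedup_rows(np.vstack([Z, np.array(new_pts)]), abs_tol * 1e-3)
        hull = _hull(Z)
    else:
        raise ProjectionToleranceError(
            f"projection of {model.name!r} did not converge in {max_refinements} refinements"
        )

    vert_z = Z[hull.vertices]
    vertices = center + vert_z @ basis.T
    halfspaces = []
    for eq in _unique_facets(hull.equations, 1e-9):
        a, b = eq[:-1], eq[-1]
        normal = basis @ a  # unit, since basis is orthonormal and |a| = 1
        offset = float(-b + normal @ center)
        halfspaces.append((normal, offset))
    prov["n_vertices"] = int(len(vertices))
    prov["n_facets"] = int(len(halfspaces))
    return NicheProjection(
        list(reactions_of_interest), vertices, halfspaces, equalities, tol, scale, prov
    )


def _unit(u: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(u)
    return u / n if n > 0 else u


def _dedup_rows(X: np.ndarray, tol: float) -> np.ndarray:
    if len(X) == 0:
        return X
    q = np.round(X / max(tol, 1e-12)).astype(np.int64)
    _, keep = np.unique(q, axis=0, return_index=True)
    return X[np.sort(keep)]


def _unique_facets(equations: np.ndarray, tol: float) -> np.ndarray:
    q = np.round(equations / tol).astype(np.int64)
    _, keep = np.unique(q, axis=0, return_index=True)
    return equations[np.sort(keep)]


def _hull(Z: np.ndarray) -> ConvexHull:
    try:
        return ConvexHull(Z, qhull_options="Qt")
    except QhullError:
        # nearly degenerate input despite rank detection: fall back to
        # bounding-box rescaling which is still joggle-free
        return ConvexHull(Z, qhull_options="Qt QbB")


# ---------------------------------------------------------------------------
# growth extraction on the niche (Liebig-style LP in p dimensions)


def _niche_lp_arrays(niche: NicheProjection):
    A_ub = np.array([n for n, _ in niche.halfspaces]) if niche.halfspaces else None
    b_ub = np.array([o for _, o in niche.halfspaces]) if niche.halfspaces else None
    A_eq = np.array([n for n, _ in niche.equalities]) if niche.equalities else None
    b_eq = np.array([o for _, o in niche.equalities]) if niche.equalities else None
    return A_ub, b_ub, A_eq, b_eq


def max_biomass_on_niche(
    niche: NicheProjection,
    bioavailability: dict[str, float],
    biomass_reaction: str | None = None,
) -> NicheGrowthResult:
    """Maximal growth on the niche under nutrient bioavailability caps.

    Solves ``max x_bio`` subject to the niche halfspaces and
    ``0 <= x_env <= x_env^b`` for every capped coordinate.  Bioavailability
    is an upper limit on uptake, not a prescribed uptake.  If the LP is
    infeasible the environmental condition lies outside the niche: growth is
    reported as 0 with ``outside_niche=True``.  The realised uptake vector is
    canonicalised by a secondary LP minimising total uptake at the optimum.
    """
    roi = niche.reactions_of_interest
    if biomass_reaction is None:
        biomass_reaction = roi[-1]
    jb = niche.coordinate(biomass_reaction)
    for rid, xb in bioavailability.items():
        if rid not in roi:
            raise KeyError(f"bioavailability names {rid!r}, not a niche coordinate")
        if rid == biomass_reaction:
            raise KeyError("bioavailability cannot constrain the biomass coordinate")
        if xb < 0:
            raise ValueError(f"negative bioavailability {xb} for {rid!r}")

    p = niche.p
    bounds = []
    for i, rid in enumerate(roi):
        if i == jb:
            bounds.append((0.0, BIG))
        elif rid in bioavailability:
            bounds.append((0.0, float(bioavailability[rid])))
        else:
            bounds.append((0.0, BIG))
    A_ub, b_ub, A_eq, b_eq = _niche_lp_arrays(niche)
    c = np.zeros(p)
    c[jb] = -1.0
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status == 2:
        return NicheGrowthResult(0.0, {}, outside_niche=True)
    if res.status != 0:
        raise RuntimeError(f"niche LP failed (status {res.status}): {res.message}")
    growth = float(-res.fun)

    # canonical realised uptake: minimal total uptake sustaining the optimum
    eps = EPS_FIX * max(1.0, abs(growth))
    bounds2 = list(bounds)
    bounds2[jb] = (max(0.0, growth - eps), growth + eps)
    c2 = np.ones(p)
    c2[jb] = 0.0
    res2 = linprog(c2, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds2, method="highs")
    x = res2.x if res2.status == 0 else res.x
    realized = {rid: float(x[i]) for i, rid in enumerate(roi) if i != jb}
    return NicheGrowthResult(growth, realized, outside_niche=False)


def lift_to_full_flux(
    model: MetabolicModel,
    niche: NicheProjection,
    niche_point,
) -> FluxVector:
    """Feasibility witness: a complete flux vector restricting to ``niche_point``.

    The reactions of interest are pinned to the point's coordinates (within
    the niche's absolute tolerance, escalating twice by x10 before giving
    up) and the rest of the network is filled in parsimoniously.  A point
    that is not a niche member raises :class:`NicheMembershipError`; a
    member that cannot be lifted signals a projection defect via
    :class:`ProjectionToleranceError`.
    """
    point = np.asarray(niche_point, dtype=float)
    if not niche.contains(point):
        raise NicheMembershipError("point is not a member of the niche")
    lb0, ub0 = _effective_bounds(model, None)
    for escalation in (1.0, 10.0, 100.0):
        delta = max(niche.abs_tol, 1e-9) * escalation
        lb, ub = lb0.copy(), ub0.copy()
        ok = True
        for rid, val in zip(niche.reactions_of_interest, point):
            j = model.reaction_index(rid)
            lb[j] = max(lb[j], val - delta)
            ub[j] = min(ub[j], val + delta)
            if lb[j] > ub[j]:
                ok = False
        if not ok:
            continue
        try:
            v = _pfba_flux(model, lb, ub, {})
        except RuntimeError:
            continue
        return FluxVector(dict(zip(model.reaction_ids, v.tolist())))
    raise ProjectionToleranceError(
        "niche point could not be lifted to a feasible full flux vector "
        "(tolerance escalated x100); this indicates a projection defect"
    )
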