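"""Niche projection: exactness against support-function oracles, growth
extraction equivalence with direct FBA, membership, lifting, and the
convexity/monotonicity structure of growth as a function of the
environment."""

import numpy as np
import pytest

from metaniche import (
    env_bound_overrides,
    fba_max_biomass,
    lift_to_full_flux,
    make_random_feasible_model,
    max_biomass_on_niche,
    niche_membership,
    project_niche,
)
from metaniche.model import mass_balance_residual, _effective_bounds
from metaniche.niche import ProjectionCapabilityError, NicheMembershipError, _support
from metaniche.synthetic import uptake_exchange_ids

from conftest import ENV_N_LIMITED, ENV_REFERENCE, TOY1_ROI, random_bioavailability


def _support_oracle_deviation(model, niche, n_dirs=200, seed=0):
    """Max |exact support - hull support| over random directions and the
    niche's own facet normals: the Hausdorff distance between two convex
    bodies is the sup over unit directions of the support-function gap."""
    rng = np.random.default_rng(seed)
    p = niche.p
    idx = np.array([model.reaction_index(r) for r in niche.reactions_of_interest])
    lb, ub = _effective_bounds(model, None)
    dirs = [n for n, _ in niche.halfspaces] + [n for n, _ in niche.equalities]
    dirs += [-n for n, _ in niche.equalities]
    for _ in range(n_dirs):
        u = rng.standard_normal(p)
        dirs.append(u / np.linalg.norm(u))
    dev = 0.0
    for u in dirs:
        h_exact, _ = _support(model, idx, lb, ub, np.asarray(u, dtype=float))
        h_hull = float(max(niche.vertices @ np.asarray(u, dtype=float)))
        dev = max(dev, abs(h_exact - h_hull))
    return dev


# -- projection correctness -------------------------------------------------


def test_toy1_projection_matches_support_oracle(toy1, toy1_niche):
    dev = _support_oracle_deviation(toy1, toy1_niche)
    assert dev <= 1e-5 * max(1.0, toy1_niche.scale)


def test_toy1_projection_structure(toy1_niche):
    # stoichiometry pins EX_N = BIO and EX_P = 0.2 BIO: affine rank 2
    assert toy1_niche.provenance["affine_rank"] == 2
    assert len(toy1_niche.equalities) == 2
    # biomass coordinate is non-negative everywhere
    jb = toy1_niche.coordinate("BIO")
    assert np.all(toy1_niche.vertices[:, jb] >= -toy1_niche.abs_tol)
    # the maximal-biomass vertex attains the Liebig minimum over the caps
    b_max = float(toy1_niche.vertices[:, jb].max())
    assert b_max == pytest.approx(min(20.0 / 1.0, 20.0 / 0.2, 20.0 / 5.0), abs=1e-6)


def test_degenerate_single_coordinate_projection(toy1):
    m = toy1.copy()
    j = m.reaction_index("EX_N")
    m.lb[j] = m.ub[j] = 1.0
    niche = project_niche(m, ["EX_N", "BIO"])
    jn = niche.coordinate("EX_N")
    assert np.allclose(niche.vertices[:, jn], 1.0, atol=1e-6)
    # EX_N = BIO in TOY1, so pinning EX_N collapses the whole projection
    assert len(niche.vertices) == 1


def test_identity_projection_of_small_model():
    # projecting onto every reaction reproduces the polytope itself
    m = make_random_feasible_model(2, 3, seed=5)
    niche = project_niche(m, list(m.reaction_ids))
    dev = _support_oracle_deviation(m, niche, n_dirs=100)
    assert dev <= 1e-5 * max(1.0, niche.scale)


@pytest.mark.parametrize("seed", range(8))
def test_random_model_projections_match_oracle(seed):
    m = make_random_feasible_model(6, 12, seed=seed)
    roi = uptake_exchange_ids(m)[:2] + [m.biomass_reaction]
    niche = project_niche(m, roi)
    dev = _support_oracle_deviation(m, niche, n_dirs=100, seed=seed)
    assert dev <= 1e-5 * max(1.0, niche.scale)


def test_projection_capability_limit(toy1):
    with pytest.raises(ProjectionCapabilityError):
        project_niche(toy1, list(toy1.reaction_ids) + ["BIO"] * 2)


def test_every_vertex_lifts_to_feasible_flux(toy1, toy1_niche):
    for v in toy1_niche.vertices:
        flux = lift_to_full_flux(toy1, toy1_niche, v)
        assert mass_balance_residual(toy1, flux) <= 1e-6
        restricted = flux.as_array(toy1_niche.reactions_of_interest)
        assert np.allclose(restricted, v, atol=10 * toy1_niche.abs_tol)


# -- membership -------------------------------------------------------------


def test_membership_of_balanced_and_unbalanced_points(toy1_niche):
    assert niche_membership(toy1_niche, [1.0, 0.2, 5.0, 1.0])  # exact balance
    assert not niche_membership(toy1_niche, [0.0, 0.2, 5.0, 1.0])  # growth w/o N
    for v in toy1_niche.vertices:
        assert niche_membership(toy1_niche, v)


def test_membership_dimension_mismatch(toy1_niche):
    with pytest.raises(ValueError, match="dimension"):
        niche_membership(toy1_niche, [1.0, 0.2])


def test_lift_rejects_non_member(toy1, toy1_niche):
    with pytest.raises(NicheMembershipError):
        lift_to_full_flux(toy1, toy1_niche, [0.0, 0.2, 5.0, 1.0])


# -- growth extraction ------------------------------------------------------


@pytest.mark.parametrize(
    "env, expected",
    [
        (ENV_REFERENCE, 1.0),
        (ENV_N_LIMITED, 0.5),
        ({"EX_N": 0.0, "EX_P": 0.0, "CFIX": 0.0}, 0.0),
    ],
)
def test_growth_on_niche_matches_liebig(toy1_niche, env, expected):
    res = max_biomass_on_niche(toy1_niche, env)
    assert not res.outside_niche
    assert res.growth == pytest.approx(expected, abs=1e-6)


def test_realized_uptake_is_canonical_minimum(toy1_niche):
    res = max_biomass_on_niche(toy1_niche, ENV_REFERENCE)
    assert res.realized_uptake["EX_N"] == pytest.approx(1.0, abs=1e-5)
    assert res.realized_uptake["EX_P"] == pytest.approx(0.2, abs=1e-5)
    assert res.realized_uptake["CFIX"] == pytest.approx(5.0, abs=1e-5)


def test_growth_rejects_negative_bioavailability(toy1_niche):
    with pytest.raises(ValueError, match="negative"):
        max_biomass_on_niche(toy1_niche, {"EX_N": -1.0})


def test_niche_direct_equivalence_toy1(toy1, toy1_niche):
    rng = np.random.default_rng(7)
    for _ in range(100):
        xb = random_bioavailability(rng, TOY1_ROI[:-1], hi=3.0)
        g_niche = max_biomass_on_niche(toy1_niche, xb).growth
        g_direct, _ = fba_max_biomass(toy1, env_bound_overrides(toy1, xb))
        assert abs(g_niche - g_direct) <= 1e-6 * max(1.0, g_direct)


@pytest.mark.parametrize("seed", range(5))
def test_niche_direct_equivalence_random_models(seed):
    m = make_random_feasible_model(5, 10, seed=100 + seed)
    roi = uptake_exchange_ids(m)[:2] + [m.biomass_reaction]
    niche = project_niche(m, roi)
    rng = np.random.default_rng(seed)
    for _ in range(40):
        xb = random_bioavailability(rng, roi[:-1])
        g_niche = max_biomass_on_niche(niche, xb, biomass_reaction=m.biomass_reaction).growth
        g_direct, _ = fba_max_biomass(m, env_bound_overrides(m, xb))
        assert abs(g_niche - g_direct) <= 1e-6 * max(1.0, g_direct)


def test_growth_monotone_in_bioavailability(toy1_niche):
    rng = np.random.default_rng(11)
    for _ in range(20):
        xb = random_bioavailability(rng, TOY1_ROI[:-1], hi=2.0)
        g0 = max_biomass_on_niche(toy1_niche, xb).growth
        bigger = {k: v * float(rng.uniform(1.0, 2.0)) for k, v in xb.items()}
        g1 = max_biomass_on_niche(toy1_niche, bigger).growth
        assert g1 >= g0 - 1e-9


def test_growth_concave_in_bioavailability(toy1_niche):
    rng = np.random.default_rng(13)
    keys = TOY1_ROI[:-1]
    for _ in range(20):
        a = random_bioavailability(rng, keys, hi=3.0)
        b = random_bioavailability(rng, keys, hi=3.0)
        mid = {k: 0.5 * (a[k] + b[k]) for k in keys}
        ga = max_biomass_on_niche(toy1_niche, a).growth
        gb = max_biomass_on_niche(toy1_niche, b).growth
        gm = max_biomass_on_niche(toy1_niche, mid).growth
        assert gm >= 0.5 * (ga + gb) - 1e-8


def test_serialization_round_trip(toy1_niche, tmp_path):
    from metaniche.io import read_niche, write_niche

    path = tmp_path / "niche.json"
    write_niche(toy1_niche, path)
    back = read_niche(path)
    assert back.reactions_of_interest == toy1_niche.reactions_of_interest
    assert np.allclose(back.vertices, toy1_niche.vertices)
    assert len(back.halfspaces) == len(toy1_niche.halfspaces)
    res0 = max_biomass_on_niche(toy1_niche, ENV_REFERENCE)
    res1 = max_biomass_on_niche(back, ENV_REFERENCE)
    assert res1.growth == pytest.approx(res0.growth, abs=1e-9)
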