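"""Bi-level physiology: auxiliary ranges vs the brute-force oracle,
carbon-equivalent composition ratios, nutrient slacks, resource
constraints and the glycogen storage index."""

import numpy as np
import pytest

from metaniche import (
    auxiliary_flux_range,
    component_ratio,
    env_bound_overrides,
    fva_at_optimum,
    fva_range,
    glycogen_storage_index,
    make_quota_chain_model,
    make_random_feasible_model,
    nutrient_slack,
    resource_constraint,
)
from metaniche.physiology import UndefinedRatioError
from metaniche.synthetic import QuotaChainSpec, StorageComponent, uptake_exchange_ids

from conftest import ENV_N_LIMITED, ENV_REFERENCE, random_bioavailability


# -- auxiliary flux ranges --------------------------------------------------


@pytest.mark.parametrize(
    "env, expected",
    [
        (ENV_REFERENCE, (0.0, 1.0)),  # carbon slack 7, glycogen costs 7 C
        ({"EX_N": 1.0, "EX_P": 0.2, "CFIX": 5.0}, (0.0, 0.0)),  # no slack
    ],
)
def test_glycogen_range_with_growth_pinned(toy1, toy1_niche, env, expected):
    lo, hi = auxiliary_flux_range(toy1, env, "EX_GLY", niche=toy1_niche)
    assert lo == pytest.approx(expected[0], abs=1e-5)
    assert hi == pytest.approx(expected[1], abs=1e-5)


def test_auxiliary_range_equals_fva_oracle_random_envs(toy1, toy1_niche):
    rng = np.random.default_rng(21)
    for _ in range(25):
        env = random_bioavailability(rng, ["EX_N", "EX_P", "CFIX"], hi=3.0)
        ours = auxiliary_flux_range(toy1, env, "EX_GLY", niche=toy1_niche)
        oracle = fva_at_optimum(toy1, "EX_GLY", env_bound_overrides(toy1, env))
        assert ours[0] == pytest.approx(oracle[0], abs=1e-6)
        assert ours[1] == pytest.approx(oracle[1], abs=1e-6)


def test_auxiliary_range_contained_in_unpinned_fva(toy1, toy1_niche):
    rng = np.random.default_rng(22)
    for _ in range(10):
        env = random_bioavailability(rng, ["EX_N", "EX_P", "CFIX"], hi=3.0)
        pinned = auxiliary_flux_range(toy1, env, "EX_GLY", niche=toy1_niche)
        free = fva_range(toy1, "EX_GLY", env_bound_overrides(toy1, env))
        assert pinned[0] >= free[0] - 1e-7
        assert pinned[1] <= free[1] + 1e-7


def test_auxiliary_range_on_random_models():
    rng = np.random.default_rng(23)
    for seed in range(5):
        m = make_random_feasible_model(5, 10, seed=200 + seed)
        ups = uptake_exchange_ids(m)
        target = m.reaction_ids[-2]  # some non-biomass reaction
        for _ in range(5):
            env = random_bioavailability(rng, ups)
            ours = auxiliary_flux_range(m, env, target)
            oracle = fva_at_optimum(m, target, env_bound_overrides(m, env))
            assert ours[0] == pytest.approx(oracle[0], abs=1e-6)
            assert ours[1] == pytest.approx(oracle[1], abs=1e-6)


# -- composition ratios -----------------------------------------------------


def test_glycogen_ratio_is_carbon_scaled(toy1):
    # glycogen: 7 C, absent from biomass -> ratio = 7 x_glyc / x_bio
    assert component_ratio(toy1, 1.0, 1.0, "GLY") == pytest.approx(7.0)


def test_lipid_ratio_includes_biomass_draw():
    spec = QuotaChainSpec(
        storage=(StorageComponent("LIP", 33.0, 33.0, 0.128),), name="toy-lipid"
    )
    m = make_quota_chain_model(spec)
    # zero excess production: ratio is the fixed biomass contribution c*a
    assert component_ratio(m, 1.0, 0.0, "LIP") == pytest.approx(33.0 * 0.128)
    # a component absent from biomass with zero flux has ratio 0
    assert component_ratio(m, 2.0, 0.0, "C") == pytest.approx(0.0 + 1.0 * 5.0 * 2.0 / 2.0)


def test_ratio_undefined_at_zero_growth(toy1):
    with pytest.raises(UndefinedRatioError):
        component_ratio(toy1, 0.0, 1.0, "GLY")


# -- nutrient slacks --------------------------------------------------------


def test_slacks_at_reference_environment(toy1, toy1_niche):
    d = nutrient_slack(toy1, ENV_REFERENCE, niche=toy1_niche)
    assert d["EX_N"] == pytest.approx(1.0, abs=1e-5)
    assert d["EX_P"] == pytest.approx(0.0, abs=1e-5)
    assert d["CFIX"] == pytest.approx(7.0, abs=1e-5)


def test_limiting_nutrient_has_zero_slack(toy1, toy1_niche):
    d = nutrient_slack(toy1, ENV_N_LIMITED, niche=toy1_niche)
    assert d["EX_N"] == pytest.approx(0.0, abs=1e-5)


def test_exact_quota_environment_has_zero_slacks(toy1, toy1_niche):
    env = {"EX_N": 1.0, "EX_P": 0.2, "CFIX": 5.0}
    d = nutrient_slack(toy1, env, niche=toy1_niche)
    for rid in env:
        assert d[rid] == pytest.approx(0.0, abs=1e-5)


def test_slack_bounded_by_bioavailability_and_limitation(toy1, toy1_niche):
    rng = np.random.default_rng(31)
    for _ in range(10):
        env = random_bioavailability(rng, ["EX_N", "EX_P", "CFIX"], hi=3.0)
        d = nutrient_slack(toy1, env, niche=toy1_niche)
        for rid in env:
            assert -1e-7 <= d[rid] <= env[rid] + 1e-7
        # zero slack marks limitation: shrinking that nutrient reduces growth
        from metaniche import fba_max_biomass

        g0, _ = fba_max_biomass(toy1, env_bound_overrides(toy1, env))
        for rid in env:
            if d[rid] < 1e-7 and env[rid] > 0.01 and g0 > 1e-6:
                smaller = {**env, rid: env[rid] * 0.5}
                g1, _ = fba_max_biomass(toy1, env_bound_overrides(toy1, smaller))
                assert g1 < g0 - 1e-9


# -- resource constraints ---------------------------------------------------


def test_rc_min_max_orientation():
    rc, flagged = resource_constraint({"a": {"N": 1.0}, "b": {"N": 0.0}})
    assert not flagged
    assert rc["a"]["N"] == pytest.approx(0.0)  # largest slack: unconstrained
    assert rc["b"]["N"] == pytest.approx(100.0)  # smallest slack: limiting


def test_rc_constant_slack_is_flagged_uninformative():
    rc, flagged = resource_constraint({"a": {"N": 5.0}, "b": {"N": 5.0}})
    assert flagged == {"N"}
    assert rc["a"] == {}


def test_rc_bounds_and_extremes():
    rng = np.random.default_rng(41)
    slacks = {i: {"N": float(rng.uniform(0, 4)), "P": float(rng.uniform(0, 1))} for i in range(30)}
    rc, flagged = resource_constraint(slacks)
    assert not flagged
    for n in ("N", "P"):
        vals = [rc[i][n] for i in slacks]
        assert all(-1e-9 <= v <= 100 + 1e-9 for v in vals)
        assert max(vals) == pytest.approx(100.0)
        assert min(vals) == pytest.approx(0.0)
        i_min = min(slacks, key=lambda i: slacks[i][n])
        assert rc[i_min][n] == pytest.approx(100.0)


# -- glycogen storage index -------------------------------------------------


def test_index_direct_arithmetic():
    entries = glycogen_storage_index([(0.0, 10.0), (5.0, 10.0), (10.0, 10.0)])
    assert [e.index for e in entries] == pytest.approx([0.0, 0.5, 1.0])
    # mean index 0.5: below -> consumption, at/above -> storage
    assert entries[0].regime == "consumption"
    assert entries[1].regime == "storage"
    assert entries[2].regime == "storage"
    # implied consumption of the first entry: mean-index production minus actual
    assert entries[0].implied_consumption == pytest.approx(5.0)
    assert entries[2].implied_consumption == 0.0


def test_index_extremes_and_reference_ratio(toy1, toy1_niche):
    _, hi = auxiliary_flux_range(toy1, ENV_REFERENCE, "EX_GLY", niche=toy1_niche)
    carbon_flux = hi * 7.0
    entries = glycogen_storage_index([(carbon_flux, 12.0), (0.0, 12.0)])
    assert entries[0].r_stor == pytest.approx(7.0 / 12.0, abs=1e-5)
    assert entries[0].index == pytest.approx(1.0)
    assert entries[0].regime == "storage"
    assert entries[1].index == pytest.approx(0.0)
    assert entries[1].regime == "consumption"


def test_index_invariant_under_common_rescaling():
    base = [(0.0, 5.0), (2.0, 8.0), (3.0, 6.0), (1.0, 9.0)]
    scaled = [(g * 3.5, c * 3.5) for g, c in base]
    e0 = glycogen_storage_index(base)
    e1 = glycogen_storage_index(scaled)
    for a, b in zip(e0, e1):
        assert a.r_stor == pytest.approx(b.r_stor)
        assert a.index == pytest.approx(b.index)
        assert a.regime == b.regime


def test_index_inconsistent_entry_raises():
    with pytest.raises(ValueError, match="inconsistent"):
        glycogen_storage_index([(1.0, 0.0), (0.5, 1.0)])
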