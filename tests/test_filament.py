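"""Unit and property tests for the growing-filament simulator."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bundlekit.filament import (
    FilamentState,
    SimParams,
    compare_conditions,
    divide,
    elongate,
    init_filament,
    migration_extent,
    potential_energy,
    propose_turn,
    run,
    step,
    turn_probability,
)
from bundlekit.geometry import circle_intersection

PI = math.pi


# ---------------------------------------------------------------------------
# bending energy
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a1, a2, expected",
    [
        (PI, PI, 0.0),
        (PI / 2, PI, PI**2 / 4),
        (PI - 0.1, PI - 0.2, 0.05),
        (None, PI - 0.3, 0.09),   # end cell: missing junction contributes 0
        (None, None, 0.0),
    ],
)
def test_potential_energy_values(a1, a2, expected):
    assert potential_energy(a1, a2) == pytest.approx(expected, rel=1e-12)


@given(
    a1=st.floats(min_value=1e-6, max_value=PI),
    a2=st.floats(min_value=1e-6, max_value=PI),
)
def test_potential_energy_matches_direct_substitution(a1, a2):
    v = potential_energy(a1, a2)
    assert v == pytest.approx((PI - a1) ** 2 + (PI - a2) ** 2)
    assert v >= 0.0


def test_potential_energy_zero_iff_straight():
    assert potential_energy(PI, PI) == 0.0
    assert potential_energy(PI - 1e-3, PI) > 0.0


@pytest.mark.parametrize("bad", [0.0, -0.5, PI + 0.01, 4.0])
def test_potential_energy_rejects_invalid_angles(bad):
    with pytest.raises(ValueError):
        potential_energy(bad, PI)


# ---------------------------------------------------------------------------
# turning probability
# ---------------------------------------------------------------------------

def test_turn_probability_zero_without_energy_drop():
    assert turn_probability(1.0, 1.0, k=5.0) == 0.0
    assert turn_probability(1.0, 2.0, k=5.0) == 0.0  # uphill move never adopted


def test_turn_probability_half_at_log2_drop():
    # k * (Vc - Vn) = ln 2  ->  P = 1/2
    assert turn_probability(math.log(2.0), 0.0, k=1.0) == pytest.approx(0.5)
    assert turn_probability(1.0, 1.0 - math.log(2.0) / 3.0, k=3.0) == pytest.approx(0.5)


def test_turn_probability_limits_and_monotonicity():
    assert turn_probability(10.0, 0.0, k=1e6) == pytest.approx(1.0)
    assert turn_probability(1.0, 0.0, k=0.0) == 0.0
    ks = np.linspace(0.0, 20.0, 30)
    ps = [turn_probability(1.0, 0.3, k) for k in ks]
    assert np.all(np.diff(ps) >= 0)
    drops = np.linspace(0.0, 2.0, 30)
    ps = [turn_probability(d, 0.0, 2.0) for d in drops]
    assert np.all(np.diff(ps) >= 0)
    with pytest.raises(ValueError):
        turn_probability(1.0, 0.0, k=-1.0)


# ---------------------------------------------------------------------------
# circle intersection (the geometric workhorse)
# ---------------------------------------------------------------------------

@given(
    cx=st.floats(-1, 1), cy=st.floats(-1, 1),
    px=st.floats(-1, 1), py=st.floats(-1, 1),
    qx=st.floats(-1, 1), qy=st.floats(-1, 1),
)
def test_circle_intersection_points_lie_on_both_circles(cx, cy, px, py, qx, qy):
    # build radii from actual distances to a probe point so intersections exist
    r0 = math.hypot(px - cx, py - cy)
    r1 = math.hypot(px - qx, py - qy)
    if r0 < 1e-3 or r1 < 1e-3 or math.hypot(qx - cx, qy - cy) < 1e-3:
        return
    pts = circle_intersection((cx, cy), r0, (qx, qy), r1)
    assert pts is not None  # the probe point itself is a witness
    for (x, y) in pts:
        assert math.hypot(x - cx, y - cy) == pytest.approx(r0, rel=1e-9, abs=1e-12)
        assert math.hypot(x - qx, y - qy) == pytest.approx(r1, rel=1e-9, abs=1e-12)


def test_circle_intersection_none_when_apart():
    assert circle_intersection((0, 0), 1.0, (5, 0), 1.0) is None
    assert circle_intersection((0, 0), 5.0, (1, 0), 1.0) is None  # nested


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def test_init_filament_layout():
    p = SimParams(N=4, L0=0.1, S=0.1, seed=0)
    st_ = init_filament(p)
    np.testing.assert_allclose(st_.nodes[:, 0], [0.3, 0.4, 0.5, 0.6, 0.7], atol=1e-12)
    np.testing.assert_allclose(st_.nodes[:, 1], 0.0, atol=1e-15)
    assert migration_extent(st_) == 0.0
    assert st_.n_cells == 4


def test_init_filament_overflow_error():
    with pytest.raises(ValueError):
        SimParams(N=2, L0=0.6, S=0.6)


# ---------------------------------------------------------------------------
# elongation
# ---------------------------------------------------------------------------

def test_elongate_collinear_translates_shared_pole(straight_state, loose_params):
    """On a straight chain, growth toward the right neighbor is a pure +r
    translation of the shared pole; the neighbor's length is conserved by
    relocating its far pole."""
    r = 0.02
    old = straight_state.nodes.copy()
    new = elongate(straight_state, 2, r, "right", loose_params)
    nn = new.nodes
    # shared pole (node 3) translated along +x by exactly r
    np.testing.assert_allclose(nn[3], old[3] + [r, 0.0], atol=1e-12)
    # focal cell grew by r, neighbor length conserved
    lens = new.cell_lengths()
    assert lens[2] == pytest.approx(0.1 + r, abs=1e-12)
    assert lens[3] == pytest.approx(0.1, abs=1e-9)
    assert lens[4] == pytest.approx(0.1, abs=1e-9)
    # only nodes 3 and 4 moved
    for i in (0, 1, 2, 5):
        np.testing.assert_allclose(nn[i], old[i], atol=1e-15)
    assert not np.allclose(nn[4], old[4])


def test_elongate_rejects_out_of_domain(loose_params):
    xs = np.array([0.49, 0.59, 0.69, 0.79, 0.89, 0.99])
    state = FilamentState(np.column_stack([xs, np.full(6, 0.5)]))
    before = state.nodes.copy()
    new = elongate(state, 2, 0.25, "right", loose_params)  # pushes node past x = 1
    np.testing.assert_array_equal(new.nodes, before)


def test_elongate_toward_pinned_end_is_rejected(straight_state, loose_params):
    before = straight_state.nodes.copy()
    for cell, toward in [(4, "right"), (3, "right"), (0, "left"), (1, "left")]:
        new = elongate(straight_state, cell, 0.01, toward, loose_params)
        np.testing.assert_array_equal(new.nodes, before)


def test_elongate_above_max_length_divides(straight_state, loose_params):
    params = replace(loose_params, S=0.11)
    new = elongate(straight_state, 2, 0.02, "right", params)  # 0.12 > S
    assert new.n_cells == straight_state.n_cells + 1
    lens = new.cell_lengths()
    assert lens[2] == pytest.approx(0.06, abs=1e-12)
    assert lens[3] == pytest.approx(0.06, abs=1e-12)


def test_elongate_bad_index(straight_state, loose_params):
    with pytest.raises(IndexError):
        elongate(straight_state, 99, 0.01, "right", loose_params)


# ---------------------------------------------------------------------------
# division
# ---------------------------------------------------------------------------

def test_divide_conserves_shape_and_length(kinked_state, loose_params):
    params = replace(loose_params, S=0.05, L0=0.04)  # every cell is now "too long"
    before = kinked_state.nodes.copy()
    arc_before = kinked_state.arc_length()
    st_ = kinked_state.copy()
    divide(st_, 1, params)
    assert st_.n_cells == 4
    assert st_.arc_length() == pytest.approx(arc_before, rel=1e-12)
    # all pre-existing nodes untouched
    np.testing.assert_array_equal(st_.nodes[[0, 1, 3, 4]], before)
    # daughters equally long
    lens = st_.cell_lengths()
    assert lens[1] == pytest.approx(lens[2], rel=1e-12)


def test_divide_requires_overlong_cell(straight_state, loose_params):
    with pytest.raises(ValueError):
        divide(straight_state, 2, loose_params)  # 0.1 <= S = 0.2


# ---------------------------------------------------------------------------
# turning
# ---------------------------------------------------------------------------

def test_straight_filament_rejects_all_turns(straight_state, loose_params):
    """A straight chain is the global energy minimum: no proposal is ever
    adoptable (exact collinearity even makes length-preserving turns
    geometrically infeasible, since rotation pulls the shared pole away from
    the restoring anchor)."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        prop = propose_turn(straight_state, int(rng.integers(5)), rng, loose_params)
        assert not (prop.feasible and prop.v_new < prop.v_current)
        if prop.feasible:
            assert turn_probability(prop.v_current, prop.v_new, loose_params.k) == 0.0


def test_turn_preserves_all_cell_lengths(kinked_state, loose_params):
    rng = np.random.default_rng(11)
    lens_before = kinked_state.cell_lengths()
    found = 0
    for _ in range(300):
        prop = propose_turn(kinked_state, int(rng.integers(3)), rng, loose_params)
        if not prop.feasible:
            continue
        found += 1
        st_ = kinked_state.copy()
        st_._apply(prop.candidate)
        np.testing.assert_allclose(st_.cell_lengths(), lens_before, rtol=1e-9)
        assert len(prop.candidate) <= 2
    assert found > 50


def test_kink_straightening_is_favorable(kinked_state, loose_params):
    """Some proposal at the kinked junction lowers V and gets the closed-form
    acceptance probability."""
    rng = np.random.default_rng(3)
    seen_favorable = False
    for _ in range(500):
        prop = propose_turn(kinked_state, 1, rng, loose_params)
        if prop.feasible and prop.v_new < prop.v_current:
            seen_favorable = True
            p = turn_probability(prop.v_current, prop.v_new, loose_params.k)
            expected = 1.0 - math.exp(-loose_params.k * (prop.v_current - prop.v_new))
            assert p == pytest.approx(expected, rel=1e-12)
            assert 0.0 < p < 1.0
    assert seen_favorable


def test_turn_acceptance_matches_closed_form_frequency(loose_params):
    """Empirical acceptance over many Bernoulli draws sits inside the 99%
    binomial CI of the sign-corrected closed form, at three rigidities."""
    from scipy import stats as sps

    v_c, v_n = 0.35, 0.10
    rng = np.random.default_rng(2024)
    n = 10_000
    for k in (1.0, 5.0, 20.0):
        p = turn_probability(v_c, v_n, k)
        hits = int((rng.random(n) < p).sum())
        lo, hi = sps.binom.interval(0.99, n, p)
        assert lo <= hits <= hi


# ---------------------------------------------------------------------------
# stepping, running, degenerate limits
# ---------------------------------------------------------------------------

def test_same_seed_same_trajectory():
    p = SimParams(T=2_000, seed=42)
    t1 = run(p)
    t2 = run(p)
    np.testing.assert_array_equal(t1.migration, t2.migration)
    np.testing.assert_array_equal(t1.final_state.nodes, t2.final_state.nodes)


def test_zero_growth_freezes_filament():
    p = SimParams(T=2_000, G=0.0, seed=5)
    traj = run(p)
    np.testing.assert_array_equal(traj.final_state.nodes, init_filament(p).nodes)
    assert traj.migration.max() == 0.0


def test_pure_turning_conserves_arc_length():
    p = SimParams(T=2_000, p_turn=1.0, seed=6)
    traj = run(p)
    np.testing.assert_allclose(traj.arc_length, traj.arc_length[0], rtol=1e-9)
    assert traj.n_cells[-1] == p.N


def test_pure_growth_increases_cell_count():
    p = SimParams(T=3_000, p_turn=0.0, seed=7)
    traj = run(p)
    assert traj.n_cells[-1] > p.N
    assert np.all(np.diff(traj.n_cells) >= 0)
    assert np.all(np.diff(traj.arc_length) >= -1e-12)


def test_run_invariants_hold_under_audit():
    p = SimParams(T=5_000, seed=8)
    traj = run(p, validate_every=1_000)  # check_invariants raises on violation
    assert traj.final_state.step_count == p.T
    assert 0.0 <= migration_extent(traj.final_state) <= 1.0


def test_migration_extent_is_max_node_y(straight_state):
    assert migration_extent(straight_state) == pytest.approx(0.5)
    st_ = straight_state.copy()
    st_._apply({2: (0.45, 0.62)})
    assert migration_extent(st_) == pytest.approx(0.62)


def test_zero_step_run_records_initial_state():
    p = SimParams(T=0, seed=1)
    traj = run(p)
    assert traj.migration.tolist() == [0.0]
    assert traj.n_cells.tolist() == [p.N]


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

def test_identical_variant_has_unit_relative_rate():
    base = SimParams(T=1_500, seed=9)
    cmp = compare_conditions(base, {"same": base}, n_rep=2)
    row = cmp.table.set_index("condition")
    assert row.loc["same", "relative_rate"] == pytest.approx(1.0)
    np.testing.assert_array_equal(cmp.samples["base"], cmp.samples["same"])


def test_compare_conditions_requires_shared_T():
    base = SimParams(T=1_000, seed=0)
    with pytest.raises(ValueError):
        compare_conditions(base, {"bad": replace(base, T=500)}, n_rep=2)
    with pytest.raises(ValueError):
        compare_conditions(base, {}, n_rep=1)
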