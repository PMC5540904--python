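import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cxnav.cx_model import (
    ArchConfig,
    DynamicsConfig,
    N_EB,
    N_LAL,
    N_UNITS,
    Phenotype,
    UnitPool,
    apply_manipulation,
    build_cx,
    eb_index,
    lal_index,
    manipulation_bias,
    phenotype_from_csv,
    phenotype_to_csv,
    sample_phenotype,
    step_dynamics,
    transfer,
)
from cxnav.sensory_encoding import Condition


def test_transfer_values():
    assert transfer(0.0) == 0.0
    assert transfer(-5.0) == 0.0
    assert transfer(1.0) == pytest.approx(math.tanh(1.0))
    arr = transfer(np.array([-1.0, 0.0, 0.3]))
    assert arr[0] == 0.0 and arr[2] == pytest.approx(math.tanh(0.3))


def _free_pool(u0):
    """Pool with a single nonzero potential and no sensory input weights."""
    u = np.zeros(N_UNITS)
    u[0] = u0
    return UnitPool(u=u, y=transfer(u), b=np.zeros(N_UNITS))


def _silent_conn(n_inputs=14):
    """All fixed and input weights zero: pure leak dynamics."""
    arch = ArchConfig(lateral_inhibition=0.0, eb_lal_gating=0.0, lal_eb_feedback=0.0)
    ph = Phenotype(condition=Condition.COMBINED, weights=np.zeros((n_inputs, 32)))
    return build_cx(arch).with_phenotype(ph)


def test_forward_euler_pure_decay_step():
    """One Euler step of pure decay: u = 0.4 -> 0.36 at dt/tau = 0.1."""
    cfg = DynamicsConfig(integrator="euler")
    conn = _silent_conn()
    nxt = step_dynamics(_free_pool(0.4), conn, np.zeros(14), cfg)
    assert nxt.u[0] == pytest.approx(0.36)


def test_exponential_pure_decay_step_is_exact():
    cfg = DynamicsConfig()
    conn = _silent_conn()
    nxt = step_dynamics(_free_pool(0.4), conn, np.zeros(14), cfg)
    assert nxt.u[0] == pytest.approx(0.4 * math.exp(-0.1), abs=1e-14)


@pytest.mark.parametrize("integrator", ["euler", "exponential"])
def test_constant_input_converges_to_fixed_point(integrator):
    """With constant net input c, u converges to c for both integrators."""
    cfg = DynamicsConfig(integrator=integrator)
    ph = Phenotype(condition=Condition.COMBINED, weights=np.zeros((14, 32)))
    w = ph.weights.copy()
    w[0, 0] = 0.8  # input 0 drives EB unit (wedge 0, layer 0)
    arch = ArchConfig(lateral_inhibition=0.0, eb_lal_gating=0.0, lal_eb_feedback=0.0)
    conn = build_cx(arch).with_phenotype(
        Phenotype(condition=Condition.COMBINED, weights=w)
    )
    x = np.zeros(14)
    x[0] = 1.0
    pool = UnitPool.zeros()
    for _ in range(500):
        pool = step_dynamics(pool, conn, x, cfg)
    assert pool.u[0] == pytest.approx(0.8, abs=1e-6)
    assert pool.u[24] == pytest.approx(0.8, abs=1e-6)  # hemisphere mirror
    others = np.delete(pool.u, [0, 24])
    assert np.abs(others).max() == 0.0


def test_constant_input_trajectory_matches_fine_step_oracle():
    """At t = 0.5 s the default-step trajectory under constant net input
    matches a 100x-finer reference integration within 1e-3."""
    rng = np.random.default_rng(7)
    w = rng.uniform(-1, 1, size=(14, 32))
    arch = ArchConfig(lateral_inhibition=0.0, eb_lal_gating=0.0, lal_eb_feedback=0.0)
    conn = build_cx(arch).with_phenotype(
        Phenotype(condition=Condition.COMBINED, weights=w)
    )
    x = rng.uniform(0, 1, size=14)
    coarse = UnitPool.zeros()
    cfg = DynamicsConfig(dt=0.01)
    for _ in range(50):
        coarse = step_dynamics(coarse, conn, x, cfg)
    fine = UnitPool.zeros()
    cfg_fine = DynamicsConfig(dt=0.0001)
    for _ in range(5000):
        fine = step_dynamics(fine, conn, x, cfg_fine)
    assert np.abs(coarse.u - fine.u).max() < 1e-3


def test_dynamics_config_validation():
    with pytest.raises(ValueError):
        DynamicsConfig(dt=0.2, tau_g=0.1)
    with pytest.raises(ValueError):
        DynamicsConfig(dt=0.03, decision_interval=0.1)
    with pytest.raises(ValueError):
        DynamicsConfig(integrator="rk4")
    assert DynamicsConfig().steps_per_decision == 10
    assert DynamicsConfig().n_decisions() == 300


def test_step_dynamics_rejects_non_finite():
    conn = _silent_conn()
    pool = _free_pool(np.inf)
    with pytest.raises(Exception):
        step_dynamics(pool, conn, np.zeros(14), DynamicsConfig())


def test_build_cx_structure():
    conn = build_cx()
    assert conn.w_eb_lateral.shape == (48, 48)
    assert conn.w_eb_lal.shape == (16, 48)
    assert conn.w_lal_eb.shape == (48, 16)
    assert conn.recurrent.shape == (64, 64)
    arch = conn.arch

    # EB unit (hemi L, wedge 3, layer 2) inhibits exactly the 21 other-wedge
    # units of its own hemisphere and nothing across the midline
    src = eb_index(0, 3, 2)
    col = conn.w_eb_lateral[:, src]
    inhibited = np.flatnonzero(col)
    assert len(inhibited) == 21
    assert all(t < 24 for t in inhibited)  # same hemisphere only
    assert all(t // 3 != 3 for t in inhibited)  # never its own wedge
    assert np.allclose(col[inhibited], arch.lateral_inhibition)

    # off-center gating: wedge 5 projects to every LAL module except 5, in
    # both hemispheres
    src = eb_index(0, 5, 0)
    gate = conn.w_eb_lal[:, src]
    for hemi in range(2):
        for m in range(8):
            t = hemi * 8 + m
            if m == 5:
                assert gate[t] == 0.0
            else:
                assert gate[t] == arch.eb_lal_gating

    # feedback: LAL module i excites the three layers of wedge i, same side
    src = 1 * 8 + 2  # hemi R, module 2
    fb = conn.w_lal_eb[:, src]
    targets = np.flatnonzero(fb)
    assert sorted(targets) == [eb_index(1, 2, l) for l in range(3)]
    assert np.allclose(fb[targets], arch.lal_eb_feedback)


def test_sample_phenotype_deterministic_and_bounded():
    a = sample_phenotype(42)
    b = sample_phenotype(42)
    assert np.array_equal(a.weights, b.weights)
    assert a.weights.shape == (14, 32)
    assert a.weights.size == 448
    assert (np.abs(a.weights) <= 1).all()
    c = sample_phenotype(43)
    assert not np.array_equal(a.weights, c.weights)
    # intentional phenotypes carry the two bias-input rows
    d = sample_phenotype(42, Condition.INTENTIONAL)
    assert d.weights.shape == (16, 32)
    # hemisphere mirroring duplicates the shared columns
    full = a.input_matrix()
    assert full.shape == (14, 64)
    assert np.array_equal(full[:, :24], full[:, 24:48])
    assert np.array_equal(full[:, 48:56], full[:, 56:64])


def test_apply_manipulation_scopes():
    pool = UnitPool.zeros()
    assert not pool.b.any()  # default: all biases zero
    one_layer = apply_manipulation(pool, 0.5, "layer", layer=1)
    assert (one_layer.b != 0).sum() == 16
    assert np.allclose(one_layer.b[one_layer.b != 0], 0.5)
    assert not one_layer.b[N_EB:].any()
    all_eb = apply_manipulation(pool, -0.7, "all")
    assert np.allclose(all_eb.b[:N_EB], -0.7)
    assert not all_eb.b[N_EB:].any()
    with pytest.raises(ValueError):
        manipulation_bias(0.5, "wedge")


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), input_seed=st.integers(0, 10_000))
def test_activation_boundedness_property(seed, input_seed):
    """y stays in [0, 1) along any trajectory under bounded input."""
    ph = sample_phenotype(seed)
    conn = build_cx().with_phenotype(ph)
    x = np.random.default_rng(input_seed).uniform(0, 1, size=14)
    pool = UnitPool.zeros()
    cfg = DynamicsConfig()
    for _ in range(100):
        pool = step_dynamics(pool, conn, x, cfg)
        assert (pool.y >= 0).all() and (pool.y < 1).all()


def test_decay_to_rest_is_monotone():
    """With zero input and b = 0 the potential norm decays to 0, with
    half-life consistent with tau_g."""
    conn = _silent_conn()
    cfg = DynamicsConfig()
    u0 = np.random.default_rng(3).uniform(-1, 1, size=N_UNITS)
    pool = UnitPool(u=u0.copy(), y=transfer(u0), b=np.zeros(N_UNITS))
    norms = [np.linalg.norm(pool.u)]
    for _ in range(200):
        pool = step_dynamics(pool, conn, np.zeros(14), cfg)
        norms.append(np.linalg.norm(pool.u))
    assert all(b < a for a, b in zip(norms, norms[1:]))
    # after tau_g * ln 2 the norm should have halved (exact for exponential)
    n_half = int(round(math.log(2) * cfg.tau_g / cfg.dt))
    assert norms[n_half] == pytest.approx(norms[0] / 2, rel=1e-2)


def _two_wedge_conn(arch=None):
    w = np.zeros((14, 32))
    for l in range(3):
        w[0, 6 + l] = 1.0   # input 0 -> wedge 2
        w[1, 15 + l] = 1.0  # input 1 -> wedge 5
    w[0, 24 + 2] = 1.0
    w[1, 24 + 5] = 1.0
    ph = Phenotype(condition=Condition.COMBINED, weights=w)
    return build_cx(arch or ArchConfig()).with_phenotype(ph)


def _run_constant(conn, x, pool=None, seconds=3.0, cfg=None):
    cfg = cfg or DynamicsConfig()
    pool = pool or UnitPool.zeros()
    for _ in range(int(round(seconds / cfg.dt))):
        pool = step_dynamics(pool, conn, x, cfg)
    return pool


def _wedge_mean(pool, wedge, hemi=0):
    idx = [eb_index(hemi, wedge, l) for l in range(3)]
    return pool.y[idx].mean()


def test_winner_take_all_and_adaptation():
    """The stronger of two competing wedges wins, suppresses the weaker below
    the motor threshold, and the selection flips when the inputs swap."""
    conn = _two_wedge_conn()
    x = np.zeros(14)
    x[0], x[1] = 0.9, 0.6
    pool = _run_constant(conn, x)
    assert _wedge_mean(pool, 2) > _wedge_mean(pool, 5)
    assert _wedge_mean(pool, 2) > 0.5
    assert _wedge_mean(pool, 5) < 0.5

    # fine-step oracle agrees on the winner
    fine = _run_constant(conn, x, cfg=DynamicsConfig(dt=0.001, decision_interval=0.1))
    assert _wedge_mean(fine, 2) > _wedge_mean(fine, 5)
    assert abs(_wedge_mean(fine, 2) - _wedge_mean(pool, 2)) < 0.01

    # adaptation: swapping the input strengths flips the winner
    x[0], x[1] = 0.6, 0.9
    pool = _run_constant(conn, x, pool=pool)
    assert _wedge_mean(pool, 5) > _wedge_mean(pool, 2)
    assert _wedge_mean(pool, 5) > 0.5


def test_hemisphere_symmetry():
    """Mirror-symmetric weights and shared input give identical left and
    right trajectories."""
    ph = sample_phenotype(11)
    conn = build_cx().with_phenotype(ph)
    x = np.random.default_rng(5).uniform(0, 1, size=14)
    pool = UnitPool.zeros()
    cfg = DynamicsConfig()
    for _ in range(150):
        pool = step_dynamics(pool, conn, x, cfg)
        assert np.array_equal(pool.u[:24], pool.u[24:48])
        assert np.array_equal(pool.u[48:56], pool.u[56:64])


def test_phenotype_csv_round_trip(tmp_path):
    ph = sample_phenotype((9, 4), Condition.INTENTIONAL)
    text = phenotype_to_csv(ph)
    back = phenotype_from_csv(text)
    assert back.condition == ph.condition
    assert back.seed == (9, 4)
    assert np.array_equal(back.weights, ph.weights)
    assert phenotype_to_csv(back) == text
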