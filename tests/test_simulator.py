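"""Bloch-McConnell engine: closed forms, invariants, oracle agreement."""

import numpy as np
import pytest

from cestgen import (
    Pool,
    TissueSystem,
    build_generator,
    propagate_interval,
    run_schedule_element,
    simulate_trajectory,
    simulate_zspectrum,
    two_pool,
    water_only,
)
from cestgen.sequences import SaturationPulse, ScheduleElement, uniform_protocol
from conftest import integrate_reference, random_system


# ---------------------------------------------------------------------------
# generator assembly


def test_water_only_equilibrium_is_null_drift(water_system):
    a, b = build_generator(water_system, 0.0, 0.0, 9.4)
    assert a.shape == (3, 3)
    assert np.abs(a @ np.array([0.0, 0.0, 1.0]) + b).max() < 1e-12


def test_equilibrium_null_drift_multi_pool(amine_system):
    a, b = build_generator(amine_system, 0.0, 3.0, 9.4)
    m_eq = amine_system.equilibrium()
    assert np.abs(a @ m_eq + b).max() < 1e-10


def test_zero_fraction_solute_decouples_water_block(water_system):
    coupled = two_pool(2.5, 0.8, 1.5, 0.01, 0.0, 500.0, 3.0)
    a2, b2 = build_generator(coupled, 1.0, 2.0, 9.4)
    a1, b1 = build_generator(water_system, 1.0, 2.0, 9.4)
    assert np.allclose(a2[:3, :3], a1)
    assert np.allclose(b2[:3], b1)


def test_generator_rejects_super_lorentzian_cest_pool():
    with pytest.raises(ValueError):
        TissueSystem(
            Pool("water", 2.0, 0.1),
            (Pool("s", 2.0, 0.01, 0.01, 50, 3.5, "super-lorentzian"),),
        )


def test_semisolid_pool_adds_single_z_row():
    sys_mt = two_pool(1.8, 0.05, 1.4, 4e-5, 0.1, 30.0, -2.4,
                      lineshape="super-lorentzian")
    a, b = build_generator(sys_mt, 2.0, 8.0, 9.4)
    assert a.shape == (4, 4)
    # semisolid Mz row: no transverse coupling
    assert np.allclose(a[3, :2], 0.0)
    # saturation rate strictly increases with B1
    a2, _ = build_generator(sys_mt, 4.0, 8.0, 9.4)
    assert a2[3, 3] < a[3, 3] < 0


# ---------------------------------------------------------------------------
# propagation


def test_t1_recovery_closed_form(water_system):
    a, b = build_generator(water_system, 0.0, 0.0, 3.0)
    m = propagate_interval(np.zeros(3), a, b, water_system.water.t1_s)
    assert abs(m[2] - (1 - np.exp(-1))) < 1e-12


def test_propagation_semigroup(amine_system):
    a, b = build_generator(amine_system, 2.0, 3.0, 9.4)
    m0 = amine_system.equilibrium()
    one = propagate_interval(m0, a, b, 0.6)
    two = propagate_interval(propagate_interval(m0, a, b, 0.3), a, b, 0.3)
    assert np.abs(one - two).max() < 1e-10


def test_two_pool_steady_state_matches_adaptive_oracle(amine_system):
    from scipy.integrate import solve_ivp

    a, b = build_generator(amine_system, 2.0, 3.0, 9.4)
    m = propagate_interval(amine_system.equilibrium(), a, b, 20.0)
    sol = solve_ivp(lambda t, y: a @ y + b, (0, 20.0),
                    amine_system.equilibrium(), rtol=1e-9, atol=1e-11)
    assert np.abs(m - sol.y[:, -1]).max() < 1e-6


# ---------------------------------------------------------------------------
# schedule execution


def test_full_recovery_full_excitation_reads_one(water_system):
    el = ScheduleElement(SaturationPulse(b1_ut=0.0, tp_s=0.01),
                         trec_s=60.0, fa_deg=90.0)
    s, _ = run_schedule_element(water_system.equilibrium(), el,
                                water_system, 3.0)
    assert abs(s - 1.0) < 1e-8


def test_readout_scales_longitudinal_by_cos(water_system):
    el = ScheduleElement(SaturationPulse(b1_ut=0.0, tp_s=1e-6),
                         trec_s=0.0, fa_deg=60.0)
    s, state = run_schedule_element(water_system.equilibrium(), el,
                                    water_system, 3.0)
    assert abs(s - np.sin(np.deg2rad(60.0))) < 1e-6
    assert abs(state[2] - np.cos(np.deg2rad(60.0))) < 1e-6
    assert state[0] == state[1] == 0.0


def test_degenerate_train_equals_single_block(amine_system):
    # n_p pulses with zero gap and a CW shape == one long CW block
    base = ScheduleElement(SaturationPulse(b1_ut=2.0, tp_s=0.5),
                           offset_ppm=3.0, n_p=4, gap_s=0.0,
                           trec_s=1.0, fa_deg=90.0)
    merged = ScheduleElement(SaturationPulse(b1_ut=2.0, tp_s=2.0),
                             offset_ppm=3.0, n_p=1, gap_s=0.0,
                             trec_s=1.0, fa_deg=90.0)
    s_train, _ = run_schedule_element(amine_system.equilibrium(), base,
                                      amine_system, 9.4)
    s_block, _ = run_schedule_element(amine_system.equilibrium(), merged,
                                      amine_system, 9.4)
    assert abs(s_train - s_block) < 1e-9


def test_trajectory_matches_end_to_end_oracle(amine_system):
    rng = np.random.default_rng(7)
    protocol = uniform_protocol(
        3.0, rng.uniform(0.25, 6.0, 8), 3.0, tp_s=1.0, trec_s=1.0, fa_deg=70.0
    )
    traj = simulate_trajectory(amine_system, protocol)
    ref = integrate_reference(amine_system, protocol)
    assert np.abs(traj.values - ref).max() < 1e-6


def test_oracle_equivalence_over_seeded_random_systems():
    """Matrix-exponential propagation vs adaptive integration, many systems."""
    rng = np.random.default_rng(11)
    worst = 0.0
    for _ in range(12):
        system = random_system(rng)
        protocol = uniform_protocol(
            3.0,
            rng.uniform(0.25, 6.0, 3),
            rng.uniform(-1.0, 1.0),
            tp_s=rng.uniform(0.3, 1.2),
            trec_s=rng.uniform(0.3, 1.2),
            fa_deg=rng.uniform(60, 90),
        )
        traj = simulate_trajectory(system, protocol)
        ref = integrate_reference(system, protocol)
        worst = max(worst, np.abs(traj.values - ref).max())
    assert worst < 1e-6


def test_shaped_pulse_train_matches_oracle_with_semisolid():
    rng = np.random.default_rng(13)
    system = random_system(rng, n_solutes=1, semisolid=True)
    protocol = uniform_protocol(
        3.0, [2.0, 3.5], 3.0, tp_s=0.08, trec_s=0.6, fa_deg=90.0,
        shape="sinc-gaussian", n_p=2, gap_s=0.01, n_segments=8,
    )
    traj = simulate_trajectory(system, protocol)
    ref = integrate_reference(system, protocol)
    assert np.abs(traj.values - ref).max() < 1e-6


def test_equilibrium_is_fixed_point_without_saturation(amine_system):
    a, b = build_generator(amine_system, 0.0, 3.0, 9.4)
    m = propagate_interval(amine_system.equilibrium(), a, b, 5.0)
    assert np.abs(m - amine_system.equilibrium()).max() < 1e-10


def test_signal_bounds_and_pool_order_invariance():
    rng = np.random.default_rng(17)
    water = Pool("water", 2.0, 0.5)
    p1 = Pool("a", 1.5, 0.01, 0.01, 300.0, 3.5)
    p2 = Pool("b", 2.0, 0.02, 0.005, 50.0, -3.5)
    sys_ab = TissueSystem(water, (p1, p2))
    sys_ba = TissueSystem(water, (p2, p1))
    protocol = uniform_protocol(9.4, rng.uniform(0.25, 6.0, 6), 3.5,
                                tp_s=2.0, trec_s=1.5, fa_deg=80.0)
    t_ab = simulate_trajectory(sys_ab, protocol).values
    t_ba = simulate_trajectory(sys_ba, protocol).values
    assert np.abs(t_ab - t_ba).max() < 1e-12
    assert (t_ab >= 0).all() and (t_ab <= 1).all()


def test_decoupled_recovery_is_water_closed_form():
    system = two_pool(2.0, 0.1, 1.5, 0.01, 0.0, 800.0, 3.0)  # f = 0
    a, b = build_generator(system, 0.0, 0.0, 9.4)
    m = np.zeros(6)
    for dt in (0.3, 1.0, 2.7):
        out = propagate_interval(m, a, b, dt)
        assert abs(out[2] - (1 - np.exp(-dt / 2.0))) < 1e-8


# ---------------------------------------------------------------------------
# Z-spectra


def test_water_only_zspectrum_symmetry(water_system):
    offs = np.linspace(-5, 5, 21)
    base = ScheduleElement(SaturationPulse(b1_ut=2.0, tp_s=2.0),
                           trec_s=8.0, fa_deg=90.0)
    z = simulate_zspectrum(water_system, offs, base, 9.4).values
    assert np.abs(z - z[::-1]).max() < 1e-9


def test_zero_fraction_matches_water_only(water_system):
    offs = np.linspace(-4, 4, 9)
    base = ScheduleElement(SaturationPulse(b1_ut=2.0, tp_s=2.0),
                           trec_s=5.0, fa_deg=90.0)
    ghost = two_pool(2.5, 0.8, 1.5, 0.01, 0.0, 500.0, 3.0)
    z0 = simulate_zspectrum(water_system, offs, base, 9.4).values
    z1 = simulate_zspectrum(ghost, offs, base, 9.4).values
    assert np.abs(z0 - z1).max() < 1e-10


def test_amide_asymmetry_sign(amine_system):
    sys_amide = two_pool(2.5, 0.8, 2.5, 0.01, 0.003, 50.0, 3.5)
    base = ScheduleElement(SaturationPulse(b1_ut=1.0, tp_s=3.0),
                           trec_s=6.0, fa_deg=90.0)
    z = simulate_zspectrum(sys_amide, [-3.5, 3.5], base, 9.4).values
    assert z[0] - z[1] > 1e-3


def test_zspectrum_monotone_in_fraction_and_b1():
    base = ScheduleElement(SaturationPulse(b1_ut=1.0, tp_s=4.0),
                           trec_s=8.0, fa_deg=90.0)
    z_f = []
    for f in (0.001, 0.003, 0.01, 0.03):
        system = two_pool(2.5, 0.8, 2.5, 0.01, f, 500.0, 3.0)
        z_f.append(simulate_zspectrum(system, [3.0], base, 9.4).values[0])
    assert (np.diff(z_f) < 0).all()
    system = two_pool(2.5, 0.8, 2.5, 0.01, 0.003, 500.0, 3.0)
    z_b = []
    for b1 in (0.25, 0.8, 1.6, 3.0):
        el = ScheduleElement(SaturationPulse(b1_ut=b1, tp_s=4.0),
                             trec_s=8.0, fa_deg=90.0)
        z_b.append(simulate_zspectrum(system, [3.0], el, 9.4).values[0])
    assert (np.diff(z_b) < 0).all()


def test_zspectrum_rejects_empty_or_nonfinite_offsets(water_system):
    base = ScheduleElement(SaturationPulse(b1_ut=1.0, tp_s=1.0))
    with pytest.raises(ValueError):
        simulate_zspectrum(water_system, [], base, 9.4)
    with pytest.raises(ValueError):
        simulate_zspectrum(water_system, [np.inf], base, 9.4)


# ---------------------------------------------------------------------------
# discretization convergence


def test_shaped_pulse_segment_convergence(amine_system):
    """64 segments change the trajectory < 0.1% vs 256 segments."""
    trajs = {}
    for n_seg in (64, 256):
        protocol = uniform_protocol(
            9.4, [2.0, 4.0, 1.0], 3.0, tp_s=0.1, trec_s=2.0, fa_deg=90.0,
            shape="sinc-gaussian", n_p=10, gap_s=0.01, n_segments=n_seg,
        )
        trajs[n_seg] = simulate_trajectory(amine_system, protocol).values
    rel = np.abs(trajs[64] - trajs[256]) / np.abs(trajs[256])
    assert rel.max() < 1e-3


def test_all_zero_saturation_long_recovery_constant_trajectory(water_system):
    protocol = uniform_protocol(3.0, np.zeros(5), 0.0, tp_s=1.0,
                                trec_s=40.0, fa_deg=75.0)
    traj = simulate_trajectory(water_system, protocol).values
    assert np.abs(traj - np.sin(np.deg2rad(75.0))).max() < 1e-6
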