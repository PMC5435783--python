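import numpy as np
import pytest

from umiflow import (
    BoundaryCondition,
    DopplerFrame,
    FeedbackConfig,
    FlowField,
    SolverSettings,
    error_norm,
    estimate_inlet_velocity,
    feedback_force,
    golden_section_minimize,
    project_doppler,
    run_simulation,
    solve_steady,
)
from tests.conftest import BEAM_20, frames_from_fields


def test_project_doppler_uniform_and_oracle(small_grid):
    f = FlowField.zeros(small_grid)
    beam_y = np.array([0.0, 1.0])
    assert np.allclose(project_doppler(f, beam_y, small_grid), 0.0)

    f.v[:, :] = 0.2
    assert np.allclose(project_doppler(f, beam_y, small_grid), 0.2)

    # 20-degree beam on a known parabolic u field: pointwise u sin20 + v cos20
    rng = np.random.default_rng(1)
    f2 = FlowField.zeros(small_grid)
    f2.u = rng.normal(size=f2.u.shape)
    f2.v = rng.normal(size=f2.v.shape)
    vc = project_doppler(f2, BEAM_20, small_grid)
    u_c = 0.5 * (f2.u[:, :-1] + f2.u[:, 1:])
    v_c = 0.5 * (f2.v[:-1, :] + f2.v[1:, :])
    np.testing.assert_allclose(vc, u_c * BEAM_20[0] + v_c * BEAM_20[1], rtol=1e-12)

    with pytest.raises(ValueError, match="unit"):
        project_doppler(f, np.array([0.5, 0.5]), small_grid)


def test_feedback_force_magnitude_and_trivials(small_grid):
    cfg = FeedbackConfig(k_v_star=500.0, u_char=0.1, l_char=6.4e-3, rho=1000.0)
    shape = (small_grid.ny, small_grid.nx)
    vm = np.zeros(shape)

    # V_c = V_m -> no force
    f = feedback_force(vm, vm, cfg, BEAM_20)
    assert np.all(f == 0.0)

    # K = 0 -> ordinary simulation, no force
    f = feedback_force(vm + 0.3, vm, FeedbackConfig(k_v_star=0.0), BEAM_20)
    assert np.all(f == 0.0)

    # |f| = K rho U / L * dV = 78125 N/m^3 for dV = 0.01 m/s, along -beam
    vc = vm + 0.01
    f = feedback_force(vc, vm, cfg, BEAM_20)
    mag = np.linalg.norm(f, axis=-1)
    assert mag.max() == pytest.approx(78125.0, rel=1e-12)
    assert np.dot(f[0, 0], BEAM_20) < 0  # drives V_c down toward V_m

    with pytest.raises(ValueError, match="misaligned"):
        feedback_force(np.zeros((3, 3)), np.zeros((3, 4)), cfg, BEAM_20)


def test_feedback_force_zero_outside_domain(small_grid):
    cfg = FeedbackConfig()
    shape = (small_grid.ny, small_grid.nx)
    f = feedback_force(np.ones(shape), np.zeros(shape), cfg, BEAM_20,
                       grid=small_grid, valid=small_grid.fluid)
    mask = cfg.domain_mask(small_grid)
    assert np.all(f[~mask] == 0.0)
    assert np.any(f[mask] != 0.0)
    frac = (np.arange(small_grid.nx) + 0.5) / small_grid.nx
    inside = (frac >= 1 / 36) & (frac <= 29 / 36)
    assert np.array_equal(mask.any(axis=0), inside)


def test_error_norm_values_and_oracle():
    v = np.zeros((5, 4))
    assert error_norm(v, v, np.ones_like(v, bool)) == 0.0
    # uniform |V_c - V_m| = 0.039, V_type = 0.39 -> e = 0.1
    assert error_norm(v + 0.039, v, np.ones_like(v, bool), 0.39) == pytest.approx(0.1)

    rng = np.random.default_rng(7)
    a, b = rng.normal(size=(6, 6)), rng.normal(size=(6, 6))
    mask = rng.random((6, 6)) > 0.4
    brute = sum(abs(a[i, j] - b[i, j]) for i in range(6) for j in range(6)
                if mask[i, j]) / mask.sum() / 0.39
    assert error_norm(a, b, mask, 0.39) == pytest.approx(brute, rel=1e-12)

    with pytest.raises(ValueError, match="N_e"):
        error_norm(a, b, np.zeros((6, 6), bool))


def test_golden_section_on_quadratic():
    x, fx = golden_section_minimize(lambda x: (x - 0.3) ** 2, (0.0, 1.0), tol=1e-4)
    assert abs(x - 0.3) < 1e-4
    with pytest.raises(ValueError):
        golden_section_minimize(lambda x: x, (1.0, 0.0), tol=1e-3)


def test_inlet_recovery_on_noiseless_twin(small_grid, props, settings):
    truth = solve_steady(small_grid, BoundaryCondition(0.25), props, settings,
                         tol=1e-6)
    vm = np.where(small_grid.fluid, project_doppler(truth, BEAM_20, small_grid), 0.0)
    frame = DopplerFrame(vm=vm, beam=BEAM_20, t=0.0, valid=small_grid.fluid)
    u_est, _, e = estimate_inlet_velocity(
        frame, truth, small_grid, props, FeedbackConfig(), settings,
        bracket=(0.05, 0.6), gain=0.0,
    )
    assert abs(u_est - 0.25) < 0.005
    assert e < 1e-3


def test_umi_reproduces_ordinary_when_vm_equals_its_projection(
    small_grid, props, settings, small_twin
):
    """V_m identical to the unforced solution's projection => force ~ 0."""
    frames = small_twin["frames"][:5]
    cfg = FeedbackConfig()
    res_ord = run_simulation(frames, small_grid, props, cfg, settings,
                             mode="ordinary")
    frames_self = frames_from_fields(res_ord.fields, small_grid)
    res_umi = run_simulation(frames_self, small_grid, props, cfg, settings,
                             mode="umi")
    # feedback has nothing to correct: both runs agree to within the
    # solver's residual tolerance acting on the velocity scale
    assert res_umi.error_norm.e.max() < 5e-3
    du = np.abs(res_umi.fields[-1].u - res_ord.fields[-1].u).max()
    assert du < 0.02
    assert np.abs(res_umi.inlet_velocity - res_ord.inlet_velocity).max() < 0.02


def test_assimilation_beats_ordinary_on_skewed_twin(
    small_grid, props, settings, small_twin
):
    frames = small_twin["frames"]
    res_umi = run_simulation(frames, small_grid, props, FeedbackConfig(),
                             settings, mode="umi")
    res_ord = run_simulation(frames, small_grid, props, FeedbackConfig(),
                             settings, mode="ordinary")
    e_u, e_o = res_umi.error_norm.e, res_ord.error_norm.e
    assert (e_u[3:] < e_o[3:]).all()
    assert e_u.mean() < 0.5 * e_o.mean()
    assert res_umi.error_norm.n_points == res_ord.error_norm.n_points > 0


def test_run_simulation_rejects_bad_inputs(small_grid, props, settings, small_twin):
    with pytest.raises(ValueError, match="mode"):
        run_simulation(small_twin["frames"], small_grid, props, FeedbackConfig(),
                       settings, mode="magic")
    shuffled = [small_twin["frames"][2], small_twin["frames"][0]]
    with pytest.raises(ValueError, match="time-ordered"):
        run_simulation(shuffled, small_grid, props, FeedbackConfig(), settings)


def test_feedback_config_validation():
    with pytest.raises(ValueError, match="non-negative"):
        FeedbackConfig(k_v_star=-1.0)
    with pytest.raises(ValueError, match="fractions"):
        FeedbackConfig(domain_x=(0.8, 0.2))
    assert FeedbackConfig().dimensional_gain == pytest.approx(500 * 1000 * 0.1 / 6.4e-3)
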