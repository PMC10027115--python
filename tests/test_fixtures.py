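"""Fixture models: logistic growth, the chemotaxis walk, mocks and targets."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellcalib import quantify
from cellcalib.blackbox import BlackBoxModel, make_external_runner, run_model
from cellcalib.fixtures import (
    DEFAULT_TIME_GRID,
    ChemotaxisScenario,
    LogisticParams,
    generate_target,
    logistic_growth,
    make_logistic_model,
    make_mock_executable,
    simulate_chemotaxis,
    write_fixture_settings,
)


# --- logistic growth


def test_logistic_starts_at_initial_population():
    params = LogisticParams(K=500.0, r=0.3, N0=7.0, t_grid=np.array([0.0, 1.0]))
    assert logistic_growth(params)[0] == pytest.approx(7.0)


def test_logistic_carrying_capacity_is_a_fixed_point():
    params = LogisticParams(K=1000.0, r=0.1, N0=1000.0)
    np.testing.assert_allclose(logistic_growth(params), 1000.0)


def test_logistic_reference_value_and_ode_oracle():
    """Closed form at t=100 (K=1000, N0=10, r=0.1) against the frozen value
    and an independent numerical integration of dN/dt = rN(1 - N/K)."""
    params = LogisticParams(K=1000.0, r=0.1, N0=10.0, t_grid=np.array([0.0, 100.0]))
    value = logistic_growth(params)[-1]
    assert value == pytest.approx(995.5255179295148, rel=1e-12)

    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        lambda t, n: 0.1 * n * (1 - n / 1000.0),
        (0.0, 100.0),
        [10.0],
        rtol=1e-10,
        atol=1e-10,
    )
    assert value == pytest.approx(sol.y[0, -1], rel=1e-6)


@given(
    st.floats(min_value=50.0, max_value=5000.0),
    st.floats(min_value=0.01, max_value=1.0),
    st.floats(min_value=1.0, max_value=10000.0),
)
@settings(deadline=None, derandomize=True)
def test_logistic_monotonicity(K, r, N0):
    curve = logistic_growth(LogisticParams(K=K, r=r, N0=N0))
    diffs = np.diff(curve)
    if N0 < K:
        assert np.all(diffs >= 0)
    elif N0 > K:
        assert np.all(diffs <= 0)


def test_logistic_invalid_params_rejected():
    with pytest.raises(ValueError):
        LogisticParams(K=-1.0, r=0.1)
    with pytest.raises(ValueError):
        LogisticParams(K=10.0, r=0.1, t_grid=np.array([1.0, 1.0]))


# --- chemotaxis walk


def test_full_bias_is_deterministic_gradient_following():
    scenario = ChemotaxisScenario(speed=3.0, migration_bias=1.0, n_cells=50, seed=2)
    initial, final = simulate_chemotaxis(scenario, return_initial=True)
    # straight +y travel: x unchanged, y advanced by speed * duration (or wall)
    np.testing.assert_allclose(final[:, 0], initial[:, 0])
    expected_y = np.minimum(initial[:, 1] + 3.0 * 120.0, scenario.y_max)
    np.testing.assert_allclose(final[:, 1], expected_y, atol=1e-9)


def test_full_bias_fast_cells_reach_the_far_wall():
    scenario = ChemotaxisScenario(speed=5.0, migration_bias=1.0, n_cells=20, seed=0)
    final = simulate_chemotaxis(scenario)
    np.testing.assert_allclose(final[:, 1], scenario.y_max)


def test_zero_bias_walk_is_unbiased():
    """Pure random walk: mean y-displacement ~ 0 within Monte-Carlo error."""
    # seed cells uniformly over the whole domain so wall clamping is
    # symmetric and cannot masquerade as drift
    scenario = ChemotaxisScenario(
        speed=2.0,
        migration_bias=0.0,
        n_cells=2000,
        seed=3,
        duration=30.0,
        start_band=500.0,
    )
    initial, final = simulate_chemotaxis(scenario, return_initial=True)
    displacement = final[:, 1] - initial[:, 1]
    sem = displacement.std() / np.sqrt(len(displacement))
    assert abs(displacement.mean()) < 3.0 * sem + 1e-9


def test_mean_final_y_monotone_in_bias_and_speed():
    """Chemotactic drift increases with bias at fixed speed and with speed
    at fixed bias (fixed-seed ensembles, 3x standard-error tolerance)."""

    def mean_y(speed, bias):
        scenario = ChemotaxisScenario(
            speed=speed, migration_bias=bias, n_cells=1000, seed=8, duration=30.0
        )
        y = simulate_chemotaxis(scenario)[:, 1]
        return y.mean(), 3.0 * y.std() / np.sqrt(len(y))

    means = [mean_y(2.0, b) for b in (0.1, 0.3, 0.5, 0.7, 0.9)]
    for (lo, tol_lo), (hi, tol_hi) in zip(means, means[1:]):
        assert hi >= lo - tol_lo - tol_hi
    means = [mean_y(v, 0.5) for v in (0.5, 1.0, 2.0, 4.0)]
    for (lo, tol_lo), (hi, tol_hi) in zip(means, means[1:]):
        assert hi >= lo - tol_lo - tol_hi


def test_high_bias_population_shifted_toward_far_wall():
    """At equal speed, bias 0.9 ends much closer to the attractant than 0.1."""
    high = simulate_chemotaxis(ChemotaxisScenario(speed=2.0, migration_bias=0.9, seed=5))
    low = simulate_chemotaxis(ChemotaxisScenario(speed=2.0, migration_bias=0.1, seed=5))
    assert high[:, 1].mean() > low[:, 1].mean() + 50.0


def test_unstable_persistence_discretization_rejected():
    with pytest.raises(ValueError, match="persistence"):
        ChemotaxisScenario(speed=1.0, migration_bias=0.5, dt=2.0, persistence_time=1.0)


def test_bias_outside_unit_interval_rejected():
    with pytest.raises(ValueError, match="migration_bias"):
        ChemotaxisScenario(speed=1.0, migration_bias=1.2)


def test_same_seed_reproducible_different_seed_not():
    scenario = ChemotaxisScenario(speed=2.0, migration_bias=0.5, seed=9, duration=10.0)
    a = simulate_chemotaxis(scenario)
    b = simulate_chemotaxis(scenario)
    c = simulate_chemotaxis(dataclasses.replace(scenario, seed=10))
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


# --- mock executables and targets


def test_logistic_mock_outputs_feed_every_quantify_operation(tmp_path):
    exe = make_mock_executable("logistic", tmp_path)
    settings_file = write_fixture_settings(tmp_path / "settings.xml", max_time=100.0)
    model = BlackBoxModel(
        runner=make_external_runner(exe),
        processor=quantify.cell_count_series,
        config_path=settings_file,
    )
    (counts,) = run_model(model, {}, seed=0)
    expected = np.round(
        logistic_growth(LogisticParams(K=1000.0, r=0.1, N0=10.0, t_grid=DEFAULT_TIME_GRID))
    )
    np.testing.assert_array_equal(counts, expected)


def test_logistic_mock_final_count_matches_curve_endpoint(tmp_path):
    exe = make_mock_executable("logistic", tmp_path)
    settings_file = write_fixture_settings(tmp_path / "settings.xml", max_time=100.0)

    model = BlackBoxModel(
        runner=make_external_runner(exe),
        processor=lambda outdir: [quantify.final_cell_count(outdir)],
        config_path=settings_file,
    )
    (count,) = run_model(model, {}, seed=0)
    assert count[0] == round(995.5255179295148)


def test_chemotaxis_mock_full_bias_reaches_wall(tmp_path):
    settings_file = write_fixture_settings(
        tmp_path / "settings.xml", speed=5.0, migration_bias=1.0
    )
    exe = make_mock_executable("chemotaxis", tmp_path)
    model = BlackBoxModel(
        runner=make_external_runner(exe),
        processor=lambda outdir: quantify.final_coordinates(outdir, axis="y"),
        config_path=settings_file,
    )
    (ys,) = run_model(model, {}, seed=0)
    np.testing.assert_allclose(ys, 250.0)


def test_unknown_mock_model_rejected(tmp_path):
    with pytest.raises(ValueError):
        make_mock_executable("gray_scott", tmp_path)


def test_generate_target_logistic_curve_shape(tmp_path):
    target = generate_target(
        "logistic", {"r": 0.1, "K": 1000.0}, path=tmp_path / "target.csv"
    )
    assert target.values[0] == pytest.approx(10.0)  # N(0) = N0
    assert target.values[-1] == pytest.approx(1000.0, rel=0.01)  # -> K
    reread = quantify.read_target(tmp_path / "target.csv")
    np.testing.assert_allclose(reread.values, target.values)


def test_generate_target_chemotaxis_is_seeded(tmp_path):
    a = generate_target("chemotaxis", {"speed": 2.0, "bias": 0.9}, seed=6)
    b = generate_target("chemotaxis", {"speed": 2.0, "bias": 0.9}, seed=6)
    np.testing.assert_array_equal(a.values, b.values)


def test_self_consistency_error_is_zero_at_truth():
    """Evaluating the deterministic logistic model at the target-generating
    parameters gives exactly zero error."""
    target = generate_target("logistic", {"r": 0.1, "K": 1000.0})
    (metric,) = run_model(make_logistic_model(), {"r": 0.1, "K": 1000.0}, seed=0)
    assert quantify.sse(metric, target) == 0.0


def test_fixture_settings_files_validate_as_expected(tmp_path):
    from cellcalib.config_io import ConstraintError, load_config

    ok = write_fixture_settings(tmp_path / "ok.xml")
    assert load_config(ok).cell("default").motility.migration_bias == 0.9
    bad = write_fixture_settings(tmp_path / "bad.xml", migration_bias=1.5)
    with pytest.raises(ConstraintError):
        load_config(bad)
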