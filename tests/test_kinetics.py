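"""Correlation times, window diffusivity, and passage-time integrals."""

import numpy as np
import pytest

import flipkin as fk
from flipkin.constants import DEG2RAD, kt_kcal
from flipkin.kinetics import (
    DiffusivityProfile,
    autocorrelation,
    block_standard_error,
    constant_diffusivity_variant,
    equilibrium_check,
    fit_correlation_time,
    hess_correlation_time,
    local_diffusivity,
    mfpt_backward,
    mfpt_forward,
    read_kinetics_table,
    write_kinetics_table,
    build_report,
)
from flipkin.synthetic import HarmonicBias, ModelSystem, SimulationSpec
from flipkin.umbrella import AngleSeries, UmbrellaWindow
from flipkin.wham import FreeEnergyProfile

KT = kt_kcal(300.0)


def _flat_profile(lo, hi, n=200, value=0.0):
    centers = np.linspace(lo, hi, n)
    return FreeEnergyProfile(
        bin_centers=centers, values=np.full(n, float(value)) - value,
        occupancy=np.ones(n), temperature=300.0,
    )


# -- autocorrelation ----------------------------------------------------------


def test_white_noise_autocorrelation_null():
    rng = np.random.default_rng(12)
    x = rng.normal(size=100_000)
    c = autocorrelation(x, max_lag=50)
    assert c[0] == pytest.approx(1.0)
    assert np.max(np.abs(c[1:])) < 4.0 / np.sqrt(x.size)


def test_ar1_autocorrelation_matches_closed_form():
    rng = np.random.default_rng(13)
    phi, n = 0.9, 400_000
    x = np.empty(n)
    x[0] = 0.0
    eps = rng.normal(size=n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    c = autocorrelation(x, max_lag=20)
    np.testing.assert_allclose(c, phi ** np.arange(21), atol=0.02)


def test_autocorrelation_rejects_degenerate_input():
    with pytest.raises(ValueError, match="zero-variance"):
        autocorrelation(np.ones(100), max_lag=5)
    with pytest.raises(ValueError):
        autocorrelation(np.arange(10.0), max_lag=20)


# -- correlation-time fit -----------------------------------------------------


def test_fit_single_exponential_degenerates_to_a_equals_one():
    t = np.arange(0, 100, 0.5)
    est = fit_correlation_time(np.exp(-t / 5.0), dt=0.5)
    assert est.fit_ok
    assert est.tau_int == pytest.approx(5.0, abs=1e-6)


def test_fit_double_exponential_recovers_tau_int():
    t = np.arange(0, 200, 0.5)
    c = 0.5 * np.exp(-t / 2.0) + 0.5 * np.exp(-t / 20.0)
    est = fit_correlation_time(c, dt=0.5)
    assert est.tau_int == pytest.approx(11.0, abs=1e-6)
    assert est.amplitude * est.tau1 + (1 - est.amplitude) * est.tau2 == \
        pytest.approx(est.tau_int)


def test_fit_falls_back_to_direct_integration_on_pathological_input():
    c = np.concatenate([[1.0], np.tile([0.95, 0.06], 100)])
    with pytest.warns(UserWarning, match="direct integral"):
        est = fit_correlation_time(c, dt=1.0)
    assert not est.fit_ok
    assert est.tau_int > 0


def test_block_standard_error_plateau_is_consistent_with_tau_int():
    model = ModelSystem.flat(diffusivity=0.15)
    spec = SimulationSpec(
        bias=HarmonicBias(center=0.0, force_constant=400.0), seed=21
    )
    series = fk.langevin_trajectory(model, spec)
    est = hess_correlation_time(series)
    sizes, ses = block_standard_error(series.values)
    naive = np.std(series.values, ddof=1) / np.sqrt(len(series))
    inflation = (ses[-1] / naive) ** 2
    g = 2 * est.tau_int / series.dt + 1
    # plateau variance inflation should match the statistical inefficiency
    assert inflation == pytest.approx(g, rel=0.35)


# -- diffusivity --------------------------------------------------------------


def _ou_window(seed, d=0.15, k=400.0, n=100_000):
    model = ModelSystem.flat(diffusivity=d)
    spec = SimulationSpec(
        bias=HarmonicBias(center=0.0, force_constant=k), seed=seed, n_samples=n
    )
    series = fk.langevin_trajectory(model, spec)
    return UmbrellaWindow(center=0.0, force_constant=k, temperature=300.0,
                          series=series)


def test_ou_window_diffusivity_recovered_within_ten_percent():
    d = local_diffusivity(_ou_window(seed=3))
    assert d == pytest.approx(0.15, rel=0.10)


def test_diffusivity_invariant_under_series_subsampling():
    w = _ou_window(seed=4)
    d1 = local_diffusivity(w)
    half = AngleSeries(dt=w.series.dt * 2, values=w.series.values[::2])
    d2 = local_diffusivity(
        UmbrellaWindow(center=0.0, force_constant=400.0, temperature=300.0,
                       series=half)
    )
    assert d2 == pytest.approx(d1, rel=0.10)


def test_diffusivity_units_covariance_under_angle_scaling():
    w = _ou_window(seed=5)
    c = 0.5
    scaled = UmbrellaWindow(
        center=0.0, force_constant=400.0, temperature=300.0,
        series=AngleSeries(dt=w.series.dt, values=w.series.values * c),
    )
    assert local_diffusivity(scaled) == pytest.approx(
        c**2 * local_diffusivity(w), rel=1e-6
    )


def test_diffusivity_profile_log_interpolation_and_mean():
    prof = DiffusivityProfile(centers=np.array([0.0, 10.0]),
                              values=np.array([0.01, 0.1]))
    mid = prof.interp(np.array([5.0]))[0]
    assert mid == pytest.approx(np.sqrt(0.01 * 0.1))   # geometric midpoint
    assert prof.interp(np.array([-5.0]))[0] == pytest.approx(0.01)  # clamped
    assert prof.mean() == pytest.approx(0.055)          # arithmetic window mean


# -- passage times ------------------------------------------------------------


def test_flat_potential_closed_form():
    lo, hi, d = 0.0, 60.0, 0.15
    prof = _flat_profile(lo, hi)
    dp = DiffusivityProfile.constant(d, centers=(lo, hi))
    length = (hi - lo) * DEG2RAD
    expected = length**2 / (2 * d)
    tau = mfpt_forward(prof, dp, lo, hi, n_points=1000)
    assert tau == pytest.approx(expected, rel=1e-3)


def test_mfpt_scales_inversely_with_diffusivity():
    prof = _flat_profile(-30.0, 40.0)
    d1 = DiffusivityProfile.constant(0.1, centers=(-30.0, 40.0))
    d2 = DiffusivityProfile.constant(0.2, centers=(-30.0, 40.0))
    assert mfpt_forward(prof, d1, -30.0, 40.0) == pytest.approx(
        2.0 * mfpt_forward(prof, d2, -30.0, 40.0), rel=1e-12
    )


def test_symmetric_landscape_has_equal_forward_and_backward_times():
    model = ModelSystem.flipping_double_well(barrier=3.0, delta_f=0.0)
    grid = np.linspace(-320.0, 38.0, 1440)
    prof = model.true_profile(grid)
    dp = DiffusivityProfile.constant(0.15, centers=(-320.0, 38.0))
    mins = sorted([e for e in model.extrema() if e.kind == "min"],
                  key=lambda e: e.position)
    extra, intra = mins[0].position, mins[1].position
    tp = mfpt_forward(prof, dp, intra, extra)
    tm = mfpt_backward(prof, dp, extra, intra)
    assert tm == pytest.approx(tp, rel=5e-3)


def test_mfpt_increases_monotonically_with_barrier():
    taus = []
    for barrier in (2.0, 3.0, 4.0):
        model = ModelSystem.flipping_double_well(barrier=barrier, delta_f=-1.0)
        grid = np.linspace(-320.0, 38.0, 720)
        prof = model.true_profile(grid)
        dp = DiffusivityProfile.constant(0.15, centers=(-320.0, 38.0))
        mins = sorted([e for e in model.extrema() if e.kind == "min"],
                      key=lambda e: e.position)
        taus.append(mfpt_forward(prof, dp, mins[1].position, mins[0].position))
    assert taus[0] < taus[1] < taus[2]


def test_mfpt_rejects_undefined_bins_and_nonpositive_d():
    centers = np.linspace(0.0, 50.0, 51)
    values = np.zeros(51)
    occupancy = np.ones(51)
    values[25] = np.nan
    occupancy[25] = 0.0
    prof = FreeEnergyProfile(centers, values, occupancy, 300.0)
    dp = DiffusivityProfile.constant(0.1, centers=(0.0, 50.0))
    with pytest.raises(ValueError, match="undefined"):
        mfpt_forward(prof, dp, 0.0, 50.0)


@pytest.mark.parametrize(
    "model_kwargs, reverse",
    [
        (dict(), False),                                    # flat
        (dict(barrier=2.0, delta_f=-1.0), True),            # tilted double well
        (dict(barrier=2.5, delta_f=0.5), True),             # uphill double well
    ],
)
def test_double_integral_matches_langevin_first_passage(model_kwargs, reverse):
    if model_kwargs:
        model = ModelSystem.flipping_double_well(
            diffusivity=0.15, **model_kwargs
        )
        mins = sorted([e for e in model.extrema() if e.kind == "min"],
                      key=lambda e: e.position)
        reflect, absorb = mins[1].position, mins[0].position
    else:
        model = ModelSystem.flat(diffusivity=0.15)
        reflect, absorb = 30.0, -40.0
    grid = np.linspace(-320.0, 38.0, 1440)
    prof = model.true_profile(grid)
    dp = DiffusivityProfile.constant(0.15, centers=(-320.0, 38.0))
    tau = mfpt_forward(prof, dp, reflect, absorb)
    oracle = fk.first_passage_oracle(
        model, reflect, absorb, n_walkers=3000, dt=0.002, seed=31
    )
    assert tau == pytest.approx(oracle.mean, abs=3 * oracle.std_err)


# -- equilibrium and constant-D variant ---------------------------------------


def test_equilibrium_check_symmetric_system_is_unity():
    eq = equilibrium_check(10.0, 10.0, 0.0, 300.0)
    assert eq.k_kinetic == 1.0
    assert eq.k_thermodynamic == 1.0
    assert eq.log_ratio == 0.0


def test_detailed_balance_deep_two_state_quadrature():
    from flipkin.wham import StateRegion, state_delta_f

    model = ModelSystem.flipping_double_well(barrier=4.5, delta_f=-1.0)
    grid = np.linspace(-320.0, 38.0, 720)
    prof = model.true_profile(grid)
    dp = DiffusivityProfile.constant(0.15, centers=(-320.0, 38.0))
    mins = sorted([e for e in model.extrema() if e.kind == "min"],
                  key=lambda e: e.position)
    maxs = sorted([e for e in model.extrema() if e.kind == "max"],
                  key=lambda e: e.position)
    extra, intra = mins[0].position, mins[1].position
    other, saddle = maxs[0].position, maxs[1].position
    tau_p = mfpt_forward(prof, dp, intra, extra)
    tau_m = mfpt_backward(prof, dp, extra, intra)
    df = state_delta_f(
        prof,
        StateRegion("intra", [(saddle, 38.0), (-320.0, other)]),
        StateRegion("extra", [(other, saddle)]),
    )
    eq = equilibrium_check(tau_p, tau_m, df, 300.0)
    assert abs(eq.log_ratio) < 0.2


def test_equilibrium_constant_insensitive_to_asymmetric_diffusivity():
    model = ModelSystem.flipping_double_well(barrier=4.0, delta_f=0.0)
    grid = np.linspace(-320.0, 38.0, 720)
    prof = model.true_profile(grid)
    d_asym = DiffusivityProfile(centers=np.array([-320.0, 38.0]),
                                values=np.array([0.03, 0.3]))
    mins = sorted([e for e in model.extrema() if e.kind == "min"],
                  key=lambda e: e.position)
    tp = mfpt_forward(prof, d_asym, mins[1].position, mins[0].position)
    tm = mfpt_backward(prof, d_asym, mins[0].position, mins[1].position)
    assert tm / tp == pytest.approx(1.0, abs=0.02)


def test_constant_d_variant_identity_and_roughness_speedup():
    prof = _flat_profile(0.0, 100.0)
    d_const = DiffusivityProfile.constant(0.1, centers=(0.0, 100.0))
    res = constant_diffusivity_variant(prof, d_const, 0.0, 100.0)
    assert res["tau_plus_ratio"] == pytest.approx(1.0, rel=1e-9)
    # alternating d / 2d: harmonic-mean slowdown of the local-D landscape
    centers = np.linspace(0.0, 100.0, 51)
    d_alt = DiffusivityProfile(
        centers=centers,
        values=np.where(np.arange(51) % 2 == 0, 0.1, 0.2),
    )
    res2 = constant_diffusivity_variant(prof, d_alt, 0.0, 100.0)
    assert res2["tau_plus_ratio"] < 1.0


def test_rough_diffusivity_reduction_below_factor_five():
    # one order of magnitude D fluctuation along the coordinate
    model = ModelSystem.flipping_double_well(
        d_log_amplitude=np.log(10.0) / 2.0
    )
    grid = np.linspace(-320.0, 38.0, 720)
    prof = model.true_profile(grid)
    dp = DiffusivityProfile(centers=grid.copy(), values=model.diffusivity(grid))
    mins = sorted([e for e in model.extrema() if e.kind == "min"],
                  key=lambda e: e.position)
    res = constant_diffusivity_variant(
        prof, dp, mins[1].position, mins[0].position
    )
    assert res["tau_plus_ratio"] < 1.0
    assert res["tau_plus_ratio"] > 1.0 / 5.0


# -- report round trip --------------------------------------------------------


def test_kinetics_table_roundtrip(tmp_path):
    reports = [
        build_report("demo", 230.0, 6600.0, -2.0, 30.0, -135.0),
    ]
    path = tmp_path / "kinetics.tsv"
    write_kinetics_table(path, reports)
    back = read_kinetics_table(path)
    assert back["demo"][0] == pytest.approx(230.0e-12, rel=1e-5)
    assert back["demo"][1] == pytest.approx(6600.0e-12, rel=1e-5)
    with pytest.raises(ValueError, match="not a kinetics table"):
        bad = tmp_path / "bad.tsv"
        bad.write_text("foo\tbar\n")
        read_kinetics_table(bad)
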