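"""Periodic WHAM: estimator invariances, analytic limits, ground-truth
recovery, and profile feature extraction."""

import numpy as np
import pytest
from scipy.integrate import quad

from flipkin.constants import DEG2RAD, kt_kcal
from flipkin.synthetic import ModelSystem
from flipkin.umbrella import AngleSeries, UmbrellaWindow, WindowSet
from flipkin.wham import (
    FreeEnergyProfile,
    StateRegion,
    WhamConvergenceError,
    barrier_between,
    convergence_rmsd,
    locate_extrema,
    state_delta_f,
    wham,
)

KT = kt_kcal(300.0)


def _window(center, values, k=400.0):
    return UmbrellaWindow(
        center=center, force_constant=k, temperature=300.0,
        series=AngleSeries(dt=1.0, values=np.asarray(values, float)),
    )


def _harmonic_samples(center, k, n, seed):
    """Independent draws from the bias Boltzmann distribution on a flat
    landscape: normal with variance kT/k (radians)."""
    rng = np.random.default_rng(seed)
    sigma_deg = np.sqrt(KT / k) / DEG2RAD
    return center + rng.normal(0.0, sigma_deg, size=n)


def test_flat_landscape_single_window_recovers_flat_profile():
    w = _window(0.0, _harmonic_samples(0.0, 400.0, 200_000, seed=0))
    prof = wham(WindowSet(windows=[w]), n_bins=1440)
    # far bias tails suffer bin-center discretization of the stiff bias;
    # judge flatness where the window actually samples
    occ = prof.occupancy >= 300
    f = prof.values[occ]
    n = prof.occupancy[occ]
    # each bin's free energy has standard error ~ kT/sqrt(count)
    resid = (f - f.mean()) / (KT / np.sqrt(n))
    assert np.max(np.abs(resid)) < 4.5


def test_weak_bias_limit_equals_boltzmann_inversion():
    rng = np.random.default_rng(1)
    values = rng.uniform(-180.0, 180.0, size=50_000)
    w = _window(0.0, values, k=1e-12)
    prof = wham(WindowSet(windows=[w]), n_bins=36)
    occ = prof.occupied
    direct = -KT * np.log(prof.occupancy[occ])
    direct -= direct.min()
    np.testing.assert_allclose(prof.values[occ], direct, atol=1e-6)


def test_dataset_duplication_leaves_profile_unchanged(small_campaign):
    ws = small_campaign.windows
    sub = WindowSet(windows=list(ws.windows[:10]))
    twice = WindowSet(windows=[
        _window(w.center, w.series.values) for w in sub
    ] + [
        _window(w.center + 1e-9, w.series.values) for w in sub
    ])
    p1 = wham(sub, n_bins=180)
    p2 = wham(twice, n_bins=180, grid_origin=p1.bin_centers[0] - 1.0)
    occ = p1.occupied & p2.occupied
    np.testing.assert_allclose(p1.values[occ], p2.values[occ], atol=1e-6)


def test_gauge_invariance_under_bias_energy_offsets(small_campaign):
    sub = WindowSet(windows=list(small_campaign.windows.windows[:12]))
    p0 = wham(sub, n_bins=180, tol=1e-11)
    rng = np.random.default_rng(3)
    offsets = rng.uniform(-50.0, 50.0, size=len(sub))
    p1 = wham(sub, n_bins=180, tol=1e-11, bias_offsets=offsets)
    occ = p0.occupied
    np.testing.assert_allclose(p0.values[occ], p1.values[occ], atol=1e-8)


def test_grid_rotation_cyclically_shifts_profile(small_campaign):
    sub = WindowSet(windows=list(small_campaign.windows.windows[:12]))
    origin = sub.centers[0] - 1.0
    p0 = wham(sub, n_bins=180, grid_origin=origin)
    p1 = wham(sub, n_bins=180, grid_origin=origin - 5 * p0.bin_width)
    np.testing.assert_allclose(
        np.roll(p0.values, 5)[np.roll(p0.occupied, 5)],
        p1.values[np.roll(p0.occupied, 5)], atol=1e-8,
    )


def test_double_well_recovery_against_ground_truth(
    small_campaign, small_profile, double_well_model
):
    prof = small_profile
    truth = double_well_model.true_profile(prof.bin_centers)
    occ = prof.occupied
    d = prof.values[occ] - truth.values[occ]
    rms = np.sqrt(np.mean((d - d.mean()) ** 2))
    assert rms < 0.3


def test_wham_nonconvergence_raises_with_residual(small_campaign):
    sub = WindowSet(windows=list(small_campaign.windows.windows[:8]))
    with pytest.raises(WhamConvergenceError) as err:
        wham(sub, n_bins=180, max_iter=2, tol=1e-12)
    assert err.value.residual > 0


def _profile_from(values, centers=None, temperature=300.0):
    values = np.asarray(values, float)
    if centers is None:
        centers = np.linspace(-179.0, 179.0, values.size)
    return FreeEnergyProfile(
        bin_centers=np.asarray(centers, float),
        values=values - np.nanmin(values),
        occupancy=np.ones(values.size), temperature=temperature,
    )


def test_state_delta_f_constant_offset_and_antisymmetry():
    centers = np.linspace(0.5, 359.5, 360)
    values = np.where(centers < 180, 0.0, 3.0)
    prof = _profile_from(values, centers)
    a = StateRegion("A", [(0.0, 179.9)])
    b = StateRegion("B", [(180.1, 360.0)])
    df = state_delta_f(prof, a, b)
    assert df == pytest.approx(3.0, abs=1e-12)
    assert state_delta_f(prof, b, a) == -df


def test_state_delta_f_symmetric_double_well_is_zero():
    model = ModelSystem.flipping_double_well(barrier=4.0, delta_f=0.0)
    grid = np.linspace(-320.0, 38.0, 3580)
    prof = model.true_profile(grid)
    mins = sorted([e for e in model.extrema() if e.kind == "min"],
                  key=lambda e: e.position)
    maxs = sorted([e for e in model.extrema() if e.kind == "max"],
                  key=lambda e: e.position)
    saddle, other = maxs[1].position, maxs[0].position
    intra = StateRegion("intra", [(saddle, 38.0), (-320.0, other)])
    extra = StateRegion("extra", [(other, saddle)])
    assert abs(state_delta_f(prof, intra, extra)) < 0.05


def test_state_delta_f_matches_boltzmann_quadrature():
    model = ModelSystem.flipping_double_well()
    grid = np.linspace(-320.05, 37.95, 3580)   # 0.1 deg bins
    prof = model.true_profile(grid)
    a_lo, a_hi, b_lo, b_hi = -200.0, -70.0, -20.0, 38.0
    df = state_delta_f(prof, StateRegion("A", [(a_lo, a_hi)]),
                       StateRegion("B", [(b_lo, b_hi)]))
    fmin = float(model.free_energy(grid).min())

    def weight(x):
        return np.exp(-(model.free_energy(x) - fmin) / KT)

    za, _ = quad(weight, a_lo, a_hi, limit=400)
    zb, _ = quad(weight, b_lo, b_hi, limit=400)
    expected = -KT * np.log(zb / za)
    assert df == pytest.approx(expected, abs=1e-3)


def test_locate_extrema_cosine_and_flat():
    centers = np.linspace(-179.5, 179.5, 360)
    cos_prof = _profile_from(1.0 - np.cos(np.radians(centers - 40.0)), centers)
    ext = locate_extrema(cos_prof)
    mins = [e for e in ext if e.kind == "min"]
    maxs = [e for e in ext if e.kind == "max"]
    assert len(mins) == 1 and len(maxs) == 1
    assert abs(mins[0].position - 40.0) <= cos_prof.bin_width
    flat = _profile_from(np.zeros(360), centers)
    assert locate_extrema(flat) == []


def test_locate_extrema_double_well_noise_free_within_one_bin(
    double_well_model,
):
    grid = np.linspace(-319.0, 37.0, 180)
    prof = double_well_model.true_profile(grid)
    ext = locate_extrema(prof)
    mins = [e for e in ext if e.kind == "min"]
    truth = sorted(
        e.position for e in double_well_model.extrema() if e.kind == "min"
    )
    assert len(mins) == 2
    for f, t in zip(sorted(m.position for m in mins), truth):
        assert abs(f - t) <= prof.bin_width


def test_locate_extrema_double_well_from_sampled_profile(
    small_profile, double_well_model
):
    # basin bottoms are flat, so sampling noise moves the located minimum by
    # a few bins; the well identity and neighborhood must still be right
    ext = locate_extrema(small_profile, smoothing_window=5)
    mins = sorted([e for e in ext if e.kind == "min"], key=lambda e: e.value)[:2]
    found = sorted(m.position for m in mins)
    truth = sorted(
        e.position for e in double_well_model.extrema() if e.kind == "min"
    )
    for f, t in zip(found, truth):
        assert abs(f - t) <= 4 * small_profile.bin_width


def test_barrier_between_minima(small_profile, double_well_model):
    ext = locate_extrema(small_profile, smoothing_window=3)
    mins = sorted([e for e in ext if e.kind == "min"], key=lambda e: e.value)[:2]
    a, b = (m.position for m in mins)
    # barrier is referenced to the lower (extra-helical) minimum: the model
    # saddle sits 5 kcal/mol above it (3 above the intra-helical state)
    bar = barrier_between(small_profile, a, b)
    assert bar == pytest.approx(5.0, abs=0.75)


def test_convergence_rmsd_gauge_and_identity():
    p1 = _profile_from(np.linspace(0, 5, 100))
    p2 = _profile_from(np.linspace(0, 5, 100))
    mat = convergence_rmsd([p1, p2])
    assert mat[0, 1] == pytest.approx(0.0, abs=1e-12)
    # constant offsets are re-referenced away
    shifted = _profile_from(np.linspace(0, 5, 100) + 2.0)
    assert convergence_rmsd([p1, shifted])[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_convergence_rmsd_requires_shared_occupancy():
    centers = np.linspace(-179.0, 179.0, 100)
    v1 = np.concatenate([np.zeros(50), np.full(50, np.nan)])
    v2 = np.concatenate([np.full(50, np.nan), np.zeros(50)])
    p1 = FreeEnergyProfile(centers, v1,
                           np.concatenate([np.ones(50), np.zeros(50)]), 300.0)
    p2 = FreeEnergyProfile(centers, v2,
                           np.concatenate([np.zeros(50), np.ones(50)]), 300.0)
    with pytest.raises(ValueError, match="no occupied bins"):
        convergence_rmsd([p1, p2])


def test_segment_profiles_agree(small_campaign):
    from flipkin.umbrella import split_segments

    segs = split_segments(small_campaign.windows, 2)
    profs = [wham(s, n_bins=180) for s in segs]
    assert convergence_rmsd(profs)[0, 1] < 0.5
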