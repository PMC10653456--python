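"""Chaos diagnostics: Lyapunov estimators, plane crossings, spectra, scans."""

import numpy as np
import pytest

from ecosocnet import (
    IntegratorSettings,
    NetworkModel,
    alpha_star,
    attractor_summary,
    classify_regime,
    drop_transient,
    fixed_points,
    integrate_rk4,
    largest_lyapunov,
    plane_crossing_series,
    power_spectrum,
    predictability_timescale,
    resolved_alpha_crit,
)
from ecosocnet.diagnostics import (
    LyapunovEstimate,
    bifurcation_scan,
    cluster_extrema,
    local_extrema,
)
from ecosocnet.errors import EcosocnetError
from ecosocnet.integrate import Trajectory, default_ic


# ---------------------------------------------------------------------------
# extrema utilities

def test_local_extrema_parabolic_refinement():
    t = np.arange(0, 200, 0.5)
    ext = local_extrema(np.sin(2 * np.pi * t / 25))
    # coarse sampling (50 points/period) still recovers the true extrema
    np.testing.assert_allclose(np.abs(ext), 1.0, atol=1e-4)


def test_cluster_extrema_levels():
    vals = np.array([1.0, 1.0001, -2.0, -2.00005, 1.00005])
    centers = cluster_extrema(vals, tol_rel=1e-3)
    assert centers.size == 2
    vals_split = np.array([1.0, 2.0, 3.0])
    assert cluster_extrema(vals_split, tol_rel=1e-3).size == 3


# ---------------------------------------------------------------------------
# regime classification

def test_fixed_point_run_classifies_as_fixed_point(fixed_point_traj):
    summary = attractor_summary(drop_transient(fixed_point_traj, 4000.0))
    assert summary.regime == "fixed_point"
    assert summary.ratio == pytest.approx(1.0, abs=1e-6)


def test_limit_cycle_run_classifies_as_limit_cycle(limit_cycle_traj):
    summary = attractor_summary(limit_cycle_traj)
    assert summary.regime == "limit_cycle"
    assert summary.ratio > 2  # large-amplitude cycle approaches the origin
    assert classify_regime(summary) == "limit_cycle"


def test_classification_stable_under_dt_and_burn_in(params, a_star):
    p = params.with_alpha(2 * a_star)
    labels = set()
    for dt, burn in ((0.05, 2000.0), (0.025, 2000.0), (0.05, 4000.0)):
        traj = integrate_rk4(
            p, settings=IntegratorSettings(dt=dt, t_end=6000.0, burn_in=burn, stride=4)
        )
        labels.add(attractor_summary(traj).regime)
    assert labels == {"fixed_point"}


# ---------------------------------------------------------------------------
# Lyapunov estimators

def test_lyapunov_sign_pattern(params, a_star, a_crit, chaos_bundle):
    fp_est = largest_lyapunov(
        params.with_alpha(2 * a_star),
        settings=IntegratorSettings(dt=0.05, t_end=4000.0, burn_in=1000.0),
        n_windows=2, window_span=1500.0, window_spacing=500.0,
    )
    assert fp_est.lambda_ < 0  # stable focus contracts

    lc_est = largest_lyapunov(
        params.with_alpha(2 * a_crit),
        settings=IntegratorSettings(dt=0.05, t_end=20000.0, burn_in=8000.0),
        method="benettin",
    )
    assert abs(lc_est.lambda_) < 5e-4  # neutral direction along the cycle

    assert chaos_bundle.lyapunov.lambda_ > 1e-3
    assert chaos_bundle.lyapunov_benettin.lambda_ > 1e-3


def test_two_trajectory_and_benettin_agree(chaos_bundle):
    a = chaos_bundle.lyapunov
    b = chaos_bundle.lyapunov_benettin
    combined = np.hypot(a.stderr, b.stderr)
    assert abs(a.lambda_ - b.lambda_) < 2 * combined


def test_lyapunov_insensitive_to_perturbation_size(params):
    a_crit = resolved_alpha_crit(params)
    m = NetworkModel.uniform(
        params, 3, alpha=10 * a_crit, interaction="uniform_plus_delta", delta=1e-2 / 3
    )
    ic = default_ic(3, 1e-6, 0)
    settings = IntegratorSettings(dt=0.05, t_end=40000.0, burn_in=10000.0)
    ests = [
        largest_lyapunov(m, ic=ic, settings=settings, method="benettin", perturbation=d0)
        for d0 in (1e-7, 1e-9, 1e-11)
    ]
    for other in ests[1:]:
        combined = np.hypot(ests[0].stderr, other.stderr)
        assert abs(ests[0].lambda_ - other.lambda_) < 2 * combined


def test_predictability_timescale():
    est = LyapunovEstimate(3.4e-3, 1e-4, (0.0, 1.0), "benettin")
    assert predictability_timescale(est) == pytest.approx(294.1, rel=1e-3)
    assert predictability_timescale(
        LyapunovEstimate(1e-3, 0.0, (0.0, 1.0), "benettin")
    ) == pytest.approx(1000.0)
    with pytest.raises(EcosocnetError):
        predictability_timescale(LyapunovEstimate(-0.01, 0.0, (0.0, 1.0), "benettin"))


# ---------------------------------------------------------------------------
# plane crossings

def test_fixed_point_run_has_no_late_crossings(params, a_star, fixed_point_traj):
    E = {fp.label: fp for fp in fixed_points(params.with_alpha(2 * a_star))}["E"]
    res = plane_crossing_series(fixed_point_traj, E)
    # distance settles to ~0: crossings, if any, happen during the transient
    late = res.crossing_times[res.crossing_times > 2500.0]
    assert late.size == 0 or np.allclose(res.signed_distance[-100:], 0.0, atol=1e-6)


def test_limit_cycle_crossings_are_periodic(params, a_crit, limit_cycle_traj):
    E = {fp.label: fp for fp in fixed_points(params.with_alpha(2 * a_crit))}["E"]
    res = plane_crossing_series(limit_cycle_traj, E)
    periods = np.diff(res.crossing_times[::2])  # same-direction crossings
    assert periods.size > 10
    assert (periods.max() - periods.min()) / periods.mean() < 0.01


def test_chaotic_crossings_are_aperiodic(chaos_bundle):
    res = chaos_bundle.plane_crossings
    periods = np.diff(res.crossing_times[::2])
    assert (periods.max() - periods.min()) / periods.mean() > 0.1


def test_crossing_interpolation_error_is_second_order():
    # offset + phase so crossings fall between samples where curvature != 0
    T, offset, phase = 100.0, 0.3, 0.37
    th_down = np.pi + np.arcsin(offset)
    th_up = 2 * np.pi - np.arcsin(offset)
    true = np.sort(np.array(
        [(th + 2 * np.pi * k - phase) * T / (2 * np.pi)
         for k in range(-1, 7) for th in (th_down, th_up)]
    ))
    errs = {}
    for dt in (1.0, 0.5):
        t = np.arange(0, 500 + 1e-9, dt)
        states = np.zeros((t.size, 3))
        states[:, 0] = np.sin(2 * np.pi * t / T + phase) + offset
        res = plane_crossing_series(Trajectory(t0=0.0, dt=dt, states=states), np.zeros(3))
        errs[dt] = max(np.abs(true - ct).min() for ct in res.crossing_times)
    bound = (2 * np.pi / T) ** 2 * T  # curvature scale of the sinusoid
    assert errs[1.0] < bound * 1.0**2
    # halving dt shrinks the error by ~4 (second-order interpolation)
    assert errs[0.5] < 4 * errs[1.0] * (0.5 / 1.0) ** 2


# ---------------------------------------------------------------------------
# spectra

def test_sinusoid_spectrum_single_peak():
    dt, T = 0.2, 51.2  # period aligned with a frequency bin
    t = np.arange(0, 4096 * dt, dt)
    res = power_spectrum(np.sin(2 * np.pi * t / T), dt)
    assert res.frequency[np.argmax(res.amplitude)] == pytest.approx(1 / T, rel=1e-9)
    with pytest.raises(ValueError):
        power_spectrum(np.sin(t[:100]), dt)


def test_chaotic_spectrum_is_denser_than_periodic(limit_cycle_traj, chaos_bundle):
    lc = power_spectrum(limit_cycle_traj.x(0), limit_cycle_traj.dt)
    assert chaos_bundle.spectrum.peak_density >= 5 * lc.peak_density


# ---------------------------------------------------------------------------
# bifurcation scan

def test_single_system_scan_regimes(params, a_star, a_crit):
    grid = np.array([2 * a_star, 0.8 * a_crit, 1.3 * a_crit])
    settings = IntegratorSettings(dt=0.05, t_end=20000.0, burn_in=14000.0, stride=4)
    pts = bifurcation_scan(lambda a: params.with_alpha(a), grid, settings)
    assert pts[0].n_clusters == 1  # fixed point: min = max = equilibrium
    assert pts[1].n_clusters == 1  # still below the Hopf threshold
    assert pts[2].n_clusters == 2  # limit cycle: one min, one max
    assert all(pt.error is None for pt in pts)
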