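"""Single-society model: vector field, equilibria, thresholds, stability."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy.optimize import brentq

from ecosocnet import (
    ModelParams,
    alpha_hopf,
    alpha_star,
    bifurcation_thresholds,
    fixed_points,
    hopf_detect_numeric,
    jacobian_interior,
    rhs_single,
)
from ecosocnet.errors import BoundaryRegimeError, InvalidStateError
from ecosocnet.model import _rhs_unregularized


@pytest.mark.parametrize(
    "state, expected",
    [
        # the origin and the resource-only point are equilibria
        ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
        ((0.0, 100.0, 0.0), (0.0, 0.0, 0.0)),
        # direct arithmetic at (1, 100, 1) with the typical parameters:
        # xdot = (2/1.01 - 0.05)(1 - e^-100), ydot = -alpha x^2 y, zdot = -ydot - cz
        ((1.0, 100.0, 1.0), (1.9301980198019802, -2.5e-3, -4.75e-2)),
    ],
)
def test_rhs_examples(params, state, expected):
    out = rhs_single(state, params)
    np.testing.assert_allclose(out, expected, rtol=1e-12, atol=1e-15)


def test_rhs_rejects_bad_states(params):
    with pytest.raises(InvalidStateError):
        rhs_single([np.nan, 1.0, 1.0], params)
    with pytest.raises(InvalidStateError):
        rhs_single([1.0, 1.0, -0.5], params)


def test_alpha_star_value_and_scaling(params, a_star):
    assert a_star == pytest.approx(1.25e-5, rel=1e-12)
    doubled_K = ModelParams(K=2 * params.K)
    assert alpha_star(doubled_K) == pytest.approx(a_star / 2, rel=1e-12)
    # the typical extraction rate sits exactly at twice the threshold
    assert 2 * a_star == pytest.approx(params.alpha, rel=1e-12)


def test_alpha_hopf_value_and_r_to_zero_limit(params):
    assert alpha_hopf(params) == pytest.approx(7.2005e-5, rel=1e-4)
    assert alpha_hopf(params) > 2 * alpha_star(params)
    p_small_r = ModelParams(r=1e-12)
    c, d, K, b = p_small_r.c, p_small_r.d, p_small_r.K, p_small_r.b
    limit = (2 * c * d + (c + 2 * d) ** 2) / (2 * K * b)
    assert alpha_hopf(p_small_r) == pytest.approx(limit, rel=1e-6)


def _oracle_hopf(p):
    """Independent eigenvalue-crossing detector with its own Jacobian."""

    def leading_real(alpha):
        y = p.c * p.d / (alpha * p.b)
        x = np.sqrt(p.r / alpha * (1 - y / p.K))
        z = p.d / p.b * x**2
        J = np.array(
            [
                [-p.b * z / x**2 - p.d, 0, p.b / x],
                [-2 * alpha * x * y, p.r * (1 - 2 * y / p.K) - alpha * x**2, 0],
                [2 * alpha * x * y, alpha * x**2, -p.c],
            ]
        )
        ev = np.linalg.eigvals(J)
        cx = ev[np.abs(ev.imag) > 1e-12]
        return float(np.max((cx if cx.size else ev).real))

    a0 = alpha_star(p)
    return brentq(leading_real, 1.2 * a0, 100 * a0, rtol=1e-10)


def test_hopf_formula_matches_oracle_at_defaults(params):
    assert alpha_hopf(params) == pytest.approx(_oracle_hopf(params), rel=1e-6)


def test_hopf_formula_matches_numeric_on_random_params():
    rng = np.random.default_rng(42)
    base = ModelParams()
    for _ in range(20):
        f = 1.0 + rng.uniform(-0.5, 0.5, size=5)
        p = ModelParams(b=base.b * f[0], d=base.d * f[1], r=base.r * f[2],
                        K=base.K * f[3], c=base.c * f[4])
        assert alpha_hopf(p) == pytest.approx(hopf_detect_numeric(p), rel=1e-3)


def test_interior_equilibrium_coordinates(params):
    E = {fp.label: fp for fp in fixed_points(params)}["E"]
    np.testing.assert_allclose(E.coords, [np.sqrt(1000.0), 50.0, 25.0], rtol=1e-10)
    assert np.linalg.norm(_rhs_unregularized(E.coords, params)) < 1e-8


def test_boundary_points_always_present_interior_conditional(params, a_star):
    labels_below = {fp.label for fp in fixed_points(params.with_alpha(0.5 * a_star))}
    assert labels_below == {"O", "N"}
    labels_above = {fp.label for fp in fixed_points(params)}
    assert labels_above == {"O", "N", "E"}


def test_transcritical_merge(params, a_star):
    pts = fixed_points(params.with_alpha(a_star * (1 + 1e-9)))
    E = {fp.label: fp for fp in pts}["E"]
    np.testing.assert_allclose(E.coords, [0.0, params.K, 0.0], atol=1e-2)


def test_transcritical_stability_swap(params, a_star, a_crit):
    below = {fp.label: fp for fp in fixed_points(params.with_alpha(0.5 * a_star))}
    assert below["N"].stability == "stable"
    mid = {fp.label: fp for fp in fixed_points(params.with_alpha(2 * a_star))}
    assert mid["N"].stability == "unstable"
    assert mid["E"].stability == "stable"
    assert {fp.label: fp for fp in fixed_points(params)}["O"].stability == "unstable"


def test_capacity_maximized_at_twice_alpha_star(params, a_star):
    grid = np.concatenate([np.geomspace(1.01 * a_star, 100 * a_star, 199), [2 * a_star]])
    grid.sort()
    x_eq = []
    for a in grid:
        pts = {fp.label: fp for fp in fixed_points(params.with_alpha(a))}
        x_eq.append(pts["E"].x)
    assert grid[int(np.argmax(x_eq))] == pytest.approx(2 * a_star, rel=1e-12)


def test_jacobian_eigenvalues_across_regimes(params, a_star, a_crit):
    def eigs_at(alpha):
        p = params.with_alpha(alpha)
        E = {fp.label: fp for fp in fixed_points(p)}["E"]
        return np.linalg.eigvals(jacobian_interior(E.coords, p))

    assert np.max(eigs_at(2 * a_star).real) < 0
    ev = eigs_at(2 * a_crit)
    cx = ev[np.abs(ev.imag) > 1e-12]
    assert cx.size == 2 and np.max(cx.real) > 0
    assert abs(np.max(eigs_at(hopf_detect_numeric(params)).real)) < 1e-6


def test_jacobian_rejects_boundary_states(params):
    with pytest.raises(BoundaryRegimeError):
        jacobian_interior([0.0, 100.0, 0.0], params)


def test_thresholds_record_validates(params):
    th = bifurcation_thresholds(params)
    assert 0 < th.alpha_star < th.alpha_crit
    assert th.validated
    assert abs(th.alpha_crit - th.alpha_crit_numeric) / th.alpha_crit < 1e-3


@hyp_settings(max_examples=50, derandomize=True, deadline=None)
@given(
    x=st.floats(0.0, 200.0),
    y=st.floats(0.0, 120.0),
    z=st.floats(0.0, 200.0),
)
def test_extraction_mass_action_identity(x, y, z):
    """The extraction flux enters resources and wealth with opposite signs,
    so ydot + zdot - r y (1 - y/K) + c z vanishes identically."""
    p = ModelParams()
    _, ydot, zdot = rhs_single([x, y, z], p)
    logistic = p.r * y * (1 - y / p.K)
    residual = ydot + zdot - logistic + p.c * z
    scale = max(abs(ydot), abs(zdot), abs(logistic), 1.0)
    assert abs(residual) < 1e-12 * scale
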