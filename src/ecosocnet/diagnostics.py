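"""Chaos and regime diagnostics.

The battery used to characterize attractors:

* largest Lyapunov exponent, by two-trajectory divergence fitting (with
  Benettin renormalization as an independent cross-check);
* signed distance to a fixed hyperplane through the equilibrium, a
  Poincaré-section surrogate whose crossing intervals reveal periodicity
  or its absence;
* tapered magnitude spectra with a peak-density statistic (periodic
  signals show a few well-separated peaks, chaotic ones a dense comb);
* extrema-based bifurcation scans over the extraction rate;
* regime classification (fixed point / limit cycle / aperiodic) from the
  max/min ratio of total population and extrema clustering.

A note on the divergence fit: on this attractor the separation of nearby
trajectories grows in bursts — collapse spikes amplify a small phase
difference to the attractor diameter, after which the distance falls back
between spikes.  The raw log-distance therefore saturates (in its upper
envelope) long before the bulk of the curve does.  The fit window is ended
when the *running median* of the log-distance reaches its saturation
plateau, and the estimate is averaged over several re-perturbation windows
along the attractor; single-window fits scatter widely around the
renormalized (Benettin) value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from . import _kernels
from .errors import EcosocnetError, IntegrationError, ModelViolationError
from .integrate import IntegratorSettings, Trajectory, default_ic, _as_network, _raise_for_status
from .model import FixedPoint
from .network import NetworkModel
from .params import ModelParams

__all__ = [
    "LyapunovEstimate",
    "AttractorSummary",
    "PlaneCrossings",
    "SpectrumResult",
    "ScanPoint",
    "largest_lyapunov",
    "predictability_timescale",
    "plane_crossing_series",
    "power_spectrum",
    "bifurcation_scan",
    "attractor_summary",
    "classify_regime",
    "local_extrema",
    "cluster_extrema",
]


# ---------------------------------------------------------------------------
# extrema detection and clustering

def local_extrema(series: np.ndarray) -> np.ndarray:
    """Values of all interior local extrema of a sampled series.

    Each discrete extremum (sign change of the first difference) is
    refined by a parabola through its three neighbouring samples, which
    removes the O(dt^2) sampling bias on sharp peaks.
    """
    s = np.asarray(series, dtype=float)
    d = np.diff(s)
    idx = np.where(d[:-1] * d[1:] < 0)[0] + 1
    if idx.size == 0:
        return np.empty(0)
    a, b, c = s[idx - 1], s[idx], s[idx + 1]
    den = a - 2 * b + c
    vals = b.copy()
    ok = den != 0
    vals[ok] = b[ok] - 0.125 * (a[ok] - c[ok]) ** 2 / den[ok]
    return vals


def cluster_extrema(values: np.ndarray, tol_rel: float = 1e-3) -> np.ndarray:
    """Cluster extremum values with a relative tolerance; returns centers.

    Two values are merged when they differ by less than ``tol_rel`` times
    the overall magnitude of the extrema.  A clean limit cycle yields two
    clusters (one minimum, one maximum); period-doubling adds clusters.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return np.empty(0)
    scale = max(abs(v[0]), abs(v[-1]), 1e-12)
    centers = []
    start = 0
    for i in range(1, v.size + 1):
        if i == v.size or v[i] - v[i - 1] > tol_rel * scale:
            centers.append(v[start:i].mean())
            start = i
    return np.array(centers)


# ---------------------------------------------------------------------------
# regime classification

@dataclass(frozen=True)
class AttractorSummary:
    """Post-transient summary of an attractor.

    ``extrema`` are the clustered local extrema of the observable (total
    population by default), ``ratio`` the max/min of total population on
    the attractor, ``regime`` one of "fixed_point", "limit_cycle",
    "aperiodic".
    """

    extrema: np.ndarray
    ratio: float
    regime: str

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("max/min ratio cannot be below 1")


def _regime_label(ratio: float, n_clusters: int, tol_ratio: float) -> str:
    if ratio < 1 + tol_ratio:
        return "fixed_point"
    return "limit_cycle" if n_clusters <= 2 else "aperiodic"


def attractor_summary(
    traj: Trajectory,
    tol_ratio: float = 1e-3,
    tol_extrema: float = 1e-3,
) -> AttractorSummary:
    """Summarize a post-transient trajectory via its total population."""
    tot = traj.total_population()
    mn = tot.min()
    ratio = float("inf") if mn <= 0 else float(tot.max() / mn)
    clusters = cluster_extrema(local_extrema(tot), tol_extrema)
    return AttractorSummary(
        extrema=clusters,
        ratio=max(ratio, 1.0),
        regime=_regime_label(ratio, clusters.size, tol_ratio),
    )


def classify_regime(summary: AttractorSummary, tol_ratio: float = 1e-3) -> str:
    """Regime label from a summary (re-applying the ratio tolerance)."""
    return _regime_label(summary.ratio, summary.extrema.size, tol_ratio)


# ---------------------------------------------------------------------------
# largest Lyapunov exponent

@dataclass(frozen=True)
class LyapunovEstimate:
    """Largest Lyapunov exponent (per year) with fit metadata.

    ``stderr`` is the standard error over fit windows (two-trajectory
    method) or renormalization intervals (Benettin).  ``r_squared`` is the
    mean coefficient of determination of the window fits; values below
    0.9 indicate no clean exponential regime (e.g. on a limit cycle,
    where the distance neither grows nor decays)."""

    lambda_: float
    stderr: float
    fit_window: tuple
    method: str
    r_squared: float = 1.0
    window_slopes: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "lambda": self.lambda_,
            "stderr": self.stderr,
            "fit_window": list(self.fit_window),
            "method": self.method,
            "r_squared": self.r_squared,
        }


def _fit_window_slope(ln_dist: np.ndarray, dt_sample: float) -> tuple[float, float, float]:
    """Slope of one divergence window.

    The window end is the first 250-year block whose median log-distance
    rises to within 2 ln-units of the saturation plateau (the median over
    the last quarter of the run); the slope is a least-squares fit over
    all samples up to that block.  Returns ``(slope, r_squared, t_end)``.
    """
    t = np.arange(ln_dist.size) * dt_sample
    sat = np.median(ln_dist[3 * ln_dist.size // 4:])
    grew = sat > ln_dist[0] + 5.0
    if grew:
        blk = max(int(round(250.0 / dt_sample)), 2)
        n_blocks = ln_dist.size // blk
        end = n_blocks
        for k in range(n_blocks):
            if np.median(ln_dist[k * blk:(k + 1) * blk]) >= sat - 2.0:
                end = k
                break
        n_fit = max(end * blk, 3 * blk)
    else:
        n_fit = ln_dist.size  # no exponential growth: decay/neutral fit
    n_fit = min(n_fit, ln_dist.size)
    slope, intercept = np.polyfit(t[:n_fit], ln_dist[:n_fit], 1)
    resid = ln_dist[:n_fit] - (slope * t[:n_fit] + intercept)
    var = ln_dist[:n_fit].var()
    r2 = 1.0 - resid.var() / var if var > 0 else 0.0
    return float(slope), float(r2), float(t[n_fit - 1])


def largest_lyapunov(
    model: Union[ModelParams, NetworkModel],
    ic: Optional[Sequence[float]] = None,
    settings: IntegratorSettings = IntegratorSettings(dt=0.05, t_end=60000.0, burn_in=10000.0),
    perturbation: float = 1e-9,
    method: str = "two-trajectory-fit",
    n_windows: int = 8,
    window_span: float = 12000.0,
    window_spacing: float = 5000.0,
    sample_every: float = 5.0,
    tau: float = 20.0,
) -> LyapunovEstimate:
    """Estimate the largest Lyapunov exponent (per year).

    ``two-trajectory-fit`` perturbs the reference state by
    ``perturbation`` in every component, co-integrates both copies for
    ``window_span`` years and fits the log-distance growth (see
    :func:`_fit_window_slope`); this is repeated over ``n_windows``
    starting points spaced ``window_spacing`` years apart along the
    attractor, and the mean slope is reported with its standard error.

    ``benettin`` renormalizes the companion trajectory back to separation
    ``perturbation`` every ``tau`` years over the whole post-burn-in
    horizon and averages the log growth factors; it is the more accurate
    asymptotic estimator and serves as the cross-check.
    """
    if perturbation <= 0:
        raise ValueError("perturbation must be > 0")
    m = _as_network(model)
    if ic is None:
        ic = default_ic(m.n_nodes)
    v0 = np.asarray(ic, dtype=float)
    dt = settings.dt
    args = m.kernel_args()

    status, failed, v = _kernels.rk4_final(v0, *args, dt, int(round(settings.burn_in / dt)))
    _raise_for_status(status, failed, dt)

    if method == "benettin":
        horizon = settings.t_end - settings.burn_in
        n_intervals = max(int(horizon / tau), 10)
        status, logs = _kernels.benettin_run(
            v, *args, dt, perturbation, int(round(tau / dt)), n_intervals
        )
        if status != 0:
            _raise_for_status(status, -1, dt)
        lam = float(logs.mean() / tau)
        se = float(logs.std(ddof=1) / tau / np.sqrt(logs.size))
        return LyapunovEstimate(lam, se, (0.0, horizon), "benettin", 1.0, logs / tau)

    if method != "two-trajectory-fit":
        raise ValueError(f"unknown method {method!r}")

    stride = max(int(round(sample_every / dt)), 1)
    slopes, r2s, tends = [], [], []
    for _ in range(n_windows):
        w = v + perturbation
        status, dist, _vf = _kernels.divergence_run(
            v, w, *args, dt, int(round(window_span / dt)), stride
        )
        if status != 0:
            _raise_for_status(status, -1, dt)
        ln_dist = np.log(np.maximum(dist, 1e-300))
        slope, r2, tend = _fit_window_slope(ln_dist, dt * stride)
        slopes.append(slope)
        r2s.append(r2)
        tends.append(tend)
        status, failed, v = _kernels.rk4_final(v, *args, dt, int(round(window_spacing / dt)))
        _raise_for_status(status, failed, dt)
    slopes = np.array(slopes)
    lam = float(slopes.mean())
    se = float(slopes.std(ddof=1) / np.sqrt(slopes.size)) if slopes.size > 1 else 0.0
    return LyapunovEstimate(
        lam, se, (0.0, float(np.mean(tends))), "two-trajectory-fit",
        float(np.mean(r2s)), slopes,
    )


def predictability_timescale(est: LyapunovEstimate) -> float:
    """Predictability horizon ``1 / lambda`` in years (requires chaos)."""
    if est.lambda_ <= 0:
        raise EcosocnetError(
            "predictability timescale is undefined (infinite) for lambda <= 0"
        )
    return 1.0 / est.lambda_


# ---------------------------------------------------------------------------
# Poincaré-plane surrogate

@dataclass(frozen=True)
class PlaneCrossings:
    """Signed distances to the reference hyperplane and crossing times."""

    t: np.ndarray
    signed_distance: np.ndarray
    crossing_times: np.ndarray

    @property
    def crossing_intervals(self) -> np.ndarray:
        return np.diff(self.crossing_times)


def plane_crossing_series(
    traj: Trajectory,
    reference: Union[FixedPoint, Sequence[float]],
) -> PlaneCrossings:
    """Signed distance of a trajectory to the plane
    ``sum_i (x_i + y_i + z_i) = N (x_eq + y_eq + z_eq)``.

    The distance is normalized by ``sqrt(3N)`` (the norm of the plane's
    normal vector); crossing times are located by linear interpolation
    between bracketing samples.  A trajectory that never crosses returns
    an empty crossing array (valid — e.g. a fixed-point run).
    """
    coords = reference.coords if isinstance(reference, FixedPoint) else np.asarray(reference)
    n = traj.n_nodes
    const = n * float(np.sum(coords))
    total = traj.states.sum(axis=1)
    dist = (total - const) / np.sqrt(3 * n)
    t = traj.t
    sign_change = np.where(dist[:-1] * dist[1:] < 0)[0]
    frac = dist[sign_change] / (dist[sign_change] - dist[sign_change + 1])
    crossings = t[sign_change] + frac * traj.dt
    exact = np.where(dist == 0)[0]
    if exact.size:
        crossings = np.sort(np.concatenate([crossings, t[exact]]))
    return PlaneCrossings(t=t, signed_distance=dist, crossing_times=crossings)


# ---------------------------------------------------------------------------
# power spectrum

@dataclass(frozen=True)
class SpectrumResult:
    """Magnitude spectrum with a peak-density statistic.

    ``peak_density`` counts local maxima above 1% of the dominant peak,
    per unit frequency — an operational version of the visual periodic
    (few well-separated peaks) vs chaotic (dense comb) distinction."""

    frequency: np.ndarray
    amplitude: np.ndarray
    peak_density: float


def power_spectrum(
    series: np.ndarray,
    dt: float,
    peak_threshold: float = 0.01,
) -> SpectrumResult:
    """Hann-tapered magnitude spectrum of a uniformly sampled observable.

    The series mean is removed and a single segment is transformed (no
    averaging), mirroring a raw spectrum.  Requires at least 4096 samples.
    """
    s = np.asarray(series, dtype=float)
    if s.size < 4096:
        raise ValueError(f"series too short for a spectrum: {s.size} < 4096 samples")
    s = s - s.mean()
    window = np.hanning(s.size)
    amp = np.abs(np.fft.rfft(s * window))
    freq = np.fft.rfftfreq(s.size, d=dt)
    interior = (amp[1:-1] > amp[:-2]) & (amp[1:-1] > amp[2:])
    peaks = interior & (amp[1:-1] > peak_threshold * amp.max())
    density = float(peaks.sum() / (freq[-1] - freq[0]))
    return SpectrumResult(frequency=freq, amplitude=amp, peak_density=density)


# ---------------------------------------------------------------------------
# bifurcation scan

@dataclass(frozen=True)
class ScanPoint:
    """Extrema clusters of the observable at one extraction rate."""

    alpha: float
    clusters: np.ndarray
    error: Optional[str] = None

    @property
    def n_clusters(self) -> int:
        return self.clusters.size


def bifurcation_scan(
    model_family: Callable[[float], Union[ModelParams, NetworkModel]],
    alpha_grid: Sequence[float],
    settings: IntegratorSettings,
    ic: Optional[Sequence[float]] = None,
    observable_node: int = 0,
    tol_extrema: float = 1e-3,
) -> list[ScanPoint]:
    """Post-transient extrema clusters of ``x`` at ``observable_node`` for
    each extraction rate in ``alpha_grid``.

    ``model_family`` maps an alpha value to a model; every point uses the
    same integrator settings and initial condition.  Integration failures
    are recorded per point and do not abort the scan.
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if np.any(np.diff(alpha_grid) <= 0):
        raise ValueError("alpha_grid must be strictly increasing")
    from .integrate import integrate_rk4  # local import to avoid cycle at module load

    points = []
    for a in alpha_grid:
        model = model_family(float(a))
        try:
            traj = integrate_rk4(model, ic=ic, settings=settings)
            x = traj.x(observable_node)
            clusters = cluster_extrema(local_extrema(x), tol_extrema)
            if clusters.size == 0:  # fixed point: min = max = equilibrium value
                clusters = np.array([x[-1]])
            points.append(ScanPoint(float(a), clusters))
        except (IntegrationError, ModelViolationError) as exc:
            points.append(ScanPoint(float(a), np.empty(0), error=str(exc)))
    return points
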