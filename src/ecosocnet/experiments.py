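"""Scenario runners: regime suites, the chaos scenario, diffusion scans.

Every runner resolves extraction rates as multiples of the numerically
validated Hopf threshold, so scenario definitions are insensitive to how
the closed-form threshold is grouped.  Sustainable ("white") nodes always
extract at ``2 alpha_star`` (the maximum-capacity sustainable rate);
unsustainable ("black") nodes at a chosen multiple of ``alpha_c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from . import _kernels
from .diagnostics import (
    AttractorSummary,
    LyapunovEstimate,
    PlaneCrossings,
    ScanPoint,
    SpectrumResult,
    attractor_summary,
    bifurcation_scan,
    largest_lyapunov,
    plane_crossing_series,
    power_spectrum,
)
from .integrate import IntegratorSettings, Trajectory, default_ic, integrate_rk4, _raise_for_status
from .model import bifurcation_thresholds, fixed_points, resolved_alpha_crit, alpha_star
from .network import NetworkModel, build_interaction, build_laplacian
from .params import ModelParams

__all__ = [
    "run_single_regime_suite",
    "run_chaos_scenario",
    "run_sigma_scan",
    "run_random_graph_experiment",
    "run_coupled_sustainable_comparison",
    "classify_network_regime",
    "DEFAULT_LAYOUTS",
]

#: (node count, sustainable-node indices) for the named migration topologies.
#: The star layout places the single sustainable society at the hub, so all
#: of its neighbours are unsustainable; the ring has one sustainable node.
DEFAULT_LAYOUTS = {
    "chain": (5, (2,)),
    "ring": (5, (0,)),
    "star": (5, (0,)),
}

#: IC symmetry-breaking perturbation (relative); see integrate.default_ic.
IC_PERTURBATION = 1e-6


# ---------------------------------------------------------------------------
# fast adaptive regime classification for sigma scans

def classify_network_regime(
    model: NetworkModel,
    ic: Optional[np.ndarray] = None,
    ic_seed: int = 0,
    dt: float = 0.1,
    stage_burn: float = 5000.0,
    stage_measure: float = 2000.0,
    max_total: float = 70000.0,
    hard_reject_ratio: float = 2.0,
    stagnation_factor: float = 0.7,
    tol_ratio: float = 1e-3,
) -> tuple[float, str]:
    """Max/min total-population ratio and regime label for one network.

    Transients towards a network fixed point can decay very slowly (the
    excess ratio shrinks by roughly a fixed factor every few thousand
    years), so a single short run cannot separate a decaying transient
    from a genuine small oscillation.  The classification proceeds in
    stages of ``stage_burn`` years of burn-in plus ``stage_measure`` years
    of measurement and stops as soon as either

    * the ratio is within ``tol_ratio`` of 1 (fixed point), or
    * the excess ratio stopped shrinking between stages — it stayed above
      ``stagnation_factor`` times the previous excess — or exceeds
      ``hard_reject_ratio`` outright (sustained oscillation), or
    * ``max_total`` years have been integrated (the residual ratio is
      then reported as-is).
    """
    if ic is None:
        ic = default_ic(model.n_nodes, IC_PERTURBATION, ic_seed)
    args = model.kernel_args()
    v = np.asarray(ic, dtype=float)
    t_used = 0.0
    prev_excess = None
    while True:
        status, failed, v = _kernels.rk4_final(v, *args, dt, int(stage_burn / dt))
        _raise_for_status(status, failed, dt)
        status, failed, v, tot = _kernels.rk4_total_population(
            v, *args, dt, int(stage_measure / dt)
        )
        _raise_for_status(status, failed, dt)
        ratio = float(tot.max() / tot.min())
        t_used += stage_burn + stage_measure
        if ratio < 1 + tol_ratio:
            return ratio, "fixed_point"
        excess = ratio - 1.0
        if ratio > hard_reject_ratio:
            return ratio, "oscillating"
        if prev_excess is not None and excess > stagnation_factor * prev_excess:
            return ratio, "oscillating"
        if t_used + stage_burn + stage_measure > max_total:
            return ratio, "oscillating"
        prev_excess = excess


# ---------------------------------------------------------------------------
# single-system regime suite

@dataclass(frozen=True)
class RegimeResult:
    """One single-system scenario: extraction rate, regime, amplitude."""

    name: str
    alpha: float
    regime: str
    amplitude: float
    final_state: np.ndarray


def run_single_regime_suite(
    params: ModelParams = ModelParams(),
    settings: IntegratorSettings = IntegratorSettings(dt=0.05, t_end=20000.0, burn_in=12000.0, stride=4),
    alpha_scan: Optional[Sequence[float]] = None,
) -> dict:
    """The three canonical single-society runs plus an optional alpha scan.

    From initial condition ``(1, 100, 1)``: at ``2 alpha_star`` the system
    settles on the interior fixed point; at ``2 alpha_c`` a large limit
    cycle; at ``5 alpha_c`` a limit cycle of smaller amplitude.  When
    ``alpha_scan`` is given, a min/max bifurcation diagram of the
    population is computed on that grid.
    """
    a_star = alpha_star(params)
    a_crit = resolved_alpha_crit(params)
    scenarios = {
        "fixed_point": 2 * a_star,
        "limit_cycle": 2 * a_crit,
        "limit_cycle_reduced": 5 * a_crit,
    }
    results = {}
    for name, alpha in scenarios.items():
        p = params.with_alpha(alpha)
        traj = integrate_rk4(p, settings=settings)
        summary = attractor_summary(traj)
        x = traj.x(0)
        results[name] = RegimeResult(
            name, alpha, summary.regime, float(x.max() - x.min()), traj.states[-1]
        )
    out = {"scenarios": results, "thresholds": bifurcation_thresholds(params)}
    if alpha_scan is not None:
        out["scan"] = bifurcation_scan(
            lambda a: params.with_alpha(a), alpha_scan, settings
        )
    return out


# ---------------------------------------------------------------------------
# chaos scenario

@dataclass(frozen=True)
class ChaosScenarioResult:
    """Full diagnostics bundle for the perturbed-uniform-interaction network."""

    model: NetworkModel
    alpha: float
    trajectory: Trajectory
    plane_crossings: PlaneCrossings
    spectrum: SpectrumResult
    lyapunov: LyapunovEstimate
    lyapunov_benettin: LyapunovEstimate
    summary: AttractorSummary
    sync_error_max: float
    sync_error_median: float

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "regime": self.summary.regime,
            "ratio": self.summary.ratio,
            "lyapunov": self.lyapunov.to_dict(),
            "lyapunov_benettin": self.lyapunov_benettin.to_dict(),
            "spectrum_peak_density": self.spectrum.peak_density,
            "n_plane_crossings": int(self.plane_crossings.crossing_times.size),
            "sync_error_max": self.sync_error_max,
            "sync_error_median": self.sync_error_median,
        }


def run_chaos_scenario(
    n_nodes: int = 3,
    alpha_multiple: float = 10.0,
    delta: Optional[float] = None,
    params: ModelParams = ModelParams(),
    seed: int = 0,
    dt: float = 0.05,
    burn_in: float = 10000.0,
    record_span: float = 20000.0,
    lyapunov_total: float = 50000.0,
) -> ChaosScenarioResult:
    """Run the perturbed uniform-interaction network and its diagnostics.

    The interaction matrix is ``ones/N + delta*I`` with the default
    ``delta = 1e-2 / N``; no migration.  With a common extraction rate
    above roughly three times the Hopf threshold the (approximately)
    synchronized dynamics leaves the limit cycle and becomes chaotic.
    Initial conditions are per-node ``(1, 100, 1)`` with a relative 1e-6
    node-wise perturbation to break the exact permutation symmetry.
    """
    if delta is None:
        delta = 1e-2 / n_nodes
    a_crit = resolved_alpha_crit(params)
    alpha = alpha_multiple * a_crit
    model = NetworkModel.uniform(
        params, n_nodes, alpha=alpha, interaction="uniform_plus_delta", delta=delta
    )
    ic = default_ic(n_nodes, IC_PERTURBATION, seed)

    stride = max(int(round(0.2 / dt)), 1)
    traj = integrate_rk4(
        model,
        ic=ic,
        settings=IntegratorSettings(dt=dt, t_end=burn_in + record_span, burn_in=burn_in, stride=stride),
    )

    # reference plane through the synchronized-system equilibrium
    ref = [fp for fp in fixed_points(params.with_alpha(alpha * (1 + delta))) if fp.label == "E"][0]
    crossings = plane_crossing_series(traj, ref)
    spectrum = power_spectrum(traj.x(0), traj.dt)

    from .network import sync_error

    if n_nodes >= 2:
        se = sync_error(traj.states)
        sync_max, sync_med = float(se.max()), float(np.median(se))
    else:
        sync_max = sync_med = 0.0

    n_windows = max(int(lyapunov_total // 6000), 2)
    lyap_settings = IntegratorSettings(dt=dt, t_end=burn_in + lyapunov_total, burn_in=burn_in)
    lyap = largest_lyapunov(
        model, ic=ic, settings=lyap_settings, method="two-trajectory-fit",
        n_windows=n_windows,
    )
    lyap_ben = largest_lyapunov(model, ic=ic, settings=lyap_settings, method="benettin")

    return ChaosScenarioResult(
        model=model,
        alpha=alpha,
        trajectory=traj,
        plane_crossings=crossings,
        spectrum=spectrum,
        lyapunov=lyap,
        lyapunov_benettin=lyap_ben,
        summary=attractor_summary(traj),
        sync_error_max=sync_max,
        sync_error_median=sync_med,
    )


# ---------------------------------------------------------------------------
# diffusion (sigma) scans

@dataclass(frozen=True)
class SigmaScanResult:
    """Per-sigma population ratios and the fixed-point windows they imply."""

    topology: str
    n_nodes: int
    sustainable_nodes: tuple
    black_multiple: float
    sigmas: np.ndarray
    ratios: np.ndarray
    regimes: list

    @property
    def fixed_point_windows(self) -> list[tuple[float, float]]:
        """Contiguous sigma intervals classified as a global fixed point."""
        wins = []
        start = None
        for s, lab in zip(self.sigmas, self.regimes):
            if lab == "fixed_point":
                if start is None:
                    start = s
                end = s
            else:
                if start is not None:
                    wins.append((float(start), float(end)))
                    start = None
        if start is not None:
            wins.append((float(start), float(end)))
        return wins

    @property
    def fixed_point_window_length(self) -> float:
        """Total measure of the fixed-point windows on the scan grid."""
        if self.sigmas.size < 2:
            return 0.0
        step = float(self.sigmas[1] - self.sigmas[0])
        return step * sum(lab == "fixed_point" for lab in self.regimes)

    def to_dict(self) -> dict:
        return {
            "topology": self.topology,
            "n_nodes": self.n_nodes,
            "sustainable_nodes": list(self.sustainable_nodes),
            "black_multiple": self.black_multiple,
            "sigmas": self.sigmas.tolist(),
            "ratios": self.ratios.tolist(),
            "regimes": self.regimes,
            "fixed_point_windows": self.fixed_point_windows,
        }


def _mixed_network(
    params: ModelParams,
    B: np.ndarray,
    sustainable_nodes: Sequence[int],
    black_multiple: float,
    sigma: float,
) -> NetworkModel:
    n = B.shape[0]
    a_star = alpha_star(params)
    a_crit = resolved_alpha_crit(params)
    alphas = np.full(n, black_multiple * a_crit)
    alphas[list(sustainable_nodes)] = 2 * a_star
    return NetworkModel(params, alphas, np.eye(n), B, sigma)


def run_sigma_scan(
    topology: str = "chain",
    black_multiple: float = 1.5,
    sigma_grid: Optional[Sequence[float]] = None,
    n_nodes: Optional[int] = None,
    sustainable_nodes: Optional[Sequence[int]] = None,
    params: ModelParams = ModelParams(),
    ic_seed: int = 0,
    dt: float = 0.1,
) -> SigmaScanResult:
    """Scan the diffusion constant for a mixed sustainable/unsustainable
    network with independent extraction (``A = I``).

    For each sigma the post-transient max/min ratio of total population is
    computed; ratio 1 (within tolerance) marks a globally sustainable
    fixed point.  Default layouts (node count and sustainable-node
    placement) per topology are in :data:`DEFAULT_LAYOUTS`.
    """
    if sigma_grid is None:
        sigma_grid = np.arange(0.0, 0.3 + 1e-12, 0.005)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if n_nodes is None or sustainable_nodes is None:
        layout_n, layout_white = DEFAULT_LAYOUTS[topology]
        n_nodes = layout_n if n_nodes is None else n_nodes
        sustainable_nodes = layout_white if sustainable_nodes is None else sustainable_nodes
    B = build_laplacian(topology, n_nodes)
    ratios, regimes = [], []
    for s in sigma_grid:
        model = _mixed_network(params, B, sustainable_nodes, black_multiple, float(s))
        ratio, label = classify_network_regime(model, ic_seed=ic_seed, dt=dt)
        ratios.append(ratio)
        regimes.append(label)
    return SigmaScanResult(
        topology=topology,
        n_nodes=n_nodes,
        sustainable_nodes=tuple(sustainable_nodes),
        black_multiple=black_multiple,
        sigmas=sigma_grid,
        ratios=np.array(ratios),
        regimes=regimes,
    )


# ---------------------------------------------------------------------------
# random-graph minimal sustainable fraction

@dataclass(frozen=True)
class RandomGraphSeedResult:
    graph_seed: int
    minimal_fraction: Optional[float]
    sigma_at_success: Optional[float]
    infeasible_fractions: tuple


@dataclass(frozen=True)
class RandomGraphResult:
    """Minimal sustainable fraction per graph seed, and the modal value."""

    n_nodes: int
    avg_degree: float
    black_multiple: float
    per_seed: list
    modal_fraction_percent: Optional[float]

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "avg_degree": self.avg_degree,
            "black_multiple": self.black_multiple,
            "per_seed": [
                {
                    "graph_seed": r.graph_seed,
                    "minimal_fraction": r.minimal_fraction,
                    "sigma_at_success": r.sigma_at_success,
                    "infeasible_fractions": list(r.infeasible_fractions),
                }
                for r in self.per_seed
            ],
            "modal_fraction_percent": self.modal_fraction_percent,
        }


def _independent_set(g: nx.Graph, size: int, rng: np.random.Generator, attempts: int = 400):
    """Greedy random independent set of the requested size, or None."""
    nodes = list(g.nodes)
    for _ in range(attempts):
        rng.shuffle(nodes)
        chosen: list[int] = []
        for u in nodes:
            if all(not g.has_edge(u, v) for v in chosen):
                chosen.append(u)
                if len(chosen) == size:
                    return chosen
    return None


def run_random_graph_experiment(
    n_nodes: int = 20,
    avg_degree: float = 4.0,
    black_multiple: float = 1.5,
    fraction_grid: Optional[Sequence[float]] = None,
    sigma_grid: Optional[Sequence[float]] = None,
    graph_seeds: Sequence[int] = tuple(range(1, 11)),
    params: ModelParams = ModelParams(),
    dt: float = 0.1,
) -> RandomGraphResult:
    """Smallest fraction of sustainable societies that stabilizes an
    Erdős–Rényi network for some diffusion constant.

    For each graph seed: a connected ER graph of the given average degree
    is drawn; for each fraction (5% steps by default) that many
    sustainable nodes (rate ``2 alpha_star``) are placed as an independent
    set — mutually non-adjacent — with the rest extracting at
    ``black_multiple * alpha_c``; sigma is scanned (from high to low, since
    stabilization typically needs appreciable diffusion) until some value
    yields a global fixed point.  Reports each seed's minimal successful
    fraction and the modal value across seeds.
    """
    if fraction_grid is None:
        fraction_grid = np.arange(0.05, 0.40001, 0.05)
    if sigma_grid is None:
        sigma_grid = np.arange(0.0, 0.30001, 0.01)
    sigma_desc = np.sort(np.asarray(sigma_grid, dtype=float))[::-1]

    per_seed = []
    for gseed in graph_seeds:
        rng = np.random.default_rng(gseed)
        B = build_laplacian("random", n_nodes, seed=gseed, avg_degree=avg_degree)
        g = nx.from_numpy_array(np.diag(np.diag(B)) - B)
        found = None
        sigma_found = None
        infeasible = []
        for frac in fraction_grid:
            n_sus = int(round(frac * n_nodes))
            if n_sus < 1:
                continue
            placement = _independent_set(g, n_sus, rng)
            if placement is None:
                infeasible.append(float(frac))
                continue
            for s in sigma_desc:
                model = _mixed_network(params, B, placement, black_multiple, float(s))
                ratio, label = classify_network_regime(model, ic_seed=gseed, dt=dt)
                if label == "fixed_point":
                    found = float(frac)
                    sigma_found = float(s)
                    break
            if found is not None:
                break
        per_seed.append(
            RandomGraphSeedResult(int(gseed), found, sigma_found, tuple(infeasible))
        )

    fractions = [r.minimal_fraction for r in per_seed if r.minimal_fraction is not None]
    modal = None
    if fractions:
        vals, counts = np.unique(np.round(fractions, 6), return_counts=True)
        modal = float(vals[np.argmax(counts)] * 100.0)
    return RandomGraphResult(n_nodes, avg_degree, black_multiple, per_seed, modal)


# ---------------------------------------------------------------------------
# adjacent vs non-adjacent sustainable societies

@dataclass(frozen=True)
class CouplingComparisonResult:
    """Fixed-point window lengths for the two sustainable-pair layouts."""

    scan_non_adjacent: SigmaScanResult
    scan_adjacent: SigmaScanResult

    @property
    def window_length_non_adjacent(self) -> float:
        return self.scan_non_adjacent.fixed_point_window_length

    @property
    def window_length_adjacent(self) -> float:
        return self.scan_adjacent.fixed_point_window_length

    def to_dict(self) -> dict:
        return {
            "window_length_non_adjacent": self.window_length_non_adjacent,
            "window_length_adjacent": self.window_length_adjacent,
            "non_adjacent": self.scan_non_adjacent.to_dict(),
            "adjacent": self.scan_adjacent.to_dict(),
        }


def run_coupled_sustainable_comparison(
    black_multiple: float = 1.5,
    sigma_grid: Optional[Sequence[float]] = None,
    n_nodes: int = 6,
    non_adjacent_nodes: Sequence[int] = (1, 4),
    adjacent_nodes: Sequence[int] = (2, 3),
    params: ModelParams = ModelParams(),
    ic_seed: int = 0,
    dt: float = 0.1,
) -> CouplingComparisonResult:
    """Does linking sustainable societies directly help?  Two chains that
    differ only in whether the two sustainable nodes are adjacent are
    scanned over sigma; the comparison reports the measure of the
    globally-sustainable (fixed point) window for each."""
    kw = dict(
        topology="chain",
        black_multiple=black_multiple,
        sigma_grid=sigma_grid,
        n_nodes=n_nodes,
        params=params,
        ic_seed=ic_seed,
        dt=dt,
    )
    scan_non = run_sigma_scan(sustainable_nodes=tuple(non_adjacent_nodes), **kw)
    scan_adj = run_sigma_scan(sustainable_nodes=tuple(adjacent_nodes), **kw)
    return CouplingComparisonResult(scan_non, scan_adj)
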