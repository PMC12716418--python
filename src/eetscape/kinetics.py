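"""Master-equation kinetics and antenna-to-core pathway analysis.

The cluster rate table becomes a continuous-time master equation
dp/dt = K p with one extra absorbing state (the photochemical trap fed by the
core cluster).  From K we extract eigen-lifetimes and amplitudes, mean
first-passage times (MFPT) to the trap, best antenna-to-core routes under the
display cutoff, and layer-averaged route time constants.  The route constant
is the sum of stepwise time constants along the minimal-total-tau path; the
MFPT is always co-reported since the two constructions differ on reversible
networks.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .gforster import ClusterRateTable
from .structure_io import StructureModel

__all__ = [
    "KineticModel",
    "KineticSolution",
    "Route",
    "build_kinetic_model",
    "solve_kinetics",
    "mfpt_to_trap",
    "best_route",
    "layer_average_route_time",
    "TRAP_STATE",
]

TRAP_STATE = "__trap__"


@dataclass
class KineticModel:
    """Rate matrix over cluster states plus an absorbing trap.

    Convention: K[j, i] = k(i -> j) for j != i; K[i, i] = -sum of outflows, so
    columns of non-absorbing states sum to zero and dp/dt = K p conserves
    total (transient + absorbed) probability.
    """

    states: list[str]          # last entry is the trap
    matrix: np.ndarray
    trap_state: str = TRAP_STATE
    trap_feeder: str | None = None

    def __post_init__(self) -> None:
        k = np.asarray(self.matrix, dtype=float)
        n = len(self.states)
        if k.shape != (n, n):
            raise ValueError("rate matrix shape mismatch")
        off = k - np.diag(np.diag(k))
        if (off < -1e-12).any():
            raise ValueError("off-diagonal rates must be non-negative")
        if (k.sum(axis=0) > 1e-9).any():
            raise ValueError("columns must sum to <= 0")
        self.matrix = k

    def index(self, state: str) -> int:
        return self.states.index(state)

    @property
    def transient_states(self) -> list[str]:
        return [s for s in self.states if s != self.trap_state]


@dataclass
class KineticSolution:
    """Eigen-solution of the master equation for one initial condition."""

    lifetimes: np.ndarray              # ps, ascending, decaying modes only
    amplitudes: np.ndarray             # (n_modes, n_states) incl. zero modes
    mode_rates: np.ndarray             # all eigenvalues (1/ps, <= 0)
    states: list[str]
    p0: np.ndarray

    def occupancies(self, t: np.ndarray) -> np.ndarray:
        """p(t), shape (n_times, n_states); conserves total probability."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.real(
            np.exp(np.outer(t, self.mode_rates)) @ self.amplitudes
        )


def build_kinetic_model(
    table: ClusterRateTable,
    trap_from: str | None = "core",
    trap_rate: float = 1.0,
) -> KineticModel:
    """Assemble K from the full (uncut) cluster table, optionally with a trap.

    ``trap_from`` names the state that drains irreversibly into the trap with
    ``trap_rate`` (ps^-1); the default 1 ps emulates fast charge separation in
    the reaction center.  ``trap_from=None`` builds the conservative matrix
    without an absorbing state.
    """
    if not table.rates:
        raise ValueError("empty rate table")
    states = sorted(table.states())
    if trap_from is not None:
        if trap_from not in states:
            raise KeyError(f"trap feeder {trap_from!r} not among states {states}")
        states = states + [TRAP_STATE]
    n = len(states)
    idx = {s: i for i, s in enumerate(states)}
    k = np.zeros((n, n))
    for (d, a), rate in table.rates.items():
        k[idx[a], idx[d]] += rate
    if trap_from is not None:
        k[idx[TRAP_STATE], idx[trap_from]] += trap_rate
    np.fill_diagonal(k, 0.0)
    k[np.diag_indices(n)] = -k.sum(axis=0)
    return KineticModel(states=states, matrix=k, trap_feeder=trap_from)


def solve_kinetics(model: KineticModel, p0: dict[str, float] | np.ndarray) -> KineticSolution:
    """Eigen-decompose K and express p(t) = sum_k a_k v_k exp(lambda_k t).

    Falls back to numerical propagation-based amplitudes (with a warning) when
    K is defective within tolerance.
    """
    n = len(model.states)
    if isinstance(p0, dict):
        vec = np.zeros(n)
        for s, w in p0.items():
            vec[model.index(s)] = w
    else:
        vec = np.asarray(p0, dtype=float)
    if abs(vec.sum() - 1.0) > 1e-8:
        raise ValueError("initial occupancy must be normalized")

    lam, vecs = np.linalg.eig(model.matrix)
    order = np.argsort(lam.real)[::-1]
    lam, vecs = lam[order], vecs[:, order]
    try:
        coef = np.linalg.solve(vecs, vec)
        defective = np.linalg.cond(vecs) > 1e12
    except np.linalg.LinAlgError:
        defective = True
    if defective:
        warnings.warn("rate matrix is (near-)defective; using numerical propagation")
        coef, lam, vecs = _numeric_modes(model, vec)

    amplitudes = coef[:, None] * vecs.T   # (mode, state)
    decaying = lam.real < -1e-12
    lifetimes = np.sort(-1.0 / lam.real[decaying])
    return KineticSolution(
        lifetimes=lifetimes,
        amplitudes=amplitudes,
        mode_rates=lam,
        states=list(model.states),
        p0=vec,
    )


def _numeric_modes(model: KineticModel, p0: np.ndarray):
    """Crude mode recovery by dense propagation (defective-K fallback)."""
    lam, vecs = np.linalg.eig(model.matrix + 1e-10 * np.eye(len(p0)))
    coef = np.linalg.lstsq(vecs, p0, rcond=None)[0]
    return coef, lam, vecs


def propagate_numerically(
    model: KineticModel, p0: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Reference propagation of dp/dt = K p with an adaptive integrator."""
    sol = solve_ivp(
        lambda _, p: model.matrix @ p,
        (0.0, float(t[-1])),
        np.asarray(p0, dtype=float),
        t_eval=np.asarray(t, dtype=float),
        rtol=1e-10,
        atol=1e-12,
        method="LSODA",
    )
    return sol.y.T


def mfpt_to_trap(model: KineticModel, source: str) -> float:
    """Mean first-passage time (ps) from ``source`` to the absorbing trap.

    Solves the standard linear system over transient states; an unreachable
    trap yields +inf.
    """
    if model.trap_state not in model.states:
        raise ValueError("model has no trap state")
    # restrict to states from which the trap is reachable; others have MFPT inf
    itrap = model.index(model.trap_state)
    n = len(model.states)
    reach = {itrap}
    frontier = [itrap]
    while frontier:
        j = frontier.pop()
        for i in range(n):
            if i != j and i not in reach and model.matrix[j, i] > 0:
                reach.add(i)
                frontier.append(i)
    isrc = model.index(source)
    if isrc not in reach:
        return np.inf
    idx = sorted(reach - {itrap})
    q = model.matrix[np.ix_(idx, idx)]   # transient generator block (column conv.)
    try:
        m = np.linalg.solve(q.T, -np.ones(len(idx)))
    except np.linalg.LinAlgError:
        return np.inf
    val = m[idx.index(isrc)]
    if val < 0 or not np.isfinite(val):
        return np.inf
    return float(val)


@dataclass
class Route:
    """One antenna-to-core path: subunit sequence, per-step taus, total."""

    path: list[str]
    step_taus: list[float]
    total_tau: float

    def as_dict(self) -> dict:
        return {
            "path": self.path,
            "step_taus_ps": self.step_taus,
            "route_tau_ps": self.total_tau,
        }


def best_route(
    table: ClusterRateTable,
    source: str,
    sink: str = "core",
    cutoff_ps: float = 25.0,
) -> Route | None:
    """Minimal-total-tau directed path using only edges with tau <= cutoff.

    Dijkstra with deterministic lexicographic tie-breaking on the subunit
    sequence.  Returns None when no admissible path exists.
    """
    adj: dict[str, list[tuple[str, float]]] = {}
    for (d, a), k in table.rates.items():
        if k <= 0:
            continue
        tau = 1.0 / k
        if tau <= cutoff_ps:
            adj.setdefault(d, []).append((a, tau))
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (source,))]
    best: dict[str, float] = {}
    while heap:
        dist, path = heapq.heappop(heap)
        node = path[-1]
        if node == sink:
            return Route(path=list(path), step_taus=_steps(table, path), total_tau=dist)
        if node in best and dist > best[node] + 1e-15:
            continue
        for nxt, tau in sorted(adj.get(node, [])):
            if nxt in path:
                continue
            nd = dist + tau
            if nxt not in best or nd < best[nxt] - 1e-15:
                best[nxt] = nd
                heapq.heappush(heap, (nd, path + (nxt,)))
            elif abs(nd - best[nxt]) <= 1e-15:
                heapq.heappush(heap, (nd, path + (nxt,)))
    return None


def _steps(table: ClusterRateTable, path: tuple[str, ...]) -> list[float]:
    return [1.0 / table.rates[(d, a)] for d, a in zip(path, path[1:])]


def layer_average_route_time(
    model: StructureModel,
    table: ClusterRateTable,
    layers: set[int],
    sink: str = "core",
    cutoff_ps: float = 25.0,
    trap_rate: float = 1.0,
) -> dict:
    """Mean route constant from every antenna subunit in ``layers`` to the core.

    Returns the path-sum mean, the MFPT-based mean (computed on the full
    kinetic model including back-transfer), the per-source details, and any
    sources without an admissible route (excluded from the mean with a
    warning).
    """
    sources = [
        s.name
        for s in model.antenna_subunits
        if s.layer in layers and s.name in table.states()
    ]
    kin = build_kinetic_model(table, trap_from=sink, trap_rate=trap_rate)
    routes: dict[str, Route] = {}
    mfpts: dict[str, float] = {}
    unroutable: list[str] = []
    for src in sources:
        r = best_route(table, src, sink, cutoff_ps)
        if r is None:
            unroutable.append(src)
        else:
            routes[src] = r
        mfpts[src] = mfpt_to_trap(kin, src)
    if unroutable:
        warnings.warn(f"no admissible route to {sink} from: {unroutable}")
    route_taus = [r.total_tau for r in routes.values()]
    return {
        "layers": sorted(layers),
        "sources": sources,
        "mean_route_tau_ps": float(np.mean(route_taus)) if route_taus else np.nan,
        "mean_mfpt_ps": float(np.mean(list(mfpts.values()))) if mfpts else np.nan,
        "routes": {s: r.as_dict() for s, r in routes.items()},
        "mfpt_ps": mfpts,
        "unroutable": unroutable,
    }
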