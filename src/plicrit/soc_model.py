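"""Adaptive self-organized-criticality network (Bornholdt-Rohlf type).

N binary threshold elements with states sigma_i in {-1, +1} are coupled by a
signed matrix c (c[i, j] is the weight of the link j -> i, entries in
{-1, 0, +1}, zero diagonal) and updated synchronously:

    sigma_i(t+1) = sign( sum_j c[i, j] * sigma_j(t) ),   sign(0) = -1.

Topology evolves on a slower timescale: after each epoch of T_epoch
synchronous steps one node is picked at random; if its state never changed
during the epoch (frozen) it receives a new incoming link with random source
and random sign, if it changed (active) it loses one of its incoming links.
Under this rule the mean connectivity K = (number of links)/N self-organizes
to a characteristic value independent of the initial wiring, at which the
network sits at the order/disorder phase transition.  A control variant
rewires with fixed probabilities independent of activity, which drives K off
the self-organized plateau.

The synchronous-update kernel is JIT-compiled (numba) and exits an epoch
early when the dynamics reaches a fixed point or a period-2 cycle, tiling
the recorded states over the remainder — activity flags and recordings are
identical to a full-length run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .wavelet_phase import PLISet, extract_pli, hilbert_wavelet_transform, phase_pair_series

__all__ = [
    "AdaptiveNetwork",
    "SOCConfig",
    "SOCTrajectory",
    "init_network",
    "step_dynamics",
    "run_epoch",
    "rewire_adaptive",
    "rewire_random",
    "run_soc",
    "frozen_component",
    "frozen_component_sweep",
    "model_pli",
]


@dataclass
class AdaptiveNetwork:
    """Node states plus signed coupling matrix (dense int8, zero diagonal)."""

    N: int
    sigma: np.ndarray  # int8, values in {-1, +1}
    c: np.ndarray  # int8, shape (N, N); c[i, j] = weight of link j -> i
    rng: np.random.Generator
    seed: int | None = None

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.c))

    @property
    def K(self) -> float:
        """Mean connectivity: links per node."""
        return self.n_links / self.N


@dataclass
class SOCConfig:
    T_epoch: int = 1000
    iterations: int = 8000
    rewiring_mode: str = "adaptive"  # "adaptive" | "random"
    p_add: float = 0.8
    p_del: float = 0.2
    K_init: float = 2.0

    def __post_init__(self) -> None:
        if self.T_epoch < 1:
            raise ValueError("T_epoch must be >= 1")
        if self.rewiring_mode not in ("adaptive", "random"):
            raise ValueError(f"unknown rewiring_mode {self.rewiring_mode!r}")
        for p in (self.p_add, self.p_del):
            if not 0 <= p <= 1:
                raise ValueError("p_add, p_del must lie in [0, 1]")


@dataclass
class SOCTrajectory:
    """Per-iteration record of a topology-evolution run."""

    K_series: np.ndarray  # mean connectivity after each topology update
    config: SOCConfig
    seed: int | None = None
    monitored_nodes: np.ndarray | None = None
    recorded_states: np.ndarray | None = None  # (iterations*T_epoch, n_monitored) int8
    frozen_series: np.ndarray | None = None


def init_network(N: int, K_init: float, seed: int | None = None,
                 rng: np.random.Generator | None = None) -> AdaptiveNetwork:
    """Random network with round(N*K_init) links, weights ±1, random states."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if K_init < 0:
        raise ValueError("K_init must be >= 0")
    if K_init > N - 1:
        raise ValueError(f"K_init={K_init} exceeds the maximum N-1={N - 1}")
    if rng is None:
        rng = np.random.default_rng(seed)
    c = np.zeros((N, N), dtype=np.int8)
    n_links = int(round(N * K_init))
    placed = 0
    while placed < n_links:
        i = int(rng.integers(N))
        j = int(rng.integers(N))
        if i == j or c[i, j] != 0:
            continue
        c[i, j] = 1 if rng.random() < 0.5 else -1
        placed += 1
    sigma = np.where(rng.random(N) < 0.5, -1, 1).astype(np.int8)
    return AdaptiveNetwork(N=N, sigma=sigma, c=c, rng=rng, seed=seed)


def step_dynamics(net: AdaptiveNetwork) -> np.ndarray:
    """One synchronous update of all node states; returns the new states."""
    h = net.c.astype(np.int32) @ net.sigma.astype(np.int32)
    net.sigma = np.where(h > 0, 1, -1).astype(np.int8)
    return net.sigma


@njit(cache=True)
def _epoch_kernel(indptr, indices, data, sigma_io, T, record_idx, rec):  # pragma: no cover
    """T synchronous updates; sigma_io holds the final state on return.

    rec[t] receives the monitored states after update t (i.e. state t+1), so
    concatenating epochs yields a gapless series.  Exits early on fixed
    points and period-2 cycles, tiling the recording over the remainder.
    """
    N = sigma_io.shape[0]
    n_rec = record_idx.shape[0]
    changed = np.zeros(N, np.bool_)
    cur = sigma_io.copy()  # state t
    prev = np.empty(N, np.int8)  # state t-1
    nxt = np.empty(N, np.int8)  # state t+1
    have_prev = False
    for t in range(T):
        for i in range(N):
            s = 0
            for k in range(indptr[i], indptr[i + 1]):
                s += data[k] * cur[indices[k]]
            nxt[i] = 1 if s > 0 else -1
        fixed = True
        for i in range(N):
            if nxt[i] != cur[i]:
                changed[i] = True
                fixed = False
        for r in range(n_rec):
            rec[t, r] = nxt[record_idx[r]]
        if fixed:
            for tt in range(t + 1, T):
                for r in range(n_rec):
                    rec[tt, r] = rec[t, r]
            for i in range(N):
                sigma_io[i] = nxt[i]
            return changed
        if have_prev:
            per2 = True
            for i in range(N):
                if nxt[i] != prev[i]:
                    per2 = False
                    break
            if per2:
                # states alternate cur/nxt from here on
                for tt in range(t + 1, T):
                    if (tt - t) % 2 == 0:
                        for r in range(n_rec):
                            rec[tt, r] = nxt[record_idx[r]]
                    else:
                        for r in range(n_rec):
                            rec[tt, r] = cur[record_idx[r]]
                if (T - 1 - t) % 2 == 0:
                    for i in range(N):
                        sigma_io[i] = nxt[i]
                else:
                    for i in range(N):
                        sigma_io[i] = cur[i]
                return changed
        for i in range(N):
            prev[i] = cur[i]
            cur[i] = nxt[i]
        have_prev = True
    for i in range(N):
        sigma_io[i] = cur[i]
    return changed


def _to_csr(c: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rows, cols = np.nonzero(c)
    indptr = np.zeros(c.shape[0] + 1, dtype=np.int64)
    np.add.at(indptr, rows + 1, 1)
    indptr = np.cumsum(indptr)
    return indptr, cols.astype(np.int64), c[rows, cols].astype(np.int64)


def run_epoch(
    net: AdaptiveNetwork,
    T_epoch: int,
    record_nodes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Run ``T_epoch`` synchronous steps in place.

    Returns ``(changed, recorded)``: per-node flags for whether the state
    changed at least once during the epoch, and the int8 state series of the
    monitored nodes (shape ``(T_epoch, len(record_nodes))``) or None.
    """
    if T_epoch < 1:
        raise ValueError("T_epoch must be >= 1")
    indptr, indices, data = _to_csr(net.c)
    if record_nodes is None:
        ridx = np.empty(0, dtype=np.int64)
    else:
        ridx = np.asarray(record_nodes, dtype=np.int64)
    rec = np.empty((T_epoch, len(ridx)), dtype=np.int8)
    sigma = net.sigma.astype(np.int8).copy()
    changed = _epoch_kernel(indptr, indices, data, sigma, T_epoch, ridx, rec)
    net.sigma = sigma
    return changed, (rec if record_nodes is not None else None)


def rewire_adaptive(net: AdaptiveNetwork, changed: np.ndarray) -> None:
    """One activity-dependent topology update (in place).

    A node is picked uniformly; frozen nodes (state unchanged during the
    epoch) gain one incoming link from a random distinct source with random
    sign ±1, active nodes lose one incoming link chosen uniformly.  If the
    required change is impossible the network is left unchanged.
    """
    rng = net.rng
    i = int(rng.integers(net.N))
    row = net.c[i]
    if not changed[i]:
        free = np.flatnonzero(row == 0)
        free = free[free != i]
        if free.size == 0:
            return
        j = int(free[rng.integers(free.size)])
        net.c[i, j] = 1 if rng.random() < 0.5 else -1
    else:
        present = np.flatnonzero(row != 0)
        if present.size == 0:
            return
        j = int(present[rng.integers(present.size)])
        net.c[i, j] = 0


def rewire_random(net: AdaptiveNetwork, p_add: float, p_del: float) -> None:
    """Activity-independent topology update (in place).

    With probability ``p_add`` one uniformly chosen absent link is added with
    random sign; independently, with probability ``p_del`` one uniformly
    chosen existing link is deleted.
    """
    if not (0 <= p_add <= 1 and 0 <= p_del <= 1):
        raise ValueError("p_add, p_del must lie in [0, 1]")
    rng = net.rng
    N = net.N
    if rng.random() < p_add:
        # rejection sampling over off-diagonal zero entries
        for _ in range(100 * N):
            i = int(rng.integers(N))
            j = int(rng.integers(N))
            if i != j and net.c[i, j] == 0:
                net.c[i, j] = 1 if rng.random() < 0.5 else -1
                break
    if rng.random() < p_del:
        rows, cols = np.nonzero(net.c)
        if rows.size > 0:
            k = int(rng.integers(rows.size))
            net.c[rows[k], cols[k]] = 0


def run_soc(
    N: int = 1024,
    config: SOCConfig | None = None,
    seed: int | None = None,
    record_nodes: int = 0,
    record_from: int = 0,
    net: AdaptiveNetwork | None = None,
) -> tuple[SOCTrajectory, AdaptiveNetwork]:
    """Full topology-evolution run.

    Parameters
    ----------
    record_nodes
        Number of monitored nodes (chosen uniformly once per run) whose
        states are concatenated across epochs starting at iteration
        ``record_from``.
    net
        Continue from an existing network instead of initialising a new one
        (used to switch rewiring modes mid-experiment).
    """
    cfg = config or SOCConfig()
    if net is None:
        net = init_network(N, cfg.K_init, seed=seed)
    rng = net.rng
    if record_nodes > 0:
        monitored = np.sort(rng.choice(net.N, size=record_nodes, replace=False))
        n_rec_iters = cfg.iterations - record_from
        recorded = np.empty((n_rec_iters * cfg.T_epoch, record_nodes), dtype=np.int8)
    else:
        monitored, recorded = None, None
    K_series = np.empty(cfg.iterations)
    for it in range(cfg.iterations):
        want_rec = monitored is not None and it >= record_from
        changed, rec = run_epoch(net, cfg.T_epoch, monitored if want_rec else None)
        if want_rec and rec is not None:
            off = (it - record_from) * cfg.T_epoch
            recorded[off : off + cfg.T_epoch] = rec
        if cfg.rewiring_mode == "adaptive":
            rewire_adaptive(net, changed)
        else:
            rewire_random(net, cfg.p_add, cfg.p_del)
        K_series[it] = net.K
    traj = SOCTrajectory(
        K_series=K_series,
        config=cfg,
        seed=seed,
        monitored_nodes=monitored,
        recorded_states=recorded,
    )
    return traj, net


def frozen_component(
    net: AdaptiveNetwork,
    transient: int = 500,
    observe: int = 500,
    randomize_states: bool = True,
) -> float:
    """Fraction of nodes whose state never changes along the attractor.

    The attractor is approximated by discarding ``transient`` steps from
    random initial states and counting state changes over ``observe`` further
    steps (exact cycle detection is infeasible at N ~ 1000).
    """
    if transient < 1 or observe < 1:
        raise ValueError("transient and observe must be >= 1")
    if randomize_states:
        net.sigma = np.where(net.rng.random(net.N) < 0.5, -1, 1).astype(np.int8)
    run_epoch(net, transient)
    changed, _ = run_epoch(net, observe)
    return float(np.mean(~changed))


def frozen_component_sweep(
    K_values: np.ndarray,
    N: int = 1024,
    topologies: int = 100,
    transient: int = 500,
    observe: int = 500,
    seed: int | None = None,
) -> np.ndarray:
    """Mean frozen component vs connectivity, averaged over random topologies."""
    rng = np.random.default_rng(seed)
    out = np.empty(len(K_values))
    for a, K in enumerate(K_values):
        acc = 0.0
        for _ in range(topologies):
            net = init_network(N, float(K), rng=rng)
            acc += frozen_component(net, transient, observe)
        out[a] = acc / topologies
    return out


def model_pli(
    recorded_states: np.ndarray,
    T_epoch: int = 1000,
    n_iterations: int = 100,
    scale: int = 1,
    lock_threshold: float = np.pi / 4,
    min_coherence: float = 0.5,
) -> PLISet:
    """Pooled phase-lock intervals between monitored node-state series.

    The ±1 state series of each monitored node over ``n_iterations``
    consecutive epochs (one concatenated series of ``n_iterations * T_epoch``
    steps, unit sampling rate) is treated as a real-valued signal; PLI are
    pooled over all unordered node pairs at the requested wavelet scale.
    """
    rec = np.asarray(recorded_states)
    need = n_iterations * T_epoch
    if rec.shape[0] < need:
        raise ValueError(
            f"recorded states cover {rec.shape[0]} steps, need {need} "
            f"({n_iterations} epochs of {T_epoch})"
        )
    rec = rec[:need]
    m = rec.shape[1]
    coeffs = [hilbert_wavelet_transform(rec[:, k].astype(float), 1.0, [scale]) for k in range(m)]
    durations = []
    for a in range(m):
        for b in range(a + 1, m):
            pps = phase_pair_series(coeffs[a], coeffs[b], scale, min_coherence=min_coherence)
            pli = extract_pli(pps, lock_threshold, pair_id=f"{a}-{b}")
            durations.append(pli.durations)
    all_d = np.concatenate(durations) if durations else np.zeros(0, dtype=np.int64)
    return PLISet(
        durations=all_d,
        fs=1.0,
        scale=scale,
        lock_threshold=lock_threshold,
        min_coherence=min_coherence,
        pair_id="pooled",
    )
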