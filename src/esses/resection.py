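"""Virtual resections: effect quantification and simulated-annealing search.

A virtual resection disconnects a node set R by zeroing all its links; the
node set itself is retained so infection-ratio denominators stay comparable.
Two quantities characterize a resection:

* delta-IR, the normalized decrease in simulated seizure propagation,
  ``deltaIR(R) = (<IR_0> - <IR_R>) / <IR_0>``, estimated with paired seed
  realizations and common random numbers (the same seed draw and RNG
  substream evaluate the intact and the resected network);
* the seed efficiency ``E_R(seed)``, the mean inverse network distance from
  seed nodes to the remaining giant-component nodes — a cheap structural
  proxy for delta-IR that the annealer minimizes.

The optimal resection R_op is the smallest optimized resection reaching a
90% decrease in propagation; the disconnecting resection R_D is the smallest
that fully isolates the seed (e_R = E_R / E_0 = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .network import BrainNetwork, DistanceConvention, _edge_lengths
from .seeds import SeedProbabilityMap, sample_seed, sample_seed_panel
from .sir import SIRParameters, simulate_sir

__all__ = [
    "Resection",
    "ResectionEffect",
    "SAConfig",
    "SweepResult",
    "apply_resection",
    "seed_efficiency",
    "delta_ir",
    "paired_infection_ratios",
    "anneal_min_seed_efficiency",
    "resection_size_sweep",
    "overlap_with_plan",
]


@dataclass(frozen=True)
class Resection:
    """A resected node set with provenance (planned/optimized/disconnecting)."""

    nodes: frozenset
    provenance: str = "planned"

    def __post_init__(self):
        object.__setattr__(self, "nodes", frozenset(int(i) for i in self.nodes))

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass
class ResectionEffect:
    """Summary of a resection's effect on propagation and seed efficiency."""

    ir_before: tuple  # (mean, sd)
    ir_after: tuple
    delta_ir: tuple  # (mean, sd)
    seed_eff: float  # E_R averaged over the seed panel
    e0: float
    seed_eff_norm: float  # e_R = E_R / E_0

    @property
    def disconnected(self) -> bool:
        return self.seed_eff_norm == 0.0


@dataclass
class SAConfig:
    """Simulated-annealing schedule for the seed-efficiency minimization.

    The proposal swaps one resected node with one uniformly chosen
    non-resected node; T0 is calibrated so that roughly ``init_accept`` of
    initially worsening moves are accepted; geometric cooling runs until
    ``T < t_min_frac * T0`` or a full temperature passes with no accepted
    move. ``n_restarts`` independent restarts are run and the best state
    ever evaluated is returned.
    """

    n_restarts: int = 10
    proposals_per_temp: int = 60
    cooling: float = 0.95
    t_min_frac: float = 1e-3
    init_accept: float = 0.8
    panel_size: int = 20


@dataclass
class SweepResult:
    """Optimized resections of increasing size with their effects."""

    sizes: np.ndarray
    resections: list
    delta_ir_mean: np.ndarray
    delta_ir_sd: np.ndarray
    seed_eff: np.ndarray
    seed_eff_norm: np.ndarray
    e0: float
    ir0: tuple
    r_op: Resection | None
    r_d: Resection | None

    @property
    def s_rop(self) -> int | None:
        return self.r_op.size if self.r_op is not None else None

    @property
    def censored(self) -> bool:
        """True when no size reached the delta-IR target (R_op absent)."""
        return self.r_op is None

    def delta_ir_of_optimal(self) -> float:
        """Mean delta-IR of the resection designated optimal (best found if censored)."""
        if self.r_op is not None:
            idx = next(i for i, r in enumerate(self.resections) if r is self.r_op)
            return float(self.delta_ir_mean[idx])
        return float(np.max(self.delta_ir_mean))


def apply_resection(net: BrainNetwork, resection: Resection | Iterable[int]) -> BrainNetwork:
    """Zero all links incident to the resected nodes; node count unchanged."""
    nodes = resection.nodes if isinstance(resection, Resection) else frozenset(resection)
    idx = np.asarray(sorted(nodes), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= net.n_roi):
        raise ValueError("resection node index out of range")
    w = net.weights.copy()
    w[idx, :] = 0.0
    w[:, idx] = 0.0
    return BrainNetwork(net.roi_labels, w, density=net.density)


# ---------------------------------------------------------------------------
# Seed efficiency


def _giant_mask(lengths: csr_matrix, n: int) -> np.ndarray:
    n_comp, labels = connected_components(lengths, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    giant = int(np.flatnonzero(sizes == sizes.max())[0])
    return labels == giant


class _PanelEnergy:
    """Mean E_R(seed) over a fixed seed panel, evaluated per node-set.

    Precomputes the sparse-graph structure and panel bookkeeping once so
    that each annealing proposal costs one masked-CSR rebuild and one
    multi-source Dijkstra.

    With ``restrict_giant`` the published convention is used: seed and
    complement are restricted to the giant component, and a seed entirely
    outside it scores 0. Without it (the annealing search objective),
    infinite distances simply contribute nothing and the denominators stay
    fixed, so the objective keeps a gradient even after the seed has been
    severed from the giant component and keeps rewarding resections that
    shrink the seed's residual local neighbourhood.
    """

    def __init__(
        self,
        base_lengths: np.ndarray,
        panel: Sequence[frozenset],
        restrict_giant: bool = False,
    ):
        self.n = base_lengths.shape[0]
        self.restrict_giant = restrict_giant
        base = csr_matrix(base_lengths)
        self.data = base.data
        self.indices = base.indices
        self.indptr = base.indptr
        self.rowidx = np.repeat(np.arange(self.n), np.diff(self.indptr))
        self.panel = [np.asarray(sorted(s), dtype=int) for s in panel]
        self.sources = np.asarray(sorted({i for s in panel for i in s}), dtype=int)
        row_of = {int(s): k for k, s in enumerate(self.sources)}
        self.panel_rows = [
            np.asarray([row_of[int(i)] for i in seed]) for seed in self.panel
        ]

    def _masked_graph(self, resected: np.ndarray) -> csr_matrix:
        keep = np.ones(self.n, dtype=bool)
        keep[resected] = False
        data = self.data * (keep[self.indices] & keep[self.rowidx])
        # stored zeros would count as traversable zero-length edges in csgraph
        graph = csr_matrix(
            (data, self.indices.copy(), self.indptr.copy()), shape=(self.n, self.n)
        )
        graph.eliminate_zeros()
        return graph

    def __call__(self, resected: np.ndarray) -> float:
        graph = self._masked_graph(resected)
        gc = _giant_mask(graph, self.n) if self.restrict_giant else None
        if gc is not None and not gc[self.sources].any():
            return 0.0
        dist = dijkstra(graph, directed=False, indices=self.sources)
        inv = np.zeros_like(dist)
        finite = np.isfinite(dist) & (dist > 0)
        inv[finite] = 1.0 / dist[finite]
        row_total = inv.sum(axis=1)
        total = 0.0
        for seed, rows in zip(self.panel, self.panel_rows):
            if gc is None:
                n2 = self.n - seed.size
                if n2 == 0:
                    continue
                contrib = (row_total[rows] - inv[np.ix_(rows, seed)].sum(axis=1)).sum()
                total += contrib / (seed.size * n2)
                continue
            in_gc = gc[seed]
            k = int(in_gc.sum())
            if k == 0:
                continue
            n2 = int(gc.sum()) - k
            if n2 == 0:
                continue
            r = rows[in_gc]
            # distances to non-giant nodes are infinite (contribute 0), so
            # subtracting the seed columns from the row totals leaves S2
            total += (row_total[r] - inv[np.ix_(r, seed)].sum(axis=1)).sum() / (k * n2)
        return total / len(self.panel)


def _panel_seed_efficiency(
    base_lengths: np.ndarray,
    resected: np.ndarray,
    panel: Sequence[frozenset],
) -> float:
    """Mean published-convention E_R over the seed panel (giant-component rule)."""
    return _PanelEnergy(base_lengths, panel, restrict_giant=True)(
        np.asarray(resected, dtype=int)
    )


def seed_efficiency(
    net: BrainNetwork,
    seed_set: Iterable[int],
    convention: DistanceConvention = "inverse_weight",
) -> float:
    """E_R(seed): mean inverse distance from seed to the rest of the network.

    ``E = (1 / (N_seed * N_2)) * sum_{i in seed} sum_{j in S2} 1 / d_ij``
    with both the seed and the complement S2 restricted to the giant
    component; infinite distances contribute zero, and a seed entirely
    outside the giant component has efficiency 0.
    """
    seed = frozenset(int(i) for i in seed_set)
    if not seed:
        raise ValueError("seed set must be nonempty")
    lengths = _edge_lengths(net.weights, convention)
    return _panel_seed_efficiency(lengths, np.empty(0, dtype=int), [seed])


# ---------------------------------------------------------------------------
# delta-IR (paired estimation)


def _draw_seed_sets(
    seed_source,
    n: int,
    rng: np.random.Generator,
) -> list[frozenset]:
    if isinstance(seed_source, SeedProbabilityMap):
        return [sample_seed(seed_source, rng) for _ in range(n)]
    if callable(seed_source):
        return [frozenset(seed_source(rng)) for _ in range(n)]
    fixed = frozenset(int(i) for i in seed_source)
    return [fixed] * n


def paired_infection_ratios(
    net_before: BrainNetwork,
    net_after: BrainNetwork,
    seed_sets: Sequence[frozenset],
    params: SIRParameters,
) -> tuple[np.ndarray, np.ndarray]:
    """IR on the intact and resected networks with common random numbers."""
    ir0 = np.empty(len(seed_sets))
    ir1 = np.empty(len(seed_sets))
    for r, seed in enumerate(seed_sets):
        rng = np.random.default_rng(params.rng_seed + r)
        ir0[r] = simulate_sir(net_before, seed, params, rng=rng).ir
        rng = np.random.default_rng(params.rng_seed + r)
        ir1[r] = simulate_sir(net_after, seed, params, rng=rng).ir
    return ir0, ir1


def delta_ir(
    net: BrainNetwork,
    resection: Resection | Iterable[int],
    seed_source,
    params: SIRParameters,
) -> tuple[float, float]:
    """Normalized decrease in propagation, deltaIR = (<IR0> - <IR_R>) / <IR0>.

    ``seed_source`` is a SeedProbabilityMap (seeds redrawn per realization),
    a callable, or a fixed ROI collection. Returns (mean, sd), where sd is
    the standard deviation of the paired per-realization decreases scaled by
    the mean baseline. Seed nodes inside the resection stay ictal at t = 0
    but transmit nothing; resected non-seed nodes can never be recruited.
    """
    seed_rng = np.random.default_rng(params.rng_seed + 999_983)
    seed_sets = _draw_seed_sets(seed_source, params.n_realizations, seed_rng)
    resected_net = apply_resection(net, resection)
    ir0, ir1 = paired_infection_ratios(net, resected_net, seed_sets, params)
    mean_ir0 = ir0.mean()
    mean_delta = float((mean_ir0 - ir1.mean()) / mean_ir0)
    sd = float(((ir0 - ir1) / mean_ir0).std())
    return mean_delta, sd


# ---------------------------------------------------------------------------
# Simulated annealing


def _anneal_once(
    energy: _PanelEnergy,
    size: int,
    config: SAConfig,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    n = energy.n
    if init is None:
        current = rng.choice(n, size=size, replace=False)
    else:
        current = np.asarray(init, dtype=int).copy()
    e_cur = energy(current)
    best, e_best = current.copy(), e_cur
    if e_best == 0.0:
        return best, e_best

    in_set = np.zeros(n, dtype=bool)
    in_set[current] = True

    def propose():
        out_pos = rng.integers(size)
        candidates = np.flatnonzero(~in_set)
        new_node = candidates[rng.integers(candidates.size)]
        trial = current.copy()
        trial[out_pos] = new_node
        return trial

    # calibrate T0 on the initial worsening-move scale
    pos_deltas = []
    for _ in range(20):
        trial = propose()
        e_trial = energy(trial)
        if e_trial < e_best:
            best, e_best = trial.copy(), e_trial
            if e_best == 0.0:
                return best, e_best
        d = e_trial - e_cur
        if d > 0:
            pos_deltas.append(d)
    t0 = (np.mean(pos_deltas) / np.log(1.0 / config.init_accept)) if pos_deltas else 1e-6
    t = t0
    while t > config.t_min_frac * t0:
        accepted = 0
        for _ in range(config.proposals_per_temp):
            trial = propose()
            e_trial = energy(trial)
            d = e_trial - e_cur
            if d <= 0 or rng.random() < np.exp(-d / t):
                in_set[current] = False
                current = trial
                in_set[current] = True
                e_cur = e_trial
                accepted += 1
                if e_cur < e_best:
                    best, e_best = current.copy(), e_cur
                    if e_best == 0.0:
                        return best, e_best
        if accepted == 0:
            break
        t *= config.cooling
    return best, e_best


def anneal_min_seed_efficiency(
    net: BrainNetwork,
    seed_source,
    size: int,
    config: SAConfig | None = None,
    rng: np.random.Generator | int | None = None,
    convention: DistanceConvention = "inverse_weight",
    warm_start: Iterable[int] | None = None,
    _energy: "_PanelEnergy | None" = None,
) -> tuple[Resection, float]:
    """Search for the size-S resection minimizing the panel-average E_R(seed).

    ``seed_source`` is a SeedProbabilityMap (a fixed panel of
    ``config.panel_size`` seeds is pre-sampled) or an explicit sequence of
    seed sets. All nodes are candidate targets. Returns the best resection
    found over ``config.n_restarts`` restarts and its panel energy (the
    unrestricted search objective; see _PanelEnergy); the result is never
    worse than any state the annealer evaluated.
    """
    if config is None:
        config = SAConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = net.n_roi
    if not (1 <= size < n):
        raise ValueError(f"resection size must lie in [1, {n - 1}], got {size}")
    if _energy is not None:
        energy = _energy
    else:
        if isinstance(seed_source, SeedProbabilityMap):
            panel = sample_seed_panel(seed_source, config.panel_size, rng)
        else:
            panel = [frozenset(s) for s in seed_source]
        energy = _PanelEnergy(_edge_lengths(net.weights, convention), panel)
    best, e_best = None, np.inf
    inits: list = [None] * config.n_restarts
    if warm_start is not None:
        ws = np.asarray(sorted(set(int(i) for i in warm_start)), dtype=int)
        if ws.size < size:
            pool = np.setdiff1d(np.arange(n), ws)
            extra = rng.choice(pool, size=size - ws.size, replace=False)
            ws = np.concatenate([ws, extra])
        inits[0] = ws[:size]
    for restart in range(config.n_restarts):
        state, e_state = _anneal_once(energy, size, config, rng, init=inits[restart])
        if e_state < e_best:
            best, e_best = state, e_state
            if e_best == 0.0:
                break
    return Resection(frozenset(best.tolist()), provenance="optimized"), float(e_best)


def resection_size_sweep(
    net: BrainNetwork,
    seed_map: SeedProbabilityMap,
    sizes: Sequence[int] | None = None,
    sir_params: SIRParameters | None = None,
    sa_config: SAConfig | None = None,
    target_delta: float = 0.90,
    convention: DistanceConvention = "inverse_weight",
    rng_seed: int = 0,
) -> SweepResult:
    """Optimize resections of increasing size and locate R_op and R_D.

    For each size, the annealer minimizes the seed efficiency against a
    fixed pre-sampled seed panel (one restart per size warm-starts from the
    previous size's best set plus one node, which keeps the best energy
    non-increasing in size); the paired delta-IR of each optimized resection
    is then measured with a common set of seed realizations. R_op is the
    first size reaching ``target_delta``; R_D the first with e_R = 0.
    """
    if sizes is None:
        sizes = range(1, 21)
    sizes = np.asarray(sorted(sizes), dtype=int)
    if sir_params is None:
        sir_params = SIRParameters(gamma=0.3, n_realizations=300, rng_seed=rng_seed)
    if sa_config is None:
        sa_config = SAConfig()
    rng = np.random.default_rng(rng_seed + 7)
    panel = sample_seed_panel(seed_map, sa_config.panel_size, rng)
    base_lengths = _edge_lengths(net.weights, convention)
    energy = _PanelEnergy(base_lengths, panel)  # search objective
    report = _PanelEnergy(base_lengths, panel, restrict_giant=True)  # published E_R
    e0 = report(np.empty(0, dtype=int))
    if e0 == 0.0:
        raise ValueError("seed already disconnected in the unresected network")

    seed_rng = np.random.default_rng(sir_params.rng_seed + 999_983)
    seed_sets = _draw_seed_sets(seed_map, sir_params.n_realizations, seed_rng)
    ir0 = np.empty(len(seed_sets))
    for r, seed in enumerate(seed_sets):
        sub = np.random.default_rng(sir_params.rng_seed + r)
        ir0[r] = simulate_sir(net, seed, sir_params, rng=sub).ir
    mean_ir0 = ir0.mean()

    resections, e_vals = [], []
    d_mean = np.empty(sizes.size)
    d_sd = np.empty(sizes.size)
    prev_best: frozenset | None = None
    for k, size in enumerate(sizes):
        res, e_res = anneal_min_seed_efficiency(
            net, panel, int(size), sa_config, rng, convention=convention,
            warm_start=prev_best, _energy=energy,
        )
        prev_best = res.nodes
        resections.append(res)
        e_vals.append(report(np.asarray(sorted(res.nodes), dtype=int)))
        resected_net = apply_resection(net, res)
        ir1 = np.empty(len(seed_sets))
        for r, seed in enumerate(seed_sets):
            sub = np.random.default_rng(sir_params.rng_seed + r)
            ir1[r] = simulate_sir(resected_net, seed, sir_params, rng=sub).ir
        d_mean[k] = (mean_ir0 - ir1.mean()) / mean_ir0
        d_sd[k] = ((ir0 - ir1) / mean_ir0).std()

    e_vals = np.asarray(e_vals)
    e_norm = e_vals / e0
    r_op = None
    for k in range(sizes.size):
        if d_mean[k] >= target_delta:
            r_op = resections[k]
            break
    r_d = None
    for k in range(sizes.size):
        if e_vals[k] == 0.0:
            r_d = Resection(resections[k].nodes, provenance="disconnecting")
            break
    return SweepResult(
        sizes=sizes,
        resections=resections,
        delta_ir_mean=d_mean,
        delta_ir_sd=d_sd,
        seed_eff=e_vals,
        seed_eff_norm=e_norm,
        e0=float(e0),
        ir0=(float(mean_ir0), float(ir0.std())),
        r_op=r_op,
        r_d=r_d,
    )


def find_optimal_resection(
    net: BrainNetwork,
    seed_map: SeedProbabilityMap,
    max_size: int = 20,
    sir_params: SIRParameters | None = None,
    sa_config: SAConfig | None = None,
    target_delta: float = 0.90,
    convention: DistanceConvention = "inverse_weight",
    rng_seed: int = 0,
) -> tuple[Resection, int, float, bool]:
    """Locate R_op by bisection over resection sizes.

    Exploits the (average) monotonicity of delta-IR in resection size to
    find the smallest size whose optimized resection reaches
    ``target_delta`` with O(log max_size) annealing runs instead of a full
    sweep — the reduced-scale counterpart of :func:`resection_size_sweep`.
    Returns ``(resection, s_rop, delta_ir, censored)``; when no size
    reaches the target, the largest-size optimum is returned censored.
    """
    if sir_params is None:
        sir_params = SIRParameters(gamma=0.3, n_realizations=300, rng_seed=rng_seed)
    if sa_config is None:
        sa_config = SAConfig()
    rng = np.random.default_rng(rng_seed + 7)
    panel = sample_seed_panel(seed_map, sa_config.panel_size, rng)
    energy = _PanelEnergy(_edge_lengths(net.weights, convention), panel)
    seed_rng = np.random.default_rng(sir_params.rng_seed + 999_983)
    seed_sets = _draw_seed_sets(seed_map, sir_params.n_realizations, seed_rng)
    ir0 = np.empty(len(seed_sets))
    for r, seed in enumerate(seed_sets):
        sub = np.random.default_rng(sir_params.rng_seed + r)
        ir0[r] = simulate_sir(net, seed, sir_params, rng=sub).ir
    mean_ir0 = ir0.mean()

    evaluated: dict[int, tuple[Resection, float]] = {}

    def evaluate(size: int) -> tuple[Resection, float]:
        if size in evaluated:
            return evaluated[size]
        smaller = [s for s in evaluated if s < size]
        warm = evaluated[max(smaller)][0].nodes if smaller else None
        res, _ = anneal_min_seed_efficiency(
            net, panel, size, sa_config, rng, convention=convention,
            warm_start=warm, _energy=energy,
        )
        resected_net = apply_resection(net, res)
        ir1 = np.empty(len(seed_sets))
        for r, seed in enumerate(seed_sets):
            sub = np.random.default_rng(sir_params.rng_seed + r)
            ir1[r] = simulate_sir(resected_net, seed, sir_params, rng=sub).ir
        d = float((mean_ir0 - ir1.mean()) / mean_ir0)
        evaluated[size] = (res, d)
        return res, d

    res_hi, d_hi = evaluate(max_size)
    if d_hi < target_delta:
        return res_hi, max_size, d_hi, True
    lo, hi = 1, max_size
    while lo < hi:
        mid = (lo + hi) // 2
        _, d_mid = evaluate(mid)
        if d_mid >= target_delta:
            hi = mid
        else:
            lo = mid + 1
    res, d = evaluated[hi]
    return res, hi, d, False


def overlap_with_plan(
    r_op: Resection | Iterable[int],
    resection_area: Iterable[int],
    method: str = "min",
) -> float:
    """Overlap Ov between an optimized resection and the planned area.

    ``min`` (default): |A & B| / min(|A|, |B|); ``jaccard``: |A & B| / |A | B|.
    """
    a = r_op.nodes if isinstance(r_op, Resection) else frozenset(r_op)
    b = frozenset(int(i) for i in resection_area)
    if not a or not b:
        raise ValueError("both node sets must be nonempty")
    inter = len(a & b)
    if method == "min":
        return inter / min(len(a), len(b))
    if method == "jaccard":
        return inter / len(a | b)
    raise ValueError(f"unknown overlap method: {method!r}")
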