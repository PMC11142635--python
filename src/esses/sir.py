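"""Discrete-time SIR seizure propagation on weighted brain networks.

The S-I-R compartments stand for pre-ictal, ictal and post-ictal tissue
states. At every synchronous step each ictal (infected) node attempts to
recruit each of its pre-ictal (susceptible) neighbours ``j`` independently
with probability ``beta_ij = w_ij``; after all attempts, every node that was
already ictal at the start of the step recovers with the global probability
``gamma``. Newly recruited nodes cannot recover in the step in which they
were recruited. The dynamics run to absorption (no ictal nodes left), which
happens with probability one for ``gamma > 0``.

Randomness is organised in substreams: realization ``r`` of an ensemble uses
``default_rng(rng_seed + r)``, so parallel and serial execution agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .network import BrainNetwork

__all__ = [
    "SIRParameters",
    "SeizureRealization",
    "ModelPattern",
    "AbsorptionError",
    "simulate_sir",
    "simulate_sir_async",
    "simulate_ensemble",
    "infection_ratio",
    "aggregate_pattern",
    "mean_ir",
]

SUSCEPTIBLE, INFECTED, RECOVERED = 0, 1, 2


class AbsorptionError(RuntimeError):
    """Raised when a realization exceeds the hard step cap of 10 * N."""


@dataclass
class SIRParameters:
    """Global SIR parameters.

    gamma : per-step recovery probability, in (0, 1].
    n_realizations : ensemble size N_R.
    rng_seed : base seed; realization r uses substream rng_seed + r.
    on_cap : behaviour at the 10 * N step cap — "error" (default) raises
        AbsorptionError; "truncate" stops the realization, mapping nodes
        still ictal to recovered (their activation steps are already
        recorded, so patterns and infection ratios are unaffected; useful
        for small gamma, where the recovery tail outlives the cap).
    """

    gamma: float
    n_realizations: int = 10_000
    rng_seed: int = 0
    on_cap: str = "error"

    def __post_init__(self):
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must lie in (0, 1]")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.on_cap not in ("error", "truncate"):
            raise ValueError("on_cap must be 'error' or 'truncate'")


@dataclass
class SeizureRealization:
    """One absorbed SIR realization.

    activation_step[i] is the step at which ROI i first became ictal
    (0 for seeds, np.inf if never recruited); final_states holds the
    absorbing S/R compartment codes.
    """

    seed_set: frozenset
    activation_step: np.ndarray
    final_states: np.ndarray

    @property
    def n_roi(self) -> int:
        return self.activation_step.size

    @property
    def ever_infected(self) -> np.ndarray:
        return np.isfinite(self.activation_step)

    @property
    def ir(self) -> float:
        """Infection ratio: fraction of nodes ever ictal (recovered included)."""
        return float(np.count_nonzero(self.ever_infected)) / self.n_roi


@dataclass
class ModelPattern:
    """Ensemble summary of simulated seizures.

    participation[i] is the fraction of realizations in which ROI i was
    recruited; mean_activation_step[i] averages the first-infection step over
    the realizations in which i was recruited (NaN if never). p_i_t, when
    present, is a (T, N) matrix estimating the probability that ROI i becomes
    ictal at step t.
    """

    participation: np.ndarray
    mean_activation_step: np.ndarray
    n_realizations: int
    p_i_t: np.ndarray | None = None


def _validate_seed(seed_set, n: int) -> np.ndarray:
    seeds = np.asarray(sorted(seed_set), dtype=int)
    if seeds.size == 0:
        raise ValueError("seed set must be nonempty")
    if seeds.min() < 0 or seeds.max() >= n:
        raise ValueError("seed ROI index out of range")
    return seeds


def simulate_sir(
    net: BrainNetwork,
    seed_set: Iterable[int],
    params: SIRParameters,
    rng: np.random.Generator | None = None,
) -> SeizureRealization:
    """Run one SIR realization from ``seed_set`` to absorption."""
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    w = net.weights
    n = net.n_roi
    seeds = _validate_seed(seed_set, n)
    status = np.full(n, SUSCEPTIBLE, dtype=np.int8)
    activation = np.full(n, np.inf)
    status[seeds] = INFECTED
    activation[seeds] = 0.0
    infected = seeds
    gamma = params.gamma
    cap = 10 * n
    t = 0
    while infected.size:
        t += 1
        if t > cap:
            if params.on_cap == "truncate":
                status[infected] = RECOVERED
                break
            raise AbsorptionError(f"no absorption within {cap} steps (gamma={gamma})")
        sus = np.flatnonzero(status == SUSCEPTIBLE)
        if sus.size:
            p_inf = 1.0 - np.prod(1.0 - w[np.ix_(infected, sus)], axis=0)
            if not p_inf.any():
                # no susceptible node is reachable from the ictal set, now or
                # ever; every ictal node recovers with probability one, so the
                # absorbing state is determined exactly
                status[infected] = RECOVERED
                break
            new = sus[rng.random(sus.size) < p_inf]
        else:
            status[infected] = RECOVERED
            break
        recovered = infected[rng.random(infected.size) < gamma]
        status[new] = INFECTED
        activation[new] = t
        status[recovered] = RECOVERED
        infected = np.flatnonzero(status == INFECTED)
    return SeizureRealization(frozenset(seeds.tolist()), activation, status)


try:  # compiled event loop; the numpy path below is the reference fallback
    from numba import njit as _njit

    @_njit(cache=True)
    def _async_core(w, seed_idx, gamma, rng_seed):  # pragma: no cover - compiled
        np.random.seed(rng_seed)
        n = w.shape[0]
        status = np.zeros(n, np.int8)
        act = np.full(n, np.inf)
        pressure = np.zeros(n)
        for s in seed_idx:
            status[s] = 1
            act[s] = 0.0
        for s in seed_idx:
            for j in range(n):
                if status[j] == 0:
                    pressure[j] += w[s, j]
        n_inf = len(seed_idx)
        rank = 0
        while n_inf > 0:
            total_inf = 0.0
            for k in range(n):
                total_inf += pressure[k]
            u = np.random.random() * (total_inf + gamma * n_inf)
            if u < total_inf:
                c = 0.0
                j = n - 1
                for k in range(n):
                    c += pressure[k]
                    if u < c:
                        j = k
                        break
                rank += 1
                status[j] = 1
                act[j] = rank
                n_inf += 1
                pressure[j] = 0.0
                for k in range(n):
                    if status[k] == 0:
                        pressure[k] += w[j, k]
            else:
                m = int((u - total_inf) / gamma)
                if m >= n_inf:
                    m = n_inf - 1
                cnt = 0
                idx = n - 1
                for k in range(n):
                    if status[k] == 1:
                        if cnt == m:
                            idx = k
                            break
                        cnt += 1
                status[idx] = 2
                n_inf -= 1
                for k in range(n):
                    if status[k] == 0:
                        pressure[k] -= w[idx, k]
                        if pressure[k] < 0.0:
                            pressure[k] = 0.0
        return act, status

except ImportError:  # pragma: no cover
    _async_core = None


def simulate_sir_async(
    net: BrainNetwork,
    seed_set: Iterable[int],
    params: SIRParameters,
    rng: np.random.Generator | None = None,
) -> SeizureRealization:
    """Event-driven (rejection-free) SIR realization; one event at a time.

    Competing exponential clocks: each ictal-to-susceptible link ``(i, j)``
    carries transmission propensity ``w_ij`` and each ictal node recovery
    propensity ``gamma``. Events fire one at a time with probability
    proportional to propensity, so exactly one node changes state per event
    and ``activation_step`` records the node's infection-event rank — the
    native analogue of an iEEG activation order. Reach and final states
    approximate, but do not exactly match, the synchronous reference chain.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    w = net.weights
    n = net.n_roi
    seeds = _validate_seed(seed_set, n)
    if _async_core is not None:
        child_seed = int(rng.integers(2**32))
        activation, status = _async_core(w, seeds, params.gamma, child_seed)
        return SeizureRealization(frozenset(seeds.tolist()), activation, status)
    status = np.full(n, SUSCEPTIBLE, dtype=np.int8)
    activation = np.full(n, np.inf)
    status[seeds] = INFECTED
    activation[seeds] = 0.0
    # pressure[j] = total transmission propensity onto susceptible j
    pressure = w[seeds].sum(axis=0)
    pressure[status != SUSCEPTIBLE] = 0.0
    n_infected = seeds.size
    gamma = params.gamma
    rank = 0
    while n_infected:
        total_inf = pressure.sum()
        total_rec = gamma * n_infected
        if total_inf <= 0 and total_rec <= 0:  # pragma: no cover - gamma > 0
            break
        u = rng.random() * (total_inf + total_rec)
        if u < total_inf:
            # transmission: pick the susceptible target proportionally
            cum = np.cumsum(pressure)
            j = int(np.searchsorted(cum, u))
            rank += 1
            status[j] = INFECTED
            activation[j] = rank
            n_infected += 1
            sus = status == SUSCEPTIBLE
            pressure[sus] += w[j, sus]
            pressure[j] = 0.0
        else:
            infected_idx = np.flatnonzero(status == INFECTED)
            i = infected_idx[int(rng.integers(infected_idx.size))]
            status[i] = RECOVERED
            n_infected -= 1
            sus = status == SUSCEPTIBLE
            pressure[sus] -= w[i, sus]
            np.clip(pressure, 0.0, None, out=pressure)
    return SeizureRealization(frozenset(seeds.tolist()), activation, status)


def simulate_ensemble(
    net: BrainNetwork,
    seed_set: Iterable[int],
    params: SIRParameters,
    engine: str = "sync",
) -> list[SeizureRealization]:
    """Run ``params.n_realizations`` independent realizations (substream seeds)."""
    step = simulate_sir if engine == "sync" else simulate_sir_async
    out = []
    for r in range(params.n_realizations):
        rng = np.random.default_rng(params.rng_seed + r)
        out.append(step(net, seed_set, params, rng=rng))
    return out


def infection_ratio(realization: SeizureRealization) -> float:
    """Fraction of nodes ever ictal, recovered or not."""
    return realization.ir


def aggregate_pattern(
    realizations: Sequence[SeizureRealization],
    include_p_it: bool = False,
) -> ModelPattern:
    """Aggregate realizations into a participation-weighted seizure pattern."""
    if not realizations:
        raise ValueError("need at least one realization")
    steps = np.stack([r.activation_step for r in realizations])
    infected = np.isfinite(steps)
    n_r = len(realizations)
    participation = infected.sum(axis=0) / n_r
    with np.errstate(invalid="ignore"):
        mean_step = np.where(
            participation > 0,
            np.nansum(np.where(infected, steps, np.nan), axis=0)
            / np.maximum(infected.sum(axis=0), 1),
            np.nan,
        )
    p_i_t = None
    if include_p_it:
        finite = steps[infected]
        t_max = int(finite.max()) if finite.size else 0
        n = steps.shape[1]
        p_i_t = np.zeros((t_max + 1, n))
        for t in range(t_max + 1):
            p_i_t[t] = (steps == t).sum(axis=0) / n_r
    return ModelPattern(participation, mean_step, n_r, p_i_t)


def mean_ir(
    net: BrainNetwork,
    seed_sampler: Callable[[np.random.Generator], Iterable[int]] | Iterable[int],
    params: SIRParameters,
) -> tuple[float, float]:
    """Monte-Carlo mean and sd of the infection ratio.

    ``seed_sampler`` is either a fixed ROI collection or a callable drawing a
    seed set from the realization's substream generator, so seed redraws and
    SIR dynamics share one reproducible stream.
    """
    irs = np.empty(params.n_realizations)
    fixed = None if callable(seed_sampler) else frozenset(seed_sampler)
    for r in range(params.n_realizations):
        rng = np.random.default_rng(params.rng_seed + r)
        seed_set = seed_sampler(rng) if fixed is None else fixed
        irs[r] = simulate_sir(net, seed_set, params, rng=rng).ir
    return float(irs.mean()), float(irs.std())
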