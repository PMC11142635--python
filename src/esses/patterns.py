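"""Seizure-propagation pattern comparison and global parameter fitting.

An iEEG seizure pattern is the activation order of the electrode-sampled
ROIs during one recorded seizure, together with the sampled-but-silent set.
A model pattern is the participation-weighted ensemble summary of simulated
seizures. The goodness of fit combines the agreement of activation orders
with the agreement of active/inactive partitions,

    C = max(0, C_w) * P_overlap,

where C_w is the participation-weighted Pearson correlation between the two
rank orders over ROIs active in both patterns, and P_overlap is the balanced
agreement of active and inactive sets over the sampled ROIs. The global
parameters (network density rho, recovery probability gamma) are fitted by
maximizing the cohort-average C over a log-spaced grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .network import BrainNetwork, threshold_density
from .sir import ModelPattern, SIRParameters, aggregate_pattern, simulate_ensemble

__all__ = [
    "IEEGPattern",
    "FitMap",
    "weighted_correlation",
    "overlap_score",
    "goodness_of_fit",
    "parameter_sweep",
    "default_rho_grid",
    "default_gamma_grid",
    "read_pattern_csv",
    "write_pattern_csv",
]


@dataclass
class IEEGPattern:
    """Reduced activation-order description of one recorded seizure.

    sampled_rois : ROI indices covered by iEEG electrodes.
    active_rois : the subset that activated during the seizure.
    activation_rank : rank of activation within active_rois (1 = first;
        average ranks for simultaneous activations).
    """

    sampled_rois: frozenset
    active_rois: frozenset
    activation_rank: dict

    def __post_init__(self):
        self.sampled_rois = frozenset(self.sampled_rois)
        self.active_rois = frozenset(self.active_rois)
        if not self.active_rois <= self.sampled_rois:
            raise ValueError("active ROIs must be a subset of sampled ROIs")
        if set(self.activation_rank) != set(self.active_rois):
            raise ValueError("activation_rank must cover exactly the active ROIs")


@dataclass
class FitMap:
    """Goodness-of-fit surfaces over the (rho, gamma) grid.

    c_values has shape (n_patients, n_rho, n_gamma) and holds the mean C over
    repetitions; c_mean is the patient average; c_sd the dispersion over
    repetitions of the patient-average surface.
    """

    rho_grid: np.ndarray
    gamma_grid: np.ndarray
    c_values: np.ndarray
    c_mean: np.ndarray
    c_sd: np.ndarray
    best_point: tuple  # (rho, gamma) at the argmax of c_mean
    best_index: tuple  # (i_rho, i_gamma)
    patient_best_index: list

    def to_dict(self) -> dict:
        return {
            "rho_grid": self.rho_grid.tolist(),
            "gamma_grid": self.gamma_grid.tolist(),
            "c_mean": self.c_mean.tolist(),
            "c_sd": self.c_sd.tolist(),
            "best_point": [float(v) for v in self.best_point],
            "best_index": [int(v) for v in self.best_index],
            "patient_best_index": [[int(v) for v in ix] for ix in self.patient_best_index],
        }


def default_rho_grid(n: int = 12) -> np.ndarray:
    """Log-spaced network densities in [0.01, 0.35]."""
    return np.geomspace(0.01, 0.35, n)


def default_gamma_grid(n: int = 12) -> np.ndarray:
    """Log-spaced recovery probabilities in [0.01, 1.00]."""
    return np.geomspace(0.01, 1.0, n)


def weighted_correlation(x: Sequence[float], y: Sequence[float], w: Sequence[float]) -> float:
    """Weighted Pearson correlation; NaN signals an undefined correlation.

    Undefined when fewer than 3 points or when either weighted variance
    vanishes; callers map NaN to C = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.size == y.size == w.size):
        raise ValueError("x, y, w must have equal length")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be nonnegative and not all zero")
    if x.size < 3:
        return float("nan")
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(cov / np.sqrt(vx * vy))


def _set_agreement(model_set: set, ref_set: set) -> float:
    if not ref_set:
        return 1.0 if not model_set else 0.0
    return len(model_set & ref_set) / len(ref_set)


def _model_active_set(model: ModelPattern, sampled: np.ndarray, activity_threshold) -> set:
    """Sampled ROIs the model counts as active.

    A float threshold keeps ROIs with participation >= threshold. The
    ``"expected_extent"`` strategy is self-calibrating: it keeps the top-k
    sampled ROIs by participation with k = round(sum of participation),
    the model's own expected active-set size — the natural reference when
    the observed pattern is a single recorded seizure.
    """
    part = model.participation[sampled]
    if activity_threshold == "expected_extent":
        k = int(round(part.sum()))
        if k <= 0:
            return set()
        order = np.argsort(-part, kind="stable")
        return set(sampled[order[:k]].tolist())
    return set(sampled[part >= float(activity_threshold)].tolist())


def overlap_score(
    model: ModelPattern,
    ieeg: IEEGPattern,
    activity_threshold=0.05,
) -> float:
    """Balanced active/inactive set agreement over the sampled ROIs.

    A model ROI counts as active when its participation reaches
    ``activity_threshold`` (or, with the ``"expected_extent"`` strategy,
    when it belongs to the model's top-k participating sampled ROIs, k =
    round(total participation)). P_overlap averages the fraction of
    iEEG-active ROIs the model also activates and the fraction of
    iEEG-inactive ROIs the model also leaves silent.
    """
    sampled = set(ieeg.sampled_rois)
    if not sampled:
        raise ValueError("pattern has no sampled ROIs")
    idx = np.asarray(sorted(sampled))
    model_active = _model_active_set(model, idx, activity_threshold)
    model_inactive = sampled - model_active
    ieeg_active = set(ieeg.active_rois)
    ieeg_inactive = sampled - ieeg_active
    return 0.5 * (
        _set_agreement(model_active, ieeg_active)
        + _set_agreement(model_inactive, ieeg_inactive)
    )


def goodness_of_fit(
    model: ModelPattern,
    ieeg: IEEGPattern,
    activity_threshold: float = 0.05,
) -> tuple[float, dict]:
    """Goodness of fit C = max(0, C_w) * P_overlap, with diagnostics.

    C_w is the participation-weighted correlation between iEEG activation
    ranks and ranks of the model's mean activation step, over ROIs active in
    both patterns (average ranks for ties). Anti-correlated order is floored
    to zero so C stays in [0, 1]. Fewer than 3 jointly active ROIs yields
    C = 0 with a ``degenerate`` flag.
    """
    p_overlap = overlap_score(model, ieeg, activity_threshold)
    sampled = np.asarray(sorted(ieeg.sampled_rois))
    model_active = _model_active_set(model, sampled, activity_threshold)
    joint = sorted(set(ieeg.active_rois) & model_active)
    info = {"p_overlap": p_overlap, "n_joint": len(joint), "degenerate": False, "cw": float("nan"), "floored": False}
    if len(joint) < 3:
        info["degenerate"] = True
        return 0.0, info
    ieeg_ranks = rankdata([ieeg.activation_rank[i] for i in joint])
    model_ranks = rankdata(model.mean_activation_step[joint])
    weights = model.participation[joint]
    cw = weighted_correlation(ieeg_ranks, model_ranks, weights)
    info["cw"] = cw
    if np.isnan(cw):
        info["degenerate"] = True
        return 0.0, info
    if cw < 0:
        info["floored"] = True
    return float(max(0.0, cw) * p_overlap), info


def parameter_sweep(
    net_by_patient: Sequence[BrainNetwork],
    seed_by_patient: Sequence,
    ieeg_by_patient: Sequence[IEEGPattern],
    rho_grid: np.ndarray | None = None,
    gamma_grid: np.ndarray | None = None,
    n_realizations: int = 10_000,
    n_repetitions: int = 10,
    activity_threshold: float = 0.05,
    engine: str = "async",
    rng_seed: int = 0,
) -> FitMap:
    """Fit (rho, gamma) by maximizing the cohort-average goodness of fit.

    For every grid point, each patient's base network is density-thresholded
    at rho, an ensemble of SIR seizures is simulated from the patient's seed
    set, aggregated into a model pattern, and compared with the patient's
    iEEG pattern. The sweep is repeated ``n_repetitions`` times with
    independent substreams to attach dispersion to the average surface.

    The default engine is the event-driven sampler: activation orders are
    its native output (one node is recruited per event, as in an iEEG
    activation sequence) and the recovery probability shapes the pattern
    through event-level competition between transmission and recovery.
    """
    if rho_grid is None:
        rho_grid = default_rho_grid()
    if gamma_grid is None:
        gamma_grid = default_gamma_grid()
    rho_grid = np.asarray(rho_grid, dtype=float)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if rho_grid.size == 0 or gamma_grid.size == 0:
        raise ValueError("parameter grids must be nonempty")
    if not (np.all(np.diff(rho_grid) > 0) and np.all(np.diff(gamma_grid) > 0)):
        raise ValueError("parameter grids must be strictly increasing")
    n_pat = len(net_by_patient)
    if not (n_pat == len(seed_by_patient) == len(ieeg_by_patient)):
        raise ValueError("patient records must be aligned")

    c_rep = np.zeros((n_repetitions, n_pat, rho_grid.size, gamma_grid.size))
    for rep in range(n_repetitions):
        for p in range(n_pat):
            for a, rho in enumerate(rho_grid):
                net = threshold_density(net_by_patient[p], rho)
                for b, gamma in enumerate(gamma_grid):
                    params = SIRParameters(
                        gamma=gamma,
                        n_realizations=n_realizations,
                        rng_seed=rng_seed + 1_000_003 * rep + 7_919 * p + 101 * a + b,
                        on_cap="truncate",
                    )
                    reals = simulate_ensemble(net, seed_by_patient[p], params, engine=engine)
                    pattern = aggregate_pattern(reals)
                    c, _ = goodness_of_fit(pattern, ieeg_by_patient[p], activity_threshold)
                    c_rep[rep, p, a, b] = c

    c_values = c_rep.mean(axis=0)  # per patient
    c_mean = c_values.mean(axis=0)
    c_sd = c_rep.mean(axis=1).std(axis=0)
    best_index = np.unravel_index(np.argmax(c_mean), c_mean.shape)
    patient_best = [
        tuple(np.unravel_index(np.argmax(c_values[p]), c_mean.shape)) for p in range(n_pat)
    ]
    return FitMap(
        rho_grid=rho_grid,
        gamma_grid=gamma_grid,
        c_values=c_values,
        c_mean=c_mean,
        c_sd=c_sd,
        best_point=(float(rho_grid[best_index[0]]), float(gamma_grid[best_index[1]])),
        best_index=(int(best_index[0]), int(best_index[1])),
        patient_best_index=patient_best,
    )


def read_pattern_csv(path) -> IEEGPattern:
    """Read an iEEG pattern table with columns roi,sampled,active,rank."""
    df = pd.read_csv(path)
    sampled = frozenset(df.loc[df["sampled"] == 1, "roi"].astype(int))
    active_df = df[(df["sampled"] == 1) & (df["active"] == 1)]
    ranks = dict(zip(active_df["roi"].astype(int), active_df["rank"].astype(float)))
    return IEEGPattern(sampled, frozenset(ranks), ranks)


def write_pattern_csv(pattern: IEEGPattern, path, n_roi: int) -> None:
    rows = []
    for roi in range(n_roi):
        sampled = int(roi in pattern.sampled_rois)
        active = int(roi in pattern.active_rois)
        rank = pattern.activation_rank.get(roi, "")
        rows.append({"roi": roi, "sampled": sampled, "active": active, "rank": rank})
    pd.DataFrame(rows).to_csv(path, index=False)
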