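"""Seed-probability maps from multimodal presurgical abnormality tables.

Presurgical findings are recorded per database region (a coarse 34-region
ontology, 17 per hemisphere) and per modality (EEG, MRI, MEG, PET, SPECT,
iEEG) as binary abnormality flags. Modalities carry relevance weights
``omega_m`` (iEEG most focal, EEG least) and per-patient availability flags
``D_m``; the aggregate abnormality of region i is

    A_i = (1/n) * sum_m D_m * omega_m * a_{i,m},   n = sum_m D_m * omega_m.

A_i is projected onto atlas ROIs via a total region->ROI projection and
sharpened into a seed-probability map SP_i = A_{proj(i)}**R, from which seed
realizations (seizure-onset node sets) are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MODALITIES",
    "DEFAULT_MODALITY_WEIGHTS",
    "PresurgicalRecord",
    "SeedProbabilityMap",
    "ProjectionTable",
    "database_regions",
    "aggregate_abnormality",
    "build_seed_map",
    "sample_seed",
    "sample_seed_panel",
]

MODALITIES = ("EEG", "MRI", "MEG", "PET", "SPECT", "iEEG")
DEFAULT_MODALITY_WEIGHTS = {"EEG": 1.0, "MRI": 2.0, "MEG": 2.0, "PET": 2.0, "SPECT": 2.0, "iEEG": 4.0}


def database_regions() -> list[str]:
    """The packaged 34-region presurgical-database ontology."""
    with resources.files("esses.data").joinpath("regions_34.csv").open() as fh:
        return pd.read_csv(fh)["region"].tolist()


@dataclass
class PresurgicalRecord:
    """Binary abnormality flags per database region and modality.

    availability : mapping modality -> D_m in {0, 1}.
    abnormality : (n_regions, 6) 0/1 array, columns ordered as MODALITIES;
        a_{i,m} may be 1 only where D_m = 1.
    weights : relevance factor omega_m per modality.
    """

    availability: Mapping[str, int]
    abnormality: np.ndarray
    region_labels: tuple = ()
    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MODALITY_WEIGHTS))

    def __post_init__(self):
        a = np.asarray(self.abnormality, dtype=float)
        if a.ndim != 2 or a.shape[1] != len(MODALITIES):
            raise ValueError(f"abnormality must be (n_regions, {len(MODALITIES)})")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("abnormality entries must be 0/1")
        d = np.array([self.availability.get(m, 0) for m in MODALITIES], dtype=float)
        if np.any(a * (1 - d) > 0):
            raise ValueError("abnormality flagged in an unavailable modality")
        self.abnormality = a
        if not self.region_labels:
            self.region_labels = tuple(f"region{i:02d}" for i in range(a.shape[0]))


@dataclass
class SeedProbabilityMap:
    """Per-atlas-ROI probability SP_i that a seizure starts at ROI i."""

    sp: np.ndarray
    rescale_exponent: float
    source_abnormality: np.ndarray | None = None
    roi_labels: tuple = ()

    def __post_init__(self):
        sp = np.asarray(self.sp, dtype=float)
        if np.any(sp < 0) or np.any(sp > 1):
            raise ValueError("seed probabilities must lie in [0, 1]")
        self.sp = sp

    @property
    def n_roi(self) -> int:
        return self.sp.size

    def to_frame(self) -> pd.DataFrame:
        labels = self.roi_labels or tuple(f"roi{i:03d}" for i in range(self.n_roi))
        return pd.DataFrame({"roi": labels, "sp": self.sp})


@dataclass
class ProjectionTable:
    """Total mapping from atlas ROI index to database region index."""

    region_of: np.ndarray  # shape (n_atlas_roi,), values in [0, n_regions)

    def __post_init__(self):
        self.region_of = np.asarray(self.region_of, dtype=int)
        if np.any(self.region_of < 0):
            raise ValueError("projection entries must be nonnegative region indices")

    @property
    def n_roi(self) -> int:
        return self.region_of.size

    @classmethod
    def from_csv(cls, path, roi_labels: Iterable[str], region_labels: Iterable[str]) -> "ProjectionTable":
        """Read a (atlas_roi, database_region) label table covering every ROI."""
        df = pd.read_csv(path)
        mapping = dict(zip(df["atlas_roi"].astype(str), df["database_region"].astype(str)))
        region_index = {r: k for k, r in enumerate(region_labels)}
        try:
            region_of = [region_index[mapping[str(roi)]] for roi in roi_labels]
        except KeyError as exc:
            raise ValueError(f"projection table missing entry for {exc.args[0]!r}") from exc
        return cls(np.asarray(region_of))

    def to_csv(self, path, roi_labels: Iterable[str], region_labels) -> None:
        region_labels = list(region_labels)
        pd.DataFrame(
            {
                "atlas_roi": list(roi_labels),
                "database_region": [region_labels[k] for k in self.region_of],
            }
        ).to_csv(path, index=False)


def aggregate_abnormality(rec: PresurgicalRecord) -> np.ndarray:
    """Relevance-weighted aggregate abnormality A_i per database region."""
    d = np.array([rec.availability.get(m, 0) for m in MODALITIES], dtype=float)
    omega = np.array([rec.weights[m] for m in MODALITIES], dtype=float)
    n = float(np.sum(d * omega))
    if n == 0:
        raise ValueError("no presurgical modality available (n = 0)")
    return rec.abnormality @ (d * omega) / n


def build_seed_map(
    abnormality: np.ndarray,
    proj: ProjectionTable,
    rescale_exponent: float = 3.0,
    roi_labels: tuple = (),
) -> SeedProbabilityMap:
    """Project region abnormalities to atlas ROIs and sharpen: SP = A**R.

    R >= 1 makes maps more focal (co-occurring abnormalities dominate)
    while preserving the ROI ranking.
    """
    if rescale_exponent < 1:
        raise ValueError("rescale exponent R must be >= 1")
    a = np.asarray(abnormality, dtype=float)
    if proj.region_of.max() >= a.size:
        raise ValueError("projection refers to a region outside the abnormality map")
    sp = a[proj.region_of] ** rescale_exponent
    return SeedProbabilityMap(sp, rescale_exponent, source_abnormality=a, roi_labels=roi_labels)


def sample_seed(
    sp_map: SeedProbabilityMap,
    rng: np.random.Generator,
    mode: str = "bernoulli",
    k: int | None = None,
    max_attempts: int = 1000,
) -> frozenset:
    """Draw one seed realization from a seed-probability map.

    ``bernoulli``: each ROI enters independently with probability SP_i,
    redrawn until nonempty. ``fixed_size``: k distinct ROIs with probability
    proportional to SP.
    """
    sp = sp_map.sp
    if not np.any(sp > 0):
        raise ValueError("all-zero seed-probability map")
    if mode == "bernoulli":
        for _ in range(max_attempts):
            seed = np.flatnonzero(rng.random(sp.size) < sp)
            if seed.size:
                return frozenset(seed.tolist())
        raise RuntimeError(f"no nonempty seed drawn in {max_attempts} attempts")
    if mode == "fixed_size":
        if k is None or k < 1:
            raise ValueError("fixed_size mode requires k >= 1")
        n_pos = int(np.count_nonzero(sp))
        if k > n_pos:
            raise ValueError(f"cannot draw {k} distinct ROIs from {n_pos} with SP > 0")
        p = sp / sp.sum()
        seed = rng.choice(sp.size, size=k, replace=False, p=p)
        return frozenset(seed.tolist())
    raise ValueError(f"unknown seed sampling mode: {mode!r}")


def sample_seed_panel(
    sp_map: SeedProbabilityMap,
    n_seeds: int,
    rng: np.random.Generator,
    mode: str = "bernoulli",
    k: int | None = None,
) -> list[frozenset]:
    """Pre-sample a fixed panel of seed realizations (for annealing energies)."""
    return [sample_seed(sp_map, rng, mode=mode, k=k) for _ in range(n_seeds)]
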