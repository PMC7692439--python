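"""Beta diversity: pairwise dissimilarities and the multiple-site
turnover/nestedness partition of Sorensen dissimilarity.

Pairwise metrics
----------------
* Bray-Curtis on counts: ``d = sum|x_i - y_i| / sum(x_i + y_i)``
* Jaccard distance on presence/absence: ``1 - |A & B| / |A | B|``
* Sorensen (Dice) distance on presence/absence: ``(b + c) / (2a + b + c)``
  with ``a`` shared and ``b, c`` exclusive OTU counts.

Multiple-site partition
-----------------------
Total Sorensen-family multiple-site dissimilarity (bSOR) splits additively
into a spatial-turnover component (the multiple-site Simpson dissimilarity,
bSIM) and a nestedness-resultant component (bNES = bSOR - bSIM).  With
``S_i`` the richness of site i, ``S_T`` the pooled richness and
``b_ij`` the number of OTUs present in site i but not j:

    bSIM = Smin / (Smin + (sum S_i - S_T))
    bSOR = (Smin + Smax) / (2 (sum S_i - S_T) + Smin + Smax)
    bNES = bSOR - bSIM

where ``Smin = sum over pairs i<j of min(b_ij, b_ji)`` and ``Smax`` the
corresponding sum of maxima.  Turnover (species replacement) drives bSIM;
richness differences between nested assemblages drive bNES.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .table import OtuTable, SampleMetadata, ValidationError

METRICS = ("bray_curtis", "jaccard", "sorensen")


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric pairwise sample dissimilarities in [0, 1] with a metric label."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if vals.shape != (n, n):
            raise ValidationError(f"values must be {n}x{n}, got {vals.shape}")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-12):
            raise ValidationError("dissimilarity matrix must have a zero diagonal")
        if vals.min() < -1e-12 or vals.max() > 1 + 1e-9:
            raise ValidationError("dissimilarities must lie in [0, 1]")
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "values", vals)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy condensed order."""
        return squareform(self.values, checks=False)

    def to_skbio(self) -> DistanceMatrix:
        return DistanceMatrix(self.values, ids=self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path, metric: str = "unknown") -> "DissimilarityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(frame.index.astype(str)), frame.to_numpy(dtype=float), metric)


_SCIPY_METRIC = {"bray_curtis": "braycurtis", "jaccard": "jaccard", "sorensen": "dice"}


def pairwise_dissimilarity(table: OtuTable, metric: str = "bray_curtis",
                           presence_absence: bool | None = None) -> DissimilarityMatrix:
    """Pairwise sample dissimilarities for one of the supported metrics.

    Jaccard and Sorensen always operate on presence/absence; Bray-Curtis
    requires count data (``presence_absence=True`` is rejected for it).
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if metric == "bray_curtis":
        if presence_absence:
            raise ValueError("bray_curtis requires count data, not presence/absence")
        data = table.counts.to_numpy(dtype=float).T
    else:
        data = table.presence().to_numpy().T
    empty = np.flatnonzero(table.sample_depths.to_numpy() == 0)
    if empty.size >= 2:
        names = [table.sample_ids[i] for i in empty]
        raise ValueError(f"dissimilarity undefined between all-zero samples: {names}")
    condensed = pdist(data, metric=_SCIPY_METRIC[metric])
    vals = squareform(np.clip(condensed, 0.0, 1.0))
    return DissimilarityMatrix(tuple(table.sample_ids), vals, metric)


@dataclass(frozen=True)
class BetaPartition:
    """Multiple-site Sorensen dissimilarity split into turnover and nestedness."""

    b_sor: float
    b_sim: float
    b_nes: float
    n_sites: int


def multisite_partition(table: OtuTable, sample_subset: Sequence[str] | None = None) -> BetaPartition:
    """Multiple-site bSOR / bSIM / bNES over a set of samples (sites).

    Presence/absence is taken from the counts.  All-identical sites give
    all-zero components; all-empty sites are undefined.
    """
    sub = table if sample_subset is None else table.select_samples(list(sample_subset))
    if sub.n_samples < 2:
        raise ValueError("multisite partition needs at least 2 sites")
    pres = sub.presence().to_numpy()
    if not pres.any():
        raise ValueError("multisite partition undefined: all sites empty")
    richness = pres.sum(axis=0).astype(np.int64)          # S_i
    pooled = int(pres.any(axis=1).sum())                  # S_T
    shared = pres.T.astype(np.int64) @ pres.astype(np.int64)  # a_ij
    iu, ju = np.triu_indices(sub.n_samples, k=1)
    b_ij = richness[iu] - shared[iu, ju]
    b_ji = richness[ju] - shared[iu, ju]
    sum_min = float(np.minimum(b_ij, b_ji).sum())
    sum_max = float(np.maximum(b_ij, b_ji).sum())
    core = float(richness.sum() - pooled)                 # sum S_i - S_T
    denom_sim = sum_min + core
    b_sim = sum_min / denom_sim if denom_sim > 0 else 0.0
    denom_sor = 2.0 * core + sum_min + sum_max
    b_sor = (sum_min + sum_max) / denom_sor if denom_sor > 0 else 0.0
    return BetaPartition(b_sor=b_sor, b_sim=b_sim, b_nes=b_sor - b_sim,
                         n_sites=sub.n_samples)


def partition_by_group(table: OtuTable, metadata: SampleMetadata,
                       factors: Sequence[str] = ("site", "compartment")) -> pd.DataFrame:
    """One multiple-site partition per metadata group (e.g. site x compartment).

    Each individual sample in the group acts as one "site" of the partition;
    groups with fewer than 2 samples are skipped.
    """
    labels = metadata.group_labels(factors, samples=table.sample_ids)
    rows = []
    for label, samples in labels.groupby(labels).groups.items():
        if len(samples) < 2:
            continue
        part = multisite_partition(table, list(samples))
        rows.append({"group": label, "b_sor": part.b_sor, "b_sim": part.b_sim,
                     "b_nes": part.b_nes, "n_sites": part.n_sites})
    return pd.DataFrame(rows).set_index("group") if rows else pd.DataFrame(
        columns=["b_sor", "b_sim", "b_nes", "n_sites"])
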