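"""Permutation tests of group structure and non-metric MDS ordination.

ANOSIM contrasts between- and within-group ranks of the pairwise
dissimilarities: ``R = (mean between rank - mean within rank) / (M/2)``
with ``M = n(n-1)/2`` and average ranks for ties; R lies in [-1, 1] and is
invariant under order-preserving transforms of the dissimilarities.

One-way PERMANOVA decomposes the squared dissimilarities:
``SS_total = (1/N) sum_{i<j} d_ij^2``, ``SS_within`` the analogous sum
within groups weighted by 1/n_g, and
``pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a))``.

Both tests obtain p-values by permuting group labels with a fixed seed and
use the ``(1 + #{perm stat >= observed}) / (1 + n_permutations)`` estimator,
so p is never exactly zero.  The heavy lifting is delegated to
scikit-bio's implementations, which use the same statistic and p-value
conventions; this module adds input validation and handles the degenerate
``SS_within = 0`` case (duplicated points within groups) where the
pseudo-F is infinite.

Non-metric MDS embeds the samples in 2-D so that embedded distances are a
monotone function of dissimilarity ranks, minimizing Kruskal stress-1 over
several restarts (classical metric scaling for restart 0, random starts
otherwise).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.distance import permanova as _skbio_permanova
from sklearn.manifold import MDS

from .beta import DissimilarityMatrix

DEFAULT_PERMUTATIONS = 9999


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    grouping: str


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    df_between: int
    df_within: int
    n_permutations: int
    ss_between: float
    ss_within: float
    ss_total: float

    @property
    def infinite_f(self) -> bool:
        """True when SS_within = 0 (identical points within every group)."""
        return not np.isfinite(self.pseudo_f)


@dataclass(frozen=True)
class NmdsEmbedding:
    coordinates: pd.DataFrame
    stress: float
    n_restarts: int
    seed: int


def _check_grouping(d: DissimilarityMatrix, groups) -> tuple[list[str], str]:
    if isinstance(groups, pd.Series):
        name = str(groups.name or "grouping")
        missing = [s for s in d.sample_ids if s not in groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        labels = [str(groups[s]) for s in d.sample_ids]
    else:
        labels = [str(g) for g in groups]
        name = "grouping"
        if len(labels) != d.n_samples:
            raise ValueError("grouping length must match number of samples")
    sizes = pd.Series(labels).value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"every group needs at least 2 samples; too small: {small.index.tolist()}")
    return labels, name


def anosim(d: DissimilarityMatrix, groups, n_permutations: int = DEFAULT_PERMUTATIONS,
           seed: int = 0) -> AnosimResult:
    """Clarke's ANOSIM with a seeded label-permutation p-value."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    labels, name = _check_grouping(d, groups)
    offdiag = d.condensed()
    if np.ptp(offdiag) == 0:
        raise ValueError("constant dissimilarity matrix: ANOSIM R undefined")
    res = _skbio_anosim(d.to_skbio(), labels, permutations=n_permutations, seed=seed)
    return AnosimResult(r=float(res["test statistic"]), p_value=float(res["p-value"]),
                        n_permutations=n_permutations, grouping=name)


def _ss_decomposition(values: np.ndarray, labels: list[str]) -> tuple[float, float]:
    """(SS_total, SS_within) from squared dissimilarities."""
    d2 = values ** 2
    n = values.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = float(d2[iu].sum()) / n
    arr = np.asarray(labels)
    ss_within = 0.0
    for g in np.unique(arr):
        idx = np.flatnonzero(arr == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, float(ss_within)


def permanova_oneway(d: DissimilarityMatrix, groups,
                     n_permutations: int = DEFAULT_PERMUTATIONS,
                     seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA with a seeded label-permutation p-value.

    When SS_within is exactly zero the pseudo-F is reported as ``inf`` and
    the p-value is computed purely from the permutation distribution
    (a permutation "ties" the observed statistic only if it too yields
    SS_within = 0).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    labels, _ = _check_grouping(d, groups)
    n = d.n_samples
    a = len(set(labels))
    df_between, df_within = a - 1, n - a
    ss_total, ss_within = _ss_decomposition(d.values, labels)
    ss_between = ss_total - ss_within
    if ss_within <= 1e-12 * max(ss_total, 1.0):
        rng = np.random.default_rng(seed)
        hits = 0
        arr = np.array(labels)
        for _ in range(n_permutations):
            perm = rng.permutation(arr)
            _, ss_w = _ss_decomposition(d.values, perm.tolist())
            if ss_w <= 1e-12 * max(ss_total, 1.0):
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
        return PermanovaResult(pseudo_f=np.inf, p_value=p, df_between=df_between,
                               df_within=df_within, n_permutations=n_permutations,
                               ss_between=ss_between, ss_within=ss_within, ss_total=ss_total)
    res = _skbio_permanova(d.to_skbio(), labels, permutations=n_permutations, seed=seed)
    return PermanovaResult(pseudo_f=float(res["test statistic"]), p_value=float(res["p-value"]),
                           df_between=df_between, df_within=df_within,
                           n_permutations=n_permutations, ss_between=ss_between,
                           ss_within=ss_within, ss_total=ss_total)


def nmds(d: DissimilarityMatrix, n_restarts: int = 20, max_iter: int = 300,
         tol: float = 1e-7, seed: int = 0) -> NmdsEmbedding:
    """2-D non-metric MDS minimizing Kruskal stress-1, best of `n_restarts`.

    Restart 0 is initialized from classical metric scaling of the input
    dissimilarities; the remaining restarts use seeded random starts.
    """
    if d.n_samples < 3:
        raise ValueError("nMDS needs at least 3 samples")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    values = d.values
    best_coords, best_stress = None, np.inf
    child = np.random.SeedSequence(seed).generate_state(2)
    runs = [dict(init="classical_mds", n_init=1, random_state=int(child[0]) % (2**31))]
    if n_restarts > 1:
        runs.append(dict(init="random", n_init=n_restarts - 1,
                         random_state=int(child[1]) % (2**31)))
    for kw in runs:
        model = MDS(n_components=2, metric_mds=False, metric="precomputed",
                    max_iter=max_iter, eps=tol, normalized_stress=True, **kw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            coords = model.fit_transform(values)
        if model.stress_ < best_stress:
            best_stress, best_coords = float(model.stress_), coords
    frame = pd.DataFrame(best_coords, index=list(d.sample_ids), columns=["nmds1", "nmds2"])
    frame.index.name = "sample_id"
    return NmdsEmbedding(coordinates=frame, stress=best_stress,
                         n_restarts=n_restarts, seed=seed)
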