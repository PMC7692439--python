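"""Per-sample alpha diversity: observed richness, Chao1, Simpson, equitability.

Estimator choices
-----------------
* ``chao1`` defaults to the bias-corrected form
  ``S_obs + F1(F1-1) / (2(F2+1))`` (F1 = singletons, F2 = doubletons),
  which stays defined when no doubletons exist; the classic
  ``S_obs + F1^2/(2 F2)`` form is available via ``bias_corrected=False``.
* ``simpson_index`` returns 1 - D with the plug-in estimator
  ``D = sum p_i^2`` by default; ``unbiased=True`` switches to the
  finite-sample form ``D = sum n_i (n_i - 1) / (N (N - 1))``.
* ``equitability`` is Pielou's evenness H / ln(S_obs) with natural-log
  Shannon H; the ratio is base-invariant.

The analytic ``rarefaction_curve`` gives the exact expectation of richness
under subsampling without replacement,
``E[S(q)] = sum_i [1 - C(N - N_i, q) / C(N, q)]``.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from skbio.diversity import alpha as _skalpha

from .table import OtuTable, SampleMetadata


def _as_counts(column) -> np.ndarray:
    arr = np.asarray(column)
    if arr.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if arr.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("counts must be non-negative integers")
    return arr.astype(np.int64)


def observed_richness(column) -> int:
    """Number of OTUs with at least one read."""
    return int(np.count_nonzero(_as_counts(column)))


def chao1(column, bias_corrected: bool = True) -> float:
    """Chao1 expected richness; requires at least one positive count."""
    counts = _as_counts(column)
    if counts.sum() == 0:
        raise ValueError("chao1 undefined for an all-zero sample")
    return float(_skalpha.chao1(counts, bias_corrected=bias_corrected))


def simpson_index(column, unbiased: bool = False) -> float:
    """Simpson diversity 1 - D; requires at least one read."""
    counts = _as_counts(column)
    if counts.sum() == 0:
        raise ValueError("simpson_index undefined for an all-zero sample")
    return float(_skalpha.simpson(counts, finite=unbiased))


def equitability(column) -> float:
    """Pielou evenness H / ln(S_obs); undefined for fewer than 2 observed OTUs."""
    counts = _as_counts(column)
    if observed_richness(counts) < 2:
        raise ValueError("equitability undefined for fewer than 2 observed OTUs (H_max = 0)")
    return float(_skalpha.pielou_e(counts))


def rarefaction_curve(column, depths: Sequence[int]) -> np.ndarray:
    """Exact expected richness when subsampling `q` reads without replacement.

    ``E[S(q)] = sum over OTUs i of 1 - C(N - N_i, q) / C(N, q)`` with
    N the sample depth and N_i the OTU's count.  Each requested depth must
    satisfy ``1 <= q <= N``.
    """
    counts = _as_counts(column)
    counts = counts[counts > 0]
    n_total = int(counts.sum())
    depths_arr = np.asarray(depths, dtype=np.int64)
    if np.any(depths_arr < 1) or np.any(depths_arr > n_total):
        raise ValueError(f"each depth must lie in [1, {n_total}]")

    def _log_choose(n: np.ndarray, k: int) -> np.ndarray:
        out = np.full(np.shape(n), -np.inf, dtype=float)
        ok = n >= k
        n_ok = np.asarray(n, dtype=float)[ok]
        out[ok] = gammaln(n_ok + 1) - gammaln(k + 1.0) - gammaln(n_ok - k + 1)
        return out

    expected = np.empty(depths_arr.shape, dtype=float)
    for idx, q in enumerate(depths_arr):
        log_denom = _log_choose(np.array(n_total), int(q))
        log_num = _log_choose(n_total - counts, int(q))
        p_absent = np.exp(log_num - log_denom)
        expected[idx] = float(np.sum(1.0 - p_absent))
    return expected


def alpha_table(table: OtuTable, bias_corrected: bool = True,
                unbiased_simpson: bool = False) -> pd.DataFrame:
    """One alpha-diversity record per sample.

    Columns: ``s_obs``, ``s_chao1``, ``simpson_1_minus_d``, ``equitability``
    (NaN where fewer than 2 OTUs are observed), ``depth`` and
    ``coverage_ratio`` = s_obs / s_chao1.
    """
    records = []
    for sample in table.sample_ids:
        counts = table.counts[sample].to_numpy()
        depth = int(counts.sum())
        if depth == 0:
            raise ValueError(f"sample {sample!r} has zero reads")
        s_obs = observed_richness(counts)
        s_chao = chao1(counts, bias_corrected=bias_corrected)
        records.append({
            "sample_id": sample,
            "s_obs": s_obs,
            "s_chao1": s_chao,
            "simpson_1_minus_d": simpson_index(counts, unbiased=unbiased_simpson),
            "equitability": equitability(counts) if s_obs >= 2 else np.nan,
            "depth": depth,
            "coverage_ratio": s_obs / s_chao if s_chao > 0 else np.nan,
        })
    return pd.DataFrame.from_records(records).set_index("sample_id")


def group_summary(alpha: pd.DataFrame, metadata: SampleMetadata,
                  factors: Sequence[str] = ("plant", "compartment")) -> pd.DataFrame:
    """Mean and SD of each alpha metric per group (e.g. per plant x compartment code)."""
    labels = metadata.group_labels(factors, samples=alpha.index.tolist())
    grouped = alpha.groupby(labels)
    means = grouped.mean().add_suffix("_mean")
    sds = grouped.std(ddof=1).add_suffix("_sd")
    out = pd.concat([means, sds], axis=1)
    out.insert(0, "n_samples", grouped.size())
    return out
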