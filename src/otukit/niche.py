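"""Levins niche breadth and generalist / specialist classification of OTUs.

Levins' niche breadth of OTU j over the N samples of a table is

    B_j = 1 / sum_i P_ij^2

where ``P_ij`` is the proportion of OTU j's reads found in sample i
(``sum_i P_ij = 1``).  B is the effective number of samples the OTU
occupies: B = 1 for an OTU confined to a single sample and B = N for an
OTU spread perfectly evenly over all N samples.  OTUs with B above the
generalist threshold (default 20) are called generalists, OTUs with B
below the specialist threshold (default 10) specialists, and everything
else intermediate; all comparisons are strict.

An OTU is *abundant* when its dataset-wide read total strictly exceeds a
fraction (default 0.2%) of the grand total.  *Abundant specialists* are
abundant OTUs classified as specialists; their habitat preferences are the
sample groups (default plant x compartment) where the OTU's mean
per-sample relative abundance strictly exceeds a preference threshold
(default 20%).

B should be computed on the analysis-ready table (singleton-filtered,
taxonomy-filtered, rarefied): on equal-depth samples the proportion of the
OTU's reads and the renormalized sample-relative abundance coincide, so
the two readings of P_ij give the same B.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .table import OtuTable, SampleMetadata

GENERALIST_THRESHOLD = 20.0
SPECIALIST_THRESHOLD = 10.0
ABUNDANCE_FRACTION = 0.002
PREFERENCE_THRESHOLD = 0.20

CATEGORIES = ("generalist", "specialist", "intermediate")


def levins_b(row) -> float:
    """Levins niche breadth ``B = 1 / sum_i P_i^2`` for one OTU's counts."""
    arr = np.asarray(row, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("levins_b undefined for an all-zero OTU")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    p = arr / total
    return float(1.0 / np.sum(p ** 2))


def niche_breadth(table: OtuTable) -> pd.Series:
    """Levins B for every OTU of the table (NaN for all-zero rows)."""
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals[:, None]
        b = 1.0 / np.sum(p ** 2, axis=1)
    b[totals <= 0] = np.nan
    return pd.Series(b, index=table.counts.index, name="b_value")


def classify_niche(table: OtuTable,
                   generalist_threshold: float = GENERALIST_THRESHOLD,
                   specialist_threshold: float = SPECIALIST_THRESHOLD) -> pd.DataFrame:
    """Per-OTU B value, read total, and generalist/specialist/intermediate call.

    Thresholds are strict: generalist iff B > `generalist_threshold`,
    specialist iff B < `specialist_threshold`.  Returns a DataFrame indexed
    by OTU id with columns ``b_value``, ``total_reads``, ``category``.
    """
    if not specialist_threshold < generalist_threshold:
        raise ValueError("specialist_threshold must be below generalist_threshold")
    b = niche_breadth(table)
    category = pd.Series("intermediate", index=b.index, name="category")
    # strict thresholds on the mathematical B: values within floating-point
    # noise of a threshold count as equal, hence intermediate
    at_gen = np.isclose(b, generalist_threshold, rtol=1e-9, atol=0.0)
    at_spec = np.isclose(b, specialist_threshold, rtol=1e-9, atol=0.0)
    category[(b > generalist_threshold) & ~at_gen] = "generalist"
    category[(b < specialist_threshold) & ~at_spec] = "specialist"
    out = pd.DataFrame({"b_value": b, "total_reads": table.otu_totals,
                        "category": category})
    out.index.name = "otu_id"
    return out


def abundant_otus(table: OtuTable, fraction_threshold: float = ABUNDANCE_FRACTION) -> set[str]:
    """OTUs whose read total strictly exceeds `fraction_threshold` of the grand total."""
    if not 0 < fraction_threshold < 1:
        raise ValueError("fraction_threshold must lie in (0, 1)")
    cutoff = fraction_threshold * table.grand_total
    totals = table.otu_totals
    return set(totals.index[totals > cutoff])


def generalist_otus(table: OtuTable, metadata: SampleMetadata | None = None,
                    mode: str = "intersection",
                    generalist_threshold: float = GENERALIST_THRESHOLD) -> set[str]:
    """Generalist OTU ids, by whole-dataset B or by subset intersection.

    ``mode="whole"`` classifies on the full table.  ``mode="intersection"``
    (default) additionally computes B within each site subset and within
    each compartment subset and returns the OTUs called generalist in every
    case — the conservative reading of a "ubiquitous" OTU.  Note that a
    subset with at most `generalist_threshold` samples can never contribute
    generalists, since B is bounded by the number of samples.
    """
    def _gen_set(tab: OtuTable) -> set[str]:
        b = niche_breadth(tab)
        return set(b.index[b > generalist_threshold])

    whole = _gen_set(table)
    if mode == "whole":
        return whole
    if mode != "intersection":
        raise ValueError("mode must be 'whole' or 'intersection'")
    if metadata is None:
        raise ValueError("intersection mode requires sample metadata")
    meta = metadata.for_table(table)
    result = whole
    for factor in ("site", "compartment"):
        for _, samples in meta.groupby(factor).groups.items():
            sub = table.select_samples(list(samples))
            result &= _gen_set(sub)
    return result


def abundant_specialists(table: OtuTable, metadata: SampleMetadata,
                         grouping: Sequence[str] = ("plant", "compartment"),
                         preference_threshold: float = PREFERENCE_THRESHOLD,
                         fraction_threshold: float = ABUNDANCE_FRACTION,
                         specialist_threshold: float = SPECIALIST_THRESHOLD,
                         generalist_threshold: float = GENERALIST_THRESHOLD) -> pd.DataFrame:
    """Abundant OTUs with specialist niche breadth, plus their preferred habitats.

    An OTU qualifies when it is abundant (read total > `fraction_threshold`
    of the grand total) *and* a specialist (B < `specialist_threshold`).
    Its preferred habitats are the groups (default plant x compartment)
    where the mean over the group's samples of the OTU's per-sample
    relative abundance strictly exceeds `preference_threshold`.

    Returns a DataFrame indexed by OTU id with columns ``b_value``,
    ``total_reads``, ``category``, ``is_abundant`` and
    ``preferred_habitats`` (list of ``(group label, mean relative
    abundance)`` pairs, best first).
    """
    metadata.for_table(table)
    classified = classify_niche(table, generalist_threshold, specialist_threshold)
    abundant = abundant_otus(table, fraction_threshold)
    chosen = classified[(classified["category"] == "specialist")
                        & classified.index.isin(abundant)].copy()
    chosen["is_abundant"] = True

    labels = metadata.group_labels(grouping, samples=table.sample_ids)
    rel = table.relative_abundance()
    prefs: list[list[tuple[str, float]]] = []
    group_means = {}
    for label, samples in labels.groupby(labels).groups.items():
        if len(samples) == 0:  # pragma: no cover - cannot arise from group_labels
            warnings.warn(f"group {label!r} has no samples; skipped")
            continue
        group_means[label] = rel.loc[:, list(samples)].mean(axis=1)
    for otu in chosen.index:
        hits = [(label, float(means[otu])) for label, means in group_means.items()
                if means[otu] > preference_threshold]
        hits.sort(key=lambda kv: -kv[1])
        prefs.append(hits)
    chosen["preferred_habitats"] = prefs
    return chosen


@dataclass(frozen=True)
class SharedOtuCounts:
    """Venn counts of OTU presence for one pair of sample groups."""

    group_a: str
    group_b: str
    only_a: int
    only_b: int
    shared: int

    @property
    def pooled_richness(self) -> int:
        return self.only_a + self.only_b + self.shared


def shared_otu_counts(table: OtuTable, metadata: SampleMetadata,
                      partition: Sequence[str] = ("compartment",)) -> list[SharedOtuCounts]:
    """Unique/shared OTU counts for every pair of groups of a partition.

    An OTU belongs to a group when it has at least one read in at least one
    of the group's samples.
    """
    labels = metadata.group_labels(partition, samples=table.sample_ids)
    groups = labels.groupby(labels).groups
    if len(groups) < 2:
        raise ValueError("partition must yield at least 2 groups")
    presence = table.presence()
    member: dict[str, set[str]] = {}
    for label, samples in groups.items():
        present = presence.loc[:, list(samples)].any(axis=1)
        member[label] = set(present.index[present])
    out = []
    for a, b in combinations(sorted(member), 2):
        sa, sb = member[a], member[b]
        out.append(SharedOtuCounts(group_a=a, group_b=b,
                                   only_a=len(sa - sb), only_b=len(sb - sa),
                                   shared=len(sa & sb)))
    return out


def shared_counts_frame(counts: Sequence[SharedOtuCounts]) -> pd.DataFrame:
    """Tabular form of :func:`shared_otu_counts` results."""
    return pd.DataFrame([{"group_a": c.group_a, "group_b": c.group_b,
                          "only_a": c.only_a, "only_b": c.only_b,
                          "shared": c.shared} for c in counts])
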