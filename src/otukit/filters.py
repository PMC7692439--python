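"""Count-table filtering and rarefaction.

The standard preprocessing order for amplicon OTU tables is: remove
dataset-wide singleton OTUs (suspected sequencing errors), remove unwanted
lineages (e.g. chloroplast 16S), drop samples with too few reads, then
rarefy the remaining samples to a common depth.  Rarefaction draws a
uniform subsample *without replacement* from each sample's reads — a
multivariate hypergeometric draw over the sample's OTU counts — so that a
sample at or above the target depth ends up with exactly the target number
of reads.  Samples below the target can either be kept unchanged or
dropped.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .table import OtuTable, TaxonomyMap

#: Default seed for rarefaction; pass an explicit seed for anything that matters.
DEFAULT_SEED = 0


def filter_global_singletons(table: OtuTable) -> OtuTable:
    """Remove OTUs with a single read in the entire dataset (row total < 2)."""
    keep = table.otu_totals >= 2
    return OtuTable(table.counts.loc[keep])


def filter_taxa_by_label(table: OtuTable, taxonomy: TaxonomyMap, label: str) -> OtuTable:
    """Remove OTUs whose lineage contains `label` (case-insensitive, any rank).

    OTUs without a taxonomy entry are treated as unclassified and retained.
    """
    if not label:
        raise ValueError("label must be non-empty")
    keep = [otu for otu in table.otu_ids if not taxonomy.contains_label(otu, label)]
    return OtuTable(table.counts.loc[keep])


def drop_shallow_samples(table: OtuTable, min_reads: int) -> OtuTable:
    """Drop samples with fewer than `min_reads` reads, then drop OTUs left all-zero."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = table.sample_depths >= min_reads
    sub = table.counts.loc[:, keep]
    sub = sub.loc[sub.sum(axis=1) > 0] if sub.shape[1] else sub.iloc[0:0]
    return OtuTable(sub)


def rarefy(table: OtuTable, depth: int, seed: int = DEFAULT_SEED,
           keep_below_depth: bool = True) -> OtuTable:
    """Rarefy each sample to `depth` reads by sampling without replacement.

    Each sample with at least `depth` reads is replaced by a multivariate
    hypergeometric subsample of exactly `depth` reads over its OTU counts.
    Samples below `depth` are kept unchanged when `keep_below_depth` is
    true, otherwise dropped.  The same seed yields identical output.
    """
    if depth <= 0:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    depths = table.sample_depths
    columns: dict[str, np.ndarray] = {}
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        if depths[sample] >= depth:
            columns[sample] = rng.multivariate_hypergeometric(col, depth)
        elif keep_below_depth:
            columns[sample] = col
    frame = pd.DataFrame(columns, index=table.counts.index, dtype=np.int64)
    if not columns:
        frame = table.counts.iloc[:, 0:0]
    return OtuTable(frame)
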