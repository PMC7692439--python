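"""Synthetic OTU tables with planted generalist/specialist structure.

The generator emulates the post-clustering product of a multi-site
rhizosphere/phyllosphere amplicon survey: several sampling sites, one or
more plant species per site, two compartments per plant, and a few
replicate individuals per plant x compartment.  Three OTU guilds are
planted:

* **generalists** — near-uniform expected relative abundance in every
  sample (their Levins B should approach the number of samples);
* **specialists** — each assigned one preferred plant x compartment group,
  receiving an expected share ``specialist_load`` of reads there and zero
  elsewhere (their B is bounded by the group's size);
* **background** — heavy-tailed (lognormal) mean abundances, tilted per
  site by a lognormal factor of scale ``site_effect`` so that sites
  diverge compositionally (``site_effect = 0`` gives an exchangeable null).

Per sample, counts are multinomial draws from the expected composition at
a depth uniform over ``depth_range`` (the default range straddles the
usual rarefaction depth so some samples fall below it, as in real
surveys).  Optional Dirichlet-multinomial overdispersion is available.
The same seed always reproduces the same dataset.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .table import COMPARTMENTS, OtuTable, SampleMetadata

_COMPARTMENT_CODE = {"rhizosphere": "Rz", "phyllosphere": "Ph"}

#: Default geometry: site 1 carries 1 plant with 8 replicates, sites 2 and 3
#: carry 3 plants with 5 replicates each; times 2 compartments = 76 samples.
DEFAULT_LAYOUT = ((1, 8), (3, 5), (3, 5))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic community.

    ``site_layout`` is a tuple of ``(plants, replicates)`` pairs, one per
    site; use :meth:`uniform` for a regular n_sites x plants x replicates
    design.  ``specialist_load`` is the expected fraction of a preferred
    sample's reads granted to its specialist; the loads of all specialists
    sharing a group must sum below 1.
    """

    site_layout: tuple[tuple[int, int], ...] = DEFAULT_LAYOUT
    n_generalists: int = 30
    n_specialists: int = 14
    n_background: int = 950
    generalist_share: float = 0.30     # generalists' joint share of non-specialist reads
    generalist_sigma: float = 0.5      # lognormal spread of generalist means
    abundance_sigma: float = 1.5       # lognormal shape of background means (heavy tail)
    depth_range: tuple[int, int] = (3000, 12000)
    specialist_load: float = 0.4
    site_effect: float = 1.0
    overdispersion: float = 0.0        # Dirichlet-multinomial scale; 0 = pure multinomial
    seed: int = 0

    @classmethod
    def uniform(cls, n_sites: int = 3, plants_per_site: int = 1,
                replicates: int = 4, **kwargs) -> "SimulationConfig":
        layout = tuple((plants_per_site, replicates) for _ in range(n_sites))
        return cls(site_layout=layout, **kwargs)

    def validate(self) -> None:
        if not self.site_layout:
            raise ValueError("site_layout must name at least one site")
        for plants, reps in self.site_layout:
            if plants < 1 or reps < 2:
                raise ValueError("each site needs >= 1 plant and >= 2 replicates")
        if self.n_generalists + self.n_specialists + self.n_background == 0:
            raise ValueError("config yields zero OTUs")
        if min(self.depth_range) < 1 or self.depth_range[0] > self.depth_range[1]:
            raise ValueError("depth_range must be (min, max) with min >= 1")
        if not 0 < self.specialist_load <= 1:
            raise ValueError("specialist_load must lie in (0, 1]")
        if not 0 <= self.generalist_share <= 1:
            raise ValueError("generalist_share must lie in [0, 1]")
        if self.site_effect < 0 or self.overdispersion < 0:
            raise ValueError("site_effect and overdispersion must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-OTU roles and, for specialists, the preferred group."""

    roles: dict[str, str]                 # otu_id -> generalist | specialist | background
    preferred_group: dict[str, str]       # specialist otu_id -> "plant:compartment"

    def otus_with_role(self, role: str) -> set[str]:
        return {otu for otu, r in self.roles.items() if r == role}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"otu_id": otu, "role": role,
                 "preferred_group": self.preferred_group.get(otu, "")}
                for otu, role in self.roles.items()]
        return pd.DataFrame(rows).set_index("otu_id")

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _build_metadata(layout) -> pd.DataFrame:
    rows = []
    for s, (plants, reps) in enumerate(layout, start=1):
        for p in range(1, plants + 1):
            plant = f"S{s}P{p}"
            for compartment in COMPARTMENTS:
                code = f"{plant}{_COMPARTMENT_CODE[compartment]}"
                for r in range(1, reps + 1):
                    rows.append({"sample_id": f"{code}{r}", "site": f"site{s}",
                                 "plant": plant, "compartment": compartment,
                                 "code": code})
    return pd.DataFrame(rows).set_index("sample_id")


def generate_dataset(config: SimulationConfig) -> tuple[OtuTable, SampleMetadata, SyntheticTruth]:
    """Simulate an OTU table, its metadata, and the planted ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta_frame = _build_metadata(config.site_layout)
    sample_ids = meta_frame.index.tolist()
    n_sites = len(config.site_layout)
    site_index = {f"site{s}": s - 1 for s in range(1, n_sites + 1)}

    n_gen, n_spec, n_bg = config.n_generalists, config.n_specialists, config.n_background
    otu_ids = [f"OTU_{i}" for i in range(1, n_gen + n_spec + n_bg + 1)]
    gen_ids = otu_ids[:n_gen]
    spec_ids = otu_ids[n_gen:n_gen + n_spec]
    bg_ids = otu_ids[n_gen + n_spec:]

    # Specialists are assigned round-robin over plant x compartment groups.
    group_labels = meta_frame["plant"].str.cat(meta_frame["compartment"], sep=":")
    groups = group_labels.drop_duplicates().tolist()
    preferred = {otu: groups[i % len(groups)] for i, otu in enumerate(spec_ids)}
    load_per_group = pd.Series(list(preferred.values())).value_counts() * config.specialist_load
    if n_spec and (load_per_group >= 1.0).any():
        crowded = load_per_group[load_per_group >= 1.0].index.tolist()
        raise ValueError(
            f"specialist loads sum to >= 1 in groups {crowded}; lower "
            "specialist_load or n_specialists")

    gen_w = rng.lognormal(0.0, config.generalist_sigma, n_gen)
    gen_w = gen_w / gen_w.sum() if n_gen else gen_w
    bg_base = rng.lognormal(0.0, config.abundance_sigma, n_bg)
    if config.site_effect > 0 and n_bg:
        tilt = rng.lognormal(0.0, config.site_effect, (n_bg, n_sites))
    else:
        tilt = np.ones((n_bg, n_sites))

    gshare = config.generalist_share if n_gen else 0.0
    if n_bg == 0:
        gshare = 1.0 if n_gen else 0.0

    counts = np.zeros((len(otu_ids), len(sample_ids)), dtype=np.int64)
    spec_pos = {otu: n_gen + i for i, otu in enumerate(spec_ids)}
    for j, sample in enumerate(sample_ids):
        site = site_index[meta_frame.at[sample, "site"]]
        group = group_labels[sample]
        local_spec = [otu for otu in spec_ids if preferred[otu] == group]
        load = config.specialist_load * len(local_spec)
        p = np.zeros(len(otu_ids))
        if n_gen:
            p[:n_gen] = gen_w * gshare * (1.0 - load)
        for otu in local_spec:
            p[spec_pos[otu]] = config.specialist_load
        if n_bg:
            bg_w = bg_base * tilt[:, site]
            p[n_gen + n_spec:] = bg_w / bg_w.sum() * (1.0 - gshare) * (1.0 - load)
        total = p.sum()
        if total <= 0:
            raise ValueError(f"sample {sample} has an all-zero composition; check config")
        p = p / total
        if config.overdispersion > 0:
            support = p > 0
            p_support = rng.dirichlet(p[support] / config.overdispersion)
            p = np.zeros_like(p)
            p[support] = p_support
        depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
        counts[:, j] = rng.multinomial(depth, p)

    table = OtuTable(pd.DataFrame(counts, index=otu_ids, columns=sample_ids))
    metadata = SampleMetadata(meta_frame)
    roles = {**{o: "generalist" for o in gen_ids},
             **{o: "specialist" for o in spec_ids},
             **{o: "background" for o in bg_ids}}
    truth = SyntheticTruth(roles=roles, preferred_group=preferred)
    return table, metadata, truth


def write_dataset(directory: str | Path, table: OtuTable, metadata: SampleMetadata,
                  truth: SyntheticTruth | None = None) -> dict[str, Path]:
    """Dump a simulated dataset as the TSV formats the rest of the package reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"otu_table": directory / "otu_table.tsv",
             "metadata": directory / "metadata.tsv"}
    table.to_tsv(paths["otu_table"])
    metadata.to_tsv(paths["metadata"])
    if truth is not None:
        paths["truth"] = directory / "truth.tsv"
        truth.to_tsv(paths["truth"])
    return paths
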