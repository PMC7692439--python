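import numpy as np
import pandas as pd
import pytest

from otukit import OtuTable, SampleMetadata


def make_table(rows: dict[str, list[int]], samples: list[str] | None = None) -> OtuTable:
    """OtuTable from {otu_id: counts}; sample ids default to s1, s2, ..."""
    n = len(next(iter(rows.values())))
    samples = samples or [f"s{i + 1}" for i in range(n)]
    return OtuTable(pd.DataFrame.from_dict(rows, orient="index", columns=samples))


def make_metadata(samples: list[str], site=None, plant=None, compartment=None) -> SampleMetadata:
    n = len(samples)
    frame = pd.DataFrame({
        "sample_id": samples,
        "site": site or ["siteA"] * n,
        "plant": plant or ["P1"] * n,
        "compartment": compartment or ["rhizosphere"] * n,
    })
    frame["code"] = frame["plant"] + frame["compartment"].str[:2].str.capitalize()
    return SampleMetadata(frame)


def random_table(rng: np.random.Generator, n_otus: int, n_samples: int,
                 max_count: int = 20) -> OtuTable:
    counts = rng.integers(0, max_count + 1, size=(n_otus, n_samples))
    keep = counts.sum(axis=1) > 0
    counts = counts[keep] if keep.any() else np.ones((1, n_samples), dtype=int)
    return OtuTable(pd.DataFrame(
        counts, index=[f"OTU_{i}" for i in range(counts.shape[0])],
        columns=[f"s{j}" for j in range(n_samples)]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def toy_table() -> OtuTable:
    return make_table({
        "OTU_1": [3, 0, 1],
        "OTU_2": [1, 1, 2],
        "OTU_3": [0, 5, 0],
        "OTU_4": [1, 0, 0],
    })
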