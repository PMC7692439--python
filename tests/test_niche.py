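"""Levins niche breadth, generalist/specialist calls, and shared-OTU accounting."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otukit import (
    OtuTable,
    abundant_otus,
    abundant_specialists,
    classify_niche,
    generalist_otus,
    levins_b,
    niche_breadth,
    shared_counts_frame,
    shared_otu_counts,
)

from conftest import make_metadata, make_table, random_table

row_strategy = st.lists(st.integers(min_value=0, max_value=100), min_size=1, max_size=40).filter(
    lambda xs: sum(xs) > 0)


class TestLevinsB:
    def test_single_sample_occupancy_gives_one(self):
        assert levins_b([0, 7, 0, 0]) == pytest.approx(1.0)

    def test_perfectly_even_occupancy_gives_sample_count(self):
        assert levins_b([5] * 33) == pytest.approx(33.0)

    def test_two_even_samples_give_two(self):
        assert levins_b([2, 2]) == pytest.approx(2.0)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            levins_b([0, 0])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(row_strategy)
    def test_b_bounded_by_one_and_sample_count(self, row):
        b = levins_b(row)
        n = len(row)
        assert 1 - 1e-9 <= b <= n + 1e-9
        if b == pytest.approx(n):
            positive = [x for x in row if x > 0]
            assert len(positive) == n and len(set(positive)) == 1

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(row_strategy, st.integers(min_value=2, max_value=9))
    def test_b_invariant_to_row_scaling(self, row, factor):
        assert levins_b(row) == pytest.approx(levins_b([factor * x for x in row]))

    def test_spreading_reads_to_an_empty_sample_never_decreases_b(self, rng):
        # transfer one read from the largest sample to an empty one
        for _ in range(50):
            row = rng.integers(0, 30, size=10)
            row[rng.integers(0, 10)] += 1  # ensure nonzero
            if not (row == 0).any():
                row[0] = 0
            before = levins_b(row)
            spread = row.copy()
            src = int(np.argmax(spread))
            dst = int(np.flatnonzero(spread == 0)[0])
            spread[src] -= 1
            spread[dst] += 1
            assert levins_b(spread) >= before - 1e-9

    def test_equal_depth_samples_make_both_p_readings_agree(self, rng):
        # on equal column sums, renormalizing sample-relative abundances
        # gives the same proportions as the OTU's own read shares
        counts = rng.integers(0, 10, size=(12, 6))
        counts[0] += 1
        depth = counts.sum(axis=0).max()
        counts[0] += depth - counts.sum(axis=0)  # force equal depths
        table = OtuTable(pd.DataFrame(
            counts, index=[f"o{i}" for i in range(12)],
            columns=[f"s{j}" for j in range(6)]))
        rel = table.relative_abundance().to_numpy()
        for i, otu in enumerate(table.otu_ids):
            p_alt = rel[i] / rel[i].sum()
            b_alt = 1.0 / np.sum(p_alt ** 2)
            assert niche_breadth(table)[otu] == pytest.approx(b_alt, rel=1e-12)


class TestClassifyNiche:
    def make_with_b(self, b_targets):
        # an OTU spread evenly over k samples has B = k
        rows = {f"o{k}": [10 if i < k else 0 for i in range(40)] for k in b_targets}
        return make_table(rows, samples=[f"s{i}" for i in range(40)])

    def test_threshold_rules_with_strict_boundaries(self):
        table = self.make_with_b([25, 15, 10, 5])
        cats = classify_niche(table)["category"]
        assert cats["o25"] == "generalist"
        assert cats["o15"] == "intermediate"
        assert cats["o10"] == "intermediate"  # B = 10 exactly: not < 10
        assert cats["o5"] == "specialist"

    def test_b_values_reported_per_otu(self):
        table = self.make_with_b([25, 5])
        out = classify_niche(table)
        assert out.loc["o25", "b_value"] == pytest.approx(25.0)
        assert out.loc["o5", "total_reads"] == 50

    def test_bad_thresholds_rejected(self, toy_table):
        with pytest.raises(ValueError):
            classify_niche(toy_table, generalist_threshold=5, specialist_threshold=10)

    def test_empty_table_gives_empty_result(self):
        empty = OtuTable(pd.DataFrame(np.empty((0, 3), dtype=int),
                                      columns=["a", "b", "c"]))
        assert classify_niche(empty).empty


class TestAbundantOtus:
    def test_strict_fraction_cutoff(self):
        # grand total 450000; cutoff 0.2% = 900; 901 in, 900 out
        filler = 450000 - 901 - 900
        table = make_table({"hot": [901], "edge": [900], "rest": [filler]},
                           samples=["s1"])
        abundant = abundant_otus(table, 0.002)
        assert "hot" in abundant and "edge" not in abundant

    def test_vanishing_threshold_includes_every_present_otu(self):
        table = make_table({"a": [1, 0], "b": [0, 3]})
        assert abundant_otus(table, 1e-9) == {"a", "b"}

    def test_threshold_outside_unit_interval_rejected(self, toy_table):
        with pytest.raises(ValueError):
            abundant_otus(toy_table, 0.0)


class TestAbundantSpecialists:
    def build(self):
        # 8 samples in 2 plant x compartment groups of 4
        samples = [f"s{i}" for i in range(8)]
        meta = make_metadata(samples,
                             plant=["P1"] * 4 + ["P2"] * 4,
                             compartment=["rhizosphere"] * 8)
        rows = {
            # specialist at 30% of reads in P1 samples only
            "spec": [30, 30, 30, 30, 0, 0, 0, 0],
            # generalist-like OTU, even everywhere
            "gen": [20, 20, 20, 20, 20, 20, 20, 20],
            "bulk": [50, 50, 50, 50, 80, 80, 80, 80],
        }
        return make_table(rows, samples=samples), meta

    def test_planted_specialist_returned_with_its_group(self):
        table, meta = self.build()
        out = abundant_specialists(table, meta, fraction_threshold=0.01,
                                   specialist_threshold=4.5)
        assert list(out.index) == ["spec"]
        habitats = out.loc["spec", "preferred_habitats"]
        assert len(habitats) == 1
        group, mean_rel = habitats[0]
        assert group == "P1:rhizosphere"
        assert mean_rel == pytest.approx(0.3)

    def test_non_specialist_abundant_otu_excluded(self):
        table, meta = self.build()
        out = abundant_specialists(table, meta, fraction_threshold=0.01,
                                   specialist_threshold=4.5)
        assert "gen" not in out.index and "bulk" not in out.index

    def test_exact_20_percent_mean_is_not_preferred(self):
        samples = ["a1", "a2", "b1", "b2"]
        meta = make_metadata(samples, plant=["P1", "P1", "P2", "P2"],
                             compartment=["rhizosphere"] * 4)
        table = make_table({"spec": [20, 20, 0, 0], "rest": [80, 80, 100, 100]},
                           samples=samples)
        out = abundant_specialists(table, meta, fraction_threshold=0.01)
        assert out.loc["spec", "preferred_habitats"] == []


class TestGeneralistModes:
    def test_whole_and_intersection_modes(self, rng):
        samples = [f"s{i}" for i in range(60)]
        meta = make_metadata(samples,
                             site=["X"] * 30 + ["Y"] * 30,
                             compartment=(["rhizosphere"] * 15 + ["phyllosphere"] * 15) * 2)
        rows = {"ubiq": [10] * 60,                  # even everywhere
                "half": [10] * 30 + [0] * 30,       # only site X
                "rare": [10] + [0] * 59}
        table = make_table(rows, samples=samples)
        whole = generalist_otus(table, mode="whole")
        assert whole == {"ubiq", "half"}  # B = 60 and 30
        inter = generalist_otus(table, meta, mode="intersection")
        assert inter == {"ubiq"}  # "half" fails in site Y
        union = set()
        for factor in ("site", "compartment"):
            for _, ids in meta.frame.groupby(factor).groups.items():
                sub = table.select_samples(list(ids))
                b = niche_breadth(sub)
                union |= set(b.index[b > 20])
        assert inter <= union | whole


class TestSharedOtus:
    def test_toy_venn_counts(self):
        samples = ["r1", "r2", "p1", "p2"]
        meta = make_metadata(samples,
                             compartment=["rhizosphere"] * 2 + ["phyllosphere"] * 2)
        table = make_table({
            "a": [1, 0, 0, 0], "b": [0, 2, 0, 0],        # rhizosphere only
            "c": [0, 0, 3, 0], "d": [0, 0, 0, 1],        # phyllosphere only
            "e": [1, 0, 1, 0],                            # shared
        }, samples=samples)
        [counts] = shared_otu_counts(table, meta, ("compartment",))
        assert (counts.only_a, counts.only_b, counts.shared) == (2, 2, 1)
        assert counts.pooled_richness == 5
        frame = shared_counts_frame([counts])
        assert frame.loc[0, "shared"] == 1

    def test_disjoint_groups_share_nothing(self):
        samples = ["r1", "r2", "p1", "p2"]
        meta = make_metadata(samples,
                             compartment=["rhizosphere"] * 2 + ["phyllosphere"] * 2)
        table = make_table({"a": [1, 1, 0, 0], "b": [0, 0, 1, 1]}, samples=samples)
        [counts] = shared_otu_counts(table, meta, ("compartment",))
        assert counts.shared == 0

    def test_single_group_partition_rejected(self):
        samples = ["r1", "r2"]
        meta = make_metadata(samples)
        table = make_table({"a": [1, 1]}, samples=samples)
        with pytest.raises(ValueError):
            shared_otu_counts(table, meta, ("compartment",))
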