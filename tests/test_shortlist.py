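import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccshift.shortlist import (
    build_shortlist,
    consensus_rank_changes,
    decompose_molecules,
    pair_frequencies,
    shortlist_consensus,
    shortlist_gain_pl,
    top_k_pairs,
    top_pairs_across_categories,
    two_cluster_partition,
)

from oracles import best_bipartition_ss, within_group_ss


class TestTwoClusterPartition:
    def test_clear_gap_split(self):
        res = two_cluster_partition([1.0, 2.0, 10.0, 11.0])
        assert set(res.high_group) == {2, 3}
        assert set(res.low_group) == {0, 1}
        assert not res.degenerate

    def test_identical_values_degenerate(self):
        res = two_cluster_partition([5.0, 5.0, 5.0])
        assert set(res.high_group) == {0, 1, 2}
        assert res.low_group == []
        assert res.degenerate

    def test_two_points(self):
        res = two_cluster_partition([0.0, 100.0])
        assert res.high_group == [1]
        assert res.low_group == [0]

    def test_single_value_degenerate(self):
        res = two_cluster_partition([3.0])
        assert res.high_group == [0]
        assert res.degenerate

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            two_cluster_partition([])

    def test_high_group_has_larger_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            vals = rng.normal(size=int(rng.integers(2, 15)))
            res = two_cluster_partition(vals)
            if res.degenerate:
                continue
            assert (
                np.mean(vals[res.high_group]) > np.mean(vals[res.low_group])
            )

    def test_matches_exhaustive_bipartition_oracle(self):
        """The sorted-split scan attains the global two-group minimum
        within-SS over all bipartitions, for 500 random vectors (n <= 12)."""
        rng = np.random.default_rng(42)
        for _ in range(500):
            n = int(rng.integers(2, 13))
            vals = np.round(rng.normal(0, 5, size=n), 3)
            res = two_cluster_partition(vals)
            if res.degenerate:
                assert len(np.unique(vals)) == 1
                continue
            achieved = within_group_ss(vals, res.high_group, res.low_group)
            best = best_bipartition_ss(vals)
            assert achieved == pytest.approx(best, abs=1e-9)

    def test_agrees_with_kmeans_on_clear_separations(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(7)
        for _ in range(20):
            vals = np.concatenate(
                [rng.normal(0, 0.5, 6), rng.normal(8, 0.5, 5)]
            )
            rng.shuffle(vals)
            res = two_cluster_partition(vals)
            km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(
                vals.reshape(-1, 1)
            )
            high_label = int(np.argmax(km.cluster_centers_.ravel()))
            km_high = set(np.flatnonzero(km.labels_ == high_label))
            assert set(res.high_group) == km_high

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        vals=st.lists(
            st.floats(0.01, 1e3, allow_nan=False), min_size=2, max_size=10
        ),
        scale=st.floats(0.01, 100.0),
    )
    def test_scale_equivariance(self, vals, scale):
        base = two_cluster_partition(vals)
        scaled = two_cluster_partition([v * scale for v in vals])
        assert set(base.high_group) == set(scaled.high_group)


def classified(rows):
    return pd.DataFrame(
        rows,
        columns=["source", "target", "ligand", "receptor", "category",
                 "lr_mean"],
    )


class TestShortlistGainPL:
    def test_high_mean_cluster_selected(self):
        df = classified(
            [
                ("A", "B", "L1", "R1", "gain", 0.1),
                ("A", "B", "L2", "R2", "gain", 0.2),
                ("A", "B", "L3", "R3", "gain", 3.0),
            ]
        )
        out = shortlist_gain_pl(df, "gain")
        sel = out[out["selected"]]
        assert list(sel["ligand"]) == ["L3"]

    def test_single_unit_selected_degenerately(self):
        df = classified([("A", "B", "L1", "R1", "potential_loss", 0.5)])
        out = shortlist_gain_pl(df, "potential_loss")
        assert out["selected"].all()

    def test_empty_category_empty_shortlist(self):
        out = shortlist_gain_pl(classified([]), "gain")
        assert len(out) == 0

    def test_selected_mean_dominates_unselected(self):
        rng = np.random.default_rng(3)
        rows = [
            ("A", "B", f"L{i}", f"R{i}", "gain", float(rng.lognormal()))
            for i in range(20)
        ]
        out = shortlist_gain_pl(classified(rows), "gain")
        sel = out.loc[out["selected"], "score"]
        unsel = out.loc[~out["selected"], "score"]
        assert sel.mean() >= unsel.mean()

    def test_per_type_clustering_is_independent(self):
        rows = [
            ("A", "B", "L1", "R1", "gain", 0.1),
            ("A", "B", "L2", "R2", "gain", 5.0),
            ("C", "D", "L3", "R3", "gain", 100.0),
            ("C", "D", "L4", "R4", "gain", 900.0),
        ]
        out = shortlist_gain_pl(classified(rows), "gain")
        sel = set(out.loc[out["selected"], "ligand"])
        assert sel == {"L2", "L4"}


def consensus_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["source", "target", "ligand", "receptor", "lr_mean_ref",
                 "lr_mean_cmp"],
    )


class TestShortlistConsensus:
    def test_rank_swap_scores_one_each(self):
        df = consensus_frame(
            [
                ("A", "B", "L1", "R1", 2.0, 1.0),
                ("A", "B", "L2", "R2", 1.0, 2.0),
            ]
        )
        scored = consensus_rank_changes(df)
        assert list(scored["score"]) == [1.0, 1.0]

    def test_identical_rankings_degenerate(self):
        df = consensus_frame(
            [
                ("A", "B", "L1", "R1", 3.0, 3.0),
                ("A", "B", "L2", "R2", 2.0, 2.0),
                ("A", "B", "L3", "R3", 1.0, 1.0),
            ]
        )
        out = shortlist_consensus(df)
        assert (out["score"] == 0.0).all()
        assert out["selected"].all()  # degenerate: everything selected

    def test_large_rank_move_selected(self):
        # L1 drops from rank 1 to rank 5 among five pairs; the others
        # shift by at most one rank
        df = consensus_frame(
            [
                ("A", "B", "L1", "R1", 10.0, 0.5),
                ("A", "B", "L2", "R2", 8.0, 9.0),
                ("A", "B", "L3", "R3", 6.0, 7.0),
                ("A", "B", "L4", "R4", 4.0, 5.0),
                ("A", "B", "L5", "R5", 2.0, 3.0),
            ]
        )
        out = shortlist_consensus(df)
        assert out.loc[out["ligand"] == "L1", "score"].iloc[0] == 4.0
        sel = set(out.loc[out["selected"], "ligand"])
        assert sel == {"L1"}

    def test_average_ranks_for_ties(self):
        df = consensus_frame(
            [
                ("A", "B", "L1", "R1", 5.0, 5.0),
                ("A", "B", "L2", "R2", 5.0, 5.0),
                ("A", "B", "L3", "R3", 1.0, 1.0),
            ]
        )
        scored = consensus_rank_changes(df)
        assert (scored["score"] == 0.0).all()


class TestPairFrequencies:
    def test_worked_gain_example(self):
        # the same pair gained in two distinct communication types has
        # gain-category frequency two for that interval
        df = classified(
            [
                ("Fibroblast", "Fibroblast", "FBLN1", "ITGB1", "gain", 1.0),
                ("Cardiomyocyte", "Fibroblast", "FBLN1", "ITGB1", "gain", 1.0),
            ]
        )[["source", "target", "ligand", "receptor", "category"]]
        freq = pair_frequencies(df, "1m->3m")
        assert len(freq) == 1
        assert freq.loc[0, "frequency"] == 2
        assert freq.loc[0, "category"] == "gain"
        assert freq.loc[0, "stage_interval"] == "1m->3m"

    def test_single_type_frequency_one(self):
        df = classified(
            [("A", "B", "L", "R", "gain", 1.0)]
        )[["source", "target", "ligand", "receptor", "category"]]
        assert pair_frequencies(df)["frequency"].iloc[0] == 1

    def test_categories_counted_separately(self):
        df = classified(
            [
                ("A", "B", "L", "R", "gain", 1.0),
                ("C", "D", "L", "R", "consensus", 1.0),
            ]
        )[["source", "target", "ligand", "receptor", "category"]]
        freq = pair_frequencies(df)
        assert len(freq) == 2
        assert set(freq["frequency"]) == {1}

    def test_frequency_sums_match_row_counts(self):
        rng = np.random.default_rng(5)
        cats = ["gain", "consensus", "potential_loss"]
        rows = []
        seen = set()
        for _ in range(200):
            key = (
                f"S{rng.integers(4)}", f"T{rng.integers(4)}",
                f"L{rng.integers(10)}", f"R{rng.integers(10)}",
                cats[rng.integers(3)],
            )
            if key in seen:
                continue
            seen.add(key)
            rows.append(key)
        df = pd.DataFrame(
            rows, columns=["source", "target", "ligand", "receptor",
                           "category"]
        )
        freq = pair_frequencies(df)
        for cat in cats:
            assert (
                freq.loc[freq["category"] == cat, "frequency"].sum()
                == (df["category"] == cat).sum()
            )


class TestTopKPairs:
    def _freqs(self):
        rows = [
            (f"L{i:02d}", f"R{i:02d}", "", "gain", 30 - i) for i in range(30)
        ]
        return pd.DataFrame(
            rows,
            columns=["ligand", "receptor", "stage_interval", "category",
                     "frequency"],
        )

    def test_exactly_k_largest_kept(self):
        top = top_k_pairs(self._freqs(), 20)
        assert len(top) == 20
        assert top["frequency"].min() == 11

    def test_ties_break_lexicographically(self):
        rows = [
            ("LB", "RB", "", "gain", 5),
            ("LA", "RA", "", "gain", 5),
            ("LC", "RC", "", "gain", 9),
        ]
        freqs = pd.DataFrame(
            rows,
            columns=["ligand", "receptor", "stage_interval", "category",
                     "frequency"],
        )
        top = top_k_pairs(freqs, 2)
        assert list(top["ligand"]) == ["LC", "LA"]

    def test_fewer_records_than_k_all_returned(self):
        top = top_k_pairs(self._freqs().head(5), 20)
        assert len(top) == 5

    def test_idempotent_and_order_invariant(self):
        freqs = self._freqs()
        top = top_k_pairs(freqs, 10)
        pd.testing.assert_frame_equal(top_k_pairs(top, 10), top)
        shuffled = freqs.sample(frac=1.0, random_state=1).reset_index(
            drop=True
        )
        pd.testing.assert_frame_equal(top_k_pairs(shuffled, 10), top)

    def test_across_category_selection_keeps_all_labels_of_top_pairs(self):
        rows = [
            ("L1", "R1", "", "gain", 3),
            ("L1", "R1", "", "consensus", 2),
            ("L2", "R2", "", "gain", 1),
        ]
        freqs = pd.DataFrame(
            rows,
            columns=["ligand", "receptor", "stage_interval", "category",
                     "frequency"],
        )
        top = top_pairs_across_categories(freqs, 1)
        assert set(top["category"]) == {"gain", "consensus"}
        assert set(top["ligand"]) == {"L1"}


class TestDecomposeMolecules:
    def _pairs(self, rows):
        return pd.DataFrame(
            rows,
            columns=["ligand", "receptor", "stage_interval", "category",
                     "frequency"],
        )

    def test_shared_receptor_counted_twice(self):
        top = self._pairs(
            [
                ("FBLN1", "ITGB1", "1m->3m", "gain", 2),
                ("COL1A1", "ITGB1", "1m->3m", "gain", 1),
            ]
        )
        mols = decompose_molecules(top)
        itgb1 = mols[mols["molecule"] == "ITGB1"]
        assert itgb1["occurrence_count"].iloc[0] == 2
        assert itgb1["n_as_receptor"].iloc[0] == 2

    def test_complex_split_into_subunits(self):
        top = self._pairs([("COL1A1", "ITGA1_ITGB1", "", "gain", 1)])
        mols = decompose_molecules(top, split_complexes=True)
        assert {"ITGA1", "ITGB1"} <= set(mols["molecule"])
        unsplit = decompose_molecules(top, split_complexes=False)
        assert "ITGA1_ITGB1" in set(unsplit["molecule"])

    def test_mass_conservation_without_complexes(self):
        rng = np.random.default_rng(9)
        rows = [
            (f"L{i}", f"R{rng.integers(5)}", "", "gain", 1) for i in range(15)
        ]
        top = self._pairs(rows)
        mols = decompose_molecules(top)
        assert mols["occurrence_count"].sum() == 2 * len(top)

    def test_empty_input_empty_output(self):
        assert len(decompose_molecules(self._pairs([]))) == 0


class TestBuildShortlist:
    def test_categories_scored_from_their_own_state(self):
        ref = pd.DataFrame(
            [
                ("A", "B", "L1", "R1", 1.0, 0.01, 0.01, "s1"),
                ("A", "B", "L2", "R2", 9.0, 0.01, 0.01, "s1"),
            ],
            columns=["source", "target", "ligand", "receptor", "lr_mean",
                     "pval_cellphone", "pval_cellchat", "state"],
        )
        cmp = pd.DataFrame(
            [
                ("A", "B", "L1", "R1", 2.0, 0.01, 0.01, "s2"),
                ("A", "B", "L3", "R3", 7.0, 0.01, 0.01, "s2"),
            ],
            columns=["source", "target", "ligand", "receptor", "lr_mean",
                     "pval_cellphone", "pval_cellchat", "state"],
        )
        classification = pd.DataFrame(
            [
                ("A", "B", "L1", "R1", "consensus"),
                ("A", "B", "L3", "R3", "gain"),
                ("A", "B", "L2", "R2", "potential_loss"),
            ],
            columns=["source", "target", "ligand", "receptor", "category"],
        )
        out = build_shortlist(classification, ref, cmp)
        gain = out[out["category"] == "gain"]
        assert gain["score"].iloc[0] == 7.0  # comparator lr_mean
        loss = out[out["category"] == "potential_loss"]
        assert loss["score"].iloc[0] == 9.0  # reference lr_mean

    def test_empty_classification_gives_empty_tables(self):
        empty_cls = pd.DataFrame(
            columns=["source", "target", "ligand", "receptor", "category"]
        )
        empty_state = pd.DataFrame(
            columns=["source", "target", "ligand", "receptor", "lr_mean",
                     "pval_cellphone", "pval_cellchat", "state"],
        )
        out = build_shortlist(empty_cls, empty_state, empty_state)
        assert len(out) == 0
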