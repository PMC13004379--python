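"""Expected-influence centralities, z-scoring, filtering, top edges."""

import numpy as np
import pytest

from clpnkit import (AlignmentError, EdgeMatrix, bridge_ei, centrality_table,
                     filter_edges, in_ei, out_ei, strongest_edges, zscore)


@pytest.fixture
def toy_bridge():
    # A alone in community 1; B, C in community 2; single edge A->B, OR 1.5
    w = np.ones((3, 3))
    w[0, 1] = 1.5
    matrix = EdgeMatrix(list("ABC"), list("ABC"), w)
    partition = {"A": "one", "B": "two", "C": "two"}
    return matrix, partition


class TestFixtureRankings:
    def test_out_ei_extremes(self, fixture_matrix):
        v = out_ei(fixture_matrix)
        assert v.idxmax() == "COGS5" and v.idxmin() == "PHYS15"

    def test_in_ei_extremes(self, fixture_matrix):
        v = in_ei(fixture_matrix)
        assert v.idxmax() == "PHYS6" and v.idxmin() == "PHYS9"

    def test_bridge_ei_maximum(self, fixture_matrix, partition):
        assert bridge_ei(fixture_matrix, partition).idxmax() == "COGS5"

    def test_rankings_agree_across_scales(self, fixture_matrix, partition):
        # ln(OR) and OR-1 are both monotone near 1, but the printed 2-decimal
        # weights produce near-ties that the two transforms may order
        # oppositely (by at most one print unit). The substantive property:
        # any pair ordered oppositely is a near-tie on both scales, and the
        # extremes coincide.
        def reversals_are_near_ties(a, b, tol=0.011):
            av, bv = a.to_numpy()[:, None], b.to_numpy()[:, None]
            reversed_pairs = np.sign(av - av.T) * np.sign(bv - bv.T) < 0
            close = (np.abs(av - av.T) < tol) & (np.abs(bv - bv.T) < tol)
            assert not np.any(reversed_pairs & ~close)
            assert a.idxmax() == b.idxmax() and a.idxmin() == b.idxmin()

        for fn in (out_ei, in_ei):
            reversals_are_near_ties(fn(fixture_matrix, "log_odds"),
                                    fn(fixture_matrix, "or_minus_one"))
        reversals_are_near_ties(
            bridge_ei(fixture_matrix, partition, "log_odds"),
            bridge_ei(fixture_matrix, partition, "or_minus_one"))

    def test_psys7_has_no_in_ei_on_printed_matrix(self, fixture_matrix, partition):
        table = centrality_table(fixture_matrix, partition)
        assert np.isnan(table.loc["PSYS7", "in_ei"])
        assert not np.isnan(table.loc["PSYS7", "out_ei"])


class TestEIDefinitions:
    def test_empty_network_gives_zero(self):
        m = EdgeMatrix(list("AB"), list("AB"), np.ones((2, 2)))
        assert (out_ei(m) == 0).all() and (in_ei(m) == 0).all()

    def test_in_ei_is_out_ei_of_transpose(self, fixture_matrix):
        sub = fixture_matrix.to_dataframe().loc[
            fixture_matrix.col_nodes, fixture_matrix.col_nodes]
        m = EdgeMatrix(list(sub.index), list(sub.columns), sub.to_numpy())
        mt = EdgeMatrix(list(sub.columns), list(sub.index), sub.to_numpy().T)
        np.testing.assert_allclose(in_ei(m).to_numpy(), out_ei(mt).to_numpy(),
                                   atol=1e-12)

    def test_total_out_mass_equals_total_in_mass(self, fixture_matrix):
        sub = fixture_matrix.to_dataframe().loc[
            fixture_matrix.col_nodes, fixture_matrix.col_nodes]
        m = EdgeMatrix(list(sub.index), list(sub.columns), sub.to_numpy())
        assert out_ei(m).sum() == pytest.approx(in_ei(m).sum())

    def test_toy_bridge_hand_computation(self, toy_bridge):
        matrix, partition = toy_bridge
        v = bridge_ei(matrix, partition)
        assert v["A"] == pytest.approx(np.log(1.5))
        assert v["B"] == pytest.approx(np.log(1.5))
        assert v["C"] == 0

    def test_within_community_edges_do_not_bridge(self, toy_bridge):
        matrix, partition = toy_bridge
        matrix.weights[1, 2] = 1.8   # B->C stays inside community two
        v = bridge_ei(matrix, partition)
        assert v["C"] == 0 and v["B"] == pytest.approx(np.log(1.5))

    def test_node_without_community_rejected(self, toy_bridge):
        matrix, _ = toy_bridge
        with pytest.raises(AlignmentError, match="C"):
            bridge_ei(matrix, {"A": "one", "B": "two"})

    def test_bridge_bounded_by_out_plus_in(self, fixture_matrix, partition):
        # guaranteed when all transformed weights are non-negative
        m = fixture_matrix.copy()
        m.weights = np.maximum(m.weights, 1.0)
        b = bridge_ei(m, partition)
        o = out_ei(m).reindex(b.index, fill_value=0)
        i = in_ei(m).reindex(b.index, fill_value=0)
        assert (b <= o + i + 1e-12).all()

    def test_negative_edges_count_against_influence(self):
        w = np.ones((2, 2))
        w[0, 1] = 0.8
        m = EdgeMatrix(list("AB"), list("AB"), w)
        assert out_ei(m)["A"] < 0


class TestZScore:
    def test_two_values_give_unit_scores(self):
        import pandas as pd
        table = pd.DataFrame({"out_ei": [0.0, 2.0]}, index=["A", "B"])
        z = zscore(table)
        assert z["out_ei"].tolist() == [-1.0, 1.0]

    def test_constant_column_warns_and_zeroes(self):
        import pandas as pd
        table = pd.DataFrame({"out_ei": [1.0, 1.0, 1.0]}, index=list("ABC"))
        with pytest.warns(UserWarning):
            z = zscore(table)
        assert (z["out_ei"] == 0).all()

    def test_rank_preserved_on_fixture(self, fixture_matrix, partition):
        table = centrality_table(fixture_matrix, partition)
        z = zscore(table)
        assert z["out_ei"].idxmax() == "COGS5"


class TestFilterAndTopEdges:
    def test_threshold_above_all_printed_edges_empties_network(self, fixture_matrix):
        filtered = filter_edges(fixture_matrix, 1.35)
        assert (filtered.weights == 1).all()

    def test_threshold_one_keeps_all_positive_edges(self, fixture_matrix):
        filtered = filter_edges(fixture_matrix, 1.0)
        off = ~fixture_matrix.autoregressive_mask()
        kept = filtered.weights[off] != 1
        original = fixture_matrix.weights[off] != 1
        assert kept.sum() == original.sum()

    def test_intermediate_threshold_examples(self, fixture_matrix):
        filtered = filter_edges(fixture_matrix, 1.15, keep_negative_mirror=False)
        assert filtered.weight("COGS5", "COGS4") == 1.20
        assert filtered.weight("COGS2", "COGS3") == 1.0   # printed 1.11, dropped

    def test_filtering_is_monotone_in_threshold(self, fixture_matrix):
        loose = filter_edges(fixture_matrix, 1.05)
        tight = filter_edges(fixture_matrix, 1.12)
        kept_tight = tight.weights != 1
        kept_loose = loose.weights != 1
        assert (kept_loose | ~kept_tight).all()

    def test_strongest_edges_published_order(self, fixture_matrix):
        top = strongest_edges(fixture_matrix, 2)
        assert top[0] == ("COGS5", "COGS4", 1.20)
        assert top[1] == ("COGS5", "COGS2", 1.14)

    def test_strongest_edges_empty_network(self):
        m = EdgeMatrix(list("AB"), list("AB"), np.ones((2, 2)))
        assert strongest_edges(m, 3) == []

    def test_tie_break_by_codebook_order(self):
        w = np.ones((3, 3))
        w[0, 2] = 1.2
        w[2, 0] = 1.2
        m = EdgeMatrix(list("ABC"), list("ABC"), w)
        top = strongest_edges(m, 2)
        assert top == [("A", "C", 1.2), ("C", "A", 1.2)]
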