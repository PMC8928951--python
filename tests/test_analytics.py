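"""Comparative analytics: censuses, shared/cross-domain sets, canonical
induction and heat-map clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from fdxmotif import (
    CanonicalMotif,
    ClusterType,
    TYPE_ORDER,
    cross_domain_presence,
    group_count_matrix,
    heatmap,
    induce_canonical_motifs,
    parse_signature,
    shared_subtypes,
    summarize_counts,
)


class TestSummaries:
    def test_alphaproteobacteria_census(self, matrix):
        s = summarize_counts(matrix, "Alphaproteobacteria")
        assert s.grand_total == 1307
        assert s.per_type_totals == {
            "2Fe-2S": 490, "3Fe-4S": 60, "4Fe-4S": 2,
            "7Fe-8S": 12, "2[4Fe-4S]": 712, "2[4Fe-4S]Alv": 31,
        }
        assert s.per_type_subtype_counts["2Fe-2S"] == 29
        assert s.per_type_subtype_counts["3Fe-4S"] == 5
        assert s.per_type_subtype_counts["2[4Fe-4S]"] == 16
        assert s.per_type_subtype_counts["2[4Fe-4S]Alv"] == 8

    def test_firmicutes_census(self, matrix):
        s = summarize_counts(matrix, "Firmicutes")
        assert s.grand_total == 281
        assert s.per_type_totals == {
            "2Fe-2S": 97, "3Fe-4S": 0, "4Fe-4S": 140,
            "7Fe-8S": 32, "2[4Fe-4S]": 12, "2[4Fe-4S]Alv": 0,
        }
        assert s.per_type_subtype_counts["2Fe-2S"] == 11
        assert s.per_type_subtype_counts["7Fe-8S"] == 1

    def test_literature_column_totals(self, matrix):
        assert summarize_counts(matrix, "Archaea").grand_total == 538
        assert summarize_counts(matrix, "Eukarya").grand_total == 171

    def test_unknown_group_rejected(self, matrix):
        with pytest.raises(KeyError):
            summarize_counts(matrix, "Cyanobacteria")

    def test_empty_matrix_all_zero(self, matrix):
        empty = matrix.iloc[0:0]
        s = summarize_counts(empty, "Archaea")
        assert s.grand_total == 0
        assert set(s.per_type_totals.values()) == {0}


class TestSharedSubtypes:
    def test_2fe2s_alpha_firmicutes(self, matrix):
        shared = shared_subtypes(
            matrix, ClusterType.FE2S2, "Alphaproteobacteria", "Firmicutes"
        )
        assert shared == {2, 3, 4, 5, 6, 8, 9, 18}

    def test_4fe4s_none_shared(self, matrix):
        assert shared_subtypes(
            matrix, ClusterType.FE4S4, "Alphaproteobacteria", "Firmicutes"
        ) == set()

    def test_7fe8s_subtype1_shared(self, matrix):
        assert shared_subtypes(
            matrix, ClusterType.FE7S8, "Alphaproteobacteria", "Firmicutes"
        ) == {1}
        assert matrix.loc[("7Fe-8S", 1), "Firmicutes"] == 32

    def test_firmicutes_double_cluster_subtypes_all_in_alpha(self, matrix):
        shared = shared_subtypes(
            matrix, ClusterType.BIS_FE4S4, "Alphaproteobacteria", "Firmicutes"
        )
        firm = matrix.loc["2[4Fe-4S]"]["Firmicutes"]
        assert shared == set(firm.index[firm > 0])


class TestCrossDomain:
    def test_all_three_domain_sets(self, matrix):
        res = cross_domain_presence(matrix)
        assert res.all_domains.get("2Fe-2S") == {3, 9, 18}
        assert res.all_domains.get("2[4Fe-4S]") == {9, 12}
        assert "3Fe-4S" not in res.all_domains
        assert "4Fe-4S" not in res.all_domains

    def test_pairwise_exclusive_sets(self, matrix):
        res = cross_domain_presence(matrix)
        ae = res.pairwise_only[("Archaea", "Eukarya")]
        be = res.pairwise_only[("Bacteria", "Eukarya")]
        assert ae.get("2Fe-2S") == {24, 38}
        assert ae.get("4Fe-4S") == {9}
        assert be.get("7Fe-8S") == {6}
        assert be.get("2[4Fe-4S]") == {17}

    def test_unmapped_column_rejected(self, matrix):
        with pytest.raises(KeyError):
            cross_domain_presence(matrix, {"Archaea": "Archaea"})


EXPECTED_CANONICAL = {
    "2Fe-2S": ["CX3-5CX1-2CX22-82C", "CX2-12CX30-44CX3C", "CX4-7CX29-35C"],
    "3Fe-4S": ["CX5CX35-49CP"],
    "4Fe-4S": ["CX2-5CX2-3CX30-45CP"],
    "7Fe-8S": ["CX3-10CX3CPX17-40CX2CX2CX3CP"],
    # the published ranged motif prints CX1-2 at gap 5, but subtype 11's
    # signature (gap 5 = 3) sits outside it; induction over the full
    # inventory necessarily widens that bound to CX1-3
    "2[4Fe-4S]": ["CX2-7CX2-4CX2-3CX14-42CX1-3CX2-8CX3C"],
    "2[4Fe-4S]Alv": ["CX2CX2CX3CX18-46CX2CX2-8CX3CX3C"],
}


class TestCanonicalInduction:
    @pytest.mark.parametrize("ct", TYPE_ORDER, ids=lambda t: t.value)
    def test_induced_motifs_over_registry(self, registry, ct):
        recs = registry.records_for(ct)
        motifs = induce_canonical_motifs(
            [r.signature for r in recs], ct, [r.subtype_number for r in recs]
        )
        assert [m.to_string() for m in motifs] == EXPECTED_CANONICAL[ct.value]

    def test_containment_property(self, registry):
        """Every registered signature lies inside the induced motif of its class."""
        for ct in TYPE_ORDER:
            recs = registry.records_for(ct)
            motifs = induce_canonical_motifs([r.signature for r in recs], ct)
            for r in recs:
                assert any(m.admits(r.signature) for m in motifs)

    def test_member_bookkeeping(self, registry):
        recs = registry.records_for(ClusterType.FE2S2)
        motifs = induce_canonical_motifs(
            [r.signature for r in recs], ClusterType.FE2S2,
            [r.subtype_number for r in recs],
        )
        members = [set(m.member_subtypes) for m in motifs]
        assert members[2] == {14, 15, 16}  # the three 3-cysteine subtypes
        assert sorted(len(m) for m in members) == sorted([37, 15, 3])
        assert set().union(*members) == {r.subtype_number for r in recs}

    def test_single_signature_degenerate_ranges(self):
        sig = parse_signature("CX5CX38CP")
        (m,) = induce_canonical_motifs([sig], ClusterType.FE3S4)
        assert m.gap_ranges == ((5, 5), (38, 38))
        assert m.to_string() == "CX5CX38CP"

    def test_empty_input(self):
        assert induce_canonical_motifs([], ClusterType.FE2S2) == []

    def test_from_string_accepts_en_dash(self):
        m = CanonicalMotif.from_string("CX_3–5_CX_1–2_CX_22–82_C", ClusterType.FE2S2)
        assert m.gap_ranges == ((3, 5), (1, 2), (22, 82))


class TestHeatmap:
    def test_encoding_is_plus_minus_three(self, matrix):
        res = heatmap(matrix)
        assert set(np.unique(res.encoded.values)) == {-3, 3}
        # encoding is 3 iff the domain-aggregated count is positive
        assert res.encoded.loc[("2Fe-2S", 1), "Bacteria"] == 3
        assert res.encoded.loc[("2Fe-2S", 1), "Archaea"] == -3

    def test_row_distance_arithmetic(self, matrix):
        res = heatmap(matrix)
        everywhere = res.encoded.loc[("2Fe-2S", 3)].values   # present in all 3
        bacteria_only = res.encoded.loc[("2Fe-2S", 5)].values
        d = np.sqrt(((everywhere - (-everywhere)) ** 2).sum())
        assert math.isclose(d, math.sqrt(108))
        assert (everywhere == 3).all()

    def test_leaf_orders_are_permutations(self, matrix):
        res = heatmap(matrix)
        assert sorted(res.row_order) == sorted(res.encoded.index)
        assert sorted(res.col_order) == sorted(res.encoded.columns)

    def test_single_row_trivial(self, matrix):
        res = heatmap(matrix.iloc[[0]])
        assert res.row_linkage is None
        assert res.row_order == (("2Fe-2S", 1),)
        nwk = res.to_newick("rows")
        assert nwk.endswith(";") and "2Fe-2S|1" in nwk

    def test_newick_contains_all_leaves(self, matrix):
        res = heatmap(matrix)
        nwk = res.to_newick("columns")
        for d in ("Archaea", "Bacteria", "Eukarya"):
            assert d in nwk

    def test_row_permutation_invariance(self, matrix):
        sub = matrix.iloc[:12]
        res = heatmap(sub)
        shuffled = sub.iloc[::-1]
        res2 = heatmap(shuffled)
        assert set(res.row_order) == set(res2.row_order)
        # cluster memberships at any cut are order-independent; compare
        # pairwise distances between identically-labelled rows
        d1 = pd.DataFrame(
            squareform(pdist(res.encoded.values)),
            index=res.encoded.index, columns=res.encoded.index,
        )
        d2 = pd.DataFrame(
            squareform(pdist(res2.encoded.values)),
            index=res2.encoded.index, columns=res2.encoded.index,
        )
        d2 = d2.loc[d1.index, d1.columns]
        assert np.allclose(d1.values, d2.values)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_pairwise_distances_symmetric_zero_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, size=(6, 3))
        df = pd.DataFrame(
            x,
            index=pd.MultiIndex.from_tuples(
                [("2Fe-2S", i + 1) for i in range(6)],
                names=["cluster_type", "subtype"],
            ),
            columns=["Archaea", "Bacteria_lit", "Eukarya"],
        )
        part = {"Archaea": "Archaea", "Bacteria_lit": "Bacteria", "Eukarya": "Eukarya"}
        res = heatmap(df, part)
        dm = squareform(pdist(res.encoded.values))
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0)
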