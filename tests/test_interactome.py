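"""Link-table parsing, network construction, and negative sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from dtifuse.interactome import (
    InteractionNetwork,
    LabeledPairSet,
    LinkFormatError,
    read_compound_table,
    read_fasta,
    read_links,
    read_positive_pairs,
    restrict_to_common_entities,
    sample_negatives,
    write_fasta,
    write_links,
)


class TestReadLinks:
    def test_threshold_retains_score_at_or_above(self, link_table_writer):
        path = link_table_writer(
            [("a", "b", 800), ("a", "c", 650), ("b", "c", 700)]
        )
        net = read_links(path, "experimental", 700)
        assert net.n_edges == 2
        assert net.weight("a", "b") == pytest.approx(0.8)
        assert net.weight("b", "c") == pytest.approx(0.7)

    def test_boundary_score_and_weight(self, link_table_writer):
        path = link_table_writer([("a", "b", 150), ("a", "c", 149)])
        net = read_links(path, "experimental", 150)
        assert net.n_edges == 1
        assert net.weight("a", "b") == pytest.approx(0.15)

    def test_missing_channel_is_format_error(self, link_table_writer):
        path = link_table_writer([("a", "b", 10)], channel="database")
        with pytest.raises(LinkFormatError, match="experimental"):
            read_links(path, "experimental", 0)

    def test_bad_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("a b experimental\nx y 100\nx z oops\n")
        with pytest.raises(LinkFormatError, match=":3"):
            read_links(p, "experimental", 0)

    def test_self_loops_dropped_and_duplicates_keep_max(
        self, link_table_writer
    ):
        path = link_table_writer(
            [("a", "a", 900), ("a", "b", 300), ("b", "a", 500)]
        )
        net = read_links(path, "experimental", 0)
        assert net.nodes == {"a", "b"}
        assert net.n_edges == 1
        assert net.weight("a", "b") == pytest.approx(0.5)

    @settings(max_examples=25, deadline=None, derandomize=True,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(
        scores=st.lists(st.integers(0, 1000), min_size=1, max_size=20),
        t1=st.integers(0, 1000),
        t2=st.integers(0, 1000),
    )
    def test_filtering_is_monotone(self, tmp_path, scores, t1, t2):
        lo, hi = sorted((t1, t2))
        rows = [(f"u{i}", f"v{i}", s) for i, s in enumerate(scores)]
        path = tmp_path / "mono.txt"
        with open(path, "w") as fh:
            fh.write("a b experimental\n")
            for u, v, s in rows:
                fh.write(f"{u}\t{v}\t{s}\n")
        low = {frozenset(e[:2]) for e in read_links(path, "experimental", lo).edges()}
        high = {frozenset(e[:2]) for e in read_links(path, "experimental", hi).edges()}
        assert high <= low

    def test_write_read_round_trip(self, tmp_path):
        rows = [("a", "b", 700), ("b", "c", 850), ("c", "d", 150)]
        write_links(tmp_path / "rt.txt", rows, "experimental")
        net = read_links(tmp_path / "rt.txt", "experimental", 150)
        assert {(u, v): w for u, v, w in net.edges()} == {
            ("a", "b"): 0.7,
            ("b", "c"): 0.85,
            ("c", "d"): 0.15,
        }


class TestReadPositivePairs:
    def test_duplicates_collapse(self, link_table_writer):
        path = link_table_writer(
            [("p1", "c1", 800), ("p1", "c1", 900), ("p2", "c1", 750),
             ("p3", "c2", 600)]
        )
        pairs = read_positive_pairs(path, "experimental", 700)
        assert len(pairs) == 2
        assert set(pairs.frame["label"]) == {1}

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("protein chemical experimental\n")
        assert len(read_positive_pairs(p, "experimental", 700)) == 0

    def test_threshold_zero_keeps_all(self, link_table_writer):
        path = link_table_writer([("p1", "c1", 0), ("p2", "c2", 5)])
        assert len(read_positive_pairs(path, "experimental", 0)) == 2


class TestSampleNegatives:
    def test_one_to_two_ratio(self):
        pos = LabeledPairSet.from_records([("p1", "c1", 1), ("p2", "c2", 1)])
        out = sample_negatives(pos, ["p1", "p2", "p3"], ["c1", "c2", "c3"],
                               ratio=2.0, seed=1)
        frame = out.frame
        assert (frame["label"] == 0).sum() == 4
        assert (frame["label"] == 1).sum() == 2
        neg = set(map(tuple, frame[frame["label"] == 0][
            ["protein_id", "compound_id"]].to_numpy()))
        assert neg.isdisjoint(pos.pair_index)

    def test_infeasible_request_errors_with_max(self):
        pos = LabeledPairSet.from_records([("p1", "c1", 1), ("p1", "c2", 1)])
        with pytest.raises(ValueError, match="only 2"):
            sample_negatives(pos, ["p1"], ["c1", "c2", "c3", "c4"], ratio=2.0)

    def test_seed_reproducibility(self):
        pos = LabeledPairSet.from_records([(f"p{i}", f"c{i}", 1)
                                           for i in range(5)])
        prots = [f"p{i}" for i in range(10)]
        comps = [f"c{i}" for i in range(10)]
        a = sample_negatives(pos, prots, comps, seed=42).frame
        b = sample_negatives(pos, prots, comps, seed=42).frame
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("n_pos,ratio", [(3, 1.0), (4, 2.0), (5, 0.5)])
    def test_exact_count_when_feasible(self, n_pos, ratio):
        pos = LabeledPairSet.from_records([(f"p{i}", f"c{i}", 1)
                                           for i in range(n_pos)])
        prots = [f"p{i}" for i in range(8)]
        comps = [f"c{i}" for i in range(8)]
        out = sample_negatives(pos, prots, comps, ratio=ratio, seed=0)
        # round-half-up convention
        assert (out.frame["label"] == 0).sum() == int(
            np.floor(ratio * n_pos + 0.5)
        )


class TestRestrict:
    def _nets(self, prot_edges, comp_edges):
        ppi, cci = InteractionNetwork(), InteractionNetwork()
        for u, v in prot_edges:
            ppi.add_edge(u, v, 0.5)
        for u, v in comp_edges:
            cci.add_edge(u, v, 0.5)
        return ppi, cci

    def test_pair_missing_cci_node_dropped(self):
        pairs = LabeledPairSet.from_records([("p1", "c1", 1), ("p1", "c9", 1)])
        ppi, cci = self._nets([("p1", "p2")], [("c1", "c2")])
        rep = restrict_to_common_entities(
            pairs, ppi, cci, {"p1": "ACD"}, {"c1": "CCO", "c9": "CCN"}
        )
        assert len(rep.pairs) == 1
        assert rep.n_dropped_compound == 1

    def test_identity_when_all_present(self):
        pairs = LabeledPairSet.from_records([("p1", "c1", 1), ("p2", "c2", 0)])
        ppi, cci = self._nets([("p1", "p2")], [("c1", "c2")])
        rep = restrict_to_common_entities(
            pairs, ppi, cci,
            {"p1": "ACD", "p2": "ACD"}, {"c1": "CCO", "c2": "CCN"},
        )
        assert len(rep.pairs) == 2
        assert rep.n_dropped_protein == rep.n_dropped_compound == 0

    def test_empty_networks_empty_result(self):
        pairs = LabeledPairSet.from_records([("p1", "c1", 1)])
        rep = restrict_to_common_entities(
            pairs, InteractionNetwork(), InteractionNetwork(), {}, {}
        )
        assert len(rep.pairs) == 0


class TestMolecularIO:
    def test_fasta_round_trip(self, tmp_path):
        seqs = {"p1": "ACDEFGHIKLMNPQRSTVWY" * 4, "p2": "MKV"}
        write_fasta(tmp_path / "s.fasta", seqs)
        assert read_fasta(tmp_path / "s.fasta") == seqs

    def test_compound_table(self, tmp_path):
        (tmp_path / "c.tsv").write_text("compound_id\tsmiles\nc1\tCCO\n")
        assert read_compound_table(tmp_path / "c.tsv") == {"c1": "CCO"}


def test_labeled_pair_set_rejects_duplicates_and_bad_labels():
    with pytest.raises(ValueError, match="duplicate"):
        LabeledPairSet.from_records([("p", "c", 1), ("p", "c", 0)])
    with pytest.raises(ValueError, match="binary"):
        LabeledPairSet.from_records([("p", "c", 2)])
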