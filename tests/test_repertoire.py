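"""CDR3 filtering, clone selection, clustering and repertoire readers."""

import numpy as np
import pytest

from deepcatcr.repertoire import (CloneRecord, Repertoire,
                                  RepertoireFormatError, cluster_cdr3s,
                                  clustered_subset, filter_cdr3s,
                                  filter_repertoire, read_cluster_file,
                                  read_repertoire, select_expanded_clones,
                                  select_top_clones, write_repertoire)
from deepcatcr.simulate import FixtureSpec, generate_cdr3


class TestFilterCdr3s:
    def test_each_rejection_reason_assigned_once(self):
        seqs = ["CASSLGQAYEQYF",   # retained
                "ASSLGQAYEQYF",    # incomplete (no leading C)
                "CASS*GQAYEQYF",   # non-productive
                "CASF"]            # length (complete, productive, too short)
        kept, report = filter_cdr3s(seqs)
        assert kept == ["CASSLGQAYEQYF"]
        assert report.n_input == 4
        assert report.n_rejected_incomplete == 1
        assert report.n_rejected_nonproductive == 1
        assert report.n_rejected_length == 1
        assert report.n_rejected_public == 0
        assert report.n_retained == 1

    def test_empty_input_gives_zeroed_report(self):
        kept, report = filter_cdr3s([])
        assert kept == []
        assert report.n_input == report.n_retained == 0

    def test_public_sequences_rejected_after_other_rules(self):
        rng = np.random.default_rng(0)
        spec = FixtureSpec(seed=0)
        seqs = [generate_cdr3(spec, rng) for _ in range(50)]
        public = set(seqs[:10])
        kept, report = filter_cdr3s(seqs, public_set=public)
        assert report.n_rejected_public == 10
        assert report.n_retained == 40
        assert not public & set(kept)

    def test_order_preserved(self):
        seqs = ["CDDDDDDDDDDF", "CAAAAAAAAAAF", "CBBBBBBBBBBF"]
        kept, _ = filter_cdr3s(seqs)
        assert kept == ["CDDDDDDDDDDF", "CAAAAAAAAAAF"]

    def test_oracle_counts_on_mixed_fixture(self):
        """Rule-by-rule hand application on a generated 1,000-sequence mix."""
        rng = np.random.default_rng(42)
        spec = FixtureSpec(seed=42)
        good: list[str] = []
        while len(good) < 700:
            s = generate_cdr3(spec, rng)
            if s not in good:
                good.append(s)
        incomplete = ["A" + generate_cdr3(spec, rng)[1:]
                      for _ in range(100)]
        nonproductive = [s[:5] + "*" + s[6:] for s in
                         (generate_cdr3(spec, rng) for _ in range(80))]
        short = ["C" + "A" * 7 + "F"] * 70
        public = good[:50]
        seqs = good + incomplete + nonproductive + short
        kept, report = filter_cdr3s(seqs, public_set=set(public))
        assert report.n_input == 950
        assert report.n_rejected_incomplete == 100
        assert report.n_rejected_nonproductive == 80
        assert report.n_rejected_length == 70
        assert report.n_rejected_public == 50
        assert report.n_retained == 650
        assert len(kept) == 650


class TestCloneSelection:
    def make_rep(self, counts):
        clones = [CloneRecord(f"CASS{chr(65 + i)}GQAYEQYF", c)
                  for i, c in enumerate(counts)]
        return Repertoire("s1", clones)

    def test_expanded_threshold_is_fold_times_minimum(self):
        rep = self.make_rep([1, 2, 4, 5])
        out = select_expanded_clones(rep, fold=4)
        assert sorted(c.count for c in out.clones) == [4, 5]

    def test_all_equal_counts_yield_empty(self):
        rep = self.make_rep([3, 3, 3])
        assert len(select_expanded_clones(rep, fold=4)) == 0

    def test_singleton_below_fold_is_dropped(self):
        rep = self.make_rep([10])
        assert len(select_expanded_clones(rep, fold=4)) == 0

    def test_fold_one_returns_everything(self):
        rep = self.make_rep([1, 7, 3])
        assert len(select_expanded_clones(rep, fold=1)) == 3

    def test_empty_repertoire_passes_through(self):
        assert len(select_expanded_clones(Repertoire("x", []))) == 0

    def test_top_n_more_than_available_keeps_all(self):
        rep = self.make_rep([5, 1, 3])
        assert len(select_top_clones(rep, 10_000)) == 3

    def test_top_n_ties_broken_lexicographically(self):
        rep = Repertoire("s", [CloneRecord("CBBBBBBBBBBF", 5),
                               CloneRecord("CAAAAAAAAAAF", 5),
                               CloneRecord("CCCCCCCCCCCF", 3)])
        out = select_top_clones(rep, 2)
        assert [c.cdr3_aa for c in out.clones] == ["CAAAAAAAAAAF",
                                                   "CBBBBBBBBBBF"]

    def test_top_n_matches_full_sort_oracle(self):
        rng = np.random.default_rng(1)
        spec = FixtureSpec(seed=1)
        clones = [CloneRecord(generate_cdr3(spec, rng),
                              float(rng.integers(1, 1000)))
                  for _ in range(2000)]
        rep = Repertoire("big", clones)
        out = select_top_clones(rep, 1000)
        oracle = sorted(clones, key=lambda c: (-c.count, c.cdr3_aa))[:1000]
        assert sorted((c.cdr3_aa, c.count) for c in out.clones) == sorted(
            (c.cdr3_aa, c.count) for c in oracle)


class TestClustering:
    def test_one_central_mismatch_clusters_equal_lengths(self):
        seqs = ["CASSLGQAYEQYF", "CASSLGQSYEQYF", "CASRWDTEAGFGF"]
        clusters = cluster_cdr3s(seqs, max_mismatch=1)
        assert clusters == [["CASSLGQAYEQYF", "CASSLGQSYEQYF"]]

    def test_identical_duplicates_form_one_cluster(self):
        seqs = ["CASSLGQAYEQYF"] * 4
        clusters = cluster_cdr3s(seqs)
        assert len(clusters) == 1 and len(clusters[0]) == 4

    def test_distinct_lengths_never_cluster(self):
        seqs = ["CASSLGQAYEQYF", "CASSLGQAYEQYYF", "CASSLGQAYEQYYYF"]
        assert cluster_cdr3s(seqs) == []

    def test_pairwise_hamming_oracle_on_random_set(self):
        rng = np.random.default_rng(3)
        spec = FixtureSpec(seed=3)
        seqs = list({generate_cdr3(spec, rng) for _ in range(60)})
        clusters = cluster_cdr3s(seqs, max_mismatch=1)
        # oracle: brute-force transitive closure of the closeness relation
        def close(a, b):
            return len(a) == len(b) and sum(
                a[i] != b[i] for i in range(3, len(a) - 3)) <= 1
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(seqs)
        g.add_edges_from((a, b) for i, a in enumerate(seqs)
                         for b in seqs[i + 1:] if close(a, b))
        oracle = sorted(sorted(c) for c in nx.connected_components(g)
                        if len(c) > 1)
        assert sorted(sorted(c) for c in clusters) == oracle

    def test_singletons_kept_when_requested(self):
        seqs = ["CASSLGQAYEQYF", "CARRWDTEAGFGF"]
        clusters = cluster_cdr3s(seqs, drop_singletons=False)
        assert sorted(len(c) for c in clusters) in ([1, 1], [2])


class TestPipelineInvariants:
    def test_filter_top_cluster_composition_idempotent(self):
        rng = np.random.default_rng(5)
        spec = FixtureSpec(seed=5)
        base = [generate_cdr3(spec, rng) for _ in range(300)]
        # duplicate a few to guarantee non-empty clusters
        seqs = base + base[:30]
        def chain(ss):
            kept, _ = filter_cdr3s(ss)
            rep = Repertoire("x", [CloneRecord(s) for s in kept])
            top = select_top_clones(rep, 200)
            return clustered_subset(sorted(set(top.sequences)))
        once = chain(seqs)
        assert chain(once) == sorted(once) or chain(once) == once

    def test_clustered_subset_nested_in_top_nested_in_filtered(self):
        rng = np.random.default_rng(6)
        spec = FixtureSpec(seed=6)
        seqs = [generate_cdr3(spec, rng) for _ in range(200)] * 2
        kept, _ = filter_cdr3s(seqs)
        rep = Repertoire("x", [CloneRecord(s) for s in kept])
        top = select_top_clones(rep, 150)
        clustered = clustered_subset(top.sequences)
        assert set(clustered) <= set(top.sequences) <= set(kept)


class TestReaders:
    def test_airr_rows_aggregate_duplicate_junctions(self, tmp_path):
        p = tmp_path / "donor.tsv"
        p.write_text("junction_aa\tduplicate_count\n"
                     "CASSLGQAYEQYF\t5\nCASSLGQAYEQYF\t2\nCASSWDTEAYEQF\t1\n")
        rep = read_repertoire(p, format="airr")
        assert len(rep) == 2
        by_seq = {c.cdr3_aa: c.count for c in rep.clones}
        assert by_seq["CASSLGQAYEQYF"] == 7.0
        assert by_seq["CASSWDTEAYEQF"] == 1.0

    def test_plain_lines_default_count_one(self, tmp_path):
        p = tmp_path / "donor.txt"
        p.write_text("".join(f"CASS{c}GQAYEQYF\n" for c in "ADEGH"))
        rep = read_repertoire(p, format="plain")
        assert len(rep) == 5
        assert all(c.count == 1.0 for c in rep.clones)

    def test_immunoseq_missing_aminoacid_column_raises(self, tmp_path):
        p = tmp_path / "donor.tsv"
        p.write_text("sequence\tcount (templates/reads)\nCASSF\t3\n")
        with pytest.raises(RepertoireFormatError, match="aminoAcid"):
            read_repertoire(p, format="immunoseq")

    def test_airr_missing_junction_column_raises(self, tmp_path):
        p = tmp_path / "donor.tsv"
        p.write_text("cdr3\tduplicate_count\nCASSF\t3\n")
        with pytest.raises(RepertoireFormatError, match="junction_aa"):
            read_repertoire(p, format="airr")

    def test_unparseable_count_names_line(self, tmp_path):
        p = tmp_path / "donor.tsv"
        p.write_text("junction_aa\tduplicate_count\n"
                     "CASSLGQAYEQYF\t5\nCASSWDTEAYEQF\toops\n")
        with pytest.raises(RepertoireFormatError, match="line 3"):
            read_repertoire(p, format="airr")

    def test_airr_roundtrip(self, tmp_path):
        rep = Repertoire("d1", [CloneRecord("CASSLGQAYEQYF", 5.0),
                                CloneRecord("CASSWDTEAYEQF", 2.0)])
        p = tmp_path / "d1.tsv"
        write_repertoire(rep, p, format="airr")
        back = read_repertoire(p, format="airr")
        assert [(c.cdr3_aa, c.count) for c in back.clones] == [
            (c.cdr3_aa, c.count) for c in rep.clones]

    def test_cluster_exchange_file(self, tmp_path):
        p = tmp_path / "clusters.tsv"
        p.write_text("cluster_id\tcdr3_aa\n1\tCASSLGQAYEQYF\n1\tCASSLGQSYEQYF\n"
                     "2\tCARRWDTEAGFGF\n")
        clusters = read_cluster_file(p)
        assert clusters == [["CASSLGQAYEQYF", "CASSLGQSYEQYF"],
                            ["CARRWDTEAGFGF"]]

    def test_filter_repertoire_keeps_counts(self):
        rep = Repertoire("d", [CloneRecord("CASSLGQAYEQYF", 9.0),
                               CloneRecord("BADSEQ", 1.0)])
        out, report = filter_repertoire(rep)
        assert [(c.cdr3_aa, c.count) for c in out.clones] == [
            ("CASSLGQAYEQYF", 9.0)]
        assert report.n_rejected_incomplete == 1
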