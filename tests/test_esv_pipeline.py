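"""The per-marker ESV filtering cascade, LCA assignment and MOTU clustering."""

import numpy as np
import pytest

from dietmerge import (
    ExclusionPolicy,
    HitTable,
    MarkerConfig,
    ProvenanceLog,
    STUDY_MARKERS,
    TaxonLabel,
    assign_lca,
    cluster_motus,
    denoise_one_off,
    drop_failed_pcrs,
    exclude_taxa,
    filter_length,
    relative_abundance_filter,
    run_marker_pipeline,
    sequence_identity,
    to_detections,
)
from dietmerge.simulate import ESVFixtureSpec, generate_esv_fixture

from conftest import det, lin, make_table

CFG = MarkerConfig("M", min_len=90, max_len=110)


class TestLengthFilter:
    @pytest.mark.parametrize(
        "length,window,kept",
        [
            (120, (94, 153), True),   # 18S mid-window
            (94, (94, 153), True),    # closed interval at min
            (153, (94, 153), True),   # closed interval at max
            (150, (155, 159), False), # too short for ZBJ
            (93, (94, 153), False),
        ],
    )
    def test_closed_window(self, length, window, kept):
        cfg = MarkerConfig("M", *window)
        table = make_table("M", {"e": "A" * length}, {"e": {"p1": 10}})
        out = filter_length(table, cfg)
        assert ("e" in out.esv_ids) is kept

    def test_counts_untouched_for_survivors(self):
        table = make_table(
            "M", {"a": "A" * 100, "b": "A" * 10},
            {"a": {"p1": 7, "p2": 3}, "b": {"p1": 5}},
        )
        out = filter_length(table, CFG)
        assert out.esv_ids == ["a"]
        assert out.counts.loc["a"].tolist() == [7, 3]


class TestDenoise:
    parent = "ACGT" * 25  # 100 bp

    def child(self, pos=0):
        alt = "C" if self.parent[pos] != "C" else "G"
        return self.parent[:pos] + alt + self.parent[pos + 1:]

    def test_one_off_cooccurring_child_removed(self):
        table = make_table(
            "M", {"B": self.parent, "A": self.child()},
            {"B": {"p1": 60, "p2": 40}, "A": {"p1": 3, "p2": 2}},
        )
        out = denoise_one_off(table)
        assert out.esv_ids == ["B"]

    def test_distant_esvs_both_retained(self):
        far = "TTTT" + self.parent[4:]
        table = make_table(
            "M", {"B": self.parent, "A": far},
            {"B": {"p1": 100}, "A": {"p1": 5}},
        )
        assert set(denoise_one_off(table).esv_ids) == {"A", "B"}

    def test_child_occurring_alone_is_retained(self):
        # A present in p3 without B: co-occurrence clause fails
        table = make_table(
            "M", {"B": self.parent, "A": self.child()},
            {"B": {"p1": 100}, "A": {"p1": 5, "p3": 2}},
        )
        assert set(denoise_one_off(table).esv_ids) == {"A", "B"}

    def test_single_indel_counts_as_one_edit(self):
        shorter = self.parent[1:]
        table = make_table(
            "M", {"B": self.parent, "A": shorter},
            {"B": {"p1": 100}, "A": {"p1": 5}},
        )
        assert denoise_one_off(table).esv_ids == ["B"]

    def test_no_cascade_and_top_esv_never_removed(self):
        # chain: top (100) <- mid (50) <- leaf (10); mid is removed by top,
        # leaf is one edit from mid only. Single-pass: leaf judged against
        # the ORIGINAL table, where mid still exists, so leaf is removed
        # too — but by mid's original counts, not by a cascade artifact.
        mid = self.child(0)
        leaf = self.child(0)[:50] + ("A" if mid[50] != "A" else "T") + mid[51:]
        table = make_table(
            "M", {"top": self.parent, "mid": mid, "leaf": leaf},
            {"top": {"p1": 100}, "mid": {"p1": 50}, "leaf": {"p1": 10}},
        )
        out = denoise_one_off(table)
        assert "top" in out.esv_ids
        assert out.totals().idxmax() == "top"

    def test_equal_counts_not_removed(self):
        table = make_table(
            "M", {"B": self.parent, "A": self.child()},
            {"B": {"p1": 50}, "A": {"p1": 50}},
        )
        assert set(denoise_one_off(table).esv_ids) == {"A", "B"}

    def test_idempotent(self):
        table = make_table(
            "M", {"B": self.parent, "A": self.child()},
            {"B": {"p1": 60}, "A": {"p1": 3}},
        )
        once = denoise_one_off(table)
        twice = denoise_one_off(once)
        assert once.esv_ids == twice.esv_ids


class TestPcrFailure:
    def test_under_100_dropped_exactly_100_kept(self):
        table = make_table(
            "M", {"e": "A" * 100, "f": "C" * 100},
            {"e": {"p1": 99, "p2": 60}, "f": {"p2": 40}},
        )
        out = drop_failed_pcrs(table, CFG)
        assert list(out.counts.columns) == ["p2"]

    def test_exactly_threshold_kept(self):
        table = make_table("M", {"e": "A" * 100}, {"e": {"p1": 100}})
        out = drop_failed_pcrs(table, CFG)
        assert list(out.counts.columns) == ["p1"]

    def test_empty_table_passthrough(self):
        table = make_table("M", {}, {})
        out = drop_failed_pcrs(table, CFG)
        assert out.esv_ids == []

    def test_failure_logged(self):
        log = ProvenanceLog()
        table = make_table("M", {"e": "A" * 100}, {"e": {"p1": 50}})
        drop_failed_pcrs(table, CFG, log)
        frame = log.to_frame()
        assert list(frame.stage) == ["pcr_failure"]
        assert list(frame.record_id) == ["p1"]


class TestRelativeAbundance:
    def test_sub_one_percent_zeroed(self):
        table = make_table(
            "M", {"big": "A" * 100, "small": "C" * 100},
            {"big": {"p1": 9901}, "small": {"p1": 99}},
        )
        out = relative_abundance_filter(table, CFG)
        assert out.esv_ids == ["big"]

    def test_exactly_one_percent_kept(self):
        table = make_table(
            "M", {"big": "A" * 100, "small": "C" * 100},
            {"big": {"p1": 9900}, "small": {"p1": 100}},
        )
        out = relative_abundance_filter(table, CFG)
        assert set(out.esv_ids) == {"big", "small"}

    def test_single_esv_pcr_always_kept(self):
        table = make_table("M", {"e": "A" * 100}, {"e": {"p1": 7}})
        out = relative_abundance_filter(table, CFG)
        assert out.esv_ids == ["e"]

    def test_per_pcr_decision(self):
        # small passes in p2 (20%), fails in p1 (<1%)
        table = make_table(
            "M", {"big": "A" * 100, "small": "C" * 100},
            {"big": {"p1": 9950, "p2": 80}, "small": {"p1": 50, "p2": 20}},
        )
        out = relative_abundance_filter(table, CFG)
        assert out.counts.loc["small", "p1"] == 0
        assert out.counts.loc["small", "p2"] == 20


class TestAssignLca:
    def _hits(self, rows):
        return HitTable(rows=tuple(rows))

    def test_two_species_same_family_at_similar_identity(self):
        sp1 = lin("Animalia;Arthropoda;Insecta;Coleoptera;Carabidae;GenA;sp1")
        sp2 = lin("Animalia;Arthropoda;Insecta;Coleoptera;Carabidae;GenB;sp2")
        assigned, un = assign_lca(self._hits([("e", sp1, 99.0), ("e", sp2, 99.0)]))
        assert not un
        assert assigned["e"].deepest_rank == "family"
        assert assigned["e"].deepest_name == "Carabidae"

    def test_single_hit_full_lineage(self):
        sp = lin("Animalia;Arthropoda;Insecta;Coleoptera;Carabidae;GenA;sp1")
        assigned, _ = assign_lca(self._hits([("e", sp, 100.0)]))
        assert assigned["e"] == sp

    def test_tolerance_window_excludes_weak_hits(self):
        sp1 = lin("Animalia;Arthropoda;Insecta;Coleoptera;Carabidae;GenA;sp1")
        other = lin("Plantae;Tracheophyta;Magnoliopsida;Vitales")
        assigned, _ = assign_lca(
            self._hits([("e", sp1, 99.0), ("e", other, 90.0)]), tolerance=1.0
        )
        assert assigned["e"] == sp1

    def test_kingdom_disagreement_flagged(self):
        a = lin("Animalia;Arthropoda;Insecta;Coleoptera")
        p = lin("Plantae;Tracheophyta;Magnoliopsida;Vitales")
        assigned, un = assign_lca(self._hits([("e", a, 99.0), ("e", p, 99.0)]))
        assert un == ["e"] and not assigned


class TestMotuClustering:
    FAM = "Animalia;Arthropoda;Insecta;Coleoptera;Carabidae"

    def test_identical_sequences_one_motu(self):
        s = "ACGT" * 25
        labels = cluster_motus([("a", s, lin(self.FAM)), ("b", s, lin(self.FAM))])
        assert labels["a"] == labels["b"]

    @staticmethod
    def _random_seq(n, seed):
        rng = np.random.default_rng(seed)
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

    @staticmethod
    def _mutate(seq, positions):
        out = list(seq)
        for p in positions:
            out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
        return "".join(out)

    def test_95_percent_identity_split_at_98(self):
        # aperiodic sequence: 5 spread substitutions on 100 bp stay 5 edits
        s = self._random_seq(100, seed=1)
        s2 = self._mutate(s, [5, 25, 45, 65, 85])
        assert sequence_identity(s, s2) == pytest.approx(0.95)
        labels = cluster_motus(
            [("a", s, lin(self.FAM)), ("b", s2, lin(self.FAM))], identity=0.98
        )
        assert labels["a"].motu != labels["b"].motu

    def test_single_linkage_chains(self):
        # 200 bp: a~b 3 edits (98.5%), b~c 3 edits, a~c 6 edits (97%)
        a = self._random_seq(200, seed=2)
        b = self._mutate(a, [10, 70, 130])
        c = self._mutate(b, [40, 100, 160])
        assert sequence_identity(a, b) >= 0.98
        assert sequence_identity(b, c) >= 0.98
        assert sequence_identity(a, c) < 0.98
        labels = cluster_motus(
            [("a", a, lin(self.FAM)), ("b", b, lin(self.FAM)),
             ("c", c, lin(self.FAM))],
            identity=0.98,
        )
        assert labels["a"].motu == labels["b"].motu == labels["c"].motu

    def test_numbering_by_total_reads(self):
        s = "ACGT" * 25
        s2 = "GTCAG" + s[5:]
        labels = cluster_motus(
            [("a", s, lin(self.FAM)), ("b", s2, lin(self.FAM))],
            identity=0.98, totals={"a": 10, "b": 500},
        )
        assert labels["b"].motu == 1 and labels["a"].motu == 2
        assert labels["b"].display == "Carabidae 1"

    def test_species_level_input_rejected(self):
        sp = lin("Animalia;Arthropoda;Insecta;Coleoptera;Carabidae;G;s")
        with pytest.raises(ValueError):
            cluster_motus([("a", "ACGT" * 25, sp)])

    def test_different_lineages_never_cluster(self):
        s = "ACGT" * 25
        other = "Animalia;Arthropoda;Insecta;Coleoptera;Chrysomelidae"
        labels = cluster_motus(
            [("a", s, lin(self.FAM)), ("b", s, lin(other))]
        )
        assert labels["a"].lineage != labels["b"].lineage


class TestExclusion:
    POLICY = ExclusionPolicy()

    @pytest.mark.parametrize(
        "lineage,kept",
        [
            ("Animalia;Nematoda;Chromadorea;Rhabditida", False),
            ("Animalia;Arthropoda;Insecta;Coleoptera;Tenebrionidae", False),
            ("Animalia;Chordata;Aves;Passeriformes", False),
            ("Animalia;Chordata;Mammalia;Primates", False),
            ("Fungi;Ascomycota;Sordariomycetes", False),
            ("Plantae;Bryophyta;Bryopsida", False),
            ("Animalia;Arthropoda;Insecta;Coleoptera;Carabidae", True),
            ("Plantae;Tracheophyta;Magnoliopsida;Vitales", True),
        ],
    )
    def test_policy_defaults(self, lineage, kept):
        d = det("s1", "M", lineage, motu=1)
        out = exclude_taxa([d], self.POLICY)
        assert (len(out) == 1) is kept

    def test_removals_logged_with_reason(self):
        log = ProvenanceLog()
        d = det("s1", "M", "Animalia;Nematoda;Chromadorea", motu=1)
        exclude_taxa([d], self.POLICY, log)
        assert "Nematoda" in log.to_frame().reason.iloc[0]


class TestToDetections:
    def test_same_motu_same_sample_collapses(self, carabidae):
        label = TaxonLabel(lineage=carabidae, motu=1)
        table = make_table(
            "M", {"a": "A" * 100, "b": "C" * 100},
            {"a": {"p1": 10}, "b": {"p1": 5}},
        )
        dets = to_detections(table, {"a": label, "b": label})
        assert len(dets) == 1

    def test_presence_in_three_samples_three_detections(self, carabidae):
        label = TaxonLabel(lineage=carabidae, motu=1)
        table = make_table(
            "M", {"a": "A" * 100}, {"a": {"p1": 10, "p2": 1, "p3": 99}},
        )
        assert len(to_detections(table, {"a": label})) == 3

    def test_zero_counts_no_detection(self, carabidae):
        label = TaxonLabel(lineage=carabidae, motu=1)
        table = make_table("M", {"a": "A" * 100}, {"a": {"p1": 0}})
        assert to_detections(table, {"a": label}) == []


class TestPipelineRecovery:
    def test_planted_errors_removed_and_truth_recovered(self):
        spec = ESVFixtureSpec()
        table, hits, truth = generate_esv_fixture(spec, seed=11)
        log = ProvenanceLog()
        dets, clean = run_marker_pipeline(
            table, spec.marker, hits, ExclusionPolicy(allowed_kingdoms=("Animalia",)),
            log=log,
        )
        assert sorted(clean.esv_ids) == truth["true_esvs"]
        assert not set(truth["error_esvs"]) & set(clean.esv_ids)
        frame = log.to_frame()
        failed = frame[frame.stage == "pcr_failure"].record_id.tolist()
        assert failed == truth["failed_pcrs"]

    def test_zero_error_rate_identity(self):
        spec = ESVFixtureSpec(error_rate=0.0, force_failed_pcr=False)
        table, hits, truth = generate_esv_fixture(spec, seed=3)
        _, clean = run_marker_pipeline(table, spec.marker, hits)
        assert sorted(clean.esv_ids) == truth["true_esvs"]
        assert clean.counts.equals(table.counts.loc[clean.counts.index])
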