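from itertools import product

import numpy as np
import pytest

from polpause.chromatin_state import (
    DE_PRESETS,
    DEFAULT_RULE_TABLE,
    DERecord,
    MarkWindows,
    call_chromatin_states,
    classify_state,
    filter_de,
    mark_present,
    overlap_summary,
    read_de_table,
    state_composition,
)
from polpause.genome_io import GeneModel, GenomicInterval, Peak


def peak(chrom, start, end):
    return Peak(GenomicInterval(chrom, start, end), 1.0, "p")


class TestMarkPresence:
    def test_peak_at_tss_hits_k4_window(self, plus_gene):
        w = MarkWindows().window(plus_gene, "k4")
        assert mark_present(plus_gene, [peak("chr1", plus_gene.tss - 10,
                                             plus_gene.tss + 10)], w)

    def test_3kb_upstream_misses_k4_hits_k27(self, plus_gene):
        p = [peak("chr1", plus_gene.tss - 3100, plus_gene.tss - 2900)]
        mw = MarkWindows()
        assert not mark_present(plus_gene, p, mw.window(plus_gene, "k4"))
        assert mark_present(plus_gene, p, mw.window(plus_gene, "k27"))

    def test_k79_window_is_strand_oriented(self, plus_gene, minus_gene):
        mw = MarkWindows()
        wp = mw.window(plus_gene, "k79")
        wm = mw.window(minus_gene, "k79")
        assert (wp.start, wp.end) == (plus_gene.tss, plus_gene.tss + 5000)
        assert (wm.start, wm.end) == (minus_gene.tss - 5000, minus_gene.tss)

    def test_random_peaks_match_interval_scan_oracle(self, plus_gene):
        rng = np.random.default_rng(0)
        mw = MarkWindows()
        w = mw.window(plus_gene, "k27")
        peaks = []
        for _ in range(100):
            s = int(rng.integers(0, 99_000))
            peaks.append(peak("chr1", s, s + int(rng.integers(50, 900))))
        got = mark_present(plus_gene, peaks, w)
        oracle = any(p.interval.start < w.end and w.start < p.interval.end
                     for p in peaks)
        assert got == oracle
        # and per-peak agreement
        for p in peaks:
            assert mark_present(plus_gene, [p], w) == (
                p.interval.start < w.end and w.start < p.interval.end)


class TestClassifyState:
    @pytest.mark.parametrize("flags,state", [
        ((True, True, False), "active"),
        ((True, False, False), "active"),
        ((False, True, False), "active"),
        ((True, False, True), "bivalent"),
        ((True, True, True), "bivalent"),
        ((False, False, True), "silent"),
        ((False, True, True), "silent"),
        ((False, False, False), "silent"),
    ])
    def test_default_rule_table(self, flags, state):
        assert classify_state(flags) == state

    def test_table_is_total(self):
        assert set(DEFAULT_RULE_TABLE) == set(product([True, False], repeat=3))

    def test_incomplete_custom_table_rejected(self):
        with pytest.raises(ValueError, match="incomplete"):
            classify_state((True, True, True), {(True, True, True): "active"})

    def test_custom_table_changes_labels_only(self):
        table = {t: "silent" for t in product([True, False], repeat=3)}
        assert classify_state((True, True, False), table) == "silent"


class TestFilterDE:
    def rec(self, gid, lfc, p, fdr):
        return DERecord(gid, lfc, p, fdr)

    def test_examples(self):
        up = self.rec("u", 1.0, 0.01, 0.05)
        weak = self.rec("w", 0.2, 0.001, 0.001)
        out = filter_de([up, weak])
        assert [r.gene_id for r in out["up"]] == ["u"]
        assert out["down"] == []

    def test_boundary_equality_included(self):
        import math
        rec = self.rec("b", -math.log2(1.5), 0.05, 0.1)
        assert filter_de([rec])["down"] == [rec]

    def test_toy_table_planted_passes(self):
        rows = [
            self.rec("a", 2.0, 0.01, 0.01),    # up
            self.rec("b", -1.5, 0.02, 0.05),   # down
            self.rec("c", 2.0, 0.2, 0.01),     # p fails
            self.rec("d", 2.0, 0.01, 0.5),     # fdr fails
            self.rec("e", 0.3, 0.01, 0.01),    # fold fails
            self.rec("f", -0.1, 0.9, 0.9),     # null
        ]
        out = filter_de(rows)
        assert [r.gene_id for r in out["up"]] == ["a"]
        assert [r.gene_id for r in out["down"]] == ["b"]
        # disjoint and subset
        assert not ({r.gene_id for r in out["up"]}
                    & {r.gene_id for r in out["down"]})

    def test_presets_exist(self):
        assert DE_PRESETS["results-v1"]["fold_min"] == 1.5
        assert DE_PRESETS["methods"]["fold_min"] == 2.0

    def test_malformed_records_skipped_on_read(self, tmp_path):
        p = tmp_path / "de.tsv"
        p.write_text("gene_id\tlog2fc\tp\tfdr\n"
                     "ok\t1.0\t0.01\t0.02\n"
                     "bad\tnan\t0.01\t0.02\n")
        recs = read_de_table(p)
        assert [r.gene_id for r in recs] == ["ok"]


class TestComposition:
    def make_calls(self, states):
        from polpause.chromatin_state import ChromatinCall
        return [ChromatinCall(f"g{i}", True, True, False, s)
                for i, s in enumerate(states)]

    def test_all_active(self):
        calls = self.make_calls(["active"] * 4)
        comp = state_composition([c.gene_id for c in calls], calls)
        assert comp["pct_active"] == 100.0
        assert comp["pct_silent"] == 0.0

    def test_three_active_one_silent(self):
        calls = self.make_calls(["active", "active", "active", "silent"])
        comp = state_composition([c.gene_id for c in calls], calls)
        assert comp["pct_active"] == pytest.approx(75.0)
        assert comp["pct_silent"] == pytest.approx(25.0)

    def test_uncalled_reported_separately(self):
        calls = self.make_calls(["active"])
        comp = state_composition(["g0", "unknown"], calls)
        assert comp["n_uncalled"] == 1
        assert comp["pct_active"] == 100.0

    def test_planted_composition_recovered(self):
        rng = np.random.default_rng(1)
        states = rng.choice(["active", "bivalent", "silent"], size=1000,
                            p=[0.60, 0.25, 0.15])
        calls = self.make_calls(list(states))
        comp = state_composition([c.gene_id for c in calls], calls)
        assert comp["pct_active"] == pytest.approx(60, abs=3)
        assert comp["pct_bivalent"] == pytest.approx(25, abs=3)
        assert comp["pct_silent"] == pytest.approx(15, abs=3)


class TestOverlap:
    def test_identical_and_disjoint(self):
        s = {"x": {"a", "b"}, "y": {"a", "b"}}
        summ = overlap_summary(s)
        assert summ.non_overlap_pct == {"x": 0.0, "y": 0.0}
        summ = overlap_summary({"x": {"a"}, "y": {"b"}})
        assert summ.non_overlap_pct == {"x": 100.0, "y": 100.0}

    def test_enumeration_example(self):
        summ = overlap_summary({"s1": {"A", "B", "C"}, "s2": {"B", "C", "D"}})
        assert summ.non_overlap_pct["s1"] == pytest.approx(100 / 3)
        assert summ.non_overlap_pct["s2"] == pytest.approx(100 / 3)

    def test_inclusion_exclusion_three_sets(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(200)]
        sets = {n: set(rng.choice(universe, size=80, replace=False))
                for n in ("a", "b", "c")}
        summ = overlap_summary(sets)
        names = list(sets)
        ie = (sum(summ.sizes.values())
              - sum(summ.pairwise.values())
              + summ.triple)
        assert ie == summ.union_size

    def test_wrong_set_count(self):
        with pytest.raises(ValueError):
            overlap_summary({"only": {"a"}})


def test_call_chromatin_states_end_to_end(plus_gene, minus_gene):
    k4 = [peak("chr1", plus_gene.tss - 100, plus_gene.tss + 100)]
    k27 = [peak("chr1", plus_gene.tss - 100, plus_gene.tss + 100),
           peak("chr1", minus_gene.tss - 100, minus_gene.tss + 100)]
    calls = call_chromatin_states([plus_gene], k4, [], k27)
    assert calls[0].state == "bivalent"
    calls = call_chromatin_states([minus_gene], [], [], k27)
    assert calls[0].state == "silent"
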