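import functools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from translocq.align import align_global, glocal_score
from translocq.edits import (
    IndelEvent,
    bin_indels,
    call_tag_integration,
    classify_offtarget,
    extract_indels,
    quantify_reads,
    required_coverage,
)
from translocq.edits import test_bins as compute_bin_pvalues
from translocq.panel import DonorTemplate, PanelValidationError, revcomp
from translocq.sim import IndelSpec, SimConfig, sim_panel, sim_reads

from conftest import make_locus

MATCH, MISMATCH, OPEN, EXTEND = 1, -1, -2, -1


def oracle_best_score(a, b):
    """Independent alignment oracle: recursive enumeration over alignment
    paths with last-operation state (gap of length L costs OPEN + (L-1) *
    EXTEND), memoized."""

    @functools.lru_cache(maxsize=None)
    def rec(i, j, last):
        if i == len(a) and j == len(b):
            return 0
        best = -(10**9)
        if i < len(a) and j < len(b):
            s = MATCH if a[i] == b[j] else MISMATCH
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = EXTEND if last == "I" else OPEN
            best = max(best, cost + rec(i + 1, j, "I"))
        if j < len(b):
            cost = EXTEND if last == "D" else OPEN
            best = max(best, cost + rec(i, j + 1, "D"))
        return best

    return rec(0, 0, "start")


def apply_ops(read, ref, aln):
    """Reconstruct the read from the reference and the op list."""
    out = []
    for op, ref_pos, length, seq in aln.ops:
        if op == "M":
            out.append((ref_pos, ref_pos + length))
        elif op == "D":
            pass
    # verify op bookkeeping: total read length consumed
    consumed = sum(l for op, _, l, _ in aln.ops if op in ("M", "I"))
    assert consumed == len(read)
    ref_consumed = sum(l for op, _, l, _ in aln.ops if op in ("M", "D"))
    assert ref_consumed == len(ref)


short_dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestAlignGlobal:
    def test_identity_scores_length(self):
        a = align_global("ACGTACGTAC", "ACGTACGTAC")
        assert a.score == 10
        assert a.ops == (("M", 0, 10, ""),)

    def test_three_bp_deletion_at_cut(self):
        ref = "ACGTACTCAGGATCCTTGGAA"
        cut = 10
        read = ref[:cut] + ref[cut + 3 :]
        a = align_global(read, ref)
        dels = [(p, l) for op, p, l, _ in a.ops if op == "D"]
        assert dels == [(10, 3)]
        assert not any(op == "I" for op, *_ in a.ops)

    def test_twelve_bp_insertion_carries_sequence(self):
        ref = "ACGTACTCAGGATCCTTGGAA"
        ins = "TTTGGGCCCAAT"
        read = ref[:10] + ins + ref[10:]
        a = align_global(read, ref)
        inserts = [(p, l, s) for op, p, l, s in a.ops if op == "I"]
        assert inserts == [(10, 12, ins)]

    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(a=short_dna, b=short_dna)
    def test_score_matches_exhaustive_path_oracle(self, a, b):
        aln = align_global(a, b)
        assert aln.score == oracle_best_score(a, b)
        apply_ops(a, b, aln)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=short_dna, b=short_dna)
    def test_reverse_complement_mirror(self, a, b):
        fwd = align_global(a, b)
        rc = align_global(revcomp(a), revcomp(b))
        assert fwd.score == rc.score
        # equal-scoring traces may partition gaps differently; the total
        # inserted and deleted base counts must mirror
        def totals(aln):
            ins = sum(l for op, _, l, _ in aln.ops if op == "I")
            dels = sum(l for op, _, l, _ in aln.ops if op == "D")
            return ins, dels

        assert totals(fwd) == totals(rc)

    def test_unambiguous_deletion_mirrors_exactly(self):
        ref = "ACGGTTCAGATCCA"
        read = ref[:5] + ref[8:]  # delete GAT-free unique context
        fwd = align_global(read, ref)
        rc = align_global(revcomp(read), revcomp(ref))
        d_f = [(p, l) for op, p, l, _ in fwd.ops if op == "D"]
        d_r = [(p, l) for op, p, l, _ in rc.ops if op == "D"]
        assert d_f == [(5, 3)]
        assert d_r == [(len(ref) - 5 - 3, 3)]


class TestExtractAndBin:
    def test_indel_free_reads_yield_no_events(self, two_locus_panel):
        locus = two_locus_panel["A"]
        events, total = quantify_reads(
            [("r1", locus.amplicon_ref), ("r2", locus.amplicon_ref)], locus
        )
        assert events == [] and total == 2

    def test_deletion_offset_relative_to_cut(self, two_locus_panel):
        locus = two_locus_panel["A"]
        cut = locus.cut_offset
        ref = locus.amplicon_ref
        read = ref[: cut - 1] + ref[cut + 2 :]  # 3-bp deletion starting at -1
        events = extract_indels(read, locus, "r")
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "deletion" and ev.length == 3
        assert -3 <= ev.start <= 1  # optimal placement within homology slack

    def test_bins_empty_without_events(self):
        table = bin_indels([], total_reads=100)
        assert table.counts == {}

    def test_bin_increment_and_window_exclusion(self):
        events = [
            IndelEvent("r1", "deletion", -1, 2),
            IndelEvent("r2", "deletion", 15, 2),  # outside +/-8
            IndelEvent("r3", "insertion", 0, 1, "A"),
        ]
        table = bin_indels(events, total_reads=10, window=8)
        assert table.counts == {-1: 1, 0: 1}

    def test_one_read_counts_once_per_bin(self):
        events = [
            IndelEvent("r1", "deletion", 0, 2),
            IndelEvent("r1", "insertion", 0, 1, "C"),
        ]
        table = bin_indels(events, total_reads=10)
        assert table.counts == {0: 1}


class TestTestBins:
    def test_identical_tables_not_significant(self):
        t = bin_indels([IndelEvent("r", "deletion", 0, 1)], 1000, locus_id="L")
        c = bin_indels([IndelEvent("r", "deletion", 0, 1)], 1000, locus_id="L")
        p = compute_bin_pvalues(t, c)
        assert all(v > 0.05 for v in p.values())

    def test_enriched_bin_significant(self):
        evs = [IndelEvent(f"r{i}", "deletion", 0, 1) for i in range(50)]
        t = bin_indels(evs, 1000, locus_id="L")
        c = bin_indels([], 1000, locus_id="L")
        p = compute_bin_pvalues(t, c)
        assert p[("L", 0)] < 0.05

    def test_single_bin_adjustment_is_identity(self):
        evs = [IndelEvent(f"r{i}", "deletion", 0, 1) for i in range(5)]
        t = bin_indels(evs, 100, locus_id="L")
        c = bin_indels([], 100, locus_id="L")
        from translocq.transloc import hypergeom_pair_test

        p = compute_bin_pvalues(t, c)
        assert p[("L", 0)] == pytest.approx(hypergeom_pair_test(5, 100, 0, 100))

    def test_zero_coverage_is_error(self):
        t = bin_indels([], 0, locus_id="L")
        with pytest.raises(PanelValidationError, match="zero total reads"):
            compute_bin_pvalues(t, t)


class TestRequiredCoverage:
    @pytest.mark.parametrize(
        "freq,expected", [(0.001, 5000), (1.0, 5), (0.0001, 50000), (0.01, 500)]
    )
    def test_values(self, freq, expected):
        assert required_coverage(freq) == expected

    def test_zero_rejected(self):
        with pytest.raises(PanelValidationError):
            required_coverage(0)


class TestClassifyOfftarget:
    def test_all_null_site(self):
        rep = classify_offtarget("L", {}, [], 1000, 1000)
        assert not rep.edited
        assert not rep.crit_significant_bin
        assert rep.crit_coverage_all  # coverage fine, other criteria fail

    def test_significant_bin_far_from_cut_blocks(self):
        evs = [IndelEvent(f"r{i}", "deletion", 6, 1) for i in range(50)]
        rep = classify_offtarget("L", {6: 0.001}, evs, 1000, 1000)
        assert rep.crit_significant_bin
        assert not rep.crit_cut_proximal
        assert not rep.edited

    def test_low_coverage_blocks(self):
        evs = [IndelEvent(f"r{i}", "deletion", 0, 1) for i in range(20)]
        rep = classify_offtarget("L", {0: 0.001}, evs, 90, 1000)
        assert not rep.crit_coverage_all

    def test_depth_rule_blocks_rare_edit(self):
        # 0.5% editing at 400x: required coverage is 1000
        evs = [IndelEvent("r1", "deletion", 0, 1), IndelEvent("r2", "deletion", 0, 1)]
        rep = classify_offtarget("L", {0: 0.001}, evs, 400, 400)
        assert rep.cumulative_freq == pytest.approx(0.005)
        assert not rep.crit_depth_vs_freq

    def test_simulated_editing_recovered_and_called(self):
        panel = sim_panel(2, seed=31)
        locus = panel["OFT1"]
        freq, cov = 0.02, 1000
        t_cfg = SimConfig(seed=32, coverage=cov, indels=(IndelSpec("OFT1", freq),))
        c_cfg = SimConfig(seed=33, coverage=cov)
        rt, truth = sim_reads(panel, t_cfg)
        rc, _ = sim_reads(panel, c_cfg)
        rt = [(rid, s) for rid, s in rt if rid.startswith("OFT1|")]
        rc = [(rid, s) for rid, s in rc if rid.startswith("OFT1|")]
        ev_t, n_t = quantify_reads(rt, locus)
        ev_c, n_c = quantify_reads(rc, locus)
        p = compute_bin_pvalues(
            bin_indels(ev_t, n_t, locus_id="OFT1"),
            bin_indels(ev_c, n_c, locus_id="OFT1"),
        )
        rep = classify_offtarget(
            "OFT1", {off: v for (_, off), v in p.items()}, ev_t, n_t, n_c
        )
        assert rep.edited
        se = math.sqrt(freq * (1 - freq) / cov)
        assert abs(rep.cumulative_freq - freq) <= 3 * se


DONOR = DonorTemplate(
    name="ssodn",
    sequence="GATTACAGATTACAGGCCTTAAGGCCTTGGATCCATCGATAAGCTTGAGCTCGAGATCTG",
    insert_region=(14, 54),
)


class TestTagIntegration:
    def test_exact_donor_subsequence_perfect(self):
        sub = DONOR.sequence[10:50]  # 40 nt
        ev = IndelEvent("r", "insertion", 0, 40, sub)
        (call,) = call_tag_integration([ev], DONOR)
        assert call.alignment_score == pytest.approx(80)
        assert call.is_tag and call.perfect

    def test_one_substitution_imperfect(self):
        sub = DONOR.sequence[10:50]
        mutated = sub[:20] + ("A" if sub[20] != "A" else "C") + sub[21:]
        ev = IndelEvent("r", "insertion", 0, 40, mutated)
        (call,) = call_tag_integration([ev], DONOR)
        assert call.alignment_score == pytest.approx(77)
        assert call.is_tag and not call.perfect

    def test_short_insertion_not_evaluated(self):
        ev = IndelEvent("r", "insertion", 0, 8, "ACGTACGT")
        assert call_tag_integration([ev], DONOR) == []

    def test_unrelated_insertion_not_tag(self):
        ev = IndelEvent("r", "insertion", 0, 20, "GT" * 10)
        (call,) = call_tag_integration([ev], DONOR)
        assert not call.is_tag

    def test_deletions_ignored(self):
        ev = IndelEvent("r", "deletion", 0, 40)
        assert call_tag_integration([ev], DONOR) == []
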