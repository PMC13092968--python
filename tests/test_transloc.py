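import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from translocq.panel import PanelValidationError
from translocq.primer import PairCountMatrix, assign_many
from translocq.sim import SimConfig, TranslocationSpec, sim_panel, sim_reads
from translocq.transloc import (
    TranslocationCall,
    adjust_bh,
    burden,
    call_translocations,
    enumerate_junctions,
    hypergeom_pair_test,
    junction_detectable,
    theoretical_lod,
    transloc_frequency,
)


def hypergeom_oracle(k, N, K, n):
    """P(X >= k) by exact pmf summation with rational arithmetic."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for x in range(k, min(K, n) + 1):
        if n - x <= N - K:
            total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), denom)
    return float(total)


class TestHypergeomPairTest:
    def test_zero_treatment_count_is_one(self):
        assert hypergeom_pair_test(0, 1000, 5, 1000) == 1.0

    def test_exact_combinatorial_value(self):
        # C(3,3) * C(17,7) / C(20,10) = 19448/184756
        p = hypergeom_pair_test(3, 10, 0, 10)
        assert p == pytest.approx(19448 / 184756, rel=1e-12)

    def test_symmetric_case_at_least_half(self):
        for n in (1, 3, 7):
            assert hypergeom_pair_test(n, 100, n, 100) >= 0.5

    def test_count_exceeding_total_rejected(self):
        with pytest.raises(PanelValidationError):
            hypergeom_pair_test(11, 10, 0, 10)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_matches_pmf_summation_oracle(self, data):
        total_t = data.draw(st.integers(1, 20))
        total_c = data.draw(st.integers(1, 20))
        n_t = data.draw(st.integers(0, total_t))
        n_c = data.draw(st.integers(0, total_c))
        p = hypergeom_pair_test(n_t, total_t, n_c, total_c)
        if n_t + n_c == 0:
            assert p == 1.0
        else:
            expect = hypergeom_oracle(n_t, total_t + total_c, n_t + n_c, total_t)
            assert p == pytest.approx(expect, rel=1e-9)


class TestAdjustBH:
    def test_single_p_identity(self):
        assert adjust_bh([0.03]) == [pytest.approx(0.03)]

    def test_hand_computed_step_up(self):
        out = adjust_bh([0.001, 0.01, 0.02, 0.04])
        assert out == pytest.approx([0.004, 0.02, 0.0266666667, 0.04])

    def test_all_ones(self):
        assert adjust_bh([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(PanelValidationError):
            adjust_bh([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(ps=st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_permutation_invariant(self, ps):
        adj = adjust_bh(ps)
        assert all(a >= p - 1e-12 and a <= 1.0 + 1e-12 for p, a in zip(ps, adj))
        perm = list(reversed(ps))
        assert sorted(adjust_bh(perm)) == pytest.approx(sorted(adj))


class TestTranslocFrequency:
    def test_zero_count(self):
        assert transloc_frequency(0, 990, 990) == 0.0

    def test_printed_equation_arithmetic(self):
        assert transloc_frequency(10, 990, 990) == pytest.approx(10 / 990)
        assert transloc_frequency(5, 495, 1495) == pytest.approx(5 / 995)

    def test_zero_denominator_error(self):
        with pytest.raises(PanelValidationError, match="undefined"):
            transloc_frequency(0, 0, 0)

    def test_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert transloc_frequency(100, 10, 10) == 1.0


def _call(P_adjusted, called=True):
    return TranslocationCall(
        pair=(("A", "F"), ("B", "R")), n_t=1, f_total=10, r_total=10,
        P_t=P_adjusted, P_t_ctrl=0.0, P_adjusted=P_adjusted,
        p_raw=0.001, p_adj=0.001,
        pass_significance=called, pass_frequency=called,
        pass_background=called, pass_coverage=called,
    )


class TestBurden:
    def test_no_calls(self):
        assert burden([]).B == 0.0

    def test_single_call(self):
        assert burden([_call(0.05)]).B == pytest.approx(0.05)

    def test_product_form(self):
        res = burden([_call(0.01), _call(0.02)])
        assert res.B == pytest.approx(1 - 0.99 * 0.98)

    def test_uncalled_events_excluded(self):
        assert burden([_call(0.5, called=False)]).B == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(ps=st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_union_bounds(self, ps):
        B = burden([_call(p) for p in ps]).B
        assert B >= max(ps) - 1e-12
        assert B <= min(sum(ps), 1.0) + 1e-12


class TestJunctions:
    def test_four_distinct_classes(self):
        js = enumerate_junctions("A", "B")
        assert len(js) == 4
        assert len(set(js)) == 4
        assert {j.topology for j in js} == {
            "balanced_1", "balanced_2", "dicentric_like", "acentric_like"
        }

    def test_identical_sites_rejected(self):
        with pytest.raises(PanelValidationError):
            enumerate_junctions("A", "A")

    def test_top20_pair_and_junction_count(self):
        loci = [f"L{i}" for i in range(20)]
        pairs = [
            (a, b) for i, a in enumerate(loci) for b in loci[i + 1 :]
        ]
        assert len(pairs) == 190
        junctions = [j for a, b in pairs for j in enumerate_junctions(a, b)]
        assert len(junctions) == 760

    def test_classic_detects_half_tq_all(self):
        js = enumerate_junctions("A", "B")
        classic = [junction_detectable(j, "classic") for j in js]
        assert sum(classic) == 2
        assert all(junction_detectable(j, "tq") for j in js)

    def test_same_side_products_undetectable_classic(self):
        js = {j.topology: j for j in enumerate_junctions("A", "B")}
        assert not junction_detectable(js["dicentric_like"], "classic")
        assert not junction_detectable(js["acentric_like"], "classic")
        assert junction_detectable(js["balanced_1"], "classic")


class TestTheoreticalLod:
    def test_50ng_matches_printed_values(self):
        haplotypes, lod = theoretical_lod(50)
        assert haplotypes == pytest.approx(15151.5, abs=0.1)
        assert lod * 100 == pytest.approx(0.0066, abs=0.0001)
        assert round(lod * 100, 3) == 0.007  # as printed

    def test_single_haplotype_boundary(self):
        haplotypes, lod = theoretical_lod(3.3e-3)
        assert haplotypes == pytest.approx(1.0)
        assert lod == pytest.approx(1.0)

    def test_100ng(self):
        haplotypes, lod = theoretical_lod(100)
        assert haplotypes == pytest.approx(30303, rel=1e-4)
        assert lod == pytest.approx(3.3e-5, rel=1e-2)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(PanelValidationError):
            theoretical_lod(0)


def _matrix(sample_id, entries):
    mat = PairCountMatrix(sample_id=sample_id)
    for (a, b), c in entries.items():
        key = (a, b) if a <= b else (b, a)
        mat.counts[key] = c
    return mat


class TestCallTranslocations:
    def test_treatment_identical_to_control_no_calls(self):
        entries = {
            (("A", "F"), ("A", "R")): 1000,
            (("B", "F"), ("B", "R")): 1000,
            (("A", "F"), ("B", "R")): 5,
        }
        calls = call_translocations(_matrix("t", entries), _matrix("c", entries))
        assert all(not c.called for c in calls)

    def test_coverage_filter_blocks_call(self):
        treat = {
            (("A", "F"), ("A", "R")): 40,  # only 80x coverage at A
            (("B", "F"), ("B", "R")): 5000,
            (("A", "F"), ("B", "R")): 40,
        }
        ctrl = {
            (("A", "F"), ("A", "R")): 5000,
            (("B", "F"), ("B", "R")): 5000,
        }
        calls = call_translocations(_matrix("t", treat), _matrix("c", ctrl))
        (call,) = calls
        assert call.p_adj < 0.01
        assert not call.pass_coverage
        assert not call.called

    def test_background_subtraction(self):
        treat = {
            (("A", "F"), ("A", "R")): 10_000,
            (("B", "F"), ("B", "R")): 10_000,
            (("A", "F"), ("B", "R")): 200,
        }
        ctrl = {
            (("A", "F"), ("A", "R")): 10_000,
            (("B", "F"), ("B", "R")): 10_000,
            (("A", "F"), ("B", "R")): 50,
        }
        (call,) = call_translocations(_matrix("t", treat), _matrix("c", ctrl))
        assert call.P_adjusted == pytest.approx(call.P_t - call.P_t_ctrl)
        assert call.P_adjusted < call.P_t

    def test_simulated_one_percent_recovered(self):
        panel = sim_panel(3, seed=21)
        freq, cov = 0.01, 2000
        treat_cfg = SimConfig(
            seed=22, coverage=cov,
            translocations=(TranslocationSpec("ONT", "OFT1", freq),),
        )
        ctrl_cfg = SimConfig(seed=23, coverage=cov)
        rt, truth = sim_reads(panel, treat_cfg)
        rc, _ = sim_reads(panel, ctrl_cfg)
        calls = call_translocations(
            assign_many(panel, rt, sample_id="t"),
            assign_many(panel, rc, sample_id="c"),
        )
        called = [c for c in calls if c.called]
        assert len(called) == 1
        se = math.sqrt(freq * (1 - freq) / cov)
        assert abs(called[0].P_adjusted - freq) <= 3 * se
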