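"""Statistical translocation calling from unexpected primer-pair counts.

The model: each read assigned to a primer-pair product is one sampled
molecule. For an unexpected pair, enrichment of the treatment over the
paired unedited control is tested with a one-tailed hypergeometric test
(equivalently a one-sided Fisher exact test on the pair-vs-rest 2x2 table),
Benjamini-Hochberg corrected across all tested pairs of the comparison.
A significant pair is quantified as

    P_t = n_t / ((f_total + r_total) / 2)

where n_t is the pair's treatment count and f_total / r_total are the
total counts of events sharing the pair's first / second primer, each
excluding n_t itself. The reported frequency is background-subtracted
against the control, and called events combine into a total burden
B = 1 - prod(1 - P_t) under independence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .panel import PanelValidationError
from .primer import PairCountMatrix, PairKey

__all__ = [
    "PairTestResult",
    "TranslocationCall",
    "BurdenResult",
    "JunctionClass",
    "hypergeom_pair_test",
    "adjust_bh",
    "transloc_frequency",
    "call_translocations",
    "burden",
    "enumerate_junctions",
    "junction_detectable",
    "theoretical_lod",
]


def hypergeom_pair_test(
    n_treat: int, total_treat: int, n_ctrl: int, total_ctrl: int
) -> float:
    """One-tailed hypergeometric p-value for treatment enrichment.

    Urn: population N = total_treat + total_ctrl assigned reads, successes
    K = n_treat + n_ctrl, draws n = total_treat; p = P(X >= n_treat).
    Returns 1.0 when K = 0 (nothing to enrich).
    """
    for name, count, total in (
        ("treatment", n_treat, total_treat),
        ("control", n_ctrl, total_ctrl),
    ):
        if count < 0 or total < count:
            raise PanelValidationError(
                f"{name} count {count} exceeds its total {total} or is negative"
            )
    if total_treat <= 0 or total_ctrl < 0 or total_treat + total_ctrl <= 0:
        raise PanelValidationError("totals must be positive")
    K = n_treat + n_ctrl
    if K == 0:
        return 1.0
    N = total_treat + total_ctrl
    # sf(k) = P(X > k), so P(X >= n_treat) = sf(n_treat - 1)
    return float(hypergeom.sf(n_treat - 1, N, K, total_treat))


def adjust_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = list(p_values)
    for v in p:
        if not (0.0 <= v <= 1.0):
            raise PanelValidationError(f"p-value {v} outside [0, 1]")
    if not p:
        return []
    return list(multipletests(p, method="fdr_bh")[1])


def transloc_frequency(n_t: int, f_total: float, r_total: float) -> float:
    """Translocation frequency P_t = n_t / ((f_total + r_total) / 2).

    ``f_total``/``r_total`` already exclude n_t. Values above 1 are clamped
    with a warning, never silently.
    """
    if n_t < 0 or f_total < 0 or r_total < 0:
        raise PanelValidationError("counts must be non-negative")
    denom = (f_total + r_total) / 2.0
    if denom <= 0:
        raise PanelValidationError(
            "undefined translocation frequency: zero primer marginals"
        )
    p = n_t / denom
    if p > 1.0:
        warnings.warn(
            f"translocation frequency {p:.4g} > 1 clamped to 1", stacklevel=2
        )
        return 1.0
    return p


@dataclass(frozen=True)
class PairTestResult:
    pair: PairKey
    n_treat: int
    n_ctrl: int
    p_raw: float
    p_adj: float


@dataclass(frozen=True)
class TranslocationCall:
    """One tested unexpected primer pair with statistics and filter verdicts."""

    pair: PairKey
    n_t: int
    f_total: int
    r_total: int
    P_t: float
    P_t_ctrl: float
    P_adjusted: float
    p_raw: float
    p_adj: float
    pass_significance: bool
    pass_frequency: bool
    pass_background: bool
    pass_coverage: bool

    @property
    def called(self) -> bool:
        return (
            self.pass_significance
            and self.pass_frequency
            and self.pass_background
            and self.pass_coverage
        )

    def as_record(self) -> dict[str, object]:
        (l1, r1), (l2, r2) = self.pair
        return {
            "primer_1": f"{l1}:{r1}",
            "primer_2": f"{l2}:{r2}",
            "n_t": self.n_t,
            "f_total": self.f_total,
            "r_total": self.r_total,
            "P_t": self.P_t,
            "P_t_ctrl": self.P_t_ctrl,
            "P_adjusted": self.P_adjusted,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
            "pass_significance": self.pass_significance,
            "pass_frequency": self.pass_frequency,
            "pass_background": self.pass_background,
            "pass_coverage": self.pass_coverage,
            "called": self.called,
        }


@dataclass
class BurdenResult:
    calls: list[TranslocationCall]
    B: float


def _pair_frequency(mat: PairCountMatrix, key: PairKey) -> float:
    """P_t of one pair within one sample (0 when marginals are empty)."""
    n = mat.counts.get(key, 0)
    p1, p2 = key
    f_total = mat.marginal(*p1) - n
    r_total = mat.marginal(*p2) - n
    if f_total + r_total <= 0:
        return 0.0
    return transloc_frequency(n, f_total, r_total)


def call_translocations(
    treat: PairCountMatrix,
    ctrl: PairCountMatrix,
    alpha: float = 0.01,
    min_freq: float = 1e-4,
    max_ctrl_background: float = 0.01,
    min_coverage: int = 100,
) -> list[TranslocationCall]:
    """Test every unexpected pair observed in the treatment sample.

    A call requires p_adj < alpha, background-subtracted frequency
    > min_freq, control frequency < max_ctrl_background, and >= min_coverage
    assigned reads over both participating amplicons in treatment and
    control. All tested pairs are returned with their verdicts; ``called``
    marks the conjunction.
    """
    total_treat = treat.total_assigned
    total_ctrl = ctrl.total_assigned
    pairs = [k for k in treat.unexpected_pairs() if treat.counts.get(k, 0) > 0]
    if not pairs:
        return []
    p_raw = [
        hypergeom_pair_test(
            treat.counts[k], total_treat, ctrl.counts.get(k, 0), total_ctrl
        )
        for k in pairs
    ]
    p_adj = adjust_bh(p_raw)

    calls: list[TranslocationCall] = []
    for key, praw, padj in zip(pairs, p_raw, p_adj):
        n_t = treat.counts[key]
        p1, p2 = key
        f_total = treat.marginal(*p1) - n_t
        r_total = treat.marginal(*p2) - n_t
        if f_total + r_total > 0:
            P_t = transloc_frequency(n_t, f_total, r_total)
        else:
            P_t = 0.0
        P_ctrl = _pair_frequency(ctrl, key)
        P_adjusted = max(P_t - P_ctrl, 0.0)
        cov_ok = all(
            mat.locus_coverage(lid) >= min_coverage
            for mat in (treat, ctrl)
            for lid in (p1[0], p2[0])
        )
        calls.append(
            TranslocationCall(
                pair=key,
                n_t=n_t,
                f_total=f_total,
                r_total=r_total,
                P_t=P_t,
                P_t_ctrl=P_ctrl,
                P_adjusted=P_adjusted,
                p_raw=praw,
                p_adj=padj,
                pass_significance=padj < alpha,
                pass_frequency=P_adjusted > min_freq,
                pass_background=P_ctrl < max_ctrl_background,
                pass_coverage=cov_ok,
            )
        )
    return calls


def burden(calls: Iterable[TranslocationCall]) -> BurdenResult:
    """Total translocation burden B = 1 - prod(1 - P) over called events.

    Uses the background-subtracted frequency of each called event;
    independence of events is assumed.
    """
    called = [c for c in calls if c.called]
    prod = 1.0
    for c in called:
        if not (0.0 <= c.P_adjusted <= 1.0):
            raise PanelValidationError("call frequency outside [0, 1]")
        prod *= 1.0 - c.P_adjusted
    return BurdenResult(calls=called, B=1.0 - prod)


@dataclass(frozen=True)
class JunctionClass:
    """One of the four ways the ends of two distinct DSBs can be joined.

    ``side`` is the retained side of each cut ("left_of_cut" keeps the
    sequence 5' of the cut on the forward strand and is amplified by the
    locus's forward primer; "right_of_cut" keeps the 3' side, amplified by
    the reverse primer).
    """

    site_a: str
    side_a: str
    site_b: str
    side_b: str

    _TOPOLOGY = {
        ("left_of_cut", "right_of_cut"): "balanced_1",
        ("right_of_cut", "left_of_cut"): "balanced_2",
        ("left_of_cut", "left_of_cut"): "dicentric_like",
        ("right_of_cut", "right_of_cut"): "acentric_like",
    }

    @property
    def topology(self) -> str:
        return self._TOPOLOGY[(self.side_a, self.side_b)]

    @property
    def amplifying_roles(self) -> tuple[str, str]:
        """Primer roles (F/R) amplifying each retained end."""
        role = {"left_of_cut": "F", "right_of_cut": "R"}
        return role[self.side_a], role[self.side_b]


def enumerate_junctions(site_a: str, site_b: str) -> list[JunctionClass]:
    """The 4 distinct end-joining classes of two distinct cut sites."""
    if site_a == site_b:
        raise PanelValidationError("junction enumeration needs two distinct sites")
    sides = ("left_of_cut", "right_of_cut")
    return [
        JunctionClass(site_a, sa, site_b, sb) for sa in sides for sb in sides
    ]


def junction_detectable(j: JunctionClass, scheme: str = "classic") -> bool:
    """Whether a junction class forms a sequenceable product.

    classic chemistry puts P5 on every forward primer and P7 on every
    reverse primer, so a product needs one primer of each role (P5/P5 and
    P7/P7 products cannot cluster); tq ligation attaches adapters after
    amplification, so every class is detectable.
    """
    if scheme == "tq":
        return True
    if scheme != "classic":
        raise PanelValidationError(f"unknown adapter scheme {scheme!r}")
    ra, rb = j.amplifying_roles
    return {ra, rb} == {"F", "R"}


def theoretical_lod(
    input_ng: float, pg_per_haploid_genome: float = 3.3
) -> tuple[float, float]:
    """Haploid genome equivalents assayed and the resulting detection limit.

    50 ng of human genomic DNA at 3.3 pg per haploid genome is ~15 000
    haplotypes, giving a theoretical limit of detection of 1/15 000
    (~0.007% printed to one significant digit).
    """
    if input_ng <= 0:
        raise PanelValidationError("input mass must be positive")
    if pg_per_haploid_genome <= 0:
        raise PanelValidationError("genome mass must be positive")
    haplotypes = input_ng * 1000.0 / pg_per_haploid_genome
    return haplotypes, 1.0 / haplotypes
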