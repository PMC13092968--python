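"""Indel quantification around the cut site and edited-site classification.

Reads are aligned globally to their amplicon reference; indels are placed
into 1-bp bins by their start offset relative to the cut site, within a
configurable analysis window (default +/- 8 bp). Per bin, treatment vs
control indel read counts are compared with the one-tailed hypergeometric
test and Benjamini-Hochberg correction (threshold 0.05). A site is
classified as edited when all five criteria hold:

  (i)   some bin is significant (p_adj < 0.05),
  (ii)  every sample has > 100x coverage at the site,
  (iii) a significant bin lies at or adjacent to the cut (offset -1/0/+1),
  (iv)  the cumulative frequency of reads in significant bins exceeds
        0.01%, and
  (v)   mean coverage is at least 5 / cumulative frequency (e.g. 0.1%
        editing demands 5000x).

Donor-tag (ssODN) integrations are scored for insertions longer than
10 bp by glocal alignment to the donor oligo; a score above 50 counts as
a tag integration, imperfect when any donor base in the aligned region is
mutated or missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import align_global, glocal_score
from .panel import DonorTemplate, Locus, PanelValidationError
from .transloc import adjust_bh, hypergeom_pair_test

__all__ = [
    "IndelEvent",
    "BinTable",
    "EditSiteReport",
    "TagIntegrationCall",
    "extract_indels",
    "quantify_reads",
    "bin_indels",
    "test_bins",
    "required_coverage",
    "classify_offtarget",
    "call_tag_integration",
]

DEFAULT_WINDOW = 8
TAG_MIN_INSERTION = 10
TAG_SCORE_THRESHOLD = 50.0


@dataclass(frozen=True)
class IndelEvent:
    """One insertion or deletion in a read, placed relative to the cut.

    ``start`` is the signed offset of the event's first reference position
    from the cut site (0 = the base immediately 3' of the blunt cut).
    """

    read_id: str
    kind: str  # "insertion" | "deletion"
    start: int
    length: int
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise PanelValidationError(f"unknown indel kind {self.kind!r}")
        if self.length < 1:
            raise PanelValidationError("indel length must be >= 1")
        if self.kind == "insertion" and len(self.inserted_seq) != self.length:
            raise PanelValidationError("inserted_seq length mismatch")


def extract_indels(read: str, locus: Locus, read_id: str = "") -> list[IndelEvent]:
    """Align one read to its amplicon reference and list its indels."""
    aln = align_global(read, locus.amplicon_ref)
    cut = locus.cut_offset
    events: list[IndelEvent] = []
    for op, ref_pos, length, seq in aln.ops:
        if op == "I":
            events.append(
                IndelEvent(read_id, "insertion", ref_pos - cut, length, seq)
            )
        elif op == "D":
            events.append(IndelEvent(read_id, "deletion", ref_pos - cut, length))
    return events


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def quantify_reads(
    reads: Iterable[tuple[str, str]], locus: Locus
) -> tuple[list[IndelEvent], int]:
    """Indel events and total read count for one locus.

    Reads of reference length within Hamming distance 2 take a fast path:
    under the scoring in use (match +1, mismatch -1, gap open -2) an
    equal-length alignment with <= 2 substitutions cannot be beaten by any
    gapped alignment, and the mismatch-over-gap tie-break keeps the
    diagonal at equality, so such reads provably carry no indels.
    """
    events: list[IndelEvent] = []
    total = 0
    ref = locus.amplicon_ref
    for read_id, seq in reads:
        total += 1
        if len(seq) == len(ref) and _hamming(seq, ref) <= 2:
            continue
        events.extend(extract_indels(seq, locus, read_id))
    return events, total


@dataclass
class BinTable:
    """Per-offset indel read counts at one locus for one sample."""

    locus_id: str
    sample_id: str
    window: int
    counts: dict[int, int]
    total_reads: int

    def __post_init__(self) -> None:
        for off, c in self.counts.items():
            if abs(off) > self.window:
                raise PanelValidationError(f"bin offset {off} outside window")
            if c > self.total_reads:
                raise PanelValidationError("bin count exceeds total reads")


def bin_indels(
    events: Iterable[IndelEvent],
    total_reads: int,
    window: int = DEFAULT_WINDOW,
    locus_id: str = "",
    sample_id: str = "",
) -> BinTable:
    """Count indel-carrying reads per 1-bp start-offset bin.

    Only events starting within [-window, +window] are binned; a read
    contributes at most once per bin.
    """
    per_bin: dict[int, set[str]] = {}
    for ev in events:
        if -window <= ev.start <= window:
            per_bin.setdefault(ev.start, set()).add(ev.read_id)
    counts = {off: len(reads) for off, reads in per_bin.items()}
    return BinTable(
        locus_id=locus_id,
        sample_id=sample_id,
        window=window,
        counts=counts,
        total_reads=total_reads,
    )


def test_bins(
    treat: BinTable | Sequence[BinTable], ctrl: BinTable | Sequence[BinTable]
) -> dict[tuple[str, int], float]:
    """Adjusted p-value per (locus, bin) for treatment/control comparison.

    The BH family spans all bins of all loci passed in one call; passing a
    single pair of tables tests that locus alone.
    """
    treats = [treat] if isinstance(treat, BinTable) else list(treat)
    ctrls = [ctrl] if isinstance(ctrl, BinTable) else list(ctrl)
    if len(treats) != len(ctrls):
        raise PanelValidationError("treatment/control table lists differ in length")
    keys: list[tuple[str, int]] = []
    p_raw: list[float] = []
    for t, c in zip(treats, ctrls):
        if t.total_reads == 0 or c.total_reads == 0:
            raise PanelValidationError(
                f"zero total reads at locus {t.locus_id or c.locus_id!r}"
            )
        for off in range(-t.window, t.window + 1):
            nt = t.counts.get(off, 0)
            nc = c.counts.get(off, 0)
            if nt == 0 and nc == 0:
                continue
            keys.append((t.locus_id, off))
            p_raw.append(
                hypergeom_pair_test(nt, t.total_reads, nc, c.total_reads)
            )
    p_adj = adjust_bh(p_raw)
    return dict(zip(keys, p_adj))


def required_coverage(cumulative_freq: float) -> int:
    """Minimum mean coverage for a cumulative edit frequency.

    At least 5 reads are demanded at the ascribed frequency: 0.1% editing
    requires 5000x coverage.
    """
    if not (0 < cumulative_freq <= 1):
        raise PanelValidationError("cumulative frequency must be in (0, 1]")
    return math.ceil(5.0 / cumulative_freq)


@dataclass
class EditSiteReport:
    locus_id: str
    bin_p_adj: dict[int, float]
    significant_bins: list[int]
    cumulative_freq: float
    coverage: dict[str, int]
    crit_significant_bin: bool
    crit_coverage_all: bool
    crit_cut_proximal: bool
    crit_cumulative_freq: bool
    crit_depth_vs_freq: bool

    @property
    def edited(self) -> bool:
        return (
            self.crit_significant_bin
            and self.crit_coverage_all
            and self.crit_cut_proximal
            and self.crit_cumulative_freq
            and self.crit_depth_vs_freq
        )

    def as_record(self) -> dict[str, object]:
        return {
            "locus_id": self.locus_id,
            "n_significant_bins": len(self.significant_bins),
            "significant_bins": ",".join(map(str, self.significant_bins)),
            "cumulative_freq": self.cumulative_freq,
            "crit_significant_bin": self.crit_significant_bin,
            "crit_coverage_all": self.crit_coverage_all,
            "crit_cut_proximal": self.crit_cut_proximal,
            "crit_cumulative_freq": self.crit_cumulative_freq,
            "crit_depth_vs_freq": self.crit_depth_vs_freq,
            "edited": self.edited,
        }


def classify_offtarget(
    locus_id: str,
    bin_p_adj: Mapping[int, float],
    treat_events: Sequence[IndelEvent],
    treat_total: int,
    ctrl_total: int,
    alpha: float = 0.05,
    min_coverage: int = 100,
    min_cumulative_freq: float = 1e-4,
    window: int = DEFAULT_WINDOW,
) -> EditSiteReport:
    """Apply the five edited-off-target criteria to one locus.

    ``bin_p_adj`` maps bin offsets to adjusted p-values for this locus
    (from :func:`test_bins`). The cumulative frequency counts each
    treatment read once even when it carries indels in several significant
    bins.
    """
    significant = sorted(off for off, p in bin_p_adj.items() if p < alpha)
    sig_set = set(significant)
    reads_in_sig = {
        ev.read_id
        for ev in treat_events
        if ev.start in sig_set and -window <= ev.start <= window
    }
    cumulative = len(reads_in_sig) / treat_total if treat_total else 0.0
    coverage = {"treatment": treat_total, "control": ctrl_total}
    mean_cov = (treat_total + ctrl_total) / 2.0
    crit_depth = cumulative > 0 and mean_cov >= required_coverage(cumulative)
    return EditSiteReport(
        locus_id=locus_id,
        bin_p_adj=dict(bin_p_adj),
        significant_bins=significant,
        cumulative_freq=cumulative,
        coverage=coverage,
        crit_significant_bin=bool(significant),
        crit_coverage_all=all(v > min_coverage for v in coverage.values()),
        crit_cut_proximal=any(off in (-1, 0, 1) for off in significant),
        crit_cumulative_freq=cumulative > min_cumulative_freq,
        crit_depth_vs_freq=crit_depth,
    )


@dataclass(frozen=True)
class TagIntegrationCall:
    read_id: str
    insertion_length: int
    alignment_score: float
    is_tag: bool
    perfect: bool


def call_tag_integration(
    events: Iterable[IndelEvent],
    donor: DonorTemplate,
    min_length: int = TAG_MIN_INSERTION,
    score_threshold: float = TAG_SCORE_THRESHOLD,
) -> list[TagIntegrationCall]:
    """Score insertions longer than ``min_length`` against the donor oligo.

    Insertions of ``min_length`` bases or fewer are not evaluated.
    """
    if not donor.sequence:
        raise PanelValidationError("empty donor template")
    calls: list[TagIntegrationCall] = []
    for ev in events:
        if ev.kind != "insertion" or ev.length <= min_length:
            continue
        score, perfect = glocal_score(ev.inserted_seq, donor.sequence)
        is_tag = score > score_threshold
        calls.append(
            TagIntegrationCall(
                read_id=ev.read_id,
                insertion_length=ev.length,
                alignment_score=score,
                is_tag=is_tag,
                perfect=bool(is_tag and perfect),
            )
        )
    return calls
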