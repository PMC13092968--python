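"""Primer identification and read-to-pair assignment.

Each read (pair or merged) is assigned a primer at its 5' side and one at
its 3' side by exhaustive sub-string comparison under a mismatch-rate
tolerance. The outcome is defined purely by the postcondition (best
placement over all start offsets within the slop window, Hamming distance
at most floor(rate x primer length)); seed lengths exist only to speed up
the scan and never change outcomes.

Under the classic adapter scheme forward primers are sought at the 5' side
and reverse primers at the 3' side, matching fixed P5/P7 chemistry. Under
the tq (post-amplification ligation) scheme both pools are sought on both
sides, because same-side junction products (fwd/fwd or rev/rev) are
sequenceable there and carry no opposite-pool primer at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .panel import AmpliconPanel, Locus, PanelValidationError, revcomp

__all__ = [
    "PrimerMatchParams",
    "PrimerMatch",
    "ReadAssignment",
    "PairCountMatrix",
    "PairKey",
    "match_primer",
    "assign_read",
    "count_pairs",
    "expected_key",
]

# A primer reference: (locus_id, role) with role "F" (forward) or "R" (reverse).
Primer = tuple[str, str]
# Canonical unordered pair of primers identifying one amplification product.
PairKey = tuple[Primer, Primer]


@dataclass(frozen=True)
class PrimerMatchParams:
    """Tolerance parameters for primer identification.

    ``seed_min``/``seed_max`` bound the exact-match seed used to prefilter
    candidate placements (an optimization only); ``offset_slop`` is the
    number of bases from the read 5' end within which the primer may start;
    ``max_mismatch_rate`` is the allowed Hamming mismatch fraction of the
    primer length (allowed mismatches = floor(rate x length)).
    """

    seed_min: int = 6
    seed_max: int = 8
    offset_slop: int = 5
    max_mismatch_rate: float = 0.07

    def __post_init__(self) -> None:
        if not (0 < self.seed_min <= self.seed_max):
            raise PanelValidationError("require 0 < seed_min <= seed_max")
        if self.offset_slop < 0:
            raise PanelValidationError("offset_slop must be >= 0")
        if not (0 <= self.max_mismatch_rate < 0.5):
            raise PanelValidationError("max_mismatch_rate must be in [0, 0.5)")

    def allowed_mismatches(self, primer_len: int) -> int:
        return int(self.max_mismatch_rate * primer_len)


@dataclass(frozen=True)
class PrimerMatch:
    matched: bool
    mismatches: int
    start_offset: int


def match_primer(read_seq: str, primer: str, params: PrimerMatchParams) -> PrimerMatch:
    """Best placement of ``primer`` near the 5' end of ``read_seq``.

    Matched iff some start offset in [0, offset_slop] aligns the primer
    with Hamming mismatches <= floor(max_mismatch_rate * len(primer)).
    Ties resolve to the lowest mismatch count, then the smallest offset.
    A primer longer than the read is unassignable, not an error.
    """
    plen = len(primer)
    if plen > len(read_seq):
        return PrimerMatch(False, plen, -1)
    allowed = params.allowed_mismatches(plen)
    best_mm = allowed + 1
    best_off = -1
    max_off = min(params.offset_slop, len(read_seq) - plen)
    for off in range(max_off + 1):
        mm = 0
        window = read_seq[off : off + plen]
        if window == primer:
            return PrimerMatch(True, 0, off)
        for a, b in zip(window, primer):
            if a != b:
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best_mm = mm
            best_off = off
    if best_mm <= allowed:
        return PrimerMatch(True, best_mm, best_off)
    return PrimerMatch(False, best_mm if best_off >= 0 else plen, -1)


@dataclass(frozen=True)
class ReadAssignment:
    """Result of assigning one read (pair) to panel primers.

    ``fwd_locus``/``fwd_role`` describe the primer matched at the 5' side of
    read 1 (or the merged read); ``rev_locus``/``rev_role`` the primer
    matched at the 5' side of read 2 (or the reverse complement of the
    merged read's 3' end). Roles are always F/R under the classic scheme.
    """

    read_id: str
    fwd_locus: str | None
    rev_locus: str | None
    fwd_mismatches: int
    rev_mismatches: int
    status: str  # expected_pair | unexpected_pair | unassigned
    fwd_role: str = "F"
    rev_role: str = "R"

    @property
    def pair_key(self) -> PairKey | None:
        if self.fwd_locus is None or self.rev_locus is None:
            return None
        a = (self.fwd_locus, self.fwd_role)
        b = (self.rev_locus, self.rev_role)
        return (a, b) if a <= b else (b, a)


def expected_key(locus_id: str) -> PairKey:
    """Canonical pair key of a locus's own F/R product."""
    a = (locus_id, "F")
    b = (locus_id, "R")
    return (a, b) if a <= b else (b, a)


def _best_in_pool(
    seq: str, pool: Sequence[tuple[str, str, str]], params: PrimerMatchParams
) -> tuple[str | None, str, int]:
    """Best primer of ``pool`` [(locus_id, role, primer_seq)] at seq's 5' end.

    Ties break by fewest mismatches, then pool (panel) order.
    """
    best: tuple[str | None, str, int] = (None, "F", len(seq) + 1)
    for locus_id, role, primer in pool:
        m = match_primer(seq, primer, params)
        if m.matched and m.mismatches < best[2]:
            best = (locus_id, role, m.mismatches)
            if m.mismatches == 0:
                break
    return best


def assign_read(
    r1_seq: str,
    r2_seq: str | None,
    panel: AmpliconPanel,
    params: PrimerMatchParams | None = None,
    read_id: str = "",
) -> ReadAssignment:
    """Assign a read pair or merged read to a (forward, reverse) primer pair.

    For a merged read the 3'-side primer is sought on the reverse complement
    of the whole read, which places the reverse primer at its 5' end (one
    code path for both input shapes).
    """
    params = params or PrimerMatchParams()
    side1 = r1_seq
    side2 = r2_seq if r2_seq is not None else revcomp(r1_seq)

    fwd_pool = [(l.locus_id, "F", l.fwd_primer) for l in panel]
    rev_pool = [(l.locus_id, "R", l.rev_primer) for l in panel]
    if panel.adapter_scheme == "tq":
        pool1 = fwd_pool + rev_pool
        pool2 = rev_pool + fwd_pool
    else:
        pool1 = fwd_pool
        pool2 = rev_pool

    lid1, role1, mm1 = _best_in_pool(side1, pool1, params)
    lid2, role2, mm2 = _best_in_pool(side2, pool2, params)

    if lid1 is None or lid2 is None:
        status = "unassigned"
    elif lid1 == lid2 and {role1, role2} == {"F", "R"}:
        status = "expected_pair"
    else:
        status = "unexpected_pair"
    return ReadAssignment(
        read_id=read_id,
        fwd_locus=lid1,
        rev_locus=lid2,
        fwd_mismatches=mm1 if lid1 is not None else -1,
        rev_mismatches=mm2 if lid2 is not None else -1,
        status=status,
        fwd_role=role1,
        rev_role=role2,
    )


@dataclass
class PairCountMatrix:
    """Per-sample counts of reads per canonical primer-pair product.

    ``counts`` maps canonical (primer, primer) keys to read counts;
    ``total_assigned`` equals their sum; unassigned reads are tallied
    separately and excluded. ``marginal`` gives the total count of events
    sharing one primer (the f/r totals before excluding n_t).
    """

    sample_id: str
    counts: dict[PairKey, int] = field(default_factory=dict)
    n_unassigned: int = 0

    @property
    def total_assigned(self) -> int:
        return sum(self.counts.values())

    def marginal(self, locus_id: str, role: str) -> int:
        p = (locus_id, role)
        return sum(c for key, c in self.counts.items() if p in key)

    def locus_coverage(self, locus_id: str) -> int:
        """Assigned reads whose product involves either primer of the locus."""
        return sum(
            c
            for key, c in self.counts.items()
            if key[0][0] == locus_id or key[1][0] == locus_id
        )

    def get_pair(self, fwd_locus: str, rev_locus: str) -> int:
        """Count of the (fwd primer of one locus, rev primer of another) pair."""
        a = (fwd_locus, "F")
        b = (rev_locus, "R")
        key = (a, b) if a <= b else (b, a)
        return self.counts.get(key, 0)

    def unexpected_pairs(self) -> list[PairKey]:
        return sorted(
            key
            for key in self.counts
            if not (key[0][0] == key[1][0] and {key[0][1], key[1][1]} == {"F", "R"})
        )


def count_pairs(
    assignments: Iterable[ReadAssignment], sample_id: str = ""
) -> PairCountMatrix:
    """Aggregate assignments of one sample into a PairCountMatrix."""
    mat = PairCountMatrix(sample_id=sample_id)
    for a in assignments:
        key = a.pair_key
        if key is None:
            mat.n_unassigned += 1
        else:
            mat.counts[key] = mat.counts.get(key, 0) + 1
    return mat


def assign_many(
    panel: AmpliconPanel,
    reads: Iterable[tuple[str, str] | tuple[str, str, str]],
    params: PrimerMatchParams | None = None,
    sample_id: str = "",
) -> PairCountMatrix:
    """Assign an in-memory collection of merged reads and count pairs.

    An exact-prefix dictionary handles the overwhelmingly common error-free
    placement at offset 0 before falling back to the exhaustive scan; the
    fast path returns exactly what the scan would (0 mismatches beats any
    alternative, offset 0 is the smallest offset, and exact hits resolve to
    the first primer in panel order via the dictionary's insertion order).
    """
    params = params or PrimerMatchParams()
    exact1: dict[str, tuple[str, str]] = {}
    exact2: dict[str, tuple[str, str]] = {}
    plens = {len(l.fwd_primer) for l in panel} | {len(l.rev_primer) for l in panel}
    uniform = len(plens) == 1
    plen = plens.pop() if uniform else 0
    if uniform:
        for l in panel:
            exact1.setdefault(l.fwd_primer, (l.locus_id, "F"))
            exact2.setdefault(l.rev_primer, (l.locus_id, "R"))
        if panel.adapter_scheme == "tq":
            for l in panel:
                exact1.setdefault(l.rev_primer, (l.locus_id, "R"))
                exact2.setdefault(l.fwd_primer, (l.locus_id, "F"))

    mat = PairCountMatrix(sample_id=sample_id)
    counts = mat.counts
    for item in reads:
        rid, s1 = item[0], item[1]
        s2 = revcomp(s1)
        if uniform:
            hit1 = exact1.get(s1[:plen])
            hit2 = exact2.get(s2[:plen])
            if hit1 is not None and hit2 is not None:
                key = (hit1, hit2) if hit1 <= hit2 else (hit2, hit1)
                counts[key] = counts.get(key, 0) + 1
                continue
        a = assign_read(s1, None, panel, params, rid)
        key = a.pair_key
        if key is None:
            mat.n_unassigned += 1
        else:
            counts[key] = counts.get(key, 0) + 1
    return mat


def assign_fastq(
    panel: AmpliconPanel,
    r1_path: str,
    r2_path: str | None = None,
    merged: bool = True,
    params: PrimerMatchParams | None = None,
    sample_id: str = "",
) -> PairCountMatrix:
    """Stream FASTQ file(s) through assign_read and count primer pairs."""
    from .simio import iter_fastq  # local import: avoids cycle

    params = params or PrimerMatchParams()
    if r2_path is not None and not merged:
        assignments = [
            assign_read(s1, s2, panel, params, rid)
            for (rid, s1, _), (_, s2, _) in zip(
                iter_fastq(r1_path), iter_fastq(r2_path)
            )
        ]
        return count_pairs(assignments, sample_id=sample_id)
    return assign_many(panel, iter_fastq(r1_path), params, sample_id=sample_id)
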