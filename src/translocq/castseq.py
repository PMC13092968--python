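"""Post-alignment processing of junction-capture translocation candidates.

Consumes a candidate table produced by an upstream junction-capture
alignment pipeline (one row per raw junction read with its sonication
shear position) and applies, in order: molecule deduplication by shear
position ("sonic abundance"), replicate-concordance filtering (a minimum
of seven deduplicated reads found independently in at least two
replicates), partner-site classification by exact sequence homology to
the on-target locus (OMT: shared run > 25 bases with the protospacer
region; HMT: such a run anywhere in the +/- 5-kb on-target flank; NBS:
neither), and donor-bridge (ITT) detection by 35-mer content. A separate
helper normalizes per-base sequencing depth profiles for large-deletion
visualization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .panel import DonorTemplate, PanelValidationError

__all__ = [
    "RawJunctionRead",
    "OnTargetContext",
    "CastCandidate",
    "dedup_hits",
    "replicate_filter",
    "max_common_substring",
    "classify_site",
    "detect_itt",
    "normalize_depth",
]

MIN_HOMOLOGY = 25
ITT_KMER = 35


@dataclass(frozen=True)
class RawJunctionRead:
    read_id: str
    replicate: int
    shear_position: int
    junction_seq: str

    def __post_init__(self) -> None:
        if self.shear_position < 0:
            raise PanelValidationError("shear_position must be >= 0")


@dataclass(frozen=True)
class OnTargetContext:
    """Sequence context of the on-target cut used for homology classing.

    ``protospacer_region`` is the sequence immediately around the on-target
    cut; ``flank_5kb`` the +/- 5-kb region containing it.
    """

    protospacer_region: str
    flank_5kb: str

    def __post_init__(self) -> None:
        if self.protospacer_region not in self.flank_5kb:
            raise PanelValidationError(
                "protospacer_region must be contained in flank_5kb"
            )


@dataclass
class CastCandidate:
    site_id: str
    chrom: str
    window: tuple[int, int]
    per_replicate_hits: dict[int, int] = field(default_factory=dict)
    junction_seqs: tuple[str, ...] = ()
    category: str = "unclassified"
    itt: bool = False

    def __post_init__(self) -> None:
        if self.window[1] <= self.window[0]:
            raise PanelValidationError("candidate window is empty")
        if any(h < 0 for h in self.per_replicate_hits.values()):
            raise PanelValidationError("hit counts must be >= 0")

    @property
    def total_hits(self) -> int:
        return sum(self.per_replicate_hits.values())


def dedup_hits(reads: Iterable[RawJunctionRead]) -> dict[int, int]:
    """Molecules per replicate: distinct shear positions collapse reads.

    Idempotent and order-invariant by construction.
    """
    shear: dict[int, set[int]] = {}
    for r in reads:
        shear.setdefault(r.replicate, set()).add(r.shear_position)
    return {rep: len(pos) for rep, pos in sorted(shear.items())}


def replicate_filter(
    candidate: CastCandidate,
    min_reads: int = 7,
    min_replicates: int = 2,
    per_replicate: bool = False,
) -> bool:
    """True iff the candidate is replicate-supported.

    Default reading: total deduplicated reads >= min_reads AND hits present
    in >= min_replicates replicates. With ``per_replicate=True`` the
    stricter reading (>= min_reads in each of >= min_replicates
    replicates) applies instead.
    """
    hits = candidate.per_replicate_hits
    if per_replicate:
        return sum(1 for h in hits.values() if h >= min_reads) >= min_replicates
    supported = sum(1 for h in hits.values() if h > 0)
    return candidate.total_hits >= min_reads and supported >= min_replicates


def max_common_substring(a: str, b: str) -> int:
    """Length of the longest exact substring shared by ``a`` and ``b``.

    Binary search over the run length with k-mer sets: a shared run of
    length L implies a shared run of every shorter length, so the predicate
    is monotone.
    """
    if not a or not b:
        return 0
    if len(a) > len(b):
        a, b = b, a

    def shares(L: int) -> bool:
        if L > len(a):
            return False
        kmers = {a[i : i + L] for i in range(len(a) - L + 1)}
        return any(b[i : i + L] in kmers for i in range(len(b) - L + 1))

    lo, hi = 0, len(a)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if shares(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def classify_site(
    candidate: CastCandidate,
    ctx: OnTargetContext,
    min_homology: int = MIN_HOMOLOGY,
) -> str:
    """Classify a translocation partner site as OMT, HMT or NBS.

    OMT: a maximal exact shared run longer than ``min_homology`` bases with
    the protospacer region; HMT: such a run anywhere within the 5-kb
    on-target flank; NBS: neither. Priority OMT > HMT > NBS makes the
    categories exclusive and exhaustive.
    """
    if ctx is None:
        raise PanelValidationError("on-target context required")
    seqs = candidate.junction_seqs
    if not seqs:
        raise PanelValidationError(
            f"candidate {candidate.site_id!r} has no junction sequences"
        )
    best_proto = max(max_common_substring(s, ctx.protospacer_region) for s in seqs)
    if best_proto > min_homology:
        return "OMT"
    best_flank = max(max_common_substring(s, ctx.flank_5kb) for s in seqs)
    if best_flank > min_homology:
        return "HMT"
    return "NBS"


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def detect_itt(
    junction_seq: str,
    donor: DonorTemplate,
    ctx: OnTargetContext,
    k: int = ITT_KMER,
    partner_refs: Sequence[str] = (),
) -> bool:
    """Donor-bridged (interchromosomal template-bridged) junction test.

    True iff the junction read carries at least one exact k-mer unique to
    the donor insert (absent from the on-target flank and any partner
    reference supplied) AND at least one k-mer of on-target sequence — the
    donor bridging the two partners.
    """
    insert = donor.insert_seq
    if k > len(insert):
        raise PanelValidationError(
            f"k={k} exceeds donor insert length {len(insert)}"
        )
    background = _kmers(ctx.flank_5kb, k)
    for ref in partner_refs:
        background |= _kmers(ref, k)
    donor_specific = _kmers(insert, k) - background
    read_kmers = _kmers(junction_seq, k)
    if not (read_kmers & donor_specific):
        return False
    on_target_kmers = _kmers(ctx.protospacer_region, k)
    return bool(read_kmers & on_target_kmers)


def normalize_depth(
    depth: Sequence[float], control_depth: Sequence[float] | None = None
) -> np.ndarray:
    """Scale a per-base depth profile by its own maximum.

    With a control profile, returns the per-base ratio of the two
    max-normalized profiles; positions where the normalized control is zero
    yield NaN markers rather than errors.
    """
    d = np.asarray(depth, dtype=float)
    if d.size == 0:
        raise PanelValidationError("empty depth vector")
    if np.any(d < 0):
        raise PanelValidationError("depths must be non-negative")
    if d.max() == 0:
        raise PanelValidationError("all-zero depth vector")
    norm = d / d.max()
    if control_depth is None:
        return norm
    c = np.asarray(control_depth, dtype=float)
    if c.shape != d.shape:
        raise PanelValidationError("depth vectors differ in length")
    if np.any(c < 0):
        raise PanelValidationError("depths must be non-negative")
    if c.max() == 0:
        raise PanelValidationError("all-zero control depth vector")
    cn = c / c.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cn > 0, norm / np.where(cn > 0, cn, 1.0), np.nan)
    return ratio
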