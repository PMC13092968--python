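"""sgRNA batch purity analysis from spacer sequencing.

Read pairs are merged by 3'-overlap consensus, filtered for the invariant
scaffold sequence immediately downstream of the spacer, and clipped to the
spacer itself. Each spacer is scored for global-alignment identity to the
expected guide and classified as expected (exact), expected variant
(identity above a threshold — substitutions or truncations of the expected
guide), contaminant (near-exact match to another catalogued guide), or
unmapped (exported for external genome alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import identity_nw
from .panel import PanelValidationError, revcomp

__all__ = [
    "MergeResult",
    "SpacerRead",
    "GuideCatalogue",
    "GuidePoolReport",
    "merge_pairs",
    "extract_spacer",
    "score_identity",
    "classify_pool",
]

MIN_ANCHOR_LEN = 12
VARIANT_THRESHOLD = 0.75
CONTAMINANT_THRESHOLD = 0.9


@dataclass(frozen=True)
class MergeResult:
    merged: bool
    seq: str = ""
    qual: str = ""
    overlap: int = 0


def merge_pairs(
    r1: str,
    r2: str,
    q1: str | None = None,
    q2: str | None = None,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> MergeResult:
    """Merge a read pair by maximal 3'-overlap consensus.

    ``r2`` is reverse-complemented and slid against the 3' end of ``r1``;
    the longest overlap with mismatch fraction <= ``max_mismatch_frac``
    (and >= ``min_overlap``) wins; at disagreeing positions the
    higher-quality base is taken (first read wins without qualities).
    Failure is a value, never an exception.
    """
    rc2 = revcomp(r2)
    qr2 = q2[::-1] if q2 is not None else None
    n1, n2 = len(r1), len(rc2)
    best = None  # (overlap, mismatches)
    max_ov = min(n1, n2)
    for ov in range(max_ov, min_overlap - 1, -1):
        a = r1[n1 - ov :]
        b = rc2[:ov]
        mm = sum(1 for x, y in zip(a, b) if x != y)
        if mm <= max_mismatch_frac * ov:
            best = (ov, mm)
            break
    if best is None:
        return MergeResult(False)
    ov, _ = best
    head = r1[: n1 - ov]
    tail = rc2[ov:]
    cons = []
    consq = []
    for k in range(ov):
        b1 = r1[n1 - ov + k]
        b2 = rc2[k]
        if q1 is not None and qr2 is not None:
            p1 = q1[n1 - ov + k]
            p2 = qr2[k]
        else:
            p1 = p2 = "I"
        if b1 == b2:
            cons.append(b1)
            consq.append(max(p1, p2))
        elif p2 > p1:
            cons.append(b2)
            consq.append(p2)
        else:
            cons.append(b1)
            consq.append(p1)
    headq = q1[: n1 - ov] if q1 is not None else "I" * len(head)
    tailq = qr2[ov:] if qr2 is not None else "I" * len(tail)
    return MergeResult(
        True, head + "".join(cons) + tail, headq + "".join(consq) + tailq, ov
    )


def extract_spacer(
    read: str,
    scaffold_anchor: str,
    max_spacer_len: int = 25,
    tso: str | None = None,
) -> str | None:
    """Clip a read to its spacer using the scaffold as anchor.

    The spacer is the (up to ``max_spacer_len``) bases immediately 5' of
    the first exact occurrence of ``scaffold_anchor``, after trimming a
    detected TSO/adapter prefix. Reads lacking the anchor return None and
    are excluded from composition.
    """
    if len(scaffold_anchor) < MIN_ANCHOR_LEN:
        raise PanelValidationError(
            f"scaffold anchor must be >= {MIN_ANCHOR_LEN} nt"
        )
    pos = read.find(scaffold_anchor)
    if pos < 0:
        return None
    upstream = read[:pos]
    if tso:
        t = upstream.find(tso)
        if t >= 0:
            upstream = upstream[t + len(tso) :]
    return upstream[-max_spacer_len:] if upstream else ""


def score_identity(spacer: str, expected_spacer: str) -> float:
    """Global-alignment identity: matches / max(len(spacer), len(expected))."""
    if not expected_spacer:
        raise PanelValidationError("empty expected spacer")
    return identity_nw(spacer, expected_spacer)


@dataclass(frozen=True)
class GuideCatalogue:
    """Named spacer sequences of known guides (stands in for genome
    alignment of contaminants)."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, spacer in self.entries.items():
            if not (16 <= len(spacer) <= 25) or set(spacer) - set("ACGT"):
                raise PanelValidationError(
                    f"catalogue spacer {name!r} must be 16-25 nt ACGT"
                )


@dataclass(frozen=True)
class SpacerRead:
    read_id: str
    spacer: str
    identity_score: float
    assigned_class: str  # expected | expected_variant | contaminant | unmapped
    matched_catalogue_entry: str | None = None


@dataclass
class GuidePoolReport:
    """Composition of a sequenced sgRNA batch."""

    n_total: int
    n_extraction_failed: int
    class_counts: dict[str, int]
    contaminant_counts: dict[str, int]
    reads: list[SpacerRead]
    unmapped_spacers: list[tuple[str, str]]  # (read_id, spacer)

    @property
    def n_classified(self) -> int:
        return sum(self.class_counts.values())

    @property
    def class_fractions(self) -> dict[str, float]:
        n = self.n_classified
        return {k: v / n for k, v in self.class_counts.items()} if n else {}

    @property
    def contaminant_fractions(self) -> dict[str, float]:
        n = self.n_classified
        return {k: v / n for k, v in self.contaminant_counts.items()} if n else {}


def classify_pool(
    spacers: Iterable[tuple[str, str | None]],
    expected_spacer: str,
    catalogue: GuideCatalogue | None = None,
    variant_threshold: float = VARIANT_THRESHOLD,
    contaminant_threshold: float = CONTAMINANT_THRESHOLD,
) -> GuidePoolReport:
    """Classify extracted spacers into a pool-composition report.

    ``spacers`` yields (read_id, spacer-or-None); None marks extraction
    failures, which are tallied but excluded from composition fractions.
    Deterministic and permutation-invariant up to read order in listings.
    """
    if not expected_spacer:
        raise PanelValidationError("empty expected spacer")
    cat = catalogue.entries if catalogue else {}
    class_counts = {
        "expected": 0,
        "expected_variant": 0,
        "contaminant": 0,
        "unmapped": 0,
    }
    contaminant_counts: dict[str, int] = {}
    reads: list[SpacerRead] = []
    unmapped: list[tuple[str, str]] = []
    n_total = 0
    n_failed = 0
    for read_id, spacer in spacers:
        n_total += 1
        if spacer is None or spacer == "":
            n_failed += 1
            continue
        ident = score_identity(spacer, expected_spacer)
        if spacer == expected_spacer:
            cls, entry = "expected", None
        elif ident >= variant_threshold:
            cls, entry = "expected_variant", None
        else:
            best_name, best_ident = None, 0.0
            for name, cat_spacer in sorted(cat.items()):
                ci = score_identity(spacer, cat_spacer)
                if ci > best_ident:
                    best_name, best_ident = name, ci
            if best_name is not None and best_ident >= contaminant_threshold:
                cls, entry = "contaminant", best_name
                contaminant_counts[best_name] = (
                    contaminant_counts.get(best_name, 0) + 1
                )
            else:
                cls, entry = "unmapped", None
                unmapped.append((read_id, spacer))
        class_counts[cls] += 1
        reads.append(SpacerRead(read_id, spacer, ident, cls, entry))
    return GuidePoolReport(
        n_total=n_total,
        n_extraction_failed=n_failed,
        class_counts=class_counts,
        contaminant_counts=contaminant_counts,
        reads=reads,
        unmapped_spacers=unmapped,
    )
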