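"""Synthetic-data generator with exact ground-truth manifests.

Everything the analysis modules consume can be generated here under a
fixed seed: amplicon panels with non-cross-hybridizing primers, merged
amplicon read sets carrying chimeric (translocated) primer pairs and
cut-site indels at controlled frequencies, junction-capture candidate
tables with planted homology tracts, and sgRNA pools with spiked
contaminant guides. Realized event counts are recorded exactly, so
recovery tests compare estimates against known truth rather than against
the nominal rates.

The sequencing error model is substitution-only at a uniform rate
(default 0.1%); indel sequencing errors are excluded so that every indel
in a read is a planted editing event. Under the classic adapter scheme,
junction classes forming P5/P5 or P7/P7 products are generated but
recorded as unsequenceable instead of being emitted, reproducing the
half-detectability of fixed-adapter chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .castseq import CastCandidate, OnTargetContext, RawJunctionRead
from .panel import AmpliconPanel, DonorTemplate, Locus, PanelValidationError, revcomp
from .transloc import JunctionClass, junction_detectable

__all__ = [
    "TranslocationSpec",
    "IndelSpec",
    "PoolSpec",
    "SimConfig",
    "GroundTruth",
    "sim_panel",
    "sim_reads",
    "sim_pool",
    "sim_cast_candidates",
    "TSO_SEQ",
    "SCAFFOLD_ANCHOR",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Template-switch oligo and the invariant SpCas9 scaffold prefix used to
# structure simulated sgRNA sequencing reads.
TSO_SEQ = "AAGCAGTGGTATCAACGCAGAGTAC"
SCAFFOLD_ANCHOR = "GTTTTAGAGCTAGAAATAGCAAG"


def _rand_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length).astype(str))


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass(frozen=True)
class TranslocationSpec:
    """One planted reciprocal junction between two loci.

    ``side_a``/``side_b`` name the retained side of each cut
    ("left_of_cut"/"right_of_cut"); the default balanced orientation joins
    the left arm of A to the right arm of B and is detectable under both
    adapter schemes.
    """

    locus_a: str
    locus_b: str
    frequency: float
    side_a: str = "left_of_cut"
    side_b: str = "right_of_cut"

    @property
    def junction(self) -> JunctionClass:
        return JunctionClass(self.locus_a, self.side_a, self.locus_b, self.side_b)


@dataclass(frozen=True)
class IndelSpec:
    """Planted cut-site editing at one locus.

    ``lengths`` are drawn uniformly per event; ``insertion_fraction`` of
    events are insertions (random sequence unless ``insert_seq`` pins the
    inserted bases, e.g. a donor tag), the rest deletions starting at the
    cut.
    """

    locus_id: str
    frequency: float
    lengths: tuple[int, ...] = (1, 2, 3, 4, 5)
    insertion_fraction: float = 0.5
    insert_seq: str | None = None


@dataclass(frozen=True)
class PoolSpec:
    """Composition of a simulated sgRNA batch."""

    expected_spacer: str
    variant_fraction: float = 0.0
    contaminants: tuple[tuple[str, str, float], ...] = ()  # (name, spacer, frac)
    truncation_fraction: float = 0.5  # of variants; the rest substitutions

    def __post_init__(self) -> None:
        total = self.variant_fraction + sum(f for _, _, f in self.contaminants)
        if total > 1.0 + 1e-9:
            raise PanelValidationError("pool fractions exceed 1")


@dataclass(frozen=True)
class SimConfig:
    seed: int
    coverage: int = 2000
    error_rate: float = 0.001
    translocations: tuple[TranslocationSpec, ...] = ()
    indels: tuple[IndelSpec, ...] = ()
    adapter_scheme: str = "classic"


@dataclass
class GroundTruth:
    """Exact realized event counts for one simulated read set."""

    n_reads: int = 0
    per_locus_reads: dict[str, int] = field(default_factory=dict)
    transloc_counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    transloc_unsequenceable: dict[tuple[str, str, str], int] = field(
        default_factory=dict
    )
    indel_counts: dict[str, int] = field(default_factory=dict)
    pool_class_counts: dict[str, int] = field(default_factory=dict)
    pool_contaminant_counts: dict[str, int] = field(default_factory=dict)

    def transloc_frequency_truth(self, spec: TranslocationSpec, coverage: int) -> float:
        key = (spec.locus_a, spec.locus_b, spec.junction.topology)
        return self.transloc_counts.get(key, 0) / coverage


def sim_panel(
    n_loci: int,
    seed: int,
    amplicon_len: int = 160,
    primer_len: int = 20,
    min_primer_distance: int = 6,
    adapter_scheme: str = "classic",
    max_retries: int = 200,
) -> AmpliconPanel:
    """Generate a panel of non-cross-hybridizing primers and amplicons.

    All 2 x n_loci primers are pairwise Hamming distance
    >= ``min_primer_distance`` apart; the first locus is the on-target.
    """
    if n_loci < 1:
        raise PanelValidationError("n_loci must be >= 1")
    if amplicon_len < 2 * primer_len + 10:
        raise PanelValidationError("amplicon too short for primers")
    rng = np.random.default_rng(seed)
    primers: list[str] = []
    for _ in range(2 * n_loci):
        for attempt in range(max_retries):
            cand = _rand_dna(rng, primer_len)
            if all(_hamming(cand, p) >= min_primer_distance for p in primers):
                primers.append(cand)
                break
        else:
            raise PanelValidationError(
                "could not generate non-cross-hybridizing primers"
            )
    loci = []
    cut_offset = amplicon_len // 2
    for i in range(n_loci):
        fwd = primers[2 * i]
        rev = primers[2 * i + 1]
        middle = _rand_dna(rng, amplicon_len - 2 * primer_len)
        amplicon = fwd + middle + revcomp(rev)
        lid = "ONT" if i == 0 else f"OFT{i}"
        loci.append(
            Locus(
                locus_id=lid,
                chrom=f"chr{i + 1}",
                cut_site=1000 + cut_offset,
                fwd_primer=fwd,
                rev_primer=rev,
                amplicon_ref=amplicon,
                is_on_target=(i == 0),
                amplicon_start=1000,
            )
        )
    return AmpliconPanel(
        loci=tuple(loci), adapter_scheme=adapter_scheme, on_target_id="ONT"
    )


def _chimera_seq(panel: AmpliconPanel, spec: TranslocationSpec) -> str:
    a = panel[spec.locus_a]
    b = panel[spec.locus_b]
    ca, cb = a.cut_offset, b.cut_offset
    sa, sb = spec.side_a, spec.side_b
    if sa == "left_of_cut" and sb == "right_of_cut":
        return a.amplicon_ref[:ca] + b.amplicon_ref[cb:]
    if sa == "right_of_cut" and sb == "left_of_cut":
        return b.amplicon_ref[:cb] + a.amplicon_ref[ca:]
    if sa == "left_of_cut" and sb == "left_of_cut":
        return a.amplicon_ref[:ca] + revcomp(b.amplicon_ref[:cb])
    return revcomp(a.amplicon_ref[ca:]) + b.amplicon_ref[cb:]


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for p in pos:
        old = chars[p]
        alt = [b for b in "ACGT" if b != old]
        chars[p] = alt[int(rng.integers(3))]
    return "".join(chars)


def sim_reads(
    panel: AmpliconPanel, config: SimConfig
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Emit merged amplicon reads with planted chimeras and indels.

    Each locus receives ``coverage`` expected reads; each translocation
    spec adds Binomial(coverage, frequency) chimeric reads of the
    configured junction geometry. Read names carry provenance tags
    (locus|exp|i, a~b|chim|topology|i, locus|indel|kind|i).
    """
    if config.coverage < 1:
        raise PanelValidationError("coverage must be >= 1")
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    reads: list[tuple[str, str]] = []
    indel_by_locus = {s.locus_id: s for s in config.indels}

    for locus in panel:
        n = config.coverage
        spec = indel_by_locus.get(locus.locus_id)
        n_indel = rng.binomial(n, spec.frequency) if spec else 0
        truth.indel_counts[locus.locus_id] = n_indel
        truth.per_locus_reads[locus.locus_id] = n
        ref = locus.amplicon_ref
        cut = locus.cut_offset
        for i in range(n - n_indel):
            seq = _apply_errors(ref, rng, config.error_rate)
            reads.append((f"{locus.locus_id}|exp|{i}", seq))
        for i in range(n_indel):
            assert spec is not None
            length = int(spec.lengths[int(rng.integers(len(spec.lengths)))])
            if rng.random() < spec.insertion_fraction:
                ins = spec.insert_seq if spec.insert_seq else _rand_dna(rng, length)
                seq = ref[:cut] + ins + ref[cut:]
                kind = "ins"
            else:
                seq = ref[:cut] + ref[cut + length :]
                kind = "del"
            seq = _apply_errors(seq, rng, config.error_rate)
            reads.append((f"{locus.locus_id}|indel|{kind}|{i}", seq))

    for spec in config.translocations:
        junction = spec.junction
        key = (spec.locus_a, spec.locus_b, junction.topology)
        n_chim = int(rng.binomial(config.coverage, spec.frequency))
        detectable = junction_detectable(junction, panel.adapter_scheme)
        if not detectable:
            truth.transloc_unsequenceable[key] = n_chim
            truth.transloc_counts[key] = 0
            continue
        truth.transloc_counts[key] = n_chim
        chimera = _chimera_seq(panel, spec)
        for i in range(n_chim):
            seq = _apply_errors(chimera, rng, config.error_rate)
            if panel.adapter_scheme == "tq" and rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(
                (f"{spec.locus_a}~{spec.locus_b}|chim|{junction.topology}|{i}", seq)
            )

    truth.n_reads = len(reads)
    return reads, truth


def sim_pool(
    spec: PoolSpec,
    n_reads: int,
    seed: int,
    error_rate: float = 0.0,
    tail_len: int = 10,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Emit sgRNA sequencing reads: TSO + spacer + scaffold anchor + tail."""
    if n_reads < 1:
        raise PanelValidationError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    classes = ["expected", "expected_variant"] + [
        f"contaminant:{name}" for name, _, _ in spec.contaminants
    ]
    probs = [
        1.0 - spec.variant_fraction - sum(f for _, _, f in spec.contaminants),
        spec.variant_fraction,
    ] + [f for _, _, f in spec.contaminants]
    contaminant_spacers = {name: s for name, s, _ in spec.contaminants}
    draws = rng.choice(len(classes), size=n_reads, p=probs)
    reads: list[tuple[str, str]] = []
    for i, d in enumerate(draws):
        cls = classes[int(d)]
        if cls == "expected":
            spacer = spec.expected_spacer
        elif cls == "expected_variant":
            if rng.random() < spec.truncation_fraction:
                t = int(rng.integers(1, 4))
                spacer = spec.expected_spacer[:-t]
            else:
                spacer = spec.expected_spacer
                while spacer == spec.expected_spacer:
                    pos = int(rng.integers(len(spacer)))
                    alt = "ACGT"[int(rng.integers(4))]
                    spacer = spacer[:pos] + alt + spacer[pos + 1 :]
        else:
            name = cls.split(":", 1)[1]
            spacer = contaminant_spacers[name]
            truth.pool_contaminant_counts[name] = (
                truth.pool_contaminant_counts.get(name, 0) + 1
            )
        base_cls = cls.split(":", 1)[0]
        truth.pool_class_counts[base_cls] = (
            truth.pool_class_counts.get(base_cls, 0) + 1
        )
        seq = TSO_SEQ + spacer + SCAFFOLD_ANCHOR + _rand_dna(rng, tail_len)
        seq = _apply_errors(seq, rng, error_rate)
        reads.append((f"pool|{base_cls}|{i}", seq))
    truth.n_reads = n_reads
    return reads, truth


@dataclass(frozen=True)
class CastSiteSpec:
    category: str  # OMT | HMT | NBS
    hits: tuple[int, ...]  # per replicate
    itt: bool = False
    homology_len: int = 30


def sim_cast_candidates(
    ctx: OnTargetContext,
    specs: Sequence[CastSiteSpec],
    seed: int,
    donor: DonorTemplate | None = None,
    junction_len: int = 300,
) -> tuple[list[CastCandidate], dict[str, list[RawJunctionRead]], GroundTruth]:
    """Generate candidate sites with planted homology tracts.

    OMT sites embed a tract of the protospacer region, HMT sites a tract
    of the 5-kb flank outside it, NBS sites are random sequence; ITT sites
    additionally embed the donor insert followed by on-target sequence.
    Per-replicate hit counts are realized as distinct shear positions,
    each shear position duplicated by one extra read to exercise
    deduplication.
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    candidates: list[CastCandidate] = []
    reads: dict[str, list[RawJunctionRead]] = {}
    proto = ctx.protospacer_region
    flank = ctx.flank_5kb
    p_start = flank.find(proto)
    for idx, s in enumerate(specs):
        if s.homology_len >= len(flank):
            raise PanelValidationError("homology tract longer than context")
        site_id = f"site{idx}"
        base = _rand_dna(rng, junction_len)
        mid = junction_len // 2
        if s.category == "OMT":
            if s.homology_len > len(proto):
                raise PanelValidationError("homology tract longer than context")
            off = int(rng.integers(0, len(proto) - s.homology_len + 1))
            tract = proto[off : off + s.homology_len]
            seq = base[:mid] + tract + base[mid:]
        elif s.category == "HMT":
            # pick a tract in the flank that avoids the protospacer region
            lo = p_start + len(proto) + 50
            if lo + s.homology_len > len(flank):
                raise PanelValidationError("homology tract longer than context")
            off = int(rng.integers(lo, len(flank) - s.homology_len + 1))
            tract = flank[off : off + s.homology_len]
            seq = base[:mid] + tract + base[mid:]
        elif s.category == "NBS":
            seq = base
        else:
            raise PanelValidationError(f"unknown category {s.category!r}")
        if s.itt:
            if donor is None:
                raise PanelValidationError("ITT sites require a donor template")
            seq = seq + donor.insert_seq + proto[:40]
        cand = CastCandidate(
            site_id=site_id,
            chrom=f"chr{idx + 2}",
            window=(10_000 * (idx + 1), 10_000 * (idx + 1) + junction_len),
            per_replicate_hits={r + 1: h for r, h in enumerate(s.hits)},
            junction_seqs=(seq,),
            itt=s.itt,
        )
        candidates.append(cand)
        rep_reads: list[RawJunctionRead] = []
        for rep, h in enumerate(s.hits, start=1):
            positions = rng.choice(5000, size=h, replace=False) if h else []
            for k, pos in enumerate(positions):
                for dup in range(2):  # duplicate reads share a shear position
                    rep_reads.append(
                        RawJunctionRead(
                            read_id=f"{site_id}|r{rep}|{k}|{dup}",
                            replicate=rep,
                            shear_position=int(pos) + cand.window[0],
                            junction_seq=seq,
                        )
                    )
        reads[site_id] = rep_reads
    truth.n_reads = sum(len(v) for v in reads.values())
    return candidates, reads, truth
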