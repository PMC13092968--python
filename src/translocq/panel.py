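"""Domain model and I/O for amplicon panels, references, manifests and reports.

Coordinate convention used throughout the package: 0-based, half-open
intervals. ``cut_site`` is the genomic position of the first base 3' of the
blunt double-strand break on the forward strand (for SpCas9 this is the
resolved coordinate 3 bp 5' of the PAM; panels store the coordinate, the
tool never infers it from a protospacer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "PanelError",
    "PanelFormatError",
    "PanelValidationError",
    "Locus",
    "AmpliconPanel",
    "ManifestEntry",
    "SampleManifest",
    "DonorTemplate",
    "revcomp",
    "parse_panel",
    "write_panel",
    "load_fasta",
    "write_report",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGT")


class PanelError(Exception):
    """Base class for panel-layer errors."""


class PanelFormatError(PanelError):
    """A file is structurally malformed (missing column, bad FASTA, ...)."""


class PanelValidationError(PanelError):
    """Well-formed input violating a domain invariant."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str) -> None:
    if not seq:
        raise PanelValidationError(f"{what} is empty")
    bad = set(seq) - VALID_BASES
    if bad:
        raise PanelValidationError(
            f"{what} contains non-ACGT characters: {sorted(bad)!r}"
        )


@dataclass(frozen=True)
class Locus:
    """One targeted locus of a multiplex amplicon panel.

    ``fwd_primer`` is stored 5'->3' on the forward genomic strand and must be
    a prefix of ``amplicon_ref``; ``rev_primer`` is stored 5'->3' as
    synthesized (i.e. on the reverse strand), so its reverse complement must
    be a suffix of ``amplicon_ref``. ``amplicon_start`` is the 0-based
    genomic coordinate of the first base of ``amplicon_ref``, anchoring
    ``cut_site`` inside the amplicon's genomic span.
    """

    locus_id: str
    chrom: str
    cut_site: int
    fwd_primer: str
    rev_primer: str
    amplicon_ref: str
    is_on_target: bool = False
    amplicon_start: int = 0

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise PanelValidationError("locus_id is empty")
        _check_dna(self.fwd_primer, f"fwd_primer of {self.locus_id}")
        _check_dna(self.rev_primer, f"rev_primer of {self.locus_id}")
        _check_dna(self.amplicon_ref, f"amplicon_ref of {self.locus_id}")
        if not self.amplicon_ref.startswith(self.fwd_primer):
            raise PanelValidationError(
                f"fwd_primer of {self.locus_id} is not a prefix of its amplicon_ref"
            )
        if not self.amplicon_ref.endswith(revcomp(self.rev_primer)):
            raise PanelValidationError(
                f"reverse complement of rev_primer of {self.locus_id} "
                "is not a suffix of its amplicon_ref"
            )
        if not (
            self.amplicon_start
            <= self.cut_site
            <= self.amplicon_start + len(self.amplicon_ref)
        ):
            raise PanelValidationError(
                f"cut_site of {self.locus_id} lies outside the amplicon span"
            )

    @property
    def cut_offset(self) -> int:
        """Cut position relative to the start of ``amplicon_ref``."""
        return self.cut_site - self.amplicon_start

    @property
    def amplicon_end(self) -> int:
        return self.amplicon_start + len(self.amplicon_ref)


@dataclass(frozen=True)
class AmpliconPanel:
    """An ordered multiplex panel of loci sharing one adapter scheme.

    ``adapter_scheme`` is ``"classic"`` (P5 on every forward primer, P7 on
    every reverse primer; same-side junction products are unsequenceable) or
    ``"tq"`` (adapters attached by post-amplification ligation; every
    junction orientation forms a sequenceable product).
    """

    loci: tuple[Locus, ...]
    adapter_scheme: str = "classic"
    on_target_id: str | None = None

    def __post_init__(self) -> None:
        if self.adapter_scheme not in ("classic", "tq"):
            raise PanelValidationError(
                f"unknown adapter_scheme {self.adapter_scheme!r}"
            )
        ids = [l.locus_id for l in self.loci]
        seen: set[str] = set()
        for lid in ids:
            if lid in seen:
                raise PanelValidationError(f"duplicate locus_id {lid!r}")
            seen.add(lid)
        flagged = [l.locus_id for l in self.loci if l.is_on_target]
        if len(flagged) > 1:
            raise PanelValidationError(
                f"more than one on-target locus flagged: {flagged}"
            )
        if self.on_target_id is not None and self.on_target_id not in seen:
            raise PanelValidationError(
                f"on_target_id {self.on_target_id!r} not in panel"
            )

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, locus_id: str) -> Locus:
        for locus in self.loci:
            if locus.locus_id == locus_id:
                return locus
        raise KeyError(locus_id)

    @property
    def locus_ids(self) -> tuple[str, ...]:
        return tuple(l.locus_id for l in self.loci)


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    role: str  # "treatment" | "control"
    replicate: int
    reads: tuple[str, ...]
    pair_key: str

    def __post_init__(self) -> None:
        if self.role not in ("treatment", "control"):
            raise PanelValidationError(f"unknown role {self.role!r}")
        if self.replicate < 1:
            raise PanelValidationError("replicate indices are positive integers")


@dataclass(frozen=True)
class SampleManifest:
    """Treatment/control sample pairing for one run."""

    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        controls: dict[str, list[ManifestEntry]] = {}
        for e in self.entries:
            if e.role == "control":
                controls.setdefault(e.pair_key, []).append(e)
        for e in self.entries:
            if e.role == "treatment":
                paired = controls.get(e.pair_key, [])
                if len(paired) != 1:
                    raise PanelValidationError(
                        f"treatment {e.sample_id!r} needs exactly one paired "
                        f"control (pair_key {e.pair_key!r}, found {len(paired)})"
                    )

    def pairs(self) -> list[tuple[ManifestEntry, ManifestEntry]]:
        ctrl = {e.pair_key: e for e in self.entries if e.role == "control"}
        return [
            (e, ctrl[e.pair_key]) for e in self.entries if e.role == "treatment"
        ]


@dataclass(frozen=True)
class DonorTemplate:
    """An ssODN donor; ``insert_region`` is the half-open sub-interval of
    ``sequence`` absent from the unedited genome (the tag)."""

    name: str
    sequence: str
    insert_region: tuple[int, int]

    def __post_init__(self) -> None:
        _check_dna(self.sequence, f"donor {self.name}")
        lo, hi = self.insert_region
        if not (0 <= lo < hi <= len(self.sequence)):
            raise PanelValidationError(
                f"insert_region {self.insert_region} outside donor bounds"
            )

    @property
    def insert_seq(self) -> str:
        lo, hi = self.insert_region
        return self.sequence[lo:hi]


_PANEL_COLUMNS = (
    "locus_id",
    "chrom",
    "cut_site",
    "fwd_primer",
    "rev_primer",
    "amplicon_ref",
    "is_on_target",
)


def parse_panel(path: str | Path, adapter_scheme: str = "classic") -> AmpliconPanel:
    """Parse and validate a tab-separated panel definition file.

    Required columns: locus_id, chrom, cut_site, fwd_primer, rev_primer,
    amplicon_ref, is_on_target. Optional column: amplicon_start (default 0).
    Every malformed input raises a typed error; a partial panel is never
    returned.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise PanelFormatError(f"{path}: empty panel file")
        header = header_line.split("\t")
        for col in _PANEL_COLUMNS:
            if col not in header:
                raise PanelFormatError(f"{path}: missing required column {col!r}")
        idx = {c: i for i, c in enumerate(header)}
        loci: list[Locus] = []
        on_target: str | None = None
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise PanelFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )

            def get(col: str) -> str:
                return fields[idx[col]]

            try:
                cut_site = int(get("cut_site"))
                start = (
                    int(fields[idx["amplicon_start"]])
                    if "amplicon_start" in idx
                    else 0
                )
            except ValueError as exc:
                raise PanelFormatError(f"{path}:{lineno}: {exc}") from exc
            flag = get("is_on_target").strip().lower()
            if flag not in ("true", "false", "0", "1"):
                raise PanelFormatError(
                    f"{path}:{lineno}: is_on_target must be boolean, got {flag!r}"
                )
            locus = Locus(
                locus_id=get("locus_id"),
                chrom=get("chrom"),
                cut_site=cut_site,
                fwd_primer=get("fwd_primer").upper(),
                rev_primer=get("rev_primer").upper(),
                amplicon_ref=get("amplicon_ref").upper(),
                is_on_target=flag in ("true", "1"),
                amplicon_start=start,
            )
            if locus.is_on_target:
                on_target = locus.locus_id
            loci.append(locus)
    return AmpliconPanel(
        loci=tuple(loci), adapter_scheme=adapter_scheme, on_target_id=on_target
    )


def write_panel(panel: AmpliconPanel, path: str | Path) -> None:
    cols = _PANEL_COLUMNS + ("amplicon_start",)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for l in panel:
            fh.write(
                "\t".join(
                    [
                        l.locus_id,
                        l.chrom,
                        str(l.cut_site),
                        l.fwd_primer,
                        l.rev_primer,
                        l.amplicon_ref,
                        "true" if l.is_on_target else "false",
                        str(l.amplicon_start),
                    ]
                )
                + "\n"
            )


def load_fasta(path: str | Path) -> dict[str, str]:
    """Load a (multi-)FASTA file into {name: uppercase sequence}.

    Duplicate record names and empty files are rejected.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise PanelValidationError(f"{path}: duplicate record name {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise PanelFormatError(f"{path}: no FASTA records found")
    return records


def _fmt_value(v: object) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return format(v, ".6g")
    return str(v)


def write_report(
    records: Sequence[Mapping[str, object]],
    path: str | Path,
    format: str = "tsv",
    columns: Iterable[str] | None = None,
) -> None:
    """Write result records deterministically as TSV or JSON.

    Column order is the order of ``columns`` when given, else the key order
    of the first record; floats are serialized at 6 significant digits so a
    TSV round-trips losslessly at that precision.
    """
    if records is None:
        raise PanelValidationError("records must not be None")
    records = list(records)
    if columns is None:
        columns = list(records[0].keys()) if records else []
    else:
        columns = list(columns)
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(columns) + "\n")
            for rec in records:
                fh.write("\t".join(_fmt_value(rec.get(c, "")) for c in columns) + "\n")
    elif format == "json":
        rounded = [
            {
                c: (float(_fmt_value(rec.get(c))) if isinstance(rec.get(c), float) else rec.get(c))
                for c in columns
            }
            for rec in records
        ]
        with open(path, "w") as fh:
            json.dump(rounded, fh, indent=2, sort_keys=False)
            fh.write("\n")
    else:
        raise PanelValidationError(f"unknown report format {format!r}")
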