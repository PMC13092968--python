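import numpy as np
import pytest

from translocq.panel import AmpliconPanel, Locus, revcomp


def make_locus(
    locus_id: str,
    fwd: str,
    rev: str,
    middle: str,
    chrom: str = "chr1",
    start: int = 100,
    is_on_target: bool = False,
) -> Locus:
    amplicon = fwd + middle + revcomp(rev)
    return Locus(
        locus_id=locus_id,
        chrom=chrom,
        cut_site=start + len(amplicon) // 2,
        fwd_primer=fwd,
        rev_primer=rev,
        amplicon_ref=amplicon,
        is_on_target=is_on_target,
        amplicon_start=start,
    )


@pytest.fixture
def two_locus_panel() -> AmpliconPanel:
    """Tiny hand-built panel: two loci with 10-nt primers, 40-nt amplicons."""
    a = make_locus(
        "A", "ACGTACGTAC", "TTGGCCAATT", "GGGGCCCCAAAATTTTGGCC",
        chrom="chr1", start=100, is_on_target=True,
    )
    b = make_locus(
        "B", "TGCATGCATG", "CCAATTGGAA", "CCCCGGGGTTTTAAAACCGG",
        chrom="chr2", start=500,
    )
    return AmpliconPanel(loci=(a, b), adapter_scheme="classic", on_target_id="A")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
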