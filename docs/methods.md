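# Methods

This note documents the statistical model, the conventions and defaults,
what the synthetic-data generator does and does not emulate, and the
design choices made where the problem was genuinely open.

## Coordinates and panel model

All intervals are 0-based, half-open. `cut_site` is the genomic position
of the first base 3′ of the blunt double-strand break on the forward
strand; for SpCas9 this is the resolved coordinate 3 bp 5′ of the PAM.
The panel file stores the resolved coordinate — the tool never infers it
from a protospacer. Amplicon references are stored on the forward
genomic strand; reverse primers are stored 5′→3′ as synthesized, so the
reverse complement of the reverse primer is a suffix of the amplicon.
Each locus also carries `amplicon_start`, the genomic coordinate of the
amplicon's first base, which anchors the cut site inside the amplicon
span and makes window arithmetic unambiguous.

Validation is total: any malformed panel, FASTA, or manifest raises a
typed error; a partial panel is never returned.

## Primer identification

A read (pair or merged) is assigned a primer per side by exhaustive
comparison: a primer matches if some start offset within `offset_slop`
(default 5) bases of the read end aligns it with at most
floor(`max_mismatch_rate` × primer length) Hamming mismatches (default
rate 0.07, i.e. one mismatch for a 20-mer). Ties resolve to fewest
mismatches, then smallest offset, then panel order. The mismatch model
is substitution-only: primer-binding regions are amplified from the
primer itself, so indels there are vanishingly rare. Seed lengths
(`seed_min`/`seed_max`, defaults 6/8) describe the exact-prefix
dictionary used to shortcut the common error-free case; they are an
optimization only and cannot change outcomes, because an exact hit at
offset 0 is already optimal under the tie-break order.

Under the *classic* adapter scheme, forward primers are sought at the 5′
side and reverse primers at the 3′ side (fixed P5/P7 chemistry). Under
the *tq* (post-amplification ligation) scheme both primer pools are
sought on both sides: same-side junction products (two forward or two
reverse primers) are sequenceable there and contain no opposite-pool
primer at all. Pair counts are keyed by the canonical unordered pair of
(locus, primer-role) so that both read orientations of a ligated product
count as one event.

## Translocation test and quantification

For each unexpected primer pair observed in the treatment, the one-tailed
hypergeometric test uses the urn: population N = assigned reads in
treatment + control, successes K = pair count in treatment + control,
draws n = assigned treatment reads; p = P(X ≥ n_treat). This equals a
one-sided Fisher exact test of the pair-vs-rest 2×2 table. K = 0 returns
p = 1. Benjamini–Hochberg correction (statsmodels, default settings)
spans all unexpected pairs of one treatment/control comparison.

The frequency of a significant pair is P_t = n_t / ((f_total +
r_total)/2), with f_total and r_total the marginal counts of the pair's
two primers, each excluding n_t itself; other unexpected pairs sharing a
primer are *not* excluded. The reported frequency subtracts the same
quantity measured in the control, floored at zero. A call requires, with
defaults:

1. p_adj < 0.01,
2. background-subtracted frequency > 0.01% (`min_freq = 1e-4`),
3. control frequency < 1%,
4. ≥ 100× coverage of both amplicons in treatment and control, where an
   amplicon's coverage is the count of assigned reads whose product
   involves either of its primers.

Burden is B = 1 − ∏(1 − P) over called events, assumed independent,
using the background-subtracted frequency (the subtraction immediately
precedes the burden computation in the procedure this implements).
Frequencies above 1 are clamped with a warning, never silently.

Power note: the smallest detectable event is bounded by molecule counts,
not by thresholds. At 0.1% frequency and 5000× coverage only ~5 junction
molecules are expected; a 6-vs-0 split yields p ≈ 0.016, above the 0.01
significance cut, so such events are quantifiable but may not reach
significance. This mirrors the input-limited detection floor: 50 ng of
gDNA at 3.3 pg per haploid genome is ~15 000 haplotypes, a theoretical
LOD of ~0.007% of alleles.

## Junction orientations and adapter detectability

Two distinct cuts join in exactly four orientations (left/right arm of
each cut), labelled balanced_1, balanced_2, dicentric_like,
acentric_like. The retained left arm is amplified by that locus's
forward primer, the right arm by its reverse primer. Classic chemistry
therefore sequences a junction iff its two arms carry opposite primer
roles — exactly 2 of 4 classes; ligation-based adapter attachment
sequences all 4.

## Indel quantification and edited-site criteria

Reads are aligned to their amplicon by a global affine-gap aligner
(match +1, mismatch −1, gap open −2, gap extend −1, a length-L gap
costing open + (L−1)·extend) with deterministic tie-breaking: diagonal
steps are preferred over gaps at equal score and gaps are placed
leftmost. The aligner is written in-package because downstream
classification depends on the exact indel decomposition, which
off-the-shelf aligners do not pin down at ties; it is verified against
an exhaustive-path oracle in the tests. The pipeline wrapper takes a
provably safe fast path: a read of reference length within Hamming
distance 2 cannot be beaten by any gapped alignment under this scoring
(an insertion/deletion pair costs ≥ 4 while at most 2 mismatches, cost
4, could be saved — and the tie-break keeps the diagonal at equality),
so such reads carry no indels by construction.

Indels are binned by the signed offset of their start from the cut site,
1-bp bins within ±8 (`window`, configurable; the external tool this
replaces documents an 8-bp analysis window without defining
half- vs full-width — ±8 is the permissive reading). A read counts at
most once per bin. Per bin, the same hypergeometric test compares indel
read counts against totals, BH-corrected across all bins of all loci in
the comparison, threshold 0.05. A site is *edited* iff:

1. some bin has p_adj < 0.05,
2. every sample has > 100× coverage,
3. a significant bin lies at offset −1, 0, or +1 ("at or adjacent to the
   cut" read literally),
4. the cumulative frequency — the fraction of treatment reads carrying
   an indel in any significant bin, each read counted once — exceeds
   0.01%, and
5. mean coverage ≥ ceil(5 / cumulative frequency), i.e. at least five
   supporting molecules at the ascribed frequency (0.1% ⇒ 5000×).

Donor-tag integration: insertions longer than 10 bp are aligned to the
donor oligo glocally — global in the inserted sequence, free end gaps in
the donor — scoring match +2, mismatch −1, gap open −2, extend −1 (the
threshold of 50 presumes a scoring matrix the source procedure does not
state; these parameters are fixed defaults echoed into output metadata
so the threshold is reproducible). Score > 50 is a tag integration;
*imperfect* if any donor base within the aligned donor region is
substituted or missing.

## Junction-capture post-processing

Hits are molecules: reads sharing a sonication shear position collapse
to one. The replicate filter defaults to total hits ≥ 7 AND presence in
≥ 2 replicates; the stricter per-replicate reading (≥ 7 in each of ≥ 2)
is selectable by flag. Partner classification measures homology as the
maximal exact common substring (computed by binary search over k-mer
sets; "> 25 bases" means ≥ 26, mismatches not allowed — the reproducible
reading of a bare base count, with the threshold configurable): OMT if
such a run matches the protospacer region, else HMT if it matches
anywhere in the ±5-kb on-target flank (the flank is centred on the
on-target site, matching the homology-directed-repair interpretation of
that class), else NBS. The priority makes the classes exclusive and
exhaustive. Donor-bridged junctions (ITT) require the read to contain at
least one 35-mer unique to the donor insert (absent from the on-target
flank and any supplied partner references) and at least one 35-mer of
on-target sequence. Depth profiles are normalized by their own maximum;
with a control, the per-base ratio of the two normalized profiles is
reported, NaN where the control is zero.

## sgRNA pool analysis

Pairs merge by maximal 3′-overlap consensus (minimum overlap 10,
mismatch fraction ≤ 0.1, higher-quality base wins). The spacer is
clipped as the ≤ 25 bases immediately 5′ of the first exact scaffold
anchor occurrence (anchor ≥ 12 nt, supplied by configuration since
scaffold chemistry varies by vendor), after trimming a detected
TSO/adapter prefix. Identity is global-alignment matches divided by the
longer of the two sequences (the axis of the published composition plot
is not defined numerically; this is the package's own definition).
Classes: *expected* (exact), *expected_variant* (identity ≥ 0.75),
*contaminant* (identity ≥ 0.9 to a non-expected catalogue guide),
*unmapped* (exported as FASTA for external genome alignment — genome
alignment itself is out of scope; a user-provided guide catalogue stands
in for it). Both thresholds are package choices, configurable and echoed
in outputs.

## Synthetic data

The generator emulates merged amplicon reads (full amplicon length,
default 160 nt with 20-nt primers, cut at the midpoint), chimeric
junction reads with the exact arm geometry of each of the four junction
classes, cut-site indels (uniform lengths 1–5 by default, insertions
carry random or donor-tag sequence), and sgRNA reads structured as
TSO + spacer + scaffold + tail. Event counts are drawn binomially per
specification and recorded exactly in the ground-truth manifest, so
recovery tests compare against realized truth. Sequencing error is
substitution-only at a uniform 0.1% default; indel sequencing errors are
excluded so every indel is a planted event. Under the classic scheme,
same-side chimeras are generated but recorded as unsequenceable rather
than emitted, reproducing half-detectability from the manifest. All
sampling flows from one seeded generator per call; identical seeds give
byte-identical FASTQ output.

What the generator does **not** model — and what passing tests therefore
do not show about real data: PCR chimera artifacts (the dominant real
source of false unexpected pairs; with error-free primers at pairwise
Hamming distance ≥ 6 and one allowed mismatch, substitution errors alone
cannot convert one primer into another, so simulated null runs contain
no unexpected pairs at all and the null false-call test exercises the
statistical machinery only on structurally clean data), quality-score
trajectories, coverage imbalance between amplicons, microhomology-driven
junction resection, or structural variants beyond reciprocal junctions
and cut-site indels.

## Problem sizes and defaults used in the checks

The automated checks run at desk scale by choice: null calibration uses
50 seeded runs of a 20-locus panel at 2000× per sample; translocation
recovery uses {0.1%, 1%, 5%} at 5000×; indel recovery {0.1%, 1%, 10%}
at coverages satisfying the depth rule (5000× for 0.1%, 2000×
otherwise); pool spike recovery 0.5–10% at 10⁴ reads. The acceptance
script's simulated section uses a 4-locus panel at 2000× and ten null
runs of a 10-locus panel.

## Known limitations

- The hypergeometric urn treats reads as exchangeable molecules; UMI
  deduplication is out of scope, so PCR duplicates inflate counts in
  real data.
- Homology classification is exact-match only; diverged homology below
  a 26-base exact run is classed NBS.
- The glocal tag threshold (score > 50) is meaningful only under the
  documented scoring parameters.
- Paired-end inputs are assumed pre-trimmed; adapter/quality trimming is
  not performed.
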