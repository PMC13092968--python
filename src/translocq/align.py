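"""Pairwise alignment primitives.

The global affine-gap aligner here underpins indel quantification and has
fully specified, deterministic tie-breaking (prefer a diagonal step —
match or mismatch — over a gap, then place gaps leftmost), which is why it
is written out rather than delegated: callers classify reads by the exact
indel decomposition, so the decomposition must be reproducible bit-for-bit.
Scoring: match +1, mismatch -1; a gap of length L costs open + (L-1) x
extend with open = -2, extend = -1.

The donor-tag scorer is glocal — global in the query (the inserted
sequence), free end gaps in the target (the donor oligo) — and uses
Bio.Align.PairwiseAligner with match +2, mismatch -1, gap open -2,
gap extend -1.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

__all__ = [
    "GlobalAlignment",
    "align_global",
    "glocal_score",
    "identity_nw",
]

_NEG = -(10**9)

MATCH = 1
MISMATCH = -1
GAP_OPEN = -2
GAP_EXTEND = -1


@dataclass(frozen=True)
class GlobalAlignment:
    """A global alignment as a score plus an op list.

    ``ops`` is a list of (op, ref_pos, length, seq) tuples with op one of
    "M" (diagonal block, match or mismatch), "I" (insertion in the read;
    ``seq`` carries the inserted bases; ``ref_pos`` is the reference
    position the insertion precedes) and "D" (deletion of reference bases
    starting at ``ref_pos``).
    """

    score: int
    ops: tuple[tuple[str, int, int, str], ...]


def align_global(read: str, ref: str) -> GlobalAlignment:
    """Needleman-Wunsch with affine gaps and deterministic tie-breaking."""
    n, m = len(read), len(ref)
    if n == 0 or m == 0:
        raise ValueError("align_global requires non-empty sequences")
    # Gotoh matrices: M ends in a diagonal step, X in a gap consuming the
    # read (insertion), Y in a gap consuming the reference (deletion).
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        Y[0][j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    for i in range(1, n + 1):
        ri = read[i - 1]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        for j in range(1, m + 1):
            s = MATCH if ri == ref[j - 1] else MISMATCH
            Mi[j] = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1]) + s
            Xi[j] = max(Mi1[j] + GAP_OPEN, Xi1[j] + GAP_EXTEND, Yi1[j] + GAP_OPEN)
            Yi[j] = max(Mi[j - 1] + GAP_OPEN, Yi[j - 1] + GAP_EXTEND, Xi[j - 1] + GAP_OPEN)
    score = max(M[n][m], X[n][m], Y[n][m])

    # Traceback from the end; preferring the diagonal state at ties defers
    # gaps toward the sequence start (leftmost placement).
    i, j = n, m
    if M[n][m] == score:
        state = "M"
    elif Y[n][m] == score:
        state = "Y"
    else:
        state = "X"
    steps: list[str] = []  # reversed op chars
    while i > 0 or j > 0:
        if state == "M":
            s = MATCH if read[i - 1] == ref[j - 1] else MISMATCH
            target = M[i][j] - s
            steps.append("M")
            i, j = i - 1, j - 1
            if M[i][j] == target:
                state = "M"
            elif Y[i][j] == target:
                state = "Y"
            else:
                state = "X"
        elif state == "X":
            target = X[i][j]
            steps.append("I")
            i -= 1
            if M[i][j] + GAP_OPEN == target:
                state = "M"
            elif X[i][j] + GAP_EXTEND == target:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            target = Y[i][j]
            steps.append("D")
            j -= 1
            if M[i][j] + GAP_OPEN == target:
                state = "M"
            elif Y[i][j] + GAP_EXTEND == target:
                state = "Y"
            else:
                state = "X"

    steps.reverse()
    ops: list[tuple[str, int, int, str]] = []
    rp = 0  # read position
    fp = 0  # ref position
    for op in steps:
        if op == "M":
            if ops and ops[-1][0] == "M":
                prev = ops[-1]
                ops[-1] = ("M", prev[1], prev[2] + 1, "")
            else:
                ops.append(("M", fp, 1, ""))
            rp += 1
            fp += 1
        elif op == "I":
            if ops and ops[-1][0] == "I":
                prev = ops[-1]
                ops[-1] = ("I", prev[1], prev[2] + 1, prev[3] + read[rp])
            else:
                ops.append(("I", fp, 1, read[rp]))
            rp += 1
        else:  # D
            if ops and ops[-1][0] == "D":
                prev = ops[-1]
                ops[-1] = ("D", prev[1], prev[2] + 1, "")
            else:
                ops.append(("D", fp, 1, ""))
            fp += 1
    return GlobalAlignment(score=score, ops=tuple(ops))


def _glocal_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    # free end gaps in the target (donor): global only in the query
    aligner.end_deletion_score = 0.0
    return aligner


def glocal_score(inserted_seq: str, donor_seq: str) -> tuple[float, bool]:
    """Score an inserted sequence against a donor oligo, glocally.

    Returns (score, perfect) where ``perfect`` means every donor base in
    the aligned donor region is present and identical (no substitution, no
    missing base).
    """
    if not donor_seq:
        raise ValueError("empty donor sequence")
    if not inserted_seq:
        return 0.0, False
    aligner = _glocal_aligner()
    score = float(aligner.score(donor_seq, inserted_seq))
    aln = next(iter(aligner.align(donor_seq, inserted_seq)))
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return score, False
    perfect = True
    # missing donor base: the donor advances between consecutive aligned
    # blocks while inside the covered donor region
    for k in range(len(t_blocks) - 1):
        if t_blocks[k + 1][0] > t_blocks[k][1]:
            perfect = False
            break
    if perfect:
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            if donor_seq[ts:te] != inserted_seq[qs:qe]:
                perfect = False
                break
    return score, perfect


def identity_nw(a: str, b: str) -> float:
    """Global-alignment identity: matches / max(len(a), len(b)).

    Linear gap model (match +1, mismatch -1, gap -2) with deterministic
    tie-breaking (diagonal, then gap in ``a``, then gap in ``b``); among
    equal-scoring traces the match count is maximized.
    """
    if not b:
        raise ValueError("empty expected sequence")
    if not a:
        return 0.0
    n, m = len(a), len(b)
    GAP = -2
    # score plus, as tie value, the number of matches on the best path
    S = [[(_NEG, 0)] * (m + 1) for _ in range(n + 1)]
    S[0][0] = (0, 0)
    for i in range(1, n + 1):
        S[i][0] = (i * GAP, 0)
    for j in range(1, m + 1):
        S[0][j] = (j * GAP, 0)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            is_match = ai == b[j - 1]
            ds, dm = S[i - 1][j - 1]
            diag = (ds + (MATCH if is_match else MISMATCH), dm + (1 if is_match else 0))
            us, um = S[i - 1][j]
            up = (us + GAP, um)
            ls, lm = S[i][j - 1]
            left = (ls + GAP, lm)
            S[i][j] = max(diag, up, left)
    matches = S[n][m][1]
    return matches / max(n, m)
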