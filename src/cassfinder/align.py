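"""Pairwise alignment and identity primitives.

Identity throughout the package is the fraction of matched columns over all
columns where at least one sequence has a residue, terminal overhangs
excluded (internal gap columns count in the denominator).  Default scoring
mirrors the megablast-style parameters used for element searches: match +1,
mismatch -2, gaps -2.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from cassfinder.seqtypes import AlignmentResult, Interval, SequenceRecord, SequenceError


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -2.0
    gap_extend: float = -2.0


DEFAULT_SCORING = Scoring()


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _aligner(scoring: Scoring, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _identity_from_gapped(ga: str, gb: str) -> float:
    """Identity over non-overhang columns; N never counts as a match."""
    n = len(ga)
    # trim terminal overhangs: leading/trailing columns gapped in either row
    lo = 0
    while lo < n and (ga[lo] == "-" or gb[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (ga[hi - 1] == "-" or gb[hi - 1] == "-"):
        hi -= 1
    denom = 0
    matched = 0
    for x, y in zip(ga[lo:hi], gb[lo:hi]):
        if x == "-" and y == "-":
            continue
        denom += 1
        if x == y and x != "-" and x != "N":
            matched += 1
    if denom == 0:
        return 0.0
    return 100.0 * matched / denom


def _as_residues(x: SequenceRecord | str) -> str:
    return x.residues if isinstance(x, SequenceRecord) else x.upper()


def _result_from_alignment(aln, a: str, b: str) -> AlignmentResult:
    ga, gb = str(aln[0]), str(aln[1])
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        raise ValueError("empty alignment")
    span_a = Interval(int(blocks_a[0][0]), int(blocks_a[-1][1]))
    span_b = Interval(int(blocks_b[0][0]), int(blocks_b[-1][1]))
    return AlignmentResult(
        aligned_a=ga,
        aligned_b=gb,
        score=float(aln.score),
        identity_pct=_identity_from_gapped(ga, gb),
        span_a=span_a,
        span_b=span_b,
    )


def global_identity(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scoring: Scoring = DEFAULT_SCORING,
) -> AlignmentResult:
    """Optimal global alignment of two sequences with its identity percent.

    Among co-optimal alignments the aligner's tie-break depends on argument
    order, which would make the overhang-excluded identity asymmetric; the
    pair is therefore aligned in a canonical order and swapped back, so
    identity(a, b) == identity(b, a) by construction.
    """
    sa, sb = _as_residues(a), _as_residues(b)
    if not sa or not sb:
        raise SequenceError("global_identity requires non-empty sequences")
    swap = (len(sa), sa) > (len(sb), sb)
    first, second = (sb, sa) if swap else (sa, sb)
    aln = _aligner(scoring, "global").align(first, second)[0]
    result = _result_from_alignment(aln, first, second)
    if swap:
        result.aligned_a, result.aligned_b = result.aligned_b, result.aligned_a
        result.span_a, result.span_b = result.span_b, result.span_a
    return result


def local_align(
    query: SequenceRecord | str,
    target: SequenceRecord | str,
    scoring: Scoring = DEFAULT_SCORING,
    min_score: float = 0.0,
) -> AlignmentResult | None:
    """Best local alignment; ``None`` when the best score is below ``min_score``."""
    sq, st = _as_residues(query), _as_residues(target)
    if not sq or not st:
        raise SequenceError("local_align requires non-empty sequences")
    alns = _aligner(scoring, "local").align(sq, st)
    try:
        aln = alns[0]
    except IndexError:
        return None
    if aln.score < min_score:
        return None
    return _result_from_alignment(aln, sq, st)
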