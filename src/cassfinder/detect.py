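"""Structure-based TRIM detection.

Finds candidate terminal-repeat retrotransposons in miniature: two similar
direct repeats (the LTRs, 30-500 bp) separated by a short internal region
(30-2000 bp), with the two copies at >= 70% pairwise identity.  Seeding uses
exact word matches between positions at an admissible distance; seeds on one
diagonal are chained and extended with an x-drop rule, and the two repeat
copies are re-aligned globally to score identity.  PBS, PPT, TSD and TG..CA
termini are annotated as evidence; in the default (relaxed) mode none of
them filters a candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cassfinder.align import Scoring, global_identity, hamming
from cassfinder.seqtypes import Interval, SequenceRecord
from cassfinder.simulate import DEFAULT_PBS

_PURINES = frozenset("AG")


@dataclass(frozen=True)
class DetectorConfig:
    min_ltr: int = 30
    max_ltr: int = 500
    min_between: int = 30
    max_between: int = 2000
    min_ltr_identity: float = 70.0
    seed_word: int = 12
    tsd_min: int = 4
    tsd_max: int = 6
    require_tg_ca: bool = False  # strict mode: TG..CA termini become a filter
    require_tsd: bool = False  # strict mode: TSD becomes a filter
    pbs_motif: str = DEFAULT_PBS
    pbs_max_mm: int = 2
    pbs_search: int = 20  # nt searched 3' of the 5' LTR
    ppt_window: int = 10
    ppt_min_purines: int = 8
    ppt_search: int = 20  # nt searched 5' of the 3' LTR
    xdrop: float = 10.0
    boundary_margin: float = 3.0  # net gain required to move a boundary
    max_seed_positions: int = 100  # skip hyper-repetitive seed words
    scoring: Scoring = field(default_factory=Scoring)

    def __post_init__(self) -> None:
        if not (0 < self.min_ltr <= self.max_ltr):
            raise ValueError("need 0 < min_ltr <= max_ltr")
        if not (0 <= self.min_between <= self.max_between):
            raise ValueError("need 0 <= min_between <= max_between")
        if not (0 < self.min_ltr_identity <= 100):
            raise ValueError("min_ltr_identity must lie in (0, 100]")


@dataclass
class LtrPairCandidate:
    """A detected two-LTR element with its supporting evidence."""

    contig_id: str
    element: Interval
    ltr5: Interval
    ltr3: Interval
    internal: Interval
    ltr_identity_pct: float
    tsd: str | None = None
    pbs: tuple[int, int] | None = None  # (offset 3' of ltr5, mismatches)
    ppt: tuple[int, int] | None = None  # (offset 5' of ltr3, purine count)
    tg_ca: bool = False

    def __post_init__(self) -> None:
        assert self.ltr5.end <= self.internal.start <= self.internal.end <= self.ltr3.start
        assert self.element.contains(self.ltr5) and self.element.contains(self.ltr3)


def _extend(
    m: np.ndarray, start: int, end: int, lo: int, hi: int, cfg: DetectorConfig
) -> tuple[int, int]:
    """Extend [start, end) over match array ``m`` within [lo, hi) by x-drop.

    A boundary only moves when the extension's net score gain reaches
    ``boundary_margin``, so isolated chance matches beyond the true repeat
    boundary do not shift it.
    """
    match, mismatch = 1.0, -2.0
    # rightward
    score, best, best_j = 0.0, 0.0, end
    j = end
    while j < hi:
        score += match if m[j] else mismatch
        if score >= best + 1e-9 and score >= cfg.boundary_margin:
            best, best_j = score, j + 1
        if score < best - cfg.xdrop:
            break
        j += 1
    end = best_j
    # leftward
    score, best, best_i = 0.0, 0.0, start
    i = start - 1
    while i >= lo:
        score += match if m[i] else mismatch
        if score >= best + 1e-9 and score >= cfg.boundary_margin:
            best, best_i = score, i
        if score < best - cfg.xdrop:
            break
        i -= 1
    return best_i, end


def _span_overlap_frac(a: Interval, b: Interval) -> float:
    ov = a.overlap(b)
    return ov / min(a.length(), b.length())


def _resolve_overlaps(cands: list[LtrPairCandidate]) -> list[LtrPairCandidate]:
    """Among candidates sharing >= 50% of their element span keep the one
    with highest LTR identity; ties broken by longer element, then leftmost."""
    ranked = sorted(
        cands,
        key=lambda c: (-c.ltr_identity_pct, -c.element.length(), c.element.start),
    )
    kept: list[LtrPairCandidate] = []
    for cand in ranked:
        if all(_span_overlap_frac(cand.element, k.element) < 0.5 for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: (c.element.start, c.element.end))
    return kept


def detect_tsd(seq: SequenceRecord, cand: LtrPairCandidate, cfg: DetectorConfig) -> str | None:
    """Longest identical flank duplication in [tsd_min, tsd_max] immediately
    outside the element; ``None`` otherwise."""
    s = seq.residues
    for length in range(cfg.tsd_max, cfg.tsd_min - 1, -1):
        left_start = cand.element.start - length
        right_end = cand.element.end + length
        if left_start < 0 or right_end > len(s):
            continue
        left = s[left_start : cand.element.start]
        right = s[cand.element.end : right_end]
        if left == right and "N" not in left:
            return left
    return None


def detect_pbs(seq: SequenceRecord, cand: LtrPairCandidate, cfg: DetectorConfig) -> tuple[int, int] | None:
    """Best match to the PBS motif within ``pbs_search`` nt 3' of the 5' LTR."""
    s = seq.residues
    motif = cfg.pbs_motif
    best: tuple[int, int] | None = None
    for off in range(0, cfg.pbs_search + 1):
        start = cand.ltr5.end + off
        window = s[start : start + len(motif)]
        if len(window) < len(motif):
            break
        mm = hamming(window, motif)
        if mm <= cfg.pbs_max_mm and (best is None or mm < best[1]):
            best = (off, mm)
            if mm == 0:
                break
    return best


def detect_ppt(seq: SequenceRecord, cand: LtrPairCandidate, cfg: DetectorConfig) -> tuple[int, int] | None:
    """First purine-rich window within ``ppt_search`` nt 5' of the 3' LTR.

    Returns (offset of the window start measured back from ltr3.start,
    purine count)."""
    s = seq.residues
    w = cfg.ppt_window
    lo = max(cand.internal.start, cand.ltr3.start - cfg.ppt_search)
    for p in range(lo, cand.ltr3.start - w + 1):
        window = s[p : p + w]
        purines = sum(c in _PURINES for c in window)
        if purines >= cfg.ppt_min_purines:
            return (cand.ltr3.start - p, purines)
    return None


def _annotate(seq: SequenceRecord, cand: LtrPairCandidate, cfg: DetectorConfig) -> LtrPairCandidate:
    s = seq.residues
    cand.tsd = detect_tsd(seq, cand, cfg)
    cand.pbs = detect_pbs(seq, cand, cfg)
    cand.ppt = detect_ppt(seq, cand, cfg)
    cand.tg_ca = s[cand.element.start : cand.element.start + 2] == "TG" and s[cand.element.end - 2 : cand.element.end] == "CA"
    return cand


def find_ltr_pairs(seq: SequenceRecord, cfg: DetectorConfig | None = None) -> list[LtrPairCandidate]:
    """Detect candidate two-LTR elements on the given strand of ``seq``."""
    cfg = cfg or DetectorConfig()
    s = seq.residues
    n = len(s)
    k = cfg.seed_word
    min_d = cfg.min_ltr + cfg.min_between  # distance between repeat starts
    max_d = cfg.max_ltr + cfg.max_between
    if n < 2 * cfg.min_ltr + cfg.min_between:
        return []

    # seed: exact k-mer matches at admissible distances, grouped by diagonal
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        word = s[i : i + k]
        if "N" in word:
            continue
        index.setdefault(word, []).append(i)
    diagonals: dict[int, list[int]] = {}
    for positions in index.values():
        if len(positions) < 2 or len(positions) > cfg.max_seed_positions:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                d = positions[bi] - positions[ai]
                if min_d <= d <= max_d:
                    diagonals.setdefault(d, []).append(positions[ai])

    arr = np.frombuffer(s.encode(), dtype="S1")
    raw: list[LtrPairCandidate] = []
    seen: set[tuple[int, int, int]] = set()
    for d, seed_starts in diagonals.items():
        m = arr[: n - d] == arr[d:]
        # N never matches
        if "N" in s:
            nmask = arr == b"N"
            m = m & ~nmask[: n - d] & ~nmask[d:]
        seed_starts = sorted(set(seed_starts))
        # chain seeds into clusters separated by at most max_ltr
        clusters: list[list[int]] = [[seed_starts[0]]]
        for p in seed_starts[1:]:
            if p - clusters[-1][-1] <= cfg.max_ltr:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        max_len = min(cfg.max_ltr, d - cfg.min_between)
        if max_len < cfg.min_ltr:
            continue
        for cluster in clusters:
            start, end = cluster[0], min(cluster[-1] + k, n - d)
            start, end = _extend(m, start, end, 0, n - d, cfg)
            if end - start > max_len:
                # trim the lower-scoring side down to the admissible length
                while end - start > max_len:
                    if not m[start]:
                        start += 1
                    elif not m[end - 1]:
                        end -= 1
                    else:
                        end -= 1
            length = end - start
            if not (cfg.min_ltr <= length <= cfg.max_ltr):
                continue
            between = d - length
            if not (cfg.min_between <= between <= cfg.max_between):
                continue
            key = (start, end, d)
            if key in seen:
                continue
            seen.add(key)
            copy_a = s[start:end]
            copy_b = s[start + d : end + d]
            identity = global_identity(copy_a, copy_b, cfg.scoring).identity_pct
            if identity < cfg.min_ltr_identity:
                continue
            cand = LtrPairCandidate(
                contig_id=seq.id,
                element=Interval(start, end + d),
                ltr5=Interval(start, end),
                ltr3=Interval(start + d, end + d),
                internal=Interval(end, start + d),
                ltr_identity_pct=identity,
            )
            raw.append(cand)

    resolved = _resolve_overlaps(raw)
    annotated = [_annotate(seq, c, cfg) for c in resolved]
    if cfg.require_tsd:
        annotated = [c for c in annotated if c.tsd is not None]
    if cfg.require_tg_ca:
        annotated = [c for c in annotated if c.tg_ca]
    return annotated


def candidates_to_gff(cands: list[LtrPairCandidate]):
    """GFF3 features (SO terms) for a list of candidates."""
    from cassfinder.io import Gff3Feature

    feats = []
    for i, c in enumerate(cands):
        eid = f"ltrpair_{c.contig_id}_{i}"
        attrs = {"ID": eid, "ltr_identity": f"{c.ltr_identity_pct:.1f}"}
        if c.tsd:
            attrs["tsd"] = c.tsd
        feats.append(Gff3Feature(c.contig_id, "LTR_retrotransposon", c.element, attrs))
        feats.append(Gff3Feature(c.contig_id, "long_terminal_repeat", c.ltr5, {"Parent": eid}))
        feats.append(Gff3Feature(c.contig_id, "long_terminal_repeat", c.ltr3, {"Parent": eid}))
        if c.pbs is not None:
            off = c.ltr5.end + c.pbs[0]
            feats.append(Gff3Feature(c.contig_id, "primer_binding_site", Interval(off, off + len(DEFAULT_PBS)), {"Parent": eid, "mismatches": str(c.pbs[1])}))
        if c.ppt is not None:
            start = c.ltr3.start - c.ppt[0]
            feats.append(Gff3Feature(c.contig_id, "RR_tract", Interval(start, start + 10), {"Parent": eid, "purines": str(c.ppt[1])}))
    return feats


def candidate_rows(cands: list[LtrPairCandidate]) -> list[dict]:
    """TSV rows, one per candidate."""
    rows = []
    for i, c in enumerate(cands):
        rows.append(
            {
                "element_id": f"ltrpair_{c.contig_id}_{i}",
                "contig": c.contig_id,
                "start": c.element.start,
                "end": c.element.end,
                "ltr5_start": c.ltr5.start,
                "ltr5_end": c.ltr5.end,
                "ltr3_start": c.ltr3.start,
                "ltr3_end": c.ltr3.end,
                "ltr_identity_pct": f"{c.ltr_identity_pct:.2f}",
                "tsd": c.tsd or "",
                "pbs_offset": "" if c.pbs is None else c.pbs[0],
                "pbs_mismatches": "" if c.pbs is None else c.pbs[1],
                "ppt_offset": "" if c.ppt is None else c.ppt[0],
                "ppt_purines": "" if c.ppt is None else c.ppt[1],
                "tg_ca": int(c.tg_ca),
            }
        )
    return rows
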