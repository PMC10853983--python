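"""5S promoter annotation inside LTRs and 5S genes.

Annotates the internal control region of RNA-polymerase-III transcription
(A-Box, intermediate element IE, C-Box), classifies C-Box variants (the
"promoter mimicry" readout), extracts the 4 nt MotIE and 5 nt MotC spacer
motifs, locates the 5S-derived similarity region within an LTR, and
classifies elements as Cassandra vs Cassandra-like TRIM vs other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from cassfinder.align import Scoring, hamming, local_align
from cassfinder.detect import LtrPairCandidate
from cassfinder.seqtypes import Interval, SequenceRecord
from cassfinder.simulate import CBOX_REFS, DEFAULT_ABOX, DEFAULT_IE, TATA_BOX, TATA_OFFSET


@dataclass(frozen=True)
class MotifConfig:
    abox_seq: str = DEFAULT_ABOX
    ie_seq: str = DEFAULT_IE
    cbox_refs: dict = field(default_factory=lambda: dict(CBOX_REFS))
    max_mm_abox: int = 2
    max_mm_ie: int = 2
    cbox_assign_max_mm: int = 2
    ie_window: int = 20  # IE searched this far downstream of the A-Box end
    cbox_window: int = 30  # C-Box searched this far downstream of the IE end
    tata_seq: str = TATA_BOX
    tata_offset: int = TATA_OFFSET
    tata_tol: int = 5
    min_core_score: float = 40.0
    min_core_len: int = 40
    scoring: Scoring = field(default_factory=Scoring)

    def __post_init__(self) -> None:
        if not self.abox_seq or not self.ie_seq:
            raise ValueError("A-Box and IE motifs must be non-empty")
        if any(len(v) != 10 for v in self.cbox_refs.values()):
            raise ValueError("C-Box reference motifs must all be 10 nt")


@dataclass
class PromoterAnnotation:
    abox: Interval | None = None
    ie: Interval | None = None
    cbox: Interval | None = None
    cbox_seq: str | None = None
    cbox_class: str = "other"  # canonical / anthemideae_rdna / anthemideae_cassandra / ambiguous / other
    cbox_distance: int | None = None
    mot_ie: str | None = None
    mot_c: str | None = None


@dataclass
class SimilarityRegion:
    """The 5S-derived region shared between an LTR and the 5S rRNA gene."""

    ltr_span: Interval  # LTR-relative
    gene_span: Interval  # gene-relative
    identity_pct: float
    relative_midpoint: float  # midpoint of ltr_span as a fraction of LTR length


@dataclass
class ElementClassification:
    label: str  # cassandra / cassandra_like_trim / other_trim
    similarity: SimilarityRegion | None = None
    similarity_3prime: SimilarityRegion | None = None
    tata_offset: int | None = None


def classify_cbox(seq10: str, cfg: MotifConfig | None = None) -> tuple[str, int]:
    """Assign a 10-mer to its nearest C-Box reference motif.

    Returns (class, Hamming distance to the winning reference).  Distances
    above ``cbox_assign_max_mm`` give class ``other``; an exact tie between
    two references gives ``ambiguous``.
    """
    cfg = cfg or MotifConfig()
    seq10 = seq10.upper()
    if len(seq10) != 10:
        raise ValueError(f"C-Box classification needs a 10-mer, got {len(seq10)} nt")
    dists = sorted(
        ((hamming(seq10, ref), name) for name, ref in cfg.cbox_refs.items()),
        key=lambda t: (t[0], t[1]),
    )
    best_d, best_name = dists[0]
    if best_d > cfg.cbox_assign_max_mm:
        return ("other", best_d)
    if len(dists) > 1 and dists[1][0] == best_d:
        return ("ambiguous", best_d)
    return (best_name, best_d)


def _best_occurrence(
    seq: str, motif: str, max_mm: int, from_pos: int = 0, to_pos: int | None = None
) -> tuple[int, int] | None:
    """Leftmost-best approximate occurrence of ``motif`` in [from_pos, to_pos]."""
    best: tuple[int, int] | None = None  # (mm, pos)
    m = len(motif)
    hi = len(seq) - m + 1 if to_pos is None else min(to_pos + 1, len(seq) - m + 1)
    for p in range(from_pos, hi):
        mm = hamming(seq[p : p + m], motif)
        if mm <= max_mm and (best is None or mm < best[0]):
            best = (mm, p)
            if mm == 0:
                break
    if best is None:
        return None
    return (best[1], best[0])


def _best_cbox(
    seq: str, cfg: MotifConfig, from_pos: int, to_pos: int | None = None
) -> tuple[int, str, int] | None:
    """Best (pos, winning ref name, mm) over all C-Box references downstream."""
    best: tuple[int, int, str] | None = None  # (mm, pos, ref)
    hi = len(seq) - 9 if to_pos is None else min(to_pos + 1, len(seq) - 9)
    for p in range(from_pos, hi):
        window = seq[p : p + 10]
        for name, ref in cfg.cbox_refs.items():
            mm = hamming(window, ref)
            if mm <= cfg.cbox_assign_max_mm and (best is None or mm < best[0]):
                best = (mm, p, name)
        if best is not None and best[0] == 0:
            break
    if best is None:
        return None
    return (best[1], best[2], best[0])


def extract_motifs(seq: str, ann: PromoterAnnotation) -> tuple[str | None, str | None]:
    """MotIE = 4 nt immediately preceding the IE; MotC = 5 nt immediately
    preceding the C-Box.  ``None`` when the bounding box is absent or the
    spacer is too short."""
    mot_ie = mot_c = None
    if ann.ie is not None:
        lo = ann.ie.start - 4
        upstream_end = ann.abox.end if ann.abox is not None else 0
        if lo >= upstream_end:
            mot_ie = seq[lo : ann.ie.start]
    if ann.cbox is not None:
        lo = ann.cbox.start - 5
        upstream_end = ann.ie.end if ann.ie is not None else 0
        if lo >= upstream_end:
            mot_c = seq[lo : ann.cbox.start]
    return mot_ie, mot_c


def scan_boxes(seq: SequenceRecord | str, cfg: MotifConfig | None = None) -> PromoterAnnotation:
    """Ordered, anchored scan for A-Box, then IE, then C-Box.

    The A-Box (15 nt, the most specific motif) anchors the internal control
    region; the IE is searched only within ``ie_window`` nt downstream of it
    and the C-Box within ``cbox_window`` nt downstream of the IE, reflecting
    the fixed ICR geometry and keeping short degenerate motifs from matching
    by chance.  Absence of any box is data, not an error.
    """
    cfg = cfg or MotifConfig()
    s = seq.residues if isinstance(seq, SequenceRecord) else seq.upper()
    ann = PromoterAnnotation()

    hit = _best_occurrence(s, cfg.abox_seq, cfg.max_mm_abox)
    if hit is not None:
        ann.abox = Interval(hit[0], hit[0] + len(cfg.abox_seq))
        hit = _best_occurrence(
            s, cfg.ie_seq, cfg.max_mm_ie,
            from_pos=ann.abox.end, to_pos=ann.abox.end + cfg.ie_window,
        )
        if hit is not None:
            ann.ie = Interval(hit[0], hit[0] + len(cfg.ie_seq))
            chit = _best_cbox(s, cfg, ann.ie.end, ann.ie.end + cfg.cbox_window)
            if chit is not None:
                pos, _, _ = chit
                ann.cbox = Interval(pos, pos + 10)
                ann.cbox_seq = s[pos : pos + 10]
                ann.cbox_class, ann.cbox_distance = classify_cbox(ann.cbox_seq, cfg)
    ann.mot_ie, ann.mot_c = extract_motifs(s, ann)
    return ann


def locate_similarity_region(
    ltr: SequenceRecord | str,
    five_s_gene: SequenceRecord | str,
    cfg: MotifConfig | None = None,
) -> SimilarityRegion | None:
    """Best local alignment of an LTR against the 5S rRNA gene.

    ``None`` when the best score falls below ``min_core_score`` or the
    aligned LTR span is shorter than ``min_core_len``.
    """
    cfg = cfg or MotifConfig()
    ltr_seq = ltr.residues if isinstance(ltr, SequenceRecord) else ltr.upper()
    aln = local_align(ltr_seq, five_s_gene, cfg.scoring, min_score=cfg.min_core_score)
    if aln is None or aln.span_a.length() < cfg.min_core_len:
        return None
    mid = (aln.span_a.start + aln.span_a.end) / 2.0
    return SimilarityRegion(
        ltr_span=aln.span_a,
        gene_span=aln.span_b,
        identity_pct=aln.identity_pct,
        relative_midpoint=mid / len(ltr_seq),
    )


def _find_tata(ltr_seq: str, cfg: MotifConfig) -> int | None:
    lo = max(0, cfg.tata_offset - cfg.tata_tol)
    hi = min(len(ltr_seq) - len(cfg.tata_seq), cfg.tata_offset + cfg.tata_tol)
    for p in range(lo, hi + 1):
        if ltr_seq[p : p + len(cfg.tata_seq)] == cfg.tata_seq:
            return p
    return None


def classify_element(
    cand: LtrPairCandidate,
    seq: SequenceRecord,
    five_s_gene: SequenceRecord | str,
    cfg: MotifConfig | None = None,
) -> ElementClassification:
    """Cassandra if either LTR carries a 5S similarity region; otherwise a
    Cassandra-like TRIM if a TATA box sits ~48 nt into the 5' LTR; otherwise
    a plain TRIM."""
    cfg = cfg or MotifConfig()
    ltr5 = seq.residues[cand.ltr5.start : cand.ltr5.end]
    ltr3 = seq.residues[cand.ltr3.start : cand.ltr3.end]
    reg5 = locate_similarity_region(ltr5, five_s_gene, cfg)
    reg3 = locate_similarity_region(ltr3, five_s_gene, cfg)
    if reg5 is not None or reg3 is not None:
        # the 5' LTR's region is primary when both are present
        return ElementClassification("cassandra", similarity=reg5 or reg3, similarity_3prime=reg3)
    tata = _find_tata(ltr5, cfg)
    if tata is not None:
        return ElementClassification("cassandra_like_trim", tata_offset=tata)
    return ElementClassification("other_trim")


def annotate_element(
    cand: LtrPairCandidate,
    seq: SequenceRecord,
    five_s_gene: SequenceRecord | str,
    cfg: MotifConfig | None = None,
) -> tuple[ElementClassification, PromoterAnnotation]:
    """Classify an element and annotate its 5' LTR promoter boxes."""
    cfg = cfg or MotifConfig()
    classification = classify_element(cand, seq, five_s_gene, cfg)
    ltr5 = seq.residues[cand.ltr5.start : cand.ltr5.end]
    ann = scan_boxes(ltr5, cfg)
    return classification, ann


def tally_cbox_populations(annotations: list[PromoterAnnotation]) -> dict[str, int]:
    """Counts of C-Box classes over annotated elements; elements without a
    located C-Box are counted under ``none``."""
    tally: dict[str, int] = {}
    for ann in annotations:
        key = ann.cbox_class if ann.cbox is not None else "none"
        tally[key] = tally.get(key, 0) + 1
    return tally
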