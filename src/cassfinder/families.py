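"""Family clustering and variant splitting of detected elements.

Elements are grouped into families by single-linkage clustering on pairwise
global identity at an inclusive 70% threshold.  Single linkage is used
deliberately: indel-bearing variants depress the mean identity of a family
but remain chained to it through their similarity in non-indel regions.
Families are then split into variants by shared large-indel signatures, and
per-family statistics (median lengths, mean pairwise identities) mirror the
standard summary-table layout for repeat families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import networkx as nx
import numpy as np

from cassfinder.align import Scoring, global_identity
from cassfinder.seqtypes import SequenceRecord


@dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, percent

    def __post_init__(self) -> None:
        assert self.values.shape == (len(self.ids), len(self.ids))

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass
class FamilyAssignment:
    family_id: str
    member_ids: list[str]
    variants: list[list[str]] = field(default_factory=list)
    median_full_length: float | None = None
    median_ltr_length: float | None = None
    median_internal_length: float | None = None
    overall_identity_pct: float | None = None
    ltr_identity_pct: float | None = None
    internal_identity_pct: float | None = None


def identity_matrix(seqs: list[SequenceRecord], scoring: Scoring | None = None) -> IdentityMatrix:
    """All-pairs global identity; symmetric by construction, diagonal 100."""
    scoring = scoring or Scoring()
    n = len(seqs)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pct = global_identity(seqs[i], seqs[j], scoring).identity_pct
            values[i, j] = values[j, i] = pct
    return IdentityMatrix(ids=[s.id for s in seqs], values=values)


def cluster_families(m: IdentityMatrix, threshold: float = 70.0) -> list[FamilyAssignment]:
    """Single-linkage families: connected components of the graph whose edges
    are pairs with identity >= threshold (inclusive, '70% and above').

    Family ids are assigned by descending size, ties by lexicographically
    smallest member.
    """
    g = nx.Graph()
    g.add_nodes_from(m.ids)
    n = len(m.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if m.values[i, j] >= threshold:
                g.add_edge(m.ids[i], m.ids[j])
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), c[0]))
    return [
        FamilyAssignment(family_id=f"family_{k + 1}", member_ids=comp)
        for k, comp in enumerate(components)
    ]


def _mean_offdiag(sub: np.ndarray) -> float | None:
    n = sub.shape[0]
    if n < 2:
        return None
    iu = np.triu_indices(n, k=1)
    return float(np.mean(sub[iu]))


def family_stats(
    family: FamilyAssignment,
    full: dict[str, SequenceRecord],
    ltr: dict[str, SequenceRecord] | None = None,
    internal: dict[str, SequenceRecord] | None = None,
    scoring: Scoring | None = None,
) -> FamilyAssignment:
    """Fill in median lengths and mean pairwise identities for one family.

    Median of an even-sized list is the mean of the two central values.
    Identity of a single-member family is undefined and reported as None.
    """
    members = family.member_ids

    def _median_len(pool: dict[str, SequenceRecord] | None) -> float | None:
        if not pool:
            return None
        lens = [len(pool[mid].residues) for mid in members if mid in pool]
        return float(median(lens)) if lens else None

    def _mean_identity(pool: dict[str, SequenceRecord] | None) -> float | None:
        if not pool or len(members) < 2:
            return None
        seqs = [pool[mid] for mid in members if mid in pool]
        if len(seqs) < 2:
            return None
        m = identity_matrix(seqs, scoring)
        return _mean_offdiag(m.values)

    family.median_full_length = _median_len(full)
    family.median_ltr_length = _median_len(ltr)
    family.median_internal_length = _median_len(internal)
    family.overall_identity_pct = _mean_identity(full)
    family.ltr_identity_pct = _mean_identity(ltr)
    family.internal_identity_pct = _mean_identity(internal)
    return family


# Signature alignments use affine gaps with cheap extension so that a real
# 30 bp indel stays one contiguous gap run; under the flat default scoring
# (mismatch cost == gap cost) optimal alignments can scatter the gap.
_SIGNATURE_SCORING = Scoring(match=1.0, mismatch=-2.0, gap_open=-10.0, gap_extend=-0.5)


def _indel_signature(
    member: SequenceRecord,
    reference: SequenceRecord,
    min_indel: int,
    bin_size: int,
    scoring: Scoring,
) -> tuple:
    """Large internal gap events of a member vs the family reference,
    position-binned; the signature key used for variant grouping."""
    aln = global_identity(member, reference, scoring)
    ga, gb = aln.aligned_a, aln.aligned_b
    events = []
    ref_pos = 0
    i = 0
    n = len(ga)
    # skip terminal overhangs
    lo = 0
    while lo < n and (ga[lo] == "-" or gb[lo] == "-"):
        if gb[lo] != "-":
            ref_pos += 1
        lo += 1
    hi = n
    while hi > lo and (ga[hi - 1] == "-" or gb[hi - 1] == "-"):
        hi -= 1
    i = lo
    while i < hi:
        if ga[i] == "-":  # deletion in member
            j = i
            while j < hi and ga[j] == "-":
                j += 1
            length = j - i
            if length >= min_indel:
                events.append(("del", ref_pos // bin_size, int(round(length / bin_size))))
            ref_pos += length
            i = j
        elif gb[i] == "-":  # insertion in member
            j = i
            while j < hi and gb[j] == "-":
                j += 1
            length = j - i
            if length >= min_indel:
                events.append(("ins", ref_pos // bin_size, int(round(length / bin_size))))
            i = j
        else:
            ref_pos += 1
            i += 1
    return tuple(events)


def split_variants(
    family: FamilyAssignment,
    seqs: dict[str, SequenceRecord],
    min_indel: int = 10,
    bin_size: int = 10,
    scoring: Scoring | None = None,
) -> FamilyAssignment:
    """Split a family into indel-defined variants.

    Each member is aligned to a family reference (the longest member, ties
    by smallest id); members sharing the same signature of large internal
    gap events form a variant, and members with no such events form the base
    variant.  Variants are ordered by size then smallest member id.
    """
    scoring = scoring or _SIGNATURE_SCORING
    members = [mid for mid in family.member_ids if mid in seqs]
    if not members:
        family.variants = []
        return family
    reference_id = max(members, key=lambda mid: (len(seqs[mid].residues), mid))
    groups: dict[tuple, list[str]] = {}
    for mid in members:
        if mid == reference_id:
            sig: tuple = ()
        else:
            sig = _indel_signature(seqs[mid], seqs[reference_id], min_indel, bin_size, scoring)
        groups.setdefault(sig, []).append(mid)
    variants = [sorted(v) for v in groups.values()]
    variants.sort(key=lambda v: (-len(v), v[0]))
    family.variants = variants
    return family


def family_rows(families: list[FamilyAssignment]) -> list[dict]:
    """TSV rows: one row per member with its family and variant labels."""
    rows = []
    for fam in families:
        variant_of = {}
        for vi, members in enumerate(fam.variants or [fam.member_ids]):
            for mid in members:
                variant_of[mid] = f"{fam.family_id}.v{vi + 1}"
        for mid in fam.member_ids:
            rows.append({"element_id": mid, "family": fam.family_id, "variant": variant_of.get(mid, "")})
    return rows


def stats_rows(families: list[FamilyAssignment]) -> list[dict]:
    """Summary-table rows: one per family, mirroring the standard layout
    (member count, median lengths, overall/LTR/internal pairwise identity)."""

    def fmt(x: float | None) -> str:
        return "" if x is None else f"{x:.1f}"

    return [
        {
            "family": fam.family_id,
            "n_members": len(fam.member_ids),
            "n_variants": len(fam.variants) if fam.variants else 1,
            "median_length_bp": fmt(fam.median_full_length),
            "median_ltr_bp": fmt(fam.median_ltr_length),
            "median_internal_bp": fmt(fam.median_internal_length),
            "overall_identity_pct": fmt(fam.overall_identity_pct),
            "ltr_identity_pct": fmt(fam.ltr_identity_pct),
            "internal_identity_pct": fmt(fam.internal_identity_pct),
        }
        for fam in families
    ]
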