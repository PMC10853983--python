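"""Synthetic genomes with planted ground truth.

Generates tandem 5S rDNA arrays (~120 bp gene + variable nontranscribed
spacer), 35S rDNA monomers with or without an internal 5S copy (linked vs
separated arrangement), Cassandra retrotransposons (two near-identical LTRs
flanking a short internal region, with a ~70 bp 5S-derived promoter core
located mid-LTR, PBS/PPT motifs and optional target-site duplication),
Cassandra-like TRIMs (TATA box 48 nt from the 5' LTR terminus, no 5S core),
divergence between copies, and uniform random background.  Every planted
feature is recorded as an exact truth annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from cassfinder.seqtypes import Interval, SequenceRecord

_BASES = np.array(list("ACGT"))

# C-Box references: the canonical plant motif, the shifted motif of certain
# Asteraceae 5S rRNA genes, and the further-shifted motif mirrored by the
# corresponding Cassandra elements ("promoter mimicry").
CBOX_REFS: dict[str, str] = {
    "canonical": "AGGATGGGTG",
    "anthemideae_rdna": "GGCTTGGGTG",
    "anthemideae_cassandra": "GGCCTGGGTG",
}

# A-Box / IE default strings are configurable stand-ins following the
# standard plant internal-control-region layout; only the C-Box motifs above
# are treated as reference ground truth.  The layout leaves a 4 nt spacer
# (MotIE) between A-Box and IE and a 5+ nt spacer (MotC) before the C-Box.
DEFAULT_ABOX = "GGATGCGATCATACC"  # 15 nt, occupies gene offsets [47, 62)
DEFAULT_IE = "CGATAG"  # 6 nt, gene offsets [66, 72)

DEFAULT_PBS = "TGGTATCAGAGC"  # methionine-tRNA complementary primer site
DEFAULT_PPT = "AGGGAGAGGG"  # 10 nt polypurine tract
TATA_BOX = "TATAAA"
TATA_OFFSET = 48  # nt from the 5' LTR terminus in Cassandra-like TRIMs


class SpecError(ValueError):
    """Invalid generator specification."""


def random_dna(length: int, rng: np.random.Generator) -> str:
    if length <= 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@dataclass(frozen=True)
class TruthAnnotation:
    """Ground-truth record for one planted feature."""

    contig_id: str
    feature_type: str
    interval: Interval
    attributes: dict = field(default_factory=dict)

    def shift(self, offset: int, contig_id: str | None = None) -> "TruthAnnotation":
        return TruthAnnotation(
            contig_id=contig_id or self.contig_id,
            feature_type=self.feature_type,
            interval=self.interval.shift(offset),
            attributes=dict(self.attributes),
        )


@dataclass(frozen=True)
class FiveSUnitSpec:
    """Layout of one 5S rDNA unit: ~120 bp gene + nontranscribed spacer."""

    gene_length: int = 120
    nts_length: int = 300
    cbox_variant: str = "canonical"
    abox: Interval = Interval(47, 62)
    ie: Interval = Interval(66, 72)
    cbox: Interval = Interval(79, 89)
    abox_seq: str = DEFAULT_ABOX
    ie_seq: str = DEFAULT_IE

    def __post_init__(self) -> None:
        if self.cbox_variant not in CBOX_REFS:
            raise SpecError(f"unknown C-Box variant {self.cbox_variant!r}")
        if self.cbox.end > self.gene_length:
            raise SpecError("C-Box extends past the gene end")
        if not (self.abox.end <= self.ie.start and self.ie.end <= self.cbox.start):
            raise SpecError("boxes must be ordered A-Box < IE < C-Box without overlap")
        if self.abox.length() != len(self.abox_seq) or self.ie.length() != len(self.ie_seq):
            raise SpecError("box interval lengths must match their motif strings")

    @property
    def cbox_seq(self) -> str:
        return CBOX_REFS[self.cbox_variant]


@dataclass(frozen=True)
class CassandraSpec:
    """Architecture of a synthetic Cassandra retrotransposon."""

    ltr_length: int = 270
    internal_length: int = 82
    core_offset_fraction: float = 0.5
    cbox_variant: str = "canonical"
    tsd_length: int = 5
    pbs_motif: str = DEFAULT_PBS
    ppt_seq: str = DEFAULT_PPT
    core_length: int = 70
    divergence: float = 0.0  # per-site substitution rate applied to each LTR
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (30 <= self.ltr_length <= 500):
            raise SpecError("ltr_length must lie in [30, 500]")
        if not (30 <= self.internal_length <= 2000):
            raise SpecError("internal_length must lie in [30, 2000]")
        if not (0.0 < self.core_offset_fraction < 1.0):
            raise SpecError("core_offset_fraction must lie in (0, 1)")
        if self.tsd_length and not (4 <= self.tsd_length <= 6):
            raise SpecError("tsd_length must be 0 or in [4, 6]")
        if self.internal_length < len(self.pbs_motif) + len(self.ppt_seq):
            raise SpecError("internal region too short for PBS + PPT")

    def validate_core(self) -> None:
        """The 5S core must sit strictly inside the LTR (never at a terminus)."""
        half = self.core_length // 2
        mid = self.core_offset_fraction * self.ltr_length
        if mid - half <= 0 or mid + (self.core_length - half) >= self.ltr_length:
            raise SpecError("5S core would touch an LTR terminus")


@dataclass(frozen=True)
class RdnaArraySpec:
    """Synthetic 35S rDNA monomer built from seeded marker blocks."""

    unit: FiveSUnitSpec = FiveSUnitSpec()
    len_18s: int = 1800
    len_58s: int = 160
    len_26s: int = 3400
    spacer_length: int = 400  # intergenic spacer; linked monomers carry the 5S inside it


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype="S1")


def mutate(
    seq: SequenceRecord | str,
    substitution_rate: float,
    indel_rate: float,
    seed: int,
    protect: list[Interval] | None = None,
) -> SequenceRecord:
    """Apply per-site substitutions and indels (length 1-30, uniform).

    Positions inside ``protect`` intervals are never altered and never fall
    inside a deletion.
    """
    rng = np.random.default_rng(seed)
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    name = seq.id if isinstance(seq, SequenceRecord) else "seq"
    n = len(residues)
    protected = np.zeros(n, dtype=bool)
    for iv in protect or []:
        protected[iv.start : iv.end] = True

    chars = list(residues)
    if substitution_rate > 0:
        hits = np.nonzero((rng.random(n) < substitution_rate) & ~protected)[0]
        for i in hits:
            old = chars[i]
            options = [b for b in "ACGT" if b != old]
            chars[i] = options[rng.integers(0, 3)]

    if indel_rate > 0:
        out: list[str] = []
        i = 0
        while i < n:
            if not protected[i] and rng.random() < indel_rate:
                length = int(rng.integers(1, 31))
                if rng.random() < 0.5:
                    out.append(random_dna(length, rng))  # insertion before i
                    out.append(chars[i])
                    i += 1
                else:  # deletion of up to `length` unprotected bases
                    j = i
                    while j < n and j - i < length and not protected[j]:
                        j += 1
                    i = j
            else:
                out.append(chars[i])
                i += 1
        chars = out

    return SequenceRecord(id=name, residues="".join(chars), source="mutated")


def make_5s_unit(
    spec: FiveSUnitSpec, seed: int, unit_id: str = "5S_unit"
) -> tuple[SequenceRecord, list[TruthAnnotation]]:
    """One 5S rDNA unit: gene with planted promoter boxes, then random NTS."""
    rng = np.random.default_rng(seed)
    gene = list(random_dna(spec.gene_length, rng))
    for iv, motif in (
        (spec.abox, spec.abox_seq),
        (spec.ie, spec.ie_seq),
        (spec.cbox, spec.cbox_seq),
    ):
        gene[iv.start : iv.end] = motif
    nts = random_dna(spec.nts_length, rng)
    record = SequenceRecord(id=unit_id, residues="".join(gene) + nts, source="synthetic")
    truth = [
        TruthAnnotation(unit_id, "gene", Interval(0, spec.gene_length), {"name": "5S_rRNA_gene", "cbox_variant": spec.cbox_variant}),
        TruthAnnotation(unit_id, "region", spec.abox, {"name": "A-Box"}),
        TruthAnnotation(unit_id, "region", spec.ie, {"name": "IE"}),
        TruthAnnotation(unit_id, "region", spec.cbox, {"name": "C-Box", "cbox_variant": spec.cbox_variant}),
    ]
    return record, truth


def five_s_gene(spec: FiveSUnitSpec, seed: int) -> SequenceRecord:
    """Just the ~120 bp gene portion of a 5S unit (the reference sequence)."""
    unit, _ = make_5s_unit(spec, seed)
    return SequenceRecord(id="5S_gene", residues=unit.residues[: spec.gene_length], source="synthetic")


def make_rdna_array(
    spec: RdnaArraySpec,
    n_copies: int,
    linked: bool,
    seed: int,
) -> tuple[list[SequenceRecord], list[TruthAnnotation]]:
    """Tandem rDNA array(s): one linked array, or a 35S-only plus 5S-only pair.

    All monomers within one array are identical copies, emulating a
    homogenised tandem array.
    """
    if n_copies < 2:
        raise SpecError("n_copies must be >= 2")
    rng = np.random.default_rng(seed)
    b18 = random_dna(spec.len_18s, rng)
    b58 = random_dna(spec.len_58s, rng)
    b26 = random_dna(spec.len_26s, rng)
    unit_rec, unit_truth = make_5s_unit(spec.unit, int(rng.integers(0, 2**31)))
    gene = unit_rec.residues[: spec.unit.gene_length]

    truth: list[TruthAnnotation] = []
    records: list[SequenceRecord] = []
    label = "L" if linked else "S"

    if linked:
        spacer_pad = max(0, spec.spacer_length - spec.unit.gene_length)
        left = random_dna(spacer_pad // 2, rng)
        right = random_dna(spacer_pad - spacer_pad // 2, rng)
        monomer = b18 + b58 + b26 + left + gene + right
        arr_id = "rdna_linked_array"
        seq = monomer * n_copies
        records.append(SequenceRecord(id=arr_id, residues=seq, source="synthetic"))
        gene_off = spec.len_18s + spec.len_58s + spec.len_26s + len(left)
        for c in range(n_copies):
            base = c * len(monomer)
            truth.append(TruthAnnotation(arr_id, "rDNA_monomer", Interval(base, base + len(monomer)), {"arrangement": label}))
            truth.append(TruthAnnotation(arr_id, "gene", Interval(base + gene_off, base + gene_off + len(gene)), {"name": "5S_rRNA_gene", "arrangement": label}))
    else:
        spacer = random_dna(spec.spacer_length, rng)
        monomer35 = b18 + b58 + b26 + spacer
        arr35 = "rdna_35s_array"
        records.append(SequenceRecord(id=arr35, residues=monomer35 * n_copies, source="synthetic"))
        for c in range(n_copies):
            base = c * len(monomer35)
            truth.append(TruthAnnotation(arr35, "rDNA_monomer", Interval(base, base + len(monomer35)), {"arrangement": label}))
        monomer5 = unit_rec.residues  # gene + NTS
        arr5 = "rdna_5s_array"
        records.append(SequenceRecord(id=arr5, residues=monomer5 * n_copies, source="synthetic"))
        for c in range(n_copies):
            base = c * len(monomer5)
            truth.append(TruthAnnotation(arr5, "gene", Interval(base, base + spec.unit.gene_length), {"name": "5S_rRNA_gene", "arrangement": label}))

    return records, truth


def rdna_references(spec: RdnaArraySpec, seed: int) -> dict[str, SequenceRecord]:
    """The marker reference sequences matching :func:`make_rdna_array` at ``seed``."""
    rng = np.random.default_rng(seed)
    b18 = random_dna(spec.len_18s, rng)
    b58 = random_dna(spec.len_58s, rng)
    b26 = random_dna(spec.len_26s, rng)
    unit_rec, _ = make_5s_unit(spec.unit, int(rng.integers(0, 2**31)))
    gene = unit_rec.residues[: spec.unit.gene_length]
    return {
        "18S": SequenceRecord(id="18S", residues=b18, source="synthetic"),
        "5.8S": SequenceRecord(id="5.8S", residues=b58, source="synthetic"),
        "26S": SequenceRecord(id="26S", residues=b26, source="synthetic"),
        "5S": SequenceRecord(id="5S", residues=gene, source="synthetic"),
    }


def _core_slice(spec: CassandraSpec, five_s: SequenceRecord, unit: FiveSUnitSpec) -> tuple[str, Interval, Interval]:
    """5S gene slice spanning A-Box..C-Box plus flanks, total ``core_length``.

    Returns (core string, gene-relative interval, core-relative C-Box interval).
    """
    span = Interval(unit.abox.start, unit.cbox.end)
    extra = spec.core_length - span.length()
    if extra < 0:
        raise SpecError("core_length shorter than the A-Box..C-Box span")
    left = min(extra // 2, span.start)
    right = min(extra - left, len(five_s.residues) - span.end)
    gene_iv = Interval(span.start - left, span.end + right)
    core = five_s.residues[gene_iv.start : gene_iv.end]
    cbox_rel = Interval(unit.cbox.start - gene_iv.start, unit.cbox.end - gene_iv.start)
    return core, gene_iv, cbox_rel


@dataclass(frozen=True)
class PlantedElement:
    """An element sequence plus its element-relative truth, ready to plant."""

    record: SequenceRecord
    truth: list[TruthAnnotation]
    tsd_length: int = 0


def make_cassandra(
    spec: CassandraSpec,
    five_s: SequenceRecord,
    seed: int,
    element_id: str = "cassandra",
    unit: FiveSUnitSpec | None = None,
) -> PlantedElement:
    """One Cassandra element: 5'LTR + internal + 3'LTR.

    Both LTRs carry a copy of the 5S-derived core centred at
    ``core_offset_fraction``; the C-Box inside the core is rewritten to the
    element's configured variant motif.  The PBS sits immediately 3' of the
    5' LTR, the PPT immediately 5' of the 3' LTR.  Divergence is applied
    independently to the two LTR copies (C-Box positions protected so that
    variant identity is preserved).
    """
    unit = unit or FiveSUnitSpec()
    spec.validate_core()
    rng = np.random.default_rng(seed)
    core, gene_iv, cbox_rel = _core_slice(spec, five_s, unit)
    core_list = list(core)
    core_list[cbox_rel.start : cbox_rel.end] = CBOX_REFS[spec.cbox_variant]
    core = "".join(core_list)

    half = spec.core_length // 2
    core_start = int(round(spec.core_offset_fraction * spec.ltr_length)) - half
    ltr = list(random_dna(spec.ltr_length, rng))
    ltr[core_start : core_start + spec.core_length] = core
    ltr_seq = "".join(ltr)

    pad = spec.internal_length - len(spec.pbs_motif) - len(spec.ppt_seq)
    internal = spec.pbs_motif + random_dna(pad, rng) + spec.ppt_seq

    cbox_in_ltr = Interval(core_start + cbox_rel.start, core_start + cbox_rel.end)
    protect = [cbox_in_ltr]
    ltr5 = mutate(ltr_seq, spec.divergence, spec.indel_rate, int(rng.integers(0, 2**31)), protect).residues
    ltr3 = mutate(ltr_seq, spec.divergence, spec.indel_rate, int(rng.integers(0, 2**31)), protect).residues

    residues = ltr5 + internal + ltr3
    n5, ni = len(ltr5), len(internal)
    truth = [
        TruthAnnotation(element_id, "LTR_retrotransposon", Interval(0, len(residues)), {"ID": element_id, "element_type": "cassandra", "cbox_variant": spec.cbox_variant}),
        TruthAnnotation(element_id, "long_terminal_repeat", Interval(0, n5), {"Parent": element_id, "which": "5prime"}),
        TruthAnnotation(element_id, "long_terminal_repeat", Interval(n5 + ni, len(residues)), {"Parent": element_id, "which": "3prime"}),
        TruthAnnotation(element_id, "primer_binding_site", Interval(n5, n5 + len(spec.pbs_motif)), {"Parent": element_id}),
        TruthAnnotation(element_id, "RR_tract", Interval(n5 + ni - len(spec.ppt_seq), n5 + ni), {"Parent": element_id}),
        TruthAnnotation(element_id, "region", Interval(core_start, core_start + spec.core_length), {"Parent": element_id, "name": "5S_core", "gene_span": f"{gene_iv.start}-{gene_iv.end}"}),
    ]
    rec = SequenceRecord(id=element_id, residues=residues, source="synthetic cassandra")
    return PlantedElement(record=rec, truth=truth, tsd_length=spec.tsd_length)


def make_cassandra_like_trim(
    spec: CassandraSpec, seed: int, element_id: str = "trim"
) -> PlantedElement:
    """A Cassandra-like TRIM: same two-LTR architecture, no 5S core, and a
    TATA box starting 48 nt from the 5' LTR terminus."""
    if spec.ltr_length < TATA_OFFSET + len(TATA_BOX):
        raise SpecError(f"ltr_length must be >= {TATA_OFFSET + len(TATA_BOX)} to fit the TATA box")
    rng = np.random.default_rng(seed)
    ltr = list(random_dna(spec.ltr_length, rng))
    ltr[TATA_OFFSET : TATA_OFFSET + len(TATA_BOX)] = TATA_BOX
    ltr_seq = "".join(ltr)
    pad = spec.internal_length - len(spec.pbs_motif) - len(spec.ppt_seq)
    internal = spec.pbs_motif + random_dna(pad, rng) + spec.ppt_seq
    tata_iv = Interval(TATA_OFFSET, TATA_OFFSET + len(TATA_BOX))
    ltr5 = mutate(ltr_seq, spec.divergence, spec.indel_rate, int(rng.integers(0, 2**31)), [tata_iv]).residues
    ltr3 = mutate(ltr_seq, spec.divergence, spec.indel_rate, int(rng.integers(0, 2**31)), [tata_iv]).residues
    residues = ltr5 + internal + ltr3
    n5, ni = len(ltr5), len(internal)
    truth = [
        TruthAnnotation(element_id, "LTR_retrotransposon", Interval(0, len(residues)), {"ID": element_id, "element_type": "cassandra_like_trim"}),
        TruthAnnotation(element_id, "long_terminal_repeat", Interval(0, n5), {"Parent": element_id, "which": "5prime"}),
        TruthAnnotation(element_id, "long_terminal_repeat", Interval(n5 + ni, len(residues)), {"Parent": element_id, "which": "3prime"}),
        TruthAnnotation(element_id, "primer_binding_site", Interval(n5, n5 + len(spec.pbs_motif)), {"Parent": element_id}),
        TruthAnnotation(element_id, "RR_tract", Interval(n5 + ni - len(spec.ppt_seq), n5 + ni), {"Parent": element_id}),
        TruthAnnotation(element_id, "TATA_box", tata_iv, {"Parent": element_id}),
    ]
    rec = SequenceRecord(id=element_id, residues=residues, source="synthetic cassandra-like TRIM")
    return PlantedElement(record=rec, truth=truth, tsd_length=spec.tsd_length)


class PlacementError(RuntimeError):
    """Elements could not be placed without overlap."""


def plant_elements(
    background_length: int,
    elements: list[PlantedElement],
    seed: int,
    contig_id: str = "contig",
    min_separation: int = 3200,
) -> tuple[SequenceRecord, list[TruthAnnotation]]:
    """Insert elements at non-overlapping seeded positions in random background.

    For ``tsd_length`` > 0 the insertion-site flank of that length is
    duplicated on both sides of the element, emulating a target-site
    duplication.  Truth intervals are exact genome coordinates.

    Copies are planted dispersed: insertion sites are at least
    ``min_separation`` apart.  The default exceeds the span of the largest
    admissible TRIM, so the shared 5S core of two neighbouring copies cannot
    itself be mistaken for an element's LTR pair.
    """
    rng = np.random.default_rng(seed)
    background = random_dna(background_length, rng)
    margin = 10  # distance kept from the contig ends
    needed = sum(e.tsd_length for e in elements) + 2 * margin + min_separation * max(0, len(elements) - 1)
    if elements and background_length < needed:
        raise PlacementError("background too short for the requested elements")

    positions: list[int] = []
    max_tsd = max((e.tsd_length for e in elements), default=0)
    for _ in range(10000):
        if len(positions) == len(elements):
            break
        p = int(rng.integers(margin, background_length - margin - max_tsd + 1))
        if all(abs(p - q) >= min_separation for q in positions):
            positions.append(p)
    if len(positions) < len(elements):
        raise PlacementError("could not place all elements without overlap")

    order = np.argsort(positions)
    pieces: list[str] = []
    truth: list[TruthAnnotation] = []
    cursor = 0  # background coordinate consumed so far
    out_len = 0
    for idx in order:
        elem = elements[idx]
        p = positions[idx]
        t = elem.tsd_length
        site = background[p : p + t]
        pieces.append(background[cursor : p + t])
        out_len += (p + t) - cursor
        start = out_len
        pieces.append(elem.record.residues)
        out_len += len(elem.record.residues)
        for ann in elem.truth:
            truth.append(ann.shift(start, contig_id))
        if t:
            pieces.append(site)
            out_len += t
            truth.append(
                TruthAnnotation(contig_id, "target_site_duplication", Interval(start - t, start), {"Parent": elem.record.id, "site": site})
            )
        cursor = p + t
    pieces.append(background[cursor:])
    genome = SequenceRecord(id=contig_id, residues="".join(pieces), source="synthetic genome")
    truth.sort(key=lambda a: (a.interval.start, a.interval.end))
    return genome, truth


def simulate_reads(
    genome: SequenceRecord | list[SequenceRecord],
    read_length: int,
    coverage: float,
    seed: int,
) -> list[SequenceRecord]:
    """Uniformly placed error-free reads at the requested coverage."""
    records = [genome] if isinstance(genome, SequenceRecord) else list(genome)
    rng = np.random.default_rng(seed)
    reads: list[SequenceRecord] = []
    for rec in records:
        n = len(rec.residues)
        if n < read_length:
            continue
        n_reads = int(round(coverage * n / read_length))
        if n_reads <= 0:
            continue
        starts = rng.integers(0, n - read_length + 1, size=n_reads)
        for i, s in enumerate(sorted(starts.tolist())):
            reads.append(
                SequenceRecord(
                    id=f"{rec.id}_read{i}",
                    residues=rec.residues[s : s + read_length],
                    source="simulated read",
                )
            )
    return reads


def truth_to_gff(truth: list[TruthAnnotation]):
    """Convert truth annotations to GFF3 features (lazy import avoids cycles)."""
    from cassfinder.io import Gff3Feature

    return [
        Gff3Feature(
            seqid=t.contig_id,
            ftype=t.feature_type,
            interval=t.interval,
            attributes={k: str(v) for k, v in t.attributes.items()},
            source="cassfinder-simulate",
        )
        for t in truth
    ]
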