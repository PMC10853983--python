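"""End-to-end orchestration: simulate -> detect -> annotate -> cluster ->
dotplot -> linkage -> report, plus evaluation against planted truth.

Every stage reads and writes plain files, so each is runnable standalone
with the outputs of the previous stage; two runs with the same config and
seed produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np

from cassfinder import io
from cassfinder.config import ClusterConfig, LinkageConfig, PipelineConfig, SimulateConfig, dump_config
from cassfinder.detect import DetectorConfig, LtrPairCandidate, candidate_rows, candidates_to_gff, find_ltr_pairs
from cassfinder.dotplot import DotplotConfig, all_vs_all, match_rows, shade_rows
from cassfinder.families import cluster_families, family_rows, family_stats, identity_matrix, split_variants
from cassfinder.linkage import build_kmer_graph, call_rows, classify_arrangement, color_nodes, extract_neighborhood, graph_rows
from cassfinder.promoter import MotifConfig, annotate_element, tally_cbox_populations
from cassfinder.seqtypes import Interval, SequenceRecord
from cassfinder import simulate as sim

log = logging.getLogger("cassfinder")


def _timer(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.2fs", stage, time.perf_counter() - self.t0)

    return _T()


def simulate_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    """Generate the synthetic genome, rDNA arrays, reads, references and truth."""
    sc = cfg.simulate
    rng = np.random.default_rng(cfg.seed)
    unit_spec = sim.FiveSUnitSpec(cbox_variant=sc.gene_cbox_variant)
    gene = sim.five_s_gene(unit_spec, int(rng.integers(0, 2**31)))

    elements = []
    for i in range(sc.n_cassandra):
        spec = sim.CassandraSpec(
            ltr_length=sc.ltr_length,
            internal_length=sc.internal_length,
            divergence=sc.divergence,
            tsd_length=sc.tsd_length,
            cbox_variant=sc.element_cbox_variant,
        )
        elements.append(
            sim.make_cassandra(spec, gene, int(rng.integers(0, 2**31)), element_id=f"cassandra_{i}", unit=unit_spec)
        )
    for i in range(sc.n_trim):
        spec = sim.CassandraSpec(
            ltr_length=max(54, sc.ltr_length),
            internal_length=sc.internal_length,
            divergence=sc.divergence,
            tsd_length=sc.tsd_length,
        )
        elements.append(sim.make_cassandra_like_trim(spec, int(rng.integers(0, 2**31)), element_id=f"trim_{i}"))

    genome, truth = sim.plant_elements(sc.background_length, elements, int(rng.integers(0, 2**31)))

    rdna_spec = sim.RdnaArraySpec(
        unit=unit_spec,
        len_18s=int(1800 * sc.rdna_scale),
        len_58s=int(160 * sc.rdna_scale),
        len_26s=int(3400 * sc.rdna_scale),
        spacer_length=int(400 * sc.rdna_scale),
    )
    rdna_seed = int(rng.integers(0, 2**31))
    arrays, rdna_truth = sim.make_rdna_array(rdna_spec, sc.rdna_copies, sc.rdna_linked, rdna_seed)
    refs = sim.rdna_references(rdna_spec, rdna_seed)
    reads = sim.simulate_reads(arrays, cfg.linkage.read_length, cfg.linkage.coverage, int(rng.integers(0, 2**31)))

    io.write_fasta(outdir / "genome.fasta", [genome])
    io.write_fasta(outdir / "five_s_gene.fasta", [gene])
    io.write_gff3(outdir / "truth.gff3", sim.truth_to_gff(truth + rdna_truth))
    io.write_fasta(outdir / "rdna_reads.fasta", reads)
    io.write_fasta(outdir / "rdna_references.fasta", list(refs.values()))
    manifest = [
        {
            "element_id": t.attributes.get("ID", ""),
            "type": t.attributes.get("element_type", ""),
            "cbox_variant": t.attributes.get("cbox_variant", ""),
            "contig": t.contig_id,
            "start": t.interval.start,
            "end": t.interval.end,
            "arrangement": "L" if sc.rdna_linked else "S",
        }
        for t in truth
        if t.feature_type == "LTR_retrotransposon"
    ]
    io.write_tsv(outdir / "manifest.tsv", manifest, columns=["element_id", "type", "cbox_variant", "contig", "start", "end", "arrangement"])
    return {
        "genome": genome,
        "gene": gene,
        "truth": truth,
        "reads": reads,
        "references": list(refs.values()),
        "arrangement": "L" if sc.rdna_linked else "S",
    }


def detect_stage(genome: SequenceRecord, cfg: DetectorConfig, outdir: Path) -> list[LtrPairCandidate]:
    cands = find_ltr_pairs(genome, cfg)
    io.write_gff3(outdir / "candidates.gff3", candidates_to_gff(cands))
    io.write_tsv(
        outdir / "candidates.tsv",
        candidate_rows(cands),
        columns=[
            "element_id", "contig", "start", "end", "ltr5_start", "ltr5_end",
            "ltr3_start", "ltr3_end", "ltr_identity_pct", "tsd", "pbs_offset",
            "pbs_mismatches", "ppt_offset", "ppt_purines", "tg_ca",
        ],
    )
    return cands


def annotate_stage(
    cands: list[LtrPairCandidate],
    genome: SequenceRecord,
    gene: SequenceRecord,
    cfg: MotifConfig,
    outdir: Path,
) -> list[dict]:
    results = []
    for i, cand in enumerate(cands):
        classification, ann = annotate_element(cand, genome, gene, cfg)
        reg = classification.similarity
        results.append(
            {
                "element_id": f"ltrpair_{cand.contig_id}_{i}",
                "label": classification.label,
                "cbox_seq": ann.cbox_seq or "",
                "cbox_class": ann.cbox_class if ann.cbox else "none",
                "mot_ie": ann.mot_ie or "",
                "mot_c": ann.mot_c or "",
                "core_ltr_start": "" if reg is None else reg.ltr_span.start,
                "core_ltr_end": "" if reg is None else reg.ltr_span.end,
                "core_identity_pct": "" if reg is None else f"{reg.identity_pct:.1f}",
                "relative_midpoint": "" if reg is None else f"{reg.relative_midpoint:.3f}",
                "tata_offset": "" if classification.tata_offset is None else classification.tata_offset,
                "_annotation": ann,
                "_classification": classification,
                "_candidate": cand,
            }
        )
    io.write_tsv(
        outdir / "annotation.tsv",
        [{k: v for k, v in r.items() if not k.startswith("_")} for r in results],
        columns=[
            "element_id", "label", "cbox_seq", "cbox_class", "mot_ie", "mot_c",
            "core_ltr_start", "core_ltr_end", "core_identity_pct", "relative_midpoint", "tata_offset",
        ],
    )
    tally = tally_cbox_populations([r["_annotation"] for r in results])
    io.write_tsv(
        outdir / "cbox_populations.tsv",
        [{"cbox_class": k, "count": v} for k, v in sorted(tally.items())],
        columns=["cbox_class", "count"],
    )
    return results


def cluster_stage(
    cands: list[LtrPairCandidate],
    genome: SequenceRecord,
    cfg: ClusterConfig,
    outdir: Path,
):
    seqs = [genome.slice(c.element, new_id=f"ltrpair_{c.contig_id}_{i}") for i, c in enumerate(cands)]
    ltrs = {
        f"ltrpair_{c.contig_id}_{i}": genome.slice(c.ltr5, new_id=f"ltrpair_{c.contig_id}_{i}")
        for i, c in enumerate(cands)
    }
    internals = {
        f"ltrpair_{c.contig_id}_{i}": genome.slice(c.internal, new_id=f"ltrpair_{c.contig_id}_{i}")
        for i, c in enumerate(cands)
    }
    if not seqs:
        io.write_tsv(outdir / "families.tsv", [], columns=["element_id", "family", "variant"])
        io.write_tsv(outdir / "family_stats.tsv", [], columns=["family", "n_members", "n_variants"])
        return []
    matrix = identity_matrix(seqs)
    families = cluster_families(matrix, cfg.threshold)
    pool = {s.id: s for s in seqs}
    for fam in families:
        split_variants(fam, pool, cfg.min_indel, cfg.bin_size)
        family_stats(fam, pool, ltrs, internals)
    io.write_tsv(outdir / "families.tsv", family_rows(families), columns=["element_id", "family", "variant"])
    from cassfinder.families import stats_rows

    io.write_tsv(
        outdir / "family_stats.tsv",
        stats_rows(families),
        columns=[
            "family", "n_members", "n_variants", "median_length_bp", "median_ltr_bp",
            "median_internal_bp", "overall_identity_pct", "ltr_identity_pct", "internal_identity_pct",
        ],
    )
    return families


def dotplot_stage(cands, genome: SequenceRecord, cfg: DotplotConfig, outdir: Path):
    seqs = [genome.slice(c.ltr5, new_id=f"ltrpair_{c.contig_id}_{i}_ltr") for i, c in enumerate(cands)]
    if not seqs:
        io.write_tsv(outdir / "dotplot_matches.tsv", [], columns=["seq_a", "seq_b", "i", "j"])
        io.write_tsv(outdir / "dotplot_shading.tsv", [], columns=["seq_a", "seq_b", "shade_metric", "n_matches"])
        return {}
    grid = all_vs_all(seqs, cfg)
    io.write_tsv(outdir / "dotplot_matches.tsv", match_rows(grid), columns=["seq_a", "seq_b", "i", "j"])
    io.write_tsv(outdir / "dotplot_shading.tsv", shade_rows(grid), columns=["seq_a", "seq_b", "shade_metric", "n_matches"])
    return grid


def linkage_stage(reads, references, cfg: LinkageConfig, outdir: Path):
    graph = build_kmer_graph(reads, cfg.k, cfg.min_count)
    color_nodes(graph, references)
    sub = extract_neighborhood(graph, cfg.distance)
    call = classify_arrangement(sub)
    io.write_tsv(outdir / "linkage_call.tsv", call_rows(call), columns=["label", "colored_components", "colors", "cyclic", "reason"])
    io.write_tsv(outdir / "graph.tsv", graph_rows(sub), columns=["unitig", "length", "n_kmers", "mean_coverage", "links", "colors"])
    return call


def run_full(cfg: PipelineConfig) -> dict:
    """Run the whole pipeline under one config; returns in-memory results."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    dump_config(cfg, outdir / "resolved_config.yaml")

    with _timer("simulate"):
        data = simulate_stage(cfg, outdir)
    with _timer("detect"):
        cands = detect_stage(data["genome"], cfg.detector, outdir)
    with _timer("annotate"):
        annotations = annotate_stage(cands, data["genome"], data["gene"], cfg.motifs, outdir)
    with _timer("cluster"):
        families = cluster_stage(cands, data["genome"], cfg.clustering, outdir)
    with _timer("dotplot"):
        grid = dotplot_stage(cands, data["genome"], cfg.dotplot, outdir)
    with _timer("linkage"):
        call = linkage_stage(data["reads"], data["references"], cfg.linkage, outdir)

    family_of = {}
    for fam in families:
        for vi, members in enumerate(fam.variants or [fam.member_ids]):
            for mid in members:
                family_of[mid] = (fam.family_id, f"{fam.family_id}.v{vi + 1}")
    summary = []
    for row in annotations:
        fam, var = family_of.get(row["element_id"], ("", ""))
        summary.append(
            {
                "element_id": row["element_id"],
                "label": row["label"],
                "family": fam,
                "variant": var,
                "cbox_class": row["cbox_class"],
                "arrangement": call.label,
            }
        )
    io.write_tsv(outdir / "summary.tsv", summary, columns=["element_id", "label", "family", "variant", "cbox_class", "arrangement"])

    with _timer("evaluate"):
        metrics = evaluate_against_truth(cands, annotations, call, data["truth"], data["arrangement"], outdir)
    return {
        "cands": cands,
        "annotations": annotations,
        "families": families,
        "grid": grid,
        "call": call,
        "truth": data["truth"],
        "metrics": metrics,
    }


def _reciprocal_overlap(a: Interval, b: Interval) -> float:
    ov = a.overlap(b)
    return min(ov / a.length(), ov / b.length())


def evaluate_against_truth(
    cands: list[LtrPairCandidate],
    annotations: list[dict],
    call,
    truth: list,
    true_arrangement: str,
    outdir: Path | None = None,
) -> dict:
    """Per-stage metrics vs planted truth.

    Detection matches at >= 50% reciprocal overlap of element spans;
    classification accuracy over matched elements; arrangement accuracy for
    the linkage call.  With no truth elements and no detections, precision
    and recall are reported as not-applicable.
    """
    true_elements = [t for t in truth if t.feature_type == "LTR_retrotransposon"]
    matched_truth: dict[int, int] = {}
    matched_cand: set[int] = set()
    for ci, cand in enumerate(cands):
        for ti, t in enumerate(true_elements):
            if ti in matched_truth:
                continue
            if t.contig_id == cand.contig_id and _reciprocal_overlap(cand.element, t.interval) >= 0.5:
                matched_truth[ti] = ci
                matched_cand.add(ci)
                break
    if not true_elements and not cands:
        precision = recall = None
    else:
        precision = len(matched_cand) / len(cands) if cands else (None if not true_elements else 0.0)
        recall = len(matched_truth) / len(true_elements) if true_elements else (None if not cands else 0.0)

    label_map = {"cassandra": "cassandra", "cassandra_like_trim": "cassandra_like_trim"}
    n_labelled = n_correct = 0
    by_candidate = {ci: annotations[ci] for ci in range(len(annotations))}
    for ti, ci in matched_truth.items():
        true_label = true_elements[ti].attributes.get("element_type", "")
        pred = by_candidate.get(ci, {}).get("label", "")
        if true_label in label_map:
            n_labelled += 1
            if pred == true_label:
                n_correct += 1
    classification_acc = (n_correct / n_labelled) if n_labelled else None
    arrangement_ok = None
    if call is not None:
        arrangement_ok = 1.0 if call.label == true_arrangement else 0.0

    metrics = {
        "detection_precision": precision,
        "detection_recall": recall,
        "classification_accuracy": classification_acc,
        "arrangement_accuracy": arrangement_ok,
        "n_truth_elements": len(true_elements),
        "n_candidates": len(cands),
    }
    if outdir is not None:
        rows = [
            {"metric": k, "value": "NA" if v is None else (f"{v:.4f}" if isinstance(v, float) else v)}
            for k, v in metrics.items()
        ]
        io.write_tsv(outdir / "metrics.tsv", rows, columns=["metric", "value"])
    return metrics
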