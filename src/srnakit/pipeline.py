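"""Chained execution of the five pipeline stages with a run manifest.

Stages run in the fixed order qc -> align -> annotate -> microbe -> function,
but any subset can be requested as long as the inputs each stage needs are
available — either produced by an earlier stage in the same run or supplied
in the config (e.g. a SAM file for annotate-only runs). A JSON manifest
records parameters, input hashes and per-stage read counts so a run can be
audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

from . import __version__, align, annotate, microbe, qc, stats
from .fixtures import read_acc2taxid

STAGE_ORDER = ("qc", "align", "annotate", "microbe", "function")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; CLI flags map onto these fields."""

    out_dir: str
    stages: Sequence[str] = STAGE_ORDER
    # sample inputs: parallel lists of names and raw FASTQ paths
    sample_names: Sequence[str] = ()
    fastq_paths: Sequence[str] = ()
    qc_config: qc.QCConfig = field(default_factory=qc.QCConfig)
    # align
    genome_fasta: str | None = None
    max_mismatch: int = 1
    # annotate-only runs may supply pre-made alignments per sample
    sam_paths: dict[str, str] = field(default_factory=dict)
    feature_dbs: Sequence[tuple[str, str, str]] = ()  # (path, db_name, rna_type)
    min_ratio: float = 1.0
    strand_mode: str = "same"
    export_types: Sequence[str] = ()  # -abam
    # microbe
    microbe_ref_fasta: str | None = None
    taxonomy_tsv: str | None = None
    acc2taxid_tsv: str | None = None
    microbe_max_mismatch: int = 0
    max_evalue: float = 1e-3
    min_identity: float = 90.0
    # function
    case: Sequence[str] = ()
    control: Sequence[str] = ()
    normalize: str | None = "cpm"
    detection_threshold: int = stats.DEFAULT_DETECTION_THRESHOLD


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages; returns the manifest (also written as
    ``manifest.json`` in the output directory)."""
    stages = [s for s in STAGE_ORDER if s in config.stages]
    unknown = set(config.stages) - set(STAGE_ORDER)
    _require(not unknown, f"unknown stage(s): {sorted(unknown)}")
    _require(bool(stages), "no stages requested")
    os.makedirs(config.out_dir, exist_ok=True)

    samples = list(config.sample_names)
    _require(
        len(samples) == len(set(samples)), "sample names must be unique"
    )
    manifest: dict = {
        "tool": "srnakit",
        "version": __version__,
        "stages": stages,
        "samples": samples,
        "parameters": {
            "qc": asdict(config.qc_config),
            "max_mismatch": config.max_mismatch,
            "min_ratio": config.min_ratio,
            "strand_mode": config.strand_mode,
            "microbe": {
                "max_mismatch": config.microbe_max_mismatch,
                "max_evalue": config.max_evalue,
                "min_identity": config.min_identity,
            },
            "normalize": config.normalize,
            "detection_threshold": config.detection_threshold,
        },
        "inputs": {},
        "per_stage": {},
    }
    for path in list(config.fastq_paths) + [
        p for p in (config.genome_fasta, config.microbe_ref_fasta,
                    config.taxonomy_tsv, config.acc2taxid_tsv) if p
    ] + [p for p, _, _ in config.feature_dbs] + list(config.sam_paths.values()):
        manifest["inputs"][path] = _sha256(path)

    # per-sample state
    qualified: dict[str, list[qc.Read]] = {}
    alignments: dict[str, list[align.Alignment]] = {}
    unmapped: dict[str, list[qc.Read]] = {}
    count_tables: dict[str, dict] = {}

    def sample_dir(sample: str) -> str:
        d = os.path.join(config.out_dir, sample)
        os.makedirs(d, exist_ok=True)
        return d

    if "qc" in stages:
        _require(
            len(config.fastq_paths) == len(samples) and samples,
            "qc stage requires one FASTQ per sample",
        )
        stage_stats = {}
        for sample, fastq_path in zip(samples, config.fastq_paths):
            d = sample_dir(sample)
            reads, report = qc.run_qc(
                fastq_path,
                config.qc_config,
                out_fastq=os.path.join(d, "qualified.fastq"),
                report_path=os.path.join(d, "qc_report.tsv"),
            )
            qualified[sample] = reads
            stage_stats[sample] = {
                "input": report.n_input,
                "qualified": report.n_qualified,
            }
        manifest["per_stage"]["qc"] = stage_stats

    genome = None
    if "align" in stages:
        _require(config.genome_fasta is not None, "align stage requires a genome FASTA")
        genome = align.GenomeRef.from_fasta(config.genome_fasta)
        stage_stats = {}
        for sample in samples:
            if sample not in qualified:
                _require(
                    len(config.fastq_paths) == len(samples),
                    f"align stage for {sample}: no qualified reads "
                    "(run qc or supply qualified FASTQ)",
                )
                fastq_path = dict(zip(samples, config.fastq_paths))[sample]
                qualified[sample] = list(qc.read_fastq(fastq_path))
            d = sample_dir(sample)
            alns, unm = align.micro_align(
                qualified[sample], genome, config.max_mismatch
            )
            alignments[sample] = alns
            unmapped[sample] = unm
            align.write_sam(
                alns,
                os.path.join(d, "aligned.sam"),
                genome.lengths,
                reads={r.id: r for r in qualified[sample]},
            )
            align.write_unmapped_fasta(unm, os.path.join(d, "unmapped.fa"))
            stage_stats[sample] = {
                "alignments": len(alns),
                "mapped_reads": len({a.read_id for a in alns}),
                "unmapped_reads": len(unm),
            }
        manifest["per_stage"]["align"] = stage_stats

    if "annotate" in stages:
        _require(bool(config.feature_dbs), "annotate stage requires feature databases")
        records = []
        for path, db_name, rna_type in config.feature_dbs:
            records.extend(annotate.load_feature_db(path, db_name, rna_type))
        index = annotate.FeatureIndex(records)
        stage_stats = {}
        for sample in samples:
            if sample not in alignments:
                _require(
                    sample in config.sam_paths,
                    f"annotate stage for {sample}: no alignments "
                    "(run align or supply a SAM path)",
                )
                alns, unm = align.ingest_sam(config.sam_paths[sample])
                alignments[sample] = alns
                unmapped.setdefault(sample, unm)
            d = sample_dir(sample)
            groups = align.group_by_read(alignments[sample])
            tables, read_annotations = annotate.quantify(
                groups, index, config.min_ratio, config.strand_mode
            )
            count_tables[sample] = tables
            for rna_type, table in tables.items():
                annotate.write_count_table(
                    table, os.path.join(d, f"counts_{rna_type}.tsv")
                )
            for rna_type in config.export_types:
                lengths = (
                    genome.lengths
                    if genome is not None
                    else {a.chrom: a.end for a in alignments[sample]}
                )
                annotate.export_reads_by_type(
                    alignments[sample],
                    read_annotations,
                    rna_type,
                    os.path.join(d, f"reads_{rna_type}.sam"),
                    lengths,
                    reads={r.id: r for r in qualified.get(sample, [])},
                )
            stage_stats[sample] = {
                rna_type: int(table["Count"].sum()) for rna_type, table in tables.items()
            }
        manifest["per_stage"]["annotate"] = stage_stats

    if "microbe" in stages:
        _require(
            config.microbe_ref_fasta is not None
            and config.taxonomy_tsv is not None
            and config.acc2taxid_tsv is not None,
            "microbe stage requires reference FASTA, taxonomy TSV and acc2taxid map",
        )
        references = {
            r.id: r.seq for r in align.read_fasta(config.microbe_ref_fasta)
        }
        tree = microbe.TaxonomyTree.from_tsv(config.taxonomy_tsv)
        acc2taxid = read_acc2taxid(config.acc2taxid_tsv)
        stage_stats = {}
        for sample in samples:
            _require(
                sample in unmapped,
                f"microbe stage for {sample}: no unmapped reads (run align first)",
            )
            d = sample_dir(sample)
            raw_hits = microbe.micro_match(
                unmapped[sample], references, config.microbe_max_mismatch
            )
            microbe.write_blast_tabular(raw_hits, os.path.join(d, "microbe_hits.tsv"))
            hits = [
                h for h in raw_hits if h.subject_id in acc2taxid
            ]
            hits = [
                microbe.BlastHit(**{**asdict(h), "taxid": acc2taxid[h.subject_id]})
                for h in hits
            ]
            table = microbe.screen_reads(
                hits, tree, config.max_evalue, config.min_identity
            )
            table.to_csv(os.path.join(d, "microbe_counts.tsv"), sep="\t", index=False)
            stage_stats[sample] = {"hits": len(hits), "taxa": len(table)}
        manifest["per_stage"]["microbe"] = stage_stats

    if "function" in stages:
        _require(bool(count_tables), "function stage requires count tables (run annotate)")
        stage_stats = {}
        for rna_type in annotate.RNA_TYPES:
            tables = [
                (sample, count_tables[sample][rna_type]) for sample in samples
            ]
            tables = [(s, t) for s, t in tables if len(t)]
            if not tables:
                continue
            merged = stats.merge_samples(tables)
            merged_path = os.path.join(config.out_dir, f"merged_{rna_type}.tsv")
            merged.to_csv(merged_path, sep="\t")
            entry = {"molecules": len(merged), "samples": len(merged.columns)}
            if config.case and config.control:
                de = stats.mann_whitney_de(
                    merged, list(config.case), list(config.control), config.normalize
                )
                de.to_csv(os.path.join(config.out_dir, f"de_{rna_type}.tsv"), sep="\t")
                entry["tested"] = len(de)
            stage_stats[rna_type] = entry
        manifest["per_stage"]["function"] = stage_stats

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest
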