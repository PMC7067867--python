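"""Overlap-ratio annotation of aligned reads against small RNA databases.

The degree of read support for a feature is the overlap ratio

    r_olp = l_olp / l_read

where ``l_olp`` is the number of read bases covered by the feature interval
and ``l_read`` the number of aligned bases of the read. At the default
stringency ``min_ratio = 1`` a read is annotated to a feature only when its
aligned span lies completely within the annotation interval.

Counting rules for multi-mapped reads:

* a read aligned to several loci of one molecule is counted once for that
  molecule (deduplication at the (rna_type, name) level);
* a read whose alignment supports molecules of different types — e.g. a miRNA
  nested inside a longer piRNA — contributes one count to EACH molecule; no
  RNA type takes priority over another.

Feature databases are BED6-like tab-delimited text (chrom, start, end, name,
id, strand; 0-based half-open), tagged on load with their database of origin
and RNA type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .align import Alignment, write_sam
from .qc import Read

logger = logging.getLogger(__name__)

RNA_TYPES = ("miRNA", "piRNA", "snRNA", "snoRNA", "tRNA", "circRNA", "other")

#: A molecule is identified by (rna_type, name) — one molecule may own
#: multiple genomic intervals (multi-locus genes) and entries in several
#: databases.
MoleculeKey = tuple[str, str]


@dataclass(frozen=True)
class FeatureRecord:
    """One annotation interval of a small RNA molecule."""

    db: str
    rna_type: str
    name: str
    id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.rna_type not in RNA_TYPES:
            raise ValueError(
                f"unknown RNA type {self.rna_type!r}; valid types: {', '.join(RNA_TYPES)}"
            )
        if self.start >= self.end:
            raise ValueError(f"feature {self.name}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.name}: strand must be + or -")

    @property
    def molecule(self) -> MoleculeKey:
        return (self.rna_type, self.name)


@dataclass(frozen=True)
class OverlapRatio:
    """Degree of read support: overlapped bases over aligned read bases."""

    l_olp: int
    l_read: int

    @property
    def r_olp(self) -> float:
        return self.l_olp / self.l_read


class FeatureIndex:
    """Per-chromosome interval index over feature records."""

    def __init__(self, records: Iterable[FeatureRecord] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._records: list[FeatureRecord] = []
        for rec in records:
            self.add(rec)

    def add(self, rec: FeatureRecord) -> None:
        self._trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, rec)
        self._records.append(rec)

    def query(self, chrom: str, start: int, end: int) -> list[FeatureRecord]:
        """All features whose interval intersects [start, end) on ``chrom``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)


def compute_overlap_ratio(
    aln: Alignment,
    feat: FeatureRecord,
    full_read_length: bool = False,
) -> OverlapRatio:
    """Overlap ratio between an alignment and a feature interval.

    ``l_olp`` is the size of the intersection of the aligned reference span
    and the feature interval (0 when on different chromosomes). ``l_read`` is
    the aligned span on the read by default, so an isomiR whose non-templated
    end bases were soft-clipped by a local aligner can still reach ratio 1;
    set ``full_read_length`` to divide by the complete read length instead.
    """
    l_read = (
        aln.read_length if full_read_length else aln.read_span[1] - aln.read_span[0]
    )
    if l_read <= 0:
        raise ValueError(f"alignment {aln.read_id}: zero-length read span")
    if aln.chrom != feat.chrom:
        return OverlapRatio(0, l_read)
    l_olp = max(0, min(aln.end, feat.end) - max(aln.start, feat.start))
    return OverlapRatio(l_olp, l_read)


def annotate_read(
    group: Sequence[Alignment],
    index: FeatureIndex,
    min_ratio: float = 1.0,
    strand_mode: str = "same",
    full_read_length: bool = False,
) -> set[FeatureRecord]:
    """All features supported by any alignment of one read.

    Returns every feature record with overlap ratio >= ``min_ratio`` for at
    least one alignment in the read's multimap group. ``strand_mode`` is
    ``"same"`` (feature strand must match alignment strand; small RNA
    annotations are strand-specific) or ``"ignore"``. Molecule-level
    deduplication happens downstream in :func:`quantify`; here the full
    record set is returned so database support can be reported.
    """
    if not 0.0 < min_ratio <= 1.0:
        raise ValueError("min_ratio must be in (0, 1]")
    if strand_mode not in ("same", "ignore"):
        raise ValueError("strand_mode must be 'same' or 'ignore'")
    matched: set[FeatureRecord] = set()
    for aln in group:
        for feat in index.query(aln.chrom, aln.start, aln.end):
            if strand_mode == "same" and feat.strand != aln.strand:
                continue
            ratio = compute_overlap_ratio(aln, feat, full_read_length=full_read_length)
            if ratio.r_olp >= min_ratio:
                matched.add(feat)
    return matched


_COUNT_COLUMNS = ["DB", "Name", "ID", "Count"]


def quantify(
    groups: Mapping[str, Sequence[Alignment]],
    index: FeatureIndex,
    min_ratio: float = 1.0,
    strand_mode: str = "same",
    full_read_length: bool = False,
) -> tuple[dict[str, pd.DataFrame], dict[str, set[MoleculeKey]]]:
    """Per-type count tables for one sample.

    The count of a molecule is the number of distinct reads whose annotation
    contains it — each read contributes at most 1 to any molecule, however
    many loci or databases supported the assignment. Because no RNA type has
    priority, a read can count toward molecules of several types, so column
    sums may exceed the number of annotated reads by design.

    Returns ``(tables, read_annotations)`` where ``tables`` maps rna_type to a
    four-column DataFrame (DB, Name, ID, Count; DB and ID list all supporting
    databases/ids, ';'-joined) and ``read_annotations`` maps read id to its
    molecule set.
    """
    counts: dict[MoleculeKey, int] = {}
    dbs: dict[MoleculeKey, set[str]] = {}
    ids: dict[MoleculeKey, set[str]] = {}
    read_annotations: dict[str, set[MoleculeKey]] = {}
    for read_id, group in groups.items():
        records = annotate_read(
            group, index, min_ratio, strand_mode, full_read_length=full_read_length
        )
        molecules = {rec.molecule for rec in records}
        read_annotations[read_id] = molecules
        for mol in molecules:
            counts[mol] = counts.get(mol, 0) + 1
        for rec in records:
            dbs.setdefault(rec.molecule, set()).add(rec.db)
            ids.setdefault(rec.molecule, set()).add(rec.id)
    tables: dict[str, pd.DataFrame] = {}
    for rna_type in RNA_TYPES:
        rows = [
            {
                "DB": ";".join(sorted(dbs[mol])),
                "Name": mol[1],
                "ID": ";".join(sorted(ids[mol])),
                "Count": counts[mol],
            }
            for mol in counts
            if mol[0] == rna_type
        ]
        table = pd.DataFrame(rows, columns=_COUNT_COLUMNS)
        if len(table):
            table = table.sort_values(
                ["Count", "Name"], ascending=[False, True], ignore_index=True
            )
        tables[rna_type] = table
    return tables, read_annotations


def write_count_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_count_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"DB": str, "Name": str, "ID": str})
    missing = [c for c in _COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return table


def export_reads_by_type(
    alignments: Sequence[Alignment],
    read_annotations: Mapping[str, set[MoleculeKey]],
    rna_type: str,
    path: str,
    reference_lengths: Mapping[str, int],
    reads: Mapping[str, Read] | None = None,
) -> int:
    """Write the alignments of all reads annotated to ``rna_type`` as SAM.

    A read annotated to several types appears in each type's export (the
    no-priority rule). Returns the number of records written.
    """
    if rna_type not in RNA_TYPES:
        raise ValueError(
            f"unknown RNA type {rna_type!r}; valid types: {', '.join(RNA_TYPES)}"
        )
    wanted = {
        read_id
        for read_id, molecules in read_annotations.items()
        if any(mol[0] == rna_type for mol in molecules)
    }
    subset = [aln for aln in alignments if aln.read_id in wanted]
    write_sam(subset, path, reference_lengths, reads)
    return len(subset)


def load_feature_db(path: str, db_name: str, rna_type: str) -> list[FeatureRecord]:
    """Load a BED6-like feature database file.

    Columns: chrom, start, end, name, id, strand (tab-delimited); ``track``,
    ``browser`` and ``#`` comment lines are skipped. Coordinates are taken
    verbatim (BED is already 0-based half-open). Duplicate lines are
    deduplicated with a log message; malformed lines raise with their
    1-based line number.
    """
    records: list[FeatureRecord] = []
    seen: set[FeatureRecord] = set()
    n_dup = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 tab-delimited columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name, feat_id, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            try:
                rec = FeatureRecord(
                    db=db_name,
                    rna_type=rna_type,
                    name=name,
                    id=feat_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if rec in seen:
                n_dup += 1
                continue
            seen.add(rec)
            records.append(rec)
    if n_dup:
        logger.info("%s: skipped %d duplicate feature line(s)", path, n_dup)
    return records


def write_feature_db(records: Iterable[FeatureRecord], path: str) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t{rec.id}\t{rec.strand}\n"
            )
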