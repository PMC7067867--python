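"""Genome alignments for qualified reads.

Two routes produce the same in-memory representation:

* :func:`ingest_sam` converts SAM/BAM records from an external aligner
  (soft clips honored, secondary alignments grouped by read id);
* :func:`micro_align` is a built-in exhaustive micro-aligner — end-to-end
  Hamming matching on both strands — for self-contained, test-scale genomes.

Coordinates are 0-based half-open everywhere internally; SAM's 1-based
positions are translated at the boundary. Reads with no placement form the
unmapped set, which can be written to FASTA for microbial screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from .qc import Read

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Alignment:
    """One placement of a read on the genome.

    ``start``/``end`` are 0-based half-open genomic coordinates of the aligned
    reference span. ``read_span`` is the (start, end) half-open interval of the
    read's bases that are aligned (soft-clipped bases excluded); for end-to-end
    alignments it covers the whole read. ``read_length`` is the full read
    length including any clipped bases.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_mismatch: int = 0
    read_span: tuple[int, int] = (0, 0)
    read_length: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"alignment {self.read_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"alignment {self.read_id}: strand must be + or -")
        if self.n_mismatch < 0:
            raise ValueError(f"alignment {self.read_id}: negative mismatch count")


@dataclass
class GenomeRef:
    """An in-memory reference genome: chromosome name -> sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise ValueError(f"chromosome {name}: invalid bases {sorted(bad)}")
            self.sequences[name] = seq.upper()

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeRef":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")})

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as handle:
            for name, seq in self.sequences.items():
                handle.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    handle.write(seq[i : i + width] + "\n")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def micro_align(
    reads: Iterable[Read],
    genome: GenomeRef,
    max_mismatch: int = 1,
) -> tuple[list[Alignment], list[Read]]:
    """Exhaustively place each read on the genome with <= ``max_mismatch``.

    Every end-to-end placement on either strand (the read reverse-complemented
    for '-') within the mismatch budget is reported, so multi-mapped reads
    yield complete multimap groups. Reads with no placement — including reads
    longer than every chromosome — go to the unmapped set.
    """
    encoded = {name: _encode(seq) for name, seq in genome.sequences.items()}
    alignments: list[Alignment] = []
    unmapped: list[Read] = []
    for read in reads:
        n = len(read.seq)
        if n == 0:
            unmapped.append(read)
            continue
        hits: list[Alignment] = []
        for strand, seq in (("+", read.seq), ("-", reverse_complement(read.seq))):
            query = _encode(seq)
            for chrom, garr in encoded.items():
                if n > len(garr):
                    continue
                n_windows = len(garr) - n + 1
                mism = np.zeros(n_windows, dtype=np.int32)
                for j in range(n):
                    mism += garr[j : j + n_windows] != query[j]
                for pos in np.nonzero(mism <= max_mismatch)[0]:
                    hits.append(
                        Alignment(
                            read_id=read.id,
                            chrom=chrom,
                            start=int(pos),
                            end=int(pos) + n,
                            strand=strand,
                            n_mismatch=int(mism[pos]),
                            read_span=(0, n),
                            read_length=n,
                        )
                    )
        if hits:
            alignments.extend(hits)
        else:
            unmapped.append(read)
    return alignments, unmapped


def group_by_read(alignments: Iterable[Alignment]) -> dict[str, list[Alignment]]:
    """Group alignments into multimap groups keyed by read id."""
    groups: dict[str, list[Alignment]] = {}
    for aln in alignments:
        groups.setdefault(aln.read_id, []).append(aln)
    return groups


def ingest_sam(path: str) -> tuple[list[Alignment], list[Read]]:
    """Read SAM/BAM into alignments plus the unmapped read set.

    SAM's 1-based POS becomes a 0-based half-open interval; the CIGAR string
    determines both the reference span and the soft-clip-aware span on the
    read. Mismatch counts come from the NM tag when present. Records flagged
    unmapped are returned as reads (qualities default to 0 when absent).
    """
    alignments: list[Alignment] = []
    unmapped: list[Read] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as handle:
        for i, rec in enumerate(handle):
            try:
                if rec.is_unmapped:
                    seq = rec.query_sequence or ""
                    qual = list(rec.query_qualities) if rec.query_qualities else [0] * len(seq)
                    unmapped.append(Read(id=rec.query_name, seq=seq, qual=qual))
                    continue
                if rec.cigartuples is None:
                    raise ValueError("mapped record without CIGAR")
                n_mismatch = rec.get_tag("NM") if rec.has_tag("NM") else 0
                read_length = rec.infer_read_length() or (rec.query_alignment_end or 0)
                alignments.append(
                    Alignment(
                        read_id=rec.query_name,
                        chrom=rec.reference_name,
                        start=rec.reference_start,
                        end=rec.reference_end,
                        strand="-" if rec.is_reverse else "+",
                        n_mismatch=int(n_mismatch),
                        read_span=(rec.query_alignment_start, rec.query_alignment_end),
                        read_length=int(read_length),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"invalid SAM record at line-record {i}: {exc}") from exc
    return alignments, unmapped


def write_sam(
    alignments: Sequence[Alignment],
    path: str,
    reference_lengths: Mapping[str, int],
    reads: Mapping[str, Read] | None = None,
) -> None:
    """Write alignments as SAM.

    The first alignment of each read is primary, later ones secondary. When
    ``reads`` provides sequences they are emitted (reverse-complemented for
    '-' records, per SAM convention, with soft clips from ``read_span``);
    otherwise SEQ is '*'.
    """
    names = list(reference_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": reference_lengths[n]} for n in names],
    }
    seen: set[str] = set()
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.reference_id = names.index(aln.chrom)
            rec.reference_start = aln.start
            rec.mapping_quality = 255
            flag = 0
            if aln.strand == "-":
                flag |= 16
            if aln.read_id in seen:
                flag |= 256
            seen.add(aln.read_id)
            rec.flag = flag
            s5, s3 = aln.read_span[0], aln.read_length - aln.read_span[1]
            span = aln.read_span[1] - aln.read_span[0]
            if aln.strand == "-":
                s5, s3 = s3, s5
            cigar = []
            if s5:
                cigar.append((4, s5))
            cigar.append((0, span))
            if s3:
                cigar.append((4, s3))
            rec.cigartuples = cigar
            if reads is not None and aln.read_id in reads:
                read = reads[aln.read_id]
                seq = read.seq if aln.strand == "+" else reverse_complement(read.seq)
                qual = read.qual if aln.strand == "+" else read.qual[::-1]
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in qual)
                )
            rec.set_tag("NM", aln.n_mismatch)
            out.write(rec)


def write_unmapped_fasta(unmapped: Sequence[Read], path: str) -> None:
    """Write unmapped reads to FASTA (ids preserved, input order kept)."""
    with open(path, "w") as handle:
        for read in unmapped:
            handle.write(f">{read.id}\n{read.seq}\n")


def read_fasta(path: str) -> list[Read]:
    """Read FASTA records as qualities-of-zero reads (for unmapped round trips)."""
    return [
        Read(id=rec.id, seq=str(rec.seq), qual=[0] * len(rec.seq))
        for rec in SeqIO.parse(path, "fasta")
    ]
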