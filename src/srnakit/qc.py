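"""Quality control of raw small RNA-seq reads.

Turns raw FASTQ into "qualified reads" through a fixed sequence of steps:

1. 3'-adapter trimming (cutadapt-like prefix search),
2. removal of randomized ligation bases added by some library kits
   (e.g. 4 degenerate nucleotides at each end for NEXTflex-style kits),
3. stripping of low-quality runs at the read ends,
4. mean-PHRED read filtering,
5. length selection.

Boundary semantics follow the ``<=`` convention throughout: a read with mean
PHRED exactly equal to the threshold is removed, and an end base with PHRED
exactly equal to the threshold is stripped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, TextIO

_U2T = str.maketrans("Uu", "Tt")
_VALID_BASES = frozenset("ACGTN")

#: Illumina TruSeq small RNA 3' adapter, the default for most small RNA kits.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class Read:
    """A sequencing read: identifier, sequence and per-base PHRED qualities.

    Sequences are normalized to the DNA alphabet on construction (``U``/``u``
    becomes ``T``, everything uppercased); RNA databases print U but alignment
    targets DNA genomes.
    """

    id: str
    seq: str
    qual: list[int]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be nonempty")
        self.seq = self.seq.translate(_U2T).upper()
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(f"read {self.id!r}: invalid bases {sorted(bad)}")
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: {len(self.qual)} qualities for {len(self.seq)} bases"
            )
        if any(q < 0 for q in self.qual):
            raise ValueError(f"read {self.id!r}: negative PHRED score")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class QCConfig:
    """Parameters of the QC stage.

    ``min_mean_phred``, ``head_phred`` and ``tail_phred`` correspond to the
    ``-rr``, ``-rh`` and ``-rt`` command-line flags (all default 20).
    ``n_random_5p``/``n_random_3p`` default to 4, matching kits that ligate 4
    randomized bases at each junction. The qualified-length interval is closed:
    ``min_len <= len <= max_len``.
    """

    adapter: str = DEFAULT_ADAPTER
    n_random_5p: int = 4
    n_random_3p: int = 4
    min_mean_phred: float = 20.0
    head_phred: float = 20.0
    tail_phred: float = 20.0
    min_len: int = 15
    max_len: int = 45
    min_adapter_overlap: int = 3
    max_adapter_mismatch_rate: float = 0.1
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.n_random_5p < 0 or self.n_random_3p < 0:
            raise ValueError("randomized-base counts must be >= 0")
        for name in ("min_mean_phred", "head_phred", "tail_phred"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def trim_adapter(
    read: Read,
    adapter: str,
    min_overlap: int = 3,
    max_mismatch_rate: float = 0.1,
) -> Read:
    """Trim the 3' adapter from a read.

    3'-anchored prefix search: at each read position, a prefix of the adapter
    (of length >= ``min_overlap``) is compared to the read from that position
    to the read end; the read is truncated at the leftmost position where the
    mismatch fraction is <= ``max_mismatch_rate``. If no position qualifies the
    read is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    seq = read.seq
    for start in range(0, len(seq) - min_overlap + 1):
        span = min(len(adapter), len(seq) - start)
        allowed = int(max_mismatch_rate * span)
        mismatches = 0
        for j in range(span):
            if seq[start + j] != adapter[j]:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return replace(read, seq=seq[:start], qual=read.qual[:start])
    return read


def trim_random_bases(read: Read, n5: int, n3: int) -> Read:
    """Remove exactly ``n5`` leading and ``n3`` trailing randomized bases.

    A read shorter than ``n5 + n3`` collapses to length 0 (a legal outcome:
    with a fully adapter-trimmed 8 nt read and 4+4 randomized bases nothing of
    the insert remains).
    """
    if n5 < 0 or n3 < 0:
        raise ValueError("randomized-base counts must be >= 0")
    end = max(n5, len(read.seq) - n3)
    return replace(read, seq=read.seq[n5:end], qual=read.qual[n5:end])


def mean_phred(read: Read) -> float:
    """Arithmetic mean of the read's PHRED scores."""
    if len(read.qual) == 0:
        raise ValueError(f"read {read.id!r}: mean PHRED undefined for zero-length read")
    return sum(read.qual) / len(read.qual)


def filter_by_mean_quality(read: Read, threshold: float) -> bool:
    """Return True (keep) iff mean PHRED is strictly above ``threshold``.

    The boundary is inclusive on the removal side: mean PHRED <= threshold
    discards the read.
    """
    return mean_phred(read) > threshold


def trim_low_quality_ends(read: Read, head_threshold: float, tail_threshold: float) -> Read:
    """Strip maximal runs of low-quality bases from both read ends.

    Leading bases with PHRED <= ``head_threshold`` and trailing bases with
    PHRED <= ``tail_threshold`` are removed; interior bases are untouched. An
    all-bad read becomes length 0.
    """
    lo = 0
    hi = len(read.qual)
    while lo < hi and read.qual[lo] <= head_threshold:
        lo += 1
    while hi > lo and read.qual[hi - 1] <= tail_threshold:
        hi -= 1
    return replace(read, seq=read.seq[lo:hi], qual=read.qual[lo:hi])


def select_length(read: Read, min_len: int, max_len: int) -> bool:
    """Return True (keep) iff ``min_len <= len(read) <= max_len`` (closed)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return min_len <= len(read.seq) <= max_len


@dataclass
class QCReport:
    """Per-filter accounting of a QC run plus the trimmed-length histogram.

    ``length_hist`` is tallied after all trimming but before length selection,
    so it is the full trimmed-read-length distribution (0 nt upward) that a
    read-length figure would plot.
    """

    n_input: int = 0
    n_discarded_quality: int = 0
    n_discarded_length: int = 0
    n_qualified: int = 0
    length_hist: Counter = field(default_factory=Counter)

    def write(self, handle: TextIO) -> None:
        handle.write("metric\tvalue\n")
        handle.write(f"input_reads\t{self.n_input}\n")
        handle.write(f"discarded_mean_quality\t{self.n_discarded_quality}\n")
        handle.write(f"discarded_length\t{self.n_discarded_length}\n")
        handle.write(f"qualified_reads\t{self.n_qualified}\n")
        for length in sorted(self.length_hist):
            handle.write(f"length_{length}\t{self.length_hist[length]}\n")


def qc_read(read: Read, config: QCConfig) -> Read:
    """Apply the trimming steps (adapter, randomized bases, low-quality ends)."""
    read = trim_adapter(
        read,
        config.adapter,
        min_overlap=config.min_adapter_overlap,
        max_mismatch_rate=config.max_adapter_mismatch_rate,
    )
    read = trim_random_bases(read, config.n_random_5p, config.n_random_3p)
    read = trim_low_quality_ends(read, config.head_phred, config.tail_phred)
    return read


def qc_reads(reads: Iterable[Read], config: QCConfig) -> tuple[list[Read], QCReport]:
    """Run the full QC pipeline over an iterable of reads.

    Order is fixed: adapter trim, randomized-base trim, end trim, mean-quality
    filter (evaluated on the remaining sequence), length selection. Reads
    trimmed to length 0 are discarded at the quality filter (no mean defined).
    """
    report = QCReport()
    qualified: list[Read] = []
    for read in reads:
        report.n_input += 1
        trimmed = qc_read(read, config)
        report.length_hist[len(trimmed)] += 1
        if len(trimmed) == 0 or not filter_by_mean_quality(trimmed, config.min_mean_phred):
            report.n_discarded_quality += 1
            continue
        if not select_length(trimmed, config.min_len, config.max_len):
            report.n_discarded_length += 1
            continue
        qualified.append(trimmed)
    report.n_qualified = len(qualified)
    return qualified, report


def read_fastq(path: str, phred_offset: int = 33) -> Iterator[Read]:
    """Parse a 4-line-record FASTQ file into :class:`Read` objects.

    Malformed records raise :class:`ValueError` naming the (0-based) record
    index.
    """
    with open(path) as handle:
        record_index = 0
        while True:
            header = handle.readline()
            if not header:
                return
            lines = [header, handle.readline(), handle.readline(), handle.readline()]
            lines = [ln.rstrip("\n") for ln in lines]
            if not lines[0].startswith("@") or lines[2][:1] != "+" or not lines[3]:
                raise ValueError(f"malformed FASTQ record at index {record_index}")
            seq, qual_str = lines[1], lines[3]
            if len(seq) != len(qual_str):
                raise ValueError(
                    f"malformed FASTQ record at index {record_index}: "
                    f"sequence/quality length mismatch"
                )
            qual = [ord(c) - phred_offset for c in qual_str]
            try:
                yield Read(id=lines[0][1:].split()[0], seq=seq, qual=qual)
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {record_index}: {exc}")
            record_index += 1


def write_fastq(reads: Iterable[Read], path: str, phred_offset: int = 33) -> None:
    with open(path, "w") as handle:
        for read in reads:
            qual_str = "".join(chr(q + phred_offset) for q in read.qual)
            handle.write(f"@{read.id}\n{read.seq}\n+\n{qual_str}\n")


def run_qc(
    fastq_path: str,
    config: QCConfig,
    out_fastq: str | None = None,
    report_path: str | None = None,
) -> tuple[list[Read], QCReport]:
    """File-level QC entry point: FASTQ in, qualified FASTQ + report out."""
    qualified, report = qc_reads(read_fastq(fastq_path, config.phred_offset), config)
    if out_fastq is not None:
        write_fastq(qualified, out_fastq, config.phred_offset)
    if report_path is not None:
        with open(report_path, "w") as handle:
            report.write(handle)
    return qualified, report
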