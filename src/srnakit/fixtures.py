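"""Deterministic synthetic inputs for every pipeline stage.

Generates a toy genome with planted small RNA features, raw 50 nt reads with
the library structure ``4 randomized bases + genomic insert + 4 randomized
bases + 3' adapter``, a microbial reference set with a small taxonomy, and
differential-expression count matrices — all from a single integer seed, with
a truth table recording each read's origin so expected per-molecule counts
are known in advance.

Planted scenarios exercised by the genome:

* a 22-mer copied to 11 loci, all annotated to one miRNA molecule — the
  multi-locus, count-once case;
* the let-7a-5p 22-mer nested at the 5' end of a 30 nt piRNA (piR_008113)
  interval — the overlapping-molecules, one-count-each case.

All randomness flows from ``numpy.random.default_rng(seed)``; identical specs
produce byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .align import GenomeRef, reverse_complement
from .annotate import FeatureRecord, write_feature_db
from .microbe import TaxonNode, TaxonomyTree
from .qc import DEFAULT_ADAPTER, Read, write_fastq

#: hsa-let-7a-5p mature sequence (DNA alphabet).
LET7A_SEQ = "TGAGGTAGTAGGTTGTATAGTT"
#: piR_008113: shares its first 22 nt with let-7a-5p, 8 nt 3' extension.
PIR008113_SEQ = LET7A_SEQ + "TTAGGGTC"

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    """Parameters of the synthetic data set.

    Defaults emulate a NEXTflex-style library: 50 nt raw reads, 4 randomized
    ligation bases at each end, Illumina small RNA 3' adapter; inserts of
    18–32 nt so trimmed reads land in the small RNA size range. Good reads
    have per-base PHRED in [25, 40] (pass the mean-20 filter untouched), bad
    reads in [8, 18] (fail it).
    """

    seed: int = 17
    genome_len: int = 20000
    n_features: dict = field(
        default_factory=lambda: {
            "miRNA": 8,
            "piRNA": 6,
            "snoRNA": 4,
            "snRNA": 4,
            "tRNA": 4,
            "circRNA": 3,
        }
    )
    reads_per_molecule: tuple[int, int] = (2, 8)
    n_low_quality: int = 10
    n_short_insert: int = 5
    n_microbial: int = 6
    adapter: str = DEFAULT_ADAPTER
    n_random_5p: int = 4
    n_random_3p: int = 4
    read_len: int = 50
    good_quality: tuple[int, int] = (25, 40)
    bad_quality: tuple[int, int] = (8, 18)


@dataclass
class GenomeFixture:
    genome: GenomeRef
    features: list[FeatureRecord]
    multi_locus_seq: str
    multi_locus_molecule: tuple[str, str]
    nested_mirna: tuple[str, str]
    nested_pirna: tuple[str, str]


@dataclass
class MicrobeFixture:
    tree: TaxonomyTree
    references: dict[str, str]
    acc2taxid: dict[str, int]
    inserts: list[tuple[str, str, set[int]]]  # (label, sequence, expected taxids)


@dataclass
class FixtureSet:
    spec: FixtureSpec
    genome_fixture: GenomeFixture
    microbe_fixture: MicrobeFixture
    reads: list[Read]
    truth: pd.DataFrame


_FEATURE_LENGTHS = {
    "miRNA": (22, 22),
    "piRNA": (26, 31),
    "snoRNA": (70, 100),
    "snRNA": (100, 150),
    "tRNA": (72, 80),
    "circRNA": (100, 200),
}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _occurs(genome: str, seq: str) -> int:
    """Occurrences of ``seq`` in the genome on either strand (overlap-aware)."""
    count, start = 0, 0
    for query in (seq, reverse_complement(seq)):
        start = 0
        while True:
            pos = genome.find(query, start)
            if pos < 0:
                break
            count += 1
            start = pos + 1
    return count


def make_genome(spec: FixtureSpec) -> GenomeFixture:
    """Random genome with planted feature sequences and their annotations.

    The genome is laid out in fixed-size blocks so planted sequences never
    overlap. Construction is verified: the multi-locus 22-mer occurs exactly
    11 times and the nested piRNA sequence exactly once (both strands
    checked); on the vanishingly rare accidental collision the background is
    redrawn from a derived seed.
    """
    if spec.genome_len < 1000:
        raise ValueError("genome_len must be >= 1000")
    block = 260
    n_generic = sum(spec.n_features.values())
    n_blocks_needed = 11 + 1 + n_generic
    if spec.genome_len // block < n_blocks_needed:
        raise ValueError(
            f"genome_len {spec.genome_len} too small for {n_blocks_needed} feature blocks"
        )
    for attempt in range(10):
        rng = np.random.default_rng((spec.seed, 0, attempt))
        genome_arr = rng.choice(_BASES, size=spec.genome_len)
        blocks = list(range(0, spec.genome_len - block, block))
        rng.shuffle(blocks)
        features: list[FeatureRecord] = []

        def plant(seq: str, block_start: int) -> int:
            pos = block_start + 10
            genome_arr[pos : pos + len(seq)] = list(seq)
            return pos

        multi_seq = _random_seq(rng, 22)
        for i in range(11):
            pos = plant(multi_seq, blocks.pop())
            features.append(
                FeatureRecord(
                    db="mirdb_toy",
                    rna_type="miRNA",
                    name="mir-plex",
                    id=f"MI-PLEX-{i + 1:02d}",
                    chrom="chr1",
                    start=pos - 5,
                    end=pos + 27,
                    strand="+",
                )
            )
        nested_pos = plant(PIR008113_SEQ, blocks.pop())
        features.append(
            FeatureRecord(
                db="mirdb_toy",
                rna_type="miRNA",
                name="let-7a-5p",
                id="MIMAT0000062",
                chrom="chr1",
                start=nested_pos,
                end=nested_pos + 22,
                strand="+",
            )
        )
        features.append(
            FeatureRecord(
                db="pirdb_toy",
                rna_type="piRNA",
                name="piR_008113",
                id="piR_008113",
                chrom="chr1",
                start=nested_pos,
                end=nested_pos + 30,
                strand="+",
            )
        )
        for rna_type, n in spec.n_features.items():
            lo, hi = _FEATURE_LENGTHS[rna_type]
            for i in range(n):
                length = int(rng.integers(lo, hi + 1))
                start = blocks.pop() + 10
                strand = "+" if rng.random() < 0.8 else "-"
                features.append(
                    FeatureRecord(
                        db=f"{rna_type.lower()}db_toy",
                        rna_type=rna_type,
                        name=f"{rna_type}-{i + 1:03d}",
                        id=f"{rna_type.upper()}-ID-{i + 1:03d}",
                        chrom="chr1",
                        start=start,
                        end=start + length,
                        strand=strand,
                    )
                )
        genome_str = "".join(genome_arr)
        if _occurs(genome_str, multi_seq) == 11 and _occurs(genome_str, PIR008113_SEQ) == 1:
            return GenomeFixture(
                genome=GenomeRef({"chr1": genome_str}),
                features=features,
                multi_locus_seq=multi_seq,
                multi_locus_molecule=("miRNA", "mir-plex"),
                nested_mirna=("miRNA", "let-7a-5p"),
                nested_pirna=("piRNA", "piR_008113"),
            )
    raise RuntimeError("could not construct a collision-free genome")


def _make_taxonomy() -> tuple[TaxonomyTree, dict[int, str]]:
    """A ~20-node taxonomy spanning the four microbial groups.

    Returns the tree and a map of species taxid -> reference accession for
    species that carry a reference sequence.
    """
    nodes = [
        TaxonNode(1, 1, "root", "root", "other"),
        TaxonNode(2157, 1, "superkingdom", "Archaea", "archaea"),
        TaxonNode(2, 1, "superkingdom", "Bacteria", "bacteria"),
        TaxonNode(4751, 1, "kingdom", "Fungi", "fungi"),
        TaxonNode(10239, 1, "superkingdom", "Viruses", "viruses"),
        TaxonNode(2158, 2157, "genus", "Methanarchaeum", "archaea"),
        TaxonNode(2159, 2158, "species", "Methanarchaeum toyense", "archaea"),
        TaxonNode(20, 2, "genus", "Escherichium", "bacteria"),
        TaxonNode(201, 20, "species", "Escherichium alpha", "bacteria"),
        TaxonNode(202, 20, "species", "Escherichium beta", "bacteria"),
        TaxonNode(21, 2, "genus", "Staphyloccum", "bacteria"),
        TaxonNode(211, 21, "species", "Staphyloccum gamma", "bacteria"),
        TaxonNode(47511, 4751, "genus", "Candidum", "fungi"),
        TaxonNode(475111, 47511, "species", "Candidum albidum", "fungi"),
        TaxonNode(475112, 47511, "species", "Candidum glabrum", "fungi"),
        TaxonNode(102391, 10239, "family", "Toyviridae", "viruses"),
        TaxonNode(1023911, 102391, "species", "Toyvirus one", "viruses"),
        TaxonNode(1023912, 102391, "species", "Toyvirus two", "viruses"),
    ]
    species_refs = {
        2159: "ARC001",
        201: "BAC001",
        202: "BAC002",
        211: "BAC003",
        475111: "FUN001",
        1023911: "VIR001",
    }
    return TaxonomyTree(nodes), species_refs


def make_microbe_fixture(spec: FixtureSpec) -> MicrobeFixture:
    """Microbial references, taxonomy and planted read inserts.

    One insert is planted in two species of the same genus (the
    all-potential-taxa case: both species reported, genus rollup counts the
    read once); the remainder are species-unique. Inserts are 30 nt so they
    survive QC at the default length interval.
    """
    rng = np.random.default_rng((spec.seed, 2))
    tree, species_refs = _make_taxonomy()
    references = {acc: _random_seq(rng, 400) for acc in species_refs.values()}
    acc2taxid = {acc: taxid for taxid, acc in species_refs.items()}

    inserts: list[tuple[str, str, set[int]]] = []
    shared = _random_seq(rng, 30)
    for acc in ("BAC001", "BAC002"):
        pos = int(rng.integers(0, len(references[acc]) - 30))
        references[acc] = references[acc][:pos] + shared + references[acc][pos + 30 :]
    inserts.append(("mic_shared", shared, {201, 202}))

    unique_targets = ["ARC001", "BAC003", "FUN001", "VIR001"]
    for i in range(max(0, spec.n_microbial - 2)):
        acc = unique_targets[i % len(unique_targets)]
        pos = int(rng.integers(0, len(references[acc]) - 30))
        seq = references[acc][pos : pos + 30]
        inserts.append((f"mic_unique_{i + 1}", seq, {acc2taxid[acc]}))
    inserts.append(("mic_nohit", _random_seq(rng, 30), set()))
    return MicrobeFixture(
        tree=tree, references=references, acc2taxid=acc2taxid, inserts=inserts
    )


def _assemble_read(
    rng: np.random.Generator,
    read_id: str,
    insert: str,
    spec: FixtureSpec,
    quality_range: tuple[int, int],
) -> Read:
    """Build one raw read: 5' random bases + insert + 3' random bases +
    adapter, padded with random bases / truncated to the raw read length."""
    seq = (
        _random_seq(rng, spec.n_random_5p)
        + insert
        + _random_seq(rng, spec.n_random_3p)
        + spec.adapter
    )
    if len(seq) < spec.read_len:
        seq += _random_seq(rng, spec.read_len - len(seq))
    seq = seq[: spec.read_len]
    lo, hi = quality_range
    qual = [int(q) for q in rng.integers(lo, hi + 1, size=len(seq))]
    return Read(id=read_id, seq=seq, qual=qual)


def make_reads(
    spec: FixtureSpec,
    genome_fixture: GenomeFixture,
    microbe_fixture: MicrobeFixture | None = None,
) -> tuple[list[Read], pd.DataFrame]:
    """Raw reads plus a truth table of expected per-read fate.

    Per genome molecule, a random number of reads is drawn from its interval
    (minus-strand features yield reverse-complemented inserts); planted
    scenario reads use the multi-locus 22-mer and the let-7a-5p sequence.
    Low-quality and too-short reads are added as QC-negative truth, microbial
    inserts (if given) as unmapped truth. Insert uniqueness in the genome is
    verified at construction so expected counts are exact.

    Truth columns: read_id, category, molecules (';'-joined "type:name"),
    qc_pass, mapped.
    """
    rng = np.random.default_rng((spec.seed, 3))
    genome = genome_fixture.genome.sequences["chr1"]
    reads: list[Read] = []
    rows: list[dict] = []

    def add(read_id, insert, category, molecules, qc_pass, mapped, quality):
        reads.append(_assemble_read(rng, read_id, insert, spec, quality))
        rows.append(
            {
                "read_id": read_id,
                "category": category,
                "molecules": ";".join(sorted(f"{t}:{n}" for t, n in molecules)),
                "qc_pass": qc_pass,
                "mapped": mapped,
            }
        )

    lo, hi = spec.reads_per_molecule
    n_idx = 0
    # planted scenarios
    for _ in range(int(rng.integers(lo, hi + 1))):
        n_idx += 1
        add(
            f"r{n_idx:04d}_plex",
            genome_fixture.multi_locus_seq,
            "multi_locus",
            [genome_fixture.multi_locus_molecule],
            True,
            True,
            spec.good_quality,
        )
    for _ in range(int(rng.integers(lo, hi + 1))):
        n_idx += 1
        add(
            f"r{n_idx:04d}_let7a",
            LET7A_SEQ,
            "nested_pair",
            [genome_fixture.nested_mirna, genome_fixture.nested_pirna],
            True,
            True,
            spec.good_quality,
        )

    # generic molecules: group intervals by molecule, draw unique inserts
    by_molecule: dict[tuple[str, str], list[FeatureRecord]] = {}
    skip = {
        genome_fixture.multi_locus_molecule,
        genome_fixture.nested_mirna,
        genome_fixture.nested_pirna,
    }
    for feat in genome_fixture.features:
        if feat.molecule not in skip:
            by_molecule.setdefault(feat.molecule, []).append(feat)
    for molecule, feats in by_molecule.items():
        for _ in range(int(rng.integers(lo, hi + 1))):
            feat = feats[int(rng.integers(0, len(feats)))]
            for _attempt in range(20):
                max_ins = min(feat.end - feat.start, 32)
                length = int(rng.integers(min(18, max_ins), max_ins + 1))
                offset = int(rng.integers(0, feat.end - feat.start - length + 1))
                segment = genome[feat.start + offset : feat.start + offset + length]
                if "N" not in segment and _occurs(genome, segment) == 1:
                    break
            else:
                continue
            insert = segment if feat.strand == "+" else reverse_complement(segment)
            n_idx += 1
            add(
                f"r{n_idx:04d}",
                insert,
                "feature",
                [molecule],
                True,
                True,
                spec.good_quality,
            )

    # QC-negative reads
    for i in range(spec.n_low_quality):
        n_idx += 1
        pos = int(rng.integers(0, spec.genome_len - 25))
        add(
            f"r{n_idx:04d}_lowq",
            genome[pos : pos + 25],
            "low_quality",
            [],
            False,
            False,
            spec.bad_quality,
        )
    for i in range(spec.n_short_insert):
        n_idx += 1
        for _attempt in range(20):
            pos = int(rng.integers(0, spec.genome_len - 8))
            segment = genome[pos : pos + 8]
            if "N" not in segment:
                break
        add(
            f"r{n_idx:04d}_short",
            segment,
            "short_insert",
            [],
            False,
            False,
            spec.good_quality,
        )

    # microbial (genome-unmapped) reads
    if microbe_fixture is not None:
        for label, insert, _taxids in microbe_fixture.inserts:
            n_idx += 1
            add(
                f"r{n_idx:04d}_{label}",
                insert,
                f"microbial:{label}",
                [],
                True,
                False,
                spec.good_quality,
            )

    truth = pd.DataFrame(
        rows, columns=["read_id", "category", "molecules", "qc_pass", "mapped"]
    )
    return reads, truth


def expected_molecule_counts(truth: pd.DataFrame) -> dict[tuple[str, str], int]:
    """Expected per-molecule read counts implied by the truth table."""
    counts: dict[tuple[str, str], int] = {}
    usable = truth[truth.qc_pass & truth.mapped]
    for molecules in usable.molecules:
        if not molecules:
            continue
        for token in molecules.split(";"):
            rna_type, name = token.split(":", 1)
            counts[(rna_type, name)] = counts.get((rna_type, name), 0) + 1
    return counts


def make_de_fixture(
    spec: FixtureSpec,
    n_null: int = 1000,
    n_shifted: int = 50,
    n_case: int = 6,
    n_control: int = 6,
) -> tuple[pd.DataFrame, list[str], list[str], pd.DataFrame]:
    """Expression matrix with known null and shifted rows.

    Null rows draw all samples from one log-normal distribution (median ~100,
    sigma 1 on the log scale — a typical normalized-abundance spread). Shifted
    rows separate completely: controls uniform on [10, 20], cases uniform on
    [100, 200], so with 6 vs 6 tie-free groups the exact two-sided
    Mann-Whitney p is 2/924 for every shifted row. Values are continuous
    (normalized scale) so the exact, tie-free test path is exercised.

    Returns (table, case_columns, control_columns, truth).
    """
    if n_case < 3 or n_control < 3:
        raise ValueError("need at least 3 case and 3 control samples")
    rng = np.random.default_rng((spec.seed, 4))
    case_cols = [f"case_{i + 1}" for i in range(n_case)]
    control_cols = [f"ctrl_{i + 1}" for i in range(n_control)]
    n_samples = n_case + n_control
    null_block = rng.lognormal(mean=np.log(100), sigma=1.0, size=(n_null, n_samples))
    shifted_case = rng.uniform(100, 200, size=(n_shifted, n_case))
    shifted_control = rng.uniform(10, 20, size=(n_shifted, n_control))
    shifted_block = np.hstack([shifted_case, shifted_control])
    values = np.vstack([null_block, shifted_block])
    index = pd.MultiIndex.from_tuples(
        [("dedb_toy", f"mol-{i + 1:04d}", f"ID-{i + 1:04d}") for i in range(len(values))],
        names=["DB", "Name", "ID"],
    )
    table = pd.DataFrame(values, index=index, columns=case_cols + control_cols)
    truth = pd.DataFrame(
        {"shifted": [False] * n_null + [True] * n_shifted}, index=index
    )
    return table, case_cols, control_cols, truth


def make_all(spec: FixtureSpec) -> FixtureSet:
    """Generate the full, mutually consistent fixture set."""
    genome_fixture = make_genome(spec)
    microbe_fixture = make_microbe_fixture(spec)
    reads, truth = make_reads(spec, genome_fixture, microbe_fixture)
    return FixtureSet(
        spec=spec,
        genome_fixture=genome_fixture,
        microbe_fixture=microbe_fixture,
        reads=reads,
        truth=truth,
    )


def write_fixture_files(fixture_set: FixtureSet, out_dir: str) -> dict[str, str]:
    """Write the fixture set in the dialects the pipeline consumes.

    Returns a name -> path map of everything written.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    fixture_set.genome_fixture.genome.to_fasta(p("genome.fa"))
    by_db: dict[tuple[str, str], list[FeatureRecord]] = {}
    for feat in fixture_set.genome_fixture.features:
        by_db.setdefault((feat.db, feat.rna_type), []).append(feat)
    for (db, rna_type), records in sorted(by_db.items()):
        write_feature_db(records, p(f"features_{db}_{rna_type}.bed"))
    write_fastq(fixture_set.reads, p("reads.fastq"))
    fixture_set.truth.to_csv(p("truth.tsv"), sep="\t", index=False)
    mf = fixture_set.microbe_fixture
    with open(p("microbe_refs.fa"), "w") as handle:
        for acc, seq in mf.references.items():
            handle.write(f">{acc}\n{seq}\n")
    mf.tree.write_tsv(p("taxonomy.tsv"))
    with open(p("acc2taxid.tsv"), "w") as handle:
        for acc, taxid in mf.acc2taxid.items():
            handle.write(f"{acc}\t{taxid}\n")
    return paths


def read_acc2taxid(path: str) -> dict[str, int]:
    """Load a 2-column accession -> taxid map."""
    mapping: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            mapping[fields[0]] = int(fields[1])
    return mapping
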