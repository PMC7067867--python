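"""Taxonomic screening of genome-unmapped reads.

Reads that fail to map to the host genome are compared against microbial
references (BLAST against nt in production; :func:`micro_match` provides a
BLAST-shaped exhaustive matcher for test-scale references). Because of
sequence homology between species, one read often hits many subjects; ALL
potential taxa are retained per read — no best-hit selection and no
lowest-common-ancestor collapse — and counts are rolled up the taxonomy tree
so that a read contributes at most once to any taxon, at every rank. Results
are grouped into the four major microbial groups: archaea, bacteria, fungi
and viruses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import reverse_complement
from .qc import Read

logger = logging.getLogger(__name__)

GROUPS = ("archaea", "bacteria", "fungi", "viruses", "other")


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent: int
    rank: str
    name: str
    group: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"taxid {self.taxid}: unknown group {self.group!r}")


class TaxonomyTree:
    """A rooted taxonomy: taxid -> node, with ancestor traversal.

    The root is the node whose parent is itself (NCBI convention, taxid 1).
    The tree is validated on construction: every parent exists, exactly one
    root, no cycles.
    """

    def __init__(self, nodes: Iterable[TaxonNode]) -> None:
        self.nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxid in self.nodes:
                raise ValueError(f"duplicate taxid {node.taxid}")
            self.nodes[node.taxid] = node
        roots = [n.taxid for n in self.nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for node in self.nodes.values():
            if node.parent not in self.nodes:
                raise ValueError(f"taxid {node.taxid}: missing parent {node.parent}")
            self.ancestors(node.taxid)  # raises on cycles

    def ancestors(self, taxid: int) -> list[int]:
        """Taxids from ``taxid`` up to and including the root (self first)."""
        if taxid not in self.nodes:
            raise KeyError(f"unknown taxid {taxid}")
        chain = [taxid]
        seen = {taxid}
        while chain[-1] != self.root:
            parent = self.nodes[chain[-1]].parent
            if parent in seen:
                raise ValueError(f"taxonomy cycle at taxid {parent}")
            chain.append(parent)
            seen.add(parent)
        return chain

    @classmethod
    def from_tsv(cls, path: str) -> "TaxonomyTree":
        """Load a 5-column TSV: taxid, parent, rank, name, group."""
        nodes = []
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 5:
                    raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
                nodes.append(
                    TaxonNode(
                        taxid=int(fields[0]),
                        parent=int(fields[1]),
                        rank=fields[2],
                        name=fields[3],
                        group=fields[4],
                    )
                )
        return cls(nodes)

    @classmethod
    def from_ncbi_dumps(
        cls, nodes_path: str, names_path: str, group_roots: Mapping[int, str]
    ) -> "TaxonomyTree":
        """Load NCBI-style nodes.dmp/names.dmp (pipe-delimited) dumps.

        ``group_roots`` maps subtree-root taxids to group labels (e.g.
        ``{2: "bacteria", 2157: "archaea", ...}``); every descendant inherits
        its nearest labelled ancestor's group, others become ``other``.
        """
        raw: dict[int, tuple[int, str]] = {}
        with open(nodes_path) as handle:
            for line in handle:
                fields = [f.strip() for f in line.split("|")]
                raw[int(fields[0])] = (int(fields[1]), fields[2])
        names: dict[int, str] = {}
        with open(names_path) as handle:
            for line in handle:
                fields = [f.strip() for f in line.split("|")]
                if len(fields) > 3 and fields[3] == "scientific name" or int(fields[0]) not in names:
                    names[int(fields[0])] = fields[1]

        def group_of(taxid: int) -> str:
            seen = set()
            while taxid not in seen:
                if taxid in group_roots:
                    return group_roots[taxid]
                seen.add(taxid)
                taxid = raw[taxid][0]
            return "other"

        return cls(
            TaxonNode(
                taxid=t, parent=p, rank=r, name=names.get(t, str(t)), group=group_of(t)
            )
            for t, (p, r) in raw.items()
        )

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as handle:
            for node in self.nodes.values():
                handle.write(
                    f"{node.taxid}\t{node.parent}\t{node.rank}\t{node.name}\t{node.group}\n"
                )


@dataclass(frozen=True)
class BlastHit:
    """One 12-column tabular hit, plus the subject's taxid."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    taxid: int = -1

    def __post_init__(self) -> None:
        if self.align_len <= 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: align_len must be > 0")
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative e-value")


def parse_blast_tabular(
    path: str, acc2taxid: Mapping[str, int]
) -> tuple[list[BlastHit], int]:
    """Parse 12-column BLAST tabular output (outfmt 6).

    Hits whose subject accession has no taxid mapping are dropped; the count
    of dropped hits is returned alongside the kept hits. A line with the
    wrong column count raises with its 1-based line number.
    """
    hits: list[BlastHit] = []
    n_dropped = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            subject = fields[1]
            if subject not in acc2taxid:
                n_dropped += 1
                continue
            hits.append(
                BlastHit(
                    query_id=fields[0],
                    subject_id=subject,
                    pct_identity=float(fields[2]),
                    align_len=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    taxid=acc2taxid[subject],
                )
            )
    if n_dropped:
        logger.info("%s: dropped %d hit(s) with unmapped accessions", path, n_dropped)
    return hits, n_dropped


def write_blast_tabular(hits: Iterable[BlastHit], path: str) -> None:
    with open(path, "w") as handle:
        for h in hits:
            handle.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t{h.align_len}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.q_start}\t{h.q_end}\t"
                f"{h.s_start}\t{h.s_end}\t{h.evalue:g}\t{h.bitscore:g}\n"
            )


def assign_read_taxa(
    hits: Sequence[BlastHit],
    max_evalue: float = 1e-3,
    min_identity: float = 90.0,
    best_hit_only: bool = False,
) -> set[int]:
    """The set of taxa a read may originate from.

    All distinct taxids among filter-passing hits are kept (homologous species
    are reported without bias). ``best_hit_only`` restricts to the taxa of the
    top-bitscore hits — a convenience, off by default.
    """
    if hits:
        ids = {h.query_id for h in hits}
        if len(ids) != 1:
            raise ValueError(f"hits from multiple reads passed together: {sorted(ids)}")
    passing = [
        h for h in hits if h.evalue <= max_evalue and h.pct_identity >= min_identity
    ]
    if best_hit_only and passing:
        best = max(h.bitscore for h in passing)
        passing = [h for h in passing if h.bitscore == best]
    return {h.taxid for h in passing}


def count_taxa(
    read_taxa: Mapping[str, set[int]], tree: TaxonomyTree
) -> pd.DataFrame:
    """Per-taxon read counts rolled up the taxonomy tree.

    A taxon's count is the number of reads whose taxon set contains it or any
    of its descendants; a read counts at most once per taxon even when it hit
    several descendants. Returns a table (taxid, name, rank, group, count)
    sorted by group then descending count; taxa with zero reads are omitted.
    """
    counts: dict[int, int] = {}
    for taxids in read_taxa.values():
        ancestor_union: set[int] = set()
        for taxid in taxids:
            ancestor_union.update(tree.ancestors(taxid))
        for t in ancestor_union:
            counts[t] = counts.get(t, 0) + 1
    rows = [
        {
            "taxid": t,
            "name": tree.nodes[t].name,
            "rank": tree.nodes[t].rank,
            "group": tree.nodes[t].group,
            "count": c,
        }
        for t, c in counts.items()
    ]
    table = pd.DataFrame(rows, columns=["taxid", "name", "rank", "group", "count"])
    if len(table):
        table = table.sort_values(
            ["group", "count", "taxid"], ascending=[True, False, True], ignore_index=True
        )
    return table


def micro_match(
    reads: Iterable[Read],
    reference: Mapping[str, str],
    max_mismatch: int = 0,
) -> list[BlastHit]:
    """Exhaustive substring matcher emitting BLAST-tabular-shaped hits.

    Scans every offset of every reference sequence on both strands for
    placements of each read within the mismatch budget. Identity and bitscore
    derive from the mismatch count; e-values are synthesized deterministically
    (10^(mismatches - 20)) so downstream filters behave as with real hits.
    Subject coordinates are 1-based inclusive, reversed for minus-strand
    matches, per BLAST convention.
    """
    hits: list[BlastHit] = []
    for read in reads:
        n = len(read.seq)
        if n == 0:
            continue
        for acc, ref in reference.items():
            ref = ref.upper()
            for strand, query in (("+", read.seq), ("-", reverse_complement(read.seq))):
                for pos in range(len(ref) - n + 1):
                    mism = sum(
                        1 for a, b in zip(query, ref[pos : pos + n]) if a != b
                    )
                    if mism > max_mismatch:
                        continue
                    s_start, s_end = pos + 1, pos + n
                    if strand == "-":
                        s_start, s_end = s_end, s_start
                    hits.append(
                        BlastHit(
                            query_id=read.id,
                            subject_id=acc,
                            pct_identity=100.0 * (n - mism) / n,
                            align_len=n,
                            mismatches=mism,
                            gap_opens=0,
                            q_start=1,
                            q_end=n,
                            s_start=s_start,
                            s_end=s_end,
                            evalue=10.0 ** (mism - 20),
                            bitscore=float(2 * n - 3 * mism),
                        )
                    )
    return hits


def group_hits_by_read(hits: Iterable[BlastHit]) -> dict[str, list[BlastHit]]:
    grouped: dict[str, list[BlastHit]] = {}
    for hit in hits:
        grouped.setdefault(hit.query_id, []).append(hit)
    return grouped


def screen_reads(
    hits: Iterable[BlastHit],
    tree: TaxonomyTree,
    max_evalue: float = 1e-3,
    min_identity: float = 90.0,
    best_hit_only: bool = False,
    groups: Sequence[str] = ("archaea", "bacteria", "fungi", "viruses"),
) -> pd.DataFrame:
    """Full microbe stage: hits -> per-read taxa -> rolled-up counts by group."""
    read_taxa = {
        read_id: assign_read_taxa(read_hits, max_evalue, min_identity, best_hit_only)
        for read_id, read_hits in group_hits_by_read(hits).items()
    }
    table = count_taxa(read_taxa, tree)
    return table[table["group"].isin(groups)].reset_index(drop=True)
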