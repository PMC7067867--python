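"""Shared test utilities: read construction and independent oracles.

The oracles here deliberately use the dumbest correct algorithm (exhaustive
scans, full enumeration) so they stay independent of the library code paths
they check.
"""

from __future__ import annotations

from itertools import combinations

from srnakit.qc import Read

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def mk_read(seq: str, qual: "int | list[int]" = 30, read_id: str = "r1") -> Read:
    if isinstance(qual, int):
        qual = [qual] * len(seq)
    return Read(id=read_id, seq=seq, qual=qual)


def rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def adapter_trim_oracle(seq: str, adapter: str, min_overlap: int, rate: float) -> int:
    """Leftmost position where an adapter prefix matches to the read end
    within the mismatch budget; len(seq) if none. Exhaustive scan."""
    for start in range(0, len(seq) - min_overlap + 1):
        span = min(len(adapter), len(seq) - start)
        mism = sum(1 for j in range(span) if seq[start + j] != adapter[j])
        if mism <= int(rate * span):
            return start
    return len(seq)


def end_trim_oracle(qual: list[int], head: float, tail: float) -> tuple[int, int]:
    """(lo, hi) bounds after scanning from each end past bases <= threshold."""
    lo = 0
    while lo < len(qual) and qual[lo] <= head:
        lo += 1
    hi = len(qual)
    while hi > lo and qual[hi - 1] <= tail:
        hi -= 1
    return lo, hi


def brute_force_align(seq: str, genome: dict[str, str], max_mismatch: int):
    """Every placement of ``seq`` on either strand with <= max_mismatch
    Hamming mismatches: set of (chrom, start, strand, n_mismatch)."""
    hits = set()
    n = len(seq)
    for strand, query in (("+", seq), ("-", rc(seq))):
        for chrom, ref in genome.items():
            for pos in range(len(ref) - n + 1):
                mism = 0
                for a, b in zip(query, ref[pos : pos + n]):
                    if a != b:
                        mism += 1
                        if mism > max_mismatch:
                            break
                else:
                    hits.add((chrom, pos, strand, mism))
    return hits


def linear_scan_overlap(records, chrom: str, start: int, end: int):
    """Features intersecting [start, end) on chrom, by exhaustive scan."""
    return {
        rec
        for rec in records
        if rec.chrom == chrom and rec.start < end and start < rec.end
    }


def mann_whitney_enumeration(x: list[float], y: list[float]) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration of label assignments.

    Requires tie-free pooled data. U is the count of (x_i, y_j) pairs with
    x_i > y_j; the two-sided p is the fraction of the C(n, n_x) relabelings
    whose U is at least as far from the null mean n_x*n_y/2 as observed.
    """
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "enumeration oracle needs tie-free data"

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    mu = len(x) * len(y) / 2.0
    total = extreme = 0
    for idx in combinations(range(len(pooled)), len(x)):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu):
            extreme += 1
    return float(u_obs), extreme / total


def taxon_rollup_oracle(read_taxa: dict[str, set[int]], tree) -> dict[int, int]:
    """Per-taxon read counts via descendant sets (independent of the
    ancestor-walk used by the implementation)."""
    descendants: dict[int, set[int]] = {t: {t} for t in tree.nodes}
    changed = True
    while changed:
        changed = False
        for node in tree.nodes.values():
            if node.taxid == tree.root:
                continue
            before = len(descendants[node.parent])
            descendants[node.parent] |= descendants[node.taxid]
            if len(descendants[node.parent]) != before:
                changed = True
    counts = {}
    for taxid, desc in descendants.items():
        n = sum(1 for taxa in read_taxa.values() if taxa & desc)
        if n:
            counts[taxid] = n
    return counts
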