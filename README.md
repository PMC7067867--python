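# srnakit

A modular toolkit for quantifying the small RNA'ome — miRNA, piRNA, snRNA,
snoRNA, tRNA and circRNA fragments, plus microbial RNA among host-unmapped
reads — from small RNA-seq data. It is aimed at anyone profiling circulating
or cellular small RNAs who needs per-class counts with explicit, unbiased
multi-mapper handling rather than a miRNA-only pipeline.

## The model

Reads are quality-controlled (3' adapter trimming, removal of the randomized
ligation bases some kits add at each junction, PHRED filtering with the
`-rr`/`-rh`/`-rt` thresholds, length selection) and aligned to the genome.
Annotation against BED-like feature databases is governed by the **overlap
ratio** (degree of read support):

```
r_olp = L_olp / L_read
```

where `L_olp` is the number of read bases covered by the annotation interval
and `L_read` the number of aligned bases of the read. The default
`-ann_overlap 1` requires the read to lie completely within the annotation.

Multi-mapped reads follow two counting rules, with no priority among RNA
types:

1. **Count once** — a read aligning to several loci of one molecule (e.g. a
   miRNA derivable from 11 pre-miRNA loci) contributes a single count to that
   molecule.
2. **One count each** — a read mapping inside two distinct overlapping
   molecules (e.g. a miRNA sharing its sequence with the 5' end of a longer
   piRNA) contributes one count to *each* of them.

Reads that fail to map to the host genome are screened against microbial
references; every potential taxon per read is retained (no best-hit or LCA
reduction) and counts are rolled up the taxonomy tree so a read counts at
most once per taxon, grouped into archaea, bacteria, fungi and viruses.
Sample-level analysis merges per-sample counts into a molecule × sample
matrix, normalizes by counts-per-million (each library rescaled to 10^6),
flags detection at raw count ≥ 5, and tests case vs control per molecule
with the two-sided Mann-Whitney U (Wilcoxon rank-sum) test.

## Worked example

Everything below runs from a single seeded synthetic data set — no
downloads. `srnakit fixtures -o inputs --seed 17` writes the same files to
disk for the CLI route.

```python
from srnakit import fixtures, qc, align, annotate

spec = fixtures.FixtureSpec(seed=17)
fs = fixtures.make_all(spec)

qualified, rep = qc.qc_reads(fs.reads, qc.QCConfig())
print(f"QC: {rep.n_qualified}/{rep.n_input} reads qualified")

alns, unmapped = align.micro_align(qualified, fs.genome_fixture.genome,
                                   max_mismatch=1)
print(f"align: {len({a.read_id for a in alns})} reads mapped "
      f"({len(alns)} alignments), {len(unmapped)} unmapped")
index = annotate.FeatureIndex(fs.genome_fixture.features)
tables, _ = annotate.quantify(align.group_by_read(alns), index, min_ratio=1.0)
print(tables["miRNA"].head(3).to_string(index=False))
```

prints

```
QC: 157/172 reads qualified
align: 151 reads mapped (181 alignments), 6 unmapped
         DB      Name           ID  Count
mirnadb_toy miRNA-002 MIRNA-ID-002      8
mirnadb_toy miRNA-001 MIRNA-ID-001      7
mirnadb_toy miRNA-004 MIRNA-ID-004      7
```

157 of 172 raw reads survive QC (10 low-quality, 5 with inserts too short);
151 map to the toy genome and the 6 planted microbial reads stay unmapped,
ready for the microbe stage. Each count table row is one RNA molecule with
the databases supporting its annotation and the number of distinct reads
assigned under the rules above — these match the generator's truth table
exactly.

The same run as a shell pipeline, manifest included:

```sh
srnakit fixtures -o inputs --seed 17
srnakit pipeline -o out --sample s1=inputs/reads.fastq \
    --genome inputs/genome.fa \
    --db inputs/features_mirnadb_toy_miRNA.bed:mirnadb_toy:miRNA \
    --microbe-ref inputs/microbe_refs.fa --taxonomy inputs/taxonomy.tsv \
    --acc2taxid inputs/acc2taxid.tsv
```

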