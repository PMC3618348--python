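# plastomekit

A toolkit for assembling and comparing plastid genomes (plastomes) from
total-DNA shotgun sequencing, together with a fully seeded synthetic-data
simulator so that every stage is testable offline.

The pipeline mirrors the classic reference-guided plastome workflow:

1. **qc** — custom read quality control (N-runs, low-quality counts,
   median quality; 3'-trimming; minimum length 25).
2. **classify** — read-origin estimation (plastid vs bacterial vs
   unassigned) by canonical k-mer voting with banded edit-distance
   verification against a labeled reference panel.
3. **assembly** — plastome read recruitment against published references,
   de Bruijn unitig assembly swept over a k range (selected by additive
   contig length closest to a target), contig merging at 97 % identity /
   50 bp overlap, reference-guided ordering, iterative gap closure against
   ever-closer relatives, and circularization by re-inserting the second
   inverted-repeat copy.
4. **structure** — inverted-repeat detection, LSC/IRb/SSC/IRa
   quadripartite partitioning, and gene/intron/intergenic space accounting.
5. **annotate** — homology transfer of gene models, cross-species
   codon-length tables, and grass-specific feature calls (rbcL–psaI
   hot-spot length, rpl23/rpl32 remnant, accD pseudogene state, rpoC2
   insertion length via user-supplied flank anchors).
6. **compare** — anchor-chained pairwise whole-genome alignment, sliding
   window identity tracks, and a catalogue of deletions > 40 bp within a
   named region.
7. **phylo** — gap-free character matrices from reference-projected
   alignments, exact maximum-parsimony search (exhaustive or
   branch-and-bound) with Fitch scoring, and bootstrap supports.
8. **synth** — synthetic quadripartite plastomes, evolved descendants with
   byte-exact event logs (SNPs, indels, deletions, pseudogene ablations),
   and paired-end read simulation with contaminants and truth labels.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (quadripartite
arithmetic, gene-length differences, gene-count bookkeeping, end-to-end
synthetic genome recovery, deletion-catalogue fidelity, phylogeny
recovery, and the property suites). Two optional tests that download
published GenBank records run only when `PLASTOMEKIT_NETWORK_TESTS=1`.

## Command line

```sh
plastomekit simulate --seed 3 --n-pairs 10000 --out sim/
plastomekit qc sim/reads_1.fastq sim/reads_2.fastq --out qc/
plastomekit classify sim/reads_1.fastq --panel panel.tsv --out cls/
plastomekit assemble qc/filtered_1.fastq qc/filtered_2.fastq \
    --references ref.fasta --relatives rel1.fasta,rel2.fasta \
    --k-sweep 41,51,61 --target-length 135282 --out asm/
plastomekit structure asm/assembly.fasta --gff ann.gff3 --out st/
plastomekit annotate asm/assembly.fasta --reference ref.fasta \
    --reference-gff ref.gff3 --out ann/
plastomekit compare q1.fasta q2.fasta --reference ref.fasta \
    --region 56000:58000 --min-del 40 --out cmp/
plastomekit phylo sp1.fasta sp2.fasta sp3.fasta --reference ref.fasta \
    --replicates 1000 --seed 7 --out tree/
plastomekit pipeline reads_1.fastq reads_2.fastq \
    --references ref.fasta --reference-gff ref.gff3 --out run/
```

Every subcommand is deterministic given its inputs and `--seed`, and
writes the resolved options to `run_config.json` next to its outputs.

## Conventions

- Coordinates are 0-based, half-open, everywhere inside the package;
  GFF3's 1-based inclusive convention is converted at the I/O boundary.
- Circular genomes fix their origin at the first base of the large
  single-copy region, ordered LSC, IRb, SSC, IRa.
- FASTA headers may carry a `[circular]` tag; FASTQ is PHRED+33 by
  default (PHRED+64 via flag).
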