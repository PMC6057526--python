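# svforge

Structural-variant spike-in simulation for benchmarking SV callers and
tumor-heterogeneity tools.

`svforge` embeds deletions, insertions, tandem and inverted duplications,
inversions, translocations and compound events into template genomes and
produces, at the user's choice of output level:

1. **contig** — a FASTA of all original and altered contigs plus the ground
   truth of spiked-in variants as a BED3+ file;
2. **read** — additionally paired-end FASTQ files simulated wgsim-style from
   those contigs;
3. **alignment** — additionally a sorted, indexed BAM via an external
   `bwa mem` / `samtools` wrapper.

Every event carries its own breakpoints (base-pair exact), cell fraction
(allele fraction) and ploidy/haplotype state, so heterozygous, subclonal and
multi-sample tumor/normal designs are all expressible. Event fractions can
be derived from a clonal-evolution phylogeny (`tree2var`), and whole
simulations are driven by small tab-delimited control files (`mutforge`).

## The model

**Clonal trees to allele fractions.** A clonal evolution scenario is a
strictly binary tree: internal node *j* is the bifurcation at which a
fraction *f*(*V<sub>j</sub>*) ∈ [0,1] of the parental cell population gains
variant *V<sub>j</sub>*; leaves are terminal somatic genotypes
*C<sub>i</sub>*. Encoding each root-to-leaf path as a tertiary vector
*c<sub>i,j</sub>* ∈ {0,1,2} (off path / on path but not carried / carried),
the terminal population frequency is

    F(C_i) = prod_{j : c_ij > 0} [ (c_ij - 1) f(V_j) + (2 - c_ij)(1 - f(V_j)) ]

and the marginal carrier fraction of a variant is the sum over carrying
leaves,

    F(V_j) = sum_i 1{c_ij = 2} F(C_i).

`tree2var` computes these from a NEWICK tree whose internal labels name
variants and whose branch weights hold the conditional fractions, and
rewrites the fraction column of a VAR file accordingly.

**Divide and conquer.** For simulation, each chromosome is partitioned into
equal `plan_size` blocks B₁…B_N (`B_k = [G(k-1)/N + 1, Gk/N]`), with
*ligation regions* of width `l` straddling each internal boundary
(`L_k = [Gk/N - l/2 + 1, Gk/N + l/2]`). Each variant becomes an independent
task owning the blocks its impact region touches; unaltered gaps become
no-op tasks capped at `trunk_size` blocks. A task loads its block run plus
half a ligation region on each side, edits the sequence per haplotype, and
samples read pairs from the original and altered contigs in proportion to
the event's cell fraction and each contig's length. Because adjacent contigs
overlap by one ligation region, read sampling there runs at **half rate**
per contig; merged coverage across block boundaries is flat. Per-task seeds
are fixed before dispatch, so results are byte-identical for any worker
count.

## Worked example

Five 2 kb deletions on a 100 kb toy chromosome, with fractions taken from
the six-genotype example phylogeny:

```sh
cat tree.nwk
# ((C1, C2) V5: 0.8, ((C3, C4) V4:0.8, (C5, C6) V3: 0.9) V2:0.6) V1:0.5;

tree2var --tree tree.nwk --var events.var --out clonal.var
```

`tree2var` prints the parsed tree with conditional (f) and final (F)
frequencies to standard error:

```
V1  f=0.5  F=0.5
V5  f=0.8  F=0.4
C1  F=0.4
`-- C2  F=0.1
`-- V2  f=0.6  F=0.3
    |-- V4  f=0.8  F=0.24
    |   |-- C3  F=0.24
    |   `-- C4  F=0.06
    `-- V3  f=0.9  F=0.18
        |-- C5  F=0.18
        `-- C6  F=0.02
```

Half of all cells carry the truncal event V1; 40% carry V5; the V2 lineage
splits further into V4 (24%) and V3 (18%) subclones, and C6 is a nearly
extinct genotype at 2%. The rewritten VAR file carries exactly these
marginal fractions:

```
#vid  pid  fraction  ploidy  chrom  pos    del_len  ins_seq  svtype
V1    .    0.5       2/1,2   chr1   15000  2000     .        DEL
V2    .    0.3       2/1,2   chr1   35000  2000     .        DEL
V3    .    0.18      2/1,2   chr1   55000  2000     .        DEL
V4    .    0.24      2/1,2   chr1   75000  2000     .        DEL
V5    .    0.4       2/1,2   chr1   90000  2000     .        DEL
```

Simulate a 60x paired-end library (insert 300 ± 50 bp, 2 × 150 bp reads,
`libs.par` line: `300 50 150 60 0.0`):

```sh
mutforge --fasta genome.fa --var clonal.var --par libs.par \
         --out sim --level read --plan-size 10000 --ligation 1200 --seed 7
# wrote 6 files to sim (19832 read pairs)
```

`sim/` then contains `contigs.fa`, `reads_1.fq`/`reads_2.fq` (19,832 pairs,
i.e. ~60x over 100 kb), the ground truth `truth.bed`

```
#chrom  start  end    vid  pid  fraction  ploidy  chrom  pos    del_len  ins_seq  svtype
chr1    14999  16999  V1   .    0.5       2/1,2   chr1   15000  2000     .        DEL
chr1    34999  36999  V2   .    0.3       2/1,2   chr1   35000  2000     .        DEL
...
```

and `manifest.tsv` with MD5 checksums and per-task pair counts. Aligning the
reads shows depth inside each deletion reduced by its fraction (e.g. ~50%
for V1, ~18% for V3) with the longer implied insert sizes and clipped reads
an SV caller looks for.

Control files are documented in `svforge/formats.py`: VAR (exact variants),
META (per-class count/size/fraction/ploidy distributions, e.g.
`DEL 100 uniform:100,10000 uniform:0,1 bernoulli:0.5`), PAR (one sequencing
library per line). Masks/targets are plain BED3; `--dry-run` stops after
META expansion so the drawn variants can be inspected or fed to `tree2var`.

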