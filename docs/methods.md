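# Methods

This note records the models implemented by `svforge`, the choices made
where the design was genuinely open, and what the bundled tests do and do
not establish.

## Clonal trees and allele fractions

The clonal model is a strictly binary tree with `n = m + 1` leaves for `m`
internal nodes. Each internal node carries one structural variant and the
conditional fraction `f` of its parental population that gains it; the two
subtrees below a node partition that population into carriers and
non-carriers, so the leaf frequencies are products of branch probabilities
(`f` on the carrying side, `1 - f` on the other) and always sum to exactly
one. A variant's marginal frequency is the total frequency of the leaves
beneath its carrying child, equivalently the product of the branch factors
reaching the node times its own `f`. Fractions of 0 or 1 express deceased
populations (zero-frequency leaves); an empty event at the root (reserved
label `-`) with both child fractions at 1 models a multiclonal origin.

**Gaining-child convention.** NEWICK does not say which child of a
bifurcation inherits the variant. The first-listed child gains by default;
`gaining_child`/`--gaining-child second` flips it. At any single bifurcation
the choice only relabels the two subtrees, but for nested trees it changes
which lineage continues to mutate, so it is part of the scenario definition.

**Numerical policy.** Frequencies are exact floating products; comparisons
use absolute tolerance 1e-9, and `tree2var` rounds rewritten fractions at
1e-12 (three orders below the tolerance) so that control files stay
readable. Optional NEWICK leaf weights are echoed with a warning when they
disagree with the computed leaf frequencies; the computed value is
authoritative.

## Genome partitioning and tasks

Chromosomes are tiled independently with `plan_size` blocks (default 1 Mb;
chromosome-end blocks may be shorter) and ligation regions of width
`ligation` centred on internal block boundaries. The default ligation width
is `2 * (insert_mean + 3 * insert_sd)` of the widest library: a fragment
whose start lies in the overlap then almost surely ends inside it, which is
what makes the half-rate bookkeeping below exact. `ligation` must be
smaller than `plan_size`; odd widths are rounded down to the next even
number when splitting across a boundary.

A variant's impact region (`[pos, pos + del_len - 1]` for deleting/segment
events, the insertion point and the base before it for insertions) is
expanded by half a ligation region before mapping to blocks, so no
breakpoint can fall inside the sequence overlap two neighbouring tasks
share — both tasks must agree on that sequence. Variants whose expanded
runs would share a block are refused with a diagnostic asking for a smaller
`plan_size`; silent merging would break the one-variant-per-task contract
that gives each event its own provenance and seed. Gaps become no-op tasks
capped at `trunk_size` blocks (default 10). Per-task seeds are derived from
`(master_seed, task ordinal)` before dispatch, so any executor — the serial
loop used in tests or a process pool — produces identical bytes.

## META expansion

Event classes are drawn sequentially: sample a size, pick a start uniformly
over all positions whose footprint (impact region plus one full ligation
width of guard on each side) still fits in the available space (targets
minus masks minus previous placements), then remove the footprint. The
guard keeps later tasks' overlap zones breakpoint-free and enforces
pairwise-disjoint impact regions. After 1,000 failed draws the expansion
aborts, naming the event class and the remaining space. Supported
distribution families: `fixed`, `uniform`, `normal` (sizes truncated to
>= 1 bp, fractions clipped to [0,1]), and for zygosity `bernoulli:p`
(homozygous with probability p, else heterozygous) plus the shorthands
`hom`/`het`. Insertion content is uniform random sequence unless a foreign
FASTA source is named, in which case a record and strand are drawn.

## Sequence editing

Edits run in slice-local coordinates; the single genome-to-local conversion
happens at task construction. Each edit also produces a piecewise map from
altered-contig coordinates back to the template (novel insertions map to
nothing; inverted pieces map strand-reversed). The map is what an aligner
would recover, and the analysis helpers use it to compute reference-frame
depth and implied insert sizes without running one. Reverse complementation
handles the full IUPAC alphabet, preserves case (soft-masking survives),
and raises on any other character. Tandem duplications have copy number 2;
higher copy numbers are expressed as repeated insertion records sharing a
pid. Translocations are pid-linked groups: a source arm (`TDEL` excised, or
`TSRC` retained for duplicated translocations) and a destination arm
(`TINS`, or `ITINS` for inverted re-insertion) whose sequence is extracted
once from the template before dispatch, so the arms may live in different
tasks or chromosomes. Ground truth reports every group member under its
shared pid.

## Read sampling

Per contig and library, the expected pair count is
`coverage_share * contig_length / (2 * read_len)`; realized counts are
Poisson. An altered haplotype samples from the altered contig with weight
`fraction` and from the original with `1 - fraction`; each haplotype gets
`coverage / ploidy`. Because expectations scale with each contig's own
length, a large deletion automatically yields proportionally fewer pairs
from the altered contig. Insert sizes are normal per library, resampled
while shorter than `2 * read_len` or longer than the contig (mixtures of
libraries approximate irregular insert distributions); fragment starts are
uniform; mates face inward with the forward mate chosen by a fair coin.
Base qualities are constant at `Q = round(-10 log10(max(base_error,
1e-4)))`.

**Ligation attenuation.** A fragment is kept with probability 0.5 when it
lies *entirely inside* a flagged ligation zone, and at full rate otherwise.
The containment condition (rather than the fragment start alone) is what
makes the scheme exact: a fragment protruding past the zone's inner edge
has no counterpart on the neighbouring contig — the zone sits at that
contig's very end — so halving it would leave a coverage dip of order one
insert length at every block boundary, and the per-contig zone mean would
sit measurably below one half. With containment, the per-contig mean depth
inside a zone is exactly half the interior for any insert-length
distribution (the boundary-straddling full-rate fragments exactly offset
the end-of-contig geometry), and the merged two-contig profile is exactly
flat. The predicate is isolated in `readsim.attenuated`.

**Noise.** Per-read substitution errors are independent per base.
Contig-level SNVs and indels are planted once per contig before sampling,
so overlapping reads agree on the planted allele; indel planting shifts
downstream coordinates and should be off when reference-frame analyses are
wanted.

## Outputs and determinism

Merging concatenates task products in ordinal order (not completion order).
Altered contigs are named `{chrom}_t{ordinal}_{vid}_h{hap}_alt` and reads
`{contig_id}:{pair_ordinal}`, so every read's provenance is
machine-readable and every ground-truth vid appears in a contig header.
Ground truth is BED3 (0-based half-open; a pure insertion covers the base
before its breakpoint so the interval is never empty) followed by the VAR
columns verbatim — including unresolved foreign-sequence tokens. The
manifest lists MD5 checksums and per-task pair counts; determinism tests
compare checksums across worker counts. The alignment level shells out to
`bwa mem` and `samtools` and degrades to read level with a warning when
they are absent; as external glue it is exercised only manually.

## What the tests show

Simulations in the test-suite and acceptance script run at desk scale —
10–100 kb contigs, 30–120x coverage, thousands of events at most — chosen
so every depth/insert assertion has at least ~3-sigma resolution. The
synthetic templates are uniform random sequence: they exercise coordinate
arithmetic, fraction bookkeeping and coverage accounting exactly, but
contain no repeats, GC bias, or platform error structure, so passing tests
say nothing about caller performance on real genomes — that is precisely
the question this simulator is built to let its users ask. Coverage checks
use the analytical bound `SE(mean depth) <= sqrt(read_len * mean / width)`
(reads correlate positions up to one read length), with 3 SE acceptance
bands; clonal-tree frequencies are cross-checked against an independent
Monte-Carlo population cascade at 10^6 cells within 3 binomial SE.

## Known limitations

No microhomology or untemplated breakpoint artifacts; no quality ramps or
homopolymer indel error models; no long-read simulation; duplication copy
number fixed at 2 per record; variants closer than one block must be run
with a smaller plan size. VCF output is out of scope — ground truth is the
BED3+VAR dialect.
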