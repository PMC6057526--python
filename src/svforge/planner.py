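"""Simulation planning: block grid, META expansion, task assignment.

The genome is cut, chromosome by chromosome, into equal-size non-overlapping
blocks of ``plan_size`` bp (chromosome-end blocks may be shorter).  Adjacent
blocks share a symmetric *ligation region* of ``ligation`` bp straddling the
boundary; tasks load their block run plus half a ligation region on each
side, so neighbouring contigs overlap by exactly one ligation region and can
be sampled at half rate there (see :mod:`svforge.readsim`).

Each spiked-in variant becomes one task owning the run of blocks its impact
region touches (expanded by half a ligation region, so breakpoints stay out
of the contig overlaps).  The unaltered gaps between variants become no-op
tasks, capped at ``trunk_size`` blocks for parallel balance.

META expansion draws concrete events from the per-class distributions and
places them sequentially: each event's start is uniform over the positions
that can still accommodate it (inside targets, outside masks, one ligation
length clear of previously placed events), and its footprint is then removed
from the available space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .formats import (
    ForeignRef,
    MetaSpec,
    ValidationError,
    VariantSpec,
)

__all__ = [
    "PlanningError",
    "PlacementError",
    "Block",
    "BlockGrid",
    "Task",
    "plan_blocks",
    "expand_meta",
    "assign_tasks",
]

PLACEMENT_RETRIES = 1000


class PlanningError(ValueError):
    """Variant layout incompatible with the block grid."""


class PlacementError(RuntimeError):
    """META expansion ran out of placeable space."""


@dataclass(frozen=True)
class Block:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class BlockGrid:
    chrom_lengths: dict
    plan_size: int
    ligation: int
    blocks_by_chrom: dict

    @property
    def half(self) -> int:
        return self.ligation // 2

    def blocks(self, chrom: str) -> list[Block]:
        return self.blocks_by_chrom[chrom]

    def ligation_regions(self, chrom: str) -> list[tuple[int, int]]:
        """1-based inclusive regions of width 2*half centred on block boundaries."""
        blocks = self.blocks_by_chrom[chrom]
        out = []
        for left, _right in zip(blocks, blocks[1:]):
            c = left.end
            out.append((c - self.half + 1, c + self.half))
        return out

    def block_run(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Indices (inclusive) of this chromosome's blocks overlapping [start, end]."""
        blocks = self.blocks_by_chrom[chrom]
        first = max(0, (max(start, 1) - 1) // self.plan_size)
        last = min(len(blocks) - 1, (min(end, self.chrom_lengths[chrom]) - 1) // self.plan_size)
        if last < first:
            raise PlanningError(f"empty block run for {chrom}:{start}-{end}")
        return first, last


def plan_blocks(chrom_lengths: dict, plan_size: int, ligation: int) -> BlockGrid:
    """Partition every chromosome into plan_size blocks with ligation regions."""
    if ligation <= 0 or plan_size <= ligation:
        raise ValidationError(
            f"need 0 < ligation ({ligation}) < plan_size ({plan_size})"
        )
    blocks_by_chrom: dict[str, list[Block]] = {}
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise ValidationError(f"chromosome {chrom} has non-positive length")
        blocks = []
        start = 1
        while start <= length:
            end = min(start + plan_size - 1, length)
            blocks.append(Block(chrom, start, end))
            start = end + 1
        blocks_by_chrom[chrom] = blocks
    return BlockGrid(
        chrom_lengths=dict(chrom_lengths),
        plan_size=plan_size,
        ligation=ligation,
        blocks_by_chrom=blocks_by_chrom,
    )


# ---------------------------------------------------------------------------
# META expansion


def _impact_span(svtype: str, size: int) -> int:
    # bases of template the event footprint anchors on
    if svtype == "INS":
        return 2  # the insertion point plus the base before it
    return size


def expand_meta(
    metas: list[MetaSpec],
    grid: BlockGrid,
    rng: np.random.Generator,
    mask: list[tuple[str, int, int]] | None = None,
    target: list[tuple[str, int, int]] | None = None,
    foreign_fastas: dict | None = None,
) -> list[VariantSpec]:
    """Draw concrete, pairwise-disjoint variants from META distributions.

    ``mask``/``target`` are BED3 interval lists (0-based half-open).  Returns
    exactly ``sum(count)`` variants or raises :class:`PlacementError`.
    """
    available = _initial_regions(grid.chrom_lengths, mask, target)
    guard = grid.ligation  # keeps ligation regions breakpoint-free
    variants: list[VariantSpec] = []
    counter: dict[str, int] = {}
    for meta in metas:
        for _ in range(meta.count):
            v = _place_one(meta, available, guard, rng, counter, foreign_fastas)
            variants.append(v)
    return variants


def _initial_regions(chrom_lengths, mask, target):
    # 1-based inclusive interval lists per chromosome
    regions: dict[str, list[tuple[int, int]]] = {}
    if target:
        for chrom, s0, e0 in target:
            if chrom in chrom_lengths:
                regions.setdefault(chrom, []).append(
                    (s0 + 1, min(e0, chrom_lengths[chrom]))
                )
        for chrom in regions:
            regions[chrom] = _merge(regions[chrom])
    else:
        regions = {c: [(1, l)] for c, l in chrom_lengths.items()}
    if mask:
        for chrom, s0, e0 in mask:
            if chrom in regions:
                regions[chrom] = _subtract(regions[chrom], (s0 + 1, e0))
    return regions


def _merge(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(intervals, cut):
    cs, ce = cut
    out = []
    for s, e in intervals:
        if ce < s or cs > e:
            out.append((s, e))
            continue
        if s < cs:
            out.append((s, cs - 1))
        if ce < e:
            out.append((ce + 1, e))
    return out


def _place_one(meta, available, guard, rng, counter, foreign_fastas):
    last_size = None
    for _ in range(PLACEMENT_RETRIES):
        if meta.foreign_source:
            ins_seq, foreign = "", _pick_foreign(meta, rng, foreign_fastas)
            size = None
            span = 2
        else:
            size = meta.size_dist.sample_size(rng)
            span = _impact_span(meta.svtype, size)
            ins_seq, foreign = "", None
            if meta.svtype == "INS":
                ins_seq = "".join(rng.choice(list("ACGT"), size=size))
        last_size = span
        slots = []  # (chrom, interval index, n feasible starts)
        total = 0
        for chrom, intervals in available.items():
            for ix, (a, b) in enumerate(intervals):
                n = (b - span + 1 - guard) - (a + guard) + 1
                if n > 0:
                    slots.append((chrom, ix, n))
                    total += n
        if total == 0:
            continue  # resample the size; maybe a smaller event fits
        pick = int(rng.integers(total))
        for chrom, ix, n in slots:
            if pick < n:
                a, b = available[chrom][ix]
                pos = a + guard + pick
                available[chrom] = _subtract(
                    available[chrom], (pos - guard, pos + span - 1 + guard)
                )
                k = counter.get(meta.svtype, 0) + 1
                counter[meta.svtype] = k
                ploidy, haps = meta.ploidy_dist.sample_ploidy(rng)
                return VariantSpec(
                    vid=f"{meta.svtype}{k:04d}",
                    chrom=chrom,
                    pos=pos,
                    fraction=meta.fraction_dist.sample_fraction(rng),
                    ploidy=ploidy,
                    haplotypes=haps,
                    del_len=0 if meta.svtype == "INS" else size,
                    ins_seq=ins_seq,
                    foreign=foreign,
                    svtype=meta.svtype,
                )
            pick -= n
    remaining = sum(e - s + 1 for iv in available.values() for s, e in iv)
    raise PlacementError(
        f"could not place a {meta.svtype} event (last footprint {last_size} bp "
        f"+ 2x{guard} bp guard) after {PLACEMENT_RETRIES} tries; "
        f"{remaining} bp of placeable space remain"
    )


def _pick_foreign(meta, rng, foreign_fastas):
    if not foreign_fastas or meta.foreign_source not in foreign_fastas:
        raise ValidationError(
            f"META references unknown foreign FASTA {meta.foreign_source!r}"
        )
    records = sorted(foreign_fastas[meta.foreign_source])
    record = records[int(rng.integers(len(records)))]
    strand = "+" if rng.random() < 0.5 else "-"
    return ForeignRef(meta.foreign_source, record, strand)


# ---------------------------------------------------------------------------
# task assignment


@dataclass
class Task:
    ordinal: int
    chrom: str
    kind: str  # "variant" | "noop"
    first_block: int
    last_block: int
    span_start: int  # 1-based inclusive genome coords of the block run
    span_end: int
    load_start: int  # block run +- half a ligation region, clipped
    load_end: int
    variant: VariantSpec | None = None
    seed: int | None = None

    @property
    def contig_length(self) -> int:
        return self.load_end - self.load_start + 1

    def ligation_zones(self, ligation: int) -> list[tuple[int, int]]:
        """Contig-local 0-based half-open zones shared with neighbour tasks."""
        zones = []
        width = 2 * (ligation // 2)
        n = self.contig_length
        if self.load_start < self.span_start:
            zones.append((0, min(width, n)))
        if self.load_end > self.span_end:
            zones.append((max(0, n - width), n))
        return zones


def assign_tasks(
    grid: BlockGrid, variants: list[VariantSpec], trunk_size: int = 10
) -> list[Task]:
    """One task per variant plus capped no-op tasks covering every other block."""
    if trunk_size < 1:
        raise ValidationError("trunk_size must be >= 1")
    half = grid.half
    runs_by_chrom: dict[str, list[tuple[int, int, VariantSpec]]] = {
        c: [] for c in grid.chrom_lengths
    }
    for v in variants:
        if v.chrom not in grid.chrom_lengths:
            raise ValidationError(f"{v.vid}: unknown chromosome {v.chrom!r}")
        if v.end > grid.chrom_lengths[v.chrom]:
            raise ValidationError(
                f"{v.vid}: impact region runs past the end of {v.chrom}"
            )
        impact_start = v.pos - 1 if v.effective_svtype in ("INS", "TINS", "ITINS") else v.pos
        first, last = grid.block_run(
            v.chrom, max(1, impact_start - half), v.end + half
        )
        runs_by_chrom[v.chrom].append((first, last, v))

    tasks: list[Task] = []
    for chrom in grid.chrom_lengths:
        blocks = grid.blocks(chrom)
        runs = sorted(runs_by_chrom[chrom], key=lambda r: (r[0], r[2].pos))
        for (f1, l1, v1), (f2, l2, v2) in zip(runs, runs[1:]):
            if f2 <= l1:
                raise PlanningError(
                    f"variants {v1.vid} and {v2.vid} need overlapping block runs "
                    f"on {chrom}; re-plan with a smaller plan_size or more spacing"
                )
        cursor = 0
        for first, last, v in runs:
            _noop_tasks(tasks, grid, chrom, cursor, first - 1, trunk_size)
            tasks.append(_make_task(tasks, grid, chrom, first, last, "variant", v))
            cursor = last + 1
        _noop_tasks(tasks, grid, chrom, cursor, len(blocks) - 1, trunk_size)
    return tasks


def _noop_tasks(tasks, grid, chrom, first, last, trunk_size):
    start = first
    while start <= last:
        end = min(start + trunk_size - 1, last)
        tasks.append(_make_task(tasks, grid, chrom, start, end, "noop", None))
        start = end + 1


def _make_task(tasks, grid, chrom, first, last, kind, variant):
    blocks = grid.blocks(chrom)
    span_start, span_end = blocks[first].start, blocks[last].end
    half = grid.half
    return Task(
        ordinal=len(tasks),
        chrom=chrom,
        kind=kind,
        first_block=first,
        last_block=last,
        span_start=span_start,
        span_end=span_end,
        load_start=max(1, span_start - half),
        load_end=min(grid.chrom_lengths[chrom], span_end + half),
        variant=variant,
    )
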