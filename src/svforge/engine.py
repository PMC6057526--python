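"""End-to-end orchestration (the ``mutforge`` run).

Plan the block grid, expand/validate variants, assign tasks, run every task
(spike the edit in, sample reads), and merge the per-task products into the
final deliverables:

contig level
    ``contigs.fa`` (all original and altered contigs) + ``truth.bed``
read level
    additionally ``reads_1.fq`` / ``reads_2.fq``
alignment level
    additionally a sorted, indexed BAM via an external bwa-mem/samtools
    wrapper (gracefully degraded to read level when the tools are absent)

Products are a pure function of (inputs, master seed): each task draws from
its own generator seeded by (master seed, task ordinal), and merging follows
task ordinal order, so any worker count yields byte-identical files.
A tab-delimited ``manifest.tsv`` records every product with its MD5 checksum
and the per-task realized pair counts.
"""

from __future__ import annotations

import hashlib
import multiprocessing
import os
import shutil
import subprocess
import warnings
from dataclasses import dataclass, field

import numpy as np
import pyfaidx

from . import formats, planner, readsim
from .forge import forge, resolve_compound
from .formats import ValidationError

__all__ = ["RunConfig", "TaskProduct", "mutforge", "merge_outputs", "align_wrapper"]

LEVELS = ("contig", "read", "alignment")


@dataclass
class RunConfig:
    fasta: str
    out_dir: str
    var: str | None = None
    meta: str | None = None
    par: str | None = None
    level: str = "read"
    plan_size: int = 1_000_000
    ligation: int | None = None  # default: 2 * max(insert_mean + 3 * insert_sd)
    trunk_size: int = 10
    mask: str | None = None
    target: str | None = None
    foreign: dict = field(default_factory=dict)  # name -> FASTA path
    seed: int = 0
    workers: int = 1
    dry_run: bool = False

    def validate(self) -> None:
        if (self.var is None) == (self.meta is None):
            raise ValidationError("provide exactly one of --var / --meta")
        if self.level not in LEVELS:
            raise ValidationError(f"output level must be one of {LEVELS}")
        if self.level in ("read", "alignment") and not self.par:
            raise ValidationError(f"output level {self.level!r} requires a PAR file")
        if self.workers < 1:
            raise ValidationError("workers must be >= 1")


@dataclass
class TaskProduct:
    ordinal: int
    contigs: list  # [(name, sequence)]
    pairs: list  # [ReadPair]


def task_seed(master_seed: int, ordinal: int) -> int:
    """Per-task seed, fixed before dispatch so scheduling cannot matter."""
    return int(np.random.SeedSequence([master_seed, ordinal]).generate_state(1)[0])


def mutforge(config: RunConfig) -> dict:
    """Run the full simulation; returns the manifest as a dict."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    template = pyfaidx.Fasta(config.fasta, as_raw=True, sequence_always_upper=False)
    chrom_lengths = {name: len(template[name]) for name in template.keys()}
    libraries = formats.read_par(config.par) if config.par else []
    if config.level in ("read", "alignment") and not libraries:
        raise ValidationError("read-level output requested but the PAR file is empty")
    foreign_fastas = {
        name: formats.read_fasta(path) for name, path in config.foreign.items()
    }
    ligation = config.ligation
    if ligation is None:
        if libraries:
            ligation = int(2 * max(l.insert_mean + 3 * l.insert_sd for l in libraries))
        else:
            ligation = 600
    grid = planner.plan_blocks(chrom_lengths, config.plan_size, ligation)

    mask = formats.read_bed3(config.mask) if config.mask else None
    target = formats.read_bed3(config.target) if config.target else None
    if config.var:
        variants = formats.read_var(config.var)
    else:
        metas = formats.read_meta(config.meta)
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed])))
        variants = planner.expand_meta(
            metas, grid, rng, mask=mask, target=target, foreign_fastas=foreign_fastas
        )
    chrom_order = {c: i for i, c in enumerate(chrom_lengths)}
    for v in variants:
        if v.chrom not in chrom_lengths:
            raise ValidationError(f"{v.vid}: unknown chromosome {v.chrom!r}")
    variants = sorted(variants, key=lambda v: (chrom_order[v.chrom], v.pos))
    edits, truth = resolve_compound(variants, template, foreign_fastas)

    tasks = planner.assign_tasks(grid, edits, config.trunk_size)
    for t in tasks:
        t.seed = task_seed(config.seed, t.ordinal)

    var_path = os.path.join(config.out_dir, "expanded.var")
    formats.write_var(truth, var_path)
    plan_path = os.path.join(config.out_dir, "plan.tsv")
    _write_plan(tasks, plan_path)
    if config.dry_run:
        return _manifest(config, [var_path, plan_path], {})

    inputs = []
    for t in tasks:
        zone_flags = (t.load_start < t.span_start, t.load_end > t.span_end)
        slice_seq = str(template[t.chrom][t.load_start - 1 : t.load_end])
        inputs.append(
            (
                t.ordinal,
                t.chrom,
                slice_seq,
                t.load_start,
                t.variant,
                t.ligation_zones(ligation),
                zone_flags,
                2 * grid.half,
                libraries if config.level in ("read", "alignment") else [],
                t.seed,
            )
        )
    if config.workers == 1:
        products = [_run_task(args) for args in inputs]
    else:
        with multiprocessing.Pool(config.workers) as pool:
            products = pool.map(_run_task, inputs)

    files = merge_outputs(products, truth, config.out_dir, config.level)
    files = [var_path, plan_path] + files
    if config.level == "alignment":
        bam = align_wrapper(
            os.path.join(config.out_dir, "reads_1.fq"),
            os.path.join(config.out_dir, "reads_2.fq"),
            config.fasta,
            os.path.join(config.out_dir, "aligned"),
        )
        if bam:
            files.append(bam)
    counts = {p.ordinal: len(p.pairs) for p in products}
    return _manifest(config, files, counts)


def _run_task(args) -> TaskProduct:
    (
        ordinal,
        chrom,
        slice_seq,
        load_start,
        variant,
        zones,
        zone_flags,
        zone_width,
        libraries,
        seed,
    ) = args
    rng = np.random.Generator(np.random.PCG64(seed))
    prefix = f"{chrom}_t{ordinal}"
    if variant is None:
        pair = forge_noop(slice_seq, load_start)
        fraction = 0.0
    else:
        prefix = f"{prefix}_{variant.vid}"
        pair = forge(slice_seq, variant, load_start, zones)
        fraction = variant.fraction
    contigs = [(f"{prefix}_org", pair.original)]
    if pair.altered is not None:
        for h in sorted(pair.altered_haps):
            contigs.append((f"{prefix}_h{h}_alt", pair.altered))
    pairs = []
    if libraries:
        entries = readsim.build_sampling_plan(
            pair, libraries, fraction, prefix, zone_flags, zone_width
        )
        pairs = readsim.simulate_plan(entries, rng)
    return TaskProduct(ordinal=ordinal, contigs=contigs, pairs=pairs)


def forge_noop(slice_seq: str, load_start: int):
    from .forge import ContigPair

    return ContigPair(original=slice_seq, altered=None, pieces=(), offset=load_start)


def merge_outputs(
    products: list[TaskProduct], truth, out_dir: str, level: str
) -> list[str]:
    """Concatenate task products in ordinal order into the final files."""
    products = sorted(products, key=lambda p: p.ordinal)
    if [p.ordinal for p in products] != list(range(len(products))):
        missing = set(range(len(products))) - {p.ordinal for p in products}
        raise RuntimeError(f"missing task products: {sorted(missing)}")
    fasta_path = os.path.join(out_dir, "contigs.fa")
    formats.write_fasta(
        ((name, seq) for p in products for name, seq in p.contigs), fasta_path
    )
    bed_path = os.path.join(out_dir, "truth.bed")
    formats.write_ground_truth_bed(truth, bed_path)
    files = [fasta_path, bed_path]
    if level in ("read", "alignment"):
        fq1 = os.path.join(out_dir, "reads_1.fq")
        fq2 = os.path.join(out_dir, "reads_2.fq")
        formats.write_fastq_pair(
            (pair for p in products for pair in p.pairs), fq1, fq2
        )
        files += [fq1, fq2]
    return files


def align_wrapper(fq1: str, fq2: str, reference: str, out_prefix: str) -> str | None:
    """Thin bwa-mem + samtools wrapper (external glue, untested by default).

    Returns the sorted BAM path, or None (with a warning) when the external
    executables are unavailable, degrading the run to read-level products.
    """
    if not (shutil.which("bwa") and shutil.which("samtools")):
        warnings.warn("bwa/samtools not found; degrading to read-level output")
        return None
    bam = out_prefix + ".bam"
    if not os.path.exists(reference + ".bwt"):
        subprocess.run(["bwa", "index", reference], check=True, capture_output=True)
    mem = subprocess.Popen(
        ["bwa", "mem", reference, fq1, fq2],
        stdout=subprocess.PIPE,
        stderr=subprocess.DEVNULL,
    )
    subprocess.run(
        ["samtools", "sort", "-o", bam],
        stdin=mem.stdout,
        check=True,
        capture_output=True,
    )
    mem.stdout.close()
    if mem.wait() != 0:
        raise RuntimeError("bwa mem exited non-zero")
    subprocess.run(["samtools", "index", bam], check=True, capture_output=True)
    return bam


def _write_plan(tasks, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#ordinal\tchrom\tkind\tfirst_block\tlast_block\tspan_start\t"
            "span_end\tload_start\tload_end\tvid\tseed\n"
        )
        for t in tasks:
            fh.write(
                f"{t.ordinal}\t{t.chrom}\t{t.kind}\t{t.first_block}\t{t.last_block}\t"
                f"{t.span_start}\t{t.span_end}\t{t.load_start}\t{t.load_end}\t"
                f"{t.variant.vid if t.variant else '.'}\t{t.seed}\n"
            )


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(config: RunConfig, files: list[str], pair_counts: dict) -> dict:
    manifest = {
        "files": {os.path.basename(f): _md5(f) for f in files},
        "pair_counts": dict(sorted(pair_counts.items())),
        "total_pairs": int(sum(pair_counts.values())),
        "seed": config.seed,
        "level": config.level,
    }
    path = os.path.join(config.out_dir, "manifest.tsv")
    with open(path, "w") as fh:
        fh.write("#key\tvalue\n")
        fh.write(f"seed\t{config.seed}\n")
        fh.write(f"level\t{config.level}\n")
        fh.write(f"total_pairs\t{manifest['total_pairs']}\n")
        for name, digest in manifest["files"].items():
            fh.write(f"md5:{name}\t{digest}\n")
        for ordinal, count in manifest["pair_counts"].items():
            fh.write(f"pairs:task{ordinal}\t{count}\n")
    return manifest
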