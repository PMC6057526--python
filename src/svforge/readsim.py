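"""Paired-end short-read sampling from original and altered contigs.

For every contig the expected pair count is ``coverage_share * contig_length
/ (2 * read_len)``; realized counts are Poisson around that expectation.
Fragment starts are uniform, insert sizes are normal per library (resampled
while shorter than two read lengths or longer than the contig) and mates
face inward (FR orientation) with the forward mate chosen by a fair coin.

Allele fractions enter through the sampling plan: an altered haplotype
contributes reads from the altered contig with weight ``fraction`` and from
the original with weight ``1 - fraction``; each haplotype receives
``coverage / ploidy`` of a library's coverage.

Ligation regions — the overlap a task's contig shares with its neighbours —
are sampled at half rate so that merged coverage stays flat: a fragment
lying *entirely inside* a flagged zone is kept with probability 0.5, while a
fragment protruding beyond the zone (which the neighbouring contig cannot
produce, as the zone sits at its very end) is kept at full rate.  This one
predicate (:func:`attenuated`) makes the per-contig mean depth inside a zone
exactly half the interior depth and the merged two-contig profile exactly
flat, for any insert-length distribution.

Optional noise: per-base substitution errors per read, and contig-level
random SNV/indels planted once before sampling so overlapping reads agree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .forge import ContigPair, Piece, reverse_complement
from .formats import LibrarySpec

__all__ = [
    "ReadPair",
    "PlanEntry",
    "build_sampling_plan",
    "attenuated",
    "sample_pairs",
    "apply_errors",
    "plant_small_variants",
    "simulate_plan",
    "read_depth",
    "reference_read_depth",
    "lift_interval",
    "implied_reference_insert",
]

_BASES = "ACGT"
MIN_ERROR_FOR_QUAL = 1e-4


@dataclass(frozen=True)
class ReadPair:
    """One simulated pair; fragment coordinates are contig-local 0-based."""

    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    contig_id: str
    frag_start: int
    insert: int
    read1_forward: bool

    @property
    def read_len(self) -> int:
        return len(self.seq1)

    def read_intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """Contig-local half-open spans of the two reads (left first)."""
        r = self.read_len
        s, ins = self.frag_start, self.insert
        return (s, s + r), (s + ins - r, s + ins)


@dataclass(frozen=True)
class PlanEntry:
    """One (contig, haplotype, library) sampling assignment."""

    contig_id: str
    seq: str
    coverage: float  # effective fold coverage for this entry
    library: LibrarySpec
    zones: tuple = ()  # contig-local 0-based half-open attenuated zones
    pieces: tuple = ()  # altered->original map; identity for originals
    hap: int = 0  # 0 = haplotype-agnostic (merged original / no-op)
    kind: str = "org"  # "org" | "alt"

    @property
    def expected_pairs(self) -> float:
        return self.coverage * len(self.seq) / (2 * self.library.read_len)


def _zones_for_length(flags: tuple[bool, bool], width: int, n: int) -> tuple:
    zones = []
    if flags[0]:
        zones.append((0, min(width, n)))
    if flags[1]:
        zones.append((max(0, n - width), n))
    return tuple(zones)


def build_sampling_plan(
    pair: ContigPair,
    libraries: list[LibrarySpec],
    fraction: float,
    name_prefix: str,
    zone_flags: tuple[bool, bool] = (False, False),
    zone_width: int = 0,
) -> list[PlanEntry]:
    """Expand one task's contigs into per-(contig, haplotype, library) entries.

    ``zone_flags`` say whether the contig's left/right end overlaps a
    neighbour task; ``zone_width`` is the full ligation-region width.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0,1]")
    entries: list[PlanEntry] = []
    n_org = len(pair.original)
    org_zones = _zones_for_length(zone_flags, zone_width, n_org)
    identity = (Piece(n_org, 0),)
    for lib in libraries:
        if pair.altered is None or not pair.altered_haps:
            entries.append(
                PlanEntry(
                    contig_id=f"{name_prefix}_org",
                    seq=pair.original,
                    coverage=lib.coverage,
                    library=lib,
                    zones=org_zones,
                    pieces=identity,
                )
            )
            continue
        per_hap = lib.coverage / pair.ploidy
        n_alt_haps = len(pair.altered_haps)
        org_cov = per_hap * ((pair.ploidy - n_alt_haps) + n_alt_haps * (1.0 - fraction))
        if org_cov > 0:
            entries.append(
                PlanEntry(
                    contig_id=f"{name_prefix}_org",
                    seq=pair.original,
                    coverage=org_cov,
                    library=lib,
                    zones=org_zones,
                    pieces=identity,
                )
            )
        if fraction > 0:
            n_alt = len(pair.altered)
            alt_zones = _zones_for_length(zone_flags, zone_width, n_alt)
            for h in sorted(pair.altered_haps):
                entries.append(
                    PlanEntry(
                        contig_id=f"{name_prefix}_h{h}_alt",
                        seq=pair.altered,
                        coverage=per_hap * fraction,
                        library=lib,
                        zones=alt_zones,
                        pieces=pair.pieces,
                        hap=h,
                        kind="alt",
                    )
                )
    return entries


def attenuated(frag_start: int, frag_end: int, zones) -> bool:
    """True if the fragment lies entirely inside one flagged ligation zone."""
    return any(zs <= frag_start and frag_end <= ze for zs, ze in zones)


def _draw_insert(rng, lib: LibrarySpec, contig_len: int) -> int:
    lo, hi = 2 * lib.read_len, contig_len
    for _ in range(1000):
        ins = int(round(rng.normal(lib.insert_mean, lib.insert_sd)))
        if lo <= ins <= hi:
            return ins
    return min(max(lo, int(lib.insert_mean)), hi)


def sample_pairs(entry: PlanEntry, rng: np.random.Generator) -> list[ReadPair]:
    """Draw this entry's read pairs (no base errors yet; see apply_errors)."""
    lib = entry.library
    L, R = len(entry.seq), lib.read_len
    if L < 2 * R:
        if entry.expected_pairs > 0:
            warnings.warn(
                f"contig {entry.contig_id} ({L} bp) shorter than the minimum "
                f"insert {2 * R} bp; no reads sampled",
                stacklevel=2,
            )
        return []
    n = int(rng.poisson(entry.expected_pairs))
    qual_char = chr(_phred(lib.base_error) + 33)
    quals = qual_char * R
    pairs: list[ReadPair] = []
    for _ in range(n):
        ins = _draw_insert(rng, lib, L)
        start = int(rng.integers(0, L - ins + 1))
        if attenuated(start, start + ins, entry.zones) and rng.random() >= 0.5:
            continue
        read1_forward = bool(rng.random() < 0.5)
        fwd = entry.seq[start : start + R]
        rev = reverse_complement(entry.seq[start + ins - R : start + ins])
        seq1, seq2 = (fwd, rev) if read1_forward else (rev, fwd)
        pairs.append(
            ReadPair(
                name=f"{entry.contig_id}:{len(pairs)}",
                seq1=seq1,
                qual1=quals,
                seq2=seq2,
                qual2=quals,
                contig_id=entry.contig_id,
                frag_start=start,
                insert=ins,
                read1_forward=read1_forward,
            )
        )
    return pairs


def _phred(base_error: float) -> int:
    return int(round(-10.0 * math.log10(max(base_error, MIN_ERROR_FOR_QUAL))))


def apply_errors(pair: ReadPair, library: LibrarySpec, rng: np.random.Generator) -> ReadPair:
    """Substitute each base independently with the library's error rate."""
    e = library.base_error
    if e <= 0.0:
        return pair
    return _dc_replace(
        pair, seq1=_mutate(pair.seq1, e, rng), seq2=_mutate(pair.seq2, e, rng)
    )


def _mutate(seq: str, rate: float, rng) -> str:
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        old = chars[i].upper()
        alternatives = [b for b in _BASES if b != old] or list(_BASES)
        chars[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def plant_small_variants(seq: str, library: LibrarySpec, rng: np.random.Generator) -> str:
    """Plant random SNVs/indels on a contig before sampling.

    Planting precedes read drawing, so every overlapping read sees the same
    change.  Indels shift downstream coordinates; runs mixing indel planting
    with reference-frame analysis should keep indel_rate at 0.
    """
    if library.snv_rate <= 0 and library.indel_rate <= 0:
        return seq
    chars = list(seq)
    if library.snv_rate > 0:
        for i in np.nonzero(rng.random(len(chars)) < library.snv_rate)[0]:
            old = chars[i].upper()
            alternatives = [b for b in _BASES if b != old] or list(_BASES)
            chars[i] = alternatives[int(rng.integers(len(alternatives)))]
    if library.indel_rate > 0:
        sites = np.nonzero(rng.random(len(chars)) < library.indel_rate)[0]
        for i in reversed(sites):  # right-to-left keeps earlier sites valid
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                del chars[i : i + size]
            else:
                chars[i:i] = rng.choice(list(_BASES), size=size).tolist()
    return "".join(chars)


def simulate_plan(entries: list[PlanEntry], rng: np.random.Generator) -> list[ReadPair]:
    """Run every plan entry in order through planting, sampling and errors."""
    out: list[ReadPair] = []
    for entry in entries:
        lib = entry.library
        seq = plant_small_variants(entry.seq, lib, rng)
        if seq is not entry.seq:
            entry = _dc_replace(entry, seq=seq)
        for pair in sample_pairs(entry, rng):
            out.append(apply_errors(pair, lib, rng))
    return out


# ---------------------------------------------------------------------------
# analysis helpers (depth and insert size without an aligner)


def read_depth(pairs, contig_len: int) -> np.ndarray:
    """Per-base read depth on the source contig."""
    depth = np.zeros(contig_len + 1)
    for p in pairs:
        for s, e in p.read_intervals():
            depth[s] += 1
            depth[e] -= 1
    return np.cumsum(depth[:-1])


def lift_interval(pieces, start: int, end: int):
    """Map an altered-contig half-open interval to original-slice intervals."""
    out = []
    alt_pos = 0
    for piece in pieces:
        lo = max(start, alt_pos)
        hi = min(end, alt_pos + piece.length)
        if lo < hi and piece.ref_start is not None:
            off_lo, off_hi = lo - alt_pos, hi - alt_pos
            if piece.strand == "+":
                out.append((piece.ref_start + off_lo, piece.ref_start + off_hi))
            else:
                out.append(
                    (
                        piece.ref_start + piece.length - off_hi,
                        piece.ref_start + piece.length - off_lo,
                    )
                )
        alt_pos += piece.length
    return out


def reference_read_depth(pairs, pieces, ref_len: int) -> np.ndarray:
    """Reference-frame read depth of pairs sampled from a (possibly altered) contig."""
    depth = np.zeros(ref_len + 1)
    for p in pairs:
        for s, e in p.read_intervals():
            for rs, re_ in lift_interval(pieces, s, e):
                depth[rs] += 1
                depth[re_] -= 1
    return np.cumsum(depth[:-1])


def implied_reference_insert(pair: ReadPair, pieces) -> int | None:
    """Reference-frame insert an aligner would infer for this pair.

    Requires both reads to map contiguously (each fully inside one piece);
    returns None otherwise (e.g. a read crossing a junction, which would be
    soft-clipped or split).
    """
    spans = []
    for s, e in pair.read_intervals():
        lifted = lift_interval(pieces, s, e)
        if len(lifted) != 1 or lifted[0][1] - lifted[0][0] != e - s:
            return None
        spans.append(lifted[0])
    lo = min(s for s, _ in spans)
    hi = max(e for _, e in spans)
    return hi - lo
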