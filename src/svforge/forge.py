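"""Sequence editing: apply one structural variant to a template slice.

All edits run in slice-local coordinates (the conversion from genome
coordinates happens once, at task construction).  Besides the altered
sequence, every edit produces a piecewise map from altered-contig
coordinates back to the original slice — the same map an aligner would
recover — which downstream code uses to compute reference-frame depth and
implied insert sizes without running an aligner.

Supported classes (``pos`` 1-based slice-local, segment = ``[pos,
pos+del_len-1]``):

=========  ==============================================================
DEL/TDEL   excise the segment
INS        insert ``ins_seq`` before ``pos``
DELINS     excise the segment, then insert ``ins_seq`` in its place
DUP        tandem duplication: a second copy right after the segment
IDUP       inverted duplication: reverse-complement copy after the segment
INV        replace the segment by its reverse complement
TINS       translocation destination: insert the source segment
ITINS      inverted translocation destination
TSRC       duplicated-translocation source: segment retained, no edit
=========  ==============================================================

Compound events (translocations) arrive as pid-linked groups of the above;
:func:`resolve_compound` extracts each source segment once and routes it to
the destination record before task dispatch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .formats import ValidationError, VariantSpec

__all__ = [
    "DataError",
    "reverse_complement",
    "Piece",
    "ContigPair",
    "forge",
    "resolve_compound",
]


class DataError(ValueError):
    """Sequence content violates assumptions (e.g. non-IUPAC characters)."""


_IUPAC = "ACGTUMRWSYKVHDBN"
_COMP = "TGCAAKYWSRMBDHVN"
_RC_TABLE = str.maketrans(_IUPAC + _IUPAC.lower(), _COMP + _COMP.lower())
_VALID = set(_IUPAC + _IUPAC.lower())


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement; case (soft-masking) is preserved."""
    bad = set(seq) - _VALID
    if bad:
        raise DataError(f"cannot reverse-complement non-IUPAC characters {sorted(bad)}")
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class Piece:
    """One run of the altered contig mapping to one original-slice interval.

    ``ref_start`` is 0-based in original-slice coordinates, or None for
    novel (inserted) sequence.  ``strand`` '-' means the run is the reverse
    complement of the original interval.
    """

    length: int
    ref_start: int | None
    strand: str = "+"

    @property
    def ref_end(self) -> int | None:
        return None if self.ref_start is None else self.ref_start + self.length


@dataclass(frozen=True)
class ContigPair:
    """Original and per-haplotype altered sequence of one task's contig."""

    original: str
    altered: str | None  # None for no-op tasks
    pieces: tuple  # Piece map of the altered sequence
    offset: int  # 1-based genome coordinate of original[0]
    ploidy: int = 2
    altered_haps: frozenset = frozenset()
    breakpoints: tuple = ()  # altered-contig 0-based junction coordinates

    def haplotype(self, h: int) -> str:
        """Sequence of haplotype h (1-based index)."""
        if self.altered is not None and h in self.altered_haps:
            return self.altered
        return self.original

    def __post_init__(self):
        if self.altered is not None:
            delta = sum(p.length for p in self.pieces) - len(self.altered)
            if delta != 0:
                raise AssertionError("piece map does not cover the altered contig")


def _segment(seq: str, pos: int, del_len: int, vid: str) -> str:
    if del_len < 1:
        raise ValidationError(f"{vid}: segment operation needs del_len >= 1")
    if pos < 1 or pos - 1 + del_len > len(seq):
        raise ValidationError(f"{vid}: segment [{pos},{pos + del_len - 1}] outside contig")
    return seq[pos - 1 : pos - 1 + del_len]


def apply_edit(
    seq: str, svtype: str, pos: int, del_len: int, ins_seq: str, vid: str = "?"
) -> tuple[str, tuple, tuple]:
    """Return (altered sequence, piece map, altered-coordinate breakpoints)."""
    p = pos - 1  # 0-based
    n = len(seq)
    if not 0 <= p <= n:
        raise ValidationError(f"{vid}: position {pos} outside contig of length {n}")
    if svtype in ("DEL", "TDEL"):
        _segment(seq, pos, del_len, vid)
        altered = seq[:p] + seq[p + del_len :]
        pieces = (Piece(p, 0), Piece(n - p - del_len, p + del_len))
        return altered, pieces, (p,)
    if svtype in ("INS", "TINS", "ITINS"):
        if not ins_seq:
            raise ValidationError(f"{vid}: insertion without sequence")
        altered = seq[:p] + ins_seq + seq[p:]
        pieces = (Piece(p, 0), Piece(len(ins_seq), None), Piece(n - p, p))
        return altered, pieces, (p, p + len(ins_seq))
    if svtype == "DELINS":
        _segment(seq, pos, del_len, vid)
        if not ins_seq:
            raise ValidationError(f"{vid}: DELINS without replacement sequence")
        altered = seq[:p] + ins_seq + seq[p + del_len :]
        pieces = (Piece(p, 0), Piece(len(ins_seq), None), Piece(n - p - del_len, p + del_len))
        return altered, pieces, (p, p + len(ins_seq))
    if svtype in ("DUP", "IDUP"):
        seg = _segment(seq, pos, del_len, vid)
        copy = reverse_complement(seg) if svtype == "IDUP" else seg
        altered = seq[: p + del_len] + copy + seq[p + del_len :]
        strand = "-" if svtype == "IDUP" else "+"
        pieces = (
            Piece(p + del_len, 0),
            Piece(del_len, p, strand),
            Piece(n - p - del_len, p + del_len),
        )
        return altered, pieces, (p + del_len, p + 2 * del_len)
    if svtype == "INV":
        seg = _segment(seq, pos, del_len, vid)
        altered = seq[:p] + reverse_complement(seg) + seq[p + del_len :]
        pieces = (Piece(p, 0), Piece(del_len, p, "-"), Piece(n - p - del_len, p + del_len))
        return altered, pieces, (p, p + del_len)
    raise ValidationError(f"{vid}: svtype {svtype!r} is not an editable class")


def _original_breakpoints(svtype: str, pos: int, del_len: int) -> tuple[int, ...]:
    # 0-based slice-local coordinates of template junctions
    p = pos - 1
    if svtype in ("INS", "TINS", "ITINS"):
        return (p,)
    return (p, p + del_len)


def forge(
    original: str,
    variant: VariantSpec,
    offset: int,
    ligation_zones: list[tuple[int, int]] = (),
) -> ContigPair:
    """Spike ``variant`` into ``original`` (the task's loaded slice).

    ``offset`` is the 1-based genome coordinate of ``original[0]``;
    ``ligation_zones`` are contig-local 0-based half-open intervals shared
    with neighbour tasks, which no breakpoint may enter.
    """
    if variant.foreign is not None:
        raise ValidationError(
            f"{variant.vid}: unresolved foreign insertion; run resolve_compound first"
        )
    svtype = variant.effective_svtype
    if svtype == "TSRC":
        return ContigPair(
            original=original, altered=None, pieces=(), offset=offset,
            ploidy=variant.ploidy, altered_haps=frozenset(),
        )
    local_pos = variant.pos - offset + 1
    for bp in _original_breakpoints(svtype, local_pos, variant.del_len):
        for zs, ze in ligation_zones:
            if zs <= bp < ze:
                raise PlanningContractError(
                    f"{variant.vid}: breakpoint at contig offset {bp} falls inside "
                    f"ligation zone [{zs},{ze}); the planner must assign wider runs"
                )
    altered, pieces, breakpoints = apply_edit(
        original, svtype, local_pos, variant.del_len, variant.ins_seq, variant.vid
    )
    return ContigPair(
        original=original,
        altered=altered,
        pieces=pieces,
        offset=offset,
        ploidy=variant.ploidy,
        altered_haps=variant.haplotypes,
        breakpoints=breakpoints,
    )


class PlanningContractError(RuntimeError):
    """A breakpoint landed inside a ligation buffer; planning bug upstream."""


# ---------------------------------------------------------------------------
# compound events


def resolve_compound(
    variants: list[VariantSpec],
    template: dict | None = None,
    foreign_fastas: dict | None = None,
) -> tuple[list[VariantSpec], list[VariantSpec]]:
    """Validate pid groups and materialize routed/foreign insertion sequences.

    Returns ``(edit_variants, truth_variants)``: the records to dispatch as
    edits (TSRC rows dropped, TINS/ITINS and foreign insertions carrying
    literal sequence) and the untouched input records for ground truth.

    ``template`` maps chromosome name to sequence (any str-sliceable mapping,
    e.g. a pyfaidx Fasta); required when translocation arms are present.
    """
    by_vid = {v.vid: v for v in variants}
    groups: dict[str, list[VariantSpec]] = {}
    for v in variants:
        if v.pid:
            groups.setdefault(v.pid, []).append(v)
    for pid, members in groups.items():
        if pid not in by_vid and len(members) < 2:
            raise ValidationError(
                f"dangling pid {pid!r} on {members[0].vid}: matches no vid and no group"
            )
    _check_cycles(variants, by_vid)
    for pid, members in groups.items():
        anchor = [by_vid[pid]] if pid in by_vid else []
        group = anchor + members
        fracs = {round(v.fraction, 12) for v in group}
        codes = {v.ploidy_code for v in group}
        if len(fracs) > 1 or len(codes) > 1:
            raise ValidationError(
                f"compound group {pid!r}: members disagree on fraction/ploidy"
            )

    edits: list[VariantSpec] = []
    for v in variants:
        sv = v.effective_svtype
        if sv == "TSRC":
            continue  # segment retained; no edit at the source
        if sv in ("TINS", "ITINS") and not v.ins_seq:
            source = _find_source(v, groups, by_vid)
            if template is None:
                raise ValidationError(
                    f"{v.vid}: translocation needs the template to extract its segment"
                )
            seg = str(template[source.chrom][source.pos - 1 : source.pos - 1 + source.del_len])
            if sv == "ITINS":
                seg = reverse_complement(seg)
            edits.append(replace(v, ins_seq=seg))
            continue
        if v.foreign is not None:
            if not foreign_fastas or v.foreign.fasta not in foreign_fastas:
                raise ValidationError(
                    f"{v.vid}: foreign FASTA {v.foreign.fasta!r} not provided"
                )
            records = foreign_fastas[v.foreign.fasta]
            if v.foreign.record not in records:
                raise ValidationError(
                    f"{v.vid}: record {v.foreign.record!r} absent from "
                    f"{v.foreign.fasta!r}"
                )
            seq = str(records[v.foreign.record])
            if v.foreign.strand == "-":
                seq = reverse_complement(seq)
            edits.append(replace(v, ins_seq=seq, foreign=None))
            continue
        edits.append(v)
    return edits, list(variants)


def _check_cycles(variants, by_vid):
    for v in variants:
        seen = {v.vid}
        cur = v
        while cur.pid and cur.pid in by_vid:
            if cur.pid in seen:
                raise ValidationError(f"pid cycle involving {cur.pid!r}")
            seen.add(cur.pid)
            cur = by_vid[cur.pid]


def _find_source(dest: VariantSpec, groups, by_vid) -> VariantSpec:
    pool = list(groups.get(dest.pid, []))
    if dest.pid in by_vid:
        pool.append(by_vid[dest.pid])
    sources = [m for m in pool if m.effective_svtype in ("TDEL", "TSRC")]
    if not sources:
        raise ValidationError(
            f"{dest.vid}: no TDEL/TSRC source arm in compound group {dest.pid!r}"
        )
    dests = sorted(
        (m for m in pool if m.effective_svtype in ("TINS", "ITINS")),
        key=lambda m: m.vid,
    )
    sources = sorted(sources, key=lambda m: m.vid)
    ix = [m.vid for m in dests].index(dest.vid) if dest.vid in [m.vid for m in dests] else 0
    return sources[min(ix, len(sources) - 1)]
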