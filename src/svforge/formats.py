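"""File dialects used by the simulator.

Standard formats: FASTA (templates, foreign sequences, output contigs),
FASTQ (Sanger Phred+33), BED3+ (ground truth; plain BED3 masks/targets) and
NEWICK (clonal trees, parsed in :mod:`svforge.clonal_tree`).

Tool-defined tab-delimited control files:

``VAR``
    one exact variant per line:
    ``vid  pid  fraction  ploidy  chrom  pos  del_len  ins_seq  [svtype]``.
    Coordinates are 1-based inclusive. ``pid`` groups the arms of a compound
    event (e.g. a translocation); ``.`` means empty. ``ploidy`` is
    ``P/h1,h2,...`` (total haploid count, slash, altered haplotype indices)
    with shorthands ``hom`` (all haplotypes of a diploid) and ``het``
    (haplotype 1 of a diploid). ``ins_seq`` is ``.``, a literal sequence, or
    a foreign reference ``fasta_name:record_id:strand``.

``META``
    one variant meta-distribution per line:
    ``svtype  count  size_dist  fraction_dist  ploidy_dist  [foreign_source]``.
    Distribution tokens are ``family:p1,p2`` with families ``fixed``,
    ``uniform``, ``normal`` (sizes truncated to >=1, fractions clipped to
    [0,1]) and, for ploidy, ``bernoulli:p`` (hom with probability p, else
    het) plus bare ``hom`` / ``het``.

``PAR``
    one sequencing library per line:
    ``insert_mean  insert_sd  read_len  coverage  base_error  [snv_rate  indel_rate]``.

All three accept ``#``-prefixed header/comment lines and blank lines.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "FormatError",
    "ValidationError",
    "ForeignRef",
    "VariantSpec",
    "Distribution",
    "MetaSpec",
    "LibrarySpec",
    "parse_ploidy_code",
    "format_ploidy_code",
    "read_var",
    "write_var",
    "read_meta",
    "write_meta",
    "read_par",
    "write_par",
    "read_bed3",
    "read_ground_truth_bed",
    "write_ground_truth_bed",
    "read_fasta",
    "write_fasta",
    "write_fastq_pair",
    "read_newick",
]

# Variant class tags. TDEL/TSRC mark the source arm of a (duplicated)
# translocation; TINS/ITINS the destination arm ((inverted) re-insertion).
SVTYPES = {"DEL", "INS", "DUP", "IDUP", "INV", "DELINS", "TDEL", "TSRC", "TINS", "ITINS"}

_SEQ_RE = re.compile(r"^[ACGTUMRWSYKVHDBNacgtumrwsykvhdbn]+$")


class FormatError(ValueError):
    """Malformed file content; message names the offending line."""


class ValidationError(ValueError):
    """Well-formed content violating a field invariant."""


def _err(kind, path, lineno, msg):
    return kind(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# ploidy codes


def parse_ploidy_code(code: str) -> tuple[int, frozenset[int]]:
    """Parse ``P/h1,h2,...`` (or ``hom``/``het``) into (P, altered haplotypes)."""
    code = code.strip()
    if code == "hom":
        return 2, frozenset({1, 2})
    if code == "het":
        return 2, frozenset({1})
    try:
        total_s, haps_s = code.split("/")
        total = int(total_s)
        haps = frozenset(int(h) for h in haps_s.split(",")) if haps_s else frozenset()
    except ValueError as exc:
        raise ValidationError(f"bad ploidy code {code!r}") from exc
    if total < 1:
        raise ValidationError(f"ploidy must be >= 1 in {code!r}")
    if not haps:
        raise ValidationError(f"no altered haplotype in {code!r}")
    if not haps <= set(range(1, total + 1)):
        raise ValidationError(f"altered haplotypes outside 1..{total} in {code!r}")
    return total, haps


def format_ploidy_code(ploidy: int, haplotypes: frozenset[int]) -> str:
    return f"{ploidy}/{','.join(str(h) for h in sorted(haplotypes))}"


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class ForeignRef:
    """Named reference into a foreign-sequence FASTA (e.g. a viral genome)."""

    fasta: str
    record: str
    strand: str = "+"  # '-' means reverse complement on insertion

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"foreign strand must be + or -, got {self.strand!r}")

    def __str__(self) -> str:
        return f"{self.fasta}:{self.record}:{self.strand}"

    @classmethod
    def parse(cls, token: str) -> "ForeignRef":
        parts = token.split(":")
        if len(parts) == 2:
            parts.append("+")
        if len(parts) != 3:
            raise ValidationError(f"bad foreign reference {token!r}")
        return cls(*parts)


@dataclass(frozen=True)
class VariantSpec:
    """One spike-in event, in 1-based inclusive template coordinates."""

    vid: str
    chrom: str
    pos: int
    fraction: float = 1.0
    ploidy: int = 2
    haplotypes: frozenset = frozenset({1, 2})
    del_len: int = 0
    ins_seq: str = ""
    foreign: ForeignRef | None = None
    svtype: str = ""
    pid: str = ""

    def __post_init__(self):
        if not self.vid:
            raise ValidationError("empty variant id")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError(
                f"{self.vid}: fraction {self.fraction} outside [0,1]"
            )
        if self.pos < 1:
            raise ValidationError(f"{self.vid}: pos {self.pos} < 1")
        if self.del_len < 0:
            raise ValidationError(f"{self.vid}: del_len {self.del_len} < 0")
        if self.haplotypes and not set(self.haplotypes) <= set(range(1, self.ploidy + 1)):
            raise ValidationError(f"{self.vid}: haplotypes outside 1..{self.ploidy}")
        if self.svtype and self.svtype not in SVTYPES:
            raise ValidationError(f"{self.vid}: unknown svtype {self.svtype!r}")
        if self.ins_seq and not _SEQ_RE.match(self.ins_seq):
            raise ValidationError(f"{self.vid}: non-IUPAC insertion sequence")
        if not self.svtype:  # canonicalize so write/read round trips are identities
            object.__setattr__(self, "svtype", self._inferred_svtype())
        eff = self.svtype
        # TSRC never edits; TINS/ITINS receive their sequence from the source
        # arm during compound resolution, so they may start out empty.
        if eff not in ("TSRC", "TINS", "ITINS") and self.del_len + len(self.ins_seq) == 0 and self.foreign is None:
            # DUP/INV reuse del_len as the segment length, so this catches
            # genuinely empty events only.
            raise ValidationError(f"{self.vid}: event alters nothing")

    def _inferred_svtype(self) -> str:
        if self.foreign is not None:
            return "INS"
        if self.del_len > 0 and not self.ins_seq:
            return "DEL"
        if self.ins_seq and self.del_len == 0:
            return "INS"
        return "DELINS"

    @property
    def effective_svtype(self) -> str:
        return self.svtype or self._inferred_svtype()

    @property
    def end(self) -> int:
        """Last template base touched (1-based inclusive); pos-anchored for insertions."""
        return self.pos + max(self.del_len, 1) - 1

    @property
    def ploidy_code(self) -> str:
        return format_ploidy_code(self.ploidy, self.haplotypes)

    def with_fraction(self, fraction: float) -> "VariantSpec":
        return replace(self, fraction=fraction)


@dataclass(frozen=True)
class Distribution:
    """A ``family:params`` token from a META line."""

    family: str
    params: tuple = ()

    _FAMILIES = {"fixed", "uniform", "normal", "bernoulli", "hom", "het"}

    def __post_init__(self):
        if self.family not in self._FAMILIES:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        n_expected = {"fixed": 1, "uniform": 2, "normal": 2, "bernoulli": 1,
                      "hom": 0, "het": 0}[self.family]
        if len(self.params) != n_expected:
            raise ValidationError(
                f"{self.family} takes {n_expected} parameter(s), got {len(self.params)}"
            )
        if self.family == "bernoulli" and not 0 <= self.params[0] <= 1:
            raise ValidationError("bernoulli parameter outside [0,1]")
        if self.family == "uniform" and self.params[0] > self.params[1]:
            raise ValidationError("uniform lower bound exceeds upper bound")

    @classmethod
    def parse(cls, token: str) -> "Distribution":
        name, _, rest = token.partition(":")
        params = tuple(float(p) for p in rest.split(",")) if rest else ()
        return cls(name, params)

    def __str__(self) -> str:
        if not self.params:
            return self.family
        return self.family + ":" + ",".join(_num(p) for p in self.params)

    # sampling -------------------------------------------------------------
    def sample_size(self, rng) -> int:
        if self.family == "fixed":
            return max(1, int(round(self.params[0])))
        if self.family == "uniform":
            lo, hi = (int(self.params[0]), int(self.params[1]))
            return int(rng.integers(lo, hi + 1))
        if self.family == "normal":
            return max(1, int(round(rng.normal(self.params[0], self.params[1]))))
        raise ValidationError(f"{self.family} is not a size distribution")

    def sample_fraction(self, rng) -> float:
        if self.family == "fixed":
            return float(self.params[0])
        if self.family == "uniform":
            return float(rng.uniform(self.params[0], self.params[1]))
        if self.family == "normal":
            return float(min(1.0, max(0.0, rng.normal(*self.params))))
        raise ValidationError(f"{self.family} is not a fraction distribution")

    def sample_ploidy(self, rng) -> tuple[int, frozenset[int]]:
        if self.family == "hom":
            return 2, frozenset({1, 2})
        if self.family == "het":
            return 2, frozenset({1})
        if self.family == "bernoulli":
            hom = rng.random() < self.params[0]
            return (2, frozenset({1, 2})) if hom else (2, frozenset({1}))
        raise ValidationError(f"{self.family} is not a ploidy distribution")


def _num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


@dataclass(frozen=True)
class MetaSpec:
    """A class of events to generate: count plus size/fraction/ploidy laws."""

    svtype: str
    count: int
    size_dist: Distribution
    fraction_dist: Distribution
    ploidy_dist: Distribution
    foreign_source: str = ""

    def __post_init__(self):
        if self.svtype not in {"DEL", "INS", "DUP", "IDUP", "INV"}:
            raise ValidationError(f"META cannot expand svtype {self.svtype!r}")
        if self.count < 0:
            raise ValidationError(f"negative count {self.count}")


@dataclass(frozen=True)
class LibrarySpec:
    """One paired-end sequencing library."""

    insert_mean: float
    insert_sd: float
    read_len: int
    coverage: float
    base_error: float = 0.0
    snv_rate: float = 0.0
    indel_rate: float = 0.0

    def __post_init__(self):
        if self.insert_mean <= 0:
            raise ValidationError("insert_mean must be > 0")
        if self.insert_sd < 0:
            raise ValidationError("insert_sd must be >= 0")
        if self.read_len < 1:
            raise ValidationError("read_len must be >= 1")
        if self.coverage < 0:
            raise ValidationError("coverage must be >= 0")
        for name in ("base_error", "snv_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} outside [0,1]")
        if self.insert_mean < 2 * self.read_len:
            warnings.warn(
                f"insert_mean {self.insert_mean} < 2*read_len {2 * self.read_len}: "
                "mates will overlap and short inserts are resampled upward",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# tab-delimited readers/writers

def _data_lines(path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, re.split(r"\t|\s+", line.strip())


VAR_COLUMNS = ("vid", "pid", "fraction", "ploidy", "chrom", "pos", "del_len", "ins_seq", "svtype")


def _variant_from_fields(fields: Sequence[str]) -> VariantSpec:
    if len(fields) not in (8, 9):
        raise FormatError(f"expected 8 or 9 columns, got {len(fields)}")
    vid, pid, frac_s, ploidy_s, chrom, pos_s, dlen_s, ins = fields[:8]
    svtype = fields[8] if len(fields) == 9 and fields[8] != "." else ""
    try:
        fraction = float(frac_s)
        pos = int(pos_s)
        del_len = int(dlen_s)
    except ValueError as exc:
        raise FormatError(f"non-numeric field: {exc}") from exc
    ploidy, haps = parse_ploidy_code(ploidy_s)
    ins_seq, foreign = "", None
    if ins != ".":
        if ":" in ins:
            foreign = ForeignRef.parse(ins)
        else:
            ins_seq = ins
    return VariantSpec(
        vid=vid,
        pid="" if pid == "." else pid,
        fraction=fraction,
        ploidy=ploidy,
        haplotypes=haps,
        chrom=chrom,
        pos=pos,
        del_len=del_len,
        ins_seq=ins_seq,
        foreign=foreign,
        svtype=svtype,
    )


def _variant_to_fields(v: VariantSpec) -> list[str]:
    if v.foreign is not None:
        ins = str(v.foreign)
    else:
        ins = v.ins_seq or "."
    return [
        v.vid,
        v.pid or ".",
        _num(v.fraction),
        v.ploidy_code,
        v.chrom,
        str(v.pos),
        str(v.del_len),
        ins,
        v.effective_svtype,
    ]


def read_var(path) -> list[VariantSpec]:
    """Read a VAR file; preserves record order, rejects duplicate vids."""
    variants: list[VariantSpec] = []
    seen: set[str] = set()
    for lineno, fields in _data_lines(path):
        try:
            v = _variant_from_fields(fields)
        except (FormatError, ValidationError) as exc:
            raise type(exc)(f"{path}:{lineno}: {exc}") from exc
        if v.vid in seen:
            raise _err(ValidationError, path, lineno, f"duplicate variant id {v.vid!r}")
        seen.add(v.vid)
        variants.append(v)
    return variants


def write_var(variants: Iterable[VariantSpec], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(VAR_COLUMNS) + "\n")
        for v in variants:
            fh.write("\t".join(_variant_to_fields(v)) + "\n")


def read_meta(path) -> list[MetaSpec]:
    metas: list[MetaSpec] = []
    for lineno, fields in _data_lines(path):
        if len(fields) not in (5, 6):
            raise _err(FormatError, path, lineno, f"expected 5 or 6 columns, got {len(fields)}")
        try:
            metas.append(
                MetaSpec(
                    svtype=fields[0],
                    count=int(fields[1]),
                    size_dist=Distribution.parse(fields[2]),
                    fraction_dist=Distribution.parse(fields[3]),
                    ploidy_dist=Distribution.parse(fields[4]),
                    foreign_source="" if len(fields) < 6 or fields[5] == "." else fields[5],
                )
            )
        except (ValidationError, ValueError) as exc:
            raise _err(ValidationError, path, lineno, str(exc))
    return metas


def write_meta(metas: Iterable[MetaSpec], path) -> None:
    with open(path, "w") as fh:
        fh.write("#svtype\tcount\tsize_dist\tfraction_dist\tploidy_dist\tforeign_source\n")
        for m in metas:
            fh.write(
                "\t".join(
                    [m.svtype, str(m.count), str(m.size_dist), str(m.fraction_dist),
                     str(m.ploidy_dist), m.foreign_source or "."]
                )
                + "\n"
            )


def read_par(path) -> list[LibrarySpec]:
    libs: list[LibrarySpec] = []
    for lineno, fields in _data_lines(path):
        if len(fields) not in (5, 7):
            raise _err(FormatError, path, lineno, f"expected 5 or 7 columns, got {len(fields)}")
        try:
            vals = [float(x) for x in fields]
            libs.append(
                LibrarySpec(
                    insert_mean=vals[0],
                    insert_sd=vals[1],
                    read_len=int(vals[2]),
                    coverage=vals[3],
                    base_error=vals[4],
                    snv_rate=vals[5] if len(vals) == 7 else 0.0,
                    indel_rate=vals[6] if len(vals) == 7 else 0.0,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise _err(ValidationError, path, lineno, str(exc))
    return libs


def write_par(libs: Iterable[LibrarySpec], path) -> None:
    with open(path, "w") as fh:
        fh.write("#insert_mean\tinsert_sd\tread_len\tcoverage\tbase_error\tsnv_rate\tindel_rate\n")
        for l in libs:
            fh.write(
                "\t".join(
                    _num(x)
                    for x in (l.insert_mean, l.insert_sd, l.read_len, l.coverage,
                              l.base_error, l.snv_rate, l.indel_rate)
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED

def read_bed3(path) -> list[tuple[str, int, int]]:
    """Plain BED3 intervals (0-based half-open), e.g. mask/target regions."""
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise _err(FormatError, path, lineno, "BED3 needs 3 columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if start < 0 or end <= start:
            raise _err(ValidationError, path, lineno, f"bad interval [{start},{end})")
        out.append((chrom, start, end))
    return out


def variant_bed_interval(v: VariantSpec) -> tuple[int, int]:
    """Ground-truth BED interval (0-based half-open) of a variant.

    Deleting/segment events cover [pos-1, pos-1+del_len); pure insertions get
    the base before the insertion point, [pos-2, pos-1) clamped at 0, so the
    interval is never empty.
    """
    if v.del_len > 0:
        return v.pos - 1, v.pos - 1 + v.del_len
    start = max(0, v.pos - 2)
    return start, start + 1


def write_ground_truth_bed(variants: Iterable[VariantSpec], path) -> None:
    rows = []
    for v in variants:
        start, end = variant_bed_interval(v)
        rows.append((v.chrom, start, end, _variant_to_fields(v)))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\t" + "\t".join(VAR_COLUMNS) + "\n")
        for chrom, start, end, fields in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t" + "\t".join(fields) + "\n")


def read_ground_truth_bed(path) -> list[VariantSpec]:
    """Parse the VariantSpec payload columns back out of a ground-truth BED."""
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 11:
            raise _err(FormatError, path, lineno, "ground-truth BED needs 3+8 columns")
        try:
            out.append(_variant_from_fields(fields[3:]))
        except (FormatError, ValidationError) as exc:
            raise type(exc)(f"{path}:{lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path) -> dict[str, str]:
    """Small-file FASTA reader returning {name: sequence} in file order."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq_pair(pairs, path1, path2) -> None:
    """Write read pairs to two FASTQ files with matching name stems.

    ``pairs`` yields objects with ``name``, ``seq1``, ``qual1``, ``seq2``,
    ``qual2`` attributes (see :class:`svforge.readsim.ReadPair`).
    """
    n1 = n2 = 0
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual2}\n")
            n1 += 1
            n2 += 1
    if n1 != n2:  # structurally impossible here; guards future refactors
        raise RuntimeError(f"read-1/read-2 count mismatch: {n1} vs {n2}")


def read_newick(path_or_string):
    """Parse a clonal-evolution NEWICK file or string into a ClonalTree."""
    from .clonal_tree import ClonalTree  # local import avoids a cycle

    if isinstance(path_or_string, (str, os.PathLike)) and os.path.exists(str(path_or_string)):
        with open(path_or_string) as fh:
            data = fh.read()
    else:
        data = str(path_or_string)
    return ClonalTree.from_newick(data)
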