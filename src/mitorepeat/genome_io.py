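"""Readers, writers and coordinate arithmetic for the pipeline's external formats.

All internal coordinates are 1-based inclusive, matching the conventions of
samtools and the printed coordinates this pipeline is usually compared
against.  Conversion to 0-based half-open happens only at the BED boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CircularSequence",
    "Region",
    "DepthProfile",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_depth_tsv",
    "write_depth_tsv",
    "depth_from_sam",
    "write_bed",
    "read_bed",
]

_IUPAC = frozenset("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    """A file did not conform to the expected external format."""


@dataclass(frozen=True)
class CircularSequence:
    """A named DNA sequence, optionally circular.

    Residues are stored uppercase.  On a circular sequence every coordinate
    operation is taken modulo the length, so ``fetch`` may wrap past the end.
    """

    id: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        res = self.residues.upper()
        bad = set(res) - _IUPAC
        if bad:
            pos = next(i for i, c in enumerate(res) if c in bad)
            raise FormatError(
                f"record {self.id!r}: non-IUPAC character {res[pos]!r} at position {pos + 1}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def position(self, pos: int) -> int:
        """Normalize a 1-based position onto the sequence (modulo length if circular)."""
        if self.circular:
            return (pos - 1) % len(self) + 1
        if not 1 <= pos <= len(self):
            raise IndexError(f"position {pos} outside linear sequence of length {len(self)}")
        return pos

    def fetch(self, start: int, end: int) -> str:
        """Residues from ``start`` to ``end``, 1-based inclusive; wraps when circular.

        ``end`` may exceed the length (or be < start after normalization) on a
        circular sequence; the span then crosses the origin.
        """
        n = len(self)
        if not self.circular:
            if start < 1 or end > n or start > end:
                raise IndexError(f"[{start}, {end}] outside linear sequence of length {n}")
            return self.residues[start - 1 : end]
        span = end - start + 1
        if span < 1:
            span += n
        if span < 1 or span > n:
            raise IndexError(f"span of [{start}, {end}] invalid on circle of length {n}")
        s0 = (start - 1) % n
        doubled = self.residues + self.residues
        return doubled[s0 : s0 + span]

    def rotate(self, offset: int) -> "CircularSequence":
        """Return the circle re-origined so old position ``offset+1`` becomes position 1."""
        if not self.circular:
            raise ValueError("cannot rotate a linear sequence")
        n = len(self)
        k = offset % n
        return CircularSequence(self.id, self.residues[k:] + self.residues[:k], True)


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive interval on a named sequence.

    ``wraps`` is true when the interval crosses the origin of a circular
    sequence (end < start).
    """

    seq_id: str
    start: int
    end: int
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"region positions must be >= 1, got {self.start}..{self.end}")
        if not self.wraps and self.end < self.start:
            raise ValueError(f"non-wrapping region with end < start: {self.start}..{self.end}")

    def span(self, length: int | None = None) -> int:
        if self.wraps:
            if length is None:
                raise ValueError("span of a wrapping region needs the sequence length")
            return self.end - self.start + 1 + length
        return self.end - self.start + 1

    def slice0(self) -> tuple[int, int]:
        """0-based half-open (start, end); only defined for non-wrapping regions."""
        if self.wraps:
            raise ValueError("wrapping region has no linear slice; rotate the sequence first")
        return self.start - 1, self.end


@dataclass
class DepthProfile:
    """Per-position read depth over one reference for one sample."""

    sample_id: str
    ref_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1 or len(self.depth) < 1:
            raise ValueError("depth must be a non-empty 1-D array")
        if np.any(self.depth < 0):
            raise ValueError("negative depth values")

    def __len__(self) -> int:
        return len(self.depth)

    def window_values(self, region: Region) -> np.ndarray:
        a, b = region.slice0()
        if b > len(self):
            raise IndexError(
                f"window {region.start}..{region.end} outside profile of length {len(self)}"
            )
        return self.depth[a:b]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, circular: bool = False) -> list[CircularSequence]:
    """Read all records of a FASTA file.

    The circular flag is not representable in FASTA; it is supplied by the
    caller (a config/CLI option) and applied to every record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        try:
            out.append(CircularSequence(rec.id, str(rec.seq), circular))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return out


def write_fasta(seqs: Iterable[CircularSequence], path: str | Path, width: int = 60) -> None:
    if width < 1:
        raise ValueError("line width must be >= 1")
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# per-base depth TSV (samtools-depth dialect: ref, 1-based pos, depth)


def read_depth_tsv(
    path: str | Path,
    ref_length: int | None = None,
    sample_id: str | None = None,
) -> DepthProfile:
    """Read a 3-column depth dump; positions absent from the file are depth 0."""
    path = Path(path)
    ref = None
    rows: list[tuple[int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{ln}: expected 3 tab-separated columns")
            name, pos_s, depth_s = parts
            if ref is None:
                ref = name
            elif name != ref:
                raise FormatError(f"{path}:{ln}: multiple reference names ({ref!r}, {name!r})")
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer position or depth") from exc
            if pos < 1 or depth < 0:
                raise FormatError(f"{path}:{ln}: position must be >= 1 and depth >= 0")
            rows.append((pos, depth))
    if ref is None:
        if ref_length is None:
            raise FormatError(f"{path}: empty depth file and no reference length given")
        ref = "unknown"
    length = ref_length if ref_length is not None else (max(p for p, _ in rows) if rows else 0)
    arr = np.zeros(length, dtype=np.int64)
    seen = set()
    for pos, depth in rows:
        if pos in seen:
            raise FormatError(f"{path}: duplicate position {pos}")
        seen.add(pos)
        if pos > length:
            raise FormatError(f"{path}: position {pos} beyond reference length {length}")
        arr[pos - 1] = depth
    return DepthProfile(sample_id or path.stem, ref, arr)


def write_depth_tsv(profile: DepthProfile, path: str | Path, omit_zero: bool = False) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(profile.depth, 1):
            if omit_zero and d == 0:
                continue
            fh.write(f"{profile.ref_id}\t{i}\t{int(d)}\n")


# ---------------------------------------------------------------------------
# SAM pile-up

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
# ops that consume the query sequence / the reference, per the SAM spec
_CONSUMES_QUERY = frozenset("MIS=X")
_CONSUMES_REF = frozenset("MDN=X")
_ADDS_DEPTH = frozenset("M=X")


def depth_from_sam(
    path: str | Path,
    ref_length: int | None = None,
    *,
    include_supplementary: bool = False,
    min_mapq: int = 0,
    sample_id: str | None = None,
) -> DepthProfile:
    """Per-position count of aligned read bases from SAM text.

    M/=/X add depth, D/N advance the reference without adding depth, and
    I/S/H/P do not advance the reference.  Unmapped and secondary records are
    always ignored; supplementary records (flag 2048) are ignored by default
    because a split mapping could represent the same molecule twice, but the
    internal simulation mapper emits disjoint split segments and opts in.
    """
    path = Path(path)
    ref = None
    header_len: dict[str, int] = {}
    arr: np.ndarray | None = None

    def _ensure(length: int) -> np.ndarray:
        nonlocal arr
        if arr is None:
            arr = np.zeros(length, dtype=np.int64)
        return arr

    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    fields = dict(
                        f.split(":", 1) for f in line.split("\t")[1:] if ":" in f
                    )
                    if "SN" in fields and "LN" in fields:
                        header_len[fields["SN"]] = int(fields["LN"])
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise FormatError(f"{path}:{ln}: SAM record with fewer than 11 fields")
            flag = int(cols[1])
            if flag & 0x4 or flag & 0x100:
                continue
            if flag & 0x800 and not include_supplementary:
                continue
            if int(cols[4]) < min_mapq:
                continue
            rname, pos, cigar, seq = cols[2], int(cols[3]), cols[5], cols[9]
            if rname == "*" or cigar == "*":
                continue
            if ref is None:
                ref = rname
            elif rname != ref:
                raise FormatError(f"{path}:{ln}: multiple references ({ref!r}, {rname!r})")
            ops = _CIGAR_RE.findall(cigar)
            if "".join(n + c for n, c in ops) != cigar:
                raise FormatError(f"{path}:{ln}: malformed CIGAR {cigar!r}")
            if seq != "*":
                qlen = sum(int(n) for n, c in ops if c in _CONSUMES_QUERY and c != "H")
                if qlen != len(seq):
                    raise FormatError(
                        f"{path}:{ln}: CIGAR consumes {qlen} query bases but SEQ has {len(seq)}"
                    )
            length = ref_length or header_len.get(rname)
            if length is None:
                raise FormatError(f"{path}: no @SQ LN for {rname!r} and no ref_length given")
            a = _ensure(length)
            cursor = pos - 1
            for n_s, op in ops:
                n = int(n_s)
                if op in _ADDS_DEPTH:
                    if cursor < 0 or cursor + n > length:
                        raise FormatError(
                            f"{path}:{ln}: alignment runs outside reference (POS {pos}, CIGAR {cigar})"
                        )
                    a[cursor : cursor + n] += 1
                    cursor += n
                elif op in _CONSUMES_REF:
                    cursor += n
    if arr is None:
        length = ref_length or (next(iter(header_len.values())) if header_len else None)
        if length is None:
            raise FormatError(f"{path}: no alignments and no reference length available")
        arr = np.zeros(length, dtype=np.int64)
        ref = ref or (next(iter(header_len)) if header_len else "unknown")
    return DepthProfile(sample_id or path.stem, ref or "unknown", arr)


# ---------------------------------------------------------------------------
# BED3 (+ optional name column)


def write_bed(
    regions: Sequence[Region],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    """Write regions as BED, converting 1-based inclusive to 0-based half-open."""
    if names is not None and len(names) != len(regions):
        raise ValueError("names must match regions one-to-one")
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            if r.wraps:
                raise ValueError(
                    f"region {r.start}..{r.end} wraps the origin; rotate the sequence "
                    "to linear coordinates before exporting BED"
                )
            a, b = r.slice0()
            line = f"{r.seq_id}\t{a}\t{b}"
            if names is not None:
                line += f"\t{names[i]}"
            fh.write(line + "\n")


def read_bed(path: str | Path) -> list[tuple[Region, str | None]]:
    out: list[tuple[Region, str | None]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED line with fewer than 3 columns")
            region = Region(parts[0], int(parts[1]) + 1, int(parts[2]))
            out.append((region, parts[3] if len(parts) > 3 else None))
    return out
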