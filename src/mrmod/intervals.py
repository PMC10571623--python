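"""Genomic interval primitives and plain-text BED I/O.

All coordinates are 0-based half-open ``[start, end)``, the BED convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed; message carries the line number."""


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval on a named sequence.

    Parameters
    ----------
    seq_id : str
        Name of the sequence (chromosome / contig / record id).
    start, end : int
        0-based half-open bounds; ``end > start`` is required.
    name : str, optional
        BED name column.
    score : float, optional
        BED score column.
    strand : str, optional
        ``'+'``, ``'-'`` or ``'.'``.
    """

    seq_id: str
    start: int
    end: int
    name: str = field(default="", compare=False)
    score: float = field(default=0.0, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError(f"negative start in {self.seq_id}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        """Length of the intersection with ``other`` (0 if different sequences)."""
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def sort_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    return sorted(ivs, key=lambda iv: (iv.seq_id, iv.start, iv.end))


def merge_intervals(ivs: Iterable[Interval], *, bookended: bool = True) -> list[Interval]:
    """Merge overlapping (and, by default, bookended) intervals per sequence.

    Name/score/strand of merged intervals are dropped.
    """
    out: list[Interval] = []
    cur: Interval | None = None
    for iv in sort_intervals(ivs):
        if cur is not None and iv.seq_id == cur.seq_id and (
            iv.start < cur.end or (bookended and iv.start == cur.end)
        ):
            if iv.end > cur.end:
                cur = Interval(cur.seq_id, cur.start, iv.end)
            continue
        if cur is not None:
            out.append(cur)
        cur = Interval(iv.seq_id, iv.start, iv.end)
    if cur is not None:
        out.append(cur)
    return out


def complement_intervals(
    ivs: Sequence[Interval], seq_lengths: dict[str, int]
) -> list[Interval]:
    """Per-sequence set complement of ``ivs`` within ``[0, seq_length)``.

    Sequences present in ``seq_lengths`` but carrying no interval contribute a
    single full-length complement region.
    """
    merged = merge_intervals(ivs)
    for iv in merged:
        if iv.seq_id not in seq_lengths:
            raise KeyError(f"no length for sequence {iv.seq_id!r}")
        if iv.end > seq_lengths[iv.seq_id]:
            raise ValueError(
                f"interval {iv.seq_id}:{iv.start}-{iv.end} exceeds sequence "
                f"length {seq_lengths[iv.seq_id]}"
            )
    out: list[Interval] = []
    by_seq: dict[str, list[Interval]] = {}
    for iv in merged:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    for seq_id in sorted(seq_lengths):
        length = seq_lengths[seq_id]
        pos = 0
        for iv in by_seq.get(seq_id, []):
            if iv.start > pos:
                out.append(Interval(seq_id, pos, iv.start))
            pos = iv.end
        if pos < length:
            out.append(Interval(seq_id, pos, length))
    return out


def total_length(ivs: Iterable[Interval]) -> int:
    return sum(len(iv) for iv in ivs)


def read_bed(path: str | Path) -> list[Interval]:
    """Read a BED3/BED6 file; raises :class:`BedParseError` with the line number."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = parts[3] if len(parts) > 3 else ""
            try:
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: bad score") from exc
            strand = parts[5] if len(parts) > 5 else "."
            try:
                out.append(Interval(parts[0], start, end, name, score, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(ivs: Iterable[Interval], path: str | Path, *, columns: int = 6) -> None:
    with open(path, "w") as fh:
        for iv in ivs:
            fields = [iv.seq_id, str(iv.start), str(iv.end)]
            if columns >= 6:
                fields += [iv.name or ".", format_score(iv.score), iv.strand]
            elif columns >= 4:
                fields.append(iv.name or ".")
            fh.write("\t".join(fields) + "\n")


def format_score(score: float) -> str:
    if float(score).is_integer():
        return str(int(score))
    return f"{score:g}"


def read_fai_lengths(path: str | Path) -> dict[str, int]:
    """Sequence lengths from a ``samtools faidx``-style .fai (name, length, ...)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}: line {lineno}: expected >=2 columns")
            lengths[parts[0]] = int(parts[1])
    return lengths
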