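"""Two-strand PWM scanning and per-position binding-site coverage."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .pwm import PWM, encode


@dataclass(frozen=True)
class BindingSite:
    """A motif hit in forward-strand coordinates, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str
    pwm_id: str
    score: float


@dataclass
class CoverageTrack:
    """Per-position count of binding sites covering each base."""

    seq_id: str
    counts: np.ndarray  # int per position
    n_mask: np.ndarray  # bool per position, True at non-ACGT bases


def _window_scores(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    """Scores of every length-L window; -inf where the window contains an N."""
    L = len(pwm)
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    # 5th lookup column sends N-containing windows to -inf
    lo5 = np.hstack([pwm.log_odds, np.full((L, 1), -np.inf)])
    scores = np.zeros(n)
    for j in range(L):
        scores += lo5[j, codes[j : j + n]]
    return scores


def find_sites(
    sequence: str,
    pwm: PWM,
    threshold: float,
    seq_id: str = "",
) -> list[BindingSite]:
    """All windows on either strand scoring ``>= threshold``.

    Minus-strand windows are scored on the reverse complement and reported in
    forward coordinates.  Windows containing non-ACGT characters are skipped.
    Output is sorted by (start, strand, pwm_id).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    codes = encode(sequence)
    L = len(pwm)
    sites: list[BindingSite] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = _window_scores(codes, mat)
        for i in np.nonzero(scores >= threshold - 1e-12)[0]:
            sites.append(
                BindingSite(seq_id, int(i), int(i) + L, strand, pwm.id,
                            float(scores[i]))
            )
    sites.sort(key=lambda s: (s.start, s.strand, s.pwm_id))
    return sites


def build_coverage(
    sites: Iterable[BindingSite],
    seq_length: int,
    n_mask: np.ndarray | None = None,
    seq_id: str = "",
    count_mode: str = "coverage",
) -> CoverageTrack:
    """Accumulate sites into a per-position count track.

    ``count_mode='coverage'`` counts every site overlapping a position
    (footprint occupancy); ``'starts'`` counts only site start positions.
    """
    if count_mode not in ("coverage", "starts"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    if n_mask is None:
        n_mask = np.zeros(seq_length, dtype=bool)
    diff = np.zeros(seq_length + 1, dtype=np.int64)
    for s in sites:
        if s.start < 0 or s.end > seq_length:
            raise ValueError(
                f"site {s.pwm_id} {s.seq_id}:{s.start}-{s.end} outside "
                f"[0, {seq_length})"
            )
        if count_mode == "coverage":
            diff[s.start] += 1
            diff[s.end] -= 1
        else:
            diff[s.start] += 1
            diff[s.start + 1] -= 1
    counts = np.cumsum(diff[:-1])
    if counts[n_mask].any():
        raise ValueError(f"{seq_id}: binding site spans a non-ACGT position")
    return CoverageTrack(seq_id=seq_id, counts=counts, n_mask=np.asarray(n_mask, bool))


def n_mask_of(sequence: str) -> np.ndarray:
    return encode(sequence) == 4


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (record id, sequence) pairs from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq)


def write_sites_bed(sites: Iterable[BindingSite], path: str | Path) -> None:
    """BED6: name = pwm id, score = log-odds x100 rounded."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.seq_id}\t{s.start}\t{s.end}\t{s.pwm_id}\t"
                f"{round(100 * s.score)}\t{s.strand}\n"
            )


def write_bedgraph(track: CoverageTrack, path: str | Path, values=None) -> None:
    """Run-length-encoded bedGraph of the counts (or a supplied value array)."""
    vals = track.counts if values is None else values
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[start]:
                v = vals[start]
                if v == int(v):
                    fh.write(f"{track.seq_id}\t{start}\t{i}\t{int(v)}\n")
                else:
                    fh.write(f"{track.seq_id}\t{start}\t{i}\t{v:.4f}\n")
                start = i
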