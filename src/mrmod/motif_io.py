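"""Reading and writing motif libraries (JASPAR raw-count and MEME minimal).

Parsing is delegated to :mod:`Bio.motifs`; writing emits the same dialect that
was read so a consolidated library round-trips.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .pwm import BASES, DEFAULT_PSEUDOCOUNT, PWM


def sniff_format(path: str | Path) -> str:
    """Return 'minimal' for MEME minimal files, else 'jaspar'."""
    with open(path) as fh:
        head = fh.read(2048)
    return "minimal" if "MEME version" in head else "jaspar"


def read_motifs(
    path: str | Path,
    fmt: str | None = None,
    background=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[PWM]:
    """Load a motif library into :class:`~mrmod.pwm.PWM` objects.

    MEME minimal matrices store frequencies; they are rescaled by ``nsites``
    (default 20) to recover pseudo-counts.
    """
    fmt = fmt or sniff_format(path)
    with open(path) as fh:
        records = bio_motifs.parse(fh, fmt)
    out: list[PWM] = []
    for i, m in enumerate(records):
        name = m.name or getattr(m, "matrix_id", None) or f"motif_{i + 1}"
        counts = np.array([[m.counts[b][j] for b in BASES] for j in range(m.length)],
                          dtype=float)
        if fmt == "minimal":
            nsites = getattr(m, "num_occurrences", 0) or 20
            totals = counts.sum(axis=1, keepdims=True)
            counts = counts / np.where(totals > 0, totals, 1.0) * nsites
        out.append(PWM(str(name), counts, background=background,
                       pseudocount=pseudocount))
    return out


def write_motifs(pwms: Sequence[PWM], path: str | Path, fmt: str = "jaspar") -> None:
    if fmt == "jaspar":
        _write_jaspar(pwms, path)
    elif fmt == "minimal":
        _write_meme_minimal(pwms, path)
    else:
        raise ValueError(f"unknown motif format {fmt!r}")


def _write_jaspar(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.id}\n")
            for bi, base in enumerate(BASES):
                vals = " ".join(f"{v:6.2f}" for v in p.counts[:, bi])
                fh.write(f"{base} [ {vals} ]\n")


def _write_meme_minimal(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if pwms:
            bg = pwms[0].background
            fh.write("Background letter frequencies\n")
            fh.write(" ".join(f"{b} {q:.4f}" for b, q in zip(BASES, bg)) + "\n\n")
        for p in pwms:
            nsites = int(round(p.counts.sum(axis=1).max()))
            fh.write(f"MOTIF {p.id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(p)} "
                f"nsites= {max(nsites, 1)} E= 0\n"
            )
            freqs = p.counts / p.counts.sum(axis=1, keepdims=True)
            for row in freqs:
                fh.write(" ".join(f"{v:8.6f}" for v in row) + "\n")
            fh.write("\n")
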