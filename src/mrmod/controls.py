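"""Length-matched control regions carved from predicted non-functional space.

The scheme: complement the full prediction set, drop mostly-N regions,
discard short (< 400 bp) gaps squeezed between two predictions, trim 40 bp
off each end of what remains, and pack fragments exactly matching the length
multiset of the sub-250 bp prediction subset, with 5 bp padding between
fragments carved from the same region.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import (
    Interval,
    complement_intervals,
    merge_intervals,
    sort_intervals,
    total_length,
)

LENGTH_CAP_DEFAULT = 250
MIN_GAP_DEFAULT = 400
TRIM_DEFAULT = 40
PAD_DEFAULT = 5
CAP_STEP = 10


class CapacityError(ValueError):
    """The candidate space cannot host the requested length multiset."""


@dataclass
class ControlPlan:
    """Result of control construction; controls match ``crmsub`` lengths exactly."""

    crmsub: list[Interval]
    candidates: list[Interval]
    controls: list[Interval]
    length_cap: int
    seed: int

    def validate(self, crmfull: Sequence[Interval] | None = None) -> None:
        if Counter(len(c) for c in self.controls) != Counter(
            len(m) for m in self.crmsub
        ):
            raise AssertionError("control lengths do not match crmsub lengths")
        for c in self.controls:
            if not any(
                c.seq_id == k.seq_id and c.start >= k.start and c.end <= k.end
                for k in self.candidates
            ):
                raise AssertionError(f"control {c} outside candidate space")
        if crmfull is not None:
            for c in self.controls:
                if any(c.overlap(m) for m in crmfull):
                    raise AssertionError(f"control {c} overlaps a predicted CRM")

    def to_json(self) -> str:
        return json.dumps(
            {
                "length_cap": self.length_cap,
                "seed": self.seed,
                "n_crmsub": len(self.crmsub),
                "n_controls": len(self.controls),
                "crmsub_bp": total_length(self.crmsub),
                "controls_bp": total_length(self.controls),
                "candidate_bp": total_length(self.candidates),
            },
            indent=2,
        )


def _n_overlap(iv: Interval, n_runs: Sequence[Interval]) -> int:
    return sum(iv.overlap(r) for r in n_runs)


def complement_regions(
    crms: Sequence[Interval],
    seq_lengths: dict[str, int],
    n_runs: Sequence[Interval] = (),
    max_n_fraction: float = 0.5,
) -> list[Interval]:
    """Regions not covered by any prediction, minus mostly-N regions.

    Complement regions whose N fraction exceeds ``max_n_fraction`` are dropped.
    """
    comp = complement_intervals(crms, seq_lengths)
    return [
        iv for iv in comp if _n_overlap(iv, n_runs) <= max_n_fraction * len(iv)
    ]


def filter_short_gaps(
    complement: Sequence[Interval],
    seq_lengths: dict[str, int],
    min_len: int = MIN_GAP_DEFAULT,
) -> list[Interval]:
    """Drop complement regions shorter than ``min_len`` that sit between two
    predictions (they may belong to a neighbouring module).

    Terminal regions touching a sequence end are kept regardless of length.
    """
    out = []
    for iv in complement:
        terminal = iv.start == 0 or iv.end == seq_lengths[iv.seq_id]
        if not terminal and len(iv) < min_len:
            continue
        out.append(iv)
    return out


def select_crmsub(
    crms: Sequence[Interval], length_cap: int = LENGTH_CAP_DEFAULT
) -> list[Interval]:
    """Predictions strictly shorter than ``length_cap``."""
    return [iv for iv in crms if len(iv) < length_cap]


def carve_controls(
    candidates: Sequence[Interval],
    lengths: Sequence[int],
    trim: int = TRIM_DEFAULT,
    pad: int = PAD_DEFAULT,
    seed: int = 0,
    crmsub: Sequence[Interval] | None = None,
    length_cap: int = LENGTH_CAP_DEFAULT,
) -> ControlPlan:
    """Pack fragments of the requested lengths into trimmed candidate regions.

    Each candidate is shrunk by ``trim`` at both ends; fragments are placed
    longest-first into the largest free segment, with uniform random start
    jitter under ``seed`` and ``pad`` bases reserved on each side of every
    placement.  If the jittered packing fails, a deterministic left-packed
    retry is attempted before raising :class:`CapacityError`.
    """
    lengths = sorted((int(x) for x in lengths), reverse=True)
    for jitter in (True, False):
        rng = np.random.default_rng(seed)
        placed = _try_pack(candidates, lengths, trim, pad, rng, jitter)
        if placed is not None:
            return ControlPlan(
                crmsub=list(crmsub) if crmsub is not None else [],
                candidates=list(candidates),
                controls=sort_intervals(placed),
                length_cap=length_cap,
                seed=seed,
            )
    capacity = sum(max(0, len(c) - 2 * trim) for c in candidates)
    raise CapacityError(
        f"cannot place {len(lengths)} fragments totalling {sum(lengths)} bp "
        f"into {capacity} bp of trimmed candidate space"
    )


def _try_pack(candidates, lengths, trim, pad, rng, jitter) -> list[Interval] | None:
    free: list[list] = []
    for c in candidates:
        if len(c) > 2 * trim:
            free.append([c.seq_id, c.start + trim, c.end - trim])
    placed: list[Interval] = []
    for i, length in enumerate(lengths):
        free.sort(key=lambda s: (s[2] - s[1], s[0], s[1]), reverse=True)
        if not free or free[0][2] - free[0][1] < length:
            return None
        seq_id, lo, hi = free.pop(0)
        slack = hi - lo - length
        off = int(rng.integers(0, slack + 1)) if jitter and slack > 0 else 0
        start = lo + off
        placed.append(Interval(seq_id, start, start + length, name=f"CTRL_{i + 1}"))
        if start - pad - lo > 0:
            free.append([seq_id, lo, start - pad])
        if hi - (start + length + pad) > 0:
            free.append([seq_id, start + length + pad, hi])
    return placed


def build_control_plan(
    crms: Sequence[Interval],
    seq_lengths: dict[str, int],
    n_runs: Sequence[Interval] = (),
    length_cap: int = LENGTH_CAP_DEFAULT,
    trim: int = TRIM_DEFAULT,
    pad: int = PAD_DEFAULT,
    min_gap: int = MIN_GAP_DEFAULT,
    seed: int = 0,
    cap_step: int = CAP_STEP,
) -> ControlPlan:
    """End-to-end control construction with automatic cap lowering.

    Starting from ``length_cap``, the cap is reduced in ``cap_step`` steps
    (gradually eliminating the longest predictions) until the candidate space
    can host the resulting length multiset.  Raises :class:`CapacityError` if
    no cap leaves a feasible, nonempty subset.
    """
    merged = merge_intervals(crms)
    comp = complement_regions(merged, seq_lengths, n_runs)
    candidates = filter_short_gaps(comp, seq_lengths, min_len=min_gap)
    cap = length_cap
    while cap > 0:
        crmsub = select_crmsub(crms, cap)
        if not crmsub:
            break
        try:
            plan = carve_controls(
                candidates, [len(m) for m in crmsub], trim=trim, pad=pad,
                seed=seed, crmsub=crmsub, length_cap=cap,
            )
        except CapacityError:
            cap -= cap_step
            continue
        plan.validate(crmfull=merged)
        return plan
    raise CapacityError(
        f"no feasible length cap at or below {length_cap} "
        f"(candidate space {total_length(candidates)} bp)"
    )
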