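"""CRM calling: coverage-track z-scores, thresholded seeding, and gap-limited
extension along positive-z stepping stones.

A position seeds a module when its z-score exceeds ``z_seed`` (2.33 by
default, the one-tailed p < 0.01 cutoff).  Each seed is extended in both
directions: the boundary jumps to the nearest position with z > 0 whenever
that position is fewer than ``max_gap`` bases away, repeatedly; final
endpoints are the outermost z > 0 positions reached, so the flanking
positions have z <= 0.  Seeds swallowed by an earlier extension are not
re-emitted, and overlapping or bookended calls are merged.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .intervals import Interval
from .pwm import PWM, default_threshold, pvalue_threshold
from .scan import (
    BindingSite,
    CoverageTrack,
    build_coverage,
    find_sites,
    n_mask_of,
    read_fasta,
)

logger = logging.getLogger("mrmod")

Z_SEED_DEFAULT = 2.33
MAX_GAP_DEFAULT = 30


class DegenerateTrackError(ValueError):
    """Constant coverage track: the z-score is undefined (sigma == 0)."""


@dataclass(frozen=True)
class TrackStats:
    seq_id: str
    mu: float
    sigma: float
    n_positions: int


@dataclass(frozen=True)
class CRMCall:
    seq_id: str
    start: int
    end: int
    max_z: float
    n_seeds: int


def compute_z(track: CoverageTrack) -> tuple[np.ndarray, TrackStats]:
    """Per-position z = (count - mu) / sigma over non-N positions.

    mu and sigma are the plain mean and population SD of the counts at non-N
    positions; z is NaN at N positions.  Raises
    :class:`DegenerateTrackError` when sigma is zero.
    """
    valid = ~track.n_mask
    n = int(valid.sum())
    if n < 2:
        raise DegenerateTrackError(f"{track.seq_id}: fewer than 2 scorable positions")
    counts = track.counts[valid].astype(float)
    mu = float(counts.mean())
    sigma = float(counts.std())  # population SD (divide by n)
    if sigma == 0:
        raise DegenerateTrackError(
            f"{track.seq_id}: constant coverage track (sigma = 0)"
        )
    z = np.full(len(track.counts), np.nan)
    z[valid] = (track.counts[valid] - mu) / sigma
    return z, TrackStats(track.seq_id, mu, sigma, n)


def call_crms(
    z: np.ndarray,
    z_seed: float = Z_SEED_DEFAULT,
    max_gap: int = MAX_GAP_DEFAULT,
    seq_id: str = "",
) -> list[CRMCall]:
    """Seed-and-extend module calling on a z-score track.

    NaN positions (masked bases) are barriers: extension never crosses them,
    so no call spans a masked run.  Output is sorted and non-overlapping.
    """
    if z_seed <= 0:
        raise ValueError("z_seed must be positive")
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    n = len(z)
    with np.errstate(invalid="ignore"):
        pos = z > 0  # NaN compares False
    masked = np.isnan(z)
    seeds = np.nonzero(np.where(masked, False, z > z_seed))[0]
    if len(seeds) == 0:
        return []

    # nearest z>0 position strictly to the right/left of each index
    nxt = np.full(n + 1, n, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        nxt[i] = i if pos[i] else nxt[i + 1]
    prv = np.full(n + 1, -1, dtype=np.int64)
    for i in range(n):
        prv[i + 1] = i if pos[i] else prv[i]
    # nearest masked position to the right/left (barrier bookkeeping)
    nxt_mask = np.full(n + 1, n, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        nxt_mask[i] = i if masked[i] else nxt_mask[i + 1]
    prv_mask = np.full(n + 1, -1, dtype=np.int64)
    for i in range(n):
        prv_mask[i + 1] = i if masked[i] else prv_mask[i]

    raw: list[tuple[int, int]] = []
    consumed_until = -1
    for s in seeds:
        if s <= consumed_until:
            continue
        right = int(s)
        while True:
            p = nxt[right + 1] if right + 1 <= n else n
            if p >= n or p - right >= max_gap or nxt_mask[right + 1] < p:
                break
            right = int(p)
        left = int(s)
        while True:
            p = prv[left]
            if p < 0 or left - p >= max_gap or prv_mask[left] > p:
                break
            left = int(p)
        raw.append((left, right + 1))
        consumed_until = max(consumed_until, right)

    # merge overlapping / bookended calls
    merged: list[list[int]] = []
    for a, b in sorted(raw):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])

    out = []
    for a, b in merged:
        seg = z[a:b]
        with np.errstate(invalid="ignore"):
            n_seeds = int(np.nansum(seg > z_seed))
        out.append(CRMCall(seq_id, a, b, float(np.nanmax(seg)), n_seeds))
    return out


@dataclass
class MrmodConfig:
    """Tunable knobs of the end-to-end caller."""

    z_seed: float = Z_SEED_DEFAULT
    max_gap: int = MAX_GAP_DEFAULT
    count_mode: str = "coverage"  # or "starts"
    threshold_mode: str = "patser-default"  # or "pvalue:<x>"
    bin_width: float = 0.01

    def threshold_for(self, pwm: PWM) -> float:
        if self.threshold_mode == "patser-default":
            return default_threshold(pwm, self.bin_width)
        if self.threshold_mode.startswith("pvalue:"):
            return pvalue_threshold(
                pwm, float(self.threshold_mode.split(":", 1)[1]), self.bin_width
            )
        raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")


def run_mrmod(
    fasta: str | Iterable[tuple[str, str]],
    pwms: Sequence[PWM],
    config: MrmodConfig | None = None,
) -> tuple[list[CRMCall], list[BindingSite]]:
    """Scan -> coverage -> z -> call, per FASTA record.

    ``fasta`` may be a path or an iterable of (id, sequence) pairs.  Records
    whose coverage track is degenerate (no or constant signal) contribute no
    calls and log a warning.
    """
    config = config or MrmodConfig()
    records = read_fasta(fasta) if isinstance(fasta, (str, bytes)) else fasta
    thresholds = {p.id: config.threshold_for(p) for p in pwms}
    all_calls: list[CRMCall] = []
    all_sites: list[BindingSite] = []
    for seq_id, seq in records:
        sites: list[BindingSite] = []
        for p in pwms:
            sites.extend(find_sites(seq, p, thresholds[p.id], seq_id=seq_id))
        sites.sort(key=lambda s: (s.start, s.strand, s.pwm_id))
        mask = n_mask_of(seq)
        track = build_coverage(
            sites, len(seq), n_mask=mask, seq_id=seq_id, count_mode=config.count_mode
        )
        try:
            z, stats = compute_z(track)
        except DegenerateTrackError as exc:
            logger.warning("%s; no CRMs called", exc)
            all_sites.extend(sites)
            continue
        calls = call_crms(z, config.z_seed, config.max_gap, seq_id=seq_id)
        mean_len = float(np.mean([c.end - c.start for c in calls])) if calls else 0.0
        logger.info(
            "%s: %d sites, mu=%.4f sigma=%.4f, %d CRMs, mean length %.1f",
            seq_id, len(sites), stats.mu, stats.sigma, len(calls), mean_len,
        )
        all_calls.extend(calls)
        all_sites.extend(sites)
    return all_calls, all_sites


def calls_to_intervals(calls: Iterable[CRMCall]) -> list[Interval]:
    out = []
    counters: dict[str, int] = {}
    for c in calls:
        k = counters.get(c.seq_id, 0) + 1
        counters[c.seq_id] = k
        score = min(1000, round(100 * c.max_z))
        out.append(Interval(c.seq_id, c.start, c.end,
                            name=f"CRM_{c.seq_id}_{k}", score=score, strand="."))
    return out


def write_crms_bed(calls: Iterable[CRMCall], path) -> None:
    from .intervals import write_bed

    write_bed(calls_to_intervals(calls), path)
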