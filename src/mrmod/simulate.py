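"""Synthetic fixtures: background sequence with implanted motif-site clusters
plus matching truth intervals, and a doublet-preserving negative control."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intervals import Interval
from .pwm import BASES, PWM

MIN_CLUSTER_SEPARATION = 200
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class SimConfig:
    """Parameters of one simulated record.

    Clusters are placed pairwise separated by at least 200 bp; each receives a
    uniform-random number of non-overlapping sites sampled from the motifs'
    smoothed frequency models, on random strands.
    """

    seq_length: int = 100_000
    n_clusters: int = 20
    cluster_len_range: tuple[int, int] = (150, 250)
    sites_per_cluster_range: tuple[int, int] = (6, 12)
    motif_ids: Sequence[str] = ()
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    n_run_spec: Sequence[tuple[int, int]] = ()
    seed: int = 0
    seq_id: str = "sim"

    def __post_init__(self) -> None:
        if self.cluster_len_range[0] > self.cluster_len_range[1]:
            raise ValueError("empty cluster_len_range")
        if self.sites_per_cluster_range[0] > self.sites_per_cluster_range[1]:
            raise ValueError("empty sites_per_cluster_range")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")


@dataclass
class SimRecord:
    seq_id: str
    sequence: str
    clusters: list[Interval] = field(default_factory=list)
    sites: list[Interval] = field(default_factory=list)  # strand + motif in name


def _place_spaced(rng, total: int, lengths: list[int], min_sep: int) -> list[int]:
    """Random starts for blocks of the given lengths inside [0, total), kept in
    order and separated by at least ``min_sep``."""
    k = len(lengths)
    if k == 0:
        return []
    occupied = sum(lengths) + min_sep * (k - 1)
    slack = total - occupied
    if slack < 0:
        raise ValueError(
            f"cannot place {k} blocks ({occupied} bp incl. separation) in {total} bp"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=k))
    starts = []
    prefix = 0
    for i, length in enumerate(lengths):
        starts.append(int(cuts[i]) + prefix)
        prefix += length + min_sep
    return starts


def _sample_site(rng, pwm: PWM) -> str:
    f = pwm.freqs
    idx = [int(rng.choice(4, p=f[j] / f[j].sum())) for j in range(len(pwm))]
    return "".join(BASES[i] for i in idx)


def revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq.upper()))


def generate(config: SimConfig, pwms: Sequence[PWM]) -> SimRecord:
    """Build one record: i.i.d. background, implanted clusters, optional N runs.

    Fully deterministic under ``config.seed``.
    """
    by_id = {p.id: p for p in pwms}
    motif_ids = list(config.motif_ids) or [p.id for p in pwms]
    missing = [m for m in motif_ids if m not in by_id]
    if missing:
        raise ValueError(f"motif ids not in library: {missing}")

    rng = np.random.default_rng(config.seed)
    bg = np.asarray(config.background, float)
    seq = rng.choice(4, size=config.seq_length, p=bg)

    cluster_lens = [
        int(rng.integers(config.cluster_len_range[0], config.cluster_len_range[1] + 1))
        for _ in range(config.n_clusters)
    ]
    starts = _place_spaced(rng, config.seq_length, cluster_lens,
                           MIN_CLUSTER_SEPARATION)
    clusters, sites = [], []
    for ci, (cstart, clen) in enumerate(zip(starts, cluster_lens)):
        clusters.append(
            Interval(config.seq_id, cstart, cstart + clen, name=f"cluster_{ci + 1}")
        )
        k = int(rng.integers(config.sites_per_cluster_range[0],
                             config.sites_per_cluster_range[1] + 1))
        chosen = [motif_ids[int(rng.integers(0, len(motif_ids)))] for _ in range(k)]
        site_lens = [len(by_id[m]) for m in chosen]
        if sum(site_lens) > clen:
            raise ValueError(
                f"cluster {ci + 1}: {k} sites ({sum(site_lens)} bp) exceed "
                f"cluster length {clen}"
            )
        offs = _place_spaced(rng, clen, site_lens, 0)
        for m, off, sl in zip(chosen, offs, site_lens):
            strand = "+" if rng.random() < 0.5 else "-"
            word = _sample_site(rng, by_id[m])
            if strand == "-":
                word = revcomp(word)
            pos = cstart + off
            seq[pos : pos + sl] = [BASES.index(b) for b in word]
            sites.append(
                Interval(config.seq_id, pos, pos + sl, name=m, strand=strand)
            )

    chars = np.array(list(BASES + "N"))
    for nstart, nlen in config.n_run_spec:
        seq[nstart : nstart + nlen] = 4
    sequence = "".join(chars[seq])
    return SimRecord(config.seq_id, sequence, clusters, sites)


def dinucleotide_shuffle(sequence: str, seed: int = 0) -> str:
    """Altschul-Erikson doublet-preserving shuffle.

    Mono- and dinucleotide counts of the result equal the input's exactly;
    deterministic under ``seed``.
    """
    s = sequence.upper()
    if len(s) < 3:
        return s
    rng = np.random.default_rng(seed)
    verts = sorted(set(s))
    edges: dict[str, list[str]] = {v: [] for v in verts}
    for x, y in zip(s, s[1:]):
        edges[x].append(y)
    last = s[-1]

    # choose one "last edge" per non-terminal vertex so that every vertex
    # reaches the terminal vertex through last edges (random arborescence
    # by rejection; the alphabet is tiny so this converges immediately)
    non_terminal = [v for v in verts if v != last and edges[v]]
    while True:
        last_edge = {v: edges[v][int(rng.integers(0, len(edges[v])))]
                     for v in non_terminal}
        ok = True
        for v in non_terminal:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break

    remaining: dict[str, list[str]] = {}
    for v in verts:
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        remaining[v] = pool

    out = [s[0]]
    ptr = {v: 0 for v in verts}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = remaining[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def spike_negative_controls(record: SimRecord, seed: int = 0) -> SimRecord:
    """Doublet-shuffled copy of a record (clusters destroyed, composition kept)."""
    return SimRecord(
        seq_id=record.seq_id + "_shuffled",
        sequence=dinucleotide_shuffle(record.sequence, seed=seed),
        clusters=[],
        sites=[],
    )
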