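"""Position weight matrix model: log-odds scoring, exact score distributions,
automatic cutoffs, and ALLR/OLAP-based redundancy consolidation.

Conventions
-----------
* Base order is A, C, G, T (axis 1 of every array).
* Log-odds are in natural log units (nats) throughout.
* Smoothed column frequencies are ``(counts + pseudocount * background) /
  (column_total + pseudocount)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
UNIFORM_BG = np.full(4, 0.25)
#: Patser-style smoothing mass split across bases in background proportion.
DEFAULT_PSEUDOCOUNT = 0.375
#: Redundancy thresholds used by motif consolidation.
ALLR_THRESHOLD = 6.57
OLAP_THRESHOLD = 68.1
MIN_OVERLAP = 5
#: Lattice resolution (nats) for exact score distributions.
DEFAULT_BIN_WIDTH = 0.01

_COMPLEMENT = np.array([3, 2, 1, 0])


class DegeneratePWMWarning(UserWarning):
    """A PWM with zero information content: every window passes the cutoff."""


def _as_background(background) -> np.ndarray:
    bg = UNIFORM_BG.copy() if background is None else np.asarray(background, float)
    if bg.shape != (4,):
        raise ValueError("background must have 4 entries (A,C,G,T)")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError(f"background probabilities sum to {bg.sum()}, not 1")
    if np.any(bg <= 0):
        raise ValueError("background probabilities must be positive")
    return bg


@dataclass(frozen=True)
class PWM:
    """A positional base-count model of a binding motif.

    Parameters
    ----------
    id : str
        Motif identifier.
    counts : (L, 4) array
        Non-negative base counts (or scaled frequencies) per position.
    background : (4,) array, optional
        Base probabilities of the null model; uniform by default.
    pseudocount : float
        Total smoothing mass added per column, split in background proportion.
    total_score : float or None
        Importance rank used to order greedy consolidation.  When ``None`` it
        defaults to ``IC * L`` (information content in bits times length).
    """

    id: str
    counts: np.ndarray
    background: np.ndarray = field(default=None)  # type: ignore[assignment]
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    total_score: float | None = None

    def __post_init__(self) -> None:
        counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError(f"{self.id}: counts must be (L, 4), got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError(f"{self.id}: negative counts")
        if np.any(counts.sum(axis=1) <= 0):
            raise ValueError(f"{self.id}: column with zero total count")
        if self.pseudocount < 0:
            raise ValueError(f"{self.id}: negative pseudocount")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "background", _as_background(self.background))

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def freqs(self) -> np.ndarray:
        """Smoothed per-position base frequencies, shape (L, 4)."""
        totals = self.counts.sum(axis=1, keepdims=True)
        return (self.counts + self.pseudocount * self.background) / (
            totals + self.pseudocount
        )

    @property
    def log_odds(self) -> np.ndarray:
        """ln(f/q) per position and base; ``-inf`` where a frequency is zero."""
        with np.errstate(divide="ignore"):
            return np.log(self.freqs) - np.log(self.background)

    @property
    def ic_nats(self) -> float:
        """Information content sum f*ln(f/q) in nats (zero-frequency terms vanish)."""
        f = self.freqs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * (np.log(f) - np.log(self.background)), 0.0)
        return float(terms.sum())

    @property
    def ic_bits(self) -> float:
        return self.ic_nats / np.log(2)

    def rank_score(self) -> float:
        """``total_score`` if supplied, else the IC*L fallback."""
        if self.total_score is not None:
            return self.total_score
        return self.ic_bits * len(self)

    def reverse_complement(self) -> "PWM":
        rc = self.counts[::-1, _COMPLEMENT]
        return replace(self, counts=rc)


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact window-score distribution under the i.i.d. background model.

    Scores live on an integer lattice ``k * bin_width``; ``probs[j]`` is the
    probability of lattice index ``offset + j``.  Windows containing a base
    with zero smoothed frequency score ``-inf``; their total probability is
    carried separately in ``neg_inf_mass``.
    """

    pwm_id: str
    bin_width: float
    offset: int
    probs: np.ndarray
    neg_inf_mass: float = 0.0

    @property
    def min_score(self) -> float:
        return self.offset * self.bin_width

    @property
    def max_score(self) -> float:
        return (self.offset + len(self.probs) - 1) * self.bin_width

    def sf(self, score: float) -> float:
        """P(S >= score); -inf outcomes never reach any finite score."""
        k = int(np.ceil(score / self.bin_width - 1e-9))
        j = k - self.offset
        if j <= 0:
            return float(self.probs.sum())
        if j >= len(self.probs):
            return 0.0
        return float(self.probs[j:].sum())


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to integers A,C,G,T -> 0..3, anything else -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(BASES):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def score_window(pwm: PWM, window: str) -> float | None:
    """Log-odds score of one window, or ``None`` for windows with non-ACGT bases.

    Raises ``ValueError`` if the window length differs from the motif length.
    """
    if len(window) != len(pwm):
        raise ValueError(
            f"window length {len(window)} != motif length {len(pwm)} for {pwm.id}"
        )
    codes = encode(window)
    if np.any(codes == 4):
        return None
    return float(pwm.log_odds[np.arange(len(pwm)), codes].sum())


def score_distribution(
    pwm: PWM, bin_width: float = DEFAULT_BIN_WIDTH
) -> ScoreDistribution:
    """Exact background score distribution by per-column lattice convolution.

    Each column's log-odds are rounded to the nearest lattice point
    (discretization error <= bin_width/2 per column); column distributions are
    convolved.  Probability of drawing a zero-frequency base in any column is
    accumulated into ``neg_inf_mass``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = pwm.log_odds
    bg = pwm.background
    probs = np.array([1.0])
    offset = 0
    finite_total = 1.0
    for j in range(len(pwm)):
        finite = np.isfinite(lo[j])
        col_p = bg[finite]
        ks = np.round(lo[j][finite] / bin_width).astype(int)
        finite_total *= col_p.sum()
        kmin, kmax = int(ks.min()), int(ks.max())
        col = np.zeros(kmax - kmin + 1)
        np.add.at(col, ks - kmin, col_p)
        probs = np.convolve(probs, col)
        offset += kmin
    return ScoreDistribution(
        pwm_id=pwm.id,
        bin_width=bin_width,
        offset=offset,
        probs=probs,
        neg_inf_mass=1.0 - finite_total,
    )


def default_threshold(pwm: PWM, bin_width: float = DEFAULT_BIN_WIDTH) -> float:
    """Automatic score cutoff: the smallest lattice score ``s`` with
    ``ln P(S >= s) <= -IC`` (IC in nats) under the background model.

    A zero-IC matrix yields the minimum score (everything passes) and emits
    :class:`DegeneratePWMWarning`.
    """
    dist = score_distribution(pwm, bin_width)
    ic = pwm.ic_nats
    if ic <= 0:
        warnings.warn(
            f"{pwm.id}: zero information content; threshold admits all windows",
            DegeneratePWMWarning,
            stacklevel=2,
        )
        return dist.min_score
    target = np.exp(-ic)
    # survival at each lattice index, from the top down
    surv = np.cumsum(dist.probs[::-1])[::-1]
    idx = np.nonzero(surv <= target + 1e-15)[0]
    if len(idx) == 0:
        # even the max score is too probable; cut at just above the max
        return dist.max_score + dist.bin_width
    return float((dist.offset + idx[0]) * dist.bin_width)


def pvalue_threshold(
    pwm: PWM, pvalue: float, bin_width: float = DEFAULT_BIN_WIDTH
) -> float:
    """Smallest lattice score whose background tail probability is <= pvalue."""
    if not 0 < pvalue <= 1:
        raise ValueError("pvalue must be in (0, 1]")
    dist = score_distribution(pwm, bin_width)
    surv = np.cumsum(dist.probs[::-1])[::-1]
    idx = np.nonzero(surv <= pvalue + 1e-15)[0]
    if len(idx) == 0:
        return dist.max_score + dist.bin_width
    return float((dist.offset + idx[0]) * dist.bin_width)


# ---------------------------------------------------------------------------
# ALLR similarity and consolidation
# ---------------------------------------------------------------------------

def _smooth(counts: np.ndarray, background: np.ndarray, pseudocount: float) -> np.ndarray:
    total = counts.sum()
    return (counts + pseudocount * background) / (total + pseudocount)


def allr(
    column1_counts,
    column2_counts,
    background=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Average log-likelihood ratio between two aligned motif columns.

    ``[sum_b n2_b ln(p1_b/q_b) + sum_b n1_b ln(p2_b/q_b)] / (n1 + n2)`` with
    smoothed frequencies ``p``.  Symmetric in its arguments; may be negative.
    """
    n1 = np.asarray(column1_counts, float)
    n2 = np.asarray(column2_counts, float)
    if n1.shape != (4,) or n2.shape != (4,):
        raise ValueError("columns must have 4 entries (A,C,G,T)")
    if n1.sum() <= 0 or n2.sum() <= 0:
        raise ValueError("zero-total column in ALLR")
    q = _as_background(background)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp1 = np.log(_smooth(n1, q, pseudocount) / q)
        lp2 = np.log(_smooth(n2, q, pseudocount) / q)
        # 0 * -inf (zero count against zero frequency) contributes nothing
        t1 = np.where(n2 > 0, n2 * lp1, 0.0)
        t2 = np.where(n1 > 0, n1 * lp2, 0.0)
    return float((t1.sum() + t2.sum()) / (n1.sum() + n2.sum()))


@dataclass(frozen=True)
class Alignment:
    """Best ungapped alignment of two motifs."""

    allr_total: float
    olap_percent: float
    offset: int
    orientation: str  # "forward" | "reverse-complement"


@dataclass(frozen=True)
class ConsolidationDecision:
    kept_id: str
    removed_id: str
    allr_score: float
    olap_percent: float
    offset: int
    orientation: str


def align_pwms(p1: PWM, p2: PWM, min_overlap: int = MIN_OVERLAP) -> Alignment:
    """Best ungapped alignment of ``p2`` (either orientation) against ``p1``.

    All offsets with at least ``min_overlap`` aligned columns are scored by
    summed column ALLR; the overlap percentage is relative to the shorter
    motif.  Column smoothing uses the larger of the two motifs' pseudocounts.
    """
    l1, l2 = len(p1), len(p2)
    if min(l1, l2) < min_overlap:
        raise ValueError(
            f"motifs {p1.id}/{p2.id} shorter than min_overlap={min_overlap}"
        )
    q = p1.background
    best: Alignment | None = None
    for orientation, cand in (("forward", p2), ("reverse-complement", p2.reverse_complement())):
        for off in range(-(l2 - min_overlap), l1 - min_overlap + 1):
            lo = max(0, off)
            hi = min(l1, off + l2)
            n_aligned = hi - lo
            if n_aligned < min_overlap:
                continue
            total = 0.0
            for i in range(lo, hi):
                total += allr(
                    p1.counts[i], cand.counts[i - off], q,
                    pseudocount=max(p1.pseudocount, p2.pseudocount),
                )
            olap = 100.0 * n_aligned / min(l1, l2)
            # report the shift of p1 into p2's frame: 0 for a head-to-head
            # alignment, +k when p1 starts k columns into p2
            a = Alignment(total, olap, -off, orientation)
            if best is None or a.allr_total > best.allr_total + 1e-12:
                best = a
    assert best is not None  # unreachable: offset 0 always has >= min_overlap
    return best


def consolidate(
    pwms: Sequence[PWM],
    allr_threshold: float = ALLR_THRESHOLD,
    olap_threshold: float = OLAP_THRESHOLD,
    min_overlap: int = MIN_OVERLAP,
) -> tuple[list[PWM], list[ConsolidationDecision]]:
    """Greedy redundancy removal.

    Motifs are ranked by ``rank_score`` (ties broken by id); the best remaining
    motif is kept and every remaining motif redundant to it (ALLR total above
    ``allr_threshold`` AND overlap percentage above ``olap_threshold``) is
    removed, recording one decision per removal.
    """
    if not pwms:
        raise ValueError("empty motif list")
    queue = sorted(pwms, key=lambda p: (-p.rank_score(), p.id))
    kept: list[PWM] = []
    decisions: list[ConsolidationDecision] = []
    while queue:
        top = queue.pop(0)
        kept.append(top)
        survivors = []
        for other in queue:
            aln = align_pwms(top, other, min_overlap=min_overlap)
            if aln.allr_total > allr_threshold and aln.olap_percent > olap_threshold:
                decisions.append(
                    ConsolidationDecision(
                        top.id, other.id, aln.allr_total, aln.olap_percent,
                        aln.offset, aln.orientation,
                    )
                )
            else:
                survivors.append(other)
        queue = survivors
    return kept, decisions


def uniform_pwm(id: str, length: int, background=None) -> PWM:
    """A zero-information matrix (columns equal to the background)."""
    bg = _as_background(background)
    return PWM(id, np.tile(bg, (length, 1)), background=bg, pseudocount=0.0)


def write_decisions_tsv(decisions: Iterable[ConsolidationDecision], path) -> None:
    with open(path, "w") as fh:
        fh.write("kept_id\tremoved_id\tallr\tolap\toffset\torientation\n")
        for d in decisions:
            fh.write(
                f"{d.kept_id}\t{d.removed_id}\t{d.allr_score:.4f}\t"
                f"{d.olap_percent:.1f}\t{d.offset}\t{d.orientation}\n"
            )
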