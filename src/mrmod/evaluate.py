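"""Statistical comparison of predicted regions against reference region sets.

Covers reference preparation (merge + size filter), overlap hit calls at the
1 bp and 50 %-of-shorter cutoffs, the 2x2 detection table with odds ratio /
Woolf CI / Pearson chi-square, a positional-shuffle sensitivity null,
genomic-feature annotation, hypergeometric gene-set enrichment, and the
region-by-factor count matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from scipy.io import mmread, mmwrite
from statsmodels.stats.multitest import multipletests

from .intervals import Interval, merge_intervals, sort_intervals
from .scan import BindingSite

MAX_REF_LEN_DEFAULT = 2500
PROMOTER_WINDOW = 3000
DOWNSTREAM_WINDOW = 3000

FEATURE_PRECEDENCE = (
    "Promoter",
    "5' UTR",
    "3' UTR",
    "Exon",
    "Intron",
    "Downstream",
    "Distal Intergenic",
)


@dataclass(frozen=True)
class OverlapPolicy:
    """Hit rule: 'one_bp' needs >= 1 bp overlap; 'half_shorter' needs at least
    half the shorter fragment's length."""

    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("one_bp", "half_shorter"):
            raise ValueError(f"unknown overlap policy {self.mode!r}")

    def satisfied(self, ref: Interval, query: Interval) -> bool:
        ov = ref.overlap(query)
        if self.mode == "one_bp":
            return ov >= 1
        return ov >= 0.5 * min(len(ref), len(query))


ONE_BP = OverlapPolicy("one_bp")
HALF_SHORTER = OverlapPolicy("half_shorter")


@dataclass(frozen=True)
class EvalResult:
    """2x2 detection table and its derived statistics.

    a/b: references hit/missed by the prediction set; c/d: hit/missed by the
    control set.  The odds ratio uses the Haldane-Anscombe +0.5 correction
    only when a cell is zero; the chi-square test is Pearson's without
    continuity correction.
    """

    a: int
    b: int
    c: int
    d: int
    sensitivity_pred: float
    sensitivity_ctrl: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_chi2: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


@dataclass(frozen=True)
class NullSummary:
    n_reps: int
    mean_sensitivity: float
    sd_sensitivity: float
    p_empirical: float
    observed_sensitivity: float


def prepare_reference(
    peaks: Sequence[Interval], max_len: int = MAX_REF_LEN_DEFAULT
) -> list[Interval]:
    """Merge overlapping/bookended peaks and drop merged intervals longer than
    ``max_len``."""
    return [iv for iv in merge_intervals(peaks) if len(iv) <= max_len]


def is_hit(ref: Interval, queries: Iterable[Interval], policy: OverlapPolicy) -> bool:
    return any(policy.satisfied(ref, q) for q in queries)


def _hits(refs: Sequence[Interval], queries: Sequence[Interval],
          policy: OverlapPolicy) -> int:
    by_seq: dict[str, list[Interval]] = {}
    for q in queries:
        by_seq.setdefault(q.seq_id, []).append(q)
    return sum(1 for r in refs if is_hit(r, by_seq.get(r.seq_id, ()), policy))


def evaluate(
    refs: Sequence[Interval],
    predictions: Sequence[Interval],
    controls: Sequence[Interval],
    policy: OverlapPolicy = ONE_BP,
) -> EvalResult:
    """Fill the 2x2 table of reference detection by predictions vs controls."""
    if not refs:
        raise ValueError("no reference regions")
    a = _hits(refs, predictions, policy)
    c = _hits(refs, controls, policy)
    b, d = len(refs) - a, len(refs) - c
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    aa, bb, cc, dd = cells
    odds = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = math.exp(math.log(odds) - 1.96 * se)
    ci_high = math.exp(math.log(odds) + 1.96 * se)
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        p = 1.0
    else:
        p = float(st.chi2_contingency(table, correction=False)[1])
    return EvalResult(
        a=a, b=b, c=c, d=d,
        sensitivity_pred=a / len(refs),
        sensitivity_ctrl=c / len(refs),
        odds_ratio=float(odds),
        ci_low=ci_low, ci_high=ci_high,
        p_chi2=p,
    )


def shuffle_null(
    refs: Sequence[Interval],
    predictions: Sequence[Interval],
    seq_lengths: Mapping[str, int],
    policy: OverlapPolicy = ONE_BP,
    n_reps: int = 10000,
    seed: int = 0,
) -> NullSummary:
    """Sensitivity null from repositioning predictions uniformly within their
    own sequences, preserving lengths and allowing overlaps between shuffled
    intervals.

    The empirical p uses the add-one rule:
    ``(1 + #{rep sensitivity >= observed}) / (n_reps + 1)``.
    """
    if not refs:
        raise ValueError("no reference regions")
    for p_iv in predictions:
        if len(p_iv) > seq_lengths[p_iv.seq_id]:
            raise ValueError(
                f"prediction {p_iv.seq_id}:{p_iv.start}-{p_iv.end} longer than "
                f"its sequence ({seq_lengths[p_iv.seq_id]} bp)"
            )
    observed = _hits(refs, list(predictions), policy) / len(refs)
    rng = np.random.default_rng(seed)
    lens = np.array([len(p) for p in predictions])
    max_start = np.array([seq_lengths[p.seq_id] - len(p) for p in predictions])
    # (n_reps, n_pred) random starts
    starts = rng.integers(0, max_start + 1, size=(n_reps, len(predictions)))
    ends = starts + lens
    hit_counts = np.zeros(n_reps)
    for r in refs:
        same = np.array([p.seq_id == r.seq_id for p in predictions])
        if not same.any():
            continue
        s, e = starts[:, same], ends[:, same]
        ov = np.minimum(e, r.end) - np.maximum(s, r.start)
        if policy.mode == "one_bp":
            need = 1
            hit = (ov >= need).any(axis=1)
        else:
            need = 0.5 * np.minimum(len(r), lens[same])
            hit = (ov >= need).any(axis=1)
        hit_counts += hit
    sens = hit_counts / len(refs)
    p_emp = (1 + int((sens >= observed - 1e-12).sum())) / (n_reps + 1)
    return NullSummary(
        n_reps=n_reps,
        mean_sensitivity=float(sens.mean()),
        sd_sensitivity=float(sens.std()),
        p_empirical=float(p_emp),
        observed_sensitivity=float(observed),
    )


# ---------------------------------------------------------------------------
# Genomic-feature annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transcript:
    """Minimal transcript model used for feature annotation."""

    seq_id: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def transcripts_from_gff(path: str | Path) -> list[Transcript]:
    """Load transcript models from GFF3/GTF via gffutils (in-memory DB)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True, disable_infer_genes=True, disable_infer_transcripts=True,
    )
    out = []
    for t in db.all_features(featuretype=("mRNA", "transcript")):
        exons, utr5, utr3 = [], [], []
        for ch in db.children(t):
            iv = (ch.start - 1, ch.end)  # GFF is 1-based closed
            if ch.featuretype == "exon":
                exons.append(iv)
            elif ch.featuretype in ("five_prime_UTR", "5UTR"):
                utr5.append(iv)
            elif ch.featuretype in ("three_prime_UTR", "3UTR"):
                utr3.append(iv)
        out.append(
            Transcript(t.seqid, t.start - 1, t.end, t.strand,
                       tuple(sorted(exons)), tuple(sorted(utr5)),
                       tuple(sorted(utr3)))
        )
    return out


def _overlaps_span(region: Interval, seq_id: str, start: int, end: int) -> bool:
    return region.seq_id == seq_id and region.start < end and region.end > start


def annotate_features(
    regions: Sequence[Interval],
    transcripts: Sequence[Transcript],
    promoter_window: int = PROMOTER_WINDOW,
    downstream_window: int = DOWNSTREAM_WINDOW,
) -> tuple[list[str], pd.DataFrame]:
    """Assign each region one category by fixed precedence.

    Promoter (within ``promoter_window`` of any TSS) > 5' UTR > 3' UTR > Exon
    > Intron > Downstream (within ``downstream_window`` past a 3' end) >
    Distal Intergenic.  Returns the per-region categories and a percentage
    table summing to 100.
    """
    if not transcripts:
        raise ValueError("no transcript annotation supplied")
    cats = []
    for r in regions:
        flags = {k: False for k in FEATURE_PRECEDENCE}
        for t in transcripts:
            if r.seq_id != t.seq_id:
                continue
            if _overlaps_span(r, t.seq_id, t.tss - promoter_window,
                              t.tss + promoter_window + 1):
                flags["Promoter"] = True
            for a, b in t.utr5:
                if _overlaps_span(r, t.seq_id, a, b):
                    flags["5' UTR"] = True
            for a, b in t.utr3:
                if _overlaps_span(r, t.seq_id, a, b):
                    flags["3' UTR"] = True
            for a, b in t.exons:
                if _overlaps_span(r, t.seq_id, a, b):
                    flags["Exon"] = True
            if _overlaps_span(r, t.seq_id, t.start, t.end):
                flags["Intron"] = True  # inside the body; demoted by exon/UTR
            if t.strand == "+":
                dn = (t.end, t.end + downstream_window)
            else:
                dn = (max(0, t.start - downstream_window), t.start)
            if dn[1] > dn[0] and _overlaps_span(r, t.seq_id, *dn):
                flags["Downstream"] = True
        cat = next((k for k in FEATURE_PRECEDENCE[:-1] if flags[k]),
                   "Distal Intergenic")
        cats.append(cat)
    counts = pd.Series(cats).value_counts()
    table = pd.DataFrame(
        {
            "feature": list(FEATURE_PRECEDENCE),
            "count": [int(counts.get(k, 0)) for k in FEATURE_PRECEDENCE],
        }
    )
    table["percent"] = 100.0 * table["count"] / max(len(regions), 1)
    return cats, table


# ---------------------------------------------------------------------------
# Gene-set enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrich(
    query_genes: set[str],
    gene_sets: Mapping[str, set[str]],
    population: set[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query_genes`` in each gene
    set, Benjamini-Hochberg corrected across sets."""
    if not population:
        raise ValueError("empty population")
    if not set(query_genes) <= set(population):
        raise ValueError("query genes must be a subset of the population")
    rows = []
    n_pop, n_query = len(population), len(query_genes)
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & population
        k = len(members & query_genes)
        p = float(st.hypergeom.sf(k - 1, n_pop, len(members), n_query))
        rows.append((name, len(members), k, p))
    df = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["q"] < fdr
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


# ---------------------------------------------------------------------------
# Region x factor abundance matrix
# ---------------------------------------------------------------------------

def build_tf_matrix(
    crms: Sequence[Interval],
    sites: Sequence[BindingSite],
    pwm_to_tf: Mapping[str, str],
) -> tuple[sp.csr_matrix, list[str], list[str], int]:
    """Count, per region and factor, the sites whose midpoint falls inside the
    region.

    Returns (matrix, row names in input region order, sorted factor names,
    number of sites skipped for lacking a factor mapping).
    """
    tf_names = sorted(set(pwm_to_tf.values()))
    tf_index = {t: j for j, t in enumerate(tf_names)}
    row_names = [iv.name or f"{iv.seq_id}:{iv.start}-{iv.end}" for iv in crms]
    by_seq: dict[str, list[tuple[int, int, int]]] = {}
    for i, iv in enumerate(crms):
        by_seq.setdefault(iv.seq_id, []).append((iv.start, iv.end, i))
    for lst in by_seq.values():
        lst.sort()
    mat = sp.dok_matrix((len(crms), len(tf_names)), dtype=np.int64)
    skipped = 0
    for s in sites:
        tf = pwm_to_tf.get(s.pwm_id)
        if tf is None:
            skipped += 1
            continue
        mid = (s.start + s.end) // 2
        for a, b, i in by_seq.get(s.seq_id, ()):
            if a <= mid < b:
                mat[i, tf_index[tf]] += 1
                break
    if skipped:
        import logging

        logging.getLogger("mrmod").warning(
            "%d sites skipped: pwm id without factor mapping", skipped
        )
    return mat.tocsr(), row_names, tf_names, skipped


def write_tf_matrix(
    matrix: sp.spmatrix, row_names: Sequence[str], col_names: Sequence[str],
    prefix: str | Path,
) -> None:
    """Matrix Market file plus plain-text row/column name sidecars."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), matrix)
    prefix.with_suffix(".rows.txt").write_text("\n".join(row_names) + "\n")
    prefix.with_suffix(".cols.txt").write_text("\n".join(col_names) + "\n")


def read_tf_matrix(prefix: str | Path):
    prefix = Path(prefix)
    matrix = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
    rows = prefix.with_suffix(".rows.txt").read_text().splitlines()
    cols = prefix.with_suffix(".cols.txt").read_text().splitlines()
    return matrix, rows, cols
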