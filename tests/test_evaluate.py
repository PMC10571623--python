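import math

import numpy as np
import pytest
import scipy.stats as st

from mrmod.evaluate import (
    HALF_SHORTER,
    ONE_BP,
    OverlapPolicy,
    Transcript,
    annotate_features,
    build_tf_matrix,
    evaluate,
    hypergeom_enrich,
    is_hit,
    prepare_reference,
    read_tf_matrix,
    shuffle_null,
    write_tf_matrix,
)
from mrmod.intervals import Interval
from mrmod.scan import BindingSite


def contingency_fixture(n_refs, n_hit_pred, n_hit_ctrl):
    """Interval sets realizing the given detection margins.

    Reference i sits at [i*1000, i*1000+100); predictions overlap the first
    n_hit_pred references, controls (disjoint from predictions) the first
    n_hit_ctrl.
    """
    refs, preds, ctrls = [], [], []
    for i in range(n_refs):
        base = i * 1000
        refs.append(Interval("chr", base, base + 100))
        if i < n_hit_pred:
            preds.append(Interval("chr", base + 10, base + 40))
        if i < n_hit_ctrl:
            ctrls.append(Interval("chr", base + 60, base + 90))
    return refs, preds, ctrls


class TestPrepareReference:
    def test_merge_and_keep(self):
        out = prepare_reference([Interval("s", 0, 1000), Interval("s", 900, 2000)])
        assert [(iv.start, iv.end) for iv in out] == [(0, 2000)]

    def test_oversize_merged_dropped(self):
        out = prepare_reference([Interval("s", 0, 2600)])
        assert out == []

    def test_empty(self):
        assert prepare_reference([]) == []


class TestIsHit:
    def test_one_bp_vs_half(self):
        ref = Interval("s", 0, 100)
        q = [Interval("s", 99, 200)]
        assert is_hit(ref, q, ONE_BP)
        assert not is_hit(ref, q, HALF_SHORTER)  # 1 < 50

    def test_identical_both_policies(self):
        ref = Interval("s", 0, 100)
        assert is_hit(ref, [Interval("s", 0, 100)], ONE_BP)
        assert is_hit(ref, [Interval("s", 0, 100)], HALF_SHORTER)

    def test_half_shorter_satisfied(self):
        ref = Interval("s", 0, 100)
        q = [Interval("s", 40, 200)]  # overlap 60 >= 0.5*min(100,160)=50
        assert is_hit(ref, q, HALF_SHORTER)

    def test_half_implies_one_bp(self, rng):
        for _ in range(200):
            ref = Interval("s", 0, int(rng.integers(10, 200)))
            start = int(rng.integers(0, 250))
            q = [Interval("s", start, start + int(rng.integers(5, 150)))]
            if is_hit(ref, q, HALF_SHORTER):
                assert is_hit(ref, q, ONE_BP)

    def test_bad_policy(self):
        with pytest.raises(ValueError):
            OverlapPolicy("both")


class TestEvaluate:
    def test_mouse_table(self):
        """77/97 vs 26/97 detection -> cross-product OR 10.51."""
        r = evaluate(*contingency_fixture(97, 77, 26))
        assert (r.a, r.b, r.c, r.d) == (77, 20, 26, 71)
        assert round(r.odds_ratio, 2) == 10.51
        assert r.p_chi2 <= 2.5e-13
        assert r.ci_low <= r.odds_ratio <= r.ci_high

    def test_human_table(self):
        """34/60 vs 12/60 detection -> cross-product OR 5.23."""
        r = evaluate(*contingency_fixture(60, 34, 12))
        assert (r.a, r.b, r.c, r.d) == (34, 26, 12, 48)
        assert round(r.odds_ratio, 2) == 5.23
        assert r.p_chi2 <= 3.9e-05

    def test_independence(self):
        r = evaluate(*contingency_fixture(40, 20, 20))
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p_chi2 == pytest.approx(1.0)

    def test_woolf_ci(self):
        r = evaluate(*contingency_fixture(97, 77, 26))
        se = math.sqrt(1 / 77 + 1 / 20 + 1 / 26 + 1 / 71)
        assert r.ci_low == pytest.approx(r.odds_ratio * math.exp(-1.96 * se))
        assert r.ci_high == pytest.approx(r.odds_ratio * math.exp(1.96 * se))

    def test_zero_cell_haldane(self):
        r = evaluate(*contingency_fixture(10, 10, 0))
        # +0.5 on all cells: (10.5 * 10.5) / (0.5 * 0.5)
        assert r.odds_ratio == pytest.approx(441.0)

    def test_no_refs_raises(self):
        with pytest.raises(ValueError):
            evaluate([], [], [])

    def test_matches_scipy_chi2(self):
        r = evaluate(*contingency_fixture(50, 30, 15))
        expected = st.chi2_contingency(
            [[r.a, r.b], [r.c, r.d]], correction=False
        )[1]
        assert r.p_chi2 == pytest.approx(expected)


class TestShuffleNull:
    def test_closed_form_calibration(self):
        """One 100 bp interval shuffled in 1 kb vs one fixed 100 bp reference:
        hit probability is 199/901 per rep."""
        refs = [Interval("s", 450, 550)]
        preds = [Interval("s", 0, 100)]
        ns = shuffle_null(refs, preds, {"s": 1000}, ONE_BP, n_reps=10000, seed=7)
        p = 199 / 901
        se = math.sqrt(p * (1 - p) / 10000)
        assert abs(ns.mean_sensitivity - p) <= 3 * se

    def test_full_coverage_no_freedom(self):
        refs = [Interval("s", 100, 200)]
        preds = [Interval("s", 0, 1000)]
        ns = shuffle_null(refs, preds, {"s": 1000}, ONE_BP, n_reps=100, seed=0)
        assert ns.sd_sensitivity == 0.0
        assert ns.mean_sensitivity == 1.0

    def test_disjoint_sequences_zero(self):
        refs = [Interval("A", 0, 100)]
        preds = [Interval("B", 0, 50)]
        ns = shuffle_null(refs, preds, {"A": 1000, "B": 1000}, ONE_BP,
                          n_reps=50, seed=0)
        assert ns.mean_sensitivity == 0.0

    def test_p_empirical_in_range(self):
        refs = [Interval("s", 450, 550)]
        preds = [Interval("s", 440, 560)]
        ns = shuffle_null(refs, preds, {"s": 1000}, ONE_BP, n_reps=200, seed=1)
        assert 0 < ns.p_empirical <= 1

    def test_oversized_prediction_raises(self):
        with pytest.raises(ValueError):
            shuffle_null([Interval("s", 0, 10)], [Interval("s", 0, 2000)],
                         {"s": 1000}, ONE_BP, n_reps=10, seed=0)


def two_gene_annotation():
    # gene1 on +: tx [10000, 16000), exon1 [10000,10500) incl 5'UTR
    # gene2 on +: tx [20000, 26000)
    t1 = Transcript("chr", 10000, 16000, "+",
                    exons=((10000, 10500), (12000, 12400), (15500, 16000)),
                    utr5=((10000, 10200),), utr3=((15800, 16000),))
    t2 = Transcript("chr", 20000, 26000, "+",
                    exons=((20000, 20500), (25500, 26000)),
                    utr5=((20000, 20100),), utr3=((25900, 26000),))
    return [t1, t2]


class TestAnnotateFeatures:
    def test_tss_straddle_is_promoter(self):
        cats, _ = annotate_features([Interval("chr", 9950, 10050)],
                                    two_gene_annotation())
        assert cats == ["Promoter"]

    def test_intron_near_other_tss_is_promoter(self):
        # inside gene1's intron but within 3 kb of gene2's TSS
        ts = two_gene_annotation()
        region = Interval("chr", 17500, 17600)
        # distance to gene2 TSS (20000) is 2400 < 3000
        cats, _ = annotate_features([region], ts)
        assert cats == ["Promoter"]

    def test_intron(self):
        cats, _ = annotate_features([Interval("chr", 14000, 14100)],
                                    two_gene_annotation())
        assert cats == ["Intron"]

    def test_exon_beats_intron(self):
        # exon (15500,16000) of gene1, > 3 kb from either TSS, outside UTRs
        cats, _ = annotate_features([Interval("chr", 15550, 15650)],
                                    two_gene_annotation())
        assert cats == ["Exon"]

    def test_distal_intergenic(self):
        cats, _ = annotate_features([Interval("chr", 50000, 50100)],
                                    two_gene_annotation())
        assert cats == ["Distal Intergenic"]

    def test_distribution_sums_to_100(self, rng):
        regions = [
            Interval("chr", int(s), int(s) + 100)
            for s in rng.integers(0, 60000, size=40)
        ]
        _, table = annotate_features(regions, two_gene_annotation())
        assert table["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_missing_annotation(self):
        with pytest.raises(ValueError):
            annotate_features([Interval("chr", 0, 10)], [])

    def test_transcripts_from_gff3(self, tmp_path):
        from mrmod.evaluate import transcripts_from_gff

        gff = tmp_path / "anno.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr\ttest\tgene\t10001\t16000\t.\t+\t.\tID=gene1\n"
            "chr\ttest\tmRNA\t10001\t16000\t.\t+\t.\tID=tx1;Parent=gene1\n"
            "chr\ttest\texon\t10001\t10500\t.\t+\t.\tID=ex1;Parent=tx1\n"
            "chr\ttest\texon\t15501\t16000\t.\t+\t.\tID=ex2;Parent=tx1\n"
            "chr\ttest\tfive_prime_UTR\t10001\t10200\t.\t+\t.\tID=u5;Parent=tx1\n"
            "chr\ttest\tthree_prime_UTR\t15801\t16000\t.\t+\t.\tID=u3;Parent=tx1\n"
        )
        ts = transcripts_from_gff(gff)
        assert len(ts) == 1
        t = ts[0]
        assert (t.start, t.end, t.strand) == (10000, 16000, "+")
        assert t.exons == ((10000, 10500), (15500, 16000))
        assert t.utr5 == ((10000, 10200),)
        cats, _ = annotate_features([Interval("chr", 9950, 10050)], ts)
        assert cats == ["Promoter"]


class TestHypergeomEnrich:
    def test_hand_combinatorics(self):
        """N=10, K=5, n=4, k=4 -> C(5,4)*C(5,0)/C(10,4) = 5/210."""
        pop = {f"g{i}" for i in range(10)}
        query = {"g0", "g1", "g2", "g3"}
        sets = {"S": {"g0", "g1", "g2", "g3", "g4"}}
        df = hypergeom_enrich(query, sets, pop)
        assert df.loc[0, "p"] == pytest.approx(5 / 210)
        assert df.loc[0, "q"] == pytest.approx(5 / 210)  # single test: q = p

    def test_zero_overlap_p_one(self):
        pop = {f"g{i}" for i in range(10)}
        df = hypergeom_enrich({"g0"}, {"S": {"g5", "g6"}}, pop)
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_population_raises(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(set(), {"S": set()}, set())

    def test_bh_ordering(self):
        pop = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(10)}
        sets = {
            "hit": {f"g{i}" for i in range(10)},
            "miss": {f"g{i}" for i in range(50, 60)},
        }
        df = hypergeom_enrich(query, sets, pop).set_index("gene_set")
        assert df.loc["hit", "q"] < df.loc["miss", "q"]
        assert bool(df.loc["hit", "significant"])


class TestTfMatrix:
    def test_counts_by_midpoint(self):
        crms = [Interval("s", 0, 100, name="m1"), Interval("s", 200, 300, name="m2")]
        sites = [BindingSite("s", 10, 20, "+", "pwmX", 1.0)] * 3
        mat, rows, cols, skipped = build_tf_matrix(crms, sites, {"pwmX": "X"})
        assert mat.toarray().tolist() == [[3], [0]]
        assert rows == ["m1", "m2"] and cols == ["X"] and skipped == 0

    def test_unmapped_sites_skipped(self):
        crms = [Interval("s", 0, 100, name="m1")]
        sites = [BindingSite("s", 10, 20, "+", "unknown", 1.0)]
        mat, _, _, skipped = build_tf_matrix(crms, sites, {"pwmX": "X"})
        assert skipped == 1
        assert mat.sum() == 0

    def test_empty_sites_shape(self):
        crms = [Interval("s", 0, 100), Interval("s", 200, 300)]
        mat, rows, cols, _ = build_tf_matrix(crms, [], {"p": "X", "q": "Y"})
        assert mat.shape == (2, 2)
        assert mat.sum() == 0

    def test_round_trip(self, tmp_path):
        crms = [Interval("s", 0, 100, name="m1"), Interval("s", 200, 300, name="m2")]
        sites = [
            BindingSite("s", 10, 20, "+", "p1", 1.0),
            BindingSite("s", 250, 260, "-", "p2", 1.0),
        ]
        mat, rows, cols, _ = build_tf_matrix(crms, sites, {"p1": "X", "p2": "Y"})
        write_tf_matrix(mat, rows, cols, tmp_path / "tfmat")
        mat2, rows2, cols2 = read_tf_matrix(tmp_path / "tfmat")
        assert (mat2.toarray() == mat.toarray()).all()
        assert rows2 == rows and cols2 == cols
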