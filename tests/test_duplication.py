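import pytest

from pcfam import (
    ClockRate,
    GeneModel,
    KaKsResult,
    ParalogPair,
    chain_collinear_anchors,
    classify_duplication_pair,
    classify_selection,
    date_duplication,
    find_tandem_clusters,
    lineage_gain,
    percent_change,
)

from .oracles import brute_single_linkage, longest_monotone_chain

ARA = ClockRate("arabidopsis", 1.5e-8)


def _kaks(ka, ks):
    ratio = None if ks == 0 else ka / ks
    return KaKsResult(S=100, N=300, Sd=ks * 50, Nd=ka * 150,
                      pS=0.1, pN=0.1, Ka=ka, Ks=ks, ratio=ratio)


class TestDating:
    # printed Ks -> printed age, all eleven Arabidopsis pairs at
    # lambda = 1.5e-8 (one pair differs in the last digit from the
    # published table, consistent with pre-rounding of its Ks)
    @pytest.mark.parametrize(
        "ks,age",
        [
            (0.70102, 23.37), (0.31929, 10.64), (0.70152, 23.38),
            (0.77783, 25.93), (0.85669, 28.56), (1.45391, 48.46),
            (1.36091, 45.36), (0.71432, 23.81), (3.00941, 100.31),
            (0.59184, 19.73),
        ],
    )
    def test_arabidopsis_pairs(self, ks, age):
        assert date_duplication(ks, ARA) == age

    def test_zero_ks_is_zero_age(self):
        assert date_duplication(0.0, ARA) == 0.0

    def test_doubling_rate_halves_age(self):
        t1 = date_duplication(0.6, 1.5e-8, decimals=None)
        t2 = date_duplication(0.6, 3.0e-8, decimals=None)
        assert t1 == pytest.approx(2 * t2)

    def test_linear_in_ks(self):
        t1 = date_duplication(0.3, ARA, decimals=None)
        t2 = date_duplication(0.6, ARA, decimals=None)
        assert t2 == pytest.approx(2 * t1)

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            date_duplication(-0.1, ARA)


class TestSelection:
    def test_published_positive_pair(self):
        # the one maize pair with Ka/Ks above 1
        r = _kaks(0.02184, 0.01847)
        assert r.ratio == pytest.approx(1.18246, abs=5e-6)
        assert classify_selection(r) == "positive"

    def test_purifying(self):
        assert classify_selection(_kaks(0.1, 0.2)) == "purifying"

    def test_neutral_within_tolerance(self):
        assert classify_selection(_kaks(0.2, 0.2)) == "neutral"

    def test_undefined_ratio_unclassified(self):
        assert classify_selection(_kaks(0.0, 0.0)) == "unclassified"


def _gene(gid, ordinal, chrom="c1"):
    start = ordinal * 1000
    return GeneModel(gid, "sp", chrom, "+", start, start + 299,
                     exons=[(start, start + 299)], ordinal=ordinal)


class TestTandemClusters:
    def test_adjacent_pair_clusters(self):
        genes = [_gene("a", 7), _gene("b", 8)]
        assert find_tandem_clusters(genes) == [["a", "b"]]

    def test_distant_genes_do_not_cluster(self):
        genes = [_gene("a", 1), _gene("b", 100)]
        assert find_tandem_clusters(genes) == []

    def test_mixed_ordinals_match_single_linkage_oracle(self):
        ordinals = [3, 5, 30, 31, 32]
        genes = [_gene(f"g{o}", o) for o in ordinals]
        got = find_tandem_clusters(genes, max_intervening=5)
        got_ordinals = sorted(
            tuple(int(g[1:]) for g in cluster) for cluster in got
        )
        assert got_ordinals == brute_single_linkage(ordinals, 5)
        assert got_ordinals == [(3, 5), (30, 31, 32)]

    def test_random_layouts_match_oracle(self):
        import numpy as np

        rng = np.random.default_rng(23)
        for _ in range(50):
            ordinals = sorted(
                int(o) for o in rng.choice(200, size=12, replace=False)
            )
            genes = [_gene(f"g{o:03d}", o) for o in ordinals]
            got = sorted(
                tuple(int(g[1:]) for g in cluster)
                for cluster in find_tandem_clusters(genes, 5)
            )
            assert got == brute_single_linkage(ordinals, 5)

    def test_different_chromosomes_never_cluster(self):
        genes = [_gene("a", 5, "c1"), _gene("b", 6, "c2")]
        assert find_tandem_clusters(genes) == []


class TestCollinearChains:
    def test_three_collinear_anchors_form_block(self):
        anchors = [("c1", i, "c2", 10 + i) for i in (1, 2, 3)]
        blocks = chain_collinear_anchors(anchors)
        assert len(blocks) == 1
        assert blocks[0].anchors == [(1, 11), (2, 12), (3, 13)]

    def test_two_anchors_below_minimum(self):
        anchors = [("c1", 1, "c2", 11), ("c1", 2, "c2", 12)]
        assert chain_collinear_anchors(anchors, min_anchors=3) == []

    def test_outlier_excluded_matches_lis_oracle(self):
        pts = [(1, 11), (2, 12), (3, 5), (4, 14), (5, 15)]
        anchors = [("c1", a, "c2", b) for a, b in pts]
        blocks = chain_collinear_anchors(anchors)
        assert len(blocks) == 1
        assert len(blocks[0].anchors) == longest_monotone_chain(pts, 20) == 4
        assert (3, 5) not in blocks[0].anchors

    def test_inverted_block_detected(self):
        anchors = [("c1", i, "c2", 50 - i) for i in (1, 2, 3, 4)]
        blocks = chain_collinear_anchors(anchors)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_large_gap_breaks_chain(self):
        anchors = [("c1", 1, "c2", 11), ("c1", 2, "c2", 12),
                   ("c1", 50, "c2", 60)]
        assert chain_collinear_anchors(anchors, min_anchors=3) == []


class TestMechanism:
    def setup_method(self):
        self.locs = {
            "t1": ("c1", 10), "t2": ("c1", 11),
            "s1": ("c1", 20), "s2": ("c2", 40),
            "r1": ("c1", 30), "r2": ("c3", 5),
        }
        self.clusters = [["t1", "t2"]]
        anchors = [("c1", o, "c2", o + 20) for o in (19, 20, 21)]
        self.blocks = chain_collinear_anchors(anchors)

    def test_tandem_precedence(self):
        pair = ParalogPair("t1", "t2")
        assert classify_duplication_pair(
            pair, self.locs, self.clusters, self.blocks
        ) == "tandem"

    def test_segmental_anchor_pair(self):
        pair = ParalogPair("s1", "s2")
        assert classify_duplication_pair(
            pair, self.locs, self.clusters, self.blocks
        ) == "segmental"

    def test_dispersed_pair_is_retrotransposition(self):
        pair = ParalogPair("r1", "r2")
        mech = classify_duplication_pair(
            pair, self.locs, self.clusters, self.blocks,
            intron_evidence={"r1": True, "r2": False},
        )
        assert mech == "retrotransposition"
        assert pair.retro_intron_support

    def test_unplaced_gene_is_unknown(self):
        pair = ParalogPair("t1", "nowhere")
        assert classify_duplication_pair(
            pair, self.locs, self.clusters, self.blocks
        ) == "unknown"

    def test_tandem_beats_segmental_on_constructed_conflict(self):
        # both genes in one cluster AND inside a block span: tandem wins
        locs = {"a": ("c1", 20), "b": ("c1", 21)}
        clusters = [["a", "b"]]
        anchors = [("c1", o, "c1", o + 1) for o in (19, 20, 21)]
        blocks = chain_collinear_anchors(anchors)
        assert classify_duplication_pair(
            ParalogPair("a", "b"), locs, clusters, blocks
        ) == "tandem"

    def test_every_pair_gets_exactly_one_label(self):
        for a, b in [("t1", "t2"), ("s1", "s2"), ("r1", "r2"),
                     ("t1", "s1"), ("t1", "missing")]:
            mech = classify_duplication_pair(
                ParalogPair(a, b), self.locs, self.clusters, self.blocks
            )
            assert mech in {
                "tandem", "segmental", "retrotransposition", "unknown"
            }


class TestGainLoss:
    def test_poplar_gain_from_ancestral_seven(self):
        assert lineage_gain(77, 7) == (70, 0)

    def test_no_change(self):
        assert lineage_gain(7, 7) == (0, 0)

    def test_loss_direction(self):
        assert lineage_gain(38, 109) == (0, 71)

    def test_arabidopsis_percent_decrease(self):
        assert percent_change(109, 38) == 65.1

    def test_tomato_percent_decrease(self):
        assert percent_change(109, 49) == 55.0

    def test_no_decrease_is_zero(self):
        assert percent_change(100, 100) == 0.0

    def test_zero_ancestral_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0, 10)
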