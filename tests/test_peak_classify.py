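"""Summit merging, window counting, ratio classification, heat-map
matrices, FRiP and region annotation."""

import numpy as np
import pytest

from isoformgrid import io_formats as iof
from isoformgrid import peak_classify as pc
from tests.conftest import class_accuracy


def peak(chrom, start, end, summit=-1, name="."):
    return iof.PeakRecord(
        iof.GenomicInterval(chrom, start, end), summit, name=name
    )


def summit_peaks(positions, chrom="chr1", width=10):
    return [
        peak(chrom, p - width // 2, p + width // 2, width // 2, f"pk{i}")
        for i, p in enumerate(positions)
    ]


def track(positions, factor="f", chrom="chr1"):
    return iof.TagTrack(factor, {chrom: np.array(positions)})


class TestMergeSummits:
    def test_two_close_summits_merge_at_mean(self):
        out = pc.merge_summits(summit_peaks([100]), summit_peaks([150]))
        assert len(out) == 1
        assert out[0].summit_pos == 125
        assert out[0].source == "both"

    def test_distant_summits_stay_separate(self):
        out = pc.merge_summits(summit_peaks([100]), summit_peaks([400]))
        assert len(out) == 2
        assert {m.source for m in out} == {"p42_only", "p30_only"}

    def test_single_linkage_chain(self):
        out = pc.merge_summits(summit_peaks([100, 400]), summit_peaks([250]))
        assert len(out) == 1
        assert out[0].summit_pos == 250

    def test_matches_brute_force_single_linkage(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = sorted(rng.integers(0, 5000, size=rng.integers(1, 15)))
            b = sorted(rng.integers(0, 5000, size=rng.integers(1, 15)))
            got = pc.merge_summits(summit_peaks(a), summit_peaks(b), 200)
            # oracle: sort all summits, break where the gap exceeds 200
            allpos = sorted(list(a) + list(b))
            clusters, cur = [], [allpos[0]]
            for x in allpos[1:]:
                if x - cur[-1] > 200:
                    clusters.append(cur)
                    cur = []
                cur.append(x)
            clusters.append(cur)
            assert [m.summit_pos for m in got] == [
                int(round(np.mean(c))) for c in clusters
            ]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pc.merge_summits([], summit_peaks([100]))

    def test_summitless_peak_uses_midpoint(self):
        a = [peak("chr1", 100, 200)]  # midpoint 150
        out = pc.merge_summits(a, summit_peaks([150]))
        assert len(out) == 1 and out[0].summit_pos == 150


class TestWindowCounting:
    def test_unit_normalisation(self):
        t = iof.TagTrack(
            "f", {"chr1": np.concatenate([np.full(5, 1000),
                                          np.arange(5e6, 5e6 + 9_999_995)])}
        )
        assert t.total_tags == 10_000_000
        got = pc.count_window_tags(t, ("chr1", 1000), half_width=200)
        assert got == pytest.approx(5.0)

    def test_half_open_window_boundary(self):
        t = track([1200, 1199, 800, 799])
        raw_in = t.count_in("chr1", 1000 - 200, 1000 + 200)
        assert raw_in == 2  # 800 and 1199 in; 799 and 1200 out

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 100_000, size=10_000)
        t = track(pos)
        for _ in range(1000):
            s = int(rng.integers(0, 100_000))
            hw = int(rng.integers(1, 500))
            brute = int(np.sum((pos >= s - hw) & (pos < s + hw)))
            assert t.count_in("chr1", s - hw, s + hw) == brute


class TestClassify:
    def _classify_counts(self, p30, p42, **kw):
        """Classify one synthetic summit with exact window tag counts on
        10M-tag tracks (so normalised counts equal raw counts)."""
        filler = np.arange(5e6, 5e6 + 1e7)

        def mk(n):
            inside = np.full(n, 1000) if n else np.empty(0, dtype=int)
            return iof.TagTrack(
                "f", {"chr1": np.concatenate([inside, filler[: 10_000_000 - n]])}
            )

        summit = pc.MergedSummit("chr1", 1000, "both", ())
        return pc.classify([summit], mk(p30), mk(p42), **kw)[0]

    def test_symmetric_empty_is_shared(self):
        got = self._classify_counts(0, 0)
        assert got.log2_ratio == 0.0 and got.peak_class == "shared"

    def test_hand_computed_ratio(self):
        got = self._classify_counts(40, 5)
        assert got.log2_ratio == pytest.approx(np.log2(41 / 6), abs=1e-9)
        assert got.peak_class == "p30_specific"

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            self._classify_counts(1, 1, pseudocount=0.0)

    def test_fixture_recovery_accuracy(self, classified, simulation):
        assert class_accuracy(classified, simulation["truth"]) >= 0.95

    def test_mirror_symmetry_under_track_swap(self, simulation):
        """Swapping the tracks mirrors labels and negates ratios."""
        tracks = simulation["tracks"]
        summits = pc.merge_summits(
            simulation["calls"]["p42"], simulation["calls"]["p30"]
        )
        fwd = pc.classify(summits, tracks["p30"], tracks["p42"])
        rev = pc.classify(summits, tracks["p42"], tracks["p30"])
        mirror = {"p30_specific": "p42_specific",
                  "p42_specific": "p30_specific", "shared": "shared"}
        by_uid_f = {p.uid: p for p in fwd}
        for p in rev:
            q = by_uid_f[p.uid]
            assert p.log2_ratio == pytest.approx(-q.log2_ratio, abs=1e-9)
            assert p.peak_class == mirror[q.peak_class]

    def test_rank_is_strict_total_order_and_shuffle_stable(self, simulation):
        tracks = simulation["tracks"]
        summits = pc.merge_summits(
            simulation["calls"]["p42"], simulation["calls"]["p30"]
        )
        out1 = pc.classify(summits, tracks["p30"], tracks["p42"])
        rng = np.random.default_rng(2)
        shuffled = [summits[i] for i in rng.permutation(len(summits))]
        out2 = pc.classify(shuffled, tracks["p30"], tracks["p42"])
        assert [p.rank for p in out1] == list(range(1, len(summits) + 1))
        assert [p.uid for p in out1] == [p.uid for p in out2]
        ratios = [p.log2_ratio for p in out1]
        assert ratios == sorted(ratios)


class TestTagMatrix:
    def test_shape_at_defaults(self, classified, simulation):
        tm = pc.tag_matrix(simulation["tracks"]["p42"], classified)
        assert tm.matrix.shape == (len(classified), 80)
        assert tm.peak_uids == [
            p.uid for p in sorted(classified, key=lambda q: q.rank)
        ]

    def test_bin_must_divide_window(self, classified, simulation):
        with pytest.raises(ValueError):
            pc.tag_matrix(simulation["tracks"]["p42"], classified, 2000, 33)

    def test_centre_enrichment_follows_class(self, classified, simulation):
        """p42 signal concentrates at window centres of p42-specific rows
        but not of p30-specific rows."""
        tm = pc.tag_matrix(simulation["tracks"]["p42"], classified)
        by_class = {p.uid: p.peak_class for p in classified}
        rows = np.array([by_class[u] for u in tm.peak_uids])
        centre = tm.matrix[:, 38:42].mean(axis=1)
        edges = tm.matrix[:, list(range(4)) + list(range(76, 80))].mean(axis=1)
        # edge bins still catch neighbouring peaks (~2-3 kb spacing), so
        # the contrast is strong but not background-clean
        assert centre[rows == "p42_specific"].mean() > 3 * max(
            edges[rows == "p42_specific"].mean(), 1e-9
        )
        assert centre[rows == "p42_specific"].mean() > 5 * centre[
            rows == "p30_specific"
        ].mean()

    def test_uniform_track_is_flat(self, classified):
        rng = np.random.default_rng(3)
        t = track(rng.integers(0, 2_000_000, size=200_000))
        tm = pc.tag_matrix(t, classified)
        col_means = tm.matrix.mean(axis=0)
        assert col_means.std() / col_means.mean() < 0.2


class TestFRiP:
    def test_all_tags_inside(self):
        peaks = [peak("chr1", 0, 1000)]
        assert pc.frip(track([5, 500, 999]), peaks) == 1.0

    def test_no_tags_inside(self):
        peaks = [peak("chr1", 0, 1000)]
        assert pc.frip(track([1000, 2000]), peaks) == 0.0

    def test_k313kk_flagged_at_floor(self, simulation):
        fr = pc.frip(simulation["tracks"]["k313kk"], simulation["calls"]["k313kk"])
        assert fr == pytest.approx(0.1, abs=0.02)
        assert fr < 0.15  # flagged non-specific at that floor

    def test_specific_tracks_pass_the_floor(self, simulation):
        for f in ("p42", "p30"):
            fr = pc.frip(simulation["tracks"][f], simulation["calls"][f])
            assert fr > 0.5


class TestAnnotateRegions:
    def _models(self):
        return [
            iof.GeneModel(
                "gA", "gA", iof.GenomicInterval("chr1", 5000, 8000, "+"), "+",
                2000, ((5000, 6000), (7000, 8000)),
            )
        ]

    def _summit(self, pos):
        return pc.MergedSummit("chr1", pos, "both", ())

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (4800, "promoter"),    # 200 bp upstream of the TSS
            (5999, "promoter"),    # within TSS +- 1 kb, precedence
            (7500, "exonic"),
            (6500, "intronic"),
            (100_000, "intergenic"),
        ],
    )
    def test_labels_and_precedence(self, pos, expected):
        table, _ = pc.annotate_regions([self._summit(pos)], self._models())
        assert table["region"].iloc[0] == expected

    def test_percentages_sum_to_100(self, classified, simulation):
        _, pct = pc.annotate_regions(classified, simulation["models"])
        assert pct.sum() == pytest.approx(100.0)


def test_classified_frame_round_trip(classified):
    df = pc.classified_to_frame(classified)
    back = pc.classified_from_frame(df)
    assert [p.uid for p in back] == [
        p.uid for p in sorted(classified, key=lambda q: q.rank)
    ]
    assert [p.peak_class for p in back] == [
        p.peak_class for p in sorted(classified, key=lambda q: q.rank)
    ]
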