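import numpy as np
import pytest

from mosaicscan import Genome, detect_mosaics, filter_is, mosaic_density, pair_category
from mosaicscan.mosaics import (
    Mosaic,
    PairResult,
    map_is_catalog,
    summarize_categories,
)

from conftest import mutate_seq, random_seq


def _mosaic(g1_start, g1_end, g2_start=None, g2_end=None, identity=0.96, **kw):
    g2_start = g1_start if g2_start is None else g2_start
    g2_end = g1_end if g2_end is None else g2_end
    return Mosaic(
        g1_id=kw.get("g1_id", "a"), g2_id=kw.get("g2_id", "b"),
        g1_start=g1_start, g1_end=g1_end, g2_start=g2_start, g2_end=g2_end,
        strand="+", length=g1_end - g1_start, identity=identity, score=100.0,
    )


class TestDetectMosaics:
    def test_identical_genomes_single_spanning_mosaic(self):
        rng = np.random.default_rng(0)
        s = random_seq(rng, 10_000)
        mosaics = detect_mosaics(Genome("a", s), Genome("b", s))
        assert len(mosaics) == 1
        m = mosaics[0]
        assert (m.g1_start, m.g1_end) == (0, 10_000)
        assert m.identity == 1.0

    def test_same_genome_rejected(self):
        g = Genome("a", "ACGT" * 100)
        with pytest.raises(ValueError, match="distinct"):
            detect_mosaics(g, g)

    def test_planted_mosaics_recovered(self, small_cohort):
        genomes, truth = small_cohort
        by_id = {g.id: g for g in genomes}
        for pair in truth.pairs:
            detected = detect_mosaics(by_id[pair.g1_id], by_id[pair.g2_id])
            assert len(detected) == len(pair.mosaics)
            for det, t in zip(detected, pair.mosaics):
                # boundaries are fuzzy inside the planted anchors (their
                # local identity can approach the mosaic's): require the
                # planted segment covered and the hit confined to the
                # mosaic-plus-anchor span
                ov = min(det.g1_end, t.end) - max(det.g1_start, t.start)
                assert ov >= 0.8 * (t.end - t.start)
                lo = min([t.start] + [a.start for a in t.anchors]) - 15
                hi = max([t.end] + [a.end for a in t.anchors]) + 15
                assert det.g1_start >= lo and det.g1_end <= hi
                assert det.identity > 0.90 and det.length >= 100

    def test_unrelated_genomes_none(self):
        rng = np.random.default_rng(1)
        g1 = Genome("a", random_seq(rng, 8000))
        g2 = Genome("b", random_seq(rng, 8000))
        assert detect_mosaics(g1, g2) == []

    def test_thresholds_hold_on_output(self, small_scan):
        df = small_scan.mosaics
        assert (df["length"] >= 100).all()
        assert (df["identity_pct"] > 90).all()


class TestFilterIs:
    def test_empty_catalog_keeps_all(self):
        mosaics = [_mosaic(100, 300)]
        kept, removed, pct = filter_is(mosaics, None)
        assert kept == mosaics and removed == [] and pct == 0.0

    def test_small_overlap_kept(self):
        mosaics = [_mosaic(100, 300)]
        kept, removed, pct = filter_is(mosaics, {"a": [(280, 400)], "b": []})
        assert len(kept) == 1 and pct == 0.0
        assert kept[0].is_overlap == pytest.approx(0.1)

    def test_majority_overlap_removed_either_genome(self):
        mosaics = [_mosaic(100, 300), _mosaic(1000, 1200)]
        intervals = {"a": [], "b": [(1050, 1300)]}
        kept, removed, pct = filter_is(mosaics, intervals)
        assert [m.g1_start for m in kept] == [100]
        assert [m.g1_start for m in removed] == [1000]
        assert pct == 50.0

    def test_partition_is_exact(self):
        mosaics = [_mosaic(i * 500, i * 500 + 200) for i in range(4)]
        intervals = {"a": [(0, 220), (1000, 1150)], "b": []}
        kept, removed, pct = filter_is(mosaics, intervals)
        assert len(kept) + len(removed) == len(mosaics)
        assert pct == pytest.approx(100 * len(removed) / len(mosaics))

    def test_planted_is_copy_detected_and_removed(self):
        rng = np.random.default_rng(2)
        is_seq = random_seq(rng, 800)
        s = random_seq(rng, 3000) + is_seq + random_seq(rng, 3000)
        s2 = random_seq(rng, 1000) + is_seq + random_seq(rng, 5000)
        g1, g2 = Genome("a", s), Genome("b", s2)
        mosaics = detect_mosaics(g1, g2)
        assert len(mosaics) == 1
        catalog = [Genome("IS1", is_seq)]
        intervals = map_is_catalog([g1, g2], catalog)
        kept, removed, pct = filter_is(mosaics, intervals)
        assert kept == [] and len(removed) == 1 and pct == 100.0


class TestDensityAndCategories:
    def test_density_zero(self):
        g = Genome("a", "ACGT" * 2500)
        assert mosaic_density([], g, g) == 0.0

    def test_density_arithmetic(self):
        g1 = Genome("a", "ACGT" * 10_000)  # 40 kb
        g2 = Genome("b", "ACGT" * 10_000)
        mosaics = [_mosaic(0, 200), _mosaic(500, 700)]
        assert mosaic_density(mosaics, g1, g2) == pytest.approx(0.5)
        assert mosaic_density(mosaics, g1, g2, "min") == pytest.approx(0.5)
        with pytest.raises(ValueError):
            mosaic_density(mosaics, g1, g2, "median")

    @pytest.mark.parametrize(
        "pair, expected",
        [
            (("temperate", "temperate"), "T-T"),
            (("temperate", "defective"), "T-D"),
            (("defective", "temperate"), "T-D"),
            (("defective", "defective"), "D-D"),
            (("virulent", "virulent"), "V-V"),
            (("virulent", "temperate"), "V-other"),
            (("defective", "virulent"), "V-other"),
            (("unknown", "temperate"), None),
        ],
    )
    def test_pair_category(self, pair, expected):
        assert pair_category(*pair) == expected

    def test_single_mosaic_medians(self):
        result = PairResult(
            g1_id="a", g2_id="b", category="T-T", n_hits=1,
            mosaics=[_mosaic(0, 404, identity=0.961)],
        )
        rows = {s.category: s for s in summarize_categories([result])}
        tt = rows["T-T"]
        assert tt.median_len == 404 and tt.median_id == pytest.approx(96.1)
        assert tt.n_pairs == 1 and tt.mosaics_per_pair == 1.0

    def test_empty_category_row(self):
        rows = {s.category: s for s in summarize_categories([])}
        assert rows["V-V"].n_pairs == 0
        assert np.isnan(rows["V-V"].median_len)

    def test_counts_match_truth(self, small_cohort, small_scan):
        _, truth = small_cohort
        n_truth = sum(len(p.mosaics) for p in truth.pairs)
        rows = {s["category"]: s for _, s in small_scan.summaries.iterrows()}
        assert rows["T-T"]["n_mosaics"] == n_truth
        assert rows["T-T"]["mosaics_per_pair"] == pytest.approx(
            n_truth / len(truth.pairs)
        )
        counts = rows["T-T"]
        assert (
            counts["n_zero_trace"] + counts["n_one_trace"] + counts["n_two_trace"]
            == counts["n_mosaics"]
        )

    def test_summary_permutation_invariant(self, small_cohort):
        from mosaicscan.pipeline import RunConfig, run_scan

        genomes, truth = small_cohort
        config = RunConfig(
            skip_ani=True,
            pairs=[(p.g1_id, p.g2_id) for p in truth.pairs],
            proximal_cols=250,
        )
        forward = run_scan(genomes, config).summaries
        backward = run_scan(genomes[::-1], config).summaries
        assert forward.equals(backward)
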