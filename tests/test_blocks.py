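"""Block grouping, smoothing, detection, FWER, and block-level tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methdrift import blocks, regions


def _os_clusters(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "cluster_id": [f"os{i}" for i in range(len(positions))],
            "chrom": chrom,
            "start": positions,
            "end": positions,
            "region_class": regions.OPEN_SEA,
        }
    )


class TestGroupOpensea:
    def test_gap_boundary(self):
        # 250000 apart -> one group; 250001 -> two
        near = blocks.group_opensea(_os_clusters([1, 250_001]))
        far = blocks.group_opensea(_os_clusters([1, 250_002]))
        assert near["group_id"].nunique() == 1
        assert far["group_id"].nunique() == 2

    def test_non_opensea_rejected(self):
        bad = _os_clusters([1, 2])
        bad.loc[0, "region_class"] = regions.ISLAND
        with pytest.raises(ValueError):
            blocks.group_opensea(bad)

    def test_matches_brute_force_partition(self, rng):
        for _ in range(50):
            pos = np.sort(rng.integers(1, 5_000_000, size=30))
            grouped = blocks.group_opensea(_os_clusters(pos))
            # brute force: same group iff every intermediate gap <= max_gap
            gids = grouped["group_id"].to_numpy()
            starts = grouped["start"].to_numpy()
            ends = grouped["end"].to_numpy()
            for i in range(1, len(pos)):
                same = gids[i] == gids[i - 1]
                assert same == (starts[i] - ends[i - 1] <= 250_000)


class TestSmoothing:
    def test_constant_vector_unchanged(self):
        pos = np.arange(10) * 10_000
        out = blocks.smooth_coefficients(np.full(10, 0.02), pos)
        np.testing.assert_allclose(out, 0.02, atol=1e-12)

    def test_isolated_spike_attenuated(self):
        pos = np.arange(11) * 10_000
        coefs = np.zeros(11)
        coefs[5] = -0.1
        out = blocks.smooth_coefficients(coefs, pos)
        assert abs(out[5]) < 0.1
        assert out[5] < 0  # sign preserved

    def test_small_groups_pass_through(self):
        coefs = np.array([0.1, -0.2, 0.3])
        out = blocks.smooth_coefficients(coefs, np.array([0, 100, 200]), min_regions=7)
        np.testing.assert_array_equal(out, coefs)

    def test_matches_direct_weighted_mean(self, rng):
        pos = np.sort(rng.integers(0, 500_000, size=20))
        coefs = rng.normal(size=20)
        out = blocks.smooth_coefficients(coefs, pos, span_bp=250_000)
        i = 10
        h = 125_000
        d = np.abs(pos - pos[i]) / h
        w = np.where(d < 1, (1 - d**3) ** 3, 0.0)
        assert out[i] == pytest.approx(np.sum(w * coefs) / np.sum(w), abs=1e-10)


class TestFindBlocks:
    def test_no_signal_no_blocks(self):
        out = blocks.find_blocks(
            np.zeros(5), np.arange(5), np.arange(5), [f"c{i}" for i in range(5)], "chr1", 0.005
        )
        assert out == []

    def test_run_area_arithmetic(self):
        sm = np.array([0.0, -0.02, -0.03, -0.01, 0.0])
        pos = np.array([100, 200, 300, 400, 500])
        out = blocks.find_blocks(sm, pos, pos, [f"c{i}" for i in range(5)], "chr1", 0.005)
        assert len(out) == 1
        blk = out[0]
        assert blk.area == pytest.approx(0.06)
        assert blk.direction == "hypo"
        assert (blk.start, blk.end) == (200, 400)

    def test_cutoff_must_be_positive(self):
        with pytest.raises(ValueError):
            blocks.find_blocks(np.zeros(3), np.arange(3), np.arange(3), list("abc"), "c", 0.0)

    def test_runs_are_maximal(self, rng):
        sm = rng.normal(0, 0.01, size=100)
        pos = np.arange(100) * 1000
        out = blocks.find_blocks(sm, pos, pos, [f"c{i}" for i in range(100)], "chr1", 0.005)
        idx = {p: i for i, p in enumerate(pos)}
        for blk in out:
            i, j = idx[blk.start], idx[blk.end]
            sign = 1 if blk.direction == "hyper" else -1
            assert (sign * sm[i : j + 1] > 0.005).all()
            if i > 0:
                assert not (sign * sm[i - 1] > 0.005)
            if j < 99:
                assert not (sign * sm[j + 1] > 0.005)

    def test_planted_block_detected_with_high_overlap(self, small_dataset):
        ds = small_dataset
        cb = regions.summarize_clusters(ds.betas, ds.clusters)
        osc = ds.clusters[ds.clusters["region_class"] == regions.OPEN_SEA]
        cands, _, _ = blocks.detect_blocks(
            cb, osc, ds.samples["age"].to_numpy(), ds.samples[["sex", "plate"]]
        )
        hypo = [b for b in cands if b.direction == "hypo"]
        from methdrift.workflow import _interval_jaccard

        for r in ds.truth.planted_block_intervals.itertuples():
            best = max(
                _interval_jaccard((b.chrom, b.start, b.end), (r.chrom, r.start, r.end))
                for b in hypo
            )
            assert best >= 0.8


@pytest.fixture(scope="module")
def fwer_setup(small_dataset):
    ds = small_dataset
    cb = regions.summarize_clusters(ds.betas, ds.clusters)
    osc = ds.clusters[ds.clusters["region_class"] == regions.OPEN_SEA]
    age = ds.samples["age"].to_numpy()
    cov = ds.samples[["sex", "plate"]]
    cands, scan, _ = blocks.detect_blocks(cb, osc, age, cov)
    return blocks.block_fwer(cands, cb, scan, age, cov, n_boot=50, seed=1)


class TestBlockFwer:
    def test_planted_blocks_reach_minimum_fwer(self, fwer_setup):
        big = sorted(fwer_setup, key=lambda b: -b.area)[:2]
        for b in big:
            assert b.fwer == 0.0
            assert b.fwer_label == "< 0.02"

    def test_fwer_monotone_in_area(self, fwer_setup):
        by_area = sorted(fwer_setup, key=lambda b: b.area)
        fwers = [b.fwer for b in by_area]
        assert all(a >= b for a, b in zip(fwers, fwers[1:]))

    def test_nboot_validation(self, small_dataset):
        with pytest.raises(ValueError):
            blocks.block_fwer([], pd.DataFrame(), None, None, n_boot=0)


class TestCgiEnrichment:
    def _block(self):
        return blocks.Block("b", "chr1", 1000, 9000, [], "hypo", 1.0, -0.1)

    def _cgis(self, n, flags):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.linspace(1500, 8000, n).astype(int),
                "end": np.linspace(1600, 8100, n).astype(int),
                "hyper_dmr": flags,
            }
        )

    def test_zero_observed_gives_p_one(self):
        out = blocks.cgi_block_enrichment(self._block(), self._cgis(6, [False] * 6), 0.3)
        assert out.p_binom == pytest.approx(1.0)

    def test_all_flagged_closed_form(self):
        out = blocks.cgi_block_enrichment(self._block(), self._cgis(10, [True] * 10), 0.5)
        assert out.p_binom == pytest.approx(0.5**10, rel=1e-9)

    def test_matches_exhaustive_enumeration(self):
        for n_cgi in (5, 12, 20, 25):
            for obs in (0, 1, n_cgi // 2, n_cgi):
                flags = [True] * obs + [False] * (n_cgi - obs)
                out = blocks.cgi_block_enrichment(self._block(), self._cgis(n_cgi, flags), 0.2)
                exact = sum(
                    math.comb(n_cgi, k) * 0.2**k * 0.8 ** (n_cgi - k)
                    for k in range(obs, n_cgi + 1)
                )
                assert out.p_binom == pytest.approx(exact, abs=1e-12)

    def test_no_cgis_flagged(self):
        out = blocks.cgi_block_enrichment(
            self._block(), self._cgis(4, [False] * 4).assign(chrom="chr9"), 0.2
        )
        assert out.note == "no CGIs" and np.isnan(out.p_binom)


class TestMatchedRandomBlocks:
    def _observed(self, lengths):
        return [
            blocks.Block(f"b{i}", "chr1", 0, L - 1, [], "hypo", 1.0, -0.1)
            for i, L in enumerate(lengths)
        ]

    def test_identical_candidates_match_exactly(self):
        obs = self._observed([1000, 2000, 3000])
        cands = pd.DataFrame(
            {
                "chrom": "chr2",
                "start": np.arange(9) * 10_000,
                "end": np.arange(9) * 10_000 + np.tile([999, 1999, 2999], 3),
            }
        )
        cands["length"] = cands["end"] - cands["start"] + 1
        out = blocks.matched_random_blocks(obs, cands, seed=0)
        assert sorted(out["length"]) == [1000, 2000, 3000]

    def test_deterministic_given_seed(self):
        obs = self._observed([1000] * 5)
        cands = pd.DataFrame(
            {"chrom": "chr2", "start": np.arange(50) * 10_000}
        ).assign(end=lambda d: d["start"] + 999, length=1000)
        a = blocks.matched_random_blocks(obs, cands, seed=3)
        b = blocks.matched_random_blocks(obs, cands, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_candidates_error(self):
        obs = self._observed([1000] * 5)
        cands = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [999], "length": [1000]})
        with pytest.raises(ValueError):
            blocks.matched_random_blocks(obs, cands, seed=0)


class TestCrossCohort:
    def test_wilcoxon_small_sample_exact(self):
        res = sps.mannwhitneyu([1, 2, 3], [4, 5, 6], alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(0.1)

    def test_identical_cohorts_give_null_statistics(self, small_dataset):
        ds = small_dataset
        blk = ds.truth.planted_block_intervals
        out = blocks.cross_cohort_block_test(blk, ds.betas, ds.betas, ds.probes)
        np.testing.assert_allclose(out["t"], 0.0, atol=1e-10)
        assert (out["p_wilcoxon"] > 0.9).all()

    def test_planted_shift_detected(self, small_dataset):
        from methdrift.simulate import generate_second_cohort

        ds = small_dataset
        b2, s2 = generate_second_cohort(ds, extra_block_hypo=0.05)
        bn = b2.loc[:, (s2["group"] == "normal").to_numpy()]
        bc = b2.loc[:, (s2["group"] == "cancer").to_numpy()]
        out = blocks.cross_cohort_block_test(
            ds.truth.planted_block_intervals, bn, bc, ds.probes
        )
        assert (out["t"] < -5).all()  # cancer minus normal strongly negative

    def test_missing_probes_skipped(self, small_dataset, caplog):
        ds = small_dataset
        ghost = pd.DataFrame({"chrom": ["chr9"], "start": [1], "end": [100]})
        out = blocks.cross_cohort_block_test(ghost, ds.betas, ds.betas, ds.probes)
        assert out.empty
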