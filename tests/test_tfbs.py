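"""narrowPeak parsing, profile mapping, Fisher enrichment, Eq.-style model."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from methdrift import tfbs


class TestNarrowPeak:
    def test_basic_line(self, tmp_path):
        f = tmp_path / "a.narrowPeak"
        f.write_text("chr1\t100\t200\t.\t0\t.\t5.0\t10.0\t8.0\t50\n")
        ps = tfbs.read_narrowpeak(f, "TF1", "lab")
        assert len(ps.intervals) == 1
        row = ps.intervals.iloc[0]
        assert (row["chrom"], row["start"], row["end"], row["summit"]) == ("chr1", 100, 200, 50)

    def test_empty_file(self, tmp_path):
        f = tmp_path / "e.narrowPeak"
        f.write_text("")
        assert tfbs.read_narrowpeak(f).intervals.empty

    def test_track_line_skipped_and_roundtrip(self, tmp_path):
        f = tmp_path / "t.narrowPeak"
        f.write_text(
            "track name=peaks\n"
            "chr1\t100\t200\t.\t0\t.\t1\t2\t3\t-1\n"
            "chr2\t5\t9\t.\t0\t.\t1\t2\t3\t2\n"
        )
        ps = tfbs.read_narrowpeak(f)
        out = tmp_path / "out.narrowPeak"
        tfbs.write_narrowpeak(ps, out)
        again = tfbs.read_narrowpeak(out)
        pd.testing.assert_frame_equal(ps.intervals, again.intervals)

    @pytest.mark.parametrize(
        "line,msg",
        [
            ("chr1\t100\t200\n", "expected 10"),
            ("chr1\tx\t200\t.\t0\t.\t1\t2\t3\t-1\n", "malformed"),
            ("chr1\t200\t100\t.\t0\t.\t1\t2\t3\t-1\n", "start must be"),
        ],
    )
    def test_malformed_lines_raise_with_line_number(self, tmp_path, line, msg):
        f = tmp_path / "bad.narrowPeak"
        f.write_text(line)
        with pytest.raises(ValueError, match=msg):
            tfbs.read_narrowpeak(f)


def _cluster_df(probe_groups):
    return pd.DataFrame(
        {
            "cluster_id": [f"c{i}" for i in range(len(probe_groups))],
            "probe_ids": probe_groups,
        }
    )


class TestMapProfiles:
    def _peaks(self, ivals):
        df = pd.DataFrame(ivals, columns=["chrom", "start", "end"])
        for col, val in [("name", "."), ("score", 0), ("strand", "."),
                         ("signal", 0.0), ("pvalue", 0.0), ("qvalue", 0.0), ("summit", -1)]:
            df[col] = val
        return tfbs.PeakSet("TF", "", df)

    def test_half_open_boundary_convention(self):
        probes = pd.DataFrame(
            {"probe_id": ["a", "b", "c"], "chrom": "chr1", "pos": [100, 150, 200]}
        )
        prof = tfbs.map_profiles(
            self._peaks([("chr1", 100, 200)]), probes, _cluster_df([["a"], ["b"], ["c"]])
        )
        # peak [100,200) covers 1-based 101..200: pos 100 out, 150 and 200 in
        assert list(prof.flags) == [0, 1, 1]

    def test_cluster_flag_is_or_over_members(self):
        probes = pd.DataFrame(
            {"probe_id": ["a", "b"], "chrom": "chr1", "pos": [50, 150]}
        )
        prof = tfbs.map_profiles(
            self._peaks([("chr1", 100, 200)]), probes, _cluster_df([["a", "b"]])
        )
        assert list(prof.flags) == [1]

    def test_matches_quadratic_scan_oracle(self, rng):
        probes = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(80)],
                "chrom": rng.choice(["chr1", "chr2"], 80),
                "pos": rng.integers(1, 5000, 80),
            }
        )
        ivals = [
            ("chr1" if rng.random() < 0.5 else "chr2",
             int(s := rng.integers(0, 4900)), int(s + rng.integers(1, 300)))
            for _ in range(25)
        ]
        clusters = _cluster_df([[f"p{i}"] for i in range(80)])
        prof = tfbs.map_profiles(self._peaks(ivals), probes, clusters)
        for i, (c, p) in enumerate(zip(probes["chrom"], probes["pos"])):
            want = any(ch == c and s < p <= e for ch, s, e in ivals)
            assert bool(prof.flags.iloc[i]) == want

    def test_invariant_to_peak_split(self):
        probes = pd.DataFrame({"probe_id": ["a"], "chrom": "chr1", "pos": [150]})
        clusters = _cluster_df([["a"]])
        whole = tfbs.map_profiles(self._peaks([("chr1", 100, 200)]), probes, clusters)
        split = tfbs.map_profiles(
            self._peaks([("chr1", 100, 150), ("chr1", 150, 200)]), probes, clusters
        )
        assert list(whole.flags) == list(split.flags)


def hypergeom_tail(a, b, c, d):
    """P(X >= a) for the 2x2 table margins by direct enumeration."""
    n_sel, n_flag, N = a + b, a + c, a + b + c + d
    denom = math.comb(N, n_sel)
    return sum(
        math.comb(n_flag, k) * math.comb(N - n_flag, n_sel - k) / denom
        for k in range(a, min(n_sel, n_flag) + 1)
    )


class TestFisherEnrichment:
    def _profile(self, flagged, universe):
        flags = pd.Series([1 if c in flagged else 0 for c in universe], index=universe)
        return tfbs.TFProfile("TF", flags)

    def test_worked_example_or_and_p(self):
        universe = [f"c{i}" for i in range(1000)]
        sel = set(universe[:100])
        flagged = set(universe[:30]) | set(universe[100:110])  # a=30 b=70 c=10 d=890
        res = tfbs.fisher_enrichment(sel, self._profile(flagged, universe), set(universe))
        assert res.table == (30, 70, 10, 890)
        assert res.odds_ratio == pytest.approx(30 * 890 / (70 * 10), rel=1e-12)
        assert res.p == pytest.approx(hypergeom_tail(30, 70, 10, 890), rel=1e-9)

    def test_proportional_table_is_null(self):
        universe = [f"c{i}" for i in range(200)]
        sel = set(universe[:50])
        flagged = set(universe[:10]) | set(universe[50:80])  # a/b = 10/40 = c/d = 30/120
        res = tfbs.fisher_enrichment(sel, self._profile(flagged, universe), set(universe))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p >= 0.5

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(25):
            N = int(rng.integers(20, 200))
            universe = [f"c{i}" for i in range(N)]
            sel = set(rng.choice(universe, size=int(rng.integers(1, N // 2)), replace=False))
            flagged = set(rng.choice(universe, size=int(rng.integers(1, N // 2)), replace=False))
            res = tfbs.fisher_enrichment(sel, self._profile(flagged, universe), set(universe))
            a, b, c, d = res.table
            assert res.p == pytest.approx(hypergeom_tail(a, b, c, d), rel=1e-8)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            tfbs.fisher_enrichment(set(), self._profile(set(), []), set())


class TestJaccardFilter:
    def _profiles(self, named_sets, universe):
        return [
            tfbs.TFProfile(
                name, pd.Series([1 if c in s else 0 for c in universe], index=universe)
            )
            for name, s in named_sets
        ]

    def test_moderate_overlap_both_retained(self):
        u = list("12345")
        profs = self._profiles([("A", {"1", "2", "3"}), ("B", {"2", "3", "4"})], u)
        kept, mat = tfbs.jaccard_filter(profs)
        assert len(kept) == 2
        assert mat.loc["A", "B"] == pytest.approx(0.5)

    def test_identical_profiles_collapse(self):
        u = list("1234")
        profs = self._profiles([("A", {"1", "2"}), ("B", {"1", "2"})], u)
        kept, _ = tfbs.jaccard_filter(profs)
        assert [p.tf_name for p in kept] == ["A"]

    def test_high_overlap_drops_smaller(self):
        u = [str(i) for i in range(20)]
        big = set(u[:10])
        small = set(u[:9])  # J = 9/10 > 0.7
        kept, _ = tfbs.jaccard_filter(self._profiles([("S", small), ("B", big)], u))
        assert [p.tf_name for p in kept] == ["B"]

    def test_matrix_matches_set_oracle(self, rng):
        u = [str(i) for i in range(30)]
        named = [
            (f"T{k}", set(rng.choice(u, size=int(rng.integers(1, 15)), replace=False)))
            for k in range(5)
        ]
        _, mat = tfbs.jaccard_filter(self._profiles(named, u), threshold=1.1)
        for i, (_, si) in enumerate(named):
            for j, (_, sj) in enumerate(named):
                want = len(si & sj) / len(si | sj)
                assert mat.iloc[i, j] == pytest.approx(want, abs=1e-12)

    def test_empty_profile_dropped_with_warning(self, caplog):
        u = list("123")
        profs = self._profiles([("A", {"1"}), ("Z", set())], u)
        kept, _ = tfbs.jaccard_filter(profs)
        assert [p.tf_name for p in kept] == ["A"]
        assert "no flagged clusters" in caplog.text


class TestMultivariateRegression:
    def _profiles_from_matrix(self, B, universe):
        return [
            tfbs.TFProfile(f"T{j}", pd.Series(B[:, j], index=universe))
            for j in range(B.shape[1])
        ]

    def test_single_factor_exact_fit(self):
        universe = [f"c{i}" for i in range(40)]
        b = np.array([1] * 10 + [0] * 30)
        t = pd.Series(2.0 * b, index=universe)
        res = tfbs.multivariate_tf_regression(t, self._profiles_from_matrix(b[:, None], universe))
        assert res.coefficients.loc["intercept", "alpha"] == pytest.approx(0.0, abs=1e-10)
        assert res.coefficients.loc["T0", "alpha"] == pytest.approx(2.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_statsmodels_and_recovers_planted_effects(self, rng):
        n = 5000
        universe = [f"c{i}" for i in range(n)]
        B = (rng.uniform(size=(n, 2)) < 0.1).astype(float)
        y = 3.0 * B[:, 0] - 2.0 * B[:, 1] + rng.normal(size=n)
        t = pd.Series(y, index=universe)
        res = tfbs.multivariate_tf_regression(t, self._profiles_from_matrix(B, universe))
        X = sm.add_constant(B)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(res.coefficients["alpha"], ref.params, atol=1e-8)
        np.testing.assert_allclose(res.coefficients["t"], ref.tvalues, atol=1e-6)
        for truth, name in ((3.0, "T0"), (-2.0, "T1")):
            est = res.coefficients.loc[name, "alpha"]
            se = abs(est / res.coefficients.loc[name, "t"])
            assert abs(est - truth) < 2 * se

    def test_orthogonal_profile_leaves_coefficient_stable(self, rng):
        n = 400
        universe = [f"c{i}" for i in range(n)]
        b1 = np.zeros(n)
        b1[:100] = 1
        b2 = np.zeros(n)
        b2[200:300] = 1  # disjoint, same size -> balanced
        y = 1.5 * b1 + rng.normal(size=n)
        t = pd.Series(y, index=universe)
        single = tfbs.multivariate_tf_regression(t, self._profiles_from_matrix(b1[:, None], universe))
        both = tfbs.multivariate_tf_regression(
            t, self._profiles_from_matrix(np.column_stack([b1, b2]), universe)
        )
        a1 = single.coefficients.loc["T0", "alpha"]
        a2 = both.coefficients.loc["T0", "alpha"]
        # disjoint profiles are not exactly orthogonal to the intercept;
        # the shared-coefficient shift is bounded by the b2 group mean effect
        assert a2 == pytest.approx(a1, abs=0.2)

    def test_collinear_profiles_rejected_by_name(self):
        universe = [f"c{i}" for i in range(10)]
        b = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0], dtype=float)
        profs = self._profiles_from_matrix(np.column_stack([b, b]), universe)
        with pytest.raises(ValueError, match="T1"):
            tfbs.multivariate_tf_regression(pd.Series(np.zeros(10), index=universe), profs)


def test_enriched_factors_rank_above_null_factors(small_dataset):
    """Planted enriched TFs beat null TFs on Fisher p in the hyper-DMR set."""
    from methdrift import dmr, regions

    ds = small_dataset
    cb = regions.summarize_clusters(ds.betas, ds.clusters)
    st_df = dmr.dmr_table(cb, ds.samples["age"].to_numpy(), ds.samples[["sex", "plate"]])
    sel = dmr.select_dmrs(st_df, "top_fraction", 0.05)
    profiles = [tfbs.map_profiles(ps, ds.probes, ds.clusters) for ps in ds.peaks]
    hyper = set(sel.loc[sel["direction"] == "hyper", "cluster_id"])
    tab = tfbs.enrichment_table(hyper, profiles, set(st_df["cluster_id"]), "hyperDMR")
    enriched = set(ds.truth.enriched_tf_ids)
    assert set(tab["tf_name"].head(len(enriched))) == enriched
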