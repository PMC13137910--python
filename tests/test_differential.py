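"""Welch tests, BH adjustment, size factors and the NB Wald engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats, special

from nitromics.containers import CountMatrix, raw_design
from nitromics.differential import (KO_STIM_VS_WT_STIM, Contrast, bh_adjust,
                                    diff_intensity, filter_low_counts,
                                    nb_wald, size_factors, welch_test)
from nitromics.simulate import SimParams, generate_proteomics


class TestWelch:
    def test_hand_computed_example(self):
        t, df, p = welch_test([1, 2, 3, 4], [2, 3, 4, 5])
        assert t == pytest.approx(-1.0954451, abs=1e-6)
        assert df == pytest.approx(6.0, abs=1e-9)
        assert p == pytest.approx(0.3153, abs=1e-3)

    def test_identical_groups(self):
        t, df, p = welch_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 5), rng.normal(1, 2, 7)
        t1, df1, p1 = welch_test(x, y)
        t2, df2, p2 = welch_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert df1 == pytest.approx(df2)
        assert p1 == pytest.approx(p2)

    def test_constant_equal_groups_convention(self):
        t, df, p = welch_test([2, 2, 2], [2, 2, 2])
        assert (t, p) == (0.0, 1.0)
        with pytest.raises(ValueError, match="zero pooled"):
            welch_test([2, 2, 2], [3, 3, 3])

    def test_matches_scipy_oracle(self):
        """Independent route: scipy's Welch ttest on 200 random draws."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            nx, ny = rng.integers(2, 12, 2)
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), nx)
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), ny)
            t, df, p = welch_test(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert df == pytest.approx(ref.df, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_p_matches_incomplete_beta(self):
        """p agrees with the regularized incomplete beta to 1e-10 on a
        fixed (t, df) grid."""
        for t in (0.1, 0.5, 1.0, 2.0, 3.5, 6.0):
            for df in (1.5, 3.0, 6.0, 10.7, 30.0):
                p_impl = 2.0 * stats.t.sf(t, df)
                p_beta = special.betainc(df / 2.0, 0.5, df / (df + t * t))
                assert p_impl == pytest.approx(p_beta, abs=1e-10)


class TestBH:
    def test_all_tie_to_largest(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_two_values(self):
        assert np.allclose(bh_adjust([0.005, 0.5]), [0.01, 0.5])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        def brute(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            for pos, i in enumerate(order):
                q[i] = min(min(m * p[j] / (list(order).index(j) + 1)
                               for j in order[pos:]), 1.0)
            return q

        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, rng.integers(1, 30))
            mine = bh_adjust(p)
            assert np.allclose(mine, brute(p), atol=1e-12)
            assert np.allclose(mine, multipletests(p, method="fdr_bh")[1],
                               atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=40))
    def test_dominates_raw_p_and_bounded(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestDiffIntensity:
    def test_doubled_means_give_lfc_one(self, intensity_factory):
        rng = np.random.default_rng(3)
        base = np.abs(rng.normal(100, 0.1, (20, 8))) + 1
        values = base.copy()
        values[:, 2:4] = base[:, 2:4] * 2  # WT.stim columns
        m = intensity_factory(values)
        c = Contrast({"genotype": "WT", "stimulation": "unstim"},
                     {"genotype": "WT", "stimulation": "stim"}, "x")
        out = diff_intensity(m, c)
        assert np.allclose(out["log2fc"], 1.0, atol=0.02)

    def test_antisymmetric_under_swap(self, intensity_factory):
        rng = np.random.default_rng(4)
        m = intensity_factory(np.abs(rng.normal(50, 10, (30, 8))) + 1)
        fwd = Contrast({"genotype": "WT"}, {"genotype": "iNOS_KO"}, "f")
        rev = Contrast({"genotype": "iNOS_KO"}, {"genotype": "WT"}, "r")
        a, b = diff_intensity(m, fwd), diff_intensity(m, rev)
        assert np.allclose(a["log2fc"], -b["log2fc"])
        assert np.allclose(a["p_raw"], b["p_raw"])

    def test_sample_order_within_groups_irrelevant(self, raw16):
        from nitromics.containers import IntensityMatrix
        params = SimParams(n_features=50, missing_rate=0.0, seed=5)
        m, _ = generate_proteomics(raw16, params)
        out1 = diff_intensity(m, KO_STIM_VS_WT_STIM)
        perm = raw16.sample(frac=1, random_state=0).reset_index(drop=True)
        m2 = IntensityMatrix(m.values[perm["sample_id"].to_numpy()], perm)
        out2 = diff_intensity(m2, KO_STIM_VS_WT_STIM)
        pd.testing.assert_frame_equal(out1, out2)

    def test_small_group_rejected(self, intensity_factory):
        m = intensity_factory(np.ones((3, 8)) * 2)
        bad = Contrast({"genotype": "WT", "stimulation": "unstim",
                        "donor": "none", "replicate": 1}, {"genotype": "iNOS_KO"})
        with pytest.raises(ValueError):
            diff_intensity(m, bad)


class TestSizeFactors:
    def _counts(self, arr, design):
        frame = pd.DataFrame(np.asarray(arr),
                             index=[f"g{i}" for i in range(len(arr))],
                             columns=design["sample_id"].to_numpy()[:len(arr[0])])
        return CountMatrix(frame, design[:len(arr[0])].reset_index(drop=True))

    def test_hand_computed_two_samples(self, design4):
        counts = self._counts([[4, 8], [10, 20]], design4)
        sf = size_factors(counts)
        assert sf.iloc[0] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
        assert sf.iloc[1] == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_identical_samples_give_unit_factors(self, design4):
        counts = self._counts(np.tile([[7], [13], [2]], (1, 8)), design4)
        assert np.allclose(size_factors(counts), 1.0)

    def test_scaling_homogeneity(self, design4):
        """Scaling one sample's counts by c scales its factor by c relative
        to every other sample (factors are defined up to normalization:
        the geometric-mean reference itself shifts by c**(1/n))."""
        rng = np.random.default_rng(6)
        base = rng.integers(1, 500, (50, 8))
        c1 = self._counts(base, design4)
        scaled = base.copy()
        scaled[:, 3] *= 5
        c2 = self._counts(scaled, design4)
        sf1, sf2 = size_factors(c1), size_factors(c2)
        assert sf2.iloc[3] / sf2.iloc[0] == pytest.approx(
            5 * sf1.iloc[3] / sf1.iloc[0], rel=1e-9)
        # other samples' relative factors are untouched
        assert sf2.iloc[5] / sf2.iloc[0] == pytest.approx(
            sf1.iloc[5] / sf1.iloc[0], rel=1e-9)

    def test_no_all_positive_gene_is_error(self, design4):
        arr = np.ones((3, 8), dtype=int)
        arr[:, 0] = 0
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(self._counts(arr, design4))


class TestFilterLowCounts:
    def test_boundary_of_ten(self, design4):
        arr = np.zeros((2, 8), dtype=int)
        arr[0, 0] = 9    # total 9 -> removed
        arr[1, :5] = 2   # total 10 -> retained
        frame = pd.DataFrame(arr, index=["low", "keep"],
                             columns=design4["sample_id"].to_numpy())
        out = filter_low_counts(CountMatrix(frame, design4), 10)
        assert list(out.values.index) == ["keep"]

    def test_zero_threshold_is_identity(self, design4):
        arr = np.random.default_rng(7).integers(0, 5, (10, 8))
        frame = pd.DataFrame(arr, index=[f"g{i}" for i in range(10)],
                             columns=design4["sample_id"].to_numpy())
        cm = CountMatrix(frame, design4)
        assert filter_low_counts(cm, 0).values.shape == (10, 8)


class TestNBWald:
    def _simulate(self, n_genes, lfc, n_per, disp, seed, n_null=0,
                  balanced=True):
        """NB counts for a two-group contrast.  The scored DE genes sit on
        a background of null genes (so median-of-ratios factors lock onto
        unregulated genes) plus, when ``balanced``, an equal block of
        oppositely regulated genes (so the median is not displaced by
        one-directional regulation)."""
        rng = np.random.default_rng(seed)
        design = raw_design(n_per)
        ids = (design[design["genotype"] == "WT"]["sample_id"].tolist()
               + design[design["genotype"] == "iNOS_KO"]["sample_id"].tolist())
        design = design.set_index("sample_id").loc[ids].reset_index()
        n_wt = 2 * n_per
        n_opposite = n_genes if (balanced and lfc != 0) else 0
        total = n_genes + n_opposite + n_null
        base = rng.lognormal(np.log(100), 1.0, total)
        sf = rng.uniform(0.7, 1.4, 2 * n_wt)
        mu = base[:, None] * sf[None, :]
        mu[:n_genes, n_wt:] *= 2.0 ** lfc
        mu[n_genes:n_genes + n_opposite, n_wt:] *= 2.0 ** -lfc
        r = 1.0 / disp
        counts = rng.negative_binomial(r, r / (r + mu))
        frame = pd.DataFrame(counts, index=[f"g{i:05d}" for i in range(total)],
                             columns=design["sample_id"].to_numpy())
        c = Contrast({"genotype": "WT"}, {"genotype": "iNOS_KO"}, "sim")
        return CountMatrix(frame, design), c

    def test_identical_group_means_give_zero_lfc(self, design4):
        arr = np.tile([[40], [100], [7]], (1, 8))
        frame = pd.DataFrame(arr, index=["a", "b", "c"],
                             columns=design4["sample_id"].to_numpy())
        c = Contrast({"genotype": "WT"}, {"genotype": "iNOS_KO"}, "x")
        out = nb_wald(CountMatrix(frame, design4), c)
        assert np.allclose(out["log2fc"], 0.0)

    def test_recovers_planted_lfc(self):
        """500 genes at true lfc 1 over a null background, n=8/group."""
        counts, c = self._simulate(500, 1.0, 4, 0.05, seed=8, n_null=2000)
        out = nb_wald(counts, c).set_index("gene_symbol")
        de = [f"g{i:05d}" for i in range(500)]
        assert out.loc[de, "log2fc"].mean() == pytest.approx(1.0, abs=0.1)

    def test_null_type_one_error(self):
        counts, c = self._simulate(2000, 0.0, 4, 0.05, seed=9)
        out = nb_wald(counts, c)
        assert 0.03 <= (out["p_raw"] < 0.05).mean() <= 0.08

    def test_zero_group_mean_capped_and_flagged(self, design4):
        arr = np.tile([[50], [120]], (1, 8))
        extra = np.zeros((1, 8), dtype=int)
        extra[0, 4:] = 30   # zero in WT group, positive in KO group
        frame = pd.DataFrame(np.vstack([arr, extra]),
                             index=["a", "b", "z"],
                             columns=design4["sample_id"].to_numpy())
        c = Contrast({"genotype": "WT"}, {"genotype": "iNOS_KO"}, "x")
        out = nb_wald(CountMatrix(frame, design4), c).set_index("gene_symbol")
        assert out.loc["z", "log2fc"] == 10.0
        assert bool(out.loc["z", "lfc_capped"])

    def test_all_zero_gene_excluded(self, design4):
        arr = np.vstack([np.tile([[50], [120]], (1, 8)),
                         np.zeros((1, 8), dtype=int)])
        frame = pd.DataFrame(arr, index=["a", "b", "dead"],
                             columns=design4["sample_id"].to_numpy())
        c = Contrast({"genotype": "WT"}, {"genotype": "iNOS_KO"}, "x")
        out = nb_wald(CountMatrix(frame, design4), c)
        assert "dead" not in set(out["gene_symbol"])
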