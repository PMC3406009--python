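import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from screenkit.screen import (
    BindingScreenModel,
    background_filter,
    centered_log_ratio,
    classify_binders,
    combine_p,
    dual_set_null_rate,
    fisher_p,
    gaussian_p,
    product_null_cdf,
    zscore,
)

from conftest import scan_from_ratios


class TestBackgroundFilter:
    @pytest.mark.parametrize(
        "f1,f2,mode,expected",
        [
            (200.0, 300.0, "all_channels", True),
            (140.0, 300.0, "all_channels", False),
            (140.0, 300.0, "any_channel", True),
            (140.0, 140.0, "any_channel", False),
        ],
    )
    def test_detectability_modes(self, tiny_scan, f1, f2, mode, expected):
        scan = tiny_scan
        scan.features.loc[0, ["f_ch1", "f_ch2"]] = [f1, f2]
        mask = background_filter(scan, k=1.5, mode=mode)
        assert bool(mask.iloc[0]) is expected

    def test_nonpositive_factor_rejected(self, tiny_scan):
        with pytest.raises(ValueError):
            background_filter(tiny_scan, k=0.0)

    def test_threshold_is_strict(self, tiny_scan):
        tiny_scan.features.loc[0, ["f_ch1", "f_ch2"]] = [150.0, 150.0]  # == 1.5*b
        assert not background_filter(tiny_scan, k=1.5).iloc[0]


class TestCenteredLogRatio:
    def test_median_centering_of_two_proteins(self):
        scan = scan_from_ratios([2.0, 0.0], background=0.0)
        rep = centered_log_ratio(scan, k=1e-9)
        np.testing.assert_allclose(rep.ratios.to_numpy(), [1.0, -1.0], atol=1e-12)

    def test_dye_swap_preserves_signed_ratios(self):
        values = [1.5, -0.5, 0.2, 0.0]
        a = scan_from_ratios(values, dye_set="A", background=0.0)
        b = scan_from_ratios(values, dye_set="B", background=0.0)
        ra = centered_log_ratio(a, k=1e-9).ratios
        rb = centered_log_ratio(b, k=1e-9).ratios
        np.testing.assert_allclose(ra.to_numpy(), rb.to_numpy(), atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-3, 3), min_size=3, max_size=30))
    def test_mean_and_median_centering_differ_by_constant(self, values):
        scan = scan_from_ratios(values, background=0.0)
        med = centered_log_ratio(scan, center="median", k=1e-9).ratios
        mean = centered_log_ratio(scan, center="mean", k=1e-9).ratios
        diff = (med - mean).to_numpy()
        np.testing.assert_allclose(diff, diff[0], atol=1e-9)

    def test_centered_median_is_zero_over_passing(self, screen_set):
        rep = centered_log_ratio(screen_set.scans[0])
        assert abs(rep.ratios.median()) < 1e-12


class TestZScore:
    def test_hand_computed_population_standardization(self):
        np.testing.assert_allclose(
            zscore(np.array([1.0, 2.0, 3.0])),
            [-1.224744871, 0.0, 1.224744871],
            atol=1e-8,
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            zscore(np.array([2.0, 2.0, 2.0]))

    def test_idempotence(self):
        x = np.array([0.3, -1.2, 4.0, 0.9])
        np.testing.assert_allclose(zscore(zscore(x)), zscore(x), atol=1e-12)


class TestGaussianP:
    def test_symmetry_and_known_quantiles(self):
        assert gaussian_p(0.0) == pytest.approx(0.5)
        assert gaussian_p(1.6449) == pytest.approx(0.05, abs=1e-4)
        assert gaussian_p(-1.6449) == pytest.approx(0.95, abs=1e-4)

    def test_matches_trapezoid_integration_oracle(self):
        # numeric integration of the standard normal density, independent of sf
        zs = np.linspace(-6, 6, 25)
        grid = np.linspace(-12, 12, 2_000_001)
        dens = np.exp(-grid**2 / 2) / np.sqrt(2 * np.pi)
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2) * (grid[1] - grid[0])])
        for z in zs:
            oracle = 1.0 - np.interp(z, grid, cdf)
            assert gaussian_p(float(z)) == pytest.approx(oracle, abs=1e-6)

    def test_strictly_decreasing(self):
        z = np.linspace(-6, 6, 200)
        p = gaussian_p(z)
        assert np.all(np.diff(p) < 0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            gaussian_p(float("nan"))


class TestCombineP:
    def test_product_arithmetic(self):
        assert combine_p([1.0, 1.0, 1.0]) == 1.0
        assert combine_p([0.05, 0.05, 0.04]) == pytest.approx(1.0e-4)

    def test_missing_replicate_rejected(self):
        with pytest.raises(ValueError):
            combine_p([0.05, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combine_p([0.0, 0.5, 0.5])

    def test_null_distribution_matches_closed_form(self):
        # product of three uniforms: P(prod <= x) = x * sum_{j<3} (-ln x)^j / j!
        rng = np.random.default_rng(11)
        prods = rng.random((200_000, 3)).prod(axis=1)
        for x in (1e-4, 1e-3, 1e-2, 0.1):
            expected = product_null_cdf(x, k=3)
            observed = float((prods <= x).mean())
            sd = np.sqrt(expected * (1 - expected) / prods.size)
            assert abs(observed - expected) <= 3 * max(sd, 1e-7)

    def test_fisher_calibration_is_uniform_quantile(self):
        # chi2 with 6 df at -2*sum(log p): p=(0.5,0.5,0.5) has a known tail
        assert 0 < fisher_p([0.5, 0.5, 0.5]) < 1
        assert fisher_p([1.0, 1.0, 1.0]) == pytest.approx(1.0)


class TestClassifyBinders:
    def test_dual_threshold_examples(self):
        pa = pd.Series({"p1": 9e-5, "p2": 9e-5})
        pb = pd.Series({"p1": 9.9e-5, "p2": 2e-4})
        out = classify_binders(pa, pb, alpha=1e-4)
        assert bool(out.loc["p1", "classified"])
        assert not bool(out.loc["p2", "classified"])

    def test_rank_by_worst_set_with_id_ties(self):
        pa = pd.Series({"b": 1e-6, "a": 1e-6, "c": 1e-8})
        pb = pd.Series({"b": 1e-6, "a": 1e-6, "c": 1e-5})
        out = classify_binders(pa, pb)
        assert out.sort_values("rank").index.tolist() == ["a", "b", "c"]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.1, 1.0))
    def test_decreasing_p_never_removes_a_call(self, factor):
        pa = pd.Series({"x": 5e-5, "y": 2e-4})
        pb = pd.Series({"x": 8e-5, "y": 5e-5})
        before = classify_binders(pa, pb)["classified"]
        after = classify_binders(pa * factor, pb * factor)["classified"]
        assert (after | ~before).all()  # before => after

    def test_unscorable_protein_not_classified(self):
        pa = pd.Series({"x": 1e-9, "y": np.nan})
        pb = pd.Series({"x": 1e-9, "y": 1e-9})
        out = classify_binders(pa, pb)
        assert not bool(out.loc["y", "classified"])
        assert np.isnan(out.loc["y", "rank"])


class TestBindingScreenModel:
    def test_per_replicate_zscores_are_standardized(self, screen_set):
        res = BindingScreenModel(screen_set).fit()
        zcols = [c for c in res.table.columns if c.startswith("z_")]
        assert len(zcols) == 6
        for col in zcols:
            vals = res.table[col].dropna()
            assert abs(vals.mean()) < 1e-12
            assert abs(vals.std(ddof=0) - 1) < 1e-12

    def test_combined_is_product_of_replicate_ps(self, screen_set):
        res = BindingScreenModel(screen_set).fit()
        pa = res.table[[c for c in res.table.columns if c.startswith("p_A")]]
        np.testing.assert_allclose(
            res.table["combined_A"].dropna(),
            pa.prod(axis=1)[res.table["combined_A"].notna()],
            rtol=1e-12,
        )

    def test_protein_failing_filter_in_one_set_is_unclassifiable(self, screen_set):
        # make P0001 undetectable on one dye-set-B array
        screen_set.scans[5].features.loc[0, ["f_ch1", "f_ch2"]] = [100.0, 100.0]
        res = BindingScreenModel(screen_set).fit()
        row = res.table.loc["P0001"]
        assert np.isnan(row["combined_B"]) and not row["classified"]

    def test_dual_set_null_rate_closed_form(self):
        rate = dual_set_null_rate(1e-4)
        assert rate == pytest.approx(product_null_cdf(1e-4) ** 2, rel=1e-12)
        assert rate == pytest.approx(2.7694e-5, rel=1e-3)
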