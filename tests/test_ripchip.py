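from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import special

from screenkit.io import ExperimentSet
from screenkit.ripchip import (
    RipChipModel,
    default_min_count,
    enrichment_ttest,
    median_center,
    mock_correct,
    presence_filter,
    rank_genes,
    sam_two_class,
    summarize_hac1_probes,
)
from screenkit.simulate import simulate_ripchip

from conftest import scan_from_ratios


class TestMedianCenter:
    def test_examples(self):
        np.testing.assert_allclose(median_center(np.array([1.0, 2.0, 3.0])), [-1, 0, 1])
        np.testing.assert_allclose(median_center(np.array([5.0])), [0.0])

    def test_shift_invariance(self):
        x = np.array([0.4, -1.0, 2.2, 0.0])
        np.testing.assert_allclose(median_center(x + 7.3), median_center(x), atol=1e-12)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            median_center(np.array([np.nan, np.nan]))


class TestMockCorrect:
    def test_subtracts_mock_mean_gene_wise(self):
        ip = pd.DataFrame({"ip1": {"g1": 2.0}})
        mocks = pd.DataFrame({"m1": {"g1": 0.0}, "m2": {"g1": 1.0}})
        e, flag = mock_correct(ip, mocks)
        assert e.loc["g1", "ip1"] == pytest.approx(1.5)
        assert not flag["g1"]

    def test_zero_mocks_identity(self):
        ip = pd.DataFrame({"ip1": {"g1": 2.0, "g2": -1.0}})
        mocks = pd.DataFrame({"m1": {"g1": 0.0, "g2": 0.0}})
        e, _ = mock_correct(ip, mocks)
        pd.testing.assert_frame_equal(e, ip)

    def test_constant_shift_invariance(self):
        ip = pd.DataFrame({"ip1": {"g1": 2.0, "g2": 0.5}})
        mocks = pd.DataFrame({"m1": {"g1": 0.2, "g2": 0.1}})
        e1, _ = mock_correct(ip, mocks)
        e2, _ = mock_correct(ip + 3.0, mocks + 3.0)
        pd.testing.assert_frame_equal(e1, e2)

    def test_gene_without_mock_flagged(self):
        ip = pd.DataFrame({"ip1": {"g1": 2.0, "g2": 1.0}})
        mocks = pd.DataFrame({"m1": {"g1": 0.5}})
        e, flag = mock_correct(ip, mocks)
        assert flag["g2"] and e.loc["g2", "ip1"] == 1.0

    def test_no_mocks_is_error(self):
        with pytest.raises(ValueError):
            mock_correct(pd.DataFrame({"ip1": {"g1": 1.0}}), pd.DataFrame(index=["g1"]))


def _presence_set(pass_counts, n_arrays):
    """Arrays where gene i is detectable in exactly pass_counts[i] scans."""
    scans = []
    for a in range(n_arrays):
        ratios = np.zeros(len(pass_counts))
        scan = scan_from_ratios(ratios, array_id=f"arr{a}")
        for g, cnt in enumerate(pass_counts):
            if a >= cnt:  # undetectable in this array
                scan.features.loc[g, ["f_ch1", "f_ch2"]] = 100.0
        scans.append(scan)
    return ExperimentSet(scans=scans, design="ripchip")


class TestPresenceFilter:
    def test_nine_of_twelve_rule(self):
        es = _presence_set([9, 8], n_arrays=12)
        mask = presence_filter(es, min_count=9)
        assert bool(mask.iloc[0]) and not bool(mask.iloc[1])

    def test_strict_majority_default_for_small_designs(self):
        assert default_min_count(4) == 3
        assert default_min_count(12) == 9
        es = _presence_set([3, 2], n_arrays=4)
        mask = presence_filter(es)  # >50% of 4 arrays -> 3
        assert bool(mask.iloc[0]) and not bool(mask.iloc[1])

    def test_parameter_errors(self):
        es = _presence_set([2], n_arrays=3)
        with pytest.raises(ValueError):
            presence_filter(es, min_count=0)
        with pytest.raises(ValueError):
            presence_filter(es, min_count=4)


class TestEnrichmentTTest:
    def test_one_sample_against_reference_cdf(self):
        t, p = enrichment_ttest([1.0, 2.0, 3.0], "greater")
        assert t == pytest.approx(3.4641016, rel=1e-6)
        # independent oracle: regularized incomplete beta form of the t tail
        oracle = special.stdtr(2, -t)
        assert p == pytest.approx(oracle, abs=1e-8)
        assert p == pytest.approx(0.0371, abs=2e-4)

    def test_near_zero_signal_is_coin_flip(self):
        _, p = enrichment_ttest([0.0, 0.001, -0.001], "greater")
        assert p == pytest.approx(0.5, abs=1e-3)

    def test_tail_complementarity(self):
        x = [0.4, 1.1, -0.2, 0.9]
        _, pg = enrichment_ttest(x, "greater")
        _, pl = enrichment_ttest(x, "less")
        assert pg + pl == pytest.approx(1.0, abs=1e-12)

    def test_two_sample_welch_matches_oracle(self):
        a, b = [1.0, 1.4, 0.8, 1.2], [0.1, -0.2, 0.3, 0.0]
        t, p = enrichment_ttest(a, "greater", group_b=b)
        va, vb = np.var(a, ddof=1) / 4, np.var(b, ddof=1) / 4
        t_oracle = (np.mean(a) - np.mean(b)) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        assert t == pytest.approx(t_oracle, rel=1e-10)
        assert p == pytest.approx(special.stdtr(df, -t_oracle), abs=1e-8)

    def test_insufficient_replicates(self):
        with pytest.raises(ValueError):
            enrichment_ttest([1.0, 2.0])
        with pytest.raises(ValueError):
            enrichment_ttest([1.0, 1.0, 1.0])


def _brute_force_sam(A, B, s0=None):
    """Independent enumeration oracle for small designs (all label splits)."""
    X = np.hstack([A, B])
    na = A.shape[1]
    n = X.shape[1]

    def dstat(cols_a, s0_val):
        a = X[:, list(cols_a)]
        b = X[:, [c for c in range(n) if c not in cols_a]]
        ma, mb = a.mean(1), b.mean(1)
        sp = np.sqrt(
            (1 / a.shape[1] + 1 / b.shape[1])
            * (((a.T - ma).T ** 2).sum(1) + ((b.T - mb).T ** 2).sum(1))
            / (n - 2)
        )
        return (ma - mb) / (sp + s0_val), sp

    obs_cols = tuple(range(na))
    _, sp = dstat(obs_cols, 0.0)
    s0_val = np.median(sp) if s0 is None else s0
    d_obs, _ = dstat(obs_cols, s0_val)
    perm_ds = [dstat(c, s0_val)[0] for c in combinations(range(n), na)]
    q = np.empty_like(d_obs)
    for i, di in enumerate(np.abs(d_obs)):
        r = (np.abs(d_obs) >= di).sum()
        v = np.median([(np.abs(dp) >= di).sum() for dp in perm_ds])
        q[i] = min(v / r, 1.0)
    # monotonize: larger |d| never has larger q
    order = np.argsort(np.abs(d_obs))[::-1]
    q_sorted = np.minimum.accumulate(q[order][::-1])[::-1]
    out = np.empty_like(q)
    out[order] = q_sorted
    return d_obs, out


class TestSamTwoClass:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(3)
        A = pd.DataFrame(rng.normal(0, 1, (50, 3)))
        res = sam_two_class(A, A.copy(), n_perm=100, seed=0)
        np.testing.assert_allclose(res.d, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.q, 1.0, atol=1e-12)

    def test_label_exchange_negates_d(self):
        rng = np.random.default_rng(4)
        A = pd.DataFrame(rng.normal(0, 1, (40, 3)))
        B = pd.DataFrame(rng.normal(0.5, 1, (40, 3)))
        r1 = sam_two_class(A, B, n_perm=100, seed=5)
        r2 = sam_two_class(B, A, n_perm=100, seed=5)
        np.testing.assert_allclose(r1.d, -r2.d, atol=1e-12)

    def test_matches_full_enumeration_oracle_on_toy(self):
        rng = np.random.default_rng(6)
        A = pd.DataFrame(rng.normal(0, 1, (100, 3)))
        B = pd.DataFrame(rng.normal(0, 1, (100, 3)))
        A.iloc[0] += 8.0  # one hugely separated gene
        res = sam_two_class(A, B, n_perm=100, seed=0)  # C(6,3)=20 -> enumerated
        d_oracle, q_oracle = _brute_force_sam(A.to_numpy(), B.to_numpy())
        np.testing.assert_allclose(res.d, d_oracle, atol=1e-10)
        np.testing.assert_allclose(res.q, q_oracle, atol=1e-10)
        assert res.q.iloc[0] == res.q.min()

    def test_degenerate_group_rejected(self):
        A = pd.DataFrame(np.ones((5, 1)))
        B = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError):
            sam_two_class(A, B)


class TestRankGenes:
    def test_descending_mean_with_id_ties(self):
        e = pd.DataFrame({"r1": {"g1": 2.0, "g2": 0.0, "g3": 1.0}})
        out = rank_genes(e)
        assert out.index.tolist() == ["g1", "g3", "g2"]
        assert out["rank"].tolist() == [1, 2, 3]

    def test_invariant_to_experiment_order(self):
        rng = np.random.default_rng(8)
        e = pd.DataFrame(rng.normal(0, 1, (20, 4)), columns=list("abcd"))
        r1 = rank_genes(e)
        r2 = rank_genes(e[["d", "b", "a", "c"]])
        pd.testing.assert_frame_equal(r1, r2)


class TestProbeSummary:
    def test_class_means_and_aggregates(self):
        e = pd.DataFrame(
            {"r1": {"u1": 1.9, "u2": 2.3, "i": 1.9, "o": 1.0, "s": 0.1},
             "r2": {"u1": 2.1, "u2": 2.5, "i": 2.1, "o": 1.2, "s": -0.1}}
        )
        ann = {"u1": "unspliced_jxn_1", "u2": "unspliced_jxn_2", "i": "intron",
               "o": "ORF", "s": "spliced_jxn"}
        summ = summarize_hac1_probes(e, ann)
        assert summ.per_class.loc["intron", "mean_enrichment"] == pytest.approx(2.0)
        assert len(summ.per_class) == 5
        assert summ.unspliced_mean == pytest.approx(np.mean([1.9, 2.1, 2.3, 2.5, 1.9, 2.1]))
        assert summ.spliced_mean == pytest.approx(0.0)

    def test_empty_class_reported_missing(self):
        e = pd.DataFrame({"r1": {"i": 2.0}})
        summ = summarize_hac1_probes(e, {"i": "intron"})
        assert np.isnan(summ.per_class.loc["ORF", "mean_enrichment"])

    def test_unannotated_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_hac1_probes(pd.DataFrame({"r1": {"g": 1.0}}), {"g": "na"})


class TestRipChipModel:
    def test_spiked_unspliced_probes_dominate_spliced(self):
        es, _ = simulate_ripchip(
            n_genes=300, noise_sd=0.3, seed=9,
            hac1_probe_effects={"unspliced_jxn_1": 2.0, "unspliced_jxn_2": 2.0,
                                "intron": 2.0, "ORF": 1.0, "spliced_jxn": 0.0},
        )
        res = RipChipModel(es).fit()
        summ = res.hac1_summary()
        assert summ.unspliced_mean > summ.spliced_mean + 1.0

    def test_zero_noise_enrichment_equals_effect(self):
        # background=0 so raw-foreground ratios carry no additive compression
        es, truth = simulate_ripchip(
            n_genes=100, enriched_set=3, effect=2.0, noise_sd=0.0,
            array_offset_sd=0.0, baseline_sd=0.0, background=0.0, seed=1,
        )
        res = RipChipModel(es).fit()
        spiked = res.enrichment.loc[list(truth.truth_set)]
        # median centering over 100 genes with 3 spiked leaves nulls at 0
        np.testing.assert_allclose(spiked.to_numpy(), 2.0, atol=1e-9)

    def test_requires_mock_arrays(self):
        es, _ = simulate_ripchip(n_genes=20, n_ip=3, n_mock=3, seed=2)
        es.groups = {aid: "IP" for aid in es.groups}
        with pytest.raises(ValueError, match="Mock"):
            RipChipModel(es)
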