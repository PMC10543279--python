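import numpy as np
import pandas as pd
import pytest

from gcnbsd import stats
from gcnbsd.fnc import default_atlas
from gcnbsd.simulate import GeneratorConfig, generate_cohort


def t_oracle(a, b):
    """Textbook pooled two-sample t."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    return (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))


class TestTwoSampleT:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p, df = stats.two_sample_t(a, a)
        assert t == 0.0 and p == pytest.approx(1.0) and df == 4

    def test_matches_textbook_oracle(self):
        a = np.array([0.0, 0.0, 0.0, 1.0])
        b = np.array([1.0, 1.0, 1.0, 0.0])
        t, p, df = stats.two_sample_t(a, b)
        assert t == pytest.approx(t_oracle(a, b), abs=1e-12)
        assert df == 6

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=5)
        t1, p1, _ = stats.two_sample_t(a, b)
        t2, p2, _ = stats.two_sample_t(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            stats.two_sample_t([1.0, 1.0], [2.0, 2.0])


class TestSummaryPath:
    def test_equal_means_give_zero(self):
        a = stats.SummaryStats("a", 4, 1.0, 1.0)
        b = stats.SummaryStats("b", 4, 1.0, 2.0)
        assert stats.two_sample_t_from_summary(a, b)[0] == 0.0

    def test_closed_form_sqrt2(self):
        a = stats.SummaryStats("a", 4, 1.0, 1.0)
        b = stats.SummaryStats("b", 4, 0.0, 1.0)
        t, _, df = stats.two_sample_t_from_summary(a, b)
        assert t == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert df == 6

    def test_raw_and_summary_paths_agree(self, rng):
        for _ in range(10):
            a = rng.normal(size=rng.integers(5, 20))
            b = rng.normal(loc=0.5, size=rng.integers(5, 20))
            sa = stats.SummaryStats("a", len(a), a.mean(), a.std(ddof=1))
            sb = stats.SummaryStats("b", len(b), b.mean(), b.std(ddof=1))
            t_raw, p_raw, _ = stats.two_sample_t(a, b)
            t_sum, p_sum, _ = stats.two_sample_t_from_summary(sa, sb)
            assert t_raw == pytest.approx(t_sum, abs=1e-10)
            assert p_raw == pytest.approx(p_sum, abs=1e-10)


class TestCohensD:
    def test_equal_means_zero(self):
        a = stats.SummaryStats("a", 10, 5.0, 2.0)
        b = stats.SummaryStats("b", 10, 5.0, 3.0)
        assert stats.cohens_d_from_summary(a, b) == 0.0

    def test_rms_standardizer_closed_form(self):
        a = stats.SummaryStats("a", 10, 1.0, 3.0)
        b = stats.SummaryStats("b", 40, 0.0, 4.0)
        # rms denominator sqrt((9+16)/2); unaffected by group sizes
        assert stats.cohens_d_from_summary(a, b) == pytest.approx(
            1.0 / np.sqrt(12.5), abs=1e-12)

    def test_pooled_variant_weights_by_n(self):
        a = stats.SummaryStats("a", 100, 1.0, 1.0)
        b = stats.SummaryStats("b", 2, 0.0, 5.0)
        pooled_sd = np.sqrt((99 * 1 + 1 * 25) / 100)
        assert stats.cohens_d_from_summary(a, b, method="pooled") == \
            pytest.approx(1.0 / pooled_sd, abs=1e-12)

    def test_zero_sds_rejected(self):
        a = stats.SummaryStats("a", 3, 1.0, 0.0)
        with pytest.raises(ValueError):
            stats.cohens_d_from_summary(a, a)


class TestEdgeTTests:
    def test_planted_edge_attains_max_t(self, rng):
        x = rng.normal(size=(40, 50))
        x[:20, 17] += 3.0
        out = stats.edge_ttests(x, np.arange(20), np.arange(20, 40))
        assert out["t"].abs().idxmax() == 17

    def test_subject_permutation_invariance(self, rng):
        x = rng.normal(size=(20, 10))
        a, b = np.arange(10), np.arange(10, 20)
        t1 = stats.edge_ttests(x, a, b)["t"]
        perm_a = rng.permutation(a)
        perm_b = rng.permutation(b)
        t2 = stats.edge_ttests(x, perm_a, perm_b)["t"]
        assert np.allclose(t1, t2)

    def test_overlapping_groups_rejected(self, rng):
        x = rng.normal(size=(10, 5))
        with pytest.raises(ValueError, match="disjoint"):
            stats.edge_ttests(x, [0, 1], [1, 2])

    def test_degenerate_edge_flagged_not_fatal(self, rng):
        x = rng.normal(size=(10, 3))
        x[:, 1] = 7.0
        out = stats.edge_ttests(x, np.arange(5), np.arange(5, 10))
        assert not out["valid"][1]
        assert out["valid"][[0, 2]].all()

    def test_atlas_annotation(self, rng):
        atlas = default_atlas()
        x = rng.normal(size=(10, 1378))
        out = stats.edge_ttests(x, np.arange(5), np.arange(5, 10), atlas=atlas)
        assert out.iloc[0][["icn_i", "icn_j"]].tolist() == [1, 2]
        assert out.iloc[0]["network_i"] == "SC"
        assert out.iloc[-1][["network_i", "network_j"]].tolist() == ["CB", "CB"]


class TestTopK:
    def test_sort_oracle_with_ties(self):
        t = np.array([0.5, -2.0, 2.0, 1.0, -1.0])
        table = pd.DataFrame({"edge": np.arange(5), "t": t,
                              "valid": [True] * 5})
        out = stats.top_k_edges(table, k=3)
        # |t| ties between edges 1 and 2 -> lower index kept first
        assert sorted(out[out["selected"]]["edge"]) == [1, 2, 3]

    def test_select_all_is_identity(self, rng):
        table = pd.DataFrame({"edge": np.arange(10),
                              "t": rng.normal(size=10), "valid": True})
        out = stats.top_k_edges(table, k=10)
        assert out["selected"].all()

    def test_invalid_k_rejected(self):
        table = pd.DataFrame({"edge": [0, 1], "t": [1.0, 2.0], "valid": True})
        for k in (0, 3):
            with pytest.raises(ValueError):
                stats.top_k_edges(table, k=k)

    def test_stable_under_monotone_transform(self, rng):
        t = rng.normal(size=40)
        base = pd.DataFrame({"edge": np.arange(40), "t": t, "valid": True})
        cubed = base.assign(t=np.sign(t) * np.abs(t) ** 3)
        sel1 = stats.top_k_edges(base, 10)["selected"]
        sel2 = stats.top_k_edges(cubed, 10)["selected"]
        assert sel1.equals(sel2)


class TestOverlapAndScales:
    def test_overlap_cases(self, rng):
        a = np.arange(100)
        assert len(stats.edge_overlap(a, a)) == 100
        assert len(stats.edge_overlap(a, a + 200)) == 0
        b = rng.choice(1378, size=100, replace=False)
        c = rng.choice(1378, size=100, replace=False)
        assert np.array_equal(stats.edge_overlap(b, c),
                              np.array(sorted(set(b) & set(c))))
        assert np.array_equal(stats.edge_overlap(b, c), stats.edge_overlap(c, b))

    def test_scale_correlation_affine_and_oracle(self, rng):
        edge = rng.normal(size=(30, 1))
        scales = pd.DataFrame({"lin": 2.0 * edge[:, 0] - 1.0,
                               "noise": rng.normal(size=30)})
        out = stats.scale_correlations(edge, scales)
        lin = out[out["scale"] == "lin"].iloc[0]
        assert abs(lin["r"]) == pytest.approx(1.0)
        noise = out[out["scale"] == "noise"].iloc[0]
        x, s = edge[:, 0], scales["noise"].to_numpy()
        xc, sc_ = x - x.mean(), s - s.mean()
        assert noise["r"] == pytest.approx(
            np.sum(xc * sc_) / np.sqrt(np.sum(xc ** 2) * np.sum(sc_ ** 2)),
            abs=1e-12)

    def test_missing_values_dropped_pairwise(self, rng):
        edge = rng.normal(size=(10, 1))
        s = pd.DataFrame({"partial": [1.0, 2.0, np.nan, 4.0, 5.0,
                                      np.nan, 7.0, 8.0, 9.0, 10.0]})
        out = stats.scale_correlations(edge, s)
        assert out.iloc[0]["n"] == 8

    def test_constant_scale_flagged(self, rng):
        edge = rng.normal(size=(10, 1))
        out = stats.scale_correlations(edge, pd.DataFrame({"const": np.ones(10)}))
        assert not out.iloc[0]["valid"]


class TestBonferroni:
    def test_scaling_and_cap(self):
        assert stats.bonferroni([0.01], m=10)[0] == pytest.approx(0.1)
        assert stats.bonferroni([0.5], m=10)[0] == 1.0

    def test_elementwise_oracle(self, rng):
        p = rng.uniform(0.001, 1.0, size=20)
        assert np.allclose(stats.bonferroni(p), np.minimum(1.0, 20 * p))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            stats.bonferroni([0.0])
        with pytest.raises(ValueError):
            stats.bonferroni([0.1, 0.2], m=1)


class TestNullCalibration:
    def test_split_of_identical_population(self, mini_atlas7):
        """Two random halves of the control group should show ~5% of edges
        with p < 0.05."""
        cohort = generate_cohort(GeneratorConfig(
            seed=11, atlas=mini_atlas7, n_hc=80, n_biotype1=2, n_biotype2=2))
        hc = np.flatnonzero(cohort.true_labels == 0)
        out = stats.edge_ttests(cohort.fnc, hc[:40], hc[40:])
        frac = float((out["p"] < 0.05).mean())
        # binomial 99.9% envelope around 0.05 with 91 edges
        bound = 3.29 * np.sqrt(0.05 * 0.95 / len(out))
        assert abs(frac - 0.05) < bound + 1e-9


def test_reference_summaries_load():
    for cohort, n in [("abcd", 7), ("pku", 5)]:
        table = stats.load_reference_summaries(cohort)
        assert len(table) == n
        assert {"measure", "n_biotype1", "mean_biotype1", "sd_biotype1",
                "n_biotype2", "mean_biotype2", "sd_biotype2"} <= set(table.columns)
    with pytest.raises(ValueError):
        stats.load_reference_summaries("ukb")
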