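"""cPGS arithmetic, standardization, distribution tests, decile overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ckdclust.scores import (
    ad_normality,
    compute_cpgs,
    decile_membership,
    mw_test,
    standardize_cpgs,
)


def frame(data, cols):
    return pd.DataFrame(data, index=[f"I{i}" for i in range(len(data))], columns=cols)


class TestComputeCpgs:
    def test_weighted_sum(self):
        d = frame([[1.0, 2.0]], ["v1", "v2"])
        w = pd.DataFrame([[2.0, 0.5]], index=["C0"], columns=["v1", "v2"])
        raw, _ = compute_cpgs(d, w)
        assert raw.loc["I0", "C0"] == pytest.approx(3.0)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(1)
        d = frame(rng.integers(0, 3, (20, 5)).astype(float), [f"v{i}" for i in range(5)])
        w = pd.DataFrame(rng.uniform(0, 2, (2, 5)), index=["C0", "C1"],
                         columns=d.columns)
        raw1, _ = compute_cpgs(d, w)
        raw2, _ = compute_cpgs(d, 2.0 * w)
        pd.testing.assert_frame_equal(raw2, 2.0 * raw1)

    def test_missing_dosage_mean_imputed(self):
        d = frame([[0.0], [2.0], [np.nan], [1.6]], ["v1"])
        w = pd.DataFrame([[2.0]], index=["C0"], columns=["v1"])
        raw, _ = compute_cpgs(d, w)
        assert raw.loc["I2", "C0"] == pytest.approx(2.0 * 1.2)

    def test_additivity_over_variant_partitions(self):
        rng = np.random.default_rng(2)
        cols = [f"v{i}" for i in range(10)]
        d = frame(rng.integers(0, 3, (30, 10)).astype(float), cols)
        w = pd.DataFrame(rng.uniform(0.1, 2, (3, 10)), index=["A", "B", "C"], columns=cols)
        full, _ = compute_cpgs(d, w)
        part1, _ = compute_cpgs(d[cols[:4]], w[cols[:4]])
        part2, _ = compute_cpgs(d[cols[4:]], w[cols[4:]])
        pd.testing.assert_frame_equal(full, part1 + part2)

    def test_absent_variants_dropped_and_counted(self):
        d = frame([[1.0], [2.0]], ["v1"])
        w = pd.DataFrame([[1.0, 5.0]], index=["C0"], columns=["v1", "vMissing"])
        raw, log = compute_cpgs(d, w)
        assert log["dropped_variants"] == 1
        assert raw.loc["I1", "C0"] == pytest.approx(2.0)

    def test_no_overlap_errors_naming_cluster(self):
        d = frame([[1.0]], ["v1"])
        w = pd.DataFrame([[1.0]], index=["LONELY"], columns=["vX"])
        with pytest.raises(ValueError, match="LONELY"):
            compute_cpgs(d, w)

    def test_allele_flip(self):
        d = frame([[2.0]], ["v1"])
        w = pd.DataFrame([[1.0]], index=["C0"], columns=["v1"])
        raw, _ = compute_cpgs(
            d, w,
            effect_alleles=pd.Series({"v1": "A"}),
            panel_alleles=pd.Series({"v1": "G"}),
        )
        assert raw.loc["I0", "C0"] == pytest.approx(0.0)  # 2 - 2


class TestStandardize:
    def test_three_point_closed_form(self):
        raw = frame([[1.0], [2.0], [3.0]], ["C0"])
        z = standardize_cpgs(raw)
        np.testing.assert_allclose(z["C0"].to_numpy(), [-1.0, 0.0, 1.0])
        # sample SD convention: rescaling by the computed SD reproduces
        # the +-1.2247 population-SD z of 3 equally spaced points
        sd = raw["C0"].std(ddof=1)
        pop = z["C0"].to_numpy() * sd / raw["C0"].std(ddof=0)
        np.testing.assert_allclose(pop, [-1.22474487, 0.0, 1.22474487])

    def test_constant_scores_error(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_cpgs(frame([[1.0], [1.0], [1.0]], ["C0"]))

    def test_mean_zero_sd_one(self, scored_cohort):
        _, _, z = scored_cohort
        assert z.mean().abs().max() < 1e-8
        assert (z.std(ddof=1) - 1).abs().max() < 1e-8

    def test_pooled_standardization_for_subgroups(self):
        rng = np.random.default_rng(3)
        raw = frame(rng.normal(10, 2, (100, 1)), ["C0"])
        z_all = standardize_cpgs(raw)
        z_ref = standardize_cpgs(raw, cohort=raw.index[:50])
        # same transform applied to everyone, anchored on the subset
        sub = raw.iloc[:50]
        np.testing.assert_allclose(
            z_ref["C0"].iloc[:50].mean(), 0.0, atol=1e-12
        )
        assert not np.allclose(z_all["C0"], z_ref["C0"])


class TestAndersonDarling:
    def test_type_i_error_on_normal_samples(self):
        rng = np.random.default_rng(4)
        rejections = sum(
            ad_normality(rng.normal(0, 1, 5000))[1] <= 0.05 for _ in range(100)
        )
        assert rejections <= 10  # ~5 expected; allow slack

    def test_bimodal_strongly_rejected(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-3, 1, 1000), rng.normal(3, 1, 1000)])
        _, p = ad_normality(x)
        assert p < 0.001

    def test_statistic_matches_scipy(self):
        import warnings

        from scipy import stats as st

        x = np.random.default_rng(6).normal(0, 1, 500)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sp = st.anderson(x, "norm").statistic
        a2_star, _ = ad_normality(x)
        assert a2_star == pytest.approx(sp * (1 + 0.75 / 500 + 2.25 / 500**2), rel=1e-10)

    def test_small_n_and_constant_rejected(self):
        with pytest.raises(ValueError):
            ad_normality(np.arange(7))
        with pytest.raises(ValueError):
            ad_normality(np.full(20, 3.0))


def mw_enumeration_oracle(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group splits."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    def u_of(idx):
        ra = sum(ranks[pooled[i]] for i in idx)
        return ra - n_a * (n_a + 1) / 2
    u_obs = u_of(range(n_a))
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n_a)]
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(p, 1.0)


class TestMannWhitney:
    def test_textbook_example(self):
        u, p = mw_test([1, 2], [3, 4])
        assert u == 0 and p == pytest.approx(2 / 6)

    def test_identical_groups_p_one(self):
        u, p = mw_test([1, 4, 7], [2, 5, 8])
        uo, po = mw_enumeration_oracle(np.array([1, 4, 7]), np.array([2, 5, 8]))
        assert p == pytest.approx(po)

    def test_matches_enumeration_small_samples(self):
        rng = np.random.default_rng(7)
        for n_a, n_b in [(2, 3), (3, 3), (4, 3), (4, 4)]:
            x = rng.permutation(np.arange(1.0, n_a + n_b + 1.0))
            a, b = x[:n_a], x[n_a:]
            u, p = mw_test(a, b)
            uo, po = mw_enumeration_oracle(a, b)
            assert u == pytest.approx(uo)
            assert p == pytest.approx(po)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        pool=st.sets(st.integers(-500, 500), min_size=4, max_size=14),
        split=st.integers(2, 12),
    )
    def test_monotone_transform_invariance(self, pool, split):
        vals = sorted(pool)
        n_a = min(max(2, split), len(vals) - 2)
        a, b = np.array(vals[:n_a], float), np.array(vals[n_a:], float)
        u1, p1 = mw_test(a, b)
        f = lambda x: np.exp(np.asarray(x) / 250.0)
        u2, p2 = mw_test(f(a), f(b))
        assert u1 == pytest.approx(u2)
        assert p1 == pytest.approx(p2)


class TestDecileMembership:
    def test_single_cluster_distinct_scores_flags_ten_percent(self):
        z = frame(np.arange(100.0)[:, None], ["C0"])
        s = decile_membership(z)
        assert (s.counts >= 1).sum() == 10
        assert s.fraction_at_least_one == pytest.approx(0.10)

    def test_independent_uniform_matches_closed_form(self):
        rng = np.random.default_rng(8)
        z = frame(rng.uniform(0, 1, (50_000, 9)), [f"C{k}" for k in range(9)])
        s = decile_membership(z)
        assert s.fraction_at_least_one == pytest.approx(1 - 0.9**9, abs=0.02)

    def test_comonotone_clusters_fraction_ten_percent(self):
        base = np.random.default_rng(9).normal(0, 1, 1000)
        z = frame(np.column_stack([base, 2 * base, base + 5]), ["a", "b", "c"])
        s = decile_membership(z)
        assert s.fraction_at_least_one == pytest.approx(0.10, abs=1e-9)

    def test_distribution_sums_to_one(self, scored_cohort):
        _, _, z = scored_cohort
        s = decile_membership(z)
        assert sum(s.count_distribution.values()) == pytest.approx(1.0)

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            decile_membership(frame(np.arange(5.0)[:, None], ["C0"]))
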