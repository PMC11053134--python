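"""Phecode construction, Bonferroni alpha, regression harness."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from ckdclust.phewas import (
    PhenotypeSet,
    compute_alpha,
    map_phecodes,
    results_to_frame,
    run_phewas,
    validate_top_traits,
)


class TestMapPhecodes:
    @pytest.fixture()
    def code_map(self):
        return pd.DataFrame({"icd_code": ["SYN000"], "phecode": ["PC000"]})

    def test_two_events_is_case(self, code_map):
        ev = pd.DataFrame({"individual_id": ["a", "a"], "code": ["SYN000"] * 2})
        binary, _ = map_phecodes(ev, code_map, ["a", "b"])
        assert binary.loc["a", "PC000"] == 1.0
        assert binary.loc["b", "PC000"] == 0.0

    def test_one_event_excluded(self, code_map):
        ev = pd.DataFrame({"individual_id": ["a"], "code": ["SYN000"]})
        binary, _ = map_phecodes(ev, code_map, ["a"])
        assert np.isnan(binary.loc["a", "PC000"])

    def test_unmapped_codes_logged(self, code_map):
        ev = pd.DataFrame({"individual_id": ["a"], "code": ["UNKNOWN"]})
        binary, log = map_phecodes(ev, code_map, ["a"])
        assert log["unmapped_codes"] == ["UNKNOWN"]


class TestAlpha:
    def test_paper_scale_family(self):
        alpha = compute_alpha(9, 988, 832, 0.05)
        assert alpha == pytest.approx(0.05 / (9 * 1820))
        # 2 significant figures
        assert float(f"{alpha:.1e}") == 3.1e-06

    @pytest.mark.parametrize(
        "args,expected", [((1, 1, 0, 0.05), 0.05), ((2, 5, 5, 0.05), 2.5e-3)]
    )
    def test_simple_families(self, args, expected):
        assert compute_alpha(*args) == pytest.approx(expected)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            compute_alpha(0, 0, 0)


def _covariates(rng, n, index):
    cov = pd.DataFrame(
        {"sex": rng.integers(0, 2, n), "age": rng.uniform(20, 80, n)}, index=index
    )
    for k in range(10):
        cov[f"PC{k + 1}"] = rng.normal(0, 1, n)
    return cov


class TestRunPhewas:
    def test_planted_quantitative_effect_recovered(self):
        rng = np.random.default_rng(1)
        n = 5000
        idx = [f"I{i}" for i in range(n)]
        z = pd.DataFrame({"C0": rng.normal(0, 1, n)}, index=idx)
        y = 0.3 * z["C0"] + rng.normal(0, np.sqrt(1 - 0.09), n)
        phenos = PhenotypeSet(
            quantitative=pd.DataFrame({"trait": y}),
            binary=pd.DataFrame(index=idx),
            covariates=_covariates(rng, n, idx),
        )
        (res,) = run_phewas(z, phenos, alpha=3.05e-6)
        assert 0.25 <= res.estimate <= 0.35
        assert res.p < 3.05e-6 and res.significant

    def test_standardized_beta_equals_correlation_without_covariates(self):
        rng = np.random.default_rng(2)
        n = 800
        idx = [f"I{i}" for i in range(n)]
        z = pd.DataFrame({"C0": rng.normal(0, 1, n)}, index=idx)
        y = 0.4 * z["C0"] + rng.normal(0, 1, n)
        phenos = PhenotypeSet(
            quantitative=pd.DataFrame({"trait": y}),
            binary=pd.DataFrame(index=idx),
            covariates=pd.DataFrame(index=idx),
        )
        (res,) = run_phewas(z, phenos, alpha=0.05)
        r, _ = pearsonr(z["C0"], y)
        assert res.estimate == pytest.approx(r, abs=1e-8)

    def test_logistic_or_matches_contingency_table(self):
        # binary exposure (z in {0,1}), no covariates: OR == ad/bc
        a, b, c, d = 40, 60, 25, 75  # exposed cases/controls, unexposed
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d, float)
        x = np.array([1] * (a + b) + [0] * (c + d), float)
        idx = [f"I{i}" for i in range(len(y))]
        z = pd.DataFrame({"C0": x}, index=idx)
        phenos = PhenotypeSet(
            quantitative=pd.DataFrame(index=idx),
            binary=pd.DataFrame({"D": y}, index=idx),
            covariates=pd.DataFrame(index=idx),
        )
        (res,) = run_phewas(z, phenos, alpha=0.05)
        # undo the z-scoring of the exposure to recover the per-unit OR
        or_per_unit = np.exp(np.log(res.estimate) / x.std(ddof=1))
        assert or_per_unit == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_trait_below_min_n_skipped(self):
        rng = np.random.default_rng(3)
        n = 300
        idx = [f"I{i}" for i in range(n)]
        z = pd.DataFrame({"C0": rng.normal(0, 1, n)}, index=idx)
        sparse = pd.Series(rng.normal(0, 1, n), index=idx)
        sparse.iloc[99:] = np.nan  # measured in 99 individuals
        phenos = PhenotypeSet(
            quantitative=pd.DataFrame({"dense": rng.normal(0, 1, n), "sparse": sparse},
                                      index=idx),
            binary=pd.DataFrame(index=idx),
            covariates=_covariates(rng, n, idx),
        )
        res = run_phewas(z, phenos, min_n=100, alpha=0.05)
        assert [r.trait for r in res] == ["dense"]

    def test_binary_min_cases_rule(self):
        rng = np.random.default_rng(4)
        n = 500
        idx = [f"I{i}" for i in range(n)]
        z = pd.DataFrame({"C0": rng.normal(0, 1, n)}, index=idx)
        rare = pd.Series(0.0, index=idx)
        rare.iloc[:10] = 1.0  # 10 cases < 20
        common = pd.Series(0.0, index=idx)
        common.iloc[:50] = 1.0
        phenos = PhenotypeSet(
            quantitative=pd.DataFrame(index=idx),
            binary=pd.DataFrame({"rare": rare, "common": common}),
            covariates=_covariates(rng, n, idx),
        )
        res = run_phewas(z, phenos, alpha=0.05)
        assert [r.trait for r in res] == ["common"]

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(5)
        n = 1000
        idx = [f"I{i}" for i in range(n)]
        z = pd.DataFrame({"C0": rng.normal(0, 1, n)}, index=idx)
        quant = pd.DataFrame(rng.normal(0, 1, (n, 300)),
                             columns=[f"t{j}" for j in range(300)], index=idx)
        phenos = PhenotypeSet(quant, pd.DataFrame(index=idx), _covariates(rng, n, idx))
        res = run_phewas(z, phenos, alpha=0.05)
        frac = np.mean([r.p < 0.05 for r in res])
        half = 2.576 * np.sqrt(0.05 * 0.95 / 300)
        assert abs(frac - 0.05) <= half

    def test_alpha_recomputed_matches_compute_alpha(self, scored_cohort):
        geno, pheno, z = scored_cohort
        binary, _ = map_phecodes(pheno.code_events, pheno.phecode_map, z.index)
        phenos = PhenotypeSet(pheno.quantitative, binary, pheno.covariates)
        res = run_phewas(z, phenos)
        n_quant = len({r.trait for r in res if r.trait_type == "quantitative"})
        n_bin = len({r.trait for r in res if r.trait_type == "binary"})
        alpha = compute_alpha(z.shape[1], n_quant, n_bin)
        for r in res:
            assert r.significant == (r.p < alpha)


class TestValidateTopTraits:
    def _result(self, **kw):
        from ckdclust.phewas import PhewasResult

        base = dict(cluster_id="C0", trait="T", trait_type="quantitative",
                    estimate=0.1, ci95=(0.05, 0.15), p=1e-8, n=1000,
                    n_cases=None, significant=True)
        base.update(kw)
        return PhewasResult(**base)

    def test_sign_and_significance_rule(self):
        res = [self._result()]
        tab = validate_top_traits(res, {"C0": [("T", "+")]})
        assert tab.validated.all()
        tab = validate_top_traits([self._result(significant=False, p=0.5)],
                                  {"C0": [("T", "+")]})
        assert not tab.validated.any()
        tab = validate_top_traits([self._result(estimate=-0.1)], {"C0": [("T", "+")]})
        assert not tab.validated.any()

    def test_binary_direction_uses_log_or(self):
        res = [self._result(trait_type="binary", estimate=1.2, ci95=(1.1, 1.3))]
        tab = validate_top_traits(res, {"C0": [("T", "+")]})
        assert tab.validated.all()
        res = [self._result(trait_type="binary", estimate=0.8, ci95=(0.7, 0.9))]
        tab = validate_top_traits(res, {"C0": [("T", "-")]})
        assert tab.validated.all()

    def test_unmatched_traits_flagged(self):
        tab = validate_top_traits([self._result()], {"C0": [("Unknown trait", "+")]})
        assert not tab.matched.any() and not tab.validated.any()

    def test_synonym_map_used(self):
        tab = validate_top_traits(
            [self._result(trait="Serum urate")],
            {"C0": [("Urate measurement", "+")]},
            synonym_map={"Urate measurement": "Serum urate"},
        )
        assert tab.matched.all() and tab.validated.all()

    def test_end_to_end_planted_effects_validated(self, truth_k3, scored_cohort):
        geno, pheno, z = scored_cohort
        binary, _ = map_phecodes(pheno.code_events, pheno.phecode_map, z.index)
        phenos = PhenotypeSet(pheno.quantitative, binary, pheno.covariates)
        res = run_phewas(z, phenos)
        top = {f"C{k}": [(f"quant_c{k}", "+"), (f"PC{k:03d}", "+")]
               for k in range(truth_k3.K_true)}
        tab = validate_top_traits(res, top)
        assert tab.validated.all()  # planted diagonal effects
        null = {f"C{k}": [("no such trait", "+")] for k in range(truth_k3.K_true)}
        assert not validate_top_traits(res, null).validated.any()
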