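"""Logistic LRT, genomic control, exact 2x2 path and the scan orchestration."""

import math

import numpy as np
import pytest
from scipy import stats

from lofburden.association import (ContingencyTable2x2, GeneBurdenModel,
                                   fisher_exact_test, genomic_control_adjust,
                                   logistic_lrt, results_to_frame,
                                   run_dataset, wald_ci)
from lofburden.burden import GeneBurden
from lofburden.cohort import Cohort
from lofburden.exceptions import ConfigError, SeparationError
from lofburden.pipeline import run_burden_scan

from oracles import fisher_two_sided_enumeration, logistic_2x2_mle

import pandas as pd


def table_cohort(a, b, c, d, rng=None):
    """Build carrier/status vectors realising a 2x2 table."""
    status = np.array([1] * (a + b) + [0] * (c + d))
    carrier = np.array([1] * a + [0] * b + [1] * c + [0] * d)
    return carrier, status


class TestFisherExact:
    def test_sparse_cohort_worked_example(self):
        # 3538 cases / 2365 controls, 6 carriers of whom 5 are cases
        t = ContingencyTable2x2(5, 3533, 1, 2364)
        p, orr = fisher_exact_test(t)
        assert round(p, 2) == 0.41
        assert round(orr, 2) == 3.35

    def test_symmetric_table_is_null(self):
        t = ContingencyTable2x2(7, 93, 7, 93)
        p, orr = fisher_exact_test(t)
        assert p == pytest.approx(1.0)
        assert orr == pytest.approx(1.0)

    def test_infinite_odds_ratio_when_no_control_carriers(self):
        p, orr = fisher_exact_test(ContingencyTable2x2(4, 96, 0, 100))
        assert math.isinf(orr) and 0 < p < 1

    def test_degenerate_margin_returns_p_one(self):
        p, orr = fisher_exact_test(ContingencyTable2x2(0, 100, 0, 100))
        assert p == 1.0 and math.isnan(orr)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle_sparse_tables(self, seed):
        # every table with <= 8 carriers must agree with full enumeration
        rng = np.random.default_rng(seed)
        carriers = int(rng.integers(1, 9))
        a = int(rng.integers(0, carriers + 1))
        c = carriers - a
        b = int(rng.integers(50, 4000))
        d = int(rng.integers(50, 4000))
        p, _ = fisher_exact_test(ContingencyTable2x2(a, b, c, d))
        assert p == pytest.approx(
            fisher_two_sided_enumeration(a, b, c, d), rel=1e-7)


class TestGenomicControl:
    def test_unit_intercept_leaves_statistic_unchanged(self):
        chi2_adj, p = genomic_control_adjust(7.0, 1.00)
        assert chi2_adj == 7.0
        assert p == pytest.approx(stats.chi2.sf(7.0, 1))

    def test_division_by_intercept(self):
        chi2_adj, _ = genomic_control_adjust(11.4, 1.14)
        assert chi2_adj == pytest.approx(10.0)

    def test_five_percent_quantile(self):
        _, p = genomic_control_adjust(3.841459, 1.0)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_nonpositive_intercept_rejected(self):
        with pytest.raises(ConfigError):
            genomic_control_adjust(5.0, 0.0)

    def test_p_monotone_in_intercept(self):
        ps = [genomic_control_adjust(8.0, lam)[1] for lam in (1.0, 1.14, 1.5)]
        assert ps == sorted(ps)


class TestWaldCi:
    def test_published_interval_round_trip(self):
        # Iceland row: OR 7.5 with (2.0, 27.4) implies se 0.668; the
        # published one-decimal rounding of the OR limits agreement to ~2%
        lo, hi = wald_ci(math.log(7.5), 0.668)
        assert lo == pytest.approx(2.0, rel=0.02)
        assert hi == pytest.approx(27.4, rel=0.02)

    def test_direct_arithmetic(self):
        lo, hi = wald_ci(1.0, 0.5)
        assert lo == pytest.approx(math.exp(1 - 1.959964 * 0.5), rel=1e-9)
        assert hi == pytest.approx(math.exp(1 + 1.959964 * 0.5), rel=1e-9)

    def test_degenerate_se_rejected(self):
        with pytest.raises(ValueError):
            wald_ci(0.0, 0.0)


class TestLogisticLrt:
    def test_reduces_to_2x2_mle_without_covariates(self):
        carrier, status = table_cohort(30, 470, 12, 488)
        beta, se, chi2 = logistic_lrt(carrier, status)
        oracle_beta, oracle_chi2 = logistic_2x2_mle(30, 470, 12, 488)
        sample_or = (30 * 488) / (470 * 12)
        assert beta == pytest.approx(math.log(sample_or), rel=1e-6)
        assert beta == pytest.approx(oracle_beta, rel=1e-6)
        assert chi2 == pytest.approx(oracle_chi2, rel=1e-6)

    def test_agrees_with_fisher_for_dense_tables(self):
        # asymptotic agreement band: within a factor of 2 at >= 10 carriers
        for cells in [(25, 975, 12, 988), (40, 460, 15, 485),
                      (18, 282, 20, 280)]:
            carrier, status = table_cohort(*cells)
            _, _, chi2 = logistic_lrt(carrier, status)
            p_lrt = stats.chi2.sf(chi2, 1)
            p_f, _ = fisher_exact_test(ContingencyTable2x2(*cells))
            assert 0.5 < p_lrt / p_f < 2.0

    def test_complete_separation_raises(self):
        carrier, status = table_cohort(8, 492, 0, 500)
        with pytest.raises(SeparationError):
            logistic_lrt(carrier, status)

    def test_no_carriers_raises(self):
        with pytest.raises(SeparationError):
            logistic_lrt(np.zeros(100), np.r_[np.ones(50), np.zeros(50)])

    def test_covariate_adjustment_changes_estimate(self, rng):
        n = 4000
        confounder = rng.normal(size=n)
        carrier = (rng.random(n) < stats.norm.cdf(confounder - 1.8)).astype(int)
        p_case = 1 / (1 + np.exp(-(-0.5 + 1.2 * confounder)))
        status = (rng.random(n) < p_case).astype(int)
        beta_unadj, _, _ = logistic_lrt(carrier, status)
        beta_adj, _, _ = logistic_lrt(carrier, status,
                                      confounder.reshape(-1, 1))
        # confounding inflates the crude estimate; adjustment shrinks it
        assert abs(beta_adj) < abs(beta_unadj)


class TestModelAndScan:
    def _cohort(self, n=1200, seed=5):
        rng = np.random.default_rng(seed)
        status = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        cov = pd.DataFrame({"sex": rng.integers(0, 2, n),
                            "age_z": rng.normal(size=n)})
        return Cohort(ids=np.array([f"I{i}" for i in range(n)]),
                      status=status, covariates=cov, dataset="simtest"), rng

    def test_model_fit_and_summary(self):
        cohort, rng = self._cohort()
        carrier = rng.binomial(1, 0.04, cohort.n)
        model = GeneBurdenModel(cohort.status, carrier, cohort.covariates,
                                dataset="simtest", gene="GENE1")
        res = model.fit(gc_intercept=1.14)
        assert res.method == "logistic_lrt"
        assert res.chi2_adj == pytest.approx(res.chi2_raw / 1.14)
        assert res.ci_low < res.or_point < res.ci_high
        assert "GENE1" in res.summary()

    def test_sparse_gene_uses_fisher(self):
        cohort, rng = self._cohort()
        carrier = np.zeros(cohort.n, dtype=int)
        carrier[rng.choice(cohort.n, 5, replace=False)] = 1
        res = GeneBurdenModel(cohort.status, carrier,
                              cohort.covariates).fit(sparse_threshold=10)
        assert res.method == "fisher_exact"

    def test_separation_falls_back_to_fisher(self):
        cohort, _ = self._cohort()
        carrier = np.zeros(cohort.n, dtype=int)
        carrier[:15] = 1  # all carriers are cases
        res = GeneBurdenModel(cohort.status, carrier,
                              cohort.covariates).fit(sparse_threshold=10)
        assert res.method == "fisher_exact"
        assert math.isinf(res.or_point)

    def test_zero_carrier_gene_skipped(self):
        cohort, rng = self._cohort()
        burdens = [GeneBurden(gene="EMPTY",
                              carrier_indicator=np.zeros(cohort.n, dtype=np.int8)),
                   GeneBurden(gene="OK",
                              carrier_indicator=rng.binomial(
                                  1, 0.05, cohort.n).astype(np.int8))]
        for b in burdens:
            b.n_carriers = int(b.carrier_indicator.sum())
            b.n_case_carriers = int(b.carrier_indicator[cohort.status == 1].sum())
        results = run_dataset(cohort, burdens)
        assert [r.gene for r in results] == ["OK"]

    def test_results_frame_has_canonical_columns(self, small_synth):
        results = run_burden_scan(small_synth.cohort, small_synth.variants,
                                  small_synth.genotype_table,
                                  small_synth.read_evidence)
        df = results_to_frame(results)
        assert list(df.columns) == [
            "gene", "dataset", "n_variants", "cvf_cases", "cvf_controls",
            "n_carriers", "n_case_carriers", "or", "ci_low", "ci_high",
            "p", "method"]
        assert (df["p"] > 0).all() and (df["p"] <= 1).all()
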