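"""Synthetic cohort generator: determinism, generative structure, evidence."""

import numpy as np
import pytest

from lofburden.exceptions import ConfigError
from lofburden.qc import fit_depth_slope
from lofburden.simulate import (SimulationConfig, simulate_cohort,
                                simulate_read_evidence)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("n_cases", 0), ("n_controls", -5), ("n_genes", 0),
        ("variants_per_gene", 0), ("lof_fraction", 1.5),
        ("error_rate", 0.2), ("spurious_site_fraction", -0.1),
        ("depth_mean", 0.0), ("maf_range", (0.0, 0.001)),
        ("maf_range", (1e-4, 0.01)),
    ])
    def test_invalid_field_is_named(self, field, value):
        cfg = SimulationConfig(**{field: value})
        with pytest.raises(ConfigError) as exc:
            cfg.validate()
        assert exc.value.field == field

    def test_per_gene_effects_must_match_gene_count(self):
        cfg = SimulationConfig(n_genes=3, burden_log_or=[1.0, 0.0])
        with pytest.raises(ConfigError) as exc:
            cfg.validate()
        assert exc.value.field == "burden_log_or"


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_cases=120, n_controls=120, n_genes=3,
                               variants_per_gene=3, seed=42)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert np.array_equal(a.genotype_table, b.genotype_table)
        assert np.array_equal(a.cohort.status, b.cohort.status)
        assert a.cohort.covariates.equals(b.cohort.covariates)
        assert [v.key for v in a.variants] == [v.key for v in b.variants]
        assert all(
            a.read_evidence[j] == b.read_evidence[j] for j in a.read_evidence)

    def test_different_seed_differs(self):
        base = SimulationConfig(n_cases=200, n_controls=200, seed=1)
        other = SimulationConfig(n_cases=200, n_controls=200, seed=2)
        assert not np.array_equal(simulate_cohort(base).genotype_table,
                                  simulate_cohort(other).genotype_table)


class TestGenerativeStructure:
    def test_case_fraction_hits_target_in_expectation(self):
        cfg = SimulationConfig(n_cases=3000, n_controls=9000, n_genes=2,
                               variants_per_gene=2, seed=9)
        synth = simulate_cohort(cfg)
        frac = synth.cohort.status.mean()
        assert frac == pytest.approx(0.25, abs=0.02)

    def test_null_carrier_cvf_matches_closed_form(self):
        # fixed MAF, null effect: P(carrier) = 1 - (1 - maf)^(2 V)
        maf, V = 0.002, 4
        cfg = SimulationConfig(n_cases=4000, n_controls=4000, n_genes=6,
                               variants_per_gene=V, maf_range=(maf, maf),
                               lof_fraction=1.0, spurious_site_fraction=0.0,
                               burden_log_or=0.0, seed=17)
        synth = simulate_cohort(cfg)
        expected = 1 - (1 - maf) ** (2 * V)
        observed = np.mean([c.mean() for c in synth.truth.true_carrier.values()])
        n_eff = cfg.n * cfg.n_genes
        mc_sd = np.sqrt(expected * (1 - expected) / n_eff)
        assert observed == pytest.approx(expected, abs=4 * mc_sd)

    def test_null_gene_carrier_independent_of_status(self):
        cfg = SimulationConfig(n_cases=2500, n_controls=2500, n_genes=4,
                               variants_per_gene=3, maf_range=(1e-3, 3e-3),
                               burden_log_or=0.0, lof_fraction=1.0,
                               spurious_site_fraction=0.0, seed=23)
        synth = simulate_cohort(cfg)
        status = synth.cohort.status
        for carrier in synth.truth.true_carrier.values():
            n_c = carrier.sum()
            if n_c < 20:
                continue
            # case rate among carriers ~ overall case rate under the null,
            # within 4 binomial standard deviations
            p = status.mean()
            tol = 4 * np.sqrt(p * (1 - p) / n_c)
            assert abs(status[carrier == 1].mean() - p) < tol

    def test_causal_gene_enriches_cases(self):
        cfg = SimulationConfig(n_cases=3000, n_controls=3000, n_genes=2,
                               variants_per_gene=4, maf_range=(2e-3, 4e-3),
                               burden_log_or=[2.0, 0.0], lof_fraction=1.0,
                               spurious_site_fraction=0.0, seed=31)
        synth = simulate_cohort(cfg)
        status = synth.cohort.status
        carrier = synth.truth.true_carrier["GENE0001"]
        assert status[carrier == 1].mean() > status[carrier == 0].mean() + 0.1

    def test_truth_covers_every_gene_and_variant(self, small_synth):
        genes = {v.gene for v in small_synth.variants}
        assert set(small_synth.truth.gene_log_or) == genes
        assert set(small_synth.truth.true_carrier) == genes
        assert len(small_synth.truth.spurious) == len(small_synth.variants)
        n, m = small_synth.genotype_table.shape
        assert n == small_synth.cohort.n and m == len(small_synth.variants)


class TestReadEvidence:
    def test_homref_zero_error_gives_zero_alt(self):
        ev = simulate_read_evidence(np.zeros(50, dtype=int), depth_mean=30,
                                    error_rate=0.0, spurious=False, seed=1)
        assert all(r.alt_count == 0 for r in ev)

    def test_heterozygote_mean_is_half_depth(self):
        ev = simulate_read_evidence(np.ones(4000, dtype=int), depth_mean=30,
                                    error_rate=0.0, spurious=False, seed=2)
        ratio = np.array([r.alt_count for r in ev]).sum() \
            / np.array([r.depth for r in ev]).sum()
        assert ratio == pytest.approx(0.5, abs=0.01)

    def test_spurious_sites_fail_slope_filter(self):
        # over 200 seeds, the fitted slope of an artifact site at depth ~30
        # must fall below 0.5 in at least 95% of draws
        fails = 0
        for seed in range(200):
            ev = simulate_read_evidence(np.ones(40, dtype=int), depth_mean=30,
                                        error_rate=0.002, spurious=True,
                                        seed=seed)
            if fit_depth_slope(ev) < 0.5:
                fails += 1
        assert fails >= 190

    def test_clean_sites_pass_slope_filter(self):
        passes = 0
        for seed in range(200):
            ev = simulate_read_evidence(np.ones(40, dtype=int), depth_mean=30,
                                        error_rate=0.002, spurious=False,
                                        seed=seed)
            if fit_depth_slope(ev) >= 0.5:
                passes += 1
        assert passes >= 190

    def test_rejects_bad_dosages(self):
        with pytest.raises(ConfigError):
            simulate_read_evidence(np.array([0, 3]), 30, 0.0, False, seed=0)
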