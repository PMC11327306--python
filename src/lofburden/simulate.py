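"""Seedable synthetic case-control cohorts for burden-test validation.

The generator emulates a rare-variant WGS case-control study with the exact
statistical structure the pipeline assumes:

* rare biallelic variants with allele frequencies drawn from a configured
  range (upper bound 0.005 so sites are plausibly rare yet can straddle the
  0.1% qualifying threshold), genotypes sampled under Hardy-Weinberg;
* a fraction of variants annotated as loss-of-function (cycled over the six
  LOF consequence classes, LOFTEE high-confidence), the rest missense;
* disease status drawn from a logistic model whose linear predictor is
  ``intercept + burden_log_or * carrier(gene) + covariate effects``, where
  carrier(gene) indicates >= 1 alternate allele at any of the gene's clean
  LOF variants — the same 0/1 coding the burden test fits.  The intercept
  is solved by bisection so the expected case fraction matches the
  requested n_cases / (n_cases + n_controls);
* per-site read evidence (depth, alternate-allele count) that follows the
  depth-conditional identity line for clean sites, while "spurious" sites
  show alternate reads at a fixed sub-fraction of depth regardless of
  genotype — an artifact/somatic failure mode that the allele-balance slope
  filter is designed to catch.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .burden import LOF_CONSEQUENCES, VariantRecord
from .cohort import Cohort
from .exceptions import ConfigError
from .qc import ReadEvidence

__all__ = ["CovariateSpec", "SimulationConfig", "SyntheticCohort",
           "SimulationTruth", "simulate_cohort", "simulate_read_evidence"]

_LOF_CYCLE = sorted(LOF_CONSEQUENCES)
#: fraction of depth at which spurious sites emit alternate reads,
#: independent of the called genotype (fitted het slope ~ 2 * this value)
SPURIOUS_ALT_FRACTION = 0.1


@dataclass(frozen=True)
class CovariateSpec:
    """One adjustment covariate: name, distribution family, logit effect.

    ``family`` is ``"bernoulli"`` (parameter = success probability) or
    ``"normal"`` (standard normal).
    """

    name: str
    family: str = "normal"
    effect: float = 0.0
    param: float = 0.5


def _default_covariates() -> list[CovariateSpec]:
    # minimal stand-ins for a real adjustment set: a binary sex indicator
    # (mild male excess on the logit) and a standardised age
    return [CovariateSpec("sex", "bernoulli", effect=0.4, param=0.5),
            CovariateSpec("age_z", "normal", effect=0.8)]


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    ``burden_log_or`` is either a scalar applied to every gene or one value
    per gene; 0 marks a null gene.
    """

    n_cases: int = 500
    n_controls: int = 500
    n_genes: int = 10
    variants_per_gene: int = 5
    maf_range: tuple[float, float] = (1e-5, 5e-4)
    lof_fraction: float = 0.8
    burden_log_or: Union[float, Sequence[float]] = 0.0
    covariate_spec: list[CovariateSpec] = dc_field(default_factory=_default_covariates)
    depth_mean: float = 38.0
    error_rate: float = 0.002
    spurious_site_fraction: float = 0.05
    seed: int = 0
    max_ref_evidence: int = 50  # hom-ref read-evidence records kept per site
    simulate_reads: bool = True  # skip read evidence for association-only studies

    def validate(self) -> None:
        for f in ("n_cases", "n_controls", "n_genes", "variants_per_gene"):
            v = getattr(self, f)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigError(f, "must be a strictly positive integer")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.005):
            raise ConfigError("maf_range",
                              "must satisfy 0 < low <= high <= 0.005")
        if not (0.0 <= self.lof_fraction <= 1.0):
            raise ConfigError("lof_fraction", "must be in [0, 1]")
        if not (0.0 <= self.error_rate <= 0.05):
            raise ConfigError("error_rate", "must be in [0, 0.05]")
        if not (0.0 <= self.spurious_site_fraction <= 1.0):
            raise ConfigError("spurious_site_fraction", "must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean", "must be > 0")
        if np.ndim(self.burden_log_or) == 1 and \
                len(np.atleast_1d(self.burden_log_or)) != self.n_genes:
            raise ConfigError("burden_log_or",
                              f"needs one value per gene ({self.n_genes})")
        for spec in self.covariate_spec:
            if spec.family not in ("bernoulli", "normal"):
                raise ConfigError("covariate_spec",
                                  f"unknown family {spec.family!r}")

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    def gene_effects(self) -> np.ndarray:
        return np.broadcast_to(np.atleast_1d(np.asarray(
            self.burden_log_or, dtype=float)), (self.n_genes,)).copy()


@dataclass
class SimulationTruth:
    """Ground truth backing the simulated data."""

    gene_log_or: dict[str, float]
    spurious: np.ndarray  # per-variant flag, aligned with variant columns
    true_carrier: dict[str, np.ndarray]  # per-gene generative carrier vector


@dataclass
class SyntheticCohort:
    cohort: Cohort
    variants: list[VariantRecord]
    genotype_table: np.ndarray  # individuals x variants, dosage in {0,1,2}
    read_evidence: dict[int, list[ReadEvidence]]  # keyed by variant column
    truth: SimulationTruth

    def gene_variants(self, gene: str) -> list[VariantRecord]:
        return [v for v in self.variants if v.gene == gene]


def simulate_read_evidence(genotypes: np.ndarray, depth_mean: float,
                           error_rate: float, spurious: bool,
                           seed: Union[int, np.random.Generator],
                           ids: Optional[Sequence[str]] = None,
                           ) -> list[ReadEvidence]:
    """Draw per-individual (depth, alt count) read support for one site.

    Clean sites: ``alt ~ Binomial(depth, g/2)`` with the success probability
    shrunk toward ``error_rate`` for sequencing error, so heterozygotes
    average depth/2 and the identity line holds.  Spurious sites: alternate
    reads appear at a fixed sub-fraction of depth whatever the genotype, so
    the fitted allele-balance slope collapses well below 0.5.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    g = np.asarray(genotypes)
    if not np.isin(g, (0, 1, 2)).all():
        raise ConfigError("genotypes", "dosages must be in {0,1,2}")
    if depth_mean <= 0:
        raise ConfigError("depth_mean", "must be > 0")
    n = len(g)
    depth = rng.poisson(depth_mean, size=n)
    if spurious:
        p_alt = np.full(n, SPURIOUS_ALT_FRACTION)
    else:
        frac = g / 2.0
        p_alt = frac * (1.0 - error_rate) + (1.0 - frac) * error_rate
    alt = rng.binomial(depth, p_alt)
    if ids is None:
        ids = [f"I{i:07d}" for i in range(n)]
    return [ReadEvidence(individual_id=str(ids[i]), depth=int(depth[i]),
                         alt_count=int(alt[i]), genotype=int(g[i]))
            for i in range(n)]


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Bisect the logistic intercept so mean sigmoid(c + eta) == target."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        mean = float((1.0 / (1.0 + np.exp(-(mid + eta)))).mean())
        if mean < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``.

    The gene-level carrier indicator over clean (non-spurious) LOF variants
    is the true generative exposure; status follows the logistic disease
    model with the intercept solved to hit the requested case fraction in
    expectation.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    n_var = config.n_genes * config.variants_per_gene
    effects = config.gene_effects()

    # --- variants and genotypes (HWE, biallelic, rare) -------------------
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_var)
    genotypes = rng.binomial(2, mafs[None, :], size=(n, n_var)).astype(np.int8)
    is_lof = rng.random(n_var) < config.lof_fraction
    is_spurious = rng.random(n_var) < config.spurious_site_fraction

    variants: list[VariantRecord] = []
    genes = [f"GENE{g+1:04d}" for g in range(config.n_genes)]
    bases = ["A", "C", "G", "T"]
    for j in range(n_var):
        g_idx = j // config.variants_per_gene
        chrom = f"chr{(g_idx % 22) + 1}"
        ref = bases[j % 4]
        alt = bases[(j + 1) % 4]
        cons = _LOF_CYCLE[j % len(_LOF_CYCLE)] if is_lof[j] else "missense_variant"
        ac = int(genotypes[:, j].sum())
        af = ac / (2 * n)
        variants.append(VariantRecord(
            chrom=chrom, pos=1000 + 10 * j, ref=ref, alt=alt,
            gene=genes[g_idx], consequence=cons,
            loftee_tag="HC" if is_lof[j] else None,
            aascore=float(rng.uniform(0.9, 1.0)),
            maf=min(af, 1.0 - af), column=j))

    # --- covariates ------------------------------------------------------
    cov_cols = {}
    eta_cov = np.zeros(n)
    for spec in config.covariate_spec:
        if spec.family == "bernoulli":
            x = rng.binomial(1, spec.param, size=n).astype(float)
        else:
            x = rng.normal(size=n)
        cov_cols[spec.name] = x
        eta_cov += spec.effect * x
    covariates = pd.DataFrame(cov_cols)

    # --- disease model ---------------------------------------------------
    true_carrier: dict[str, np.ndarray] = {}
    eta = eta_cov.copy()
    for g_idx, gene in enumerate(genes):
        cols = np.arange(g_idx * config.variants_per_gene,
                         (g_idx + 1) * config.variants_per_gene)
        causal = cols[is_lof[cols] & ~is_spurious[cols]]
        carrier = (genotypes[:, causal] >= 1).any(axis=1).astype(np.int8) \
            if causal.size else np.zeros(n, dtype=np.int8)
        true_carrier[gene] = carrier
        if effects[g_idx] != 0.0:
            eta += effects[g_idx] * carrier
    target = config.n_cases / n
    intercept = _solve_intercept(eta, target)
    status = (rng.random(n) < 1.0 / (1.0 + np.exp(-(intercept + eta)))
              ).astype(np.int8)

    ids = np.array([f"I{i:07d}" for i in range(n)])
    onset = np.full(n, np.nan)
    onset[status == 1] = rng.normal(70.0, 9.8, size=int(status.sum()))
    cohort = Cohort(ids=ids, status=status, covariates=covariates,
                    dataset="synthetic", age_at_onset=onset)

    # --- read evidence (hom-ref records down-sampled per site) ----------
    read_evidence: dict[int, list[ReadEvidence]] = {}
    for j in range(n_var if config.simulate_reads else 0):
        carriers = np.flatnonzero(genotypes[:, j] > 0)
        refs = np.flatnonzero(genotypes[:, j] == 0)
        if refs.size > config.max_ref_evidence:
            refs = rng.choice(refs, size=config.max_ref_evidence, replace=False)
        idx = np.concatenate([carriers, refs])
        read_evidence[j] = simulate_read_evidence(
            genotypes[idx, j], config.depth_mean, config.error_rate,
            bool(is_spurious[j]), rng, ids=ids[idx])

    truth = SimulationTruth(
        gene_log_or={g: float(effects[i]) for i, g in enumerate(genes)},
        spurious=is_spurious, true_carrier=true_carrier)
    return SyntheticCohort(cohort=cohort, variants=variants,
                           genotype_table=genotypes,
                           read_evidence=read_evidence, truth=truth)
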