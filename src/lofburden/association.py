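"""Per-gene, per-dataset burden association.

The primary test is an additive logistic regression of disease status on
the per-gene 0/1 carrier indicator plus adjustment covariates; the two-sided
P value comes from the likelihood-ratio test (LRT) of the carrier term
(chi-squared, 1 df).  The LRT statistic is divided by a dataset-specific
genomic-control intercept (an LD-score-regression intercept supplied as
configuration, e.g. 1.14 for the Icelandic dataset, 1.00 for the UK) to
correct residual inflation from stratification and cryptic relatedness;
the standard error is rescaled by sqrt(intercept) so downstream
meta-analysis is consistent with the adjusted per-dataset P values.

Sparse genes (fewer carriers than ``sparse_threshold``) and genes with
complete separation are analysed instead with a two-sided Fisher's exact
test on the carriers-by-status 2x2 table; the reported odds ratio for that
path is the sample cross-product ratio and its confidence interval is the
conditional exact interval.

The model/results surface mirrors statsmodels: build a
:class:`GeneBurdenModel` from arrays or a DataFrame, call :meth:`fit`,
inspect the returned :class:`GeneBurdenResults`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio
import statsmodels.api as sm

from .burden import GeneBurden, cumulative_variant_frequency
from .cohort import Cohort
from .exceptions import ConfigError, InputError, SeparationError

__all__ = [
    "ContingencyTable2x2", "BurdenResult", "GeneBurdenModel",
    "GeneBurdenResults", "logistic_lrt", "genomic_control_adjust",
    "fisher_exact_test", "fisher_exact_ci", "wald_ci", "run_dataset",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

Z_95 = 1.959964  # two-sided 95% normal quantile

#: genes with fewer carriers than this are sent to the exact-test path
DEFAULT_SPARSE_THRESHOLD = 10

_MAX_ABS_BETA = 15.0  # |log OR| beyond this is treated as separation
_IRLS_TOL = 1e-8
_IRLS_MAXITER = 50


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier-by-status table for the exact-test path."""

    case_carriers: int
    case_noncarriers: int
    control_carriers: int
    control_noncarriers: int

    def __post_init__(self):
        for f in ("case_carriers", "case_noncarriers",
                  "control_carriers", "control_noncarriers"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.case_carriers, self.case_noncarriers],
                         [self.control_carriers, self.control_noncarriers]])

    @classmethod
    def from_burden(cls, burden: GeneBurden, n_cases: int,
                    n_controls: int) -> "ContingencyTable2x2":
        cc = burden.n_case_carriers
        ctrl_c = burden.n_carriers - burden.n_case_carriers
        return cls(case_carriers=cc, case_noncarriers=n_cases - cc,
                   control_carriers=ctrl_c,
                   control_noncarriers=n_controls - ctrl_c)


@dataclass
class BurdenResult:
    """Per-gene, per-dataset association summary."""

    gene: str
    dataset: str
    n_variants: int
    cvf_cases: float
    cvf_controls: float
    n_carriers: int
    n_case_carriers: int
    beta: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    chi2_raw: float
    chi2_adj: float
    p: float
    method: str  # "logistic_lrt" | "fisher_exact"


def logistic_lrt(carrier: np.ndarray, status: np.ndarray,
                 covariates: Optional[np.ndarray] = None,
                 null_loglik: Optional[float] = None,
                 ) -> tuple[float, float, float]:
    """Additive logistic regression with a likelihood-ratio test.

    Fits ``status ~ intercept + covariates + carrier`` by iteratively
    reweighted least squares (Newton), and the null model without the
    carrier term; returns ``(beta, se, chi2_raw)`` where
    ``chi2_raw = 2 * (loglik_full - loglik_null)`` (1 df).

    ``null_loglik`` lets a caller testing many genes against the same
    phenotype/covariate set fit the null model once and reuse it.

    Raises
    ------
    SeparationError
        If all carriers fall in one outcome class, the fit does not
        converge, or the carrier coefficient diverges.
    """
    carrier = np.asarray(carrier, dtype=float)
    status = np.asarray(status, dtype=float)
    n = len(status)
    if len(carrier) != n:
        raise InputError("carrier and status lengths differ")
    if carrier.sum() < 1:
        raise SeparationError("no carriers in the pooled sample")

    case_carriers = carrier[status == 1].sum()
    if case_carriers == 0 or case_carriers == carrier.sum():
        raise SeparationError("all carriers in one outcome class")

    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        x_null = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.shape[0] != n:
            raise InputError("covariate matrix is not aligned with status")
        x_null = np.column_stack([np.ones(n), covariates])
    x_full = np.column_stack([x_null, carrier])

    try:
        if null_loglik is None:
            null_fit = sm.Logit(status, x_null).fit(
                disp=0, method="newton", tol=_IRLS_TOL, maxiter=_IRLS_MAXITER)
            if not null_fit.mle_retvals["converged"]:
                raise SeparationError("null model did not converge")
            null_loglik = float(null_fit.llf)
        full_fit = sm.Logit(status, x_full).fit(
            disp=0, method="newton", tol=_IRLS_TOL, maxiter=_IRLS_MAXITER)
    except SeparationError:
        raise
    except Exception as exc:  # perfect separation, singular Hessian, ...
        raise SeparationError(f"logistic fit failed: {exc}") from exc

    if not full_fit.mle_retvals["converged"]:
        raise SeparationError("full model did not converge")
    beta = float(full_fit.params[-1])
    if abs(beta) > _MAX_ABS_BETA:
        raise SeparationError(f"carrier coefficient diverged (|beta|={abs(beta):.1f})")
    se = float(full_fit.bse[-1])
    chi2_raw = 2.0 * (float(full_fit.llf) - null_loglik)
    return beta, se, max(chi2_raw, 0.0)


def fit_null_loglik(status: np.ndarray,
                    covariates: Optional[np.ndarray] = None) -> float:
    """Log-likelihood of the covariate-only logistic model (no carrier term).

    Shared across all genes of one dataset, so it is fit once per scan.
    """
    status = np.asarray(status, dtype=float)
    n = len(status)
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        x = np.ones((n, 1))
    else:
        x = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    fit = sm.Logit(status, x).fit(disp=0, method="newton",
                                  tol=_IRLS_TOL, maxiter=_IRLS_MAXITER)
    if not fit.mle_retvals["converged"]:
        raise SeparationError("null model did not converge")
    return float(fit.llf)


def genomic_control_adjust(chi2_raw: float, intercept: float) -> tuple[float, float]:
    """Divide the LRT chi-squared by the genomic-control intercept.

    ``intercept`` is the dataset's LD-score-regression intercept (a
    configuration input, not estimated here).  Values below 1 are accepted
    with a warning but never rescaled upward.  Returns ``(chi2_adj, p)``
    with ``p`` the upper tail of chi-squared(1 df) at ``chi2_adj``.
    """
    if intercept <= 0:
        raise ConfigError("gc_intercept", "must be > 0")
    if intercept < 1:
        logger.warning("genomic-control intercept %.3f < 1 inflates the "
                       "statistic; applied as given", intercept)
    chi2_adj = chi2_raw / intercept
    p = float(stats.chi2.sf(chi2_adj, df=1))
    return chi2_adj, p


def fisher_exact_test(t: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the carrier-by-status table.

    The two-sided P sums hypergeometric probabilities (margins fixed) of
    every table at most as probable as the observed one — the
    probability-mass definition used by R's ``fisher.test``.  The returned
    odds ratio is the sample cross-product ratio ``(a*d)/(b*c)``, ``inf``
    when ``b*c == 0``; a fully degenerate margin (no carriers at all)
    yields ``p = 1`` and an undefined (nan) odds ratio.
    """
    a, b = t.case_carriers, t.case_noncarriers
    c, d = t.control_carriers, t.control_noncarriers
    if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
        logger.warning("degenerate 2x2 margin; p=1, odds ratio undefined")
        return 1.0, float("nan")
    p = float(stats.fisher_exact(t.as_array, alternative="two-sided").pvalue)
    or_sample = (a * d) / (b * c) if b * c > 0 else float("inf")
    return p, or_sample


def fisher_exact_ci(t: ContingencyTable2x2, level: float = 0.95,
                    ) -> tuple[float, float]:
    """Conditional exact confidence interval for the 2x2 odds ratio."""
    res = _conditional_odds_ratio(t.as_array)
    ci = res.confidence_interval(confidence_level=level)
    return float(ci.low), float(ci.high)


def wald_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Odds-ratio-scale Wald interval ``exp(beta -/+ z * se)``."""
    if se <= 0:
        raise ValueError("se must be > 0")
    z = Z_95 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2.0))
    return math.exp(beta - z * se), math.exp(beta + z * se)


class GeneBurdenModel:
    """Logistic burden model for a single gene in one dataset.

    Parameters
    ----------
    status : array of 0/1
        Disease status (the dependent variable).
    carrier : array of 0/1
        Gene-level LOF carrier indicator.
    covariates : DataFrame or 2-d array, optional
        Adjustment covariates (no intercept column; one is added).
    dataset, gene : str
        Labels carried through to the results.
    """

    def __init__(self, status, carrier, covariates=None,
                 dataset: str = "cohort", gene: str = "gene"):
        self.status = np.asarray(status, dtype=np.int8)
        self.carrier = np.asarray(carrier, dtype=np.int8)
        if covariates is None:
            self.covariates = None
        elif isinstance(covariates, pd.DataFrame):
            self.covariates = covariates.to_numpy(dtype=float)
        else:
            self.covariates = np.asarray(covariates, dtype=float)
        self.dataset = dataset
        self.gene = gene

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, carrier_col: str,
                       status_col: str = "status",
                       covariate_cols: Optional[Sequence[str]] = None,
                       **labels) -> "GeneBurdenModel":
        cov = df[list(covariate_cols)] if covariate_cols else None
        return cls(df[status_col], df[carrier_col], cov, **labels)

    def fit(self, gc_intercept: float = 1.0,
            sparse_threshold: int = DEFAULT_SPARSE_THRESHOLD,
            null_loglik: Optional[float] = None) -> "GeneBurdenResults":
        """Fit the burden association, choosing the test automatically.

        Genes with at least ``sparse_threshold`` carriers are tested by the
        covariate-adjusted logistic LRT with genomic control; sparse genes
        and separated fits fall back to the exact 2x2 test.
        """
        n_carriers = int(self.carrier.sum())
        n_case_carriers = int(self.carrier[self.status == 1].sum())
        n_cases = int(self.status.sum())
        n_controls = len(self.status) - n_cases
        table = ContingencyTable2x2(
            case_carriers=n_case_carriers,
            case_noncarriers=n_cases - n_case_carriers,
            control_carriers=n_carriers - n_case_carriers,
            control_noncarriers=n_controls - (n_carriers - n_case_carriers))

        method = "logistic_lrt"
        if n_carriers < sparse_threshold:
            method = "fisher_exact"
        else:
            try:
                beta, se, chi2_raw = logistic_lrt(
                    self.carrier, self.status, self.covariates,
                    null_loglik=null_loglik)
            except SeparationError as exc:
                logger.info("gene %s: %s; falling back to Fisher's exact test",
                            self.gene, exc)
                method = "fisher_exact"

        if method == "logistic_lrt":
            chi2_adj, p = genomic_control_adjust(chi2_raw, gc_intercept)
            se_adj = se * math.sqrt(gc_intercept)
            ci_low, ci_high = wald_ci(beta, se_adj)
            core = dict(beta=beta, se=se_adj, or_point=math.exp(beta),
                        ci_low=ci_low, ci_high=ci_high,
                        chi2_raw=chi2_raw, chi2_adj=chi2_adj, p=p)
        else:
            p, or_sample = fisher_exact_test(table)
            ci_low, ci_high = fisher_exact_ci(table)
            if or_sample > 0 and math.isfinite(or_sample):
                beta = math.log(or_sample)
                from .meta import ci_to_se  # deferred: meta imports assoc types
                se = ci_to_se(or_sample, ci_low, ci_high) \
                    if 0 < ci_low < or_sample < ci_high else float("nan")
            else:
                beta, se = float("nan"), float("nan")
            core = dict(beta=beta, se=se, or_point=or_sample,
                        ci_low=ci_low, ci_high=ci_high,
                        chi2_raw=float("nan"), chi2_adj=float("nan"), p=p)

        return GeneBurdenResults(model=self, n_carriers=n_carriers,
                                 n_case_carriers=n_case_carriers,
                                 n_cases=n_cases, n_controls=n_controls,
                                 method=method, gc_intercept=gc_intercept,
                                 **core)


@dataclass
class GeneBurdenResults:
    """Fitted burden association for one gene (statsmodels-style results)."""

    model: GeneBurdenModel
    n_carriers: int
    n_case_carriers: int
    n_cases: int
    n_controls: int
    method: str
    gc_intercept: float
    beta: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    chi2_raw: float
    chi2_adj: float
    p: float

    def summary(self) -> str:
        lines = [
            f"Gene burden association: {self.model.gene} [{self.model.dataset}]",
            f"  test            {self.method}"
            + (f" (genomic control lambda={self.gc_intercept:g})"
               if self.method == "logistic_lrt" else ""),
            f"  carriers        {self.n_carriers} ({self.n_case_carriers} cases)"
            f" of {self.n_cases} cases / {self.n_controls} controls",
            f"  odds ratio      {self.or_point:.3g}"
            f" (95% CI {self.ci_low:.3g}-{self.ci_high:.3g})",
            f"  log OR (se)     {self.beta:.4g} ({self.se:.4g})",
            f"  P (two-sided)   {self.p:.3g}",
        ]
        if self.method == "logistic_lrt":
            lines.insert(4, f"  chi2 raw/adj    {self.chi2_raw:.4g} / {self.chi2_adj:.4g}")
        return "\n".join(lines)

    def to_burden_result(self, n_variants: int = 0,
                         cvf: Optional[tuple[float, float]] = None) -> BurdenResult:
        if cvf is None:
            from .burden import round_sig
            cvf = (round_sig(100.0 * self.n_case_carriers / self.n_cases),
                   round_sig(100.0 * (self.n_carriers - self.n_case_carriers)
                             / self.n_controls))
        return BurdenResult(
            gene=self.model.gene, dataset=self.model.dataset,
            n_variants=n_variants, cvf_cases=cvf[0], cvf_controls=cvf[1],
            n_carriers=self.n_carriers, n_case_carriers=self.n_case_carriers,
            beta=self.beta, se=self.se, or_point=self.or_point,
            ci_low=self.ci_low, ci_high=self.ci_high,
            chi2_raw=self.chi2_raw, chi2_adj=self.chi2_adj,
            p=self.p, method=self.method)


def run_dataset(cohort: Cohort, burdens: Sequence[GeneBurden],
                gc_intercept: float = 1.0,
                sparse_threshold: int = DEFAULT_SPARSE_THRESHOLD,
                ) -> list[BurdenResult]:
    """Test every collapsed gene of one dataset.

    Genes with zero carriers are skipped with a logged reason.  The
    covariate-only null model is fit once and shared across genes.
    """
    results: list[BurdenResult] = []
    cov = cohort.covariates.to_numpy(dtype=float) if cohort.covariates.shape[1] else None
    null_ll = fit_null_loglik(cohort.status, cov)
    for burden in burdens:
        if burden.n_carriers == 0:
            logger.info("gene %s skipped: zero_carriers", burden.gene)
            continue
        if len(burden.carrier_indicator) != cohort.n:
            raise InputError(
                f"gene {burden.gene}: carrier indicator is not aligned "
                "with the cohort")
        model = GeneBurdenModel(cohort.status, burden.carrier_indicator,
                                cohort.covariates, dataset=cohort.dataset,
                                gene=burden.gene)
        res = model.fit(gc_intercept=gc_intercept,
                        sparse_threshold=sparse_threshold,
                        null_loglik=null_ll)
        cvf = cumulative_variant_frequency(burden, cohort.n_cases,
                                           cohort.n_controls)
        results.append(res.to_burden_result(
            n_variants=len(burden.qualifying_variants), cvf=cvf))
    return results


def results_to_frame(results: Sequence[BurdenResult]) -> pd.DataFrame:
    """Tabulate burden results with the canonical column order."""
    cols = ["gene", "dataset", "n_variants", "cvf_cases", "cvf_controls",
            "n_carriers", "n_case_carriers", "or", "ci_low", "ci_high",
            "p", "method"]
    rows = [{**{c: getattr(r, c) for c in cols if hasattr(r, c)},
             "or": r.or_point} for r in results]
    return pd.DataFrame(rows, columns=cols)
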