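"""Fixed-effects inverse-variance meta-analysis with heterogeneity testing.

Per-dataset burden results are pooled on the log-odds-ratio scale under a
common-effect assumption: each study contributes weight ``w_i = 1/se_i^2``,
the pooled effect is the weighted mean and its variance ``1/sum(w_i)``.
Heterogeneity is assessed with Cochran's Q, which under the Gaussian
summary-data likelihood is algebraically identical to the likelihood-ratio
statistic comparing per-study free effects against a single common effect;
its null distribution is chi-squared with k-1 degrees of freedom.

Studies analysed by the exact 2x2 path enter with a standard error
recovered from their exact confidence interval (``ci_to_se``), a documented
approximation that lets sparse cohorts contribute to the pooled estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import Z_95, BurdenResult
from .exceptions import InputError

__all__ = ["MetaResult", "FixedEffectsMeta", "MetaResults", "ci_to_se",
           "ivw_fixed", "heterogeneity_test", "meta_analyse"]


@dataclass
class MetaResult:
    """Pooled per-gene meta-analysis summary."""

    gene: str
    k: int
    beta_pooled: float
    se_pooled: float
    or_pooled: float
    ci_low: float
    ci_high: float
    p: float
    q_stat: float
    df_het: int
    p_het: float


def ci_to_se(or_point: float, ci_low: float, ci_high: float,
             level: float = 0.95) -> float:
    """Recover the log-OR standard error from a 95% confidence interval.

    ``se = (ln ci_high - ln ci_low) / (2 z)`` with z the two-sided normal
    quantile; works for Wald intervals exactly and for exact intervals as a
    documented approximation.
    """
    if not (0 < ci_low < or_point < ci_high):
        raise InputError(
            f"confidence interval must satisfy 0 < low < point < high; "
            f"got ({or_point}, {ci_low}, {ci_high})")
    z = Z_95 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2.0))
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)


def ivw_fixed(betas: Sequence[float], ses: Sequence[float],
              ) -> tuple[float, float, float]:
    """Fixed-effects inverse-variance pooling.

    Returns ``(beta_pooled, se_pooled, p)`` where ``p`` is the two-sided
    normal test of ``beta_pooled / se_pooled``.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.shape != s.shape or b.ndim != 1:
        raise InputError("betas and ses must be equal-length 1-d sequences")
    if b.size == 0:
        raise InputError("meta-analysis requires at least one study")
    if not (s > 0).all() or not np.isfinite(s).all():
        raise InputError("standard errors must be finite and > 0")
    w = 1.0 / s ** 2
    beta_pooled = float((w * b).sum() / w.sum())
    se_pooled = float(1.0 / math.sqrt(w.sum()))
    p = float(2.0 * stats.norm.sf(abs(beta_pooled / se_pooled)))
    return beta_pooled, se_pooled, p


def heterogeneity_test(betas: Sequence[float], ses: Sequence[float],
                       ) -> tuple[float, int, float]:
    """Cochran's Q / Gaussian-likelihood LRT for effect heterogeneity.

    ``Q = sum w_i (beta_i - beta_pooled)^2`` equals twice the log-likelihood
    gain of per-study free effects over a common effect when each study's
    summary is treated as Gaussian with known variance.  Returns
    ``(q_stat, df, p_het)`` with the chi-squared(k-1) upper tail.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise InputError("heterogeneity test requires at least two studies")
    beta_pooled, _, _ = ivw_fixed(b, s)
    w = 1.0 / s ** 2
    q = float((w * (b - beta_pooled) ** 2).sum())
    df = b.size - 1
    p_het = float(stats.chi2.sf(q, df=df))
    return q, df, p_het


class FixedEffectsMeta:
    """Meta-analysis model over per-dataset (log OR, se) summaries.

    Build from raw arrays, from published odds ratios with confidence
    intervals (:meth:`from_intervals`), or from per-dataset
    :class:`~lofburden.association.BurdenResult` rows
    (:meth:`from_results`); ``fit()`` returns :class:`MetaResults`.
    """

    def __init__(self, betas: Sequence[float], ses: Sequence[float],
                 gene: str = "gene", datasets: Optional[Sequence[str]] = None):
        self.betas = np.asarray(betas, dtype=float)
        self.ses = np.asarray(ses, dtype=float)
        self.gene = gene
        self.datasets = list(datasets) if datasets is not None else \
            [f"study{i+1}" for i in range(len(self.betas))]

    @classmethod
    def from_intervals(cls, ors: Sequence[float], ci_lows: Sequence[float],
                       ci_highs: Sequence[float], **kw) -> "FixedEffectsMeta":
        betas = [math.log(o) for o in ors]
        ses = [ci_to_se(o, lo, hi) for o, lo, hi in zip(ors, ci_lows, ci_highs)]
        return cls(betas, ses, **kw)

    @classmethod
    def from_results(cls, results: Sequence[BurdenResult],
                     gene: Optional[str] = None) -> "FixedEffectsMeta":
        usable = [r for r in results
                  if np.isfinite(r.beta) and np.isfinite(r.se) and r.se > 0]
        if not usable:
            raise InputError("no dataset contributed a usable (beta, se) pair")
        genes = {r.gene for r in usable}
        if gene is None:
            if len(genes) != 1:
                raise InputError(f"results span multiple genes: {sorted(genes)}")
            gene = genes.pop()
        return cls([r.beta for r in usable], [r.se for r in usable],
                   gene=gene, datasets=[r.dataset for r in usable])

    def fit(self) -> "MetaResults":
        beta, se, p = ivw_fixed(self.betas, self.ses)
        if len(self.betas) >= 2:
            q, df, p_het = heterogeneity_test(self.betas, self.ses)
        else:
            q, df, p_het = 0.0, 0, 1.0
        ci_low = math.exp(beta - Z_95 * se)
        ci_high = math.exp(beta + Z_95 * se)
        core = MetaResult(gene=self.gene, k=len(self.betas),
                          beta_pooled=beta, se_pooled=se,
                          or_pooled=math.exp(beta), ci_low=ci_low,
                          ci_high=ci_high, p=p, q_stat=q, df_het=df,
                          p_het=p_het)
        return MetaResults(model=self, result=core)


@dataclass
class MetaResults:
    """Fitted meta-analysis (statsmodels-style results wrapper)."""

    model: FixedEffectsMeta
    result: MetaResult

    def __getattr__(self, name):
        # delegate scalar fields (or_pooled, p_het, ...) to the core record
        return getattr(self.result, name)

    def summary(self) -> str:
        r = self.result
        lines = [
            f"Fixed-effects IVW meta-analysis: {r.gene} ({r.k} datasets)",
            "  dataset        OR (95% CI)",
        ]
        for name, b, s in zip(self.model.datasets, self.model.betas,
                              self.model.ses):
            lines.append(f"  {name:<14} {math.exp(b):.2f} "
                         f"({math.exp(b - Z_95 * s):.2f}-{math.exp(b + Z_95 * s):.2f})")
        lines += [
            f"  pooled         {r.or_pooled:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})",
            f"  P (two-sided)  {r.p:.3g}",
            f"  heterogeneity  Q={r.q_stat:.3g} (df={r.df_het}), P-het={r.p_het:.2g}",
        ]
        return "\n".join(lines)


def meta_analyse(results: Sequence[BurdenResult]) -> list[MetaResult]:
    """Pool per-dataset results gene by gene.

    Datasets with no usable (beta, se) pair for a gene — e.g. zero carriers
    — are dropped from that gene's pooling with a logged note; genes with
    no usable dataset are skipped.
    """
    out: list[MetaResult] = []
    by_gene: dict[str, list[BurdenResult]] = {}
    for r in results:
        by_gene.setdefault(r.gene, []).append(r)
    for gene, rows in by_gene.items():
        try:
            model = FixedEffectsMeta.from_results(rows, gene=gene)
        except InputError:
            continue
        out.append(model.fit().result)
    return out


def meta_to_frame(results: Sequence[MetaResult]) -> pd.DataFrame:
    rows = [{"gene": r.gene, "k": r.k, "or": r.or_pooled,
             "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
             "q": r.q_stat, "p_het": r.p_het} for r in results]
    return pd.DataFrame(rows, columns=["gene", "k", "or", "ci_low",
                                       "ci_high", "p", "q", "p_het"])
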