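"""Descriptive reporting: carrier summaries, onset comparison, thresholds.

Display conventions follow the usual presentation of gene-burden tables:
cumulative variant frequencies and significance thresholds to two
significant figures, odds ratios >= 1 to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .association import BurdenResult, results_to_frame
from .burden import round_sig
from .meta import MetaResult, meta_to_frame

__all__ = ["CarrierSummary", "bonferroni_threshold", "onset_compare",
           "carrier_summary", "format_report"]


@dataclass
class CarrierSummary:
    """Carrier counts and age-at-onset contrast for one gene/dataset."""

    gene: str
    dataset: str
    n_carriers: int
    n_case_carriers: int
    pct_carriers_with_disease: float
    mean_onset_carriers: Optional[float] = None
    sd_onset_carriers: Optional[float] = None
    n_onset_carriers: int = 0
    mean_onset_noncarriers: Optional[float] = None
    sd_onset_noncarriers: Optional[float] = None
    onset_p: Optional[float] = None


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold ``alpha / n_tests``.

    Returned at full precision; use :func:`lofburden.burden.round_sig` for
    the two-significant-figure display form.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def onset_compare(onsets_carriers: Sequence[float],
                  onsets_noncarriers: Sequence[float],
                  ) -> tuple[tuple[float, float], tuple[float, float],
                             Optional[float]]:
    """Welch unequal-variance comparison of age at onset by carrier status.

    Returns ``((mean_c, sd_c), (mean_n, sd_n), p)``; the two-sided P is
    omitted (None) when either group has fewer than two observations.
    SDs are sample (ddof=1) standard deviations.
    """
    a = np.asarray(onsets_carriers, dtype=float)
    b = np.asarray(onsets_noncarriers, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    mean_sd = lambda x: (float(x.mean()), float(x.std(ddof=1))) \
        if x.size >= 2 else (float(x.mean()) if x.size else float("nan"),
                             float("nan"))
    stats_a, stats_b = mean_sd(a), mean_sd(b)
    if a.size < 2 or b.size < 2:
        return stats_a, stats_b, None
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return stats_a, stats_b, p


def carrier_summary(gene: str, dataset: str, carrier: np.ndarray,
                    status: np.ndarray,
                    age_at_onset: Optional[np.ndarray] = None,
                    ) -> CarrierSummary:
    """Summarise carriers of a gene and, if onsets are given, compare
    onset age between carrier and non-carrier cases."""
    carrier = np.asarray(carrier).astype(bool)
    status = np.asarray(status).astype(bool)
    n_carriers = int(carrier.sum())
    n_case_carriers = int((carrier & status).sum())
    pct = 100.0 * n_case_carriers / n_carriers if n_carriers else float("nan")
    summary = CarrierSummary(gene=gene, dataset=dataset,
                             n_carriers=n_carriers,
                             n_case_carriers=n_case_carriers,
                             pct_carriers_with_disease=pct)
    if age_at_onset is not None:
        onset = np.asarray(age_at_onset, dtype=float)
        oc = onset[carrier & status]
        onc = onset[~carrier & status]
        (m_c, s_c), (m_n, s_n), p = onset_compare(oc, onc)
        summary.mean_onset_carriers = m_c
        summary.sd_onset_carriers = s_c
        summary.n_onset_carriers = int(np.sum(~np.isnan(oc)))
        summary.mean_onset_noncarriers = m_n
        summary.sd_onset_noncarriers = s_n
        summary.onset_p = p
    return summary


def _fmt_or(x: float) -> str:
    if not np.isfinite(x):
        return "inf"
    return f"{x:.1f}" if x >= 1 else f"{round_sig(x, 2):g}"


def format_report(results: Sequence[BurdenResult],
                  meta_results: Sequence[MetaResult],
                  n_tests: int, alpha: float = 0.05) -> str:
    """Plain-text association report with the multiple-testing threshold."""
    thr = bonferroni_threshold(n_tests, alpha)
    lines = [
        "Gene-based rare LOF burden association report",
        f"Significance threshold (Bonferroni, {n_tests} genes): "
        f"P < {alpha:g}/{n_tests} = {round_sig(thr, 2):.2g}",
        "",
        "Per-dataset results:",
        results_to_frame(list(results)).to_string(index=False),
        "",
    ]
    if meta_results:
        lines += ["Meta-analysis:",
                  meta_to_frame(list(meta_results)).to_string(index=False)]
        hits = [m for m in meta_results if m.p < thr]
        lines += ["", f"Genes below the threshold: "
                  f"{', '.join(m.gene for m in hits) if hits else '(none)'}"]
    return "\n".join(lines)
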