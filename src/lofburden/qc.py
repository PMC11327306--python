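"""Sequence-variant quality control.

Two filters are applied per variant:

1. **Depth-conditional allele-balance slope.**  For a well-behaved biallelic
   variant the alternate-allele read count of an individual should equal
   ``depth * genotype / 2`` on average: 0 for homozygous reference, half the
   depth for heterozygotes, the full depth for homozygous alternate.  Plotting
   observed alternate counts against that expectation, real germline variants
   fall on the identity line (slope 1, intercept 0); artifact and somatic
   signal falls below it.  We fit a single through-origin least-squares
   regression of observed alternate count on expected count, pooled over
   genotype classes, and fail variants whose slope is below 0.5.

2. **Caller confidence (AAscore).**  The variant caller assigns each site a
   probability of being a true positive; sites must exceed 0.8 (strictly).

Homozygous-reference records carry no expected signal under the
through-origin model and are excluded from the fit.  A variant with no
genotype-positive evidence cannot be assessed and is failed by policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import UndefinedSlopeError

__all__ = ["ReadEvidence", "QCResult", "fit_depth_slope", "apply_qc",
           "SLOPE_THRESHOLD", "AASCORE_THRESHOLD"]

#: variants with fitted slope below this are filtered (slope == 0.5 passes)
SLOPE_THRESHOLD = 0.5
#: variants must have caller true-positive probability strictly above this
AASCORE_THRESHOLD = 0.8


@dataclass(frozen=True)
class ReadEvidence:
    """Per-individual read support for one variant.

    Parameters
    ----------
    individual_id : str
        Sample identifier.
    depth : int
        Total read depth at the site (>= 0).
    alt_count : int
        Reads supporting the alternate allele, ``0 <= alt_count <= depth``.
    genotype : int
        Called alternate-allele dosage in {0, 1, 2}.
    """

    individual_id: str
    depth: int
    alt_count: int
    genotype: int

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError(
                f"alt_count must be in [0, depth]; got alt_count="
                f"{self.alt_count}, depth={self.depth}")
        if self.genotype not in (0, 1, 2):
            raise ValueError(f"genotype must be in {{0,1,2}}, got {self.genotype}")


@dataclass(frozen=True)
class QCResult:
    """Outcome of the two variant-quality filters."""

    slope: float
    aascore: float
    pass_slope: bool
    pass_aascore: bool

    @property
    def passed(self) -> bool:
        """True iff both the slope and the caller-score filter pass."""
        return self.pass_slope and self.pass_aascore


def fit_depth_slope(evidence: Iterable[ReadEvidence] | Sequence[ReadEvidence]) -> float:
    """Through-origin least-squares slope of alt count on expected alt count.

    The regressor for each genotype-positive record is
    ``x = depth * genotype / 2`` (the expected alternate count under the
    called genotype) and the response is the observed ``alt_count``; the
    returned slope is ``sum(x * y) / sum(x**2)``.  A perfectly behaved
    variant yields 1.0 exactly.

    Raises
    ------
    UndefinedSlopeError
        If no record has ``genotype > 0`` and ``depth > 0``; such variants
        cannot be assessed and are failed by QC policy.
    """
    ev = list(evidence)
    x = np.array([r.depth * r.genotype / 2.0 for r in ev], dtype=float)
    y = np.array([r.alt_count for r in ev], dtype=float)
    keep = x > 0
    if not keep.any():
        raise UndefinedSlopeError(
            "no genotype-positive read evidence; slope is undefined")
    x, y = x[keep], y[keep]
    return float(np.dot(x, y) / np.dot(x, x))


def fit_depth_slope_arrays(depth: np.ndarray, alt: np.ndarray,
                           genotype: np.ndarray) -> float:
    """Vectorised form of :func:`fit_depth_slope` on parallel arrays."""
    x = np.asarray(depth, dtype=float) * np.asarray(genotype, dtype=float) / 2.0
    y = np.asarray(alt, dtype=float)
    keep = x > 0
    if not keep.any():
        raise UndefinedSlopeError(
            "no genotype-positive read evidence; slope is undefined")
    x, y = x[keep], y[keep]
    return float(np.dot(x, y) / np.dot(x, x))


def apply_qc(slope: float, aascore: float) -> QCResult:
    """Apply the slope and caller-score filters.

    Boundary semantics follow the filter definitions literally: variants
    with slope *less than* 0.5 are removed, so slope exactly 0.5 passes;
    the caller-score filter requires AAscore *greater than* 0.8, so exactly
    0.8 fails.
    """
    if not (0.0 <= aascore <= 1.0):
        raise ValueError(f"aascore must be a probability in [0,1], got {aascore}")
    pass_slope = slope >= SLOPE_THRESHOLD
    pass_aascore = aascore > AASCORE_THRESHOLD
    return QCResult(slope=float(slope), aascore=float(aascore),
                    pass_slope=pass_slope, pass_aascore=pass_aascore)


def qc_variant(evidence: Iterable[ReadEvidence], aascore: float) -> QCResult:
    """Fit the slope on ``evidence`` and apply both filters.

    Variants whose slope is undefined (no assessable evidence) are failed
    conservatively with ``slope = nan``.
    """
    try:
        slope = fit_depth_slope(evidence)
    except UndefinedSlopeError:
        return QCResult(slope=float("nan"), aascore=float(aascore),
                        pass_slope=False,
                        pass_aascore=aascore > AASCORE_THRESHOLD)
    return apply_qc(slope, aascore)
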