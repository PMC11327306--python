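"""End-to-end orchestration: QC -> qualifying filter -> collapse -> test.

This stitches the stage modules together for callers holding either a
:class:`~lofburden.simulate.SyntheticCohort` or parsed VCF + phenotype
inputs.  Every filtered variant and skipped gene is logged with a
structured reason code (``qc_slope``, ``qc_aascore``, ``maf``, ``loftee``,
``zero_carriers``, ``non_autosomal``).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .association import BurdenResult, run_dataset
from .burden import (GeneBurden, VariantRecord, classify_lof, collapse_gene,
                     qualifying_filter)
from .cohort import Cohort
from .exceptions import InputError
from .qc import ReadEvidence, qc_variant

logger = logging.getLogger(__name__)

__all__ = ["annotate_qc", "qualifying_variants", "collapse_all",
           "run_burden_scan"]


def annotate_qc(variants: Sequence[VariantRecord],
                read_evidence: dict[int, list[ReadEvidence]]) -> None:
    """Attach a QCResult to every variant from its read evidence in place."""
    for v in variants:
        ev = read_evidence.get(v.column, [])
        v.qc = qc_variant(ev, v.aascore)


def qualifying_variants(variants: Sequence[VariantRecord],
                        maf_threshold: float = 0.001,
                        ) -> dict[str, list[VariantRecord]]:
    """Group qualifying variants by gene, logging every exclusion reason."""
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in variants:
        if not v.is_autosomal:
            logger.info("variant %s excluded: non_autosomal", v.key)
            continue
        if not classify_lof(v.consequence):
            continue
        if not (v.maf < maf_threshold):
            logger.info("variant %s excluded: maf (%.2g)", v.key, v.maf)
            continue
        if v.loftee_tag != "HC":
            logger.info("variant %s excluded: loftee (%s)", v.key, v.loftee_tag)
            continue
        if v.qc is None or not v.qc.pass_slope:
            logger.info("variant %s excluded: qc_slope", v.key)
            continue
        if not v.qc.pass_aascore:
            logger.info("variant %s excluded: qc_aascore", v.key)
            continue
        assert qualifying_filter(v, maf_threshold)
        by_gene.setdefault(v.gene, []).append(v)
    return by_gene


def collapse_all(genotype_table: np.ndarray,
                 by_gene: dict[str, list[VariantRecord]],
                 status: np.ndarray) -> list[GeneBurden]:
    return [collapse_gene(genotype_table, vs, gene, status)
            for gene, vs in by_gene.items()]


def run_burden_scan(cohort: Cohort, variants: Sequence[VariantRecord],
                    genotype_table: np.ndarray,
                    read_evidence: Optional[dict[int, list[ReadEvidence]]] = None,
                    maf_threshold: float = 0.001,
                    gc_intercept: float = 1.0,
                    sparse_threshold: int = 10) -> list[BurdenResult]:
    """Full per-dataset scan from annotated variants to association rows."""
    if genotype_table.shape[0] != cohort.n:
        raise InputError("genotype table rows do not match the cohort")
    if read_evidence is not None:
        annotate_qc(variants, read_evidence)
    by_gene = qualifying_variants(variants, maf_threshold)
    burdens = collapse_all(genotype_table, by_gene, cohort.status)
    return run_dataset(cohort, burdens, gc_intercept=gc_intercept,
                       sparse_threshold=sparse_threshold)
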