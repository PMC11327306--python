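"""Loss-of-function classification and per-gene carrier collapsing.

A variant qualifies for the burden of a gene when all of the following hold:

* its predicted consequence is one of the six LOF classes (start-lost,
  stop-gain, stop-lost, splice donor, splice acceptor, frameshift);
* its minor allele frequency is strictly below the rarity threshold
  (default 0.1%);
* the LOFTEE annotation flags it as high-confidence (``HC``);
* it passed variant QC (allele-balance slope and caller score).

Individuals are then coded 1 if they carry at least one qualifying variant
in the gene and 0 otherwise — an indicator, not a count.  Only autosomal
genes (chr1-22) are tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .qc import QCResult

__all__ = [
    "LOF_CONSEQUENCES", "VariantRecord", "GeneBurden",
    "classify_lof", "qualifying_filter", "collapse_gene",
    "cumulative_variant_frequency", "round_sig",
]

logger = logging.getLogger(__name__)

#: sequence-ontology terms counted as loss-of-function
LOF_CONSEQUENCES = frozenset({
    "start_lost",
    "stop_gained",
    "stop_lost",
    "splice_donor_variant",
    "splice_acceptor_variant",
    "frameshift_variant",
})

# non-LOF terms we recognise and silently classify as non-LOF; anything
# outside this vocabulary triggers a warning-level log event
_KNOWN_NON_LOF = frozenset({
    "missense_variant", "synonymous_variant", "intron_variant",
    "intergenic_variant", "upstream_gene_variant", "downstream_gene_variant",
    "5_prime_utr_variant", "3_prime_utr_variant", "splice_region_variant",
    "splice_donor_region_variant", "splice_polypyrimidine_tract_variant",
    "inframe_insertion", "inframe_deletion", "stop_retained_variant",
    "start_retained_variant", "coding_sequence_variant",
    "non_coding_transcript_variant", "non_coding_transcript_exon_variant",
    "protein_altering_variant", "incomplete_terminal_codon_variant",
    "nmd_transcript_variant", "regulatory_region_variant", "tf_binding_site_variant",
})

_AUTOSOMES = frozenset(
    {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}
)


@dataclass
class VariantRecord:
    """One biallelic site with its annotations.

    ``loftee_tag`` is ``"HC"`` (high confidence), ``"LC"`` (low confidence)
    or ``None`` when the LOFTEE plugin emitted nothing for the site.
    ``column`` is the variant's column index in the cohort genotype matrix,
    assigned by the VCF reader / simulator in record order.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    loftee_tag: Optional[str] = None
    aascore: float = 1.0
    maf: float = 0.0
    qc: Optional[QCResult] = None
    column: Optional[int] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"maf must be in [0, 0.5], got {self.maf}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_autosomal(self) -> bool:
        return self.chrom in _AUTOSOMES


@dataclass
class GeneBurden:
    """Collapsed 0/1 carrier indicator for one gene."""

    gene: str
    qualifying_variants: list = field(default_factory=list)
    carrier_indicator: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))
    n_carriers: int = 0
    n_case_carriers: int = 0


def classify_lof(consequence: str) -> bool:
    """True iff any component of an (ampersand-joined) consequence string
    is one of the six loss-of-function classes.

    Unrecognised terms are logged at warning level and treated as non-LOF.
    """
    terms = [t.strip().lower() for t in consequence.split("&") if t.strip()]
    is_lof = False
    for term in terms:
        if term in LOF_CONSEQUENCES:
            is_lof = True
        elif term not in _KNOWN_NON_LOF:
            logger.warning("unrecognized consequence term %r; treated as non-LOF", term)
    return is_lof


def qualifying_filter(v: VariantRecord, maf_threshold: float = 0.001,
                      missing_loftee: str = "exclude") -> bool:
    """Decide whether a variant enters the gene burden.

    Requires LOF consequence, ``maf < maf_threshold`` (strict), LOFTEE
    high-confidence tag and a passing QC record.  A LOF-class variant with
    no LOFTEE tag follows the ``missing_loftee`` policy (``"exclude"``,
    the default, logs a warning; ``"include"`` keeps it).
    """
    if missing_loftee not in ("exclude", "include"):
        raise ValueError("missing_loftee must be 'exclude' or 'include'")
    if not classify_lof(v.consequence):
        return False
    if not (v.maf < maf_threshold):
        return False
    if v.loftee_tag is None:
        if missing_loftee == "exclude":
            logger.warning("LOF variant %s has no LOFTEE tag; excluded", v.key)
            return False
    elif v.loftee_tag != "HC":
        return False
    if v.qc is None or not v.qc.passed:
        return False
    return True


def collapse_gene(genotype_table: np.ndarray,
                  variants: Sequence[VariantRecord],
                  gene: str,
                  status: np.ndarray) -> GeneBurden:
    """Collapse qualifying variants of ``gene`` into a 0/1 carrier indicator.

    Parameters
    ----------
    genotype_table : ndarray, shape (n_individuals, n_variants)
        Allele dosages in {0, 1, 2}; negative values mark missing genotypes
        and count as non-carrier (conservative for a rarity indicator).
    variants : sequence of VariantRecord
        The qualifying variants, each carrying its ``column`` index into
        ``genotype_table``.
    status : ndarray of 0/1
        Case flags aligned with the rows of ``genotype_table``.

    An empty variant list yields an all-zero indicator; such genes are
    skipped downstream.
    """
    n = genotype_table.shape[0]
    status = np.asarray(status)
    if status.shape[0] != n:
        raise ValueError("status length does not match genotype table rows")
    indicator = np.zeros(n, dtype=np.int8)
    for v in variants:
        if v.gene != gene:
            raise ValueError(f"variant {v.key} belongs to {v.gene}, not {gene}")
        if v.column is None:
            raise ValueError(f"variant {v.key} has no genotype column assigned")
        indicator |= (genotype_table[:, v.column] >= 1)
    n_carriers = int(indicator.sum())
    n_case_carriers = int(indicator[status == 1].sum())
    return GeneBurden(gene=gene, qualifying_variants=list(variants),
                      carrier_indicator=indicator,
                      n_carriers=n_carriers, n_case_carriers=n_case_carriers)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 maps to 0)."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(np.round(x, -int(np.floor(np.log10(abs(x)))) + (sig - 1)))


def cumulative_variant_frequency(burden: GeneBurden, n_cases: int,
                                 n_controls: int) -> tuple[float, float]:
    """Percent of cases and of controls carrying >= 1 qualifying variant.

    Returns ``(cvf_cases, cvf_controls)`` in percent, rounded to two
    significant figures (the reporting convention for these frequencies).
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must be positive")
    n_control_carriers = burden.n_carriers - burden.n_case_carriers
    if n_control_carriers < 0:
        raise ValueError("n_case_carriers exceeds n_carriers")
    cvf_cases = 100.0 * burden.n_case_carriers / n_cases
    cvf_controls = 100.0 * n_control_carriers / n_controls
    return round_sig(cvf_cases, 2), round_sig(cvf_controls, 2)
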