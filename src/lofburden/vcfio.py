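"""VCF and phenotype-table I/O.

The reader consumes VCF v4.2 with VEP-style ``CSQ`` INFO annotations (the
subfield layout is parsed from the ``##INFO=<ID=CSQ...Format: ...>`` header
line; required subfields: ``Consequence``, one of ``SYMBOL``/``Gene``, and
``LoF`` for the LOFTEE tag), a float ``AAS`` INFO field carrying the caller
true-positive probability, and ``GT``/``DP``/``AD`` FORMAT fields backing
the allele-balance QC regression.  Coordinates are 1-based fully closed,
as in the VCF text itself.

Records must be biallelic: multi-ALT lines are rejected with an error,
because consequence and allele-frequency semantics are per alternate
allele — decompose upstream.  Missing genotypes are coded -1 in the dosage
matrix and count as non-carrier downstream.  The minor allele frequency of
each variant is computed from the non-missing genotypes of the loaded
samples (a per-dataset sample frequency).

The writer emits the same layout from a synthetic cohort so simulated data
exercises the identical parsing path as real data.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .burden import VariantRecord
from .cohort import Cohort
from .exceptions import InputError
from .qc import ReadEvidence
from .simulate import SyntheticCohort

__all__ = ["write_vcf", "read_vcf", "write_phenotypes", "read_phenotypes",
           "VcfData"]

_CSQ_FIELDS = ["Allele", "Consequence", "SYMBOL", "Gene", "LoF"]


class VcfData:
    """Parsed VCF payload: variants, dosage matrix, read evidence."""

    def __init__(self, samples: list[str], variants: list[VariantRecord],
                 genotype_table: np.ndarray,
                 read_evidence: dict[int, list[ReadEvidence]]):
        self.samples = samples
        self.variants = variants
        self.genotype_table = genotype_table
        self.read_evidence = read_evidence


def write_vcf(synth: SyntheticCohort, path: str | Path) -> None:
    """Write a minimal single-ALT VCF v4.2 with CSQ, AAS and GT:AD:DP."""
    path = Path(path)
    cohort = synth.cohort
    n = cohort.n
    contigs = sorted({v.chrom for v in synth.variants},
                     key=lambda c: int(re.sub(r"\D", "", c) or 0))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=CSQ,Number=.,Type=String,Description="'
                 'Consequence annotations. Format: '
                 + "|".join(_CSQ_FIELDS) + '">\n')
        fh.write('##INFO=<ID=AAS,Number=1,Type=Float,Description="'
                 'Caller probability that the variant is a true positive">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="'
                 'Allelic depths (ref,alt)">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in cohort.ids) + "\n")
        order = sorted(range(len(synth.variants)),
                       key=lambda j: (contigs.index(synth.variants[j].chrom),
                                      synth.variants[j].pos))
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in order:
            v = synth.variants[j]
            dosages = synth.genotype_table[:, v.column]
            ev = {r.individual_id: r for r in synth.read_evidence.get(v.column, [])}
            csq = "|".join([v.alt, v.consequence, v.gene, v.gene,
                            v.loftee_tag or ""])
            fields = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS",
                      f"CSQ={csq};AAS={v.aascore:.4f}", "GT:AD:DP"]
            samples_out = []
            for i in range(n):
                g = int(dosages[i])
                r = ev.get(str(cohort.ids[i]))
                if r is None:
                    samples_out.append(gt_str[g] + ":.:.")
                else:
                    samples_out.append(
                        f"{gt_str[g]}:{r.depth - r.alt_count},{r.alt_count}:{r.depth}")
            fh.write("\t".join(fields + samples_out) + "\n")


def _parse_csq_format(header: pysam.VariantHeader) -> list[str]:
    rec = header.info.get("CSQ")
    if rec is None:
        raise InputError("VCF header has no CSQ INFO definition")
    m = re.search(r"Format:\s*([^\"]+)", rec.description or "")
    if not m:
        raise InputError("CSQ header line lacks a 'Format:' subfield list")
    return [f.strip() for f in m.group(1).split("|")]


def read_vcf(path: str | Path) -> VcfData:
    """Load a biallelic annotated VCF into pipeline containers."""
    vf = pysam.VariantFile(str(path))
    csq_fields = _parse_csq_format(vf.header)
    idx = {f: i for i, f in enumerate(csq_fields)}
    if "Consequence" not in idx:
        raise InputError("CSQ format lacks a Consequence subfield")
    gene_field = "SYMBOL" if "SYMBOL" in idx else "Gene"
    if gene_field not in idx:
        raise InputError("CSQ format lacks a SYMBOL/Gene subfield")

    samples = list(vf.header.samples)
    n = len(samples)
    variants: list[VariantRecord] = []
    dosage_cols: list[np.ndarray] = []
    read_evidence: dict[int, list[ReadEvidence]] = {}

    for col, rec in enumerate(vf.fetch() if vf.index else vf):
        if rec.alts is None or len(rec.alts) != 1:
            raise InputError(
                f"multi-allelic record at {rec.chrom}:{rec.pos}; decompose "
                "to biallelic records first")
        csq_raw = rec.info.get("CSQ")
        if csq_raw is None:
            raise InputError(f"record {rec.chrom}:{rec.pos} lacks CSQ")
        parts = (csq_raw[0] if isinstance(csq_raw, tuple) else csq_raw).split("|")
        consequence = parts[idx["Consequence"]]
        gene = parts[idx[gene_field]]
        lof = parts[idx["LoF"]] if "LoF" in idx and len(parts) > idx["LoF"] else ""
        try:
            aascore = float(rec.info["AAS"])
        except (KeyError, ValueError):
            aascore = 1.0

        dos = np.full(n, -1, dtype=np.int8)
        evidence: list[ReadEvidence] = []
        for i, s in enumerate(samples):
            smp = rec.samples[s]
            gt = smp.get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            g = int(sum(gt))
            dos[i] = g
            dp, ad = smp.get("DP"), smp.get("AD")
            if dp is not None and ad is not None and ad[1] is not None:
                evidence.append(ReadEvidence(individual_id=s, depth=int(dp),
                                             alt_count=int(ad[1]), genotype=g))
        called = dos >= 0
        af = dos[called].sum() / (2.0 * called.sum()) if called.any() else 0.0
        variants.append(VariantRecord(
            chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
            gene=gene, consequence=consequence,
            loftee_tag=lof if lof else None, aascore=aascore,
            maf=float(min(af, 1.0 - af)), column=col))
        dosage_cols.append(dos)
        read_evidence[col] = evidence

    table = np.column_stack(dosage_cols) if dosage_cols \
        else np.zeros((n, 0), dtype=np.int8)
    return VcfData(samples=samples, variants=variants, genotype_table=table,
                   read_evidence=read_evidence)


def write_phenotypes(cohort: Cohort, path: str | Path) -> None:
    """Tab-separated phenotype/covariate table (iid, status, covariates)."""
    df = pd.DataFrame({"iid": cohort.ids, "status": cohort.status})
    for c in cohort.covariates.columns:
        df[c] = cohort.covariates[c].to_numpy()
    if cohort.age_at_onset is not None:
        df["age_at_onset"] = cohort.age_at_onset
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | Path, covariate_cols: Optional[Sequence[str]] = None,
                    dataset: str = "cohort") -> Cohort:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    onset_col = "age_at_onset" if "age_at_onset" in df.columns else None
    return Cohort.from_dataframe(df, covariate_cols=list(covariate_cols or []),
                                 dataset=dataset, onset_col=onset_col)
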