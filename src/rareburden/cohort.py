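"""Cohort genotype container and VCF / phenotype-sheet I/O.

The central in-memory object of the pipeline is :class:`CohortGenotypes`: a
samples x loci matrix of unphased diploid alt-allele dosages ({0,1,2}, with
``-1`` marking a missing genotype call) together with case/control labels and
a site table (gene, variant id, chrom, pos, ref, alt).

Cohorts round-trip through plain-text VCF 4.2 (``GT`` only, ``GENE`` carried
in INFO) plus a two-column phenotype sheet ``sample_id<TAB>status`` with
status in {case, control}.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

#: sentinel dosage for a missing genotype call
MISSING: int = -1

SITE_COLUMNS = ["gene", "variant_id", "chrom", "pos", "ref", "alt"]


@dataclass
class CohortGenotypes:
    """Diploid dosage matrix with phenotype labels.

    Parameters
    ----------
    sites : pandas.DataFrame
        One row per locus with columns ``gene, variant_id, chrom, pos, ref,
        alt`` (1-based VCF coordinates and allele conventions).
    genotypes : numpy.ndarray
        ``(n_samples, n_loci)`` integer alt-allele dosages; ``MISSING`` (-1)
        marks no-calls.
    sample_ids : list of str
    is_case : numpy.ndarray of bool
        Case/control label per sample, aligned to ``sample_ids``.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    sample_ids: list[str]
    is_case: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        n_samples, n_loci = self.genotypes.shape
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match genotype rows")
        if len(self.sites) != n_loci:
            raise ValueError("site table length does not match genotype columns")
        if self.is_case.shape != (n_samples,):
            raise ValueError("is_case length does not match genotype rows")
        bad = ~np.isin(self.genotypes, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype dosages must be in {-1, 0, 1, 2}")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    def locus_index(self, variant_id: str) -> int:
        hits = np.flatnonzero(self.sites["variant_id"].to_numpy() == variant_id)
        if hits.size == 0:
            raise KeyError(f"variant {variant_id!r} not in cohort")
        return int(hits[0])

    def case_genotypes(self) -> np.ndarray:
        return self.genotypes[self.is_case]

    def control_genotypes(self) -> np.ndarray:
        return self.genotypes[~self.is_case]

    def to_frame(self) -> pd.DataFrame:
        """Dosage matrix as a DataFrame (samples x variant ids)."""
        return pd.DataFrame(
            self.genotypes,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.sites["variant_id"].to_list(),
        )


# -- phenotype sheets ----------------------------------------------------


def write_phenotypes(cohort: CohortGenotypes, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "status": np.where(cohort.is_case, "case", "control"),
        }
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    if list(sheet.columns[:2]) != ["sample_id", "status"]:
        # headerless two-column sheet
        sheet = pd.read_csv(
            path, sep="\t", dtype=str, header=None, names=["sample_id", "status"]
        )
    bad = set(sheet["status"]) - {"case", "control"}
    if bad:
        raise ValueError(f"phenotype status must be case/control, got {sorted(bad)}")
    return sheet


# -- VCF I/O -------------------------------------------------------------

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(cohort: CohortGenotypes, path: str | os.PathLike) -> None:
    """Write the cohort as an uncompressed VCF 4.2 with GT genotypes."""
    lines = ["##fileformat=VCFv4.2", "##source=rareburden"]
    for chrom in pd.unique(cohort.sites["chrom"].astype(str)):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(cohort.sample_ids)
    )
    order = np.lexsort(
        (cohort.sites["pos"].to_numpy(), cohort.sites["chrom"].astype(str).to_numpy())
    )
    for j in order:
        site = cohort.sites.iloc[j]
        gts = "\t".join(_GT_STRING[int(g)] for g in cohort.genotypes[:, j])
        lines.append(
            f"{site['chrom']}\t{int(site['pos'])}\t{site['variant_id']}\t"
            f"{site['ref']}\t{site['alt']}\t.\tPASS\tGENE={site['gene']}\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(
    path: str | os.PathLike, phenotype_sheet: str | os.PathLike | pd.DataFrame
) -> CohortGenotypes:
    """Read a GT-bearing VCF plus a phenotype sheet into a cohort.

    Every sample in the VCF must appear in the phenotype sheet; an unknown
    sample raises a ``ValueError`` naming it.
    """
    if isinstance(phenotype_sheet, pd.DataFrame):
        sheet = phenotype_sheet
    else:
        sheet = read_phenotypes(phenotype_sheet)
    status = dict(zip(sheet["sample_id"], sheet["status"]))

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in status:
            raise ValueError(f"sample {s!r} in VCF is absent from the phenotype sheet")

    rows, columns = [], []
    for v in vcf:
        dosages = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            alleles = gt[:2]
            dosages[i] = MISSING if min(alleles) < 0 else int(sum(alleles))
        columns.append(dosages)
        rows.append(
            {
                "gene": v.INFO.get("GENE") or "",
                "variant_id": v.ID or f"{v.CHROM}:{v.POS}",
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
            }
        )
    vcf.close()
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    genotypes = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0), np.int8)
    )
    is_case = np.array([status[s] == "case" for s in samples])
    return CohortGenotypes(sites, genotypes, samples, is_case)
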