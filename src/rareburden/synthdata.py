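"""Synthetic cohorts with the statistical structure of the PPROM study.

The generator plants candidate loci at chosen case/control alt-allele
frequencies in a diploid case/control cohort, with per-genotype
missingness (missing completely at random), and simulates AIMs genotypes
under the forward model of two-way admixture. Defaults mirror the study
conditions this pipeline targets: 264 cases and 218 controls (76 + 188 and
43 + 175 across discovery and follow-up), fourteen planted loci at the
published frequency pairs — rare loci carried strictly heterozygously, the
one common FUT2 locus (freq ~ 0.37) drawn under Hardy-Weinberg so
homozygotes occur — a 102-marker AIMs panel with mean ancestral frequency
difference delta ~ 0.733, and individual admixture proportions centred on
0.70.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .ancestry import AIMsPanel
from .cohort import (  # noqa: F401  (re-exported: cohorts are this module's output format)
    MISSING,
    SITE_COLUMNS,
    CohortGenotypes,
    read_phenotypes,
    read_vcf,
    write_phenotypes,
    write_vcf,
)


@dataclass(frozen=True)
class PlantedLocus:
    """One locus to plant: site definition plus per-group frequencies.

    With ``hwe=True`` genotypes are Binomial(2, f) draws (homozygotes occur
    at Hardy-Weinberg rates); with ``hwe=False`` carriers are strictly
    heterozygous (each sample het with probability 2f, so the expected
    alt-allele frequency is still f; requires f <= 0.5).
    """

    gene: str
    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    case_freq: float
    control_freq: float
    hwe: bool = False

    def __post_init__(self) -> None:
        for f in (self.case_freq, self.control_freq):
            if not np.isfinite(f) or not 0 <= f <= 1:
                raise ValueError(f"{self.variant_id}: frequency {f} outside [0, 1]")
        if not self.hwe and max(self.case_freq, self.control_freq) > 0.5:
            raise ValueError(
                f"{self.variant_id}: heterozygous-only planting needs freq <= 0.5"
            )
        if self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref == alt")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort dimensions, planted loci, missingness and seed."""

    n_cases: int
    n_controls: int
    loci: tuple[PlantedLocus, ...]
    missing_rate: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("each group needs at least one sample")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        object.__setattr__(self, "loci", tuple(self.loci))


def _anchor_alleles(ref: str, alt: str, pos: int) -> tuple[str, str, int]:
    """Rewrite published '-'-style indel alleles as VCF anchored alleles."""
    if ref == "-":
        return "A", "A" + alt, pos
    if alt == "-":
        return "A" + ref, "A", max(1, pos - 1)
    return ref, alt, pos


def study_loci(hwe_threshold: float = 0.1) -> tuple[PlantedLocus, ...]:
    """The fourteen planted loci at the published case/control frequencies.

    Loci with frequency above ``hwe_threshold`` (the common FUT2 stop) are
    drawn under Hardy-Weinberg; the rare loci are carried heterozygously,
    matching how the mutations were observed.
    """
    table = load_published_freqs()
    loci = []
    for r in table.itertuples():
        ref, alt, pos = _anchor_alleles(str(r.ref), str(r.alt), int(r.pos))
        loci.append(
            PlantedLocus(
                gene=str(r.gene),
                variant_id=str(r.variant_id),
                chrom=str(r.chrom),
                pos=pos,
                ref=ref,
                alt=alt,
                case_freq=float(r.case_freq),
                control_freq=float(r.control_freq),
                hwe=max(float(r.case_freq), float(r.control_freq)) > hwe_threshold,
            )
        )
    return tuple(loci)


def default_study_config(seed: int | None = None, missing_rate: float = 0.02) -> CohortConfig:
    """Combined-cohort study conditions: 264 cases / 218 controls."""
    return CohortConfig(
        n_cases=264, n_controls=218, loci=study_loci(), missing_rate=missing_rate, seed=seed
    )


def load_published_freqs() -> pd.DataFrame:
    """The bundled published per-locus frequency table (14 rows)."""
    with resources.files("rareburden.data").joinpath("published_variant_freqs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def gen_cohort(config: CohortConfig) -> CohortGenotypes:
    """Simulate a case/control cohort with the configured planted loci."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    is_case = np.zeros(n, dtype=bool)
    is_case[: config.n_cases] = True
    genotypes = np.zeros((n, len(config.loci)), dtype=np.int8)
    for j, locus in enumerate(config.loci):
        for mask, f in ((is_case, locus.case_freq), (~is_case, locus.control_freq)):
            m = int(mask.sum())
            if locus.hwe:
                genotypes[mask, j] = rng.binomial(2, f, size=m)
            else:
                genotypes[mask, j] = (rng.random(m) < 2 * f).astype(np.int8)
    if config.missing_rate > 0:
        drop = rng.random(genotypes.shape) < config.missing_rate
        genotypes[drop] = MISSING
    sites = pd.DataFrame(
        [
            {
                "gene": l.gene,
                "variant_id": l.variant_id,
                "chrom": l.chrom,
                "pos": l.pos,
                "ref": l.ref,
                "alt": l.alt,
            }
            for l in config.loci
        ],
        columns=SITE_COLUMNS,
    )
    width = len(str(n))
    sample_ids = [
        f"{'case' if is_case[i] else 'ctrl'}{i:0{width}d}" for i in range(n)
    ]
    return CohortGenotypes(sites, genotypes, sample_ids, is_case)


def gen_panel(n_markers: int, target_delta: float, seed: int | None = None) -> AIMsPanel:
    """AIMs panel whose mean |pA - pB| lands on ``target_delta``.

    Per-marker frequency gaps are jittered around the target and rescaled so
    the panel delta matches it (within 0.02 by construction); marker centres
    are uniform within the feasible band and the higher population is
    randomised per marker.
    """
    if not 0 < target_delta < 1:
        raise ValueError("target_delta must lie strictly between 0 and 1")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = np.random.default_rng(seed)
    jitter = 0.5 * min(0.3, target_delta, 1 - target_delta)
    gaps = target_delta + rng.uniform(-jitter, jitter, n_markers)
    gaps *= target_delta / gaps.mean()  # hit the target exactly in expectation
    gaps = np.clip(gaps, 1e-6, 1 - 1e-6)
    centres = rng.uniform(gaps / 2, 1 - gaps / 2)
    hi, lo = centres + gaps / 2, centres - gaps / 2
    swap = rng.random(n_markers) < 0.5
    freq_a = np.where(swap, lo, hi)
    freq_b = np.where(swap, hi, lo)
    panel = AIMsPanel(
        tuple(f"aim{i + 1:03d}" for i in range(n_markers)), freq_a, freq_b
    )
    if abs(panel.delta - target_delta) > 0.02:
        raise RuntimeError("panel delta missed the target; infeasible configuration")
    return panel


def gen_aims(thetas, panel: AIMsPanel, seed: int | None = None, missing_rate: float = 0.0) -> np.ndarray:
    """Forward-simulate AIMs genotypes under two-way admixture.

    Individual i at marker m is Binomial(2, theta_i * pA_m + (1 - theta_i)
    * pB_m). Returns an (n_individuals, n_markers) dosage matrix.
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.ndim != 1:
        raise ValueError("thetas must be a 1-D vector")
    if np.any((thetas < 0) | (thetas > 1)) or not np.all(np.isfinite(thetas)):
        raise ValueError("admixture proportions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = thetas[:, None] * panel.freq_a[None, :] + (1 - thetas[:, None]) * panel.freq_b[None, :]
    geno = rng.binomial(2, p).astype(np.int8)
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = MISSING
    return geno


def gen_thetas(
    n: int, mean: float = 0.70, sd: float = 0.08, seed: int | None = None
) -> np.ndarray:
    """Individual admixture proportions: normal draws clipped to [0, 1]."""
    rng = np.random.default_rng(seed)
    return np.clip(rng.normal(mean, sd, n), 0.0, 1.0)
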