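"""Coding-consequence classification and damaging-variant selection.

Variants are applied directly to a transcript's CDS (1-based CDS
coordinates, VCF-style ref/alt strings) and classified by translating the
mutated sequence:

* ``nonsense`` — substitution or in-frame change creating a premature stop;
  ``truncation_aa`` is the codon of the new stop.
* ``frameshift`` — indel whose length difference is not divisible by 3;
  ``truncation_aa`` is the first stop reached in the shifted frame, absent
  when no stop occurs before the transcript end.
* ``start_loss`` — any change that destroys the initiator ATG.
* ``missense`` / ``synonymous`` / ``inframe_indel`` — by comparison of the
  translated proteins.

Damaging-variant selection keeps all truncating classes and, optionally,
missense variants called damaging by *both* PolyPhen-2 (probably damaging)
and SIFT (damaging/deleterious) — the consensus rule used for the candidate
genes this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

from Bio.Seq import Seq

from .transcripts import START_CODON, TranscriptModel

Effect = Literal[
    "nonsense",
    "frameshift",
    "start_loss",
    "missense",
    "synonymous",
    "inframe_indel",
    "noncoding",
]

TRUNCATING_EFFECTS = frozenset({"nonsense", "frameshift", "start_loss"})

#: PolyPhen-2 / SIFT labels accepted by the consensus missense rule
POLYPHEN_DAMAGING = frozenset({"probably_damaging", "probably damaging"})
SIFT_DAMAGING = frozenset({"damaging", "deleterious"})


@dataclass(frozen=True)
class ConsequenceCall:
    """Predicted effect of one variant on one transcript."""

    effect: Effect
    codon_index: int | None = None  # 1-based first affected codon
    truncation_aa: int | None = None  # new stop position, truncating calls only
    aa_ref: str | None = None
    aa_alt: str | None = None


@dataclass(frozen=True)
class PredictionLabels:
    """Externally produced damaging-missense predictions for one variant."""

    variant_id: str
    polyphen_label: str
    sift_label: str

    @property
    def consensus_damaging(self) -> bool:
        return (
            self.polyphen_label.strip().lower() in POLYPHEN_DAMAGING
            and self.sift_label.strip().lower() in SIFT_DAMAGING
        )


def _translate(seq: str) -> str:
    """Translate complete codons; trailing partial codon ignored."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def call_consequence(
    transcript: TranscriptModel, cds_pos: int, ref: str, alt: str
) -> ConsequenceCall:
    """Classify a ref->alt change at a 1-based CDS position.

    The reference allele must match the CDS at ``cds_pos``; a mismatch is an
    error. Positions outside the CDS yield a ``noncoding`` call.
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty allele strings")
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    cds = transcript.cds
    if cds_pos < 1 or cds_pos > len(cds):
        return ConsequenceCall(effect="noncoding")
    if cds[cds_pos - 1 : cds_pos - 1 + len(ref)] != ref:
        raise ValueError(
            f"{transcript.gene}: ref allele {ref!r} does not match CDS at "
            f"position {cds_pos}"
        )

    mutated = cds[: cds_pos - 1] + alt + cds[cds_pos - 1 + len(ref) :]
    codon_index = (cds_pos - 1) // 3 + 1

    # initiator codon destroyed -> start loss regardless of downstream effect
    if cds_pos <= 3 and mutated[:3] != START_CODON:
        return ConsequenceCall(effect="start_loss", codon_index=1)

    shift = abs(len(ref) - len(alt)) % 3
    if shift != 0:
        protein = _translate(mutated)
        stop = protein.find("*")
        return ConsequenceCall(
            effect="frameshift",
            codon_index=codon_index,
            truncation_aa=None if stop == -1 else stop + 1,
        )

    old_protein = _translate(cds)
    new_protein = _translate(mutated)
    if len(ref) == len(alt):  # substitution (SNV or MNV)
        stop = new_protein.find("*")
        if stop != -1 and stop + 1 < len(old_protein):
            return ConsequenceCall(
                effect="nonsense",
                codon_index=codon_index,
                truncation_aa=stop + 1,
                aa_ref=old_protein[stop],
                aa_alt="*",
            )
        if new_protein == old_protein:
            return ConsequenceCall(effect="synonymous", codon_index=codon_index)
        # report the first changed residue
        diff = next(
            i for i, (a, b) in enumerate(zip(old_protein, new_protein)) if a != b
        )
        return ConsequenceCall(
            effect="missense",
            codon_index=diff + 1,
            aa_ref=old_protein[diff],
            aa_alt=new_protein[diff],
        )

    # in-frame indel: a stop anywhere before the last codon is premature
    stop = new_protein.find("*")
    if stop != -1 and stop < len(new_protein) - 1:
        return ConsequenceCall(
            effect="nonsense", codon_index=codon_index, truncation_aa=stop + 1
        )
    return ConsequenceCall(effect="inframe_indel", codon_index=codon_index)


@dataclass(frozen=True)
class DomainPartition:
    retained: tuple[str, ...]
    lost: tuple[str, ...]
    partial: tuple[str, ...]


def domains_affected(
    protein_length: int,
    truncation_aa: int,
    domains: Iterable[tuple[str, int, int]],
) -> DomainPartition:
    """Partition domains by a truncation at ``truncation_aa``.

    A domain ending before the truncation is retained; one starting at or
    after it is lost entirely; a domain straddling the cut is partial.
    """
    if not 1 <= truncation_aa <= protein_length:
        raise ValueError("truncation position outside the protein")
    retained, lost, partial = [], [], []
    for name, start, end in domains:
        if not (1 <= start <= end <= protein_length):
            raise ValueError(f"domain {name} [{start},{end}] outside [1,{protein_length}]")
        if end < truncation_aa:
            retained.append(name)
        elif start >= truncation_aa:
            lost.append(name)
        else:
            partial.append(name)
    return DomainPartition(tuple(retained), tuple(lost), tuple(partial))


def truncated_fraction(protein_length: int, truncation_aa: int) -> float:
    """Fraction of the protein removed by a stop at ``truncation_aa``.

    The residue at the truncation position and everything C-terminal of it
    is lost, so a stop at position 211 of a 248-residue protein removes
    38/248 of the chain.
    """
    if not 1 <= truncation_aa <= protein_length:
        raise ValueError("truncation position outside the protein")
    return (protein_length - truncation_aa + 1) / protein_length


def select_damaging(
    calls: Mapping[str, ConsequenceCall],
    labels: Mapping[str, PredictionLabels] | None = None,
    mode: Literal["truncating_only", "truncating_plus_consensus_missense"] = "truncating_only",
) -> list[str]:
    """Variant ids passing the damaging-variant inclusion rule.

    ``truncating_only`` keeps nonsense/frameshift/start-loss calls.
    ``truncating_plus_consensus_missense`` additionally keeps missense
    variants labelled probably-damaging by PolyPhen-2 AND damaging by SIFT;
    every missense call must then carry labels.
    """
    if mode not in ("truncating_only", "truncating_plus_consensus_missense"):
        raise ValueError(f"unknown mode {mode!r}")
    included = [vid for vid, c in calls.items() if c.effect in TRUNCATING_EFFECTS]
    if mode == "truncating_plus_consensus_missense":
        labels = labels or {}
        missense = [vid for vid, c in calls.items() if c.effect == "missense"]
        unlabelled = [vid for vid in missense if vid not in labels]
        if unlabelled:
            raise ValueError(
                "missing prediction labels for missense variants: "
                + ", ".join(sorted(unlabelled))
            )
        included += [vid for vid in missense if labels[vid].consensus_damaging]
    return included
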