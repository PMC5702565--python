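"""Toy transcript models: coding sequences with named protein domains.

A :class:`TranscriptModel` is a complete CDS (start codon through stop codon,
standard nuclear code) plus closed amino-acid intervals naming the protein's
domains. Consequence calling operates directly in CDS coordinates on these
models; genomic projection and splicing are out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"


@dataclass
class TranscriptModel:
    """A candidate-gene CDS with named domain intervals.

    ``cds`` must begin with ATG, end with a stop codon, have length divisible
    by three and contain no internal stop. ``domains`` are ``(name, start_aa,
    end_aa)`` closed 1-based intervals within the protein.
    """

    gene: str
    cds: str
    domains: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        if len(self.cds) % 3 != 0:
            raise ValueError(f"{self.gene}: CDS length {len(self.cds)} not divisible by 3")
        if not self.cds.startswith(START_CODON):
            raise ValueError(f"{self.gene}: CDS does not begin with ATG")
        if self.cds[-3:] not in STOP_CODONS:
            raise ValueError(f"{self.gene}: CDS does not end with a stop codon")
        protein = str(Seq(self.cds).translate())
        if "*" in protein[:-1]:
            raise ValueError(f"{self.gene}: internal stop codon in CDS")
        for name, start, end in self.domains:
            if not (1 <= start <= end <= self.protein_length):
                raise ValueError(
                    f"{self.gene}: domain {name} [{start},{end}] outside protein "
                    f"of length {self.protein_length}"
                )

    @property
    def protein_length(self) -> int:
        """Amino acids in the mature product, excluding the stop."""
        return len(self.cds) // 3 - 1

    @property
    def protein(self) -> str:
        return str(Seq(self.cds).translate())[:-1]


def gen_transcript(
    gene: str,
    protein_length: int,
    n_domains: int = 2,
    seed: int | None = None,
) -> TranscriptModel:
    """Generate a random toy transcript with non-overlapping domains.

    Codons are drawn uniformly from the 61 sense codons so the CDS carries no
    internal stop by construction.
    """
    if protein_length < 1:
        raise ValueError("protein_length must be >= 1")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    sense = [
        a + b + c
        for a in bases
        for b in bases
        for c in bases
        if a + b + c not in STOP_CODONS
    ]
    body = [sense[i] for i in rng.integers(0, len(sense), protein_length - 1)]
    stop = STOP_CODONS[rng.integers(0, 3)]
    cds = START_CODON + "".join(body) + stop

    domains: list[tuple[str, int, int]] = []
    if n_domains > 0 and protein_length >= 2 * n_domains:
        cuts = np.sort(rng.choice(np.arange(1, protein_length + 1), 2 * n_domains, replace=False))
        for k in range(n_domains):
            domains.append((f"dom{k + 1}", int(cuts[2 * k]), int(cuts[2 * k + 1])))
    return TranscriptModel(gene, cds, domains)


# -- I/O: CDS FASTA plus a domains TSV ----------------------------------


def write_transcripts(
    transcripts: list[TranscriptModel],
    fasta_path: str | os.PathLike,
    domains_path: str | os.PathLike,
) -> None:
    records = [
        SeqRecord(Seq(t.cds), id=t.gene, description="CDS") for t in transcripts
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {"gene": t.gene, "domain": name, "start_aa": start, "end_aa": end}
        for t in transcripts
        for name, start, end in t.domains
    ]
    pd.DataFrame(rows, columns=["gene", "domain", "start_aa", "end_aa"]).to_csv(
        domains_path, sep="\t", index=False
    )


def read_transcripts(
    fasta_path: str | os.PathLike, domains_path: str | os.PathLike | None = None
) -> list[TranscriptModel]:
    domains_by_gene: dict[str, list[tuple[str, int, int]]] = {}
    if domains_path is not None:
        table = pd.read_csv(domains_path, sep="\t")
        for row in table.itertuples():
            domains_by_gene.setdefault(row.gene, []).append(
                (row.domain, int(row.start_aa), int(row.end_aa))
            )
    return [
        TranscriptModel(rec.id, str(rec.seq), domains_by_gene.get(rec.id, []))
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
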