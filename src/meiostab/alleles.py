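"""Containers and FASTA I/O for per-gene haplotype allele sets.

A *haplotype allele* is one named sequence variant of a meiosis gene, labelled
with its inferred origin (ancestral diploid *A. lyrata*, ancestral diploid
*A. arenosa*, derived tetraploid, or unknown) and the ploidy of the plants it
was sampled from.  Sets of such alleles, length-aligned per gene, are the
inputs to diagnostic-site discovery, origin assignment and structural
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ORIGINS = ("diploid_lyrata", "diploid_arenosa", "derived_tetraploid", "unknown")

#: IUPAC subset accepted for allele sequences; '-' is allowed so that aligned
#: sets (with gaps) can be carried in the same container.
_ALPHABET = frozenset("ACGTN-")


@dataclass(frozen=True)
class HaplotypeAllele:
    """A named allele sequence for one gene with origin and ploidy labels."""

    gene: str
    allele_id: str
    origin: str
    sequence: str
    ploidy: int = 4

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"allele {self.allele_id!r}: empty sequence")
        if self.origin not in ORIGINS:
            raise ValueError(
                f"allele {self.allele_id!r}: origin {self.origin!r} not in {ORIGINS}"
            )
        bad = set(self.sequence.upper()) - _ALPHABET
        if bad:
            raise ValueError(
                f"allele {self.allele_id!r}: invalid characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")


def write_fasta(alleles: Iterable[HaplotypeAllele], path: str | Path) -> None:
    """Write alleles with ``>gene|allele_id|origin|ploidy`` headers."""
    records = [
        SeqRecord(
            Seq(a.sequence),
            id=f"{a.gene}|{a.allele_id}|{a.origin}|{a.ploidy}",
            description="",
        )
        for a in alleles
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[HaplotypeAllele]:
    """Read alleles written by :func:`write_fasta`.

    Headers without the full four-field form fall back to
    ``allele_id=header, origin=unknown, ploidy=4``.
    """
    out: list[HaplotypeAllele] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) == 4:
            gene, allele_id, origin, ploidy = parts
            out.append(
                HaplotypeAllele(gene, allele_id, origin, str(rec.seq), int(ploidy))
            )
        else:
            out.append(HaplotypeAllele("unknown", rec.id, "unknown", str(rec.seq)))
    return out
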