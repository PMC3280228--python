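"""Sequence records and FASTA I/O.

A :class:`ProteinRecord` is the unit that gets classified, aligned and
placed in trees: an identifier plus an amino-acid sequence over the
20-letter alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    seq: str

    def __post_init__(self):
        bad = set(self.seq) - set(AMINO_ACIDS)
        if bad:
            raise InputError(
                f"record {self.id!r}: non-amino-acid characters {sorted(bad)}"
            )
        if not self.seq:
            raise InputError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [ProteinRecord(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta_nt(path: str | Path) -> dict[str, str]:
    """Read a nucleotide FASTA into an id -> sequence mapping."""
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fasta_nt(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
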