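"""Sequence records and FASTA input/output.

All sequences are stored DNA-style in uppercase over {A, C, G, T, N}; RNA
input (containing U) is mapped to T on ingest and the original presentation
is remembered so round-trips are faithful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

_ALLOWED = set("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, normalised to DNA characters."""

    id: str
    seq: str
    alphabet_note: str = "DNA"  # "DNA" or "RNA", how the input was presented

    def __post_init__(self) -> None:
        bad = set(self.seq) - _ALLOWED
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-nucleotide characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "SequenceRecord":
        """Build a record from raw text, mapping U->T and uppercasing."""
        up = raw.upper()
        note = "RNA" if "U" in up else "DNA"
        return cls(id=id, seq=up.replace("U", "T"), alphabet_note=note)

    def as_rna(self) -> str:
        return self.seq.replace("T", "U")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-record, wrapped or unwrapped) FASTA file."""
    return [
        SequenceRecord.from_raw(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = (
        _BioRecord(Seq(r.as_rna() if r.alphabet_note == "RNA" else r.seq),
                   id=r.id, description="")
        for r in records
    )
    SeqIO.write(bio, str(path), "fasta")


def as_record(seq: "str | SequenceRecord", id: str = "seq") -> SequenceRecord:
    """Coerce a plain string (DNA or RNA) into a SequenceRecord."""
    if isinstance(seq, SequenceRecord):
        return seq
    return SequenceRecord.from_raw(id, seq)
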