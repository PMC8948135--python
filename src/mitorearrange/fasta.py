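"""Single-record FASTA reading/writing (uppercase-normalized)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Return (record id, uppercase sequence) of a single-record FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def write_fasta(seq: str, path: str | Path, name: str = "synthetic_mitogenome",
                description: str = "") -> None:
    rec = SeqRecord(Seq(seq.upper()), id=name, description=description)
    SeqIO.write([rec], str(path), "fasta")
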