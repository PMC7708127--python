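"""Thin FASTA helpers shared across modules."""

from __future__ import annotations

from typing import Dict

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> Dict[str, str]:
    """Load a FASTA file into an ordered name -> uppercase sequence dict.

    Raises ValueError on duplicate names or an empty file.
    """
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(records: Dict[str, str], path, width: int = 60) -> None:
    """Write sequences wrapped at a fixed column width (byte-reproducible)."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
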