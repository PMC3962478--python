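"""Small sequence utilities shared across the pipeline.

Contigs are held in memory as numpy byte arrays (dtype ``S1``) so that
context classification, methylome assignment and read simulation can all be
vectorised. FASTA I/O goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Genome = Dict[str, np.ndarray]  # contig name -> array of single bytes (S1)

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def seq_to_array(seq: str | bytes) -> np.ndarray:
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return np.frombuffer(seq.upper(), dtype="S1").copy()


def array_to_bytes(arr: np.ndarray) -> bytes:
    return arr.tobytes()


def revcomp_bytes(seq: bytes) -> bytes:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    return seq_to_array(revcomp_bytes(arr.tobytes()))


def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA file into a contig-name -> byte-array mapping."""
    genome: Genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = seq_to_array(str(rec.seq))
    return genome


def write_fasta(genome: Mapping[str, np.ndarray], path: str | Path, width: int = 70) -> None:
    records: Iterable[SeqRecord] = (
        SeqRecord(Seq(arr.tobytes().decode("ascii")), id=name, description="")
        for name, arr in genome.items()
    )
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
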