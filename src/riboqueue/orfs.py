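"""ORF annotation records and their on-disk representation.

Coordinate conventions used throughout the package:

* transcript coordinates are 0-based, half-open;
* the coding region ``[cds_start, cds_end)`` includes the stop codon;
* stop-anchored coordinates place 0 on the first nucleotide of the stop
  codon, so the last sense codon occupies ``[-3, 0)`` and the first
  nucleotide after the stop codon is ``+3``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError

ANNOTATION_COLUMNS = [
    "transcript_id",
    "cds_start",
    "cds_end",
    "strand",
    "utr3_len",
    "tx_len",
]


@dataclass(frozen=True)
class OrfAnnotation:
    """One ORF on one transcript.

    ``cds_seq`` is the DNA coding sequence including the stop codon.
    ``expression`` is a relative expression multiplier (1.0 for real
    annotations; the simulator records the generative value).
    """

    transcript_id: str
    cds_start: int
    cds_end: int
    utr3_len: int
    tx_len: int
    cds_seq: str
    strand: str = "+"
    expression: float = 1.0

    def __post_init__(self) -> None:
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise FormatError(
                f"{self.transcript_id}: coding length not divisible by 3"
            )
        if self.cds_seq and len(self.cds_seq) != self.cds_end - self.cds_start:
            raise FormatError(
                f"{self.transcript_id}: sequence length does not match coordinates"
            )

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def stop_start(self) -> int:
        """Transcript coordinate of the first stop-codon nucleotide."""
        return self.cds_end - 3

    @property
    def stop_codon(self) -> str:
        """Stop codon identity in RNA alphabet (UAA/UAG/UGA)."""
        return self.cds_seq[-3:].upper().replace("T", "U")

    @property
    def cterm_aa(self) -> str:
        """Amino acid encoded by the last sense codon."""
        return str(Seq(self.cds_seq[-6:-3]).translate())

    @property
    def protein(self) -> str:
        """Translation of the coding sequence without the stop codon."""
        return str(Seq(self.cds_seq[:-3]).translate())

    def to_stop_anchored(self, position: int) -> int:
        """Convert a transcript coordinate to a stop-anchored one."""
        return position - self.stop_start


def write_annotation(orfs: Iterable[OrfAnnotation], path: str | Path) -> None:
    rows = [
        {
            "transcript_id": o.transcript_id,
            "cds_start": o.cds_start,
            "cds_end": o.cds_end,
            "strand": o.strand,
            "utr3_len": o.utr3_len,
            "tx_len": o.tx_len,
            "expression": o.expression,
        }
        for o in orfs
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS + ["expression"]).to_csv(
        path, sep="\t", index=False
    )


def write_fasta(orfs: Iterable[OrfAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(f">{o.transcript_id}\n{o.cds_seq}\n")


def load_annotation(
    annotation_path: str | Path, fasta_path: str | Path | None = None
) -> list[OrfAnnotation]:
    """Read an annotation TSV (and optionally the coding-sequence FASTA).

    The TSV must carry transcript_id, cds_start, cds_end, strand, utr3_len;
    tx_len and expression are optional (tx_len defaults to
    cds_end + utr3_len).
    """
    df = pd.read_csv(annotation_path, sep="\t", comment="#")
    missing = set(ANNOTATION_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise FormatError(f"annotation missing columns: {sorted(missing)}")
    seqs: dict[str, str] = {}
    if fasta_path is not None:
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
    orfs = []
    for row in df.itertuples(index=False):
        tx = str(row.transcript_id)
        tx_len = int(getattr(row, "tx_len", row.cds_end + row.utr3_len))
        orfs.append(
            OrfAnnotation(
                transcript_id=tx,
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                utr3_len=int(row.utr3_len),
                tx_len=tx_len,
                cds_seq=seqs.get(tx, ""),
                strand=str(row.strand),
                expression=float(getattr(row, "expression", 1.0)),
            )
        )
    return orfs
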