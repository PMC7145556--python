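"""Footprint processing: P-site assignment, RPM normalisation, pooling.

Turns ribosome-footprint alignments (transcript coordinates, BED-like) into
per-transcript P-site coverage tracks. The P-site of each read is located by
a read-length-specific offset from the 5' end; reads whose length is absent
from the offset table, or whose P-site would fall outside the transcript,
are dropped and counted.

Short footprints (20-22 nt) come from ribosomes with a vacant A-site, long
ones (28-30 nt) from ribosomes with an occupied A-site; the class balance is
reported per library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, RiboQueueError

ALIGNMENT_COLUMNS = ["transcript_id", "start", "end", "read_length"]

SHORT_CLASS = (20, 22)  # vacant A-site footprints, inclusive bounds
LONG_CLASS = (28, 30)  # occupied A-site footprints

#: Default 5'-end -> P-site offsets. The 5' boundary of the yeast ribosome
#: sits approximately 12 nt upstream of the P-site codon for all footprint
#: lengths handled here; fully overridable via a TSV offset table.
DEFAULT_OFFSET = 12
DEFAULT_OFFSET_LENGTHS = range(20, 33)


@dataclass(frozen=True)
class OffsetTable:
    """Map read length (nt) -> distance from the 5' end to the P-site."""

    offsets: Mapping[int, int]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for length, off in self.offsets.items():
            if off < 0:
                raise FormatError(f"negative offset for length {length}")

    def __contains__(self, length: int) -> bool:
        return length in self.offsets

    def __getitem__(self, length: int) -> int:
        return self.offsets[length]


def default_offset_table() -> OffsetTable:
    return OffsetTable(
        {ln: DEFAULT_OFFSET for ln in DEFAULT_OFFSET_LENGTHS},
        provenance=f"built-in constant {DEFAULT_OFFSET} nt (lengths 20-32)",
    )


def load_offsets(path: str | Path) -> OffsetTable:
    """Read a two-column TSV (read length, offset) into an OffsetTable."""
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=["length", "offset"]
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse offset table {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"no offsets in {path}")
    # a header row is tolerated: drop non-numeric first line
    if not str(df.iloc[0, 0]).lstrip("-").isdigit():
        df = df.iloc[1:]
        if df.empty:
            raise FormatError(f"no offsets in {path}")
    try:
        lengths = df["length"].astype(int)
        offs = df["offset"].astype(int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-integer value in offset table {path}") from exc
    if (df["length"].astype(float) != lengths).any() or (
        df["offset"].astype(float) != offs
    ).any():
        raise FormatError(f"non-integer value in offset table {path}")
    if lengths.duplicated().any():
        dupes = sorted(lengths[lengths.duplicated()].unique())
        raise FormatError(f"duplicate read length(s) in offset table: {dupes}")
    return OffsetTable(dict(zip(lengths, offs)), provenance=str(path))


@dataclass
class CoverageTrack:
    """Per-transcript vector of P-site counts (and RPM) at nt resolution."""

    transcript_id: str
    counts: np.ndarray
    library_size: int
    rpm: np.ndarray | None = None
    condition: str | None = None

    def require_rpm(self) -> np.ndarray:
        if self.rpm is None:
            raise RiboQueueError(
                f"{self.transcript_id}: track is not RPM-normalised"
            )
        return self.rpm


@dataclass
class LibraryStats:
    """Read accounting for one footprint library."""

    total_reads: int = 0
    assigned_reads: int = 0
    dropped_unknown_length: int = 0
    dropped_out_of_bounds: int = 0
    per_length: dict[int, int] = field(default_factory=dict)

    @property
    def dropped_reads(self) -> int:
        return self.dropped_unknown_length + self.dropped_out_of_bounds

    def _class_count(self, bounds: tuple[int, int]) -> int:
        lo, hi = bounds
        return sum(n for ln, n in self.per_length.items() if lo <= ln <= hi)

    @property
    def short_fraction(self) -> float:
        return self._fraction(SHORT_CLASS)

    @property
    def long_fraction(self) -> float:
        return self._fraction(LONG_CLASS)

    def _fraction(self, bounds: tuple[int, int]) -> float:
        classified = self._class_count(SHORT_CLASS) + self._class_count(LONG_CLASS)
        if self.total_reads == 0:
            return float("nan")
        if classified == 0:
            return 0.0
        return self._class_count(bounds) / classified


def load_alignments(path: str | Path) -> pd.DataFrame:
    """Read a BED-like alignment TSV (transcript_id, start, end, read_length)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"alignment file missing columns: {sorted(missing)}")
    return df[ALIGNMENT_COLUMNS]


def write_alignments(alignments: pd.DataFrame, path: str | Path) -> None:
    alignments.to_csv(path, sep="\t", index=False, columns=ALIGNMENT_COLUMNS)


def length_histogram(alignments: pd.DataFrame) -> LibraryStats:
    """Per-length read counts and short/long class fractions."""
    stats = LibraryStats(total_reads=len(alignments))
    counts = alignments["read_length"].value_counts()
    stats.per_length = {int(k): int(v) for k, v in counts.items()}
    return stats


def assign_psites(
    alignments: pd.DataFrame,
    offsets: OffsetTable,
    transcript_lengths: Mapping[str, int],
) -> tuple[dict[str, CoverageTrack], LibraryStats]:
    """Assign each footprint's P-site as 5' start + offset(read length).

    Returns one count track per transcript plus library statistics. Reads
    with an unknown length or a P-site outside the transcript are dropped
    and counted; ``library_size`` is the number of assigned reads.
    """
    unknown_tx = set(alignments["transcript_id"]) - set(transcript_lengths)
    if unknown_tx:
        raise RiboQueueError(
            f"alignments refer to unknown transcript(s): {sorted(unknown_tx)[:10]}"
        )
    stats = length_histogram(alignments)

    lengths = alignments["read_length"].to_numpy()
    offset_map = {ln: offsets[ln] for ln in np.unique(lengths) if ln in offsets}
    known = np.isin(lengths, list(offset_map))
    stats.dropped_unknown_length = int((~known).sum())

    sub = alignments.loc[known]
    off = sub["read_length"].map(offset_map).to_numpy()
    psite = sub["start"].to_numpy() + off
    tx_len = sub["transcript_id"].map(transcript_lengths).to_numpy()
    in_bounds = (psite >= 0) & (psite < tx_len)
    stats.dropped_out_of_bounds = int((~in_bounds).sum())

    kept = pd.DataFrame(
        {"transcript_id": sub["transcript_id"].to_numpy()[in_bounds],
         "psite": psite[in_bounds]}
    )
    stats.assigned_reads = len(kept)

    tracks: dict[str, CoverageTrack] = {}
    grouped = {
        tx: grp["psite"].to_numpy()
        for tx, grp in kept.groupby("transcript_id", sort=False, observed=True)
    }
    for tx, n in transcript_lengths.items():
        sites = grouped.get(tx)
        counts = (
            np.bincount(sites, minlength=n).astype(np.int64)
            if sites is not None
            else np.zeros(n, dtype=np.int64)
        )
        tracks[tx] = CoverageTrack(
            transcript_id=tx, counts=counts, library_size=stats.assigned_reads
        )
    return tracks, stats


def normalize_rpm(
    tracks: dict[str, CoverageTrack], library_size: int | None = None
) -> dict[str, CoverageTrack]:
    """Fill the reads-per-million vector: rpm = counts * 1e6 / library size."""
    if library_size is None:
        sizes = {t.library_size for t in tracks.values()}
        if len(sizes) != 1:
            raise RiboQueueError("tracks carry inconsistent library sizes")
        library_size = sizes.pop()
    if library_size <= 0:
        raise RiboQueueError("library size must be positive for RPM normalisation")
    for t in tracks.values():
        t.library_size = library_size
        t.rpm = t.counts * (1e6 / library_size)
    return tracks


def pool_libraries(
    tracks_by_replicate: Sequence[dict[str, CoverageTrack]],
    condition: str | None = None,
) -> dict[str, CoverageTrack]:
    """Sum replicate count tracks; RPM is recomputed over the pooled size."""
    if not tracks_by_replicate:
        raise RiboQueueError("no libraries to pool")
    ref = tracks_by_replicate[0]
    for other in tracks_by_replicate[1:]:
        if set(other) != set(ref):
            raise RiboQueueError("cannot pool libraries over different transcripts")
    pooled_size = sum(next(iter(rep.values())).library_size for rep in tracks_by_replicate)
    pooled: dict[str, CoverageTrack] = {}
    for tx in ref:
        counts = sum(rep[tx].counts for rep in tracks_by_replicate)
        pooled[tx] = CoverageTrack(
            transcript_id=tx,
            counts=counts,
            library_size=pooled_size,
            condition=condition,
        )
    return normalize_rpm(pooled, pooled_size)


def project_to_transcript(
    genomic_alignments: pd.DataFrame, gff3_path: str | Path
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Project genome-space alignments onto spliced transcript coordinates.

    ``genomic_alignments`` needs columns chrom, start, end (0-based,
    half-open). Reads fully contained in a single exon of a single gene are
    mapped into that gene's spliced-transcript coordinates (minus-strand
    genes reversed); junction-spanning or intergenic reads are dropped and
    logged. Returns (transcript-space alignments, drop log).
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise FormatError(f"malformed GFF3 {gff3_path}: {exc}") from exc

    # exon chains per gene, with cumulative spliced offsets
    exon_index: dict[str, list[tuple[int, int, str, int, str]]] = {}
    for gene in db.features_of_type("gene"):
        exons = sorted(
            db.children(gene, featuretype="exon"), key=lambda e: e.start
        )
        if not exons:
            continue
        chain = [(e.start - 1, e.end) for e in exons]  # GFF3 is 1-based closed
        offset = 0
        for lo, hi in chain if gene.strand == "+" else reversed(chain):
            exon_index.setdefault(gene.seqid, []).append(
                (lo, hi, gene.id, offset, gene.strand)
            )
            offset += hi - lo

    rows = []
    dropped = {"intergenic_or_junction": 0}
    for read in genomic_alignments.itertuples(index=False):
        hit = None
        for lo, hi, gene_id, offset, strand in exon_index.get(read.chrom, []):
            if read.start >= lo and read.end <= hi:
                hit = (lo, hi, gene_id, offset, strand)
                break
        if hit is None:
            dropped["intergenic_or_junction"] += 1
            continue
        lo, hi, gene_id, offset, strand = hit
        length = read.end - read.start
        if strand == "+":
            t_start = offset + (read.start - lo)
        else:
            t_start = offset + (hi - read.end)
        rows.append((gene_id, t_start, t_start + length, length))
    out = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    return out, dropped


def write_bedgraph(
    tracks: Mapping[str, CoverageTrack], path: str | Path, use_rpm: bool = True
) -> None:
    """Write per-transcript coverage as bedGraph intervals of constant value."""
    with open(path, "w") as fh:
        for tx in sorted(tracks):
            track = tracks[tx]
            values = track.require_rpm() if use_rpm else track.counts
            if not len(values):
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(values)]))
            for s, e in zip(starts, ends):
                if values[s] != 0:
                    fh.write(f"{tx}\t{s}\t{e}\t{values[s]:.6g}\n")
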