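"""Readthrough diagnostics: 3'UTR ribosome density and frame periodicity.

Elevated density after the stop codon can reflect either stop-codon
readthrough (ribosomes still translating, hence codon-periodic signal in
the frame of the upstream ORF) or non-translating species. The verdict is
therefore reported as a density ratio plus frame fractions with a
chi-square test against uniform frames, never as a binary call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .orfs import OrfAnnotation
from .processing import CoverageTrack

Window = tuple[int, int]

#: default stop-anchored windows: the UTR window starts at +3 (first nt
#: after the stop codon) and spans 60 nt; the ORF window is the scored
#: 3'-terminal 120 nt
DEFAULT_UTR_WINDOW: Window = (3, 63)
DEFAULT_ORF_WINDOW: Window = (-120, 0)


def utr3_ratio(
    track: CoverageTrack,
    orf: OrfAnnotation,
    utr_window: Window = DEFAULT_UTR_WINDOW,
    orf_window: Window = DEFAULT_ORF_WINDOW,
) -> dict | None:
    """Mean 3'UTR density over mean ORF-terminal density for one ORF.

    The UTR window is truncated (and flagged) if the annotated 3'UTR is
    shorter; ORFs with no 3'UTR, or too short for the ORF window, are
    excluded (None).
    """
    rpm = track.require_rpm()
    anchor = orf.stop_start
    if orf.utr3_len <= 0:
        return None
    if anchor + orf_window[0] < 0 or orf.cds_len < 3 - orf_window[0]:
        return None
    flag = None
    utr_lo, utr_hi = utr_window
    max_hi = 3 + orf.utr3_len
    if utr_hi > max_hi:
        utr_hi = max_hi
        flag = "utr_truncated"
    orf_mean = float(rpm[anchor + orf_window[0] : anchor + orf_window[1]].mean())
    utr_mean = float(rpm[anchor + utr_lo : anchor + utr_hi].mean())
    if orf_mean == 0.0:
        return {
            "orf_id": orf.transcript_id, "utr_mean_rpm": utr_mean,
            "orf_window_mean_rpm": 0.0, "ratio": math.nan,
            "flag": "zero_orf_window",
        }
    return {
        "orf_id": orf.transcript_id,
        "utr_mean_rpm": utr_mean,
        "orf_window_mean_rpm": orf_mean,
        "ratio": utr_mean / orf_mean,
        "flag": flag,
    }


def frame_counts(
    track: CoverageTrack, orf: OrfAnnotation, region: Window = DEFAULT_UTR_WINDOW
) -> np.ndarray:
    """Raw P-site counts binned by reading frame within a stop-anchored
    region; frame 0 continues the frame of the upstream ORF provided the
    region start is a multiple of 3 (the default +3 is)."""
    lo, hi = region
    a, b = orf.stop_start + lo, orf.stop_start + hi
    a, b = max(a, 0), min(b, len(track.counts))
    counts = np.zeros(3, dtype=np.int64)
    seg = track.counts[a:b]
    idx = (np.arange(a, b) - (orf.stop_start + lo)) % 3
    for f in range(3):
        counts[f] = int(seg[idx == f].sum())
    return counts


def frame_periodicity(counts: np.ndarray) -> dict:
    """Frame fractions and chi-square goodness of fit against uniform
    (1/3, 1/3, 1/3) frame usage, 2 degrees of freedom."""
    total = int(np.sum(counts))
    if total == 0:
        return {"n_reads": 0, "f0": math.nan, "f1": math.nan, "f2": math.nan,
                "chi2": math.nan, "p": math.nan}
    chi2, p = stats.chisquare(counts)
    f = np.asarray(counts) / total
    return {"n_reads": total, "f0": f[0], "f1": f[1], "f2": f[2],
            "chi2": float(chi2), "p": float(p)}


def score_readthrough(
    tracks: Mapping[str, CoverageTrack],
    orfs: Sequence[OrfAnnotation],
    utr_window: Window = DEFAULT_UTR_WINDOW,
    orf_window: Window = DEFAULT_ORF_WINDOW,
) -> pd.DataFrame:
    """Per-ORF readthrough table: density ratio + UTR frame periodicity."""
    rows = []
    for orf in orfs:
        track = tracks.get(orf.transcript_id)
        if track is None:
            continue
        row = utr3_ratio(track, orf, utr_window, orf_window)
        if row is None:
            continue
        row.update(frame_periodicity(frame_counts(track, orf, utr_window)))
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_utr_frame_test(
    tracks: Mapping[str, CoverageTrack],
    orfs: Sequence[OrfAnnotation],
    region: Window = DEFAULT_UTR_WINDOW,
) -> dict:
    """Frame periodicity of UTR counts pooled over all ORFs."""
    total = np.zeros(3, dtype=np.int64)
    for orf in orfs:
        track = tracks.get(orf.transcript_id)
        if track is not None and orf.utr3_len > 0:
            total += frame_counts(track, orf, region)
    return frame_periodicity(total)
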