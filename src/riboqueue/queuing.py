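"""The C-terminal ribosome queuing metric.

When termination or ribosome recycling is slow, elongating ribosomes stack
behind the terminating one, producing coverage peaks spaced one protected-
fragment length (~30 nt) apart upstream of the stop codon. The queuing
metric Q of an ORF is the ratio between the sum of the maximal P-site
densities within the three peak windows preceding the stop codon and the
average density between the peaks. Q is dimensionless and invariant under
library rescaling; on a flat positive track it equals exactly 3 (one
maximum per peak window, each equal to the inter-peak mean).

The default peak layout places the k-th queued ribosome's P-site codon at
stop-anchored position -3 - 30k (the terminating ribosome occupies the last
sense codon at -3): peak windows of half-width 5 nt around -33, -63, -93,
inter-peak windows filling the gaps, and the stop-proximal zone [-6, 0)
excluded because terminating footprints are depleted without cycloheximide
stabilisation. The layout is fully configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RiboQueueError
from .orfs import OrfAnnotation
from .processing import CoverageTrack

Window = tuple[int, int]  # stop-anchored, half-open


@dataclass(frozen=True)
class PeakLayout:
    """Stop-anchored peak and inter-peak windows (half-open intervals)."""

    peak_windows: tuple[Window, ...] = ((-38, -28), (-68, -58), (-98, -88))
    inter_windows: tuple[Window, ...] = ((-28, -6), (-58, -38), (-88, -68))

    def __post_init__(self) -> None:
        spans = list(self.peak_windows) + list(self.inter_windows)
        for lo, hi in spans:
            if not (-120 <= lo < hi <= 0):
                raise ConfigurationError(f"window {(lo, hi)} outside [-120, 0)")
        covered: set[int] = set()
        for lo, hi in spans:
            cells = set(range(lo, hi))
            if covered & cells:
                raise ConfigurationError("peak/inter-peak windows overlap")
            covered |= cells

    @property
    def min_extent(self) -> int:
        """Most-upstream stop-anchored coordinate any window touches."""
        return min(lo for lo, _ in self.peak_windows + self.inter_windows)


def default_peak_layout() -> PeakLayout:
    return PeakLayout()


@dataclass
class QueuingConfig:
    layout: PeakLayout = field(default_factory=default_peak_layout)
    coverage_window: Window = (-120, 0)
    min_coverage_rpm: float = 10.0
    zscore_cutoff: float = 1.0
    #: conditions that must pass the coverage filter; None = all present
    conditions: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.min_coverage_rpm < 0:
            raise ConfigurationError("min coverage must be >= 0")


# reason codes for excluded ORFs
TOO_SHORT = "too_short"
ZERO_INTERPEAK = "undefined_zero_interpeak"


def _window_values(
    values: np.ndarray, anchor: int, window: Window
) -> np.ndarray:
    lo, hi = anchor + window[0], anchor + window[1]
    if lo < 0 or hi > len(values):
        raise RiboQueueError("window outside transcript")
    return values[lo:hi]


def queuing_metric_vector(
    values: np.ndarray, anchor: int, layout: PeakLayout | None = None
) -> tuple[float, str | None]:
    """Q on a raw density vector with the stop codon starting at ``anchor``.

    Returns ``(Q, flag)``; Q is NaN (flagged) when the inter-peak mean is 0.
    """
    layout = layout or default_peak_layout()
    peak_vals = [_window_values(values, anchor, w) for w in layout.peak_windows]
    inter = np.concatenate(
        [_window_values(values, anchor, w) for w in layout.inter_windows]
    )
    # dividing by the common window maximum leaves the ratio unchanged but
    # makes Q exact (= number of peaks) on constant tracks
    scale = max(float(inter.max(initial=0.0)), *(float(v.max()) for v in peak_vals))
    if scale <= 0.0:
        return math.nan, ZERO_INTERPEAK
    peak_sum = sum(float((v / scale).max()) for v in peak_vals)
    denom = float((inter / scale).mean())
    if denom == 0.0:
        return math.nan, ZERO_INTERPEAK
    return peak_sum / denom, None


def queuing_metric(
    track: CoverageTrack, orf: OrfAnnotation, layout: PeakLayout | None = None
) -> tuple[float, str | None]:
    """Queuing metric of one ORF from its RPM-normalised coverage track."""
    layout = layout or default_peak_layout()
    if orf.cds_len < 3 - layout.min_extent:
        return math.nan, TOO_SHORT
    return queuing_metric_vector(track.require_rpm(), orf.stop_start, layout)


def window_mean_rpm(
    track: CoverageTrack, orf: OrfAnnotation, window: Window = (-120, 0)
) -> float:
    return float(_window_values(track.require_rpm(), orf.stop_start, window).mean())


def coverage_filter(
    tracks_by_condition: Mapping[str, Mapping[str, CoverageTrack]],
    orf: OrfAnnotation,
    config: QueuingConfig,
) -> tuple[bool, str | None]:
    """Pass iff mean RPM over the coverage window >= threshold in every
    required condition (inclusive), and the window fits in the ORF."""
    lo, _ = config.coverage_window
    if orf.cds_len < 3 - lo:  # window must sit in the coding region
        return False, TOO_SHORT
    required = config.conditions or tuple(tracks_by_condition)
    for cond in required:
        if cond not in tracks_by_condition:
            raise RiboQueueError(f"missing condition {cond!r}")
        track = tracks_by_condition[cond].get(orf.transcript_id)
        if track is None:
            raise RiboQueueError(
                f"missing track for {orf.transcript_id} in condition {cond!r}"
            )
        if window_mean_rpm(track, orf, config.coverage_window) < config.min_coverage_rpm:
            return False, f"low_coverage:{cond}"
    return True, None


def score_all(
    tracks_by_condition: Mapping[str, Mapping[str, CoverageTrack]],
    orfs: Sequence[OrfAnnotation],
    config: QueuingConfig | None = None,
) -> pd.DataFrame:
    """Q and Z-score per ORF per condition, on the coverage-filtered set.

    The filtered ORF set is shared across conditions (an ORF is scored only
    if it passes the coverage filter in every required condition). Z-scores
    are computed within each condition over the defined Q values with the
    sample standard deviation (ddof=1).
    """
    config = config or QueuingConfig()
    rows = []
    for orf in orfs:
        ok, reason = coverage_filter(tracks_by_condition, orf, config)
        if not ok:
            continue
        for cond, tracks in tracks_by_condition.items():
            track = tracks[orf.transcript_id]
            q, flag = queuing_metric(track, orf, config.layout)
            rows.append(
                {
                    "orf_id": orf.transcript_id,
                    "condition": cond,
                    "Q": q,
                    "cterm_aa": orf.cterm_aa,
                    "stop_codon": orf.stop_codon,
                    "mean_rpm": window_mean_rpm(track, orf, config.coverage_window),
                    "flag": flag,
                }
            )
    scores = pd.DataFrame(
        rows,
        columns=["orf_id", "condition", "Q", "cterm_aa", "stop_codon", "mean_rpm", "flag"],
    )
    scores["z"] = np.nan
    for cond, grp in scores.groupby("condition"):
        defined = grp["Q"].dropna()
        if len(defined) < 2:
            warnings.warn(f"condition {cond!r}: <2 defined Q values, no Z-scores")
            continue
        sd = defined.std(ddof=1)
        if sd == 0:
            warnings.warn(f"condition {cond!r}: zero Q variance, no Z-scores")
            continue
        scores.loc[defined.index, "z"] = (defined - defined.mean()) / sd
    return scores


def zscore_select(
    scores: pd.DataFrame, cutoff: float = 1.0, condition: str | None = None
) -> pd.DataFrame:
    """ORFs with Z-score strictly above the cutoff (optionally one condition)."""
    sub = scores if condition is None else scores[scores["condition"] == condition]
    return sub[sub["z"] > cutoff]


def group_by_cterm(scores: pd.DataFrame) -> pd.DataFrame:
    """Per (condition, C-terminal amino acid): n, mean Q and the Q values.

    All 20 amino acids appear for every condition; groups with no ORFs get
    n=0 and NaN mean. The ``q_values`` column keeps the full distribution
    for plotting.
    """
    amino_acids = list("ACDEFGHIKLMNPQRSTVWY")
    defined = scores.dropna(subset=["Q"])
    out = []
    for cond in sorted(defined["condition"].unique()):
        sub = defined[defined["condition"] == cond]
        for aa in amino_acids:
            qs = sub.loc[sub["cterm_aa"] == aa, "Q"].to_numpy()
            out.append(
                {
                    "condition": cond,
                    "cterm_aa": aa,
                    "n": len(qs),
                    "mean_Q": qs.mean() if len(qs) else math.nan,
                    "q_values": qs,
                }
            )
    return pd.DataFrame(out, columns=["condition", "cterm_aa", "n", "mean_Q", "q_values"])
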