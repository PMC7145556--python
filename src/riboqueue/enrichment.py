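"""Positional sequence enrichment on C-terminal windows (pLogo-style).

For each position in a stop-anchored window of codons and each residue,
the statistic is the signed log10-odds of the exact binomial tail
probability of the foreground count k out of n given the background
frequency p:

    over-representation  (k >= n*p):  p_val = P[Bin(n, p) >= k],
                                      s = +log10((1 - p_val) / p_val)
    under-representation (k <  n*p):  p_val = P[Bin(n, p) <= k],
                                      s = -log10((1 - p_val) / p_val)

The family-wise significance line at level alpha over m tests is the
log-odds of the Bonferroni-corrected tail probability,
log10((1 - alpha/m) / (alpha/m)); alpha = 0.05 over a 7-codon x 20-residue
window (140 tests) gives 3.45.

The same machinery applied to the 61 sense codons at the last coding
position yields the stop-codon-context analysis; a Kruskal-Wallis test on
queuing metrics grouped by stop codon identity checks whether the stop
codon itself is associated with queuing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, RiboQueueError
from .orfs import OrfAnnotation

#: sentinel used in place of an infinite log-odds (background frequency 0/1
#: or tail probability underflow)
LOGODDS_CAP = 99.0

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class BackgroundFreqs:
    """Position-specific residue frequencies of the comparison set.

    ``freqs`` is indexed by stop-anchored codon position (-1 = last sense
    codon) with one column per symbol; each row sums to 1.
    """

    freqs: pd.DataFrame
    source: str = "coverage-filtered ORF set"

    def prob(self, position: int, residue: str) -> float:
        return float(self.freqs.at[position, residue]) if residue in self.freqs.columns else 0.0


@dataclass
class EnrichmentMatrix:
    """Long-form (position, residue) table of counts and log-odds values."""

    table: pd.DataFrame  # position, residue, k, n, p_bg, p_value, s, flag
    window: tuple[int, int]
    threshold: float | None = None

    def significant(self) -> pd.DataFrame:
        if self.threshold is None:
            raise RiboQueueError("no threshold set")
        return self.table[self.table["s"] > self.threshold]


def cterm_window(orf: OrfAnnotation, n_codons: int) -> str | None:
    """The last ``n_codons`` amino acids before the stop codon, or None if
    the ORF is shorter than the window."""
    protein = orf.protein
    if len(protein) < n_codons:
        return None
    return protein[-n_codons:]


def background_frequencies(
    orfs: Sequence[OrfAnnotation],
    n_codons: int = 7,
    symbols: Sequence[str] = AMINO_ACIDS,
    windows: Sequence[str] | None = None,
) -> BackgroundFreqs:
    """Position-specific symbol frequencies over the comparison ORF set.

    Positions are stop-anchored codon indices -n_codons..-1. ``windows``
    may pass pre-extracted sequence windows directly (one string per ORF,
    aligned at the stop codon).
    """
    if windows is None:
        windows = [w for o in orfs if (w := cterm_window(o, n_codons)) is not None]
    windows = [w for w in windows if len(w) == n_codons]
    if not windows:
        raise RiboQueueError("empty background set")
    positions = list(range(-n_codons, 0))
    mat = pd.DataFrame(0.0, index=positions, columns=list(symbols))
    for w in windows:
        for pos, sym in zip(positions, w):
            if sym in mat.columns:
                mat.at[pos, sym] += 1
    mat = mat.div(mat.sum(axis=1), axis=0)
    return BackgroundFreqs(freqs=mat)


def signed_logodds(k: int, n: int, p_bg: float) -> tuple[float, float, str | None]:
    """Signed log10-odds of the exact binomial tail of k successes in n.

    Returns (s, tail probability, flag); infinities are capped at +/-99 and
    flagged.
    """
    if not 0 <= p_bg <= 1:
        raise ConfigurationError(f"background frequency {p_bg} outside [0, 1]")
    if not 0 <= k <= n:
        raise ConfigurationError("need 0 <= k <= n")
    if p_bg == 0.0:
        return (LOGODDS_CAP if k > 0 else 0.0), math.nan, "p_bg_zero"
    if p_bg == 1.0:
        return (-LOGODDS_CAP if k < n else 0.0), math.nan, "p_bg_one"
    if k >= n * p_bg:
        p_val = float(stats.binom.sf(k - 1, n, p_bg))
        sign = 1.0
    else:
        p_val = float(stats.binom.cdf(k, n, p_bg))
        sign = -1.0
    if p_val <= 0.0:
        return sign * LOGODDS_CAP, p_val, "underflow"
    if p_val >= 1.0:
        return -sign * LOGODDS_CAP, p_val, "saturated"
    return sign * math.log10((1 - p_val) / p_val), p_val, None


def positional_logodds(
    foreground_windows: Sequence[str],
    background: BackgroundFreqs,
    alpha: float = 0.05,
    symbols: Sequence[str] = AMINO_ACIDS,
) -> EnrichmentMatrix:
    """Per-position, per-residue binomial log-odds of the foreground set.

    The Bonferroni threshold over all position x residue cells at level
    ``alpha`` is stored on the result.
    """
    positions = list(background.freqs.index)
    n_codons = len(positions)
    fg = [w for w in foreground_windows if len(w) == n_codons]
    n = len(fg)
    if n < 1:
        raise RiboQueueError("empty foreground set")
    rows = []
    for i, pos in enumerate(positions):
        col = [w[i] for w in fg]
        for sym in symbols:
            k = sum(1 for c in col if c == sym)
            p_bg = background.prob(pos, sym)
            s, p_val, flag = signed_logodds(k, n, p_bg)
            rows.append(
                {"position": pos, "residue": sym, "k": k, "n": n,
                 "p_bg": p_bg, "p_value": p_val, "s": s, "flag": flag}
            )
    table = pd.DataFrame(rows)
    thr = bonferroni_threshold(alpha, len(positions) * len(symbols))
    return EnrichmentMatrix(
        table=table, window=(positions[0], positions[-1] + 1), threshold=thr
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Log10-odds corresponding to a Bonferroni-corrected P of ``alpha``."""
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ConfigurationError("n_tests must be >= 1")
    a = alpha / n_tests
    return math.log10((1 - a) / a)


def stop_codon_context(
    foreground_orfs: Sequence[OrfAnnotation],
    comparison_orfs: Sequence[OrfAnnotation],
    alpha: float = 0.05,
) -> EnrichmentMatrix:
    """Binomial log-odds of the last sense codon (61 sense codons).

    Background = C-terminal codon frequencies across the comparison set;
    threshold Bonferroni-corrected over the codons observed there.
    """
    from .simulate import SENSE_CODONS

    def last_codon(o: OrfAnnotation) -> str:
        return o.cds_seq[-6:-3].upper()

    # windows are symbol sequences; one 3-letter codon = one symbol
    bg_windows = [[last_codon(o)] for o in comparison_orfs]
    fg_windows = [[last_codon(o)] for o in foreground_orfs]
    background = background_frequencies(
        [], n_codons=1, symbols=SENSE_CODONS, windows=bg_windows
    )
    mat = positional_logodds(fg_windows, background, alpha=alpha, symbols=SENSE_CODONS)
    # window here is a single codon position (-1)
    mat.table["position"] = -1
    return mat


def stop_identity_association(
    scores: pd.DataFrame, condition: str | None = None
) -> tuple[float, float]:
    """Kruskal-Wallis test of the queuing metric across stop-codon groups.

    Returns (H, p). Requires at least two stop-codon groups with at least
    two defined Q values each.
    """
    sub = scores if condition is None else scores[scores["condition"] == condition]
    sub = sub.dropna(subset=["Q"])
    groups = [g["Q"].to_numpy() for _, g in sub.groupby("stop_codon") if len(g) >= 2]
    if len(groups) < 2:
        raise RiboQueueError("need >= 2 stop-codon groups with >= 2 ORFs")
    if all(np.ptp(np.concatenate(groups)) == 0 for _ in (0,)):
        return 0.0, 1.0  # identical values everywhere: no association
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
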