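"""Synthetic ribosome-footprint libraries with known queuing structure.

The generator emulates the design of a yeast termination/recycling
ribosome-profiling experiment: per-condition footprint libraries with a
short (20-22 nt, vacant A-site) and a long (28-30 nt, occupied A-site)
read class, Poisson coverage noise over ORF bodies, an optional 3'UTR
background, and - on a configurable subset of ORFs, by default those ending
in lysine or arginine - stacked-ribosome queue peaks spaced one
protected-fragment length (default 30 nt) apart upstream of the stop codon.

The per-position intensity of an ORF is

    lambda(x) = b * w(x mod 3) / w(0)            on sense-codon positions
              + u                                 on 3'UTR positions
              + A * rho**(k-1)  at x = -3 - k*L   (k = 1..K, if queued)
              + w0 * A          at x = -3         (terminating ribosome)

in stop-anchored coordinates (0 = first stop-codon nucleotide), all scaled
by depth_scale and a per-ORF expression multiplier. b is the expected read
count per in-frame codon-start position; the frame weights w distribute
body reads across sub-codon positions and are anchored so that the frame-0
intensity is exactly b. Queue peaks are point masses at the queued
ribosomes' P-site codon starts (a Gaussian-jitter option exists, off by
default); the terminating-ribosome peak weight w0 defaults to 0 because
footprints of post-termination complexes are lost without cycloheximide
stabilisation.

Reads are emitted by drawing, per transcript position, a Poisson count with
mean lambda, a read length from the class mixture, and a 5' start equal to
the P-site position minus the default length-specific offset - so P-site
assignment with the same offset table recovers the sampled P-site count
vector exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.stats import norm

from .errors import ConfigurationError
from .orfs import OrfAnnotation, write_annotation, write_fasta
from .processing import (
    default_offset_table,
    write_alignments,
    ALIGNMENT_COLUMNS,
)
from .queuing import default_peak_layout, queuing_metric_vector

_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
STOP_CODONS_DNA: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))

#: yeast-like stop codon usage
DEFAULT_STOP_DISTRIBUTION = {"UAA": 0.47, "UAG": 0.23, "UGA": 0.30}

#: 3' head-room beyond the annotated 3'UTR so that no simulated footprint
#: overhangs the transcript end (max read length - min offset)
TX_TAIL_PAD = 20


def _check_distribution(dist: Mapping[str, float], name: str) -> None:
    total = sum(dist.values())
    if any(v < 0 for v in dist.values()):
        raise ConfigurationError(f"{name}: negative probability")
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ConfigurationError(f"{name}: probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic footprint experiment."""

    n_orfs: int = 200
    #: coding length range in nt (inclusive; includes the stop codon)
    orf_length_range: tuple[int, int] = (300, 900)
    cterm_aa_distribution: Mapping[str, float] | None = None  # None = uniform
    stop_codon_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STOP_DISTRIBUTION)
    )
    #: probability that an eligible ORF carries queue peaks
    queued_fraction: float = 0.9
    #: C-terminal amino acids eligible for queuing (None = all)
    queue_cterm_aas: tuple[str, ...] | None = ("K", "R")
    #: expected extra P-site reads at the first queue peak
    queue_amplitude: float = 50.0
    #: multiplicative decay per successive queued ribosome, in (0, 1]
    queue_decay: float = 0.7
    n_queue_peaks: int = 3
    #: relative intensity of the terminating-ribosome peak at -3
    stop_peak_weight: float = 0.0
    #: nt between successive queued P-sites (protected-fragment length)
    footprint_spacing: int = 30
    #: expected reads per in-frame codon-start position
    body_intensity: float = 5.0
    #: sub-codon distribution of body reads; frame-0 weight sets the scale
    frame_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    #: log-normal sigma of the per-ORF expression multiplier
    expression_sigma: float = 1.0
    utr_intensity: float = 0.5
    utr_length: int = 90
    utr5_length: int = 30
    #: probability of the long (28-30 nt) class, then within-class weights
    long_class_prob: float = 0.7
    short_length_probs: Mapping[int, float] = field(
        default_factory=lambda: {20: 1 / 3, 21: 1 / 3, 22: 1 / 3}
    )
    long_length_probs: Mapping[int, float] = field(
        default_factory=lambda: {28: 0.3, 29: 0.4, 30: 0.3}
    )
    #: optional Gaussian jitter (sd, nt) of the queue peaks; 0 = point mass
    queue_jitter_sd: float = 0.0
    depth_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_orfs < 0:
            raise ConfigurationError("n_orfs must be >= 0")
        lo, hi = self.orf_length_range
        if lo % 3 or hi % 3 or lo < 9 or hi < lo:
            raise ConfigurationError(
                "orf_length_range must be divisible-by-3 lengths >= 9, lo <= hi"
            )
        if self.cterm_aa_distribution is not None:
            _check_distribution(self.cterm_aa_distribution, "cterm_aa_distribution")
            unknown = set(self.cterm_aa_distribution) - set(AMINO_ACIDS)
            if unknown:
                raise ConfigurationError(f"unknown amino acid(s) {sorted(unknown)}")
        _check_distribution(self.stop_codon_distribution, "stop_codon_distribution")
        if set(self.stop_codon_distribution) - {"UAA", "UAG", "UGA"}:
            raise ConfigurationError("stop codons must be UAA/UAG/UGA")
        if not 0 <= self.queued_fraction <= 1:
            raise ConfigurationError("queued_fraction must be in [0, 1]")
        if self.queue_amplitude < 0:
            raise ConfigurationError("queue_amplitude must be >= 0")
        if not 0 < self.queue_decay <= 1:
            raise ConfigurationError("queue_decay must be in (0, 1]")
        if self.n_queue_peaks < 1:
            raise ConfigurationError("n_queue_peaks must be >= 1")
        if self.footprint_spacing < 1:
            raise ConfigurationError("footprint_spacing must be >= 1")
        if min(self.body_intensity, self.utr_intensity, self.depth_scale) < 0:
            raise ConfigurationError("intensities must be >= 0")
        _check_distribution(
            dict(enumerate(self.frame_weights)), "frame_weights"
        )
        if self.frame_weights[0] <= 0:
            raise ConfigurationError("frame-0 weight must be positive")
        if not 0 <= self.long_class_prob <= 1:
            raise ConfigurationError("long_class_prob must be in [0, 1]")
        _check_distribution(self.short_length_probs, "short_length_probs")
        _check_distribution(self.long_length_probs, "long_length_probs")

    @property
    def cterm_probs(self) -> dict[str, float]:
        if self.cterm_aa_distribution is None:
            return {aa: 1 / len(AMINO_ACIDS) for aa in AMINO_ACIDS}
        return dict(self.cterm_aa_distribution)


def _draw(rng: np.random.Generator, dist: Mapping[str, float] | Mapping[int, float]):
    keys = list(dist)
    p = np.asarray([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def generate_annotation(
    config: SimConfig,
) -> tuple[list[OrfAnnotation], pd.DataFrame]:
    """Seeded ORF set with coding sequences and per-ORF ground truth.

    Each coding sequence is built from uniform sense codons (no internal
    stop), a penultimate codon drawn synonymously for an amino acid from
    the C-terminal distribution, and a stop codon from the stop
    distribution. The truth table records queuing status, expression
    multiplier and the expected queuing metric of the noise-free intensity.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.orf_length_range
    lengths = rng.integers(lo // 3, hi // 3 + 1, size=config.n_orfs) * 3
    cterm = config.cterm_probs
    layout = default_peak_layout()

    orfs: list[OrfAnnotation] = []
    truth_rows = []
    for i in range(config.n_orfs):
        total_codons = int(lengths[i]) // 3  # codons incl. stop
        internal = rng.choice(len(SENSE_CODONS), size=total_codons - 2)
        aa = _draw(rng, cterm)
        penult = AA_TO_CODONS[aa][rng.integers(len(AA_TO_CODONS[aa]))]
        stop_rna = _draw(rng, config.stop_codon_distribution)
        seq = (
            "".join(SENSE_CODONS[j] for j in internal)
            + penult
            + stop_rna.replace("U", "T")
        )
        eligible = (
            config.queue_cterm_aas is None or aa in config.queue_cterm_aas
        )
        is_queued = bool(eligible and rng.random() < config.queued_fraction)
        expression = float(rng.lognormal(0.0, config.expression_sigma)) if config.expression_sigma > 0 else 1.0
        cds_start = config.utr5_length
        cds_end = cds_start + len(seq)
        orf = OrfAnnotation(
            transcript_id=f"orf{i:05d}",
            cds_start=cds_start,
            cds_end=cds_end,
            utr3_len=config.utr_length,
            tx_len=cds_end + config.utr_length + TX_TAIL_PAD,
            cds_seq=seq,
            expression=expression,
        )
        lam = expected_intensity(config, orf, is_queued)
        q, _ = queuing_metric_vector(lam, orf.stop_start, layout) if orf.cds_len >= 123 else (math.nan, None)
        orfs.append(orf)
        truth_rows.append(
            {
                "orf_id": orf.transcript_id,
                "is_queued": is_queued,
                "cterm_aa": aa,
                "stop_codon": stop_rna,
                "expression": expression,
                "expected_q": q,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["orf_id", "is_queued", "cterm_aa", "stop_codon", "expression", "expected_q"],
    )
    return orfs, truth


def expected_intensity(
    config: SimConfig, orf: OrfAnnotation, is_queued: bool
) -> np.ndarray:
    """Noise-free per-position P-site intensity vector for one transcript.

    Peaks that would fall upstream of the coding region are dropped. The
    stop codon itself carries no body intensity (terminating footprints are
    depleted in this protocol).
    """
    lam = np.zeros(orf.tx_len, dtype=float)
    w = np.asarray(config.frame_weights, dtype=float)
    body = np.arange(orf.cds_start, orf.stop_start)
    lam[body] = config.body_intensity * w[(body - orf.cds_start) % 3] / w[0]
    utr = slice(orf.cds_end, orf.cds_end + orf.utr3_len)
    lam[utr] += config.utr_intensity

    if is_queued:
        peaks = [
            (orf.stop_start - 3, config.stop_peak_weight * config.queue_amplitude)
        ]
        for k in range(1, config.n_queue_peaks + 1):
            pos = orf.stop_start - 3 - k * config.footprint_spacing
            if pos < orf.cds_start:
                break  # peak would sit upstream of the start codon
            peaks.append((pos, config.queue_amplitude * config.queue_decay ** (k - 1)))
        for pos, amp in peaks:
            if amp == 0:
                continue
            if config.queue_jitter_sd > 0:
                sd = config.queue_jitter_sd
                span = int(math.ceil(3 * sd))
                offs = np.arange(-span, span + 1)
                wts = norm.pdf(offs, scale=sd)
                wts /= wts.sum()
                for o, wt in zip(offs, wts):
                    if 0 <= pos + o < orf.tx_len:
                        lam[pos + o] += amp * wt
            else:
                lam[pos] += amp
    return lam * config.depth_scale * orf.expression


def simulate_footprints(
    config: SimConfig,
    orfs: Sequence[OrfAnnotation],
    truth: pd.DataFrame,
    seed: int | None = None,
    amplitude_scale: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Sample one footprint alignment library from the generative model.

    ``amplitude_scale`` rescales the queue amplitude (0 turns queuing off),
    letting one annotation/truth pair serve several experimental
    conditions. Returns (alignments, drop log); the drop log also carries
    the sampled P-site count vectors so tests can verify exact round-trip
    recovery through P-site assignment.
    """
    cfg = (
        config
        if amplitude_scale == 1.0
        else replace(config, queue_amplitude=config.queue_amplitude * amplitude_scale)
    )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    offsets = default_offset_table()
    queued = dict(zip(truth["orf_id"], truth["is_queued"]))

    short_lens = np.asarray(list(cfg.short_length_probs))
    short_p = np.asarray([cfg.short_length_probs[k] for k in short_lens], float)
    long_lens = np.asarray(list(cfg.long_length_probs))
    long_p = np.asarray([cfg.long_length_probs[k] for k in long_lens], float)
    offset_lut = np.zeros(int(max(short_lens.max(), long_lens.max())) + 1, dtype=int)
    for ln in np.concatenate([short_lens, long_lens]):
        offset_lut[ln] = offsets[int(ln)]

    idx_arrays, start_arrays, len_arrays = [], [], []
    sampled_counts: dict[str, np.ndarray] = {}
    dropped = 0
    for orf_idx, orf in enumerate(orfs):
        lam = expected_intensity(cfg, orf, bool(queued.get(orf.transcript_id, False)))
        counts = rng.poisson(lam)
        sampled_counts[orf.transcript_id] = counts
        psites = np.repeat(np.arange(orf.tx_len), counts)
        n = len(psites)
        if n == 0:
            continue
        is_long = rng.random(n) < cfg.long_class_prob
        lens = np.empty(n, dtype=int)
        n_long = int(is_long.sum())
        if n_long:
            lens[is_long] = rng.choice(long_lens, size=n_long, p=long_p / long_p.sum())
        if n - n_long:
            lens[~is_long] = rng.choice(
                short_lens, size=n - n_long, p=short_p / short_p.sum()
            )
        starts = psites - offset_lut[lens]
        ok = starts >= 0
        dropped += int((~ok).sum())
        idx_arrays.append(np.full(int(ok.sum()), orf_idx, dtype=np.int32))
        start_arrays.append(starts[ok])
        len_arrays.append(lens[ok])
    if start_arrays:
        starts = np.concatenate(start_arrays)
        lens = np.concatenate(len_arrays)
        codes = np.concatenate(idx_arrays)
        alignments = pd.DataFrame(
            {
                "transcript_id": pd.Categorical.from_codes(
                    codes, categories=[o.transcript_id for o in orfs]
                ),
                "start": starts,
                "end": starts + lens,
                "read_length": lens,
            }
        )
    else:
        alignments = pd.DataFrame(columns=ALIGNMENT_COLUMNS)
    log = {
        "dropped_reads": dropped,
        "sampled_total": int(sum(c.sum() for c in sampled_counts.values())),
        "sampled_counts": sampled_counts,
        "offset_provenance": offsets.provenance,
    }
    return alignments, log


#: condition label -> queue-amplitude scale, emulating a wt/mutant pair at
#: a permissive and a restrictive temperature (queuing absent in wt, full
#: at the cold-sensitive 20C, attenuated at 30C)
DEFAULT_CONDITION_DESIGN: dict[str, float] = {
    "wt_20C": 0.0,
    "new1d_20C": 1.0,
    "wt_30C": 0.0,
    "new1d_30C": 0.5,
}


def simulate_experiment(
    config: SimConfig,
    design: Mapping[str, float] | None = None,
    n_replicates: int = 2,
) -> tuple[list[OrfAnnotation], pd.DataFrame, dict[str, pd.DataFrame], dict[str, dict]]:
    """Simulate a multi-condition, replicated footprint experiment.

    Returns (annotation, truth, libraries keyed ``condition_rep{i}``,
    per-library drop logs). Library seeds are spawned deterministically
    from ``config.seed``.
    """
    design = dict(design) if design is not None else dict(DEFAULT_CONDITION_DESIGN)
    orfs, truth = generate_annotation(config)
    n_libs = len(design) * n_replicates
    seeds = np.random.SeedSequence(config.seed).generate_state(n_libs) % (2**31)
    libraries: dict[str, pd.DataFrame] = {}
    logs: dict[str, dict] = {}
    i = 0
    for cond, scale in design.items():
        for rep in range(1, n_replicates + 1):
            aln, log = simulate_footprints(
                config, orfs, truth, seed=int(seeds[i]), amplitude_scale=scale
            )
            libraries[f"{cond}_rep{rep}"] = aln
            logs[f"{cond}_rep{rep}"] = log
            i += 1
    return orfs, truth, libraries, logs


def write_dataset(
    orfs: Sequence[OrfAnnotation],
    libraries: Mapping[str, pd.DataFrame],
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write FASTA, annotation TSV, truth TSV and one alignment TSV per
    library; everything is re-readable by the processing module."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {
        "fasta": out / "sequences.fasta",
        "annotation": out / "annotation.tsv",
        "truth": out / "truth.tsv",
    }
    write_fasta(orfs, paths["fasta"])
    write_annotation(orfs, paths["annotation"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    for name, aln in libraries.items():
        p = out / f"{name}.alignments.tsv"
        write_alignments(aln, p)
        paths[f"library:{name}"] = p
    return paths
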