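# Methods

## The generative model behind the synthetic libraries

The simulator emulates a yeast termination/recycling Ribo-Seq experiment:
a wild-type/mutant pair at a permissive and a restrictive temperature, two
replicate libraries each (eight libraries per run). Each transcript has a
30 nt 5' leader, a coding region of 300–900 nt (uniform over
divisible-by-3 lengths, stop codon included), a 90 nt 3'UTR and a short
3' pad so no sampled footprint overhangs the transcript end. Internal
codons are uniform over the 61 sense codons; the last sense codon is drawn
synonymously for an amino acid from the C-terminal distribution (uniform
over the 20 amino acids by default); the stop codon follows yeast-like
usage (UAA 0.47, UAG 0.23, UGA 0.30).

The noise-free P-site intensity of an ORF, in stop-anchored coordinates
(0 = first stop-codon nucleotide), is

```
lambda(x) = b * w(x mod 3)/w(0)              sense-codon positions
          + u                                 3'UTR positions
          + A * rho^(k-1)   at x = -3 - k*L   (k = 1..K, if queued)
          + w0 * A          at x = -3
```

scaled by a global depth factor and a per-ORF log-normal expression
multiplier (sigma = 1 by default, mimicking the expression spread that
makes coverage filters non-trivial on real libraries). Parameters and
defaults:

| parameter | default | meaning |
|---|---|---|
| `body_intensity` b | 5 | expected reads per in-frame codon-start position |
| `frame_weights` w | (1/3, 1/3, 1/3) | sub-codon read distribution, anchored so frame-0 intensity is exactly b |
| `queue_amplitude` A | 50 | extra reads at the first queued P-site (10 × b) |
| `queue_decay` rho | 0.7 | attenuation per successive queued ribosome |
| `n_queue_peaks` K | 3 | stacked ribosomes behind the terminating one |
| `footprint_spacing` L | 30 nt | protected-fragment length = wave period |
| `stop_peak_weight` w0 | 0 | terminating-ribosome peak (post-termination complexes are lost without cycloheximide, so metagenes lack a stop peak) |
| `utr_intensity` u | 0.5 | frame-uniform 3'UTR background |
| `queued_fraction` | 0.9 | queueing probability among eligible ORFs |
| `queue_cterm_aas` | (K, R) | only ORFs ending K/R are eligible for queuing |
| length classes | 70% long | short 20–22 nt uniform; long 28/29/30 at 0.3/0.4/0.3 |

Queue peaks are point masses at P-site codon starts (a Gaussian-jitter
option exists, off by default) so closed-form expectations stay exact: on
the noise-free intensity with flat body the default layout gives
Q = (3b + A(1 + rho + rho²))/b, which the truth table records per ORF.
Footprint 5' starts are P-site minus the built-in offset (12 nt for all
lengths 20–32), so P-site assignment round-trips the sampled count vectors
exactly; that offset constant reflects the approximately fixed 5' boundary
of the yeast ribosome and is fully overridable via a TSV table, whose
provenance is recorded in every output header.

A is the paper-free knob of the model: real data constrain the wave
period, not the peak amplitude or decay, so A and rho are calibration
parameters chosen to produce clearly visible (amplitude ≈ 10 × body) but
not saturating queues. What the generator does **not** model: sequence-
dependent elongation pace, codon-specific pausing away from the stop,
ligation/PCR biases, multimapping, stop-codon readthrough as a process
(the UTR background is non-translational by construction), or
genome-space alignment with introns. Passing tests therefore demonstrate
that the statistics recover the queueing structure they target under
Poisson noise and expression spread — not that they are robust to every
artefact of a real library.

## Processing

P-site = 5' start + offset(read length); reads with unknown lengths or
out-of-transcript P-sites are dropped and counted, and assigned + dropped
always equals input (audited in logs). RPM uses the number of reads
assigned in the library as denominator, so a library's RPM sums to 10⁶ by
construction. Replicates are pooled by summing counts and recomputing RPM
over the pooled size (never by averaging RPM). A small projector maps
genome-space reads fully contained in one exon of one annotated gene into
spliced-transcript coordinates (minus-strand genes reversed);
junction-spanning and intergenic reads are dropped and counted.

## Metagene and wave period

Each qualifying gene's [-120, +60) window around the stop codon is divided
by its own window mean and the normalised windows are averaged with equal
weight, making the profile invariant to library scale and to
high-expression genes dominating. A gene qualifies if the window fits
inside the transcript, its mean RPM is positive (and above
`min_window_mean_rpm`, default 0), and its mean raw count is at least 0.25
reads/nt — the count floor exists because per-gene normalisation of a
near-empty window turns single reads into enormous spikes that corrupt the
average.

The wave period is the median spacing between local maxima of the profile
in [-120, -6) with prominence at least max(10% of the profile maximum,
6 × the profile's noise level), the noise level being estimated from the
median absolute deviation of first differences. The 10%-of-max term alone
admits shot noise on flat (wild-type-like) profiles as spurious peaks; the
MAD term suppresses that while leaving genuine queue peaks (whose
prominences are an order of magnitude above the noise) untouched. Fewer
than two peaks is reported as "not detected", a value, not an error.

## Queuing metric

Q = (sum of the per-window maxima of the three peak windows) / (mean over
the inter-peak windows), computed on RPM. Default layout: peak windows
[-38,-28), [-68,-58), [-98,-88) (half-width 5 nt around the expected
queued P-site codon starts at -33, -63, -93), inter-peak windows
[-28,-6), [-58,-38), [-88,-68); the stop-proximal [-6, 0) zone is excluded
because terminating footprints are depleted in cycloheximide-free
protocols. The layout is configurable; window values are divided by their
common maximum before the ratio, which changes nothing mathematically but
makes Q bit-exactly 3.0 on constant tracks. A zero inter-peak mean leaves
Q undefined with a reason code — no pseudocounts. ORFs shorter than the
123 nt needed to host the windows are excluded with a reason code.

Coverage filtering (mean RPM over [-120, 0) ≥ 10 in every required
condition, inclusive) defines one shared ORF set across conditions;
Z-scores are computed per condition over defined Q values with the sample
standard deviation (ddof = 1) on the raw Q scale, and selection takes
z > cutoff (default 1). Note that per-position RPM scales inversely with
the number of covered positions, so on small uniform synthetic ORF sets
the 10 RPM default would reject everything; end-to-end tests on synthetic
data run the filter at 0 and test the 10 RPM boundary behaviour
separately.

## Enrichment statistics

For residue r at position i, with foreground count k of n and background
frequency p: if k ≥ np the statistic is +log₁₀((1−P)/P) with
P = P[Bin(n,p) ≥ k]; otherwise −log₁₀((1−P)/P) with P = P[Bin(n,p) ≤ k].
Tails are exact (scipy's binomial distribution; an explicit summation
oracle verifies them to 1e-9 in tests) — n is at most a few hundred here,
so no normal approximation is needed. Background defaults to
position-specific frequencies over the coverage-filtered comparison set;
p ∈ {0,1} or an underflowing tail is rendered as a capped sentinel ±99
with a flag. The significance line is log₁₀((1−α')/α') with α' = α/m;
the default window of 7 codons × 20 residues gives m = 140 and a 3.45
line at α = 0.05 (a 5-codon window, m = 100, line 3.30, is one config
switch away). The same machinery at codon level (61 sense codons,
position −1) yields the stop-codon-context analysis, and a Kruskal–Wallis
test of Q across UAA/UAG/UGA groups (≥2 groups with ≥2 ORFs required)
checks stop-identity association.

## Readthrough diagnostics

Per ORF: mean RPM over [+3, +63) after the stop divided by mean RPM over
[-120, 0) (window truncated and flagged for short UTRs; zero-UTR ORFs
excluded), plus frame fractions of raw counts in the UTR window binned by
(position − window start) mod 3 — the window start at +3 keeps frame 0
continuous with the ORF's frame — with a 2-df chi-square test against
uniform frames. The result is always the ratio plus the test, never a
binary readthrough call.

## Pipeline, sizes and determinism

The pipeline runs simulate → process → metagene → queue → enrich →
readthrough as a prefix-closed stage list from one YAML config; every
table carries version, config hash, seed and offset provenance in its
header, and the manifest lists each file with its checksum, so identical
configs reproduce identical deterministic outputs (library seeds are
spawned from the master seed). Plots are intentionally out of scope: the
outputs are tidy TSV/bedGraph/JSON for downstream plotting tools.

Test and acceptance problem sizes were chosen to make the statistical
checks decisive at desk scale: 200 ORFs (~1.1 M reads) for wave-period
recovery, 1000 ORFs across 10 seeds for the K/R-pattern contrast, 100
seeded runs of 80 ORFs for null calibration of the stop-identity and
frame-periodicity tests.

## Known limitations

* The default 12 nt offset-for-all-lengths table is a reasonable yeast
  approximation, not a per-dataset calibration; analyses of real libraries
  should supply their own offset TSV (the value used is recorded in every
  output).
* The exact peak/inter-peak windows of the queuing metric are a design
  choice anchored at the expected queued P-sites; absolute Q values (and
  their means) shift with the layout, though rankings are robust.
* The Z-score selection on the raw Q scale is sensitive to the heavy tail
  it is meant to capture; it is a selection device, not a calibrated test.
* The genome→transcript projector handles reads fully contained in single
  exons only; junction-spanning footprints are dropped rather than split.
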