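# riboqueue

Stop-codon-anchored ribosome queuing analysis for ribosome profiling
(Ribo-Seq) data.

When translation termination or ribosome recycling slows down, elongating
ribosomes pile up behind the terminating one. Because each ribosome
protects ~30 nt of mRNA, the pile-up leaves a characteristic fingerprint in
Ribo-Seq coverage: periodic density waves upstream of the stop codon,
spaced one protected-fragment length apart. This package quantifies that
fingerprint — per gene and genome-wide — and asks which sequence features
(the C-terminal amino acid, the stop codon, its context) predict it. It was
built for yeast termination/recycling studies (e.g. loss of the
ribosome-associated ATPase New1, where queuing concentrates on ORFs ending
in lysine or arginine) but works on any transcript-space footprint
alignments.

## What it computes

* **P-site coverage tracks** — each footprint of length ℓ is assigned to
  the first nucleotide of its ribosomal P-site codon at
  `5'-end + offset(ℓ)`, using a read-length-specific offset table;
  coverage is normalised to reads per million (RPM). Footprints are
  classed *short* (20–22 nt, vacant A-site) or *long* (28–30 nt, occupied
  A-site).
* **Stop-anchored metagene** — per-gene-normalised average density around
  the stop codon, and the wave period as the median spacing between
  prominent local maxima.
* **The C-terminal ribosome queuing metric** — for each ORF,

  Q = ( Σₖ max RPM in peak window k ) / ( mean RPM between the peaks ),

  with three peak windows centred on the expected queued P-sites at
  −33, −63 and −93 nt from the stop codon. Q is scale-invariant and equals
  exactly 3 on a flat track. ORFs are filtered for coverage (≥10 RPM over
  the 3'-terminal 120 nt by default) and high-queuing ORFs are selected by
  Z-score (cutoff 1).
* **Positional enrichment (pLogo-style)** — for each residue at each of
  the last 7 codons, the signed log₁₀-odds of the exact binomial tail
  probability of its foreground count given background frequencies, with a
  Bonferroni-corrected significance line (3.45 for α = 0.05 over 140
  tests); plus stop-codon context enrichment (61 sense codons at the last
  position) and a Kruskal–Wallis test of Q across stop-codon identities.
* **Readthrough diagnostics** — 3'UTR/ORF density ratio and a chi-square
  test of codon (frame) periodicity after the stop codon.
* **A synthetic footprint generator** — seeded Poisson libraries over
  generated ORF sets with configurable queue peaks (amplitude, decay,
  spacing), short/long length classes, expression spread and 3'UTR
  background, with per-ORF ground truth. The whole pipeline is testable
  without any sequencing download.

## Worked example

```python
import riboqueue as rq

config = rq.SimConfig(n_orfs=200, seed=42)        # queued K/R-ending ORFs
orfs, truth = rq.generate_annotation(config)
aln, _ = rq.simulate_footprints(config, orfs, truth, seed=43)
tracks, stats = rq.assign_psites(
    aln, rq.default_offset_table(), {o.transcript_id: o.tx_len for o in orfs}
)
rq.normalize_rpm(tracks)

profile = rq.metagene_profile(tracks, orfs)
print(rq.wave_period(profile))                     # 30.0

scores = rq.score_all({"mutant": tracks}, orfs,
                      rq.QueuingConfig(min_coverage_rpm=0.0))
selected = rq.zscore_select(scores)
```

Output for this run:

```
assigned reads : 1135832
short/long     : 0.300/0.700
wave period    : 30.0 nt
mean Q         : 7.47
mean Q (K/R)   : 22.71   mean Q (other): 5.49
selected (z>1) : 21 ORFs
log-odds line  : 3.45
  position -1  K  s = 6.13
  position -1  R  s = 9.42
```

The metagene recovers the 30 nt queue spacing; ORFs ending K/R carry a
much higher queuing metric than the rest; and after Z-score selection only
lysine and arginine at the last codon exceed the 3.45 log-odds line — the
expected signature of termination-linked queuing. An amplitude-0 control
run detects no wave period and flags no residue.

The same stages run from the shell:

```
riboqueue all --config run.yaml --seed 42 --out results/
```

with every threshold (10 RPM, the peak layout, Z > 1, α = 0.05, windows)
configurable in the YAML. Real datasets enter as transcript-space BED-like
TSVs (or genome-space alignments via `project_to_transcript` with a GFF3)
plus an annotation TSV/FASTA and an offset table TSV.

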