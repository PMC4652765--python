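# gqfold

Tools for assessing the G-quadruplex (GQ) forming propensity and
conformation of DNA sequences, in both single-stranded and double-stranded
contexts.

G-rich sequences matching the G3N1-7 pattern — four runs of ≥3 guanines
separated by three loops of 1–7 nucleotides — can fold into four-stranded
GQ structures. Whether a given motif actually folds, and into which
topology (parallel vs antiparallel), depends strongly on its loop-length
profile and on whether the motif sits in ssDNA or is embedded in a duplex:
a single-nucleotide loop drives parallel folding, longer loops favour
antiparallel or unfolded species in ssDNA, and the antiparallel fold is not
supported inside duplex DNA at all. `gqfold` packages that empirical
mapping together with the two assays used to establish it:

- **`gqfold.motifs` / `gqfold.rules`** — a G3N1-7 motif scanner (both
  strands, BED-style coordinates, exhaustive or greedy overlap handling)
  plus loop-profile rule tables that call conformation
  (parallel / antiparallel / unfolded), propensity class, and a calibrated
  dsDNA folded percentage per motif.
- **`gqfold.spectra`** — processing of conformation-selective ligand
  fluorescence: NMM (parallel-selective, emission peaks 610/670 nm) and
  Crystal Violet (antiparallel-selective, 640 nm). Peak extraction,
  background subtraction, normalization to a reference sample, and
  nearest-centroid classification in the (NMM%, CV%) plane; plus a
  rule-based circular-dichroism topology call (260/240 nm vs 290 nm
  signatures).
- **`gqfold.simulate`** — a synthetic smFRET generator: two-channel
  (donor/acceptor) intensity traces at 100 ms frames with static folded
  (E ≈ 0.8), static duplex (E ≈ 0.3), dynamic (two-state Markov) and
  donor-only molecules, photobleaching, additive channel noise, a
  direct-acceptor-excitation marker pulse, and 400–500-molecule fields of
  view. Also synthetic NMM/CV emission spectra.
- **`gqfold.pipeline`** — the single-molecule analysis: apparent FRET
  efficiency `E = I_A / (I_D + I_A)` per frame, dual-label selection via
  the red-pulse record, bleach truncation, FRET histogramming, two-Gaussian
  area quantitation of the folded fraction, and a dynamic-trace census.

## Worked example

```python
from gqfold import (
    scan_g_quadruplex, classify_conformation,
    construct_config, simulate_dataset, analyze_dataset,
)

# 1. sequence-level call for the 1-4-4 construct (GGG T GGG TTTT GGG TTTT GGG)
(motif,) = scan_g_quadruplex("GGGTGGGTTTTGGGTTTTGGG")
print(motif.loop_profile, motif.motif_length)   # 1-4-4 21
call = classify_conformation(motif, context="ds")
print(call.conformation, call.predicted_folded_percent)  # parallel 66.0

# 2. recover that folded fraction from a synthetic smFRET experiment
config = construct_config("1-4-4", seed=7, n_molecules=5000)
report = analyze_dataset(simulate_dataset(config))
print(round(report["folded"]["folded_percent"], 1))      # 67.2
print(round(report["folded"]["fit"]["mean_high"], 3))    # 0.798
print(round(report["dynamics"]["percent_dynamic"], 1))   # 3.8
```

The scanner reports the 21-nt motif with loop profile 1-4-4; the rule table
calls it parallel in duplex DNA with a calibrated 66% folded fraction; and
the simulated single-molecule experiment, analyzed blind by the pipeline,
recovers 67.2% folded from the area of the high-FRET (E ≈ 0.8) Gaussian
component, with ~4% of traces showing dynamic folding/unfolding
transitions.

A command-line interface mirrors the library:

```
gqfold scan --fasta in.fasta --context ds --out-bed out.bed --out-json out.json
gqfold simulate-traces --config sim.yaml --out store/ --seed 7
gqfold fret-analyze --traces store/ --out report.json
gqfold ligand-classify --manifest m.csv --reference 1-1-1 --calibration cal.csv --out calls.json
gqfold cd-classify --spectrum cd.csv
```

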