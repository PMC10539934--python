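# eegraph

Resting-state EEG group analysis for two-cohort (healthy control vs MCI)
contrasts on the 19-channel 10–20 montage:

- **preprocess** — zero-phase 0.1–50 Hz band-pass, 2-s epoching, automatic
  amplitude/flatline artifact screening, selection of the first 50 clean
  epochs per subject.
- **spectral** — DPSS multitaper PSD, band power over delta/theta/alpha/
  beta/gamma, tabular dB topographies.
- **complexity** — multiscale entropy: coarse-graining over scales 1–30 with
  sample entropy (m=1, r=0.25·SD) and permutation entropy (m=3).
- **connectivity** — weighted phase-lag index (wPLI) for all 171 channel
  pairs per band; whole-brain and intra/inter-regional averages (frontal /
  central / parieto-occipital).
- **graph** — top-N binarization over a sparsity sweep; global, local and
  nodal efficiency, clustering coefficient, characteristic path length, and
  the small-world coefficient σ against 100 degree-preserving random
  references.
- **stats** — Shapiro-gated t / Wilcoxon rank-sum comparisons (exact null
  distribution at small n), χ² for counts, Benjamini–Hochberg FDR with
  per-family correction schemes, percentile bootstrap CIs.
- **synthetic** — a fully controllable two-group cohort generator
  (band-limited oscillations, constant-lag phase coupling, zero-lag
  volume-conduction mixing, AR(1) entropy deficits) plus canonical graph
  fixtures, so the entire pipeline is testable without any recordings.
- **io_edf** — minimal self-contained EDF reader/writer.

## CLI

```sh
# write a synthetic cohort as EDF files + roster
eegraph simulate --out cohort/ --seed 1 --effect

# run the full analysis from a YAML config
eegraph analyze --config run.yaml

# digest of significant findings
eegraph report --run out/
```

A minimal `run.yaml`:

```yaml
edf_dir: cohort
roster: cohort/roster.tsv
out_dir: out
seed: 1
```

All knobs (band edges are fixed; epoch length, epoch count, artifact limits,
entropy scales, wPLI pooling, sparsity grids, reference-graph and bootstrap
counts, seeds) are `RunConfig` fields and may be set in the YAML. Outputs are
TSV tables (per-subject features and group statistics per family) plus a
`manifest.json` with config echo, seeds and table checksums; identical
config + seed reproduces identical tables byte for byte. Alternatively, set
a `cohort:` section (a serialized cohort spec) instead of `edf_dir`/`roster`
to generate the cohort in-process.

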