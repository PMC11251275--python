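# rubikit

Analysis pipeline for high-throughput enzyme carboxylation-rate surveys
based on NADH-coupled plate-reader assays with CABP active-site titration.
The package covers the full computational path from raw absorbance traces
to comparative statistics:

- **`rubikit.synthetic`** — ground-truth generators: titration-plate
  traces (linear NADH depletion, lag dead-time, Gaussian read noise,
  depletion plateaus), variant panels with log-normal group-wise rate
  distributions matched to target medians/IQRs, and protein-sequence
  families with controlled within/between-cluster identity.
- **`rubikit.traces`** — initial-rate extraction from single A340 traces
  (adaptive linear-window selection with QC flags) and Beer–Lambert
  conversion of slopes to carboxylation fluxes (nM/s).
- **`rubikit.titration`** — the central inference: fit flux vs [CABP],
  take the x-intercept as the in-assay active-site concentration, and
  divide the uninhibited activity by it to get k_cat per active site;
  includes iterative exclusion of fully-inhibited ladder points,
  saturation/poor-fit QC, and internal-standard batch checks.
- **`rubikit.selection`** — exact global pairwise identity (affine-gap
  alignment with a canonical, oracle-testable identity definition),
  centroid-greedy clustering at identity thresholds, and iterative
  multi-stage representative selection over tagged subsets.
- **`rubikit.stats`** — median/IQR summaries, Mann–Whitney U (exact by
  enumeration or tie-corrected normal approximation), Kruskal–Wallis,
  Dunn post-hoc tests with Holm/Bonferroni adjustment, Q10 temperature
  correction, and panel-level group comparisons with box-plot summaries.
- **`rubikit.attribution`** — depth-limited CART regression trees over
  binary biological features, repeated train/test splits, and exact
  (interventional, coalition-enumerating) Shapley feature attribution
  with across-split dispersion.
- **`rubikit.io` / `rubikit.cli`** — CSV/TSV/FASTA/JSON formats, strict
  validating readers, YAML run configuration, and a pipeline driver that
  writes a reproducibility manifest.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(parameter recovery, oracle equivalences, Shapley properties,
distribution emulation, clustering correctness); the other files are
per-module unit and property tests.

## CLI

All subcommands accept `--seed`, `--out`, and where relevant `--config`:

```sh
rubikit simulate-plate --seed 1 --kcat 5 --sites-nm 40 --out traces.csv
rubikit fit-kinetics   --traces traces.csv --out kinetics.tsv --report report.json
rubikit simulate-panel --seed 1 --out panel.tsv
rubikit compare-groups --panel panel.tsv --out comparisons.json
rubikit attribute      --panel panel.tsv --seed 42 --splits 100 --out shap.json
rubikit simulate-seqs  --seed 1 --n-clusters 3 --out family.faa
rubikit select-reps    --fasta family.faa --threshold 0.8 --out reps/
rubikit run            --seed 1 --out demo_out/    # full demo pipeline
```

`rubikit run` executes simulate → fit-kinetics → compare-groups →
attribute on a synthetic panel and writes `manifest.json` recording the
config hash, seeds, package versions, and per-stage status.

## Conventions

Concentrations are nM, times are seconds, k_cat is s^-1 throughout.
Default assay constants: ε₃₄₀ = 6220 M⁻¹cm⁻¹, path length 0.26 cm,
NADH:carboxylation stoichiometry 2:1, CABP ladder (0, 0, 10, 20, 30,
90) nM, 900 s reads at 2 s intervals, activity threshold 0.5 s⁻¹.
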