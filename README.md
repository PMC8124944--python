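# mirpanel

A tested, reusable implementation of a serum-miRNA biomarker-panel discovery
workflow: absolute RT-qPCR quantification via per-assay standard curves,
sample/feature quality control, global geometric-mean normalization,
differential expression, and a cross-validated SFFS + logistic-regression
panel search with frozen-model validation. Because the motivating cohort is
private, the package ships a first-class synthetic cohort generator that
emulates the study's data-generating process (per-assay amplification
efficiency, spike-in-recoverable isolation variation, technical duplicates
with Ct noise, hemolysis contamination), so every downstream stage is
testable end to end without any download.

## Workflow

1. **`synthetic`** — generates plate-level Ct tables (samples × assays ×
   duplicate wells), 6-log serial-dilution standard-curve plates, and sample
   annotations (cohort, diagnosis, clinicopathology), plus a latent truth
   record for oracle testing.
2. **`quantify`** — per-assay OLS calibration of Ct vs log10(copies) with
   efficiency correction, duplicate collapsing with discordance flags,
   Ct → copies/reaction interpolation, and spike-in normalization to
   copies/mL serum (geometric mean of three spike-in recoveries, volumetric
   constant 62.5/mL).
3. **`qc`** — hemolysis calling by the ΔCt(miR-23a-3p − miR-451a) > 7 rule,
   and the "≥ 500 copies/mL in all subjects" expression filter.
4. **`diffexpr`** — per-sample geometric-mean centering on the log2 scale;
   pooled-variance t-tests with Benjamini–Hochberg adjustment and
   single-marker ROC AUCs.
5. **`panels`** — panels of size 2–8 selected by sequential forward floating
   selection inside repeated stratified two-fold cross-validation (default
   200 rounds), with a ridge-stabilized logistic model and fold-frozen
   feature standardization; focused (significant miRNAs only) and unbiased
   (all retained miRNAs) candidate strategies.
6. **`evaluate`** — frozen-panel ROC/AUC against benign or benign∪normal
   controls, high-specificity / high-sensitivity cutoff selection,
   confusion metrics with Wilson 95% intervals, and Jonckheere–Terpstra
   permutation trend tests across ordinal clinicopathological groups.
7. **`pipeline`** — the end-to-end study replica with deterministic seeding
   and a digest-carrying run manifest.

## CLI

```sh
mirpanel simulate   --config config.txt --seed 1 --out sim/
mirpanel quantify   --ct sim/ct_table.csv --standards sim/standards.csv --out expr.csv
mirpanel qc         --ct sim/ct_table.csv --out qc.csv
mirpanel filter     --expr expr.csv --min-copies 500 --out retained.txt
mirpanel de         --expr expr.csv --labels sim/annotations.csv --out de.csv
mirpanel build-panel --expr expr.csv --labels sim/annotations.csv \
                     --strategy unbiased --k 6 --rounds 200 --seed 1 --out panel/
mirpanel evaluate   --model panel/panel_model.json --expr expr.csv \
                     --labels sim/annotations.csv --include-normals --out eval.csv
mirpanel run-all    --config config.txt --seed 1 --rounds 200 --out study/
```

`config.txt` is a flat `key = value` file; keys mirror
`mirpanel.CohortConfig` (e.g. `n_mirnas = 324`, `hemolysis_fraction = 0.10`,
`informative_mirnas = hsa-miR-451a:0.39,hsa-miR-195-5p:0.41`). Omitted keys
take the defaults.

## Library use

```python
import mirpanel as mp

cfg = mp.CohortConfig(seed=1)          # study-shaped cohort: 269+269 patients, 100 normals
result = mp.run_study(cfg, rounds=200)
result.panel_summary                    # median CV / resubstitution / validation AUC per (strategy, k)
result.optimal_search.optimal_panel     # frozen PanelModel (miRNAs, coefficients, standardization)
result.evaluations["validation+normals"].auc
```
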