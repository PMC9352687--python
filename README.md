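# cnclonal

Analysis of segmented somatic copy-number profiles for comparing primary
tumors with their metastases:

- **SEG I/O and harmonization** — read/write tab-delimited SEG files
  (1-based inclusive; internal coordinates 0-based half-open), restrict to
  autosomes, and re-express two profiles on the intersection of their
  segmentations.
- **Absolute transform** — convert segmented log2 ratios to absolute copy
  numbers under a candidate tumor purity α and mean ploidy τ
  (`q = (r·(ατ + 2(1−α)) − 2(1−α)) / α`, normal cells diploid).
- **CNH** — copy-number heterogeneity: length-weighted mean distance of the
  corrected copy numbers to the nearest integers, minimized exhaustively
  over a purity × ploidy grid (defaults: α 0.20–1.00 step 0.01, τ 1.50–5.00
  step 0.01).
- **Profile distance *d*** — weighted mean absolute difference of two
  corrected profiles divided by the pooled weighted standard deviation,
  minimized over the 4-D grid (α₁, τ₁, α₂, τ₂); exact `exhaustive` search or
  the default `coarse_to_fine` strategy (strided coarse pass, then full
  refinement around the top candidates). Patient-level results average all
  primary × metastasis pairs.
- **Simulator** — integer-copy-number clones on a 100-kb lattice, diluted by
  diploid normal cells at a given purity with Gaussian segment noise, under
  two metastatic seeding modes (`polyclonal`: metastasis keeps the primary's
  clone mixture; `monoclonal`: metastasis is a single subclone).
- **Cohort pipeline** — gain/loss frequency tracks, per-patient distances,
  one-way ANOVA with Tukey HSD (rank test for two groups), deterministic
  TSV outputs.

## CLI

```sh
# simulate a cohort (SEG + sample sheet + truth table)
cnclonal simulate --out sim/ --patients-per-mode 5 --seed 1

# per-sample CNH
cnclonal cnh --seg sim/cohort.seg --out cnh.tsv

# per-patient primary-metastasis distances
cnclonal distance --seg sim/cohort.seg --sheet sim/samples.tsv --out dist/ \
    --strategy coarse_to_fine

# gain/loss frequency track
cnclonal frequency --seg sim/cohort.seg --out freq.tsv --gain 0.1 --loss -0.1

# full pipeline from a flat YAML config
cnclonal run --config config.yaml --out results/ --seed 1
```

The sample sheet is tab-delimited with columns `sample_id`, `patient_id`,
`role` (`primary`/`metastasis`) and `group`. Grid overrides use
`--grid-alpha min,max,step` / `--grid-tau min,max,step`. If no
`--chrom-sizes` file is given the genome model is inferred from the SEG
file's extent.

`run` writes `cnh.tsv`, `distances.tsv`, `pairs.tsv` (per-pair minimizing
(α₁, τ₁, α₂, τ₂)), `frequency.tsv`, `comparison.tsv` and `run.log`. All
tables are byte-identical across runs given the same config and seed; the
log records timings and is exempt.

## Library use

```python
from cnclonal import (SearchGrid, SimulationConfig, cnh_minimize,
                      pair_distance_minimize, simulate_patient)

patient = simulate_patient(SimulationConfig(seed=1), seed=1)
primary, metastasis = patient.profiles.values()
print(cnh_minimize(primary))                       # CNHResult(cnh=..., best=..., n_ties=...)
print(pair_distance_minimize(primary, metastasis)) # PairDistanceResult(d=..., best=...)
```
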