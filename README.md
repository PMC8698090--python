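# vstenergetics

Energetics analysis pipeline for vaquejada simulation tests (VST): from
1 Hz heart-rate/GPS telemetry and carried-mass metadata to gait-segmented
energy expenditure (EE), cost of transport (COT) and metabolic power
(Pmet), plasma-lactate curve summaries, and pull-horse vs helper-horse
group statistics. Because the original device recordings are not public,
a seeded synthetic-cohort generator with the same statistical structure is
a first-class part of the package.

## What it computes

* **Gait segmentation** — each second is labelled by speed band
  (walk < 1.67 m/s, trot 1.94–4.17 m/s, gallop > 4.44 m/s, explicit
  `transition` for the unclassified gaps), collapsed into bouts, and the
  three-race VST structure is detected as gallop spans separated by rest.
* **Energetics** — per race × gait cell and per session:
  `EE (J/kg/min) = 0.0566 · HR^1.9955`, plus COT and Pmet as heart beats
  above a 35 bpm baseline normalized by carried mass (horse + rider +
  tack) and distance or time, scaled by 10³. COT has two documented unit
  conventions (`dimensional`, default, and `paper_numeric`).
* **Lactate** — six-timepoint curves (T0 rest, T1–T3 after each race,
  T4/T5 at 30/240 min of recovery): baseline, peak, delta, 4 mmol/L
  anaerobic-threshold exceedance, recovery assessment.
* **Group statistics** — Kolmogorov–Smirnov normality screening,
  within-subject one-way repeated-measures ANOVA, Tukey pairwise
  comparisons, and "mean (±SD)" report tables with significance letters.
* **Synthetic cohorts** — deterministic per (seed, role, subject):
  first-order HR relaxation toward gait set-points, clipped-Gaussian
  within-band speeds, and a piecewise lactate kinetic model. The
  `coelho2021` preset encodes the published group-level structure
  (PH gallop HR > HH; HH trot HR > PH; PH lactate peak ≈ 10.6 mmol/L,
  HH ≈ 6.7 mmol/L).

## CLI

```bash
# write a synthetic cohort (8 subjects, canonical CSVs + metadata sidecars)
vst simulate --preset coelho2021 --seed 1 --out cohort/

# analyze a cohort directory (or generate one on the fly with --synthetic)
vst analyze --in cohort/ --out bundle/ --cot-mode dimensional --alpha 0.05
vst analyze --synthetic --preset coelho2021 --seed 1 --out bundle/

# re-print the rendered tables of an existing bundle
vst report --in bundle/
```

`--config run.json` loads any of the tunable settings from a JSON file;
explicit flags override it field by field. The analysis bundle contains
tidy CSVs (`energetics_cells.csv`, `energetics_totals.csv`, `stats.csv`,
`lactate_summary.csv`, `lactate_curves.csv`), rendered lettered tables
(`tables.txt`) and a `manifest.json` with the configuration hash —
rerunning the same configuration reproduces every file byte-for-byte.

## Session format

Canonical session CSV columns: `t_s, hr_bpm, speed_mps, cum_dist_m`
(0-based whole seconds, beats/min, m/s, non-decreasing metres). Subject
metadata travels in a `key=value` sidecar (`subject_id`, `role` PH/HH and
the three masses in kg).

## Caveats

* The published per-gait EE/COT/Pmet table values are not reproducible
  from the stated formulas and group-mean HRs; those tables are treated
  as qualitative references. The formulas themselves are implemented
  literally and are the tested surface.
* Gait assignment at band boundaries follows the printed inequalities;
  speeds in the two gaps are reported as `transition` and excluded from
  per-gait energetics.
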