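# divesat

Blood-oxygen analysis of bird dive recordings: from raw bio-logger files
(1 Hz depth, sparse intravascular P_O2) to typed hemoglobin-saturation
profiles and arterio-venous O2 extraction estimates.

Diving birds manage a finite O2 store through bradycardia and peripheral
vasoconstriction.  Venous hemoglobin saturation during a dive is a window
onto that regulation: if tissues are perfused and extracting O2, venous
saturation falls progressively (**Type B** profile); if the periphery is
clamped down and arterio-venous shunts carry blood past the tissues,
venous saturation stays high or even approaches arterial values and falls
only during the final ascent (**Type A** profile).  `divesat` implements
the full analysis chain behind that comparison:

* **ODC conversion** — Hill-model dissociation curve
  `S = 100·Pⁿ/(P50ⁿ+Pⁿ)` with an exact inverse, plus Hb-bound O2 content
  `C = (S/100)·[Hb]·1.34` and a-v content differences (ml O2 dl⁻¹);
* **dive segmentation** — submergence detection (depth > 2 m, strictly
  > 2 min), descent/bottom/ascent phases from a smoothed vertical rate,
  direction changes, dive-fraction arithmetic;
* **per-dive metrics** — start / peak / end / mean saturation, the
  start-to-peak increase, decline landmarks (2.5/5/10 pp below peak) with
  times and dive fractions via the nearest-sample rule, and desaturation
  interruptions (inflections > 4 pp vs near-flat plateaus) with phase
  labels;
* **profile typing** — a deterministic rule cascade assigning Type A /
  Type B / Other with a full audit trail of which rule fired;
* **synthetic data** — a seeded generator producing labelled depth + P_O2
  records whose population statistics match the study groups, so every
  stage is testable without any field data;
* **pipeline** — orchestration, group summary tables (mean ± s.e.m.,
  median, aerobic-dive-limit counts), a-v difference series, and a tidy
  export for external mixed-effects modelling.

See `docs/methods.md` for the models, operational definitions and their
rationale.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (outputs land under `results/`):

```bash
python analysis/01_simulate.py            # 160 labelled records, seed 7
python analysis/02_segment_dives.py       # dive + phase tables
python analysis/03_saturation_metrics.py  # per-dive O2 metrics
python analysis/04_classify_profiles.py   # Type A/B/Other labels
python analysis/05_summarize.py           # group summary, a-v series
```

The final step prints (seed 7 shown):

```
group summary (dive-weighted):
   group  n_dives  peak_sat_mean  increase_start_to_peak_mean  end_sat_mean  mean_sat_mean  duration_min_mean  n_dives_ge_adl
arterial       65           99.2                          2.3          78.5           94.8                5.6              28
   TypeA       29           94.1                         12.5          75.9           88.9                4.7               8
   TypeB       66           79.7                          2.5          30.9           51.5                8.9              59
TypeA dive (record 6): early-dive a-v difference 1.82 ml O2/dl (range 0.57 to 3.10)
TypeB dive (record 0): early-dive a-v difference 4.79 ml O2/dl (range 3.54 to 6.33)
```

Reading this: arterial saturation stays near-full until late in the dive
(end 78.5%); Type A venous dives peak near-arterial (94.1%) after a
~12 pp rise and end almost as high as arterial blood ends — evidence of
a-v shunting — while Type B dives barely rise above their starting value
(peak 79.7%) and desaturate to ~31% by surfacing.  Correspondingly, the
early-dive a-v Hb-bound O2 difference is small in the Type A dive
(~1.8 ml O2 dl⁻¹, minimal extraction) and larger and more variable in
Type B dives.  The classifier recovered the generator's ground-truth
labels for 100% of these 95 venous dives (step 04 prints the audit).

The same functionality is available as a library:

```python
from divesat import (GeneratorConfig, RecordInput, generate_dataset, run_pipeline)

records, manifest = generate_dataset(GeneratorConfig(n_dives=50, seed=1))
inputs = [RecordInput(r.record_id, r.depth, r.po2, r.bird_id, r.year) for r in records]
result = run_pipeline(inputs)          # per_dive, interruptions, summary tables
```

Pipeline thresholds live in one dataclass (`RunConfig`), loadable from
YAML — see `configs/default_run.yaml`.

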