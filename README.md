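# camtrapniche

Niche-overlap analysis for two-species camera-trap surveys: spatial and
temporal partitioning between sympatric ungulates (or any two species) from
raw detection records.

Camera traps yield timestamped species records at fixed sites. After
thinning serially dependent records, two questions drive coexistence
analysis: do the species use the same *places* (spatial overlap of relative
activity across cameras) and the same *hours* (overlap of circular diel
activity densities)? `camtrapniche` implements that full chain:

- **Independence filtering** — 30-min sliding-anchor rule per
  camera × species stream; deterministic and idempotent.
- **Relative activity indices** — RAI1 (independent detections per 100
  camera-days per site) and RAI2 (per month, pooled across years), with
  Welch's t-test between species and seasonal ANOVA + Tukey HSD.
- **Habitat suitability by multi-model inference** — Spearman collinearity
  screen (|ρ| < 0.7), all-subsets Gaussian GLMs, AICc ranking, Akaike
  weights *wᵢ*, Δᵢ < 2 best-model sets, conditional model-averaged
  coefficients with unconditional SEs.
- **Spatial overlap** — Pianka's index
  *O = Σpᵢqᵢ / √(Σpᵢ² Σqᵢ²)* on per-site utilization proportions.
- **Temporal overlap** — von Mises kernel density estimates of diel
  activity, overlap coefficient Δ (area under min(f̂, ĝ)) via the Δ̂1 /
  Δ̂4 estimators with the n < 75 selection rule, smoothed-bootstrap 95%
  confidence intervals, and strong / moderate / low classification.
- **Diel-period selection** — crepuscular / diurnal / nocturnal occupancy
  from a sunrise–sunset calendar, selection ratios *wᵢ = oᵢ/πᵢ*
  (π_crepuscular = 4/24), ANOVA test of non-random period use.
- **Synthetic surveys with ground truth** — a generator with known
  covariate effects, diel mixtures and overlap, so every estimator is
  testable for parameter recovery.
- **Pipeline + CLI** — `camtrapniche simulate` and `camtrapniche run`
  (config-driven, seeded, reproducible report files).

## Worked example

Simulate a two-year, 26-camera survey and measure both overlap axes:

```python
import numpy as np
import pandas as pd
from camtrapniche import simulate, rai, spatial, activity

cfg = simulate.SyntheticConfig(seed=42)
tables, truth = simulate.simulate_survey(cfg)
det, eff = tables["detections"], tables["effort"]
print("detections:", len(det))

oryx = rai.rai1(det, eff, "oryx")
gaz = rai.rai1(det, eff, "gazelle")
print(oryx.head(3).to_string(index=False))
merged = oryx.merge(gaz, on="camera_id", suffixes=("_o", "_g"))
print("Pianka:", round(spatial.pianka(merged.rai1_o, merged.rai1_g), 3))
print("true Pianka:", round(truth.pianka, 3))

ts = pd.to_datetime(det["timestamp"])
rad = (ts.dt.hour + ts.dt.minute / 60) / 24 * 2 * np.pi
a = rad[det.species == "oryx"].to_numpy()
b = rad[det.species == "gazelle"].to_numpy()
res = activity.bootstrap_ci(a, b, resamples=1000, seed=1)
print(f"Delta ({res.estimator}): {res.delta:.3f}"
      f"  95% CI [{res.ci_low:.3f}, {res.ci_high:.3f}]"
      f"  -> {activity.classify_overlap(res.delta)}")
print("true Delta:", round(truth.delta, 3))
```

Output:

```
detections: 4804
camera_id species  detections  camera_days      rai1
      C01    oryx         158          730 21.643836
      C02    oryx          56          730  7.671233
      C03    oryx         198          730 27.123288
Pianka: 0.866
true Pianka: 0.883
Delta (Dhat4): 0.836  95% CI [0.821, 0.865]  -> strong
true Delta: 0.881
```

`truth.delta` is the overlap of the two species' *baseline* diel mixtures;
the pooled sample also contains the oryx-like species' summer nocturnal
shift, so the estimated all-year Δ̂ sits slightly below it — exactly the
kind of seasonal pooling effect the per-season pipeline stages exist to
separate. The bootstrap at this sample size (~2,400 detections per species)
takes several minutes; pass a smaller `resamples` for a quick look.

The same analysis end-to-end from files:

```bash
camtrapniche simulate --seed 42 --outdir survey/
camtrapniche run --detections survey/detections.csv --effort survey/effort.csv \
    --sites survey/sites.csv --calendar survey/calendar.csv --outdir results/
```

which writes `rai1.csv`, `rai2.csv`, `rai_tests.json`, `model_table.csv`,
`mmi_summary.csv`, `spatial_overlap.csv`, `overlap.csv`,
`activity_density.csv`, `selection_ratios.csv` and `run_meta.json`
(inputs hash + seed for provenance).

## Reproduction

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from per-period detection counts and the fixed crepuscular
time share, a set of published desk-scale selection-ratio values through
the package's own machinery, and writes them as JSON. The script is
deterministic; the `--seed` argument is accepted for interface uniformity.

## Documentation

- [`docs/methods.md`](docs/methods.md) — models, estimators, defaults and
  their rationale, numerical choices (circular-KDE bandwidth rule,
  bootstrap interval calibration), generator scope, known limitations.

## Layout

```
src/camtrapniche/
  survey.py    independence filter, seasons, readers, time conversion
  rai.py       RAI1/RAI2 + tests
  habitat.py   collinearity screen, all-subsets AICc MMI
  spatial.py   Pianka overlap
  activity.py  circular KDE, Δ estimators, smoothed bootstrap
  diel.py      period classification and selection ratios
  simulate.py  synthetic surveys with ground truth
  pipeline.py  orchestration;  cli.py  command line
```
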