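# netmtv

Quantitative imaging and survival analysis for peptide receptor
radionuclide therapy (PRRT) prognosis in neuroendocrine tumors (NETs).

Patients with somatostatin-receptor (SSTR) positive NETs are selected
for and monitored under PRRT with SSTR-PET. This package implements the
full measurement chain from PET volume to prognosis, for nuclear
medicine researchers who want a tested, scriptable version of that
chain:

1. **MTV segmentation** — the molecular tumor volume is every connected
   region of voxels whose SUV exceeds the liver-referenced threshold

   `SUV > 1.5 · SUVmean_liver + 2 · SD_liver`

   with liver statistics from a 5 ml spherical VOI and caller-supplied
   masks to exclude physiological uptake (kidneys, pituitary, ...).
2. **Response classification** — relative MTV change between baseline
   and the interim scan after two therapy cycles: ΔMTV < −73% → PR,
   ΔMTV > +63% → PD, otherwise SD; PR/SD are responders.
3. **Composite biomarker** — imaging and blood tumor burden combined:
   `0.5·[z(ln MTV) + z(ln CgA)]` (CgA = chromogranin A).
4. **Survival layer** — univariable/multivariable Cox models (Efron
   ties) with Schoenfeld proportional-hazards diagnostics,
   Kaplan–Meier curves, log-rank tests, Mann–Whitney comparisons, and
   fixed-horizon ROC analysis (default 60 months = 5-year OS) with
   Youden-optimal cutoffs and DeLong AUC confidence intervals.
5. **Synthetic data** — seeded digital PET phantoms with known lesion
   volumes and simulated cohorts from a Weibull proportional-hazards
   model, so every stage is testable end to end without patient data.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import netmtv as nm

# a phantom standing in for a baseline SSTR-PET scan
cfg = nm.paper_like_phantom_config(seed=7)        # 25 mm lesion = 65.45 ml
vol, exclusion, truth = nm.generate_phantom(cfg)

liver = nm.reference_stats(
    vol, nm.SphereVOI(center=truth.liver_voi_center, volume_ml=5.0, label="liver")
)
thr = nm.segmentation_threshold(liver)
seg = nm.segment_mtv(vol, thr, exclusion_mask=exclusion, min_lesion_ml=0.5)
print(f"threshold {thr:.3f} SUV -> MTV {seg.total_mtv_ml:.2f} ml "
      f"in {len(seg.lesions)} lesion(s), {seg.excluded_component_count} excluded")

# interim scan with the lesion shrunk to 20% of its volume
vol_i, excl_i, _ = nm.generate_interim_phantom(cfg, (0.2,))
mtv_i = nm.segment_mtv(vol_i, thr, exclusion_mask=excl_i, min_lesion_ml=0.5).total_mtv_ml
pct = nm.percent_change(seg.total_mtv_ml, mtv_i)
cls = nm.classify_response(pct)
print(f"interim MTV {mtv_i:.2f} ml ({pct:+.1f}%) -> {cls.value}, "
      f"responder={nm.is_responder(cls)}")
```

prints

```
threshold 9.026 SUV -> MTV 65.15 ml in 1 lesion(s), 1 excluded
interim MTV 13.12 ml (-79.9%) -> PR, responder=True
```

The measured threshold is the liver VOI realization of
1.5·mean + 2·SD (at the nominal liver values 4.41/1.14 it is exactly
8.895); the recovered MTV is within 0.5% of the generated 65.45 ml
lesion; the physiological hot sphere was excluded, not counted as
tumor; and a volume reduction of 79.9% crosses the −73% bound, so the
scan pair is classified as partial response.

The cohort side follows the same pattern (`analysis/04`, `analysis/05`):

```python
df, truth = nm.generate_cohort(nm.paper_like_cohort_config(seed=7, n=62))
from netmtv.pipeline import add_composite
fit = nm.fit_cox(add_composite(df).pipe(lambda d: d.assign(
    composite_std=d.mtv_cga_composite / d.mtv_cga_composite.std())),
    ["composite_std"])
```

At n=62 such fits are intentionally noisy; on an n=2000 cohort the
per-SD composite hazard ratio converges to its generating value
(`analysis/05` prints `2.74 (2.54–2.95)` against the generating 2.66).

## Analysis scripts

Numbered drivers under `analysis/` reproduce the full chain on
synthetic data and write their tables to `results/`:

| script | writes |
| --- | --- |
| `01_simulate_phantoms.py` | phantom NIfTIs (`scratch/`), ground truth |
| `02_segment_mtv.py` | per-lesion CSV, MTV vs truth |
| `03_classify_response.py` | PR/SD/PD table for the scan pairs |
| `04_simulate_cohort.py` | n=62 cohort CSV + generating model |
| `05_survival_analysis.py` | Cox/KM/ROC report JSON and CSV |

There is also a CLI (`netmtv mtv | respond | composite |
cohort-analyze | simulate | run`) wrapping the same library calls.

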