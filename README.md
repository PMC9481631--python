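# gafunc

Structure–function analysis of **geographic atrophy (GA)** — the atrophic
late stage of age-related macular degeneration — from OCT segmentation
probability volumes.

Given per-eye probability rasters for the three morphological features of
GA (RPE-loss, photoreceptor degeneration, choroidal hypertransmission),
`gafunc`:

1. **reduces** each volume to a 2-D en-face map (one probability per
   A-scan, max over depth) and derives **RORA** — RPE-and-outer-retinal
   atrophy — as the per-A-scan co-occurrence of all three features
   (cell-wise minimum, so thresholding commutes with the binary AND);
2. **standardizes** maps to a fovea-centred grid, mirroring left eyes so
   +x is nasal for every eye, and assigns cells to the nine **ETDRS
   subfields** (foveal disc r < 0.5 mm, parafoveal ring to 1.5 mm,
   perifoveal ring to 3 mm, quadrants split at the 45° diagonals);
3. **predicts visual function** — visual acuity (VA), low-luminance VA
   (LLVA), or the low-luminance deficit (LLD = VA − LLVA), in ETDRS
   letters — with a 100-replicate **bootstrapped random forest** using
   patient-level 80/20 splits (fellow eyes never straddle a split),
   reporting r² and MAE with quartiles;
4. **maps feature importance** back onto the macula: percentage
   contribution per (feature, grid cell), aggregated into a 9-region ×
   4-feature ETDRS table with foveal vs non-foveal shares, and rendered
   as per-feature heatmaps.

Clinical GA datasets with paired visual function are not redistributable,
so the package includes a fully seeded **synthetic-cohort generator**: 
correlated lesion rasters whose cohort median areas are calibrated to
published values, bilateral eyes sharing a patient-level burden effect,
~15 % foveal-sparing eyes, and outcomes generated from a configurable
linear structure–function law. Planted-law recovery and permutation-null
experiments validate the whole chain end to end. See
[`docs/methods.md`](docs/methods.md) for the model details and design
choices.

Intended users: researchers in retinal image analysis and
ophthalmic-biomarker validation who need a transparent, testable reference
pipeline from segmentation output to spatial structure–function maps.

## Worked example

```python
from gafunc import PipelineConfig, SynthConfig, run_pipeline

config = PipelineConfig(seed=42, n_replicates=25,
                        synth=SynthConfig(n_patients=60))
report = run_pipeline(config)          # simulate -> reduce -> standardize
                                       # -> featurize -> fit -> importance
c, m, s = report["cohort"], report["model"], report["shares"]
print(c["n_eyes"], c["n_patients"])
print({k: round(v, 2) for k, v in c["median_areas_mm2"].items()})
print(round(m["r2"], 3), round(m["mae"], 1))
print({k: round(v, 1) for k, v in s.items()})
```

prints

```
82 60
{'rpe_loss': 6.61, 'photoreceptor_degeneration': 12.23, 'hypertransmission': 8.19, 'rora': 6.06}
0.344 13.5
{'foveal_share': 58.6, 'nonfoveal_share': 41.4}
```

Reading the output: 60 synthetic patients contributed 82 eyes; the median
lesion areas (mm²) show the expected nesting — photoreceptor degeneration
largest, derived RORA smallest. The bootstrapped forest predicts VA with a
median held-out r² of 0.344 and a median absolute error of 13.5 ETDRS
letters, and 58.6 % of the model's total feature importance sits in the
central 1-mm foveal subfield — as it should, since the default synthetic
law drives VA primarily through foveal RORA.

The same pipeline is scriptable from the shell:

```sh
gafunc simulate --n-patients 60 --seed 42 --out cohort/
gafunc reduce --in cohort/ --threshold 0.5 --out enface/
gafunc standardize --in enface/ --resolution 49 --out standard/
gafunc featurize --grids standard/ --cohort cohort/cohort.csv \
                 --outcome va --downsample-k 7 --out features.csv
gafunc fit-eval --table features.csv --replicates 100 --seed 7 --out result.json
gafunc importance --result result.json --out importance/
gafunc run --seed 42 --out full_run/          # everything in one step
```

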