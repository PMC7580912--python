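# octaquant

Quantification of en-face OCT angiography (OCTA) slabs for retinal
perfusion studies:

- **Skeletonized-vessel-length thresholding** — derives one binarization
  value per eye from its deep capillary plexus (DCP) slab by sweeping
  integer thresholds, counting skeleton pixels, and intersecting
  regression lines fitted to the steep (noise) and plateau (signal)
  portions of the count-vs-threshold curve.  The same value binarizes the
  superficial (SCP), middle (MCP) and deep plexus slabs of that eye.
  Classical Mean and Huang histogram thresholders are included as
  comparators.
- **Perfusion metrics** — parafoveal vessel density (VD, %), vessel
  length density (VLD, mm⁻¹), adjusted flow index (AFI, mean normalized
  decorrelation of suprathreshold pixels), and foveal avascular zone
  (FAZ) area from a traced mask or an assisted flood fill.  The
  parafovea is the annulus with 3 mm outer / 1 mm inner diameter centred
  on the scan.
- **Synthetic data** — seeded multi-plexus angiograms grown as branched
  random-walk capillary networks with exact ground truth (vessel mask,
  centerline skeleton, noise/signal boundary, true VD/VLD), plus
  synthetic per-eye cohort tables with stage effects and age/quality
  covariate confounding.
- **Cohort statistics** — Spearman trend across ordered severity stages,
  ANCOVA adjusted for age and Q-score with covariate-adjusted group
  means, Benjamini–Hochberg-corrected pairwise post-hoc contrasts,
  Cohen's *d*, noncentral-*t* a-priori sample size, and ROC screening
  analysis (rank-based AUC, Youden operating point).

## Command line

```sh
# synthetic eye with ground truth (PNG slabs + truth masks + truth.json)
octaquant simulate eye --seed 1 --out-dir scratch/eye1

# derive the per-eye threshold from the DCP slab
octaquant threshold --dcp scratch/eye1/dcp.png --out scratch/threshold.json

# per-eye metrics at the derived threshold
octaquant metrics --scp scratch/eye1/scp.png --mcp scratch/eye1/mcp.png \
    --dcp scratch/eye1/dcp.png --retina scratch/eye1/retina.png \
    --faz-seed 152,152 --out scratch/metrics.csv

# synthetic cohort table and the full statistics report
octaquant simulate cohort --seed 1 --out scratch/cohort.csv
octaquant stats --table scratch/cohort.csv \
    --params SCP_VD,MCP_VD,DCP_VD,SCP_VLD,SCP_AFI,MCP_AFI,DCP_AFI,FAZ \
    --roc-params SCP_VD,SCP_VLD,MCP_VD --out-dir scratch/reports

# statistics-only study driver (per-eye table in, report tables out)
octaquant run-study --table scratch/cohort.csv --out-dir scratch/study
```

Per-eye CSV columns: `eye_id, stage, age, sex, q_score, ssi, cmt_um`
plus parameter columns (`SCP_VD`, `MCP_VD`, `DCP_VD`, `SCP_VLD`,
`SCP_AFI`, `MCP_AFI`, `DCP_AFI`, `FAZ`).  Stages are coded 0 = healthy,
1 = diabetic without retinopathy, 2 = mild, 3 = moderate, 4 = severe
NPDR.

## Layout

```
src/octaquant/
  image_io.py   slab/mask/table IO, QC eligibility, record types
  geometry.py   parafoveal annulus, pixel/mm conversion
  binarize.py   threshold sweep, two-segment fit, Mean/Huang, skeletonization
  metrics.py    VD / VLD / AFI / FAZ and the per-eye metric set
  synthetic.py  seeded angiogram + cohort generators with ground truth
  stats.py      Spearman / ANCOVA / BH post-hoc / Cohen's d / power / ROC
  pipeline.py   per-eye and per-study orchestration, run config, logging
  cli.py        click entry points
```
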