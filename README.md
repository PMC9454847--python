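# tmespatial

Spatial analysis of the tumor immune microenvironment from multiplex-IHC
cell tables.

Multiplex fluorescent immunohistochemistry (mfIHC) assigns every segmented
cell on a tissue-microarray (TMA) core a position (μm) and a binary call for
each stained marker. `tmespatial` turns those per-cell tables into a
cohort-level answer to the question *"does MHC-II (HLA-DR) expression
reorganise the immune infiltrate?"*: it phenotypes cells, measures how
phenotypes are arranged relative to one another inside each 0.6 mm core,
aggregates cores to patients, splits the cohort into HIGH/LOW HLA-DR
expressors around the cohort mean, and runs the full two-group comparison
battery. A synthetic-cohort generator with controllable stratum effects
makes every stage testable without patient data.

It is written for computational pathology / immuno-oncology analysts who
receive inForm-style cell exports and want reproducible spatial statistics
rather than spreadsheet pipelines.

## What it computes

**Phenotypes** from lineage markers, with precedence CD3 > CD163 > PanCK:
cytotoxic T cells (CD3⁺CD8⁺), helper T cells (CD3⁺CD8⁻FoxP3⁻), regulatory
T cells (CD3⁺CD8⁻FoxP3⁺), antigen-presenting cells (CD163⁺), epithelial
tumor cells (PanCK⁺), other. GZMB/Ki67/PD-L1 flag activation and checkpoint
state and never change lineage.

**Per-core spatial metrics** for each reference → target phenotype pair
(x → y):

- *nearest-neighbor distance*: Euclidean distance from each x cell to its
  closest y cell;
- *engagement*: percent of x cells with ≥1 y cell within 40 μm
  center-to-center, and the mean number of simultaneous y contacts among
  engaged x cells;
- *cross-type G-function*: G_xy(r) = P(nearest y within r of an x cell),
  which under complete spatial randomness equals
  1 − exp(−λ_y π r²). Because a core is a small window, the estimator
  right-censors each nearest-neighbor distance at the cell's distance to
  the core boundary and takes the Kaplan–Meier product-limit estimate of
  the distance distribution (edge correction). The curve is summarised by
  its trapezoidal AUC over [0, 60] μm — higher AUC, stronger mixing.

**Cohort statistics**: per-patient metrics (unweighted mean over triplicate
cores) are compared between HLA-DR strata — Shapiro–Wilk gate at α = 0.05,
then two-sided one-way ANOVA or Wilcoxon rank-sum — and correlated
(Pearson) against percent HLA-DR-positive surface area, with
Benjamini–Hochberg adjustment within each result panel (distances,
engagement, infiltration, mixing, activation). Fisher's exact test
(probability-ordering, two-sided) is available for categorical contrasts.

## Worked example

```python
import tmespatial as t

cfg = t.default_config(seed=21, n_patients=12)        # synthetic TMA cohort
patients, truth = t.generate_cohort(cfg)
cores = [c for p in patients for c in p.cores]

res = t.SpatialCohortModel(cores).fit()
print(res.summary())
```

prints (abridged):

```
==============================================================================
Spatial TME cohort analysis — HLA-DR stratification
==============================================================================
Patients: 12  (HIGH 5 / LOW 7)   Cores: 36   Cells: 20754
HLA-DR stratification threshold (cohort mean): 8.79% positive surface area
Marker-lineage conflicts resolved: 0
------------------------------------------------------------------------------
[distances]  (group means; ANOVA/Wilcoxon; BH within panel)
           metric  mean_high  mean_low     test  statistic    p_raw     p_bh
   mean_nn|T->APC      28.83     45.56 WILCOXON          2   0.0101  0.01684
  mean_nn|Th->APC      24.16     44.01    ANOVA      19.35 0.001338 0.006691
...
[mixing]  (group means; ANOVA/Wilcoxon; BH within panel)
       metric  mean_high  mean_low     test  statistic    p_raw     p_bh
g_auc|Th->APC      37.02        25    ANOVA      20.08 0.001178 0.002356
g_auc|CTL->EC      45.91     37.45 WILCOXON         30 0.007969 0.007969
```

Reading it: helper T cells sit on average 24 μm from the nearest APC in
HLA-DR-high patients versus 44 μm in low ones, and the Th–APC G-function
AUC (mixing on a 0–60 μm scale) is 37 vs 25 — this cohort was generated
with exactly those attraction effects, and the pipeline recovers them.
`res.comparisons_frame()`, `res.correlations_frame()` and
`res.summaries_frame(level=...)` expose everything as tidy DataFrames.

The same pipeline runs from a shell:

```bash
tmespatial simulate --config sim.yaml --out simdir/
tmespatial analyze --cells simdir/cells.csv --out results/
```

`analyze` accepts any CSV with columns `cell_id, core_id, patient_id, x_um,
y_um, CD3, CD8, FoxP3, CD163, PanCK, PDL1, GZMB, Ki67, hladr_area_pct`
(optional `window_cx_um, window_cy_um, window_r_um`), so exports from
upstream image software can enter directly.

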