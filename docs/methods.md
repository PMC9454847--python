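# Methods

## Setting and data model

The unit of observation is a TMA core: a circular tissue punch of 0.6 mm
diameter (300 μm radius) carrying a few hundred to a few thousand segmented
cells, each with coordinates in μm and binary positivity calls for CD3,
CD8, FoxP3, CD163, pancytokeratin (PanCK), PD-L1, GZMB and Ki67. Cores come
in triplicate per patient; each core also carries the percent of its
surface area staining positive for HLA-DR, measured upstream (this package
consumes cell tables, not images, and never computes pixel areas).
Coordinates are treated as an arbitrary image frame: every statistic used
is a function of inter-point distances and the window geometry only, hence
invariant to translation, rotation and axis orientation.

## Phenotyping

Lineage is assigned by a fixed precedence CD3 > CD163 > PanCK:

| rule | phenotype |
|---|---|
| CD3⁺CD8⁺ | cytotoxic T cell (CTL) |
| CD3⁺CD8⁻FoxP3⁻ | helper T cell |
| CD3⁺CD8⁻FoxP3⁺ | regulatory T cell |
| CD3⁻CD163⁺ | antigen-presenting cell (APC) |
| CD3⁻CD163⁻PanCK⁺ | epithelial (tumor) cell |
| CD3⁻CD163⁻PanCK⁻ | other |

The precedence resolves biologically contradictory co-positivity (typically
segmentation bleed-through); conflicts are counted per core and reported,
never dropped. GZMB, Ki67 and PD-L1 are state flags: "activated" means
GZMB⁺Ki67⁺ within a T-cell phenotype, and PD-L1± splits target sets (e.g.
CTL → PD-L1⁻ EC) without altering lineage. Assignment is total and
deterministic: exactly one phenotype per cell.

## Spatial statistics

All pairwise metrics take a reference set x and target set y inside one
core; when x = y, self-pairs are excluded. Metrics with an empty reference
or target set are *missing*, not zero, and stay missing through
aggregation.

**Nearest-neighbor distance** — Euclidean distance from each x cell to the
closest y cell (k-d tree; verified exactly against the all-pairs
computation).

**Engagement** — an x cell is engaged when ≥1 y cell lies within the
interaction radius, 40 μm center-to-center, boundary inclusive. Reported as
the percent of x cells engaged and, among engaged cells, the mean count of
simultaneous y contacts. The 40 μm radius is the package default and is
configurable.

**Cross-type G-function** — the distribution function
G_xy(r) = P(distance from an x cell to the nearest y cell ≤ r). Under
complete spatial randomness (CSR, homogeneous Poisson with target intensity
λ_y), G(r) = 1 − exp(−λ_y π r²); that closed form is exposed as the
theoretical reference and used as the simulation oracle. The *estimator* is
the Kaplan–Meier product-limit CDF of right-censored distances: each x cell
contributes min(d, c) with event indicator d ≤ c, where d is its nearest-y
distance and c its distance to the window boundary. Censoring removes the
downward bias of the naive ECDF for cells whose true nearest neighbor may
lie outside the observed core (edge effect); at tied times events precede
censorings (the standard convention), and the estimate is clipped to [0,1]
and made nondecreasing against floating-point jitter. The uncorrected ECDF
remains available (`correction="none"`) for diagnostics. Curves are
evaluated on a fixed grid, 0–60 μm in 1 μm steps — sub-micron resolution is
below a cell diameter, and a shared grid keeps AUCs comparable across
cores — and summarised by the trapezoidal AUC over [0, 60] μm (range 0–60,
higher = stronger mixing).

Windows are circles (center + radius) or axis-aligned rectangles. When a
cell table carries no window columns, the window is inferred as a 300 μm
circle at the coordinate centroid, expanded 1% beyond the farthest cell if
needed.

## Aggregation and stratification

Patient-level metrics are the unweighted mean over cores where the metric
is non-missing (triplicate cores have equal design weight); a metric
missing in all cores stays missing. A pooled alternative
(reference-cell-count weighting across cores, pooled counts for fractions)
is exposed via `RunConfig(aggregation="POOLED")` since the per-core vs
pooled choice is genuinely open; the default is per-core averaging.

The cohort is stratified around the arithmetic mean of per-patient HLA-DR
area percent: strictly above → HIGH, strictly below → LOW, exact tie →
HIGH (deterministic; ties are measure-zero on continuous measurements).
Unequal strata are expected and preserved.

## Hypothesis testing

For each metric the HIGH and LOW groups are compared with a normality gate:
both groups must pass Shapiro–Wilk at α = 0.05 (a constant group counts as
non-normal) to use the two-sided one-way ANOVA — for two groups identical
to the squared pooled-variance t test; otherwise the Wilcoxon rank-sum test
is used, with exact enumeration when combined n ≤ 20 without ties, and the
tie-corrected continuity-adjusted normal approximation otherwise. Groups
with fewer than 3 usable values make the comparison not-computable rather
than raising. Fisher's exact test for 2×2 tables uses the
probability-ordering two-sided convention (sum of hypergeometric
probabilities of tables no more likely than observed); a zero margin is
degenerate and returns p = 1 with a warning.

Benjamini–Hochberg adjustment (step-up, q_(i) = min_{j≥i} p_(j)·m/j capped
at 1) is applied within each declared metric family, defaulting to one
family per result panel: distances, engagement, infiltration, mixing,
activation. Family membership is configuration, not hard-coded. Note BH is
not idempotent — re-adjusting adjusted values inflates them — so adjusted
p's are computed exactly once per family.

Correlations against the continuous HLA-DR percent are Pearson r with the
two-sided t-transform p and pairwise deletion; r² is reported alongside r.

## Synthetic cohort generator

The generator emulates the cohort structure the analysis assumes, so every
stage is testable without patient data. Per patient: a latent stratum
(HIGH with probability 0.5), an HLA-DR area percent from the stratum's
normal truncated to [0, 100], and triplicate 300 μm cores. Per core, cells
are a marked point process:

- counts per phenotype ~ Poisson(λ·πR²) with stratum-specific intensities;
  positions uniform in the disc (CSR);
- attraction is Thomas-like: a Bernoulli(fraction_clustered) subset of an
  offspring phenotype is displaced from uniformly chosen parent cells by an
  isotropic Gaussian (sd σ), resampled until inside the disc. Counts are
  drawn before any position, so clustering moves cells without changing
  marginal counts. If the parent phenotype drew zero cells the offspring
  fall back to CSR (logged);
- GZMB/Ki67/PD-L1 states are independent Bernoulli per cell given phenotype
  and stratum.

Everything is a pure function of the config including its seed
(per-patient `SeedSequence` spawning), giving byte-identical cell tables.

Default parameters encode the study conditions: 149 patients × 3 cores,
total intensity 0.002 cells/μm² (~565 cells/core), phenotype mixes giving
immune fractions of ~17% (HIGH) vs ~8% (LOW) with helper-T, CTL and Treg
shares matching the reported infiltration contrasts; Th→APC attraction
(σ = 15 μm; clustered fraction 0.6 vs 0.2) and CTL→EC attraction (σ = 20 μm;
0.5 vs 0.15); activation rates giving ~7% vs ~4% GZMB⁺Ki67⁺ helper T cells;
HLA-DR at 14 ± 6 % (HIGH) vs 4 ± 2 % (LOW), making the cohort mean ≈ 9%.
The total intensity was chosen so that, at those phenotype fractions, the
CSR closed form also places T→APC engagement and nearest-neighbor distances
in the tens-of-μm / 50–65% range typical of this assay. A zero-effect
configuration (`null_config`, both strata = HIGH parameters) supports
type-I-error simulations.

**What the generator does not emulate** — and what passing tests therefore
do not certify on real data: stromal banding and tumor-nest architecture
(real EC patterns are strongly clumped, so EC-target engagement sits near
its CSR ceiling of ~100% here versus 14–23% in tissue), inhomogeneous cell
intensity across a core, segmentation noise and marker-call errors
(conflict rates are ~0 in simulation), correlated activation states, and
any dependence between HLA-DR level and spatial structure beyond the
two-stratum switch. Recovery tests certify directions and calibration, not
tissue-realistic magnitudes.

## Numerical and design choices

- Distances via `scipy.spatial.cKDTree`; equality with brute force is
  exact up to float summation order (≲1e-12 relative).
- KM at-risk accounting is vectorised over unique times; curves clipped to
  [0,1], enforced nondecreasing.
- The engagement boundary is inclusive (≤ radius) — the criterion is
  "within" a radius of a cell center.
- Patient aggregation ignores missing cores per metric rather than zeroing
  them; `n_ref`/`n_target` are carried so analyses can filter on counts.
- Stratification ties go HIGH; all-equal cohorts stratify entirely HIGH
  with a warning.
- Statistical primitives delegate to scipy/statsmodels (`shapiro`,
  `f_oneway`, `mannwhitneyu`, `fisher_exact`, `pearsonr`,
  `multipletests(fdr_bh)`); tests verify them against hand formulas,
  enumeration, and (for the KM curve) `lifelines`.

## Problem sizes used in the checked experiments

Simulation-based checks run at sizes chosen for tight-but-fast Monte Carlo:
estimator accuracy pools 20 CSR cores at λ = 0.002 μm⁻² (~11,000 reference
cells); the type-I-error study uses 200 null cohorts of 60 patients × 1
core; effect-direction recovery uses 20 cohorts of 100 patients × 3 cores;
oracle equivalence uses 100 random cores of up to 500 cells. The acceptance
script additionally analyses one full default cohort (149 × 3).

## Known limitations

- The cross-G estimator assumes independent censoring, which holds only
  approximately for point processes; the residual bias is well below the
  Monte-Carlo tolerance at core scale.
- Engagement and G metrics are first-order summaries; no inhomogeneous
  (intensity-varying) correction is offered.
- The Shapiro-gated test selection slightly distorts test calibration in
  principle; simulations show the battery's false-positive rate stays
  within the 99% binomial band of the nominal 0.05.
- Survival/outcome analysis is out of scope; the package stops at spatial
  and compositional comparisons.
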