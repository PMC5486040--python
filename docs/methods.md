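# Methods

This note documents the model, the defaults and why they were chosen, the
numerical decisions, what the synthetic generator does and does not emulate,
and the known limitations.

## Preprocessing chain

The chain runs in a fixed order; each step's parameters are recorded in the
output provenance.

1. **Grubbs single-outlier scan.** Per marker, the two-sided one-outlier
   test: G = maxᵢ |xᵢ − x̄| / s with the sample (n−1) standard deviation.
   The p-value uses the standard t-bound
   p = min(1, 2n·P(T₍ₙ₋₂₎ > t)), t² = n(n−2)G² / ((n−1)² − nG²); when the
   denominator is non-positive (G beyond its attainable maximum) p = 0. We
   also report U = SSD without the flagged point / SSD with it. Default
   α = 0.05, single pass (iterative re-testing available via
   `iterative_grubbs`, off by default). A flagged subject's **whole row**
   is removed, not the single cell: the analysis operates on per-subject
   vectors and a missing cell would break the data space. Ties between two
   equally extreme values go to the lower row index.
   *Caveat:* the test assumes normal marginals. On raw log-normal
   concentrations (our generator's marginals, and typical of serum panels)
   the skew inflates G, so at cohort size n ≈ 400 the scan tends to flag
   roughly one row per marker (~10 of 403 subjects with the defaults). This
   is the method's honest behavior on skewed input, kept because outlier
   elimination on raw concentrations precedes the log transform in the
   procedure this package implements.
2. **Covariate correction**, age then sex, on raw concentrations (before
   any scaling). Age: replace the marker by the residuals of OLS on age,
   plus the marker's original mean (mean-preserving). Sex: shift the
   smaller sex group by the difference of sex-wise medians so that
   post-correction medians are exactly equal — the minimal-perturbation
   reading of a "median difference" correction. Single-sex cohorts skip the
   sex step with a warning.
3. **Percent scaling**: x → 100·(x − min)/(max − min); endpoints are forced
   exact (min → 0, max → 100) to avoid last-ulp drift.
4. **Zero-invariant log**: ln(x + 1), the standard zero-safe choice on a
   [0, 100] scale.
5. **z-transform** with the sample (n−1) sd. After the full chain every
   marker has |mean| < 1e−8 and |sd − 1| < 1e−8.

## Toroidal ESOM

A Kohonen SOM on a 30 × 48 lattice (1440 units) with opposite edges
identified. Lattice distance wraps per axis (δ = min(|Δ|, size − |Δ|)), so
the farthest two units are √(15² + 24²) apart. Prototypes are initialized
uniformly from each data column's [min, max] range. Training is online: per
epoch the subjects are presented in a seed-shuffled order; for each subject
the BMU (argmin Euclidean data-space distance, ties to the lowest row-major
unit index) is found and every unit is updated by

w(u) ← w(u) + η(t) · exp(−d²(u, bmu) / (2ρ(t)²)) · (x − w(u)),

with learning rate η and radius ρ decaying **linearly over the total number
of presentation steps**: η 0.5 → 0.05, ρ 12 → 1, over 20 epochs. The grid
size, toroid and epoch count are the method's fixed conventions; the
schedules and online mode are this package's defaults (all exposed in the
estimator parameters) chosen as conventional ESOM settings — a start radius
near the half-height of the lattice organizes global topology, and the
end radius of 1 sharpens cluster borders without decoupling neighbors.
Quantization error (mean subject-to-BMU distance) is recorded before
training and after each epoch; on structured data it falls from first to
last epoch with only small transient rises.

## Height matrices

- **U-matrix**: height at unit i = mean data-space distance of w(mᵢ) to its
  8 Moore neighbors, taken with toroidal wrap (every unit has exactly 8).
  4-connectivity is available via `connectivity=4`.
- **P-matrix**: p(mᵢ) = |{x : ‖x − w(mᵢ)‖ < r}| with a strict inequality
  (open ball; a measure-zero choice, noted here). By default r is the
  20.13% quantile of all pairwise subject–subject distances (the Pareto-
  radius convention of the U*-matrix literature); a fixed r can be given.
- **U\*-matrix**: U\*(i) = U(i)·s(i) with s = 1 where P(i) ≤ mean(P) and
  s = (max(P) − P(i)) / (max(P) − mean(P)) otherwise, clipped to [0, 1];
  constant P leaves U unchanged. This linear above-mean damping is a
  reconstruction — the combination is named, not printed, in the method's
  source literature — and it guarantees 0 ≤ U\* ≤ U.

## Valley clusters and the threshold quantile

Units with U\* height at or below the `threshold_quantile` of all heights
form valleys; toroidal 8-connected valley components become clusters
1..k (numbered by first row-major appearance); each ridge unit is filled
with the cluster of its nearest valley unit by lattice distance (exact
integer squared distances; ties to the lower cluster id). Subjects inherit
their BMU's post-fill cluster. A constant U\* yields a single cluster with
a warning.

**Default `threshold_quantile` = 0.8.** This value comes from the geometry
of ESOM landscapes, not from a fit: cluster *interiors* cover most of the
lattice (the SOM allocates units roughly in proportion to data), while the
separating watershed is a thin closed band — on a 30 × 48 torus a
non-contractible separating ridge needs only on the order of 50–150 units,
i.e. 5–15% of the lattice. The valley set should therefore be large
(≈ 80–90% of units) and the ridge set small. Two further facts rule out a
half/half split: (a) a 50% valley mask sits above the site-percolation
threshold of an 8-connected lattice (≈ 0.41), so it almost surely forms one
giant component swallowing both groups; and (b) the U\* damping pivot at
mean(P) leaves a *smaller* cluster undamped when group sizes are unequal
(e.g. 102 vs. 301), dragging the global median below the small cluster's
valley floor. With the 0.8 default the three synthetic scenarios behave as
designed: near-perfect agreement under full separation, responder-limited
sensitivity with preserved specificity under partial separation, and
chance-level agreement without structure. The quantile remains a
configuration parameter.

Agreement scoring maps each cluster to its majority class (ties to
`control`, the conservative choice preventing sensitivity inflation), then
computes sensitivity, specificity and balanced accuracy
(= their mean, exactly, pre-rounding); reports round to one decimal while
exact values are kept internally.

## Synthetic cohorts

The generator emulates a two-group LC-MS/MS-style serum panel:
log x = log_mean + age_slope·(age − mean age) + sex_offset·1[male] +
effect_size·log_sd·1[affected patient ∧ affected marker] + N(0, log_sd),
exponentiated; outliers add outlier_magnitude·log_sd on the log scale in a
random fraction of cells. Scenarios: `full_separation` (all patients carry
the effect), `partial_separation` (a responder subset of exact size
round(responder_fraction·n_patients) carries it), `no_structure` (effect
ignored). Defaults, chosen once as a realistic desk-scale cohort:

| parameter | default | rationale |
|---|---|---|
| n_patients / n_controls | 102 / 301 | typical disease/control imbalance of such cohorts |
| n_markers | 10 | mid-sized lipid panel |
| log_mean / log_sd | 1.0 / 0.5 | log-normal with CV ≈ 53%, common for serum analytes |
| effect_size | 3 (log_sd units) | a clear but not degenerate group shift |
| affected_marker_fraction | 0.5 | the first ⌈0.5·d⌉ markers carry the effect |
| responder_fraction | 0.55 | partial-separation default: about half the patients respond |
| age_range | 18–63 y | adult cohort |
| male_fraction | 0.3 | typical of autoimmune-disease cohorts |
| age_slope / sex_offset | 0 | covariate effects off unless exercised |
| outlier_rate | 0 | outliers off except in outlier-scan fixtures |

These defaults are **stand-ins**: the generator does not reproduce any real
panel's absolute concentration ranges, units, or inter-marker correlation
structure (markers are conditionally independent given group, age and sex).
Passing recovery tests therefore show that the pipeline finds structure *of
the kind it assumes* — log-normal marginals, a mean-shift group effect —
not that it would perform identically on real serum data with correlated
markers and heavier preprocessing artifacts.

## Numerical choices and degenerate inputs

- Sample (n−1) standard deviation throughout (Grubbs, z-transform).
- BMU and Grubbs ties break to the lowest index; ridge-fill ties to the
  lowest cluster id — all deterministic and tested.
- All randomness (generator, weight init, presentation order) flows from a
  single integer seed; reruns are byte-identical, verified by manifest
  hashes.
- Constant marker columns raise a named degenerate-marker error at the
  first step that cannot proceed (Grubbs, percent scaling, z-transform).
- Torus connected components are computed by planar labeling plus
  union–find merging across the two wrap seams; ridge-fill uses exact
  integer squared lattice distances so ties are exact, not
  floating-point-fragile.

## Test design

Oracle tests compare against independent brute-force implementations
(exhaustive BMU loop, neighbor-enumeration U-matrix, double-loop sphere
counts, scalar U\* evaluation, leave-one-out Grubbs, BFS flood fill on the
torus). Monte-Carlo checks are sized for seconds-scale runs (e.g. the
null-scenario replicate check uses 400 replicates of a 40 + 40 cohort; the
two-blob topology check a 12 × 18 torus), while end-to-end recovery runs
the full study-sized configuration (403 subjects, d = 10, 1440 units,
20 epochs) over 5 seeds — the default map trains in well under a second.

## Limitations

- The U\* combination formula and the density radius are reconstructions;
  both are parameters, and different choices move the landscape.
- The valley threshold is a global quantile; strongly multi-scale
  landscapes (many clusters of very different depths) may need a different
  quantile or per-basin logic (not implemented).
- No significance testing of the cluster/diagnosis agreement, no
  multi-class evaluation, no sub-cluster detection.
- Batch SOM, growing maps and non-Euclidean data metrics are out of scope.
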