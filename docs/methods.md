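# Methods

## Model

The maturation score treats cardiomyocyte maturation as motion along a
single transcriptome axis. A reference atlas of bulk 3′-tag RNA-seq
samples spanning development (embryonic through adult, both ventricles
and atria) is normalized to TPM, log-transformed as log(ε + 1), and
decomposed by PCA — the SVD of the column-centered matrix with genes as
variables and **no unit-variance scaling**. Unscaled loadings let
high-dynamic-range maturation genes (energy metabolism, sarcomere)
dominate PC1, which is the intended behavior; the chamber program
(atrium vs ventricle) is orthogonal and falls on PC2. The unit-norm PC1
loading vector ω, the per-gene reference means μ, an orientation sign
and an affine calibration are frozen into a `MaturationAtlas`; any
query sample is then scored as

    score = scale × ( offset + Σᵢ ωᵢ (xᵢ − μᵢ) )

with x the query's log-TPM restricted to the atlas gene set.

Assumptions: 3′-tag libraries yield one fragment per transcript, so TPM
is computed without transcript-length division (counts-per-million);
maturation is monotone along PC1 within the reference design; the query
was normalized with the same unit, log base and gene space as the atlas
(checked via atlas provenance).

### Centered vs uncentered projection

The published formula projects uncentered log expression, Σωᵢ·log(εᵢ+1).
The two conventions differ by the constant Σωᵢμᵢ, which is absorbable
into the calibration offset. The package computes the centered
projection by default — it is self-consistent for arbitrary query
samples (the reference mean profile scores PC1 = 0) — and exposes the
uncentered variant through `project(..., centered=False)`. The
published constants are treated as one valid calibration of the
uncentered variant, rounded empirically.

### Calibration

* `data_driven` (default): offset = −min(PC1), scale = 100/(max − min)
  over the reference **ventricle** samples, mapping their range exactly
  onto [0, 100]. Atlases are built from both chambers but calibrated on
  ventricles only; atrial maturation is genuinely lower on this axis
  and would otherwise compress the scale.
* `paper_constants`: a user-supplied (offset, scale) stored verbatim —
  mouse (32, 1.5), humanized (27, 1.8). These reproduce the published
  0–100 conversion but are dataset-specific rounded values.

### Orientation

PCA signs are arbitrary; the loading is flipped so the Spearman
correlation between reference PC1 scores and age in days is positive.
An exactly zero correlation falls back to making the largest-|ω| gene
positive, a deterministic tie-break.

## Parameters and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| QC minimum reads/sample | 1,000,000 | reads | strict <; standard shallow-library cutoff for 3′-tag data |
| low-expression threshold | 1.0 | TPM (reference mean) | strict <; computed over reference heart samples only — queries never change the atlas gene set |
| log base | natural | — | the choice only rescales ω linearly; recorded in atlas provenance and enforced at scoring time |
| pseudocount | 1.0 | TPM | the +1 inside log(ε + 1) |
| missing-weight cap | 5% | of Σ\|ω\| | queries lacking more weighted mass are refused (override available); absent genes are imputed at μ, the unique unbiased choice under the atlas's own distribution |
| exact-Wilcoxon limit | 25 | samples/group | groups this small use the exact rank-sum null; larger use the normal approximation |
| minimum group size | 3 | samples | no statistics on n < 3; smaller groups report NA with a warning |
| GO gene selection | mean ± 2·SD of ω | — | population SD over all weights; boundary inclusive; sd = 0 yields empty lists |
| screen hit threshold | mean + 1·SD | channel units | sample (n−1) SD over non-control TF wells, per ±T3 condition; strict >; controls excluded to avoid diluting the screen distribution |
| marker flag | p < 0.05 and fold change > 2 | — | fold change on the linear TPM scale as ratio of group means; both arms required |

No multiple-testing correction is applied by default (the hit-calling
and marker thresholds are raw); an optional Benjamini–Hochberg column
is available for transparency.

## Cross-species ("humanized") scoring

Mouse and human symbols are matched case-insensitively (Title-case vs
UPPER-case conventions); many-to-many collisions are dropped and
logged, an explicit two-column table overrides matching. TPM is
recomputed **after** reduction to the shared gene space so each sample
re-sums to one million — scoring requires compositional consistency
within the space the atlas was built on. The atlas pipeline is then
rerun unchanged on the reduced mouse reference. Harmonization refuses
maps covering less than 50% of an atlas's |ω| mass.

## Synthetic data

The generator emulates the statistical structure the method relies on,
not the biology of any particular dataset:

* 8 stages at conception-anchored ages {11, 16, 22, 28, 35, 77, 171,
  321} days (E11 → 10 months; dense early, sparse late, matching the
  nonuniform sampling of real developmental designs), 4 replicates per
  stage per chamber; true pseudotime is log-age rescaled to [0, 1].
* 2,000 genes: 15% maturation-up and 10% maturation-down (log-mean
  linear in pseudotime, slope magnitude U(1, 3) natural-log units), 5%
  chamber genes (±2.0 log-units shift in atria, flat in time), the rest
  flat. Baseline log-abundance N(3, 2).
* negative-binomial counts (Gamma–Poisson, dispersion 0.05 — typical
  bulk RNA-seq) around library-size-scaled compositional means; library
  sizes LogNormal with mean 4×10⁶ and CV 0.3, so the 1M-read QC rule is
  occasionally exercised.
* screens: 92 TFs, 4 control wells, ±T3 conditions (T3 adds a uniform
  +5 score shift, which hit thresholds are invariant to). Null TF wells
  draw from the screen's null spread (SD 3 score units, independent per
  condition — the spread is dominated by between-well experimental
  variability, e.g. transduction efficiency, so it does not persist
  across experiments). Planted pro-maturation TFs instead carry a
  reproducible shift of effect × 3 score units measured with well-level
  noise of SD 0.5. This asymmetry is deliberate: it is what makes
  "planted" mean a real, condition-reproducible effect rather than a
  lucky well, and it is the regime in which the both-conditions hit rule
  is informative. The reporter channel carries half the planted effect,
  emulating the observed discordance between reporter and score.

What the simulator does **not** emulate: transcript-length and GC
biases, batch effects, isoform switching, cell-type composition drift
in whole-tissue samples, and correlated gene–gene noise. Passing tests
therefore demonstrate that the estimator recovers a planted monotone
program under realistic count noise — not that any particular real
dataset will show the same effect sizes.

## Numerical choices

* PCA via `numpy.linalg.svd` of the centered matrix; an all-constant
  reference (zero variance) is a hard error.
* Atlas files store floats with `repr`, and matrix TSVs are parsed with
  Python's `float()` (exact repr round-trip; fast strtod parsers can be
  off by one ulp), so write → read round-trips are bit-exact; a SHA-256
  checksum over the weight table detects corruption.
* Exact Wilcoxon rank-sum p-values come from the exact Mann–Whitney
  null (no tie correction in the exact branch); tests cross-check them
  against a brute-force enumeration oracle.
* Degenerate inputs error early with located messages: empty matrices,
  duplicate ids, zero-sum TPM columns, empty reference sets, sd = 0
  calibration ranges.

## Problem sizes

The default test and acceptance workloads are sized for a laptop-class
single core: the standard atlas is 2,000 genes × 64 samples (seconds to
build), oracle-equivalence checks use ≤ 50 genes × 12 samples × 20
random matrices, and screen recovery uses 20 simulated 92-TF screens.

## Known limitations

* The score is a ventricular maturation axis; adult atria score lower
  than adult ventricles by construction, and no atrial-specific score
  or PC2+ modeling is provided.
* Symbol-based orthology is deliberately naive (no HGNC alias or
  curated orthology resolution); an explicit table is the escape hatch.
* Stage annotations of query samples are descriptive
  (nearest-reference) only; the package does not re-derive stage labels.
* The published calibration constants are empirical for their dataset;
  scores under `paper_constants` are only comparable across datasets
  processed with the same gene space and normalization.
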