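# imodkit

Decompose a bacterial gene-expression compendium into **i-modulons** —
independently modulated gene sets with condition-specific activities —
and use them as a quantitative scaffold for the transcriptional
regulatory network (TRN).

A measured expression profile mixes the effects of every active
transcriptional regulator. Given a diverse compendium **X** (genes x
samples, log₂(TPM+1), centered on a reference condition), independent
component analysis separates those effects:

```
X = S A
```

where the columns of **S** (zero mean, unit L2 norm) hold per-gene
coefficients of statistically independent signals and the rows of **A**
hold each signal's condition-specific activity. The genes whose
coefficients stand out of a component's near-Gaussian background form an
i-modulon; when the i-modulon matches a known regulon, its activity
tracks the condition-dependent state of that regulator.

`imodkit` is aimed at microbial systems biologists with a bulk RNA-seq
(or microarray) compendium and a curated regulator→gene table
(RegulonDB-style) who want module structure, regulator links, and
activity statistics without hand-tuning a decomposition.

## What the package implements

- **Preprocessing** — log-TPM from counts and gene lengths (GFF3 or
  table), gene QC (length ≥ 100 nt, ≥ 10 fragments per million in at
  least one sample), replicate QC (R² ≥ 0.9 between replicate log-TPM
  profiles), and centering on designated reference samples.
- **Robust decomposition** — FastICA (logcosh contrast, parallel
  updates, tolerance 1e-8) restarted many times; pooled components
  clustered by DBSCAN (ε = 0.1, minimum cluster size 50% of restarts)
  under the sign-invariant distance `d(x,y) = 1 − |ρ(x,y)|`; cluster
  centroids sign-aligned so the largest-|weight| gene is positive; the
  whole procedure repeated with disjoint seed streams, keeping only
  components re-identified in every repetition (d < 0.1). Components are
  ordered by activity norm and scored by cumulative explained variance
  `CEV(K) = 1 − TSS(X − Σ_{k≤K} s_k a_k)/TSS(X)`.
- **Thresholding** — iterative removal of largest-|coefficient| genes
  until the D'Agostino K² statistic of the remainder drops below a
  cutoff (default 550); cutoff calibration by F1 against linked regulons
  over the grid 200..1000 (step 50), with a three-fold cross-validated
  variant; orientation so positive-weight genes form the majority.
- **Regulon enrichment** — two-sided Fisher's exact test over the gene
  universe, including intersections (`+`) and unions (`/`) of up to
  three regulons, with Benjamini–Hochberg FDR (< 1e-5) per i-modulon,
  plus precision / recall / F1 and i-modulon categorization.
- **Activity analysis** — log-normal replicate-noise model, differential
  activity between conditions (significant when |ΔA| > 5 and FDR < 0.01),
  profile correction `x₂′ = x₂ − Σ s̃ᵢ (a_{i,2} − a_{i,1})`, projection
  of new profiles `A′ = pinv(S) X′` over shared (core) genes, and
  activity-versus-regulator-expression association (linear and
  single-breakpoint fits).
- **Synthetic fixtures** — generator for compendia with planted sparse
  modules, block activities with replicate jitter, reference samples,
  matching toy regulons with size-matched decoys, and knockout samples,
  so every stage can be validated with no external data.

## Worked example

`examples/threshold_and_enrich.py` generates the default synthetic
compendium (4000 genes x 60 samples, 10 planted modules, noise σ = 0.05),
decomposes it, thresholds at K² = 550, and links each i-modulon to the
toy regulon table:

```
10 i-modulons from 10 components
  M0: 27 genes -> reg_4 (p=5.5e-54, precision=0.81, recall=1.00, F1=0.90)
  M1: 16 genes -> reg_1 (p=5.3e-35, precision=0.81, recall=1.00, F1=0.90)
  M2: 25 genes -> reg_6 (p=1.2e-49, precision=0.80, recall=1.00, F1=0.89)
  ...
```

Each line reads: the i-modulon's significant genes, its best-ranked
regulator, the Fisher p-value of the overlap, and precision/recall
against the regulon. The generator's regulons cover 80% of each planted
module, so a correct link shows precision ≈ 0.8 with recall 1.0 — the
module recovered every regulon gene plus the planted members the toy
"database" does not know about, mirroring how real i-modulons extend
documented regulons.

Other examples: `decompose_synthetic.py` (recovery distances and
explained variance), `differential_activity.py` (knockout vs wild type),
`project_and_correct.py` (fixed-basis projection and module
subtraction), `full_pipeline.py` (file-based run). The same stages are
available as a CLI: `imodkit simulate | preprocess | decompose |
threshold | enrich | diffact | project | run`.

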