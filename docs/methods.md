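# Methods

## Differential expression model

Counts for gene *g* in sample *s* are modeled as negative binomial with
mean μ<sub>gs</sub> and variance μ + α<sub>g</sub>μ² (α is the per-gene
dispersion; α → 0 recovers Poisson). The mean is linked log-linearly to a
tumor indicator with the log normalization factor as offset:

log μ<sub>gs</sub> = β₀ + β₁·tumor(s) + log f<sub>gs</sub>

β₁ is the natural-log fold change; log2FC = β₁ / ln 2, so a positive value
means higher expression in tumor. The Wald statistic z = β₁ / SE(β₁) gives
a two-sided normal p-value per gene, and p-values are adjusted with the
Benjamini–Hochberg step-up procedure (genes with no counts anywhere are
untested and excluded from the adjustment). The GLM is fit by IRLS via
statsmodels with the dispersion held fixed at its estimate.

**Normalization.** Per-sample size factors use the median-of-ratios
estimator: the reference is the per-gene geometric mean across samples
(over genes expressed in every sample), and each sample's factor is the
median ratio to that reference. An optional gene×sample factor matrix
(e.g. externally computed GC-content/length bias weights) can be supplied;
each of its rows is divided by its geometric mean before being multiplied
by the size factors, so the gene-level component of every row has
geometric mean exactly 1 and normalized counts stay on the scale of the
raw counts. No bias model is fit internally — the contract is the
row-rescaling, and the factor matrix is an input.

**Dispersion.** Per-gene method of moments on normalized counts:
α̂ = (s² − m̄)/m̄² computed within each condition, averaged across the two
conditions, floored at 10⁻⁸. This is deliberately simple — no
empirical-Bayes shrinkage across genes — which is adequate at the cohort
sizes the pipeline targets (tens of samples per arm) and keeps every
estimate locally testable. At very small n (≲ 10 per arm) the Wald test
with MoM dispersions becomes anti-conservative; shrinkage estimators are
the standard remedy and are out of scope here.

**Degenerate genes.** A gene expressed in only one condition has an
infinite MLE fold change. The convergence guard refits such genes (and any
gene whose fit fails or exceeds |β₁| > 20 on the natural-log scale) with a
0.5 pseudocount added to its counts, then clips β₁ to ±20. The gene stays
tested with a finite, capped estimate; a gene that still fails is marked
untested with a warning, never aborting the run.

## Ranking and filtering

For genes with FDR < 0.05 (strict inequality) and log2FC > 0:

Metric = max(0, log2FC − FDR / 0.05)

The clamp at zero reflects the score's intended scale (lower bound zero, no
upper bound); a small fold change with an FDR near 0.05 can drive the raw
value negative, and such genes are kept in the ranking at 0 rather than
discarded, since they satisfied both eligibility conditions. Ties are
broken by gene symbol for deterministic output.

The FPKM filter is a hard cutoff at 10 (moderate expression) on per-gene
average FPKM. Because values just under the cutoff are biologically
indistinguishable from values just over it, a borderline band —
[0.9·cutoff, cutoff) by default, configurable via `borderline_frac` — is
flagged in the output; borderline genes are reported but are **not**
eligible and do not anchor heterodimer calls (configurable upstream by
lowering the cutoff if a user disagrees). When no external FPKM table
exists, `fpkm_from_counts` computes count / (length<sub>kb</sub> ×
mapped-millions) averaged over tumor samples; tumor-sample averaging is
used because the filter asks whether the *tumor* expresses the target.

## IHC quantification

Ordinal staining levels map to not detected = 0, low = 0.33, medium =
0.66, high = 1. A gene/cancer tally of n samples gives

weighted average = (1·n_high + 0.66·n_med + 0.33·n_low + 0·n_nd) / n

and the gene is protein-overexpressed iff this strictly exceeds the value
of the single level assigned to normal tissue (equality is not
overexpression). The input contract requires the normal level already
collapsed to one descriptor per gene/cancer, and assumes antibody
validation happened upstream; an `antibody_id` column is carried through
for provenance only. Gene/cancer combinations without any tally are
emitted with `reason = no_data` so downstream integration can distinguish
absence of evidence from negative evidence. IHC resources that pool
cancers by organ (one lung record covering both lung subtypes) are
expanded through an explicit organ→subtype mapping, never by name
matching.

## Heterodimer calling

A call requires the (α, β) pair to be one of the 24 legal receptors.
Strict mode: both chains pass the per-subunit filter (Metric-eligible and
FPKM-pass for RNA; protein-overexpressed for IHC). Relaxed mode: one
passing chain suffices — the rationale being that abundant mRNA of one
chain can drive receptor assembly with a partner expressed at normal
levels — and the number of passing chains is recorded (2 ⇒ also a strict
call). Strict calls are provably a subset of relaxed calls, and ITGBL1 can
never appear in a call because it has no pairing rule. Evidence classes
partition the union of RNA and IHC call sets into `both`, `rna_only`,
`ihc_only`. The same per-subunit criterion anchors both modes; a
borderline-FPKM subunit does not anchor a relaxed call.

The packaged pairing table is: β1×{α1–α11, αv} (12), β2×{αL, αM, αX, αD}
(4), β3×{αIIb, αv} (2), β4×{α6} (1), β5×{αv}, β6×{αv}, β8×{αv} (1 each),
β7×{α4, αE} (2) = 24. αIIb (ITGA2B) is included as the 18th α chain; it is
the only assignment consistent with the 18α/9β/24-receptor combinatorics
and the named constraints (β4–α6 exclusivity, five αv receptors, unpaired
ITGBL1).

## Synthetic cohorts

The generator emulates exactly the data structures the pipeline consumes:
NB counts with gene-specific dispersions, planted tumor/normal fold
changes, per-sample library-size factors (log-normal), optional log-normal
gene×sample factors (row geomean 1), FPKM tables, and multinomial IHC
tallies. All randomness flows from one seeded numpy Generator; a fixed
seed reproduces every table byte for byte.

Default study conditions: 50 tumor + 50 normal samples, baseline mean 200
counts, dispersion 0.1, planted log2FC = 2, planted FPKM 50 vs 5 for null
genes, library-size spread 0.15 on the log scale — sizes and effects
typical of a mid-sized solid-tumor cohort with a clearly overexpressed
target. The demo study adds 150 background genes (baseline means 50–2000)
so median-of-ratios size factors are estimated from a realistic gene pool,
and sets non-planted integrins' FPKM below the cutoff so that an
occasional false positive among 25 null integrin genes (expected under 5 %
FDR control) cannot enter the call set: planted-truth recovery is then
deterministic, which is what the end-to-end tests assert.

What the generator does **not** emulate: GC-content bias structure (factor
matrices are accepted, not simulated from sequence), outlier samples,
batch effects, correlated genes, or real integrin expression profiles.
Passing tests therefore demonstrate the statistical machinery is correct
under its own model assumptions, not that real cohorts satisfy those
assumptions.

Calibration simulations plant the fold change in a small minority of genes
(2 %). Planting a large fraction shifts the median-of-ratios reference —
the size factors absorb part of a globally shared fold change — which is a
property of the normalization, not an estimator defect; the same caveat
applies to real datasets where most of the transcriptome moves.

## Numerical choices

- Dispersion floor 10⁻⁸ (Poisson limit); NB family falls back to this
  floor rather than switching families, keeping one code path.
- Coefficient cap |β₁| ≤ 20 (natural log) ≈ ±28.9 log2 units — far beyond
  any biologically meaningful fold change.
- BH adjustment via statsmodels, verified in tests against a brute-force
  step-up oracle (min over j ≥ i of p₍ⱼ₎·m/j, capped at 1).
- Geometric means are computed in log space; the row-geomean-1 contract is
  enforced to 10⁻⁸.
- All output tables sort deterministically (cancers and genes
  lexicographic, metric descending with symbol tie-break).

## Known limitations

- Two-group design only: no covariates, batch terms or paired samples.
- No fold-change shrinkage and no outlier handling (Cook's distance);
  reported log2FC is the raw MLE.
- FDR threshold, FPKM cutoff and borderline band are global constants per
  run, not per-cancer adaptive.
- The IHC score treats the ordinal level spacing (0/0.33/0.66/1) as
  meaningful cardinal distances, inheriting that convention's arbitrariness.
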