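# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical conventions that make results reproducible.

## Study design assumed

Three sample groups — A (control), B (elicitation/acute), C (remission) —
with few replicates per group (default 4, i.e. 12 arrays), and three RNA
classes measured on separate single-channel platforms. Contrasts are
B-vs-A ("elicitation") and C-vs-A ("remission"). Any other label set and
contrast list can be configured.

## Normalization and detection filtering (`normio`)

* **Quantile normalization** (long-transcript arrays): every sample is
  mapped onto the mean empirical distribution. Ties within a sample receive
  the average of the tied ranks' reference values — the standard convention;
  the operation is idempotent by construction.
* **Median normalization** (short-RNA arrays): the reference set is the
  genes with intensity ≥ 30 (configurable) in *all* samples; each sample is
  scaled by (grand mean of per-sample reference medians)/(own reference
  median). Scaling to the grand mean rather than to 1 keeps values on the
  original intensity scale; within-sample rank order is preserved.
* **Detection filter**: keep genes flagged Present or Marginal in ≥ 3
  samples (the usual "3 of 12" rule; configurable).
* Missing values are rejected at read time; no policy for them is defined
  anywhere in this pipeline, and silently imputing would be worse.

## Differential expression (`diffexpr`)

* FC is the ratio of **linear-scale group means** (microarray convention);
  testing is a **Welch t-test on log₂ intensities**. The test form is an
  assumption of this package — small-sample array studies rarely state one —
  and is deliberately the least-committal classical choice. No
  moderated-variance (empirical Bayes) shrinkage is attempted; with the
  simulator's homoskedastic noise it would change nothing, and with real
  data users should know they are getting the plain Welch test.
* A variance floor of 1e-8 (log₂ scale) is added to each group variance so
  zero-variance fixtures yield t = 0, p = 1 instead of 0/0.
* **BH step-up** is the FDR procedure (via statsmodels). Significance
  calling uses the raw p by default with q always reported; `use_fdr=True`
  switches the filter to q. The default follows the common practice of
  filtering on p while reporting FDR.
* Class thresholds: miRNA FC > 1.5, long RNAs FC > 2.0, both p ≤ 0.05,
  strict (>) comparisons. The triplet-assembly stage owns its *own*
  threshold object with an inclusive bound (FC ≥ 2.0, p < 0.05) because the
  two filters are conventionally stated differently; keeping two objects
  makes the discrepancy explicit rather than hiding it.
* Hierarchical clustering: average linkage on 1 − Pearson r, via SciPy;
  items with zero variance are rejected (undefined correlation).
* qPCR utility: relative expression 2^−ΔΔCt with
  ΔCt = Ct_target − Ct_reference per condition.

## MRE scanning (`mre_scan`)

This stage is authored here in full; it stands in the architectural role of
external target predictors, which are services/binaries, not libraries.

* **Seed geometry** follows the canonical site taxonomy: the 6mer core is
  the reverse complement of miRNA nt 2–7; an additional Watson–Crick match
  to nt 8 (one base 5′ on the target) and/or an A opposite nt 1 (one base 3′)
  upgrade the anchor to 7mer-m8 / 7mer-A1 / 8mer. All distinct anchors are
  reported; one anchor keeps only its best type.
* **Pair score**: Smith–Waterman local alignment of the full miRNA (3′→5′)
  against the `window` (default 30 nt) of target ending at the site's 3′
  edge; WC +5, G:U wobble +2, mismatch −3, linear gap −8. The constants are
  classical duplex-alignment defaults, exposed in `AlignmentScoring`.
  Traceback is deterministic (earliest maximal cell; diagonal > up > left).
* **Energy score**: additive per closed base pair, G:C −3.0 / A:U −2.0 /
  G:U −1.0 kcal/mol. This is a transparent stability proxy, *not*
  nearest-neighbor folding and not an accessibility model; it keeps the
  stage dependency-free and exactly testable (the test suite checks it
  against hand sums and translation invariance).
* **Pass rule**: a prediction passes iff a single site has a seed anchor
  AND pair score ≥ S_min (80) AND energy ≤ E_max (−14) — an intersection of
  the seed method and the score method. With these defaults a bare 8mer in
  a random context does not pass (score ≈ 40–55); extensive 3′
  complementarity is required, so chance passes are rare (none observed in
  the null simulations) while fully complementary planted sites always pass
  (score ≥ 5·(L−1) ≥ 90 for a 19–24-nt miRNA).
* lncRNA MREs use the same scanner and thresholds; the ceRNA criterion only
  needs "possesses a passed MRE".

## Co-expression (`coexpr`)

Pearson r on log₂ profiles over the shared samples (optionally one group);
p from the exact t transform with n − 2 df; BH family = all tested pairs
(no narrower family is defensible without extra structure). Defaults
|r| ≥ 0.995, FDR < 0.05. The absolute value is used for the cut, the sign
is kept on the edge for the triplet direction rule. At n = 12 the null
tail P(|r| ≥ 0.995) ≈ 1e-13, so independent noise essentially never
produces an edge — the acceptance run measures 0 edges in 20 × 100,000
null pairs.

## ceRNA assembly (`cerna_net`)

The five criteria are listed in the module docstring. Two choices were
genuinely open:

* **Direction consistency** (lncRNA ∥ mRNA, both ⊥ miRNA) is imposed by
  default — it is what the sponge mechanism predicts — and can be disabled
  (`require_direction=False`).
* "Correlated with the miRNA's targets" is read in the *strictest* way: the
  lncRNA must form a retained, positively signed CNC edge with the specific
  target mRNA of the triple, not merely with any target. This makes every
  emitted triplet auditable; `audit_triplet` re-verifies all criteria from
  the raw inputs and is exercised in the tests.
* miRNA–lncRNA expression anti-correlation is *not* additionally required:
  MRE possession plus the DE direction pattern already encodes the
  antagonism, and requiring a second correlation screen at |r| ≥ 0.995
  would make the criterion nearly unsatisfiable at n = 12.

Networks are exported as GraphML (node attrs: `rna_class`, `direction`;
edge attrs: `evidence` ∈ {regulatory, mre, coexpression} plus scores) and
as TSV edge lists; GraphML round-trips through networkx.

## Enrichment (`enrichment`)

Upper-tail hypergeometric P(X ≥ k) per term with BH across terms,
enrichment score −log₁₀ p, output ordered by (p, term_id) for determinism.
Gene sets come from GMT; the background universe defaults to the genes
surviving detection filtering — a user decision, not hard-coded. Fisher's
exact one-sided test on the 2×2 table is identical to this statistic; no
ontology-graph propagation is done.

## Simulator (`synthdata`)

What it emulates: a 3 × n_per_group lognormal intensity design
(log₂ x = baseline + group effect + triplet coupling + noise), per-cell
detection flags (Present iff intensity ≥ floor, default 30), class-specific
planted DE with a massive-elicitation / sparse-remission asymmetry
(defaults 15 % vs 2 % of each class, alternating up/down at |log₂FC| = 2.5),
and sponge triplets: a shared latent N(0,1) factor per triplet with
loadings (−k, +k, +k) inside the triplet's phase group yields
miRNA-vs-partner anti-correlation and partner–partner positive correlation
with one parameter, while the planted mean effects (miRNA up, partners
down by default) give the DE signature.

Sequences are uniform random RNA (miRNA 19–24 nt, lncRNA 400 nt, 3′UTR
300 nt). For each triplet the *full* complement of the miRNA (reverse
complement of nt 2..L plus a 3′ A) is written into both partners, with the
recorded 8mer span at its 3′ end, so planted sites clear the scanner's
intersection thresholds by construction; `plant_8mer` also exists for
minimal seed-only sites.

What it does **not** emulate: probe-level artifacts, dye/batch effects,
heteroskedastic or intensity-dependent noise, correlated background genes,
mRNA secondary structure, or realistic sequence composition. Passing tests
therefore demonstrate the *machinery* is correct and calibrated under the
stated generative model — not that the biological predictions on real
arrays would have the same operating characteristics.

One integer seed drives everything; each stage derives a deterministic
child stream (`default_rng([seed, stage])`), so matrices, FASTA files and
manifests are byte-identical across runs.

### Chosen study scales

* Replicates: n_per_group = 4 (12 arrays), a typical small-animal design.
* Stage-level triplet recovery is demonstrated at 100 lncRNAs / 30 miRNAs /
  300 mRNAs with 10 planted triplets, coupling k = 0.5 and noise SD 0.05
  ("strong coupling, low noise": the latent factor is 10× the noise SD but
  does not swamp the planted mean effects — couplings ≳ 1.5 inflate the
  within-group variance enough to cost Welch power at n = 4).
* DE calibration uses 1000 genes with 50 planted at |log₂FC| = 2, noise SD
  0.25, over 20 replicate simulations; the null CNC screen uses 200 × 500
  independent genes at n = 12 over 20 seeds.

## Known limitations

* Quantile normalization at toy scale (≤ a few hundred genes with ≥ 10 %
  planted DE) visibly compresses planted effects and costs ~0.001–0.004 in
  lncRNA–mRNA correlation — enough to lose 1–2 triplets against the razor-thin
  0.995 cut. This is a property of quantile normalization under asymmetric
  DE, exaggerated by small gene counts; on full-size arrays (tens of
  thousands of genes, ≤ 16 % DE) the distortion is far smaller. The pipeline
  therefore accepts `normalization = "none"` per class for data already on
  a common scale, and the planted-truth pipeline test uses it; a companion
  test documents the attenuated (≥ 0.8 recall) behaviour with
  normalization enabled at an array-like scaled design.
* The energy proxy is additive; no stacking, loops or accessibility.
* No paired designs, no covariates, no moderated variance.
* The scanner reports plus-strand single-stranded RNA sites only.
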