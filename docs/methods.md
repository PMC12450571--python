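# Methods

This note documents the models, numerical choices and limitations behind
`miraudit`, in the order data flows through the pipeline.

## Expression audit

The audited quantity is, for each mature miRNA, the maximum cpm it attains
over every sample of every dataset supplied. Datasets are deliberately
never merged cell-wise: public resources differ in sample sets and
normalisation provenance, so only the per-miRNA maxima are combined. Ties
in the argmax are broken first-seen (dataset order as given, then column
order), which makes the audit invariant to sample/row permutations in
everything except the reported provenance.

Threshold semantics follow the phrase "never expressed above T": a miRNA
*fails* T when max ≤ T, so bins have inclusive upper bounds
(≤10, (10,100], (100,1000], >1000 by default) and a maximum of exactly
100 cpm fails the 100 cpm threshold. 200 cpm corresponds to 0.02% of the
small-RNA pool (cpm/10⁶), a conversion exposed directly because it is the
functional threshold the reporter data calibrate.

Locus aggregation treats a hairpin as being as expressed as its best arm.
Two policies exist for matures annotated at several paralogous loci: the
default credits the shared mature's maximum to *every* parent locus (the
conservative, function-favouring choice — expression attests activity of
at most one parent, ambiguously — and such loci are flagged
`multi_locus_credit`), the alternative credits only the first-listed
locus. Annotated matures absent from every matrix receive max = 0 and a
`not_detected` flag: absence from a cpm export is treated as evidence of
non-detection while preserving the distinction from a measured zero.
Matures observed in expression data but missing from the annotation are
reported in an `unmapped` table, never silently dropped.

cpm validation: full matrices must have column sums within 1% of 10⁶
(public exports are rounded); matrices declared "prefiltered" (a subset of
miRNAs) only need sums ≤ 10⁶ + tolerance. Negative, non-finite and
non-numeric cells are hard errors with coordinates.

## Seed families

The family key is the 6-mer at mature positions 2–7 (1-based from the 5′
end) — the criterion under which other family members are predicted to
target a reporter. The 8-nt site (positions 2–9) is carried for describing
seed-only reporter constructs but is never a family key, and no weighting
distinguishes members matching 2–7 but mismatching 8–9; the module records
both seeds and leaves any such weighting to the user. Family-summed
expression includes the target itself by default ("the total dose expected
to act on the reporter"); a flag exposes the family-excluding-target
increment. No target prediction beyond seed identity is attempted (no
context scores, no 3′-supplementary pairing).

## Reporter analysis

The unit of analysis is the biological replicate: technical replicates are
averaged first, and each reporter contributes one relative activity per
biological replicate (its technical-mean Renilla/Firefly ratio divided by
the same replicate's empty-vector technical-mean ratio). This treats
biological replicates as the independent units and makes every activity
invariant to common scaling of a replicate's readings.

The group control pools reporters whose target is below 20 cpm in the
assayed cells. Its band spans the member reporters' *means* (min to max),
not raw wells — raw-well extremes would widen the band artifactually; the
pooled t-test sample defaults to the per-(member, biological replicate)
activities, with a wells-level pooling mode selectable since the source
description ("summation of measurements") is ambiguous. Fewer than two
eligible members is a hard error ("group control not constructible").

Tests are unpaired two-tailed Student's t with pooled variance (a Welch
flag exists); zero-variance degenerate inputs resolve by the limit (equal
means → p = 1, unequal → p = 0 with a warning) instead of NaN. Stars use
inclusive boundaries (p ≤ 0.05 → \*, ≤ 0.01 → \*\*, ≤ 0.001 → \*\*\*,
≤ 0.0001 → \*\*\*\*). "Detected" requires p ≤ 0.05 **and** a mean below
the band's lower bound, so significant *de-repression* above the band is
never called repression. No multiple-testing correction is applied by
default, matching the assay's conventional analysis; a Bonferroni option
exists. The detection-vs-dose summary uses the family-summed ("Seed") cpm
as its dose axis, because seed-sharing paralogs repress the same reporter.

## Synthetic data generator

The generator's defaults encode the study conditions; they are fixed, not
fitting knobs.

* **Annotation.** 1,744 loci; 62% produce both arms (≈ 2,800 matures);
  seeds drawn from a 400-seed pool so non-trivial families exist;
  sequences otherwise uniform over {A,C,G,U} with no compositional
  realism. Each locus draws a taxonomic node from five ordered lineages
  (ages 650/530/180/75/0 Mya, probabilities .15/.20/.25/.20/.20), a
  curation flag with node-dependent probability (.80/.60/.30/.15/.08 —
  ancient loci are almost always curated), and a low/high expression label
  with probability depending on the joint (curation, node) stratum:
  curated 0/.02/.08/.12/.20, uncurated .30/.45/.60/.70/.85. These values
  reproduce the observed conditionals (≈66% of uncurated loci below
  100 cpm, ≈27% below 10 cpm, 20% of curated human-specific loci below
  100 cpm, essentially no low curated ancient loci); the resulting overall
  low fraction (≈44% of loci) is emergent, slightly below the ≈50%
  reported for the real complement. A one-dimensional per-stratum map
  cannot satisfy the curation-conditional and node-conditional statements
  simultaneously, hence the joint keying; the implied per-node marginal is
  exposed (`expected_low_fraction_by_node`) for recovery tests.
* **Expression.** log₁₀ basal abundance is Normal(1.0, 0.45) for low and
  Normal(3.0, 0.45) for high matures; the basal vector is rescaled to sum
  to 10⁶, then per-(miRNA, sample) multiplicative log-normal noise
  (ln-sd 0.35) is applied and every column renormalised to exactly 10⁶.
  Renormalisation enforces cpm compositionality — one miRNA's rise
  depresses the others — which the audit must tolerate. A consequence is
  that the absolute scale depends on the simulated complement: at the
  default locus count the two components are separated around the 100 cpm
  line with ~1–2% crossover, while much smaller simulations shift the
  whole scale upward. Recovery tests therefore run at ≥2,000 loci.
* **Repression.** a(E) = floor + (1 − floor)/(1 + (E/K)^h) with K = 2000
  cpm, h = 1.3, floor = 0.02, and effective dose E = Exact + w(Seed −
  Exact) with w = 0.05. The real dose–response's shape between 200 and
  1000 cpm is unconstrained ("variable" detection); the Hill defaults are
  chosen so the simulated detection threshold lands between 200 and
  1000 cpm, and they are tunable, not inferred. Plates: Firefly log-normal
  around a plate mean (ln-sd 0.10), Renilla = Firefly × a(E) × control
  ratio × per-(reporter, bio) factor (ln-sd 0.08) × per-well noise
  (ln-sd 0.15); 4 technical × 3 biological replicates per condition. The
  Firefly term cancels exactly in the per-well ratio, so the ratio noise
  is the well term alone. A "mimic" scenario forces strong repression on
  reporters whose targets do not exist in the genome, reproducing the
  demonstration that over-expression repression is uninformative about
  endogenous function.

All randomness flows from a single integer seed through one generator;
identical seeds give byte-identical output files.

### What the generator does and does not emulate

It reproduces: compositional cpm vectors, bimodal expression correlated
with curation and lineage age, seed-family structure, replicate-structured
plate noise, and threshold-like dose–response. It does not model reads,
ligation bias, single-cell sparsity, tissue-specific expression programs
(samples differ only by exchangeable noise), realistic sequence
composition, or the extreme upper tail of real expression (the simulated
maximum is ~10⁴–10⁵ cpm). Passing recovery tests therefore shows the
*audit machinery* is correct under the assumed statistical structure, not
that real resources would yield the same numbers.

## Problem sizes and numerics

Test and acceptance runs use: the default 1,744-locus simulation with
three 40-sample datasets for audit quantities; 2,000 loci × 200 samples
for stratum recovery (tolerance ±3 binomial standard deviations); 500
seeded screen repetitions for type-I control (nominal α = 0.05; the
detected flag's band condition makes the realised false-positive rate
≈1%); 200 repetitions for the dose–response summary; and 100 random
instances per brute-force oracle comparison. The t statistic is required
to agree with the direct textbook formula to 10⁻¹⁰. Reports serialise
numbers with `%.10g`, sufficient for lossless round-trips at the
precisions involved; report rows sort by (max_cpm, mature_id) for stable
output.

## Known limitations

* The audit is purely descriptive — no differential expression, batch
  correction, or tissue-specificity scores.
* DROSHA processing classes are pass-through annotation, never recomputed.
* Identifier matching between expression rows and annotation is exact
  string matching after trimming; no alias resolution across miRBase
  versions.
* The multi-locus crediting choice changes locus-level counts when shared
  matures exist; both policies are implemented because the right choice
  depends on the question being asked.
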