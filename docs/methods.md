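# Methods

## The analysis problem

A paired cohort design: each patient contributes one supragingival dental
plaque specimen and one odontogenic abscess specimen, both profiled by 16S
amplicon sequencing into a taxa × samples count table with a taxonomy
lineage per taxon. The questions the pipeline answers, in order: do the two
specimen types form distinct communities (ordination, clustering, alpha
diversity)? which taxa shift between them (consensus differential
abundance)? what polymicrobial signatures organise the communities (LDA
topic modeling)? how predictable is specimen type from composition
(cross-validated classification)? and which functional pathways are
over-represented among the shifted features (hypergeometric enrichment)?
Because the specimens are patient-matched, every test statistic is paired:
the per-patient plaque-minus-abscess contrast is the unit of inference
throughout.

## Cohort filtering

Four rules, applied in this order: (1) taxa on a user-supplied contaminant
list are dropped; (2) taxa whose counts are nonzero only in blank
(PCR/reagent control) samples are dropped; (3) blanks are dropped; (4) any
patient pair in which either member has ≤ 1,000 total reads is dropped
entirely — the inequality is strict (exactly 1,000 fails), and the rule acts
on pairs, never single samples. The ordering matters because the blank-only
determination (rule 2) must see the post-contaminant table; contaminant
removal first, then blank-only detection, mirrors the natural reading of the
protocol. Whether depth filtering should precede contaminant removal is
genuinely ambiguous; this package fixes the order above as a convention.
Every removal is logged with its rule, so the log length always equals taxa
removed + samples removed, and the whole filter is idempotent.

## Transforms

* **TSS**: columns divided by their totals (relative abundance).
* **CLR**: `ln(x + 0.5) − mean(ln(x + 0.5))` per column. The half-count
  pseudocount is the standard convention where none is otherwise specified.
* **css_log**: a fixed dialect of cumulative-sum scaling — per sample,
  counts are divided by the sum of counts at or below the median of that
  sample's nonzero counts, rescaled by 1,000, then `ln(x + 1)`. The quantile
  (0.5) and scale constant (1,000) are part of the contract, documented here
  rather than swept; the transform is scale-invariant per sample by
  construction.
* Shannon diversity and CLR use natural logs; the Monte-Carlo DA engine uses
  log10 (see below).

## Paired test machinery

The Wilcoxon signed-rank test drops zero differences, mid-ranks the absolute
values, and reports the positive-rank sum W⁺ with a two-sided p. When the
effective n is ≤ 25 and the |differences| are tie-free, the p comes from the
exact null distribution of W⁺, computed by a dynamic program over rank sums
(mathematically identical to enumerating all 2ⁿ sign patterns, and verified
against literal enumeration in the tests) and cached per n. Otherwise a
normal approximation with tie correction and a 0.5 continuity correction is
used. The all-zero case degenerates to p = 1 with a flag. BH-FDR is the
standard step-up with input order preserved.

## Ordination

Distances: Bray–Curtis `Σ|x−y| / Σ(x+y)` (requires non-negative input),
Jaccard on presence/absence, Euclidean. PCoA is Gower double-centering
`B = −½ J D² J` followed by eigendecomposition; negative eigenvalues are
reported but excluded from both the coordinates and the percent-variance
denominator (no Cailliez/Lingoes correction — Bray–Curtis on TSS typically
produces only a small negative tail), and each axis is oriented so its
largest-magnitude coordinate is positive, making runs comparable. Silhouette
widths use the standard `(b − a)/max(a, b)` per sample with singletons and
the all-coincident case scored 0; the package reports the **median** width
per specimen type, computed on the full distance matrix (a flag-free
convention chosen over 2-D-coordinate silhouettes, which discard axes).

The sweep evaluates every (transform, distance) combination — defaults TSS
and CLR × all three distances; a `raw` tag exists for diagnostics — and
ranks valid combinations lexicographically by ascending |Spearman ρ| between
axis 1 and library size, then descending sum of per-type median silhouettes.
The lexicographic order reflects that a depth-driven first axis invalidates
an ordination regardless of its silhouettes. Percent variance of axes 1–2 is
reported but not used for ranking. Combinations that are undefined
(Bray–Curtis on signed CLR values) or degenerate (Jaccard on dense CLR
values) are kept in the table with a skip reason.

Hierarchical clustering uses 1 − Pearson r between `ln(TSS + pseudocount)`
columns (pseudocount = half the smallest nonzero value, per matrix) with
average linkage and index-order tie-breaking.

## Consensus differential abundance

Three methods produce per-taxon significance calls at q < 0.05:

1. **Paired signed-rank** on TSS values, BH across taxa; the effect is the
   median paired difference and fixes the direction.
2. **Monte-Carlo compositional engine**: per instance, each sample's
   composition is drawn from Dirichlet(counts + 0.5) — the half-count prior
   is the established convention for this engine family — CSS-scaled,
   log10-transformed, and paired-signed-rank tested per taxon; the reported
   p is the mean over 128 instances. The log10 is applied directly to the
   scaled compositions (all strictly positive; no +1 shift). Taxa whose raw
   counts are identical in every pair are reported at p = 1 up front: with
   no observed paired signal any Monte-Carlo call would be resampling noise.
3. **Paired linear model**: OLS of css_log abundance on a specimen-type
   indicator plus per-patient intercepts. Modeling the pairing is
   deliberate — ignoring it would be anticonservative for matched
   specimens. For this balanced design the type coefficient equals the mean
   per-patient difference and is t-tested at the residual df.

Tiers: significant in all methods (≥ 3 supplied) = high, all-but-one =
medium, exactly one = low, else none. Methods that disagree on the direction
of a taxon they both call significant demote it to **none** with a conflict
flag — coercing a direction would fabricate a result. External call sets
(e.g. from a bias-correcting mixed-model tool this package deliberately does
not re-implement) can be imported as (taxon, significant, direction) TSVs
and voted alongside the built-ins.

## Topic modeling

Relative abundances are scaled to pseudo-token counts `round(TSS × S)`
(half-away-from-zero, so ties round deterministically), making every sample
a document of ~S tokens regardless of sequencing depth — the model then
weights samples equally rather than by library size. The LDA is fitted by
collapsed Gibbs sampling (full conditional in the README); collapsed Gibbs
was chosen over variational EM because it natively supports the
harmonic-mean marginal-likelihood estimate used in model selection and is
trivially exactly-seeded. Defaults: α = 50/K, η = 0.1 (classical Gibbs-LDA
priors), 2,000 sweeps with 1,000 burn-in and thinning 50 for final fits;
model-selection fits use 800/400/40, which the recovery experiments show is
enough for stable metric curves at this corpus size (~50 documents × ~1,000
tokens).

Topic-number selection fits each K on a grid (default 2..12) with a shared
seed and computes: **Griffiths2004** (harmonic mean of the complete-data log
likelihood trace; maximise), **CaoJuan2009** (mean pairwise cosine of topic
rows; minimise), **Arun2010** (symmetric KL between the normalised singular
values of beta and the length-weighted topic proportions; minimise), and
**Deveaud2014** (mean pairwise half-symmetric KL between eta-smoothed
topics; maximise — the half-symmetric variant matches the common
implementation of that metric). Because joint visual inspection of four
curves is not reproducible, the package picks K deterministically: each
curve is min-max normalised over the grid and K minimises
(cao + arun − deveaud − griffiths), smallest K on ties; the full table is
always returned so a human can override the choice in config. The scaling
factor S is selected from {10, 100, 1000, 10000} by maximising the sum of
per-type median silhouettes on Euclidean distances between gamma rows
(gamma space, not the 2-D embedding).

Topic–type association applies the paired signed-rank test to per-patient
(gamma_plaque − gamma_abscess) per topic with BH across topics; a topic is
plaque- or abscess-classified only at q < 0.05 with the matching median
ordering, otherwise shared. The 2-D visualisation of gamma rows uses a
seeded UMAP embedding (library-provided; the contract is only determinism at
fixed seed and neighborhood preservation) with silhouettes computed on the
embedding.

## Classification and enrichment

Random-forest classification uses TSS values with folds drawn over
**patients**, not samples: both members of a pair stay in one fold, since
splitting a pair would leak patient identity into the test set (a stricter
choice than the underlying study protocol states). Per fold, the held-out
class probabilities give a rank-based (Mann–Whitney) AUC with half credit
for ties, and feature importances (mean impurity decrease) are reported as
ranks, 1 = most important, ties broken by name — ranks are stable across
implementations where raw importances are not.

Over-representation: for each pathway, the one-sided hypergeometric upper
tail P(X ≥ k | N, K, n) over a user-supplied item→pathway map (no live
database client — version- and network-dependent), BH across pathways, fold
enrichment (k/n)/(K/N), and k = 0 reported at p = 1 rather than dropped.

## The synthetic cohort generator

The generator emulates the paired study design with a latent-topic
Dirichlet-multinomial model. Defaults are the study conditions: 25 patients,
150 taxa, six topics (2 plaque-specific, 1 abscess-specific, 3 shared) with
topic concentration 0.05 (sparse, well-separated topics), membership
concentration 0.5, type bias 0.8, log-normal library sizes (median 20,000,
log-sd 0.35), 2 blank samples and 5 contaminant taxa at relative abundance
1e-3 each.

Pairing: both samples of a patient share one base Dirichlet topic-weight
draw; specimen type then re-splits only the type-specific portion of that
mass, own-type topics receiving fraction `type_bias` of it (proportionally
within each group), shared topics untouched. This makes `type_bias = 0.5` an
exact null (both members of a pair have identical expected weights) and
`type_bias → 1` the fully separated limit in which plaque samples carry only
plaque + shared topics. Contaminants are uniform across all specimens and
are the only content of blanks, so both blank-related filtering rules are
exercisable.

Ground truth labels a taxon enriched toward a type when its mean probability
across that type's topics exceeds 4× its mean across the other type's
topics **and** is at least the uniform level 1/n_taxa. The ratio alone would
label taxa with vanishing absolute abundance (say 1e-6 vs 1e-8) as enriched;
no method can detect those at realistic depth, so a recovery rate against
the unfloored rule would measure the Dirichlet's tail rather than the
methods. The floor is part of the truth definition, fixed before any
recovery experiment was run.

What the generator does **not** emulate: sequencing error and chimeras, PCR
amplification bias, overdispersion beyond the Dirichlet-multinomial,
phylogenetic correlation between taxa, or realistic taxonomy (lineages are
synthetic labels). Passing recovery tests therefore demonstrates that the
statistics behave correctly under the stated generative model — not that
they are robust to artefacts real amplicon data adds on top of it.

## Problem sizes, determinism, numerics

The validation experiments run at the study scale: 25 pairs × 150 taxa,
corpus ≈ 50 × 1,000 tokens, full fits at 2,000 Gibbs sweeps, selection fits
at 800, differential-abundance replication over 10 cohorts at 64 Monte-Carlo
instances, and pipeline-level checks on a 10-patient, 60-taxon cohort with
reduced grids — sizes at which every experiment completes in seconds to a
couple of minutes on one CPU while leaving the statistical conclusions
unchanged.

All randomness flows from explicit seeds: the generator from its config
seed, each pipeline stage from a SHA-256-derived seed keyed by (global seed,
stage name) so adding a stage never perturbs another stage's stream, and the
Gibbs kernel from a per-fit seed, making fitted models bit-reproducible.
Tolerances: stochastic-matrix rows sum to 1 within 1e-9; exact-test
equivalences hold to 1e-12; PCoA/PCA agreement to 1e-8. Degenerate inputs
have defined behaviour rather than exceptions wherever a convention exists
(all-zero differences → p = 1 flagged; singleton silhouette 0; k = 0 pathway
p = 1); hard errors are reserved for genuinely unanswerable requests
(zero-total samples under TSS, single-class AUC, unpaired patients).

## Known limitations

* The two built-in DA engines are deliberate simplifications of the
  generalized-linear-model and Monte-Carlo compositional tool families; they
  share those tools' normalisation and testing skeletons but none of their
  bias-correction machinery. The consensus vote accepts imported call sets
  precisely so a third, fully external method can participate.
* The K-selection rule is a deterministic stand-in for joint visual curve
  inspection; on flat or conflicting curves the normalised sum can be
  sensitive to the grid, which is why the full curve is always reported.
* PCoA excludes negative eigenvalues rather than correcting for them; for
  strongly non-Euclidean distance matrices percent-variance figures are
  correspondingly optimistic.
* NMDS, UniFrac, rarefaction, and phylogenetic gene-content inference are
  out of scope.
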