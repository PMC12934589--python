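# oralpair

Community-ecology analysis of **patient-matched oral microbiome specimens**:
dental plaque (the commensal baseline) versus odontogenic abscess (the
inflammation-selected endpoint community). Pairing the two specimens within
each patient removes inter-individual variability, so every statistic in the
package is built around the per-patient paired contrast.

The package implements the full analysis arc for a paired 16S count table:

1. **Cohort filtering** — contaminant removal, blank-only taxa removal, blank
   removal, and a strict per-pair depth rule (both members must exceed 1,000
   reads or the pair is dropped), with a complete removal log.
2. **Transforms & diversity** — TSS (relative abundance), CLR, a
   cumulative-sum-scaling log transform, Shannon and observed richness, an
   exact/approximate Wilcoxon signed-rank test and Benjamini–Hochberg FDR.
3. **Ordination** — Bray–Curtis/Jaccard/Euclidean distances, PCoA, per-type
   median silhouette widths, Pearson-correlation hierarchical clustering, and
   a transform × distance **parameter sweep** ranked by (low |Spearman ρ|
   between axis 1 and library size, high silhouette sum).
4. **Consensus differential abundance** — three methods (paired signed-rank on
   TSS; a Monte-Carlo Dirichlet/CSS/log10 engine; a paired linear model on
   css-log values) voted into high/medium/low confidence tiers, with
   per-patient enrichment tallies and a top-k effect ranking.
5. **LDA topic modeling** — the core method: samples become documents whose
   ~S tokens are drawn by scaling relative abundances (`round(TSS × S)`,
   default S = 1000), fitted by a **collapsed Gibbs sampler**; the topic
   number is selected from four metrics (Griffiths2004, CaoJuan2009,
   Arun2010, Deveaud2014), the scaling factor by per-type silhouettes on the
   sample–topic matrix; topics are tested for specimen-type association by the
   paired signed-rank test on per-patient gamma differences.
6. **Classification & enrichment** — patient-stratified 4-fold random-forest
   classification with rank-based AUC and feature-importance ranks, and
   one-sided hypergeometric pathway over-representation with fold enrichment
   `(k/n)/(K/N)`.
7. **Synthetic paired cohorts** — a Dirichlet-multinomial latent-topic
   generator with plaque-specific, abscess-specific and shared topics,
   patient-level correlation, log-normal library sizes, contaminants and
   blanks, and a known ground truth (true topics, per-sample weights, truly
   enriched taxa) for validating every stage above.

## The model

Each sample `d` is a multinomial draw of `N_d` reads from a mixture of `K`
latent topics: `p(taxon w | d) = Σ_k γ_dk β_kw`, with topic–taxon rows
`β_k ~ Dirichlet(η)` and sample–topic weights `γ_d ~ Dirichlet(α)`. The
collapsed Gibbs sampler resamples each token's topic from

    P(z = k | rest) ∝ (n_dk + α) · (n_kw + η) / (n_k + V η)

and reports posterior-mean `β̂_kw = (n_kw + η)/(n_k + Vη)` and
`γ̂_dk = (n_dk + α)/(n_d + Kα)` from the final state, with the complete-data
log likelihood traced over thinned post-burn-in sweeps (the Griffiths2004
harmonic-mean estimate of `log P(w|K)` comes from this trace).

## Worked example

```bash
python examples/03_differential_abundance.py
```

prints, for the default synthetic cohort (25 pairs, 150 taxa, seed 42):

```
tier
high      56
none      46
medium    33
low       15

recovered 35/40 planted enriched taxa at medium+high confidence with the correct direction

top 5 taxa by |median paired TSS difference| (with per-patient tallies):
  taxon_0062: effect=-0.0918 (abscess), q=2.88e-07, higher in plaque/abscess/tied = 0/25/0
  ...
```

i.e. 87% of the generator's truly enriched taxa are found at medium-or-high
consensus confidence with the right direction, and the strongest effects are
consistent in every one of the 25 patients (not outlier-driven). The other
examples cover the generator (`01`), the ordination sweep (`02`), topic
modeling (`04` — fitted topics match the generator's latent topics with
best-match cosines ≥ 0.998 and the plaque/abscess-specific topics are
classified correctly), and classification/enrichment (`05`).

A thin CLI wraps the same functions: `oralpair synth | run | topics | da |
ordinate | classify | enrich` (see `oralpair --help`); `oralpair run` executes
the whole pipeline into a results directory with a hash manifest, a stage log
and deterministic per-stage seeding.

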