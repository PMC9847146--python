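# Methods

This note documents the models, the parameters that matter, the synthetic
data the tests run on, and the numerical and design choices made where the
analysis left room for them.

## Differential expression index

The index combines two complementary views of differential expression
between sample groups *A* and *B*:

* **Ratio component** `r = |log2((m_A + c)/(m_B + c))|` with pseudocount
  `c = 1` CPM (configurable). Group means `m` are arithmetic means of
  per-sample CPM, so the ratio and difference components share one group
  summary. As `c → 0` on positive means this converges to the plain log2
  fold change. The component can alternatively be computed on
  median-of-ratios-normalized counts (the normalization scheme DESeq2
  uses): `median_of_ratios_size_factors` divides each sample's counts by
  the median ratio to the per-gene geometric-mean reference over genes with
  all-positive counts.
* **Difference component** `d = |m_A − m_B|` in CPM units, deliberately on
  the linear scale: the ratio term is sensitive at low abundance, the
  difference term at high abundance.

`DEI = sqrt(r·d)`, the geometric mean, with the direction of the ratio kept
as a separate sign — a geometric mean of signed quantities is undefined.
DEI is zero iff either component is zero, monotone in both, and invariant
under exchanging the groups (the sign flips).

Note one structural property with practical consequences: rescaling a
gene's expression by a factor *k* scales its DEI by √*k*. The index
therefore weights abundant genes up — both their signal *and* their
sampling noise. This is intentional (top-ranked genes are transcripts whose
absolute output changes materially) but it bounds how cleanly the ranking
can separate planted signal from noise in heterogeneous-abundance data; see
"What the recovery tests show" below.

**Filtering.** A gene is blocked when its CPM is below `min_cpm = 2` in
*every* sample of the comparison; blocked genes are excluded from ranking
rather than set to zero. The CPM-filtered gene set is also the background
universe for enrichment — overrepresentation is judged against genes that
could have been called, not against the genome.

**CPM normalization.** `value = count/total × 1e6` per sample; columns sum
to 10⁶ (relative tolerance 1e−9 in tests). Because the definition rescales
each column, per-sample size factors cancel in it; normalized values that
genuinely depend on size factors are provided by `size_factor_normalize`
(counts divided by the factor), which is what the ratio component and
fold-change analyses use when median-of-ratios normalization is requested.

## Convergence and divergence

`score(g) = DEI(standard vs primary) − DEI(postconfluent vs primary)`,
computed per lineage (LEp and MEp separately); a pooled mode sums
specimen-matched LEp + MEp counts first, for genes expressed across the
epithelial bilayer (basement-membrane components). The difference of
indices is the minimal statistic consistent with "moved toward/away from
the reference"; it is antisymmetric under exchanging its inputs, and no
per-gene significance is attached to it. Top-*n* lists (default n = 200,
roughly 1% of a transcriptome-scale feature set) rank by |score| within a
direction with a deterministic lexicographic tie-break.

## Gene-set overrepresentation

One-sided enrichment via the exact hypergeometric upper tail
`p = P(X ≥ k)` for X ~ HG(N, K, n), where N is the universe size, K the
set's overlap with the universe, n the hit-list size and k the observed
overlap; fold enrichment is `(k/n)/(K/N)`. Benjamini–Hochberg adjustment is
applied across the sets tested for one hit list (convergent and divergent
lists are adjusted separately, mirroring separate submissions to an
enrichment service), significance is `q < 0.05`, and an empty significant
set is a valid result. Depletion testing is not implemented.

## Flow gating

One-dimensional threshold gates, since only +/− marker definitions are
given: DAPI ≥ t → discarded; else LEp iff CD133 ≥ t₁ ∧ CD271 < t₂; MEp iff
CD133 < t₁ ∧ CD271 ≥ t₂; remaining events "other". Intensity equal to a
threshold counts as positive. The c-Kit flag (CD117 ≥ t₃) is evaluated on
non-discarded events orthogonally to the LEp/MEp partition, because the
progenitor population overlaps the luminal gate. Thresholds can be set per
culture type — postconfluent cells are markedly autofluorescent, which
shifts every channel upward. Compositions are percentages of DAPI-negative
events; `pct_LEp + pct_MEp + pct_other = 100` exactly, `pct_cKit` is
reported on the same denominator but outside the partition.

## Longitudinal models

Viability and SAβG⁺ area fractions live in [0, 1]; they are transformed
with a clamped logit (`ε = 1e−3` default, because exact 100% viability
readings occur) and fitted with ordinary least squares on
`logit(y) ~ C(timepoint) + C(specimen)`. Treating the specimen term as a
fixed block rather than a REML random intercept is deliberate: for the
balanced, few-specimen designs this package targets, the timepoint
contrasts and their t-tests coincide with the random-intercept analysis,
without re-implementing mixed-model machinery. For unbalanced data the two
diverge — a documented limitation, not handled. Specimens observed at a
single timepoint are dropped with a warning (they contribute nothing to
within-specimen contrasts). Marginal means average the specimen blocks;
back-transformed marginal means are reported as fractions.

Two-way ANOVA uses sequential (type-I) sums of squares in formula order —
identical to every other type on the balanced designs in view, logged for
unbalanced input. Effect sizes are classical `η² = SS_effect/SS_total` and
`f = √(η²/(1−η²))`; η² = 0.23 gives f = 0.5465 (0.55 at two decimals) and
η² = 0.17 gives 0.4526 (0.45). A published table row with η² = 0.31
printed alongside f = 0.68 computes to 0.6703 from the rounded η²; the
discrepancy is consistent with the source rounding η² after computing f.
Tukey HSD contrasts use the studentized-range distribution with the fitted
model's residual mean square and degrees of freedom (Tukey–Kramer form for
unequal group sizes); on one-way layouts this reproduces the standard
implementation exactly, which the tests verify.

## Synthetic data generators

All generators are pure functions of (configuration, seed); sub-streams are
spawned from one `SeedSequence`, so outputs are byte-reproducible.

**Counts.** Negative binomial with `var = μ + μ²·disp` (the RNA-seq
standard parameterization; dispersion 0 is admitted as the Poisson limit).
Gene means are `2^(b_g + effect + u_{g,s}) · L_sample` with baseline
log2-means `b_g ~ N(5, 2)` truncated below at 0 (spanning the 2-CPM filter
boundary), specimen effects `u` shared by all of a specimen's samples
(emulating the specimen-matched design; SD 0.3 by default), and log-normal
library-size factors (SD 0.2 — a config knob, not a claim about any real
library). Planted classes, with δ = 2 log2 units and shrink s = 0.25 by
default: convergent genes sit δ from primary in standard culture and s·δ in
postconfluent culture; divergent genes sit at primary level in standard and
δ away in postconfluent; offsets are `effect_direction · δ` with
up-regulation (+1) the default. Defaults describe a 2000-gene,
five-specimen design — a 1:10 scale model of a transcriptome that keeps the
full pipeline under a second per run.

**Flow events.** Mixtures of five labelled populations (LEp, MEp, cKit,
double-negative, dead) with log-normal marker intensities (median `loc`,
log-scale `scale`; scale 0 collapses to the median) and an optional
additive autofluorescence shift applied to every channel. The cKit
population is CD133+/CD271−/CD117+: it gates as LEp in the lineage
partition and is counted by the orthogonal c-Kit flag, as in the real
panel.

**Longitudinal tables.** `y = expit(μ_t + b_specimen + ε)` with
`b ~ N(0, 0.3)` and `ε ~ N(0, 0.2)` on the logit scale — exactly the
generative form the blocked model assumes, so null simulations are a clean
calibration check. The default timepoint profiles encode the study
conditions: viability 99% from confluence through week 4, declining at week
5; SAβG⁺ area 5% at confluence rising to 18/30/35% at weeks 1/2/3.

**What the generators do not emulate:** batch effects beyond specimen
intercepts, gene–gene correlation, count overdispersion heterogeneity
across genes, spectral spillover or compensation artifacts in flow data,
and measurement error structure of image-derived area fractions. Passing
tests demonstrate correct implementation of the stated models and recovery
under their assumptions — not robustness to real-data pathologies outside
them.

## What the recovery tests show

The end-to-end property anchoring the package is that the convergence
ranking recovers planted truth. Under the reference conditions (2000 genes,
10% convergent / 10% divergent, δ = 2, s = 0.25, five specimens, dispersion
0.1), the measured precision of the top-200 convergent/divergent lists is
≈ 0.75–0.85 per lineage (≈ 0.85–0.92 in pooled-lineage mode), not higher.
This is a property of the index, not an implementation artifact: DEI noise
scales as √(mean CPM) exactly as DEI signal does, so with baseline
abundances spread over four decades (log2 SD 2), the noise tail of the most
abundant neutral genes — |ΔCPM| fluctuations of order 0.2·μ at dispersion
0.1 with n = 5 — overlaps the full signal of weakly expressed planted
genes. Simulation sweeps over specimen SD (0–0.3), library-size SD, effect
sign, pooled vs per-lineage analysis and dispersion (0.01/0.05/0.1) confirm
the ceiling: even at dispersion 0.01 precision only reaches ≈ 0.9. The
acceptance suite asserts the 90% level and therefore documents this gap
rather than hiding it; users applying the index to their own data should
expect its top lists to be enriched for, not identical to, the truly
convergent set, with the contamination concentrated among highly expressed
genes.

## Numerical choices and degenerate inputs

* Floats are written with 6 significant digits; TSV/CSV/GMT in UTF-8 with
  '.' decimals; gene symbols case-sensitive (HGNC symbols are
  case-significant).
* Missing timepoints are NA, never 0.
* Ranking ties break lexicographically by gene symbol, so repeated runs and
  platforms agree.
* `select_significant` uses strict `q < α`; α ≥ 1 disables the filter
  (q-values are capped at exactly 1).
* A constant ANOVA response reports all effects as η² = 0 with a warning; a
  singular blocked-model design is a hard error.
* Zero-total samples, negative counts, duplicate identifiers, unknown
  enum levels and malformed GMT lines are hard errors naming the offending
  sample/cell/line; recoverable irregularities (orphan metadata, skipped
  pooling pairs, all-discarded flow groups) warn and continue.
* Every stage logs input dimensions, filter counts and the configuration
  used, so "records surviving filter" is auditable from the log.

## Scope

Out of scope by design: read alignment and quantification (the package
consumes count matrices), negative-binomial GLM/Wald testing and dispersion
estimation, FCS binary parsing and compensation, REML mixed models,
deformability-index computation from raw traces (only the downstream ANOVA
of a provided wCDI table), and reproduction of database-dependent
enrichment tables (the hypergeometric machinery is general; published
fold-enrichment values depend on a service's annotation version).
Reproducing the published viability/SAβG/PCNA figures from the *actual*
raw measurement files requires those supplementary files; the acceptance
checks here verify that the pipeline's aggregation stages recover the same
figures when the generators are parameterized at the study conditions.
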