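# conflux

Analysis toolkit for **postconfluent culture of human mammary epithelial
cells (HMECs)**: quantify how keeping primary HMECs past confluency (fed but
unpassaged for 1–5 weeks) shifts lineage composition and gene expression
relative to standard subconfluent culture and to uncultured primary tissue.

It is written for researchers working with sorted luminal (LEp),
myoepithelial (MEp) and c-Kit+ progenitor populations who want a
reproducible, scriptable version of this analysis: RNA-seq count matrices
in, ranked gene lists, enrichment tables, flow compositions and longitudinal
statistics out. Synthetic-data generators with the same statistical
structure as each data modality make every stage testable without any
external download.

## The statistics at the core

**Differential expression index (DEI).** For a gene *g* between sample
groups *A* and *B*, with group means of CPM (counts per million)
*m<sub>A</sub>*, *m<sub>B</sub>* and pseudocount *c* = 1:

```
r = | log2( (m_A + c) / (m_B + c) ) |        (ratio-based DE, log2 units)
d = | m_A − m_B |                            (difference-based DE, CPM units)
DEI = sqrt( r · d )
```

the geometric mean of a ratio-based and a difference-based measure of
differential expression; the direction of change is carried as a separate
sign. Genes below 2 CPM in every sample of the comparison are blocked from
ranking.

**Convergence score.** With primary tissue as the reference,

```
score(g) = DEI(standard vs primary) − DEI(postconfluent vs primary)
```

positive scores mean postconfluent culture moved the gene's expression
*toward* the primary-tissue level (convergent), negative means away
(divergent). The 200 most extreme genes per direction feed a one-sided
hypergeometric gene-set overrepresentation test against the CPM-filtered
universe, with Benjamini–Hochberg FDR control at q < 0.05.

**Flow gating.** Events are classified with threshold gates: DAPI+ events
discarded; LEp = CD133+/CD271−, MEp = CD133−/CD271+, c-Kit+ = CD117+
(orthogonal flag); compositions reported as percent of DAPI-negative events.

**Longitudinal statistics.** Bounded fractions (viability, SAβG+ area) are
logit-transformed and fitted with `fraction ~ timepoint + specimen block`;
timepoint contrasts against baseline are tested on the residual df. Two-way
ANOVA (e.g. deformability `wCDI ~ culture_type + specimen`) reports
classical η², Cohen's f = √(η²/(1−η²)) and Tukey HSD contrasts.

## Worked example

```python
from conflux import *

cfg = SimConfig(n_genes=2000, seed=42)          # 5 specimens, 3 cultures
counts, meta, truth = simulate_counts(cfg)      # planted convergent/divergent genes
cpm = cpm_normalize(counts)

std = compute_dei(cpm, meta.samples_where(culture="standard", lineage="LEp"),
                  meta.samples_where(culture="primary", lineage="LEp"))
post = compute_dei(cpm, meta.samples_where(culture="postconfluent", lineage="LEp"),
                   meta.samples_where(culture="primary", lineage="LEp"))
scores = convergence_scores(std, post)
print(top_n_selection(scores, n=5, direction="convergent").round(2))
```

prints

```
        dei_std_vs_primary  dei_post_vs_primary   score       label  rank
gene
G01397              170.57                26.78  143.79  convergent     1
G00866              143.24                 3.01  140.23  convergent     2
G01434              131.43                 9.19  122.24  convergent     3
G00597              116.25                16.30   99.96  convergent     4
G01096              104.67                11.47   93.20  convergent     5
```

Each row is a gene whose distance from primary tissue (as DEI) was large in
standard culture but small in postconfluent culture — expression that
postconfluency pulled toward the primary-tissue level. Checking the top-200
such calls against the generator's planted truth labels 81.5% of them as
truly convergent under the default noise conditions (negative-binomial
dispersion 0.1, five specimens); see `docs/methods.md` for why the
abundance-weighted index bounds this recovery rate.

The same analyses are available from the shell:

```sh
conflux sim counts --seed 3 --out simdir/
conflux dei --counts simdir/counts.tsv --meta simdir/meta.tsv \
    --group-a culture=postconfluent --group-b culture=standard \
    --lineage LEp --out dei.tsv
conflux converge --dei-std a.tsv --dei-post b.tsv --n 200 --out conv.tsv
conflux enrich --hits hits.txt --universe universe.txt --gmt sets.gmt --out enr.tsv
conflux flow --events events.csv --out composition.tsv
conflux longitudinal --data viability.tsv --out model.tsv
conflux anova --data wcdi.tsv --value wCDI --factor-a culture --factor-b specimen --out anova.tsv
```

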