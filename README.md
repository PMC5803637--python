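# citenet

Claim-specific citation-network analysis of **selective citation** — do
articles on a contested scientific claim get cited because of *what they
found* (citation bias) or because of *who wrote them and how*?

`citenet` is aimed at meta-researchers studying citation dynamics in small,
claim-specific literatures (a few dozen articles identified by a systematic
search, e.g. the network on swimming in chlorinated pools and childhood
asthma).  It rebuilds, as a reusable and tested pipeline, the standard
analysis for such networks:

1. **Records** — read a bibliographic export (one row per article with its
   raw reference list) and a manually coded extraction sheet (conclusions,
   article type, sample size, quality, specificity, funding,
   corresponding-author metadata).
2. **Matching** — link every reference to in-network articles by DOI, or by
   the composite key (first author's surname, first initial, year, volume,
   first page) when no DOI match is available.  Exact matching only;
   ambiguous matches are errors.
3. **Potential citation paths** — the unit of analysis.  An ordered pair
   (cited, citing) is a potential path when the *time to citation*
   t = (submission date of citing − publication date of cited) is strictly
   positive, in months/12.  Missing submission dates are imputed as
   publication minus 7 months.  The outcome is whether the path was
   *realized* (the citation actually occurred).
4. **Determinants** — per path: self-citation (shared author), within-network
   authority (cumulative citations to any of the cited article's authors by
   the citing year, maximum over authors, banded 0–5 / 6–50 / ≥51),
   attribute concordance between cited and citing article, and the cited
   article's coded characteristics; co-authorship research groups are the
   connected components among authors with ≥3 in-network publications.
5. **Models** — per determinant, the odds of citation via logistic
   regression.  Paths are clustered under citing articles, so the main
   estimator adds a normal random intercept per citing article:

   logit P(realized_ij = 1) = β₀ + b_i + xᵀ_ij β,  b_i ~ N(0, σ²),

   fitted by maximum likelihood with adaptive Gauss–Hermite quadrature
   (15 nodes).  Fixed-effects fits, the 2×2 cross-product odds ratio with
   Wald CI, crude and article-type-adjusted variants, sensitivity subsets,
   and the Pearson χ² *discordance* test (data-based vs authors' conclusion)
   round out the battery.
6. **Synthetic networks** — a generator draws complete inputs (records,
   reference lists with imperfect DOI coverage, coded attributes, planted
   co-authorship communities) and realizes citations from the same logistic
   model with known coefficients, so every stage is verifiable against
   ground truth without any external data.

## Worked example

```python
from citenet import (build_citation_edges, enumerate_paths,
                     fit_citation_model, ModelSpec, round_or)
from citenet.experiments import pipeline_frame
from citenet.synthetic_network import generate_network, PAPER_LIKE_CONFIG

records, sheet, truth = generate_network(PAPER_LIKE_CONFIG)  # 36 articles
edges = build_citation_edges(records)
dataset = enumerate_paths(records, edges)
print(len(dataset.paths), dataset.n_realized)          # 575 188  (33%)

frame = pipeline_frame(records)                        # one row per path
result = fit_citation_model(
    frame, ModelSpec(determinant="self_citation", estimator="random-intercept")
)
e = result.effect()
print(round_or(e.odds_ratio), round_or(e.ci_low), round_or(e.ci_high))
# 4.0 2.5 6.4   — the generator planted log(4.6) for self-citation
print(round(result.random_intercept_sd, 2))            # 0.49 (planted 0.5)
```

The 575 potential paths arise from 36 articles with publication dates over
2002–2015; 188 (33%) are realized.  The self-citation odds ratio of 4.0
(95% CI 2.5–6.4) estimates the planted effect of 4.6 — articles sharing an
author cite each other about four times more often — and the estimated
random-intercept SD 0.49 recovers the planted between-citing-article
heterogeneity of 0.5.

The same pipeline runs from the shell:

```sh
citenet simulate --paper-like --out data/
citenet report --records data/records.tsv --sheet data/extraction_sheet.csv \
       --out results/
```

which writes the characteristics table, the odds-ratio table (crude +
adjusted, all standard determinants), article/author rankings, GraphML
network exports, and a JSON run manifest.

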