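# metasense

Sensitivity analyses for correlation meta-analyses: random-effects
pooling, leave-one-out influence diagnostics, a seven-method
publication-bias battery, and range-based triangulation of the adjusted
estimates — built for the kind of question personnel-selection research
keeps asking: *how much of a pooled validity coefficient survives when
you stop trusting a single point estimate?*

## The problem

A meta-analysis of k studies pools Pearson correlations r_i (e.g. between
a conscientiousness score and job performance, n_i subjects each) into a
random-effects mean. That single number is fragile: it moves when one
influential study is removed, and it is inflated when small
nonsignificant effects were never published. `metasense` runs the full
sensitivity battery and summarises how far the defensible estimates
spread:

- **Pooling** (Hedges–Olkin): Fisher z = arctanh(r), variance 1/(n−3),
  inverse-variance weights, DerSimonian–Laird τ²; fixed- and
  random-effects means, 95% CI, 90% prediction interval, Q, I², τ.
- **Influence**: one-sample-removed range of the pooled mean, plus the
  case-deletion diagnostics (externally standardised deleted residuals,
  DFFITS, Cook's distance, covariance ratio, leverage) with a two-part
  outlier rule.
- **Publication bias**: Duval–Tweedie trim-and-fill (L estimator),
  Vevea–Woods one-tailed moderate/severe a-priori selection models,
  PET-PEESE precision regressions, p-uniform, the test of excess
  significance (TES), cumulative meta-analysis by precision, and
  contour-enhanced funnel data.
- **Triangulation**: collect every adjusted mean, take the baseline
  range estimate BRE = |r̄_RE − farthest estimate| and the maximum range
  estimate MRE = highest − lowest, express both as a percent of the RE
  mean, and classify the spread (negligible < 20% ≤ moderate < 40% ≤
  large).
- **Synthetic corpora**: a generator that draws true effects from
  N(μ_z, τ²) on the z scale and filters candidate studies through a
  step-function of their one-tailed p-value — publication suppression as
  a data-generating mechanism — so every stage of the pipeline can be
  exercised and calibrated without proprietary data.

## Worked example

Generate a 113-study corpus with journal-concentrated suppression and
triangulate it:

```
$ metasense simulate --out corpus.csv --seed 1
wrote 113 studies (total N=17875) to corpus.csv

$ metasense triangulate corpus.csv
lowest=0.12 re_mean=0.18 highest=0.18
BRE=0.06 (33%) moderate; MRE=0.06 (33%) moderate
Moderate difference
```

The naive random-effects mean of this corpus is .18, but the battery's
adjusted estimates reach down to .12 — a 33% relative spread, i.e. a
moderate overestimate consistent with suppression of small
nonsignificant correlations. The full pipeline writes the report tables:

```
$ metasense run corpus.csv --out report --seed 1
$ head -3 report/results_table1.csv
distribution,k,r-oRE,95% CI,90% PI,Q,I2,tau,r-oFE,osr,FPS,ik,t&f r-o,...
corpus,113,.18,".16, .20",".02, .33",267.30,58.10,.095,.17,".18, .18; .18",L,16,.15,...
source: journal,48,.21,".18, .24",".06, .34",101.92,53.88,.086,.20,".20, .21; .21",L,14,.16,...
```

Reading the first row: k=113 correlations pool to r̄_RE = .18 (95% CI
.16–.20) with substantial heterogeneity (I² = 58); trim-and-fill imputes
16 studies on the left (FPS = L) and lowers the mean to .15; the severe
selection model gives .12. The journal sub-distribution pools higher
(.21) and is corrected harder (to .16) than the rest of the corpus —
the signature of journal-concentrated suppression. `ranges_table2.csv`
holds the BRE/MRE classifications per distribution and
`subgroup_q_table3.csv` the between-group Q tests.

The same operations are available as a library:

```python
from metasense import paper_like_corpus, pool, trim_and_fill, run_battery, triangulate

corpus = paper_like_corpus(seed=1)
print(pool(corpus).mean)                 # naive RE mean
print(trim_and_fill(corpus).adjusted_mean)
print(triangulate(run_battery(corpus)).conclusion)
```

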