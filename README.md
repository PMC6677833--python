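# heterosub

Nearest-centroid "heterocellular" subtype analysis for bulk transcriptomes:
classify samples against subtype expression centroids by Pearson
correlation with confidence gating, relate the resulting labels to any
other classification by hypergeometric enrichment, score gene signatures
per sample, compute microarray-adapted recurrence-risk scores, and compare
groups by Kaplan–Meier / log-rank / concordance analysis. A synthetic
cohort generator with known ground truth makes the whole chain testable
end to end without downloading any data.

The intended users are computational biologists applying a fixed centroid
table (e.g. the five colon-crypt cell-type centroids: stem-like,
inflammatory, transit-amplifying, goblet-like, enterocyte — or any other
PAM-style centroid set) to a new cohort, and wanting the downstream
association and survival statistics in one reproducible pipeline.

## The method

For sample *x* and centroids *c₁ … c_K* over their shared genes, the
classifier computes Pearson correlations *rₖ = corr(x, cₖ)* (optionally
after per-gene median centering of the cohort) and gates each sample:

- **low confidence** if max *rₖ* < 0.15 — the sample resembles no centroid;
- **mixed** if *r₍₁₎ − r₍₂₎* < 0.06 — the two best centroids are nearly
  tied; the argmax is reported as the *dominant* subtype;
- **high confidence** otherwise.

Downstream:

- **Enrichment** — for two labellings of a cohort, each cross-tab cell
  (a, b) with overlap *k* gets a one-sided hypergeometric p-value
  P(X ≥ k), Benjamini–Hochberg adjusted over all cells, plus an overall
  Pearson chi-square of association.
- **Signature scores** — per-sample arithmetic mean of log2 expression
  over a gene set (e.g. an 18-gene expanded-immune signature), compared
  across groups with Kruskal–Wallis.
- **Risk scores** — a 21-gene recurrence score (five housekeeping genes'
  mean subtracted from sixteen scored genes, then the published weighted
  combination of group scores; unscaled by default on log2 microarray
  data) and a centroid-correlation risk score Σₖ βₖ·corr(x, cₖ), with
  tertile or fixed-threshold risk groups.
- **Survival** — product-limit curves, k-group log-rank, and Harrell's
  concordance index with usable-pair count and a normal-approximation CI.

## Worked example

```python
import heterosub as hs

params = hs.GeneratorParams(seed=17)          # 5 subtypes, 200 samples
cohort = hs.generate_cohort(params)
calls = hs.classify.classify(cohort.expression, cohort.centroids,
                             hs.ClassifierParams(center_genes=False))
print(calls["confidence"].value_counts().to_dict())
labels = hs.dominant_subtype_table(calls, {"high", "mixed"})
print(hs.proportion_report(labels))
from heterosub import survival as surv
stat, dof, p = surv.logrank_test(cohort.clinical, labels)
print(f"log-rank chi2 = {stat:.2f} (dof {dof}), p = {p:.2e}")
```

prints

```
{'high': 169, 'mixed': 21, 'low': 10}
              count  fraction  percent
subtype
stem-like        41  0.215789       22
inflammatory     41  0.215789       22
goblet-like      37  0.194737       19
enterocyte       36  0.189474       19
TA               35  0.184211       18
log-rank chi2 = 25.55 (dof 4), p = 3.90e-05
```

Of the 200 generated samples, the 10 signal-free ones are gated low
confidence and the near-even centroid mixtures are gated mixed; the
proportion report covers the 190 classifiable samples with their dominant
subtype. The log-rank test detects the threefold event hazard that the
generator assigns to the TA subtype.

The same chain is available from the shell:

```sh
heterosub simulate --out cohort/ --seed 17
heterosub classify --matrix cohort/expression.gct --format gct \
    --centroids cohort/centroids.tsv --no-center --out calls.tsv
heterosub run --config analysis.yaml        # full pipeline + manifest.json
```

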