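# chdi — composite hospital development index toolkit

`chdi` builds a ranked composite index of hospital performance from a
hospitals × indicators table. It is aimed at health-services researchers who
assemble publicly available performance indicators — bibliometric output,
academic standing, malpractice litigation rates, accreditation counts — for
a set of hospitals and want a transparent, reproducible scoring chain from
that table to a single development index per hospital, in the style of the
China Hospital Development Index for grade III level A tertiary hospitals.

## Method

Indicators are grouped into three domains: **research and development**,
**academic reputation**, and **quality and safety**. Cost-direction
indicators (e.g. the ratio of malpractice compensation cases) are negated so
that larger is better everywhere. The chain is then:

1. **Suitability diagnostics.** Kaiser–Meyer–Olkin sampling adequacy
   (pass if KMO > 0.7) for all-numeric domains, Cronbach's α for domains
   with ordinal/nominal indicators.
2. **Dimension reduction per domain.** Correlation-matrix PCA for numeric
   domains; CATPCA (optimal scaling by alternating least squares, with
   monotone quantifications for ordinal variables) for categorical ones.
   Each domain retains k = 2 components by default, with variance shares
   C_i and cumulative variance G(m). A model is chosen by exhaustively
   fitting **every nonempty indicator subset** and keeping the largest
   subset whose diagnostic exceeds its threshold and whose G(m) reaches the
   configured bar (0.90 by default).
3. **Logit transformation.** Component scores F_hi are mapped into (0,1) by
   S_hi = 1 / (1 + exp(−(C_i / G(m)) · F_hi)).
4. **Entropy weighting.** Within a domain, component weights are
   diversification degrees d_i = 1 − e_i, where e_i is the normalised
   Shannon entropy of the hospitals' share distribution on component i;
   components that separate hospitals more get more weight. The domain score
   is the resulting convex combination.
5. **Aggregation and rescaling.** Domain scores are combined with expert
   domain weights (equal by default) into a raw score, then min-max rescaled:
   index = (raw − min) / range, so the top hospital scores 1 (or 100).
   Pearson correlations among the three domain scores and the total are
   reported as a coherence check.

Because real hospital-level tables of this kind are generally not publicly
shareable, the package ships a synthetic-data generator
(`chdi.synthetic`) that draws tables with the assumed structure — three
correlated latent strength factors, heavy-tailed count indicators,
small-integer ordinal indicators, cost-direction ratios, plus designed
pure-noise columns — together with the ground truth, so the whole chain is
testable end to end.

## Worked example

```python
from chdi import ScoringConfig, default_fixture, run_pipeline, DOMAINS

table, truth = default_fixture(seed=2021)          # 310 synthetic hospitals
pipeline = run_pipeline(table, ScoringConfig(seed=2021))
for d in DOMAINS:
    m, s = pipeline.models[d], pipeline.searches[d]
    print(f"{d:<28} {len(s.records):>5} candidate subsets -> "
          f"{len(s.chosen):>2} indicators, G(m) = {m.cumulative_variance:.3f}")
print(pipeline.result.ranking[["raw_score", "chdi", "rank"]].head(5).round(4))
```

prints

```
research_and_development      8191 candidate subsets -> 11 indicators, G(m) = 0.939
academic_reputation            511 candidate subsets ->  6 indicators, G(m) = 0.922
quality_and_safety               7 candidate subsets ->  3 indicators, G(m) = 0.962
      raw_score    chdi  rank
H038     0.9731  1.0000   1.0
H166     0.9637  0.9899   2.0
H024     0.9474  0.9723   3.0
H253     0.9436  0.9683   4.0
H121     0.9435  0.9681   5.0
```

The subset search dropped exactly the two research-domain and three
reputation-domain columns that the generator planted as pure noise; the
retained two components explain 92–96% of the variance of each selected
indicator set; the top hospital attains the maximum of the index scale and
ranks descend from there.

The same run from the shell:

```bash
chdi simulate --seed 2021 --out table.csv --truth truth.csv --config-out cfg.yaml
chdi run --input table.csv --config cfg.yaml --outdir results/
```

which writes `ranking.csv`, `entropy_weights.csv`, `diagnostics.csv`,
`validation_correlations.csv`, per-domain model files, a four-section
plain-text report and a provenance manifest.

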