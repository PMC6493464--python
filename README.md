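# tsapool

Identification and prioritization of **tumor-specific antigen (TSA) pools**
from bulk RNA-seq count data.

Targeted immunotherapies (antibodies, vaccines, adoptive T-cell transfer)
need antigens that are strongly expressed in tumor cells and absent — or
nearly absent — from healthy tissue, because any normal-tissue expression of
the target invites an immune attack on that tissue. `tsapool` implements an
in-silico screen for such antigens over a cohort of tumor samples and a
panel of normal tissues: starting from a raw gene × sample read-count
matrix, it normalizes library depth, summarizes normal-tissue expression,
filters candidates, ranks them by a combined specificity/coverage score, and
evaluates how many patients a small antigen "cocktail" would cover. A
synthetic-cohort generator with ground truth lets the whole pipeline run and
be verified without any external data download.

It is written for computational immunologists and bioinformaticians who
work with gene-level count matrices (e.g. HTSeq output) and accompanying
sample metadata.

## The screen and its scores

For every gene *a*, mean normalized expression in each normal tissue *t* is
bucketed into *none* (≤ 10 counts), *low* (10–50] or *high* (> 50), encoded
by an indicator e(a,t) ∈ {0, 0.5, 1}. A **predicted potential adverse event
(PPAE)** is a non-essential normal tissue where e(a,t) > 0. Candidate TSAs
must be protein coding, exceed 50 counts in at least one tumor sample, stay
at ≤ 10 average counts in the *essential* tissues (brain, heart, lung), and
have at most 6 PPAEs. The surviving pool is ranked by the **digital target
prioritization factor**

    I_PPAE(a) = Σ_t e(a,t)·w(t) / max_pool Σ_t e(a,t)·w(t)
    I_TSCR(a) = Σ_s t(a,s) / M
    DTPF(a)   = (1 − I_PPAE(a)) + I_TSCR(a)  ∈ [0, 2]

where w(t) ∈ [0, 1] is a clinical-relevance tissue weight (1.0 for kidney
or bone marrow down to 0.0 for testis and prostate), t(a,s) ∈ {0, 1} flags
high expression in tumor sample *s*, and M is the number of tumor samples.
Targets are also classed as high / low / no priority by thresholding
1 − I_PPAE at 0.5 and I_TSCR at 0.25. A combination analysis reports union
coverage, a per-sample multiplicity histogram and Venn regions for the
top-k cocktail (or a greedy maximum-coverage alternative), and a grid
search over the three filter thresholds exposes the Pareto trade-off
between pool size, antigens per patient and patients per antigen.

## Worked example

```python
import tsapool as tp

# synthetic cohort: 98 tumor samples + 345 normals from 29 tissues, with
# planted antigens mirroring the relationships of published top targets
counts, meta, annot, truth = tp.fixture_table1_like(seed=17)
res = tp.run_all(counts, meta, annot, ippae_denominator=3.044, top=5)

print(f"{'rank':>4} {'gene':<9} {'avg_expr':>8} {'TSCR':>5} {'PPAE':>4} {'DTPF':>6} priority")
for t in res.ranked:
    print(f"{t.rank:>4} {t.gene_id:<9} {t.profile.avg_tumor_expression:>8.0f} "
          f"{t.i_tscr:>5.2f} {t.profile.ppae_count:>4} {t.dtpf:>6.3f} {t.priority}")
c = res.cocktail
print("cocktail:", ", ".join(c.genes))
print("cumulative coverage: " + ", ".join(f"{100*f:.1f}%" for f in c.cumulative_fractions))
print(f"total coverage: {100*c.total_coverage:.1f}%")
```

prints

```
rank gene      avg_expr  TSCR PPAE   DTPF priority
   1 CT83L          574  0.66    2  1.499 high
   2 ACTL8L        2174  0.57    2  1.440 high
   3 MAGEB4L         85  0.32    1  1.316 high
   4 TLX3L           87  0.32    0  1.316 high
   5 PRDM13L         69  0.30    1  1.296 high
   6 C4orf51L        45  0.17    1  1.173 low
cocktail: CT83L, ACTL8L, MAGEB4L, TLX3L, PRDM13L
cumulative coverage: 66.3%, 82.7%, 91.8%, 95.9%, 95.9%
total coverage: 95.9%
```

The rank-1 antigen is covered (> 50 normalized counts) in 65 of 98 tumor
samples (TSCR 0.66) and carries two adverse events — high expression in
salivary gland (weight 0.5) and testis (weight 0.0) — giving a weighted
numerator of 0.5 and, against the reference denominator 3.044,
DTPF = (1 − 0.5/3.044) + 65/98 = 1.499. Antigens whose only adverse event
lies in a zero-weight tissue keep I_PPAE = 0, so their DTPF is simply
1 + TSCR (e.g. 1 + 31/98 = 1.316). The cocktail lines show the union
patient coverage as each antigen is added.

The same stages are available as a CLI:

```sh
tsapool simulate --seed 17 --outdir cohort/ --table1-like
tsapool run-all --counts cohort/counts.tsv --meta cohort/metadata.tsv \
        --annot cohort/annotation.tsv --outdir results/
tsapool optimize --counts norm.tsv --meta meta.tsv --annot genes.tsv --out pareto.tsv
```

## Layout

- `src/tsapool/io.py` — containers, validation, TSV/YAML readers and writers,
  built-in tissue-weight table
- `src/tsapool/normalization.py` — median-of-ratios size factors
- `src/tsapool/expression.py` — tissue averages, expression buckets, PPAEs
- `src/tsapool/identification.py` — candidate filter and target types
- `src/tsapool/prioritization.py` — I_PPAE, I_TSCR, DTPF, priority, ranking
- `src/tsapool/coverage.py` — union/multiplicity/Venn coverage, cocktails
- `src/tsapool/optimization.py` — threshold grid search and Pareto front
- `src/tsapool/simulate.py` — synthetic cohorts with ground truth
- `src/tsapool/pipeline.py`, `src/tsapool/cli.py` — orchestration and CLI

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
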