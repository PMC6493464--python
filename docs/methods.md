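# Methods

This note documents the statistical model, the defaults, and the design
choices behind `tsapool`, in the spirit of a package methods appendix. It
states no numbers that the test suite or `scripts/acceptance.py` do not
themselves compute.

## Pipeline model

The screen operates on a gene × sample matrix of gene-level read counts
from a mixed cohort: M tumor samples and normal samples grouped into T
tissue types. Stages run strictly in order:

1. **Normalization.** Median-of-ratios size factors: for each sample j,
   `sf_j = median_i counts[i,j] / geomean_i`, where the median runs over
   "reference" genes with a nonzero count in every sample (so the
   geometric mean is positive). Counts are divided by `sf_j`. Only the
   size-factor estimator is implemented — no dispersion modelling or
   differential testing, which the screen does not use. Normalization is
   joint over tumor and normal samples (one comparable expression scale is
   the point of the exercise); a per-batch mode is not offered. A
   `pseudocount` option rescues degenerate matrices in which every gene
   contains a zero; a single-sample matrix gets factor 1.0 by convention.
   The estimator fixes only *relative* scale: multiplying one library by c
   moves the geometric-mean pseudo-sample by c^(1/S), so absolute
   normalized values are defined up to a common constant.

2. **Normal-tissue summaries.** The arithmetic mean of normalized counts
   per (gene, tissue) over that tissue's normal samples; tumor samples are
   excluded. A median option exists but the mean is the default summary.
   Means are bucketed into *none* (≤ t_none), *low* (t_none, t_high] and
   *high* (> t_high) with defaults t_none = 10, t_high = 50 counts; both
   boundaries belong to the lower bucket. The bucket indicator
   e(a,t) ∈ {0, 0.5, 1} feeds the adverse-event index. Buckets are applied
   to full-precision means, not to rounded display values.

3. **Candidate filter.** A gene enters the TSA pool iff it is
   (i) protein coding, (ii) above `tumor_high_threshold` (default 50
   normalized counts, strict `>`) in at least one tumor sample,
   (iii) at or below `essential_max_avg` (default 10) mean counts in every
   essential tissue — brain, heart and lung, where any cross-reactivity is
   unacceptable — and (iv) has at most `max_ppae` (default 6) predicted
   potential adverse events, i.e. non-essential tissues in the low or high
   bucket. The essential-tissue cap uses the same ≤ 10 boundary as the
   "none" bucket for internal consistency. The PPAE cap is inclusive
   (≤ 6) by default and configurable, since an exclusive reading ("fewer
   than six") is also defensible; both are one flag apart. Genes missing
   from the annotation cannot be verified as protein coding and are
   excluded, with a warning count.

4. **Prioritization.** I_PPAE is the tissue-weighted sum of bucket
   indicators, normalized by the maximum such sum over the candidate pool;
   a pool whose numerators are all zero scores 0 for everyone (this avoids
   0/0 and matches the no-adverse-event ideal). The normalizing maximum
   can be pinned to an explicit value when a subset must be scored on the
   scale of a larger reference pool; `solve_pool_denominator` recovers
   that constant from one reference target's numerator, coverage and
   score. I_TSCR is the fraction of tumor samples above the tumor
   threshold. DTPF = (1 − I_PPAE) + I_TSCR; ranking is by descending
   DTPF, ties broken by higher I_TSCR then gene id. Priority classes use
   strict thresholds: high iff 1 − I_PPAE > 0.5 and I_TSCR > 0.25; low
   iff only the first holds; none otherwise — boundary values fall to the
   lower class.

5. **Cocktail coverage.** Each antigen covers the tumor samples where its
   indicator is 1. The default "rank" mode evaluates the top-k targets by
   DTPF; the "greedy" mode is an explicit extension that picks the set
   with the largest marginal union gain at each step (ties by DTPF then
   gene id) and inherits the (1 − 1/e) maximum-coverage guarantee, which
   the tests verify against exhaustive search on pools of ≤ 12 sets.
   Reported: cumulative union sizes, the exact-multiplicity histogram
   (which sums to M, with the k = 0 bin the uncovered samples), Venn
   regions for ≤ 6 sets, and percentages at one decimal place.

6. **Threshold search.** The three filter knobs span a small integer
   field: tumor threshold 10–100, essential cap 5–20, PPAE cap 0–8
   (≤ 91 × 16 × 9 points). The search is exhaustive on the requested grid
   rather than a literal gradient ascent — on a discrete field this size,
   enumeration is exact and cheaper than stochastic ascent. Three pool
   objectives are maximized simultaneously: pool size, mean antigens per
   tumor sample, mean covered samples per antigen. Because no principled
   single aggregation of the three exists, the full Pareto set is
   returned together with a documented default pick (equal-weight sum of
   min–max normalized objectives, first occurrence winning ties), and an
   optional coordinate hill-climb for coarse custom grids.

## Tissue weights

The built-in weight table encodes a generalized clinical severity of
damage per tissue, in the spirit of organ-failure scoring: 1.0 for bone
marrow, kidney, liver and leukocytes (immediately life threatening); 0.8
for colon, duodenum, esophagus, stomach, adipose tissue, small intestine,
pancreas; 0.5 for adrenal gland, bladder, skin, thyroid gland, salivary
gland, skeletal muscle, lymph node; 0.3 for appendix, gall bladder,
endometrium, breast, ovary, spleen, placenta; 0.0 for testis and prostate
(no effect — e.g. testis is irrelevant for a female breast-cancer cohort).
Brain, heart and lung carry no weight because they are hard-filtered
instead. Tissue labels are canonicalized (case, whitespace, singular
/plural aliases); a tissue present in the data but missing from the table
is a hard error unless `--allow-unweighted` is set, which assigns the
maximally conservative weight 1.0 — silent zero-weighting would hide
adverse events. Weight entries matching no cohort tissue (the table ships
a gall bladder entry; a cohort may lack one) are kept and logged.

## Synthetic cohorts

`simulate_cohort` draws counts from a negative binomial — the standard
count model for RNA-seq, with variance μ + αμ² — with per-sample
log-normal library factors (α = 0 degrades to Poisson). Defaults emulate
the intended study design: 98 tumor samples and 345 normal samples over
29 tissue types (11–12 each), ~300 background genes expressed everywhere
(10% non-coding to exercise the biotype filter), one tissue-specific gene
per tissue, dispersion 0.1 and library spread 0.15 as typical bulk
RNA-seq magnitudes. Planted antigens are expressed at a configured mean
in a uniformly drawn subset of ⌊coverage·M + 0.5⌋ tumor samples and at
mean ≈ 1 elsewhere; planted adverse events place tissue means at the
bucket centres (25 for low, 200 for high) unless an exact level is given.
Everything is reproducible from one seed.

`fixture_table1_like` plants six antigens reproducing the coverage
counts, tumor averages and adverse-event profiles of the screen's
published top-ranked targets (65, 56, 31, 31, 29 and 17 covered samples
of 98; adverse events in salivary gland, colon and testis at the reported
levels). Dispersion is lowered to 0.005 and library spread to 0 so that
category and indicator recovery is effectively deterministic for any
seed: every planted mean sits several standard errors away from the
nearest bucket boundary. Note that under this six-antigen pool the
I_PPAE denominator is the pool maximum 0.5; reproducing scores reported
against a several-hundred-gene reference pool requires pinning the
denominator (≈ 3.04), which `solve_pool_denominator` recovers from the
rank-1 row and which the rank-2 row independently confirms to within
0.01.

What the generator does *not* emulate: alignment artefacts, batch and
GC/length biases, isoform structure, correlated gene programs, or
real-data dispersion heterogeneity. Passing tests therefore demonstrate
the correctness of the arithmetic and the filter logic under the assumed
count model, not robustness to the full messiness of real cohorts.

## Problem sizes and numerical choices

The default verification cohort is 335 genes × 443 samples, which the
full pipeline processes in seconds; the end-to-end acceptance run and the
whole test suite complete on one CPU in well under the scale of minutes.
Grid searches in tests use reduced axes (e.g. 3 × 2 × 3) of the same
integer field. Reported numbers follow the display conventions of the
field: DTPF to 3 decimals, coverage ratios to 2, average expression to
the nearest integer, percentages to 1 decimal; all comparisons and
round-trips run at full precision, with display rounding applied only in
reports.

Degenerate inputs are defined rather than left to chance: single-sample
matrices get size factor 1.0; an all-zero I_PPAE pool scores zero; empty
target lists produce header-only reports and empty histograms;
`venn_counts` refuses more than 6 sets; cocktail size must not exceed
the pool.

## Known limitations

- Subcellular-localization labels are consumed as given input; the
  package does not derive them from sequence or external databases.
- The screen is purely transcriptomic: protein-level confirmation,
  peptide–HLA binding prediction and receptor-status sample triage are
  out of scope.
- The PPAE concept uses average tissue expression; a tissue with a rare
  high-expressing subpopulation averaged below threshold is invisible to
  it.
- The greedy cocktail optimizes raw union coverage only; it ignores
  antigen redundancy benefits (multiplicity ≥ 2) and clinical
  constraints.
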