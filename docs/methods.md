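# Methods

## Transaction encoding

Each survey question contributes at most one item per participant: the item
code of (question *q*, option *k*) is *q*·1000 + *k* with *k* ≥ 1. The
scheme is bijective without consulting the codebook (a question may have at
most 999 options) and makes reports self-describing — printed codes such as
`130001` or `68002` identify the question and option directly. Blank answers
contribute no item; "Refused"/"Don't know" are ordinary options with their
own codes, since refusal is itself an informative response category.
Records with a missing outcome are excluded before any mining.

The adherence outcome is adherent iff any guideline criterion holds: FOBT
within 1 year, sigmoidoscopy within 5 years, or colonoscopy within the
guideline window. Guidelines state the colonoscopy interval as 7–10 years
depending on individual risk; the package defaults to the 10-year outer
bound, configurable through `ScreeningIntervals`. Unknown screening-history
fields (unknown whether a test was ever taken, or how long ago) resolve to
*not adherent-qualifying*: an unknown cannot demonstrate adherence. The
fields imputed this way are returned alongside the derived history so the
caller can audit them.

## Mining

Support of itemset *S* in class *C* is |{r ∈ C : S ⊆ r}| / |C|. Mining is
class-conditional: the adherent and non-adherent classes are mined
independently at the same threshold (default 0.6, inclusive), and pooled
support is never used — only rule confidence pools the classes. The
frequency decision is exact: *S* is frequent iff count ≥ ⌈s·n⌉ with the
threshold held as a rational number, because 0.6 of a 411-record class
(246.6) is not integral and a floating-point comparison can misclassify
boundary counts.

The miner is classic level-wise Apriori: candidates are generated by
joining (k−1)-prefix-sharing sorted itemsets, pruned by (k−1)-subset
frequency, with question-disjointness enforced at join time. Since two
options of one question never co-occur in a record, their union has support
0; rejecting such candidates at the join is an optimisation, not a
semantics change. Output order is deterministic (size, then lexicographic
item codes), so a re-run serialises byte-identically.

`brute_force_frequent` enumerates every question-disjoint itemset directly
(guarded to ≤ 16 distinct items) and exists purely as an independent test
oracle for the level-wise path; `maximal_filter` keeps itemsets with no
proper frequent superset, yielding an antichain.

`support_sweep` reruns the miner across a threshold grid (the workflow used
to choose an operating threshold: counts are anti-monotone in the
threshold, and the chosen level trades descriptive volume against
specificity).

## Contrast extraction

* **Strong class itemsets**: support ≥ *high* (default 0.8) in the target
  class and strictly < *low* (default 0.6) in the other, then
  maximal-filtered. "Does not appear above 60%" is read as strict
  `< 0.6`. The input tables must be mined at a threshold ≤ *low* so the
  condition is decidable from them.
* **M1**: itemsets frequent in *both* classes with |support₁ − support₂| ≥
  0.20, the gap being absolute (percentage points), not relative. An
  itemset with a large gap but infrequent in one class belongs to the
  strong family, not M1.
* **M2**: for each itemset *S* frequent in exactly one class, every
  nonempty proper subset *B* frequent in both classes yields the pair
  (shared subset *B*, extension *S∖B*, class of *S*). By default only
  subsets *B* maximal among the qualifying subsets of *S* are reported —
  every sub-subset of a qualifying *B* also qualifies, and reporting them
  all floods the output with redundancy; `maximal_shared_only=False`
  restores the complete list. Emptiness for one class is a legitimate
  outcome (a class may have no unique frequent itemsets at all).

Confidence of rule *S* → *C* is the fraction of all records containing *S*
that belong to *C* (the two-class confidences sum to 1). No confidence
cutoff is applied; confidence is attached to every strong rule as reported
evidence, with variable selection deferred to the regression stage.
Output orderings are fixed (descending support / gap, ties by item codes)
for reproducibility. No significance testing of contrast sets is done at
this stage: contrasts are support arithmetic, and statistical confirmation
belongs to the regression.

## Logistic regression

Predictors are coded per a `DesignSpec`: binary terms as 0/1 indicators
(either "equals this option" or "differs from the reference level") and
Likert-style items as ordinal integers over declared levels. Missing
handling is listwise: any record missing the outcome or any predictor is
dropped, and `n_used` reports the remainder.

Fitting is Newton–Raphson IRLS from β = 0 with step-halving, which makes
the log-likelihood non-decreasing across iterations; convergence when
max |score| < 1e-8 or the relative log-likelihood change < 1e-10, capped at
100 iterations. Rank deficiency is detected up front via a pivoted QR and
reported with the collinear column names. Separation (divergence, or any
|β| > 30) raises a diagnostic naming the offending predictor;
`on_separation="firth"` refits with Jeffreys-prior penalisation instead.

Reported statistics: Wald = (B/SE)², OR = e^B, CI95 = exp(B ± 1.96·SE)
(the SPSS-style Wald interval). A published table built with the opposite
indicator direction shows −B and 1/OR; the package always reports e^B
under its own coding and leaves the direction to the `DesignSpec`.
Pseudo-R²: Cox & Snell = 1 − exp(2(LL₀ − LL₁)/n) with LL₀ the
intercept-only log-likelihood; Nagelkerke divides by its attainable
maximum 1 − exp(2·LL₀/n).

Hosmer–Lemeshow: records sorted by fitted probability and cut at decile
boundaries, with ties never split — runs of identical fitted probabilities
stay in one bin. With few binary predictors the number of distinct
covariate patterns bounds the realised group count *g*, so *g* < 10 and
df = *g* − 2 shrink naturally (seven patterns give df = 5). Fewer than 3
groups makes the test undefined: the library raises, and the pipeline
report records the test as unavailable rather than failing. The
classification table predicts class 1 iff fitted probability ≥ 0.5
(configurable) and reports percent correct within each observed class and
overall.

## Synthetic data generator

The generator emulates the study-scale shape: 608 adherent + 411
non-adherent analyzable records, 2 extra rows with a blank outcome (1021
surveyed), 144 questions × 5 options. Answers are independent given class,
drawn per question from a class profile; the default profile
(0.40, 0.25, 0.15, 0.12, 0.08) is a typical single-dominant-answer survey
marginal whose maximum sits below the 0.6 mining threshold, so an unplanted
dataset yields empty mining output — the null configuration.

Plants force known structure. A deterministic plant overwrites the planted
questions' answers in the first ⌈support·n⌉ records of the class and
removes the planted option elsewhere, so the realised support is *exactly*
⌈support·n⌉/n and co-occurring plants overlap in nested head slices
(unions of plants are therefore themselves deterministic itemsets — real
structure, accounted for in recovery tests). Stochastic plants use
Bernoulli inclusion for sampling-noise realism. Two plants may not touch
the same question. The standard configuration plants a strong-C1 itemset
(0.85/0.55), an M1 itemset (0.85/0.62) and an M2 pair (shared singleton at
0.90/0.90, extension at 0.85/0.40). A regression scenario drives a
Bernoulli outcome through a logistic model over (question, option)
indicators with known coefficients.

All randomness flows from the single integer seed through named
`numpy` substreams (table vs. outcome), so identical specs produce
byte-identical CSV output.

What the generator does **not** emulate: inter-question correlation
(answers are independent given class; an optional dependence hook was
considered and left out as untestable without real data), demographic
marginals, attitude-scale structure, or item nonresponse patterns. Passing
tests therefore demonstrate algorithmic correctness and recoverability
under known conditions — not that any particular substantive finding about
screening behaviour would replicate on real survey data.

## Problem sizes used in checks

The oracle-equivalence checks run on 200 random datasets of ≤ 12 items and
≤ 100 records — the regime where exhaustive enumeration is exact and fast.
Planted recovery runs at the full 1019-record, 144-question scale over 20
seeds. Regression coverage uses 200 replicates at n = 1000 with true
coefficients (−1.5, 1.5, −0.3) and intercept 0, pooling the three
per-coefficient Wald intervals (600 intervals) for a stable 95%-coverage
estimate; bias checks use n ∈ {500, 2000, 8000}.

## Known limitations

* Deterministic plants concentrate structure in head slices, which makes
  M2 output combinatorially rich on planted data; real surveys with noisy
  co-occurrence produce far sparser M2 lists.
* The Hosmer–Lemeshow grouping follows the deciles-of-risk convention with
  tie merging; other software may split ties differently and report
  slightly different χ² for identical fits.
* No significance correction across the many mined contrasts; the
  confirmatory regression is the only inferential stage, as designed.
* The Firth fallback targets separation rescue, not routine small-sample
  bias correction; its standard errors are Wald-based, not profile
  penalised-likelihood intervals.
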