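# Methods

## Signature model and ranking

A compound signature is one real z-score per gene over a shared, ordered
gene universe; the data model is agnostic to how the z-scores were
produced (moderated z from a perturbation compendium, fold-change, …) and
assumes one score per gene per compound. Ranks are descending (rank 1 =
most up-regulated) with ties broken by ascending lexicographic gene id —
an arbitrary but platform-independent convention that makes every ranking
a deterministic permutation, which the byte-level reproducibility
guarantees of the CLI rely on.

GCT 1.2 text is the interchange format for matrices; values are written
at full shortest-round-trip precision, so write→read reproduces the
matrix bit for bit. (A fixed 6-significant-digit format was considered
and rejected: it caps round-trip agreement near 1e−7 for unit-scale
values, which would break both the exact round-trip contract and
byte-level determinism of derived outputs.) Gene-set files are GMT with
`<name>_UP` / `<name>_DOWN` lines; disease genes absent from the compound
universe are dropped with a logged count, the standard harmonization
practice in connectivity mapping, and an empty post-harmonization set is
an error rather than a silent zero score.

## Enrichment and reversal

The enrichment statistic is the classic unweighted KS running sum over
rank positions. For a t-gene set at sorted positions p(1)<…<p(t) in an
n-gene ranking, a = max_j (j/t − p(j)/n) measures concentration at the
top and b = max_j (p(j)/n − (j−1)/t) at the bottom; the signed ES is a if
a > b else −b. Both one-sided deviations coincide with the one-sided KS
statistics of {p(j)/n} against the uniform distribution, which is the
independent oracle the tests use. The two-set connectivity is
(ES_up − ES_down)/2 gated to 0 when the enrichments share a sign; the
reversal score is its negation. The unweighted form and the sign gate are
the canonical published choices; a score-weighted variant would slot in
behind the same `EnrichmentResult` interface. ES values are not
normalized against a permutation null; that is a documented extension
point, not implemented.

A subtlety the test suite pins down: the signed statistic is *not*
antisymmetric under list reversal near ties. Reversing the list maps
a′ = b − 1/n and b′ = a + 1/n, so es + es′ = −1/n exactly when
|a − b| > 2/n, but inside that tie band both orientations can return the
signed bottom deviation. The property test asserts the exact relation
outside the band.

## CGEM

The combination model is additive: combined z = z_a + z_b, re-ranked.
Additivity is the minimal assumption for a two-drug transcriptional
effect; it is isolated in `combine_signatures` so an alternative merge
(max-magnitude, weighted) can be substituted without touching the
ranking. The pair scan is exhaustive — all m(m−1)/2 unordered pairs —
with a streaming inner loop (one lexsort per pair, O(n log n)); no
heuristic pruning. Ties are broken by lexicographic pair id. Scoring the
pair's *combined signature* (rather than combining two single-drug
connectivity scores) is a deliberate reading of how a combination should
be evaluated, and the one the planted-truth construction makes provable.

## TargOpt

Engagement is binary with a ±1 direction; no potency or affinity tiers.
`on_count` counts disease targets hit in the desired direction by at
least one drug of the pair (idempotent coverage — both drugs hitting the
same target count once); `off_count` counts distinct targets engaged
outside the disease set *or in the wrong direction* — a drug pushing a
disease target the wrong way is treated as a liability, not a miss. The
scalarization score = α·on − β·off defaults to α=1, β=0.5: on-target
coverage is the objective and off-target burden a soft penalty at half
weight, so one extra disease target is never traded away for fewer than
two off-targets. Because any fixed (α, β) is a modelling choice, rankings
also annotate the (on, off) Pareto front.

## Prioritization

Mean rank across the two engines, with a missing-method penalty of
(worst rank in that method's list + 1) and a `single_method_only` flag.
Mean rank was chosen as the simplest auditable aggregation; the `method`
parameter isolates it for substitution. Annotation flags (`ddi_alert`
from a blocklist, `same_mechanism` from a drug→class map) never remove
or reorder pairs — triage decisions belong to the human expert.

## Behavioural endpoints

D2 = (t_novel − t_familiar)/(t_novel + t_familiar), bounded in [−1, 1],
for NOR/OL/SR. The minimum-exploration inclusion rule is read as a
threshold on *total* exploration time (novel + familiar ≥ 3 s, boundary
inclusive) — the natural reading of "explore the objects for a minimum of
3 s" — and is configurable. Applying inclusion before the D2 formula also
removes the zero-division case. Hyponeophagia latencies are capped at the
test duration (default 300 s for a 5-min test); an animal with no
drinking event receives the maximal latency and is marked censored. A
latency recorded exactly at test end is scored as observed by default;
`censor_at_boundary` flips that convention, since either reading is
defensible. Group summaries use SD with the n−1 denominator and
SEM = SD/√n (the GraphPad convention); a single-animal group reports NaN
SD/SEM with a note, and a group with no included animals yields a warning
row rather than statistics. Inferential statistics are intentionally out
of scope: the tidy endpoint tables are the hand-off to any stats package.

## Synthetic data and planted truth

`generate_library(m, n, seed)` draws i.i.d. standard-normal z-scores — a
deliberate simplification of real compendium signatures (no gene–gene
correlation, batch, plate or dose structure, no moderated-z heavy tails).
Passing tests on this generator therefore demonstrates the *machinery*
(scoring, ranking, recovery of an embedded optimum), not performance on
real perturbation data.

`plant_reversal` derives the disease signature *from* the planted pair's
combined profile: the n_up most-negative combined-z genes become the
disease up-set, the n_down most-positive the down-set. The planted pair's
combined ranking then places the up-set at the exact bottom and down-set
at the exact top — the largest reversal any pair with those set sizes can
achieve, (2 − t_up/n − (t_down−1)/n)/2-style by the order-statistics
argument — so noiseless recovery is provable, not probabilistic. The
whole library is then perturbed with N(0, σ) measurement noise: at σ=0
recovery is certain, at σ=0.1 the planted pair's observed signature stays
close to the one the disease was derived from and recovery is
near-certain, and at σ≫1 the ranking decouples from the disease sets and
recovery degrades to chance. Noise is applied to every compound,
including the planted pair — noise that spared the planted pair would
leave its reversal extremal at any σ and make the noise level
inconsequential.

`generate_target_catalog` splits the disease targets between the two
planted drugs (desired directions, zero off-targets) while every decoy
drug covers at most ⌈k/2⌉ disease targets and carries at least one decoy
off-target, so for any β > 0 the planted pair's score α·k strictly
dominates. Behavioural cohorts draw from normals truncated at zero
(times cannot be negative), 10 animals per group by default, matching
the usual phenotyping design; sd=0 degenerates to the group mean.

## Problem sizes and numerical choices

The validation-scale configuration — 50 compounds × 978 genes, 50-gene
up/down sets, 20 seeds; 12-drug catalogue with 5 disease and 6 decoy
targets; 6 behavioural groups of 10 — keeps the full acceptance sweep in
the seconds-to-minutes range on a single CPU while leaving the pair space
(1225 pairs) large enough that chance-level recovery is ~0.1%. All
generators are pure functions of their arguments including the seed; CLI
outputs use fixed float formatting so equal inputs give byte-identical
files. Floating-point comparisons in tests use exact equality where the
arithmetic is exact (counting, closed-form cases) and `pytest.approx`
defaults elsewhere.

## Known limitations

- Additive combination ignores pharmacological interaction (synergy,
  antagonism) at the transcriptional level; no dose modelling.
- Unweighted KS enrichment ignores z-score magnitudes; no null-model
  normalization of ES.
- Binary target engagement without affinity or pathway expansion.
- The synthetic generator's independence assumptions make planted-truth
  recovery easier than real-data discovery; results on it bound
  correctness, not real-world sensitivity.
- Only 2-drug combinations; higher-order combinations are out of scope.
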