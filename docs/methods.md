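# Methods

## Model

The core model is latent Dirichlet allocation over bag-of-words documents
built from concatenated titles and abstracts. Topics φ_k ~ Dirichlet(β)
(symmetric, over V words), document mixtures θ_d ~ Dirichlet(α) (symmetric,
over K topics), token topics z ~ Categorical(θ_d), words w ~ Categorical(φ_z).
K is fixed a priori; the toolkit treats choosing K as a model-selection sweep
(below), not an inference problem.

Estimation is collapsed Gibbs sampling: φ and θ are integrated out
analytically and each token's assignment is resampled from

    p(z_i = k | z_−i, w) ∝ (n_dk^−i + α) (n_kw^−i + β) / (n_k^−i + Vβ).

A single chain is run; point estimates are the posterior means given the
final assignment state, φ̂_kw = (n_kw+β)/(n_k+Vβ) and
θ̂_dk = (n_dk+α)/(n_d+Kα). This is the simplest estimator that admits an
exact small-case oracle: on corpora of ≤ 8 tokens the collapsed joint can be
enumerated over all K^N assignment vectors, and the test suite checks the
sampler's co-assignment probabilities p(z_i = z_j) against that enumeration.
Co-assignment rather than raw marginals is the informative quantity: under
symmetric priors the posterior is invariant to topic relabelling, so every
raw marginal is exactly 1/K.

Held-out documents are folded in by Gibbs sampling over the new document's
tokens only, with φ fixed at the trained estimate; the reported θ is the
posterior mean averaged over post-burn-in sweeps (more stable than the final
state for short documents). An empty document (everything out-of-vocabulary)
yields the uniform distribution, flagged.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| α | 50/K | standard topic-modelling heuristic; small corpora in tests use 0.1 to match their concentrated generative truth |
| β | 0.01 | standard; keeps φ strictly positive so log-scores are defined |
| n_iter | 1000 | Gibbs sweeps; 150–300 suffice for the small corpora used in tests |
| burn-in | 0.5 · n_iter | fixed fraction, single chain |
| K sweep | 20, 25, 30, 60, 90, 120, 200 | the candidate grid for corpus-scale model selection; default working K is 30 |

The trace of the collapsed joint log likelihood is recorded every 10 sweeps;
convergence is declared when the second half of the trace has no practically
relevant upward slope. This is a pragmatic diagnostic, not a convergence
proof.

Topic numbering is made stable across runs by sorting topics by decreasing
marginal prevalence (ties broken by lowest dominant word ID). One integer
seed drives initial assignments and all sweeps; fits are bitwise
reproducible. The token-level inner loop is numba-compiled; seeding happens
inside the compiled kernel, which is deterministic.

## Preprocessing

Tokenisation is deliberately minimal and deterministic: lowercase, keep
maximal runs of ASCII letters, drop stopwords (shipped English list) and
words shorter than 3 characters. No stemming, n-grams or language detection.
Titles and abstracts are concatenated with equal weight. Dictionary IDs are
assigned lexicographically so identical input files give byte-identical
dictionaries and corpora regardless of record order; vocabulary pruning
keeps words with document frequency ≥ `no_below` and ≤ `no_above`·n_docs.
At fold-in time out-of-vocabulary tokens are dropped and counted, never
added: held-out inference must not mutate the dictionary.

## Corpus expansion

The expansion rule admits a candidate iff at least `min_matches` = 5
articles in the accepted corpus are at least `threshold` = 0.95 similar to
it, processing candidates in training cycles of `batch_size` = 100 and
refitting the model on the enlarged corpus after each cycle. "Similar in
frequency of words and topics" is implemented as a conjunction: the
similarity is min(cosine of term-frequency vectors, cosine of folded-in
topic distributions), so both views must clear the threshold; either clause
alone is selectable (`mode="word" | "topic"`). Candidates within a cycle are
judged against the corpus as it stood at the start of the cycle, so verdicts
are invariant to within-batch order (the fold-in seed is derived from the
candidate's ID, not its position). A `threshold_sweep` utility reports
acceptance counts across cut-offs for exploratory threshold selection.

## Topic summaries, distances, topic-count sweep

Term ranking uses λ-relevance, r(w,k) = λ·log φ_kw + (1−λ)·log(φ_kw/p_w),
with p_w the model-implied corpus term distribution Σ_k prevalence_k φ_kw
and λ = 0.6 by default (the commonly recommended compromise between
within-topic frequency, λ=1, and lift, λ=0). Saliency
p_w·KL(p(k|w)‖prevalence) is provided for corpus-level term ordering.
Prevalence_k = Σ_d n_d θ_dk / Σ_d n_d is the topic's token-mass share
("circle size"). Inter-topic distance is the Jensen–Shannon divergence
(natural log, bounded by ln 2) between φ rows; the 2D layout is classical
multidimensional scaling (principal coordinates) of that distance matrix:
double-centre the squared distances, eigendecompose, keep the two leading
non-negative eigenpairs. When the Gram form has rank ≤ 2 (e.g. three
topics) the layout reproduces the distances exactly; otherwise it is the
usual least-squares projection. Which dimensionality-reduction backend a
given interactive viewer uses varies; PCoA is this package's documented
choice.

The topic-count sweep makes the usual eyeball criteria quantitative: for
each K it reports mean pairwise JSD (separation), prevalence entropy
normalised by log K (evenness), and the number of topic pairs with JSD
below 0.2 (overlap), plus training perplexity.

## Screening and consensus

Screening decisions use a frozen seven-reason exclusion taxonomy; reasons
may overlap, so per-reason counts can sum to more than the number of
exclusions. Percentages are rounded half-up to one decimal. One published
flow is used as the arithmetic anchor in tests: 2469 screened, 848 included
⇒ 1621 excluded (65.7%). (One tabulated exclusion row is printed as "44%"
where context implies a count of 44; the toolkit treats such entries as
counts.)

Consensus: although pairwise Cohen's kappa is the better-known statistic,
the procedure actually described — counting how many raters' labels coincide
with the modal label — corresponds to a mode-agreement kappa, implemented
here as the primary statistic: p_o = (mode count)/R, p_e = q_mode² + Σ
q_other² with the modal category's frequencies merged, κ = (p_o−p_e)/(1−p_e).
The stringent variant uses the single top mode; the lenient variant, on
bimodal topics (exact tie by default; a near-tie margin δ is configurable),
merges the two modal labels first, which weakly increases κ. Fleiss'
multi-rater kappa (statsmodels) is reported alongside as the textbook
alternative; no claim is made about which variant any particular published
figure used. Interpretation bands are implemented as half-open intervals at
the second decimal (0.20 → slight, 0.21 → fair, …, 0.81–1 → almost perfect);
all-identical columns define κ = 1.

A property worth knowing: the mode-agreement statistic conditions on the
column's largest count, so under pure chance its expectation is slightly
positive at finite R (a max-statistic selection effect, ≈ 0.12 at R = 10
with 8 labels). The test suite checks the statistic against a direct
simulation of its own chance level, and checks Fleiss' κ ≈ 0, whose chance
correction is unbiased.

Synonym reconciliation is an explicit user-supplied many-to-one map (e.g.
"allergy" → "allergies"); the semantic judgement itself is out of scope, as
it is an expert task.

## Synthetic data: what it shows and what it does not

The generator draws corpora from the LDA generative process itself
(optionally with disjoint per-topic vocabulary blocks for maximal
separability), candidate streams mixing in-domain documents (same generative
truth) with off-domain documents over a disjoint shifted vocabulary, and
rater tables under a "true label + uniform noise" model. Defaults: 5 topics,
100-word vocabulary, 100 documents of mean length 60 (Poisson), document
concentration α_true = 0.1, 30% off-domain candidates, 20% rater noise —
scales chosen so the full suite runs in seconds while leaving all the
statistical structure intact.

Synthetic documents are far shorter and their vocabulary far smaller than
real PubMed abstracts, which changes one constant materially: cosine
similarities between same-topic synthetic documents are noise-limited, so
the 0.95 similarity threshold appropriate for real abstracts accepts nothing
at synthetic scale. The separability experiments therefore run the
conjunction rule at threshold 0.5 (chosen by exploratory calibration before
the tests were frozen, the same way a working threshold would be chosen for
any new corpus; the shipped default remains 0.95). Consequently, passing
tests demonstrate the correctness of the machinery — sampler, filter,
statistics, determinism — under known truth; they do not certify the 0.95
threshold, topic quality, or retrieval behaviour on real literature, all of
which depend on the corpus at hand.

Problem sizes used by the test suite and the acceptance script (50–500
documents, 3–5 topics, vocabulary ≤ 100, 150–300 Gibbs sweeps) are the
package's chosen desk-scale study conditions; recovery error at those sizes
(mean permutation-matched L1 of φ ≈ 0.13 → 0.04 from 50 → 500 documents) is
computed fresh on every run.

## Known limitations

- Single-chain Gibbs with a fixed burn-in fraction; no R̂ or multi-chain
  diagnostics, no hyperparameter optimisation, no variational alternative.
- Tokenisation is ASCII-alphabetic only; non-Latin scripts and hyphenated
  terms are split or dropped.
- The expansion rule refits from scratch each cycle (cost grows with corpus
  size); incremental updating is not implemented.
- Fleiss' kappa treats an explicit missing marker by excluding those labels
  from per-topic statistics, but the tablewide Fleiss computation assumes a
  complete table.
- The E-utilities fetcher is a thin convenience, not a crawler: no retry
  logic, no date windows, no cross-database deduplication.
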