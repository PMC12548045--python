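# Methods

## The scoring model

Each gene is judged against eight fixed disease-relevance criteria on a
0–10 integer rubric (0 = no evidence; 1–3 = very limited evidence; 4–6 =
some evidence requiring validation; 7–8 = good evidence; 9–10 = strong
evidence). Individual scores map to confidence bins — High (≥7), Medium
(4–6), Low (≤3) — and the gene-level aggregate is the confidence-
weighted score

    W = 1.0·p_High + 0.7·p_Medium + 0.3·p_Low,

with each proportion computed over the fixed denominator of 8 criteria
regardless of how many were observed. Unobserved criteria (malformed
backend responses, criteria filtered out by the faithfulness gate)
therefore contribute zero weight. This is the only reading under which
both stated properties of the aggregate hold simultaneously: the range
is 0.0–1.0 (a gene with nothing observed scores 0.0), while a fully
observed all-Low gene scores 0.3. The score is monotone in every
individual criterion and equals 1.0 exactly when all eight criteria are
observed and High.

Priority Set 1 admission uses the rule "any criterion ≥ 5" by default;
a weighted-score threshold and conjunctions are available through
configuration. Quantile stratification places cluster boundaries at the
k-quantiles of the weighted-score distribution with Q1 the top bin.
Equal scores always share a bin: duplicate quantile edges are merged,
so heavy ties produce fewer, larger bins (this is also why the
literature-validated set can come out with fewer clusters than
requested — validated genes concentrate at high weighted scores). The
once-stated alternative of refusing k larger than the number of
distinct values was rejected because tie-merging is the behavior the
quantile-cut semantics imply and the one the downstream re-clustering
step depends on.

Ordering everywhere is weighted score descending, then gene symbol
ascending — a documented, reproducible tie-break.

Percentages are reported at one decimal with half-up rounding through a
single shared routine (`genesieve.utils.pct`), exact over integer
numerator/denominator pairs.

## Retrieval and gating

The knowledge base keeps full documents only above a citation-
percentile threshold (default 0.8, strict inequality); records without
a percentile — typically paywalled abstracts — are always kept.
Preprocessing strips a trailing reference/bibliography block by heading
heuristic; chunking uses 1500-character windows with 150-character
overlap (0-based, half-open spans; reassembly minus overlaps
reconstructs the preprocessed text exactly). Chunk size is a
paragraph-scale retrieval granularity choice; nothing upstream pins it.
Entity tagging is whole-token, case-sensitive lexicon matching over the
evaluated gene universe — entities are retrieval metadata, not
load-bearing — with model-based taggers pluggable behind the same
function signature.

The default embedder is a deterministic hashed bag-of-words vectorizer
(MD5 token hashing into 256 buckets, L2-normalized, cosine geometry).
It captures lexical overlap, not semantics, which is sufficient to
exercise the retrieval contract (determinism, rank-monotone scores,
tie-breaking by chunk id, embedder-identity checking on persisted
indexes); transformer document embedders implement the same contract as
optional adapters. Likewise the default reranker scores query-token
overlap and is stable with respect to dense rank on ties, honoring the
cross-encoder contract deterministically.

Per (gene, criterion) query: dense top-25, rerank to top-10, assemble a
source-attributed context bundle (query-isolated: a bundle is only
usable for the query it was built for). Scoring from an empty bundle
short-circuits to score 0 / Low — absent evidence is never upgraded.
Cited source ids must be a subset of the bundle; violations flag the
instance as an attribution failure and exclude it. The faithfulness
judge returns a strict binary Pass/Fail; anything else is a malformed
verdict and the instance is excluded. Only passing instances reach
arbitration — enforced with a hard gate error, and re-checked by the
pipeline invariant that pass + non-pass counts partition the instances.

Dual-evaluator agreement is the share of shared query ids with equal
verdicts; the high-confidence subgroup is defined as instances whose
retrieval-augmented score category is High. The grouping variable is an
interpretive choice (the upstream description ties high-scoring
instances to pass behavior without defining "high-confidence"), flagged
as such.

## Arbitration and re-scoring

The Chain-of-Thought synthesis executes three roles as three sequential
backend calls — naive-judgment critic, retrieved-evidence analyst,
final arbiter — with prior outputs injected into the later prompts.
Only the arbiter's structured output (decision, recalibrated 0–10
score, explanation) is parsed. The decision label is re-derived from
the recalibrated score via the standard bins; a mismatch with the
backend's stated label is logged as a consistency warning rather than
an error, tolerating model noise while preserving auditability.

PS2 weighted scores are computed over pass instances only, fixed
denominator 8, so failed criteria drag the aggregate down; genes with
zero passing instances drop out entirely. Transition accounting
cross-tabulates PS1 against PS2 clusters with a "dropped" sink column;
conservation (row sums = PS1 cluster sizes, total inflow = |PS1|) is an
enforced invariant.

## Candidate optimization

Per-cluster enrichment uses the two-sided Fisher exact test on the 2×2
membership table, with each gene set intersected with the universe
first and the universe defaulting to all screened genes. Odds ratios
apply the Haldane–Anscombe +0.5 correction when any cell is zero;
q-values are Benjamini–Hochberg over the tested collection. The
most-enriched cluster is the one with the most sets at q < 0.05, ties
resolved by larger mean −log10 q and then lexically smaller cluster
label; "no cluster enriched" is an explicit error, never a silent pick.
The count-of-significant-sets rule is a declared choice — magnitude-
or judgment-based selection would also be defensible.

PCA standardizes columns to zero mean/unit variance (zero-variance
columns held at zero with a warning), uses a full SVD, and fixes signs
so each component's largest-magnitude loading is positive.
Sub-clustering is k-means with k = 4, n_init = 10 and a fixed seed; the
clustering algorithm is a deliberate simple-and-deterministic choice.
The candidate set is the sub-cluster maximizing the mean of its eight
per-criterion mean scores (ties to the lower cluster id); candidates
are labeled Known/New by upper-case-normalized membership in the prior
evidence set.

## The synthetic study

The generator emulates the statistical structure the pipeline assumes
of real model output, not biomedical text. Defaults (the reference
study): 1000 genes, 60 planted relevant, per-criterion scores from
clipped, rounded Normal(8, 1) for relevant and Normal(2, 1.5) for
irrelevant genes; 2% malformed responses; literature support for each
relevant (gene, criterion) pair with probability 0.9. Criterion scores
within a gene share a latent gene-level component carrying 0.7 of the
variance (relevance is a property of the gene, so its criteria rise and
fall together); the marginals remain the stated normals. Scripted
retrieval-augmented scores are high for supported pairs and
conservative-low (mostly zero) otherwise; the scripted judge passes
exactly the supported pairs, mirroring the rule "Pass iff the cited
chunk mentions the gene together with the criterion keyword", which
holds by construction of the corpus. The scripted arbiter recalibrates
to 0.25·naive + 0.75·rag (rounded), citing the discrepancy when the two
differ by ≥4.

The corpus contains one short supporting article per supported pair
(gene symbol and criterion keyword co-occur; citation percentile drawn
above the filter), neutral ten-gene methods abstracts covering the
whole universe (no percentile), and a few generic reviews with
reference blocks to exercise preprocessing. Benchmark sets follow the
two-database shape (sizes 32 and 48, 28 shared, union 52), drawn 90%
from relevant genes; the gene-set collection plants one pathway of 40
relevant genes among 10 random decoys; publication counts are
log-normal with a higher location for relevant genes.

Every generation step draws from its own child seed of the study seed,
so independent calls agree (scripts and corpus see the same supported
pairs) and the whole study is deterministic across platforms.

What the defaults produce end to end (measured, not asserted targets):
PS1 retains roughly 20% of the universe — the stated irrelevant-score
marginal leaves each irrelevant gene a ≈5% per-criterion chance of
reaching 5, so the any-of-8 rule admits a nontrivial tail — and the
faithfulness gate passes ≈20–25% of instances, covering essentially all
planted genes and no others (only supported pairs can pass, and only
relevant genes have supported pairs). Consequently the planted-gene
recovery properties hold with margin, and the final candidate set is
composed of planted genes.

What passing tests do and do not show: the synthetic study validates
the pipeline's bookkeeping, gating, statistics and determinism under a
favorable, well-separated signal. It says nothing about real LLM
scoring quality, real retrieval semantics (the default embedder is
lexical), or real literature structure; headline figures from any real
deployment (recall levels, pass rates, candidate counts) are emergent
properties of the models and corpus used there and are not reproduced
here.

## Problem sizes and numerical notes

The reference study (1000 genes, 60 relevant) runs the full pipeline in
a few seconds on one CPU; tests use 80–400-gene studies. At this scale
the PS3 set is ~20 genes and k-means occasionally isolates very small
top sub-clusters (1–4 genes); enrichment tests on such tiny candidate
sets are power-limited, so pathway significance in the candidate set is
assessed under the reference conditions rather than guaranteed for
every seed. Floating-point comparisons in tests use 1e-12 absolute
tolerance against exact-rational oracles; Fisher/BH equivalence is
checked at 1e-9 relative tolerance against a pure-python hypergeometric
enumeration. Degenerate inputs are handled explicitly: empty score
vectors score 0.0, empty retrieval bundles score 0/Low, all-equal
quantile inputs collapse to a single cluster, constant PCA columns are
zeroed with a warning, and empty sub-clusters are excluded from
candidate selection with a warning.

## Known limitations

- The default embedder/reranker are lexical test doubles; semantic
  retrieval quality is out of scope of the tested path.
- Faithfulness is a binary contract; graded NLI-style evaluation is
  not modeled.
- The scripted judge in the synthetic study is exact (no judge noise),
  so dual-evaluator disagreement must be constructed explicitly in
  tests rather than emerging from the generator.
- Gene symbols are treated as opaque strings; no HGNC validation or
  alias resolution.
- Production model adapters (OpenAI-compatible, local servers) share
  the backend contract but are intentionally untested offline.
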