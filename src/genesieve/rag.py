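"""Stage 2 — retrieval-augmented evaluation with faithfulness gating.

For each (gene, criterion) query the engine runs two-stage retrieval
(dense top-25 by cosine, then rerank to top-10), assembles a
source-attributed context bundle, obtains a literature-grounded score
through the backend, and submits the justification to a binary
Pass/Fail faithfulness judge.  Only passing instances may proceed to
hybrid arbitration; the gate is enforced downstream.

The default reranker scores lexical term overlap between query and
chunk — a deterministic stand-in honoring the cross-encoder contract;
semantic rerankers plug in behind the same interface.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .corpus import _TOKEN_RE, Chunk, CorpusIndex, Embedder
from .errors import (
    AttributionError,
    ConfigError,
    IsolationError,
    MalformedVerdictError,
    RetrievalError,
)
from .gateway import (
    Backend,
    BackendRequest,
    PromptTemplate,
    ScoreRubric,
    ScoredJudgment,
    Stage,
    parse_judgment,
    render_prompt,
)
from .screen import bin_score
from .utils import pct


@dataclass
class RetrievalHit:
    chunk: Chunk
    dense_score: float
    rank: int
    rerank_score: float | None = None

    @property
    def source_id(self) -> str:
        return self.chunk.chunk_id


def dense_retrieve(query_text: str, index: CorpusIndex, embedder: Embedder,
                   k: int = 25) -> list[RetrievalHit]:
    """Top-k chunks by cosine similarity, deterministic, ranks 1..n."""
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    if len(index) == 0:
        raise RetrievalError("dense retrieval over an empty index")
    results = index.query(query_text, k, embedder)
    return [RetrievalHit(chunk=chunk, dense_score=score, rank=rank)
            for rank, (chunk, score) in enumerate(results, start=1)]


class LexicalOverlapReranker:
    """Deterministic reranker: counts query tokens present in the chunk."""

    reranker_id = "lexical-overlap"

    def score(self, query_text: str, chunk_text: str) -> float:
        query_tokens = set(_TOKEN_RE.findall(query_text.lower()))
        chunk_tokens = set(_TOKEN_RE.findall(chunk_text.lower()))
        return float(len(query_tokens & chunk_tokens))


def rerank(query_text: str, hits: Sequence[RetrievalHit], k: int = 10,
           reranker: LexicalOverlapReranker | None = None
           ) -> list[RetrievalHit]:
    """Reorder hits by reranker score (descending) and truncate to k.

    The sort is stable with respect to the incoming dense rank, so equal
    rerank scores preserve dense order.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    if not hits:
        raise ConfigError("rerank requires a non-empty hit list")
    if reranker is None:
        reranker = LexicalOverlapReranker()
    scored = [(reranker.score(query_text, hit.chunk.text), hit) for hit in hits]
    reordered = sorted(scored, key=lambda pair: (-pair[0], pair[1].rank))
    out: list[RetrievalHit] = []
    for new_rank, (score, hit) in enumerate(reordered[:k], start=1):
        out.append(RetrievalHit(chunk=hit.chunk, dense_score=hit.dense_score,
                                rank=new_rank, rerank_score=score))
    return out


@dataclass
class ContextBundle:
    """Ranked, source-attributed chunks for one (gene, criterion) query."""

    gene: str
    criterion: str
    hits: list[RetrievalHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [hit.source_id for hit in self.hits]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate source ids within a bundle")

    @property
    def query_id(self) -> str:
        return f"{self.gene}|{self.criterion}"

    @property
    def source_ids(self) -> tuple[str, ...]:
        return tuple(hit.source_id for hit in self.hits)

    def format_context(self) -> str:
        if not self.hits:
            return "(no retrieved context)"
        blocks = []
        for hit in self.hits:
            blocks.append(f"[source: {hit.source_id}]\n{hit.chunk.text}")
        return "\n\n".join(blocks)


@dataclass
class RagAssessment:
    """A literature-grounded judgment plus its attribution audit."""

    judgment: ScoredJudgment
    category: str
    query_id: str
    attribution_errors: tuple[str, ...] = ()
    raw_text: str = ""

    @property
    def ok(self) -> bool:
        return not self.attribution_errors


def rag_assess(gene: str, criterion: str, bundle: ContextBundle,
               backend: Backend, template: PromptTemplate,
               rubric: ScoreRubric) -> RagAssessment:
    """Score a (gene, criterion) pair from its retrieved context.

    An empty bundle short-circuits to the conservative zero: score 0,
    Low category, no backend call — absence of retrieved evidence is
    never upgraded by the model's own knowledge.  Cited source ids must
    be a subset of the bundle; violations are flagged as attribution
    errors and fail the instance.
    """
    if (bundle.gene, bundle.criterion) != (gene, criterion):
        raise IsolationError(
            f"bundle for {bundle.query_id} used on {gene}|{criterion}")
    if not bundle.hits:
        judgment = ScoredJudgment(gene=gene, criterion=criterion, score=0,
                                  justification="no retrieved evidence")
        return RagAssessment(judgment=judgment, category="Low",
                             query_id=bundle.query_id)
    prompt = render_prompt(template, {
        "gene": gene, "criterion": criterion,
        "rubric": rubric.as_text(), "context": bundle.format_context(),
    })
    request = BackendRequest(stage=Stage.RAG_SYNTH, gene=gene,
                             criterion=criterion, prompt=prompt)
    response = backend.complete(request)
    judgment = parse_judgment(response.text, Stage.RAG_SYNTH,
                              gene=gene, criterion=criterion)
    bundle_ids = set(bundle.source_ids)
    bad = tuple(s for s in judgment.cited_source_ids if s not in bundle_ids)
    return RagAssessment(judgment=judgment,
                         category=bin_score(judgment.score),
                         query_id=bundle.query_id,
                         attribution_errors=bad,
                         raw_text=response.text)


# ---------------------------------------------------------------------------
# faithfulness


@dataclass(frozen=True)
class FaithfulnessVerdict:
    query_id: str
    evaluator_id: str
    verdict: str  # "Pass" | "Fail"

    def __post_init__(self) -> None:
        if self.verdict not in ("Pass", "Fail"):
            raise ValueError(f"verdict must be Pass/Fail, got {self.verdict!r}")

    @property
    def passed(self) -> bool:
        return self.verdict == "Pass"


_VERDICT_RE = re.compile(r"(?mi)^\s*(?:verdict\s*[:=]\s*)?(pass|fail)\s*\.?\s*$")


def parse_verdict(raw: str) -> str:
    match = _VERDICT_RE.search(raw or "")
    if not match:
        raise MalformedVerdictError(
            f"judge response not parseable as Pass/Fail: {raw!r}")
    return match.group(1).capitalize()


def evaluate_faithfulness(assessment: RagAssessment, bundle: ContextBundle,
                          judge_backend: Backend, template: PromptTemplate
                          ) -> FaithfulnessVerdict:
    """Binary judgment of justification-context alignment."""
    if assessment.query_id != bundle.query_id:
        raise IsolationError(
            f"verdict for {assessment.query_id} judged against "
            f"bundle {bundle.query_id}")
    prompt = render_prompt(template, {
        "gene": bundle.gene, "criterion": bundle.criterion,
        "context": bundle.format_context(),
        "rag_judgment": assessment.judgment.justification or assessment.raw_text,
    })
    request = BackendRequest(stage=Stage.FAITH_JUDGE, gene=bundle.gene,
                             criterion=bundle.criterion, prompt=prompt)
    response = judge_backend.complete(request)
    return FaithfulnessVerdict(query_id=bundle.query_id,
                               evaluator_id=response.backend_id,
                               verdict=parse_verdict(response.text))


def pass_rate(verdicts: Sequence[FaithfulnessVerdict]) -> float:
    """Share of Pass verdicts, as a one-decimal percentage."""
    if not verdicts:
        raise ConfigError("pass rate over zero verdicts")
    return pct(sum(v.passed for v in verdicts), len(verdicts))


# ---------------------------------------------------------------------------
# dual-evaluator agreement


@dataclass
class AgreementReport:
    n_instances: int
    overall_agreement: float  # percent, one decimal
    subgroup_agreements: dict[str, float] = field(default_factory=dict)


def _verdict_value(v: FaithfulnessVerdict | str) -> str:
    if isinstance(v, FaithfulnessVerdict):
        return v.verdict
    if v not in ("Pass", "Fail"):
        raise ValueError(f"verdict must be Pass/Fail, got {v!r}")
    return v


def dual_agreement(verdicts_a: Mapping[str, FaithfulnessVerdict | str],
                   verdicts_b: Mapping[str, FaithfulnessVerdict | str],
                   subgroup: Mapping[str, str] | None = None
                   ) -> AgreementReport:
    """Agreement between two evaluators over shared query ids.

    Overall agreement is the share of query ids with equal verdicts; a
    subgroup map (e.g. query id -> RAG score category, with High as the
    high-confidence group) yields per-label agreement alongside.
    """
    common = sorted(set(verdicts_a) & set(verdicts_b))
    if not common:
        raise ConfigError("no shared query ids between evaluators")
    agree = {qid: _verdict_value(verdicts_a[qid]) == _verdict_value(verdicts_b[qid])
             for qid in common}
    report = AgreementReport(
        n_instances=len(common),
        overall_agreement=pct(sum(agree.values()), len(common)),
    )
    if subgroup:
        labels = sorted({subgroup[qid] for qid in common if qid in subgroup})
        for label in labels:
            members = [qid for qid in common if subgroup.get(qid) == label]
            if members:
                report.subgroup_agreements[label] = pct(
                    sum(agree[qid] for qid in members), len(members))
    return report
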