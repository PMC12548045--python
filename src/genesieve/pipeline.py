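"""End-to-end orchestration of the three-stage prioritization pipeline.

Stage order: naive screen -> corpus index -> retrieval-augmented
evaluation -> faithfulness gate -> hybrid arbitration -> re-clustering
-> enrichment-based cluster selection -> PCA sub-clustering and
candidate selection -> benchmark evaluation.  A run manifest records
the filtering funnel (which must be monotone: candidates ⊆ PS3 ⊆ PS2 ⊆
PS1 ⊆ universe) plus config hash, seeds and component versions; with
the scripted backend, identical config and seed yield identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from typing import Mapping

import pandas as pd

from .benchmark import (
    BenchmarkSet,
    RecallReport,
    TopKReport,
    rank_correlation,
    recall_at_rule,
    topk_overlap,
    union_benchmark,
)
from .corpus import CorpusIndex, HashingEmbedder, build_index_from_records
from .criteria import CRITERIA, CRITERION_KEYWORDS, N_CRITERIA
from .errors import (
    AttributionError,
    ConfigError,
    MalformedResponseError,
    MalformedVerdictError,
    ScoreRangeError,
)
from .gateway import (
    Backend,
    BackendRequest,
    BackendResponse,
    DEFAULT_RUBRIC,
    ScriptedBackend,
    Stage,
    default_templates,
    parse_judgment,
    render_prompt,
)
from .hybrid import (
    HybridAssessment,
    arbitrate,
    method_agreement,
    ps2_weighted_scores,
    recluster_ps2,
    transition_table,
    TransitionTable,
)
from .rag import (
    ContextBundle,
    FaithfulnessVerdict,
    RagAssessment,
    dense_retrieve,
    evaluate_faithfulness,
    rag_assess,
    rerank,
)
from .screen import (
    AnyCriterionGE,
    CriterionScoreVector,
    PrioritySet,
    select_priority,
)
from .selection import (
    Ps3Selection,
    annotate_known_new,
    pca_project,
    profile_and_select,
    score_matrix,
    select_ps3,
    subcluster,
)
from .simulate import StudyConfig, SyntheticStudy, generate_study
from .utils import pct

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Per-stage parameters wrapped around the study config."""

    study: StudyConfig = field(default_factory=StudyConfig)
    ps1_threshold: int = 5
    k_quantiles_ps1: int = 5
    k_quantiles_ps2: int = 4
    retrieve_k: int = 25
    rerank_k: int = 10
    chunk_chars: int = 1500
    overlap_chars: int = 150
    embed_dim: int = 256
    pca_components: int = 2
    subcluster_k: int = 4
    enrichment_alpha: float = 0.05
    percentile_min: float = 0.8

    def __post_init__(self) -> None:
        for attr in ("k_quantiles_ps1", "k_quantiles_ps2", "retrieve_k",
                     "rerank_k", "subcluster_k", "pca_components"):
            if getattr(self, attr) < 1:
                raise ConfigError(f"{attr} must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    counts: dict[str, int] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)

    def check_consistency(self) -> None:
        c = self.counts
        checks = [
            c["rag_instances"] == c["ps1_genes"] * N_CRITERIA,
            c["faithfulness_pass"] <= c["rag_instances"],
            c["ps2_genes"] <= c["ps1_genes"],
            c["ps3_genes"] <= c["ps2_genes"],
            c["candidates"] <= c["ps3_genes"],
            c["ps1_genes"] <= c["universe_genes"],
        ]
        if not all(checks):
            raise ConfigError(f"inconsistent manifest counts: {c}")

    def to_json(self) -> str:
        return json.dumps({
            "config_hash": self.config_hash, "seed": self.seed,
            "counts": self.counts, "versions": self.versions,
        }, indent=2, sort_keys=True)


class CachingBackend:
    """Memoizing wrapper keyed by (stage, gene, criterion, prompt hash).

    A second identical run performs zero inner calls; editing a template
    changes the prompt hash and invalidates every affected entry.
    Corrupt cache entries are recomputed with a warning.
    """

    def __init__(self, inner: Backend,
                 store: dict[tuple[str, str, str, str], str] | None = None):
        self.inner = inner
        self.backend_id = inner.backend_id
        self.store = store if store is not None else {}
        self.hits = 0
        self.misses = 0

    @staticmethod
    def _key(request: BackendRequest) -> tuple[str, str, str, str]:
        prompt_hash = hashlib.sha256(request.prompt.encode()).hexdigest()
        return (Stage(request.stage).value, request.gene, request.criterion,
                prompt_hash)

    def complete(self, request: BackendRequest) -> BackendResponse:
        key = self._key(request)
        if key in self.store:
            cached = self.store[key]
            if isinstance(cached, str) and cached:
                self.hits += 1
                return BackendResponse(text=cached, backend_id=self.backend_id)
            warnings.warn(f"corrupt cache entry for {key[:3]}; recomputing",
                          stacklevel=2)
            del self.store[key]
        self.misses += 1
        response = self.inner.complete(request)
        self.store[key] = response.text
        return response


def cache_backend(backend: Backend, store: dict | None = None
                  ) -> CachingBackend:
    return CachingBackend(backend, store=store)


# ---------------------------------------------------------------------------
# stage helpers


def run_naive_screen(genes: list[str], backend: Backend, templates, rubric
                     ) -> tuple[list[CriterionScoreVector], list[dict]]:
    """Screen every gene across all criteria, tolerating malformed replies.

    Parse failures leave the criterion unobserved and are recorded in
    the returned failure log (the run manifest's raw material), never
    aborting the batch.
    """
    vectors: list[CriterionScoreVector] = []
    failures: list[dict] = []
    naive_template = templates["naive"]
    rubric_text = rubric.as_text()
    for gene in genes:
        scores: dict[str, int] = {}
        for criterion in CRITERIA:
            prompt = render_prompt(naive_template, {
                "gene": gene, "criterion": criterion, "rubric": rubric_text})
            response = backend.complete(BackendRequest(
                stage=Stage.NAIVE, gene=gene, criterion=criterion,
                prompt=prompt))
            try:
                judgment = parse_judgment(response.text, Stage.NAIVE,
                                          gene=gene, criterion=criterion)
                scores[criterion] = judgment.score
            except (MalformedResponseError, ScoreRangeError) as exc:
                failures.append({"gene": gene, "criterion": criterion,
                                 "error": type(exc).__name__,
                                 "detail": str(exc)})
        vectors.append(CriterionScoreVector(gene=gene, scores=scores))
    return vectors, failures


def retrieval_query(gene: str, criterion: str) -> str:
    return f"{gene} sepsis {CRITERION_KEYWORDS[criterion]}"


@dataclass
class RagInstance:
    bundle: ContextBundle
    assessment: RagAssessment
    verdict: FaithfulnessVerdict | None
    error: str | None = None

    @property
    def passed(self) -> bool:
        return (self.verdict is not None and self.verdict.passed
                and self.assessment.ok)


def run_rag_stage(ps1: PrioritySet, index: CorpusIndex, embedder,
                  rag_backend: Backend, judge_backend: Backend,
                  templates, rubric, retrieve_k: int = 25,
                  rerank_k: int = 10) -> list[RagInstance]:
    """Retrieval, grounded scoring and faithfulness gating for PS1 genes."""
    instances: list[RagInstance] = []
    for gene in ps1.members:
        for criterion in CRITERIA:
            hits = dense_retrieve(retrieval_query(gene, criterion), index,
                                  embedder, k=retrieve_k)
            hits = rerank(retrieval_query(gene, criterion), hits, k=rerank_k)
            bundle = ContextBundle(gene=gene, criterion=criterion, hits=hits)
            assessment = rag_assess(gene, criterion, bundle, rag_backend,
                                    templates["rag_synth"], rubric)
            if not assessment.ok:
                instances.append(RagInstance(
                    bundle=bundle, assessment=assessment, verdict=None,
                    error="attribution"))
                continue
            try:
                verdict = evaluate_faithfulness(assessment, bundle,
                                                judge_backend,
                                                templates["faith_judge"])
            except MalformedVerdictError:
                instances.append(RagInstance(
                    bundle=bundle, assessment=assessment, verdict=None,
                    error="malformed_verdict"))
                continue
            instances.append(RagInstance(bundle=bundle, assessment=assessment,
                                         verdict=verdict))
    return instances


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineResult:
    config: PipelineConfig
    study: SyntheticStudy
    vectors: list[CriterionScoreVector]
    naive_failures: list[dict]
    ps1: PrioritySet
    index_size: int
    rag_instances: list[RagInstance]
    pass_rate_pct: float
    hybrid_assessments: list[HybridAssessment]
    ps2: PrioritySet
    transitions: TransitionTable
    ps3_selection: Ps3Selection
    candidates: list[str]
    candidate_labels: dict[str, str]
    profiles: list
    recall_reports: dict[str, RecallReport]
    topk_report: TopKReport
    spearman: tuple[float, float]
    manifest: RunManifest

    @property
    def ps3(self) -> PrioritySet:
        return self.ps3_selection.priority_set


def run_pipeline(config: PipelineConfig | None = None,
                 seed: int | None = None) -> PipelineResult:
    """Execute the full synthetic study end to end.

    With the scripted backend the run is a pure function of (config,
    seed); the returned manifest's funnel counts are consistency-checked
    before returning.
    """
    if config is None:
        config = PipelineConfig()
    if seed is not None:
        from dataclasses import replace
        config = replace(config, study=replace(config.study, seed=seed))

    study = generate_study(config.study)
    templates = default_templates()
    rubric = DEFAULT_RUBRIC
    naive_backend = ScriptedBackend(study.scripts.naive, backend_id="naive-llm")
    rag_backend = ScriptedBackend(study.scripts.rag_synth, backend_id="rag-llm")
    judge_backend = ScriptedBackend(study.scripts.faith_judge,
                                    backend_id="judge-llm")
    arbiter_backend = ScriptedBackend(study.scripts.hybrid_arbiter,
                                      backend_id="arbiter-llm")

    # stage 1: naive screen
    vectors, failures = run_naive_screen(study.universe.genes, naive_backend,
                                         templates, rubric)
    ps1 = select_priority(vectors, AnyCriterionGE(config.ps1_threshold),
                          name="PS1")
    ps1.stratify(config.k_quantiles_ps1)
    vector_map = {v.gene: v for v in vectors}

    # stage 2: knowledge base + RAG + faithfulness
    embedder = HashingEmbedder(dim=config.embed_dim)
    from .corpus import ingest_corpus
    kept, _report = ingest_corpus(study.corpus,
                                  percentile_min=config.percentile_min,
                                  apply_filter=True)
    index = build_index_from_records(kept, embedder,
                                     lexicon=study.universe.genes,
                                     chunk_chars=config.chunk_chars,
                                     overlap_chars=config.overlap_chars)
    rag_instances = run_rag_stage(ps1, index, embedder, rag_backend,
                                  judge_backend, templates, rubric,
                                  retrieve_k=config.retrieve_k,
                                  rerank_k=config.rerank_k)
    n_pass = sum(inst.passed for inst in rag_instances)
    rate = pct(n_pass, len(rag_instances)) if rag_instances else 0.0

    # stage 2b: hybrid arbitration over pass instances
    hybrid_assessments: list[HybridAssessment] = []
    for inst in rag_instances:
        if not inst.passed:
            continue
        gene, criterion = inst.bundle.gene, inst.bundle.criterion
        naive_score = vector_map[gene].scores.get(criterion)
        if naive_score is None:
            # naive reply was malformed; arbitration treats prior as absent
            naive_score = 0
        from .gateway import ScoredJudgment
        naive_judgment = ScoredJudgment(gene=gene, criterion=criterion,
                                        score=naive_score)
        hybrid_assessments.append(arbitrate(
            naive_judgment, inst.assessment, inst.bundle, arbiter_backend,
            templates, rubric, inst.verdict))

    ps2_scores = ps2_weighted_scores(hybrid_assessments)
    ps2 = recluster_ps2(ps2_scores, k=config.k_quantiles_ps2, name="PS2")
    transitions = transition_table(ps1, ps2)

    # stage 3: enrichment-selected cluster, PCA sub-clustering, candidates
    ps3_selection = select_ps3(ps2, study.collection, study.universe.genes,
                               alpha=config.enrichment_alpha)
    ps3 = ps3_selection.priority_set
    matrix = score_matrix(
        [a for a in hybrid_assessments if a.gene in set(ps3.members)],
        genes=ps3.members)
    pca = pca_project(matrix, n_components=min(config.pca_components,
                                               matrix.shape[1]))
    k_eff = min(config.subcluster_k, matrix.shape[0])
    assignments = subcluster(pca.coordinates, k=k_eff,
                             seed=config.study.seed)
    profiles, optimal = profile_and_select(matrix, assignments)
    candidates = [g for g in ps3.members
                  if int(assignments.loc[g]) == optimal]
    evidence = union_benchmark([study.benchmark_a, study.benchmark_b]).genes
    candidate_labels = annotate_known_new(candidates, evidence)

    # benchmark evaluation of the naive screen
    recall_reports = {}
    for bset in (study.benchmark_a, study.benchmark_b):
        recall_reports[bset.name] = recall_at_rule(vector_map, bset)
    combined = union_benchmark([study.benchmark_a, study.benchmark_b])
    recall_reports["combined"] = recall_at_rule(vector_map, combined)

    from .screen import weighted_score
    naive_weighted = {v.gene: weighted_score(v).value for v in vectors}
    reference_ranking = sorted(study.pubcounts,
                               key=lambda g: (-study.pubcounts[g], g))
    topk = topk_overlap(naive_weighted, reference_ranking,
                        reference_name="pubcounts")
    spearman = rank_correlation(naive_weighted,
                                {g: float(c)
                                 for g, c in study.pubcounts.items()})

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.study.seed,
        counts={
            "universe_genes": len(study.universe.genes),
            "naive_failures": len(failures),
            "ps1_genes": len(ps1),
            "corpus_documents": len(kept),
            "index_chunks": len(index),
            "rag_instances": len(rag_instances),
            "faithfulness_pass": n_pass,
            "ps2_genes": len(ps2),
            "ps3_genes": len(ps3),
            "candidates": len(candidates),
        },
        versions={
            "embedder": embedder.embedder_id,
            "templates": hashlib.sha256(
                "".join(t.body for t in templates.values()).encode()
            ).hexdigest()[:12],
        })
    manifest.check_consistency()

    return PipelineResult(
        config=config, study=study, vectors=vectors, naive_failures=failures,
        ps1=ps1, index_size=len(index), rag_instances=rag_instances,
        pass_rate_pct=rate, hybrid_assessments=hybrid_assessments, ps2=ps2,
        transitions=transitions, ps3_selection=ps3_selection,
        candidates=candidates, candidate_labels=candidate_labels,
        profiles=profiles, recall_reports=recall_reports, topk_report=topk,
        spearman=spearman, manifest=manifest)


def naive_rag_hybrid_agreement(result: PipelineResult) -> pd.DataFrame:
    """Pairwise category agreement between the three scoring methods.

    Labels are gene-level confidence bins of the weighted scores, over
    genes present in all methods.
    """
    from .screen import bin_score as _bin, weighted_score

    def categorize(value: float) -> str:
        return _bin(round(value * 10))

    naive = {v.gene: categorize(weighted_score(v).value)
             for v in result.vectors}
    rag_scores: dict[str, dict[str, int]] = {}
    for inst in result.rag_instances:
        rag_scores.setdefault(inst.bundle.gene, {})[
            inst.bundle.criterion] = inst.assessment.judgment.score
    rag = {gene: categorize(weighted_score(
        CriterionScoreVector(gene=gene, scores=scores)).value)
        for gene, scores in rag_scores.items()}
    hybrid = {gene: categorize(ws.value)
              for gene, ws in ps2_weighted_scores(
                  result.hybrid_assessments).items()}
    return method_agreement({"naive": naive, "rag": rag, "hybrid": hybrid})
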