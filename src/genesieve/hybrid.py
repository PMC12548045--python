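"""Stage 2b — Chain-of-Thought hybrid arbitration and re-clustering.

Passing instances are synthesized by three structured roles executed as
three sequential backend calls — a critic of the naive judgment, an
analyst of the retrieved evidence, and a final arbiter that emits a
High/Medium/Low decision, a recalibrated 0-10 score and an explanation,
with explicit preference for strong retrieved evidence.  The decision
label is re-derived from the recalibrated score via the standard
confidence bins; a disagreement with the backend's stated label is
logged as a consistency warning, not an error.

Gene-level weighted scores are then recomputed over pass instances only
(fixed denominator 8), genes with zero passing instances drop out, the
survivors are re-stratified into quantile clusters, and every gene's
cluster transition is accounted in a conservation-checked table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    ConfigError,
    GateViolationError,
    IsolationError,
    ProvenanceError,
)
from .gateway import (
    Backend,
    BackendRequest,
    PromptTemplate,
    ScoreRubric,
    ScoredJudgment,
    Stage,
    format_judgment,
    parse_judgment,
    render_prompt,
)
from .rag import ContextBundle, FaithfulnessVerdict, RagAssessment
from .screen import (
    CriterionScoreVector,
    PrioritySet,
    WeightedScore,
    bin_score,
    order_by_score,
    stratify_quantiles,
    weighted_score,
)
from .utils import pct

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HybridAssessment:
    gene: str
    criterion: str
    decision: str  # High | Medium | Low, consistent with recalibrated_score
    recalibrated_score: int
    explanation: str
    naive_score: int
    rag_score: int

    def __post_init__(self) -> None:
        if not 0 <= self.recalibrated_score <= 10:
            raise ValueError(f"recalibrated score {self.recalibrated_score}")
        if self.decision != bin_score(self.recalibrated_score):
            raise ValueError("decision inconsistent with recalibrated score")


def arbitrate(naive: ScoredJudgment, rag: RagAssessment | ScoredJudgment,
              bundle: ContextBundle, backend: Backend,
              templates: Mapping[str, PromptTemplate], rubric: ScoreRubric,
              verdict: FaithfulnessVerdict) -> HybridAssessment:
    """Run the critic/analyst/arbiter role sequence for one pass instance.

    Fail-verdict instances are a gate violation; the faithfulness gate
    is absolute.  Only the arbiter's structured output is parsed — the
    critic and analyst calls provide the reasoning scaffold.
    """
    rag_judgment = rag.judgment if isinstance(rag, RagAssessment) else rag
    if (naive.gene, naive.criterion) != (rag_judgment.gene, rag_judgment.criterion):
        raise IsolationError(
            f"naive {naive.gene}|{naive.criterion} vs "
            f"rag {rag_judgment.gene}|{rag_judgment.criterion}")
    if (bundle.gene, bundle.criterion) != (naive.gene, naive.criterion):
        raise IsolationError(
            f"bundle {bundle.query_id} used for {naive.gene}|{naive.criterion}")
    if verdict.query_id != bundle.query_id:
        raise IsolationError(
            f"verdict {verdict.query_id} used for bundle {bundle.query_id}")
    if not verdict.passed:
        raise GateViolationError(
            f"{bundle.query_id}: Fail-verdict instance reached arbitration")

    gene, criterion = naive.gene, naive.criterion
    naive_text = format_judgment(naive)
    rag_text = format_judgment(rag_judgment)
    context = bundle.format_context()

    for name, bindings in (
        ("hybrid_critic",
         {"gene": gene, "criterion": criterion, "naive_judgment": naive_text}),
        ("hybrid_analyst",
         {"gene": gene, "criterion": criterion, "context": context,
          "rag_judgment": rag_text}),
    ):
        prompt = render_prompt(templates[name], bindings)
        backend.complete(BackendRequest(stage=Stage.HYBRID_ARBITER, gene=gene,
                                        criterion=criterion, prompt=prompt))

    arbiter_prompt = render_prompt(templates["hybrid_arbiter"], {
        "gene": gene, "criterion": criterion, "rubric": rubric.as_text(),
        "naive_judgment": naive_text, "rag_judgment": rag_text,
        "context": context,
    })
    response = backend.complete(BackendRequest(
        stage=Stage.HYBRID_ARBITER, gene=gene, criterion=criterion,
        prompt=arbiter_prompt))
    parsed = parse_judgment(response.text, Stage.HYBRID_ARBITER,
                            gene=gene, criterion=criterion)
    derived = bin_score(parsed.score)

    from .gateway import _field  # structured-field helper shared with parsing
    stated = _field(response.text, "decision")
    if stated and stated.strip().capitalize() != derived:
        logger.warning("%s: arbiter decision %r inconsistent with score %d (%s)",
                       bundle.query_id, stated, parsed.score, derived)
    explanation = _field(response.text, "explanation") or parsed.justification
    return HybridAssessment(gene=gene, criterion=criterion, decision=derived,
                            recalibrated_score=parsed.score,
                            explanation=explanation,
                            naive_score=naive.score,
                            rag_score=rag_judgment.score)


def ps2_weighted_scores(assessments: Iterable[HybridAssessment]
                        ) -> dict[str, WeightedScore]:
    """Gene-level weighted scores over pass instances only.

    Each gene's vector holds its passing criteria's recalibrated scores;
    the fixed denominator 8 means missing (failed/absent) criteria pull
    the weighted score down.  Genes with zero pass instances simply do
    not appear — they are dropped from the downstream priority set.
    """
    per_gene: dict[str, dict[str, int]] = {}
    for assessment in assessments:
        scores = per_gene.setdefault(assessment.gene, {})
        if assessment.criterion in scores:
            raise ConfigError(
                f"duplicate assessment for "
                f"{assessment.gene}|{assessment.criterion}")
        scores[assessment.criterion] = assessment.recalibrated_score
    return {gene: weighted_score(CriterionScoreVector(gene=gene, scores=scores))
            for gene, scores in per_gene.items()}


def recluster_ps2(scores: Mapping[str, WeightedScore | float], k: int = 4,
                  name: str = "PS2") -> PrioritySet:
    """Quantile re-stratification of literature-validated genes."""
    values = {gene: (ws.value if isinstance(ws, WeightedScore) else float(ws))
              for gene, ws in scores.items()}
    members = order_by_score(values)
    ps = PrioritySet(name=name, members=members, scores=values,
                     provenance={gene: {"admitted": True,
                                        "rule": "pass_instances >= 1"}
                                 for gene in members})
    ps.cluster = stratify_quantiles(values, k)
    return ps


@dataclass
class TransitionTable:
    """Cluster membership flow between two priority sets.

    Every upstream gene lands in exactly one (source, target) cell;
    genes absent downstream collect in the 'dropped' column, so row sums
    reproduce the upstream cluster sizes and the total inflow equals the
    upstream set size.
    """

    counts: dict[tuple[str, str], int]
    source_clusters: list[str]
    target_clusters: list[str]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(0, index=self.source_clusters,
                             columns=self.target_clusters, dtype=int)
        for (src, dst), n in self.counts.items():
            frame.loc[src, dst] = n
        return frame


def transition_table(ps1: PrioritySet, ps2: PrioritySet) -> TransitionTable:
    """Cross-tabulate cluster membership between consecutive stages."""
    ps1_members = set(ps1.members)
    stray = [g for g in ps2.members if g not in ps1_members]
    if stray:
        raise ProvenanceError(
            f"{ps2.name} genes absent from {ps1.name}: {sorted(stray)[:5]}")
    counts: dict[tuple[str, str], int] = {}
    for gene in ps1.members:
        src = ps1.cluster.get(gene, "unclustered")
        dst = ps2.cluster.get(gene, "dropped") if gene in ps2 else "dropped"
        counts[(src, dst)] = counts.get((src, dst), 0) + 1
    def _qsort(labels: set[str]) -> list[str]:
        return sorted(labels, key=lambda s: (s == "dropped", s))
    sources = _qsort({src for src, _ in counts})
    targets = _qsort({dst for _, dst in counts})
    return TransitionTable(counts=counts, source_clusters=sources,
                           target_clusters=targets)


def method_agreement(labelings: Mapping[str, Mapping[str, str]]) -> pd.DataFrame:
    """Pairwise % agreement between named labelings (clusters/categories).

    Entry (i, j) is the share of genes common to methods i and j that
    carry equal labels, x100 at one decimal; the matrix is symmetric
    with 100 on the diagonal.
    """
    names = list(labelings)
    if len(names) < 2:
        raise ConfigError("method agreement needs >= 2 methods")
    matrix = pd.DataFrame(100.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            common = set(labelings[a]) & set(labelings[b])
            if not common:
                raise ConfigError(f"no shared genes between {a!r} and {b!r}")
            agree = sum(labelings[a][g] == labelings[b][g] for g in common)
            value = pct(agree, len(common))
            matrix.loc[a, b] = value
            matrix.loc[b, a] = value
    return matrix
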