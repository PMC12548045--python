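"""Stage 1 — naive multi-criteria screening.

Each gene carries up to eight integer criterion scores (0-10).  Scores
are binned into confidence levels — High (>=7), Medium (4-6), Low (<=3)
— and aggregated into a confidence-weighted score

    W = 1.0 * p_high + 0.7 * p_med + 0.3 * p_low

where each proportion divides the bin count by the fixed number of
criteria (8), not by the number observed.  Unobserved criteria (e.g.
malformed model responses) therefore contribute zero weight, which is
what makes the 0.0 floor attainable: a fully observed all-Low gene
scores 0.3, an unobserved gene scores 0.0, and a fully observed
all-High gene scores 1.0.

Genes passing a selection rule (default: any criterion >= 5) form a
priority set, which is then stratified into quantile clusters Q1..Qk
(Q1 = highest scores, ties always co-assigned).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .criteria import CRITERIA, N_CRITERIA
from .errors import ConfigError, ScoreRangeError

BIN_WEIGHTS = {"High": 1.0, "Medium": 0.7, "Low": 0.3}


def bin_score(score: int) -> str:
    """Map an integer criterion score to its confidence bin."""
    if not 0 <= score <= 10:
        raise ScoreRangeError(f"score {score} outside 0-10")
    if score >= 7:
        return "High"
    if score >= 4:
        return "Medium"
    return "Low"


@dataclass(frozen=True)
class CriterionScoreVector:
    """A gene's (possibly partially observed) criterion scores."""

    gene: str
    scores: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for criterion, score in self.scores.items():
            if criterion not in CRITERIA:
                raise ValueError(f"unknown criterion: {criterion!r}")
            if not 0 <= score <= 10:
                raise ScoreRangeError(
                    f"{self.gene}/{criterion}: score {score} outside 0-10")

    @property
    def n_observed(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class WeightedScore:
    gene: str
    p_high: float
    p_med: float
    p_low: float
    value: float
    n_observed: int


def weighted_score(vector: CriterionScoreVector,
                   denominator: int = N_CRITERIA) -> WeightedScore:
    """Confidence-weighted aggregate of a criterion score vector.

    ``denominator`` is the number of criteria in the scheme (8); it must
    be at least the number of observed scores.  An empty vector yields
    value 0.0 with ``n_observed`` 0 — not an error.
    """
    if denominator < vector.n_observed:
        raise ConfigError(
            f"denominator {denominator} < observed scores {vector.n_observed}")
    counts = {"High": 0, "Medium": 0, "Low": 0}
    for score in vector.scores.values():
        counts[bin_score(score)] += 1
    p_high = counts["High"] / denominator
    p_med = counts["Medium"] / denominator
    p_low = counts["Low"] / denominator
    value = (BIN_WEIGHTS["High"] * p_high
             + BIN_WEIGHTS["Medium"] * p_med
             + BIN_WEIGHTS["Low"] * p_low)
    return WeightedScore(gene=vector.gene, p_high=p_high, p_med=p_med,
                         p_low=p_low, value=value,
                         n_observed=vector.n_observed)


# ---------------------------------------------------------------------------
# selection rules


@dataclass(frozen=True)
class AnyCriterionGE:
    """Admit a gene if any single criterion score reaches ``threshold``."""

    threshold: int = 5

    def evaluate(self, vector: CriterionScoreVector,
                 ws: WeightedScore) -> tuple[bool, dict]:
        for criterion in CRITERIA:
            score = vector.scores.get(criterion)
            if score is not None and score >= self.threshold:
                return True, {"rule": repr(self), "criterion": criterion,
                              "score": score}
        return False, {"rule": repr(self),
                       "reason": f"no criterion >= {self.threshold}"}


@dataclass(frozen=True)
class WeightedGE:
    """Admit a gene if its weighted score reaches ``threshold``."""

    threshold: float

    def evaluate(self, vector: CriterionScoreVector,
                 ws: WeightedScore) -> tuple[bool, dict]:
        if ws.value >= self.threshold:
            return True, {"rule": repr(self), "weighted_score": ws.value}
        return False, {"rule": repr(self),
                       "reason": f"weighted score {ws.value:.3f} < {self.threshold}"}


@dataclass(frozen=True)
class ConjunctionRule:
    """Admit only if every sub-rule admits."""

    rules: tuple[object, ...]

    def evaluate(self, vector: CriterionScoreVector,
                 ws: WeightedScore) -> tuple[bool, dict]:
        details = []
        for rule in self.rules:
            ok, detail = rule.evaluate(vector, ws)
            details.append(detail)
            if not ok:
                return False, {"rule": repr(self), "failed": detail}
        return True, {"rule": repr(self), "parts": details}


def rule_from_config(mapping: Mapping[str, object]) -> object:
    """Build a selection rule from a config mapping.

    Recognized keys: ``any_criterion_ge``, ``weighted_ge``, ``all_of``.
    """
    if len(mapping) != 1:
        raise ConfigError(
            f"selection rule must have exactly one key: {mapping}")
    (name, value), = mapping.items()
    if name == "any_criterion_ge":
        return AnyCriterionGE(int(value))  # type: ignore[arg-type]
    if name == "weighted_ge":
        return WeightedGE(float(value))  # type: ignore[arg-type]
    if name == "all_of":
        return ConjunctionRule(tuple(rule_from_config(s) for s in value))  # type: ignore
    raise ConfigError(f"unknown selection rule: {name!r}")


# ---------------------------------------------------------------------------
# priority sets


@dataclass
class PrioritySet:
    """A named, ordered gene set with cluster labels and provenance.

    Members are ordered by weighted score descending, gene symbol
    ascending on ties.  ``provenance`` records, per screened gene, the
    rule decision that admitted or excluded it.
    """

    name: str
    members: list[str]
    scores: dict[str, float]
    cluster: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"{self.name}: duplicate members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)

    def stratify(self, k: int) -> None:
        """Assign quantile cluster labels Q1..Qk to all members."""
        self.cluster = stratify_quantiles(
            {g: self.scores[g] for g in self.members}, k)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, gene in enumerate(self.members, start=1):
            rows.append({
                "symbol": gene,
                "rank": rank,
                "weighted_score": self.scores[gene],
                "cluster": self.cluster.get(gene, ""),
                "provenance": json.dumps(self.provenance.get(gene, {})),
            })
        return pd.DataFrame(rows)


def order_by_score(scores: Mapping[str, float]) -> list[str]:
    """Score descending, symbol ascending — the package-wide tie-break."""
    return sorted(scores, key=lambda g: (-scores[g], g))


def select_priority(vectors: Iterable[CriterionScoreVector],
                    rule: object | None = None,
                    name: str = "PS1",
                    denominator: int = N_CRITERIA) -> PrioritySet:
    """Apply a selection rule to screened genes and build a priority set.

    Provenance records the triggering criterion/value for every admitted
    gene and the failure mode for every excluded gene.
    """
    if rule is None:
        rule = AnyCriterionGE(5)
    if not hasattr(rule, "evaluate"):
        raise ConfigError(f"not a selection rule: {rule!r}")
    admitted: dict[str, float] = {}
    provenance: dict[str, dict] = {}
    for vector in vectors:
        ws = weighted_score(vector, denominator=denominator)
        ok, detail = rule.evaluate(vector, ws)
        detail["admitted"] = ok
        provenance[vector.gene] = detail
        if ok:
            admitted[vector.gene] = ws.value
    members = order_by_score(admitted)
    return PrioritySet(name=name, members=members, scores=admitted,
                       provenance=provenance)


def stratify_quantiles(scores: Mapping[str, float], k: int) -> dict[str, str]:
    """Partition genes into quantile clusters Q1 (top) .. Qk (bottom).

    Bin boundaries sit at the k-quantiles of the score distribution and
    equal scores always share a bin, so bin sizes can be uneven and
    heavy ties can leave fewer than k non-empty bins (duplicate quantile
    edges are merged).  The assignment depends only on the score values,
    hence is invariant to input order.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    if not scores:
        return {}
    series = pd.Series(dict(scores), dtype=float)
    if k == 1 or series.nunique() == 1:
        return {gene: "Q1" for gene in scores}
    codes = pd.qcut(series, q=k, labels=False, duplicates="drop")
    n_bins = int(codes.max()) + 1
    # qcut code 0 = lowest scores; relabel so Q1 = top bin
    return {gene: f"Q{n_bins - int(code)}" for gene, code in codes.items()}


ScoreMap = Mapping[str, float]
RuleEvaluator = Callable[[CriterionScoreVector, WeightedScore],
                         tuple[bool, dict]]


def vectors_to_frame(vectors: Sequence[CriterionScoreVector],
                     denominator: int = N_CRITERIA) -> pd.DataFrame:
    """Gene x criteria score table plus weighted score and bin proportions."""
    rows = []
    for vector in vectors:
        ws = weighted_score(vector, denominator=denominator)
        row: dict[str, object] = {"symbol": vector.gene}
        for criterion in CRITERIA:
            row[criterion] = vector.scores.get(criterion, pd.NA)
        row["weighted_score"] = ws.value
        row["p_high"] = ws.p_high
        row["p_med"] = ws.p_med
        row["p_low"] = ws.p_low
        row["n_observed"] = ws.n_observed
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_vectors(frame: pd.DataFrame) -> list[CriterionScoreVector]:
    """Inverse of :func:`vectors_to_frame` (score columns only)."""
    vectors = []
    for _, row in frame.iterrows():
        scores = {}
        for criterion in CRITERIA:
            value = row.get(criterion)
            if pd.notna(value):
                scores[criterion] = int(value)
        vectors.append(CriterionScoreVector(gene=str(row["symbol"]), scores=scores))
    return vectors
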