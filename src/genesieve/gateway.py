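"""Backend contract for all model calls.

Every model interaction in the pipeline — naive scoring, retrieval-
augmented synthesis, faithfulness judging and hybrid arbitration — goes
through a :class:`Backend` implementing a single ``complete`` method.
The default backend is a deterministic :class:`ScriptedBackend` that
replays canned responses keyed by ``(stage, gene, criterion)``, which
makes an entire pipeline run a pure function of its inputs, config and
seed.  Production adapters (OpenAI-compatible chat endpoints, local
model servers) can implement the same contract; they are deliberately
outside the tested path.

Prompt templates are editable text assets with ``{placeholder}`` syntax;
the scientific wording is configurable while the placeholder contract
per stage is fixed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Protocol

from .criteria import CRITERIA
from .errors import (
    MalformedResponseError,
    ScoreRangeError,
    ScriptLookupError,
    UnboundPlaceholderError,
)


class Stage(str, Enum):
    """The four model-call stages of the pipeline."""

    NAIVE = "naive"
    RAG_SYNTH = "rag_synth"
    FAITH_JUDGE = "faith_judge"
    HYBRID_ARBITER = "hybrid_arbiter"


#: Placeholders that must be bound when rendering each stage's canonical
#: template.  Templates may declare their own requirement set (the hybrid
#: critic/analyst role prompts do).
REQUIRED_PLACEHOLDERS: dict[Stage, frozenset[str]] = {
    Stage.NAIVE: frozenset({"gene", "criterion", "rubric"}),
    Stage.RAG_SYNTH: frozenset({"gene", "criterion", "rubric", "context"}),
    Stage.FAITH_JUDGE: frozenset({"gene", "criterion", "context", "rag_judgment"}),
    Stage.HYBRID_ARBITER: frozenset(
        {"gene", "criterion", "rubric", "naive_judgment", "rag_judgment"}
    ),
}

#: Default sampling temperature per stage; retrieval-augmented synthesis
#: runs near-deterministic at 0.1.
DEFAULT_TEMPERATURE: dict[Stage, float] = {
    Stage.NAIVE: 0.1,
    Stage.RAG_SYNTH: 0.1,
    Stage.FAITH_JUDGE: 0.0,
    Stage.HYBRID_ARBITER: 0.1,
}

_PLACEHOLDER_RE = re.compile(r"\{([a-z_]+)\}")


@dataclass(frozen=True)
class PromptTemplate:
    """A prompt body with named ``{placeholder}`` slots.

    ``required`` defaults to the stage's canonical placeholder set.
    """

    stage: Stage
    body: str
    name: str = ""
    required: frozenset[str] | None = None

    @property
    def required_placeholders(self) -> frozenset[str]:
        if self.required is not None:
            return self.required
        return REQUIRED_PLACEHOLDERS[self.stage]

    def render(self, bindings: Mapping[str, str]) -> str:
        return render_prompt(self, bindings)


def render_prompt(template: PromptTemplate, bindings: Mapping[str, str]) -> str:
    """Substitute placeholders, refusing to leave any marker unbound."""
    for name in sorted(template.required_placeholders):
        if name not in bindings:
            raise UnboundPlaceholderError(name)

    def _sub(match: re.Match[str]) -> str:
        name = match.group(1)
        if name not in bindings:
            raise UnboundPlaceholderError(name)
        return str(bindings[name])

    rendered = _PLACEHOLDER_RE.sub(_sub, template.body)
    leftover = _PLACEHOLDER_RE.search(rendered)
    if leftover:  # a binding value itself introduced a marker
        raise UnboundPlaceholderError(leftover.group(1))
    return rendered


def load_template(name: str, stage: Stage,
                  required: frozenset[str] | None = None,
                  directory: str | Path | None = None) -> PromptTemplate:
    """Load a template text asset by file stem.

    ``directory`` overrides the packaged defaults, letting users swap in
    their own prompt wording without touching code.
    """
    if directory is not None:
        body = Path(directory, f"{name}.txt").read_text()
    else:
        body = (resources.files("genesieve") / "templates" / f"{name}.txt").read_text()
    return PromptTemplate(stage=stage, body=body, name=name, required=required)


def default_templates(directory: str | Path | None = None) -> dict[str, PromptTemplate]:
    """The six shipped templates, keyed by name."""
    return {
        "naive": load_template("naive", Stage.NAIVE, directory=directory),
        "rag_synth": load_template("rag_synth", Stage.RAG_SYNTH, directory=directory),
        "faith_judge": load_template("faith_judge", Stage.FAITH_JUDGE,
                                     directory=directory),
        "hybrid_critic": load_template(
            "hybrid_critic", Stage.HYBRID_ARBITER,
            required=frozenset({"gene", "criterion", "naive_judgment"}),
            directory=directory),
        "hybrid_analyst": load_template(
            "hybrid_analyst", Stage.HYBRID_ARBITER,
            required=frozenset({"gene", "criterion", "context", "rag_judgment"}),
            directory=directory),
        "hybrid_arbiter": load_template("hybrid_arbiter", Stage.HYBRID_ARBITER,
                                        directory=directory),
    }


# ---------------------------------------------------------------------------
# scoring rubric


@dataclass(frozen=True)
class RubricBand:
    low: int
    high: int
    label: str


@dataclass(frozen=True)
class ScoreRubric:
    """Ordered score bands covering 0-10 without gaps."""

    bands: tuple[RubricBand, ...]

    def __post_init__(self) -> None:
        covered = []
        for band in self.bands:
            covered.extend(range(band.low, band.high + 1))
        if covered != list(range(11)):
            raise ValueError("rubric bands must cover 0-10 exactly once, in order")

    def band_for(self, score: int) -> RubricBand:
        if not 0 <= score <= 10:
            raise ScoreRangeError(f"score {score} outside 0-10")
        for band in self.bands:
            if band.low <= score <= band.high:
                return band
        raise AssertionError("unreachable: bands cover 0-10")

    def as_text(self) -> str:
        lines = []
        for band in self.bands:
            span = str(band.low) if band.low == band.high else f"{band.low}-{band.high}"
            lines.append(f"{span} = {band.label}")
        return "\n".join(lines)


DEFAULT_RUBRIC = ScoreRubric(bands=(
    RubricBand(0, 0, "no evidence"),
    RubricBand(1, 3, "very limited evidence"),
    RubricBand(4, 6, "some evidence requiring validation"),
    RubricBand(7, 8, "good evidence"),
    RubricBand(9, 10, "strong evidence"),
))


# ---------------------------------------------------------------------------
# requests / responses / judgments


@dataclass(frozen=True)
class BackendRequest:
    stage: Stage
    gene: str
    criterion: str
    prompt: str
    temperature: float | None = None

    def __post_init__(self) -> None:
        if self.temperature is None:
            object.__setattr__(
                self, "temperature", DEFAULT_TEMPERATURE[Stage(self.stage)]
            )


@dataclass(frozen=True)
class BackendResponse:
    text: str
    backend_id: str
    usage: Mapping[str, int] | None = None


class Backend(Protocol):
    """Anything that can answer a :class:`BackendRequest`."""

    backend_id: str

    def complete(self, request: BackendRequest) -> BackendResponse:
        ...


@dataclass(frozen=True)
class ScoredJudgment:
    """One parsed model judgment for one (gene, criterion)."""

    gene: str
    criterion: str
    score: int
    official_name: str = ""
    summary: str = ""
    justification: str = ""
    cited_source_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 10:
            raise ScoreRangeError(f"score {self.score} outside 0-10")
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion: {self.criterion!r}")


_FIELD_RES = {
    name: re.compile(rf"^[ \t]*{name}[ \t]*[:=][ \t]*(.*?)[ \t]*$", re.M | re.I)
    for name in ("official_name", "summary", "score", "justification",
                 "sources", "decision", "explanation")
}


def _field(raw: str, name: str) -> str | None:
    match = _FIELD_RES[name].search(raw)
    return match.group(1) if match else None


def parse_judgment(raw: str, stage: Stage, *, gene: str, criterion: str
                   ) -> ScoredJudgment:
    """Parse a structured ``key: value`` response into a judgment.

    The parse is total: the same input always yields the same output (or
    the same error).  A missing score field raises
    :class:`MalformedResponseError`; a score outside 0-10 raises
    :class:`ScoreRangeError`.
    """
    if not raw or not raw.strip():
        raise MalformedResponseError("empty response")
    score_text = _field(raw, "score")
    if score_text is None:
        raise MalformedResponseError("response has no 'score' field")
    try:
        score = int(score_text)
    except ValueError as exc:
        raise MalformedResponseError(
            f"score field not an integer: {score_text!r}") from exc
    if not 0 <= score <= 10:
        raise ScoreRangeError(f"score {score} outside 0-10")

    sources: tuple[str, ...] = ()
    if Stage(stage) in (Stage.RAG_SYNTH, Stage.HYBRID_ARBITER):
        src_text = _field(raw, "sources")
        if src_text:
            sources = tuple(s.strip() for s in src_text.split(",") if s.strip())
    return ScoredJudgment(
        gene=gene,
        criterion=criterion,
        score=score,
        official_name=_field(raw, "official_name") or "",
        summary=_field(raw, "summary") or "",
        justification=_field(raw, "justification") or "",
        cited_source_ids=sources,
    )


def format_judgment(judgment: ScoredJudgment) -> str:
    """Serialize a judgment back into the structured response format.

    Round-trip guarantee: ``parse_judgment(format_judgment(j), ...)``
    recovers an equal judgment.  Used by the synthetic fixture writer.
    """
    lines = [
        f"official_name: {judgment.official_name}",
        f"summary: {judgment.summary}",
        f"score: {judgment.score}",
        f"justification: {judgment.justification}",
    ]
    if judgment.cited_source_ids:
        lines.append("sources: " + ", ".join(judgment.cited_source_ids))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# scripted backend


ScriptKey = tuple[str, str, str]  # (stage, gene, criterion)

DEFAULT_ZERO_TEXT = "score: 0\njustification: no evidence (scripted default)"


@dataclass
class ScriptTable:
    """Canned responses keyed by (stage, gene, criterion).

    ``miss_policy`` governs unknown keys: ``"error"`` raises a lookup
    error naming the key, ``"default_zero"`` substitutes a canonical
    zero-score response.
    """

    responses: dict[ScriptKey, str] = field(default_factory=dict)
    miss_policy: str = "error"

    def __post_init__(self) -> None:
        if self.miss_policy not in ("error", "default_zero"):
            raise ValueError(f"unknown miss_policy: {self.miss_policy!r}")

    def add(self, stage: Stage | str, gene: str, criterion: str, response: str
            ) -> None:
        key = (Stage(stage).value, gene, criterion)
        if key in self.responses:
            raise ValueError(f"duplicate script key: {key}")
        self.responses[key] = response

    def lookup(self, stage: Stage | str, gene: str, criterion: str) -> str:
        key = (Stage(stage).value, gene, criterion)
        if key in self.responses:
            return self.responses[key]
        if self.miss_policy == "default_zero":
            return DEFAULT_ZERO_TEXT
        raise ScriptLookupError(f"no scripted response for {key}")

    def __len__(self) -> int:
        return len(self.responses)

    @classmethod
    def from_jsonl(cls, source: str | Path | Iterable[str],
                   miss_policy: str = "error") -> "ScriptTable":
        if isinstance(source, (str, Path)):
            lines: Iterable[str] = Path(source).read_text().splitlines()
        else:
            lines = source
        table = cls(miss_policy=miss_policy)
        for lineno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"bad script record at line {lineno}") from exc
            table.add(record["stage"], record["gene"], record["criterion"],
                      record["response"])
        return table

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for (stage, gene, criterion), response in self.responses.items():
                fh.write(json.dumps({
                    "stage": stage, "gene": gene,
                    "criterion": criterion, "response": response,
                }) + "\n")


@dataclass
class ScriptedBackend:
    """Deterministic replay backend: the test double for real models."""

    script: ScriptTable
    backend_id: str = "scripted"

    def complete(self, request: BackendRequest) -> BackendResponse:
        text = self.script.lookup(request.stage, request.gene, request.criterion)
        return BackendResponse(text=text, backend_id=self.backend_id)
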