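"""Synthetic study generator.

Produces a complete, self-consistent offline study: a gene universe
with planted "relevant" genes, scripted backend responses for all four
model stages, a literature corpus whose chunks assert criterion-
specific associations for relevant genes, two overlapping benchmark
sets, a gene-set collection with one planted pathway, and publication
counts correlated with relevance.

The statistical structure mirrors what the pipeline assumes of real
model output: relevant genes draw criterion scores from a clipped,
rounded Normal(8, 1) and are supported by the literature with
probability ``rag_fidelity``; irrelevant genes draw from a clipped
Normal(2, 1.5) and appear in the corpus only in neutral sentences, so
the faithfulness judge fails their instances.  Criterion scores within
a gene share a latent gene-level component (70% of the variance), because
a gene that is genuinely disease-relevant tends to score high across
criteria together; the marginals stay at the stated normals.

Everything is a pure function of the config seed: independent child
seeds drive each generation step, so e.g. scripts and corpus agree on
which (gene, criterion) pairs are literature-supported without sharing
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .benchmark import BenchmarkSet
from .corpus import DocumentRecord
from .criteria import CRITERIA, CRITERION_KEYWORDS, CRITERION_PHRASES
from .errors import ConfigError
from .gateway import ScriptTable, Stage
from .screen import bin_score
from .selection import GeneSetCollection

_STREAMS = {
    "universe": 1,
    "supported": 2,
    "naive": 3,
    "rag": 4,
    "corpus": 5,
    "benchmark": 6,
    "pubcounts": 7,
}


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the synthetic study; defaults are the reference study.

    ``rag_fidelity`` is the probability that a relevant gene's criterion
    has a supporting sentence in the corpus.  ``score_correlation`` is
    the share of score variance carried by the gene-level latent
    component (criteria within a gene are correlated by this amount).
    """

    n_genes: int = 1000
    n_relevant: int = 60
    seed: int = 0
    relevant_mean: float = 8.0
    relevant_sd: float = 1.0
    irrelevant_mean: float = 2.0
    irrelevant_sd: float = 1.5
    score_correlation: float = 0.7
    malformed_rate: float = 0.02
    rag_fidelity: float = 0.9
    # benchmark shape: two curated sets with a configured overlap, drawn
    # mostly (benchmark_relevant_frac) from relevant genes
    benchmark_size_a: int = 32
    benchmark_size_b: int = 48
    benchmark_overlap: int = 28
    benchmark_relevant_frac: float = 0.9
    pathway_size: int = 40
    n_decoy_sets: int = 10
    decoy_set_size: int = 40

    def __post_init__(self) -> None:
        if self.n_relevant > self.n_genes:
            raise ConfigError(
                f"n_relevant {self.n_relevant} > n_genes {self.n_genes}")
        for attr in ("malformed_rate", "rag_fidelity", "score_correlation",
                     "benchmark_relevant_frac"):
            value = getattr(self, attr)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{attr} must be in [0,1], got {value}")
        if self.malformed_rate >= 1.0:
            raise ConfigError("malformed_rate must be < 1")
        if self.benchmark_overlap > min(self.benchmark_size_a,
                                        self.benchmark_size_b):
            raise ConfigError("benchmark overlap exceeds a set size")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


@dataclass
class Universe:
    genes: list[str]
    relevant: set[str]

    @property
    def irrelevant(self) -> list[str]:
        return [g for g in self.genes if g not in self.relevant]


def generate_universe(config: StudyConfig) -> Universe:
    """Synthetic symbols G000001... with a seeded random relevant subset."""
    genes = [f"G{i + 1:06d}" for i in range(config.n_genes)]
    rng = config.rng("universe")
    relevant_idx = rng.choice(config.n_genes, size=config.n_relevant,
                              replace=False)
    relevant = {genes[i] for i in relevant_idx}
    return Universe(genes=genes, relevant=relevant)


def supported_pairs(universe: Universe, config: StudyConfig
                    ) -> set[tuple[str, str]]:
    """(gene, criterion) pairs with literature support.

    Relevant genes are supported per criterion with probability
    ``rag_fidelity``; irrelevant genes never are.  Drawn from a
    dedicated child seed so scripts and corpus agree independently.
    """
    rng = config.rng("supported")
    pairs: set[tuple[str, str]] = set()
    for gene in sorted(universe.relevant):
        for criterion in CRITERIA:
            if rng.random() < config.rag_fidelity:
                pairs.add((gene, criterion))
    return pairs


def _draw_scores(rng: np.random.Generator, mean: float, sd: float,
                 rho: float, n_criteria: int) -> list[int]:
    """One gene's criterion scores: latent gene effect + criterion noise."""
    sd_between = sd * np.sqrt(rho)
    sd_within = sd * np.sqrt(1.0 - rho)
    mu = rng.normal(mean, sd_between)
    draws = rng.normal(mu, sd_within, size=n_criteria)
    return [int(np.clip(np.rint(x), 0, 10)) for x in draws]


def _naive_scores(universe: Universe, config: StudyConfig
                  ) -> dict[tuple[str, str], int]:
    rng = config.rng("naive")
    scores: dict[tuple[str, str], int] = {}
    for gene in universe.genes:
        relevant = gene in universe.relevant
        mean = config.relevant_mean if relevant else config.irrelevant_mean
        sd = config.relevant_sd if relevant else config.irrelevant_sd
        values = _draw_scores(rng, mean, sd, config.score_correlation,
                              len(CRITERIA))
        for criterion, value in zip(CRITERIA, values):
            scores[(gene, criterion)] = value
    return scores


def _rag_scores(universe: Universe, config: StudyConfig,
                supported: set[tuple[str, str]]
                ) -> dict[tuple[str, str], int]:
    """Literature-grounded scores: high when supported, conservative-low
    otherwise (frequent zeros when evidence is absent)."""
    rng = config.rng("rag")
    scores: dict[tuple[str, str], int] = {}
    for gene in universe.genes:
        for criterion in CRITERIA:
            if (gene, criterion) in supported:
                draw = rng.normal(config.relevant_mean, config.relevant_sd)
                scores[(gene, criterion)] = int(np.clip(np.rint(draw), 0, 10))
            else:
                # no usable evidence: mostly zero, occasionally 1-2
                scores[(gene, criterion)] = int(rng.choice(
                    [0, 0, 0, 1, 2], p=[0.6, 0.1, 0.1, 0.1, 0.1]))
    return scores


def _supporting_doc_id(gene: str, criterion: str) -> str:
    return f"A_{gene}_{CRITERIA.index(criterion)}"


def supporting_chunk_id(gene: str, criterion: str) -> str:
    """Chunk id of the (single-chunk) supporting article for a pair."""
    return f"{_supporting_doc_id(gene, criterion)}:0"


MALFORMED_TEXT = ("The assessment could not be completed in the requested "
                  "structured format.")


@dataclass
class ScriptBundle:
    naive: ScriptTable
    rag_synth: ScriptTable
    faith_judge: ScriptTable
    hybrid_arbiter: ScriptTable
    #: ground truth kept for tests and wiring
    naive_scores: dict[tuple[str, str], int] = field(default_factory=dict)
    rag_scores: dict[tuple[str, str], int] = field(default_factory=dict)
    supported: set[tuple[str, str]] = field(default_factory=set)
    malformed: set[tuple[str, str]] = field(default_factory=set)

    def merged(self, miss_policy: str = "error") -> ScriptTable:
        table = ScriptTable(miss_policy=miss_policy)
        for part in (self.naive, self.rag_synth, self.faith_judge,
                     self.hybrid_arbiter):
            for (stage, gene, criterion), text in part.responses.items():
                table.add(stage, gene, criterion, text)
        return table


def _naive_text(gene: str, criterion: str, score: int) -> str:
    band = bin_score(score)
    return "\n".join([
        f"official_name: {gene} protein",
        f"summary: {gene} is a blood transcript evaluated for sepsis "
        f"relevance.",
        f"score: {score}",
        f"justification: {band}-confidence prior knowledge of "
        f"{CRITERION_PHRASES[criterion]} for {gene}.",
    ])


def _rag_text(gene: str, criterion: str, score: int,
              supported: bool) -> str:
    if supported:
        chunk_id = supporting_chunk_id(gene, criterion)
        return "\n".join([
            f"official_name: {gene} protein",
            f"summary: {gene} is a blood transcript evaluated for sepsis "
            f"relevance.",
            f"score: {score}",
            f"justification: retrieved literature states that {gene} is "
            f"implicated in {CRITERION_KEYWORDS[criterion]} in sepsis "
            f"[source: {chunk_id}].",
            f"sources: {chunk_id}",
        ])
    return "\n".join([
        f"official_name: {gene} protein",
        f"summary: {gene} is a blood transcript evaluated for sepsis "
        f"relevance.",
        f"score: {score}",
        f"justification: the retrieved context contains no specific "
        f"evidence linking {gene} to {CRITERION_KEYWORDS[criterion]} "
        f"in sepsis.",
    ])


def _arbiter_text(naive_score: int, rag_score: int) -> str:
    # recalibrate toward the retrieved-evidence score
    recal = int(np.clip(round(0.25 * naive_score + 0.75 * rag_score), 0, 10))
    decision = bin_score(recal)
    explanation = ("final score synthesizes prior knowledge with retrieved "
                   "evidence, weighting the literature-grounded assessment.")
    if abs(naive_score - rag_score) >= 4:
        explanation += (" The large discrepancy between the naive and "
                        "retrieved-evidence scores is resolved in favor of "
                        "the literature.")
    return "\n".join([
        f"decision: {decision}",
        f"score: {recal}",
        f"explanation: {explanation}",
    ])


def generate_scripts(universe: Universe, config: StudyConfig) -> ScriptBundle:
    """Scripted responses for all four stages over the full universe.

    The faithfulness judge implements the rule "Pass iff the cited chunk
    mentions the gene together with the criterion keyword", which by
    construction holds exactly for literature-supported pairs.
    """
    supported = supported_pairs(universe, config)
    naive_scores = _naive_scores(universe, config)
    rag_scores = _rag_scores(universe, config, supported)

    malformed_rng = np.random.default_rng([config.seed, 8])
    bundle = ScriptBundle(
        naive=ScriptTable(), rag_synth=ScriptTable(),
        faith_judge=ScriptTable(), hybrid_arbiter=ScriptTable(),
        naive_scores=naive_scores, rag_scores=rag_scores,
        supported=supported)

    for gene in universe.genes:
        for criterion in CRITERIA:
            n_score = naive_scores[(gene, criterion)]
            if malformed_rng.random() < config.malformed_rate:
                bundle.malformed.add((gene, criterion))
                bundle.naive.add(Stage.NAIVE, gene, criterion, MALFORMED_TEXT)
            else:
                bundle.naive.add(Stage.NAIVE, gene, criterion,
                                 _naive_text(gene, criterion, n_score))
            pair_supported = (gene, criterion) in supported
            r_score = rag_scores[(gene, criterion)]
            bundle.rag_synth.add(Stage.RAG_SYNTH, gene, criterion,
                                 _rag_text(gene, criterion, r_score,
                                           pair_supported))
            bundle.faith_judge.add(
                Stage.FAITH_JUDGE, gene, criterion,
                "verdict: Pass" if pair_supported else "verdict: Fail")
            bundle.hybrid_arbiter.add(Stage.HYBRID_ARBITER, gene, criterion,
                                      _arbiter_text(n_score, r_score))
    return bundle


# ---------------------------------------------------------------------------
# corpus


def generate_corpus(universe: Universe, config: StudyConfig
                    ) -> list[DocumentRecord]:
    """Synthetic literature corpus matching the scripted study.

    One short full-text article per literature-supported (gene,
    criterion) pair asserts the association (gene symbol and criterion
    keyword co-occur); every gene additionally appears in neutral
    methods-style abstracts, so retrieval always has something to
    return; a handful of generic reviews round out the type mix.  All
    generated full articles carry citation percentiles above the 0.8
    filter; abstracts carry none.
    """
    supported = supported_pairs(universe, config)
    rng = config.rng("corpus")
    records: list[DocumentRecord] = []
    for gene, criterion in sorted(supported):
        keyword = CRITERION_KEYWORDS[criterion]
        text = (
            f"Studies of septic patients show that {gene} is implicated in "
            f"{keyword} during sepsis. Elevated {gene} expression "
            f"correlated with {keyword} outcomes in whole blood. These "
            f"findings support {gene} as relevant to "
            f"{CRITERION_PHRASES[criterion]}.")
        records.append(DocumentRecord(
            doc_id=_supporting_doc_id(gene, criterion),
            title=f"{gene} and {keyword} in sepsis",
            year=int(rng.integers(1990, 2026)),
            doc_type="article",
            text=text,
            citation_percentile=float(rng.uniform(0.801, 1.0))))
    # neutral abstracts: 10 genes each, no criterion keywords, no percentile
    for start in range(0, len(universe.genes), 10):
        group = universe.genes[start:start + 10]
        listing = ", ".join(group)
        text = (f"Transcript abundance of {listing} was measured in whole "
                f"blood samples by quantitative profiling. Expression "
                f"levels are reported without interpretation.")
        records.append(DocumentRecord(
            doc_id=f"N_{start // 10:04d}",
            title="Whole-blood transcript profiling",
            year=int(rng.integers(1990, 2026)),
            doc_type="abstract",
            text=text,
            citation_percentile=None))
    for i in range(5):
        records.append(DocumentRecord(
            doc_id=f"R_{i:02d}",
            title="Sepsis pathophysiology review",
            year=int(rng.integers(1990, 2026)),
            doc_type="review",
            text=("Sepsis is a dysregulated host response to infection "
                  "leading to life-threatening organ dysfunction. This "
                  "review summarizes inflammatory signalling cascades.\n"
                  "References\n[1] placeholder citation list."),
            citation_percentile=float(rng.uniform(0.801, 1.0))))
    return records


# ---------------------------------------------------------------------------
# benchmark sets, pathway collection, publication counts


def generate_benchmark_and_sets(universe: Universe, config: StudyConfig
                                ) -> tuple[BenchmarkSet, BenchmarkSet,
                                           GeneSetCollection, dict[str, int]]:
    """Two overlapping curated sets, a planted-pathway GMT, pub counts."""
    rng = config.rng("benchmark")
    union_size = (config.benchmark_size_a + config.benchmark_size_b
                  - config.benchmark_overlap)
    n_from_relevant = min(round(union_size * config.benchmark_relevant_frac),
                          len(universe.relevant))
    relevant_sorted = sorted(universe.relevant)
    irrelevant_sorted = universe.irrelevant
    pool = list(rng.choice(relevant_sorted, size=n_from_relevant,
                           replace=False))
    pool += list(rng.choice(irrelevant_sorted,
                            size=union_size - n_from_relevant, replace=False))
    pool = list(rng.permutation(pool))
    shared = pool[:config.benchmark_overlap]
    only_a = pool[config.benchmark_overlap:
                  config.benchmark_size_a]
    only_b = pool[config.benchmark_size_a:union_size]

    def _score(gene: str) -> float:
        if gene in universe.relevant:
            return float(rng.uniform(0.6, 1.0))
        return float(rng.uniform(0.0, 0.5))

    set_a = BenchmarkSet(name="mechanistic-db", entries={
        g: _score(g) for g in shared + only_a})
    set_b = BenchmarkSet(name="therapeutic-db", entries={
        g: _score(g) for g in shared + only_b})

    pathway_size = min(config.pathway_size, len(relevant_sorted))
    planted = set(rng.choice(relevant_sorted, size=pathway_size,
                             replace=False))
    sets = {"PLANTED_SEPSIS_CORE": planted}
    for i in range(config.n_decoy_sets):
        sets[f"DECOY_SET_{i + 1:02d}"] = set(rng.choice(
            universe.genes, size=config.decoy_set_size, replace=False))
    collection = GeneSetCollection(sets=sets, source="synthetic")

    count_rng = config.rng("pubcounts")
    pubcounts = {}
    for gene in universe.genes:
        loc = 6.0 if gene in universe.relevant else 3.0
        pubcounts[gene] = int(np.rint(np.exp(count_rng.normal(loc, 1.0))))
    return set_a, set_b, collection, pubcounts


# ---------------------------------------------------------------------------
# whole study


@dataclass
class SyntheticStudy:
    config: StudyConfig
    universe: Universe
    scripts: ScriptBundle
    corpus: list[DocumentRecord]
    benchmark_a: BenchmarkSet
    benchmark_b: BenchmarkSet
    collection: GeneSetCollection
    pubcounts: dict[str, int]


def generate_study(config: StudyConfig | None = None,
                   seed: int | None = None) -> SyntheticStudy:
    """Generate every input the pipeline consumes, from one seed."""
    if config is None:
        config = StudyConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    universe = generate_universe(config)
    scripts = generate_scripts(universe, config)
    corpus = generate_corpus(universe, config)
    bench_a, bench_b, collection, pubcounts = generate_benchmark_and_sets(
        universe, config)
    return SyntheticStudy(config=config, universe=universe, scripts=scripts,
                          corpus=corpus, benchmark_a=bench_a,
                          benchmark_b=bench_b, collection=collection,
                          pubcounts=pubcounts)


def write_fixtures(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write all study inputs as the file formats the pipeline consumes."""
    import json

    from .benchmark import write_benchmark_tsv
    from .selection import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genes.tsv", "w") as fh:
        fh.write("symbol\trelevant\n")
        for gene in study.universe.genes:
            fh.write(f"{gene}\t{int(gene in study.universe.relevant)}\n")
    with open(outdir / "corpus.jsonl", "w") as fh:
        for record in study.corpus:
            fh.write(json.dumps({
                "id": record.doc_id, "title": record.title,
                "year": record.year, "type": record.doc_type,
                "text": record.text,
                "citation_percentile": record.citation_percentile,
            }) + "\n")
    study.scripts.naive.to_jsonl(outdir / "script_naive.jsonl")
    study.scripts.rag_synth.to_jsonl(outdir / "script_rag.jsonl")
    study.scripts.faith_judge.to_jsonl(outdir / "script_judge.jsonl")
    study.scripts.hybrid_arbiter.to_jsonl(outdir / "script_arbiter.jsonl")
    write_benchmark_tsv([study.benchmark_a, study.benchmark_b],
                        outdir / "benchmark.tsv")
    write_gmt(study.collection, outdir / "genesets.gmt")
    with open(outdir / "pubcounts.tsv", "w") as fh:
        fh.write("symbol\tcount\n")
        for gene, count in study.pubcounts.items():
            fh.write(f"{gene}\t{count}\n")
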