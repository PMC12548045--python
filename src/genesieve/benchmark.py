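"""Validation harness against expert-curated benchmark gene sets.

Measures how well screening recovers independently curated disease
genes: per-database and combined recall under the admission rule (any
criterion >= 5 by default), top-K overlap curves against a reference
ranking, Spearman rank correlation against reference scores or
publication counts, and a comparison of curation scores between
identified and missed genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .errors import ConfigError
from .screen import AnyCriterionGE, CriterionScoreVector, weighted_score
from .utils import pct

DEFAULT_KS = (5, 10, 15, 20, 25, 30)


@dataclass
class BenchmarkSet:
    """A curated gene set with optional per-gene curation scores."""

    name: str
    entries: dict[str, float | None]
    #: per-gene scores keyed by originating database, populated by unions
    source_scores: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.source_scores:
            self.source_scores = {
                gene: ({self.name: score} if score is not None else {})
                for gene, score in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> set[str]:
        return set(self.entries)


def read_benchmark_tsv(path: str | Path) -> dict[str, BenchmarkSet]:
    """Read 'symbol, source_db, curation_score' TSV into per-db sets."""
    frame = pd.read_csv(path, sep="\t")
    required = {"symbol", "source_db"}
    if not required <= set(frame.columns):
        raise ConfigError(f"benchmark TSV needs columns {sorted(required)}")
    sets: dict[str, BenchmarkSet] = {}
    for source, group in frame.groupby("source_db"):
        entries: dict[str, float | None] = {}
        for _, row in group.iterrows():
            score = row.get("curation_score")
            entries[str(row["symbol"])] = (
                float(score) if pd.notna(score) else None)
        sets[str(source)] = BenchmarkSet(name=str(source), entries=entries)
    return sets


def write_benchmark_tsv(sets: Iterable[BenchmarkSet], path: str | Path) -> None:
    rows = []
    for bset in sets:
        for gene, score in sorted(bset.entries.items()):
            rows.append({"symbol": gene, "source_db": bset.name,
                         "curation_score": score})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def union_benchmark(sets: Sequence[BenchmarkSet],
                    name: str = "combined") -> BenchmarkSet:
    """Symbol-deduplicated union, retaining per-source curation scores."""
    if not sets:
        raise ConfigError("union of zero benchmark sets")
    entries: dict[str, float | None] = {}
    source_scores: dict[str, dict[str, float]] = {}
    for bset in sets:
        for gene, score in bset.entries.items():
            if gene not in entries:
                entries[gene] = score
                source_scores[gene] = {}
            for src, val in bset.source_scores.get(gene, {}).items():
                source_scores[gene][src] = val
    return BenchmarkSet(name=name, entries=entries, source_scores=source_scores)


# ---------------------------------------------------------------------------
# recall


@dataclass
class RecallReport:
    set_name: str
    identified: list[str]
    missed: list[str]

    @property
    def n_identified(self) -> int:
        return len(self.identified)

    @property
    def total(self) -> int:
        return len(self.identified) + len(self.missed)

    @property
    def recall_pct(self) -> float:
        return pct(self.n_identified, self.total)


def recall_at_rule(scores: Mapping[str, CriterionScoreVector],
                   benchmark: BenchmarkSet,
                   rule: AnyCriterionGE | None = None) -> RecallReport:
    """Share of benchmark genes recovered by the admission rule.

    Benchmark genes absent from the score table count as missed.
    """
    if not benchmark.entries:
        raise ConfigError(f"benchmark set {benchmark.name!r} is empty")
    if rule is None:
        rule = AnyCriterionGE(5)
    identified, missed = [], []
    for gene in sorted(benchmark.genes):
        vector = scores.get(gene)
        if vector is None:
            missed.append(gene)
            continue
        ok, _ = rule.evaluate(vector, weighted_score(vector))
        (identified if ok else missed).append(gene)
    return RecallReport(set_name=benchmark.name, identified=identified,
                        missed=missed)


# ---------------------------------------------------------------------------
# top-K overlap


@dataclass
class TopKReport:
    reference_name: str
    overlap_pct: dict[int, float]


def topk_overlap(method_scores: Mapping[str, float],
                 reference_ranking: Sequence[str],
                 ks: Sequence[int] = DEFAULT_KS,
                 reference_name: str = "reference") -> TopKReport:
    """Top-K overlap curve between a method ranking and a reference.

    Method ranking: score descending, symbol ascending on ties; genes
    absent from the method table rank last.  K values exceeding the
    reference length are truncated with a warning.
    """
    if any(k < 1 for k in ks):
        raise ConfigError("K values must be positive")
    full_scores = {gene: method_scores.get(gene, float("-inf"))
                   for gene in set(method_scores) | set(reference_ranking)}
    method_order = sorted(full_scores, key=lambda g: (-full_scores[g], g))
    overlap: dict[int, float] = {}
    for k in ks:
        k_eff = k
        if k > len(reference_ranking):
            warnings.warn(f"K={k} exceeds reference length "
                          f"{len(reference_ranking)}; truncated", stacklevel=2)
            k_eff = len(reference_ranking)
        top_method = set(method_order[:k_eff])
        top_reference = set(reference_ranking[:k_eff])
        overlap[k] = pct(len(top_method & top_reference), k_eff)
    return TopKReport(reference_name=reference_name, overlap_pct=overlap)


def rank_correlation(method_scores: Mapping[str, float],
                     reference_values: Mapping[str, float]
                     ) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) over the shared genes.

    Returns (rho, p) with the standard large-sample p-value.
    """
    common = sorted(set(method_scores) & set(reference_values))
    if len(common) < 3:
        raise ConfigError(f"need >= 3 common genes, got {len(common)}")
    rho, p = stats.spearmanr([method_scores[g] for g in common],
                             [reference_values[g] for g in common])
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# identified-vs-missed curation score comparison


@dataclass
class ScoreComparison:
    median_identified: float
    median_missed: float
    p_value: float
    n_identified: int
    n_missed: int


def compare_identified_scores(report: RecallReport, benchmark: BenchmarkSet
                              ) -> ScoreComparison:
    """Group medians and rank-sum p for curation scores by recovery status.

    Curation scores are min-max normalized within the benchmark set
    before comparison.
    """
    raw = {g: s for g, s in benchmark.entries.items() if s is not None}
    if len(raw) < 2:
        raise ConfigError("not enough curation scores to compare")
    low, high = min(raw.values()), max(raw.values())
    span = (high - low) or 1.0
    norm = {g: (s - low) / span for g, s in raw.items()}
    identified = [norm[g] for g in report.identified if g in norm]
    missed = [norm[g] for g in report.missed if g in norm]
    if not identified or not missed:
        raise ConfigError("one recovery group has no curation scores")
    _, p = stats.mannwhitneyu(identified, missed, alternative="two-sided")
    return ScoreComparison(
        median_identified=float(pd.Series(identified).median()),
        median_missed=float(pd.Series(missed).median()),
        p_value=float(p),
        n_identified=len(identified),
        n_missed=len(missed))
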