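"""Stage 3 — multi-dimensional candidate optimization.

Cluster-specific gene-set enrichment (two-sided Fisher exact test with
Benjamini-Hochberg FDR over the tested collection) picks the most
enriched cluster of the literature-validated set as the high-confidence
priority set.  Its genes are then projected by PCA over the
standardized 8-criterion score matrix, partitioned into centroid-based
sub-clusters, and the sub-cluster with the highest mean score profile
across all criteria becomes the final candidate set, annotated as
Known (present in a prior evidence set) or New.

The enrichment universe defaults to the full screened gene universe.
Odds ratios use the Haldane-Anscombe +0.5 correction whenever a
contingency cell is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import log10
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .criteria import CRITERIA
from .errors import ConfigError, NoEnrichedClusterError
from .hybrid import HybridAssessment
from .screen import PrioritySet


# ---------------------------------------------------------------------------
# gene-set collections (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. a hallmark-style pathway collection."""

    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read the standard GMT format: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = {g for g in parts[2:] if g}
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


# ---------------------------------------------------------------------------
# Fisher / BH enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    a: int  # in query, in set
    b: int  # in query, not in set
    c: int  # not in query, in set
    d: int  # not in query, not in set
    odds_ratio: float
    p_value: float
    q_value: float


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) == 0:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return (a * d) / (b * c)


def fisher_enrichment(query: Iterable[str], collection: GeneSetCollection,
                      universe: Iterable[str]) -> list[EnrichmentResult]:
    """Two-sided Fisher exact enrichment of ``query`` in each collection set.

    Each set is intersected with the universe before testing; BH
    q-values are computed across all tested sets; results are sorted by
    q-value then set name.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ConfigError("empty enrichment universe")
    query_set = set(query)
    offenders = query_set - universe_set
    if offenders:
        raise ConfigError(
            f"query genes outside universe: {sorted(offenders)[:5]}")
    names, tables = [], []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe_set
        a = len(query_set & members)
        b = len(query_set) - a
        c = len(members) - a
        d = len(universe_set) - a - b - c
        names.append(name)
        tables.append((a, b, c, d))
    p_values = [float(stats.fisher_exact([[a, b], [c, d]],
                                         alternative="two-sided")[1])
                for a, b, c, d in tables]
    q_values = multipletests(p_values, method="fdr_bh")[1] if p_values else []
    results = [
        EnrichmentResult(set_name=name, a=a, b=b, c=c, d=d,
                         odds_ratio=_odds_ratio(a, b, c, d),
                         p_value=p, q_value=float(q))
        for name, (a, b, c, d), p, q in zip(names, tables, p_values, q_values)
    ]
    return sorted(results, key=lambda r: (r.q_value, r.set_name))


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# cluster selection (PS3)


@dataclass
class Ps3Selection:
    priority_set: PrioritySet
    selected_cluster: str
    per_cluster: dict[str, list[EnrichmentResult]]
    n_significant: dict[str, int]


def select_ps3(ps2: PrioritySet, collection: GeneSetCollection,
               universe: Iterable[str], alpha: float = 0.05,
               name: str = "PS3") -> Ps3Selection:
    """Pick the most pathway-enriched cluster of PS2 as the next set.

    Selection rule: the cluster with the largest number of sets enriched
    at q < alpha; ties go to the larger mean -log10(q) over its
    significant sets, then to the lexically smaller cluster label.  If
    no cluster has any significant set the outcome is an explicit
    error, never a silent pick.
    """
    if not ps2.cluster:
        raise ConfigError(f"{ps2.name} has no cluster assignments")
    clusters = sorted(set(ps2.cluster.values()))
    per_cluster: dict[str, list[EnrichmentResult]] = {}
    n_significant: dict[str, int] = {}
    strength: dict[str, float] = {}
    for label in clusters:
        members = [g for g in ps2.members if ps2.cluster.get(g) == label]
        results = fisher_enrichment(members, collection, universe)
        per_cluster[label] = results
        significant = [r for r in results if r.q_value < alpha]
        n_significant[label] = len(significant)
        strength[label] = (
            float(np.mean([-log10(max(r.q_value, 1e-300)) for r in significant]))
            if significant else 0.0)
    if max(n_significant.values()) == 0:
        raise NoEnrichedClusterError(
            f"no {ps2.name} cluster enriched at q < {alpha}")
    winner = min(clusters,
                 key=lambda c: (-n_significant[c], -strength[c], c))
    members = [g for g in ps2.members if ps2.cluster.get(g) == winner]
    ps3 = PrioritySet(
        name=name,
        members=members,
        scores={g: ps2.scores[g] for g in members},
        cluster={g: winner for g in members},
        provenance={g: {"admitted": True,
                        "rule": f"member of most-enriched cluster {winner}",
                        "n_significant_sets": n_significant[winner]}
                    for g in members})
    return Ps3Selection(priority_set=ps3, selected_cluster=winner,
                        per_cluster=per_cluster, n_significant=n_significant)


# ---------------------------------------------------------------------------
# score matrix, PCA, sub-clustering


def score_matrix(assessments: Iterable[HybridAssessment],
                 genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Gene x 8-criterion matrix of recalibrated scores, absent -> 0.

    Column order follows the fixed criterion scheme; the zero fill for
    missing criteria mirrors the fixed-denominator convention of the
    weighted score.
    """
    table: dict[str, dict[str, int]] = {}
    for assessment in assessments:
        row = table.setdefault(assessment.gene, {})
        row[assessment.criterion] = assessment.recalibrated_score
    index = list(genes) if genes is not None else sorted(table)
    frame = pd.DataFrame(0, index=index, columns=list(CRITERIA), dtype=float)
    for gene in index:
        for criterion, score in table.get(gene, {}).items():
            frame.loc[gene, criterion] = score
    if frame.index.duplicated().any():
        raise ConfigError("duplicate genes in score matrix")
    return frame


@dataclass
class PcaResult:
    coordinates: pd.DataFrame       # genes x components
    explained_variance_ratio: np.ndarray
    components: pd.DataFrame        # components x criteria (loadings)


def pca_project(matrix: pd.DataFrame, n_components: int = 2) -> PcaResult:
    """PCA of the standardized score matrix with a fixed sign convention.

    Columns are standardized to zero mean / unit variance; zero-variance
    columns are kept as zeros with a warning.  For reproducibility each
    component is flipped so its largest-magnitude loading is positive.
    """
    if matrix.shape[0] < 2:
        raise ConfigError("PCA needs at least 2 genes")
    if n_components > matrix.shape[1]:
        raise ConfigError(
            f"n_components {n_components} > {matrix.shape[1]} criteria")
    values = matrix.to_numpy(dtype=float)
    means = values.mean(axis=0)
    stds = values.std(axis=0, ddof=0)
    flat = stds == 0
    if flat.any():
        warnings.warn(
            f"constant score columns held at zero: "
            f"{[matrix.columns[i] for i in np.flatnonzero(flat)]}",
            stacklevel=2)
    safe_stds = np.where(flat, 1.0, stds)
    standardized = (values - means) / safe_stds
    standardized[:, flat] = 0.0

    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(standardized)
    components = pca.components_.copy()
    for j in range(components.shape[0]):
        pivot = int(np.argmax(np.abs(components[j])))
        if components[j, pivot] < 0:
            components[j] *= -1.0
            coords[:, j] *= -1.0
    labels = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=matrix.index, columns=labels),
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=pd.DataFrame(components, index=labels,
                                columns=matrix.columns),
    )


def subcluster(coordinates: pd.DataFrame, k: int = 4, seed: int = 0,
               n_init: int = 10) -> pd.Series:
    """Centroid-based partition of PCA coordinates (k-means, fixed seed)."""
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    if k > coordinates.shape[0]:
        raise ConfigError(
            f"k {k} exceeds number of points {coordinates.shape[0]}")
    model = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = model.fit_predict(coordinates.to_numpy(dtype=float))
    return pd.Series(labels, index=coordinates.index, name="subcluster")


@dataclass
class ClusterProfile:
    cluster_id: int
    criterion_means: pd.Series  # per-criterion mean scores
    overall_mean: float
    n_genes: int


def profile_and_select(matrix: pd.DataFrame, assignments: pd.Series
                       ) -> tuple[list[ClusterProfile], int]:
    """Per-cluster mean score profiles and the optimal cluster.

    The optimal cluster maximizes the overall mean (the mean of its
    eight per-criterion means); ties go to the lower cluster id.  Empty
    clusters are excluded with a warning.
    """
    missing = set(matrix.index) - set(assignments.index)
    if missing:
        raise ConfigError(f"genes without assignment: {sorted(missing)[:5]}")
    profiles: list[ClusterProfile] = []
    for cluster_id in sorted(set(int(c) for c in assignments)):
        members = assignments.index[assignments == cluster_id]
        members = [g for g in members if g in matrix.index]
        if not members:
            warnings.warn(f"cluster {cluster_id} is empty; excluded",
                          stacklevel=2)
            continue
        sub = matrix.loc[members]
        criterion_means = sub.mean(axis=0)
        profiles.append(ClusterProfile(
            cluster_id=cluster_id,
            criterion_means=criterion_means,
            overall_mean=float(criterion_means.mean()),
            n_genes=len(members)))
    if not profiles:
        raise ConfigError("no non-empty clusters to select from")
    best = min(profiles, key=lambda p: (-p.overall_mean, p.cluster_id))
    return profiles, best.cluster_id


def annotate_known_new(candidates: Sequence[str], evidence: Iterable[str]
                       ) -> dict[str, str]:
    """Label each candidate Known (in the prior evidence set) or New.

    Matching is exact after upper-case normalization of symbols.
    """
    evidence_upper = {e.upper() for e in evidence}
    return {gene: ("Known" if gene.upper() in evidence_upper else "New")
            for gene in candidates}
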