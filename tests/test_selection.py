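"""Enrichment, PS3 selection, PCA, sub-clustering, candidate annotation."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from genesieve.criteria import CRITERIA
from genesieve.errors import ConfigError, NoEnrichedClusterError
from genesieve.screen import PrioritySet
from genesieve.selection import (
    GeneSetCollection,
    annotate_known_new,
    fisher_enrichment,
    pca_project,
    profile_and_select,
    read_gmt,
    select_ps3,
    subcluster,
    write_gmt,
)


# ---------------------------------------------------------------------------
# independent oracles


def hypergeom_pmf(k, total, n_set, n_query):
    return (math.comb(n_set, k) * math.comb(total - n_set, n_query - k)
            / math.comb(total, n_query))


def fisher_two_sided_oracle(a, b, c, d):
    """Enumeration of the hypergeometric tail: sum of all tables (with the
    same margins) whose probability does not exceed the observed one."""
    total = a + b + c + d
    n_query = a + b
    n_set = a + c
    lo = max(0, n_query + n_set - total)
    hi = min(n_query, n_set)
    p_obs = hypergeom_pmf(a, total, n_set, n_query)
    return sum(hypergeom_pmf(k, total, n_set, n_query)
               for k in range(lo, hi + 1)
               if hypergeom_pmf(k, total, n_set, n_query)
               <= p_obs * (1 + 1e-7))


def bh_oracle(p_values):
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        q[i] = running
    return q


def toy_setting(rng):
    """Random small universe/query/set for the equivalence check."""
    total = int(rng.integers(20, 120))
    universe = [f"G{i}" for i in range(total)]
    query = list(rng.choice(universe, size=int(rng.integers(3, total // 2)),
                            replace=False))
    member = list(rng.choice(universe, size=int(rng.integers(3, total // 2)),
                             replace=False))
    return universe, query, member


class TestFisherEnrichment:
    def test_matches_enumeration_oracle_on_random_settings(self):
        rng = np.random.default_rng(101)
        for _ in range(200):
            universe, query, member = toy_setting(rng)
            collection = GeneSetCollection(sets={"S": set(member)})
            result = fisher_enrichment(query, collection, universe)[0]
            expected_p = fisher_two_sided_oracle(result.a, result.b,
                                                 result.c, result.d)
            assert result.p_value == pytest.approx(expected_p, rel=1e-9)
            assert result.a + result.b + result.c + result.d == len(universe)

    def test_bh_matches_independent_implementation(self):
        rng = np.random.default_rng(55)
        universe = [f"G{i}" for i in range(200)]
        sets = {f"S{j}": set(rng.choice(universe, size=25, replace=False))
                for j in range(15)}
        query = list(rng.choice(universe, size=40, replace=False))
        results = fisher_enrichment(query, GeneSetCollection(sets=sets),
                                    universe)
        by_name = {r.set_name: r for r in results}
        names = sorted(sets)
        p_values = [by_name[n].p_value for n in names]
        expected_q = bh_oracle(p_values)
        for name, q in zip(names, expected_q):
            assert by_name[name].q_value == pytest.approx(q, rel=1e-9)
            assert by_name[name].q_value >= by_name[name].p_value - 1e-12

    def test_perfect_containment_enriched(self):
        universe = [f"G{i}" for i in range(1000)]
        query = universe[:10]
        collection = GeneSetCollection(sets={"S": set(universe[:100])})
        result = fisher_enrichment(query, collection, universe)[0]
        assert result.odds_ratio > 1
        assert result.p_value < 0.05

    def test_identical_pvalues_degenerate_bh(self):
        universe = [f"G{i}" for i in range(40)]
        # two sets identical to each other -> identical p -> q == p
        collection = GeneSetCollection(sets={"S1": set(universe[:10]),
                                             "S2": set(universe[:10])})
        results = fisher_enrichment(universe[:5], collection, universe)
        assert results[0].p_value == results[1].p_value
        for r in results:
            assert r.q_value == pytest.approx(r.p_value)

    def test_haldane_correction_on_zero_cell(self):
        universe = [f"G{i}" for i in range(50)]
        collection = GeneSetCollection(sets={"S": set(universe[:10])})
        result = fisher_enrichment(universe[:5], collection, universe)[0]
        # a=5, b=0 -> corrected finite OR
        assert math.isfinite(result.odds_ratio)
        assert result.odds_ratio > 0

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ConfigError, match="X1"):
            fisher_enrichment(["X1"], GeneSetCollection(sets={"S": {"G1"}}),
                              ["G1", "G2"])


class TestSelectPs3:
    def make_ps2(self, clusters):
        members = [g for genes in clusters.values() for g in genes]
        return PrioritySet(
            name="PS2", members=members,
            scores={g: 1.0 for g in members},
            cluster={g: label for label, genes in clusters.items()
                     for g in genes})

    def test_planted_pathway_cluster_selected(self):
        universe = [f"G{i:03d}" for i in range(300)]
        q1 = universe[:20]       # concentrated pathway members
        q2 = universe[100:120]   # background
        pathway = set(universe[:25])
        ps2 = self.make_ps2({"Q1": q1, "Q2": q2})
        collection = GeneSetCollection(sets={"PATH": pathway})
        selection = select_ps3(ps2, collection, universe)
        assert selection.selected_cluster == "Q1"
        assert selection.priority_set.members == q1

    def test_no_enriched_cluster_is_explicit(self):
        universe = [f"G{i:03d}" for i in range(300)]
        ps2 = self.make_ps2({"Q1": universe[:10], "Q2": universe[10:20]})
        collection = GeneSetCollection(sets={"IRRELEVANT": set(universe[250:])})
        with pytest.raises(NoEnrichedClusterError):
            select_ps3(ps2, collection, universe)

    def test_identical_clusters_tie_broken_by_label(self):
        universe = [f"G{i:03d}" for i in range(300)]
        pathway = set(universe[:40])
        ps2 = self.make_ps2({"Q1": universe[:20], "Q2": universe[20:40]})
        collection = GeneSetCollection(sets={"PATH": pathway})
        selection = select_ps3(ps2, collection, universe)
        # both clusters fully inside the pathway: equal counts, tie -> Q1
        if selection.n_significant["Q1"] == selection.n_significant["Q2"]:
            assert selection.selected_cluster == "Q1"


class TestPca:
    def make_matrix(self, values):
        return pd.DataFrame(values,
                            index=[f"G{i}" for i in range(len(values))],
                            columns=list(CRITERIA)[:len(values[0])])

    def test_rank_one_matrix_first_component_explains_all(self):
        base = np.array([1.0, 2.0, 3.0])
        values = np.outer([1.0, 2.0, 3.0, 4.0], base)
        result = pca_project(self.make_matrix(values), n_components=3)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(8)
        values = rng.normal(5, 2, size=(9, 3))
        matrix = self.make_matrix(values)
        result = pca_project(matrix, n_components=3)
        # independent oracle: standardize, eigendecompose the covariance
        standardized = (values - values.mean(0)) / values.std(0, ddof=0)
        cov = np.cov(standardized, rowvar=False, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        ratios = eigvals / eigvals.sum()
        assert np.allclose(result.explained_variance_ratio, ratios,
                           atol=1e-10)
        # non-increasing, sums to 1 with all components
        evr = result.explained_variance_ratio
        assert all(evr[i] >= evr[i + 1] - 1e-12 for i in range(len(evr) - 1))
        assert evr.sum() == pytest.approx(1.0)

    def test_projection_isometric_in_retained_subspace(self):
        rng = np.random.default_rng(12)
        values = rng.normal(0, 1, size=(15, 4))
        matrix = self.make_matrix(values)
        result = pca_project(matrix, n_components=4)
        standardized = (values - values.mean(0)) / values.std(0, ddof=0)
        total_var = standardized.var(0, ddof=1).sum()
        coord_var = result.coordinates.to_numpy().var(0, ddof=1).sum()
        assert coord_var == pytest.approx(total_var)

    def test_sign_convention_fixed(self):
        rng = np.random.default_rng(13)
        values = rng.normal(0, 1, size=(10, 3))
        a = pca_project(self.make_matrix(values), 2)
        b = pca_project(self.make_matrix(values), 2)
        assert np.array_equal(a.coordinates.values, b.coordinates.values)
        for _, row in a.components.iterrows():
            assert row.iloc[int(np.argmax(np.abs(row.values)))] > 0

    def test_constant_column_warns_and_zeroed(self):
        values = np.column_stack([np.arange(6.0), np.full(6, 7.0),
                                  np.arange(6.0) ** 2])
        with pytest.warns(UserWarning, match="constant"):
            result = pca_project(self.make_matrix(values), 2)
        assert result.components.iloc[:, 1].abs().max() < 1e-9

    def test_too_many_components_rejected(self):
        values = np.random.default_rng(1).normal(size=(5, 3))
        with pytest.raises(ConfigError):
            pca_project(self.make_matrix(values), 4)


class TestSubcluster:
    def test_separated_blobs_perfectly_split(self):
        rng = np.random.default_rng(21)
        blob_a = rng.normal(0, 0.1, size=(10, 2))
        blob_b = rng.normal(10, 0.1, size=(10, 2))
        coords = pd.DataFrame(np.vstack([blob_a, blob_b]),
                              index=[f"G{i}" for i in range(20)])
        labels = subcluster(coords, k=2, seed=0)
        assert len(set(labels.iloc[:10])) == 1
        assert len(set(labels.iloc[10:])) == 1
        assert labels.iloc[0] != labels.iloc[10]

    def test_k1_single_cluster(self):
        coords = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["a", "b"])
        assert set(subcluster(coords, k=1, seed=0)) == {0}

    def test_same_seed_identical(self):
        rng = np.random.default_rng(22)
        coords = pd.DataFrame(rng.normal(size=(30, 2)),
                              index=[f"G{i}" for i in range(30)])
        a = subcluster(coords, k=4, seed=5)
        b = subcluster(coords, k=4, seed=5)
        assert a.equals(b)

    def test_k_exceeding_points_rejected(self):
        coords = pd.DataFrame([[0.0], [1.0]], index=["a", "b"])
        with pytest.raises(ConfigError):
            subcluster(coords, k=3, seed=0)


class TestProfileAndSelect:
    def matrix(self, rows):
        return pd.DataFrame(rows, index=[f"G{i}" for i in range(len(rows))],
                            columns=list(CRITERIA))

    def test_dominant_cluster_selected(self):
        rows = [[9] * 8] * 5 + [[5] * 8] * 5 + [[2] * 8] * 5
        matrix = self.matrix(rows)
        assignments = pd.Series([0] * 5 + [1] * 5 + [2] * 5,
                                index=matrix.index)
        profiles, optimal = profile_and_select(matrix, assignments)
        assert optimal == 0
        by_id = {p.cluster_id: p for p in profiles}
        assert by_id[0].overall_mean == pytest.approx(9.0)

    def test_tie_goes_to_lower_cluster_id(self):
        rows = [[7] * 8] * 6
        matrix = self.matrix(rows)
        assignments = pd.Series([1, 1, 0, 0, 2, 2], index=matrix.index)
        _, optimal = profile_and_select(matrix, assignments)
        assert optimal == 0

    def test_overall_mean_is_mean_of_criterion_means(self):
        rng = np.random.default_rng(31)
        matrix = self.matrix(rng.integers(0, 11, size=(12, 8)).tolist())
        assignments = pd.Series(rng.integers(0, 3, size=12),
                                index=matrix.index)
        profiles, _ = profile_and_select(matrix, assignments)
        for p in profiles:
            assert p.overall_mean == pytest.approx(
                float(p.criterion_means.mean()))


class TestAnnotateAndGmt:
    def test_known_new_counts(self):
        candidates = [f"C{i:02d}" for i in range(30)]
        evidence = set(candidates[:19]) | {"OTHER1", "OTHER2"}
        labels = annotate_known_new(candidates, evidence)
        assert sum(1 for v in labels.values() if v == "Known") == 19
        assert sum(1 for v in labels.values() if v == "New") == 11

    def test_empty_evidence_all_new(self):
        assert set(annotate_known_new(["A", "B"], []).values()) == {"New"}

    def test_case_normalized_match(self):
        assert annotate_known_new(["il10"], {"IL10"}) == {"il10": "Known"}

    def test_gmt_round_trip(self, tmp_path):
        collection = GeneSetCollection(sets={"SET_A": {"G1", "G2"},
                                             "SET_B": {"G3"}})
        path = tmp_path / "sets.gmt"
        write_gmt(collection, path)
        loaded = read_gmt(path)
        assert loaded.sets == collection.sets
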