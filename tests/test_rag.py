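"""Two-stage retrieval, grounded assessment, faithfulness, agreement."""

import pytest

from genesieve.corpus import Chunk, HashingEmbedder, build_index
from genesieve.criteria import CRITERIA
from genesieve.errors import (
    ConfigError,
    IsolationError,
    MalformedVerdictError,
    RetrievalError,
)
from genesieve.gateway import ScriptTable, ScriptedBackend, Stage
from genesieve.rag import (
    ContextBundle,
    FaithfulnessVerdict,
    dense_retrieve,
    dual_agreement,
    evaluate_faithfulness,
    parse_verdict,
    pass_rate,
    rag_assess,
    rerank,
)


@pytest.fixture(scope="module")
def embedder():
    return HashingEmbedder()


@pytest.fixture(scope="module")
def toy_index(embedder):
    texts = [
        "IL10 suppresses inflammatory cytokine production in sepsis",
        "TREM1 amplifies neutrophil activation in septic shock",
        "unrelated metabolic pathway description",
        "IL10 expression in whole blood of septic patients",
        "complement activation cascade overview",
    ]
    chunks = [Chunk(doc_id=f"D{i}", chunk_index=0, text=t,
                    char_span=(0, len(t))) for i, t in enumerate(texts)]
    return build_index(chunks, embedder)


class TestDenseRetrieve:
    def test_truncates_to_corpus_size(self, toy_index, embedder):
        hits = dense_retrieve("IL10 sepsis", toy_index, embedder, k=25)
        assert len(hits) == 5
        assert [h.rank for h in hits] == [1, 2, 3, 4, 5]

    def test_self_similarity_ranks_first(self, toy_index, embedder):
        # brute-force scan confirms the exact-text chunk maximizes cosine
        query = "IL10 suppresses inflammatory cytokine production in sepsis"
        qvec = embedder.embed([query])[0]
        sims = toy_index.vectors @ qvec
        best = max(range(len(sims)), key=lambda i: sims[i])
        hits = dense_retrieve(query, toy_index, embedder, k=3)
        assert hits[0].chunk.chunk_id == toy_index.chunks[best].chunk_id
        assert hits[0].chunk.chunk_id == "D0:0"

    def test_scores_non_increasing_with_rank(self, toy_index, embedder):
        hits = dense_retrieve("IL10 blood sepsis", toy_index, embedder, k=5)
        scores = [h.dense_score for h in hits]
        assert scores == sorted(scores, reverse=True)

    def test_identical_vectors_tie_broken_by_chunk_id(self, embedder):
        chunks = [Chunk(doc_id=d, chunk_index=0, text="same text",
                        char_span=(0, 9)) for d in ("B", "A")]
        index = build_index(chunks, embedder)
        hits = dense_retrieve("same text", index, embedder, k=2)
        assert [h.chunk.chunk_id for h in hits] == ["A:0", "B:0"]

    def test_empty_index_is_retrieval_error(self, embedder):
        import numpy as np
        from genesieve.corpus import CorpusIndex
        empty = CorpusIndex(chunks=[], vectors=np.zeros((0, embedder.dim)),
                            embedder_id=embedder.embedder_id)
        with pytest.raises(RetrievalError):
            dense_retrieve("q", empty, embedder)

    def test_determinism(self, toy_index, embedder):
        a = dense_retrieve("IL10 sepsis", toy_index, embedder, k=5)
        b = dense_retrieve("IL10 sepsis", toy_index, embedder, k=5)
        assert [h.chunk.chunk_id for h in a] == [h.chunk.chunk_id for h in b]


class TestRerank:
    def make_hits(self, n, embedder):
        texts = [f"chunk {i} filler tokens" for i in range(n)]
        chunks = [Chunk(doc_id=f"D{i}", chunk_index=0, text=t,
                        char_span=(0, len(t))) for i, t in enumerate(texts)]
        index = build_index(chunks, embedder)
        return dense_retrieve("chunk filler", index, embedder, k=n)

    def test_25_in_10_out(self, embedder):
        hits = self.make_hits(25, embedder)
        assert len(rerank("chunk filler", hits, k=10)) == 10

    def test_fewer_hits_than_k_all_returned(self, embedder):
        hits = self.make_hits(4, embedder)
        assert len(rerank("chunk filler", hits, k=10)) == 4

    def test_equal_scores_preserve_dense_order(self, embedder):
        hits = self.make_hits(6, embedder)
        reranked = rerank("no overlap at all xyz", hits, k=6)
        assert [h.chunk.chunk_id for h in reranked] == \
            [h.chunk.chunk_id for h in hits]

    def test_overlap_reorders(self, embedder):
        chunks = [
            Chunk(doc_id="A", chunk_index=0, text="nothing relevant",
                  char_span=(0, 5)),
            Chunk(doc_id="B", chunk_index=0,
                  text="IL10 sepsis biomarker evidence", char_span=(0, 5)),
        ]
        index = build_index(chunks, embedder)
        hits = dense_retrieve("nothing relevant", index, embedder, k=2)
        reranked = rerank("IL10 sepsis biomarker", hits, k=2)
        assert reranked[0].chunk.doc_id == "B"
        assert reranked[0].rerank_score > reranked[1].rerank_score

    def test_k_below_one_rejected(self, embedder):
        with pytest.raises(ConfigError):
            rerank("q", self.make_hits(3, embedder), k=0)


def make_bundle(gene, criterion, toy_index, embedder, k=3):
    hits = dense_retrieve(f"{gene} sepsis", toy_index, embedder, k=k)
    return ContextBundle(gene=gene, criterion=criterion, hits=hits)


class TestRagAssess:
    def test_valid_citation_subset(self, toy_index, embedder, templates,
                                   rubric):
        bundle = make_bundle("IL10", CRITERIA[0], toy_index, embedder)
        cited = ", ".join(bundle.source_ids[:2])
        table = ScriptTable()
        table.add(Stage.RAG_SYNTH, "IL10", CRITERIA[0],
                  f"score: 8\njustification: grounded\nsources: {cited}")
        result = rag_assess("IL10", CRITERIA[0], bundle,
                            ScriptedBackend(table), templates["rag_synth"],
                            rubric)
        assert result.ok
        assert result.category == "High"

    def test_foreign_citation_flags_attribution_error(self, toy_index,
                                                      embedder, templates,
                                                      rubric):
        bundle = make_bundle("IL10", CRITERIA[0], toy_index, embedder)
        table = ScriptTable()
        table.add(Stage.RAG_SYNTH, "IL10", CRITERIA[0],
                  "score: 8\nsources: NOT_IN_BUNDLE:0")
        result = rag_assess("IL10", CRITERIA[0], bundle,
                            ScriptedBackend(table), templates["rag_synth"],
                            rubric)
        assert not result.ok
        assert result.attribution_errors == ("NOT_IN_BUNDLE:0",)

    def test_empty_bundle_conservative_zero(self, templates, rubric):
        bundle = ContextBundle(gene="G1", criterion=CRITERIA[0], hits=[])
        result = rag_assess("G1", CRITERIA[0], bundle,
                            ScriptedBackend(ScriptTable()),
                            templates["rag_synth"], rubric)
        assert result.judgment.score == 0
        assert result.category == "Low"
        assert result.judgment.justification == "no retrieved evidence"

    def test_bundle_gene_mismatch_isolation_error(self, toy_index, embedder,
                                                  templates, rubric):
        bundle = make_bundle("IL10", CRITERIA[0], toy_index, embedder)
        with pytest.raises(IsolationError):
            rag_assess("TREM1", CRITERIA[0], bundle,
                       ScriptedBackend(ScriptTable()),
                       templates["rag_synth"], rubric)


class TestFaithfulness:
    @pytest.mark.parametrize("raw,expected", [
        ("verdict: Pass", "Pass"), ("verdict: Fail", "Fail"),
        ("Pass", "Pass"), ("  fail  ", "Fail"),
    ])
    def test_parse_verdict(self, raw, expected):
        assert parse_verdict(raw) == expected

    @pytest.mark.parametrize("raw", ["maybe", "", "verdict: unsure"])
    def test_malformed_verdict(self, raw):
        with pytest.raises(MalformedVerdictError):
            parse_verdict(raw)

    def test_evaluate_faithfulness_pass_and_fail(self, toy_index, embedder,
                                                 templates, rubric):
        for verdict_text in ("verdict: Pass", "verdict: Fail"):
            bundle = make_bundle("IL10", CRITERIA[0], toy_index, embedder)
            rag_table = ScriptTable()
            rag_table.add(Stage.RAG_SYNTH, "IL10", CRITERIA[0],
                          "score: 7\njustification: grounded")
            assessment = rag_assess("IL10", CRITERIA[0], bundle,
                                    ScriptedBackend(rag_table),
                                    templates["rag_synth"], rubric)
            judge_table = ScriptTable()
            judge_table.add(Stage.FAITH_JUDGE, "IL10", CRITERIA[0],
                            verdict_text)
            verdict = evaluate_faithfulness(assessment, bundle,
                                            ScriptedBackend(judge_table),
                                            templates["faith_judge"])
            assert verdict.verdict == verdict_text.split()[-1]

    def test_pass_rate_formatting(self):
        verdicts = [FaithfulnessVerdict(query_id=f"q{i}", evaluator_id="e",
                                        verdict="Pass" if i < 1484 else "Fail")
                    for i in range(4872)]
        assert pass_rate(verdicts) == 30.5


class TestDualAgreement:
    def test_identical_tables_full_agreement(self):
        a = {f"q{i}": "Pass" for i in range(10)}
        assert dual_agreement(a, dict(a)).overall_agreement == 100.0

    def test_complementary_tables_zero_agreement(self):
        a = {f"q{i}": "Pass" for i in range(10)}
        b = {f"q{i}": "Fail" for i in range(10)}
        assert dual_agreement(a, b).overall_agreement == 0.0

    def test_rounding_of_agreement_share(self):
        # 2107 concordant of 2928 -> 71.9603...% -> 72.0 at one decimal
        a = {f"q{i}": "Pass" for i in range(2928)}
        b = {f"q{i}": ("Pass" if i < 2107 else "Fail") for i in range(2928)}
        report = dual_agreement(a, b)
        assert report.n_instances == 2928
        assert report.overall_agreement == 72.0

    def test_subgroup_agreement(self):
        a = {"q1": "Pass", "q2": "Pass", "q3": "Pass", "q4": "Fail"}
        b = {"q1": "Pass", "q2": "Fail", "q3": "Pass", "q4": "Fail"}
        subgroup = {"q1": "High", "q2": "High", "q3": "Low", "q4": "Low"}
        report = dual_agreement(a, b, subgroup)
        assert report.subgroup_agreements == {"High": 50.0, "Low": 100.0}

    def test_disjoint_tables_rejected(self):
        with pytest.raises(ConfigError):
            dual_agreement({"a": "Pass"}, {"b": "Pass"})
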