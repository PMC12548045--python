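"""Knowledge-base construction for retrieval.

Ingests literature records (JSONL), filters full documents by citation
percentile (records without a percentile — typically paywalled abstracts
— are always kept), strips trailing reference sections, segments into
overlapping character chunks, tags gene mentions against a lexicon, and
builds a metadata-rich cosine-geometry vector index.

The embedder is a contract: any object with an ``embedder_id``, a
``dim`` and an ``embed(texts)`` method producing unit-normalized row
vectors.  The default is a deterministic hashed bag-of-words vectorizer,
so index builds and queries are reproducible across platforms with no
model weights; transformer document embedders can be plugged in behind
the same contract.  An index refuses queries from any embedder other
than the one it was built with.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np

from .errors import (
    ConfigError,
    CorpusParseError,
    DuplicateDocumentError,
    EmbedderMismatchError,
)

DOC_TYPES = ("article", "review", "abstract")


@dataclass(frozen=True)
class DocumentRecord:
    doc_id: str
    title: str
    year: int
    doc_type: str
    text: str
    citation_percentile: float | None = None

    def __post_init__(self) -> None:
        if self.doc_type not in DOC_TYPES:
            raise ValueError(f"{self.doc_id}: unknown doc_type {self.doc_type!r}")
        if not 1900 <= self.year <= 2100:
            raise ValueError(f"{self.doc_id}: implausible year {self.year}")
        if self.citation_percentile is not None and not (
                0.0 <= self.citation_percentile <= 1.0):
            raise ValueError(f"{self.doc_id}: percentile outside [0,1]")


@dataclass
class IngestReport:
    kept_by_type: dict[str, int] = field(default_factory=dict)
    dropped_by_type: dict[str, int] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return sum(self.kept_by_type.values())

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped_by_type.values())

    @property
    def n_input(self) -> int:
        return self.n_kept + self.n_dropped


def ingest_corpus(source: str | Path | Iterable[object],
                  percentile_min: float = 0.8,
                  apply_filter: bool = True,
                  ) -> tuple[list[DocumentRecord], IngestReport]:
    """Read JSONL literature records and apply the citation filter.

    With the filter on, records whose citation percentile is at or below
    ``percentile_min`` are dropped; records lacking a percentile are
    kept unconditionally.  Duplicate doc ids and unparseable lines are
    hard errors naming the offender.
    """
    if isinstance(source, (str, Path)):
        items: Iterable[object] = Path(source).read_text().splitlines()
    else:
        items = source
    records: list[DocumentRecord] = []
    report = IngestReport()
    seen: set[str] = set()
    for lineno, item in enumerate(items, start=1):
        if isinstance(item, str):
            if not item.strip():
                continue
            try:
                payload = json.loads(item)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(f"unparseable record at line {lineno}") from exc
        elif isinstance(item, DocumentRecord):
            payload = {
                "id": item.doc_id, "title": item.title, "year": item.year,
                "type": item.doc_type, "text": item.text,
                "citation_percentile": item.citation_percentile,
            }
        else:
            payload = dict(item)  # type: ignore[arg-type]
        try:
            record = DocumentRecord(
                doc_id=str(payload["id"]),
                title=str(payload.get("title", "")),
                year=int(payload["year"]),
                doc_type=str(payload["type"]),
                text=str(payload.get("text", "")),
                citation_percentile=(
                    None if payload.get("citation_percentile") is None
                    else float(payload["citation_percentile"])),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise CorpusParseError(f"invalid record at line {lineno}: {exc}") from exc
        if record.doc_id in seen:
            raise DuplicateDocumentError(f"duplicate doc_id: {record.doc_id!r}")
        seen.add(record.doc_id)
        keep = (not apply_filter
                or record.citation_percentile is None
                or record.citation_percentile > percentile_min)
        bucket = report.kept_by_type if keep else report.dropped_by_type
        bucket[record.doc_type] = bucket.get(record.doc_type, 0) + 1
        if keep:
            records.append(record)
    return records, report


# ---------------------------------------------------------------------------
# preprocessing and chunking


_REFERENCE_HEADING_RE = re.compile(r"(?mi)^\s*(references|bibliography)\s*:?\s*$")


def strip_references(text: str) -> str:
    """Drop a trailing reference/bibliography block, if present.

    Heuristic: truncate at the last standalone 'References' or
    'Bibliography' heading line.
    """
    matches = list(_REFERENCE_HEADING_RE.finditer(text))
    if matches:
        return text[: matches[-1].start()].rstrip()
    return text.rstrip()


@dataclass
class Chunk:
    """A contiguous span of a preprocessed document.

    ``char_span`` is 0-based and half-open in the preprocessed text;
    consecutive chunks of one document overlap by the configured number
    of characters.
    """

    doc_id: str
    chunk_index: int
    text: str
    char_span: tuple[int, int]
    entities: list[str] = field(default_factory=list)
    doc_type: str = "article"
    year: int = 2000

    @property
    def chunk_id(self) -> str:
        return f"{self.doc_id}:{self.chunk_index}"


def preprocess_and_chunk(doc: DocumentRecord,
                         chunk_chars: int = 1500,
                         overlap_chars: int = 150) -> list[Chunk]:
    """Strip the reference section, then cut overlapping character chunks.

    The chunk spans tile the preprocessed text with stride
    ``chunk_chars - overlap_chars``; the final chunk may be short.
    Reassembling the chunks (dropping each overlap) reconstructs the
    preprocessed text exactly.
    """
    if overlap_chars < 0 or chunk_chars <= overlap_chars:
        raise ConfigError(
            f"need chunk_chars > overlap_chars >= 0, "
            f"got {chunk_chars}/{overlap_chars}")
    body = strip_references(doc.text)
    if not body:
        return []
    stride = chunk_chars - overlap_chars
    chunks: list[Chunk] = []
    start = 0
    index = 0
    while True:
        end = min(start + chunk_chars, len(body))
        chunks.append(Chunk(doc_id=doc.doc_id, chunk_index=index,
                            text=body[start:end], char_span=(start, end),
                            doc_type=doc.doc_type, year=doc.year))
        if end >= len(body):
            break
        start += stride
        index += 1
    return chunks


_TOKEN_RE = re.compile(r"[A-Za-z0-9-]+")


def tag_entities(chunk: Chunk, lexicon: Iterable[str],
                 case_sensitive: bool = True) -> Chunk:
    """Attach gene symbols from ``lexicon`` matched as whole tokens.

    Duplicates collapse; the entity list is sorted for determinism.  A
    substring inside a longer token ('IL10' in 'interleukin10X' tokens)
    never matches.
    """
    lex = set(lexicon)
    if not lex:
        raise ConfigError("entity lexicon is empty")
    tokens = set(_TOKEN_RE.findall(chunk.text))
    if case_sensitive:
        hits = tokens & lex
    else:
        lower = {symbol.lower(): symbol for symbol in lex}
        hits = {lower[t.lower()] for t in tokens if t.lower() in lower}
    chunk.entities = sorted(hits)
    return chunk


# ---------------------------------------------------------------------------
# embedding


class Embedder(Protocol):
    embedder_id: str
    dim: int

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        ...


class HashingEmbedder:
    """Deterministic hashed bag-of-words embedder with cosine geometry.

    Lower-cased alphanumeric tokens are hashed (MD5, platform-stable)
    into ``dim`` buckets; vectors are term-count based and
    L2-normalized.  Purely lexical — it captures token overlap, not
    semantics — but deterministic, dependency-free and sufficient for
    exercising the retrieval contract.
    """

    def __init__(self, dim: int = 256):
        if dim < 8:
            raise ConfigError("embedding dimension too small")
        self.dim = dim
        self.embedder_id = f"hashed-bow-{dim}"

    @staticmethod
    def _bucket(token: str, dim: int) -> int:
        digest = hashlib.md5(token.encode("utf-8")).digest()
        return int.from_bytes(digest[:8], "big") % dim

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        matrix = np.zeros((len(texts), self.dim), dtype=np.float64)
        for row, text in enumerate(texts):
            for token in _TOKEN_RE.findall(text.lower()):
                matrix[row, self._bucket(token, self.dim)] += 1.0
        norms = np.linalg.norm(matrix, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return matrix / norms


# ---------------------------------------------------------------------------
# vector index


@dataclass
class CorpusIndex:
    """Chunk vectors plus metadata, queryable by cosine similarity."""

    chunks: list[Chunk]
    vectors: np.ndarray
    embedder_id: str
    chunk_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.chunks) != self.vectors.shape[0]:
            raise ConfigError("one vector per chunk required")

    def __len__(self) -> int:
        return len(self.chunks)

    def query(self, query_text: str, k: int, embedder: Embedder
              ) -> list[tuple[Chunk, float]]:
        """Top-k chunks by cosine similarity, ties broken by chunk id."""
        if embedder.embedder_id != self.embedder_id:
            raise EmbedderMismatchError(
                f"index built with {self.embedder_id!r}, "
                f"queried with {embedder.embedder_id!r}")
        qvec = embedder.embed([query_text])[0]
        sims = self.vectors @ qvec
        order = sorted(range(len(self.chunks)),
                       key=lambda i: (-sims[i], self.chunks[i].chunk_id))
        return [(self.chunks[i], float(sims[i])) for i in order[:k]]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "vectors.npz", vectors=self.vectors)
        metadata = [{
            "doc_id": c.doc_id, "chunk_index": c.chunk_index, "text": c.text,
            "char_span": list(c.char_span), "entities": c.entities,
            "doc_type": c.doc_type, "year": c.year,
        } for c in self.chunks]
        (directory / "metadata.json").write_text(json.dumps(metadata))
        (directory / "manifest.json").write_text(json.dumps({
            "embedder_id": self.embedder_id,
            "chunk_params": self.chunk_params,
            "n_chunks": len(self.chunks),
        }))

    @classmethod
    def load(cls, directory: str | Path) -> "CorpusIndex":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        metadata = json.loads((directory / "metadata.json").read_text())
        with np.load(directory / "vectors.npz") as data:
            vectors = data["vectors"]
        chunks = [Chunk(doc_id=m["doc_id"], chunk_index=m["chunk_index"],
                        text=m["text"], char_span=tuple(m["char_span"]),
                        entities=list(m["entities"]), doc_type=m["doc_type"],
                        year=m["year"])
                  for m in metadata]
        return cls(chunks=chunks, vectors=vectors,
                   embedder_id=manifest["embedder_id"],
                   chunk_params=manifest["chunk_params"])


def build_index(chunks: Sequence[Chunk], embedder: Embedder,
                chunk_params: dict | None = None) -> CorpusIndex:
    """Embed all chunks and assemble the queryable index."""
    vectors = embedder.embed([c.text for c in chunks])
    if vectors.ndim != 2 or vectors.shape[0] != len(chunks):
        raise ConfigError("embedder returned wrong-shaped matrix")
    return CorpusIndex(chunks=list(chunks), vectors=vectors,
                       embedder_id=embedder.embedder_id,
                       chunk_params=dict(chunk_params or {}))


def build_index_from_records(records: Sequence[DocumentRecord],
                             embedder: Embedder,
                             lexicon: Iterable[str] | None = None,
                             chunk_chars: int = 1500,
                             overlap_chars: int = 150) -> CorpusIndex:
    """Convenience: preprocess, chunk, (optionally) tag, embed, index."""
    chunks: list[Chunk] = []
    for record in records:
        chunks.extend(preprocess_and_chunk(record, chunk_chars, overlap_chars))
    if lexicon is not None:
        lex = list(lexicon)
        for chunk in chunks:
            tag_entities(chunk, lex)
    return build_index(chunks, embedder,
                       chunk_params={"chunk_chars": chunk_chars,
                                     "overlap_chars": overlap_chars})
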