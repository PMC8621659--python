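"""Turn raw bibliographic records into the three ingredients of a topic model.

A topic model needs (i) a *corpus* — here the concatenated titles and
abstracts of PubMed-style records, (ii) a *dictionary* mapping each retained
word to a dense integer ID, and (iii) bag-of-words count vectors. This module
owns those three containers and the deterministic preprocessing that fills
them: lowercasing, stripping non-alphabetic characters, stopword and
minimum-length filtering, and document-frequency pruning of the vocabulary.

Everything is deterministic: dictionary IDs are assigned lexicographically so
the same input files always yield byte-identical dictionaries and corpora,
regardless of record order.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

_WORD_RE = re.compile(r"[a-z]+")


class EmptyDocumentError(ValueError):
    """Raised when a record has neither title nor abstract text."""


class EmptyVocabularyError(ValueError):
    """Raised when document-frequency filtering removes every word."""


class ParseError(ValueError):
    """Raised on malformed input files; the message names the offending record."""


@dataclass
class Article:
    """One bibliographic record (PMID when available) with its token list."""

    id: str
    title: str = ""
    abstract: str = ""
    tokens: list[str] = field(default_factory=list)

    def text(self) -> str:
        return f"{self.title} {self.abstract}".strip()


def default_stopwords() -> frozenset[str]:
    """English stopword list shipped with the package."""
    text = resources.files("litmine.data").joinpath("stopwords_en.txt").read_text()
    return frozenset(w for w in text.split() if w and not w.startswith("#"))


def tokenise(
    article: Article,
    stopwords: Iterable[str] | None = None,
    min_len: int = 3,
) -> Article:
    """Fill ``article.tokens`` from its title + abstract.

    Lowercases, keeps maximal runs of ASCII letters, drops stopwords and
    words shorter than ``min_len``. Deterministic for fixed inputs.

    Raises
    ------
    EmptyDocumentError
        If both title and abstract are empty.
    """
    if not article.title.strip() and not article.abstract.strip():
        raise EmptyDocumentError(f"empty document: article {article.id!r}")
    stop = frozenset(stopwords) if stopwords is not None else default_stopwords()
    words = _WORD_RE.findall(article.text().lower())
    article.tokens = [w for w in words if len(w) >= min_len and w not in stop]
    return article


def tokenise_all(
    articles: Sequence[Article],
    stopwords: Iterable[str] | None = None,
    min_len: int = 3,
) -> list[Article]:
    stop = frozenset(stopwords) if stopwords is not None else default_stopwords()
    return [tokenise(a, stop, min_len) for a in articles]


@dataclass
class Dictionary:
    """Bijection word <-> dense integer ID, with per-word document frequencies."""

    word_to_id: dict[str, int]
    doc_freq: dict[str, int]

    @property
    def id_to_word(self) -> dict[int, str]:
        return {i: w for w, i in self.word_to_id.items()}

    def __len__(self) -> int:
        return len(self.word_to_id)

    def __contains__(self, word: str) -> bool:
        return word in self.word_to_id

    def words(self) -> list[str]:
        """Vocabulary in ID order."""
        inv = self.id_to_word
        return [inv[i] for i in range(len(inv))]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\tword\tdoc_freq\n")
            for word in self.words():
                fh.write(f"{self.word_to_id[word]}\t{word}\t{self.doc_freq[word]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Dictionary":
        word_to_id: dict[str, int] = {}
        doc_freq: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if header.strip() != "id\tword\tdoc_freq":
                raise ParseError(f"unexpected dictionary header in {path}")
            for lineno, line in enumerate(fh, start=2):
                try:
                    sid, word, sdf = line.rstrip("\n").split("\t")
                    word_to_id[word] = int(sid)
                    doc_freq[word] = int(sdf)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: malformed row") from exc
        return cls(word_to_id, doc_freq)


def build_dictionary(
    articles: Sequence[Article],
    no_below: int = 1,
    no_above: float = 1.0,
) -> Dictionary:
    """Build the word->ID dictionary from tokenised articles.

    A word is retained iff its document frequency is >= ``no_below`` and
    <= ``no_above`` * n_docs. IDs are assigned in lexicographic order so the
    dictionary is independent of record order.

    Raises
    ------
    EmptyVocabularyError
        If the filters remove every word.
    """
    n_docs = len(articles)
    df: dict[str, int] = {}
    for art in articles:
        for w in set(art.tokens):
            df[w] = df.get(w, 0) + 1
    kept = sorted(w for w, c in df.items() if c >= no_below and c <= no_above * n_docs)
    if not kept:
        raise EmptyVocabularyError(
            f"empty vocabulary: no word survives no_below={no_below}, no_above={no_above}"
        )
    return Dictionary({w: i for i, w in enumerate(kept)}, {w: df[w] for w in kept})


@dataclass
class BowCorpus:
    """Sparse bag-of-words corpus: one (word_id, count) vector per document."""

    docs: list[list[tuple[int, int]]]
    vocab_size: int
    doc_ids: list[str] = field(default_factory=list)
    empty_flags: list[bool] = field(default_factory=list)
    n_oov_dropped: int = 0

    @property
    def n_docs(self) -> int:
        return len(self.docs)

    def doc_lengths(self) -> np.ndarray:
        return np.array([sum(c for _, c in d) for d in self.docs], dtype=np.int64)

    @property
    def n_tokens(self) -> int:
        return int(self.doc_lengths().sum())

    def to_sparse(self) -> scipy.sparse.csr_matrix:
        """Docs x vocab CSR count matrix."""
        rows, cols, vals = [], [], []
        for d, doc in enumerate(self.docs):
            for w, c in doc:
                rows.append(d)
                cols.append(w)
                vals.append(c)
        return scipy.sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n_docs, self.vocab_size), dtype=np.int64
        )

    def to_mtx(self, path: str | Path) -> None:
        """Write MatrixMarket sparse counts plus a doc-id sidecar list."""
        path = Path(path)
        scipy.io.mmwrite(str(path), self.to_sparse())
        ids = self.doc_ids or [str(i) for i in range(self.n_docs)]
        path.with_suffix(".docids.txt").write_text("\n".join(ids) + "\n")

    @classmethod
    def from_mtx(cls, path: str | Path) -> "BowCorpus":
        path = Path(path)
        mat = scipy.sparse.csr_matrix(scipy.io.mmread(str(path)))
        sidecar = path.with_suffix(".docids.txt")
        doc_ids = (
            sidecar.read_text().splitlines() if sidecar.exists() else []
        )
        docs = []
        for d in range(mat.shape[0]):
            row = mat.getrow(d)
            docs.append(
                sorted(zip(row.indices.tolist(), row.data.astype(int).tolist()))
            )
        return cls(
            docs=docs,
            vocab_size=mat.shape[1],
            doc_ids=doc_ids,
            empty_flags=[len(d) == 0 for d in docs],
        )


def bow_vector(tokens: Iterable[str], dictionary: Dictionary) -> tuple[list[tuple[int, int]], int]:
    """One document's (word_id, count) vector; returns (vector, n_oov_dropped)."""
    counts: dict[int, int] = {}
    oov = 0
    for tok in tokens:
        wid = dictionary.word_to_id.get(tok)
        if wid is None:
            oov += 1
        else:
            counts[wid] = counts.get(wid, 0) + 1
    return sorted(counts.items()), oov


def to_bow(articles: Sequence[Article], dictionary: Dictionary) -> BowCorpus:
    """Bag-of-words corpus over the dictionary.

    Out-of-vocabulary tokens are dropped silently but counted in the corpus
    log (``n_oov_dropped``); documents left empty are retained and flagged.
    """
    docs, flags, ids = [], [], []
    total_oov = 0
    for art in articles:
        vec, oov = bow_vector(art.tokens, dictionary)
        total_oov += oov
        docs.append(vec)
        flags.append(len(vec) == 0)
        ids.append(art.id)
    if total_oov:
        logger.info("to_bow: dropped %d out-of-vocabulary tokens", total_oov)
    return BowCorpus(
        docs=docs,
        vocab_size=len(dictionary),
        doc_ids=ids,
        empty_flags=flags,
        n_oov_dropped=total_oov,
    )


def read_records(path: str | Path, format: str = "csv") -> list[Article]:
    """Read bibliographic records from CSV (id,title,abstract) or MEDLINE text.

    Records missing both title and abstract are reported and skipped.
    """
    if format == "csv":
        return _read_csv(path)
    if format == "medline":
        return _read_medline(path)
    raise ValueError(f"unknown record format {format!r}")


def _read_csv(path: str | Path) -> list[Article]:
    articles = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "title", "abstract"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(
                f"{path}: CSV must have columns id,title,abstract "
                f"(found {reader.fieldnames})"
            )
        for i, row in enumerate(reader, start=2):
            rid = (row.get("id") or "").strip()
            if not rid:
                raise ParseError(f"{path}: row {i}: empty id")
            title = (row.get("title") or "").strip()
            abstract = (row.get("abstract") or "").strip()
            if not title and not abstract:
                logger.warning("%s: row %d (%s): no title or abstract, skipped", path, i, rid)
                continue
            articles.append(Article(id=rid, title=title, abstract=abstract))
    return articles


def _read_medline(path: str | Path) -> list[Article]:
    from Bio import Medline

    articles = []
    with open(path, encoding="utf-8") as fh:
        for n, rec in enumerate(Medline.parse(fh), start=1):
            pmid = rec.get("PMID", "")
            if not pmid:
                raise ParseError(f"{path}: record {n}: missing PMID")
            title = rec.get("TI", "") or ""
            ab = rec.get("AB", "") or ""
            if not title and not ab:
                logger.warning("%s: record %d (PMID %s): no TI or AB, skipped", path, n, pmid)
                continue
            articles.append(Article(id=pmid, title=title, abstract=ab))
    return articles


def write_records_csv(articles: Sequence[Article], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "title", "abstract"])
        for a in articles:
            writer.writerow([a.id, a.title, a.abstract])
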