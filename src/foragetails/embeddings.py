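"""Word-embedding table with word2vec-format I/O.

Semantic distances between fluency productions are computed as
``1 - cosine similarity`` between fixed word vectors.  This module holds
the in-memory table and reads/writes the plain word2vec exchange formats
(text: a ``count dim`` header then one ``token v1 ... vd`` row per word;
binary: the same header line followed by ``token + b' '`` and ``dim``
little-endian float32 values per word).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np


class EmbeddingFormatError(ValueError):
    """Malformed word2vec file (bad header, row width, or zero vector)."""


class OutOfVocabularyError(KeyError):
    """Token absent from the embedding vocabulary.

    Signalled distinctly so that path-level callers can skip the pair and
    increment ``skipped_pairs`` instead of aborting the whole list.
    """


def normalize_token(token: str) -> str:
    """Lower-case, trim, and map internal whitespace to underscores."""
    return "_".join(token.strip().lower().split())


@dataclasses.dataclass
class EmbeddingTable:
    tokens: list[str]
    vectors: np.ndarray  # (n_tokens, dimension) float64

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.tokens):
            raise EmbeddingFormatError("vectors must be (n_tokens, dimension)")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0):
            bad = self.tokens[int(np.argmin(norms))]
            raise EmbeddingFormatError(f"zero-norm vector for token {bad!r}")
        self._index = {tok: i for i, tok in enumerate(self.tokens)}

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    @property
    def vocabulary(self) -> set[str]:
        return set(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return normalize_token(token) in self._index

    def vector(self, token: str) -> np.ndarray:
        key = normalize_token(token)
        try:
            return self.vectors[self._index[key]]
        except KeyError:
            raise OutOfVocabularyError(key) from None

    def restrict(self, vocabulary: Iterable[str]) -> "EmbeddingTable":
        keep = {normalize_token(t) for t in vocabulary}
        idx = [i for i, t in enumerate(self.tokens) if t in keep]
        return EmbeddingTable([self.tokens[i] for i in idx], self.vectors[idx])


def _parse_header(line: bytes) -> tuple[int, int]:
    parts = line.split()
    if len(parts) != 2:
        raise EmbeddingFormatError(f"malformed header {line!r}: expected 'count dim'")
    try:
        count, dim = int(parts[0]), int(parts[1])
    except ValueError:
        raise EmbeddingFormatError(f"malformed header {line!r}") from None
    if count < 0 or dim <= 0:
        raise EmbeddingFormatError(f"malformed header {line!r}")
    return count, dim


def _load_text(path: Path) -> tuple[list[str], np.ndarray]:
    with path.open("rb") as fh:
        count, dim = _parse_header(fh.readline())
        tokens, rows = [], np.empty((count, dim))
        for i in range(count):
            line = fh.readline()
            if not line:
                raise EmbeddingFormatError(f"expected {count} rows, file ended at {i}")
            parts = line.decode("utf-8").rstrip("\n").split(" ")
            token, values = parts[0], parts[1:]
            if len(values) != dim:
                raise EmbeddingFormatError(
                    f"token {token!r}: {len(values)} values, declared dimension {dim}"
                )
            tokens.append(token)
            rows[i] = [float(v) for v in values]
    return tokens, rows


def _load_binary(path: Path) -> tuple[list[str], np.ndarray]:
    with path.open("rb") as fh:
        count, dim = _parse_header(fh.readline())
        tokens, rows = [], np.empty((count, dim))
        for i in range(count):
            chars = bytearray()
            while True:
                ch = fh.read(1)
                if not ch:
                    raise EmbeddingFormatError(f"expected {count} rows, file ended at {i}")
                if ch == b" ":
                    break
                if ch != b"\n":  # some writers prefix rows with a newline
                    chars.extend(ch)
            token = chars.decode("utf-8")
            buf = fh.read(4 * dim)
            if len(buf) != 4 * dim:
                raise EmbeddingFormatError(f"token {token!r}: truncated vector")
            tokens.append(token)
            rows[i] = np.frombuffer(buf, dtype="<f4")
    return tokens, rows


def load_embeddings(
    source: str | Path,
    vocabulary_filter: Iterable[str] | None = None,
    binary: bool | None = None,
) -> EmbeddingTable:
    """Load a word2vec text or binary file into an :class:`EmbeddingTable`.

    ``binary=None`` auto-detects (text parse attempted first).  Tokens are
    normalised (lower-case, spaces to underscores); on duplicate keys the
    first occurrence wins.  ``vocabulary_filter`` restricts the table to
    the given tokens.
    """
    path = Path(source)
    if binary is None:
        try:
            tokens, rows = _load_text(path)
        except (UnicodeDecodeError, ValueError) as exc:
            if isinstance(exc, EmbeddingFormatError) and "malformed header" in str(exc):
                raise
            tokens, rows = _load_binary(path)
    elif binary:
        tokens, rows = _load_binary(path)
    else:
        tokens, rows = _load_text(path)

    normed: list[str] = []
    keep_rows: list[int] = []
    seen: set[str] = set()
    for i, tok in enumerate(tokens):
        key = normalize_token(tok)
        if key in seen:
            continue
        seen.add(key)
        normed.append(key)
        keep_rows.append(i)
    table = EmbeddingTable(normed, rows[keep_rows])
    if vocabulary_filter is not None:
        table = table.restrict(vocabulary_filter)
    return table


def save_embeddings(
    table: EmbeddingTable, path: str | Path, binary: bool = False, fmt: str = "%.8f"
) -> None:
    """Write the table in word2vec text (default) or binary format."""
    path = Path(path)
    if binary:
        with path.open("wb") as fh:
            fh.write(f"{len(table)} {table.dimension}\n".encode())
            for tok, vec in zip(table.tokens, table.vectors):
                fh.write(tok.encode("utf-8") + b" ")
                fh.write(np.asarray(vec, dtype="<f4").tobytes())
                fh.write(b"\n")
    else:
        with path.open("w") as fh:
            fh.write(f"{len(table)} {table.dimension}\n")
            for tok, vec in zip(table.tokens, table.vectors):
                fh.write(tok + " " + " ".join(fmt % v for v in vec) + "\n")
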