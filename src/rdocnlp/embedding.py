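"""Sentence-embedding backends and cosine similarity.

Two interchangeable backends sit behind one small contract (``name``,
``dim``, ``embed_batch``):

* :func:`hashing_embedder` — a deterministic character-n-gram feature
  hashing embedder (signed hashing trick, L2-normalized).  It needs no
  model download, is stable across processes and platforms (fixed BLAKE2
  hash, no environment-dependent salting), and is the backend every test
  runs on.
* :func:`pretrained_backend` — an optional wrapper around a
  sentence-transformers model (the 768-dimensional ``all-mpnet-base-v2``
  by default).  Its absence never breaks any other module.

The matcher depends on a backend only through pairwise cosine
similarities, so backends are freely substitutable.
"""

from __future__ import annotations

import logging
from hashlib import blake2b
from typing import Protocol, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingBackend",
    "HashingEmbedder",
    "MissingBackendError",
    "cosine_similarity",
    "hashing_embedder",
    "pretrained_backend",
]


class EmbeddingBackend(Protocol):
    name: str
    dim: int

    def embed_batch(self, texts: Sequence[str]) -> np.ndarray: ...


class MissingBackendError(RuntimeError):
    """The optional pretrained embedding dependency is not installed."""


def cosine_similarity(a, b) -> float:
    """dot(a, b) / (||a|| ||b||), clamped to [-1, 1].

    A zero vector on either side yields similarity 0.0 (with a warning)
    rather than an error, keeping the pipeline total on degenerate inputs
    such as the hashing embedding of an empty string.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        logger.warning("cosine similarity of a zero vector defined as 0.0")
        return 0.0
    return float(np.clip(float(a @ b) / (na * nb), -1.0, 1.0))


# (dim, ngram) -> (index, sign); shared across embedder instances
_NGRAM_SLOTS: dict[tuple[int, str], tuple[int, float]] = {}


def _slot(ngram: str, dim: int) -> tuple[int, float]:
    key = (dim, ngram)
    slot = _NGRAM_SLOTS.get(key)
    if slot is None:
        h = blake2b(ngram.encode("utf-8"), digest_size=5).digest()
        idx = int.from_bytes(h[:4], "big") % dim
        sign = 1.0 if h[4] & 1 else -1.0
        slot = (idx, sign)
        _NGRAM_SLOTS[key] = slot
    return slot


class HashingEmbedder:
    """Character-n-gram feature hashing with the signed hashing trick.

    Text is lowercased, whitespace-collapsed and padded with single spaces;
    every character n-gram for n in ``ngram_range`` contributes +-1 (sign
    from a fixed BLAKE2 hash) to one of ``dim`` buckets; the result is
    L2-normalized.  An empty string embeds to the zero vector.
    """

    def __init__(self, dim: int = 256, ngram_range: tuple[int, int] = (3, 5)):
        if dim < 16:
            raise ValueError("dim must be >= 16")
        lo, hi = ngram_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad ngram_range {ngram_range!r}")
        self.dim = dim
        self.ngram_range = (lo, hi)
        self.name = f"hashing-{dim}-ngram{lo}.{hi}"
        self._cache: dict[str, np.ndarray] = {}

    def _embed_one(self, text: str) -> np.ndarray:
        cached = self._cache.get(text)
        if cached is not None:
            return cached
        vec = np.zeros(self.dim)
        norm = " ".join(text.lower().split())
        if norm:
            padded = f" {norm} "
            lo, hi = self.ngram_range
            for n in range(lo, hi + 1):
                for i in range(len(padded) - n + 1):
                    idx, sign = _slot(padded[i : i + n], self.dim)
                    vec[idx] += sign
            nrm = np.linalg.norm(vec)
            if nrm > 0:
                vec /= nrm
        vec.setflags(write=False)
        self._cache[text] = vec
        return vec

    def embed_batch(self, texts: Sequence[str]) -> np.ndarray:
        if len(texts) == 0:
            return np.zeros((0, self.dim))
        return np.stack([self._embed_one(t) for t in texts])


def hashing_embedder(dim: int = 256, ngram_range: tuple[int, int] = (3, 5)) -> HashingEmbedder:
    """Construct the offline deterministic hashing backend."""
    return HashingEmbedder(dim=dim, ngram_range=ngram_range)


class _PretrainedBackend:
    def __init__(self, model, name: str):
        self._model = model
        self.name = name
        self.dim = int(model.get_sentence_embedding_dimension())
        self._cache: dict[str, np.ndarray] = {}

    def embed_batch(self, texts: Sequence[str]) -> np.ndarray:
        missing = [t for t in texts if t not in self._cache]
        if missing:
            vecs = self._model.encode(missing, convert_to_numpy=True, show_progress_bar=False)
            for t, v in zip(missing, np.asarray(vecs, dtype=float)):
                self._cache[t] = v
        if len(texts) == 0:
            return np.zeros((0, self.dim))
        return np.stack([self._cache[t] for t in texts])


def pretrained_backend(model_name: str = "sentence-transformers/all-mpnet-base-v2"):
    """Load a pretrained sentence-transformer backend (768-dim default model).

    Raises :class:`MissingBackendError` with guidance to fall back to
    :func:`hashing_embedder` when the optional dependency is unavailable.
    """
    try:
        from sentence_transformers import SentenceTransformer
    except ImportError as exc:
        raise MissingBackendError(
            "sentence-transformers is not installed; install the 'pretrained' "
            "extra, or use the offline hashing_embedder() backend instead"
        ) from exc
    try:
        model = SentenceTransformer(model_name)
    except Exception as exc:  # download / cache failure
        raise MissingBackendError(
            f"could not load pretrained model {model_name!r}; "
            "use the offline hashing_embedder() backend instead"
        ) from exc
    return _PretrainedBackend(model, name=model_name)
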