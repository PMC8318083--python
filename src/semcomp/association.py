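"""Word-pair association from distributional embeddings.

Strength of association between the country word and the food noun is the
cosine similarity between their embedding vectors (GloVe-style 300-d vectors
read from whitespace text).  Pairs above/below fixed thresholds are labeled
high/low associative; a variant scores pairs in a PCA-reduced space fitted on
the stimulus vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class EmbeddingTable:
    """token -> dense vector table; all vectors share one dimension."""

    tokens: tuple[str, ...]
    vectors: np.ndarray  # (n_tokens, d)
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.tokens):
            raise ValueError("vectors must be (n_tokens, d)")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0):
            bad = [t for t, n in zip(self.tokens, norms) if n == 0]
            raise ValueError(f"zero-norm vectors not admitted: {bad}")
        self._index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self._index[token]]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary") from None


@dataclass
class AssociationParams:
    """Labeling thresholds and PCA dimensionality (raw-cosine > 0.3 high,
    < 0.15 low; 30 principal components for the reduced variant)."""

    high_threshold: float = 0.3
    low_threshold: float = 0.15
    n_pcs: int = 30

    def __post_init__(self) -> None:
        if not self.low_threshold < self.high_threshold:
            raise ValueError("low_threshold must be below high_threshold")


def read_embeddings(path: str | Path, source_tag: str | None = None) -> EmbeddingTable:
    """Read whitespace-text embeddings: one token + d floats per line."""
    path = Path(path)
    tokens, rows = [], []
    with path.open() as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            try:
                vec = np.array(parts[1:], dtype=np.float64)
            except ValueError as exc:
                raise IOError(f"{path}:{line_no}: malformed vector") from exc
            tokens.append(parts[0])
            rows.append(vec)
    if not rows:
        raise IOError(f"{path}: no embedding rows found")
    dims = {r.size for r in rows}
    if len(dims) != 1:
        raise IOError(f"{path}: inconsistent vector dimensions {sorted(dims)}")
    return EmbeddingTable(tuple(tokens), np.vstack(rows), source_tag or str(path))


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u . v / (|u| |v|)."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("vectors must share one dimension")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for zero-norm input")
    return float(u @ v / (nu * nv))


def pair_similarities(pairs: list[tuple[str, str]], table: EmbeddingTable) -> np.ndarray:
    """Raw cosine similarity per (token, token) pair."""
    return np.array([cosine_similarity(table.vector(a), table.vector(b)) for a, b in pairs])


def pca_similarity(
    pairs: list[tuple[str, str]], table: EmbeddingTable, n_pcs: int = 30
) -> np.ndarray:
    """Cosine similarities in an ``n_pcs``-dimensional PCA projection.

    The PCA is fitted on the stimulus vocabulary (all vectors in ``table``),
    centered; pair vectors are scored in the projected space.
    """
    for a, b in pairs:
        table.vector(a)
        table.vector(b)
    n_pcs_max = min(table.dim, len(table.tokens))
    if not 1 <= n_pcs <= n_pcs_max:
        raise ValueError(f"n_pcs must be in [1, {n_pcs_max}]")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    proj = pca.fit_transform(table.vectors)
    lookup = {t: proj[i] for i, t in enumerate(table.tokens)}
    return np.array([cosine_similarity(lookup[a], lookup[b]) for a, b in pairs])


def label_pairs(scores: np.ndarray, params: AssociationParams | None = None) -> np.ndarray:
    """high / low / excluded labels from cosine scores.

    score > high_threshold -> high; score < low_threshold -> low; the closed
    band [low, high] is excluded.
    """
    params = params or AssociationParams()
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    out = np.full(scores.shape, "excluded", dtype="U8")
    out[scores > params.high_threshold] = "high"
    out[scores < params.low_threshold] = "low"
    return out


def association_table(
    pairs: list[tuple[str, str]],
    table: EmbeddingTable,
    params: AssociationParams | None = None,
) -> pd.DataFrame:
    """Delimited-table payload: pair, raw cosine, PCA cosine, label."""
    params = params or AssociationParams()
    raw = pair_similarities(pairs, table)
    pca = pca_similarity(pairs, table, params.n_pcs)
    return pd.DataFrame(
        {
            "word1": [a for a, _ in pairs],
            "word2": [b for _, b in pairs],
            "cosine": raw,
            f"cosine_pca{params.n_pcs}": pca,
            "label": label_pairs(raw, params),
        }
    )


def toy_embeddings(n_tokens: int = 40, dim: int = 50, seed: int = 7) -> EmbeddingTable:
    """Small deterministic embedding table so everything runs offline.

    Tokens come in associated country/food pairs (shared latent direction,
    high cosine) and unassociated pairs (independent directions, low cosine),
    emulating the stimulus structure.
    """
    rng = np.random.default_rng(seed)
    tokens, rows = [], []
    n_pairs = n_tokens // 2
    for i in range(n_pairs):
        associated = i % 2 == 0
        base = rng.standard_normal(dim)
        a = base + 0.35 * rng.standard_normal(dim)
        b = (base if associated else rng.standard_normal(dim)) + 0.35 * rng.standard_normal(dim)
        tokens += [f"country{i}", f"food{i}"]
        rows += [a, b]
    return EmbeddingTable(tuple(tokens), np.vstack(rows), source_tag=f"toy(seed={seed})")
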