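"""Real-valued vector similarity and vocabulary-wide ranking.

Embedding similarity uses the Tanimoto coefficient generalised to real
vectors, T(u, v) = u.v / (|u|^2 + |v|^2 - u.v); cosine similarity is
provided for comparison with earlier embedding work.  A query is scored
against every vocabulary EFV and the vocabulary sorted by descending
similarity, with ties broken by lexicographic canonical SMILES so ranks
are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .corpus import Fragment
from .embedding import EmbeddingModel

__all__ = [
    "Ranking",
    "continuous_tanimoto",
    "cosine_similarity",
    "rank_vocabulary",
    "target_rank",
]


def continuous_tanimoto(u: np.ndarray, v: np.ndarray) -> float:
    """Tanimoto coefficient for real-valued vectors.

    Equals 1 iff u == v != 0; can be negative for strongly anti-correlated
    vectors (kept unclamped — ordering, not absolute value, drives search).
    Undefined only at u == v == 0, which raises.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError("vector dimensions differ")
    dot = float(u @ v)
    denom = float(u @ u) + float(v @ v) - dot
    if denom == 0.0:
        raise ValueError("Tanimoto undefined for two zero vectors")
    return dot / denom


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between u and v; both must be nonzero."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError("vector dimensions differ")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for a zero vector")
    return float(u @ v) / (nu * nv)


@dataclass(frozen=True)
class Ranking:
    """A similarity-sorted vocabulary: (fragment, score) pairs in
    non-increasing score order, plus query provenance."""

    entries: tuple[tuple[Fragment, float], ...]
    query_info: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("ranking scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        info = ";".join(f"{k}={v}" for k, v in sorted(self.query_info.items()))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rank\tsmiles\tscore\tquery\n")
            for rank, (frag, score) in enumerate(self.entries, start=1):
                fh.write(f"{rank}\t{frag.smiles}\t{score!r}\t{info}\n")


def rank_vocabulary(
    model: EmbeddingModel,
    query: np.ndarray,
    metric: str = "tanimoto",
    exclude: Iterable[Fragment] = (),
    query_info: dict | None = None,
) -> Ranking:
    """Score every vocabulary fragment against the query and sort.

    The query fragment itself is not excluded unless passed in ``exclude``;
    equal scores are ordered by lexicographic SMILES.
    """
    query = np.asarray(query, dtype=np.float64)
    if query.shape != (model.config.vector_size,):
        raise ValueError(
            f"query dimension {query.shape} != ({model.config.vector_size},)"
        )
    excluded = {f.smiles for f in exclude}
    keep = [i for i, f in enumerate(model.vocabulary) if f.smiles not in excluded]
    if not keep:
        raise ValueError("empty vocabulary after exclusion")
    mat = model.vectors[keep]
    dots = mat @ query
    if metric == "tanimoto":
        denom = (mat * mat).sum(axis=1) + float(query @ query) - dots
        scores = dots / denom
    elif metric == "cosine":
        norms = np.linalg.norm(mat, axis=1) * float(np.linalg.norm(query))
        scores = dots / norms
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    frags = [model.vocabulary[i] for i in keep]
    order = sorted(
        range(len(keep)), key=lambda i: (-scores[i], frags[i].smiles)
    )
    entries = tuple((frags[i], float(scores[i])) for i in order)
    return Ranking(entries, dict(query_info or {}, metric=metric))


def target_rank(ranking: Ranking, target: Fragment) -> int:
    """1-based rank of the target fragment under the ranking's total order
    (descending score, ties by lexicographic SMILES)."""
    for rank, (frag, _) in enumerate(ranking.entries, start=1):
        if frag == target:
            return rank
    raise ValueError(f"target {target.smiles!r} not present in ranking")


def rank_by_scores(
    scored: Iterable[tuple[Fragment, float]],
    query_info: dict | None = None,
) -> Ranking:
    """Build a Ranking from externally computed (fragment, score) pairs
    using the same deterministic tie-breaking; used by descriptor-baseline
    searches."""
    pairs = list(scored)
    pairs.sort(key=lambda fs: (-fs[1], fs[0].smiles))
    return Ranking(tuple(pairs), dict(query_info or {}))
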