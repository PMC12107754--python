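"""CBOW word2vec training over analogue-series sentences.

Each analogue series is a sentence whose words are substituent SMILES
tokens in ascending-potency order (terminal substituent last).  A
continuous-bag-of-words model with negative sampling is trained on these
sentences; the rows of the input weight matrix W_in are the embedded
fragment vectors (EFVs).  Training is single-threaded and fully driven by
one seeded generator, so a fixed seed reproduces the vectors bitwise.

The trainer follows the canonical word2vec recipe: mean-of-context
projection, negative sampling from the unigram^0.75 noise distribution,
per-token uniformly reduced window, optional frequency subsampling, and a
linear learning-rate decay over the planned number of tokens.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .corpus import Corpus, Fragment

__all__ = [
    "EmbeddingConfig",
    "EmbeddingModel",
    "MissingFragmentError",
    "scaled_epochs",
    "train_embedding",
    "save_model",
    "load_model",
]


class MissingFragmentError(KeyError):
    """A fragment is absent from the model vocabulary."""


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyperparameters of the CBOW trainer.

    ``vector_size``, ``window``, ``min_count``, ``seed`` and ``workers``
    are the externally meaningful settings; the remaining fields pin the
    optimisation details so a saved model is fully reproducible.  Only
    ``workers == 1`` is supported (bit-reproducibility).
    """

    vector_size: int = 100
    window: int = 5
    min_count: int = 1
    seed: int = 8
    workers: int = 1
    epochs: int = 5
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    sample: float = 1e-3
    ns_exponent: float = 0.75

    def __post_init__(self) -> None:
        if self.vector_size < 1 or self.window < 1 or self.min_count < 1:
            raise ValueError("vector_size, window, min_count must be >= 1")
        if self.workers != 1:
            raise ValueError("only workers == 1 is supported (determinism)")
        if self.epochs < 1 or self.negative < 1:
            raise ValueError("epochs and negative must be >= 1")


@dataclass(frozen=True)
class EmbeddingModel:
    """A trained embedding: an ordered vocabulary and the |V| x k matrix of
    embedded fragment vectors (rows of the trainer's W_in)."""

    vocabulary: tuple[Fragment, ...]
    vectors: np.ndarray
    config: EmbeddingConfig
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.vectors.shape != (len(self.vocabulary), self.config.vector_size):
            raise ValueError("vector matrix shape inconsistent with vocabulary")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite entries in vector matrix")

    @property
    def index(self) -> dict[str, int]:
        try:
            return self._index  # type: ignore[attr-defined]
        except AttributeError:
            idx = {f.smiles: i for i, f in enumerate(self.vocabulary)}
            object.__setattr__(self, "_index", idx)
            return idx

    def __contains__(self, fragment: Fragment) -> bool:
        return fragment.smiles in self.index

    def __len__(self) -> int:
        return len(self.vocabulary)

    def get_efv(self, fragment: Fragment) -> np.ndarray:
        """The fragment's embedded fragment vector (read-only view)."""
        try:
            row = self.index[fragment.smiles]
        except KeyError:
            raise MissingFragmentError(
                f"fragment {fragment.smiles!r} not in model vocabulary"
            ) from None
        v = self.vectors[row]
        v.flags.writeable = False
        return v


def get_efv(model: EmbeddingModel, fragment: Fragment) -> np.ndarray:
    return model.get_efv(fragment)


def scaled_epochs(
    n_tokens: int | float,
    target_updates: int = 700_000,
    lo: int = 5,
    hi: int = 300,
) -> int:
    """Training passes needed to keep the total SGD update budget roughly
    constant across corpus sizes.

    Word-embedding quality depends on the total number of context updates,
    not on the number of passes: on a web- or ChEMBL-scale corpus a handful
    of passes already performs millions of updates, while a desk-scale
    corpus of a few hundred series needs proportionally more passes.
    Returns ``clip(round(target_updates / n_tokens), lo, hi)``; the floor
    reproduces the conventional five-pass default at large scale.
    """
    if n_tokens <= 0:
        raise ValueError("n_tokens must be positive")
    return int(np.clip(round(target_updates / n_tokens), lo, hi))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _build_vocab(
    sentences: list[list[str]], min_count: int
) -> tuple[list[str], dict[str, int], np.ndarray]:
    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    kept = [t for t, c in counts.items() if c >= min_count]
    # frequency-descending, SMILES-ascending: a deterministic total order
    kept.sort(key=lambda t: (-counts[t], t))
    index = {t: i for i, t in enumerate(kept)}
    return kept, index, np.array([counts[t] for t in kept], dtype=np.int64)


def train_embedding(train: Corpus, config: EmbeddingConfig) -> EmbeddingModel:
    """Train a CBOW model on the corpus and return the fragment embeddings.

    Every fragment occurring at least ``min_count`` times gets one vector of
    length ``vector_size``.  With a fixed seed, retraining on identical
    input yields bitwise-identical vectors.
    """
    if len(train) == 0:
        raise ValueError("cannot train on an empty corpus")
    sentences = [[f.smiles for f in s.fragments] for s in train]
    tokens, index, counts = _build_vocab(sentences, config.min_count)
    n, k = len(tokens), config.vector_size
    if k > 4 * n:
        warnings.warn(
            f"vector_size {k} is large for a vocabulary of {n}", stacklevel=2
        )

    rng = np.random.default_rng(config.seed)
    w_in = (rng.random((n, k)) - 0.5) / k
    w_out = np.zeros((n, k))

    # unigram^ns_exponent noise distribution for negative sampling
    noise = counts.astype(np.float64) ** config.ns_exponent
    noise_cdf = np.cumsum(noise / noise.sum())

    # subsampling keep-probabilities (word2vec formula); inactive for rare
    # tokens, dampens very frequent ones
    total = counts.sum()
    if config.sample > 0:
        f = counts / total
        keep = (np.sqrt(f / config.sample) + 1.0) * (config.sample / f)
        keep = np.minimum(keep, 1.0)
    else:
        keep = np.ones(n)

    planned = config.epochs * total
    processed = 0
    alpha_span = config.alpha - config.min_alpha
    sent_idx = [
        np.array([index[t] for t in sent if t in index], dtype=np.int64)
        for sent in sentences
    ]

    for _ in range(config.epochs):
        for sent in sent_idx:
            processed += len(sent)
            if len(sent) < 2:
                continue
            lr = max(
                config.min_alpha,
                config.alpha - alpha_span * (processed / planned),
            )
            kept_mask = rng.random(len(sent)) < keep[sent]
            words = sent[kept_mask]
            m = len(words)
            if m < 2:
                continue
            reduced = rng.integers(1, config.window + 1, size=m)
            for pos in range(m):
                win = reduced[pos]
                lo, hi = max(0, pos - win), min(m, pos + win + 1)
                context = np.concatenate((words[lo:pos], words[pos + 1:hi]))
                if len(context) == 0:
                    continue
                center = words[pos]
                h = w_in[context].mean(axis=0)
                # negative sampling targets: center (label 1) + draws from
                # the noise distribution (label 0); draws equal to the
                # center are skipped, as in the reference implementation
                draws = np.searchsorted(
                    noise_cdf, rng.random(config.negative)
                )
                draws = draws[draws != center]
                targets = np.concatenate(([center], draws))
                labels = np.zeros(len(targets))
                labels[0] = 1.0
                u = w_out[targets]
                g = (labels - _sigmoid(u @ h)) * lr
                grad_h = g @ u
                w_out[targets] += np.outer(g, h)
                w_in[context] += grad_h / len(context)

    vocab = tuple(Fragment(t) for t in tokens)
    return EmbeddingModel(vocab, w_in, config, tuple(counts.tolist()))


# ---------------------------------------------------------------------------
# Persistence: word2vec text format + JSON sidecar with the full config

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_model(model: EmbeddingModel, path: str | Path) -> None:
    """Write the model in word2vec text format (header line ``|V| k``, then
    one line per token with its vector at full precision), plus a ``.json``
    sidecar with the effective config, token counts, and a corpus digest."""
    path = Path(path)
    n, k = model.vectors.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{n} {k}\n")
        for frag, row in zip(model.vocabulary, model.vectors):
            vals = " ".join(repr(float(v)) for v in row)
            fh.write(f"{frag.smiles} {vals}\n")
    digest = hashlib.sha256(
        "\n".join(f.smiles for f in model.vocabulary).encode()
    ).hexdigest()
    meta = {
        "config": asdict(model.config),
        "counts": list(model.counts),
        "vocab_digest": digest,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_model(path: str | Path) -> EmbeddingModel:
    """Load a model written by :func:`save_model`; exact round-trip."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}:1: malformed header")
        n, k = int(header[0]), int(header[1])
        tokens: list[str] = []
        rows = np.empty((n, k))
        for i in range(n):
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}:{i + 2}: expected {n} vector lines")
            parts = line.split()
            if len(parts) != k + 1:
                raise ValueError(
                    f"{path}:{i + 2}: expected token + {k} floats, "
                    f"got {len(parts)} fields"
                )
            tokens.append(parts[0])
            rows[i] = [float(v) for v in parts[1:]]
        if fh.readline().strip():
            raise ValueError(f"{path}:{n + 2}: trailing content")
    meta_path = _sidecar(path)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        config = EmbeddingConfig(**meta["config"])
        counts = tuple(meta["counts"])
    else:
        config = EmbeddingConfig(vector_size=k)
        counts = tuple(0 for _ in tokens)
    vocab = tuple(Fragment(t) for t in tokens)
    return EmbeddingModel(vocab, rows, config, counts)
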