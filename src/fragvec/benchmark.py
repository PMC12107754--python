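"""Multi-trial terminal-substituent retrieval benchmark.

The evaluation protocol: split the corpus into a training and a test part,
train one embedding model per trial, build a query for every test series
(a single-substituent EFV, a weighted wEFV, or a descriptor baseline), rank
the training vocabulary against it, and record the rank of the series'
terminal substituent.  Rank-interval histograms (bin width 50) summarise
trials as mean with sample standard deviation; the first bin (top-50) is
the headline retrieval statistic.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, Fragment, SplitSpec, split_corpus
from .descriptors import DescriptorCache, binary_tanimoto, mqn_similarity
from .embedding import (
    EmbeddingConfig,
    EmbeddingModel,
    scaled_epochs,
    train_embedding,
)
from .queries import WeightScheme, substituent_query, weighted_query
from .search import Ranking, rank_by_scores, rank_vocabulary, target_rank

__all__ = [
    "QUERY_TYPES",
    "TrialResult",
    "RankHistogram",
    "run_trial",
    "run_benchmark",
    "rank_histogram",
    "top_bin_summary",
]

logger = logging.getLogger(__name__)

QUERY_TYPES = (
    "efv-s1", "efv-s2", "efv-s3", "efv-s4",
    "wefv-d1", "wefv-d2", "wefv-d3", "wefv-ave",
    "cfr", "mqn", "morgan",
)

_EFV_RE = re.compile(r"^efv-s(\d+)$")
_WEFV_RE = re.compile(r"^wefv-d(\d+(?:\.\d+)?)$")


@dataclass(frozen=True)
class TrialResult:
    """Per-series terminal-substituent ranks for one trial and query type."""

    trial_id: int
    query_type: str
    ranks: tuple[tuple[str, int], ...]  # (series_id, rank of S_0)
    vocab_size: int
    n_skipped: int = 0

    def rank_values(self) -> np.ndarray:
        return np.array([r for _, r in self.ranks], dtype=np.int64)


@dataclass(frozen=True)
class RankHistogram:
    """Rank-interval counts per trial with across-trial mean and sample
    standard deviation.  Bin b covers ranks [b*width + 1, (b+1)*width]."""

    query_type: str
    bin_width: int
    counts: np.ndarray  # (n_trials, n_bins)
    mean: np.ndarray
    std: np.ndarray


def _parse_query_type(query_type: str):
    if m := _EFV_RE.match(query_type):
        return "efv", int(m.group(1))
    if m := _WEFV_RE.match(query_type):
        return "wefv", float(m.group(1))
    if query_type == "wefv-ave":
        return "wefv-ave", None
    if query_type in ("cfr", "mqn", "morgan"):
        return query_type, 1  # baselines query with the S_1 fragment
    raise ValueError(f"unknown query type: {query_type!r}")


def _baseline_ranking(
    kind: str,
    query_frag: Fragment,
    vocabulary: Sequence[Fragment],
    cache: DescriptorCache,
) -> Ranking:
    if kind == "morgan":
        qfp = cache.fingerprint(query_frag)
        scored = [
            (f, binary_tanimoto(qfp, cache.fingerprint(f))) for f in vocabulary
        ]
    elif kind == "mqn":
        qm = cache.mqn(query_frag)
        scored = [(f, mqn_similarity(qm, cache.mqn(f))) for f in vocabulary]
    else:  # cfr
        qfp, qm = cache.fingerprint(query_frag), cache.mqn(query_frag)
        scored = [
            (
                f,
                0.5 * binary_tanimoto(qfp, cache.fingerprint(f))
                + 0.5 * mqn_similarity(qm, cache.mqn(f)),
            )
            for f in vocabulary
        ]
    return Ranking(rank_by_scores(scored).entries, {"query": query_frag.smiles})


def run_trial(
    corpus: Corpus,
    split_spec: SplitSpec,
    config: EmbeddingConfig,
    query_type: str,
    trial_seed: int,
    *,
    prepared: tuple[Corpus, Corpus, EmbeddingModel | None] | None = None,
    cache: DescriptorCache | None = None,
) -> TrialResult:
    """Run one retrieval trial.

    The trial seed drives both the split and the training seed.  A prepared
    (train, test, model) triple can be passed to reuse one model across
    query types within a trial; descriptor baselines need no model.
    """
    kind, param = _parse_query_type(query_type)
    needs_model = kind in ("efv", "wefv", "wefv-ave")
    if prepared is None:
        train, test = split_corpus(corpus, replace(split_spec, seed=trial_seed))
        model = (
            train_embedding(train, replace(config, seed=trial_seed))
            if needs_model
            else None
        )
    else:
        train, test, model = prepared
        if needs_model and model is None:
            model = train_embedding(train, replace(config, seed=trial_seed))

    if needs_model:
        vocabulary: Sequence[Fragment] = model.vocabulary
    else:
        vocabulary = sorted(train.vocabulary)
        if cache is None:
            cache = DescriptorCache()

    ranks: list[tuple[str, int]] = []
    n_skipped = 0
    for series in test:
        if kind in ("efv", "cfr", "mqn", "morgan"):
            x = int(param)
            if len(series) < x + 1:
                n_skipped += 1
                continue
        if kind == "efv":
            query = substituent_query(model, series, int(param))
            ranking = rank_vocabulary(
                model, query, query_info={"series": series.series_id}
            )
        elif kind == "wefv":
            query = weighted_query(model, series, WeightScheme("slope", param))
            ranking = rank_vocabulary(
                model, query, query_info={"series": series.series_id}
            )
        elif kind == "wefv-ave":
            query = weighted_query(model, series, WeightScheme("average", None))
            ranking = rank_vocabulary(
                model, query, query_info={"series": series.series_id}
            )
        else:
            ranking = _baseline_ranking(
                kind, series.substituent(int(param)), vocabulary, cache
            )
        ranks.append((series.series_id, target_rank(ranking, series.terminal)))

    if n_skipped:
        logger.info(
            "trial %d (%s): skipped %d short test series",
            trial_seed, query_type, n_skipped,
        )
    return TrialResult(
        trial_id=trial_seed,
        query_type=query_type,
        ranks=tuple(ranks),
        vocab_size=len(vocabulary),
        n_skipped=n_skipped,
    )


def run_benchmark(
    corpus: Corpus,
    query_types: Sequence[str],
    n_trials: int = 5,
    base_seed: int = 0,
    split_spec: SplitSpec | None = None,
    config: EmbeddingConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, list[TrialResult]]:
    """Run ``n_trials`` trials for each query type.

    Each trial re-draws the split and the training seed (trial seed =
    ``base_seed + t``); one model is trained per trial and reused for every
    embedding-based query type within it.  Descriptor caches are shared
    across trials.  With ``out_dir``, per-trial rank TSVs, a histogram CSV,
    and a JSON summary are written.
    """
    split_spec = split_spec or SplitSpec()
    if config is None:
        # scale passes to the training-corpus size (constant update budget)
        train_tokens = split_spec.train_fraction * sum(
            len(s) for s in corpus
        )
        config = EmbeddingConfig(epochs=scaled_epochs(train_tokens))
    for qt in query_types:
        _parse_query_type(qt)
    cache = DescriptorCache()
    results: dict[str, list[TrialResult]] = {qt: [] for qt in query_types}

    any_model = any(
        _parse_query_type(qt)[0] in ("efv", "wefv", "wefv-ave")
        for qt in query_types
    )
    for t in range(n_trials):
        trial_seed = (base_seed + t) % 2**31
        train, test = split_corpus(corpus, replace(split_spec, seed=trial_seed))
        model = (
            train_embedding(train, replace(config, seed=trial_seed))
            if any_model
            else None
        )
        logger.info(
            "trial %d: %d train series, %d test series, vocabulary %d",
            trial_seed, len(train), len(test),
            len(model) if model else len(train.vocabulary),
        )
        for qt in query_types:
            res = run_trial(
                corpus, split_spec, config, qt, trial_seed,
                prepared=(train, test, model), cache=cache,
            )
            results[qt].append(res)

    if out_dir is not None:
        _write_outputs(results, Path(out_dir))
    return results


def rank_histogram(
    results: Sequence[TrialResult], bin_width: int = 50
) -> RankHistogram:
    """Bin terminal-substituent ranks into rank intervals per trial and
    aggregate across trials (mean, sample standard deviation)."""
    if not results:
        raise ValueError("no trial results")
    query_types = {r.query_type for r in results}
    if len(query_types) > 1:
        raise ValueError(f"mixed query types: {sorted(query_types)}")
    max_rank = max(max(r.rank_values(), default=1) for r in results)
    n_bins = int(np.ceil(max_rank / bin_width))
    counts = np.zeros((len(results), n_bins), dtype=np.int64)
    for i, r in enumerate(results):
        bins = (r.rank_values() - 1) // bin_width
        for b in bins:
            counts[i, b] += 1
    mean = counts.mean(axis=0)
    std = (
        counts.std(axis=0, ddof=1)
        if len(results) > 1
        else np.zeros(n_bins)
    )
    return RankHistogram(results[0].query_type, bin_width, counts, mean, std)


def top_bin_summary(
    hist: RankHistogram, vocab_size: int
) -> tuple[float, float]:
    """Mean first-bin (top-50) frequency and the bin's share of the
    vocabulary as a percentage."""
    return float(hist.mean[0]), 100.0 * hist.bin_width / vocab_size


def _write_outputs(
    results: dict[str, list[TrialResult]], out_dir: Path
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, dict] = {}
    hist_rows = []
    for qt, trials in results.items():
        for res in trials:
            pd.DataFrame(res.ranks, columns=["series_id", "rank"]).to_csv(
                out_dir / f"ranks_{qt}_trial{res.trial_id}.tsv",
                sep="\t", index=False,
            )
        hist = rank_histogram(trials)
        top, frac = top_bin_summary(hist, trials[0].vocab_size)
        for b in range(hist.counts.shape[1]):
            hist_rows.append(
                (qt, b * hist.bin_width + 1, (b + 1) * hist.bin_width,
                 hist.mean[b], hist.std[b])
            )
        summary[qt] = {
            "trials": len(trials),
            "vocab_size": trials[0].vocab_size,
            "n_test": len(trials[0].ranks),
            "n_skipped": [t.n_skipped for t in trials],
            "top50_mean": top,
            "top50_std": float(hist.std[0]),
            "top50_vocab_pct": frac,
        }
    pd.DataFrame(
        hist_rows, columns=["query_type", "rank_lo", "rank_hi", "mean", "std"]
    ).to_csv(out_dir / "histogram.csv", index=False)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
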