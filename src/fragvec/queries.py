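"""Similarity-search queries: single-substituent EFVs and weighted wEFVs.

To search for the terminal substituent S_0 of an analogue series, the query
can be the EFV of a single substituent S_x (global context only), or the
weighted average wEFV over all L non-terminal substituents (local context):

    w_x    = Pot_x / (1 + exp(x - L/D))         (sigmoid, slope factor D)
    w'_x   = w_x / sum_{x=1..L} w_x             (normalized weights)
    wEFV   = sum_{x=1..L} w'_x * EFV_x

Positions count from the terminal end (x = 1 is adjacent to S_0) and L is
the number of non-terminal substituents.  Larger D concentrates weight on
substituents close to S_0; the ``average`` scheme uses constant weights 1/L.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .corpus import AnalogueSeries
from .embedding import EmbeddingModel

__all__ = [
    "WeightScheme",
    "WeightProfile",
    "raw_weight",
    "normalized_weights",
    "weighted_query",
    "substituent_query",
]


@dataclass(frozen=True)
class WeightScheme:
    """Weighting mode for wEFV queries: sigmoid ``slope`` with slope factor
    D, or constant-weight ``average``."""

    mode: str = "slope"
    D: float | None = 2.0

    def __post_init__(self) -> None:
        if self.mode not in ("slope", "average"):
            raise ValueError(f"unknown weight mode: {self.mode!r}")
        if self.mode == "slope":
            if self.D is None or not self.D > 0:
                raise ValueError("slope mode requires D > 0")


@dataclass(frozen=True)
class WeightProfile:
    """Normalized weights w'_x for x = 1..L (x = 1 adjacent to the terminal
    substituent, x = L the most distant member)."""

    raw: tuple[float, ...]
    normalized: tuple[float, ...]
    scheme: WeightScheme

    def __post_init__(self) -> None:
        s = math.fsum(self.normalized)
        if abs(s - 1.0) > 1e-12:
            raise ValueError(f"normalized weights sum to {s}, not 1")
        if any(w < 0 for w in self.normalized):
            raise ValueError("negative normalized weight")

    def __len__(self) -> int:
        return len(self.normalized)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "positions": list(range(1, len(self) + 1)),
                "raw": list(self.raw),
                "normalized": list(self.normalized),
                "scheme": {"mode": self.scheme.mode, "D": self.scheme.D},
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def raw_weight(potency: float, x: int, L: int, D: float) -> float:
    """Sigmoid weight w_x = Pot_x / (1 + exp(x - L/D)).

    ``x`` is the position counted from the terminal substituent, ``L`` the
    number of non-terminal members, ``D`` the slope factor.  Computed as
    Pot_x * sigmoid(L/D - x), which is overflow-safe for any |x - L/D|.
    """
    if not (math.isfinite(potency) and math.isfinite(D)):
        raise ValueError("non-finite input")
    if not 1 <= x <= L:
        raise ValueError(f"position x={x} outside 1..{L}")
    if D <= 0:
        raise ValueError("slope factor D must be positive")
    if potency < 0:
        raise ValueError(f"negative potency {potency}")
    if potency == 0:
        warnings.warn("zero potency gives zero weight", stacklevel=2)
    return potency * float(expit(L / D - x))


def normalized_weights(
    series: AnalogueSeries, scheme: WeightScheme
) -> WeightProfile:
    """Normalized weight profile over the series' non-terminal members.

    Slope mode divides each w_x by their sum; average mode assigns the
    constant 1/L.  The terminal substituent S_0 is excluded.  Degenerate
    series whose raw weights are all zero raise ``ValueError``.
    """
    L = len(series) - 1
    if L < 1:
        raise ValueError("series needs at least one non-terminal member")
    if scheme.mode == "average":
        w = [1.0] * L
    else:
        w = [
            raw_weight(series.potency(x), x, L, scheme.D) for x in range(1, L + 1)
        ]
    total = math.fsum(w)
    if total <= 0:
        raise ValueError(
            f"series {series.series_id!r}: all raw weights zero "
            "(degenerate potencies)"
        )
    return WeightProfile(tuple(w), tuple(v / total for v in w), scheme)


def weighted_query(
    model: EmbeddingModel,
    series: AnalogueSeries,
    scheme: WeightScheme | None = None,
    profile: WeightProfile | None = None,
) -> np.ndarray:
    """The wEFV query vector: the w'_x-weighted sum of the EFVs of the L
    non-terminal substituents.

    Either a ``scheme`` (the profile is derived from the series) or an
    explicit ``profile`` of length ``len(series) - 1`` may be given.
    """
    if profile is None:
        if scheme is None:
            raise ValueError("either scheme or profile is required")
        profile = normalized_weights(series, scheme)
    elif len(profile) != len(series) - 1:
        raise ValueError(
            f"profile length {len(profile)} != {len(series) - 1} "
            "non-terminal members"
        )
    efvs = np.stack(
        [model.get_efv(series.substituent(x)) for x in range(1, len(profile) + 1)]
    )
    return np.asarray(profile.normalized) @ efvs


def substituent_query(
    model: EmbeddingModel, series: AnalogueSeries, x: int
) -> np.ndarray:
    """The EFV of S_x, the substituent x positions from the terminal S_0."""
    L = len(series) - 1
    if not 1 <= x <= L:
        raise ValueError(f"position x={x} outside 1..{L}")
    return model.get_efv(series.substituent(x))
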