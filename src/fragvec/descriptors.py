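"""Conventional fragment representations and their similarities.

Baselines against which context-dependent (embedding) similarity is
compared: the folded Morgan fingerprint (radius 2, 1024 bits), the
42-component molecular quantum numbers (MQN) count vector, and CFR — the
mean of Morgan-Tanimoto and MQN similarity.  MACCS keys are exposed behind
the same interface as an optional control.

The attachment-point wildcard atom is retained in every descriptor
calculation; applying the same convention to all fragments keeps
similarities comparable.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator, rdMolDescriptors

from .corpus import Fragment

__all__ = [
    "MQN_SIZE",
    "MORGAN_BITS",
    "MORGAN_RADIUS",
    "morgan_fingerprint",
    "maccs_fingerprint",
    "mqn_vector",
    "binary_tanimoto",
    "mqn_similarity",
    "cfr_similarity",
    "DescriptorCache",
]

MORGAN_RADIUS = 2
MORGAN_BITS = 1024
MQN_SIZE = 42

_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(
    radius=MORGAN_RADIUS, fpSize=MORGAN_BITS
)


def morgan_fingerprint(fragment: Fragment) -> np.ndarray:
    """Folded Morgan fingerprint, bond radius 2, 1024 bits (uint8 0/1)."""
    fp = _morgan_gen.GetFingerprint(fragment.mol())
    arr = np.zeros(MORGAN_BITS, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


def maccs_fingerprint(fragment: Fragment) -> np.ndarray:
    """MACCS structural keys (167 bits incl. the unused bit 0); optional
    control representation, excluded from default benchmarks."""
    fp = MACCSkeys.GenMACCSKeys(fragment.mol())
    arr = np.zeros(fp.GetNumBits(), dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


def mqn_vector(fragment: Fragment) -> np.ndarray:
    """The 42 molecular quantum numbers (atom/bond/group counts, int64)."""
    return np.asarray(rdMolDescriptors.MQNs_(fragment.mol()), dtype=np.int64)


def binary_tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| for bit vectors.

    Both all-zero is an undefined 0/0; by convention the result is 0 (with a
    warning) so featureless fragments cannot produce spurious top ranks.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint lengths differ")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints; returning 0")
        return 0.0
    return int(np.count_nonzero(a & b)) / union


def mqn_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """MQN similarity 1 / (1 + mean L1 distance of the 42 counts).

    Strictly decreasing in the L1 distance; equals 1 iff the vectors agree,
    and is always positive.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != (MQN_SIZE,) or b.shape != (MQN_SIZE,):
        raise ValueError(f"MQN vectors must have {MQN_SIZE} components")
    l1 = float(np.abs(a - b).sum())
    return 1.0 / (1.0 + l1 / MQN_SIZE)


def cfr_similarity(frag_a: Fragment, frag_b: Fragment) -> float:
    """Conventional fragment representation similarity: the arithmetic mean
    of Morgan-fingerprint Tanimoto and MQN similarity."""
    t = binary_tanimoto(morgan_fingerprint(frag_a), morgan_fingerprint(frag_b))
    m = mqn_similarity(mqn_vector(frag_a), mqn_vector(frag_b))
    return 0.5 * (t + m)


class DescriptorCache:
    """Per-fragment descriptor cache keyed by canonical SMILES.

    Avoids recomputing fingerprints and MQN vectors in vocabulary-wide
    benchmark rankings; persistable as a CSV with columns
    ``smiles, fp_hex, mqn_1..mqn_42``.
    """

    def __init__(self) -> None:
        self._fp: dict[str, np.ndarray] = {}
        self._mqn: dict[str, np.ndarray] = {}

    def fingerprint(self, fragment: Fragment) -> np.ndarray:
        if fragment.smiles not in self._fp:
            self._fp[fragment.smiles] = morgan_fingerprint(fragment)
        return self._fp[fragment.smiles]

    def mqn(self, fragment: Fragment) -> np.ndarray:
        if fragment.smiles not in self._mqn:
            self._mqn[fragment.smiles] = mqn_vector(fragment)
        return self._mqn[fragment.smiles]

    def populate(self, fragments) -> None:
        for f in fragments:
            self.fingerprint(f)
            self.mqn(f)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for smiles in sorted(self._fp):
            fp_hex = np.packbits(self._fp[smiles]).tobytes().hex()
            rows.append([smiles, fp_hex, *self._mqn[smiles].tolist()])
        cols = ["smiles", "fp_hex"] + [f"mqn_{i}" for i in range(1, 43)]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorCache":
        cache = cls()
        df = pd.read_csv(path)
        mqn_cols = [f"mqn_{i}" for i in range(1, 43)]
        for row in df.itertuples(index=False):
            bits = np.unpackbits(
                np.frombuffer(bytes.fromhex(row.fp_hex), dtype=np.uint8)
            )[:MORGAN_BITS].astype(np.uint8)
            cache._fp[row.smiles] = bits
            cache._mqn[row.smiles] = np.asarray(
                [getattr(row, c) for c in mqn_cols], dtype=np.int64
            )
        return cache
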