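"""Domain model and I/O for substituent fragments and analogue-series corpora.

An analogue series (AS) is a set of compounds sharing a core scaffold and
differing at a single substitution site.  Here a series is reduced to its
sequence of substituents, ordered by ascending potency (pIC50); the last
element — the substituent of the most potent analogue — is the *terminal*
substituent S_0, and S_x denotes the substituent x positions away from it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

__all__ = [
    "Fragment",
    "AnalogueSeries",
    "Corpus",
    "SplitSpec",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "split_corpus",
]


class CorpusFormatError(ValueError):
    """Raised for unparsable corpus files or invalid records."""


def canonicalize_smiles(smiles: str) -> str:
    """Return RDKit-canonical SMILES; atom-map numbers on the attachment
    wildcard (``[*:1]``) are stripped so mapped and unmapped inputs collapse
    to the same token."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    for atom in mol.GetAtoms():
        if atom.GetAtomMapNum():
            atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True, order=True)
class Fragment:
    """A substituent: a canonical SMILES string with exactly one attachment
    point (wildcard atom ``*``).  The canonical SMILES is the identity."""

    smiles: str

    @classmethod
    def from_smiles(cls, smiles: str) -> "Fragment":
        canonical = canonicalize_smiles(smiles)
        mol = Chem.MolFromSmiles(canonical)
        n_attach = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
        if n_attach != 1:
            raise ValueError(
                f"fragment must have exactly one attachment point, "
                f"got {n_attach} in {smiles!r}"
            )
        return cls(canonical)

    @property
    def id(self) -> str:
        return self.smiles

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass(frozen=True)
class AnalogueSeries:
    """Potency-ordered sequence of (fragment, pIC50) pairs.

    Members are sorted ascending by potency on construction (stable, so ties
    preserve input order); the last member is the terminal substituent S_0.
    """

    series_id: str
    members: tuple[tuple[Fragment, float], ...]

    def __init__(
        self,
        series_id: str,
        members: Iterable[tuple[Fragment, float]],
    ) -> None:
        ordered = tuple(sorted(members, key=lambda m: m[1]))
        if len(ordered) < 3:
            raise ValueError(
                f"series {series_id!r}: at least 3 members required, "
                f"got {len(ordered)}"
            )
        frags = [f for f, _ in ordered]
        if len(set(frags)) != len(frags):
            raise ValueError(f"series {series_id!r}: duplicate fragment")
        if any(not math.isfinite(p) for _, p in ordered):
            raise ValueError(f"series {series_id!r}: non-finite potency")
        object.__setattr__(self, "series_id", series_id)
        object.__setattr__(self, "members", ordered)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[tuple[Fragment, float]]:
        return iter(self.members)

    @property
    def fragments(self) -> tuple[Fragment, ...]:
        return tuple(f for f, _ in self.members)

    @property
    def potencies(self) -> tuple[float, ...]:
        return tuple(p for _, p in self.members)

    @property
    def terminal(self) -> Fragment:
        """S_0 — the substituent of the most potent analogue."""
        return self.members[-1][0]

    def substituent(self, x: int) -> Fragment:
        """S_x: the substituent x positions away from the terminal S_0."""
        if not 0 <= x < len(self.members):
            raise IndexError(
                f"position {x} out of range for series of {len(self)}"
            )
        return self.members[-1 - x][0]

    def potency(self, x: int) -> float:
        """pIC50 of the analogue bearing S_x."""
        if not 0 <= x < len(self.members):
            raise IndexError(
                f"position {x} out of range for series of {len(self)}"
            )
        return self.members[-1 - x][1]


@dataclass(frozen=True)
class Corpus:
    """A collection of analogue series with the union vocabulary."""

    series: tuple[AnalogueSeries, ...]
    vocabulary: frozenset[Fragment] = field(init=False)

    def __init__(self, series: Iterable[AnalogueSeries]) -> None:
        series = tuple(series)
        vocab = frozenset(f for s in series for f in s.fragments)
        object.__setattr__(self, "series", series)
        object.__setattr__(self, "vocabulary", vocab)

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self) -> Iterator[AnalogueSeries]:
        return iter(self.series)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split protocol: a train fraction of series for embedding
    training, and a capped number of long test series drawn from the
    remainder whose fragments are all covered by the train vocabulary."""

    train_fraction: float = 0.9
    n_test_series: int = 1000
    min_test_series_length: int = 9  # "more than eight compounds"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_test_series < 1:
            raise ValueError("n_test_series must be >= 1")


# ---------------------------------------------------------------------------
# I/O

def _read_long_table(path: Path) -> dict[str, list[tuple[Fragment, float]]]:
    df = pd.read_csv(path, dtype={"series_id": str})
    required = {"series_id", "smiles", "pic50"}
    if not required.issubset(df.columns):
        raise CorpusFormatError(
            f"{path}: long-table format requires columns {sorted(required)}"
        )
    groups: dict[str, list[tuple[Fragment, float]]] = {}
    errors: list[str] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            frag = Fragment.from_smiles(str(row.smiles))
        except ValueError as exc:
            errors.append(f"line {lineno}: {exc}")
            continue
        groups.setdefault(str(row.series_id), []).append(
            (frag, float(row.pic50))
        )
    if errors:
        raise CorpusFormatError(
            f"{path}: {len(errors)} invalid record(s):\n" + "\n".join(errors)
        )
    return groups


def _read_series_lines(path: Path) -> dict[str, list[tuple[Fragment, float]]]:
    groups: dict[str, list[tuple[Fragment, float]]] = {}
    errors: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            series_id, pairs = tokens[0], tokens[1:]
            members: list[tuple[Fragment, float]] = []
            for tok in pairs:
                try:
                    smiles, pot = tok.rsplit(":", 1)
                    members.append((Fragment.from_smiles(smiles), float(pot)))
                except ValueError as exc:
                    errors.append(f"line {lineno}: token {tok!r}: {exc}")
            groups[series_id] = members
    if errors:
        raise CorpusFormatError(
            f"{path}: {len(errors)} invalid record(s):\n" + "\n".join(errors)
        )
    return groups


def read_corpus(path: str | Path, format: str = "long-table") -> Corpus:
    """Read an analogue-series corpus.

    Parameters
    ----------
    path
        Input file.
    format
        ``"long-table"``: CSV with header ``series_id,smiles,pic50``
        (authoritative format), or ``"series-lines"``: one series per line,
        ``series_id SMILES:pIC50 SMILES:pIC50 ...``.

    Series members are sorted ascending by potency regardless of file order.
    Series with fewer than 3 members or a duplicate fragment are rejected
    with a warning; unparsable SMILES raise :class:`CorpusFormatError`
    naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "long-table":
        groups = _read_long_table(path)
    elif format == "series-lines":
        groups = _read_series_lines(path)
    else:
        raise ValueError(f"unknown corpus format: {format!r}")

    series: list[AnalogueSeries] = []
    for sid, members in groups.items():
        try:
            series.append(AnalogueSeries(sid, members))
        except ValueError as exc:
            warnings.warn(f"rejected series {sid!r}: {exc}", stacklevel=2)
    return Corpus(series)


def write_corpus(
    corpus: Corpus, path: str | Path, format: str = "long-table"
) -> None:
    """Write a corpus; potencies are stored to 2 decimal places."""
    path = Path(path)
    if format == "long-table":
        rows = [
            (s.series_id, f.smiles, round(p, 2))
            for s in corpus
            for f, p in s
        ]
        pd.DataFrame(rows, columns=["series_id", "smiles", "pic50"]).to_csv(
            path, index=False
        )
    elif format == "series-lines":
        with open(path, "w", encoding="utf-8") as fh:
            for s in corpus:
                toks = " ".join(f"{f.smiles}:{p:.2f}" for f, p in s)
                fh.write(f"{s.series_id} {toks}\n")
    else:
        raise ValueError(f"unknown corpus format: {format!r}")


# ---------------------------------------------------------------------------
# Split protocol

def split_corpus(corpus: Corpus, spec: SplitSpec) -> tuple[Corpus, Corpus]:
    """Split a corpus into a training corpus and a test corpus.

    The train corpus holds ``floor(train_fraction * N)`` series chosen
    uniformly at random.  From the remainder, up to ``n_test_series`` series
    are drawn among those with at least ``min_test_series_length`` members
    and all of whose fragments occur in the train vocabulary.  Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(corpus)
    order = rng.permutation(n)
    n_train = int(math.floor(spec.train_fraction * n))
    train_series = [corpus.series[i] for i in order[:n_train]]
    remainder = [corpus.series[i] for i in order[n_train:]]
    train = Corpus(train_series)

    qualifying = [
        s
        for s in remainder
        if len(s) >= spec.min_test_series_length
        and all(f in train.vocabulary for f in s.fragments)
    ]
    if len(qualifying) < spec.n_test_series:
        warnings.warn(
            f"only {len(qualifying)} qualifying test series "
            f"(requested {spec.n_test_series})",
            stacklevel=2,
        )
        test_series: Sequence[AnalogueSeries] = qualifying
    else:
        pick = rng.choice(len(qualifying), spec.n_test_series, replace=False)
        test_series = [qualifying[i] for i in sorted(pick)]
    return train, Corpus(test_series)
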