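"""Pedigree handling and the pedigree-based additive relationship matrix.

A pedigree is a list of ``(individual, sire, dam)`` records. Unknown parents
are represented by ``None`` internally; in files they may appear as an empty
field, ``0`` or ``NA``. Unknown parents are treated as unique, unrelated,
non-inbred founders — the standard base-population convention of the tabular
method.

The additive (numerator) relationship matrix ``A`` holds, for every pair of
individuals, twice their kinship coefficient: the expected fraction of
alleles shared identical-by-descent, scaled so that a non-inbred individual
has ``A[i, i] = 1``. It is the covariance structure of additive genetic
effects in the mixed model downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "PedigreeError",
    "sort_and_validate",
    "additive_relationship",
    "read_pedigree_csv",
    "write_pedigree_csv",
]

#: sentinel strings accepted for an unknown parent in files
UNKNOWN_TOKENS = {"", "0", "NA", "na", "NaN", "nan", ".", "none", "None"}


class PedigreeError(ValueError):
    """Invalid pedigree: duplicate ids, cycles, or undeclared parents."""


def _norm_parent(token) -> str | None:
    if token is None:
        return None
    if isinstance(token, float) and np.isnan(token):
        return None
    token = str(token).strip()
    return None if token in UNKNOWN_TOKENS else token


@dataclass(frozen=True)
class Pedigree:
    """An ordered collection of (individual, sire, dam) records.

    Parameters
    ----------
    records
        Tuples of ``(id, sire, dam)``; ``None`` marks an unknown parent.
        A founder has both parents unknown.
    """

    records: tuple[tuple[str, str | None, str | None], ...]

    def __post_init__(self):
        object.__setattr__(
            self,
            "records",
            tuple((str(i), _norm_parent(s), _norm_parent(d)) for i, s, d in self.records),
        )

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def founders(self) -> list[str]:
        return [i for i, s, d in self.records if s is None and d is None]

    def parents_of(self, individual: str) -> tuple[str | None, str | None]:
        for i, s, d in self.records:
            if i == individual:
                return s, d
        raise KeyError(individual)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["id", "sire", "dam"])


@dataclass
class RelationshipMatrix:
    """Additive relationship coefficients over an ordered set of individuals.

    ``values[i, j]`` is the numerator relationship; the diagonal equals
    ``1 + F_i`` where ``F_i`` is the inbreeding coefficient.
    """

    labels: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("labels/values shape mismatch")
        self._index = {lab: k for k, lab in enumerate(self.labels)}

    def subset(self, labels: Sequence[str]) -> "RelationshipMatrix":
        """Extract the sub-matrix for the sampled/genotyped individuals."""
        missing = [l for l in labels if l not in self._index]
        if missing:
            raise KeyError(f"ids absent from relationship matrix: {missing[:5]}")
        idx = np.array([self._index[l] for l in labels])
        return RelationshipMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def inbreeding(self) -> pd.Series:
        return pd.Series(np.diag(self.values) - 1.0, index=self.labels, name="F")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def sort_and_validate(pedigree: Pedigree) -> Pedigree:
    """Return a topologically sorted copy with every parent before its offspring.

    Raises
    ------
    PedigreeError
        On duplicate ids or a parentage cycle (an individual that is its own
        ancestor); the error message names the offending ids.
    """
    ids = pedigree.ids
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise PedigreeError(f"duplicate individual id: {i!r}")
        seen.add(i)

    parents = {i: (s, d) for i, s, d in pedigree.records}
    # Kahn-style DFS with cycle detection
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {i: WHITE for i in ids}
    order: list[str] = []

    def visit(node: str, stack: list[str]) -> None:
        colour[node] = GREY
        stack.append(node)
        for p in parents.get(node, (None, None)):
            if p is None or p not in parents:
                continue
            if colour[p] == GREY:
                cycle = stack[stack.index(p):] + [p]
                raise PedigreeError(f"pedigree cycle: {' -> '.join(cycle)}")
            if colour[p] == WHITE:
                visit(p, stack)
        stack.pop()
        colour[node] = BLACK
        order.append(node)

    for i in ids:
        if colour[i] == WHITE:
            visit(i, [])

    rec = {i: (i, s, d) for i, s, d in pedigree.records}
    return Pedigree(tuple(rec[i] for i in order))


def additive_relationship(pedigree: Pedigree, *, validate: bool = True) -> RelationshipMatrix:
    """Build A over the whole pedigree by the tabular (recursive) method.

    For individual ``o`` with parents ``s`` and ``d`` (processed after both):

    * ``A[o, x] = (A[s, x] + A[d, x]) / 2`` for every earlier ``x``,
      with a missing parent contributing 0;
    * ``A[o, o] = 1 + A[s, d] / 2`` (the inbreeding term), or 1 if either
      parent is unknown.

    Parameters
    ----------
    pedigree
        A pedigree; it is sorted and validated first unless ``validate=False``
        (in which case it must already be parent-first ordered).

    Raises
    ------
    PedigreeError
        If a named parent never appears as an individual in the pedigree.
    """
    ped = sort_and_validate(pedigree) if validate else pedigree
    ids = ped.ids
    pos = {i: k for k, i in enumerate(ids)}
    for i, s, d in ped.records:
        for p in (s, d):
            if p is not None and p not in pos:
                raise PedigreeError(
                    f"parent {p!r} of {i!r} is not declared as an individual; "
                    "add it as a founder row"
                )

    n = len(ids)
    A = np.zeros((n, n))
    for o, (i, s, d) in enumerate(ped.records):
        si = pos[s] if s is not None else None
        di = pos[d] if d is not None else None
        if o > 0:
            row = np.zeros(o)
            if si is not None:
                row += 0.5 * A[si, :o]
            if di is not None:
                row += 0.5 * A[di, :o]
            A[o, :o] = row
            A[:o, o] = row
        A[o, o] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    return RelationshipMatrix(ids, A)


def read_pedigree_csv(path: str | Path, *, header: bool | None = None) -> Pedigree:
    """Read an ``id,sire,dam`` CSV; empty/0/NA fields mean unknown parent.

    ``header=None`` sniffs: if the first row's first field is literally
    ``id`` it is treated as a header.
    """
    path = Path(path)
    first = path.read_text().splitlines()[0].split(",")[0].strip().lower()
    if header is None:
        header = first == "id"
    df = pd.read_csv(path, header=0 if header else None, dtype=str, keep_default_na=False)
    df.columns = ["id", "sire", "dam"] + list(df.columns[3:])
    return Pedigree(tuple(zip(df["id"], df["sire"], df["dam"])))


def write_pedigree_csv(pedigree: Pedigree, path: str | Path) -> None:
    df = pedigree.to_frame().fillna("")
    df.to_csv(path, index=False)
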