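"""Sparse data model for J-variate categorical contingency tables.

A table over ``J`` categorical variables with ``c_j`` categories each has
``L = prod(c_j)`` cells, which for questionnaire data (e.g. 40 binary items,
L = 2**40) cannot be materialized.  Everything in this package therefore works
on a *support*: the list of response patterns that actually carry observations
(plus, for augmented-empirical-likelihood fits, a few deliberately added
zero-count cells).  Cells are ordered lexicographically with the score of the
last variable varying fastest, so a table over binary a, b, c is vectorized as
(000, 001, 010, 011, 100, 101, 110, 111).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pattern",
    "MarginSpec",
    "SparseTable",
    "TableError",
    "TableSizeError",
    "pattern_index",
    "index_to_pattern",
    "build_table",
    "margin_value",
    "margin_matrix",
    "full_support",
    "pattern_to_string",
    "string_to_pattern",
    "read_frequency_tsv",
    "write_frequency_tsv",
    "read_observations_csv",
]

#: a response pattern is a tuple of J integer scores, score j in {0..c_j-1}
Pattern = tuple

#: refuse to materialize dense tables above this many cells unless overridden
DEFAULT_DENSE_CAP = 10**7


class TableError(ValueError):
    """Invalid table construction or access."""


class TableSizeError(TableError):
    """A dense materialization was requested above the configured cell cap."""


def _check_pattern(pattern: Sequence[int], cats: Sequence[int]) -> None:
    if len(pattern) != len(cats):
        raise TableError(
            f"pattern length {len(pattern)} does not match {len(cats)} variables"
        )
    for j, (score, c) in enumerate(zip(pattern, cats)):
        if not 0 <= int(score) < c:
            raise TableError(
                f"score {score} of variable {j} outside its range 0..{c - 1}"
            )


def pattern_index(pattern: Sequence[int], cats: Sequence[int]) -> int:
    """Lexicographic rank of a response pattern, last variable fastest.

    Bijective with :func:`index_to_pattern`; uses Python integers so the rank
    is exact even when ``prod(cats)`` exceeds 2**63.
    """
    _check_pattern(pattern, cats)
    idx = 0
    for score, c in zip(pattern, cats):
        idx = idx * int(c) + int(score)
    return idx


def index_to_pattern(index: int, cats: Sequence[int]) -> Pattern:
    """Inverse of :func:`pattern_index`."""
    L = math.prod(int(c) for c in cats)
    if not 0 <= index < L:
        raise TableError(f"cell index {index} outside 0..{L - 1}")
    out = []
    for c in reversed([int(c) for c in cats]):
        index, score = divmod(index, c)
        out.append(score)
    return tuple(reversed(out))


@dataclass(frozen=True)
class MarginSpec:
    """One marginal cell: a subset of variables pinned to fixed scores.

    ``MarginSpec((0,), (1,))`` over binary a, b, c is the margin
    m^a_1 = sum of all cells with a = 1; ``MarginSpec((0, 2), (0, 1))`` is the
    bivariate cell m^{ac}_{01}.  Rows of the marginalizing matrix Aᵀ are
    represented as one spec each.
    """

    variables: tuple
    values: tuple

    def __post_init__(self):
        variables = tuple(int(v) for v in self.variables)
        values = tuple(int(x) for x in self.values)
        if len(variables) != len(values):
            raise TableError("variables and values differ in length")
        if len(set(variables)) != len(variables):
            raise TableError(f"duplicate variables in margin spec {variables}")
        if any(b <= a for a, b in zip(variables, variables[1:])):
            raise TableError(f"margin variables must be sorted: {variables}")
        object.__setattr__(self, "variables", variables)
        object.__setattr__(self, "values", values)

    def validate(self, cats: Sequence[int]) -> None:
        for v, x in zip(self.variables, self.values):
            if v >= len(cats):
                raise TableError(f"margin variable {v} out of range for J={len(cats)}")
            if not 0 <= x < cats[v]:
                raise TableError(f"margin value {x} out of range for variable {v}")

    def matches(self, pattern: Sequence[int]) -> bool:
        return all(pattern[v] == x for v, x in zip(self.variables, self.values))

    def compatible(self, other: "MarginSpec") -> bool:
        """True unless the two specs pin a shared variable to different scores."""
        fixed = dict(zip(self.variables, self.values))
        return all(fixed.get(v, x) == x for v, x in zip(other.variables, other.values))

    def merged(self, other: "MarginSpec") -> "MarginSpec":
        """Joint margin cell pinning the union of both variable sets."""
        if not self.compatible(other):
            raise TableError(f"incompatible margin specs {self} and {other}")
        fixed = dict(zip(self.variables, self.values))
        fixed.update(zip(other.variables, other.values))
        variables = tuple(sorted(fixed))
        return MarginSpec(variables, tuple(fixed[v] for v in variables))


@dataclass
class SparseTable:
    """Contingency table stored as a support list of (pattern, count).

    Support cells are kept in ascending lexicographic-index order so that
    weight vectors over the support are reproducible.  Zero counts are only
    permitted on cells explicitly marked as augmented (added to the support
    without observations, the MAEL device).
    """

    cats: tuple
    patterns: list
    counts: np.ndarray
    augmented: np.ndarray = None

    def __post_init__(self):
        self.cats = tuple(int(c) for c in self.cats)
        if any(c < 2 for c in self.cats):
            raise TableError("every variable needs at least 2 categories")
        self.patterns = [tuple(int(x) for x in p) for p in self.patterns]
        self.counts = np.asarray(self.counts, dtype=float)
        if self.augmented is None:
            self.augmented = np.zeros(len(self.patterns), dtype=bool)
        self.augmented = np.asarray(self.augmented, dtype=bool)
        if not len(self.patterns) == len(self.counts) == len(self.augmented):
            raise TableError("patterns, counts and augmented flags differ in length")
        if len(self.patterns) == 0:
            raise TableError("empty table")
        for p in self.patterns:
            _check_pattern(p, self.cats)
        idx = [pattern_index(p, self.cats) for p in self.patterns]
        if len(set(idx)) != len(idx):
            raise TableError("duplicate patterns in support")
        order = np.argsort(idx)
        self.patterns = [self.patterns[i] for i in order]
        self.counts = self.counts[order]
        self.augmented = self.augmented[order]
        if np.any(self.counts < 0):
            raise TableError("negative counts")
        zero = self.counts == 0
        if np.any(zero & ~self.augmented):
            raise TableError("zero count on a non-augmented support cell")
        if self.N <= 0:
            raise TableError("table has no observations")
        self._index = {p: i for i, p in enumerate(self.patterns)}

    # -- basic geometry -----------------------------------------------------

    @property
    def J(self) -> int:
        return len(self.cats)

    @property
    def N(self) -> float:
        return float(self.counts.sum())

    @property
    def n_cells(self) -> int:
        """Full table size L = prod(c_j); derived, never materialized."""
        return math.prod(self.cats)

    @property
    def support_size(self) -> int:
        return len(self.patterns)

    def pattern_array(self) -> np.ndarray:
        """Support as an (S, J) integer array (cached)."""
        arr = getattr(self, "_parr", None)
        if arr is None:
            arr = np.asarray(self.patterns, dtype=np.int64)
            self._parr = arr
        return arr

    def index_of(self, pattern: Sequence[int]) -> int:
        """Position of a pattern within the support."""
        try:
            return self._index[tuple(int(x) for x in pattern)]
        except KeyError:
            raise TableError(f"pattern {tuple(pattern)} not in support") from None

    def __contains__(self, pattern) -> bool:
        return tuple(int(x) for x in pattern) in self._index

    # -- derived tables -----------------------------------------------------

    def add_zero_cells(self, cells: Iterable[Sequence[int]]) -> "SparseTable":
        """New table whose support is augmented with zero-count cells."""
        extra = []
        seen = set(self._index)
        for p in cells:
            p = tuple(int(x) for x in p)
            _check_pattern(p, self.cats)
            if p in seen:
                raise TableError(f"cell {p} already in support")
            seen.add(p)
            extra.append(p)
        if not extra:
            return self
        return SparseTable(
            self.cats,
            self.patterns + extra,
            np.concatenate([self.counts, np.zeros(len(extra))]),
            np.concatenate([self.augmented, np.ones(len(extra), dtype=bool)]),
        )

    def observed_only(self) -> "SparseTable":
        """Drop augmented zero cells, keeping observed cells only."""
        keep = self.counts > 0
        return SparseTable(
            self.cats,
            [p for p, k in zip(self.patterns, keep) if k],
            self.counts[keep],
            np.zeros(int(keep.sum()), dtype=bool),
        )

    def dense_counts(self, cap: int = DEFAULT_DENSE_CAP) -> np.ndarray:
        """Full L-vector of counts; guarded against huge tables."""
        L = self.n_cells
        if L > cap:
            raise TableSizeError(
                f"dense table of {L} cells exceeds the cap of {cap}; "
                "raise the cap explicitly if this is intended"
            )
        dense = np.zeros(L)
        for p, n in zip(self.patterns, self.counts):
            dense[pattern_index(p, self.cats)] = n
        return dense

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pattern": [pattern_to_string(p, self.cats) for p in self.patterns],
                "count": self.counts,
                "augmented": self.augmented,
            }
        )


def build_table(rows, cats=None) -> SparseTable:
    """Build a sparse table from respondent patterns or (pattern, count) pairs.

    ``rows`` is either a list of response patterns (one per respondent) or a
    list of ``(pattern, count)`` pairs; duplicates are merged by summing.
    ``cats`` defaults to ``max score + 1`` per variable (at least 2).
    """
    rows = list(rows)
    if not rows:
        raise TableError("empty input: no rows to tabulate")
    counted = isinstance(rows[0][0], (tuple, list, np.ndarray))
    pairs = rows if counted else [(p, 1) for p in rows]
    acc: dict = {}
    for p, n in pairs:
        p = tuple(int(x) for x in p)
        acc[p] = acc.get(p, 0) + n
    patterns = list(acc)
    J = len(patterns[0])
    if any(len(p) != J for p in patterns):
        raise TableError("patterns differ in length")
    if cats is None:
        cats = tuple(max(2, 1 + max(p[j] for p in patterns)) for j in range(J))
    counts = np.array([acc[p] for p in patterns], dtype=float)
    keep = counts > 0
    if not keep.all():
        patterns = [p for p, k in zip(patterns, keep) if k]
        counts = counts[keep]
    return SparseTable(tuple(cats), patterns, counts)


def full_support(cats: Sequence[int], cap: int = DEFAULT_DENSE_CAP) -> list:
    """All L patterns in lexicographic order (guarded)."""
    L = math.prod(int(c) for c in cats)
    if L > cap:
        raise TableSizeError(f"full support of {L} cells exceeds the cap of {cap}")
    return [index_to_pattern(i, cats) for i in range(L)]


# -- margins ----------------------------------------------------------------


def margin_value(weights, support, spec: MarginSpec) -> float:
    """Sum of ``weights`` over support cells matching the margin spec.

    ``support`` is a SparseTable or a list of patterns; ``weights`` is aligned
    with its cell order.  Equals one row of Aᵀ applied to the weight vector.
    """
    if isinstance(support, SparseTable):
        spec.validate(support.cats)
        arr = support.pattern_array()
    else:
        arr = np.asarray(support, dtype=np.int64)
        if spec.variables and max(spec.variables) >= arr.shape[1]:
            raise TableError("margin spec variable out of range for support")
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != arr.shape[0]:
        raise TableError("weights not aligned with support")
    mask = np.ones(arr.shape[0], dtype=bool)
    for v, x in zip(spec.variables, spec.values):
        mask &= arr[:, v] == x
    return float(weights[mask].sum())


def margin_matrix(specs: Sequence[MarginSpec], pattern_array: np.ndarray) -> np.ndarray:
    """Incidence matrix Aᵀ restricted to the support: (n_specs, S) of 0/1."""
    arr = np.asarray(pattern_array, dtype=np.int64)
    S = arr.shape[0]
    A = np.empty((len(specs), S))
    for i, spec in enumerate(specs):
        mask = np.ones(S, dtype=bool)
        for v, x in zip(spec.variables, spec.values):
            mask &= arr[:, v] == x
        A[i] = mask
    return A


# -- text formats -----------------------------------------------------------


def pattern_to_string(pattern: Sequence[int], cats: Sequence[int]) -> str:
    """Digit string ("011") when every variable has <= 10 categories,
    comma-separated scores otherwise."""
    if all(c <= 10 for c in cats):
        return "".join(str(int(x)) for x in pattern)
    return ",".join(str(int(x)) for x in pattern)


def string_to_pattern(text: str) -> Pattern:
    text = text.strip()
    if "," in text:
        return tuple(int(tok) for tok in text.split(","))
    return tuple(int(ch) for ch in text)


def read_frequency_tsv(path, cats=None) -> SparseTable:
    """Read a two-column TSV (`pattern`, `count`) into a sparse table."""
    df = pd.read_csv(path, sep="\t", dtype={"pattern": str})
    if df.empty:
        raise TableError(f"{path}: no rows")
    missing = {"pattern", "count"} - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing column(s) {sorted(missing)}")
    pairs = []
    for line, (text, n) in enumerate(zip(df["pattern"], df["count"]), start=2):
        try:
            pairs.append((string_to_pattern(str(text)), int(n)))
        except (ValueError, TypeError) as exc:
            raise TableError(f"{path}: line {line}: {exc}") from exc
    return build_table(pairs, cats=cats)


def write_frequency_tsv(table: SparseTable, path) -> None:
    df = table.to_dataframe()[["pattern", "count"]]
    df["count"] = df["count"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_observations_csv(path, cats=None) -> SparseTable:
    """Read a respondent-by-item CSV (header of item names, integer scores)."""
    df = pd.read_csv(path)
    if df.empty:
        raise TableError(f"{path}: no respondent rows")
    try:
        arr = df.to_numpy(dtype=np.int64)
    except (ValueError, TypeError) as exc:
        raise TableError(f"{path}: non-integer score: {exc}") from exc
    return build_table([tuple(row) for row in arr], cats=cats)
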