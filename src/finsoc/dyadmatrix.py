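"""Symmetric dyadic matrices over a fixed set of individuals.

Every pairwise statistic in the package — association indices, structural
predictors, affiliation indices, relatedness, similarity — is carried by a
:class:`DyadMatrix`: an ordered id list plus a symmetric float array whose
diagonal is ignored.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = ["DyadMatrix"]


class DyadMatrix:
    """A symmetric real matrix indexed by individual ids.

    Parameters
    ----------
    ids
        Ordered individual identifiers (coerced to ``str``).
    values
        Square array, symmetric up to ``atol``; the diagonal carries no
        meaning and is zeroed on construction.
    """

    __slots__ = ("ids", "values")

    def __init__(self, ids: Sequence, values: np.ndarray, *, atol: float = 1e-8):
        ids = [str(i) for i in ids]
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("values must be a square 2-D array")
        if len(ids) != values.shape[0]:
            raise ValueError(
                f"id list length {len(ids)} does not match matrix dimension {values.shape[0]}"
            )
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids")
        finite = np.isfinite(values)
        both = finite & finite.T
        if not np.allclose(values[both], values.T[both], atol=atol):
            raise ValueError("matrix is not symmetric")
        values = values.copy()
        np.fill_diagonal(values, 0.0)
        self.ids = ids
        self.values = values

    # -- basics ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __repr__(self) -> str:
        return f"DyadMatrix(n={self.n})"

    def copy(self) -> "DyadMatrix":
        return DyadMatrix(self.ids, self.values.copy())

    def index_of(self, individual) -> int:
        try:
            return self.ids.index(str(individual))
        except ValueError:
            raise KeyError(f"unknown individual id: {individual!r}") from None

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(self.values[self.index_of(i), self.index_of(j)])

    # -- dyad views -----------------------------------------------------
    def triu_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the strict upper triangle (each dyad once)."""
        return np.triu_indices(self.n, k=1)

    def dyad_values(self) -> np.ndarray:
        """Vector of off-diagonal values, one entry per unordered dyad."""
        iu, ju = self.triu_indices()
        return self.values[iu, ju]

    def dyad_pairs(self) -> list[tuple[str, str]]:
        iu, ju = self.triu_indices()
        return [(self.ids[a], self.ids[b]) for a, b in zip(iu, ju)]

    @classmethod
    def from_dyad_values(cls, ids: Sequence, vec: np.ndarray) -> "DyadMatrix":
        """Inverse of :meth:`dyad_values`: fold a dyad vector into a matrix."""
        ids = list(ids)
        n = len(ids)
        vec = np.asarray(vec, dtype=float)
        m = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        if vec.shape != iu.shape:
            raise ValueError("dyad vector length does not match id count")
        m[iu, ju] = vec
        m[ju, iu] = vec
        return cls(ids, m)

    def reindex(self, ids: Sequence) -> "DyadMatrix":
        """Restrict/reorder to the given ids (all must be present)."""
        idx = [self.index_of(i) for i in ids]
        return DyadMatrix([str(i) for i in ids], self.values[np.ix_(idx, idx)])

    def align_with(self, other: "DyadMatrix") -> tuple["DyadMatrix", "DyadMatrix"]:
        """Return both matrices restricted to the shared ids, same order."""
        shared = [i for i in self.ids if i in set(other.ids)]
        if len(shared) < 2:
            raise ValueError("fewer than two shared individuals")
        return self.reindex(shared), other.reindex(shared)

    # -- IO -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path) -> "DyadMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError("matrix CSV must have identical row and column ids")
        return cls(list(df.index), df.to_numpy(dtype=float))
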