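"""Labelled square matrices — the common currency of the package.

Association (HWI), interaction (DAI), relatedness, age-difference and
rank-difference matrices are all represented as :class:`pandas.DataFrame`
objects whose index and columns are the same ordered list of individual
identifiers.  The helpers here enforce that contract and extract the
dyad-level vectors (strict upper triangles) that every matrix statistic
operates on.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "labelled_matrix",
    "check_square_labelled",
    "align_matrices",
    "upper_triangle",
    "from_upper_triangle",
    "read_matrix_csv",
    "write_matrix_csv",
]


def labelled_matrix(values: np.ndarray, ids: Sequence[str]) -> pd.DataFrame:
    """Wrap an ``(n, n)`` array as a labelled square DataFrame."""
    values = np.asarray(values, dtype=float)
    ids = list(ids)
    if values.shape != (len(ids), len(ids)):
        raise ValueError(
            f"shape {values.shape} incompatible with {len(ids)} labels"
        )
    return pd.DataFrame(values, index=ids, columns=ids)


def check_square_labelled(m: pd.DataFrame, name: str = "matrix") -> pd.DataFrame:
    if not isinstance(m, pd.DataFrame):
        raise TypeError(f"{name} must be a pandas DataFrame")
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} is not square: shape {m.shape}")
    if list(m.index) != list(m.columns):
        raise ValueError(f"{name} index and columns differ")
    return m


def align_matrices(*matrices: pd.DataFrame) -> list[pd.DataFrame]:
    """Reindex all matrices to the (sorted) common id set.

    Raises if the matrices do not share an identical id set: silent
    subsetting of individuals would invalidate dyad-level statistics.
    """
    if not matrices:
        return []
    for m in matrices:
        check_square_labelled(m)
    ids = set(matrices[0].index)
    for m in matrices[1:]:
        if set(m.index) != ids:
            raise ValueError("matrices are labelled with different id sets")
    order = sorted(ids)
    return [m.reindex(index=order, columns=order) for m in matrices]


def upper_triangle(m: pd.DataFrame) -> np.ndarray:
    """Strict upper triangle of a labelled square matrix as a 1-D vector.

    Diagonals (self-dyads) are excluded from every statistic in this
    package.
    """
    check_square_labelled(m)
    a = m.to_numpy(dtype=float)
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def from_upper_triangle(vec: np.ndarray, ids: Sequence[str]) -> pd.DataFrame:
    """Inverse of :func:`upper_triangle`: build a symmetric matrix."""
    ids = list(ids)
    n = len(ids)
    vec = np.asarray(vec, dtype=float)
    if vec.size != n * (n - 1) // 2:
        raise ValueError("triangle length does not match id count")
    a = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    a[iu] = vec
    a = a + a.T
    return labelled_matrix(a, ids)


def read_matrix_csv(path) -> pd.DataFrame:
    """Read a labelled square matrix CSV (header row + label column)."""
    m = pd.read_csv(path, index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    return check_square_labelled(m, str(path))


def write_matrix_csv(m: pd.DataFrame, path) -> None:
    check_square_labelled(m).to_csv(path)


def pair_index(ids: Iterable[str]) -> list[tuple[str, str]]:
    """Ordered (i, j) dyad labels matching :func:`upper_triangle`."""
    ids = list(ids)
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
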