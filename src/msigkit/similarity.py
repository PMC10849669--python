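"""Cosine similarity and pairwise cosine-distance matrices.

Cosine similarity between two nonnegative vectors lies in [0, 1] and is
invariant to positive rescaling, so it does not matter whether it is
computed on raw counts or normalized spectra.  Distance is defined as
1 − similarity.  An all-zero vector has no direction; by convention its
similarity to anything is 0 (maximally distant) and a warning is logged,
so batch runs over catalogs containing empty samples do not abort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


def cosine_similarity(u, v) -> float:
    """Cosine of the angle between two equal-length finite vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValidationError(f"length mismatch: {u.shape} vs {v.shape}")
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValidationError("non-finite values in input vectors")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        warnings.warn("cosine similarity of a zero vector is 0 by convention",
                      stacklevel=2)
        return 0.0
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise cosine-distance matrix with labelled rows/columns."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate ids in distance matrix")
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.all(np.isfinite(v)):
            raise ValidationError("non-finite distances")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) != 0.0:
            raise ValidationError("distance matrix diagonal must be zero")
        self.values = v

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id", lineterminator="\n")


def pairwise_cosine_distance(rows, ids: list[str] | None = None) -> DistanceMatrix:
    """Pairwise cosine distance (1 − similarity) between labelled row vectors.

    ``rows`` may be a DataFrame (index supplies the ids) or a 2-D array with
    an explicit ``ids`` list.  Requires at least two rows.
    """
    if isinstance(rows, pd.DataFrame):
        ids = [str(i) for i in rows.index]
        mat = rows.to_numpy(dtype=float)
    else:
        mat = np.asarray(rows, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(mat.shape[0])]
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValidationError("need at least 2 equal-length row vectors")
    if not np.all(np.isfinite(mat)):
        raise ValidationError("non-finite values in input vectors")
    norms = np.linalg.norm(mat, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero vector(s): similarity 0 by convention",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, norms)
    unit = mat / safe[:, None]
    sim = np.clip(unit @ unit.T, 0.0, 1.0)
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    dist = 1.0 - sim
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(list(ids), dist)
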