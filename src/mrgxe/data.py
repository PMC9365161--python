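"""Individual-level data container for interaction-based MR.

A :class:`Dataset` holds one row per participant: an outcome ``y``, an
exposure ``x``, a genetic instrument (either a single score/dosage vector
``g`` or an n x M sub-instrument matrix ``g_matrix``), and an optional
n x K block ``z`` of candidate interaction covariates with column names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = ["Dataset"]


def _as_1d(name: str, v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.ndim != 1:
        raise InputError(f"{name} must be one-dimensional, got shape {a.shape}")
    return a


@dataclass
class Dataset:
    """Per-individual data for MR-GxE / MR-GENIUS analyses.

    Parameters
    ----------
    y : array-like, shape (n,)
        Continuous outcome.
    x : array-like, shape (n,)
        Continuous exposure.
    g : array-like, shape (n,), optional
        Single genetic instrument (polygenic score or dosage). If omitted,
        ``g_matrix`` must be supplied; the composite score (row sum) is then
        used wherever a single instrument is required.
    g_matrix : array-like, shape (n, M), optional
        Sub-instrument matrix (e.g. individual variant dosages underlying a
        polygenic score), used for over-identification testing.
    z : pandas.DataFrame or array-like, shape (n, K), optional
        Candidate interaction covariates. Plain arrays are given generated
        column names ``z1..zK``.
    u : array-like, shape (n,), optional
        Latent confounder. Only ever populated by the simulator, for
        oracle checks; estimators never touch it.
    """

    y: np.ndarray
    x: np.ndarray
    g: np.ndarray | None = None
    g_matrix: np.ndarray | None = None
    z: pd.DataFrame | None = None
    u: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.y = _as_1d("y", self.y)
        self.x = _as_1d("x", self.x)
        n = self.y.shape[0]
        if self.x.shape[0] != n:
            raise InputError(f"x has length {self.x.shape[0]}, expected {n}")
        if self.g is not None:
            self.g = _as_1d("g", self.g)
            if self.g.shape[0] != n:
                raise InputError(f"g has length {self.g.shape[0]}, expected {n}")
        if self.g_matrix is not None:
            gm = np.asarray(self.g_matrix, dtype=float)
            if gm.ndim != 2 or gm.shape[0] != n:
                raise InputError(
                    f"g_matrix must have shape ({n}, M), got {gm.shape}"
                )
            self.g_matrix = gm
        if self.g is None and self.g_matrix is None:
            raise InputError("either g or g_matrix is required")
        if self.z is not None:
            if not isinstance(self.z, pd.DataFrame):
                zz = np.atleast_2d(np.asarray(self.z, dtype=float))
                if zz.shape[0] != n:
                    zz = zz.T
                self.z = pd.DataFrame(
                    zz, columns=[f"z{k + 1}" for k in range(zz.shape[1])]
                )
            if len(self.z) != n:
                raise InputError(f"z has {len(self.z)} rows, expected {n}")
        if self.u is not None:
            self.u = _as_1d("u", self.u)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def score(self) -> np.ndarray:
        """Single-instrument view: ``g`` if present, otherwise the unweighted
        composite (row sum) of ``g_matrix``."""
        if self.g is not None:
            return self.g
        return self.g_matrix.sum(axis=1)

    def covariate(self, name: str | int) -> tuple[str, np.ndarray]:
        """Return ``(name, values)`` for one interaction covariate.

        Accepts a column name or a positional index into ``z``.
        """
        if self.z is None:
            raise InputError("dataset has no interaction covariates (z)")
        if isinstance(name, (int, np.integer)):
            if not 0 <= int(name) < self.z.shape[1]:
                raise InputError(f"covariate index {name} out of range")
            name = self.z.columns[int(name)]
        if name not in self.z.columns:
            raise InputError(f"covariate {name!r} not found in z columns")
        return str(name), self.z[name].to_numpy(dtype=float)

    def complete_cases(self, columns: list[np.ndarray]) -> np.ndarray:
        """Boolean mask of rows with no missing value in any given column."""
        mask = np.ones(self.n, dtype=bool)
        for c in columns:
            mask &= np.isfinite(np.asarray(c, dtype=float))
        return mask
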