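"""Pareto dominance, front extraction, and the global archive of non-dominated molecules.

All objective vectors are oriented so that *larger is better* in every
component (minimize-type metrics are negated upstream, see
:mod:`paretogen.objectives`).  Dominance is the standard componentwise
partial order: ``x`` weakly dominates ``y`` when ``x_i >= y_i`` for all
``i``, and strictly dominates when additionally ``x_i > y_i`` for some
``i``.  The *Pareto front* of a vector set is the subset not strictly
dominated by any member.

The :class:`ParetoPool` is the running archive of mutually non-dominated
molecules discovered during a search.  A candidate molecule with raw
metric vector ``h`` receives a pool-relative reward in each dimension:

    r_i = (1 / N_P) * sum_k 1[h_i >= h_i^k]

i.e. the fraction of archive members it matches or beats in objective
``i``.  Each ``r_i`` lies on the grid {0, 1/N_P, ..., 1}; an empty
archive yields the all-ones reward (the first molecule vacuously beats
the empty front).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dominance",
    "as_objective_vector",
    "dominates",
    "pareto_front",
    "MoleculeRecord",
    "ParetoPool",
]


class Dominance(enum.Enum):
    """Outcome of a pairwise dominance comparison."""

    NONE = "none"
    WEAK = "weak"
    STRICT = "strict"


def as_objective_vector(values: Iterable[float]) -> np.ndarray:
    """Coerce ``values`` to a 1-d float array and validate it.

    Raises ``ValueError`` for empty or non-finite input.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < 1:
        raise ValueError("objective vector must have dimension >= 1")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"objective vector contains non-finite entries: {arr!r}")
    return arr


def dominates(x: Iterable[float], y: Iterable[float]) -> Dominance:
    """Pairwise dominance relation between two objective vectors.

    Returns :data:`Dominance.WEAK` when ``x >= y`` componentwise,
    :data:`Dominance.STRICT` when additionally ``x_i > y_i`` for at
    least one ``i``, and :data:`Dominance.NONE` otherwise.  Note
    ``dominates(x, x)`` is ``WEAK``.
    """
    xv = as_objective_vector(x)
    yv = as_objective_vector(y)
    if xv.shape != yv.shape:
        raise ValueError(f"dimension mismatch: {xv.shape} vs {yv.shape}")
    if not np.all(xv >= yv):
        return Dominance.NONE
    if np.any(xv > yv):
        return Dominance.STRICT
    return Dominance.WEAK


def pareto_front(vectors: Sequence[Iterable[float]]) -> np.ndarray:
    """Indices of the non-dominated members of ``vectors``.

    A member belongs to the front iff no other member strictly
    dominates it.  Duplicates of a front vector are all retained
    (equal vectors do not strictly dominate each other).  Order of the
    returned indices follows the input order.
    """
    if len(vectors) == 0:
        raise ValueError("pareto_front of an empty collection is undefined")
    arr = np.vstack([as_objective_vector(v) for v in vectors])
    n = arr.shape[0]
    # strict[i, j] == True when row i strictly dominates row j
    ge = np.all(arr[:, None, :] >= arr[None, :, :], axis=2)
    gt = np.any(arr[:, None, :] > arr[None, :, :], axis=2)
    strict = ge & gt
    dominated = strict.any(axis=0)
    return np.flatnonzero(~dominated)


@dataclass(frozen=True)
class MoleculeRecord:
    """A terminal token string with its raw metric vector and archive reward.

    Attributes
    ----------
    tokens:
        Canonical molecule text (canonical SMILES in chemistry mode, the
        terminated token string in toy mode).
    h:
        Raw oriented property metrics (higher is better in every entry).
    r:
        Pool-relative reward vector, each entry in ``[0, 1]``, computed
        against the archive state *before* the molecule was inserted.
    iteration:
        Provenance index of the search iteration that produced the record.
    """

    tokens: str
    h: np.ndarray
    r: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("MoleculeRecord.tokens must be non-empty")
        object.__setattr__(self, "h", as_objective_vector(self.h))
        object.__setattr__(self, "r", as_objective_vector(self.r))
        if self.h.shape != self.r.shape:
            raise ValueError("h and r must have the same dimension")
        if np.any(self.r < -1e-12) or np.any(self.r > 1 + 1e-12):
            raise ValueError(f"reward entries must lie in [0, 1]: {self.r!r}")
        if self.iteration < 0:
            raise ValueError("iteration must be nonnegative")


class ParetoPool:
    """Global archive of mutually non-dominated molecules.

    Membership is decided on the raw oriented metric vector ``h``;
    molecules are deduplicated by canonical token string, so
    re-generating an archived molecule changes nothing.
    """

    def __init__(self, dim: int):
        if dim < 1:
            raise ValueError("pool dimension must be >= 1")
        self.dim = int(dim)
        self.members: list[MoleculeRecord] = []
        self._keys: set[str] = set()

    @property
    def size(self) -> int:
        return len(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, tokens: str) -> bool:
        return tokens in self._keys

    def reward_vector(self, h: Iterable[float]) -> np.ndarray:
        """Pool-relative reward of a candidate metric vector.

        ``r_i`` is the fraction of members whose ``i``-th metric the
        candidate matches or exceeds; the empty pool returns all ones.
        """
        hv = as_objective_vector(h)
        if hv.size != self.dim:
            raise ValueError(f"dimension mismatch: {hv.size} vs pool dim {self.dim}")
        if not self.members:
            return np.ones(self.dim)
        pool_h = np.vstack([m.h for m in self.members])
        return (hv[None, :] >= pool_h).mean(axis=0)

    def update(self, rec: MoleculeRecord) -> bool:
        """Insert ``rec`` if non-dominated; evict members it strictly dominates.

        Returns ``True`` when the record was admitted.  ``rec.r`` must
        have been computed against the pool state before this call.
        """
        if rec.h.size != self.dim:
            raise ValueError(f"dimension mismatch: {rec.h.size} vs pool dim {self.dim}")
        if rec.tokens in self._keys:
            return False
        for m in self.members:
            if dominates(m.h, rec.h) is Dominance.STRICT:
                return False
        survivors = [m for m in self.members if dominates(rec.h, m.h) is not Dominance.STRICT]
        removed = len(self.members) - len(survivors)
        if removed:
            kept = {m.tokens for m in survivors}
            self._keys &= kept
        self.members = survivors
        self.members.append(rec)
        self._keys.add(rec.tokens)
        return True

    # -- serialization ---------------------------------------------------

    def to_frame(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        """One row per member: canonical string, metrics, rewards, iteration."""
        if names is None:
            names = [f"h{i}" for i in range(self.dim)]
        if len(names) != self.dim:
            raise ValueError("one column name per objective required")
        rows = []
        for m in self.members:
            row: dict[str, object] = {"tokens": m.tokens, "iteration": m.iteration}
            for name, hv in zip(names, m.h):
                row[f"h_{name}"] = hv
            for name, rv in zip(names, m.r):
                row[f"r_{name}"] = rv
            rows.append(row)
        columns = (
            ["tokens", "iteration"]
            + [f"h_{n}" for n in names]
            + [f"r_{n}" for n in names]
        )
        return pd.DataFrame(rows, columns=columns)

    def to_csv(self, path, names: Sequence[str] | None = None) -> None:
        self.to_frame(names).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ParetoPool":
        h_cols = [c for c in frame.columns if c.startswith("h_")]
        r_cols = [c for c in frame.columns if c.startswith("r_")]
        if not h_cols or len(h_cols) != len(r_cols):
            raise ValueError("frame does not look like a serialized pool")
        pool = cls(dim=len(h_cols))
        for _, row in frame.iterrows():
            rec = MoleculeRecord(
                tokens=str(row["tokens"]),
                h=row[h_cols].to_numpy(dtype=float),
                r=row[r_cols].to_numpy(dtype=float),
                iteration=int(row["iteration"]),
            )
            pool.update(rec)
        return pool

    @classmethod
    def from_csv(cls, path) -> "ParetoPool":
        return cls.from_frame(pd.read_csv(path))
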