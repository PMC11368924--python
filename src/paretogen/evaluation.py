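"""Post-hoc metrics over generated molecule sets.

Covers the cross-target uniqueness percentage, best-molecule selection
from a Pareto archive, dominance reports against a reference ligand,
and per-objective summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .objectives import ObjectiveSet
from .pareto import Dominance, MoleculeRecord, ParetoPool, dominates

__all__ = [
    "GenerationBatch",
    "uniqueness",
    "select_best",
    "dominance_report",
    "summarize",
]


@dataclass
class GenerationBatch:
    """Canonical molecule strings generated per target protein.

    ``molecules`` maps a protein identifier to the list of molecules
    generated for it (repeats allowed; metrics dedup as specified).
    """

    molecules: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.molecules = {k: list(v) for k, v in self.molecules.items()}

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenerationBatch":
        """Build from a table with ``protein_id`` and ``smiles`` columns."""
        missing = {"protein_id", "smiles"} - set(frame.columns)
        if missing:
            raise ValueError(f"batch table lacks columns: {sorted(missing)}")
        mols: dict[str, list[str]] = {}
        for pid, sub in frame.groupby("protein_id", sort=False):
            mols[str(pid)] = [str(s) for s in sub["smiles"]]
        return cls(mols)

    @classmethod
    def from_csv(cls, path) -> "GenerationBatch":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"protein_id": pid, "smiles": smi}
            for pid, mols in self.molecules.items()
            for smi in mols
        ]
        return pd.DataFrame(rows, columns=["protein_id", "smiles"])


def uniqueness(batch: GenerationBatch) -> float:
    """Percentage of distinct molecules across all target proteins.

    Each per-protein collection is deduplicated first; the numerator is
    the size of the set union over proteins, the denominator the sum of
    the per-protein deduplicated sizes (a multiset concatenation).  100
    means no molecule recurs across proteins or, after per-protein
    dedup, at all.
    """
    if not batch.molecules or any(len(v) == 0 for v in batch.molecules.values()):
        raise ValueError("uniqueness requires >= 1 protein with >= 1 molecule each")
    per_protein = [set(mols) for mols in batch.molecules.values()]
    union: set[str] = set()
    for s in per_protein:
        union |= s
    denominator = sum(len(s) for s in per_protein)
    return 100.0 * len(union) / denominator


def select_best(pool: ParetoPool) -> MoleculeRecord:
    """Archive member with the largest reward-vector sum.

    The winner has top rankings across the property metrics jointly;
    ties break by lexicographically smaller canonical string.
    """
    if pool.size == 0:
        raise ValueError("select_best on an empty pool")
    return min(pool.members, key=lambda m: (-float(m.r.sum()), m.tokens))


def dominance_report(
    records: Iterable[MoleculeRecord], reference: MoleculeRecord
) -> list[MoleculeRecord]:
    """Records whose metric vector strictly dominates the reference's.

    Strict dominance: at least as good in every objective and better
    in at least one.  A record equal to the reference everywhere is
    excluded.
    """
    return [
        rec for rec in records if dominates(rec.h, reference.h) is Dominance.STRICT
    ]


def summarize(
    records: Sequence[MoleculeRecord], objectives: ObjectiveSet, confidence: float = 0.95
) -> pd.DataFrame:
    """Per-objective mean and normal-approximation confidence interval.

    Values are reported on the raw (un-oriented) metric scale.  At
    least two records are required for an interval.
    """
    from statistics import NormalDist

    if len(records) < 2:
        raise ValueError("summarize requires >= 2 records for a confidence interval")
    z = NormalDist().inv_cdf(0.5 + confidence / 2)
    raw = pd.DataFrame([objectives.unorient(rec.h) for rec in records])
    rows = []
    for name in objectives.names:
        col = raw[name].to_numpy(dtype=float)
        mean = float(col.mean())
        half = z * float(col.std(ddof=1)) / np.sqrt(len(col))
        rows.append(
            {
                "objective": name,
                "mean": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
                "n": len(col),
            }
        )
    return pd.DataFrame(rows, columns=["objective", "mean", "ci_low", "ci_high", "n"])
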