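"""Next-token policy contract, tabular toy policies, adapters, and multi-target fusion.

A policy maps a :class:`StateContext` — one or more target protein
sequences plus the molecule fragment generated so far — to a probability
distribution over a fixed token vocabulary whose last entry is the
reserved terminal symbol ``$``.  The search engine only ever talks to
this contract, so a pretrained autoregressive SMILES model, the shipped
tabular toy policy, and the mean-pooled multi-target fusion are all
interchangeable.
"""

from __future__ import annotations

import importlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "TERMINAL",
    "StateContext",
    "PolicyModel",
    "PolicyError",
    "PolicyLoadError",
    "validate_distribution",
    "TabularToyPolicy",
    "fuse",
    "FusedPolicy",
    "load_vocabulary",
    "save_vocabulary",
    "load_policy",
]

#: Reserved terminal symbol; adapters map it to their model's end-of-sequence token.
TERMINAL = "$"

_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class PolicyError(RuntimeError):
    """A policy violated its contract (bad distribution, bad vocabulary)."""


class PolicyLoadError(RuntimeError):
    """A policy descriptor could not be resolved at load time."""


@dataclass(frozen=True)
class StateContext:
    """Search state: target protein sequence(s) plus the current fragment.

    ``proteins`` holds one sequence per target (several for multi-target
    generation); ``fragment`` is the ordered token sequence generated so
    far, excluding nothing — the terminal symbol, once appended, marks
    the context as terminal.
    """

    proteins: tuple[str, ...]
    fragment: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if isinstance(self.proteins, str):
            object.__setattr__(self, "proteins", (self.proteins,))
        else:
            object.__setattr__(self, "proteins", tuple(self.proteins))
        object.__setattr__(self, "fragment", tuple(self.fragment))
        if not self.proteins:
            raise ValueError("at least one protein sequence is required")
        for seq in self.proteins:
            if not seq:
                raise ValueError("protein sequence must be non-empty")
            bad = set(seq.upper()) - _AMINO_ACIDS
            if bad:
                raise ValueError(
                    f"protein sequence contains non-amino-acid letters: {sorted(bad)}"
                )

    @property
    def is_terminal(self) -> bool:
        return bool(self.fragment) and self.fragment[-1] == TERMINAL

    def with_token(self, token: str) -> "StateContext":
        return replace(self, fragment=self.fragment + (token,))

    def single_target(self, index: int) -> "StateContext":
        return replace(self, proteins=(self.proteins[index],))

    @property
    def text(self) -> str:
        return "".join(self.fragment)


@runtime_checkable
class PolicyModel(Protocol):
    """Contract: an ordered vocabulary and a deterministic ``predict``."""

    vocabulary: Sequence[str]

    def predict(self, context: StateContext) -> np.ndarray:  # pragma: no cover
        ...


def validate_distribution(p: np.ndarray, size: int, where: str = "policy") -> np.ndarray:
    """Check a predicted distribution: right length, nonnegative, sums to 1.

    Tolerance on the sum is 1e-6.  Raises :class:`PolicyError` naming
    ``where`` on violation.
    """
    arr = np.asarray(p, dtype=float)
    if arr.shape != (size,):
        raise PolicyError(f"{where}: distribution has shape {arr.shape}, expected ({size},)")
    if np.any(arr < 0):
        raise PolicyError(f"{where}: distribution has negative entries")
    total = float(arr.sum())
    if abs(total - 1.0) > 1e-6:
        raise PolicyError(f"{where}: distribution sums to {total!r}, not 1")
    return arr


@dataclass
class TabularToyPolicy:
    """Deterministic lookup policy over bounded fragment suffixes.

    The table maps a fragment suffix (a tuple of tokens, longest match
    wins, up to ``order`` trailing tokens) to a distribution over the
    vocabulary; unmatched contexts fall back to the uniform
    distribution.  Protein sequences are ignored — the toy policy
    exists to make every search component testable without model
    weights.
    """

    vocabulary: tuple[str, ...]
    table: dict[tuple[str, ...], np.ndarray] = field(default_factory=dict)
    order: int = 1

    def __post_init__(self) -> None:
        self.vocabulary = tuple(self.vocabulary)
        if TERMINAL not in self.vocabulary:
            raise PolicyError(f"vocabulary must contain the terminal symbol {TERMINAL!r}")
        normalized = {}
        for suffix, dist in self.table.items():
            key = tuple(suffix)
            normalized[key] = validate_distribution(
                np.asarray(dist, dtype=float), len(self.vocabulary), f"table row {key!r}"
            )
        self.table = normalized

    def predict(self, context: StateContext) -> np.ndarray:
        frag = context.fragment
        for k in range(min(self.order, len(frag)), -1, -1):
            row = self.table.get(frag[len(frag) - k:])
            if row is not None:
                return row.copy()
        return np.full(len(self.vocabulary), 1.0 / len(self.vocabulary))

    # -- plain-text round-trip ------------------------------------------

    def save(self, path) -> None:
        """Write the table as TSV rows ``suffix  token  probability``.

        The empty suffix is spelled ``-``; suffix tokens are joined
        without a separator (toy tokens are single characters).
        """
        lines = ["#suffix\ttoken\tprobability"]
        for suffix in sorted(self.table):
            row = self.table[suffix]
            name = "".join(suffix) if suffix else "-"
            for token, prob in zip(self.vocabulary, row):
                lines.append(f"{name}\t{token}\t{float(prob)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path, vocabulary: Sequence[str], order: int | None = None) -> "TabularToyPolicy":
        vocabulary = tuple(vocabulary)
        index = {tok: i for i, tok in enumerate(vocabulary)}
        rows: dict[tuple[str, ...], np.ndarray] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, token, prob = line.split("\t")
            suffix = () if name == "-" else tuple(name)
            if token not in index:
                raise PolicyLoadError(f"{path}: unknown token {token!r}")
            rows.setdefault(suffix, np.zeros(len(vocabulary)))[index[token]] = float(prob)
        if order is None:
            order = max((len(s) for s in rows), default=0)
        return cls(vocabulary=vocabulary, table=rows, order=order)


def fuse(distributions: Sequence[np.ndarray]) -> np.ndarray:
    """Mean-pool ``m`` per-target next-token distributions into one.

    The elementwise arithmetic mean of normalized distributions is
    normalized by construction; it boosts tokens preferred by all
    targets.  Raises :class:`PolicyError` on length mismatch or
    unnormalized input.
    """
    if len(distributions) < 1:
        raise PolicyError("fuse requires at least one distribution")
    size = len(np.asarray(distributions[0]))
    stacked = np.vstack(
        [validate_distribution(np.asarray(d, float), size, f"fuse member {i}")
         for i, d in enumerate(distributions)]
    )
    return stacked.mean(axis=0)


@dataclass
class FusedPolicy:
    """Multi-target policy: one member model per protein, mean-pooled.

    All members share one vocabulary; ``predict`` evaluates member ``i``
    on the context restricted to protein ``i`` (the fragment is shared)
    and returns the mean-pooled distribution.  This is the single place
    where multi-target logic lives, so the search engine is
    target-count agnostic.
    """

    members: tuple

    def __post_init__(self) -> None:
        self.members = tuple(self.members)
        if not self.members:
            raise PolicyError("FusedPolicy requires at least one member")
        vocab = tuple(self.members[0].vocabulary)
        for i, m in enumerate(self.members[1:], start=1):
            if tuple(m.vocabulary) != vocab:
                raise PolicyError(f"member {i} vocabulary differs from member 0")
        self.vocabulary = vocab

    def predict(self, context: StateContext) -> np.ndarray:
        if len(context.proteins) != len(self.members):
            raise PolicyError(
                f"{len(self.members)} member policies but "
                f"{len(context.proteins)} protein sequences in the context"
            )
        dists = []
        for i, member in enumerate(self.members):
            try:
                dists.append(member.predict(context.single_target(i)))
            except Exception as exc:  # annotate which target failed
                raise PolicyError(f"member policy for target {i} failed: {exc}") from exc
        return fuse(dists)


# -- vocabulary files and external adapters ------------------------------


def load_vocabulary(path) -> tuple[str, ...]:
    """Read a vocabulary file: one token per line, terminal symbol last."""
    tokens = [ln for ln in Path(path).read_text().splitlines() if ln]
    if not tokens:
        raise PolicyLoadError(f"{path}: empty vocabulary file")
    if TERMINAL not in tokens:
        raise PolicyLoadError(f"{path}: vocabulary lacks the terminal symbol {TERMINAL!r}")
    if tokens[-1] != TERMINAL:
        raise PolicyLoadError(f"{path}: terminal symbol must be the last vocabulary entry")
    if len(set(tokens)) != len(tokens):
        raise PolicyLoadError(f"{path}: vocabulary contains duplicate tokens")
    return tuple(tokens)


def save_vocabulary(tokens: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(tokens) + "\n")


class _ValidatedPolicy:
    """Wrap an arbitrary callable policy, validating every prediction."""

    def __init__(self, vocabulary: Sequence[str], predict_fn: Callable[[StateContext], np.ndarray], name: str):
        self.vocabulary = tuple(vocabulary)
        self._predict = predict_fn
        self._name = name

    def predict(self, context: StateContext) -> np.ndarray:
        raw = self._predict(context)
        return validate_distribution(
            np.asarray(raw, float), len(self.vocabulary),
            f"{self._name} at fragment {context.text!r}",
        )


def load_policy(descriptor: Mapping) -> PolicyModel:
    """Resolve a policy descriptor into a validated :class:`PolicyModel`.

    Supported descriptor ``type`` values:

    ``tabular``
        ``{"type": "tabular", "path": <table file>, "vocabulary": <vocab file>}``
        — the shipped toy policy format.
    ``callable``
        ``{"type": "callable", "entry": "pkg.module:attr", "vocabulary": <vocab file>}``
        — an adapter around any external autoregressive model exposing
        ``predict(context) -> distribution``.  ``attr`` may be the
        policy object itself or a zero-argument factory.

    Load failures (missing files, unresolvable entry points, vocabulary
    mismatches) raise :class:`PolicyLoadError` immediately; there is no
    silent fallback.  Returned policies validate normalization on every
    call.
    """
    kind = descriptor.get("type")
    vocab_path = descriptor.get("vocabulary")
    if vocab_path is None:
        raise PolicyLoadError("policy descriptor lacks a 'vocabulary' file")
    vocabulary = load_vocabulary(vocab_path)

    if kind == "tabular":
        path = descriptor.get("path")
        if path is None or not Path(path).exists():
            raise PolicyLoadError(f"tabular policy file not found: {path!r}")
        inner = TabularToyPolicy.load(path, vocabulary)
        return _ValidatedPolicy(vocabulary, inner.predict, f"tabular policy {path}")

    if kind == "callable":
        entry = descriptor.get("entry", "")
        if ":" not in entry:
            raise PolicyLoadError(f"callable descriptor entry must be 'module:attr', got {entry!r}")
        mod_name, attr = entry.split(":", 1)
        try:
            obj = getattr(importlib.import_module(mod_name), attr)
        except (ImportError, AttributeError) as exc:
            raise PolicyLoadError(f"cannot resolve policy entry {entry!r}: {exc}") from exc
        if not hasattr(obj, "predict") and callable(obj):
            obj = obj()
        if not hasattr(obj, "predict"):
            raise PolicyLoadError(f"policy entry {entry!r} exposes no predict()")
        model_vocab = tuple(getattr(obj, "vocabulary", vocabulary))
        if model_vocab != vocabulary:
            raise PolicyLoadError(
                f"policy entry {entry!r} vocabulary disagrees with {vocab_path}"
            )
        return _ValidatedPolicy(vocabulary, obj.predict, f"external policy {entry}")

    raise PolicyLoadError(f"unknown policy descriptor type: {kind!r}")
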