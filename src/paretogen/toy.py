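"""Enumerable toy sequence MDPs with conflicting objectives, plus brute-force oracles.

A :class:`ToyMDP` is a tiny token world — a small vocabulary ending in
the terminal symbol ``$``, a bounded molecule length, and surrogate
token-count objectives that conflict (e.g. ``countA`` vs ``countB``).
Because the terminal space is exhaustively enumerable, the true Pareto
front is computable by brute force, which makes every search component
verifiable with no chemistry, model weights, or downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .objectives import ObjectiveSet, toy_objectives
from .policy import TERMINAL, TabularToyPolicy

__all__ = [
    "ToyMDP",
    "enumerate_terminals",
    "brute_force_front",
    "uniform_policy",
    "chain_policy",
    "make_deceptive_policy",
]

_ENUMERATION_BOUND = 100_000


@dataclass
class ToyMDP:
    """A fully enumerable sequence-design world.

    ``max_len`` bounds the number of non-terminal tokens; every
    terminal string is a (possibly empty) body over the non-terminal
    alphabet followed by ``$``.
    """

    vocabulary: tuple[str, ...] = ("A", "B", TERMINAL)
    max_len: int = 3
    objectives: ObjectiveSet = field(default_factory=lambda: toy_objectives(["countA", "countB"]))
    seed: int = 0

    def __post_init__(self) -> None:
        self.vocabulary = tuple(self.vocabulary)
        if TERMINAL not in self.vocabulary:
            raise ValueError(f"vocabulary must include the terminal symbol {TERMINAL!r}")
        if self.max_len < 0:
            raise ValueError("max_len must be nonnegative")

    @property
    def body_alphabet(self) -> tuple[str, ...]:
        return tuple(t for t in self.vocabulary if t != TERMINAL)

    @property
    def n_terminals(self) -> int:
        k = len(self.body_alphabet)
        if k <= 1:
            return self.max_len + 1
        return (k ** (self.max_len + 1) - 1) // (k - 1)

    @property
    def max_depth(self) -> int:
        """Token budget for searches in this world (body plus terminal)."""
        return self.max_len + 1


def enumerate_terminals(mdp: ToyMDP) -> list[str]:
    """All terminal strings, duplicate-free, in deterministic order.

    Strings are listed by increasing body length, lexicographically
    within a length.  Refuses worlds larger than 10^5 terminals.
    """
    if mdp.n_terminals > _ENUMERATION_BOUND:
        raise ValueError(
            f"toy world has {mdp.n_terminals} terminals, above the "
            f"enumeration bound {_ENUMERATION_BOUND}"
        )
    alphabet = sorted(mdp.body_alphabet)
    out = [TERMINAL]
    bodies = [""]
    for _ in range(mdp.max_len):
        bodies = [b + t for b in bodies for t in alphabet]
        out.extend(b + TERMINAL for b in bodies)
    return out


def brute_force_front(mdp: ToyMDP) -> tuple[list[str], np.ndarray]:
    """Exact Pareto-optimal terminal set under the surrogate objectives.

    Pure-python exhaustive pairwise dominance — deliberately
    independent of :func:`paretogen.pareto.pareto_front` so it can
    serve as an oracle for search-recovery checks.  Returns the front
    strings (enumeration order) and their metric vectors.
    """
    terminals = enumerate_terminals(mdp)
    hs = [mdp.objectives.assemble_h(t) for t in terminals]
    front_strings: list[str] = []
    front_hs: list[np.ndarray] = []
    for i, hi in enumerate(hs):
        dominated = False
        for j, hj in enumerate(hs):
            if i == j:
                continue
            if all(a >= b for a, b in zip(hj, hi)) and any(a > b for a, b in zip(hj, hi)):
                dominated = True
                break
        if not dominated:
            front_strings.append(terminals[i])
            front_hs.append(hi)
    return front_strings, np.vstack(front_hs)


def uniform_policy(mdp: ToyMDP) -> TabularToyPolicy:
    """Uniform prior over the whole vocabulary in every context."""
    return TabularToyPolicy(vocabulary=mdp.vocabulary, table={}, order=0)


def chain_policy(mdp: ToyMDP, chain: str) -> TabularToyPolicy:
    """Deterministic policy emitting ``chain`` then the terminal symbol.

    The table keys on the last generated token, so the chain must not
    repeat a token with different successors.
    """
    vocab = mdp.vocabulary
    index = {t: i for i, t in enumerate(vocab)}
    seq = list(chain) + [TERMINAL]
    table: dict[tuple[str, ...], np.ndarray] = {}
    row0 = np.zeros(len(vocab))
    row0[index[seq[0]]] = 1.0
    table[()] = row0
    for prev, nxt in zip(seq, seq[1:]):
        row = np.zeros(len(vocab))
        row[index[nxt]] = 1.0
        existing = table.get((prev,))
        if existing is not None and not np.array_equal(existing, row):
            raise ValueError(f"chain {chain!r} revisits token {prev!r} ambiguously")
        table[(prev,)] = row
    return TabularToyPolicy(vocabulary=vocab, table=table, order=1)


def make_deceptive_policy(
    mdp: ToyMDP, misleading: str, mass: float = 0.9
) -> TabularToyPolicy:
    """A prior that pulls greedy decoding off the true Pareto front.

    The empty context puts ``mass`` on the misleading token; a context
    ending in the misleading token puts ``mass`` on the terminal
    symbol, so greedy decoding yields the short off-front string
    ``misleading + "$"``.  Contexts ending in any other body token are
    uniform.  Used to check that exploration (``c > 0``) escapes the
    local optimum a purely greedy or purely exploitative search gets
    stuck in.
    """
    vocab = mdp.vocabulary
    if misleading not in vocab or misleading == TERMINAL:
        raise ValueError(f"misleading token {misleading!r} not a body token of the vocabulary")
    index = {t: i for i, t in enumerate(vocab)}
    rest = (1.0 - mass) / (len(vocab) - 1)

    def peaked(token: str) -> np.ndarray:
        row = np.full(len(vocab), rest)
        row[index[token]] = mass
        return row

    uniform = np.full(len(vocab), 1.0 / len(vocab))
    table = {(): peaked(misleading), (misleading,): peaked(TERMINAL)}
    for token in mdp.body_alphabet:
        if token != misleading:
            table[(token,)] = uniform.copy()
    return TabularToyPolicy(vocabulary=vocab, table=table, order=1)
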