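"""Independent oracles used by the test suite.

Everything here is deliberately written without calling into the
package's own dominance/search code paths, so it can serve as a
cross-check: a plain-python O(n^2) Pareto front, and a scalar-PUCT
tree search that the vectorial engine must reproduce token-for-token
when there is a single objective.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_front_indices(vectors) -> list[int]:
    """O(n^2) pairwise-dominance front, plain python loops."""
    vecs = [list(map(float, v)) for v in vectors]
    out = []
    for i, x in enumerate(vecs):
        dominated = False
        for j, y in enumerate(vecs):
            if i == j:
                continue
            if all(a >= b for a, b in zip(y, x)) and any(a > b for a, b in zip(y, x)):
                dominated = True
                break
        if not dominated:
            out.append(i)
    return out


class _RefNode:
    __slots__ = ("token", "prior", "n", "w", "children")

    def __init__(self, token: str, prior: float):
        self.token = token
        self.prior = prior
        self.n = 0
        self.w = 0.0
        self.children: dict[str, "_RefNode"] = {}


class ScalarPuctReference:
    """Single-objective PUCT searcher mirroring the engine's loop structure.

    Selection maximizes the scalar score ``w/n + c * prior * sqrt(N)/(1+n)``
    with uniform random tie-breaking; rewards come from the same
    pool-relative counting rule restricted to one dimension.  The random
    stream is consumed exactly one uniform draw per selection step, so a
    seeded run is comparable draw-for-draw with the vectorial engine.
    """

    def __init__(self, policy, objective_fn, terminal: str = "$"):
        self.policy = policy
        self.vocab = list(policy.vocabulary)
        self.objective = objective_fn
        self.terminal = terminal
        self.pool: list[tuple[str, float]] = []  # (tokens, h)

    # -- pool -----------------------------------------------------------

    def _reward(self, h: float) -> float:
        if not self.pool:
            return 1.0
        return sum(1 for _, hk in self.pool if h >= hk) / len(self.pool)

    def _pool_update(self, tokens: str, h: float) -> None:
        if any(t == tokens for t, _ in self.pool):
            return
        if any(hk > h for _, hk in self.pool):
            return
        self.pool = [(t, hk) for t, hk in self.pool if not h > hk]
        self.pool.append((tokens, h))

    # -- search ---------------------------------------------------------

    def _predict(self, frag: tuple[str, ...], proteins) -> np.ndarray:
        from paretogen.policy import StateContext

        return np.asarray(self.policy.predict(StateContext(proteins, frag)), float)

    def _rollout(self, frag: tuple[str, ...], proteins, max_depth: int) -> str:
        frag = tuple(frag)
        while not (frag and frag[-1] == self.terminal) and len(frag) < max_depth:
            dist = self._predict(frag, proteins)
            frag = frag + (self.vocab[int(np.argmax(dist))],)
        return "".join(frag)

    def search_token(self, root: _RefNode, frag, proteins, c, iterations, max_depth, rng) -> str:
        for _ in range(iterations):
            node, ctx, path = root, tuple(frag), [root]
            while node.children and not (ctx and ctx[-1] == self.terminal):
                kids = list(node.children.values())
                scores = [
                    (k.w / k.n if k.n else 0.0)
                    + c * k.prior * (math.sqrt(node.n) / (1 + k.n))
                    for k in kids
                ]
                best = max(scores)
                ties = [i for i, s in enumerate(scores) if s == best]
                node = kids[ties[int(rng.integers(len(ties)))]]
                ctx = ctx + (node.token,)
                path.append(node)
            if not (ctx and ctx[-1] == self.terminal) and len(ctx) < max_depth:
                if not node.children:
                    dist = self._predict(ctx, proteins)
                    for tok, p in zip(self.vocab, dist):
                        node.children[tok] = _RefNode(tok, float(p))
            text = self._rollout(ctx, proteins, max_depth)
            if text.endswith(self.terminal):
                h = float(self.objective(text))
                r = self._reward(h)
                self._pool_update(text, h)
            else:
                r = 0.0
            for nd in path:
                nd.n += 1
                nd.w += r
        # move rule: most visited, then larger mean reward, then lexicographic
        best_tok, best_key = None, None
        for tok in sorted(root.children):
            child = root.children[tok]
            mean = child.w / child.n if child.n else -math.inf
            key = (child.n, mean)
            if best_key is None or key > best_key:
                best_tok, best_key = tok, key
        return best_tok

    def generate(self, proteins, c, iterations, max_depth, seed) -> list[str]:
        """Outer loop over token positions with subtree reuse; returns the moves."""
        rng = np.random.default_rng(seed)
        root = _RefNode("", 1.0)
        frag: tuple[str, ...] = ()
        moves = []
        for _ in range(max_depth):
            tok = self.search_token(root, frag, proteins, c, iterations, max_depth, rng)
            moves.append(tok)
            frag = frag + (tok,)
            root = root.children[tok]
            if tok == self.terminal:
                break
        return moves


def assert_tree_invariants(root) -> int:
    """Walk a tree checking visit conservation and reward bounds; returns node count."""
    count = 0
    stack = [root]
    while stack:
        node = stack.pop()
        count += 1
        child_visits = sum(ch.n_visits for ch in node.children.values())
        assert node.n_visits >= child_visits, (
            f"visit conservation violated at {node.token!r}: "
            f"{node.n_visits} < {child_visits}"
        )
        assert np.all(node.w >= -1e-12), f"negative cumulative reward at {node.token!r}"
        assert np.all(node.w <= node.n_visits + 1e-9), (
            f"cumulative reward exceeds visit count at {node.token!r}"
        )
        stack.extend(node.children.values())
    return count
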