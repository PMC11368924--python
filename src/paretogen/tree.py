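"""Pareto Monte Carlo tree search over autoregressive token decisions.

Each node of the tree is one vocabulary token appended to the molecule
fragment; node statistics are a visit count ``N_a`` and a *vector*
cumulative reward ``W_a``, so ``W_a / N_a`` estimates the mean reward
vector of rollouts through the node.  One search iteration is the
classic four-step loop:

Selection
    From the root, repeatedly pick a child by the vectorial PUCT rule:
    score every child as ``U_p = W_a/N_a + c * P(a|C) * sqrt(N)/(1+N_a)``,
    extract the Pareto front of the ``U_p`` vectors, and draw one front
    member uniformly at random.  Unvisited children use a zero
    exploitation term, so the prior drives their ranking.
Expansion
    A leaf gets one child per vocabulary symbol, with priors from the
    policy model.
Rollout
    The fragment is completed greedily (argmax policy probability)
    until the terminal symbol or the depth cap.
Backup
    The completed molecule is scored, its pool-relative reward vector
    is computed against the global Pareto archive (which is updated),
    and ``N_a += 1``, ``W_a += r`` along the selected path.

Strings that fail chemical parsing receive a zero reward vector, are
backed up normally, and never enter the archive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .objectives import InvalidMoleculeError, ObjectiveSet
from .pareto import MoleculeRecord, ParetoPool, pareto_front
from .policy import TERMINAL, PolicyError, PolicyModel, StateContext, validate_distribution

__all__ = [
    "TreeNode",
    "SearchConfig",
    "SearchError",
    "GenerationResult",
    "paretopuct_score",
    "ucb_score",
    "select_child",
    "expand",
    "rollout",
    "backup",
    "best_move",
    "search_token",
    "generate_molecule",
]


class SearchError(RuntimeError):
    """A policy or objective failure surfaced during search."""


@dataclass
class TreeNode:
    """One token decision in the search tree.

    ``w`` is the cumulative reward vector ``W_a`` and ``n_visits`` the
    visit count ``N_a``; ``prior`` is the policy probability ``P(a|C)``
    of this token given its parent's context.
    """

    token: str
    prior: float
    dim: int
    parent: "TreeNode | None" = None
    n_visits: int = 0
    w: np.ndarray = None  # type: ignore[assignment]
    children: dict[str, "TreeNode"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.w is None:
            self.w = np.zeros(self.dim)

    @property
    def expanded(self) -> bool:
        return bool(self.children)

    def mean_reward(self) -> np.ndarray:
        """Empirical mean reward vector; zero vector while unvisited."""
        if self.n_visits == 0:
            return np.zeros(self.dim)
        return self.w / self.n_visits

    def dump(self, indent: int = 0, min_visits: int = 1) -> str:
        """Nested text rendering (token, N_a, W_a, prior) for debugging."""
        label = self.token if self.token else "<root>"
        lines = [
            "  " * indent
            + f"{label} N={self.n_visits} W={np.round(self.w, 4).tolist()} P={self.prior:.4f}"
        ]
        for tok in sorted(self.children):
            child = self.children[tok]
            if child.n_visits >= min_visits:
                lines.append(child.dump(indent + 1, min_visits))
        return "\n".join(lines)


@dataclass(frozen=True)
class SearchConfig:
    """Search hyperparameters.

    ``c`` weights the exploration bonus; ``iterations`` is the
    selection/expansion/rollout/backup budget per token decision (the
    benchmark setting is 150); ``max_depth`` caps the token count of a
    molecule, terminal symbol included.
    """

    c: float = 1.0
    iterations: int = 150
    max_depth: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("exploration constant c must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if self.max_depth < 0:
            raise ValueError("max_depth must be nonnegative")


def paretopuct_score(child: TreeNode, n_parent: int, c: float) -> np.ndarray:
    """Vectorial PUCT selection score of one child.

    ``U_p = W_a/N_a + c * P(a|C) * sqrt(N)/(1+N_a)``; the exploitation
    term is the zero vector while the child is unvisited.
    """
    if n_parent < 0:
        raise ValueError("n_parent must be nonnegative")
    exploit = child.mean_reward()
    bonus = math.sqrt(n_parent) / (1 + child.n_visits)
    return exploit + c * child.prior * bonus


def ucb_score(child: TreeNode, n_parent: int) -> float:
    """Scalar UCB1 baseline ``U = W_a/N_a + sqrt(2 ln N / N_a)``.

    Only defined for single-objective trees with ``N_a >= 1``; kept for
    comparison against the vectorial rule.
    """
    if child.dim != 1:
        raise ValueError("ucb_score applies to scalar-reward trees only")
    if child.n_visits < 1:
        raise ValueError("ucb_score requires at least one visit")
    return float(child.w[0]) / child.n_visits + math.sqrt(
        2.0 * math.log(n_parent) / child.n_visits
    )


def select_child(node: TreeNode, c: float, rng: np.random.Generator) -> TreeNode:
    """Draw uniformly from the Pareto front of the children's score vectors.

    A uniform draw is made even when the front is a singleton, so the
    random stream advances deterministically per selection step.
    """
    if not node.children:
        raise ValueError("select_child on an unexpanded node")
    children = list(node.children.values())
    scores = [paretopuct_score(ch, node.n_visits, c) for ch in children]
    front = pareto_front(scores)
    return children[front[int(rng.integers(len(front)))]]


def expand(node: TreeNode, context: StateContext, policy: PolicyModel) -> None:
    """Create one child per vocabulary symbol with policy priors.

    Idempotent: expanding an expanded node is a no-op.  A policy
    returning a non-normalized or negative distribution raises
    :class:`~paretogen.policy.PolicyError`.
    """
    if node.expanded:
        return
    vocab = list(policy.vocabulary)
    dist = validate_distribution(
        np.asarray(policy.predict(context), float), len(vocab),
        f"policy at fragment {context.text!r}",
    )
    for token, prior in zip(vocab, dist):
        node.children[token] = TreeNode(
            token=token, prior=float(prior), dim=node.dim, parent=node
        )


def rollout(
    context: StateContext, policy: PolicyModel, max_depth: int
) -> tuple[str, bool]:
    """Greedy completion of the fragment to a terminal molecule string.

    The argmax-probability token is appended until the terminal symbol
    appears or the fragment holds ``max_depth`` tokens; the flag
    reports whether termination was natural (depth-capped rollouts are
    incomplete).
    """
    vocab = list(policy.vocabulary)
    ctx = context
    while not ctx.is_terminal and len(ctx.fragment) < max_depth:
        dist = validate_distribution(
            np.asarray(policy.predict(ctx), float), len(vocab),
            f"policy at fragment {ctx.text!r}",
        )
        ctx = ctx.with_token(vocab[int(np.argmax(dist))])
    return ctx.text, ctx.is_terminal


def backup(path: Sequence[TreeNode], r: np.ndarray) -> None:
    """Propagate one rollout reward along the selected path.

    Every node on the path gets ``N_a += 1`` and ``W_a += r``; the
    path may be given in either direction since the update is
    node-local.
    """
    r = np.asarray(r, float)
    for node in path:
        node.n_visits += 1
        node.w = node.w + r


def best_move(root: TreeNode) -> str:
    """Token of the most-visited child.

    Ties break by larger mean-reward sum, then by lexicographically
    smaller token (visit count is the standard robust move statistic).
    """
    if not root.children:
        raise ValueError("best_move on an unexpanded root")
    best_token: str | None = None
    best_key: tuple[float, float] | None = None
    for token in sorted(root.children):
        child = root.children[token]
        mean_sum = float(child.mean_reward().sum()) if child.n_visits else -math.inf
        key = (child.n_visits, mean_sum)
        if best_key is None or key > best_key:
            best_key = key
            best_token = token
    assert best_token is not None
    return best_token


def search_token(
    root: TreeNode,
    context: StateContext,
    policy: PolicyModel,
    objectives: ObjectiveSet,
    pool: ParetoPool,
    config: SearchConfig,
    rng: np.random.Generator | None = None,
    trace: list | None = None,
) -> str:
    """Run the four-step loop for one token decision and return the move.

    Executes ``config.iterations`` iterations of Selection, Expansion,
    Rollout, evaluation (pool-relative reward + archive update) and
    Backup, mutating ``root`` and ``pool`` in place.  ``trace``, when
    given, collects one dict per iteration.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for it in range(config.iterations):
        node = root
        ctx = context
        path = [root]
        try:
            while node.expanded and not ctx.is_terminal:
                node = select_child(node, config.c, rng)
                ctx = ctx.with_token(node.token)
                path.append(node)
            if not ctx.is_terminal and len(ctx.fragment) < config.max_depth:
                expand(node, ctx, policy)
            text, complete = rollout(ctx, policy, config.max_depth)
        except PolicyError as exc:
            raise SearchError(f"iteration {it}: {exc}") from exc

        r = np.zeros(objectives.dim)
        h = None
        try:
            canonical = objectives.canonicalize(text)
            h = objectives.assemble_h(canonical)
            r = pool.reward_vector(h)
            pool.update(MoleculeRecord(canonical, h, r, iteration=it))
        except InvalidMoleculeError:
            pass  # zero reward, backed up normally, never archived
        backup(path, r)
        if trace is not None:
            trace.append(
                {
                    "iteration": it,
                    "path": [n.token for n in path[1:]],
                    "rollout": text,
                    "complete": complete,
                    "h": None if h is None else h.tolist(),
                    "r": r.tolist(),
                    "pool_size": pool.size,
                }
            )
    return best_move(root)


@dataclass(frozen=True)
class GenerationResult:
    """Outcome of one molecule generation run."""

    status: str  # "ok" or "failed"
    record: MoleculeRecord | None
    pool: ParetoPool
    tokens: str

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def generate_molecule(
    proteins: Sequence[str] | str,
    policy: PolicyModel,
    objectives: ObjectiveSet,
    config: SearchConfig,
    pool: ParetoPool | None = None,
    rng: np.random.Generator | None = None,
) -> GenerationResult:
    """Generate one molecule by running a search per token position.

    The root advances one token at a time: each position gets a full
    ``config.iterations`` search, the most-visited child becomes the
    move, and its subtree is reused.  The Pareto archive persists
    across all token decisions (pass ``pool`` to share it across
    several runs).  A run that never produces a valid terminal
    molecule reports ``status="failed"``.
    """
    if pool is None:
        pool = ParetoPool(objectives.dim)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    context = StateContext(proteins)
    root = TreeNode(token="", prior=1.0, dim=objectives.dim)
    for _ in range(config.max_depth):
        token = search_token(root, context, policy, objectives, pool, config, rng)
        context = context.with_token(token)
        root = root.children[token]
        root.parent = None
        if token == TERMINAL:
            break
    text = context.text
    try:
        canonical = objectives.canonicalize(text)
        h = objectives.assemble_h(canonical)
    except InvalidMoleculeError:
        return GenerationResult("failed", None, pool, text)
    record = next((m for m in pool.members if m.tokens == canonical), None)
    if record is None:
        record = MoleculeRecord(canonical, h, pool.reward_vector(h), iteration=0)
        pool.update(record)
    return GenerationResult("ok", record, pool, text)
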