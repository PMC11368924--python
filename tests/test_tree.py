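"""Selection, expansion, rollout, backup, and the per-token search driver."""

import math

import numpy as np
import pytest

from paretogen import (
    ParetoPool,
    SearchConfig,
    StateContext,
    ToyMDP,
    TreeNode,
    backup,
    best_move,
    brute_force_front,
    chain_policy,
    expand,
    generate_molecule,
    make_deceptive_policy,
    paretopuct_score,
    rollout,
    search_token,
    select_child,
    toy_objectives,
    ucb_score,
    uniform_policy,
)
from paretogen.policy import PolicyError, TabularToyPolicy

from conftest import PROTEIN
from helpers import ScalarPuctReference, assert_tree_invariants


def node(dim=2, token="A", prior=0.5, n=0, w=None):
    nd = TreeNode(token=token, prior=prior, dim=dim)
    nd.n_visits = n
    if w is not None:
        nd.w = np.asarray(w, float)
    return nd


class TestScores:
    def test_unvisited_child_scored_by_prior_only(self):
        child = node(n=0, w=(0, 0), prior=0.5)
        assert np.allclose(paretopuct_score(child, 1, c=1.0), (0.5, 0.5), atol=1e-12)

    def test_visited_child_mixes_mean_and_bonus(self):
        child = node(n=1, w=(0.5, 1.0), prior=0.5)
        assert np.allclose(paretopuct_score(child, 4, c=1.0), (1.0, 1.5), atol=1e-12)

    def test_pure_exploitation_at_c_zero(self):
        child = node(n=2, w=(1.0, 0.4), prior=0.9)
        assert np.allclose(paretopuct_score(child, 100, c=0.0), (0.5, 0.2), atol=1e-12)

    def test_ucb_closed_form(self):
        child = node(dim=1, n=4, w=(2.0,))
        assert ucb_score(child, 16) == pytest.approx(0.5 + math.sqrt(2 * math.log(16) / 4))

    def test_ucb_zero_at_single_visit_single_iteration(self):
        child = node(dim=1, n=1, w=(0.0,))
        assert ucb_score(child, 1) == 0.0

    def test_ucb_all_wins_identity(self):
        child = node(dim=1, n=9, w=(9.0,))
        assert ucb_score(child, 9) == pytest.approx(1 + math.sqrt(2 * math.log(9) / 9))

    def test_ucb_requires_visits(self):
        with pytest.raises(ValueError):
            ucb_score(node(dim=1, n=0), 4)


class TestSelectChild:
    def _parent_with(self, children):
        parent = node(token="", prior=1.0, n=10)
        for ch in children:
            parent.children[ch.token] = ch
        return parent

    def test_single_child_always_selected(self):
        only = node(token="A")
        parent = self._parent_with([only])
        rng = np.random.default_rng(0)
        assert all(select_child(parent, 1.0, rng) is only for _ in range(20))

    def test_dominant_child_always_selected(self):
        good = node(token="A", n=2, w=(2, 2), prior=0.5)
        bad = node(token="B", n=2, w=(0, 0), prior=0.1)
        parent = self._parent_with([good, bad])
        rng = np.random.default_rng(0)
        assert all(select_child(parent, 1.0, rng) is good for _ in range(50))

    def test_front_members_drawn_uniformly(self):
        # two mutually non-dominated children; binomial 95% band around 5000
        a = node(token="A", n=1, w=(1, 0), prior=0.0)
        b = node(token="B", n=1, w=(0, 1), prior=0.0)
        parent = self._parent_with([a, b])
        rng = np.random.default_rng(42)
        hits = sum(select_child(parent, 0.0, rng) is a for _ in range(10_000))
        assert abs(hits - 5000) <= 200

    def test_unexpanded_node_rejected(self):
        with pytest.raises(ValueError):
            select_child(node(), 1.0, np.random.default_rng(0))


class TestExpandRollout:
    def test_expand_creates_all_children_with_normalized_priors(self, toy_mdp, toy_policy, context):
        root = TreeNode("", 1.0, dim=2)
        expand(root, context, toy_policy)
        assert set(root.children) == {"A", "B", "$"}
        assert sum(ch.prior for ch in root.children.values()) == pytest.approx(1.0)
        for ch in root.children.values():
            assert ch.n_visits == 0 and np.all(ch.w == 0)

    def test_expand_idempotent(self, toy_policy, context):
        root = TreeNode("", 1.0, dim=2)
        expand(root, context, toy_policy)
        kids = dict(root.children)
        expand(root, context, toy_policy)
        assert root.children == kids

    def test_all_mass_on_one_token(self, toy_mdp, context):
        policy = TabularToyPolicy(toy_mdp.vocabulary, {(): np.array([0.0, 1.0, 0.0])}, order=0)
        root = TreeNode("", 1.0, dim=2)
        expand(root, context, policy)
        assert root.children["B"].prior == 1.0
        assert root.children["A"].prior == 0.0

    def test_unnormalized_policy_rejected(self, toy_mdp, context):
        class Bad:
            vocabulary = toy_mdp.vocabulary

            def predict(self, ctx):
                return np.array([0.5, 0.3, 0.1])

        with pytest.raises(PolicyError):
            expand(TreeNode("", 1.0, dim=2), context, Bad())

    def test_rollout_walks_deterministic_chain(self, toy_mdp):
        policy = chain_policy(toy_mdp, "AB")
        ctx = StateContext(PROTEIN, ("A",))
        text, complete = rollout(ctx, policy, max_depth=10)
        assert text == "AB$" and complete

    def test_rollout_on_terminal_context_is_identity(self, toy_policy):
        ctx = StateContext(PROTEIN, ("A", "$"))
        text, complete = rollout(ctx, toy_policy, max_depth=10)
        assert text == "A$" and complete

    def test_rollout_depth_cap_flags_incomplete(self, toy_mdp):
        policy = TabularToyPolicy(toy_mdp.vocabulary, {(): np.array([1.0, 0.0, 0.0])}, order=0)
        text, complete = rollout(StateContext(PROTEIN), policy, max_depth=5)
        assert text == "AAAAA" and not complete


class TestBackup:
    def test_fresh_node_accumulates(self):
        nd = node(n=0, w=(0, 0))
        backup([nd], np.array([0.2, 0.8]))
        assert nd.n_visits == 1 and np.allclose(nd.w, (0.2, 0.8))

    def test_accumulation_adds(self):
        nd = node(n=3, w=(1, 1))
        backup([nd], np.array([0.0, 1.0]))
        assert nd.n_visits == 4 and np.allclose(nd.w, (1, 2))

    def test_every_path_node_incremented_once(self):
        path = [node(token=t) for t in "ABCD"]
        backup(path, np.array([0.5, 0.5]))
        assert all(nd.n_visits == 1 for nd in path)


class TestSearchToken:
    def test_single_iteration_accounting(self, toy_mdp, toy_policy, context, empty_pool):
        root = TreeNode("", 1.0, dim=2)
        cfg = SearchConfig(iterations=1, max_depth=toy_mdp.max_depth, seed=0)
        search_token(root, context, toy_policy, toy_mdp.objectives, empty_pool, cfg)
        assert root.n_visits == 1
        assert empty_pool.size <= 1  # exactly one pool-update attempt

    def test_deterministic_under_fixed_seed(self, toy_mdp, toy_policy, context):
        outs = []
        for _ in range(2):
            root = TreeNode("", 1.0, dim=2)
            pool = ParetoPool(2)
            cfg = SearchConfig(iterations=300, max_depth=toy_mdp.max_depth, seed=11)
            tok = search_token(root, context, toy_policy, toy_mdp.objectives, pool, cfg)
            outs.append((tok, tuple(sorted(m.tokens for m in pool.members))))
        assert outs[0] == outs[1]

    def test_front_recovery_on_toy_mdp(self, toy_mdp, toy_policy, context):
        front, _ = brute_force_front(toy_mdp)
        root = TreeNode("", 1.0, dim=2)
        pool = ParetoPool(2)
        cfg = SearchConfig(c=1.0, iterations=2000, max_depth=toy_mdp.max_depth, seed=5)
        tok = search_token(root, context, toy_policy, toy_mdp.objectives, pool, cfg)
        assert sorted(m.tokens for m in pool.members) == sorted(front)
        # chosen move starts some true-front molecule
        assert any(s.startswith(tok) for s in front)

    def test_invariants_hold_on_all_nodes(self, toy_mdp, toy_policy, context):
        root = TreeNode("", 1.0, dim=2)
        pool = ParetoPool(2)
        cfg = SearchConfig(iterations=500, max_depth=toy_mdp.max_depth, seed=2)
        search_token(root, context, toy_policy, toy_mdp.objectives, pool, cfg)
        assert root.n_visits == 500
        assert_tree_invariants(root)

    def test_trace_records_every_iteration(self, toy_mdp, toy_policy, context, empty_pool):
        root = TreeNode("", 1.0, dim=2)
        cfg = SearchConfig(iterations=25, max_depth=toy_mdp.max_depth, seed=0)
        trace = []
        search_token(root, context, toy_policy, toy_mdp.objectives, empty_pool, cfg, trace=trace)
        assert [t["iteration"] for t in trace] == list(range(25))
        assert all(t["pool_size"] >= 1 for t in trace[1:])


class TestGenerateMolecule:
    def test_deterministic_chain_policy_yields_the_chain(self, toy_mdp):
        policy = chain_policy(toy_mdp, "AB")
        cfg = SearchConfig(iterations=50, max_depth=toy_mdp.max_depth, seed=0)
        result = generate_molecule(PROTEIN, policy, toy_mdp.objectives, cfg)
        assert result.ok and result.record.tokens == "AB$"
        assert [m.tokens for m in result.pool.members] == ["AB$"]

    def test_zero_depth_fails(self, toy_mdp, toy_policy):
        cfg = SearchConfig(iterations=10, max_depth=0, seed=0)
        result = generate_molecule(PROTEIN, toy_policy, toy_mdp.objectives, cfg)
        assert not result.ok and result.record is None and result.pool.size == 0

    def test_repeated_runs_identical(self, toy_mdp, toy_policy):
        cfg = SearchConfig(iterations=150, max_depth=toy_mdp.max_depth, seed=9)
        r1 = generate_molecule(PROTEIN, toy_policy, toy_mdp.objectives, cfg)
        r2 = generate_molecule(PROTEIN, toy_policy, toy_mdp.objectives, cfg)
        assert r1.tokens == r2.tokens
        assert [m.tokens for m in r1.pool.members] == [m.tokens for m in r2.pool.members]

    def test_shared_pool_persists_across_runs(self, toy_mdp, toy_policy):
        pool = ParetoPool(2)
        cfg = SearchConfig(iterations=100, max_depth=toy_mdp.max_depth, seed=1)
        generate_molecule(PROTEIN, toy_policy, toy_mdp.objectives, cfg, pool=pool)
        size_after_first = pool.size
        cfg2 = SearchConfig(iterations=100, max_depth=toy_mdp.max_depth, seed=2)
        result = generate_molecule(PROTEIN, toy_policy, toy_mdp.objectives, cfg2, pool=pool)
        assert result.pool is pool
        assert pool.size >= 1 and size_after_first >= 1


class TestScalarReduction:
    def test_single_objective_matches_scalar_puct_reference(self, toy_mdp):
        objectives = toy_objectives(["countA"])
        policy = uniform_policy(toy_mdp)
        for seed in range(5):
            cfg = SearchConfig(c=1.0, iterations=150, max_depth=toy_mdp.max_depth, seed=seed)
            result = generate_molecule(PROTEIN, policy, objectives, cfg)
            ref = ScalarPuctReference(policy, objectives.specs[0].scorer)
            moves = ref.generate((PROTEIN,), c=1.0, iterations=150,
                                 max_depth=toy_mdp.max_depth, seed=seed)
            assert result.tokens == "".join(moves)


class TestExplorationEffect:
    def test_exploration_recovers_front_missed_by_pure_exploitation(self):
        # deceptive prior: greedy decoding gives the off-front string "B$"
        mdp = ToyMDP(vocabulary=("A", "B", "$"), max_len=2,
                     objectives=toy_objectives(["countA"]))
        policy = make_deceptive_policy(mdp, misleading="B")
        front, _ = brute_force_front(mdp)
        greedy, complete = rollout(StateContext(PROTEIN), policy, mdp.max_depth)
        assert complete and greedy == "B$" and greedy not in front

        def coverage(c: float, seed: int) -> float:
            pool = ParetoPool(1)
            root = TreeNode("", 1.0, dim=1)
            cfg = SearchConfig(c=c, iterations=4000, max_depth=mdp.max_depth, seed=seed)
            search_token(root, StateContext(PROTEIN), policy, mdp.objectives, pool, cfg)
            found = {m.tokens for m in pool.members}
            return len(found & set(front)) / len(front)

        explore = np.mean([coverage(1.0, s) for s in range(20)])
        exploit = np.mean([coverage(0.0, s) for s in range(20)])
        assert explore > exploit
        assert explore > 0.9
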