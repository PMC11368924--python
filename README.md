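# paretogen

Multi-objective Pareto Monte Carlo tree search for target-aware,
atom-by-atom molecule generation.

## What problem this solves

A useful drug candidate must satisfy several competing requirements at
once: strong predicted binding to a specific protein target, high
drug-likeness (QED), low synthetic difficulty (SA score), natural-
product character (NP-likeness), and a lipophilicity in the druggable
window (LogP in [−0.4, 5.6]). Scalarizing these into one score imposes
arbitrary weights; `paretogen` instead searches directly for the
*Pareto front* — molecules no other found molecule beats in every
property simultaneously.

The package is aimed at practitioners who already have (or can adapt)
a pretrained autoregressive SMILES model conditioned on a protein
sequence, and want to steer its decoding toward multi-property optima
rather than taking its greedy output; and at method developers who
need a fully testable multi-objective MCTS core with exact oracles.

## The algorithm

Generation is token-by-token tree search. A global archive keeps every
mutually non-dominated molecule found so far; a new molecule with raw
metric vector **h** earns the pool-relative reward

```
r_i = (1/N_P) Σ_k 1[h_i ≥ h_i^k],   i = 1..d
```

— the fraction of archive members it matches or beats in objective
`i`. Tree statistics are vectors: each node holds a visit count `N_a`
and cumulative reward `W_a`, updated by `N_a ← N_a+1`, `W_a ← W_a + r`
along the rollout path. Child selection computes, for every child,

```
U_p(a) = W_a/N_a + c · P(a|C) · √N / (1 + N_a)
```

with `P(a|C)` the policy prior given the protein and fragment, then
draws uniformly at random from the **Pareto front of the `U_p`
vectors** — exploration/exploitation balancing without scalarization.
For multi-target design, per-target policy predictions are mean-pooled
into a single prior, and the rest of the machinery is unchanged.
Rollouts are greedy policy completions; invalid strings are penalized
with zero reward and never archived. With one objective the whole
scheme provably collapses to scalar PUCT (tested token-for-token
against an independent reference).

## Worked example

A two-letter toy world whose exact front is enumerable: vocabulary
`{A, B, $}`, molecules up to 3 body tokens, conflicting objectives
`(countA, countB)`.

```python
from paretogen import (ParetoPool, SearchConfig, StateContext, ToyMDP, TreeNode,
                       brute_force_front, search_token, toy_objectives,
                       uniform_policy)

mdp = ToyMDP(vocabulary=("A", "B", "$"), max_len=3,
             objectives=toy_objectives(["countA", "countB"]))
policy = uniform_policy(mdp)
pool = ParetoPool(mdp.objectives.dim)
root = TreeNode("", prior=1.0, dim=2)
config = SearchConfig(c=1.0, iterations=2000, max_depth=mdp.max_depth, seed=7)
move = search_token(root, StateContext("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
                    policy, mdp.objectives, pool, config)
print("chosen first token:", move)
print("archive:", sorted(m.tokens for m in pool.members))
print("exact front:", sorted(brute_force_front(mdp)[0]))
```

prints

```
chosen first token: B
archive: ['AAA$', 'AAB$', 'ABA$', 'ABB$', 'BAA$', 'BAB$', 'BBA$', 'BBB$']
exact front: ['AAA$', 'AAB$', 'ABA$', 'ABB$', 'BAA$', 'BAB$', 'BBA$', 'BBB$']
```

After 2,000 iterations the archive holds exactly the eight
Pareto-optimal strings (every permutation realizing the count trade-off
(3,0), (2,1), (1,2), (0,3)) — the search recovered the true front, and
the chosen first token starts one of its members.

The descriptor panel on a real drug (Tropifexor, the FXR agonist):

```python
from paretogen import score_properties
from paretogen.reference import REFERENCE_LIGANDS

print({k: round(v, 2) for k, v in
       score_properties(REFERENCE_LIGANDS["tropifexor"]).items()})
# {'logp': 7.28, 'qed': 0.21, 'sa': 4.64, 'np': -0.91}
```

i.e. lipophilicity far above the druggable window, low drug-likeness,
moderate synthetic difficulty — the trade-offs a multi-objective
search is meant to improve on.

## Command line

```bash
paretogen generate --show-config          # default YAML configuration
paretogen generate --config run.yaml      # pool.csv, selected.smi/.sdf, run.log
paretogen evaluate mols.smi --out metrics.csv
paretogen uniqueness batch.csv            # cross-target uniqueness, e.g. "75.0"
```

Run directories echo the full configuration, seed, and descriptor
versions, so toy-policy runs reproduce byte-for-byte.

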