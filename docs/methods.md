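# Methods

## Problem setting

Target-aware de novo design asks for molecules that bind a given
protein while also being drug-like, synthesizable, and within a
sensible lipophilicity window. Generation is modeled as a sparse-reward
Markov decision process over token strings: a state is the target
protein sequence plus the molecule fragment built so far, an action
appends one vocabulary token (an atom-level SMILES symbol, or a toy
letter), and the reward — a *vector*, one entry per property objective
— arrives only when the string terminates. A pretrained autoregressive
next-token model supplies priors `P(a|C)` that steer the search toward
chemically plausible, target-compatible continuations; this package
treats that model as a pluggable contract and ships a tabular toy
policy so the whole engine is testable without weights.

## Dominance, the archive, and the reward vector

All objectives are oriented so larger is better (minimize-type metrics
are negated; the LogP window becomes a {0,1} indicator). Vector `x`
weakly dominates `y` when `x_i ≥ y_i` for all `i`, strictly when some
inequality is strict. The search maintains a global archive (the
"pool") of mutually non-dominated molecules, deduplicated by canonical
string: a new molecule enters iff no member strictly dominates it, and
members it strictly dominates are evicted.

A candidate with raw metric vector `h` is rewarded relative to the
archive *before* it is inserted:

    r_i = (1/N_P) · Σ_k 1[h_i ≥ h_i^k]

the fraction of archive members it matches or beats in objective `i`.
This normalizes incommensurable scales (binding energies, QED, SA)
without fixed weights. Two edge conventions:

- **Empty archive.** The formula divides by `N_P = 0`; the first valid
  molecule receives the all-ones reward, the natural limit of "beats
  the whole front".
- **`≥` vs `>`.** The defining formula and its surrounding prose
  disagree on whether ties count. We use the non-strict `≥` (the
  formula), which also makes the reward monotone under weak dominance;
  the strict variant would only change rewards on exact metric ties.

## The search loop

Each token decision runs `IT` iterations of
Selection → Expansion → Rollout → Backup (default `IT = 150`, the
published benchmark budget; tests and the acceptance script use larger
budgets on the toy world where stated):

- **Selection** scores every child of the current node as

      U_p(a) = W_a/N_a + c · P(a|C) · √N / (1 + N_a)

  with `N` the parent's visit count, extracts the Pareto front of the
  `U_p` vectors, and draws one front member uniformly at random.
  Unvisited children use a zero exploitation term (`0/0 → 0`, the
  standard PUCT convention), so priors rank them. One uniform draw is
  consumed per selection step even when the front is a singleton,
  which keeps seeded runs draw-for-draw comparable with reference
  implementations.
- **Expansion** adds one child per vocabulary symbol with priors from
  the policy (validated to sum to 1 within 1e-6); re-expansion is a
  no-op.
- **Rollout** completes the fragment greedily (argmax probability,
  first index on ties) until the terminal symbol `$` or the depth cap
  (default 100 tokens). Depth-capped strings are flagged incomplete.
- **Backup** updates `N_a ← N_a + 1`, `W_a ← W_a + r` along the
  selected path. Strings that fail canonicalization get `r = 0`,
  are backed up normally (penalizing the path), and never enter the
  archive.

After `IT` iterations the move is the most-visited child, ties broken
by larger mean-reward sum, then lexicographic token order; visit count
is the robust PUCT move statistic and the published procedure does not
specify a rule. The chosen subtree is reused at the next position. The
archive persists across token positions, and optionally across the
`n` runs used to collect several candidates (default: shared).

With a single objective the front of scalar scores is exactly the
argmax set, so the engine reduces to scalar PUCT; the test suite
checks trajectory equality against an independently written scalar
reference under shared seeds.

## Multi-target fusion

For multi-target generation (`m` proteins, one policy evaluation per
protein on the shared fragment) the per-target next-token
distributions are mean-pooled:

    f(P_1, …, P_m)(a) = (1/m) Σ_i P_i(a|C_i)

and the fused distribution substitutes for `P(a|C)` in the selection
score — an algebraic identity with the multi-target selection rule,
asserted to 1e-12 in tests. Mean-pooling preserves normalization, is
order-invariant, and boosts tokens all targets prefer. Fusion is the
only place multi-target logic lives; the engine is target-count
agnostic. Whether the reward vector mixes per-target docking scores
with shared drug-likeness objectives is a configuration choice — both
are expressible through the objective set.

## Objectives

The chemistry panel uses the standard RDKit implementations —
Wildman–Crippen LogP, QED (in [0,1]), the Ertl–Schuffenhauer SA score
(1 easy … 10 hard, minimized), the Ertl NP-likeness (≈ −5 … 5) — with
the RDKit version recorded in run logs, since the fragment-contribution
scores can drift across releases. LogP enters dominance as the closed
window indicator `1[−0.4 ≤ LogP ≤ 5.6]` (the Ghose druggable range;
boundaries inclusive as printed). Docking through an external
`smina`-compatible executable is optional: the oriented objective is
the negated best binding energy, setup fails eagerly when the
executable or receptor is missing, and the default test configuration
uses no docking so the build is download-free. Token-count surrogate
objectives (`countA`, `length`, differences/sums thereof) stand in for
docking in pipeline tests — they are deterministic, conflicting, and
enumerable, which real docking is not.

## Toy worlds and what they do (not) show

The toy generator builds enumerable sequence MDPs: vocabulary
`{A, B, $}` (never overlapping SMILES tokens), body length ≤ 3 by
default (15 terminals; enumeration refuses worlds beyond 10^5), and
conflicting count objectives `(countA, countB)` whose exact front is
computed by an independent brute-force oracle. Policy variants are
uniform, deterministic-chain, and deceptive — the latter puts 0.9 prior
mass on a token that leads greedy decoding to the off-front string
`B$`, probing whether exploration (`c = 1`) escapes a local optimum
that pure exploitation (`c = 0`) locks into. These worlds validate the
search mechanics: front recovery, seeded determinism, visit
conservation, reward bounds. They do not emulate chemical space — no
invalid-string structure, no correlation between priors and rewards,
tiny branching factor — so passing them shows the algorithm is
implemented correctly, not that it will find potent ligands; that
depends on the external pretrained policy and docking stack.

## Evaluation

Cross-target uniqueness is the size of the union of per-protein
deduplicated molecule sets divided by the sum of their sizes, ×100.
The inner union of the defining formula is read as multiset
concatenation of the deduplicated per-protein sets — a true set union
would make the metric identically 100. The best molecule of an archive
is the member with the largest reward-vector sum (ties: lexicographic
canonical string). Dominance reports list generated molecules that
strictly dominate a reference ligand's metric vector. Summary tables
report per-objective means with normal-approximation 95% intervals on
the raw metric scale.

## Reference structures

The two case-study drugs ship as canonical free-base SMILES
(`paretogen.reference`): Tropifexor (FXR agonist, PDB 7D42 ligand,
C29H25F4N3O5S) and Copanlisib (PI3K inhibitor, PDB 5G2N ligand,
C23H28N8O4). The descriptor panel reproduces the published Tropifexor
values (LogP 7.3, QED 0.21, SA 4.6, NP −0.91) at printed precision;
Copanlisib lands within one printed digit (QED 0.543 vs 0.55, SA 3.17
vs 3.1), a gap consistent with descriptor-version or
tautomer-as-deposited differences, so tests assert agreement to one
unit in the last printed digit.

## Numerical choices and limitations

- Exploration constant `c` defaults to 1.0 and is recorded in every
  run log; the published hyperparameters live in a supplement we do
  not reproduce.
- Dominance comparisons use exact floating-point inequalities; no
  epsilon. Rewards are exact multiples of `1/N_P`.
- The engine is single-threaded and allocates one node per
  (position, token); no transposition tables, virtual loss, or
  progressive widening.
- Problem sizes in tests: 200-vector front oracles per dimension,
  2,000-iteration toy recoveries over 10 seeds, 4,000-iteration
  deceptive-world comparisons over 20 seeds — chosen so the exact
  oracles stay exact and full runs complete in seconds.
- Large-scale benchmarking (hundreds of protein targets, thousands of
  generated molecules, docking at scale under a pretrained
  protein-conditioned transformer policy) is out of scope: it requires
  external model weights and thousands of docking calls. The package
  verifies the algorithmic core and the descriptor pipeline instead.
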