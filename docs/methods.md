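# Methods

This note documents the modelling conventions and algorithms behind
`hscnet`, in enough detail to reproduce every reported number.

## Model and update scheme

The builtin network (`hscnet.hsc_model()`, stored as
`src/hscnet/data/hsc.bnet`) has **36 nodes** connected by **77 distinct
regulator→target interactions**; counting repeated literal occurrences
of the same regulator inside one rule gives **78**. Both counts are
exposed on the interaction graph (`g.graph["n_edges"]`,
`g.graph["n_literal_occurrences"]`) so neither convention is silently
preferred. The two niche inputs, `External_quiescence` and
`External_cycling`, are modelled as self-regulating nodes (`A, A`), so
their values are constant along any trajectory and partition the state
space into four closed subspaces.

Updating is **synchronous**: every node evaluates its Boolean rule on
the current state and all nodes switch simultaneously. Dynamics are
therefore deterministic; every trajectory ends in a fixed point or a
limit cycle.

## Complete attractor search

`find_attractors_complete` certifies completeness without a SAT solver:

1. **Input decomposition.** Enumerate the 2^(#inputs) input
   assignments; each fixes a closed subspace.
2. **Constant propagation.** Within a subspace, repeatedly substitute
   already-constant nodes into the remaining rules; any rule that
   becomes constant makes its node eventually constant, so it joins the
   assigned set (least fixpoint).
3. **Exhaustive reduction.** The remaining *free* nodes span a reduced
   transition system that is enumerated exactly: the full successor
   array is built by vectorized truth-table lookups, iterated 2^m-fold
   by pointer doubling, and its image is precisely the set of cycle
   states, which are then grouped into cycles and lifted back to full
   36-node states.

If a subspace retains more than `limit` free nodes (default 24) the
search raises `CompletenessError` instead of returning a possibly
truncated answer. On the builtin model every subspace reduces far below
the limit and the search takes milliseconds. Attractor cycles are
stored in canonical rotation (minimal integer encoding first, node 0 as
the least-significant bit), making attractor identity a plain equality.

`find_attractors_sampled` complements this with trajectory sampling
from uniform random states, which also yields basin-fraction estimates.

## Phenotype rules

Attractors are labelled by marker rules (LT-HSC, ST-HSC, Cycling HSC,
Unstimulated). For cyclic attractors a marker counts as active
(inactive) only if it holds that value in **every** cycle state;
`Attractor.value_of` returns `'osc'` otherwise, which satisfies neither
requirement. An attractor matching zero or several rules is reported
as `unclassified` rather than force-labelled.

## Perturbations

- **Knockout / overexpression** clamp a node's rule to constant 0 / 1.
- **Loss of interaction** (edgetic mutation) substitutes one
  regulator's literal with constant 0 in a single target's rule,
  leaving the regulator's other targets intact.

`perturbation_screen` runs the wildtype plus KO and OE of each of the
34 internal nodes (69 conditions) and returns one tidy row per
attractor state.

## Progression and the time-step convention

`progress` starts from a fixed point, switches only input nodes, and
simulates synchronously until the destination attractor is entered.
Two counters are reported: `raw_transitions`, the number of synchronous
updates applied, and `reported_steps = raw_transitions − 1`, which
labels the first post-switch state as "time step zero" as progression
figures conventionally do. Under this convention LT→ST reports 10
steps (11 raw updates) and ST→cycling reports 5 (6 raw).

## Robustness statistics

**Basin robustness.** Sample N uniform random states; for each, toggle
k node assignments drawn **uniformly with replacement** (so two hits on
the same node cancel), compute the attractor of the original and the
flipped copy independently, and report the fraction of identical pairs.
Because the builtin model has exactly one attractor per input
signature, only the hit parity of the two input nodes matters, giving
the exact expectation

    P(same) = 1/4 · [1 + 2(1 − 2/n)^k + (1 − 4/n)^k],

i.e. 0.9444 / 0.8935 / 0.8468 for k = 1/2/3 at n = 36 — the test-suite
oracle. At 3×100,000 states the observed values are ≈ 94.5% / 89.3% /
84.7%.

**Transition robustness.** For 1,000 uniform random states, flip one
uniformly chosen node, take one synchronous step of both copies, and
average the Hamming distance of the successors divided by n. The
builtin model scores ≈ 0.028 (n = 36, so roughly one differing node
per perturbed transition).

**Null ensemble.** 1,000 random Boolean networks matched to the model
in node count and per-node in-degrees, with regulators drawn uniformly
without replacement (self-loops allowed) and unbiased random truth
tables. By default tables are redrawn until **every listed regulator
is essential** (flipping it changes the output for some context), the
standard convention for random-network generation in Boolean network
tooling; `essential_inputs=False` switches to plain uniform tables.
Under the essential convention the ensemble's grand mean is ≈ 0.037;
under plain uniform tables it is ≈ 0.030 (analytically Σk_i/(2n²) =
77/2592). The model falls below the ensemble's 5% quantile, and the
reported p-value is the **left-tail** fraction of ensemble networks
whose mean Hamming distance is ≤ the model's (p < 0.001 at r = 1,000).

## Reproducibility

All stochastic routines take explicit integer seeds and spawn
independent sub-streams via `numpy.random.SeedSequence`; repeated runs
with the same seed are bit-identical. `scripts/acceptance.py --seed S
--out FILE` derives all sub-seeds (each < 2^31) from `S` and writes the
t4–t8 statistics as JSON.

## Limitations

- Synchronous updating only; asynchronous or probabilistic schemes may
  reveal additional attractors or different transient lengths.
- Complete search relies on the reduction steps keeping free-node
  counts manageable; adversarial networks with many feedback-entangled
  nodes and few inputs can exceed the limit (an explicit error, never a
  wrong answer).
- Basin fractions are exact only in expectation via sampling; the
  complete search reports attractor sets without basin sizes.
- The phenotype rules are marker heuristics tuned to the builtin
  model; on other networks they simply report `unclassified` when
  their marker nodes are absent.
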