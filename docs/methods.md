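# Methods

This note documents the models implemented in `prunechain`, the choices
made where the design was genuinely open, and what the synthetic cohort can
and cannot show.

## Task and environments

A game is played on a directed network of six nodes in which every node has
exactly two outgoing edges, each carrying one of four payoffs (−100, −20,
20, 140). An *environment* is a network plus a fixed start node; a
*solution* is a walk of eight moves whose total reward is the sum of edge
payoffs. Generation samples the two out-edge targets of each node uniformly
without replacement from the five other nodes (no self-loops, no parallel
edges) and payoffs uniformly from the four-value set, rejecting networks
that are not strongly connected. Strong connectivity is decided by boolean
squaring of the adjacency matrix, vectorized over proposal batches; about
two thirds of proposals are accepted, so the rejection loop terminates
quickly in practice.

Candidate environments (six starts per network) pass two filters:

1. **Quartile filter.** Environments whose optimal eight-move reward lies
   outside the interquartile range of the candidate pool are dropped,
   compressing the reward scale across environments. Quartiles use linear
   interpolation and the boundaries are inclusive — the estimator is a free
   choice; any conventional one shifts the cut by at most one reward
   quantum.
2. **Structural filter.** The *canonical* optimal path (ties broken toward
   the lexicographically smallest node sequence) must visit at least four
   distinct nodes and contain at least four *non-myopic* steps, i.e. steps
   at which the optimal move's immediate payoff is no larger than the
   alternative's. This removes trivial two-node loops and purely greedy
   optima. Tie-breaking matters only for the filter's edge cases; the
   canonical path is deterministic, so the filter is reproducible.

## The aversive-pruning planner

State–action values follow a finite-horizon Bellman recursion with a
payoff-dependent discount on the continuation:

    Q_d(a, s) = R(a, s) + (1 − γ_{a,s}) · max_{a′} Q_{d−1}(a′, T(a, s)),
    Q_1(a, s) = R(a, s),

with γ_{a,s} = γ_s when R(a, s) = −100 (a "large cost") and γ_g otherwise.
Equivalently, a reward k steps down a path is discounted by the product of
the (1 − γ) factors of the k − 1 moves before it — the reading
(1 − γ)^(k−1) when the rates are constant, which is the only reading
consistent with the recursion. Remaining depth d runs from 8 (first move)
to 1 (last move). Choices are softmax in Q with inverse temperature β,
stabilized by subtracting the per-state maximum before exponentiation.
γ_s > γ_g is aversive pruning (human-like); the algorithmic profile
reverses the inequality.

The exact expected episode reward propagates the state distribution
forward through the depth-indexed policy — no Monte Carlo is involved — and
is validated in the tests against (a) uniform path enumeration at β = 0 and
(b) 100,000-sample simulation at pilot parameters. The *aversive-pruning
sensitivity* of an environment is dE[total reward]/dγ_s at the reference
policy γ_g = γ_s = 0.35, β = 0.03, computed by central finite difference
with step 1e−4 on the exact expected reward (step-halving changes the value
by < 1e−4; the expected reward is smooth in γ_s, so the choice of step is
uncritical). Environments in the lowest decile of sensitivity are labeled
*human-regretful* (pruning hurts), the highest decile *human-rewarding*
(pruning helps); 400 of each are selected at random. Decile membership is
rank-based with a stable tie-break on environment id.

Whether the original classification used the exact or a simulated expected
reward is unknown; the exact computation is deterministic and removes one
source of noise from the decile split.

## Synthetic cohort

The chain engine replaces the human experiment with a generative stand-in.
Its defaults are the study conditions, not tunables:

| parameter | value | origin |
| --- | --- | --- |
| human (γ_g, γ_s, β) | (0.20, 0.45, 0.012) | pilot estimates |
| algorithm (γ_g, γ_s, β) | (0.5, 0.05, 0.0264) | design values; β performance-matched |
| copy-bias slopes (reward, large costs) | (0.394, −0.040) | measured content-bias effects |
| copy-bias intercept | log(0.3/0.7) | baseline copy propensity ≈ 0.3 |
| invalid-attempt rate | 0.09 | observed invalid-solution share |
| participants / max rounds | 177 / 80 | cohort size and round cap |

Synthetic humans either copy the observed solution wholesale — with
probability `logistic(b0 + 0.394·z(reward) − 0.040·n_large_costs)`, where z
standardizes against the running pool of rewards in the current simulation —
or innovate by sampling their pruning policy. The observed content-bias
coefficients describe copied-action *counts*; reusing them as logit slopes
for a whole-solution copy decision is a deliberate scale translation, with
the intercept pinning the baseline rate. Partial copying (mutating an
observed solution) is not modelled: matching beyond chance arises only from
full copies and shared policy structure. This is the simplest mechanism
consistent with the reported effects and the main known gap to real
behaviour.

Invalid attempts are drawn per human attempt at rate 0.09, recorded,
excluded from the chain lineage, and the slot is replayed by a fresh
participant — mirroring the experiment's slot reopening. Participant
assignment is round-robin over the synthetic pool under two constraints (no
one plays an environment twice, nobody exceeds 80 rounds); the original
availability-based live assignment is not reproduced and does not affect
any statistic computed here.

The algorithm plays its own policy sample iff its total reward ≥ the
predecessor's, else it copies the predecessor exactly. A consequence worth
making explicit: the solutions the algorithm *plays* are a reward-selected
mixture, so fitting the pruning model to played generation-2 solutions
does **not** recover (0.5, 0.05) — the estimate is pulled toward the human
profile by the copied solutions and toward low pruning by the win-only
selection. The engine therefore stores the raw policy sample on every
algorithm record (`GameRecord.own_solution`); recovery checks fit those raw
samples, and the played-solution fits are reported descriptively.

With these defaults the simulated cohort reproduces, without further
adjustment: an invalid rate of ~9%; algorithm copy-branch rates of ~21% on
human-regretful vs ~45% on human-rewarding environments; a within-
environment generation-3 reward boost of ~30–40 points on human-regretful
environments that decays to ~0 by generations 5–8.

What passing tests do *not* show: real humans copy partially, learn within
the session, and respond to time pressure; none of that is modelled, so
agreement here validates the pipeline and the direction/rough size of the
design's effects, not a behavioural theory of the cohort.

## Estimation

The log-likelihood of observed solutions sums log π(move | state, remaining
depth) over moves. Maximization uses L-BFGS-B on (γ_g, γ_s, β) ∈ [0,1]³
from a 3×3×3 start grid ({0.1, 0.5, 0.9}² × {0.005, 0.02, 0.05}),
convergence tolerance 1e−6; likelihood evaluation is vectorized over the
unique environments of the game set, so a 4,000-game fit takes seconds.
A fit is flagged non-identifiable when its likelihood does not improve on
the β = 0 (uniform-choice) model, in which case the pruning rates carry no
information. Bootstrap uncertainty resamples whole games with replacement
(the natural exchangeable unit here), refits each resample starting from
the point estimate, and reports percentile intervals; hypothesis "p-values"
are raw bootstrap fractions satisfying the null, unsmoothed. β calibration
root-finds (Brent) the inverse temperature whose mean exact expected reward
over a set of environments hits a target, to 0.5 points, with the
achievable range established on a β grid.

Parameter recovery at the pilot values with 4,000 games lands within
(±0.07, ±0.12, ±0.004) of (γ_g, γ_s, β) in ≥ 90% of replicates (measured in
the test suite at 20 replicates).

## Agent-based model

Solutions are points (s_g, s_s): general quality and specialization.
Realized reward in an environment of type τ ∈ {+1, −1} is s_g + τ·s_s.
Human and algorithmic agents are exact mirrors (bias sign ±1). Agents copy
the observed solution with probability `sigmoid(κ·(q − q0))`, where q is the
realized reward (utilitarian content bias) or the realized reward plus
w·sign·s_s (adapted bias), and otherwise innovate with s_g ~ N(0, 1),
s_s ~ N(b·sign, 1). Chains start from the neutral solution (0, 0).

All four functional forms (Gaussian innovation, linear reward, additive
adapted bonus, logistic copy rule) are this package's concrete
instantiation of a model described only qualitatively; they are the
simplest forms with the required monotonicities and symmetry. The constants
default to b = 1, w = 1, κ = 0.4, q0 = 2.5. The innovation shift and
adaptation weight are unit-scale by construction; κ and q0 were set — once,
by scanning the (κ, q0) plane — to the interior of the region where all
four qualitative chain patterns hold simultaneously at 12,500 chains:
boost-then-decay of the single-algorithm condition, faster decay under
adapted than utilitarian bias, random-mixed chains converging between the
pure compositions (higher under utilitarian bias), and near-ergodic
convergence by generation 8. Steeper/stickier copy rules (e.g. κ = 1,
q0 = 0) preserve the first three patterns but keep a visible
single-algorithm advantage at generation 8, violating the fourth; the
flatter rule trades a smaller generation-3 boost for complete mixing
within the horizon. "100,000 modelled agents" is read as 12,500 chains × 8
generations per condition; both are configurable.

## Numerical and reproducibility notes

* All randomness flows through explicit `numpy.random.Generator` objects;
  identical seeds give identical outputs, byte-for-byte for file artifacts.
  CLI stages derive independent child streams so stages can be rerun alone.
* Q tables are exact dynamic programs on 6×2 arrays; the only tolerances in
  the package are the softmax stabilization (exact), the sensitivity FD
  step (1e−4), the optimizer tolerance (1e−6) and the β-calibration target
  tolerance (0.5 points).
* Degenerate inputs: empty pools, oversized selections, unreachable
  calibration targets, exhausted participant pools and malformed files all
  raise informative errors rather than propagating bad data; empty fit
  cells are flagged, not fatal.
* Problem sizes in the test suite: the shared unit-test pool uses 2,000
  networks; end-to-end checks rebuild the full 60,000-network design. The
  bootstrap-coverage property is exercised at reduced scale (bootstrap
  refits start from the point estimate), which leaves the nominal-coverage
  claim approximate.

## Known limitations

* No partial-copy operator in the chain engine; copying fidelity between
  non-copied solutions is driven entirely by shared policy structure.
* The ABM's functional forms are stand-ins; its quantitative trajectories
  have no empirical target, only the qualitative patterns.
* The regression analyses of the original study design (mixed-effects
  models on rewards, optimality and copied-action counts) are out of scope;
  the games tables exported here are shaped to support fitting them with
  external tools.
* Real-cohort verification (recounting rates from the deposited experiment
  data) requires that external dataset and is not part of the offline test
  suite.
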