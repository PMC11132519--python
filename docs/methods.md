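# Methods

## The task and its state space

A Tower of Hanoi configuration with `n` size-ordered disks on three pegs is
written as an `n`-digit string over {0,1,2}: digit `i` is the peg holding
disk `i`, disks numbered from smallest (leftmost digit) to largest. Stack
order on a peg is forced by size, so all `3^n` strings are legal and moving
one top disk at a time induces a connected graph in which every state has
two or three neighbours. The graph decomposes recursively into three
triangles keyed by the largest disk's peg — `T1` (peg 0, contains the start
`0...0`), `T2` (peg 2, drawn lower-left), `T3` (peg 1, lower-right) — joined
pairwise by single bridge edges whose endpoints are the *critical states*
(for four disks: 1110–1112, 2220–2221, 0002–0001). The convention is pinned
by the bridge transitions 1110→1112 (into T2) and 2220→2221 (into T3).

Sub-triangles are labelled by the second-largest disk's peg with the same
peg→corner convention. A sub-triangle's *corners* are the states with all
smaller disks stacked on one peg; its *top vertex* is the corner nearest the
start side of the figure (the corner whose smaller disks sit on the peg of
the triangle's entry corner — e.g. 1112 for T2's entry sub-triangle). The
eight-state sparse feature set (2200, 1100, 1110, 2220, 0012, 2212, 1121,
0021) consists of sub-triangle corner states: the two non-start corners of
the start sub-triangle, the two T1-side bridge corners, and the non-critical
corners of the entry sub-triangles of T2 and T3.

## Planning and evaluative feedback

Each trial is a deterministic MDP with a single rewarded configuration (the
target). We make the target absorbing with unit per-step reward, so the
optimal value is exactly `V(s) = γ^d(s) / (1−γ)` with `d` the BFS move
distance; value iteration is validated against this closed form to 1e-8.
The discount is `γ = 0.95` everywhere (one configurable constant); all
qualitative quantities below are γ-invariant because `V` is monotone in
distance for any γ in (0,1).

Evaluative feedback for a move is the sign of the optimal-value change:
+1 ("good") iff the value strictly increases, −1 otherwise. Adjacent
equidistant states exist (the graph has odd cycles), so ΔV = 0 is possible;
such moves are classed bad because the binary signal has no neutral
category and a non-improving move wastes budget.

Scoring: each trial allows `m_allowed = ⌈1.5·m_min⌉` moves. The base score
is `10(m_allowed − m_used + 1)`; the numeric-feedback condition adds
`2(m_good − m_bad)`, the optional-feedback condition subtracts one point per
request, the sub-goal conditions add 5 for visiting the gate state (1110 or
2220 by target triangle). An unsolved trial scores 0 — including the bonus
terms, a choice we make because the source formula states the zero rule
only for the base metric. The percentage score
`100 (m_allowed − m_used + 1)/(m_allowed − m_min + 1)` is 100 at a perfect
solve and defined as 0 when unsolved.

## Synthetic participants

No human trajectory corpus ships with the package, so all downstream stages
are exercised on synthetic noisy-optimal cohorts. An agent carries an
implicit linear reward and chooses actions from the soft (max-ent) policy
`P(a|s) = exp(Q−V)` computed from the precision-scaled reward `β_t·θ`,
optionally modified by a feedback mechanism with gain `k` (below). Defaults,
each chosen once:

- **Implicit reward `θ`**: mass 2.0 on the trial's target and 0.5 on the two
  critical states of the target triangle, plus 0.5 on the sub-goal gate in
  the sub-goal conditions. Guidance mass is capped below half the target
  weight because the soft planner has no terminal state: if an adjacent
  non-target pair offers per-step reward matching the target's, a
  high-precision agent oscillates there ("loitering pocket") instead of
  finishing, which inverts the learning curves the generator must emulate.
- **Precision schedule** `β_t = β0 + η(t−1)` with `β0 = 1`; `η = 0.3` in the
  conditions that display per-move feedback (numeric, sub-goal+numeric) and
  `η = 0.05` otherwise. The schedule continues through the transfer task
  (skill carries over), which reproduces the direction of the observed
  transfer gap between feedback and no-feedback cohorts.
- **Condition mapping**: no-feedback and sub-goal agents ignore feedback
  (mechanism 1); numeric-feedback agents integrate it into their action
  values (mechanism 2, `k = 0.5`); optional-feedback agents request feedback
  with probability 0.1 per move and otherwise behave like the no-feedback
  cohort, matching the observed "seldom requested" behaviour.
- Targets are drawn uniformly from T2 ∪ T3 (never the start triangle);
  trials are 10 training (4 disks) then 5 transfer (5 disks, never any
  feedback); per-participant RNG streams derive from
  (master seed, condition, participant), so datasets are bit-reproducible.

What the generator does *not* emulate: fatigue, drop-out, inter-individual
heterogeneity beyond the precision schedule, response times, and the
difficulty spike humans show on transfer (synthetic precision carries over
fully, so synthetic transfer success under feedback is higher than human).
Passing recovery tests therefore demonstrate that the inference machinery
is correct and well-conditioned on data with the assumed structure — not
that human behaviour satisfies those assumptions.

## Maximum-entropy IRL

The reward is linear in state features, `r(s) = θ·f(s)` (collected on
arrival), with either one-hot features over all states or over the eight
vertex states. The soft Bellman operator
`V = log Σ_a exp(r + γ T V)` is a γ-contraction (log-sum-exp is a sup-norm
non-expansion) and is iterated to 1e-8; the step likelihood of observed
demonstrations is `Σ_t Q(s_t,a_t) − V(s_t)`. Gradients are exact: the fixed
point is differentiated implicitly, giving one linear solve per evaluation,
and every gradient in the package is finite-difference audited to 1e-5.
Transitions do not depend on the target, so trajectories with different
targets can share a fit; the target enters only through which rewards the
data support.

The L1 penalty uses the split-sign reformulation (θ = u − w, u,w ≥ 0) so
L-BFGS-B sees a smooth bounded problem and produces exact zeros;
optimization starts from zero and is deterministic. The penalty strength is
chosen by 5-fold cross-validation at the trajectory level (steps within a
trajectory are dependent) over {0, 0.1, …, 2}, maximizing mean validation
log-likelihood; ties break toward the smaller λ. Training-task fits use
trials 6–10 only (behaviour is treated as stationary there); transfer fits
use all five trials.

A numerical point that shapes the recovery studies: at λ = 0 the one-hot
MLE is degenerate — actions never taken at visited states create perfect
separation and the optimum runs to infinity, so unpenalized likelihood
comparisons depend on where the optimizer stops. The recovery studies
therefore fit at the smallest nonzero penalty of the relevant protocol grid
(0.1 for reward learning, 0.2 for model comparison) rather than
cross-validating inside every replicate; the CV path is exercised
separately.

## Feedback-integration models

Four mechanisms for folding the good/bad signal `Ĥ(s,a)` into choice:
(1) ignore it (logits Q; |f| parameters); (2) bias action values post hoc
(logits Q + kĤ, no re-propagation — equivalent to biasing action selection;
|f|+1); (3) shift the reward, r′ = r + kĤ, and re-solve the soft fixed
point (|f|+1); (4) discard the reward (logits kĤ; 1 parameter). The gain k
is never L1-penalized (it is not a reward weight). Model 2 and 3 fits
warm-start from the model-1 optimum, which also guarantees the nested
ordering logL̂₂ ≥ logL̂₁ at equal penalty.

Because the displayed signal is target-relative and targets are randomized,
model comparison first groups 4-disk trajectories by the sub-triangle of
their target, designates the sub-triangle's top vertex as the group target,
truncates each trajectory at its first state inside the sub-triangle, and
drops (but counts) trajectories that never enter. `Ĥ` is recomputed against
the designated target since truncation redefines the task. An *observation*
is one (state, action) step of a truncated trajectory; AIC and BIC are
`(2p − 2 logL̂)/o` and `(p log o − 2 logL̂)/o`. AIC and BIC are ranked
independently; they can disagree, since with all-state features the
single-parameter mechanism enjoys an enormous BIC advantage.

## Recovery studies (the package's empirical checks)

- **Reward recovery**: 10 cohorts of 30 trajectories from a stationary
  β = 5 agent with the sparse default reward, target rotating over the
  vertex states of T2/T3; sparse-feature fits at λ = 0.1. Checked: median
  Spearman rank correlation between fitted and true weights over the eight
  feature states ≥ 0.6, and the maximum fitted reward in the target triangle
  exceeds the opposite triangle's in ≥ 8/10 cohorts.
- **Mechanism recovery**: a replicate is a six-group dataset (30
  trajectories per group) generated under mechanism 2 with k = 1, β = 3 and
  vertex-state reward mass only (gate 1.0, start-sub corners 0.5, entry-sub
  corners 0.75, own target +1.25 — the layout the fitted maps exhibit;
  the target bonus is the smallest round value at which the far
  sub-triangles are reliably reached within budget while behaviour stays
  visibly stochastic). Verdict: the summed observation-normalized AIC
  across groups must pick mechanism 2 in ≥ 70% of 20 replicates, and the
  nested ordering must hold in every fit. Single-group selection is noisier
  (roughly two-thirds for mechanism 2 at ~300 observations): the
  one-parameter mechanism is a strong mimic of near-deterministic
  good-move-taking, which is why the aggregate verdict is the right unit.
- **Cohort contrast**: 100 replicate pairs of 20-participant training
  cohorts (numeric feedback vs none); the feedback cohort's mean training
  success must exceed the no-feedback cohort's. Direction only — magnitudes
  depend on the generator's precision schedule.

Problem sizes above (10 seeds, 20 replicates, 100 replicate pairs, 30
trajectories per cohort) are the package's fixed study sizes; planning and
policy work is cached across replicates so the full battery runs in a few
minutes on one core.

## Known limitations

- The soft planner is infinite-horizon; trajectories are finite and
  truncated, a standard mismatch of step-local max-ent IRL.
- Sub-triangle labels for the 5-disk puzzle extrapolate the recursive
  convention (used only for bookkeeping; model comparison is 4-disk).
- The tie rule (ΔV = 0 → bad) and the zero-score rule for unsolved trials
  with bonuses are package decisions where the source formulas are silent.
- The state-visitation (forward–backward) formulation of max-ent IRL is out
  of scope; the likelihood is local to observed steps by design.
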