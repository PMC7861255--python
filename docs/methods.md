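# Methods

## Model

One immutable message, carrying an affective and a cognitive stimulus in
[0, 1], spreads over an undirected simple graph of `n` agents. Agent `i`
holds latent attitudes `a_aff, a_cog`, a noticing threshold `t_noticing`,
and a posting threshold `t_posting`, all in [0, 1] and fixed before the
cascade starts (attitudes may change afterwards, see *Adaptation*). The
cascade is a synchronous generation process:

* step 0 seeds the most degree-central node as an unconditional sender
  (it bypasses its own thresholds and is counted as received, noticed, and
  forwarded); ties in degree break toward the smallest node id, and
  betweenness centrality is available as an alternative seed rule;
* each step, every pending sender delivers to all neighbours
  simultaneously and retires permanently (no agent ever sends twice);
* an unaware recipient evaluates exactly once: it notices iff
  `m_aff > t_noticing` (strict), and — having noticed — forwards iff
  `sqrt(((m_aff + a_aff)/2) · ((m_cog + a_cog)/2)) > t_posting` (strict);
* the run ends when no pending senders remain, which takes at most `n`
  steps; a configurable safety cap flags (never silently truncates) a run.

Both threshold comparisons are strict. Ties occur with probability zero
under the continuous sampling distributions, so the choice is visible only
in hand-constructed cases; strictness makes an agent with `t_posting = 1`
guaranteed inert.

Because no decision input changes between an agent's first receipt and any
later one, evaluating on first receipt only is provably equivalent to
re-evaluating on every receipt; the engine implements both policies
(`evaluation="first_receipt" | "every_receipt"`) and the test suite asserts
their trajectory equality on randomized instances. The same argument makes
the attitude-adaptation rule behaviourally inert: it rewrites state only of
agents that never evaluate again.

### Adaptation

A forwarding agent updates each attitude to the midpoint of its old value
and the message value — the same averaging operator the evaluation itself
uses. Since this cannot influence spread (see above), the rule is exposed
as a strategy hook (`average`, `overwrite`, `none`) for studying the
post-cascade attitude distribution rather than the dynamics.

## Agent models

*Random* agents: `a_aff, a_cog, t_noticing, t_posting ~ U(0, 1)`
independently, giving expected thresholds 0.5 with SD `1/sqrt(12) ≈ 0.289`.

*Personality* agents: a five-trait vector is drawn from a zero-mean,
unit-variance multivariate normal with the published Big Five correlation
structure (openness–extraversion 0.41, openness–conscientiousness 0.24,
extraversion–conscientiousness 0.15, …), via Cholesky factorisation, and
squashed coordinate-wise by `(tanh(x)+1)/2` onto (0, 1). Then

    t_noticing = (u + (1 − openness)) / 2,      u  ~ U(0, 1)
    t_posting  = (u′ + conscientiousness) / 2,  u′ ~ U(0, 1)

with independent `u, u′` (the independent-draw reading; a shared draw would
induce a correlation between the two thresholds that nothing in the model
motivates). "Inverse of openness" is implemented as `1 − openness`, which
keeps the threshold in [0, 1] and realises the intended direction — more
open agents notice more easily. `1/openness` would leave the unit interval
almost surely. Agreeableness and neuroticism are sampled, so the full
correlation structure shapes the three used traits, but drive no behaviour.
Pre-squash marginals are standard normal: only the correlation matrix is
prescribed, and unit variance spreads the squashed traits over most of
(0, 1). Attitudes default to `U(0, 1)` for both agent models; a
`squashed_normal` variant (`(tanh(Z)+1)/2`, `Z ~ N(0,1)`) is available
behind the `attitude_dist` config flag.

Extraversion enters through placement: under `extraversion_rank`, agents
sorted by extraversion are matched to nodes sorted by degree (ties by id),
putting sociable — and, through the 0.41 correlation, open — agents on
hubs. `identity` placement (agent `i` on node `i`) is the default for
random agents, whose traits carry no information.

## Network environments

All generators produce simple graphs with node ids `0..n−1`, deterministic
given the seeded generator, at a shared edge budget of about `2n`:

| type | construction | edges |
|---|---|---|
| random | exact-m `G(n, m)`, m = 2n | 2n |
| barabasi_albert | preferential attachment from one root, 1 edge/new node | n − 1 |
| watts_strogatz | ring lattice k = 4, rewiring probability β = 0.1 | 2n |
| scale_free | static model, weight `i^(−1/(α−1))`, α = 2.0 | 2n |
| sbm | 20 random-size blocks, sparse affinity matrix | stochastic |
| facebook | SNAP edge list, induced subsample to n nodes | data-driven |

β and α are not pinned by the study this package operationalises; β = 0.1
is the classic small-world regime and α = 2.0 a conventional heavy-tail
exponent. Both are exposed in `NetworkSpec`. The exact-m Erdős–Rényi
dialect was chosen for testability (edge count is a hard contract rather
than a distributional one).

The static scale-free generator samples endpoint pairs with probability
proportional to the weight product, rejecting self-loops and duplicates,
until exactly m distinct edges exist. At α = 2.0 the top-weight node
typically ends with several hundred neighbours at n = 1,000 — a far heavier
hub than Barabási–Albert's — which matters for seeding (below).

The stochastic block model splits `n` across 20 blocks proportionally to
uniform draws (largest-remainder rounding; empty blocks are topped up from
the largest). Its affinity matrix `W` has diagonal entries
`U(0.01, 0.05) · block_size` and off-diagonal entries `U(0.0001, 0.01)`
with exactly `⌊0.6 · pairs⌋` symmetric pairs zeroed, so most block pairs
are disconnected and the realised graph usually has several components.
`W[a, b]` is read as an expected neighbour count: the expected a–b edge
count `W[a,b] · (size_a + size_b)/2` is spread uniformly over the
`size_a · size_b` pairs (clamped to probability 1). A per-pair-probability
reading is untenable because diagonal entries exceed 1. Community count is
reported as the number of connected components (a modularity-based count
exists as `count_communities_modularity`, not the default).

## Replication harness

Replicate `r` of a configuration uses the random stream
`SeedSequence(base_seed, spawn_key=(r,))` — a fixed function of
`(base_seed, r)` that ignores the configuration, so matched replicates of
different cells share their initial randomness, and any sweep is exactly
reproducible from `base_seed`. Every replicate generates a fresh network
and a fresh population. Records are written as versioned CSV; the
schema-checked round trip is lossless (`%.17g` floats, `round_trip`
parsing).

The final sent counts are analysed with a general linear model —
Gaussian identity, i.e. OLS, which also handles the degenerate
constant-response case — on the dummy-coded factors agent model, network
type, and content type, with the random agent and the random graph as
reference levels (content reference: weak). A Poisson family is available
for count-data robustness checks.

## Problem sizes and tolerances

Defaults throughout follow the study conditions: n = 1,000 agents,
1,000 replications per cell for production sweeps. The bundled test suite
and the acceptance script use 200 replications per cell (standard errors of
the mean spread fraction are then ≈ 0.003–0.03, small against the 5-point
tolerances they are compared at) and 100,000 samples for trait-correlation
recovery (SE ≈ 0.003 against a ±0.01 band). The brute-force cascade oracle
cross-checks the engine on 1,000 randomized graphs of up to 6 nodes; it
computes final states by a closed-form reachability argument (forwarders =
the would-forward nodes connected to the seed through would-forward nodes)
rather than by stepping, so the two routes are independent.

## What the generated data does and does not show

The synthetic populations and graphs emulate the *mechanisms* posited by
the model — correlated traits, threshold heterogeneity, topology — not any
empirical message log. Passing tests therefore demonstrate internal
consistency of the simulator (state-machine soundness, determinism,
analytic edge-count and correlation contracts, qualitative orderings such
as both ≥ affective ≥ weak/cognitive content and the personality
amplification on generated graphs), not that real users behave this way.
Real cascade data would additionally exhibit re-exposure effects, competing
messages, and time-varying attention, all deliberately outside this model.

## Known limitations

* The per-exposure forwarding probability is bounded by the mean
  dual-process score (≈ 0.64 for the strongest content under uniform
  attitudes), which caps attainable spread well below saturation; headline
  spread levels reported for this class of model in the literature vary
  strongly with unstated generator parameters and denominator conventions
  (all-agents vs among-receivers). This package reports both denominators
  for every run.
* With α = 2.0 the scale-free hub seed reaches ~2–3% of agents even for
  content whose spread is otherwise subcritical, so "near-zero" spread
  claims are topology-sensitive.
* One message at a time; no re-sending, no unfollowing or rewiring during
  a cascade, no malicious agents or bots; trait→behaviour links limited to
  openness, conscientiousness, extraversion.
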