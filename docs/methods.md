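# Methods

## Motion model

Each of N agents carries a position in a 0.2 m-radius circular arena, a
heading, and a binary motion state, advanced synchronously once per 0.5 s
frame. At the start of a frame every agent's nearest-neighbour distance
*d* is computed from the frame-start configuration (agents without a
present neighbour use *d* = ∞). The agent then flips its state with
probability P_MS(d) (moving → stopped) or P_SM(d) (stopped → moving); an
agent that ends the flip moving advances by ℓ(d) along its current
heading and then turns by an angle drawn from the zero-centred wrapped
Cauchy density with spread ρ(d). The control model evaluates all four
responses at their d → ∞ limits, making its state dynamics independent of
geometry. All parameter defaults are the published fits (see README);
they are dataclass fields and fully overridable.

Choices the model description leaves open, with the defaults taken here:

- **Initial states**: all stationary at frame 0 (option
  `initial_states="equilibrium"` samples each agent's state from the
  two-state chain's stationary distribution at its initial *d*).
  Transients decay within tens of frames either way.
- **Initial headings**: uniform on (−π, π] — the walk is unbiased.
- **Update order**: state transition, then step, then turn. Both
  alternatives (`transition_before_move=False`, `turn_before_step=True`)
  are keyword-selectable.
- **Boundary**: "reflected back into the arena" is implemented as a
  radial mirror (r → 2R − r along the centre ray), with a specular
  (tangent-line) option. The fitted maximum step (0.0013 m) is 150× smaller
  than the arena radius, so the rules differ negligibly (tested).
- **Randomness**: one `numpy.random.Generator` per run; per frame, one
  transition uniform per agent (agent-index order), then one angle uniform
  per agent. Turning-angle sampling is inverse-CDF:
  θ = 2 atan(((1−ρ)/(1+ρ)) tan(π(U−½))).

## Order parameters

Velocities are one-frame backward differences x(t) − x(t−1), so all five
series run over frames 1…T−1. Stationary agents have v = 0 and therefore
drop out of the P/M_ang/M_abs sums on their own; r_i in the momentum
measures is taken relative to the centre of mass of contributing agents.
When every present agent is stationary the three ratio measures are
defined as 0 (the output would otherwise be 0/0); frames where a measure
is undefined (e.g. < 2 present agents for d_a) carry NaN and are never
silently dropped. Simulated trajectories use the model's exact states;
experimental-style data (states "unknown") use the 10⁻⁴ m displacement
threshold, ties counting as stationary.

## Topology

A k-simplex exists at scale ε when its k+1 vertices are pairwise within ε
(closed condition). Crockers are b_k on a grid of 50 uniform scales that
*includes 0* (so the first row counts distinct present points) up to
0.2 m for 2-D position clouds and 1.5 for 4-D position⊕velocity clouds
normalised by 0.2 m and 0.0013 m/frame respectively; time is downsampled
by 4. The posvel velocity is the same one-frame backward difference used
by the order parameters. Columns are computed independently per sampled
frame on the cloud of *present* agents (cloud sizes vary under dropouts);
homology is over GF(2), dimensions 0 and 1 only.

Persistence intervals use the half-open convention [birth, death): a
class counts at ε iff birth ≤ ε < death. H₀ deaths are single-linkage
merge heights (`scipy.cluster.hierarchy.linkage`, method `single` —
chosen over a sparse-graph MST because zero-length edges between
coincident points must participate). H₁ uses standard boundary-matrix
reduction: negative edges are found by union-find, triangle columns are
reduced over GF(2) with Python-int bitsets, and the filtration is
truncated at the grid maximum (unresolved deaths become +∞, which is
exact for any Betti evaluation within the grid). The independent
`betti_oracle` computes b_k = n_k − rank ∂_k − rank ∂_{k+1} by direct
GF(2) elimination at a single scale and is capped at 25 points; the two
routes are cross-checked on hundreds of random clouds in the tests.

The "upward contour trend" of a dispersing group is quantified by the
**connectivity scale**: per time column, the smallest grid ε at which b₀
≤ 1. For averaged (real-valued) crockers this is the scale at which every
contributing run has merged to one component.

## Comparison statistics

Distances: Euclidean norm between series on their common frames (frames
with a missing value in either series are excluded pairwise); Frobenius
norm between crockers on identical grids (crockers never have missing
entries). D = D_con − D_int over the two ensembles' per-run distances;
the confidence radius is a Welch unpooled two-sample t interval
(Satterthwaite df) at level α/n_comparisons, defaults α = 0.05 and
n_comparisons = 81 (nine measures × nine experiments in the full design;
configurable since synthetic studies may differ). The per-run distances
of the two ensembles share the reference trajectory and are therefore
weakly dependent; the interval follows the independent-ensembles
formulation and ignores this, which is the conservative direction for
the difference of means. Verdicts: interactive iff D − R95 > 0, control
iff D + R95 < 0, else inconclusive.

## Synthetic data

The generator emulates the *structure* of the original experiments, not
their statistics. Initial patterns: `clustered` (uniform in a sub-disk of
0.25× the arena radius, centre placed so the sub-disk fits), `dispersed`
(uniform over the disk), `ring`; the nine original group sizes
{19, 28, 27, 33, 27, 30, 26, 7, 9} are exported as presets. Tracking
dropouts are memoryless: from frame 1 on, each present agent starts an
absence run with a per-frame Bernoulli rate, run lengths geometric with
the given mean (the real tracking gaps' distribution is unreported; no
attempt is made to match it). The mask is drawn from a stream derived
from, but separate from, the walk's seed, so masking never perturbs the
walk. Positions are retained internally; all consumers honour the mask.

What passing self-consistency tests show — and don't: the pipeline
recovers a known generating model under the model's own dynamics. Real
trajectories include behaviours neither model produces (wall-following,
long stationary bouts, tracking noise), so these tests validate the
machinery, not the biological fidelity of either model.

## Problem sizes and numerics

Studies in the test suite use 25 agents, 500 frames and ensembles of 20
runs with 10 seed-replicates — large enough that the d_a, Mov% and
b₀(pos) comparisons separate the models decisively, and sized as a
desk-scale analogue of the original 100-run, ~5000-frame design. Sampler
and transition calibrations use 10⁶ draws / 10⁵ frames and three
Monte-Carlo standard errors. The contour plot suppresses levels above 11
(higher contours read as topological noise); the contour labelled n
separates b < n from b ≥ n.

## Known limitations

- No parameter fitting: model constants are inputs, taken from the
  published fits.
- Zigzag/multiparameter persistence, Wasserstein or bottleneck distances
  on crockers, and ML on vectorised crockers are out of scope.
- The H₁ reduction is designed for the study's cloud sizes (≲ 40 points);
  it is exact but not engineered for large point clouds.
- The CI procedure treats per-run distances as independent normal-enough
  samples; permutation or bootstrap alternatives are not provided.
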