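# swarmtda

Topological model selection for collective insect motion.

Groups of pea aphids (*Acyrthosiphon pisum*) walk intermittently in a
circular arena, and two stochastic models have been proposed for their
movement: an **interactive model**, in which each animal's probability of
stopping/starting, step length and turning-angle spread all depend on the
distance *d* to its nearest neighbour, and a **control model**, identical
except that every response is frozen at its *d* → ∞ (no-interaction) limit.
`swarmtda` simulates both models, summarises trajectories with
collective-motion order parameters and with topological **crocker**
signatures, and decides statistically which model better matches a
reference trajectory.

## The models

Each agent is *moving* or *stationary* in every 0.5 s frame. With *d* the
nearest-neighbour distance, the fitted responses are

- P_MS(d) = P_MS^∞ + (P_MS^0 − P_MS^∞) e^(−d/d_MS)  (moving → stopped),
  with P_MS^∞ ≈ 0.1280, P_MS^0 ≈ 0.5508, d_MS ≈ 0.0134 m
- P_SM(d) = P_SM^0 e^(−d/d_SM) + P_SM^∞ d/(d + Δ_SM)  (stopped → moving),
  with P_SM^0 ≈ 0.1587, P_SM^∞ ≈ 0.3552, d_SM ≈ 0.0079 m, Δ_SM ≈ 0.0739 m
- ℓ(d) = ℓ^∞ + (ℓ^0 − ℓ^∞) e^(−d/d_ℓ)  (step length, m),
  with ℓ^∞ ≈ 0.0013, ℓ^0 ≈ 0.0003, d_ℓ ≈ 0.0074 m
- ρ(d) = ρ^∞ + (ρ^0 − ρ^∞) e^(−d/d_ρ)  (wrapped-Cauchy turning spread),
  with ρ^∞ ≈ 0.9013, ρ^0 ≈ 0.1387, d_ρ ≈ 0.0044 m

Moving agents perform an unbiased correlated random walk (step, then a
turning angle from the zero-centred wrapped Cauchy density) inside a
0.2 m-radius arena with a reflecting wall.

## The measures

**Order parameters** per frame: polarisation *P*, angular momentum
*M_ang*, absolute angular momentum *M_abs* (all ∈ [0, 1]), mean
nearest-neighbour distance *d_a* (m), and percent moving *Mov%*.

**Crockers**: matrices b_k(t, ε) of Betti numbers of the Vietoris–Rips
complex on the group's point cloud — b₀ counts connected components, b₁
loops — over 50 proximity scales (up to 0.2 m for position clouds, 1.5 for
normalised position⊕velocity clouds) and time downsampled by 4. Both a
persistence computation (single-linkage H₀; GF(2) boundary-matrix
reduction H₁) and an independent brute-force boundary-rank oracle are
included.

**Decision rule**: for each measure, per-run distances to the reference
(Euclidean norm for series, Frobenius norm for crockers) give ensemble
means D_int and D_con over 100-run ensembles; D = D_con − D_int with a
Bonferroni-corrected (n = 81 by default) Welch 95% radius R95. The
interval excluding zero declares one model significantly more faithful.

The original tracking data is not deposited, so the `synthetic` module
generates pseudo-experiments — interactive-model runs, optionally with
tracking dropouts — giving every study a known ground truth.

## Worked example

```sh
python examples/04_model_selection.py
```

runs a self-consistency study (25 agents, clustered start, 500 frames,
20 runs per model; reference = one interactive-model run) and prints:

```
  measure   D_int  D_con        D    R95  alpha_corrected      verdict
        P   6.933  6.673  -0.2599 0.2947        0.0006173 inconclusive
    M_ang   6.896  6.885 -0.01114 0.2504        0.0006173 inconclusive
    M_abs   4.981  3.917   -1.063 0.2065        0.0006173      control
      d_a 0.05246 0.2235    0.171 0.0449        0.0006173  interactive
     Mov%   257.6   1149    891.9  19.65        0.0006173  interactive
   b0_pos   77.45  228.3    150.8     30        0.0006173  interactive
   b1_pos   19.22  26.94    7.722  3.085        0.0006173  interactive
b0_posvel   139.5  519.6      380  19.83        0.0006173  interactive
b1_posvel   18.01  55.77    37.77  4.587        0.0006173  interactive
```

The *a-priori* order parameters (*d_a*, *Mov%*) and all four crocker
measures recover the generating model (D − R95 > 0 ⇒ interactive), while
the model-agnostic order parameters do not — *M_abs* even prefers the
control model, an artefact of the reflecting boundary. Topology matches
the informed measures without using any knowledge of the models.

Other examples: `01_simulate_models.py` (the two models' motion
statistics), `02_order_parameters.py` (the five series),
`03_crocker_signatures.py` (averaged crockers and the upward contour
trend of a dispersing group). A thin CLI mirrors the library:
`swarmtda synth|simulate|orderparams|crocker|compare|pipeline --help`.

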