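# Methods

## Model

An axon is modelled as a simply connected space curve observed through an
imaging process that renders it as a thin (~1 μm diameter) bright tube on a
darker background, with voxel intensities conditionally independent given
the curve — the only spatial correlation is the ~1 μm point-spread blur.
Reconstruction between two fixed endpoints is posed as inference over
sequences of **fragments**: supervoxels no larger than a ball of radius 7 μm
carved from the thresholded foreground of an upstream classifier's
probability map. Each fragment is summarised by its two endpoints and unit
tangents; each fragment yields two oriented **states**, and a directed
trellis over the states carries the probability model:

* **Transition prior** — Boltzmann, p(s′|s) ∝ exp(−U) with
  U = α_d·gap² + α_κ·κ², gap in μm, κ² the arithmetic mean of the two
  discrete squared curvatures at the gap (1 − τ¹·τ_c and 1 − τ_c·(−τ⁰),
  τ_c the unit connector). Transitions are forbidden beyond a 15 μm gap or
  a 150° turning angle, and onto the same fragment (either orientation).
* **Appearance likelihood** — foreground/background intensity densities
  α₁, α₀ fitted as 1-D Gaussian KDEs with Scott's-rule bandwidth to labelled
  voxels. An edge's data term sums −log α₁ over the successor fragment's
  simplified line voxels *and* over the Bresenham-imputed voxels bridging
  the gap, so the path probability sees the image evidence inside dropout
  regions.
* **MAP path** — the full posterior involves likelihood ratios α₁/α₀ that
  can exceed 1 and hence negative cycles after the −log transform; dropping
  the background factor yields the path-probability formulation whose
  globally optimal nonrepeating state sequence is exactly the minimum-weight
  path in the trellis. With α₁ clipped at 1, every edge weight
  −Σ log α₁ − log p is nonnegative and Dijkstra is exact. The solver is
  verified against exhaustive simple-path enumeration in the test suite.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| probability threshold | 0.9 | — | conservative foreground binarisation; false positives hurt more than severed tubes |
| ball radius | 7 | μm | fragment size bound (diameter ≤ 14 μm) |
| min fragment voxels | 5 | voxels | smaller pieces cannot support tangent PCA |
| tangent window | 3 | μm | local-PCA neighbourhood at each endpoint |
| α_d | 10 | 1/μm² | gap-distance energy weight |
| α_κ | 1000 | — | curvature energy weight |
| d_max | 15 | μm | transition gap cutoff |
| θ_max | 150 | degrees | transition angle cutoff |
| capture radius | 10 | μm | click-to-fragment resolution |

The energies depend on the absolute values of α_d and α_κ (not just their
ratio) because the Boltzmann normaliser Z(s) varies per state; the defaults
are working values for sparse sub-micron data and should rise (α_κ
especially) in dense neuropil.

## Design choices in open territory

* **Endpoints and tangents.** The endpoint/tangent estimator is deliberately
  simple and verifiable: endpoints are the pair of voxels at maximal
  geodesic distance in the fragment's 26-connectivity graph (edge lengths in
  physical μm; ties broken by Euclidean distance, then lexicographically),
  and each tangent is the first principal axis of the voxel coordinates
  within 3 μm of the endpoint, signed to point away from the fragment
  centroid. Exact all-pairs geodesics are affordable because fragments are
  diameter-bounded.
* **Orientation handling.** Tangents are stored *outward* at both endpoints.
  This is the only convention under which the curvature formulas vanish for
  a straight continuation, and it forces the reversal rule "swap endpoints,
  swap tangents" (no negation): negating on reversal would make every
  reverse-direction transition score as a U-turn (κ² = 2) and break
  orientation covariance. The implementation's mirrored edges have identical
  energies by construction, which the tests assert.
* **Angle pruning.** "Angle between states" is interpreted as *either* of
  the two gap angles (the same two that define κ₁, κ₂) exceeding the cutoff.
* **α₁ clipping.** A density can exceed 1; evaluations are clipped at 1
  (fraction recorded on the model) so −log α₁ ≥ 0, preserving the Dijkstra
  precondition. The solver independently verifies nonnegativity and raises
  on any negative weight reaching it.
* **Ties.** Shortest-path ties resolve by fewer states, then the
  lexicographically smallest id sequence; all outputs are deterministic.

## Numerical choices

* Gap curvature below ε = half the minimum voxel spacing uses the exit
  tangent as the connector direction (the connector is geometrically
  undefined below grid resolution).
* Transition log-priors are computed with log-sum-exp (finite even for
  energy differences of thousands); displayed priors use a max-shifted
  softmax so equal energies give exactly equal probabilities.
* KL(α₁‖α₀) is trapezoid quadrature on a 2048-point grid spanning both
  sample ranges ± 4 bandwidths; integrand terms where the foreground density
  underflows contribute 0.
* Candidate successors are found with a KD-tree over state entry points with
  radius d_max — exact, since any allowed transition has gap ≤ d_max.
* Bresenham rasterisation samples once per voxel along the axis of largest
  range and rounds the other coordinates half-up (deterministic across
  platforms).

### Known bias of the plug-in KL estimate

The KDE plug-in KL systematically *overestimates* the population divergence
when the foreground's support extends beyond the background's largest
samples: a Gaussian KDE tail collapses at the bandwidth scale, so log(α₁/α₀)
blows up exactly where α₁ still has mass. For N(3,1) vs N(0,1) at n = 10⁴
(population KL = Δμ²/2 = 4.5 nats, half the squared SNR) the plug-in value
is ≈ 5.7, confirmed against adaptive quadrature and Monte-Carlo integration
of the exact fitted mixtures. The quadrature itself is accurate to < 0.1%;
the gap is estimator bias, not integration error. The statistic is used as a
relative image-quality score, where this bias is harmless; no tail
truncation or flooring is applied.

## Synthetic phantoms

The generator emulates the features the model assumes: a gently curving
axon (seeded tangent walk with discrete curvature bounded by a configurable
scale, default 0.05 rad/μm), rasterised as a tube of radius 0.5 μm
(~1 μm diameter) on an anisotropic 0.3 × 0.3 × 1 μm grid; iid foreground and
background intensities (defaults N(200, 30) vs N(100, 15)) blurred by a
0.5 μm Gaussian PSF (so spatial correlation is short-range only); an
idealised probability map equal to the Bayes posterior of the pre-blur
sample under the generating densities, with an optional label-flip noise
knob; arc-length dropout windows that sever the tube; and an optional
parallel confuser curve. The default class separation is the high-contrast
sparse-labeling regime in which a 0.9 threshold is genuinely conservative
(a marginal-intensity classifier at smaller separations produces a
false-positive voxel rate no practitioner would call conservative, and
spur-contaminated fragments whose endpoints leave the tube).

What phantoms do *not* emulate: Poisson/photon statistics, depth-dependent
attenuation and scattering, somata and branching, varying tube calibre, and
spatially structured classifier errors. Passing the phantom studies
therefore demonstrates correctness of the inference machinery under the
model's own assumptions, not performance on real brain volumes.

The end-to-end study (and `scripts/acceptance.py`) uses a 400 × 96 × 64
voxel volume (120 × 28.8 × 63 μm) with a single 100 μm tube and three 5 μm
dropout windows — large enough that fragment statistics are nontrivial,
small enough that the full suite runs in seconds.

## Limitations

* Single fixed-endpoint paths only: no branching, tree assembly or soma
  handling.
* The appearance model is marginal (per-voxel intensity); it inherits the
  upstream classifier's blind spots.
* Fragment quality limits everything downstream: fused processes (two axons
  in one fragment) violate the one-axon-per-fragment assumption.
* Dropout longer than d_max is correctly reported as unbridgeable rather
  than guessed across.
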