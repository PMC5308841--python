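# Methods

## Model

A directed connectome over *p* regions with ordinal weights
a_ij ∈ {0, …, K−1} (0 = absent) is modelled through a latent embedding
z_i ∈ R^D. Writing l_ij = ‖z_i − z_j‖₂ for the latent distance, the
cumulative-probit link

    h(i, j, k) = (b_k − l_ij + δ_i + ε_j) / σ
    P(interval k) = Φ(h(i, j, k)) − Φ(h(i, j, k−1)),   k = 1 … K,

with b_0 = −∞, b_K = +∞ and strictly increasing interior cutpoints,
partitions the distance axis into K intervals. Because larger distance
means weaker connection, interval k corresponds to user weight K − k;
the package always reports probabilities in weight coding (index 0 =
absent). This mapping is covered by a monotonicity property test: the
expected weight Σ_k k·f_ijk is strictly decreasing in l_ij and strictly
increasing in δ_i and ε_j.

The sender effect δ_i and receiver effect ε_j let hub regions deviate
from pure distance dependence. A node with no observed outgoing
(incoming) connection has its δ (ε) clamped to exactly zero and excluded
from sampling — with an injection design in which only a subset of
regions is ever a target, most ε entries are structurally zero.

Model variants share this likelihood and differ only in the distance
term: the **zero-dimensional** baseline sets l_ij ≡ 0 (random effects
only); the **fixed-position** model freezes Z at anatomical centroids;
the **latent eigenmodel** replaces the metric by the bilinear form
l_ij = −z_iᵀ Λ z_j with diagonal Λ (a generalized distance — possibly
negative, smaller = stronger). The **empirical-frequency** baseline has
no latent structure at all: one shared probability vector equal to the
training class frequencies.

**Fusion.** When anterograde and retrograde matrices are both available
they are modelled as two independent categorical draws from the *same*
f_ij; no modality-specific parameters exist. Residual directional
asymmetry is absorbed by δ and ε. Consequently, fusing a modality with
itself exactly doubles the log-likelihood (tested).

## Priors and identifiability

The likelihood is invariant under (a) rigid motions of Z and (b) joint
rescaling (Z, b, δ, ε, σ) → c·(Z, b, δ, ε, σ). Both invariances are
asserted by property tests. The priors pin these down as follows — they
are this package's own weakly-informative reconstruction, chosen for
scale-fixing rather than copied from any reference:

| parameter | prior | default scale | role |
|---|---|---|---|
| z_i | Normal(0, s_z² I_D) | s_z = 1 | fixes location/overall scale of Z |
| b_1 | Normal(0, 5²) | — | cutpoint location |
| b_k − b_{k−1} | half-Normal(0, 5) | — | ordering by construction |
| δ, ε | Normal(0, τ²), τ ~ half-Normal(0, 1) | shared τ per vector | adaptive shrinkage of hub effects |
| σ | fixed at 1 (default) or half-Normal(0, 1) | `fix_sigma` | breaks the rescaling invariance |
| Λ diag | Normal(0, 1) | eigenmodel only | spectrum weights |

σ is fixed by default because sampling it only re-parameterizes the
rescaling orbit; the option to sample it exists (`fix_sigma=False`).
Rigid-motion invariance is *not* broken: all reported quantities
(distances, probabilities, imputed weights) are invariant, so no
constraint is needed for inference — alignment is applied only for
visualization.

## Inference

Posterior sampling is Hamiltonian Monte Carlo with analytic gradients,
written directly in NumPy, on an unconstrained parameterization:
cutpoints as (b_1, log-increments), τ and σ via log transforms (with the
exp Jacobians in the target), and non-centered random effects
(δ = τ·raw) to avoid the hierarchical funnel. Defaults: 4 chains,
1000 warmup + 1000 kept iterations per chain.

* Step size: dual averaging (target acceptance 0.8) during warmup,
  re-initialized after a diagonal mass matrix is estimated from the
  second warmup quarter (regularized toward 10⁻³, Stan-style shrinkage).
* Path length: the number of leapfrog steps per iteration is drawn
  uniformly from {1, …, 32}, which avoids resonant periodic
  trajectories without implementing a full trajectory-termination
  criterion.
* Numerical guards: probit interval probabilities are computed in
  log-space through `log_ndtr` on whichever tail is accurate, with the
  straddling-zero case done directly (well conditioned there);
  gradient ratios φ/P are exponentiated from log-space with a cap;
  states whose transformed parameters exceed 10⁸ in magnitude are
  rejected outright, since the prior density there underflows double
  precision. Energy errors beyond 10³ count as divergences (reported
  per chain).
* Initialization is drawn from the priors, re-drawn up to 20 times if
  the gradient is non-finite.
* Reproducibility: all randomness descends from `RunConfig.seed`
  through `numpy.random.SeedSequence` spawning (one stream per chain,
  one for imputation); a fixed seed reproduces draws bit-exactly on the
  same platform.

Unobserved weights are *not* sampled as discrete parameters. For a
categorical outcome the marginalization is exact, so each draw's
imputed weight is generated post hoc from Categorical(f_ij at that
draw). Observed cells keep their observed weight in every draw.

Convergence diagnostics (split-R̂, bulk ESS via ArviZ) are computed on
identifiable quantities — pairwise distances (a deterministic subset of
at most 100 pairs), cutpoints, active effects — never on raw Z
coordinates, which mix freely under rigid motions. Constant quantities
are skipped. With two chains, rank-normalized split-R̂ saturates near
1.84 even for fully separated chains; values above ~1.05 on distances
warrant longer runs.

## Prediction and uncertainty

The completed connectome Â averages per-draw weights (observed cells
fixed, unobserved cells imputed), so â_ij ∈ [0, K−1] is real-valued; the
modal class under the posterior-mean f is reported alongside. Edge
uncertainty is the width of the central 95 % credible interval of
f_ijk across draws (linear-interpolation empirical quantiles at 2.5 %
and 97.5 %), maximized over the K classes; a warning is raised below 40
draws, where the interval endpoints are unstable. Relative degree uses
presence = weight > 0; for observed-only data the denominator counts the
node's *observed* candidate cells (NaN when there are none), for
completed connectomes it is p − 1, with per-draw binarization averaged
and a 0.5 presence cutoff for hard calls.

## Evaluation

Cross-validation partitions the observed off-diagonal cells into folds
of near-equal size, uniformly at random under a recorded seed (no
stratification). Masking the held-out edges is the *only* train/test
difference. Per fold:

* **MAE** — mean |a_ij^(t) − a_ij| per draw, then averaged over draws;
  the per-sample form is deliberately conservative (averaging the
  prediction first would shrink it).
* **FPR / FNR** — per-draw false-presence rate among truly absent edges
  and false-absence rate among truly present edges, averaged over
  draws; a fold with no absent (or no present) edges yields NaN with a
  warning.
* **NLL** — −(1/|F|) Σ log f̄ at the observed class, with f̄ the
  posterior-*mean* probability (Rao-Blackwellized; lower-variance than
  per-draw log-scores) and a 10⁻¹² floor so degenerate baselines score
  finitely.

D̂ is the argmin of mean held-out NLL across folds; NLL is used because
it is the only measure that sees the probabilities rather than the
sampled classes. Dimension-free models are evaluated once and
replicated across the D grid for comparison tables. A helper labels
held-out edges by whether the opposite direction was observed, for
reciprocity breakdowns.

The analytic design accounting (possible = p(p−1), observed =
|S×T| − |S∩T|) accepts label sets or plain counts; with counts the
target set is assumed nested in the source set, as in the injection
designs it describes.

## Embedding

Posterior-expected distances L̂ (draw-mean of the distance matrix; the
eigenmodel is rejected here since its bilinear form is not a metric) are
projected by classical (Torgerson) MDS: eigendecomposition of the
double-centered squared-distance Gram matrix, top eigenpairs clipped at
zero, each axis oriented so its largest-magnitude loading is positive
(deterministic output). Alignment to an anatomical reference is *rigid*
Procrustes — rotation/reflection plus translation, no scaling — so
reported distances change by < 10⁻¹²; it is applied only when a
reference exists. The anatomical-vs-latent distance correlation is
computed per draw (Pearson, upper triangle) and summarized as mean ±
SD across draws; the correlation of L̂ itself is also emitted as a
secondary value, since the two differ slightly and either reading is
defensible.

Anatomical centroids are centered and globally rescaled to unit RMS
pairwise distance before use (as frozen positions or reference), making
the cutpoint priors meaningful regardless of physical units; σ and b
absorb residual scale.

## Synthetic data

The generator draws from the exact generative model and is the fixture
factory for every test. Two modes:

* **calibrated** (default) — the study conditions for all statistical
  tests. Latent positions come from their Normal(0, 1) prior; cutpoints
  are placed across the bulk of the latent-distance distribution
  (RMS distance between two standard-normal points is √(2D)):
  b = √(2D)·(0.4 … 1.1) spread evenly for K > 2, b = 0.75·√(2D) for
  binary data, so every ordinal class is realistically populated;
  σ = 0.5, giving class boundaries that are distinct but noisy; hub
  effects are Normal(0, 0.15²), small relative to the distance range as
  observed in fitted tracer connectomes.
* **prior** — a full draw from the model's priors, for
  prior-predictive and moment checks.

Observation designs reproduce the three tracer studies: full
observation, injection (sources × injected targets; 91×29 yields
exactly 2610 observed / 5580 unobserved cells), and a random observed
fraction (the visual-system study probed 653 of 992). Presets
(`visual`, `cerebral`, `mouse`) bundle these with reduced-size variants
for fast tests; sizes are recorded in `instance.meta`. Two-modality
output draws A and R independently from the same f, so their
disagreement rate equals the categorical collision probability
1 − Σ_k f_k² (tested).

What the generator does **not** emulate: spatial wiring-cost biases
beyond the latent geometry, reciprocity correlations (a_ij and a_ji are
conditionally independent given the embedding), community structure not
expressible as spatial clustering, modality-specific sensitivity
differences (fusion noise is symmetric by construction), and
measurement artifacts such as injection-volume variability. Passing
tests therefore certify the estimator under the model's own
assumptions — correctness and calibration of the machinery — not that
real cortex follows a D-dimensional Euclidean embedding.

## Test and benchmark scales

The statistical checks run at desk scale, chosen to finish on one CPU
in minutes while leaving the assertions well clear of their pass
boundaries: distance recovery at p = 30, D = 2, K = 4 with 4 chains ×
(500 + 500); model-ordering and uncertainty–error runs at p = 30 with
10 % of edges held out, 2 × (400 + 400); cross-validated dimension
selection at p = 20, 5 folds, D ∈ {1, …, 4}, 1 × (200 + 200); fusion at
p = 16, 2 × (300 + 300). The uncertainty–error relation bins held-out
edges into uncertainty deciles *within* each fit (credible-interval
widths are only comparable within one posterior) and averages the
decile error profile across replicates before the rank test.

## Known limitations

* The sampler is plain jittered-path HMC, not NUTS; for posteriors with
  strong scale heterogeneity more warmup (or more chains) may be needed
  than a NUTS implementation would require.
* Eigenmodel axes are unidentified up to sign/permutation and Λ may mix
  with Z scale; only predictive quantities of that variant should be
  interpreted.
* Weights must already be ordinal; thresholding continuous tracer
  indices (e.g. FLNe) is upstream of this package.
* Per-draw f cubes are materialized for uncertainty quantiles
  (T·p²·K doubles); for p in the hundreds with many draws this needs
  batching that the current implementation does not attempt.
* The diagonal (self-connections) is never modelled or predicted.
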