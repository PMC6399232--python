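# Methods

This note documents the models, defaults and numerical choices behind
`sleepstates`, and what the synthetic benchmarks do and do not demonstrate.

## Observation model and variational inference

Observations are modelled as a K-state hidden Markov chain with multivariate
Gaussian emissions: state k has mean μ_k and covariance Σ_k (in PCA space;
back-projection to region space is μ_ROI = Mμ_k, Σ_ROI = MΣ_kMᵀ with M the
orthonormal mixing matrix). State parameters are shared across participants
(group level); the posterior state probabilities γ and hard paths are computed
per participant, with each participant's recording treated as an independent
chain that shares A and π.

Inference is conjugate mean-field VB:

- q(μ_k, Λ_k) is Normal–Wishart. Priors are empirical-Bayes style: prior mean
  = global data mean, E[Λ] under the prior = inverse global covariance,
  β₀ = 0.01 pseudo-observations for the mean and ν₀ = D + 2 degrees of
  freedom. These are weak (β₀ ≪ any realistic state count) but proper, so an
  unoccupied state falls back to the global distribution instead of
  collapsing.
- q(A_row) and q(π) are Dirichlet. The transition prior is a symmetric
  Dirichlet with concentration 1 per entry plus a self-transition boost
  (default +5 pseudo-counts on the diagonal): haemodynamic states persist for
  seconds, i.e. several samples at TR ≈ 2 s, and a mildly sticky prior
  encodes that without forcing it — with thousands of samples the data
  dominate. The boost is a constructor argument (`trans_stickiness`).
- The hidden-state posterior is exact given the expected natural parameters
  ("tilde" parameters, exp of digamma differences), computed by a scaled
  forward–backward pass per participant block.

The free energy F = −Σ_p log Z_p + KL(q‖prior) is evaluated after each E-step
and before the following M-step, which makes the recorded trace exactly
non-increasing (up to floating-point noise; tests allow 1e-8 relative).
Convergence is declared when the relative change falls below `tol` (default
1e-5, max 500 iterations). The posterior stored in the results object is the
one that produced the final E-step, so `decode` on training data reproduces
the stored γ and `free_energy` reproduces the last trace entry exactly.

Initialisation: k-means (on a subsample of ≤ 2000 rows) provides smoothed
one-hot responsibilities (ε = 0.25 mass spread uniformly), followed by an
M-step. `fit(n_init=5)` runs independent restarts from different k-means seeds
and returns the restart with the lowest final free energy; ties keep the first.
All randomness flows through `numpy.random.SeedSequence`, so fits are
bit-reproducible given a seed.

Degenerate states: a state whose responsibility mass drops below one sample
keeps its (prior-dominated) parameters and is reported in
`results.empty_states` and the log — never an exception. This is the expected
VB behaviour on over-specified K: surplus states are pruned toward the prior.
A consequence worth knowing: the KL complexity term is *not* strictly
monotone in K on structureless data, because pruned states contribute almost
nothing; the complexity of any K > 1 still exceeds the K = 1 baseline while
the fit term stays flat, and that is the property the tests assert.

Hard state assignment is the row-wise argmax of γ (lowest index on ties);
Viterbi decoding is available via `decode(..., viterbi=True)` for users who
want the jointly most probable path instead of the marginal one.

## Preprocessing

- Standardisation is per participant and per region, using the population
  (1/N) standard deviation — the usual z-scoring convention, chosen so the
  worked examples are exact. Constant regions raise an error naming the
  region.
- The optional temporal band-pass is a Butterworth filter (default
  0.01–0.1 Hz, design order 6 passed directly to `scipy.signal.butter`, so the
  band-pass has 2×6 poles) applied forward–backward (`sosfiltfilt`), i.e.
  zero phase, so filtering cannot shift state timings. It is applied per
  participant *before* concatenation; filtering the concatenated matrix would
  leak transients across participant boundaries.
- PCA is computed on the concatenated standardised data, without re-whitening
  the component scores: the HMM estimates full state covariances, and
  whitening would change their interpretation. Each component's
  largest-magnitude loading is made positive so mixing matrices are
  reproducible across platforms. `variance_target` selects the smallest
  component count reaching the requested cumulative explained-variance
  fraction.

## State metrics

All metrics use the hard path, matching definitions that count time "in which
a state was active"; `soft_gamma` switches sensitivity/specificity to
probability-weighted variants. Specificity is read as P(stage | state active)
(rows over stages sum to 1 for occupied states); the complementary reading,
P(state | stage) time-normalised differently, is exactly the sensitivity, so
both interpretations are available. Transitions that straddle a stage
boundary count for neither stage's switching rate: the rates divide by
within-stage time, and cross-stage switches would conflate stage effects.
Epoch-format hypnograms (one label per 30 s) are expanded to the TR grid by
assigning each sample the stage of the epoch containing its acquisition
midpoint. WASO relabelling marks every wake sample after the participant's
first N2 sample as WASO and earlier wake as W_pre.

## Permutation inference

The null preserves each participant's hypnogram structure exactly: the run
(period) boundaries and lengths stay fixed and only the run labels are
shuffled within participant; identical labels may land adjacently (runs are
not re-merged). P-values use the add-one convention
p = (1 + #{null at least as extreme}) / (1 + n_perm); Wilks' Λ is extreme when
*small*. Permuted scorings that lack a stage needed for a comparison are
excluded from that comparison's null and counted (`n_excluded`). No
multiple-testing correction is applied across stage-pair comparisons; raw
p-values are reported with conventional flags at 0.01 and 0.05.

MANOVA features default to the per-sample soft state probabilities restricted
to participants that include all four stages; rank-deficient features (the
probabilities sum to 1) are projected onto their non-null principal subspace
before the scatter determinants are formed.

A calibration subtlety: when stage periods have unequal durations, relabelling
runs changes the per-stage sample counts, so the scheme is a close but not
exact permutation test — measured type-I error then falls slightly below
nominal (conservative). The shipped calibration simulation therefore uses
equal-duration periods, under which run relabelling is a genuine permutation
of sample blocks and the test is exact; both the MANOVA and the paired-t
calibration land inside the binomial band around 0.05 in that regime. On real
hypnograms (unequal periods) the tests err on the conservative side.

## Transition graph and modularity

The group transition matrix defaults to empirical counts pooled over the
decoded paths of the analysed participant subset (never counting a transition
across a participant boundary), because the VB posterior matrix reflects the
full cohort while subset analyses need subset dynamics; `mode="model"` returns
the posterior matrix instead. States occurring (≥ 1 hard-assigned sample) in
strictly more than `min_fraction` (default 0.25) of participants are retained.
Self-transitions are removed before thresholding — they dominate any
probability ranking and the map describes between-state structure; a flag
retains them. The top `round(keep_fraction × #off-diagonal)` entries survive,
with ties broken lexicographically by (departure, destination) so results are
platform-independent.

Modules come from Newman spectral community detection generalised to directed
graphs: modularity matrix B = A − k_out k_inᵀ/m, symmetrised for the
eigen-decomposition; repeated bisection by the leading eigenvector with an
eigenvector-ordered sweep over split points, Kernighan–Lin polishing of each
candidate, recursion via the generalised modularity matrix until no split
increases Q; finally a global refinement (greedy node moves, a KL chain that
accepts temporarily losing moves, pairwise module merges, and a deterministic
multistart). On every random directed graph with n ≤ 8 tried in the test
suite, the returned partition attains the exhaustive-search maximum of the
directed modularity.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes: K_true
Gaussian states (orthogonal mean patterns scaled to a chosen separation,
default 3× the unit noise SD; identity covariances by default), sticky
Markov switching (default 0.90 self-transition), a per-participant stage
program (default W → N1 → N2 → N3 → W so WASO selectors are exercisable, with
mildly participant-varying durations), stage coupling by per-stage
re-weighting of the transition rows — the cohort stays Markovian conditional
on the hypnogram, which keeps parameter recovery a fair test — and AR(1)
blending (default coefficient 0.4) standing in for the slow band-passed
character of BOLD signals while keeping the generative process invertible for
counting oracles. Default toy scale is 6 participants × 600 samples × 12
regions × 4 states, chosen so a full end-to-end run takes seconds.

What the generator does *not* emulate: haemodynamic convolution, scanner
noise/drift, motion or physiological artefacts, EEG waveforms, inter-subject
spatial variability, or non-stationary state parameters. Passing tests
demonstrate correct inference under the model's own assumptions and graceful
qualitative behaviour (occupancy-scan flattening at the planted order,
module recovery); they do not certify performance on real EEG-fMRI data.

## Problem sizes used by the shipped benchmarks

The recovery benchmark uses 6 × 600 × 12 with 3 states; the calibration
simulation uses 200 null datasets of 5 participants × 60 samples with 99
permutations each; the scan uses 4 × 400 × 10 over K = 2…8 with 2 restarts;
modularity oracles enumerate all set partitions up to n = 8. These sizes give
stable results (recovery ≈ 0.99, type-I within the binomial band) while
keeping the whole suite around half a minute; they are the package's chosen
study conditions, and all are parameters should users want larger runs.

## Known limitations

- The VB implementation assumes contiguous participant blocks in the
  concatenated matrix (the preprocessing guarantees this).
- Free-energy comparisons across K are valid for model-order scans, but a
  caveat applies: on real data the free energy often decreases monotonically
  in K without a clear minimum, so the occupancy and lifetime diagnostics
  carry the model-order selection.
- The default K in the shipped pipeline config is 19 — the order used in the
  motivating application — but nothing in the code privileges it; synthetic
  benchmarks use the planted orders.
- No REM stage is modelled anywhere (the target cohorts reach NREM only).
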