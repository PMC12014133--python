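# Methods

This note records the models, estimators and numerical choices behind
`ecohab_maxent`, and what the synthetic-data experiments do and do not
establish about real recordings.

## From antenna crossings to locations

The raw datum is a timestamped crossing of one of the eight antennas that
flank the four tunnels of the ring-shaped habitat. A mouse's location on
the 2-s analysis grid is deduced from the most recent and next crossings:

* two consecutive reads at the two antennas of one tunnel are a traversal;
  for the bins between them the mouse is assigned the compartment it is
  about to enter;
* two reads of the same antenna less than one grid step (2 s) apart are
  collapsed into a single visit — the mouse poked into the tunnel and
  returned, an artifact of the read geometry. Reads at *different*
  antennas are never collapsed, however close, so genuine fast traversals
  survive;
* between crossings the location persists; before a mouse's first
  crossing it is undefined and the bins are masked invalid rather than
  imputed;
* simultaneous reads keep file order — the hardware does not define a tie
  order and we do not invent one.

Each bin samples the reconstructed trajectory at its start time. Analysis
is restricted to a daily 13:00–19:00 window (the first, most active half
of the dark phase; 10,800 bins/day); the day boundary sits at the light
onset so windows never straddle days. A mouse that fails to visit all four
compartments during the window of any single day is excluded as inactive,
and in paired before/after designs a mouse inactive in either phase is
masked in both.

## Empirical statistics

With δ the Kronecker delta and averages over valid bins:

* occupancy `m_ir = (λ/q + Σ_t δ_{σ_i(t),r}) / (T + λ)` with q = 4 and
  pseudocount λ = 8 — the additive smoothing that keeps inference finite
  when a mouse camps in one compartment for a whole window. The same
  smoothing gives the pair coincidence `Γ_ij` (the prior chance of a
  coincidence is also 1/q) and, for the triplet model, `Γ_ijk` with prior
  1/q² (the package's extension of the same rule to three-mouse
  coincidences).
* in-cohort sociability `C_ij = Σ_r [f_ij(r,r) − f_i(r) f_j(r)]` on **raw**
  frequencies — smoothing inside C would bias its zero, which is the whole
  point of the statistic. Pair and triplet statistics use only bins where
  all involved mice are valid, with marginals taken over those same bins
  so that independence gives zero exactly.
* triplet statistics: the raw coincidence `Γ_ijk`, the fully connected
  third cumulant `C_ijk`, and `C*_ijk = Σ_r [f_ijk(r,r,r) − f_i f_j f_k]`,
  which subtracts only individual preferences and is the quantity the
  pairwise model is asked to predict on held-out data. All are summed over
  the four compartments.

## The maximum-entropy models and their fitting

`P⁽²⁾(σ) ∝ exp(Σ h_ir δ_{σ_i,r} + Σ_{i<j} J_ij δ_{σ_i,σ_j})` is the
maximum-entropy distribution constrained by the pseudocounted `m` and `Γ`.
Fields carry a per-mouse additive redundancy removed by the zero-sum gauge
`Σ_r h_ir = 0`. The triplet extension adds `G_ijk δ_{σ_i,σ_j} δ_{σ_i,σ_k}`
(N(N−1)(N−2)/6 parameters) and an L2 penalty ½β_G ΣG².

**Learning rule.** Plain gradient descent on the moment mismatch:
`h ← h − α (m_model − m_data)`, `J ← J − α (Γ_model − Γ_data + β_J J)`,
`G ← G − α_G (Γ3_model − Γ3_data + β_G G)`, with α ∈ [0.25, 0.8]
(default 0.5 in the API, 0.8 in the validation experiments — the
log-likelihood is convex, larger steps just converge faster here).
For β_G > 0 the G step size is capped at 0.5/β_G so the shrinkage term
stays contractive. Initialization is the independent model: h = log m
(gauged), J = G = 0 — deterministic, and exact when the data really are
independent.

**Stopping.** Two conditions must hold simultaneously: (a) every
penalized-gradient component (for β = 0, the raw moment residual) is below
a per-moment tolerance, taken from the data's own block-bootstrap
variability; and (b) the mean and SD of the couplings each changed by less
than 0.005 over the last 100 steps. The penalized form of (a) matters:
a regularized fit's stationary point keeps a raw moment residual of
−βJ by construction, so raw residuals can never pass the test. A hard cap
of 5×10⁴ iterations raises a convergence error carrying the full fit
trajectory.

**Model moments.** Exact enumeration of the 4^N states for N ≤ 10
(4^10 ≈ 10⁶ states; precomputed one-hot and pair-coincidence tables turn
each gradient step into two BLAS matrix–vector products, ≈80 ms at
N = 10). Above that, persistent Gibbs chains: 128 chains, two heat-bath
sweeps per gradient step, moments smoothed by an exponential moving
average (rate 0.05) whose window trades gradient noise against a small lag
behind the current parameters. The enumeration route is the oracle the
sampler is validated against (chain-wise standard errors; chains are
independent, so the SE is valid despite within-chain autocorrelation).

**Cross-validation.** Each day's 6-h window is cut into six 1-h chunks;
each distinct hour serves once as the test set (5 h train / 1 h test, six
folds), for models built on K ∈ {1,…,10} aggregated days. Likelihoods are
exact joint log-likelihoods per 2-s observation, which limits CV to
enumeration-sized cohorts — the regime the validation experiments use.

## Derived sociability metrics

* Nested conditional log-likelihoods per mouse: l(0) = log(1/4) for the
  uniform null, l(1) = ⟨log m_i(σ_i(t))⟩ for the independent model
  (pseudocounted, avoiding −∞ on unvisited compartments), and l(1,2) =
  ⟨log P⁽²⁾(σ_i(t) | σ_−i(t))⟩ with the closed-form conditional
  softmax(h_ir + Σ_j J_ij δ_{σ_j,r}). Natural log throughout; mutual
  information alone is reported in bits.
* Mutual information I(σ_i; rest) = H(σ_i) − ⟨H(σ_i | rest)⟩, the
  conditional entropy averaged over observed configurations of the other
  mice. The marginal uses the pseudocounted empirical occupancy by default
  (consistent with averaging over observed patterns); the model marginal
  is available as an option. Bounded by log₂ 4 = 2 bits; exactly zero when
  the model factorizes and h matches the marginal.
* In-state calibration: model-predicted conditional probabilities are
  percentile-binned per mouse and compartment (equal-count bins) and
  compared with the observed occupancy frequency in each bin; an unbiased
  model lies on the diagonal.
* Food preference Δh_i = Σ_{r∈food} h_ir − Σ_{r∉food} h_ir under the
  zero-sum gauge. With two food and two non-food compartments this is a
  difference of sums, hence invariant under any per-mouse constant shift
  of the fields. (No algebraic definition is standard; this one is the
  natural gauge-invariant choice.)
* DTI: F_ijk = −J_ij J_jk J_ki if exactly one of the three couplings is
  negative, else 0 (such a triangle cannot satisfy all three preferences
  at once); the global DTI averages over all C(N,3) triangles. A
  shuffled-coupling reference (values permuted over pairs) distinguishes
  network structure from the value expected under the couplings' marginal
  distribution alone.

## Uncertainty and significance

Any statistic's uncertainty comes from random halves of 400-s blocks
(longer than twice a mouse's correlation time; 54 blocks per 6-h day,
trailing partial blocks dropped), with the half-data SD σ_bs extrapolated
to the full data as σ = σ_bs/√2 — the reading of the "divide by 2"
convention consistent with √n error scaling; the literal division by two
is available via `extrapolate="half"`. Calibration caveat: for
effectively independent blocks, the SD of a mean across random
*complementary* halves of one dataset equals the full-data SE (simple
random sampling with a finite-population correction of one half), so the
extrapolated σ sits ≈0.71× the true SE. The procedure is implemented as
specified; its unit test asserts this actual calibration. Model-dependent
statistics (couplings, DTI) are re-fitted on each half; ten replicates by
default.

Group comparisons across 5-day segments use two-sided Welch's t (means)
and the two-sample F test (variances) through `scipy.stats`, with a
Bonferroni family of m = 6 pairwise comparisons. Star conventions:
{0.05, 0.01, 0.001}/6 for means/variances and the stricter
{0.025, 0.005, 0.0005}/6 for global-DTI comparisons. Under a simulated
null both procedures' type-I error matches the corrected level within
binomial error (the F test is exact for normal data; Welch is an
approximation that holds well at the sample sizes used).

## The synthetic generator

Ground truths draw gauged fields h ~ Normal(0, s_h = 0.3) and symmetric
couplings J ~ Normal(μ_J = 0.05, s_J = 0.15) — scales matching the weakly
coupled, mixed-sign regime the inference is designed for. Dynamics are
single-mouse moves at rate `move_rate` per 2-s bin; the default kernel
proposes one of the two topology-adjacent compartments and accepts by the
Metropolis rule, so the stationary law is exactly P⁽²⁾ *and* trajectories
never jump across the ring — which lets the emitter write physically
consistent antenna-event streams. An all-compartment heat-bath kernel and
exact i.i.d. sampling (enumeration-sized cohorts) are options. An optional
circadian profile modulates the move-attempt rate only, leaving the
stationary law untouched — mirroring the restriction of real analyses to
the most active hours.

Event emission places each crossing's two antenna reads just around the
bin boundary of the transition (departure-side 0.1 s before, arrival-side
0.9 s after), routes non-adjacent changes through a shared neighbor inside
the same boundary, and anchors each mouse's starting compartment with one
lone read on a tunnel not used by its first crossing. These offsets are
chosen so that re-discretization — including the same-antenna
artifact-collapse rule, which immediate back-and-forth traversals
necessarily trigger — reproduces the input matrix bin for bin; the
round-trip identity is tested for both kernels.

**What the defaults do and do not emulate.** `move_rate = 0.25` gives
dwell times of order ten seconds, an accelerated clock: real mice dwell
for minutes, so a real 5-day recording carries roughly an order of
magnitude fewer effective samples than a default synthetic one. The
generator also has no circadian structure by default, no missed or
spurious antenna reads, and exactly pairwise ground truth. Passing
recovery tests therefore demonstrates the correctness of the estimators
and the identifiability of the model at these sample sizes — not that
five days of real data constrain J to the same precision.

## Validation experiment sizes

* Sampler oracle: N = 5, 80 chains × 400 kept sweeps, agreement within
  3 chain-wise SE of enumeration.
* Inversion: N = 4, fit to exact moments, tolerance 10⁻⁶; recovers h and J
  to <10⁻³ (observed ~10⁻⁶).
* Cohort-scale recovery: N = 10, five synthetic days (54,000 bins), full
  simulate → discretize → statistics → fit pipeline; Pearson r ≥ 0.9 (J)
  and ≥ 0.95 (h), observed ≈0.99 both.
* Triplet prediction: N = 8, three days train, three days held out;
  r(C*_pred, C*_obs) ≥ 0.8, observed ≈0.95.
* Regularization path: N = 8, one day, six hourly folds, β_G ∈
  {0, 0.1, 1, 10}. On exactly pairwise data the test likelihood rises from
  β_G = 0 (overfit deficit ≈3×10⁻³ nats/obs) to a plateau; the spread
  across β_G ≥ 0.1 is ~10⁻⁴ nats/obs with seed-dependent sign — expected
  harm and realization noise of the plateau scale identically with sample
  size, so the experiment asserts the plateau (largest β_G within 10⁻³
  nats/obs of the grid maximum) rather than a strict argmax.
* Significance calibration: 2,000 null simulations, n = 10 per group.

## Known limitations

* Exact likelihood evaluation (and hence CV) is limited to N ≤ 10; larger
  cohorts fit via persistent Gibbs chains with correspondingly noisier
  convergence, and their CV would need a sampled estimate of log Z.
* Couplings are compartment-independent by model choice; directed or
  state-dependent interactions are out of scope.
* The model is static: it describes the joint distribution of simultaneous
  positions, not transition dynamics.
* The inactivity rule treats a day with no valid bins for a mouse as
  "not covering all compartments", which conservatively flags mice that
  enter the experiment mid-recording.
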