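# ecohab-maxent

Maximum-entropy models of collective mouse behavior from Eco-HAB RFID
tracking.

The Eco-HAB is a semi-naturalistic habitat for group-housed mice: four
large compartments joined in a ring by tunnels, with RFID antennas at both
ends of every tunnel and food in two of the compartments. Cohorts of 10–15
tagged mice live in it for days while every antenna crossing is logged.
This package turns those logs into a quantitative account of sociability:

1. **Discretization** — antenna crossings become a per-mouse compartment
   label σᵢ(t) ∈ {1..4} on a 2-s grid, restricted to the most active 6 h of
   each day (13:00–19:00, the first half of the dark phase), with inactive
   mice excluded.
2. **Empirical statistics** — occupancy frequencies, the in-cohort
   sociability C₍ᵢⱼ₎ = Σᵣ [f₍ᵢⱼ₎(r,r) − fᵢ(r)fⱼ(r)] (excess co-localization
   beyond independence), triplet correlations, and the distribution of how
   many mice share a compartment.
3. **Inference** — the pairwise maximum-entropy (Potts) model

   P⁽²⁾(σ) ∝ exp( Σᵢᵣ hᵢᵣ δ(σᵢ,r) + Σᵢ₍<ⱼ₎ Jᵢⱼ δ(σᵢ,σⱼ) ),

   the least-structured distribution reproducing each mouse's
   (pseudocounted) compartment occupancy and each pair's same-compartment
   probability. The fields hᵢᵣ are intrinsic compartment preferences (in a
   zero-sum gauge); the couplings Jᵢⱼ are direct pairwise
   attraction/avoidance, disentangled from correlations inherited through
   third parties. Fitting is Boltzmann learning — gradient descent on the
   moment mismatch — with exact enumeration of the 4^N states for N ≤ 10
   and persistent Gibbs chains above. An L2-regularized triplet-coupling
   extension and the hourly cross-validation protocol used to select the
   modeling timescale are included.
4. **Sociability read-outs** — nested conditional log-likelihoods
   (null / independent / pairwise), in-state calibration curves, per-mouse
   mutual information with the rest of the cohort (0–2 bits), preference
   for the food compartments Δhᵢ, and the dissatisfaction triplet index
   (DTI): for each triangle of couplings with exactly one negative edge,
   F₍ᵢⱼₖ₎ = −Jᵢⱼ Jⱼₖ Jₖᵢ (zero otherwise), averaged over all triangles — a
   frustration measure of the interaction network.
5. **Uncertainty and significance** — 400-s-block random-half bootstrap
   with √2 extrapolation, Welch's t and two-sample F tests with a
   Bonferroni family of six 5-day-segment comparisons.
6. **Synthetic cohorts** — a generator with known ground-truth fields and
   couplings whose Glauber dynamics have exactly the model's stationary
   law, emitting either location matrices or raw antenna-event streams, so
   the entire pipeline is testable end to end without any recording.

## Worked example

Simulate a known 10-mouse cohort for five 6-h days, re-infer its model
from the simulated locations, and read off the sociability metrics:

```python
import ecohab_maxent as em

gt = em.make_ground_truth(n_mice=10, seed=11)
loc, events = em.simulate_cohort(gt, em.SimConfig(n_days=5, emit_events=True),
                                 seed=12)

model = em.PairwiseMaxEnt.from_location(loc, lam=8, seed=13)
result = model.fit(alpha=0.8)
print(result.summary())
print(em.recovery_report(gt, result.h, result.J))

mi = result.mutual_information(loc)
dti = result.dti(n_shuffles=100, seed=14)
ll = result.conditional_loglikelihoods(loc)
```

This prints:

```
Pairwise maximum-entropy model
  mice: 10   compartments: 4
  method: exact   iterations: 121   converged: True
  pseudocount lambda: 8
  couplings J: mean +0.0661  sd 0.1314  min -0.2235  max +0.3096
  fields h: sd 0.2194 (zero-sum gauge)
  final max residual: 0.000 tolerance units
coupling recovery r=0.9903 (rmse 0.0191); field recovery r=0.9961 (rmse 0.0198); PASS
```

and the metrics evaluate to a mean mutual information of 0.0271 bits per
mouse, a global DTI of 0.00084 (statistically indistinguishable from its
shuffled-coupling reference 0.00091 — the generator draws couplings with
no network structure), and conditional log-likelihoods
l(0) = −1.3863, ⟨l(1)⟩ = −1.3651, ⟨l(1,2)⟩ = −1.3464 nats per 2-s
observation: knowing the other mice's positions improves prediction of a
mouse's location by about as much as knowing its individual compartment
preferences — the signature of genuine pairwise sociability.

Real recordings enter the same way: `em.read_events` parses a TSV log
(`time_s`, `antenna`, `mouse`) against a YAML habitat topology,
`em.build_location_series` and `em.select_window` produce the
`LocationMatrix`, and `em.find_inactive_mice` implements the exclusion
rule (a mouse must cover all four compartments every day).

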