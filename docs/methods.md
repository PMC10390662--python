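# Methods

`mediabo` designs batches of serum-free cell-culture media that trade off
predicted long-term cell growth against formulation cost. This note records
the model, the algorithmic choices, the defaults and why, and what the
synthetic benchmark does and does not establish.

## The design space and the two coordinate scales

A medium is a vector of p = 26 component concentrations: 7 grouped basal
variables (amino acids, vitamins, salts, trace metals, DNA precursors,
fatty acids — dosed in "x"-multiples of a stock and carrying zero cost) and
19 individual components (carbohydrates, ascorbic acid, sodium selenite,
NaCl, and the protein growth factors that dominate cost). Each component has
bounds [conc_min, conc_max] and a unitless marginal cost coefficient c_j.
Fixed sodium-bicarbonate and water make-up are metadata, not coordinates.

Two [0, 1] scalings of a formulation coexist deliberately:

* the **min–max scale** x_k = (conc_k − min_k)/(max_k − min_k) is the search
  box for the surrogate and the acquisition;
* the **fraction-of-max scale** x̃_k = conc_k / max_k feeds the cost model
  c(x) = c_min + Σ_j c_j x̃_j with c_min = 0.

The fraction-of-max convention is the default because it uniquely reproduces
all five printed reference-media costs (0.24 for the control and
0.09 / 0.30 / 0.39 / 0.41 for the four optimized media) at two-decimal
rounding, whereas pricing on the min–max coordinates gives ≈ 0.18 for the
control. Both conventions are implemented behind the `scale` option of
`compute_cost`; tests pin the discriminating case.

## Multi-information-source Gaussian process

Observations are triples (x, m, y): normalized concentrations, a fidelity
code (m = 0 the authoritative second-passage cell count; m ≥ 1 cheap proxy
assays such as resazurin reduction or live-stain imaging), and the assay
readout. All outputs are standardized jointly (zero mean, unit sd across all
sources) before fitting, so thresholds and bounds below are on the
standardized scale. Per-assay standardization is available but off by
default — joint scaling lets amplitude hyperparameters absorb per-assay
gain differences while keeping a single interpretable output scale.

The covariance between (x, m) and (x′, m′) is

    K = S_0(x, x′) + 1[m ≠ 0] 1[m = m′] S_m(x, x′),

each S_m a squared-exponential kernel σ_f,m² exp(−½ Σ_k (x_k−x′_k)²/λ_k,m²)
with its own amplitude and per-dimension lengthscales. The shared S_0 term
carries the high-fidelity signal; each low-fidelity source adds its own
smooth discrepancy. A single prior mean μ0 is shared across fidelities, and
noise is homoscedastic (one σ_ε for all sources; per-source noise would add
M parameters the small datasets here cannot support). Lengthscales are
independent per source rather than tied — tying them is a plausible
alternative but would force the discrepancy to vary on the same scale as
the signal.

Hyperparameters maximize the log marginal likelihood by multi-start
L-BFGS-B over log-parameters (default 10 restarts: one informed start at
λ = 0.3, σ_f = 1 plus log-uniform random starts). Search boxes assume
standardized outputs: λ ∈ [10⁻², 10²], σ_f ∈ [10⁻², 10], σ_ε ∈ [σ_min, 1],
μ0 ∈ [−10, 10]. The noise variance is floored at σ_min² = 0.05 by default
(0.02 available): duplicate or near-duplicate wells otherwise drive σ_ε
toward zero and make the acquisition surface numerically fragile. Gram
factorizations escalate diagonal jitter to at most 10⁻⁶ before raising.

## Acquisition: constrained q-point expected hypervolume improvement

Two objectives are maximized: predicted high-fidelity growth μ(x) and
negated cost −c(x). Progress is the hypervolume dominated above a reference
point l = (l_μ, l_c), recomputed each batch as l_μ = mean(y) − 4·sd(y) over
all standardized observations (i.e. −4 after standardization) and
l_c = −1.1, ten percent beyond the worst possible unit cost.

The value of a batch X of q candidates is estimated as follows.

1. The incumbent front is the non-dominated set of (posterior mean, −cost)
   pairs at the observed high-fidelity designs (fixed posterior means; a
   per-MC-draw re-sampled front is a possible extension, not implemented).
2. The region above l not dominated by the front is partitioned exactly
   (S = 2) into K rectangles by the sorted-staircase construction; upper
   caps are set above the largest sampled outcome so clipping never bites.
3. N joint posterior growth samples are drawn at the candidates by the
   reparameterization trick, Y = μ(X) + L(X) Z, with one fixed matrix of
   standard-normal draws Z per optimization so the surface is deterministic.
4. Each sample's joint improvement is computed by inclusion-exclusion over
   all 2^q − 1 candidate subsets against the K rectangles. Cost enters
   deterministically (the cost coordinate of a candidate is −c(x) exactly,
   never sampled). A subset's term is weighted by the product of its
   members' feasibility scores φ = sigmoid((g − y_min)/ε) with temperature
   ε = 10⁻³, evaluated on the *sampled* growth values (an option evaluates
   it on posterior means instead). With y_min = −∞ the weights vanish and
   plain qEHVI results.
5. The acquisition α(X) is the average over the N samples.

The inclusion-exclusion sum is exponential in q; that is the intended
regime, since it is evaluated on full batches only during optimization at
desk scale (q ≤ 6 in benchmarks) and on size-q0 sub-batches (q0 = 3) during
fidelity allocation. A bitmask dynamic program computes all subset minima
and weight products incrementally, and the deterministic cost factor of
every (subset, rectangle) pair is computed once rather than per MC sample;
a test pins this fast path to the generic inclusion-exclusion routine.

α is maximized over the unit box by multi-start L-BFGS-B with
finite-difference gradients (default 20 restarts plus up to 3 starts built
by perturbing observed high-fidelity designs with N(0, 0.05) noise). The
fixed Z makes repeated runs with one seed bitwise identical.

The sigmoid argument v(x) is taken as μ(x) − y_min — the growth margin —
which is the natural choice for a minimum-growth constraint; note the
convention, since only the constraint's sign and scale are fixed by its
indicator limit.

## The batch loop

One turn: refit the surrogate on all data → maximize α for q candidates →
allocate fidelities → emit the lab sheet → ingest measured values (one
averaged technical replicate per medium and fidelity) → re-standardize.
Defaults mirror a wet-lab campaign: q = 15 media per batch with q0 = 3
high-fidelity slots, 10 Latin-hypercube initialization designs (one point
per decile of every coordinate), N = 1000 MC samples, 12 batches.

Fidelity allocation enumerates all C(q, q0) size-q0 sub-batches of the
optimized batch (455 for the defaults), scores each with α using one shared
MC sample set so all are measured against the same yardstick, and assigns
m = 0 to the best (ties → lexicographically smallest index set). The rest
get the configured low-fidelity codes round-robin, since nothing favors one
cheap assay over another a priori.

The minimum-growth threshold y_min rises over the campaign — 0.5
(standardized) from batch 1, 0.75 from batch 5, 1.0 from batch 10 — to steer
later batches toward high-growth regions once the model has coverage. The
schedule is a config field; the "takes effect at batch 5/10" convention is
the package's reading of "raised after batch four and nine" and can be
shifted by editing the schedule.

A separate pure-growth probe maximizes noisy expected improvement
NEI(x) = E[(f(x) − max f(X_incumbent))₊] under joint posterior sampling,
ignoring cost — useful late in a campaign to ask for the best achievable
growth outright.

Campaign state (raw observations, batch counter, config) serializes to
JSON; per-batch seeds are derived from the campaign seed and batch index,
so reloading mid-campaign reproduces the next proposal exactly.

## Sensitivity analysis

Two post-hoc views of a fitted model:

* **Optimum distribution** — 50 independent single-start L-BFGS-B ascents
  from uniform starts, under either argmax μ(x) (growth regardless of cost)
  or argmax α(x) s.t. μ(x) ≥ μ(control) (cost-aware, constrained to beat
  the control's predicted growth, enforced through the feasibility weight).
  The histogram of solutions shows which components the model pins down.
* **Integrated directional variogram** (VARS-style) — for component k,
  γ_k(h) = ½ E[(f(x + h e_k) − f(x))²] is estimated at 10 evenly spaced lags
  up to h_max = 0.3 (per-coordinate lags, since importance is reported per
  component; a full Euclidean-displacement variant is a noted alternative),
  with 1000/10 random base points per lag drawn so the shifted point stays
  inside the box, then integrated by the trapezoid rule on the full lag grid
  including γ(0) = 0. The lag grid is deterministic rather than free-random
  because binning free lags at bin centers leaves the tail
  [last-center, h_max] uncovered and biases the integral several percent
  low (visible against the linear-function closed form
  ∫₀^0.3 h²/2 dh = 0.0045); the stratified grid reproduces the closed form
  to well under 2% at 1000 samples. Values scale as the square of the
  output; a dummy input scores < 1% of the top-ranked one.

## Synthetic benchmark

The simulator replaces the wet lab with a known ground truth: a smooth
high-fidelity surface g0 on the unit box, and low-fidelity sources
reporting g0 + δ_m(x) + noise where each δ_m is a smooth random field
(superposition of RBF bumps) with amplitude 30% of the signal scale —
informative but systematically wrong, the regime in which a multi-source
model should pay off. Noise defaults: σ0 = 0.05 (high fidelity),
σ1 = 0.15 (low). Presets: `peaks2d` (three Gaussian bumps, one dominant
optimum, linear cost 0.5/0.3), `media26` (26-D, 8 active dimensions,
packaged cost coefficients — mirrors the sparse importance structure real
media screens exhibit), `linear-check` (linear, zero bias/noise/cost, for
closed-form tests).

The closed-loop benchmark runs full campaigns at desk scale — q = 6,
q0 = 2, 10 initialization designs alternating fidelities, N = 256 MC
samples, 6 batches, 4 acquisition restarts — against a uniform random-search
baseline with the identical evaluation budget and fidelity mix, and records
per batch the dominated hypervolume of high-fidelity observations (reference
(0, −1.1) on the raw growth/cost scale) and the best observed growth. These
problem sizes are the package's benchmark defaults, chosen so a ten-seed
replication completes in minutes on one core; the full-scale defaults
(q = 15, N = 1000, 12 batches) are what a real campaign would use.

What passing benchmarks show: the machinery is wired correctly end to end —
hypervolume rises, the loop beats random search, low-fidelity data improves
high-fidelity prediction, known optima are found. What they do not show:
anything about real cell-growth responses. The simulator's surfaces are
smooth, stationary, and additive in their active dimensions; real growth
responses have thresholds, interactions between growth factors, batch
effects, and non-stationary noise, none of which are emulated. Measured
growth numbers from any particular wet-lab campaign are experimental
quantities and are out of scope.

## Numerical choices and limitations

* Cholesky with jitter escalation 10⁻¹⁰ → 10⁻⁶; degenerate (zero-variance)
  posteriors therefore sample with sd ~10⁻⁵, so "deterministic" acquisition
  identities hold to ~10⁻⁴, not machine precision.
* The box decomposition is exact only for S = 2 (growth + cost); the qHVI
  algebra is written for general S but untested beyond S = 2, and no
  general-S non-dominated partitioning is provided.
* Acquisition gradients are finite differences; analytic gradients through
  the MC estimator would cut optimization cost several-fold and are the
  main known performance improvement.
* Exponential subset enumeration caps practical q for full-batch α
  evaluation around 15; fidelity allocation only ever scores size-q0
  subsets and is unaffected.
* The GP is exact (dense Cholesky), fine for the few hundred observations a
  campaign produces; no sparse approximations, non-Gaussian likelihoods, or
  input warping.
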