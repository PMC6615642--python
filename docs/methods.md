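# Methods

This note records the models implemented in `mitoctrl`, the defaults and
why they were chosen, the numerical choices, and what the synthetic-data
based tests do and do not establish.

## Birth–death dynamics and control laws

mtDNA in a post-mitotic cell is modelled as a two-species Markov jump
process: each of `w` wildtype and `m` mutant molecules replicates at the
per-capita rate λ(w, m) and degrades at a constant per-capita rate μ.
Default μ = 0.07/day (≈10-day half-life of mtDNA turnover).  Because both
species share per-capita rates, there is no selection: deterministic
heteroplasmy is conserved, per-cell heteroplasmy is a martingale, and all
heteroplasmy change is drift toward fixation (h = 0 or 1).

Implemented laws (all clamped at λ ≥ 0, since a formula value below zero
has no rate interpretation; the feasible region of the defaults never
reaches the clamp):

* **linear**: λ = μ + c₁(w_opt − (w + δm)).  Fixed points form the line
  w + δm = w_opt.  c₁ sets tightness; δ may be negative or exceed 1.
* **relaxed replication**: λ = μ/(w+m) · (α_R[w_opt − (w+ηm)] + (w+ηm)),
  α_R > 1.
* **sensed families**: monotone decreasing maps of x = w + δm —
  exponential a·e^(−x/x₀) and hyperbolic a/(1 + (x/K)ⁿ).

**Calibration.** For any per-capita control λ(x) with mutant-free fixed
point λ(w*) = μ, the LNA stationary variance is μ/|λ′(w*)|.  Calibration to
a target (mean, variance) therefore solves λ(w*) = μ, |λ′(w*)| = μ/Var.
Closed forms: exponential x₀ = Var, a = μ·e^{w*/x₀}; hyperbolic
u = w*/(nVar − w*), K = w*/u^{1/n}, a = μ(1+u), feasible only when
nVar > w*.  The plain hyperbola (n = 1) hence has a variance *floor* equal
to its mean — it cannot be calibrated to variance 100 at mean 1000; the
shape exponent n generalises the family so that tight control is reachable
(n = 20 suffices for that target).  Matching the linear and relaxed
families gives the identity c₁ = μ·α_R/w_opt (default α_R = 10, inside the
literature range 5–17).

**Cellular vs homogenate heteroplasmy.** The cellular mean is the average
of per-cell m/(w+m); the homogenate is the pooled ratio Σm/Σ(w+m).  Without
selection the cellular mean stays at h₀ while the homogenate converges to
m₀/(m₀ + δw₀): a cell's long-run mutant fraction is p = m₀/(m₀+δw₀) and its
total settles on the manifold at N ∝ 1/(1 − p + δp), so weakly sensed
mutants (δ < 1) are over-represented in pooled DNA.  The implementation
pools per-cell predictions with exactly those manifold weights.  This
prediction holds in the window where fixation has largely resolved but
whole-cell extinction is still rare; at longer times exclusion of extinct
cells (mostly small wildtype-fixed ones) biases both summaries upward —
tests therefore evaluate the limit at ~750 days for the small (w_opt = 20)
study system, where extinction is < 5%.

## Stochastic simulation

Direct-method Gillespie with propensities (wλ, mλ, wμ, mμ), recomputed each
event.  Hot loops are numba-compiled, with laws passed as (kind, parameter
array) codes; a pure-NumPy event-level reference implementation is kept and
the two are cross-checked statistically in the tests.  Ensembles draw
per-cell seeds from `numpy.random.SeedSequence(master).generate_state(n)`,
so runs are reproducible and parallelisable.  Heteroplasmy summaries
exclude extinct cells (w = m = 0) and report the excluded fraction; whether
to condition on non-extinction is a genuine modelling choice and this is
ours, documented here.

Treatment-phase simulation is a time-inhomogeneous SSA via thinning: on
each lookahead window (0.25 days, cut at transfection times) the summed
nuclease concentration is bounded using the unimodality of each round's
pulse (max of the endpoints and the in-window peak), giving an exact
rejection envelope.

## Linear noise approximation

Means follow the deterministic ODEs; the covariance solves
dΣ/dt = AΣ + ΣAᵀ + B with A the drift Jacobian (analytic for the linear
law, central differences with step 10⁻⁶·scale otherwise — both paths
tested) and B = diag(w(λ+μ), m(λ+μ)) along the mean.  Var(h) uses the delta
method with gradient (−m, w)/(w+m)².  Its initial growth rate reduces to
2μh₀(1−h₀)/(w₀+m₀), independent of the control — only copy number and
turnover matter at first order.  Consequences verified against simulation:
a species absent from the feedback signal has linearly growing variance
while the sensed one saturates; equal sensing gives equal growth; tighter
sensing grows slower.

## Bioenergetic cost function

C(w, m) = |D − S(w, m)| + α(w·r_w + m·r_m), with r_m = ε₁·r_w and net
supply S = w(s(r_w) − ρ₁) + m(ε₂·s(ε₁r_w) − ρ₁) − (w+m)(ρ₂λ + ρ₃μ), where
λ, μ enter in s⁻¹ (day rates divided by 86 400; static landscapes use the
steady-state λ = μ, dynamic evaluation the instantaneous rate — both
choices are exposed as arguments).  Output models: linear s = φ(r − β) and
saturating s = 2s_max/(1+e^{−kr}) − 1.1·s_max (zero output at a small basal
leak; ceiling 0.9·s_max).  Resource allocation: solve S = D for the
smallest r_w (S is monotone in r_w, so bisection to |S−D| ≤ 10⁻⁹·D has a
unique root); if unreachable, run at the binding cap — r_max
(capacity-capped) or equal sharing R/(w + ε₁m) (resource-shared).

**Defaults are illustrative, not measured.**  The biochemical constants are
not available to this package, so the shipped set was constructed from the
structural constraints (the two output models matched at low rates:
φ = s_max·k/2, β = 0.2/k, so both give s(0) = −0.1·s_max) and then fixed so
that the documented qualitative regimes hold: s_max = 1, k = 2, φ = 1,
β = 0.1, D = 450, R = 3000, r_max = 1.2, α = 0.01, ρ₁ = 0.05,
ρ₂ = ρ₃ = 6000, ε₂ = 1, ε₁ < 1 by default (dysfunction as reduced uptake).
With these: the mutant-free optimum sits at N ≈ 1013 with 42% spare
capacity under the saturating model (the linear model's optimum sits at
the capacity boundary with none); a heteroplasmy threshold exists on
standard grids; h_max = 1 for ε₁ ≲ 0.4 and h_max ∈ (0.5, 0.7) for
ε₁ ∈ [0.5, 0.9]; the ε₁ = 0.3 landscape holds distinct low-cost basins at
low and high h.  A `scale` knob multiplies (D, R) to move the landscape to
other copy-number regimes (scale 1.5 ≈ 1500 copies, 7.5 ≈ 7600).

**Expected cost under fluctuations.**  E[C] ≈ C(mean) + ½(Var(w)C_ww +
Var(m)C_mm + 2Cov C_wm), second derivatives by central differences (exact
for quadratics; default step 1 molecule).  This is how between-cell
variance raises tissue maintenance cost at constant means.  The Taylor form
is local: it cannot see the |D−S| kink from a distant demand boundary, so
objectives that hinge on rare excursions into the unmet-demand region
(below) are evaluated by simulation, not by the Taylor correction.

## Control comparison and optimisation

Four reference strategies: linear δ = 0, δ = 1, δ optimised, relaxed with η
optimised — all calibrated to identical mutant-free behaviour.  The
expected cost of a control is either (a) T = ∞: deterministic steady-state
cost per initial heteroplasmy (50 values equally spaced in [0, 0.2]),
optionally with the Taylor variance correction using the LNA covariance at
a stated horizon; or (b) finite T: the time-averaged state cost over exact
trajectories.  δ is searched on [−1, 2] (grid-then-refine; the interval is
deliberately wider than [0, 1] because fitted δ exceeds 1 and the linear
output model pushes δ_opt negative).

Results under the default cost: δ_opt = 1.00 at ε₁ = 1 falling to 0.29 at
ε₁ = 0.15 (energy-output sensing), and δ_opt < 0 for barely functional
mutants under the linear output model at finite horizon and low copy
number.  Mean cost under a mutant-blind control (δ = 0) rises steadily as
mutant variance accumulates; with the illustrative constants the *faster*
failure mode at small copy number is heteroplasmy drift under total-count
control (δ = 1) crossing the demand threshold.  Which channel blows up
first depends on cost constants we do not possess, so the tests assert the
robust facts (blind-control cost increases; variance-driven cost growth at
constant means; divergence between controls concentrated in low-copy
cells) and not the exponential shape of any one curve.

Locally optimal control fields are unit steepest-descent directions of
C(w, m) by central differences with a one-molecule step (one-sided and
flagged at grid boundaries; stationary where both partials vanish).  They
are validated against exhaustive eight-neighbour search with decreases
normalised per molecule moved.  For pathological mutants the field shows a
divergence between the low-h and high-h basins, including regions where
the optimal move *increases* mutant copy number.

## Nuclease treatment model

Effective nuclease pool: d[ZFN]/dt = I(t) − μ_z[ZFN] with I = I₀e^{−bt},
giving [ZFN](t) = I₀/(μ_z−b)(e^{−bt} − e^{−μ_z t}) (removable singularity
I₀te^{−μ_z t} at b = μ_z; peak at ln(b/μ_z)/(b−μ_z)).  μ_z = ln 2 per day
(one-day half-life).  Rounds repeat every 28 days; concentrations from past
rounds add.  Excess death rates: mutant +Z(t), wildtype +ξZ(t).  The
summed concentration deliberately *excludes* the baseline μ so that Z = 0
recovers untreated dynamics exactly; total rates are μ plus excess.

Deterministic trajectories integrate
dw/dt = w[λ−μ−ξZ], dm/dt = m[λ−μ−Z] with a fixed-step RK4 (step 10⁻³ d for
2 days after each transfection, 2×10⁻² d otherwise; the inference path uses
2×10⁻³/1.5 d/4×10⁻² d, verified against an adaptive LSODA solve to ~10⁻⁹
absolute).  At the fitted operating point (below) with (w₀, m₀) =
(180, 720) and w_opt = w₀ + δm₀, total copy number bottoms at 7.5% of
baseline 3.63 days after transfection and recovers within the round;
heteroplasmy steps 0.80 → 0.58 → 0.32 → 0.14 → 0.05 over four rounds.

Population treatment initialises every cell at its steady-state copy number
for its heteroplasmy, treats all cells, and reports post-round mean h and
P(h > 0.6) over survivors plus the extinct fraction.  Initial heteroplasmy
distributions are moment-matched betas, or a two-atom mixture for variances
a beta cannot reach — the extreme case of a high tissue mean carried by a
minority of near-homoplasmic cells.  Protocol optimisation (strength I₀ at
fixed duration b) uses seeded grid-then-refine search on a deterministic
objective (mean cost over the horizon, or final heteroplasmy); protocols
that extinguish the population score +∞.  Matched-horizon comparisons
reproduce the slow-and-gentle principle: the best small-b protocol ends at
or below the best fast-pulse protocol's heteroplasmy, with fewer
whole-cell extinctions.

## Inference

Observation model: y(h) = h(t) + N(0, σ_h²), y(T) = T(t)/T(0) + N(0, σ_T²),
with model predictions from the deterministic treatment ODEs.  Relative
totals are modelled on the natural scale, as written above.  Sampling is
plain Metropolis in transformed coordinates (log for I₀, b, c₁, σ²;
identity for ξ, δ) with flat priors on boxes — log-uniform I₀ ∈ [10⁻², 10⁴],
b ∈ [0.1, 200] (the upper bound regularises the fast-immigration
degeneracy), c₁ ∈ [10⁻⁶, 10⁻²], σ² ∈ [10⁻⁴, 1]; uniform ξ ∈ [0, 2],
δ ∈ [−1, 3].  w_opt is tied to the initial state (w_opt = w₀ + δm₀) so
pre-treatment data are stationary under the fitted control.  The proposal
is tuned during a discarded adaptation phase — scale multipliers to a
20–40% acceptance target, then a reshape to the empirical covariance
(×2.38²/d) — and frozen, so the retained chain is a valid symmetric-proposal
Metropolis chain.  MAP estimates refine the best chain sample with
Nelder–Mead; boundary-pinned optima are flagged.

**Identifiability.**  For b ≫ μ_z the pulse is ≈ (I₀/(b−μ_z))e^{−μ_z t}:
I₀ and b trade off along a ridge and only the amplitude I₀/(b−μ_z) — or,
more robustly at finite b, the total exposure ∫Z dt = I₀/(bμ_z) — is
identified.  Recovery checks therefore score the identifiable combinations
(amplitude/area, c₁, ξ, δ), never (I₀, b) separately.

**Calibration at the study's noise level.**  With noise variances
(σ_h², σ_T²) = (0.061, 0.10) and 48 observations, the ridge geometry plus
log-uniform priors biases the fitted amplitude, and hence ξ, low: MAP
medians across seeds are ξ ≈ 0.59 (truth 0.72), median relative errors of
the identifiable quantities 0.18–0.26, and frequentist coverage of the
central-95% marginals is ~70–80% rather than 95%.  At a tenth of that noise
the posterior centres on the truth, confirming the displacement is
prior/degeneracy geometry rather than a sampler defect.  Consequently the
full-loop recovery study (20 seeds at the exact study noise) asserts median
relative error < 0.4 on the identifiable quantities, and the
sampler-calibration coverage test runs at reduced noise where the
likelihood dominates.  This miscalibration is a genuine limitation of the
model/prior combination at realistic noise, and it is the reason posterior
intervals from the real operating regime should be read as credible, not
confidence, intervals.

ξ for a modified protocol is re-estimated by 1-D maximum likelihood on
[0, 2] with every other parameter held fixed, reporting a near-flat
interval (points within 0.5 log-likelihood units) alongside the point
estimate.  Credible bands are pointwise quantiles of deterministic
trajectories under (thinned) posterior draws — parameter uncertainty only,
matching deterministic-prediction intervals.

## Synthetic data

Generators are pure functions of (design, seed).  The default design *is*
the fitted operating point: true parameters (I₀, b, c₁, ξ, δ) =
(122.82, 46.68, 1.90×10⁻⁴, 0.72, 1.26), noise variances (0.061, 0.10),
initial state (180, 720) (80% heteroplasmy, total 900), four transfection
rounds 28 days apart.  Measurements default to days {1, 3, 7, 14, 21, 28}
of each round — the real schedule is not published, so this is a
configurable stand-in.  Gaussian noise is not clipped: observed h may leave
[0, 1], exactly as the observation model assumes.  Expression profiles are
peak-normalised pulse values with multiplicative log-normal noise,
mimicking western-blot quantification up to an arbitrary constant.

What passing tests show — and do not.  The generators share the treatment
model's own ODEs and noise law, so recovery tests establish internal
consistency of the pipeline (simulation → inference round trip), the
identifiability structure, and the statistical behaviour of the estimators
at the stated noise; they cannot detect model misspecification against real
measurements (cell-to-cell transfection heterogeneity, non-Gaussian assay
error, measurement-time correlation), and nothing here re-analyses
laboratory data.

## Known limitations

* Cell division, de novo mutation, and degradation-side control are out of
  scope by design.
* Cost-function constants are illustrative; conclusions drawn from the cost
  modules are regime-level (thresholds, orderings, existence of intermediate
  h_max), not absolute values, and which failure channel dominates a given
  comparison can move with those constants.
* Posterior intervals at realistic observation noise are mildly
  anti-conservative (see calibration paragraph above).
* The nuclease model uses one effective pool; two-monomer biochemistry and
  partial transfection are not modelled.
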