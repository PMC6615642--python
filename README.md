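# mitoctrl

Stochastic feedback control, bioenergetic costs, and nuclease gene therapy
of cellular mitochondrial DNA populations.

## The problem

A post-mitotic human cell carries hundreds to thousands of mitochondrial DNA
(mtDNA) molecules, a mixture of `w` wildtype and `m` mutant copies.
Pathology typically appears only once the mutant fraction — the
heteroplasmy `h = m/(w+m)` — exceeds a threshold (~60–95%), which makes the
*variance* of h across cells, not just its mean, clinically decisive.  This
package is for modellers and quantitative biologists who need to ask: how do
different cellular feedback controls shape mtDNA copy-number and
heteroplasmy fluctuations, what do mutant-laden states cost the cell
energetically, and how should mitochondrially targeted nucleases (mtZFNs)
be dosed to shift heteroplasmy in a cell population?

## The models

**Control.** Every molecule replicates at a state-dependent per-capita rate
λ(w, m) and degrades at constant rate μ ≈ 0.07/day (a ~10-day half-life).
The central family is the linear feedback

    λ(w, m) = μ + c₁ (w_opt − (w + δm)),

which steers the *effective population* `w + δm` towards a target `w_opt`;
the mutant-sensing weight δ says how strongly mutants register in the
feedback signal.  The classical relaxed-replication control and arbitrary
monotone controls of `w + δm` are included, with a calibration routine that
gives any of them identical mutant-free mean and variance (for the
linear/relaxed pair: `c₁ = μ·α_R/w_opt`).  Dynamics are available as ODEs,
as exact Gillespie simulation of the Markov jump process (propensities
`wλ, mλ, wμ, mμ`), and as linear-noise-approximation (LNA) moment ODEs
`dΣ/dt = AΣ + ΣAᵀ + B`.

**Cost.** A state (w, m) is scored by
`C(w,m) = |D − S(w,m)| + α(w·r_w + m·r_m)` — unmet energy demand plus
resource consumption — with per-mitochondrion output `s(r)` either linear in
consumption or saturating, mutants consuming a fraction ε₁ of the wildtype
rate.  The saturating model reproduces spare respiratory capacity, a
heteroplasmy threshold beyond which demand cannot be met, and a
most-expensive *intermediate* heteroplasmy `h_max` for moderately impaired
mutants.

**Therapy.** Transfection produces a nuclease pulse
`[ZFN](t) = I₀/(μ_z − b)·(e^{−bt} − e^{−μ_z t})` that adds `Z(t)` to the
mutant death rate and `ξ·Z(t)` to the wildtype rate (ξ = off-target
selectivity).  Multi-round protocols, cell-population treatment,
heteroplasmy transfer maps and protocol optimisation are built on this, in
deterministic and exact time-inhomogeneous stochastic (thinning) modes.

**Inference.** Heteroplasmy and relative copy-number time series with
Gaussian observation noise are fitted by plain Metropolis sampling over
(I₀, b, c₁, ξ, δ, σ_h², σ_T²), with MAP refinement, maximum-likelihood
re-estimation of ξ for new protocols, and posterior-predictive credible
bands.  A synthetic-data module generates all of these inputs from known
ground truth.

## Worked example

```bash
python examples/06_gene_therapy.py
```

prints

```
nuclease pulse: peak 2.47/day at t = 0.09 d; xi = 0.72 (wildtypes cleaved per mutant)
single cell, deterministic: copy number bottoms at 7% of baseline, 3.6 d after transfection
per-round post-recovery heteroplasmy: 0.58, 0.32, 0.14, 0.05
population treatment, mean h = 0.8 with increasing variance:
  Var(h) = 0.004: mean h after 4 rounds = 0.08, P(h > 0.6) = 0.01
  Var(h) = 0.040: mean h after 4 rounds = 0.29, P(h > 0.6) = 0.23
  Var(h) = 0.100: mean h after 4 rounds = 0.33, P(h > 0.6) = 0.25
```

Reading: at the fitted operating point (I₀ = 122.82, b = 46.68,
c₁ = 1.9×10⁻⁴, ξ = 0.72, δ = 1.26, one-day nuclease half-life) a single
transfection collapses copy number to ~7% of baseline within about 3.6 days
before feedback control restores it, and four rounds drive an
80%-heteroplasmy cell down to h ≈ 0.05.  The same protocol applied to cell
populations with identical mean h = 0.8 but increasing variance is
dramatically less effective — near-homoplasmic cells at either extreme
barely move — so the heteroplasmy *distribution* decides treatability.

The other scripts in `examples/` each demonstrate one capability (control
laws and calibration, stochastic drift and the cellular-mean vs homogenate
distinction, LNA variance structure, cost landscapes, optimal mutant
sensing, Bayesian refitting), and every one prints the numbers it computes
with a line on what they mean.

There is also a thin CLI over the same library calls
(`mitoctrl simulate|lna|cost-map|optimize|treat|infer|synth`); each run
writes its artifacts as CSV/JSON next to a `provenance.json` recording the
exact configuration and seed.

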