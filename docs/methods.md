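# Methods

This note records the modelling assumptions, parameter conventions,
numerical choices and known limitations behind `amynet`. It states no
empirical result that the test suite and `scripts/acceptance.py` do not
themselves compute.

## Model hierarchy and assumptions

The package implements one family of discrete aggregate-size models at
four levels. Common assumptions throughout:

- Dimers are the nucleus: sizes are tracked from *i* = 2 upward. Larger
  nucleus sizes would lengthen the lag phase but are not implemented.
- Rate constants are size-independent ensemble averages. Fragmentation,
  depolymerisation and fibril–fibril association are omitted; for Aβ42 the
  mass growth is dominated by elongation plus primary and secondary
  nucleation, with secondary nucleation saturating in a Michaelis–Menten
  fashion.
- **In vitro** the system is closed: total mass m + M is conserved, and
  secondary nucleation saturates in the *monomer* concentration,
  σ(m) = K_m/(K_m + m²). The (m, P, M) moment system closes *exactly*
  (every master-equation term depends on the distribution only through m,
  P, M), so moment trajectories are truncation-free ground truth.
- **In vivo** the monomer pool is homeostatic (dm/dt = 0) and secondary
  nucleation saturates in the aggregate *mass*, σ(M) = K_M/(K_M + M²),
  with K_M = K_m by default. Clearance is first-order per size class.
  Primary nucleation switches to the homogeneous convention k_n m²
  (see unit conventions below) and is off by default in seeded runs,
  where its contribution is negligible; it is on by default in the damage
  model, where the nucleation-fed trickle of mass is precisely what erodes
  clearance over long times.

## Parameters and unit conventions

Reference kinetics (Aβ42 in HEPES buffer), molar-hour units: k_n = 1.6e-11
M/h, k_2 = 2.1e14 M⁻²h⁻¹, K_m = K_M = 2.3e-17 M², k_+ = 1e10 M⁻¹h⁻¹,
m_0 = 3e-6 M.

All bundled fixtures work in **micromolar-hour** units — the molar values
rescaled by c = 10⁶ (k_2 = 210, k_+ = 1e4, K_M = 2.3e-5, m_0 = 3) — because
every figure-scale clearance rate, damage coefficient and toxic mass in
the literature this package engages with is quoted on that scale.
Rescaling maps k_2 → k_2/c², k_+ → k_+/c, K → K·c², m_0 → m_0·c, and
k_n → k_n·c (constant-source convention) or k_n/c (homogeneous). Every
pure-rate observable (critical clearance, halftimes) is invariant under
the rescaling to 1e-10 relative; trajectories map by scaling all
concentrations by c (both properties are tested).

**The two k_n conventions.** The in vitro model uses a constant
heterogeneous source 2k_n (units concentration/time); the in vivo models
use homogeneous nucleation k_n·m² (units 1/(concentration·time)). The same
numeric table value is reused under both readings, so
`KineticParameters` carries a `kn_convention` tag and the in vivo solvers
refuse `include_kn=True` unless the tag is homogeneous — re-tag *before*
rescaling (`ab42...(scaled=False).with_convention("homogeneous")`, then
rescale), which gives k_n = 1.6e-17 µM⁻¹h⁻¹.

**Damage coefficient β.** dλ/dt = β·M·(μ − λ) requires β in
1/(concentration·time); in scaled units the bundled damage fixture uses
β = 1e11, a free parameter of the model.

**Therapy time units.** Dosing parameters (elimination rate A = 1,
interval B, horizon t_max = 28) share one nominal time unit with the
kinetic rates. Because the kinetic relaxation rate near the diseased
equilibrium (~λ, i.e. 10–35 per unit time for the bundled regimes) is fast
relative to B, the cycle-averaged mass depends essentially only on the
shape of λ(t) — verified by the quasi-static oracle test, which compares
the driven trajectory against M₂(λ(t)) outside a boundary layer of ~1/λ
after each dose. This is why the reported averages are insensitive to
whether "days" or "hours" label the dosing axis.

## Fixed points and thresholds

Steady states obey p*_i = δ_i p*_{i−1} with δ_i = a₀/(λ_i + a₀),
a₀ = 2k_+m_0. With Δ_i the cumulative product and Δ = Σ k·Δ_k, the dimer
balance — the only equation in which the saturation factor appears —
inverts exactly:

    M* = √( K_M (k_2 m_0² Δ − λ₂ − a₀) / (λ₂ + a₀) ),   p*_2 = M*/Δ.

No numerical solve is needed; saturation does not spoil the closed form.
For constant clearance this reduces algebraically to the moment-system
fixed point M₂ (geometric sum Σ k δ^{k−2} = (2−δ)/(1−δ)²), and the
diseased state exists iff the radicand is positive, i.e.

    λ < λ* = k_2 m_0² + √(k_2 m_0³ (k_2 m_0 + 2 k_+))   (exact boundary),

which for the reference kinetics is 12 705.4 h⁻¹. The package *also*
provides the conventional closed-form threshold expression

    λ_crit = k_2 m_0² + √(2 k_2 m_0³ (k_2 m_0 + k_+)) = 12 869.3 h⁻¹,

as `critical_clearance(..., "constant")`; the two differ by a factor of 2
on the smaller term under the radical, about 1.3% here. The bisection
acceptance check verifies that the empirical ODE bifurcation coincides
with the exact boundary to better than 0.5%, and that the conventional
closed form sits within 2% of it. Size-dependent families: λ_i = iλ₀ uses
the closed form (k_+k_2m_0³ − 1)/(k_+m_0 − k_2m_0²) — note the "−1" is
dimensionally inconsistent and the expression is kept as a documented
convention, with the numerical bifurcation machinery available as the
ground truth; λ_i = λ₀/i uses 2a(a + 4k_2m_0²)/(a + k_2m_0²) ≈ 2a with
a = 2k_+m_0.

**Interval targeting.** Under a sustained clearance window
[n₀, n₁] (rates λ_a + λ_drug inside, λ_a outside), the equilibrium mass
increases monotonically as the window moves to larger sizes: suppressing
small aggregates also chokes the elongation flux into every larger size.
This is the operative therapeutic statement and is tested as such. The
*static* measure — the equilibrium mass Σ k Δ_k p*₂ held inside a window
of the *untreated* distribution — behaves differently: k·p*_k peaks near
size a₀/λ, so among equal windows the lower one holds more mass only
beyond that size and the ordering reverses below it. With the reference
kinetics a₀/λ ≈ 60 at λ = 10³, so the reversal regime covers the oligomer
range; both behaviours are asserted in the tests.

## Numerical choices

- **Truncation.** Size-resolved systems truncate at N with a *reflecting*
  boundary: size N gains from elongation of N−1 but neither elongates
  further nor consumes monomers doing so. This conserves mass exactly at
  any N. A runtime diagnostic rejects runs in which the top two size
  classes ever hold more than 1% of the aggregate mass; callers who only
  need integral quantities (e.g. decay-to-zero verdicts in supercritical
  runs, where the distribution marches rightward forever) can disable it
  explicitly. The truncated system's own fixed point differs from the
  analytic recurrence only in the top bin (no elongation loss there), so
  distribution comparisons exclude it.
- **Solvers.** LSODA with rtol 1e-8 and atol 1e-12·m_0 for local models
  (recorded in trajectory metadata); BDF with a sparse Jacobian pattern
  for the network system. The damage solvers give the moments their own
  absolute floor (1e-6·k_n m_0²) because the nucleation-fed quiescent mass
  can sit twenty decades below the clearance variable.
- **Positivity.** The in vitro constant source switches off below m = 0
  (otherwise the printed model drifts to negative monomer concentrations
  after depletion). Solver excursions in [−1e-12·m_0, 0) are clipped to
  zero with a warning; anything lower aborts the run.
- **Equilibrium sums.** `equilibrium_distribution` grows the truncation
  (up to ~2·10⁶ sizes, vectorised cumulative products) until
  N·Δ_N < 1e-8·Δ; an explicit N is honoured verbatim for like-for-like
  comparison with a solver run. Heavy polynomial tails (the inverse-size
  family near its threshold, where Δ_k ~ k^{−λ₀/a₀} with exponent barely
  above 2) cannot be converged at any affordable N; such cases are
  reported as a failed convergence condition rather than silently
  truncated, and the inverse-size consistency test instead checks
  supercritical decay.
- **Dosing steady state.** Cycles are integrated one period at a time (so
  dose discontinuities land on solver restarts) until successive cycle
  maxima agree to 1e-6 relative, with a floor of 20 cycles; the final
  cycle is re-integrated on a dense (2049-point) grid, and the cycle
  average is trapezoidal with a grid-halving consistency check at 1e-4.
- **Optimizer.** The dose budget is linear in λ_drug, so each inter-dose
  interval B on the grid determines λ_drug by exact division; the sweep
  (default 41 points over [0.2, t_max]) is therefore the full constraint
  contour, and the minimizer is read off it. No stochastic optimization
  is involved.
- **Bisection for the empirical threshold** classifies a seeded moment run
  as invaded if its late-time mass (t = 2, by which the slowest nearby
  modes have e-folded dozens of times) exceeds 1e-6·m_0, and brackets the
  transition to 1e-4 relative.

## Synthetic connectome

Real structural connectomes (tractography-derived) are out of scope. The
generator emulates their topology class: a Watts–Strogatz small-world
backbone (default 40 nodes, mean degree 6, rewiring 0.1) with i.i.d.
log-normal edge weights (heavy-tailed, positive), redrawn until connected,
fully determined by one RNG seed. The first nodes carry anatomical-style
labels (posterior_cingulate, entorhinal, …) so canonical seeding scenarios
map onto the fixture, and a peripheral "frontal_pole" node with a single
weak edge (1% of the median weight) is anchored at maximal hop distance
from the designated seed node — mirroring the anatomy in which the frontal
pole is sparsely connected and remote from posterior seeding sites, and
giving the generator a guaranteed "invaded last" region. What the
synthetic graph does **not** reproduce: anatomical geometry, hemispheric
symmetry, tract-length-dependent weights, or the degree distribution of
any specific atlas — network conclusions validated here are claims about
the topology class, not about a particular brain parcellation.

## Study conditions used by the tests

- Full-rate in vitro kinetics produce mean fibril sizes of order 10⁴
  monomers; resolving that distribution is pointless when the moment
  system is exact. Size-resolved in vitro checks therefore run with
  elongation slowed 1000× (all other constants unchanged), which puts the
  entire distribution within a few hundred size classes; all full-rate
  claims (sigmoid saturation, halftimes and their parameter
  sensitivities) are tested on the moment system.
- The subcritical showcase clearance λ = 10 implies an equilibrium size
  scale a₀/λ = 6000, so trajectory-level tests at that clearance use the
  (exact) moment closure; size-resolved/fixed-point cross-checks use
  λ ≥ 10³, where the distribution fits in a few hundred sizes.
- Network tests run on 6–30-node synthetic graphs with N = 8–150 size
  classes — large enough for hop-distance-ordered invasion fronts and
  small enough that the full battery runs in about a minute.

## Limitations

- No spatial structure below the region level; no stochastic kinetics
  (deterministic concentrations only).
- No clearance recovery: damage only decays λ toward μ.
- Monomer production is homeostatic; interventions on production (e.g.
  APP-processing inhibitors) are outside the model.
- The pharmacokinetics is a single-exponential elimination; the dose
  budget C_max is a proxy for cumulative side-effect risk, not a safety
  model.
- The linear-in-size critical-clearance expression is kept in its
  conventional (dimensionally inconsistent) printed form; treat it as a
  convention and prefer the numerical bifurcation tools where it matters.
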