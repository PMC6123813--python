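# Methods

## The forward model

A membrane region contains receptors at total surface density
[T] = [D] + [A] (receptors/µm²), a fraction x_D = [D]/[T] carrying the
donor fluorophore and x_A = 1 − x_D the acceptor. Receptors partition
between free monomers and a single n-mer species by mass action:

    [T] = [m] + n K [m]^n,      µ_oligo = K [m]^n,
    f_oligo = n µ_oligo / [T].

We deliberately model one oligomeric species at a time (no mixed
dimer + cluster populations): the order n is a model-selection variable,
not a mixture component. The conservation law above is the closure that
makes the equilibrium well-posed; its unique nonnegative root [m] is
found by bisection on [0, [T]] (80 iterations, i.e. resolved far beyond
the 1e−12 relative tolerance we require), vectorised across regions.

Donors inside an n-mer are quenched by the acceptors of the same n-mer.
With labelling binomial in (x_D, x_A) and a single pairwise efficiency Ẽ
for every donor–acceptor pair in the oligomer, the donor-averaged
efficiency from specific association is

    E_oligo = f_oligo/(n x_D) · Σ_{k=1}^{n−1} [k(n−k)Ẽ / (1+(n−k−1)Ẽ)] C(n,k) x_D^k x_A^{n−k}.

The k-th term is the probability-weighted transfer of the k donors in an
oligomer with n−k acceptors: a donor facing a acceptors transfers with
efficiency aẼ/(1+(a−1)Ẽ) (parallel rate pathways, radiative rate
normalised to 1). The tests verify this sum against a brute-force
enumeration over all 2^n label assignments for every n ≤ 6. Ẽ relates
to the fluorophore separation d through Ẽ = 1/(1+(d/R0)^6); the default
Förster radius is 54.5 Å (mTurquoise/eYFP). In all kinetic-theory sums
Ẽ is clamped to [1e−6, 1−1e−6] to keep the denominators finite at the
edges of the open interval.

The apparent (measured) efficiency adds the proximity-FRET background,
weighted by the donor fraction not in oligomers:

    E_app = E_oligo + (1 − f_oligo) · E_prox([A]).

The weighting by (1 − f_oligo) is a design choice of this package:
oligomerised donors are considered saturated by their intra-oligomer
acceptors, free donors feel the random acceptor field. It is isolated
behind `apparent_fret` so an alternative combination rule can be swapped
in without touching anything else.

## Proximity FRET

Proximity FRET is simulated donor-centrically: acceptors form a 2D
Poisson field of density ρ in an annulus around one donor, between a hard
exclusion radius (default 10 Å, the scale of a fluorescent-protein
barrel — fluorophore size is what removes the analytic solution) and a
cutoff of 10·R0 (the neglected tail of the r^−6 sum is < 1e−6 at the
highest tabulated density). Rejecting hard-core overlaps of a uniform
disc process is equivalent to Poisson sampling on the annulus, which is
what the code does. Per configuration E = S/(1+S), S = Σ(R0/r_i)^6; the
mean over 2×10⁴ independent configurations is tabulated at 41 densities
on [0, 8000] receptors/µm² (Monte-Carlo SE < 0.002 everywhere; ~2 s of
runtime). Donors do not compete for acceptors and there is no
donor–donor energy migration. Lookups interpolate linearly and refuse to
extrapolate. One root seed drives per-density spawned streams, so tables
are bit-reproducible. The tests check the simulator two independent
ways: against the leading-order pairwise quadrature in the sparse limit,
and against a characteristic-function double quadrature
(E[S/(1+S)] = 1 − ∫e^−t exp(−ρ∫(1−e^{−t(R0/r)^6})2πr dr)dt) at working
densities.

## Fitting

For each n in 2…6 the model E_app is evaluated on a grid — Ẽ from 0.01
to 0.99 in steps of 0.01, and the association strength on 61 log-spaced
nodes — and the mean squared residual against the measured efficiencies
is minimised over the grid. The MSE is computed on raw per-region
points, not on binned averages. Because K carries units that depend on n,
the 61-node axis is parametrised by the *half-saturation density* (the
total density at which f_oligo = 1/2), log-spaced over 0.1–10⁵
receptors/µm²; for a dimer this density equals K_diss exactly, and it
maps to an order-specific K for n > 2. This keeps the searched physical
regime identical across orders.

Order selection reads the MSE-vs-n profile with a relative tie tolerance
of 2% (the experimental resolution of "the same MSE"): a strict minimum
at n = 2 → dimer; a minimum at n > 2 → cluster; a profile flat across
all orders → cluster (large oligomers fit as well as anything; some
dimers cannot be excluded); a minimum at n = 2 with only some higher
orders tied → ambiguous. Exact ties resolve to the larger order.

The selected order's grid optimum seeds a nonlinear least-squares
refinement in (Ẽ, ln K) (trust-region reflective; the log
parametrisation is for conditioning only). Refinement can only decrease
the grid-best residual. 95% confidence intervals are linearised (Wald):
the Jacobian is mapped back to the (Ẽ, K) scale, the covariance is
σ²(JᵀJ)⁻¹ with σ² = SSR/(N−2), and the interval is the estimate ±
t₀.₉₇₅,N−₂ × SE. K_diss = 1/K inherits its interval by the reciprocal
transform of the K endpoints; if the K interval reaches zero (saturated
data that cannot constrain binding strength) the K_diss upper bound is
reported as unbounded and the fit is flagged. ΔG = RT ln(K_diss/K⁰_diss)
uses R = 1.9872×10⁻³ kcal/(mol·K), T = 298.15 K by default
(configurable; no measurement temperature is assumed), and the standard
state K⁰_diss = 1 receptor/nm² = 10⁶ receptors/µm².

Between-condition comparison of K_diss uses Welch's t-test: each
condition's SE is recovered from its 95% CI half-width using the t
quantile at (number of independent experiments − 1) degrees of freedom —
replicate counts must be supplied, they are never assumed — with
Welch–Satterthwaite degrees of freedom and Bonferroni multiplication of
the two-sided p-value.

The linearity diagnostic restricts to regions with [T] above 100
receptors/µm² (where f_oligo is near saturation and E depends mainly on
x_A), bins by acceptor fraction, and compares a through-origin line with
a through-origin quadratic on the bin means by an F-test at α = 0.05.
For a saturated dimer E = Ẽ·x_A exactly, so the linear verdict's slope
estimates Ẽ; clusters give a convex dependence and a nonlinear verdict.
Testing on bin means (not raw points) matches how such plots are read
and keeps the test's power aimed at real curvature rather than at the
micro-structure of the noise. The diagnostic requires at least two
donor:acceptor transfection ratios; with one ratio the acceptor fraction
has no usable span and the design is rejected.

## Synthetic data

The generator emulates the structure of spectral-imaging FRET data from
transiently transfected cells. Defaults define the study conditions:
286 cells × 3 regions = 858 points per condition (nominally pooled from
4 independent experiments); per-cell mean expression log-uniform on
[10, 3000] receptors/µm² with a log-normal σ = 0.25 region-to-region
spread; donor fraction per cell drawn from a Beta distribution centred
on the transfection ratio (concentration 100, emulating binomial
labelling jitter); additive Gaussian efficiency noise σ_E = 0.05
(absolute, clipped to [0,1] after addition); independent multiplicative
log-normal noise of σ = 0.10 on each recorded density. The ratio-series
generator concatenates 3:1, 1:1 and 1:3 designs for the linearity
diagnostic. Everything is deterministic under a seed.

What the generator does *not* emulate: pixel-level spectral unmixing
noise, cell-to-cell biology (expression-correlated behaviour), membrane
curvature artefacts, or correlated donor/acceptor measurement errors.
Passing tests therefore demonstrate that the pipeline recovers truth
under the assumed noise structure, not that the noise structure is the
instrument's.

## Known limitations and numerical behaviour

* The fit treats recorded densities as exact (errors-in-variables
  handling is out of scope). Multiplicative concentration noise
  therefore attenuates estimates slightly — at default noise the fitted
  K_diss runs ~5–10% below truth — and at very strong binding
  (K_diss ≈ 10 receptors/µm², where nearly all sampled regions are far
  above half-saturation) it flattens the MSE-vs-n profile to within the
  2% tie tolerance, so order selection saturates at its resolution limit
  there. Dissociation-constant recovery for a dimer truth is therefore
  quantified with the dimer-model fit; order selection is validated in
  the regimes where the profile is informative (dimer at
  K_diss ≈ 200/µm², hexamer spanning f ≈ 0.5–0.95), where it is correct
  in ≥ 9/10 seeds.
* MSE model selection cannot pin the exact cluster order when the
  profile is flat; classification, not the numeric n, is the robust
  output in that regime.
* Wald intervals are symmetric in K and can be poor far from the
  Gaussian regime (few informative points, parameter near a bound); the
  saturated-data flag catches the worst case. Profile or bootstrap
  intervals are a possible extension.
* The proximity model is a documented stand-in at the same limits as the
  measurement-era simulations it replaces in spirit: 2D, hard exclusion,
  no acceptor–acceptor correlation beyond the core, no donor
  competition.

## Problem sizes

Default problem sizes are the study conditions themselves: 858 regions
per synthetic condition, 10 seeded replicates per recovery experiment, a
41-density × 2×10⁴-realisation proximity table. The full test suite and
the acceptance script each run in well under a minute on one CPU.
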