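# Methods

## Model and assumptions

A planar interface at z = 0 separates an electrolyte (dielectric constant
εw, monovalent 1:1 salt of bulk density n₀, Debye length
lD = [εwε₀kBT/(2e²n₀)]^(1/2), half-space z > 0) from a salt-free medium of
dielectric constant εl (z < 0). N elementary charges sit *on* the interface
with average density σ₀ = ±eN/A; the sign never matters because every
output is quadratic in σ₀. The treatment is linear Debye-Hückel theory:
valid for small potentials (weak charging), no ion-ion correlations, no
finite ion size, point-like interfacial charges exactly in the interface
plane. Charges are modelled in a cylindrical Wigner–Seitz cell of radius R
with πR²σ₀ = e; short-range liquid-like order is enough for the cell
picture, no lattice is assumed.

Within a cell the charge is a uniform disk of radius r₀ and density
σ̄ = σ₀(R/r₀)², so the cell-averaged density is σ₀ for every r₀; r₀ → 0
realizes discrete point charges. All solvers work with the three
dimensionless groups r₀/R, λ = lD/R and η = εl/εw; the potential scale
Φ₀ = σ₀lD/(ε₀εw) and the free-energy scale F₀/A = σ₀²lD/(2εwε₀) carry the
units and enter only in the conversion layer.

## Series solution in the cell

No-flux side walls select the Bessel modes J₀(yₙr/R) with J₁(yₙ) = 0,
y₀ = 0. The zero table is produced by Newton iteration on J₁ seeded with
the McMahon asymptotic (n + 1/4)π − 3/(8β) − …, refined to |J₁(yₙ)| < 1e-12
with a bracketed-bisection fallback, cached and bitwise reproducible; the
test suite cross-checks the table against an independent library routine.
Every interface quantity is then a mode sum over the shared screening
denominator D(yₙ) = sqrt((yₙλ)² + 1) + ηλyₙ. The disk charge contributes
σₙ/σ₀ = (2R/r₀)J₁(yₙr₀/R)/(yₙJ₀(yₙ)²) for n ≥ 1; at r₀ = R these vanish
*identically* (J₁(yₙ) = 0 by construction), which the code short-circuits
so the uniform-cell identity Φs/Φ₀ ≡ 1 holds at machine precision rather
than to root tolerance.

Mode sums are accumulated in fixed order with exact compensated summation
(`math.fsum`); by default the truncation is chosen adaptively by doubling
the mode count from 64 until the result moves by less than `rel_tol`
(default 1e-6) on the O(1) scale of the scaled fields, capped at `n_max`.
The point-charge series (coefficients → yₙ) converges only conditionally:
its raw partial sums at cutoff n oscillate with the n-th term's envelope
(∝ n^(-1/2)), so the evaluator smooths the tail of the partial-sum sequence
twice with a moving average spanning one oscillation period (~2/x modes at
radius x = r/R). This never reorders terms and reduces the residual to the
second derivative of the envelope; with the smoothing disabled the raw
fixed-order partial sum is returned. The value at the charge itself (r = 0)
is a true logarithmic divergence and is refused. The Heaviside convention
u(0) = 1/2 is adopted at the charge-step radius.

## Isolated disk: Hankel transform

The R → ∞ self-potential is a semi-infinite Hankel integral whose
integrand J₀(yx)J₁(yρ₀)/(ρ₀D(y)) decays only like 1/y² with two beat
frequencies x ± ρ₀. Two measures make it robust for all radii:

1. The slowly decaying asymptotic part, obtained by replacing 1/D(y) with
   its large-y limit 1/(λ(1+η)y), is split off and integrated in closed
   form via the Weber–Schafheitlin result
   ∫₀^∞ J₀(ay)J₁(by)/y dy = ₂F₁(−1/2, 1/2; 1; (a/b)²) for a ≤ b (and the
   swapped branch for a > b). The remainder decays absolutely like y⁻⁴.
   The same subtraction turns the point-charge (Stillinger-type) integral
   into ∫₀^∞ J₀(xy) dy = 1/x plus an absolutely convergent remainder.
2. The remainder is integrated over subintervals bounded by the *merged*
   zeros of both Bessel factors — on such intervals the integrand has one
   sign, so the subinterval contributions alternate strictly — and the tail
   is summed with an Euler-type iterated-averaging acceleration whose own
   error estimate must meet max(rtol·|I|, atol) (defaults 1e-6, 1e-8); the
   tail depth deepens up to 4× before the evaluator raises. A plain
   truncated fallback (cutoff y ≈ max(400, 50R/r, 50R/r₀, 50R/lD)) exists
   for cross-checking the acceleration.

The far field obeys the screened-Coulomb + dipole asymptote
(1/2)(R/lD)²[(lD/r)e^(−r/lD) + η(lD/r)³]. Two practical caveats, both
visible in the tests: the asymptote is approached with an η-independent
~(lD/r)² correction (≈ 2.4% at r = 20lD), and for very small η the screened
Coulomb term still contaminates r ≈ 10lD, so the −3 dipole log-log slope
within ±0.1 holds on [10lD, 40lD] for η ≈ 0.1 but only beyond ~20lD for
η = 0.01. Note also that with η > 0 nothing decays exponentially through
the lower medium: the r⁻³ tail is the decisive long-range physics.

## Free energy

Charging each disk against the potential of all other cells,
ΔΦs = Φs − Φs_self, gives after the radial integrals

F/F₀ = 1 + (R/r₀)²[ Σₙ (2J₁(yₙr₀/R)/(yₙJ₀(yₙ)))²/D(yₙ)
                    − ∫₀^{y_nmax} 2J₁(yr₀/R)²/(yD(y)) dy ].

Sum and integral diverge separately as the cutoff grows; only the
difference at a *shared* cutoff y_nmax is meaningful. The implementation
therefore accumulates per-mode differences: mode n contributes its series
term minus the integral over [yₙ₋₁, yₙ] (16-point Gauss–Legendre per
subinterval, ample for the slowly varying integrand on the π-wide spacing),
and the pairs are fsum-accumulated. Each call also reports a truncation
estimate from comparing against half the cutoff. An independent route —
direct Gauss–Legendre quadrature of (2/ρ₀²)∫₀^{ρ₀}x·ΔΦs(x)/Φ₀ dx built
from the cell series and the Hankel transform — agrees with the closed
form to better than 0.5% and serves as the oracle in tests; replacing ΔΦs
by the full Φs at r₀ = R reproduces F/F₀ = 1 exactly (the self-energy
bookkeeping check).

**Point-charge limit.** F/F₀ is flat in r₀ near zero (the derivative of
J₁(r₀y)/r₀ with respect to r₀ vanishes at r₀ = 0), so the limit is reached
at small finite r₀. The procedure starts at r₀ = 0.05·min(R, lD) with
n_max = ceil(5R/r₀) and halves r₀ until successive ratios agree to
`rel_tol` (default 1e-3) on the max(|F/F₀|, 1e-3) scale. Crucially, the
mode cutoff is refined *independently* at each r₀ (doubling until the
internal truncation estimate falls below 0.3·rel_tol): the truncation error
depends essentially on the product n_max·r₀/R, so halving r₀ while doubling
n_max in lockstep would leave it unchanged and converge to a biased value —
at lD/R ≲ 0.05 the bias is large enough to corrupt the fs(s) slope (2.35
instead of 2.50 between s = 1e-3 and 1e-4). The starting factors (0.05,
5R/r₀) tighten the r₀ ≲ 0.1R, n_max ≳ 3R/r₀ rules of thumb that suffice at
lD ≈ R.

**Scaled sweep.** One charge per cell ties the geometry to the density:
R/lD = (πs)^(−1/2) with s = lD²σ₀/e. Each sweep point reports
fs = (F/F₀)s² next to the continuum reference s². The crossover diagnostic
is the least-squares log-log slope (exact two-point slope for two points):
2 in the continuum, → 2.5 for any η > 0 at small s, with exponential
suppression replacing the power law at η = 0.

## Finite-difference cross-check

An axisymmetric five-point scheme discretizes the Debye-Hückel equation
above and the Laplace equation below the interface on a uniform grid
(defaults nr = 128, nz = 512 per side, z_max = 8·max(lD, R)): symmetry
stencil at r = 0, ghost-node Neumann wall at r = R, one-sided three-point
interface fluxes, sparse direct solve with a residual gate of 1e-8.
Two discretization choices matter more than stencil order:

- the far-field caps are Dirichlet 0 *above* (all modes screened) but
  no-flux *below* — the lateral-average mode is z-independent in the
  salt-free half-space, and a Dirichlet bottom cap would inject an
  O(R/z_max) flux error (~10% at z_max = 10R);
- the step charge is control-volume averaged onto the radial grid; pointwise
  sampling misplaces the disk edge by up to one cell, loses O(hr) of the
  total charge and biases the whole profile by ~1%.

With these, the uniform-cell solution is exact to ~1e-4, z-refinement shows
clean second order, and the series profiles agree to within 1% (worst point
at the charge-step kink; ~0.3% elsewhere) for η ∈ {0, 1, 2}.

## Defaults and parameters at a glance

| parameter | default | meaning |
|---|---|---|
| `SeriesControl.n_max` | 4096 | mode-truncation cap (adaptive runs may stop earlier) |
| `SeriesControl.rel_tol` | 1e-6 | adaptive-doubling stop, O(1) scale |
| Hankel `rtol` / `atol` | 1e-6 / 1e-8 | tail-acceleration error gate |
| point-charge `rel_tol` | 1e-3 | r₀-halving and cutoff-refinement gate |
| point-charge start | r₀ = 0.05·min(R, lD), n_max = 5R/r₀ | safety-factored heuristics |
| `GridSpec` | nr 128, nz 512+512, z_max 8·max(lD, R) | cross-check grid |

Problem sizes used by the shipped checks: the fs(s) sweep down to s = 1e-4
(mode counts up to ~3.6e5, seconds on one core); the verification suite
uses nr = 161, nz = 768 grids (~5e5 unknowns per solve). Everything is
deterministic — there is no randomness anywhere in the artifact, and the
acceptance script's `--seed` exists for interface uniformity only.

## Limitations

- Linear Debye-Hückel only: no nonlinear Poisson–Boltzmann saturation, ion
  size, or correlation effects; quantitative validity requires small
  surface potentials (|Φ| ≲ kBT/e).
- Charges exactly in the interface plane; no off-plane placement, bilayer
  (two-interface) geometry, or non-axisymmetric charge patterns.
- Free energy is the electrostatic charging term of the cell model; no
  lateral entropy of the charges, inter-plate pressures, or charge
  regulation.
- Whether F/F₀ can exceed 1 for η > 1 at intermediate lD/R is reported but
  not asserted either way; the shipped bound tests restrict to η ≤ 1.
- The Wigner–Seitz cell approximates the neighbour environment as an
  axisymmetric annulus; against explicit lattice sums the model inherits
  the usual cell-model accuracy, which the package does not quantify.
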