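# Methods

## The model

helixfit describes the thermal denaturation of a single-domain polypeptide
as a helix–coil transition in a Zimm–Bragg chain whose stability weight is
renormalized by competition with polypeptide–water hydrogen bonding.  Each
of the `N` repeat units is helical (weight `s`) or coil (weight 1), with a
nucleation penalty `σ = 1/Q` per helix–coil junction.  The transfer-matrix
eigenvalues are

    λ₁,₂ = ½ [ 1 + s ± √((1 − s)² + 4σs) ],

with Vieta identities `λ₁ + λ₂ = 1 + s`, `λ₁λ₂ = s(1 − σ)`.

Tracing out the water degrees of freedom renormalizes `s`.  A water molecule
adjacent to a broken intra-chain bond can hydrogen-bond to the chain in one
of its `q` orientations (`q = 16` for water); the fraction of bonded
orientations is

    X(T) = e^{β h_ps} / (q − 1 + e^{β h_ps}),

and the renormalized stability parameter is

    s̃(T) = (1/Q) [ (A + (B − A)/q)^{-2} − 1 ],
    A = e^{−β h},  B = e^{β (h_ps − h)},

where `h` is the intra-chain N–H···C=O bond energy, `h_ps` the
chain–solvent bond energy (both J/mol), and every Boltzmann exponent uses
the same effective inverse temperature

    β(T) = 1 / (R (T − t₀)),   R = 8.314 J mol⁻¹ K⁻¹.

The glass-transition temperature `t₀` encodes the non-Arrhenius behaviour of
hydrogen-bond statistics in the supercooled solvent; the model is defined
for `T > t₀` only, and fits constrain `t₀` below the lowest data
temperature.  The inner bracket collapses to
`A (q − 1 + e^{β h_ps})/q`, so `log W` (with `W` the squared reciprocal) is
evaluated entirely with `logaddexp`; a single exponential convention feeds
every weight and every derivative.

One consequence worth knowing: `W < q² = 256` whenever `h_ps > h`, so
helix content (`s̃ ≥ 1`) requires `Q < q² − 1 = 255` in water.  The default
fitting bound `Q ∈ [1, 300]` comes from this, not from data.

### Observables

* **Partition function.**  Finite chains use the fixed-boundary closed form
  `Z = [(1 − λ₂)λ₁^N + (λ₁ − 1)λ₂^N]/(λ₁ − λ₂)` with `λ₁^N` factored out
  (`ln Z` is the canonical return; no overflow up to `N = 10⁶`), switching
  to the analytic confluent limit `Z = λ^{N−1}(λ + N(1 − λ))` when the
  eigenvalues are degenerate to 1e−10 relative.  This convention gives
  `Z(N = 1) = 1` identically — a single unit cannot close a hydrogen bond.
  Long chains use `ln Z = N ln λ₁`.
* **Helicity.**  `θ = ((s̃ + σ)/N) ∂lnZ/∂s̃`, whose long-chain limit is the
  closed form `(s̃ + σ) ∂lnλ₁/∂s̃`.  The prefactor is `(s̃ + σ) = W/Q`, the
  full helix weight; it is computed directly from `log W` so that `θ → 0`
  exactly (no cancellation) in the coil limit `s̃ → −σ`.  All s̃-derivatives
  of `ln Z` are analytic closed forms; finite differences appear only as
  test oracles.
* **Energy and heat capacity.**  The mean bonding energy per chain is
  `E = −2N [hθ + h_ps X (1 − θ)]`, which is exactly the β-derivative of the
  solvent-dressed log partition function (chain part plus the per-unit
  solvent background `(q − 1 + e^{βh_ps})/q` squared).  The heat capacity
  is its exact temperature derivative,

      C = −2N h θ′ − 2N h_ps X′ (1 − θ) + 2N h_ps X θ′,

  with `θ′` and `X′` analytic.  DSC results are reported per amino acid
  (`C/N`).  The model computes a configurational heat capacity; comparing
  it with (baseline-subtracted) DSC data invokes the usual condensed-phase
  reading that the constant-volume and constant-pressure excess heat
  capacities coincide.
* **Melting temperature.**  `T_m` solves `θ(T) = ½` on the heat-denaturation
  (decreasing) branch, by bracketing bisection to 1e−4 K.  Re-entrant
  parameter sets (`h_ps > h`) also cross ½ upward at low temperature (cold
  denaturation); that root is not reported.

### Numerical choices

* `log W` is clipped at ±300.  For `|h| ≤ 10⁵` J/mol at `T − t₀ = 1` K the
  true `ln W ≈ 24000` is unrepresentable as `W`; inside the clip every
  observable is exact to double precision, beyond it `θ` is pinned at 0 or 1
  to within 1e−129 and only `ln Z` loses accuracy.  All outputs stay finite.
* `λ₂` is computed from the Vieta product `s(1 − σ)/λ₁` and `λ₂′` from the
  conjugate-difference identity `2σ(1 − σ)/(√D (√D + s − 1 + 2σ))`; the
  textbook difference forms cancel catastrophically for `s̃ ≫ 1`.
* `λ₂/λ₁` may be slightly negative for `s̃ ∈ [−σ, 0)`; powers carry the
  sign explicitly.

## Fitting

`scipy.optimize.least_squares` (trust-region reflective, numeric Jacobian,
max 2000 evaluations) minimizes unweighted squared residuals between the
data and the mode's model curve — long-chain `θ` for `cd_long`, finite-chain
`θ` for `cd_short`, per-residue `C` for `dsc` (the per-chain data are
divided by `N`, which is why `N` must be supplied).  `q` is fixed (16 for
water, overridable for other solvents).

Optimization runs in a normalized space,
`z = [log(T_min − t₀), h/1000, h_ps/1000, log Q]`, which brings all
coordinates to O(1)–O(10), enforces `t₀ < min T` and `Q > 0` by
construction, and keeps the exponentials overflow-free.  Default starting
values are `t₀ = min T − 100 K`, `h = 4000`, `h_ps = 4500` J/mol,
`Q = 100`; default bounds are `t₀` 10–500 K below the data, energies
0.5–20 kJ/mol, `Q ∈ [1, 300]` (see above).  If the first solve fails or is
flagged `LOW_R2`, five deterministically jittered restarts are tried and the
best R² kept — single-curve fits of this model genuinely depend on the
start, and restart-plus-R²-monitoring is the working remedy.

The covariance is the residual-variance-scaled Gauss–Newton matrix in `z`,
delta-mapped to physical units; percent errors are `100·SE/|estimate|`.
Two warning codes are attached with strict thresholds: `PARAM_ERROR` when
any percent error exceeds 50%, `LOW_R2` when `R² < 0.5`.

A caution on interpretation: a single helicity sigmoid constrains roughly
three shape features, so the four-parameter CD fit is sloppy — wide flat
valleys in (t₀, h, h_ps, Q) reproduce the curve almost equally well, and a
Cramér–Rao analysis puts free-fit uncertainties at 10–25% per parameter for
typical windows at noise 0.01.  The physical bounds above, and data windows
that include curvature beyond the bare sigmoid (see below), are what make
the parameters identifiable.  DSC is much better conditioned because the
peak amplitude pins the energies directly.

## Synthetic data

The generator evaluates the forward model on a uniform temperature grid and
adds seeded homoscedastic Gaussian noise — exactly the assumption of the
unweighted least-squares objective.  It emulates preprocessed data only
(normalized CD helicity, baseline-subtracted DSC excess heat capacity);
instrument baselines, deconvolution residuals, heteroscedastic noise and
multi-domain signatures are out of scope, so passing recovery tests say
nothing about those preprocessing steps.

The default cooperative fixture was designed once, by forward analysis
(melt shape plus Cramér–Rao conditioning), and then frozen:

* truth `t₀ = 220 K`, `h = 4600`, `h_ps = 4900` J/mol, `Q = 80`, `q = 16`
  (σ = 0.0125; energies in the polypeptide hydrogen-bond range, water
  slightly favored, hence a re-entrant θ(T) with a maximum at ≈328 K);
* CD window 290–420 K, 100 points, noise sd 0.01.  The window deliberately
  includes the low-temperature shoulder where θ still rises — that
  curvature is what conditions `t₀`, taking the worst-parameter
  Cramér–Rao bound from ≈22% to ≈5%;
* DSC window 335–425 K, 100 points, noise sd 2% of the per-chain peak
  (≈84 J mol⁻¹ K⁻¹ per residue at ≈392 K).  The window starts above the
  helix maximum because the cold-side dip of C(T) creates a local minimum
  that traps default-start optimizations;
* short chains use `N = 40`, the smallest round chain length for which the
  finite-chain fixture still has a single ½-crossing;
* fixture melting temperature `T_m = 386.23 K` (frozen regression value).

## Known limitations

* Finite-size agreement between the finite-chain and long-chain helicity is
  O(θ/(N√σ)) — a boundary effect of the fixed-end partition function, about
  6e−5 at `N = 10⁵` on the fixture and 1.6e−4 at the classic midpoint
  (s̃ = 1, σ = 0.001).  It cannot be made 1e−6 at `N = 10⁵` for any
  cooperative parameter set; tests freeze the exact oracle values instead.
* Cold denaturation is present in the model but deliberately unreported by
  `melting_temperature`, and no DSC fitting mode targets it.
* Single-domain, single-transition curves only; no multi-peak fitting.
* CD fits inherit the sloppiness discussed above: parameters from a single
  curve with flat-prior bounds should be read together with their percent
  errors, not as independent measurements.
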