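# Methods

## Scope and model

`despin` treats a two-site mixed-valent dimer with local spins
(s_a, s_b) = (5/2, 2) by default. Three interaction scales compete:

* **Heisenberg exchange J** (cm⁻¹, −2J S₁·S₂ convention; J < 0
  antiferromagnetic) sets the bare ladder −J S(S+1).
* **Double exchange B** (cm⁻¹, a magnitude — signed input is
  absolute-valued with a warning) splits each S into ± branches by
  2B(S+1/2), favouring high spin.
* **Vibronic coupling Λ = λ²/k₋** (cm⁻¹) of the antisymmetric PKS
  breathing mode traps the itinerant electron, favouring low spin.

Energies are referenced to the raw E±(S) values with no global shift;
every thermal quantity downstream is built from Boltzmann ratios and is
therefore shift-invariant. Ground-state ties at the exact crossings
|B/J| = 2(S+1) are broken toward the **lower** spin (and the − branch),
with a degeneracy flag on the result, so scans across a crossing are
reproducible to the grid resolution (default 10⁻³ in |B/J|, which resolves
the crossings to three decimals).

## Vibronic surfaces

The adiabatic surfaces are computed in the dimensionless PKS coordinate y:

    E±(S, y) = −J S(S+1) + (Λ/2) y² ± √(a y² + B²(S+1/2)²)

with a = Λ² (the `standard` normalization, the default). This choice is
fixed by two requirements: the electronic splitting at y = 0 must be
2B(S+1/2), and the B = 0 lower surface must trap at y = ±1 with depth Λ/2
— the standard PKS behaviour. A second rendering with a = Λ²/2,
corresponding to a literal reading of an ambiguous printed parenthesization
of the same expression, is available via `form="as_printed"`; both run
through identical closed forms parameterized by u = a/Λ:

* double well iff B(S+1/2) < u, with minima at y₀ = √(u² − c²)/√a and
  barrier (u − c)²/(2u), c = B(S+1/2);
* relaxed minimum energy min_y E₋ = E₋(0) − max(0, (u − c)²/(2u)).

Because the relaxation grows as c shrinks, vibronic coupling always
destabilizes the higher-S (larger-c) states relative to S = 1/2, which is
why intermediate spins require *small* Λ. Well topology maps onto the
Robin–Day classes: single well → class III (fully delocalized), double
well → class II (partially localized; the B = 0 case is flagged as fully
localized). The default coordinate grid is −3…3 with 601 points; all
minima of interest lie at |y| ≤ 1 and classification is analytic, the grid
serving plotting and cross-checks.

### Surface fixtures

The three [Fe₂Q₂]⁺ fixtures carry Λ = 2200, 1400, 1650 cm⁻¹ (S, Se, Te) —
DFT-derived values that are likely upper bounds, since equal nuclear
displacements were assumed for all three compounds. Susceptibility fits
constrain only r = |B/J| (2.0, 2.9, 3.7), not the absolute scale, so each
fixture carries its own (J, B): (−250, 500), (−30, 87), (−350, 1295) cm⁻¹.
These were chosen once, qualitatively: double exchange strengthens steeply
with delocalization across the series (class III mixed-valence dimers are
known with B above 10³ cm⁻¹), which is what lets the Te member reach a
single-well, well-isolated S = 3/2 ground surface while the S member stays
a class II double-well S = 1/2 system and the Se member sits near the
S = 1/2 / 3/2 crossing with a condensed low-spin ladder. They are
illustrative study conditions, not fitted quantities.

## Susceptibility

χ_M T of the ladder is the van Vleck / Boltzmann average over all ten
(S, ±) levels (60 magnetic states),

    χ_M T = C g² Σ (2S+1) S(S+1) e^(−E/k_BT) / Σ (2S+1) e^(−E/k_BT)

with C = N_A μ_B²/(3k_B) = 0.125049 cm³ K mol⁻¹ and
k_B = 0.6950348 cm⁻¹ K⁻¹. Weights are computed after subtracting the
minimum energy (overflow-safe). A single isotropic g is shared by all
ladder states. Limits used as test oracles: T → ∞ gives
C g² ⟨S(S+1)⟩ = C g² · 14.75; T → 0 with an isolated ground level gives
that level's Curie constant.

**Fitting.** The fitter parameterizes (J, r = |B/J|, g) with g fixed by
default (to the EPR g_iso of the complex at hand), restricts to T > 50 K,
and multi-starts lmfit's Levenberg–Marquardt over a grid of r values. The
50 K floor is deliberate: the vibronic-free ladder is knowingly wrong at
low temperature, where trapping reshapes the thermally accessible states,
so including T < t_min requires an explicit `allow_low_t` override. Over a
finite window the curve shape constrains r far better than J and B
separately; the result therefore carries a residual-norm profile over r
(J re-optimized at each fixed r), and a warning fires when J is
unconstrained. Diamagnetic/TIP corrections are assumed applied upstream;
synthetic data is generated already corrected.

## Magnetization and zero-field splitting

ZFS manifolds use H = D[S_z² − S(S+1)/3] + E(S_x² − S_y²) + μ_B **B**·g·**S**
with μ_B = 0.46686 cm⁻¹ T⁻¹ and E/D restricted to the canonical [0, 1/3]
(rotate the tensor first if outside). Magnetization is the thermal average
of the Hellmann–Feynman moment operator −∂H/∂B over the full eigensystem —
never a finite difference; a finite-difference free-energy derivative
serves as an independent test oracle (agreement to 10⁻⁶ relative). Powder
averages use a Fibonacci sphere grid (default 500 orientations; < 50 is
warned). Both the orientation average and the maximum over orientations
("main magnetization axis") are reported; the exact crystallite-averaging
correction behind published per-axis saturation moments is not specified
in the source analysis, so those printed moments are treated as
simulation-capability illustrations only. Molar susceptibility of an
isolated ZFS manifold is obtained from the powder moment at a small probe
field (0.01 T) via χ_M = N_A μ_B M/B, 0.55849 (cm³ mol⁻¹)·(T/μ_B).

**Effective g.** For half-integer S the zero-field spectrum consists of
Kramers doublets (degeneracy verified to 10⁻¹⁰ relative in tests). The
effective g′ of a doublet along each principal axis is the exact B → 0
slope, computed by projecting the Zeeman operator onto the two-dimensional
zero-field eigenspace and diagonalizing the resulting 2×2 block — the
first-order (infinite-D) limit, appropriate when |D| ≫ hν as in X-band
EPR of these complexes. A finite-field mode (full diagonalization at a
0.01 T probe) is provided for comparison; for |D| ≥ 10 cm⁻¹ the two agree
to < 0.1%. Axis labels follow the convention D axial along z, η = E/D ∈
[0, 1/3]; reported g′ are available both per axis and sorted descending.
The sign of D is a free input (for fully rhombic η = 1/3 it cannot be
determined from g′ values — both doublets share the same g′ multiset), and
the intrinsic g defaults to the free-electron 2.0023. Doublet Boltzmann
populations use the zero-field energies with degeneracy 2. Nutation
frequencies follow Ω_nut = g₁ μ_B B₁/ħ · √(S(S+1)) (SI), with the
√5 ratio between S = 3/2 and S = 1/2 at equal g₁B₁ used for spin
assignment.

## Synthetic data

The generator emulates already-corrected SQUID observables:

* χ_M T on a 2–290 K grid (2 K steps) from the ladder at the fixture's
  (J = −40 cm⁻¹, r, g); J = −40 cm⁻¹ is an assumed scale of typical
  [Fe₂S₂]⁺ magnitude, since only r is published — the fit recovers r, not J.
* powder M(H) at 2 K over 0.1–7 T from ZFS manifolds: S = 1/2 (g = 1.90 or
  1.92), S = 3/2 with D = +11 cm⁻¹ (η = 0.12 for the Se complex, 1/3 for
  Te), and the Se complex's frozen-solution 50:50 S = 1/2 + S = 3/2
  spin-isomer mixture as a convex combination.

Noise is multiplicative Gaussian, σ = 1% by default (the SQUID
relative-error regime; true per-point uncertainties are unpublished, so σ
is a knob). All randomness flows from one `numpy` Generator seeded per
dataset; the same seed is bitwise reproducible. What the generator does
*not* emulate: diamagnetic impurities beyond the mixture operation,
field-dependent susceptibility corrections, intermolecular coupling,
temperature-dependent vibronic distortion of χ_M T below 50 K. Passing
round-trip tests therefore demonstrates estimator correctness under the
stated noise model, not robustness to every systematic present in real
magnetometry.

## Numerical choices and problem sizes

* Ladder scans: 10⁻³ grid in |B/J| over 0–12, with bisection refinement of
  crossings; argmin validated against exhaustive enumeration on random
  parameters.
* Replicate study: 20 susceptibility replicates at 1% noise (120 points
  each above 50 K), each refit with 8 multi-starts — the full study runs in
  seconds; the residual profile (0.2–10 in steps of 0.1) is optional and
  skipped in bulk loops.
* Powder grids: 100–500 orientations depending on use; refinement tests
  confirm < 0.5% drift on doubling.
* Boltzmann weights always subtract the minimum energy before
  exponentiation.

## Limitations

Two-site dimers only (no cubane ladders), isotropic exchange only (no
anisotropic or biquadratic terms), adiabatic vibronic treatment only (no
nuclear dynamics or multimode coupling), no EPR lineshape/strain
simulation, no hyperfine structure. The fictitious-spin g′ of an observed
doublet cannot be inverted for the intrinsic g tensor here; where the
free-electron assumption fails, computed g′ values will deviate from
experiment by the same margin it does.
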