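# Methods

This note records the models, conventions and numerical choices behind
`nqevib`, and what the synthetic fixtures do and do not establish.

## Units and conventions

Everything internal is in Hartree atomic units (hartree, bohr, electron
masses, ħ = 1); conversions happen only at I/O boundaries.  XYZ files are in
ångström on disk, bohr in memory.  Isotope masses come from a fixed table
(¹H 1.007825, ²H 2.014102, ¹²C 12, ¹⁶O 15.994915 amu; 1 amu =
1822.888486 mₑ).  Frequencies and level energies are reported in cm⁻¹;
imaginary frequencies are printed as negative numbers so tables sort.

## PIP surfaces

A basis function is the sum of the distinct monomials in one orbit of the
permutation group of like atoms, acting on the n(n−1)/2 Morse variables
`exp(−r/λ)` with λ = 2 bohr.  The group action on pair variables is induced
from atom permutations at run time, never hand-coded.  The constant
monomial is a basis member.  Orbit enumeration proceeds over all exponent
multisets up to the maximum total degree with lexicographically minimal
representatives; tests cross-check the count against Burnside's lemma.  For
9 atoms with class sizes 3+2+1+1+1+1 this gives 208 functions at degree 2
and 14 752 at degree 4.

Fitting is linear least squares on absolute energies, optionally augmented
with 3N analytic gradient rows per record (chain rule through the Morse
transform).  Gradient rows carry a relative weight of 1/(3N) by default so
one record contributes comparable energy and gradient weight.  Rank
deficiency is resolved by the minimum-norm solution and flagged; the
condition number of the design matrix is reported.  The Δ-correction is fit
on high-minus-low energy differences shifted so the minimum difference over
the training set maps to zero (the two electronic-structure references
carry an arbitrary constant offset); the corrected surface is the pointwise
sum and its gradient the sum of gradients.

## Synthetic data

The model molecule's "high-level" surface is a sum of Morse terms over all
atom pairs whose (De, a, re) depend only on the unordered pair of atom
classes — permutation invariance is exact by construction.  The equilibrium
is found by BFGS plus Newton polish (projected rotational frequencies come
out below 10⁻³ cm⁻¹).  The "low-level" surface adds a planted degree-2 PIP
perturbation, scaled to 5% of the sampled high-level energy range, plus a
constant −35 732 cm⁻¹ electronic offset, so the high-minus-low difference
is slowly varying, exactly representable at degree 2, and dominated by a
constant shift, which is the regime in which a sparse correction fit works.

Corpora are drawn by normal-mode displacements with independent normal
deviates per mode (per-mode scale 1/√(ω·nmodes)) and an overall amplitude
drawn uniformly in [0, s]; s = 4.0 fills 0–35 000 cm⁻¹ with ~97%
acceptance below the cap.  This emulates the energy coverage of an ab
initio molecular-dynamics corpus, not its Boltzmann statistics or mode
correlations — conclusions about selection counts and fit recoveries
transfer to real data, error magnitudes do not.

The selection recipe takes every eighth record of the 8500-record training
pool (1-based indices 1, 9, …, giving 1063), the first 1250 of the
2500-record test pool, and exactly six records above 30 000 cm⁻¹ from the
held-back half, for 2319 in total, randomly partitioned 2069/250 with a
stored seed.  Which "half" and how the partition is randomized are not
fixed by the recipe's source; both choices are documented and seeded here.

## Normal modes

Hessians are symmetrized central differences of analytic gradients
(default step 10⁻³ bohr) with optional Richardson extrapolation, which the
`normal_modes` convenience wrapper enables so that projected
translation/rotation frequencies at true minima are clean (< 10⁻³ cm⁻¹
on the synthetic molecule).  Translations and rotations are removed by
diagonalizing in the orthogonal complement of their mass-weighted span;
the span's rank is detected by SVD so linear molecules (3N−5) work.

## Diffusion Monte Carlo

Unbiased DMC: no importance sampling, no descendant weighting.  Per step,
each walker diffuses by Gaussians of width √(Δτ/m) per Cartesian degree of
freedom, then branches against the reference energy: death probability
`1 − exp(−(Eᵢ−E_r)Δτ)` when above, birth probability
`exp((E_r−Eᵢ)Δτ) − 1` (capped at one offspring) when below.  The reference
energy is `⟨V⟩ − α(N−N₀)/N₀` with α defaulting to 1/Δτ.  The ZPE is the
post-equilibration mean of E_r per simulation; the final estimate averages
the simulations, and the quoted σ is the standard deviation of the
per-simulation means.  Walkers whose potential drops more than
1000 cm⁻¹ below the global minimum count as holes and are killed; the
count is reported.

Defaults are desk-scale (Δτ = 5 au, a few thousand steps, 10³–10³·5
walkers, 5 simulations).  At Δτ = 5 au a 21-mode harmonic bath with modes
up to 3900 cm⁻¹ shows a time-step bias of order +1% of the ZPE, well inside
the statistical 3σ bands used in the tests; 1-D fixtures are unbiased to
within ~1 cm⁻¹.

The walker distribution in unbiased DMC samples the ground-state
wavefunction Ψ₀ itself (not |Ψ₀|²): the harmonic histogram test asserts a
Gaussian of variance ħ/(mω), which the simulation reproduces to 2%.

## AS SCIVR

All semiclassical machinery runs in mass-weighted normal-mode coordinates,
where masses are unity and the coherent-state width matrix is diagonal with
entries equal to the harmonic frequencies.  Initial conditions sit exactly
on the harmonic ZPE shell (action ħ/2 per mode, uniform random phases).
The switching Hamiltonian interpolates `(1−λ)H_harm + λH_anh` with
`λ(t) = t/T_AS − sin(2πt/T_AS)/2π` over T_AS = 25 000 au; propagation is a
fourth-order Yoshida composition of position-Verlet steps, step 10 au.  The
semiclassical stage accumulates the classical action (discrete Lagrangian:
kinetic at the kick, potential trapezoid), propagates the monodromy matrix
with the same shear substeps using Hessians along the path, and tracks the
Herman–Kluk prefactor phase as the continuous branch of
`½ arg det[(M_qq + Γ⁻¹M_ppΓ + iΓ⁻¹M_pq − iM_qpΓ)/2]` — the branch
convention is pinned by the harmonic case, where the phase is exactly
−ωt/2 and the spectral peak lands at +ω/2.  Trajectories whose monodromy
determinant drifts from unity by more than 1% (roundoff amplified by
chaotic dynamics; the shear composition is exactly symplectic in exact
arithmetic) are rejected, and the rejection rate is reported.

The spectral density is the rectangular time average over accepted
trajectories.  A rectangular window has sinc² sidelobes of 4.7% and 1.7%
flanking each peak at multiples of ~1.43·(2π/T); the default peak detector
therefore uses a 6% relative floor with quadratic interpolation
(grid spacing 1 cm⁻¹), and weak overtone peaks can be recovered by lowering
the floor inside a window away from the main lobe.  With T = 25 000 au the
harmonic peak is exact to the grid; Morse ground states come out within
5 cm⁻¹ of the analytic E₀ and hindered-rotor ZPEs within the method's
typical 20–30 cm⁻¹ of the DVR oracle.

The ensemble default (200 trajectories, configurable) is a desk-scale
choice: for the ≤ 2-dimensional fixtures shipped here the phase average
converges with a few dozen trajectories.

## 2-D torsional model

Form: `V(θ,φ) = Σ c_jk cos(jφ)cos(3kθ) + Σ d_jk sin(jφ)sin(3kθ)` (cm⁻¹),
which enforces exact 3-fold methyl symmetry, 2π-periodicity, and the
reflection symmetry V(−θ,−φ) = V(θ,φ) of the enantiomeric gauche pair; the
sin·sin block is the minimal coupling family that admits geared motion and
is zeroed for the separable comparison.  Angle conventions: φ is the
hydroxyl torsion with trans at 0° and gauche at ±120°, θ the methyl
torsion with the trans-staggered orientation at 0°.

The model is fit to stationary-point constraints only (the published cuts
are unrelaxed curves whose full shape is not tabulated): values and
stationarity at the trans minimum, eclipsed (60°) and syn (180°) saddles
and the gauche cut point on the hydroxyl cut; the methyl barriers 1208,
1283, 1404 cm⁻¹ at the trans/eclipsed/syn hydroxyl angles; and the gauche
well (38 cm⁻¹, 2-D stationary) with its 1324 cm⁻¹ methyl barrier.  The
constraints are linear in the coefficients and are satisfied exactly;
leftover freedom is resolved by a smoothness-weighted minimum-norm solution
(coefficients penalized by 1 + j² + (3k)², i.e. the angular Laplacian
scale), at default orders (J, K) = (6, 3), raised automatically if a
constraint set is infeasible.

The published cuts do not fix where the gauche methyl minimum sits in θ.
The geared coupling is encoded by placing it 5° off staggered (the mirror
well at −5°): with that choice the full-vs-separable 2-D DVR level
differences come out at 5–30 cm⁻¹, the same magnitude as the published
comparison, and the 1-D tunneling pair lands at 55/57 cm⁻¹ (published 2-D
value 52.3/54.4 cm⁻¹ against 39.5/42.8 observed).  Larger offsets
(10–15°) overdrive the coupling by an order of magnitude.  Because the
model matches stationary data only, level tables are expected to agree
qualitatively, not digit for digit.

Minimum-energy paths are computed on an unwrapped angular grid restricted
to axis-aligned moves: a bottleneck (minimax) Dijkstra pass fixes the
lowest attainable barrier, then a shortest-path pass on accumulated energy
within that sublevel set follows the valley floor.  Paths between wells
that wind in θ must cross methyl saddles, and the path maximum equals the
lowest constrained methyl barrier.

## Periodic DVR

The 1-D azimuthal DVR uses the closed-form kinetic matrix on an odd
uniform grid over [0, 2π); 161 points is spectrally converged (levels
stable to < 10⁻⁴ cm⁻¹ under grid doubling) for every potential used here.
The 2-D direct-product Hamiltonian is diagonalized densely up to 2000 grid
points and by shift-invert Lanczos above; the default 81×41 grid is
converged to ~5·10⁻⁴ cm⁻¹ for the fitted torsional model (checked against
161×81).  Level labels carry quantum numbers from nodal counting of the
dominant grid profiles and an e/o parity from the (θ,φ) → (−θ,−φ)
reflection character; nodal counting on near-degenerate multiplets is a
heuristic and is used only for qualitative table assignments.  The rotor
inertias are 2.7 (hydroxyl) and 10.5 (methyl) amu·bohr², the values that
give the published level agreement; the μr² estimate for the hydroxyl
rotor (≈3.2 amu·bohr²) is implemented for comparison.

## Known limitations

* The synthetic molecule's pairwise-Morse form has no angular three-body
  terms; it tests permutational symmetry, fitting and sampling machinery,
  not chemical realism.
* AS SCIVR is implemented for potentials with cheap Hessians
  (analytic or low-dimensional); applying it to the 27-dimensional
  synthetic molecule would need Hessian caching/updating schemes that are
  out of scope.
* DMC uses a fixed Δτ with no extrapolation; the documented ~1% bias at
  high frequencies is accepted rather than corrected.
* The torsional model reproduces constrained stationary energies exactly
  but interpolates freely elsewhere; quantities that depend on the full
  cut shapes (level tables, path shapes between saddles) are qualitative.
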