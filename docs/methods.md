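# Methods

## Units and conventions

Internal units are Hartree and Å throughout. Quantities conventionally
quoted in other units are converted at the interface with CODATA-2018
constants (`mepkit.units`): NEB spring constants in eV Å⁻¹
(5 eV Å⁻¹ = 0.1837 Hartree Å⁻¹), environment-relaxation thresholds in
kcal mol⁻¹ Å⁻¹, map energies in kcal mol⁻¹, frequencies in cm⁻¹
(ν̃ = 2720.2 · √λ cm⁻¹ for λ in Hartree Å⁻² amu⁻¹). Atom indexing is
0-based everywhere; PDB serials are mapped to file order on read.

Convergence of every geometry driver is the first geometry whose maximum
absolute gradient component over mobile atoms falls below a stated
threshold (0.01 Hartree Å⁻¹ for scan points, 0.0025 for the band force,
0.001 for saddle refinement, 0.01 kcal mol⁻¹ Å⁻¹ for environment
relaxation). Non-convergence is always an explicit, inspectable failure
carrying the best-so-far state; scans record per-point failures and
continue.

## Energy models

`EnergyModel` is a two-method contract: deterministic energy (Hartree) and
analytic Cartesian gradient for a `Structure` (labels, coordinates, masses,
per-atom mobility roles `mobile`/`env`/`frozen`). Built-ins:

* **Müller-Brown** — the standard four-Gaussian 2D benchmark, embedded as a
  single abstract particle (x, y = surface coordinates, z inert). Its
  stationary points are recomputed numerically wherever they are needed as
  oracles; no literature coordinates are trusted beyond initial guesses.
* **`AnalyticSurface2D` / `QuadraticField` / `HarmonicDiatomic`** —
  closed-form testbeds for optimizer and Hessian contracts.
* **The synthetic S_N_i model** (below).

`fd_gradient` provides the central-difference oracle used only in tests; it
computes every row including frozen atoms (masking is the optimizer's
concern, not the differentiator's).

## The synthetic reactive model

Seven atoms represent the reacting core of a glycosyl-transfer-like
front-face substitution: C1 (electrophilic carbon), O1 (leaving-group
oxygen, anchored to a heavy atom P), OA (nucleophile oxygen), H (the
transferred proton), and spectators C2, C3 bonded to C1. The energy is a
closed-form sum over internal coordinates (hence exactly invariant under
rigid motion, with analytic gradients):

* Morse wells for the four exchangeable bonds C1-O1, C1-OA, OA-H, O1-H,
  with equilibrium lengths 1.513, 1.467, 0.972 and 1.038 Å (the
  stationary-point bond lengths typical of glycosyltransferase reaction
  cores);
* anti-cooperativity couplings `C·B(r_a)·B(r_b)` with logistic bond-order
  switches `B(r) = 1/(1+exp((r−r_mid)/w))`, penalizing simultaneous bonding
  of C1 to both oxygens (C_sub = 0.12 Ha) and of H to both oxygens
  (C_prot = 0.04 Ha);
* a cross-coupling `−C_x·(1−B(d_C1O1))·B(d_O1H)` (C_x = 0.04 Ha) that makes
  O1 a good proton acceptor only once the C1-O1 bond has broken — the
  leaving group's basicity grows on heterolysis, which is what couples the
  proton transfer to the substitution;
* harmonic scaffold bonds and one angle, soft exponential repulsions, and a
  one-sided harmonic pocket wall that keeps the unbound nucleophile from
  drifting beyond ≈ 3.05 Å.

The defaults were calibrated once, at construction, so that the model
exhibits the study conditions the toolkit is meant to exercise, and are not
revisited: two locally minimized basins (reactant: C1-O1 and OA-H bound,
d(C1-OA) ≈ 3.1 Å; product: C1-OA and O1-H bound, 13.7 kcal mol⁻¹ below the
reactant); a single dominant barrier of 18.9 kcal mol⁻¹ in the
distance-difference plane with a monotone rise and fall along the band; an
abrupt > 2.5 Å jump of the unsampled C1-O1 distance when a scan drives
d(C1-OA)/d(O1-H) directly (the hidden-coordinate failure mode), against a
completely smooth distance-difference scan of the same model; and a
verified first-order saddle (one negative eigenvalue plain and
mass-weighted, reaction mode ≈ 213i cm⁻¹).

`INTERMEDIATE_PRESET` adds a shallow Gaussian well in the
(d(C1-O1), d(C1-OA)) plane centered in the dissociated oxocarbenium-like
region near the barrier top; with it the band profile develops a local
minimum ≈ 0.8 kcal mol⁻¹ deep, giving a two-step profile for tests that
need one.

What the model does *not* emulate: electronic polarization and charge
transfer, a relaxing protein/solvent environment around the core (the
`env` role and nested relaxation are exercised by tests, not by the default
fixture), entropy, and the hundreds-of-atoms dimensionality of a real
QM/MM region. Passing tests demonstrate the correctness and the failure
modes of the *methods* on a landscape with realistic topology and
kcal-scale energetics — not the chemistry of any particular enzyme.

## Scans

`run_scan` drives two harmonic restraints (default k = 5 Hartree Å⁻²) over
a scanline-major grid with warm starts: the first axis is swept once at the
second axis's start, then every point seeds a scanline along the second
axis, so the parentage graph is a tree rooted at the reactant. Stored
energies are the *unbiased* base-model values at the restrained minima (the
bias is bookkeeping, not physics), in kcal mol⁻¹ relative to the first
grid point.

The restraint stiffness matters quantitatively: the restrained minimum sits
off-target by |∂E/∂ξ|/k, so k must be large enough that grid labels mean
what they say. At k = 0.5 Hartree Å⁻² the steepest parts of the synthetic
model's surface displace targets by ≈ 0.1 Å (several kcal mol⁻¹ of
mislabeling); k = 5 keeps tracking within 0.01-0.02 Å, which is why it is
the scan default while the generic `HarmonicRestraint` default stays at
0.5 for gentle driving tasks.

Outlier flagging follows the isolated-point rule: interior points compared
with the mean of their four direct neighbors, boundary points with their
two neighbors along the boundary (corners use their two edge neighbors),
threshold 2 kcal mol⁻¹; flags never modify energies, so the operation is
idempotent. Hidden-coordinate detection reports every grid edge whose
monitored CV changes by more than 0.5 Å (default; smooth steps on these
grids are ≤ 0.2 Å, genuine hidden jumps are > 2 Å, so the threshold is not
delicate). Discrete map analysis finds minima (below all existing
neighbors) and the minimax barrier between two minima by union-find
flooding in order of increasing energy — the flooding point that first
connects the two basins is the discrete saddle.

## Band optimization

The improved-tangent scheme selects the segment toward the higher-energy
neighbor, blending both segments with energy-difference weights at local
extrema (with a chord fallback for exactly flat neighborhoods). The force
on an interior image is the true force perpendicular to the tangent, plus
the parallel spring term `k(|R₊|−|R₋|)τ̂`, plus `f(Φ)` times the
perpendicular component of the full spring vector, with
`f(Φ) = ½(1+cos(π cos Φ))`. The Φ convention: Φ = 0 means collinear
continuation, so a straight band feels no perpendicular spring and the term
only acts to straighten kinks (on an exactly flat valley floor a zigzag
band stays kinked forever without it — the band is then in equilibrium at
any kink angle — and straightens below 30° with it).

All interior images move simultaneously as one concatenated FIRE state
(defaults dt₀ = 0.1, f_inc = 1.1, f_dec = 0.5, N_min = 5, α₀ = 0.1,
f_α = 0.99, dt_max = 1.0, per-component displacement cap 0.2 Å);
quasi-Newton drivers are deliberately not offered for bands because the NEB
force field has a non-symmetric Jacobian. The convergence measure is the
total band force (nudged true force + spring terms), maximum absolute
component. Climbing image is available but off by default; saddles are
refined separately.

The discrete image maximum underestimates a barrier by up to the curvature
times the squared image spacing, so `path_maximum` reports the maximum of
the three-point parabola through the highest image and its neighbors; on
the Müller-Brown benchmark this reduces the 15-image barrier error from
≈ 0.55 to ≈ 0.16 model units against the exact saddle.

## Saddle refinement and verification

`ts_refine` takes partitioned rational-function steps: an uphill shift
along the followed (lowest) eigenmode, the RFO downhill shift (lowest root
of the secular equation, located by bisection) along all others, capped by
a 0.1 Å trust radius; the Hessian approximation is updated by Bofill's
mixed SR1/PSB formula, which preserves symmetry exactly and does not force
positive definiteness. Loss of negative curvature and step-budget
exhaustion are explicit failures.

Numerical Hessians use symmetric central differences of analytic gradients
(default step 0.01 Å) over mobile coordinates, symmetrized as (H+Hᵀ)/2.
Two finite-difference facts shape the verification defaults: the raw
asymmetry before symmetrization scales as step² (≈ 2·10⁻⁴ relative at
0.01 Å on the synthetic model), and exact rigid-body zero modes come out
with |λ| up to ≈ 10⁻⁵ Hartree Å⁻², i.e. above the 10⁻⁶ zero-counting
tolerance. `verify_saddle` therefore optionally projects the six exact
translation/rotation directions out of the Hessian (in plain or
mass-weighted coordinates as appropriate) before counting negative
eigenvalues; this is enabled for isolated molecular models and must stay
off for abstract surfaces, which are not rigid-motion invariant. Mass
weighting divides H_ij by √(m_i m_j) and cannot change the signature
(Sylvester), so disagreement between the plain and weighted counts is
always a numerical-threshold issue, never physics. A separate
negative-curvature trust threshold (10⁻⁵) keeps `ts_refine` from
"following" finite-difference noise on a minimum.

## Ring puckering

The Cremer-Pople mean plane comes from the two weighted lattice sums R′ and
R″; the normal is oriented so that the chair with even-index atoms displaced
upward maps to θ = 0 — with the pyranose anchoring (O5 = position 1,
traversal O5→C1→…→C5) that places ⁴C₁ at the north pole, the convention
under which near-chair reactant rings show θ of a few degrees. The
m = 2 mode gives (q₂, φ₂), the alternating mode q₃;
Q = √(q₂²+q₃²), θ = atan2(q₂, q₃). At the poles φ is undefined and
reported as 0.

Renumbering the ring by one position advances φ by 2·(360°/6) = 120° (the
m = 2 phase shift) and mirrors θ about the equator; Q is invariant. Any
other anchoring therefore rotates φ in 120° steps — worth keeping in mind
when comparing against tools with a different atom-1 convention.

The 38 canonical conformers (2 chairs, 6 boats, 6 twist-boats, 12
envelopes, 12 half-chairs) are not tabulated: their (θ, φ) reference points
are generated at import time from ideal displacement patterns (alternating
chairs; single-atom envelopes; adjacent-pair half-chairs; same-side para
pairs for boats; the meta pair out of the remaining four-atom plane for
twist-boats, using the standard pyranose skew-form names). Classification
is nearest-canonical-point by great-circle distance on the (θ, φ) sphere,
with the runner-up reported when it lies within 15° of the best match (the
"partial character" reading); amplitudes below 0.1 Å are reported planar.

## The map/path cross-validation

Projecting converged band images into the scanned CV plane and comparing
their energies with the bilinear map interpolation is the protocol's
consistency check; on the synthetic model every on-map image agrees to
better than 2 kcal mol⁻¹ (measured maximum 0.27). Two systematic effects
bound how far this check can be pushed, and both are properties of the
comparison rather than defects of either side. First, images whose CV
values leave the scanned rectangle (here: after the proton has fully
transferred, the proton coordinate drops below the scanned range) simply
have no interpolant. Second, on steep descents a full-dimensional MEP point
is *not* the constrained minimum at its own CV values — the path direction
has components outside the span of the two CV gradients, and the lagging
relaxation of those hidden directions leaves the image up to several
kcal mol⁻¹ above the 2D-constrained surface (measured ≈ 4 kcal mol⁻¹ on an
extended-axis map of the synthetic model's post-saddle wall). The
agreement criterion is therefore meaningful exactly where the protocol
applies it: on the mapped region around the reactant valley, barrier flank
and saddle plateau.

## Problem sizes and determinism

Default study sizes: the 18 × 12 (216-point) distance-difference grid and
11 × 6 distance grid for the synthetic model; 21 driven structures
densified to ≈ 38 band images (0.25 Å segments); 15 images on the
Müller-Brown benchmark; 10 perturbation trials for saddle reconvergence;
50 random rings for the puckering cross-check. All randomness (spectator
jitter, perturbations, random rings) flows from explicit integer seeds;
every workflow is bitwise reproducible for a fixed configuration, and
output files embed the configuration hash.

## Known limitations

* The synthetic model's reaction energy (−13.7 kcal mol⁻¹) is more
  exothermic than typical glycosyl-transfer estimates; its barrier and
  imaginary frequency are of realistic magnitude but not fitted to any
  specific enzyme.
* The minimax grid saddle is a discrete estimate, good to roughly one
  grid-cell energy variation; refine with `ts_refine` for quantitative
  work.
* Environment (`env`) relaxation is adiabatic and serial; no attempt is
  made to parallelize over images or displacements.
* Five-membered-ring pseudorotation and non-six-membered rings are out of
  scope for the puckering module.
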