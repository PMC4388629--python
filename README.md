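# mepkit

Minimum-energy reaction paths for enzymatic-reaction-style problems:
restrained potential-energy-surface (PES) scanning in distance and
distance-difference coordinates, stabilized Nudged Elastic Band (NEB)
optimization, transition-state refinement with saddle verification, and
Cremer-Pople ring-puckering analysis — all against a pluggable energy-model
interface, with built-in analytic benchmark surfaces and a synthetic
front-face nucleophilic-substitution (S_N_i) molecular model so the whole
workflow runs without any electronic-structure engine.

## Who this is for

Computational chemists who map reaction mechanisms by combining two
complementary approaches and cross-checking them against each other:

1. **2D restrained scans** give a global map E(ξ₁, ξ₂) over two collective
   variables, but silently fail when an unsampled ("hidden") coordinate
   jumps between adjacent grid points — the map then stitches together
   fragments of different surfaces and its apparent barrier is an artifact.
2. **Chain-of-states path optimization** (NEB) finds a continuous
   minimum-energy path in the full coordinate space with no assumed
   reaction coordinate, but gives no global context: a converged path may
   not be the relevant one.

Projecting the converged path onto the scanned map and requiring energetic
and geometric consistency rules out both failure modes at once. The toolkit
implements every stage of that protocol plus the diagnostics that make the
cross-check quantitative.

## The methods

**Restrained scans.** Each grid point minimizes `E + ½k(ξ−ξ₀)²` for both
scan coordinates, warm-started from the previous point of its scanline
(scanline-major ordering, parentage a tree rooted at the reactant). The map
stores the unbiased energy, convergence flags and monitored CV values.
Diagnostics: the isolated-outlier rule (point differing by > 2 kcal/mol
from the mean of its 4 direct neighbors, or 2 along-edge neighbors on the
boundary), hidden-coordinate jump detection (adjacent-point changes of a
monitored CV above a threshold), and discrete minima / minimax-barrier
analysis of the grid graph.

**NEB.** Improved (upwind) tangent estimates; spring force
`k(|R₊|−|R₋|)` parallel to the tangent (k = 5 eV/Å by default); a fraction
`f(Φ) = ½(1 + cos(π cos Φ))` of the perpendicular spring component added
back to suppress kinks (Φ = angle between adjacent segments, so f = 0 on a
straight path); all interior images driven simultaneously by FIRE (the NEB
force field is non-conservative, so quasi-Newton drivers are avoided);
convergence when the largest force component drops below 0.0025 Hartree/Å.
Paths are initialized by spline-resampled CV waypoints realized with
restrained driving, then densified by midpoint insertion to ≤ 0.25 Å
segments.

**Transition states.** Partitioned rational-function (eigenvector-
following) steps with Bofill's mixed SR1/PSB Hessian update, trust radius
0.1 Å, convergence at 0.001 Hartree/Å (configurable). Verification:
numerical Hessian by symmetric central differences of analytic gradients
(step 0.01 Å), eigenvalue counts in plain and mass-weighted coordinates —
a first-order saddle has exactly one negative eigenvalue in both — and the
imaginary frequency of the reaction mode.

**Ring puckering.** Cremer-Pople amplitude Q, polar angle θ and phase φ for
six-membered rings, with the pyranose anchoring (O5, C1 … C5; the ⁴C₁
chair at θ = 0), classification against the 38 canonical conformers
(generated geometrically, not tabulated) with runner-up labels for partial
character, and per-frame itineraries over trajectories.

## Worked example

`examples/scan_coordinate_choice.py` runs both 2D scans of the synthetic
S_N_i model while monitoring the unsampled leaving-group bond d(C1-O1):

```
distance-based scan (11x6 grid): 12 grid edges where d(C1-O1) jumps by > 0.5 A
  -> the unsampled glycosidic-analogue bond snaps between adjacent scan
     points; the apparent barrier on this map is an artifact
distance-difference scan (18x12 grid, 216 points): 0 jump edges
  -> coupling bond formation and dissociation into one coordinate samples
     the exchange smoothly; this map is trustworthy
map energy range: -14.3 to 31.7 kcal/mol relative to the first grid point
```

`examples/reaction_path_and_saddle.py` continues to the path and saddle:

```
initial path: 21 driven structures densified to 38 images
band converged in 81 iterations (spring 5 eV/A, stop at 0.0025 Ha/A)
barrier 18.9 kcal/mol, reaction energy -13.7 kcal/mol
refined saddle: 18.9 kcal/mol above reactant
negative eigenvalues: 1 plain, 1 mass-weighted -> first-order saddle confirmed
imaginary frequency of the reaction mode: 213i cm^-1
```

The other examples cover the Müller-Brown benchmark (band barrier within
0.16 model units of the independently located saddle) and ring-puckering
classification. A thin CLI exposes the same stages
(`mepkit fixtures|scan|neb|tsopt|pucker|profile`) driven by a YAML run
configuration; see `mepkit --help`.

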