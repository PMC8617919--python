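# Methods notes

This note records the model, the numerical choices, and the reasoning behind
the design decisions that were genuinely open, at the level of detail a
maintainer needs to modify the package safely.

## Collective variables and the fit gradient

CVs are projections onto principal components of *fitted* coordinates.
Fitting uses the standard optimal-superposition construction: cross
covariance `A` between the conformer's fit atoms (centroid Q) and the
reference fit atoms (centroid P), and the proper rotation maximizing
`tr(R A)`. We compute R from the SVD `A = U S Vᵀ` as
`R = V diag(1, 1, det(VUᵀ)) Uᵀ`, which equals the closed form
`(AᵀA)^{1/2} A⁻¹` whenever `det A > 0` and remains a proper rotation for
reflected or nearly singular inputs. Inputs whose two smallest singular
values vanish (collinear fit atoms) raise `DegenerateFitError`: the rotation
is genuinely undetermined there.

Fitted coordinates are `r′ = R (r − Q)`; the reference centroid P is *not*
added back. Any fixed convention differs only by a global constant in each
CV, and omitting P keeps the fitted frame centered at the origin.

Projections subtract the ensemble mean by default (`centered=True`), so the
training ensemble projects to zero mean and the region geometry is portable
across bases. The uncentered (absolute) axis convention is available as a
flag; it differs by the constant `c_n · ⟨X′⟩`.

The restraint force needs the exact gradient `∂v_m/∂X`, including the
dependence of R and Q on the fit atoms. Differentiating the optimality
condition "`R A` is symmetric" under an orthogonality-preserving perturbation
`dR = R [ω]_×` yields a 3×3 linear system `L ω = −vec(skew(R dA))` for the
skew generator ω. Because the gradient is a linear functional of ω, we solve
the *adjoint* system once per configuration (`h = L⁻ᵀ g`) and obtain every
atom's gradient component from one cross product, rather than solving per
coordinate. The three contributions are:

* direct: `Rᵀ c_i` for every atom i;
* centroid: `−Rᵀ (Σ_i c_i) / N_fit` for fit atoms (Q shifts with them);
* rotation: `−(h × (s_ν − P)) · R` columns for fit atoms.

The direct and centroid terms cancel in the sum over atoms and the rotation
term sums to zero because `Σ_ν (s_ν − P) = 0`, so the total gradient is
translation invariant to machine precision — a property the tests assert.
The whole construction is validated against central finite differences
(step 1e-4 Å) at 1e-5 absolute tolerance per component; in practice
agreement is ~1e-10.

## Flat-bottom restraint

`φ(v_m)` is zero on the closed interval `[v_min, v_max]` per CV dimension
and quadratic (`½k(·)²`) outside, summed over dimensions; the boundary
itself belongs to the flat branch, so the force is zero there. Energy is
continuous and once-differentiable at the walls by construction (quadratic
onset). Units are fixed throughout: Å, kcal/mol,
k_B = 0.0019872041 kcal mol⁻¹ K⁻¹. The spring constant is a per-run
parameter: the protein-scale default, 0.048 kcal mol⁻¹ Å⁻², matches CV
excursions of tens of ångströms; the toy pipeline uses 2.0 because its
regions are ~3 Å wide and the wall penetration depth `√(kT/k)` must stay
well below the overlap margin.

## Weight stitching: the sign convention

For adjacent regions the printed-form relative weight is a log-ratio of the
two regions' sample counts inside the geometric overlap of their sampling
rectangles (diagonal neighbors use the corner intersection with the same
counting rule). Matching the *weighted* per-sample densities in the strip
requires `e^{W_i} N_i = e^{W_j} N_j`, i.e. `W_j − W_i = ln(N_i/N_j)`; this
density-matching sign is the default. The opposite sign (`ln N_j − ln N_i`,
`convention="inverted"`) is retained as an option but demonstrably fails the
landscape-recovery property: on regions sampling a known Gaussian density
with unequal run lengths, the inverted convention doubles the population
imbalance instead of canceling it (see
`tests/test_pipeline.py::TestStitchKnownDensity`). That synthetic-density
recovery test is the arbiter of the convention.

Weights propagate breadth-first over usable edges (both overlap counts
positive) from a seed region chosen to maximize the number of usable edges
(ties to the lowest index). Each region is assigned exactly once, so noisy,
cycle-inconsistent counts give a spanning-tree answer; a least-squares
option (`method="lstsq"`) solves all edges simultaneously and averages the
inconsistency away. Both agree exactly on cycle-consistent inputs. If the
usable-edge graph leaves populated regions unlinked, propagation fails with
an error listing the components rather than silently stitching islands with
arbitrary relative offsets.

## Landscape assembly

Each retained sample contributes `e^{W_i} / M(v)` to its bin, where the
multiplicity M counts the sampling regions covering the sample's CV point.
With density-matched weights, overlap strips are covered M times at matched
density, so the 1/M factor exactly removes double counting. There is no
additional per-region division by the sample count L_i: the overlap counts
entering W already carry the run-length information, and dividing by L_i
again would undo the density matching (the brute-force enumeration test
pins this down).

The free energy is `F = −k_B T ln(weighted density)`, min-shifted so the
lowest populated bin is zero; a Boltzmann inversion with the opposite sign
would turn high-population basins into peaks. Empty bins are masked, carry
NaN, and are impassable to the barrier search. Samples never need an
`exp(+φ/kT)` reweighting factor: inside their own sampling region φ = 0 by
construction, and samples outside it are excluded by the clipping rule
before assembly.

Bin widths are configurable everywhere; the demo uses small-area width / 6,
which leaves the median occupied bin with ≥ 20 samples at the default run
lengths. One-dimensional profiles are arithmetic means of unmasked F over a
rectangle's transverse extent (masked bins are simply left out of the mean).
Barriers are measured with a minimax-path (widest-path) Dijkstra search over
4-connected bins between the minimum bins of two rectangles; the returned
`(F_saddle − F_a, F_saddle − F_b)` are non-negative by construction.

## The toy system and what it does (not) show

The synthetic stand-in for per-region MD is a 10-bead chain: harmonic bonds
(k = 5 kcal mol⁻¹ Å⁻², b₀ = 2 Å), weak second-neighbor springs
(k = 1.5 kcal mol⁻¹ Å⁻², ℓ = 3 Å) that give the chain enough bending
stiffness for the extension mode to lead the shape covariance, and a quartic
double well on the end-to-end distance with minima at 5 and 11 Å and a
barrier of 1.8 kcal/mol ≈ 3 kT at 300 K. The compact and extended states
separate along the first PCA mode; an optional linear tilt makes the wells
inequivalent by a known energy gap for oracle tests.

Sampling is overdamped Langevin (Euler–Maruyama),
`x ← x + (dt/γ) F + √(2 kT dt/γ) ξ`, in reduced time units (only dt/γ is
meaningful). The default dt = 0.01 with γ = 1 keeps `dt·k_max/γ ≈ 0.1` for
the stiffest internal mode; trajectories that leave |x| < 10⁴ Å or go
non-finite raise an integration error naming the step. The choice of an
overdamped integrator is deliberate: the stitching statistics depend only on
sampling the correct equilibrium distribution, not on realistic kinetics,
and a first-order scheme keeps the per-step cost of the fit-aware restraint
force affordable. The O(dt) discretization bias affects the restrained runs
and the unbiased oracle identically and largely cancels from their
comparison; the detailed-balance test uses dt = 0.002 so the residual bias
sits below its statistical resolution.

Ground truth comes from two independent routes: a long unbiased run
histogrammed on the same CV grid (the oracle used by the end-to-end
recovery test), and direct Boltzmann quadrature for one-dimensional
potentials (used to validate the oracle machinery itself on closed forms —
equal-width wells recover their energy gap, a Gaussian well gives a
quadratic profile).

What the toy validates: the CV machinery, restraint forces, exclusion rule,
overlap-weight stitching, multiplicity correction, and landscape assembly,
end to end, against an independent equilibrium reference. What it does not
emulate: explicit solvent, rugged atomistic energy surfaces, slow
orthogonal degrees of freedom within a region (the toy's transverse modes
relax quickly), and force-field realism. Passing the recovery test therefore
demonstrates the correctness of the reconstruction statistics, not the
adequacy of any particular region size or run length for a real protein —
region sizing remains a per-system judgment.

## Pipeline defaults and problem sizes

The demo's defaults are sized for a few minutes on one CPU while keeping
every stage statistically meaningful: a 300k-step unbiased presample
(10⁴ frames) for the PCA basis and region layout; a 2×3 region grid over the
central 99% of the presampled CV mass, with margin = ¼ of the smaller cell
width; 120k restrained steps per region (~3×10⁴ retained samples each);
a 2M-step unbiased reference (4×10⁵ CV samples). Region runs start from a
presampled structure inside the region — regions containing none are
skipped, mirroring windows that hold no experimental model. The stitched and
reference landscapes are compared on bins where both hold ≥ 100 raw samples,
after removing the mean offset (free energies are defined up to a
constant). Correlated samples mean the raw counts overstate the effective
sample size; the 0.3 kcal/mol acceptance margin absorbs that.

All stochastic stages derive their seeds from one root seed through
`numpy.random.SeedSequence`, making every pipeline product bit-reproducible;
repeated runs with different root seeds give the spread used as the
statistical-error estimate.

## Structure I/O and contact conventions

PDB parsing uses Biopython; one conformer per MODEL/ENDMDL block, single
block for X-ray files. The first alternate location wins; waters are always
dropped; other hetero residues are kept only on request (ions and ligands
are excluded from fitting but a user may include them in contact analysis —
the 4.5 Å "any atom" rule does not say how they were treated, so it is a
configuration choice). The first protein chain is read by default; residue
numbers are used exactly as printed, so a selection like "Cα 5–70" means PDB
residue numbers 5 through 70 inclusive. Contacts use a strict `< 4.5 Å`
any-atom criterion with hydrogens included when present (`heavy_only`
optional); `min_seq_sep = 1` excludes only self-pairs. A contact *group* is
"formed" when any of its pairs is in contact (`mode="any"`, default) — the
all-pairs semantics is available, and the choice matters for marking partial
interface formation on the landscape. Representative structures minimize the
summed pairwise superposed RMSD (ties to the lowest model index), computed
on Cα atoms by default.

## Known limitations

* The pairwise BFS stitching is exact only for cycle-consistent overlap
  counts; heavily undersampled strips bias individual weights (the lstsq
  option mitigates, WHAM-style self-consistent iteration is out of scope).
* Landscape bins are axis-aligned rectangles; no kernel smoothing is
  applied, so barrier heights carry bin-discretization error of order the
  local |∇F| times the bin width.
* The eigenvector sign convention (largest-magnitude coordinate positive)
  and eigenvalue tie order make axes deterministic but basis-dependent for
  degenerate spectra.
* `project` refits each conformer independently; CVs are exactly invariant
  to rigid motion of the input but are not differentiable where the fit
  rotation degenerates.
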