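# Methods

This note records the models implemented in `monodec`, the conventions
that fix every sign, the numerical choices, and what the synthetic data
do and do not establish.

## Networks and orientation conventions

A monolayer is a confluent polygonal tiling. Cells are stored as vertex
cycles wound *clockwise* (negative shoelace signed area in right-handed
axes); the orientation of every cell is represented by the fixed quarter
rotation `eps = [[0, -1], [1, 0]]`, and triangles of the dual network
carry the opposite orientation `-eps`. All other signs follow from this
single constant:

- edge orientation is arbitrary at construction (`A` row: −1 tail, +1
  head; `t_j = Σ_k A_jk r_k`); every derived operator is invariant under
  flipping individual edges;
- `B_ij = ±1` records whether cell `i` traverses edge `j` with or
  against its orientation; `B A = 0` holds in integer arithmetic because
  the boundary of a cell boundary is empty;
- link vectors are first formed as `T_j = Σ_i B_ij R_i` (peripheral
  links run from the edge centroid to the single adjacent cell centre)
  and then sign-fixed so the parallelogram area `F_j = T_j · eps t_j` is
  positive. Under the clockwise convention this flip is uniform and
  recorded per edge.

With these choices the cell areas `A_i`, interior `F_j`, and interior
triangle areas `E_k` (polygon of incident cell centres, completed by
peripheral edge centroids at the boundary) are all positive, and the
chain-leg wedge of the link-component cochains satisfies
`(T_y ∧̃ T_x)_k = 6 E_k` at every interior vertex — the orientation
convention is pinned by requiring the ratio to be +6, not −6.
Circulation-type operators (`curl^c`, `curl^v`) therefore count
rotation positively in the clockwise sense of the cell orientation;
divergence-type operators are reflection-invariant (`div^v` of the
linear field `b(x) = x` is +2 in the continuum limit).

The component pair of a pair-valued cochain is ordered `(∥, ⊥)`. The
slot assignments of the composite operators are derived from the
adjointness relations and validated two ways: the Laplacian composition
identities (`-div∘grad = L_V ⊗ I` etc.) are checked with random probes
at assembly, and the orthogonal-lattice degeneracies (`L_V = L_T`,
`grad^v = -corot^v`, …) hold to 1e-12 on the regular hexagonal fixture
and break under shear. One published prose listing attaches the labels
div/codiv to the opposite slots than its own equations imply; this
implementation follows the equations (the Poisson-problem pairing of
forcings with potentials), under which the ∥ slot of `★d★b♭` is the
forcing of `φ∥` and recovers the continuum divergence.

## Reduction and boundary conditions

Peripheral edges and peripheral vertices — including hole boundaries
created by ablation, which bound a single cell — are suppressed by
zeroing the corresponding rows/columns of `A` and `B` (`Â = D_E A D_V`,
`B̂ = B D_E`), which preserves `B̂Â = 0` exactly because the boundary of
a cell's peripheral path ends on peripheral vertices. Zeroed rows and
columns are kept in place (cochains stay full-length); retained-index
sets drop them in linear solves. This implements homogeneous Dirichlet
data on vertex potentials and Neumann-type conditions on cell
potentials. The harmonic-kernel dimension test (`dim ker = n_holes` for
0–3 holes) validates classifying hole boundaries as peripheral.

`b_j`, the edge–link intersection carrying the local tangent frame, uses
infinite-line intersection; if the lines are near-parallel the edge
centroid is used. Only tangent bases attach to `b_j`, so an intersection
outside the edge segment (possible in very irregular meshes) is
harmless.

## Laplacians, Poisson solves and harmonic modes

The six Laplacians are assembled sparsely with zero rows at suppressed
elements:
`L_V = Ê⁻¹ÂᵀT̂_e⁻¹Â`, `L_C = H⁻¹B̂T̂_l⁻¹B̂ᵀ`, `L_T = Ê⁻¹ÂᵀT̂_lÂ`,
`L_F = H⁻¹B̂T̂_eB̂ᵀ`, `L_E = ÂÊ⁻¹ÂᵀT̂_e⁻¹ + T̂_eB̂ᵀH⁻¹B̂` and the link
analogue, with `T̂_e = diag(t²/F)`, `T̂_l = diag(T²/F)`. The
non-symmetric forms are solved through their similarity-symmetrized
counterparts (e.g. `L_E = T̂_e S_E` with `S_E` symmetric PSD).

Helmholtz–Hodge decomposition of an edge field `v`: the vertex potential
solves `K_V φ = Ê(−div v)` (SPD, Dirichlet via reduction; sparse LU);
the cell potential solves `K_F u = H curl v`, which is singular with
constant kernel. The forcing is projected onto the operator's range by
subtracting its mean — the discrete solvability condition
`[1_c, curl v]_C = 0` — with the size of the applied correction reported
in the diagnostics; the system is then solved with one pinned cell and
gauged to zero area-weighted mean. The dual decomposition mirrors this
(the cell problem is the singular one there too).

Harmonic modes are the kernel of the symmetrized scalar edge Laplacian,
computed by dense symmetric eigendecomposition on the retained edges
(interior edge counts stay in the low thousands here; eigenvalues below
1e-10 of the largest count as zero, and a count different from the hole
number is an error, not a warning). Modes are orthonormalized under the
metric weight `F_j/t_j²` so unit amplitudes give unit-energy fields,
with a deterministic sign fix. For several holes any rotation of the
kernel is an eigenbasis; the basis is rotated so each mode maximizes the
energy fraction `F_j (w_j/t_j)²` carried by the edges nearest one hole
(a small generalized-Rayleigh problem inside the kernel), which
reproduces the natural one-mode-per-hole picture and makes the
mode-to-hole labelling meaningful.

## Vertex model

Energy `E = ½ Σ_i [(A_i − 1)² + Γ(L_i − L̃₀)²] − σ_p Σ_i A_i`, with cell
areas measured in units of the preferred area, `Γ = 0.2`, `L̃₀ = 0.75`
(rigid regime) throughout, and `σ_p` an isotropic peripheral stress
implemented as a boundary-area energy term (its force contributions
cancel identically at interior vertices). Forces are the exact analytic
gradients (polygon-area gradient and unit-tangent perimeter gradient),
anchored by central finite differences to 1e-6 relative in tests.

Relaxation keeps topological events well-defined: the default scheme
alternates a deterministic L-BFGS descent at fixed topology with
bounded bursts of a FIRE-type explicit integrator (inertial velocity
mixing, adaptive timestep) that executes T1 exchanges the moment an
edge crosses threshold and escapes configurations the frozen-topology
step cannot handle (a reverted polish that inverted a polygon, a
collapsing edge). FIRE alone stalls when a single near-degenerate edge
forces the global timestep down; L-BFGS alone cannot change topology
and its energy-difference line searches bottom out near the
double-precision floor, so the last decade to the 1e-8 force tolerance
is certified by a burst of pure gradient dynamics, which compares
forces rather than energies. A plain adaptive-step gradient descent
(halve the step on an energy increase, grow on success) is kept as an
alternative integrator. Damping is 1; time is in relaxation units and
only equilibria are analysed.

T1 transitions: an interior edge shorter than `t1_threshold = 0.05`
(about 8% of a unit-area hexagon's edge) collapses and re-expands
perpendicular at 1.5× the threshold; the two edge-sharing cells lose the
edge, the two vertex-sharing cells gain it, and the incidence structure
is rebuilt and revalidated. At the monolayer boundary the exterior plays
the role of a missing cell: an interior edge with one boundary endpoint
can exchange (the gaining cell reaches the boundary), and a collapsing
*peripheral* edge rotates into an interior edge between the two
neighbours pinching together. Two safeguards keep the exchange dynamics
sane: a per-edge cooldown with exponential backoff prevents marginal
configurations from flip-flopping, and a degenerate boundary corner
(a vertex belonging to a single cell whose edges collapse) is smoothed
away by merging it into its neighbour, since no exchange applies there.
All events are logged; identical seeds replay bitwise.

Growth: starting from one regular hexagon of unit area, a uniformly
random cell is divided along a uniformly random axis through its
centroid (new vertices on the two crossed edges, inserted also into the
neighbours sharing them; cuts closer than 5% to an existing vertex are
resampled, at most 10 tries), followed by relaxation toward 1e-3 with a
step cap and a plateau exit — growth is a non-equilibrium process and
the intermediate states need not be fully balanced. After the target
cell count, a strict final relaxation to 1e-8 under zero peripheral
stress prepares the state for analysis. The default peripheral stress
during growth is also zero: the prestress heterogeneity that matters for
the ablation analyses arises from the division/T1 history itself, and
all analysis configurations are load-free.

Ablation removes strictly interior cells (their vertices must not touch
the boundary), increments the hole count, and re-relaxes. Cell indices
of survivors are preserved, so pre/post states difference cell-by-cell.

## Stress layer

Corner forces `f_ik` (the contribution of cell `i`'s energy terms to the
force on vertex `k`) sum to zero per cell identically and per vertex at
equilibrium. Rotating them by `eps` and integrating around each cell
(`h_out = h_in + eps f_ik` at the shared vertex) yields the edge
potential `h_j`, propagated across the monolayer by a breadth-first
sweep from a peripheral edge gauged to zero; the loop-closure defect is
reported and must stay below 1e3× the force tolerance. Under zero
external load all peripheral `h_j` vanish to the same tolerance, which
is why the zero gauge is consistent; for ablated monolayers the
hole-boundary values follow from the integration and are not re-gauged.
The cell stress is `σ_i = A_i⁻¹ Σ_j B_ij (t_j ⊗ h_j) eps`; its trace
route and the `−½ cocurl^c h` route to the effective pressure agree to
1e-8 relative at equilibrium, `Σ_i A_i σ_i ≈ 0` under zero load, and the
square root in `ζ_i = √(−det σ_i^{Ds})` clips tiny negative arguments
(rounding) with a logged count.

Radial scaling fits use per-log-bin maxima: log-spaced bins between the
innermost bin with ≥ 3 points and a fraction of the radial range,
ordinary least squares of log10(max) against log10(bin centre), slope
and standard error returned; for clean power laws the sensitivity to
8/12/16 bins is within a few hundredths. Division-grown monolayers can
be markedly anisotropic in outline, so the periphery is excluded
geometrically rather than by a fraction of the largest radius: the
"central" ablation target is the cell deepest inside the tissue, the
harmonic magnitude is fitted at radii up to the inradius (distance
from the ablation to the nearest boundary point), the cell-level
stress changes up to three inradii with single-peripheral-edge cells
dropped (they behave differently), and the reconstruction defect
`x̆ = v − grad φ − rot u` over the inner half of the range, where the
excited harmonic component dominates the numerical background.
Reported slopes are the median over the 8/12/16-bin fits, with the
cross-binning spread folded into the quoted uncertainty. Per-bin
maxima of a heavy-tailed field at a few hundred cells remain a noisy
estimator: across seeds the harmonic-magnitude and defect slopes are
stable to about ±0.15 around −1, while the stress-change slopes
scatter by roughly ±0.45 around −2.

## Synthetic data and problem sizes

Everything is generated in code: exact fixtures (regular hexagonal
patches, annuli with 1–3 holes, sheared variants) and seeded grown
monolayers. Default analysis sizes: ~500 cells for the ablation scaling
studies, 100–200 cells for equilibrium integrals and incidence checks —
large enough for a decade of radial range, small enough that a full
pipeline runs in about a minute on one CPU. The generator emulates
division-driven disorder and growth prestress; it does not emulate
curved substrates, apical-basal structure, active fluctuations, cell
heterogeneity, or the biochemical wound response. Passing tests
therefore establish the discrete-calculus identities exactly and the
mechanical scaling laws for this class of rigid, disordered,
division-grown tilings — not for real epithelia, where jamming state,
fluidization near wounds and measurement noise modify the response.

## Known limitations

- Flat geometry only; no periodic boundaries, curved manifolds or 3D
  polyhedral cells; polygons must stay simple.
- The Helmholtz solves assume the reduced vertex Laplacian is
  nonsingular, i.e. the monolayer has a boundary; fully closed tilings
  are out of scope.
- The two-species osmotic extension of the perimeter modulus is not
  implemented; `Γ` is a plain (optionally time-dependent) scalar.
- Dense eigendecomposition for harmonic modes is comfortable to a few
  thousand interior edges; larger meshes would need a sparse
  shift-invert kernel solver.
- The general interior product is not reconstructed; only the
  uniform-amplitude contraction used to build harmonic fields exists.
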