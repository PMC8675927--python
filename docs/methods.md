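# Model and numerical methods

## The biochemical layer

Each cell carries three membrane concentration fields A(s), P(s), B(s) —
aPKC, Par-1, Bazooka — on the half-perimeter path s ∈ [0, L], running from
the apical centre over the apical surface [0, a), down the lateral surface
[a, a + ℓ), to the basal centre (L = a + b + ℓ, where a and b are the mean
centroid-to-vertex distances of the apical and basal faces and ℓ the mean
lateral edge length).  The reaction terms implement mutual inhibition of A
and P (P inhibits A linearly, A inhibits P quadratically), double inhibition
of B by A and P (both quadratic), and recruitment of A by B.  The cytosol is
well mixed; mass conservation ρ_cyto = ρ_total − ψ·ρ̄ closes each species'
budget, with ψ the cell's surface-to-volume ratio and ρ̄ the uniform-grid
mean over the membrane path.  All rate constants, exponents and total pools
default to the reference parameter set of the model (converted to 10 µm /
1 s units); they live in `PolarityParams` and in the `biochemistry` section
of the YAML config.

**Boundary condition.**  The half-perimeter path is the mirror-symmetric
half of the closed cross-section loop of length 2L.  The default `reflect`
condition (no-flux at both ends) represents that full loop exactly for
symmetric profiles and carries a single A–P interface front.  A literal
`periodic` treatment of [0, L] is provided as an option; it carries two
interface fronts which share any pool perturbation, and therefore responds
to concentration changes with exactly half the peak displacement.  Only the
reflect variant reproduces the reported ~10 % junction shifts, which is why
it is the default.

**Initial condition.**  Polarization is seeded by a Bazooka step confined to
the apical region (half of the B pool on the membrane, the exact half on the
discrete grid), with A and P starting fully cytosolic.  This membrane-empty
start matters: the polarized state coexists with an unpolarized P-dominated
uniform state, and initialising A and P with substantial membrane loading
falls into the unpolarized basin.  The final polarized profile is insensitive
to the B step height (the steady state is an attractor within its basin).

**Numerics.**  Forward-time centred-space (FTCS) on 512 equidistant nodes
(256 for the per-cell fields of tissue runs), with the stability bound
max(D)·dt/Δs² ≤ 1/2 enforced.  Steady-state integrations use dt = 0.05 s —
comfortably inside both the diffusive bound (≈ 0.14 s at 512 nodes) and the
reaction-limited bound — and declare convergence when the maximum nodewise
rate of change over a 20 000-step block drops below 10⁻⁹ per time unit; the
reported peak shifts are unchanged at dt = 0.01 or tolerance 10⁻¹⁰.
Nodal concentrations are clamped at zero after each step.  When a domain
shrinks, the rescale ρ ← ρ·(L_prev/L_new) conserves membrane amounts; a
strongly shortening cell can then transiently hold more than its total pool
on the membrane, making ρ_cyto negative, in which case the kinetics act as
net dissociation and restore the balance (the strict-positivity guard is
kept for the single-cell integrators).

**Measurements.**  The junction position s* is the global argmax of B
(apical-most node on ties; optional parabolic sub-grid refinement).  The
apical domain size is ℓ_domain = max(0, s* − a).  The reported shifts use
two conventions, matching how each figure quantity is printed: the Par-1
knockdown shift is quoted as a percentage of cell height (the shift is a
z-displacement along the lateral face, divided by ℓ), the Bazooka
overexpression shift as a percentage of the membrane path length L (the
profile-axis convention).  For the reference columnar cell L = 1.5·ℓ, so the
two differ by exactly that factor.

## The mechanical layer

Cells are hexagonal prisms sharing vertices; the tissue potential sums
apical-perimeter elasticity, basal and lateral surface tensions and volume
elasticity.  Lateral faces are registered once: a face between two cells
carries the sum of both owners' tensions (so the default per-cell value
0.0207 yields 0.0414 on interior faces), a boundary face only its owner's.
Areas are fan-triangulated about face centroids; volumes use tetrahedral
decomposition about the cell centroid, with no planarity assumption.

Forces are central finite differences of the potential (step 10⁻⁶ length
units), evaluated per vertex over only the energy terms incident on it;
explicit Euler steps with dt = 0.1 (dt = 0.02–0.05 in relaxation-sensitive
tests) stay well below the stiffest shape-mode stability limit (≈ 0.36 for
the reference cell).  Force balance is declared at max |F| < 10⁻⁸.

The closed-form single-cell analysis inverts the balance conditions exactly:
λ_ℓ = √3·P_V·r/4, λ_b = P_V·h/4, K_a = √3·P_V·h·r/(16(6r − P̂_o)) with
P_V = 2(1 − V); the frustum-mode condition is satisfied identically by this
set.  The default mechanical parameters are the (rounded) balanced values of
a columnar cell with h = 1.797, r = 0.4503, P̂_o = 2.16 — the unique prism
these printed values hold in equilibrium (a/h = 0.25, V = 0.947, ψ = 6.24,
L = 2.70); this shape is the package's reference geometry wherever a cell
must be assumed.  Stability is the positivity of trace and determinant of
the 2×2 shape Hessian, computed from its closed components and
cross-checked against numerical second differences and against
perturb-and-relax dynamics of the vertex model.

## The mechano–polarity feedback

Each cell's normalized mechanics q = (K_a, P̂_o, λ_b, λ_ℓ)/(initial values)
descend the squared deviation of the apical domain from its homeostatic size
ℓ°_domain (default: the cell's own pre-perturbation steady-state value):
dq_k/dt = −c_k · ∂(ℓ_domain − ℓ°)²/∂q_k.  The conversion rates c_k carry
multiplicative Gaussian noise c = c°(1 + ξ), ξ ~ N(0, σ²), redrawn once per
coupling interval (10 iterations) per cell and held constant in between —
interpreted as a fluctuating rate, not a Wiener increment, so no dt^(−1/2)
scaling is applied.

**Sensitivity ∂ℓ_domain/∂q_k.**  Two estimators are provided.

* `equilibrium` (default): the quasi-static response, obtained by
  linearising the isolated cell's closed-form hexagonal-frustum energy
  (three shape degrees of freedom a, b, h) around its current shape and
  solving the 3×3 system dx/dq = −H⁻¹·∂(∇U)/∂q; the domain size responds
  geometrically as dℓ = (s*/L)·dL − da.  This matches a brute-force
  perturb-and-relax probe of the vertex model to a few per cent.  Signs at
  the reference state: (+, −, +, −) for (K_a, P̂_o, λ_b, λ_ℓ) — e.g. more
  lateral tension shortens the cell and shrinks the apical domain, more
  basal tension makes it taller and grows it.
* `step`: a virtual finite-difference probe that advances only the probed
  cell's vertices over a short horizon.  It measures the transient rather
  than the equilibrium response; for the basal-tension channel the two
  differ in sign (the fast transient is apical widening, the slow
  equilibrium is cell tallening), and a feedback loop driven by the
  transient signs settles into basally-pinched, elongating cells instead of
  the short frustum phenotype.  The equilibrium estimator is therefore the
  default.

**Update numerics.**  q updates every 10 iterations with an explicit step.
The conversion gain is 0.02 per unit drive for single-perturbed-cell
scenarios and 0.005 when a whole initiating group modulates at once (the
collective shape change per update is several-fold larger, and the explicit
closed loop destabilises roughly an order of magnitude above these values);
a uniform rate
limiter of 0.05 per component per update that rescales the whole update
vector (preserving its direction; essential under σ = 5 noise where raw
updates would exceed stability), and clipping of q to [0.2, 4] so that no
modulus changes sign or grows without bound.  Cells whose apical domain sits
exactly at its homeostatic value are skipped.

**Scenario conversion-rate sets** (per the respective study conditions):
folding runs (0.2, −0.8, 2.0, 2.0) — note the anti-gradient apical-perimeter
channel, which drives apical constriction while the basal/lateral channels
perform the homeostatic work; perturbation–deformation scans
(1.0, 1.0, 5.5, 5.5); noise sweeps (0.4, 0.4, 5.0, 5.0).

**Perturbation–deformation scan baseline.**  The apical-mechanics scan runs
on a stiffened-apex baseline: K_a ×9 together with P̂_o moved to
6r − (6r − P̂_o)/9, a pair under which the same prism remains exactly
balanced (the frustum condition is invariant).  The scan then reduces the
central cell's P̂_o from that baseline, so the zero-strength configuration
is an equilibrium and the response is continuous in the strength.

**Collective squeeze.**  When a concentric group of initiating cells folds,
the six ring cells reach exact apical-domain homeostasis while the central
cell, compressed by its shortening neighbours, overshoots below its target
domain size.  This is a geometric consequence of collective deformation, not
a numerical artefact; the fold itself and the frustum shapes are carried by
the ring cells.

## Problem sizes and run lengths

Tissue patches are hexagonal: 7 cells (1 ring) for scans and noise sweeps,
19 cells (2 rings) for folding runs, configurable upward.  Per-cell membrane
fields use 256 nodes in tissue runs.  Coupled runs integrate 1 500–3 500
time units at dt = 0.1; homeostatic relaxation times are a few hundred time
units.  These sizes resolve all reported behaviours; larger patches and
durations change the quantitative fold depths but not the orderings.

## What the simulations do and do not show

The tissue here is a clean hexagonal monolayer of identical cells with no
rearrangement (no T1/T2 transitions), no division, no curved reference
geometry, and polarity reduced to one membrane dimension by rotational
symmetry.  Reproduced behaviours — polarized profiles, scaling vs.
remodeling of the junction position, spontaneous folding with apical-domain
homeostasis, threshold-like perturbation responses, robustness of the final
shape to coupling noise — are statements about this idealised system; real
dorsal-fold epithelia add cell heterogeneity, neighbour exchange and
three-dimensional membrane transport that the model deliberately omits.

## Known limitations

* The feedback outcome depends on the sensitivity estimator; only the
  quasi-static estimator yields the short-frustum folding pathway.  This is
  a genuine degeneracy of the phenomenological homeostasis law, not of the
  implementation.
* Deeply folded configurations (fold depth beyond ~2 cell heights) can
  degenerate geometrically; the integrator raises rather than continuing on
  non-finite geometry.
* The explicit FTCS/Euler integrators favour robustness over speed; the
  numba kernels keep runs tractable but no implicit stepping is provided.
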