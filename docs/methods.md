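# Methods

## Model overview

`duofilm` is a 2D individual-based biofilm model of two bacterial
lineages, resistant (R) and susceptible (S), growing on an inert
substratum under a well-mixed bulk liquid. Cells are circular agents of
unit depth (1 um); mass m and radius r are linked by a fixed cytoplasm
density rho through m = rho·pi·r². Cells grow from local solute
concentrations, divide at a threshold radius, and resolve overlaps
mechanically. Solutes diffuse and react on a regular grid and are
assumed to be in pseudo steady state relative to biomass growth. The
model contains no death, detachment, motility, EPS matrix or mutation;
an antibiotic only slows the growth of susceptible cells
(bacteriostatic), so starved or inhibited cells persist and may resume
growth.

## Kinetics and parameters

All growth follows Monod kinetics with hyperbolic inhibition. Default
parameter values: maximal specific growth rate u = 1/h for both
lineages; half-saturation K = 3.5e-5 g/L for nutrients and by-products;
yield Y = 0.5 g biomass per g substrate; inhibitory constants
Ki = 0.1 g/L for both the antibiotic and the toxins; bulk nutrient
0.05 g/L; bulk antibiotic 0 (none), 0.05 (low) or 0.2 g/L (high); one
diffusivity for every solute, 7.2e-6 m²/day = 3.0e5 um²/h. The cost of
resistance c (1/h) reduces R's maximal rate to u − c; at u = 1/h the
absolute and fractional readings of the cost coincide, and the config
accepts either. Growth-coupled detoxification removes alpha grams of
antibiotic per gram of new R biomass on every R growth route; without
growth there is no detoxification, and no degrading enzyme is released.

The four media differ only in their reaction networks: a shared
nutrient (exploitation competition), a shared nutrient plus reciprocal
toxin secretion and inhibition (interference competition), private
nutrients (non cross-feeding), and private nutrients plus reciprocal
by-product secretion and consumption (cross-feeding). In the two
private-nutrient media both N_R and N_S take the single bulk nutrient
value of 0.05 g/L: the model is fully symmetric between the lineages
apart from cost, susceptibility and detoxification, and any asymmetry
in the private supplies would break that by construction. Toxins and
by-products have no bulk supply (bulk value 0): their only sink is
diffusion up to the boundary, plus (for by-products) consumption.

One mass-unit convention is used throughout: lengths in um, time in h,
mass in fg, concentration in fg/um³, which is numerically identical to
g/L.

## Solute solver

Each step the per-voxel biomass of each lineage is obtained by
depositing every cell's mass into its containing voxel (exact
conservation). Every solute field C then satisfies
D·lap(C) + r(C, X) = 0 with Dirichlet bulk values on all nodes above
the biofilm front plus a boundary layer, a mirrored (no-flux)
substratum and laterally periodic boundaries. Defaults: grid spacing
h = 2 um, boundary layer 40 um, domain 258 × 258 um (full scale).

The coupled nonlinear system is solved by outer Picard iteration over
the solutes. For each solute the sink terms are linearised in that
solute's own concentration — a Newton linearisation where the solute
enters its own Monod factor, and an availability-limited quotient
(sink/max(C, floor), floor = 1e-3 of the solute scale) where
consumption does not depend on the solute itself (growth-coupled
antibiotic removal). Each linearised equation is an M-matrix problem
solved by red-black successive over-relaxation (numba-compiled;
a scipy sparse direct solve is the fallback), warm-started from the
previous iterate. Because the cross-feeding loop couples the two
by-product fields with a linear convergence ratio near 0.5, the outer
iteration is accelerated by Aitken extrapolation every third pass. The
outer loop stops when the relative change of every field over one pass
falls below tol = 1e-6 (relative to each solute's bulk value or field
maximum); non-convergence within 500 passes raises an error carrying
the final residual. Non-negativity follows from the M-matrix structure;
a final clip removes round-off-scale negatives. Fields retained between
steps serve as warm starts, which the tests show does not bias the
converged solution (warm-start independence within 10x tol).

The availability-limited linearisation of detoxification means that
where the antibiotic is locally exhausted the effective removal rate is
capped by what diffusion can resupply — consumption can never drive a
concentration negative.

## Growth, division, shoving

Growth is exponential within a step: m <- m·exp(mu·dt) with mu the sum
of the cell's reaction rates at its voxel concentrations (exact under
constant mu, and mu >= 0 always). Default dt = 0.02 h at full scale
(≤ 2% mass change per step); the reduced-scale suites use dt = 0.05 h.
A cell divides when its radius reaches 1.0 um (division mass
rho·pi·r² ≈ 628 fg at rho = 200 g/L); the daughters take mass fractions
f and 1−f with f ~ Uniform(0.45, 0.55) (symmetry breaking; total mass
conserved exactly) and are placed at ±(parent radius)/2 along a
uniformly random direction. Both density and division radius are
configurable; the headline outcomes are insensitive to the division
mass because they are resource- not geometry-limited.

Overlap relaxation displaces each overlapping pair symmetrically along
its centre line by half the overlap depth. Displacements from all pairs
are accumulated and applied simultaneously each sweep — deterministic
without any ordering convention — with mild over-relaxation (factor
1.2, capped so touching is never overshot by more than half the
tolerance) because free space propagates diffusively through a packed
colony. The neighbour list (KD-tree, periodic in x) is reused across
sweeps until accumulated motion invalidates its 0.6 um skin. Cells
pushed below the substratum are *reflected* (y <- 2r − y) rather than
clamped: clamping flattens the bottom layer onto a single height, all
shoving forces become horizontal, and crowded configurations jam.
Should the simultaneous scheme still stall on a symmetric squeeze
(detected as 25 sweeps without a 3% improvement), a single sequential
Gauss–Seidel pass in ascending pair order breaks the symmetry.
Relaxation stops when the largest overlap is below 0.01 um, with a
5000-sweep cap (a warning, not an error).

One simulation step is: rasterise biomass → solve solutes → grow →
divide → shove → advance clock. With a fixed seed the entire pipeline
is bit-reproducible; the only random draws are the inoculum layout and
the division fractions/directions.

## Inoculation

Simulations start with founder cells of half the division mass placed
on the substratum: `random` seeding draws independent uniform lateral
positions for all cells; `segregated` seeding places R uniformly in the
left half-domain and S in the right (two contiguous blocks). A tiny
vertical jitter (≤ 0.01 um) breaks the mechanical degeneracy of a
perfectly collinear founder row; overlaps are then relaxed as above.
Defaults: 120 cells per lineage at full scale (240 in coculture, 120 in
monoculture). Ratio sweeps round counts to the nearest integer at fixed
total. Seeding requests that could not stack within four founder layers
are rejected as configuration errors.

## Metrics and outcome statistics

The segregation index of the focal lineage is
s = (p_local − p_global)/(1 − p_global), where p_global is the focal
fraction of the population and p_local averages, over focal cells, the
same-type fraction among neighbours within 10 um (periodic in x). The
focal cell is excluded from its own neighbourhood — self-inclusion
would bias p_local toward the focal type at low density — and cells
with no neighbour in range are dropped from the average; populations
with fewer than two lineages give NaN. The implementation (KD-tree
pair counting) is verified exactly against a brute-force O(n²) oracle.

Ecological outcomes are differences of final cell counts:
coculture-minus-monoculture per lineage classifies the interaction
(both positive: mutualists; both negative: competitors; mixed:
exploitation). The antibiotic response statistics are
R_co[A>0] − R_co[A=0] (positive: competitive release; negative:
mutualistic suppression) and S_co[A>0] − S_mono[A>0] (positive:
cross-species phenotypic resistance). Counts (not biomass) are the
primary currency; biomass columns are also emitted.

## Experiment suites and scales

The `experiments` module provides seeded, restartable factorials
(medium × antibiotic × composition, cost sweeps, detoxification time
series, seeding arrangement, inoculum size/ratio, antibiotic timing)
with per-replicate and mean series. Three scales: `full` (258 um,
120 cells per lineage, 36 h, dt 0.02 h, 3 replicates), `reduced`
(130 um wide, 160 um tall — headroom for the taller mutualistic
biofilms — 40 cells, 24 h, dt 0.05 h, 2 replicates) and `tiny` (smoke
tests). The reduced design preserves the sign structure of all headline
outcomes while a full condition runs in minutes on one CPU; the
reported problem sizes accompany every result table. Replicate seeds
are derived deterministically from one base seed and shared across
conditions (matched seeds), so paired differences are less noisy.
Because no numeric detoxification coefficient is standard, detox suites
default to alpha = 1 g/g and expose it prominently.

## What the simulations do and do not show

The generator produces idealised communities: symmetric kinetics,
a single shared diffusivity, rigid circles without EPS or death, 2D
geometry, and a constant-composition bulk. Passing tests therefore
demonstrate the internal consistency of the model and the ecological
mechanisms it encodes (resource competition, toxin interference,
cross-feeding, diffusion-limited gradients, growth-coupled
detoxification), not quantitative predictions for any real biofilm.
Outcome magnitudes scale with domain size and duration; only their
signs and orderings are treated as claims.

## Numerical edge cases

Zero biomass yields uniform bulk fields exactly. dt = 0 refreshes the
fields and nothing else. Empty neighbourhoods, single-lineage
populations and zero-duration runs return NaN sentinels or single
snapshots rather than errors. A closed-system variant (no bulk
exchange, finite well-mixed nutrient pool, exact stoichiometric
bookkeeping) exists for mass-balance auditing; it is not used by the
science suites.
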