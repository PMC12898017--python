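# Methods

## Scope and conventions

All lengths are Å, times ns, charges in elementary-charge units,
voltages in mV, temperatures in K; conversions to SI happen only in
`constants.py` (k_B = 1.380649×10⁻²³ J/K, e = 1.602176634×10⁻¹⁹ C, so
1 e/ns = 160.2177 pA). Distance cutoffs are closed (≤) and use the
minimum-image convention with each frame's orthorhombic box.

## GHK electrophysiology

The dilution equation V = −(RT/F)·ln[(α+β)/(1+αβ)] and bi-ionic
equation V = (RT/F)·ln[(γ+β)/(1+β)] are inverted in closed form:
β = (u−α)/(1−αu) with u = e^(−V/RTF), and γ = u(1+β)−β with
u = e^(V/RTF). Closed-form inversion was chosen over numerical
root-finding because it is exact, and its domain analysis is explicit: a
dilution potential admits a non-negative β only inside
(−RT/F·ln α, +RT/F·ln α) ≈ (−17.07, +17.07) mV at the defaults, and
potentials outside raise a non-physical-potential error instead of
silently extrapolating. Defaults α = 1.9 (2-fold NaCl dilution with
activity correction) and RT/F = 26.6 mV are configurable; no temperature
recomputation of RT/F is attempted. The sign convention is
basal-minus-apical with the basal side modified; a `potential_sign`
flag flips measured potentials at the boundary since electrode
orientation differs between rigs.

Table-level analysis averages replicate potentials *before* inversion
(the estimator with the smaller bias at small noise), flags out-of-range
rows and continues. Relative changes in P_Na/P_Cl between conditions are
reported under both conventions — ratio of means and mean of ratios —
because published "reduced to X % of control" statements do not always
say which was used.

## Trajectory containers and I/O

Topologies come from fixed-column PDB parsing (with line-numbered parse
errors and an optional convention that the B-factor column carries
per-atom vdW radii for pseudo-atom fixtures); coordinate frames from
DCD/XTC (via MDAnalysis, ps→ns at the boundary) or from a native
JSON-lines dialect (one frame per line: index, time_ns, box, coords)
chosen so synthetic fixtures are plain text and diffable. Ion species
are recognized from HETATM residue names (including CHARMM aliases SOD,
POT, CLA, …). Polyatomic cations (MA⁺, EA⁺, TMA⁺, TEA⁺) are represented
by their central nitrogen for all distance measurements.

Unwrapping accumulates per-frame minimum-image increments along selected
axes only — no molecule re-imaging — because only displacements matter
downstream. This is exact while true inter-frame displacements stay
below half a box length; violations are undetectable by construction, so
the Brownian generator's sampling stride is chosen to keep per-frame
displacements (drift + ~3σ diffusion) well under L/2.

RMSD uses least-squares (Kabsch) superposition via
`scipy.spatial.transform.Rotation.align_vectors`; RMSF is the atomic
fluctuation about the time-mean position after superposing each frame on
the reference, averaged within residues. The backbone is {N, CA, C, O}
with a Cα-only flag, and the reference defaults to the first frame.

## Brownian synthetic trajectories

Ions are independent overdamped-Langevin particles:
Δx = (D·q·E/k_BT)·dt·ê + √(2D·dt)·η per axis, E = V/L, no ion–ion
interactions and implicit water. This deliberately ignores all dynamics
realism: only the analysis stack is under test, and for non-interacting
drift the exact conductance is the Nernst–Einstein sum
G = Σ N(qe)²D/(k_BT·L²), giving a closed-form recovery target. Defaults
are the study conditions: 333 K, field along x, 80 Å cubic box, 0.5 ps
step, equal cation/Cl⁻ counts. Diffusion coefficients in the species
table are infinite-dilution literature values in Å²/ns (e.g. Na⁺ 133,
Cl⁻ 203, K⁺ 196); they define the generator's ground truth rather than
asserting 333 K transport properties. One RNG stream per simulation,
species in declared order, makes runs bit-reproducible under
refactoring. A `sample_every` stride decouples the integration step from
frame output so 10⁶-step runs stay storable; wrapping is applied along
the field axis only (optionally with reflecting radial walls), matching
how a pore recycles ions through periodic images.

What the generator does *not* emulate: electrostatic ion–ion and
ion–protein forces, position-dependent diffusivity, actual pore
geometry coupling to transport. Passing the recovery tests therefore
demonstrates the correctness of the measurement chain
(unwrap → displacement charge → slope → G = I/V → normalizations), not
the realism of any force field.

## Currents, crossings, conductance

The displacement charge q(t) = Σ q_i(x_i(t)−x_i(0))/L counts a full
box-length traversal of a unit charge as exactly 1 e. Currents fit the
slope over a window defaulting to the last 80 % of the series (bulk
conductivity runs in the source protocol fit the last ~73 % of 15 ns);
an endpoint method (Δq/Δt) is provided as the exact
charge-conservation statement used by the crossing-equivalence check,
since an OLS slope times duration does not equal Δq for non-linear
series. The crossing counter is hysteresis-based: an ion must pass
completely from below the slab to above it (or vice versa) to count,
and slab images repeat with the box period so k box-lengths of drift
count k crossings; it is implemented by tracking, whenever the ion is
outside any slab image, the number of images entirely below it — the
net count is then a difference of integers, immune to dithering at the
slab faces.

Conductance reports both the per-voltage mean of I/V with its SD across
voltages (the source convention for error bars) and the through-origin
OLS slope with its standard error. Per-pore conductance divides by the
number of identical parallel pores rather than assigning ions to pores
geometrically. Bulk conductivity σ = G·L/A; the conductivity-set
regression (OLS with or without intercept, uncentered R² in the
no-intercept case) is provided for simulated-vs-measured comparisons
across salts but printed literature regression values are not used as a
correctness oracle (they could not be reconciled with the accompanying
table under standard OLS conventions).

## Contacts and occupancy

An ion contacts a residue when its center is within 4.0 Å (default) of
any heavy atom of the residue; hydrogens are excluded by default since
heavy-atom contacts are the common convention, with a flag to include
them. Mean contacts per frame and the fraction of frames with ≥1
contact are reported per residue, sorted by occupancy; one ion may count
toward several residues, so summed occupancies bound the contacting-ion
count from above. Channel occupancy counts ions inside a closed cylinder
(default half-length 20 Å, radius 8 Å — invented defaults, always echoed
in output metadata) anchored at the selectivity-filter center, itself
the time-averaged centroid of a user-chosen selection (for claudin-15,
the four pore-center aspartates).

## Pore-radius profiling

r(s) is the maximal clearance min_i(|c−a_i|−R_i) over in-plane centers c
at each station (0.25 Å spacing over ±20 Å by default; vdW table mirrors
HOLE's simple radii, overridable per element or per atom). The search
is 2-D per station rather than 3-D annealing: deterministic and adequate
for near-straight pores. Per station, the clearance is evaluated on a
0.5 Å grid over a ±5 Å window centered on the previous station's
optimum, then *hill-climbed along connected grid cells* before
Nelder–Mead refinement to 10⁻³ Å. The connectivity constraint is the
load-bearing choice: the global maximum of the window often lies in bulk
solvent beyond the pore wall at narrow constrictions, and a walker that
can only climb cannot cross the negative-clearance barrier of the wall
(≈3 Å wide, far wider than the grid step). Radii are clamped at a
configurable 10 Å where the pore opens to bulk. The exhaustive-grid
oracle used in testing evaluates a fixed 0.05 Å lattice windowed around
the walker's centers, with a Lipschitz-bound atom-pruning step for
speed; the averaging layer pools stations over frames and channels
(grids must align) and summarizes each (frame, channel) profile by its
span-mean and minimum, reporting mean ± SD of those. The axial span
entering the single-number summaries is configurable and echoed in the
output, since no canonical choice exists.

## Hydration analysis

Coordination counting uses the species cutoff for water oxygens and, by
default, the same cutoff for protein oxygens (published cutoffs cover
water only; a separate protein cutoff is exposed). EA⁺ is grouped with
the 4.0 Å class. Dehydration events are maximal intervals where the
(optionally moving-average-smoothed) water count drops at least 2 below
the series median; the median baseline is robust to pore-entry
transients, unlike a first-frame baseline, and smoothing defaults to
off (window 1). Dehydration participation attributes each
protein-coordinated (ion, frame) sample to every residue contributing a
coordinating oxygen; frequencies are per-residue fractions of
coordinating samples and intentionally need not sum to 1.

## Pipeline and reproducibility

Three workflows (ephys, trajectory, synthetic) are orchestrated by a
TOML-configured runner with a thin click CLI. Every output file embeds
the fully resolved configuration and seed (a `#` JSON header for CSV, a
`config` key for JSON); CSV floats are formatted with a fixed `%.10g`
so identically-seeded reruns are byte-identical, which is asserted in
the test suite. Stages that need atoms the input lacks (protein for
contacts/RMSD, water for hydration) switch off automatically and can be
forced either way.

## Problem sizes and numerical choices

Test and acceptance problem sizes are chosen as the smallest that make
each check meaningful: conductance recovery uses 8 runs of 10⁶ steps
(0.5 ps step, 500 ns) of 16 ions, where the per-run statistical error of
the transported charge is ≈1 % and the 10 % acceptance band is
comfortably a physics check rather than a noise lottery; the β-recovery
check uses 100 seeds of 8 replicates at 0.5 mV noise (median relative
error ≈2 %); the radius oracle uses 10 randomized ~1000-atom pores at 65
stations each. Degenerate inputs raise typed errors (empty selections,
single-frame RMSF, all-zero voltages, sub-minimum salt sets); ties at
cutoff boundaries resolve inclusively by the closed-≤ convention.

## Known limitations

No ion–ion electrostatics or position-dependent mobility in the
generator; no liquid-junction or activity-coefficient corrections
beyond the fixed α; no PMF/free-energy, residence-time or second-shell
analyses; the pore profiler assumes a near-straight pore with a known
axis (no automatic axis detection); per-pore conductance assumes
identical parallel pores. Quantities that depend on the exact geometry
definition of "inside the channel" (occupancy-region values) are
reproducible only given that definition, which is therefore always
echoed into the outputs.
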