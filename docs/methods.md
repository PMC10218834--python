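# Methods

This note documents the models, conventions and design choices behind each
analysis stage, what the synthetic fixtures do and do not emulate, and the
numerical details a user would need to reproduce or extend the results.

## Coordinates, units and periodicity

All coordinates are stored in ångström; GRO input (nm) is converted on
read. Energies are kJ/mol, charges in elementary-charge units,
temperatures in kelvin, times in ps. Only orthorhombic boxes are
supported — the systems this package targets are solvated in cubic boxes —
and all distance evaluations (hydrogen bonds, pair energies, RDFs) apply
the minimum-image convention when a box is present. Residue ids follow the
input file verbatim so that crystal numbering (TRP-224, LEU-372, MET-374)
survives into every report. Low-level PDB/GRO parsing and writing is
delegated to biotite; the package's own layer adds the topology model
(donor/acceptor flags, bound hydrogens, named rings, per-atom nonbonded
parameters) that the analyses need.

The selection language covers `residue_name`, `residue_id` (with `a to b`
ranges), `name`, `element`, the keywords `water`, `protein`, `ligand`,
`all`, and `and`/`or`/`not` with parentheses. `protein` includes the heme
prosthetic group: for a P450 the heme belongs to the receptor, so
`ligand` (anything that is not protein, water or a common ion) isolates
the organotin.

## Superposition, RMSD and its fluctuation

Each frame is superposed onto the reference by the Kabsch least-squares
fit (computed via scipy's `Rotation.align_vectors`, which guarantees a
proper rotation) on a fit selection — conventionally the protein backbone
or all protein heavy atoms — before the RMSD is measured on a possibly
different selection. The reported "RMSE" of an RMSD time series is its
population standard deviation about the series mean, i.e. a fluctuation
measure; whether the divisor is n or n−1 is immaterial at trajectory
lengths of 10³ frames and population was chosen. An alternative
RMS-about-a-fixed-reference mode is exposed via `series_rmse(...,
about="reference")`.

Ring planes are fitted by principal axes (the normal is the direction of
least variance), not by a cross product of two bonds: a porphyrin is large
and never perfectly planar, and the plane fit degrades gracefully with
pucker, which the `planarity_rms` field quantifies. Normals are
sign-normalised into the +z hemisphere so descriptors are deterministic.
The ring-pair descriptor (R_cen, d, θ) folds θ into [0°, 90°] (the acute
interplanar angle); d projects the A→B centroid vector onto ring B's
normal and is therefore direction-dependent, while R_cen and θ are
symmetric — tests pin this down.

## Clustering

Pairwise frame distances are Kabsch-aligned RMSDs on the analysis
selection. Single linkage at a fixed cutoff is exactly connected
components of the graph with edges at distances strictly below the cutoff,
and is computed that way (scipy csgraph); strict `<` was chosen and the
boundary is tested explicitly. Cluster ids are ordered by decreasing
population with ties broken by the lowest member frame index, and each
cluster is summarised by its medoid (the member minimising summed RMSD to
the rest; ties to the lowest frame index). The medoid differs from the
lowest-energy representative a docking code would report; docking is out
of scope here.

## Hydrogen bonds, π hydrogen bonds and water bridges

A conventional hydrogen bond requires acceptor⋯H distance < 2.5 Å and
donor–H⋯acceptor angle > 120°, with the acceptor an O or N heavy atom.
Both thresholds are strict inequalities and configurable
(`HBondCriteria`). The bond-forming probability of a site pair is the
fraction of frames with at least one qualifying event; because the
literature is ambiguous about whether quoted mean distances average over
qualifying frames only, the result carries both statistics
(`mean_distance` over qualifying events and `mean_distance_all_frames`
over the closest approach in every frame).

π hydrogen bonds (X–H⋯π) fire when the H⋯ring-centroid distance is below
3.0 Å and the H→centroid vector lies within 30° of the ring normal. The
3.0 Å working cutoff sits just above the quantum-chemical H⋯π equilibrium
distance of ~2.72 Å so that equilibrium geometries register with margin;
the 30° cone rejects in-plane (edge) approaches. Both are configurable —
they are detection thresholds, not observables.

Ring-pair categories partition descriptor space: NONE beyond R_cen = 6 Å,
T-shaped at θ ≥ 60°, stacked at θ ≤ 30° with d ≤ 5 Å, otherwise
intermediate. The θ thresholds leave the reference geometries of this
problem domain (≈85° phenyl–heme T-contacts, ≈25° offset stacks)
comfortably inside their categories.

Water bridges are found per frame by building the hydrogen-bond graph
over ligand sites, protein sites and water molecules (donor direction
ignored; a ring label at either end is treated as a π acceptor) and
enumerating all simple paths from a ligand site through 1..max_waters
waters to a protein site. Water identity is the residue id. For a bridge
pattern (fixed endpoints, free water identity), occupancy is the fraction
of frames with at least one matching path, and an exchange is counted at a
frame-to-frame transition where the pattern persists but the set of
bridging water ids changes. Enumeration is exhaustive (networkx simple
paths), so it agrees with brute-force path enumeration by construction —
the acceptance suite verifies this on randomized fixtures.

## Radial distribution functions

g(r) is the observed pair-count histogram divided by the ideal-gas
expectation 4πr²·dr·ρ_target per reference site and frame, with ρ_target
taken from the instantaneous box volume of each frame (correct under NPT).
Reference sites may be atoms or named rings; ring centroids are recomputed
every frame since rings move. Defaults dr = 0.05 Å and r_max = 12 Å
resolve first-shell peaks that differ by 0.2 Å. Under PBC, r_max must not
exceed half the smallest box edge. No excluded-volume correction is
applied below ~1 Å; the raw g(r) is reported. The first peak is the
smallest-r local maximum with a caller-chosen prominence
(scipy `find_peaks`); a monotone g(r) yields an explicit no-peak result.
Peak *heights* depend on the normalisation chosen for centroid references
and are not treated as calibrated observables; peak positions are.

## Energetics

Gas-phase interaction energies are cutoff-free pairwise sums
(E_vdW with Lorentz–Berthelot combining, E_Coul with
k_e = 138.935458 kJ·nm/(mol·e²) expressed per ångström), unlike a
simulation engine's truncated forces: end-state analysis conventionally
uses the full sums. Atom pairs closer than 0.1 Å abort the evaluation —
that is a broken input, not a large energy.

The interaction-entropy estimator −TΔS = k_B T ln⟨exp(βΔE)⟩ is evaluated
by log-sum-exp and is exactly zero for a constant series and non-negative
for any real series (Jensen's inequality) — both tested. Its default
temperature is 298.15 K, kept separate from the Ki→ΔG temperature of
310 K: the estimator temperature enters β and is part of the published
protocol this package follows, even when ensembles were generated at
body temperature; both are configurable and both defaults are reported
side by side rather than reconciled. A running estimate over ~50 series
prefixes supports a convergence flag (relative spread of the final 20 % of
checkpoints below 5 %). The flag is deliberately conservative: the
exponential average converges slowly when βσ exceeds ~2, and at σ =
10 kJ/mol even 10⁶ samples leave a Monte-Carlo scatter of order 1 kJ/mol
about the Gaussian closed form σ²/(2k_BT) — a limitation inherent to the
estimator, not to this implementation.

SASA uses Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points, probe 1.4 Å) and Bondi-style radii; the isolated-atom
closed form 4π(r+probe)² is reproduced to 0.5 % at that resolution. The
nonpolar solvation term is the linear model ΔΔG_SA = γ·ΔSASA − b with
γ = 0.0227 kJ/(mol·Å²) and b = 3.849 kJ/mol (a common end-state
convention; both configurable). The polar term is a pairwise
generalized-Born surrogate with f_GB = sqrt(r² + R_iR_j·exp(−r²/4R_iR_j))
and fixed Born radii across complex/receptor/ligand (single-trajectory
convention). It reproduces the Born ion closed form to 0.1 % and exists to
keep the bookkeeping executable end to end; it is not a Poisson–Boltzmann
solver, and no claim is made that its ΔΔG values match grid-PB results.
The ledger identities (ΔE_gas, ΔG_sol, ΔG_bind sums) hold to 1e-9 on
every table the package produces, and the per-residue decomposition sums
exactly to the total against the union of the decomposed residues.

Ki→ΔG uses ΔG = RT·ln(Ki/1 M) with R = 8.314 J/(mol·K) and T = 310 K by
default, the combination that reproduces published experimental
conversions for the organotin inhibition constants (50 μM → −25.52 kJ/mol,
0.53 μM → −37.24 kJ/mol).

## Synthetic fixtures

Every generator is seeded (`numpy.random.default_rng`) and byte-for-byte
reproducible. Their purpose is planted ground truth, and every planted
parameter is recovered by the corresponding analysis stage in the tests:

- **H-bond fixture** — a three-atom D–H⋯A geometry with the acceptor⋯H
  distance and D–H⋯A angle exact to 1e-9, for boundary testing.
- **Ring pair** — two hexagons with prescribed θ, d and lateral offset.
- **Bridge trajectory** — a ligand-hydroxyl / water / amide motif present
  in a Bernoulli(p) subset of frames, with scripted identity swaps of the
  bridging water.
- **Ideal gas / shell fixture** — uniform points for the g(r) = 1 limit,
  and a ring with n points planted on a hemisphere at an exact radius
  (plus uniform background) for first-peak recovery.
- **Two-state trajectory / planted-RMSD frames** — conformations separated
  by an exact aligned RMSD, planted by scalar root-finding on the
  perturbation amplitude (Brent's method, |error| < 1e-7 Å), for
  clustering truth.
- **Toy complex** — a five-residue pocket (carbonyl acceptor, two amide
  donors, a hydroxyl, an indole-like ring), a heme-like ring, a
  tin-centred ligand (hydroxyl + phenyl + short alkyl tail) and ten
  waters. It plants, simultaneously: a Bernoulli(0.5) hydrogen bond, a
  Bernoulli(0.7) one-water bridge with scripted exchanges, an always-on
  T-shaped phenyl–heme contact (θ jittered ~N(90°, 2°)), and a two-state
  tail motion (9 Å displacement, ≈3 Å ligand RMSD between states) that
  single-linkage clustering at 2 Å must split at the switch frame.
  Default trajectory length is 120–200 frames at a nominal 10 ps spacing.

What the fixtures do **not** emulate: the real aromatase fold and pocket
geometry, force-field-quality parameters (the toy charges/LJ values are
self-consistent but invented; tin is a generic heavy atom), solvent
density, thermalised dynamics, or correlated energy fluctuations. Passing
tests therefore demonstrate correctness of the *analysis machinery* under
known conditions — recovery of planted geometry and statistics — not
predictive accuracy on real MD data.

## Pipeline

Frame windows are specified in ps with inclusive endpoints:
floor((t_end − t_start)/stride) + 1 frames, so a 3–30 ns window yields 271
snapshots at 100 ps and 2701 at 10 ps. Stages run in dependency order
(RMSD → cluster → H-bonds → π–π → bridges → RDF → energetics); a failing
stage is recorded and later independent stages still run. The report
carries a config digest, frame/atom counts and the seed so a run can be
re-executed bit-identically (modulo timestamps). Problem sizes in the test
suite and acceptance script (≤ 200-frame trajectories, ≤ 1000-atom gas
boxes, 10⁶-sample entropy series) were chosen as the smallest sizes at
which every planted statistic is resolved well inside its stated
tolerance.

## Known limitations

- The polar-solvation surrogate is a fixed-radius pairwise GB form;
  per-atom effective Born radii are not computed.
- No normal-mode or quasi-harmonic entropy; the interaction-entropy
  estimator is the only −TΔS route and inherits its slow convergence for
  large fluctuations.
- The selection grammar is deliberately small (no distance-based or
  within-style selections).
- Single-linkage only; no average/complete linkage or dendrogram export.
- Bridge enumeration is exhaustive and intended for interfacial water
  counts (tens of waters), not bulk solvent.
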