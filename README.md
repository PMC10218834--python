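# otbind

Trajectory analysis for organotin–aromatase binding studies.

Organotins (tributyltin, triphenyltin and their hydroxides) are endocrine
disruptors that inhibit aromatase (CYP19A1), the cytochrome P450 that
converts androgens to estrogens. Molecular-dynamics studies of these
complexes lean on a recurring set of analyses: backbone-fitted RMSD and its
fluctuation, single-linkage clustering of binding conformations,
geometric hydrogen-bond criteria and bond-forming probabilities,
water-mediated ligand–water–protein bridges, π–π contact geometry between
the ligand phenyls and the heme, radial distribution functions of pocket
waters, and end-state (MM/PBSA-style) binding free-energy bookkeeping with
the interaction-entropy estimator. `otbind` implements that toolchain as a
tested, reusable library with synthetic fixtures whose ground truth is
planted by construction.

## The core quantities

**End-state free energy.** Binding free energies are assembled from
trajectory snapshots as

    ΔG_bind = ΔE_gas − TΔS_gas + ΔG_sol
    ΔE_gas  = ΔE_vdW + ΔE_Coul
    ΔG_sol  = ΔΔG_PB + ΔΔG_SA

with ΔE_vdW/ΔE_Coul from cutoff-free pairwise Lennard-Jones and Coulomb
sums (Lorentz–Berthelot combining, minimum-image distances), ΔΔG_SA from a
linear solvent-accessible-surface-area model, and ΔΔG_PB supplied either
externally or by the package's pairwise generalized-Born surrogate.

**Interaction entropy.** The entropic penalty is estimated from the
fluctuation of the protein–ligand interaction energy time series,

    −TΔS_gas = k_B T ln ⟨ exp(β ΔE_int) ⟩,   ΔE_int = E_int − ⟨E_int⟩,

evaluated with a log-sum-exp formulation that stays finite for
β·ΔE up to ~700. For Gaussian fluctuations of width σ this has the closed
form σ²/(2 k_B T), which the test suite uses as its oracle.

**Noncovalent contacts.** A hydrogen bond is counted when the acceptor⋯H
distance is < 2.5 Å and the donor–H⋯acceptor angle is > 120°; the
bond-forming probability is the fraction of frames satisfying this.
Ring pairs are described by the centroid distance R_cen, the perpendicular
centroid-to-plane distance d, and the acute interplanar angle θ, and
classified as T-shaped (θ ≥ 60°), stacked (θ ≤ 30°, d ≤ 5 Å) or
intermediate within R_cen ≤ 6 Å. Water bridges are simple paths
ligand-site → water(s) → protein-site in the per-frame hydrogen-bond graph,
with π acceptors (ring centroids) supported at either end.

## Worked example

The synthetic toy complex plants a ligand-hydroxyl → carbonyl hydrogen bond
in half the frames, a (Sn)-O⋯H₂O⋯HN-(MET-374) water bridge in 70 % of
frames, and a T-shaped phenyl–heme contact in every frame:

```python
from otbind.synthetic import make_toy_complex
from otbind.md_model import assign_parameters, select
from otbind.noncovalent import bond_forming_probability, bridge_statistics, classify_pipi
from otbind.geometry import pi_pi_descriptor
from otbind.energetics import ki_to_delta_g, mmpbsa_totals

toy = make_toy_complex(seed=42, n_frames=200, hbond_p=0.5, bridge_p=0.7,
                       exchange_frames=(60, 140))
top = toy.topology
assign_parameters(top, toy.parameter_table)

prob = bond_forming_probability(toy.trajectory, [toy.info["hbond_donor"]],
                                [toy.info["hbond_acceptor"]])
stats = bridge_statistics(toy.trajectory, toy.info["bridge_ligand_site"],
                          toy.info["bridge_protein_site"], select(top, "water"))
desc = pi_pi_descriptor(toy.trajectory[0], top.ring("alpha"), top.ring("HEM"))
table = mmpbsa_totals(dE_vdW=-184.022, dE_Coul=-18.402, ddG_PB=115.953,
                      ddG_SA=-21.718, minus_TdS=29.804)
```

This prints (seed 42):

```
H-bond occupancy:      0.525 (mean d = 2.00 A, mean angle = 176 deg)
Water-bridge occupancy: 0.685, exchanges: 0
alpha-HEM ring pair:   r_cen = 4.69 A, d = 4.58 A, theta = 89 deg -> T_SHAPED
dG_bind (bookkeeping): -78.385 kJ/mol
dG from Ki = 50 uM:    -25.52 kJ/mol
```

The H-bond and bridge occupancies recover the planted Bernoulli rates
(0.5 and 0.7) up to the binomial noise of 200 draws; the exchange counter
reports 0 here because a planted water swap is only observable when the
bridge is occupied in the frames on both sides of the swap. The
bookkeeping total reproduces the published tributyltin-hydroxide component
sum, and RT·ln(Ki) at 310 K converts the experimental inhibition constant
(Ki = 50 μM) to −25.52 kJ/mol.

A config-driven pipeline chains all stages
(`otbind run -c config.yaml`), `otbind validate -c config.yaml` checks a
config, and `otbind fixtures <kind> -o out.pdb` writes any synthetic
fixture as a multi-model PDB.

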