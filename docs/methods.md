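# Methods

`gateworks` analyzes conformations of major-facilitator-superfamily (MFS)-like
membrane transporters: whether their two gates are open or closed, whether the
permeation pathway is sterically and electrostatically sealed, what spin–spin
distance distributions a DEER experiment would see, and how an ensemble of
conformations clusters. This note records the models behind each stage, the
parameters that matter, the numerical choices, and what the synthetic fixtures
do and do not establish.

## Gate order parameters

MFS transporters alternate between cytoplasmic-open and periplasmic-open
states through occluded intermediates. Two geometric order parameters track
the gates: the Cα–Cα distance of the closest-contact residue pair of
transmembrane helices 4 and 10 (cytoplasmic gate) and of helices 1 and 7
(periplasmic gate). For LacY these pairs are E126–C333 and I32–N245; the
bundled table (`data/mfs_gate_pairs.tsv`) carries equivalent pairs for twelve
transporters. A pair is *frozen* on a reference structure
(`derive_gate_pair`: exhaustive minimization over the helix-pair cross
distance matrix, ties broken toward lower residue numbers) and then followed
across frames. Re-deriving the minimum per frame would make traces
discontinuous when the contact migrates; freezing avoids that by design.

State classification is a quadrant rule with cutoffs d_cyt < 13 Å and
d_peri < 8 Å for a closed gate. These defaults summarize the span of occluded
conformations in simulation and crystal structures; they are observations
promoted to configurable cutoffs, not sharp physical constants, and both are
exposed in the configuration. The fourth quadrant (both gates open) is
labeled `leak` — a state an alternating-access transporter must avoid — so
that the classifier is total. Bundled LacY helix ranges are reconstructed
approximations and overridable; on real structures you should supply your own
helix definitions.

## Pore-radius profiles

The profiler measures, for each height z along the membrane normal, the
radius of the largest sphere that fits among the atoms of the slab
|z_atom − z| ≤ 3 Å (the half-width admits atoms whose spheres intrude into
the plane): it maximizes min_i(|c − x_i| − r_vdw,i) over in-plane centers c.
The maximization runs Nelder–Mead refinements from a 5 × 5 grid of starts in
a configurable search box. Local optima that run into the box boundary are
open solvent rather than pore and are reported only when no interior maximum
exists (boundary-limited sentinel, radius capped at 15 Å); an empty slab
yields an infinite "unbounded" radius. This deterministic per-slab
maximization differs from HOLE's annealed connected-path search: profiles of
strongly kinked pathways can differ near the kink, and radii are attributed
to the slab's z rather than to a curvilinear pore coordinate. Ensemble
profiles are per-bin means ± SD over frames, with a configurable frame
stride. A pore radius below the water radius (~1.4 Å) at both gate bands is
the steric signature of an occluded conformation.

## Water density and pathway connectivity

Per-frame water positions are histogrammed on a regular grid (default 1 Å
spacing), time-averaged, and divided by the bulk number density of SPC water
at standard conditions (0.970 g/cm³ → 0.03243 Å⁻³); out-of-grid waters are
dropped and counted. Aqueous connectivity between two compartments is decided
on the thresholded relative-density field by connected-component labeling
(26-connectivity by default; 6-connectivity for a stricter face-sharing
criterion). Raising the threshold can only disconnect, never reconnect — the
monotonicity tested as an invariant. Because water occupancy is sampled
stochastically, connectivity verdicts on synthetic data use several frames
and a relative-density threshold of 0.5.

## Proton electrostatics

The energetics of a solvated proton are modeled in the Born picture: a charge
q = +1 in a spherical cavity whose radius is fixed by the experimental
hydration free energy of the oxonium ion through the Born equation

    a = −166 Å·kcal/mol · q² / ΔG*_solv · (1 − 1/80),

giving a = 1.4848 Å for ΔG*_solv = −110.4 kcal/mol. The detailed proton
hydration structures (Eigen/Zundel interconversion) are deliberately
coarse-grained away; the dominant physics is the electrostatics of a charge
near low-dielectric regions.

The position-resolved free energy is

    W_elec(r) = G(protein + ion at r) − G(protein) − G(ion in bulk),

with every G a *reaction-field* energy from a two-solve scheme: the linear
Poisson–Boltzmann (LPB) equation is solved in the heterogeneous environment
and in uniform vacuum (ε = 1) on identical grids, and G = ½Σqφ is taken on
the difference. Grid self-energies then cancel exactly by construction
rather than approximately in the final subtraction. The protein term is
evaluated on the same ion-centered grids as the protein+ion term, and the
bulk ion reference is a separate pure-water system; all three terms use the
same dielectric rules.

Dielectric environment (defaults): water ε = 80; protein interior ε = 10
(points within vdW + 1.4 Å probe of an atom); implicit membrane slab normal
to z with a 33.5 Å ε = 2 hydrophobic core and 6.5 Å ε = 20 headgroup layers
on each side (hard shells — a smoothed boundary belongs to implicit-solvent
MD models, not to this PB analysis); solvent-accessible interior points
(e.g. from `cavity_points`, a HOLLOW-style probe-fits lattice at 1 Å
spacing) override the protein assignment back to ε = 80; the ion cavity
(ε = 1) overrides everything. Mobile-ion screening is Debye–Hückel at
100 mM, 298.15 K (λ_D ≈ 9.7 Å) and is restricted to ε = 80 voxels: mobile
salt cannot penetrate protein or membrane. 

The FD-LPB solver discretizes ∇·(ε∇φ) − κ̄²φ = −4π k_e ρ with a 7-point
stencil. Face dielectrics are harmonic means; edges whose endpoints disagree
are sub-sampled at 9 interior points and combined harmonically (a series
combination of segments), which is what makes the sphere boundary of the
small ion cavity accurate at ~0.5 Å grid spacing. Charges are spread
trilinearly; the outer boundary takes screened-monopole (Debye–Hückel)
values; focusing proceeds through three levels — desk-scale default
(120 Å, 65³) → (60 Å, 65³) → (30 Å, 65³), each finer level taking boundary
values interpolated from the previous — with a full-scale schedule
(250/100/50 Å at 129³) selectable in configuration. The symmetric
positive-definite system is solved by Jacobi-preconditioned conjugate
gradients to a 1e-6 relative residual (cap 20 000 iterations;
non-convergence raises with the residual). At the desk-scale schedule the
two-solve Born energy of the proton ion in uniform water lands within ~0.5%
of the analytic value, and refining 33³ → 65³ shrinks the error by an order
of magnitude; at very fine grids the error oscillates at the ~1% level with
how the cavity boundary lands between nodes, so convergence claims are made
on coarse-to-desk refinement. Final-level energies change by < 5% between
65³ and 81³ grids. In a protein-free membrane the landscape rises
monotonically from ≈ 0 in bulk water to > 100 kJ/mol (≈ 215 kJ/mol at desk
scale) at the core center — the proton-leak barrier an occluded transporter
must maintain. Points assigned ε < 80 are flagged as desolvation-regime
(the Born cavity there overlaps low-dielectric material, so W is large and
grid-sensitive) but still reported.

## DEER distance distributions

A weighted rotamer library of the spin label, expressed in a canonical
side-chain frame, is attached rigidly to the backbone triad (N, Cα, C;
right-handed orthonormal frame with origin at Cα) of each labeled residue.
Rotamers whose atoms approach any non-excluded protein heavy atom closer
than the clash cutoff are discarded and the surviving weights renormalized.
The default cutoff is 2.0 Å; a more permissive 1.5 Å is appropriate for
tight sites where the stricter cutoff would discard everything (the
per-site cutoff is a `LabelSite` field). The excluded set defaults to the
entire labeled residue — the site is conceptually mutated to the label —
and hydrogens are ignored throughout (crystal structures lack them). The
spin position is the midpoint of the two reporter atoms (the nitroxide N–O
midpoint in a real library). Distances of all surviving rotamer pairs of
two sites, weighted by the independent product w_A·w_B, are histogrammed
into 1 Å bins over 0–80 Å (the usual display range). Ensembles average
per-frame distributions with equal weights, skipping (and logging) frames
where a site loses all rotamers. Library weights are treated as
backbone-independent; conditional (backbone-dependent) weighting is not
modeled.

## Conformational clustering and interaction traces

Frame-frame RMSD matrices use optimal least-squares superposition (Kabsch,
unit weights — no mass weighting) over a configurable atom selection, in nm.
Clustering follows the greedy neighbor-count algorithm of Daura et al.: the
frame with the most neighbors within the cutoff (default 0.25 nm, all
protein atoms) becomes a center, its neighborhood is removed, and the step
repeats; ties break toward the lower frame index so results are
deterministic. Salt-bridge formation (e.g. the R302–E325 interaction that
locks the occluded state of LacY) is traced as the per-frame *minimum*
distance between atom groups, defaulting to Arg NH1/NH2/NE against Glu
OE1/OE2; whether a published distance is an atom pair or a group minimum is
often unstated, so the group definition is configurable and recorded in
output metadata.

## Synthetic fixtures

The generator suite produces geometry with the features the analyses assume,
with no physical realism (no force field, lipids, or sugars):

- `make_bundle` — two half-ring domains of six idealized helices each
  (20 residues, 1.5 Å rise, bundle radius 9 Å) around the z axis, membrane
  midplane at z = 0. Helix termini taper 5 Å inward, pinching both faces
  sterically shut at gate fractions 0. Gate opening fractions (0–1)
  displace the domains apart (±x) by up to 8 Å with a ramp from the
  midplane, so the two faces open strictly monotonically and independently.
  Anchor residues (terminal Cα of the interface helix per domain per face)
  are recorded for gate tracking.
- `make_transition` — linear interpolation between conformations plus
  isotropic Gaussian noise (an idealized stand-in for a biased transition
  trajectory).
- `soft_ratchet_sample` — Brownian proposals accepted with probability
  exp(−δ/Δφ) when they increase the best-fit-RMSD progress variable toward
  a target (always when they decrease it). Δφ = 1e-4 Å behaves as a soft
  ratchet, 1e-6 Å as a nearly hard one; the progress variable is refit at
  every accepted step (not every 10 steps as an MD engine would). The
  acceptance rule itself is this package's design choice for a
  soft-ratcheting bias.
- `make_rotamer_library` — articulated five-atom arms growing along the
  canonical Cβ direction with Dirichlet weights; a synthetic stand-in for a
  published nitroxide-label library with the same interface.
- `fill_cavity_waters` — Poisson-sampled positions at a target number
  density, rejected within 2.6 Å of any atom (a hard-sphere water contact,
  not a physical model).

Passing tests on these fixtures demonstrate the correctness of the
*computations* — closest-contact minimization, histogram bookkeeping,
component labeling, PB discretization, rigid-frame attachment — under known
geometry. They do not demonstrate agreement with experiment on real
transporters: fixtures have no side-chain packing, no real rotamer
statistics, no equilibrium conformational distribution, and their "waters"
are ideal-gas points. The two crystal-structure checks (XylE gate
distances, LacY pore minimum) run whenever the corresponding PDB files are
placed under `tests/data/external/`.

## Problem sizes

Defaults are desk-scale by choice: 65³ focusing grids (the full-scale 129³
schedule is one config flag away), 5–10-frame synthetic ensembles, 8-frame
clustering matrices, ≤ 12-rotamer libraries. All generators and the pipeline
are deterministic for a fixed seed, and identical configurations reproduce
identical numeric outputs on a fixed platform.
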