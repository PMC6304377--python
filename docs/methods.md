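# Methods

`helixmodes` analyses ensembles of membrane-embedded helix pairs the way
self-assembly simulation studies of receptor transmembrane domains are
analysed: many independent replicas of two helices are started apart in the
membrane plane, allowed to associate, and the *binding modes* of the bound
dimers are discovered as density basins in an orientation space, then
characterised energetically and geometrically. Because no experimental
coordinates exist for the systems this machinery targets, the package ships
synthetic generators with planted ground truth, so every analysis operation
is validated by parameter recovery.

## Orientation coordinates and binding modes

A bound helix pair is reduced to two angles on a 360°-periodic torus:

- **β** — where partner B sits around A: the in-membrane-plane angle,
  measured about A's axis, from A's reference-residue wheel direction to the
  projected A→B inter-axis displacement;
- **χ** — which face of B points at A: the same construction evaluated on B
  toward A.

With this convention (0°, 0°) is the configuration in which the two
reference faces touch. Any self-consistent convention yields the same mode
structure; this one was fixed because it makes the origin interpretable.
Both angles are invariant under global rotation about the membrane normal
and under translation (tested), and spinning helix B by +δ about its own
axis shifts χ by −δ while leaving β unchanged.

Mode discovery follows the watershed recipe used for orientation maps of
dimerization ensembles:

1. histogram the bound samples on the (β, χ) torus (5° bins),
2. smooth with a wrapped Gaussian (σ = 10°),
3. segment by a watershed on the negated density with periodic boundary
   handling — the density is tiled 3×3, the non-periodic watershed is
   applied, the center tile is cropped, and labels are canonicalized by
   their wrapped peak position so basins straddling the seam are merged,
4. merge basins holding < 5% of the bound samples into the neighbor sharing
   the longest boundary.

Two numerical guards make step 3 robust on finite samples. Watershed
markers are seeded only at maxima that (a) survive h-maxima reconstruction
with h = 2% of the density range and (b) rise at least 6 Poisson standard
deviations above the median density. For a Gaussian-smoothed count
histogram at background level *b* the counting noise is
√(b / 4πσ_bins²); without this filter, Poisson ripples on the flat
bound-state background seed spurious basins. Second, bins below that
significance level are left **unassigned**: they belong to the flat
background rather than to any mode, so mode populations are well-local and
do not depend on where a watershed boundary happens to wander through a
featureless region. Populations over modes plus the unassigned fraction sum
to one; frame assignment distinguishes `unbound`, `unassigned`, and mode
labels, and replica population curves carry all three.

All thresholds (bin width, smoothing, floor, prominence, significance) are
keyword arguments; the values above are the defaults used everywhere in the
package.

## Energetics

Bead-pair energies are switched Lennard-Jones plus cutoff Coulomb under the
minimum-image convention. The LJ term is multiplied by a C²-continuous
quintic switch from 0.9 nm to 1.2 nm, and the Coulomb term (uniform
relative dielectric, default 15) by the same switch from 0 to 1.2 nm, so
energies and forces are continuous at both boundaries (verified by finite
differences). Association criteria:

- **dimer**: inter-monomer interaction energy ≤ −200 kJ/mol (boundary
  equality counts as bound),
- **oligomer**: energy ≤ −800 kJ/mol *and* buried surface area strictly
  greater than 10% of the complex surface.

The package ships a deliberately minimal bead-parameter table — four
one-bead-per-residue classes (C apolar, N aromatic, P polar, Q charged,
σ = 0.47 nm, radius 0.23 nm, charges only on K/R/D/E). The per-class ε
values (18–20 kJ/mol) are calibrated once so that a docked helix pair at the
surrogate's contact separation scores −300 to −600 kJ/mol: safely a dimer
under the −200 kJ/mol criterion and safely *not* an oligomer. They are
effective residue-level contact energies, roughly the magnitude of
statistical contact potentials when a whole residue is one interaction
site; no claim of force-field realism is made.

Contact maps are average minimum inter-bead distances per inter-chain
residue pair over a trailing analysis window (50 ns default). Interaction-
energy profiles average per-residue inter-chain energies over the same
window, clamp net-repulsive residues to zero (flagged in the output), and
normalize the attractive magnitudes to relative contributions summing to
one; the normalization is a package convention since relative-contribution
plots in the literature rarely define one. Salt bridges are oppositely
charged residues whose charged beads approach within 0.6 nm (a coarse bead
diameter plus margin; configurable).

SASA is deterministic Shrake–Rupley sampling with a Fibonacci lattice of
2000 points per bead (probe 0.19 nm). 2000 points keeps the two-sphere
buried-area error within 2% of the closed-form spherical-cap value across
all separations (960 points peaks at 2.3%). BSA = SASA(A) + SASA(B) −
SASA(A∪B); the criterion fraction divides by the complex surface, and the
monomer-sum denominator is reported alongside for reference.

## Geometry

Helix axes are fitted by principal component analysis of the backbone bead
cloud followed by a Gauss–Newton cylinder refinement (minimal variance of
the bead-to-axis distances). The refinement matters: a 32-residue helix at
100°/residue ends mid-turn, which biases plain PCA by ~0.6°; the cylinder
fit recovers the construction axis of an ideal helix to machine precision
and stays within 2° under 0.05 nm isotropic bead noise. Axes are oriented
N→C. Tilt is the unsigned angle to the membrane normal in [0°, 90°].
The crossing angle is the dihedral of the two axes about their connection,
folded into (−90°, 90°]; right-handed packing is negative by the common
membrane-protein convention. Helical-wheel positions advance 100°/residue
from a reference residue; face classification assigns residues to
configurable wheel sectors, and the packaged definition encodes the
conserved (TM-C) and class-specific (TM-S) faces of the IgM heavy-chain
transmembrane helix anchored on its published interface residues.

Superposition is a hand-rolled Kabsch (SVD with determinant correction)
rather than a library call because exact-fit inputs must return RMSD ≤ 1e−9
(library wrappers lose precision in the residual). RMSD is reported in Å
while coordinates are nm. The stability summary of an RMSD trace is the
mean over the trailing 20% of frames, a package convention.

## The association surrogate

The generator is a membrane-confined overdamped rigid-body model, not
bead-resolved MD. Two upright helices carry four in-plane coordinates
(two positions) and two spins. The potential is

- a long-range harmonic attraction toward contact (k = 0.8 kJ/mol/nm²),
- a narrow Gaussian contact well at 0.95 nm separation (depth 10 kT,
  σ = 0.08 nm; doubled when binding is flagged irreversible),
- a stiff harmonic core below 0.85 nm,
- an orientation potential, gated by a smooth envelope that vanishes beyond
  ~1.6 nm, with wrapped-Gaussian wells at the planted (β, χ) modes.

Every coordinate follows Euler–Maruyama overdamped Langevin dynamics with
mobility μᵢ = Dᵢ/kT and noise √(2Dᵢdt) — diagonal mobility with matching
noise, so the stationary distribution is exactly Boltzmann in the full
configuration space, and the bound-state (β, χ) marginal is the Boltzmann
weight of the planted orientation potential. That identity is the
generator's central property: it lets mode populations measured by the
analysis pipeline be compared against numerical integration of the planted
potential.

Defaults define the study conditions and were chosen once: 100 replicas,
1000 ns of toy time at 1 ns/frame, initial center-of-mass separation 5 nm
with independent uniform in-plane rotations; kT = 2.577 kJ/mol (310 K);
translational diffusion 0.03 nm²/ns; spin diffusion 1000 deg²/ns; 100
integrator substeps per stored frame; default planted wells at (60°, 120°)
and (240°, 300°), width 15°, depths 6 kT and 3 kT (a 2:1 ratio). The large
spin diffusion and fine time step are sampling choices, not physics: they
give each replica ~10 transitions between wells per run (so trailing-window
populations are equilibrated) and keep the Euler–Maruyama discretization
bias in well occupancy below ~0.01 (at 50 substeps it reaches ~0.05). Well
depths are deep enough that the wells, not the flat bound background,
dominate the populations, and shallow enough to remain ergodic on the run
length. Ground truth per frame is the wrapped-nearest planted well when the
axis separation is below 1.1 nm.

Population comparisons integrate exp(−V/kT) on a 1° grid either over
wrapped-nearest-peak cells or over the watershed basins actually
discovered; the latter is used for recovery checks so that the arbitrary
position of a basin boundary inside the flat background cancels between
measurement and reference.

What the surrogate does *not* emulate: bead-resolved packing (helices are
rigid and upright; tilt is a descriptor, not a degree of freedom),
lipid-mediated forces, multi-body association, and any real kinetics —
times are "toy ns". Passing recovery tests therefore demonstrates the
correctness of the analysis chain, not fidelity of the surrogate to any
molecular system.

## The lipid-mixture surrogate

A 64×64 periodic lattice of DPPC/DIPC/CHOL sites (40:30:30, realized
exactly by largest-remainder rounding, initially shuffled) evolves by
Metropolis swaps of random site pairs (adjacent pairs are skipped so the
swap energetics stay exact). Couplings: DPPC–DIPC +1, DPPC–CHOL −0.5,
DIPC–CHOL +0.5, scaled by a single `coupling` factor (0 = ideal mixing;
2 = strong demixing) at unit temperature. An optional fixed block of
protein sites (3×3) interacts with neighboring lipids through per-species
affinities; the planted raft-philic protein uses (DPPC −8, DIPC −4,
CHOL 0) — strong enough that a wetting layer of the preferred lipid
nucleates at the protein rather than the protein's fate depending on where
the domains happen to coarsen.

Phases are assigned compositionally: a lipid site is *ordered* when
DPPC+CHOL hold the majority of the lipid sites within a circular
neighborhood of radius 2 sites. Demixing is quantified as
1 − f_obs/f_exp, where f_obs is the DPPC–DIPC fraction of lipid–lipid
neighbor contacts and f_exp its value under random mixing, clipped to
[0, 1]. Protein domain preference averages protein–DPPC and protein–DIPC
contact energies over a trailing window (500 ns of toy time), normalizes
them to shares, and classifies by the ordered-contact fraction: ordered
above 0.6, disordered below 0.4, interface between. Both the energy-share
and contact-fraction views are reported because published domain-preference
claims are usually qualitative.

The lattice model has no chain-order physics, no registration between
leaflets, and no hydrodynamics; non-local swaps trade kinetic realism for
fast equilibration.

## Pipeline and reproducibility

`helixmodes.pipeline.run` executes the workflow steps (assembly → modes →
energetics → stability → domains → oligomers → report) from a `RunConfig`
(YAML), with every threshold a named option defaulting to the published
values (−200/−800 kJ/mol, 10% BSA, 50 ns and 500 ns windows). All
generators are pure functions of (spec, seed): identical configurations
produce bit-identical trajectories, lattices and JSON summaries. The CLI
(`helixmodes <verb>`) is a thin wrapper with exit codes 0/1/2 for
ok/config error/runtime error.

Problem sizes used by the shipped tests and the acceptance script — 100
replicas × 1000 ns for mode recovery, 64×64 × 2×10⁶ swaps for the lattice,
≤200-bead systems for brute-force energetics oracles — were chosen as the
smallest ensembles at which the statistical guarantees above hold with
comfortable margin.

## Known limitations

- GRO files carry no chain field; chains are split on residue-number
  decrease, and times are read from a `t=` token interpreted in ns.
- Orthorhombic boxes only; the minimum-image convention is applied to all
  distances.
- The β/χ construction needs a reference residue off the helix axis and
  fails (by design, with a clear error) for coincident centroids or pairs
  stacked along the membrane normal.
- Interface areas and RMSD bands quoted in the membrane-protein literature
  presuppose chemically detailed structures; with the toy bead table the
  package reproduces *relationships* (larger interface ⇒ larger BSA;
  stable complex ⇒ flat RMSD trace), not absolute literature values.
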