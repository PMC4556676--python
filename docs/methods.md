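# Methods

This note documents the scientific and numerical choices behind `mpslab`:
the implicit membrane model, the score terms and their parameters, the
sampling protocols, what the synthetic fixtures do and do not emulate, and
the known limitations.

## The slab membrane

The membrane is a flat slab of hydrophobic thickness *T* (default 30 Å,
covering the hydrophobic core plus the interfacial regions) described by a
center, a unit normal and a sigmoid steepness *k*. Depths are signed
projections onto the normal; the half-thickness (15 Å) is always derived
from *T*, never stored separately. The hydration fraction

f(z) = u^k / (1 + u^k), u = |2z/T|, k = 10

is the single transition function every depth-dependent term uses. The
functional form is the classic implicit-membrane sigmoid; k = 10 gives a
transition zone of roughly ±5 Å around the slab boundary and is
configurable. The sign of the normal (which leaflet is "up") is not
derivable from a structure alone; it defaults to the direction of the first
transmembrane span and can be set explicitly.

Coordinates are ångströms in a right-handed frame. After
`transform_into_membrane` the membrane normal points along +z. A protocol
either moves the protein with the membrane fixed, or the membrane with the
protein fixed; the choice is an explicit argument of each protocol rather
than an implicit property of a kinematic tree, with the same observable
behavior.

## Spans and embedding

A residue is membrane-embedded iff |z(CA)| ≤ T/2. A span is a maximal
consecutive embedded run within one chain whose flanking CA depths (or the
run's own terminal depths at chain ends) lie on opposite sides of the
midplane — the crossing requirement excludes interfacial surface helices.
Runs shorter than `min_len` (default 4 residues) are discarded; both the
length threshold and the crossing requirement are options, since
half-inserted helices are a genuine modeling decision. Residue numbers are
author (PDB) numbers, preserved verbatim.

A span's embedding is the midpoint and unit direction of its two anchor CA
atoms. The protein embedding averages span centers and span normals after
flipping any normal anti-parallel to the first span (so antiparallel
bundles average coherently). Spans are averaged unweighted regardless of
length; length-weighting is a possible refinement. This estimator wobbles
by roughly the helix radius over the span length (a few degrees, 1–2 Å),
which is why "transform of a structure already in membrane coordinates" is
the identity at estimator resolution, not machine precision.

`optimize_embedding` searches a depth offset along the membrane normal and
two tilts of the normal (±10 Å / ±30° coarse grid, then coordinate-wise
quadratic refinement to 10⁻³). Derivative-free search was chosen because
score tables may be depth-binned, making analytic gradients unavailable;
the contract the protocols rely on is monotone descent and determinism, and
the optimizer never returns a placement worse than its input. With an
environment-only score, tilting is always weakly favorable (it shrinks all
depths), so searches meant to recover a pure depth shift should freeze the
tilt range; the relax protocol uses the full search.

## Score function

High-resolution terms (atom level):

- **env_atom**: Σ over atoms of (1 − f(z)) · ΔG_transfer(category). The
  shipped transfer table distributes the Fauchère–Pliška side-chain octanol
  partition scale (sign-flipped to water→membrane) over side-chain
  heavy-atom categories by least squares; arginine's three guanidinium
  nitrogens form their own category so that the delocalized guanidinium and
  the localized lysine ammonium both reproduce their per-residue values
  exactly (fit RMS 0.25 kcal/mol over the 20 residues). Backbone atoms
  carry 0 by convention — the scale covers side chains only.
- **solv**: symmetric Gaussian-exclusion desolvation with per-category
  reference free energies ΔG_ref(z) = f·ΔG_water + (1 − f)·ΔG_membrane,
  correlation length 3.5 Å, 9 Å cutoff. Apolar carbon has a small positive
  reference (burial is favorable — the hydrophobic effect), polar and
  charged groups negative ones. The backbone reference is kept small
  (−1 kcal/mol) because helical backbone amides are internally hydrogen
  bonded and largely pre-desolvated; a large backbone value makes every
  helix–helix contact look like a desolvation catastrophe.
- **hbond**: a geometric gate (donor–acceptor heavy atoms ≤ 3.5 Å, angle at
  the acceptor ≥ 120°) on a fixed per-bond energy (−1), multiplied by
  1 + (w − 1)(1 − f(z_mid)) with w = 2 by default — hydrogen bonds are
  twice as strong at the slab center as in water. Because the model has no
  explicit hydrogens, two physical rules keep it honest: a donor donates at
  most one bond (to its nearest gated acceptor), and an unordered atom pair
  counts once (a hydroxyl–hydroxyl contact is one bond, not two). Without
  donor saturation, helix backbone donors — already satisfied by the
  i→i−4 ladder — would form spurious cross-partner bonds and riddle every
  docking landscape with −2 pockets.
- **packing**: 12-6 Lennard-Jones with σ = r_i + r_j from a Bondi-type
  radius set, split into an attractive part (clamped at −ε inside contact)
  and a repulsive part that is zero at and beyond σ and linearly capped
  below 0.6σ. The cap avoids the steep-gradient blowups that make
  rigid-body searches from clashed starting points diverge. Pairs within
  three bonds (template connectivity plus peptide bonds) are excluded.

Low-resolution terms (residue level): a residue×depth propensity table
(default derived from the same octanol scale modulated by 1 − f), pair and
neighbor-count potentials (shipped as all-zero placeholders — no invented
statistics are presented as fitted potentials; users supply their own text
tables), and three penalties: non-helical residues inside the slab within a
span (helicity from the dihedral window φ ∈ (−100°, −30°), ψ ∈ (−80°, −5°)
when no assignment is supplied), chain termini inside the hydrophobic layer,
and span ends projecting past the slab boundary (in Å). The termini penalty
is also available in the literal opposite reading (penalize termini outside)
behind a switch, since both conventions appear in the literature.

All tables are plain text with `# key: value` provenance headers and
round-trip exactly. Default weights are 1.0 for every enabled term — a
neutral, documented starting point; no claim of compatibility with any
other package's energy units is made. Binned lookups floor to their bin;
out-of-range depths use the flanking bin.

## Protocols

**Rotamer trials.** Side chains are rebuilt from idealized templates
(biotite's bundled chemical component dictionary) superimposed on the local
N/CA/C frame; χ angles are set by rotating the distal bond graph. The
rotamer set enumerates {−60°, 60°, 180°} per χ plus the input conformation
— a desk-scale stand-in for a statistical rotamer library. Repacking visits
movable residues in a seed-shuffled order and accepts only strict
improvements, so the final score never exceeds the initial one; it stops
when a full pass changes nothing (max 5 passes).

**ΔΔG.** The mutated position is rebuilt with idealized geometry in *both*
branches (so the identity mutation is exactly zero and ΔΔG(A→B) =
−ΔΔG(B→A) by construction); all residues with any heavy atom within 8 Å of
the mutated residue are repacked with the same seed and schedule in both
branches; ΔΔG = E(mutant) − E(native).

**Relax.** Alternates a full repack with membrane embedding optimization
(default 8 cycles). Both halves are monotone, so the per-cycle totals are
non-increasing.

**Docking.** Prepack separates the partners 100 Å in the membrane plane,
repacks interface side chains (heavy-atom pairs < 8 Å across partners, the
same radius as the ΔΔG shell), and restores the pose. Each model applies a
seeded initial perturbation (one 3σ move of each kind) and 50 Metropolis
proposals at kT = 1 over membrane-constrained moves of the moving partner
only — in-plane translation σ 0.7 Å, spin about the membrane normal σ 3°,
tilt σ 2°, depth shift σ 0.25 Å — followed by a 25-proposal greedy quench
at half amplitude and a final interface repack. The membrane stays fixed.
The interface score is E(complex) − E(partners separated 500 Å in-plane at
fixed internal conformation); ligand RMSD is computed over the moving
partner's CAs after superposing the fixed partner. Only the all-atom stage
is implemented; a centroid pre-stage is unnecessary for local docking from
a near-native start.

**Symmetric assembly.** The C_n complex is generated by rotating the
asymmetric unit about the membrane normal through the membrane center.
Each model first slides the subunit radially into contact (greedy 0.25 Å
steps while the score improves), then runs the same MC schedule with
radial/spin/depth/tilt moves; every proposal is propagated exactly to all
copies, so symmetry holds to machine precision at all times. The interface
score is E(complex) − n·E(isolated subunit), the cumulative score of all
symmetric interfaces. Model selection everywhere is lowest interface score,
ties broken by total score then model index.

## Synthetic fixtures

Fixture backbones are grown atom by atom (natural-extension reference
frame) from ideal bond geometry at φ = −57°, ψ = −47°, ω = 180°; recomputed
dihedrals match to 10⁻⁶ degrees and the CA rise is ≈ 1.56 Å per residue —
the value this dihedral pair actually produces with standard bond geometry,
slightly above the textbook 1.5 Å. Builders are bit-deterministic given
their spec.

- *helix*: single ideal helix, axis +z, CA centroid at the origin.
- *hairpin*: two antiparallel arms joined by a short synthetic loop above
  the slab; the loop is rigid-piecewise, not dihedral-continuous, which is
  sufficient for CA-level span and embedding work.
- *bundle*: n helices on a circle, either exactly C_n-replicated (the
  assembly native) or with seeded per-helix tilt jitter for span-detection
  stress tests. The C_n native is polished to the interface-score optimum
  over radial offset, spin, depth and two tilts (coarse tilt multi-start +
  Nelder–Mead), because helix bundles pack best with a supercoil-like tilt
  and the untilted pose is not the minimum.
- *dimer* (docking fixture): a two-helix fixed partner forming a groove
  (chains A and C, 8.2 Å apart) and a moving helix (chain B) packed into
  the groove, polished over all six rigid degrees of freedom the same way.
  A groove was chosen over a single-helix partner because a smooth
  poly-alanine helix pair is nearly cylindrically degenerate: any azimuth
  and registration of contact scores alike, so no unique native exists for
  a funnel to find. The double contact localizes the pose geometrically.

What passing tests on these fixtures show: the geometry, span, embedding
and scoring machinery is internally consistent, the samplers descend and
are reproducible, and the score function's funnels on *designed* landscapes
are found. What they do not show: accuracy on real membrane proteins —
fixtures have ideal backbones, no loops (beyond the synthetic hairpin
linker), no β-barrels, no prosthetic groups, and landscapes far smoother
than experimental structures.

## Numerical conventions

Dihedrals follow the IUPAC sign convention (validated against an
independent structural library). Rotamer restoration keeps the exact input
coordinates rather than rebuilding, so "no change" is bitwise. Metropolis
acceptance draws a uniform variate only when the move is uphill, keeping
trajectories deterministic per (seed, model index) via independent
`default_rng([seed, model])` streams. The packing term truncates (not
shifts) at its 6 Å cutoff; the resulting discontinuity is ~10⁻² of ε and
irrelevant at the sampling amplitudes used. Degenerate inputs (collinear
superposition sets, zero normals, zero-length spans) raise typed errors
rather than returning garbage.

## Problem sizes

The shipped test-suite and acceptance-script scales are: 21-residue
helices, a 4×21-residue C4 bundle, a 63-residue docking fixture; 200
docking models and 300 symmetric-assembly models per funnel experiment;
100 seeded random bundles for the span-detection oracle. These sizes give
stable funnel statistics across seeds while keeping a full run in minutes
on one CPU.

## Known limitations

- No internal-coordinate kinematics or backbone flexibility: all protocols
  are fixed-backbone; proline mutations that require backbone adjustment
  are therefore poorly modeled by construction.
- The pair and neighbor-count potentials default to zero; the shipped
  transfer/propensity tables are scale-derived, not database-derived.
- No lipophilicity-prediction term, no membrane-dielectric electrostatics,
  no pH/protonation sampling, no curvature or variable thickness — the
  membrane is a flat slab of fixed thickness.
- The hydrogen-bond model is heavy-atom geometric; without explicit
  hydrogens, donor direction is approximated by the saturation rule.
- Docking is local: starts are perturbations of a given pose, and global
  (blind) docking is out of scope.
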