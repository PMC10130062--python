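# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `minimet`, in the order the design workflow runs.

## Structures, symmetry, and geometry

Structures are an ordered chain → residue → atom hierarchy with author
numbering preserved; gemmi handles PDB/mmCIF parsing, PDB writing and
the space-group operator table. Alternate conformers are reduced to the
highest-occupancy one (tie → first encountered), a deterministic rule
that avoids carrying altloc semantics through the geometry code.
Symmetry expansion applies every space-group operator combined with
lattice translations of −1/0/+1 along each axis and keeps mates with
any atom within the query radius; fractional↔orthogonal conversion uses
the standard crystallographic orthogonalization matrix with **a** along
x (the PDB convention).

Superposition is the Kabsch algorithm with the determinant correction,
so only proper rotations are returned; collinear point sets are
rejected because the rotation about the line is then undetermined.
Dihedrals follow the IUPAC sign convention. One point worth recording:
a torsion angle is *invariant* under reversal of the four-atom order —
it is mirror reflection that negates it — and the tests assert exactly
that pair of properties.

χ¹ rotamers are classed by nearest canonical value with g⁺ ↦ +60°,
t ↦ 180°, g⁻ ↦ −60° and boundaries at 0°/±120°. The g⁺ ↔ +60°
orientation is one of two conventions in circulation; it is fixed here
and used consistently, so a mirrored assignment in external data would
show up as a systematic g⁺/g⁻ swap rather than noise.

"Backbone RMSD" means N/CA/C/O unless the caller restricts the atom
set; the CLI exposes `--atoms` for the CA-only or N/CA/C readings.

## Miniaturization

The twofold is computed from the molecule's own pseudo-symmetry: the
two CXXCX half-sites are paired residue-by-residue (configurable), the
Kabsch transform mapping one onto the other is converted to axis–angle
form, and the deviation of the fitted angle from 180° is reported as
the pseudo-symmetry diagnostic. When the dimer is generated the
rotation is snapped to exactly 180° about the fitted axis line —
design requires exact symmetry; the deviation is diagnostic output,
never propagated into coordinates. A supplied metal is kept once,
projected onto the axis. Interchain heavy-atom contacts below 2.0 Å
are attached as a warning, not an error, because a clashing dimer is
still a legitimate intermediate for loop search.

## Loop closure and turn census

Gap length is the number of intervening residues; the matched window
has L+2 residues and both anchors are fitted jointly (8 atoms, one
rigid fit), which is the standard two-ended closure criterion. Windows
with numbering breaks, missing backbone atoms, or consecutive C–N
distances above 2.5 Å are skipped. Hits are sorted by anchor RMSD;
the default cutoff is 1.0 Å.

Grafting splices the transformed loop between the rotated copy and the
original fragment and renumbers from 1. Junction C–N bonds outside
[1.2, 1.45] Å attach a geometry warning; beyond 2.0 Å the hit is
rejected as ungraftable.

β-turns are classified from φ/ψ of the two central residues against
the canonical table (I, I′, II, II′, VIII, III, III′), requiring
Cα(i)–Cα(i+3) ≤ 7 Å, all four angles within ±30° with one allowed
±45°; unmatched chain reversals are type IV. Types III/III′ are kept
distinct from I/I′ (they are absorbed into I/I′ in modern schemes)
because the turn census distinguishes them; a near-tie is broken by
the smaller summed angular deviation, with III/III′ preferred only
when ψ(i+2) is more than 25° from 0°. No i→i+3 hydrogen bond is
required — open turns found by loop searches are counted.

Hydrogen bonds between backbone groups use the Kabsch–Sander
electrostatic model, E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
kcal/mol with the −0.5 kcal/mol cutoff; amide hydrogens absent from
the input are built 1.0 Å from N along the external bisector of the
C(prev)–N and CA–N bonds (prolines and chain starts excluded). Motif
assignment on top of the bond list: two consecutive i→i+3 bonds mark a
3₁₀ stretch, an isolated i→i+4 bond an α-turn (consecutive i→i+4 bonds
are α-helix), Kabsch–Sander ladder rules give strands and antiparallel
pairing, and a one-residue interruption on one strand of a ladder is a
β-bulge.

## Metal-site analysis

First shell: the four M–S distances, six S–M–S angles, the
tetrahedricity score (RMS deviation of the six angles from
arccos(−1/3) = 109.47°) and the two cross-dyad Sγ–M–Sγ–Cβ torsions,
pairing ligand k with ligand k+2 in sequence order — the pseudo-dyad
partner in a two-half-site fold.

N–H···Sγ detection uses criteria appropriate for sulfur acceptors
(longer than for oxygen): donor–S ≤ 3.6 Å, H···S ≤ 2.9 Å,
N–H···S ≥ 120°, all configurable. Side-chain donors (Asn/Gln amides,
Arg guanidine, Ser/Thr/Tyr hydroxyls) are screened on heavy-atom
criteria only — distance plus an antecedent–donor–acceptor angle ≥ 90°
— because their proton positions are rotatable or ambiguous and
building them would manufacture precision the data does not have.

Crystal contacts classify atom pairs against symmetry mates within
4.0 Å: Arg/Lys side-chain N to Asp/Glu carboxylate O within 4.0 Å is a
salt bridge, any N/O/S pair within 3.6 Å an H-bond, the rest generic
contacts. Survey statistics for Zn–S geometry (2.34 ± 0.03 Å,
109 ± 4°) are bundled as constants for z-scoring rather than re-derived
from a live database query, for reproducibility.

## Zero-field splitting and rhombicity

For S = 5/2 the Hamiltonian H = D[S_z² − S(S+1)/3] + E(S_x² − S_y²) is
diagonalized exactly (6×6); each Kramers doublet's effective g along
axis k is the intra-doublet splitting per unit Zeeman probe
g₀·b·S_k, with b reduced until halving it changes no component by more
than 10⁻⁴ — the weak-field limit (microwave quantum ≪ |D|), which is
the regime where effective g values are field-independent. g₀ defaults
to the free-electron 2.0023, the standard choice for high-spin ferric
analysis.

Rhombicity estimation scans E/D over [0, 1/3] in steps of 0.001 (D > 0
ordering). Observations are matched by spectral region, as
practitioners read rhombograms: resonances with g > 5.5 lie on the
sharp, strongly E/D-dependent branches of the *outer* doublets and
form the objective; mid-field resonances (the broad g ≈ 4.3 region,
whose apparent position is dominated by E/D strain and intensity
effects) are assigned to their nearest *middle*-doublet branch and
reported with residuals but do not steer the estimate — unless no
low-field observation exists, in which case the middle-doublet match
drives the scan (so an isolated g = 4.29 maps to the rhombic limit
E/D = 1/3). A single equally-weighted objective over all nine branch
components was considered and rejected: it lets the strain-broadened
4.3-region feature drag the estimate along branches that carry little
rhombicity information.

## Electrochemistry

CV analysis splits the sweep into monotone segments, smooths with a
Savitzky–Golay filter (window 11, order 3 by default; smoothing shifts
ideal peaks by well under 1 mV), and takes the anodic peak as the
current maximum of the rising sweep and the cathodic as the minimum of
the falling one, requiring a minimal prominence (5% of the current
span) so flat traces flag "no peaks" instead of raising. E½ is the
peak midpoint plus the reference offset (+0.206 V converts Ag|AgCl,
3 M NaCl, to SHE); ΔE_p = E_pa − E_pc, with 59 mV the one-electron
Nernstian benchmark at 25 °C.

The Randles–Ševčík fit is linear least squares of |i_p| against √ν
through the origin; D and its standard error follow from the slope by
the delta method. Default cell parameters: n = 1, A = 0.0707 cm²
(3 mm diameter disc), C = 8×10⁻⁸ mol/cm³ (80 µM), T = 288.15 K (the
measurement temperature of the freely diffusing protein experiments).

## Binding and optics

The 1:1 isotherm uses the exact quadratic solution
[PL] = ((P+L+K_D) − √((P+L+K_D)² − 4PL))/2 with signal
ε·[PL]·l + baseline, fitted by bounded least squares. In the
tight-binding regime (K_D ≪ P) the titration is a stoichiometric
breakpoint and only an upper bound on K_D is identifiable; a fit
collapsing onto the zero bound (or with K_D below its own standard
error) is flagged as an upper-limit estimate, which is the honest
reading of such data.

ε₂₈₀ = 5500·nTrp + 1490·nTyr + 125·n(cystine) M⁻¹cm⁻¹; the one-letter
code B is accepted for the non-absorbing Aib (2-aminoisobutyric acid)
used in miniature scaffolds. Beer–Lambert conversion returns µM from
absorbance, ε in mM⁻¹cm⁻¹ and pathlength in cm.

## Hydrodynamics

`bead_model_diffusion` estimates the rigid-body translational
diffusion coefficient from heavy-atom coordinates. The default
`method="shell"` is a shell-model calculation: each heavy atom is a
sphere of radius 3.1 Å (an effective atomic radius that absorbs the
hydration layer), the exposed surface of the fused-sphere body is
tiled with minibeads, the 3N×3N Rotne–Prager–Yamakawa mobility
supermatrix of the shell is inverted into the translational friction
tensor, and the result is linearly extrapolated to zero minibead size
from radii s and 2s/3 (default s = 1.5 Å) — a fixed-size shell
overestimates the hydrodynamic radius by about s/2. Translation–
rotation coupling is neglected, which is accurate for roughly globular
bodies.

`method="kirkwood"` implements the classical double-sum approximation
D_t = (kT/N)[1/(6πησ) + (1/(6πη))(1/N)Σ_{i≠j}1/R_ij] with one bead of
radius σ = 3.1 Å per heavy atom. It has exact closed forms for one and
two beads (used as test oracles) but neglects finite bead size in the
interaction terms and therefore *overestimates* D_t by tens of percent
for compact globules — verified directly against the shell treatment —
which is why it is an option rather than the default. Defaults
T = 288 K and η = 1.138×10⁻³ Pa·s (water at 15 °C) match the
electrochemical conditions; both are explicit parameters.

## Synthetic data: what it emulates, and what it does not

All test inputs are generated, none downloaded. The generators are
deterministic under a fixed seed (identical bytes).

* `make_ideal_site` builds an exactly tetrahedral M(Cys)₄ site with
  prescribed bond length, cross-dyad torsions and χ¹ rotamers by
  internal-coordinate placement. Defaults (d = 2.34 Å, torsions
  180°/159°, t/g⁺ alternation) are the geometry a well-formed
  rubredoxin-type zinc site exhibits.
* `backbone_from_dihedrals` places backbones from ideal bond lengths
  and angles (N–CA 1.458, CA–C 1.525, C–N 1.329 Å); re-measured
  torsions reproduce the inputs to < 10⁻³ degrees.
* `make_synthetic_template` is a stand-in for a rubredoxin-like
  template: a 13-residue fragment whose knuckle torsions are solved
  (deterministic least squares, solution frozen as a module constant
  and re-verified in tests) so its two thiolates sit exactly on
  tetrahedral vertices, plus the exact C2 image with optional seeded
  jitter, and a loop-bridgeable terminus separation. It reproduces the
  *topology* the miniaturization operates on, not any real protein's
  coordinates.
* `make_mini_library` writes random-coil decoys (φ/ψ drawn from broad
  β/α basins, which keeps accidental anchor matches at tight cutoffs
  vanishingly rare) plus planted windows stored under random rigid
  motions with companion stub pairs. `close_gap_loop` closes a given
  stub pair numerically by optimizing the loop's free torsions — test
  machinery for planting solvable search problems, not an analytical
  closure method.
* `make_synthetic_design_pair` deforms a 28-residue backbone by
  smooth, seeded noise rescaled so the optimal-superposition backbone
  RMSD equals the requested value exactly. It exercises the
  superposition machinery; the RMSD value itself holds by
  construction.
* `make_compact_globule` places ~7.8 heavy pseudo-atoms per residue
  uniformly in a sphere at the mean folded-protein density
  (110 Å³/residue, minimum separation 1 Å) — a compact-miniprotein
  stand-in for hydrodynamics. It has no sequence, secondary structure
  or surface texture.
* `make_crystal_contact_fixture` places a minimal molecule in a C222₁
  cell so a twofold mate realizes prescribed Tyr-OH···HO-Tyr,
  guanidine–carboxylate and guanidine···Sγ contacts by construction.
* `make_measurements` draws titrations, peak-current tables and
  effective-g observations from the package's own forward models with
  seeded Gaussian noise; the effective-g set reports the two sharp
  low-field markers (ground-doublet g_y, top-doublet g_z).

Because these fixtures realize their target geometry by construction,
passing tests demonstrate that the *analysis* code measures, searches,
classifies and fits correctly — they do not constitute a re-derivation
of any deposited experimental structure's numbers.

## Problem sizes

The shipped configuration keeps every stage small enough to run
comfortably on one CPU: fragment libraries of 10–20 short chains,
28-residue scaffolds, ~220-atom hydrodynamic models, 100-seed
simulation studies for the noise-recovery checks. All are module
parameters and scale up without code changes.

## Known limitations

* No flexible or sequence alignment: residue correspondence is by
  author numbering or an explicit pairing.
* No analytical loop closure (CCD/kinematic); the search is purely
  library-based, which is the point of the method.
* Sequence design of the scaffold (side-chain packing, flexible-
  backbone optimization) is out of scope; the pipeline emits backbone
  plus template side chains.
* The motif annotator covers the vocabulary miniature scaffolds need
  (strand/bridge/bulge, 3₁₀, α-turn, β-turns); it is not a full DSSP
  replacement (no π-helices, no full sheet topology graphs).
* EPR support is the weak-field effective-g limit; no lineshape or
  resonance-field simulation, no strain modeling.
* The hydrodynamic shell model omits translation–rotation coupling and
  uses a single effective atomic radius; expect a few percent bias for
  strongly anisometric molecules.
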