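# minimet

Symmetry-guided miniaturization and validation of tetrathiolate
metalloproteins.

Rubredoxins — the smallest iron–sulfur proteins — bind a single iron
through four cysteine thiolates in a near-tetrahedral Fe(S<sub>γ</sub>)₄
site, cycling Fe(II)/Fe(III). Their fold carries an internal pseudo-C2:
two CXXCX "knuckles", each donating two thiolates, related by a twofold
axis. `minimet` implements the design calculus that exploits this
symmetry to shrink the fold into a single miniature chain, together
with the structural and biophysical analytics used to validate the
result:

* **Miniaturization** — dissect a contiguous fragment containing one
  half-site, recover the molecule's own twofold from the half-site
  correspondence (Kabsch fit → axis–angle), and regenerate the partner
  half by an exact 180° rotation (`miniaturizer`).
* **Loop closure** — a systematic fragment search: for every gap length
  *L* = 1…7, every contiguous window of *L*+2 library residues is
  superposed by the N/CA/C/O atoms of its two anchor residues (one
  joint rigid fit) onto the dimer's termini; windows within 1 Å
  backbone RMSD are hits, four-residue hits are typed as β-turns
  (I/I′/II/II′/VIII/III/III′ by canonical φ/ψ), and the best hit is
  grafted into a single renumbered chain (`loop_closure`).
* **Structure validation** — M(Cys)₄ first-shell geometry (four M–S
  distances, six S–M–S angles vs. the ideal arccos(−1/3) = 109.47°,
  cross-dyad S–M–S–Cβ torsions, χ¹ rotamers), N–H···S<sub>γ</sub>
  second-sphere hydrogen bonds, crystal-packing contacts via
  space-group symmetry expansion, Kabsch backbone RMSD, and
  DSSP-style motif annotation (`metal_site`, `motif_annotator`,
  `geometry_core`, `structure_io`).
* **Biophysics** — effective g values of the three Kramers doublets of
  an S = 5/2 zero-field-split center
  (H = D[S<sub>z</sub>² − S(S+1)/3] + E(S<sub>x</sub>² − S<sub>y</sub>²))
  and rhombicity E/D estimation from observed EPR resonances;
  cyclic-voltammetry peak analysis and Randles–Ševčík diffusion fits
  (i<sub>p</sub> = 0.4463 nFAC·√(nFνD/RT)); exact quadratic 1:1
  binding isotherms; ε₂₈₀ and Beer–Lambert bookkeeping; and a
  HYDRONMR-style bead/shell estimate of the translational diffusion
  coefficient (`biophys`).
* **Synthetic data** — deterministic generators for every input the
  analyses need: ideal tetrahedral sites, backbones built from
  canonical φ/ψ, C2-related half-site templates, fragment libraries
  with planted loops, titrations, peak-current tables and effective-g
  observations (`fixtures`).

## Worked example

Build an ideal Zn(Cys)₄ site and report its coordination geometry, then
read the rhombicity of a ferric S = 5/2 center off its EPR resonances:

```sh
$ minimet fixtures ideal-site --out site.pdb
$ minimet site site.pdb --metal ZN
{
  "mean_distance": 2.34,
  "mean_angle": 109.47,
  "torsions": [180.0, 159.0],
  "tetrahedricity": 0.0,
  "chi1_classes": {"CYS2": "t", "CYS5": "g+", "CYS17": "t", "CYS20": "g+"}
}
$ minimet rhombogram --gobs 9.15,4.26
{
  "e_over_d": 0.204,
  "assignments": [
    {"observed": 9.15, "doublet": 0, "axis": "y", "predicted": 9.151, "in_objective": true},
    {"observed": 4.26, "doublet": 1, "axis": "x", "predicted": 3.760, "in_objective": false}
  ],
  "d_positive": true
}
```

The site report confirms a textbook tetrathiolate center: mean M–S
bond of 2.34 Å, all six S–M–S angles at the tetrahedral value, the two
cross-dyad torsions at 180°/159°, and the t/g⁺ χ¹ alternation of the
coordinating cysteines. The rhombogram scan places the ferric center
at E/D ≈ 0.20 with D > 0: the sharp low-field g = 9.15 feature pins the
ground-doublet g<sub>y</sub> branch, while the broad g ≈ 4.3 feature is
assigned to the middle doublet.

The full design pipeline runs the same way from the shell:

```sh
minimet miniaturize template.pdb --chain A --range 38:50 \
    --half-sites 6-10,39-43 --metal Fe --out dimer.pdb --report mini.json
minimet loopsearch dimer.pdb --library LIBDIR --out hits.csv
minimet graft dimer.pdb --library LIBDIR --hits hits.csv --trim 1 --out model.pdb
minimet annotate model.pdb
minimet site model.pdb --metal FE
```

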