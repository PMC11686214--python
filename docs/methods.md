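# Methods

This note records the models, numerical choices and limitations behind
fibrilkit, in the package's own words.

## The unit-cell model and its symmetry

The antiparallel polyQ core is modeled as an infinite untwisted lattice
whose minimal repeating unit holds eight glutamines in a 2×2×2 arrangement:
two residues along the strand axis x (the odd/even side-chain alternation),
two strands along the fibril axis z (the antiparallel repeat), and two
β-sheets along the stacking axis y.  The four Gln–Gln pairs of the cell
each adopt one of eight hydrogen-bond classes.  A class is coded by three
binary attributes: the laboratory-frame χ1 orientation tag of each of the
two residues (`p` ≈ +62° or `m` ≈ −65°, written as the equivalent rotamer
well of a +x-running strand) and the donor→acceptor direction of the
side-chain amide ladder along z.  The orientation tags are deliberately
lab-frame: a symmetry operation that reverses a strand's running direction
maps a residue with a given intrinsic χ1 onto a slot whose label is the
opposite tag.  Dihedral values themselves are of course rotation-invariant;
only the labels transform.

The symmetry group is declared in config and closed/verified at load.  The
default generators are the sheet translation along y, the strand
translation along z re-expressed in the cell frame (which swaps the
within-pair slots and flips the orientation tags, because the shifted
strand runs the other way), and the two in-plane 2-fold rotations about
the fibril axis z and the strand axis x.  Their compositions include the
remaining 2-fold about y and the screw translation along x; the closed
group has order 16.  Acting on the 4096 raw assignments it yields 320
orbits, and the strand-uniformity filter — both pair classes of a sheet
must agree in their well tags, so that every strand is built from a single
conformer — leaves exactly 30 canonical candidates.  Canonical forms are
the lexicographic minimum over the orbit with slots ordered x-fastest,
then y.  Alternative generator phrasings that treat the orientation tags
as intrinsic wells were tested exhaustively and never reproduce the
30-candidate catalog; the lab-frame convention is therefore part of the
model definition.

Conformer tags attach per intrinsic χ1 well: `a` for the well of the
pt20° rotamer (χ1 ≈ +62°), `b` for mt-30° (χ1 ≈ −65°).

## The β-strand scaffold

Builders require a strand that is simultaneously exactly periodic and
exactly faithful to its backbone torsions.  Both hold when the per-residue
screw of a uniform (φ, ψ, ω) chain is an exact two-fold (2₁): the
two-residue repeat is then a pure translation.  With ideal bond geometry
this pins an isolated solution near the antiparallel-β point,
(φ, ψ, ω) ≈ (−138.97°, +136.03°, +180.41°), with a rise of 0.347 nm per
residue.  Both conformers share this scaffold by default; the small
per-conformer ψ differences resolved by ssNMR are not modeled in the
ideal builder (they emerge only after force-field relaxation, which is out
of scope).  The frame is oriented by the backbone carbonyls (C=O along
±z, towards the neighbouring strands); the side chains then point ±y with
the small tilt that pleating imposes.

The antiparallel partner strand is the 2-fold image about a y-parallel
axis.  Its registry — an x offset δ and a z offset ζ of the axis — is
solved once per geometry by maximizing backbone N···O hydrogen-bond
quality on both inter-strand gaps while forbidding steric overlap; the
shipped geometry gives δ = −0.05 nm, ζ = +0.03 nm, with N···O ≈ 0.29 nm
in both the narrow (0.41 nm) and wide (0.53 nm) gap of the resulting
mildly dimerized spacing (mean 0.47 nm, the cross-β constant).

## Glutamine ladder realization

For each hydrogen-bond class and each column side (+y / −y interfaces are
geometrically inequivalent because of the pleat) the builder solves the
two residues' (χ1, χ2, χ3), plus up to ±8° of the two inner side-chain
bond angles, so that successive amides stack head-to-tail with both
Oε1···Nε2 steps at the 0.285 nm target (window 0.26–0.31 nm, motivated by
the 2.7–2.9 Å distances known for glutamine ladders in amyloids).  The
solve is a deterministic coarse grid plus least squares with a
fixed-seed global fallback; solutions are cached per geometry.  All 16
contexts close at exactly 0.285 nm, and the realized angles essentially
reproduce the pt20°/mt-30° nomenclature values — the rotamers observed by
ssNMR fall out of the ladder geometry.

Five of the 30 candidates stack a sheet of uniform-p strands on a sheet of
uniform-m strands.  Their ladders close, but no orbit image can also
interdigitate the two sheets without a few side-chain overlaps per cell;
these architectures carry an interface geometry warning rather than
failing the build outright.  (They belong to the family that microsecond
simulations eliminate.)

## Fibril builders

**Periodic core lattice.**  Default 5×2×4 cells = 40 cells = 320 Gln,
i.e. four antiparallel sheets of eight strands of periodic Q10 peptides.
Chains are wrapped into the box whole (atom-wise wrapping would cut
covalent bonds across the periodic seam).  Builders emit solute-only,
unminimized coordinates; solvation and energy minimization are
deliberately out of scope.

**D₂Q₁₅K₂ fibril.**  Seven sheets of eight Ace-capped peptides with an
uncharged C-terminus, quasi-infinite along z.  Asp/Lys flanks continue
the β conformation; their side chains come from ideal residue templates.
The stack's heavy-atom extent along y is ≈ 6.24 nm, inside the 5.5–6.5 nm
TEM range.

**Q44-HTTex1 protofilament.**  Seven sheets × twenty β-hairpins = 140
chains of the full exon-1 sequence (N17, Q44, the 50-residue PRD with
oligoprolines at PRD positions 1–11 and 29–38).  Design choices:

* Only F17 of N17 sits on the core lattice register; the hairpin's second
  arm is one slot longer, so its far end reaches past F17 and F17's
  closest cross-strand register is the penultimate glutamine.
* Arm 2 pairs across the narrow, hydrogen-bonded gap *below* arm 1 — the
  natural tight-turn registry (CA–CA span across the turn ≈ 0.43 nm).
  Arm 2 is placed rigidly on its lattice slot; the six turn-region
  torsions are solved (and re-drawn per chain) around a type-I′ template
  to minimize the covalent junction strain, which remains ≈ 0.2–1 Å — an
  accepted idealization, like the rigid swing junctions below.  The solved
  turn stays within the classifier's 40° basin of type I′.
* Turns of neighbouring hairpins sit on opposite fibril ends (alternating
  hairpins are 2-fold images), so each hairpin pairs one `a` with one `b`
  arm while the per-slot conformer alternation of the lattice is kept.
* N17 (helical over residues 4–11, coil elsewhere) and the PRD (PPII
  oligoprolines, extended linkers) are rigid idealized rods swung about
  their junctions into the chain's own sheet plane along prescribed,
  sheet-parity-alternating tilts; this deterministic layout makes the rod
  families parallel translates with analytically separated crossings.
  Residual grazes are handled by seeded per-chain retries (torsion jitter,
  rod-spin, tilt jitter) against the already placed atoms, the exact core
  atoms of all future chains, and the nominal exit lanes, followed by a
  global rotamer-repair pass.

A fully clash-free (0.15 nm) rigid assembly of a 140-chain brush at
0.83 nm sheet spacing is not generally reachable without energy
minimization.  The Q44 builder therefore always raises on core–core
clashes, but by default only *reports* residual coat grazes
(`provenance["residual_coat_contacts"]`; at the full 140-chain scale on
the order of a thousand grazing pairs, i.e. roughly one percent of atoms
involved at depths ≤ 0.05 nm, concentrated in the proline-rich segments
whose rings cannot be re-rotamered); `coat_clash_policy="strict"` turns
them into errors.  Downstream minimization removes them trivially.

## Stability statistic and elimination

S(t) counts, per frame, the residues whose χ1 and χ3 lie strictly within
90° (circular distance) of their reference values, normalized by 2N.
Only χ1/χ3 enter; χ2, φ, ψ are carried for conformer analysis.  The
reference defaults to the first frame.  Checkpoints use the nearest frame
at or before the checkpoint time (never peeking forward); survival is
strict (S > 0.9); a checkpoint beyond the trajectory end is marked
unevaluated and fails rather than silently passing.  Instantaneous
(unsmoothed) values are used at checkpoints.

## Conformer analyses

Rotamer classes pt20° (62, 180, +20), mt-30° (−65, 180, −30) and pm0°
(62, −65, 0) use half-widths of 45° on χ1 and χ2; χ3 is unconstrained by
default because in ladder geometries the amide orientation is set by the
hydrogen-bond network, not the rotamer well.  Mutual exclusivity of the
configured windows is verified at load.  ssNMR windows ship as wide
(χ1 ±50°, χ2 ±50° about 180°, ψ ±45°) per-conformer estimates — the
published constraints are graphical — and compliance below 1 is an
observation, never an error.  Ladder detection groups glutamine amides
into z-columns (sheet, x-column, side) and scores Oε1···Nε2 steps with a
heavy-atom cutoff of 0.32 nm (models are built without hydrogens, so no
donor-angle term applies).  β-turns are typed by root-mean-square circular
deviation from canonical type-I′/type-II templates with a 40° radius.
Secondary structure uses a single documented φ/ψ-region rule (helix:
φ ∈ [−100, −30], ψ ∈ [−80, −5]; strand: φ ∈ [−180, −90],
ψ ≥ 90 or ψ ≤ −150; else coil, which includes PPII) for both dihedral
and coordinate input; the mode is recorded in the report.  No
Kabsch–Sander assigner is re-implemented, so bit-exact agreement with
external DSSP variants is not claimed.

## Brush theory

The ideal-solvent closed form b_max = (N a² / 2π³ σ)^¼ is exact; the PRD
parameters (N = 50 residues, a = 0.4 nm persistence length, σ = 0.7 nm⁻²)
give b_max ≈ 0.655 nm, i.e. 0.7 nm at one decimal.  A good-solvent
correction has no closed form here; an opt-in multiplicative factor is
exposed and the ideal-solvent value remains primary.  Probes penetrate
when size ≤ b_max (boundary inclusive).

## Synthetic data: what it does and does not show

The generators emulate the statistical structure of the screening
experiment, not its physics: wrapped-Gaussian fluctuation about reference
angles, far-well flips of 120–180° with exponential waiting times, an
exact flip-fraction mode (S = 1 − f/2 analytically), i.i.d. uniform
angles, and helical/coil flanking-domain mixtures with known composition.
Cohorts of 30 trajectories with 2 planted stable members exercise the
elimination protocol at desk scale.  Passing these tests shows that the
statistics, filters and protocols are implemented correctly; it does not
show that any particular architecture is stable under a force field —
that judgement requires the microsecond simulations the generators stand
in for.  All generators are bitwise reproducible for a fixed seed.

## Problem sizes

The default test and reproduction runs use the full 4096-candidate
enumeration, 2×1×2-cell builds for the 30-candidate ladder scan, the full
5×2×4 (320-residue) reference lattice, the full 56-chain peptide fibril,
and the full 140-chain protofilament; synthetic trajectories use 320
residues over ~100 frames.
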