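# Methods

## The restraint model

A monomer description assigns each chemical building block a set of
atoms and ideal internal geometry: bond lengths, bond angles, torsion
angles with a periodicity, planar groups with a per-atom deviation
sigma, and chiral centres with a volume sign (the sign of the scalar
triple product of the three centre→neighbor vectors). Each monomer
belongs to one chemical group — peptide, P-peptide (proline-like),
M-peptide (N-methylated), DNA, RNA, pyranose, ketopyranose, furanose or
non-polymer — which generic link selectors use. A link description
selects two sides (a specific component id, or a group), carries
restraint templates that span the new covalent bond, and prescribes one
modification per side: an ordered list of add/delete/change edits to the
monomer description, applied when the bond forms. Deleting an atom
cascades to every template referencing it; a change overrides only the
fields it names. All of this is read from CIF dictionaries in the
public monomer-library tag vocabulary (`_chem_comp_atom`,
`_chem_comp_bond`, `_chem_comp_angle`, `_chem_comp_tor`,
`_chem_comp_plane_atom`, `_chem_comp_chir`, `_chem_link_*`,
`_chem_mod_*`, `_chem_comp_alias`); unknown tags are warned about, not
rejected, to stay tolerant of library variants.

An alias table is a bijection from a monomer's own atom names onto the
standard names of its group. Link matching, modification application
and link-template instantiation all operate in standard names; the
inverse table translates back so the model's original names are
preserved in every output. A partial table (covering only the atoms the
group's links touch) is accepted; an alias target that collides with an
existing differently-named atom is a schema error rather than a guess.

## Link identification

Implicit polymer bonds between consecutive residues are accepted when
the linking atoms (C→N for the peptide class, O3′→P for nucleic acids,
after alias resolution) are within `ideal + 0.5 Å` (1.83 Å peptide,
2.11 Å phosphodiester). The margin and per-type ideals are options. An
explicit LINK record forces the bond regardless of distance; a LINKR
named `gap` removes it; any other LINKR name (or
`_struct_conn.ccp4_link_id`) selects that link description directly,
with an error listing the known ids if absent. A distance-based search
over covalent-radius sums (+0.4 Å) for unannotated inter-residue bonds
exists but is off by default.

Specificity scores each side: exact component match 2, group match 1
(peptide-class groups are mutually compatible, as are DNA/RNA; an alias
table's declared group also counts), summed over both orientations and
maximized. At equal integer score, a side whose group selector matches
the group *exactly* outranks a class-compatibility match — this is what
makes a proline-specific link beat the generic peptide link for an
actual proline while the generic link still wins between two ordinary
amino acids. Remaining ties (TRANS vs CIS, and glycosidic anomers in a
full library) are separated by `Σ (Δθ_periodic/σ)²` over the links'
torsion templates plus a fixed 100² penalty per violated chirality
sign; deviations equal to numerical precision count as a tie, resolved
lexicographically by link id with a warning. If no description applies,
the bond is still restrained — length only, from the covalent radii of
the two elements, sigma 0.02 Å.

Alternate conformations: two atoms pair when their altloc identifiers
are equal or either is blank, and a blank atom may participate in
several pairings. Each pairing produces its own match, so a shared C
atom can join a trans conformer through TRANS and a cis conformer
through CIS; microheterogeneous positions (several residues sharing a
(seq, icode) slot) are resolved per conformer, with blank-altloc atoms
shared across the siblings; in partial cleavage the modification is
applied only to the conformer that actually forms the bond, so the
unlinked conformer keeps its terminal atoms.

## Restraint instantiation

Per residue and conformer, the effective definition (base description
plus any link-prescribed modifications, applied in standard naming and
translated back) is instantiated against the atoms present. A monomer
template referencing a genuinely absent atom is skipped at debug level
— routine, e.g. OXT not modelled — while a *link* template failure is a
warning, since it signals a dictionary/model mismatch. Planes tolerate
absent members as long as four remain. Duplicates (same kind, same
canonical atom tuple; bonds/angles/torsions compared direction-blind,
planes order-free, chiral centres never reordered) keep the most
specific provenance: mod > link > monomer > fallback. The result is
written to a deterministic CIF-style restraint file (one category per
kind, atoms addressed by chain/seq/icode/comp/atom/altloc, columns for
ideal, sigma, period, sign, provenance and a zero-occupancy-hydrogen
flag). The format is this package's own documented dialect, not claimed
byte-compatible with any refinement engine's intermediate files.

## Riding hydrogens

Each hydrogen is placed exactly at its ideal distance from its parent
(to better than 1e−6 Å by construction: a unit direction is solved,
then scaled). Bonds to hydrogen may carry two ideals — the
electron-cloud centroid distance and the internuclear distance — and a
pipeline flag selects which one both placement and the restraint set
use (default electron-cloud; which is appropriate depends on the
experimental technique, so the package only stores and selects).

The direction is solved by case:

- **torsion-determined** (one known neighbor plus a resolvable torsion
  template, e.g. the first methyl or ammonium proton): direct
  construction from the torsion ideal;
- **two known neighbors**: the sigma-weighted least-squares problem on
  the sphere has a mirror pair of minima, found by a derivative-free
  minimization from the two frame-completing starts (tolerance 1e−10);
  a chirality template selects the side; a planarity template merges
  the pair into the in-plane solution (amide H); with neither, sibling
  hydrogens fill the two slots in a deterministic order (first pending
  sibling takes the positive chiral-volume slot);
- **three or more known neighbors**: a single least-squares solution;
- **one neighbor, no torsion** (hydroxyl/thiol type): rotationally
  ambiguous — the H is placed at torsion 180° against the
  lowest-lexicographic non-parent neighbor of the parent's neighbor,
  and its occupancy is set to zero so downstream consumers can ignore
  it. Hydrogens listed in a monomer's
  `_chem_comp.ambiguous_protonation_atoms` (unknown protonation, the
  histidine situation) are likewise placed at occupancy zero rather
  than choosing a tautomer.

Cross-link templates participate: the link bond makes the partner atom
a known neighbor of the parent, and link angle/plane templates (the
amide H geometry) constrain the solve. Placement is deterministic and
equivariant under rigid motions of the input (tested under random
rotations).

## Geometry regularization

The target is the standard sum of squared sigma-weighted residuals:
bonds `(d−ideal)²/σ²`; angles and torsions in degrees, the torsion
residual taken against the nearest period-equivalent ideal; planes as
the summed squared distances to the current least-squares plane of the
member atoms (whose gradient, by the envelope property of the
minimizing plane, is the explicit distance term only); chiral volumes
`(V−V_ideal)²/σ_V²` with `σ_V = 0.2 Å³` and the target volume derived
from the dictionary bonds and angles around the centre (tetrahedral
defaults where absent; for sign `both` the target takes the current
handedness). An optional soft quartic repulsion,
`w·(0.8·r_cov_sum − d)⁴` for non-bonded pairs closer than 80% of their
covalent-radius sum (1-2/1-3/1-4 pairs excluded via the bond graph),
prevents collapse of atoms that share no restraint; it is on by
default. Analytic gradients for every term match central finite
differences to 1e−5 relative (tested); the dihedral gradient follows
the classic analytic formulation for this sign convention.

The minimizer is L-BFGS (memory 8) with an Armijo backtracking line
search (c = 1e−4); a *cycle* is one accepted step, so the recorded
value trajectory is non-increasing by construction. Plain steepest
descent was tried first and rejected: with bond sigmas of ~0.02 Å and
angle sigmas of ~2°, the target is stiff along bonds and soft along
angles, and gradient descent leaves the angular directions essentially
unconverged within the 20-cycle budget the demonstrations use; L-BFGS
reaches link-angle RMSZ < 1 from a 0.15 Å-noise start in those 20
cycles while preserving the same monotone-descent contract.
Zero-occupancy generated hydrogens are excluded from the moving set by
default. Restraint generation itself has no randomness; the only
stochastic element anywhere is the fixture noise, which is seeded.

## The fixture data, and what it is not

The mini library is a synthetic, internally consistent miniature of a
real restraint library. The handful of published ideals it must
reproduce (free-acid C—O 1.25 Å, DEL-OXT C—O 1.23 Å, peptide-link
CA—C—N 115.9° and C—N—CA 122.1°, phosphodiester O3′—P—OP2 108.5° and
O3′—P—O5′ 101.1°) live in one transcription table asserted by a test so
the fixtures cannot drift. Everything else — hydrogen distances
(N—H 0.86/1.02 Å cloud/nucleus, C(sp3)—H 0.97/1.09, O—H 0.82/0.97),
backbone bonds and angles, covalent radii, sigmas — is ordinary
stereochemistry from standard tabulations, kept in `fixtures.py` and
`config.py` and labelled as such.

Deliberate simplifications: CIR is citrulline-like only in its naming
problem — its side chain is truncated to a methyl; ORX is a generic
deoxynucleotide with systematically renamed atoms and a deliberately
partial alias table, not the real ORP chemistry; nucleotide fixtures
carry no sugar hydrogens and a single-atom base stub; CIS reuses the
TRANS angle ideals. Toy models are built from ideal internal
coordinates (trans backbone, extended φ/ψ, B-DNA-like backbone
torsions, a furanose ring whose three free torsions were solved once so
the ring-closure bond and angles come out at their ideals) and
optionally perturbed by seeded Gaussian noise (default σ 0.15 Å).
Consequently, passing tests demonstrate the *mechanism* — parsing,
matching, alias resolution, modification algebra, placement geometry,
optimization — on models whose difficulty (noise level, conformational
strain, nomenclature conflicts) is controlled and mild. They do not
demonstrate robustness to real deposited models, to the full size and
variety of a production monomer library, to inconsistent leaving-atom
nomenclature (which static aliases cannot fix and which this package
only logs before falling back), or to metal coordination, which is out
of scope.

## Known limitations

- Sequential hydrogen placement on a parent (methyl H2/H3 after H1)
  satisfies the H—H angle templates only approximately for the later
  siblings; the deviations are well under the template sigmas.
- The restraint-file dialect and the `list/links.cif` + `list/mods.cif`
  library layout are this package's own conventions, documented but not
  byte-compatible with other software.
- LINKR column placement (link name in columns 73–80) follows the
  de-facto convention for that nonstandard record; other dialects may
  differ.
- The regularizer is a demonstration-scale tool: dense pair loops and
  per-restraint Python evaluation are fine for tens to hundreds of
  atoms, not for whole structures.
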