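# restraintsmith

Stereochemical restraint generation for macromolecular atomic models,
built around the CCP4-style monomer-dictionary idiom: monomer
descriptions (`chem_comp`), covalent-link descriptions (`chem_link`),
modifications (`chem_mod`) and per-monomer atom-name alias tables
(`_chem_comp_alias`).

It is aimed at people who work on model refinement infrastructure — the
step *before* refinement, where a coordinate file plus a restraint
dictionary must be turned into a concrete list of bond, angle, torsion,
plane and chiral-volume restraints referencing the atoms of one
particular model.

## What it does

Given a model (PDB or mmCIF) and a monomer library, the pipeline

1. **identifies covalent links**: implicit polymer bonds between
   consecutive residues (C→N for peptides, O3′→P for nucleic acids,
   accepted when the linking atoms fall within `ideal + 0.5 Å`);
   explicit `LINK` / `LINKR` / `SSBOND` / `_struct_conn` records, where a
   `LINK` overrides the distance check, a `LINKR` named `gap` suppresses
   an implicit bond, and a `LINKR` / `ccp4_link_id` name binds the bond
   to a link description directly;
2. **matches each bond to the most specific link description**: an exact
   component selector (e.g. CYS–CYS) beats a group selector
   (peptide–peptide); equally specific candidates such as TRANS vs CIS
   are separated by comparing the model's torsion angles and chiralities
   with the link ideals, `Σ (Δθ/σ)²` plus a fixed penalty per violated
   chirality sign;
3. **resolves nonstandard atom nomenclature through alias tables**, so
   that standard links (and their modifications) apply to monomers whose
   main-chain atoms carry noncanonical names;
4. **applies the prescribed modifications** to working copies of the
   monomer descriptions — e.g. the C-terminal `DEL-OXT` modification
   deletes OXT and changes the ideal C—O distance from the free-acid
   1.25 Å to the peptide 1.23 Å — per conformer, so partial cleavage and
   microheterogeneity behave correctly;
5. **instantiates restraints** against the atoms actually present, with
   provenance (`monomer:`, `link:`, `mod:`, `fallback`) and a bond-only
   fallback from covalent radii when no link description exists;
6. **places riding hydrogens** exactly at their ideal parent distance
   (electron-cloud or internuclear, selectable), angles satisfied in a
   least-squares sense, chirality and planarity honored; rotationally
   ambiguous or protonation-ambiguous hydrogens get a deterministic
   canonical position at occupancy zero;
7. optionally **regularizes geometry** with a monotone L-BFGS
   minimizer over the restraint target, and
8. **writes** the amended model (PDB with two-letter chain IDs and
   hybrid-36 serials where needed, or lossless mmCIF), a documented
   CIF-style restraint file, and a JSON run summary.

A packaged fixture generator (`restraintsmith.fixtures`) emits a small
self-contained monomer library — ALA, GLY, CYS, a citrulline-like
monomer CIR with an alias table, two deoxynucleotides, an ORP-like
nucleotide ORX with nonstandard names, the TRANS/CIS/SS/phosphodiester
links, the `gap` placeholder and the associated modifications — plus toy
models built from ideal internal coordinates, so everything here runs
without any external data.

## Worked example

```sh
restraintsmith fixtures --out minilib
python - <<'EOF'
from restraintsmith import fixtures
from restraintsmith.model_io import write_model
open("ala_cir_ala.pdb", "w").write(
    write_model(fixtures.build_peptide_model(["ALA", "CIR", "ALA"],
                                             noise=0.15, seed=1), "pdb"))
EOF
restraintsmith run --model ala_cir_ala.pdb --lib minilib \
    --hydrogens generate --regularize 20 \
    --restraints-out restraints.cif --model-out out.pdb \
    --summary-out summary.json --log-level WARNING
python -m json.tool summary.json | head -40
```

The summary reports two TRANS link matches — the standard peptide link
was applied automatically on both sides of the nonstandard-named CIR
residue through its alias table:

```
 "matches": [
  {"link": "TRANS", "fallback": false, "specificity": 2, ...
   "residue1": "A/1/ALA", "residue2": "A/2/CIR"},
  {"link": "TRANS", "fallback": false, "specificity": 2, ...
   "residue1": "A/2/CIR", "residue2": "A/3/ALA"}
 ],
 "hydrogens": {"placed": 17, "ambiguous": 0, "unsolvable": 0},
```

`restraints.cif` then contains, among others, the inter-residue angle
restraints `CA—C—N1 115.9°` and `C—N1—C2 122.1°` (CIR's own names for
its main-chain N and CA), and the residue-1 `C—O` bond at `1.23` with
provenance `mod:DEL-OXT`. The regularization block of the summary shows
a monotonically decreasing target; after 20 cycles of the 0.15 Å-noise
start, the link-angle RMSZ drops below 1, i.e. the junction geometry is
restored by the restraints that only exist because of the alias table.
Running the same model against a library without the alias
(`restraintsmith fixtures --cir-variant noalias ...`, model with
explicit LINK records) leaves only two fallback bond-length restraints
across the junctions and no angle control there at all.

## Layout

```
src/restraintsmith/
  monomer_library.py   dictionaries: chem_comp/chem_link/chem_mod/alias
  model_io.py          PDB + mmCIF with connectivity, hybrid-36
  linkage.py           bond candidates, specificity, disambiguation
  restraints.py        instantiation, provenance, restraint file
  hydrogens.py         riding-hydrogen placement
  regularize.py        restraint target, gradient, L-BFGS minimizer
  fixtures.py          mini library + toy model generators
  cli.py               `restraintsmith run` / `restraintsmith fixtures`
```

See `docs/methods.md` for the model, the numerical choices and the
limitations of the fixture data.
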