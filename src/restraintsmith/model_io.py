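"""Atomic-model input/output: PDB and mmCIF with connectivity records.

Reads and writes ATOM/HETATM coordinates together with the connectivity
annotations that drive link identification: LINK, the CCP4 LINKR extension
(which may name the link description directly, or suppress an implicit
polymer bond with the name ``gap``), SSBOND, and mmCIF ``_struct_conn``
including the ``ccp4_link_id`` extension.  PDB output supports two-letter
chain IDs and hybrid-36 encoding of serials and residue numbers; structures
that exceed even those extensions must be written as mmCIF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _cif
from .errors import FormatError, ModelError

logger = logging.getLogger("restraintsmith.model_io")


# --- hybrid-36 ---------------------------------------------------------------

_DIGITS36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _encode36(n: int, width: int) -> str:
    out = []
    while n:
        n, r = divmod(n, 36)
        out.append(_DIGITS36[r])
    s = "".join(reversed(out)) or "0"
    return s.rjust(width, "0")


def hy36_encode(n: int, width: int) -> str:
    """Hybrid-36 encoding of integer ``n`` in a fixed-width PDB field.

    Values that fit in ``width`` decimal digits are written as plain decimal;
    larger values continue in base 36, first with uppercase then lowercase
    letters in the leading position.
    """
    if width not in (4, 5):
        raise ValueError("hybrid-36 width must be 4 or 5")
    dec_limit = 10 ** width
    block = 26 * 36 ** (width - 1)
    if -(10 ** (width - 1)) < n < dec_limit:
        return str(n).rjust(width)
    if n < dec_limit + block:
        return _encode36(n - dec_limit + 10 * 36 ** (width - 1), width)
    if n < dec_limit + 2 * block:
        return _encode36(
            n - dec_limit - block + 10 * 36 ** (width - 1), width
        ).lower()
    raise ValueError(f"value {n} out of hybrid-36 range for width {width}")


def hy36_decode(s: str, width: int) -> int:
    if width not in (4, 5):
        raise ValueError("hybrid-36 width must be 4 or 5")
    if len(s) != width:
        s = s.rjust(width)
    t = s.strip()
    if not t:
        raise ValueError("empty hybrid-36 field")
    try:
        return int(t)
    except ValueError:
        pass
    f = t[0]
    if f in _DIGITS36 and f.isalpha():
        return int(t, 36) - 10 * 36 ** (width - 1) + 10 ** width
    if f.upper() in _DIGITS36 and f.islower():
        return (int(t.upper(), 36) - 10 * 36 ** (width - 1)
                + 10 ** width + 26 * 36 ** (width - 1))
    raise ValueError(f"not a hybrid-36 value: {s!r}")


# --- data model --------------------------------------------------------------


@dataclass
class AtomSite:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""            # "" means blank
    b_iso: float = 20.0
    serial: int | None = None
    is_generated_h: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ModelError(f"atom {self.name}: non-finite position")
        if not (0.0 <= self.occupancy <= 1.0):
            logger.warning(
                "atom %s: occupancy %g outside [0,1], clamping",
                self.name, self.occupancy,
            )
            self.occupancy = min(max(self.occupancy, 0.0), 1.0)


@dataclass
class Residue:
    seq_id: int
    comp_id: str
    icode: str = ""
    atoms: list[AtomSite] = field(default_factory=list)

    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.icode)

    def find_atoms(self, name: str, altloc: str | None = None) -> list[AtomSite]:
        """Atoms of this residue with the given name; a blank ``altloc``
        query (or a blank atom altloc) matches any conformer."""
        out = []
        for a in self.atoms:
            if a.name != name:
                continue
            if altloc is None or altloc == "" or a.altloc == "" or a.altloc == altloc:
                out.append(a)
        return out

    def get_atom(self, name: str, altloc: str | None = None) -> AtomSite | None:
        hits = self.find_atoms(name, altloc)
        return hits[0] if hits else None

    def altlocs(self) -> list[str]:
        seen = sorted({a.altloc for a in self.atoms if a.altloc})
        return seen if seen else [""]


POLYMER_TYPES = ("polypeptide", "polydeoxyribonucleotide", "polyribonucleotide",
                 "non-polymer", "unassigned")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    polymer_type: str = "unassigned"

    def positions(self) -> list[list[Residue]]:
        """Residues grouped by (seq_id, icode) in file order; a group with
        more than one residue represents microheterogeneity."""
        groups: list[list[Residue]] = []
        index: dict[tuple[int, str], int] = {}
        for r in self.residues:
            k = r.key()
            if k in index:
                groups[index[k]].append(r)
            else:
                index[k] = len(groups)
                groups.append([r])
        return groups


@dataclass
class AtomAddress:
    chain: str
    seq_id: int
    icode: str
    comp_id: str
    atom: str
    altloc: str = ""


@dataclass
class ConnRecord:
    kind: str                      # LINK | LINKR | SSBOND | struct_conn
    atom1: AtomAddress
    atom2: AtomAddress
    named_link_id: str | None = None
    reported_distance: float | None = None
    unresolved: bool = False


@dataclass
class StructureModel:
    chains: list[Chain] = field(default_factory=list)
    conn: list[ConnRecord] = field(default_factory=list)
    cell: tuple | None = None

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def all_atoms(self):
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def find_residues(self, chain_id: str, seq_id: int, icode: str = "",
                      comp_id: str | None = None) -> list[Residue]:
        c = self.chain(chain_id)
        if c is None:
            return []
        return [
            r for r in c.residues
            if r.seq_id == seq_id and r.icode == icode
            and (comp_id is None or r.comp_id == comp_id)
        ]

    def resolve(self, addr: AtomAddress) -> list[tuple[Residue, AtomSite]]:
        """All (residue, atom) pairs matching an address; a blank altloc in
        the address matches any conformer."""
        out = []
        for r in self.find_residues(addr.chain, addr.seq_id, addr.icode):
            if addr.comp_id and r.comp_id != addr.comp_id:
                continue
            for a in r.atoms:
                if a.name != addr.atom:
                    continue
                if addr.altloc and a.altloc and a.altloc != addr.altloc:
                    continue
                out.append((r, a))
        return out

    def mark_unresolved_conn(self) -> None:
        for cr in self.conn:
            cr.unresolved = not (self.resolve(cr.atom1) and self.resolve(cr.atom2))
            if cr.unresolved:
                logger.warning(
                    "connectivity record %s %s/%s%s/%s - %s/%s%s/%s does not "
                    "resolve to model atoms", cr.kind,
                    cr.atom1.chain, cr.atom1.seq_id, cr.atom1.icode, cr.atom1.atom,
                    cr.atom2.chain, cr.atom2.seq_id, cr.atom2.icode, cr.atom2.atom,
                )


def models_equivalent(a: StructureModel, b: StructureModel,
                      tol: float = 2e-3) -> bool:
    """Structural equality to coordinate-format precision."""
    if len(a.chains) != len(b.chains) or len(a.conn) != len(b.conn):
        return False
    for ca, cb in zip(a.chains, b.chains):
        if ca.chain_id != cb.chain_id or len(ca.residues) != len(cb.residues):
            return False
        for ra, rb in zip(ca.residues, cb.residues):
            if (ra.seq_id, ra.icode, ra.comp_id) != (rb.seq_id, rb.icode, rb.comp_id):
                return False
            if len(ra.atoms) != len(rb.atoms):
                return False
            for aa, ab in zip(ra.atoms, rb.atoms):
                if (aa.name, aa.altloc, aa.element) != (ab.name, ab.altloc, ab.element):
                    return False
                if np.max(np.abs(aa.position - ab.position)) > tol:
                    return False
                if abs(aa.occupancy - ab.occupancy) > 0.01 or abs(aa.b_iso - ab.b_iso) > 0.01:
                    return False
    def conn_class(kind: str) -> str:
        # LINK/LINKR and _struct_conn express the same information in the
        # two formats; only the disulfide class is distinct
        return "disulf" if kind == "SSBOND" else "covale"

    for xa, xb in zip(a.conn, b.conn):
        if (conn_class(xa.kind), xa.named_link_id) != (
                conn_class(xb.kind), xb.named_link_id):
            return False
        for pa, pb in ((xa.atom1, xb.atom1), (xa.atom2, xb.atom2)):
            if (pa.chain, pa.seq_id, pa.icode, pa.comp_id, pa.atom, pa.altloc) != (
                    pb.chain, pb.seq_id, pb.icode, pb.comp_id, pb.atom, pb.altloc):
                return False
    return True


# --- PDB ---------------------------------------------------------------------


def _pdb_atom_name_field(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) < 4:
        return f" {name}".ljust(4)
    return name.ljust(4)


def _col(line: str, start: int, end: int) -> str:
    """1-based inclusive column slice, padded."""
    return line[start - 1 : end].ljust(end - start + 1) if len(line) >= start else " " * (end - start + 1)


def _read_pdb(text: str) -> StructureModel:
    model = StructureModel()
    chains: dict[str, Chain] = {}
    current_res: Residue | None = None
    current_chain: Chain | None = None
    for line in text.splitlines():
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            serial = hy36_decode(_col(line, 7, 11), 5)
            name = _col(line, 13, 16).strip()
            altloc = _col(line, 17, 17).strip()
            comp = _col(line, 18, 20).strip()
            chain_id = _col(line, 21, 22).strip()
            seq = hy36_decode(_col(line, 23, 26), 4)
            icode = _col(line, 27, 27).strip()
            x = float(_col(line, 31, 38))
            y = float(_col(line, 39, 46))
            z = float(_col(line, 47, 54))
            occ_s = _col(line, 55, 60).strip()
            b_s = _col(line, 61, 66).strip()
            element = _col(line, 77, 78).strip() or name[:1]
            atom = AtomSite(
                name=name, element=element, position=np.array([x, y, z]),
                occupancy=float(occ_s) if occ_s else 1.0,
                altloc=altloc, b_iso=float(b_s) if b_s else 20.0, serial=serial,
            )
            if current_chain is None or current_chain.chain_id != chain_id:
                if chain_id not in chains:
                    chains[chain_id] = Chain(chain_id=chain_id)
                    model.chains.append(chains[chain_id])
                current_chain = chains[chain_id]
                current_res = None
            if (current_res is None or current_res.seq_id != seq
                    or current_res.icode != icode or current_res.comp_id != comp):
                # microheterogeneity: same position, different comp_id
                existing = [
                    r for r in current_chain.residues
                    if r.seq_id == seq and r.icode == icode and r.comp_id == comp
                ]
                if existing:
                    current_res = existing[0]
                else:
                    current_res = Residue(seq_id=seq, comp_id=comp, icode=icode)
                    current_chain.residues.append(current_res)
            current_res.atoms.append(atom)
        elif rec in ("LINK  ", "LINKR "):
            kind = rec.strip()
            a1 = AtomAddress(
                atom=_col(line, 13, 16).strip(), altloc=_col(line, 17, 17).strip(),
                comp_id=_col(line, 18, 20).strip(), chain=_col(line, 21, 22).strip(),
                seq_id=hy36_decode(_col(line, 23, 26), 4),
                icode=_col(line, 27, 27).strip(),
            )
            a2 = AtomAddress(
                atom=_col(line, 43, 46).strip(), altloc=_col(line, 47, 47).strip(),
                comp_id=_col(line, 48, 50).strip(), chain=_col(line, 51, 52).strip(),
                seq_id=hy36_decode(_col(line, 53, 56), 4),
                icode=_col(line, 57, 57).strip(),
            )
            named = None
            dist = None
            if kind == "LINKR":
                named = _col(line, 73, 80).strip() or None
            else:
                ds = _col(line, 74, 78).strip()
                dist = float(ds) if ds else None
            model.conn.append(ConnRecord(kind=kind, atom1=a1, atom2=a2,
                                         named_link_id=named,
                                         reported_distance=dist))
        elif rec == "SSBOND":
            a1 = AtomAddress(
                atom="SG", comp_id=_col(line, 12, 14).strip(),
                chain=_col(line, 15, 16).strip(),
                seq_id=hy36_decode(_col(line, 18, 21).strip().rjust(4), 4),
                icode=_col(line, 22, 22).strip(),
            )
            a2 = AtomAddress(
                atom="SG", comp_id=_col(line, 26, 28).strip(),
                chain=_col(line, 29, 30).strip(),
                seq_id=hy36_decode(_col(line, 32, 35).strip().rjust(4), 4),
                icode=_col(line, 36, 36).strip(),
            )
            ds = _col(line, 74, 78).strip()
            model.conn.append(ConnRecord(kind="SSBOND", atom1=a1, atom2=a2,
                                         reported_distance=float(ds) if ds else None))
        elif rec.startswith("CRYST1"):
            try:
                model.cell = tuple(float(line[i:i + 9]) for i in (6, 15, 24)) + tuple(
                    float(line[i:i + 7]) for i in (33, 40, 47)
                )
            except ValueError:
                pass
    model.mark_unresolved_conn()
    return model


def _write_pdb(model: StructureModel) -> str:
    for c in model.chains:
        if len(c.chain_id) > 2:
            raise FormatError(
                f"chain id {c.chain_id!r} has more than two characters and "
                f"cannot be written as PDB; write mmCIF instead"
            )
    lines: list[str] = []

    def chainf(cid: str) -> str:
        return cid.rjust(2)

    for cr in model.conn:
        if cr.kind in ("LINK", "LINKR"):
            a1, a2 = cr.atom1, cr.atom2
            line = (
                f"{cr.kind:<6s}      "
                f"{_pdb_atom_name_field(a1.atom, a1.atom[:1])}"
                f"{a1.altloc or ' '}{a1.comp_id:>3s}{chainf(a1.chain)}"
                f"{hy36_encode(a1.seq_id, 4)}{a1.icode or ' '}"
                + " " * 15
                + f"{_pdb_atom_name_field(a2.atom, a2.atom[:1])}"
                f"{a2.altloc or ' '}{a2.comp_id:>3s}{chainf(a2.chain)}"
                f"{hy36_encode(a2.seq_id, 4)}{a2.icode or ' '}"
            )
            line = line.ljust(72)
            if cr.kind == "LINKR":
                line += (cr.named_link_id or "").ljust(8)
            else:
                line = line.ljust(73)
                line += (f"{cr.reported_distance:5.2f}"
                         if cr.reported_distance is not None else "     ")
            lines.append(line.rstrip())
        elif cr.kind == "SSBOND":
            a1, a2 = cr.atom1, cr.atom2
            line = (
                f"SSBOND   1 {a1.comp_id:>3s}{chainf(a1.chain)} "
                f"{hy36_encode(a1.seq_id, 4)}{a1.icode or ' '}   "
                f"{a2.comp_id:>3s}{chainf(a2.chain)} "
                f"{hy36_encode(a2.seq_id, 4)}{a2.icode or ' '}"
            )
            line = line.ljust(73)
            line += (f"{cr.reported_distance:5.2f}"
                     if cr.reported_distance is not None else "     ")
            lines.append(line.rstrip())
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            for a in res.atoms:
                serial = a.serial if a.serial is not None else serial + 1
                name4 = _pdb_atom_name_field(a.name, a.element)
                lines.append(
                    f"ATOM  {hy36_encode(serial, 5)} {name4}"
                    f"{a.altloc or ' '}{res.comp_id:>3s}{chainf(chain.chain_id)}"
                    f"{hy36_encode(res.seq_id, 4)}{res.icode or ' '}   "
                    f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                    f"{a.occupancy:6.2f}{a.b_iso:6.2f}          "
                    f"{a.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# --- mmCIF -------------------------------------------------------------------


def _read_mmcif(text: str) -> StructureModel:
    blocks = _cif.parse(text)
    model = StructureModel()
    chains: dict[str, Chain] = {}

    def g(row, *keys, default=None):
        for k in keys:
            if row.get(k) is not None:
                return row[k]
        return default

    for row in _cif.category_rows(blocks, "_atom_site"):
        chain_id = g(row, "auth_asym_id", "label_asym_id", default="A")
        comp = g(row, "auth_comp_id", "label_comp_id")
        seq = int(g(row, "auth_seq_id", "label_seq_id", default="1"))
        icode = g(row, "pdbx_PDB_ins_code", default="") or ""
        altloc = g(row, "label_alt_id", default="") or ""
        atom = AtomSite(
            name=g(row, "auth_atom_id", "label_atom_id"),
            element=g(row, "type_symbol", default="") or "",
            position=np.array([float(row["Cartn_x"]), float(row["Cartn_y"]),
                               float(row["Cartn_z"])]),
            occupancy=float(g(row, "occupancy", default="1")),
            altloc=altloc,
            b_iso=float(g(row, "B_iso_or_equiv", default="20")),
            serial=int(g(row, "id", default="0")) or None,
        )
        if chain_id not in chains:
            chains[chain_id] = Chain(chain_id=chain_id)
            model.chains.append(chains[chain_id])
        chain = chains[chain_id]
        res = None
        for r in chain.residues:
            if r.seq_id == seq and r.icode == icode and r.comp_id == comp:
                res = r
                break
        if res is None:
            res = Residue(seq_id=seq, comp_id=comp, icode=icode)
            chain.residues.append(res)
        res.atoms.append(atom)

    for row in _cif.category_rows(blocks, "_struct_conn"):
        conn_type = (g(row, "conn_type_id", default="covale") or "covale").lower()
        kind = "SSBOND" if conn_type == "disulf" else "struct_conn"

        def addr(n: int) -> AtomAddress:
            return AtomAddress(
                chain=g(row, f"ptnr{n}_auth_asym_id", f"ptnr{n}_label_asym_id",
                        default=""),
                seq_id=int(g(row, f"ptnr{n}_auth_seq_id", f"ptnr{n}_label_seq_id",
                             default="0")),
                icode=g(row, f"pdbx_ptnr{n}_PDB_ins_code", default="") or "",
                comp_id=g(row, f"ptnr{n}_label_comp_id",
                          f"ptnr{n}_auth_comp_id", default="") or "",
                atom=g(row, f"ptnr{n}_label_atom_id", f"ptnr{n}_auth_atom_id",
                       default="") or "",
                altloc=g(row, f"pdbx_ptnr{n}_label_alt_id", default="") or "",
            )

        dist = g(row, "pdbx_dist_value")
        model.conn.append(ConnRecord(
            kind=kind, atom1=addr(1), atom2=addr(2),
            named_link_id=g(row, "ccp4_link_id"),
            reported_distance=float(dist) if dist else None,
        ))
    model.mark_unresolved_conn()
    return model


def _write_mmcif(model: StructureModel) -> str:
    out: list[str] = ["data_model"]
    rows = []
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            for a in res.atoms:
                serial = a.serial if a.serial is not None else serial + 1
                rows.append([
                    "ATOM", serial, a.element, a.name, a.altloc or None,
                    res.comp_id, chain.chain_id, res.seq_id, res.icode or None,
                    f"{a.position[0]:.3f}", f"{a.position[1]:.3f}",
                    f"{a.position[2]:.3f}", f"{a.occupancy:.2f}",
                    f"{a.b_iso:.2f}",
                ])
    _cif.write_loop(
        out,
        [f"_atom_site.{k}" for k in
         ("group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
          "label_comp_id", "auth_asym_id", "auth_seq_id", "pdbx_PDB_ins_code",
          "Cartn_x", "Cartn_y", "Cartn_z", "occupancy", "B_iso_or_equiv")],
        rows,
    )
    conn_rows = []
    for i, cr in enumerate(model.conn):
        conn_type = "disulf" if cr.kind == "SSBOND" else "covale"
        conn_rows.append([
            f"conn{i + 1}", conn_type, cr.named_link_id,
            cr.atom1.chain, cr.atom1.seq_id, cr.atom1.icode or None,
            cr.atom1.comp_id, cr.atom1.atom, cr.atom1.altloc or None,
            cr.atom2.chain, cr.atom2.seq_id, cr.atom2.icode or None,
            cr.atom2.comp_id, cr.atom2.atom, cr.atom2.altloc or None,
            f"{cr.reported_distance:.3f}" if cr.reported_distance is not None
            else None,
        ])
    _cif.write_loop(
        out,
        [f"_struct_conn.{k}" for k in
         ("id", "conn_type_id", "ccp4_link_id",
          "ptnr1_auth_asym_id", "ptnr1_auth_seq_id", "pdbx_ptnr1_PDB_ins_code",
          "ptnr1_label_comp_id", "ptnr1_label_atom_id", "pdbx_ptnr1_label_alt_id",
          "ptnr2_auth_asym_id", "ptnr2_auth_seq_id", "pdbx_ptnr2_PDB_ins_code",
          "ptnr2_label_comp_id", "ptnr2_label_atom_id", "pdbx_ptnr2_label_alt_id",
          "pdbx_dist_value")],
        conn_rows,
    )
    return "\n".join(out) + "\n"


# --- public API --------------------------------------------------------------


def read_model(source: str | Path, fmt: str = "auto") -> StructureModel:
    """Read a structure from a path or from file text.

    ``fmt`` is ``pdb``, ``mmcif`` or ``auto`` (sniffed from the content).
    """
    text = source
    if isinstance(source, Path) or (
        isinstance(source, str) and source and "\n" not in source
        and Path(source).is_file()
    ):
        p = Path(source)
        text = p.read_text()
        if fmt == "auto":
            fmt = "mmcif" if p.suffix.lower() in (".cif", ".mmcif") else "auto"
    if fmt == "auto":
        stripped = text.lstrip()
        if stripped.startswith("data_") or "_atom_site." in text:
            fmt = "mmcif"
        elif any(text.startswith(r) or f"\n{r}" in text
                 for r in ("ATOM", "HETATM", "LINK", "SSBOND", "CRYST1", "END",
                           "REMARK", "HEADER", "TER")):
            fmt = "pdb"
        elif stripped == "":
            fmt = "pdb"
        else:
            raise FormatError("cannot determine coordinate-file format")
    if fmt == "pdb":
        return _read_pdb(text)
    if fmt == "mmcif":
        return _read_mmcif(text)
    raise FormatError(f"unknown format {fmt!r}")


def write_model(model: StructureModel, fmt: str) -> str:
    if fmt == "pdb":
        return _write_pdb(model)
    if fmt == "mmcif":
        return _write_mmcif(model)
    raise FormatError(f"unknown format {fmt!r}")
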