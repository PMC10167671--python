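"""Pipeline options and the tunable numeric constants behind them."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

# Covalent radii (Å), Cordero-style single-bond values; used for the
# bond-length fallback when no link description matches and for the optional
# distance-based bond search.  Not taken from any dictionary file.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "D": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
    "B": 0.84, "SI": 1.11, "NA": 1.66, "MG": 1.41, "K": 2.03, "CA": 1.76,
    "MN": 1.39, "FE": 1.32, "CO": 1.26, "NI": 1.24, "CU": 1.32, "ZN": 1.22,
}

DEFAULT_COVALENT_RADIUS = 1.5  # elements missing from the table


def covalent_radius(element: str) -> float:
    return COVALENT_RADII.get(element.upper(), DEFAULT_COVALENT_RADIUS)


@dataclass
class Options:
    """Keyword options of the restraint-generation pipeline.

    Distance cutoffs for implicit polymer bonds are ``ideal + polymer_bond_margin``
    per polymer type; both are overridable.  ``auto_links`` enables the optional
    distance-based search for unannotated inter-residue bonds (off by default).
    """

    auto_links: bool = False
    polymer_bond_margin: float = 0.5       # Å over the ideal linking distance
    peptide_bond_ideal: float = 1.329      # C–N, used only for the cutoff
    phosphodiester_bond_ideal: float = 1.607  # O3'–P, used only for the cutoff
    auto_link_tolerance: float = 0.4       # Å over covalent-radius sum
    chirality_penalty: float = 100.0       # per violated sign in disambiguation
    fallback_bond_sigma: float = 0.02      # Å, bond-only fallback restraints
    h_distance_mode: str = "electron_cloud"  # or "nucleus"
    hydrogens: str = "generate"            # generate | keep | strip
    regenerate_hydrogens: bool = True
    repulsion: bool = True                 # soft nonbonded term in regularizer
    repulsion_scale: float = 0.8           # trigger below scale * radius sum
    repulsion_weight: float = 4.0
    regularize_cycles: int = 0

    def peptide_cutoff(self) -> float:
        return self.peptide_bond_ideal + self.polymer_bond_margin

    def nucleic_cutoff(self) -> float:
        return self.phosphodiester_bond_ideal + self.polymer_bond_margin

    @classmethod
    def from_config_file(cls, path) -> "Options":
        """Parse a simple key=value file; unknown keys are rejected."""
        opts = cls()
        valid = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, _, val = line.partition("=")
                key = key.strip()
                val = val.strip()
                if key not in valid:
                    raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
                cur = getattr(opts, key)
                if isinstance(cur, bool):
                    setattr(opts, key, val.lower() in ("1", "true", "yes", "on"))
                elif isinstance(cur, int):
                    setattr(opts, key, int(val))
                elif isinstance(cur, float):
                    setattr(opts, key, float(val))
                else:
                    setattr(opts, key, val)
        return opts
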