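"""Reduced torsional models of disulfide-bonded compounds.

Three builtin models of increasing complexity share the same construction: a
chain of heavy atoms at fixed bond lengths and angles, with the soft torsions
(the two flanking C-C-S-S dihedrals chi1 and chi2, the central C-S-S-C
dihedral chi3, and - for the larger models - the side-chain and backbone
torsions along the force-bearing path) as the only degrees of freedom.

* ``DEDS`` - diethyl disulfide, C-C-S-S-C-C heavy atoms, 3 torsions; the
  pulled terminal methyl carbons double as the alpha-carbon observable.
* ``cystine`` - two cysteines joined by the S-S bond, pulled at the backbone
  N and C termini; 5 torsions.
* ``polypeptide-path`` - the force-bearing path of an
  Ile-Cys-(...)-Cys-Gln disulfide loop: N and C termini through the two
  cysteine side chains and the S-S bridge, with the slack loop residues
  (which carry no tension once the force path short-circuits through the
  bridge) omitted; 9 torsions, peptide omegas frozen at 180 degrees.

Torsional energies are Fourier series per torsion type, read from the
editable parameter file ``data/torsion_params.yaml``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .geometry import AtomSpec, Conformation, build_cartesian, distance

__all__ = ["Torsion", "TorsionalModel", "builtin_model", "load_model", "load_torsion_params"]

# rigid-geometry constants (Angstrom, degrees)
B_CC = 1.53
B_CS = 1.81
B_SS = 2.05
B_NCA = 1.458
B_CAC = 1.525
B_CN = 1.329
A_CCS = 114.0   # CA-CB-SG
A_CSS = 103.8   # CB-SG-SG
A_NCACB = 110.5
A_NCAC = 111.0
A_CACN = 116.6
A_CNCA = 121.7
A_CCC_DEDS = 108.6  # C-C-S in diethyl disulfide


@dataclass(frozen=True)
class Torsion:
    """One rotatable dihedral with its Fourier potential.

    ``v`` are amplitudes V1..V3 in kJ/mol, ``gamma`` the phase offsets in
    degrees: U(phi) = sum_n 0.5*V_n*(1 + cos(n*phi - gamma_n)).
    """

    index: int
    v: tuple[float, float, float]
    gamma: tuple[float, float, float] = (0.0, 180.0, 0.0)
    label: str = ""

    def energy(self, phi_deg: float) -> float:
        phi = math.radians(phi_deg)
        e = 0.0
        for n in range(1, 4):
            e += 0.5 * self.v[n - 1] * (1.0 + math.cos(n * phi - math.radians(self.gamma[n - 1])))
        return e


@dataclass
class TorsionalModel:
    """A rigid-geometry molecule with rotatable dihedrals and a pull axis."""

    name: str
    atoms: list[AtomSpec]
    torsions: list[Torsion]
    pull_pair: tuple[int, int]
    calpha_pair: tuple[int, int]
    chi1_index: int = -1
    chi2_index: int = -1
    chi3_index: int = -1

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if not self.torsions:
            raise ValueError(f"model {self.name!r} has no rotatable dihedrals")
        for pair, what in ((self.pull_pair, "pull_pair"), (self.calpha_pair, "calpha_pair")):
            if not all(0 <= i < n for i in pair):
                raise ValueError(f"model {self.name!r}: {what} {pair} out of range")
        for t in self.torsions:
            if not all(np.isfinite(t.v)):
                raise ValueError(f"model {self.name!r}: non-finite Fourier coefficients")
        used = {
            a.dihedral_ref
            for a in self.atoms
            if isinstance(a.dihedral_ref, (int, np.integer)) and a.internal_refs != (-1, -1, -1)
        }
        if used != set(range(len(self.torsions))):
            raise ValueError(
                f"model {self.name!r}: torsion indices used by atoms {sorted(used)} do not "
                f"match declared torsions 0..{len(self.torsions) - 1}"
            )

    @property
    def n_torsions(self) -> int:
        return len(self.torsions)

    def torsion_energy(self, conf: Conformation) -> float:
        """Total Fourier torsional energy (kJ/mol) of a conformation."""
        phi = np.asarray(conf.dihedrals, dtype=float)
        return float(sum(t.energy(phi[t.index]) for t in self.torsions))

    def pull_distance(self, conf: Conformation) -> float:
        """Mechanical coordinate R: distance between the pulled atoms."""
        s = build_cartesian(self, conf)
        return distance(s, *self.pull_pair)

    def calpha_distance(self, conf: Conformation) -> float:
        s = build_cartesian(self, conf)
        return distance(s, *self.calpha_pair)


def load_torsion_params(path: str | Path | None = None) -> dict[str, Torsion]:
    """Load per-type Fourier coefficients (default: the shipped parameter file)."""
    if path is None:
        text = resources.files("dscape.data").joinpath("torsion_params.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    out = {}
    for key, rec in raw.items():
        out[key] = Torsion(index=-1, v=tuple(rec["v"]), gamma=tuple(rec.get("gamma", (0.0, 180.0, 0.0))), label=key)
    return out


def _mk_torsions(types: list[str], params: dict[str, Torsion]) -> list[Torsion]:
    return [
        Torsion(index=i, v=params[t].v, gamma=params[t].gamma, label=t)
        for i, t in enumerate(types)
    ]


def builtin_model(name: str, params_path: str | Path | None = None) -> TorsionalModel:
    """Construct a builtin disulfide model: DEDS, cystine or polypeptide-path."""
    params = load_torsion_params(params_path)
    key = name.strip().lower().replace("_", "-")
    if key == "deds":
        atoms = [
            AtomSpec("C1", "C"),
            AtomSpec("C2", "C", (-1, -1, -1), B_CC, 0.0, 0.0),
            AtomSpec("S3", "S", (-1, -1, -1), B_CS, A_CCC_DEDS, 0.0),
            AtomSpec("S4", "S", (0, 1, 2), B_SS, A_CSS, 0),
            AtomSpec("C5", "C", (1, 2, 3), B_CS, A_CSS, 1),
            AtomSpec("C6", "C", (2, 3, 4), B_CC, A_CCC_DEDS, 2),
        ]
        return TorsionalModel(
            name="DEDS",
            atoms=atoms,
            torsions=_mk_torsions(["ccss", "cssc", "ccss"], params),
            pull_pair=(0, 5),
            calpha_pair=(0, 5),
            chi1_index=0,
            chi3_index=1,
            chi2_index=2,
        )
    if key == "cystine":
        atoms = [
            AtomSpec("N1", "N"),
            AtomSpec("CA1", "C", (-1, -1, -1), B_NCA, 0.0, 0.0),
            AtomSpec("CB1", "C", (-1, -1, -1), B_CC, A_NCACB, 0.0),
            AtomSpec("SG1", "S", (0, 1, 2), B_CS, A_CCS, 0),
            AtomSpec("SG2", "S", (1, 2, 3), B_SS, A_CSS, 1),
            AtomSpec("CB2", "C", (2, 3, 4), B_CS, A_CSS, 2),
            AtomSpec("CA2", "C", (3, 4, 5), B_CC, A_CCS, 3),
            AtomSpec("C2", "C", (4, 5, 6), B_CAC, A_NCACB, 4),
        ]
        return TorsionalModel(
            name="cystine",
            atoms=atoms,
            torsions=_mk_torsions(["cccs", "ccss", "cssc", "ccss", "cccs"], params),
            pull_pair=(0, 7),
            calpha_pair=(1, 6),
            chi1_index=1,
            chi3_index=2,
            chi2_index=3,
        )
    if key in ("polypeptide-path", "polypeptide"):
        atoms = [
            AtomSpec("N_I", "N"),
            AtomSpec("CA_I", "C", (-1, -1, -1), B_NCA, 0.0, 0.0),
            AtomSpec("C_I", "C", (-1, -1, -1), B_CAC, A_NCAC, 0.0),
            AtomSpec("N_C2", "N", (0, 1, 2), B_CN, A_CACN, 0),
            AtomSpec("CA_C2", "C", (1, 2, 3), B_NCA, A_CNCA, 180.0),
            AtomSpec("CB_C2", "C", (2, 3, 4), B_CC, A_NCACB, 1),
            AtomSpec("SG_C2", "S", (3, 4, 5), B_CS, A_CCS, 2),
            AtomSpec("SG_C10", "S", (4, 5, 6), B_SS, A_CSS, 3),
            AtomSpec("CB_C10", "C", (5, 6, 7), B_CS, A_CSS, 4),
            AtomSpec("CA_C10", "C", (6, 7, 8), B_CC, A_CCS, 5),
            AtomSpec("C_C10", "C", (7, 8, 9), B_CAC, A_NCACB, 6),
            AtomSpec("N_Q", "N", (8, 9, 10), B_CN, A_CACN, 7),
            AtomSpec("CA_Q", "C", (9, 10, 11), B_NCA, A_CNCA, 180.0),
            AtomSpec("C_Q", "C", (10, 11, 12), B_CAC, A_NCAC, 8),
        ]
        return TorsionalModel(
            name="polypeptide-path",
            atoms=atoms,
            torsions=_mk_torsions(
                ["backbone", "backbone", "cccs", "ccss", "cssc", "ccss", "cccs", "backbone", "backbone"],
                params,
            ),
            pull_pair=(0, 13),
            calpha_pair=(4, 9),
            chi1_index=3,
            chi3_index=4,
            chi2_index=5,
        )
    raise ValueError(f"unknown builtin model {name!r}; expected DEDS, cystine or polypeptide-path")


def load_model(path: str | Path) -> TorsionalModel:
    """Load a user-defined torsional model from a YAML topology file.

    The file declares one atom per record (name, element, refs, bond length,
    bond angle, dihedral reference) plus per-torsion Fourier coefficients and
    the pull/Calpha atom pairs; see the builtin models for the conventions.
    """
    raw = yaml.safe_load(Path(path).read_text())
    atoms = []
    for rec in raw["atoms"]:
        ref = rec.get("dihedral_ref", 0.0)
        if isinstance(ref, str):
            ref = float(ref)
        atoms.append(
            AtomSpec(
                name=str(rec["name"]),
                element=str(rec.get("element", rec["name"][0])),
                internal_refs=tuple(rec.get("refs", (-1, -1, -1))),
                bond_length=float(rec.get("bond_length", 0.0)),
                bond_angle=float(rec.get("bond_angle", 0.0)),
                dihedral_ref=ref,
            )
        )
    torsions = [
        Torsion(
            index=i,
            v=tuple(rec["v"]),
            gamma=tuple(rec.get("gamma", (0.0, 180.0, 0.0))),
            label=rec.get("label", ""),
        )
        for i, rec in enumerate(raw["torsions"])
    ]
    return TorsionalModel(
        name=str(raw.get("name", Path(path).stem)),
        atoms=atoms,
        torsions=torsions,
        pull_pair=tuple(raw["pull_pair"]),
        calpha_pair=tuple(raw["calpha_pair"]),
        chi1_index=int(raw.get("chi1_index", -1)),
        chi2_index=int(raw.get("chi2_index", -1)),
        chi3_index=int(raw.get("chi3_index", -1)),
    )
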