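"""PDB disulfide survey: locate S-S bridges, measure their dihedrals and
Calpha-Calpha distances, classify conformers, and aggregate per protein class.

Nomenclature (disulfide mechanochemistry usage): chi1 and chi2 are the two
C-C-S-S dihedrals (Calpha-Cbeta-Sgamma-Sgamma') flanking the bridge - one per
cysteine - and chi3 is the central C-S-S-C dihedral.  A dihedral within
180 +/- 50 degrees is "closed" (trans-like, shielding the sulfur from
collinear nucleophilic attack); anything else is "open".

Parsing is delegated to gemmi; only the first model of multi-model files is
used and alternate locations are resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .geometry import dihedral, to_signed
from .landscape import is_closed

__all__ = [
    "ResidueKey",
    "PdbStructure",
    "DisulfideGeometry",
    "ClassSummary",
    "PdbParseError",
    "parse_pdb",
    "find_disulfides",
    "measure_disulfide",
    "classify",
    "summarize_class",
    "survey",
]

logger = logging.getLogger(__name__)

#: acceptance window for an S-S bond length (Angstrom)
SS_LENGTH_RANGE = (1.8, 2.5)
DEFAULT_SG_CUTOFF = 2.5


class PdbParseError(ValueError):
    """Raised for unreadable or structurally empty PDB input."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    chain: str
    seqid: int
    icode: str = " "

    def __str__(self) -> str:
        ic = self.icode.strip()
        return f"{self.chain}/{self.seqid}{ic}"


@dataclass
class PdbStructure:
    """Light container: residues keyed by (chain, seqid, icode) with per-atom
    coordinates, plus residue names."""

    pdb_id: str
    atoms: dict[ResidueKey, dict[str, np.ndarray]]
    res_names: dict[ResidueKey, str]


@dataclass
class DisulfideGeometry:
    """Measured geometry of one disulfide bridge (angles in [0, 360) deg)."""

    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    chi1: float
    chi2: float
    chi3: float
    d_calpha: float
    ss_length: float
    state_a: str
    state_b: str
    joint_state: str
    interchain: bool
    icode_a: str = " "
    icode_b: str = " "


@dataclass
class ClassSummary:
    class_label: str
    n: int
    mean_d_calpha: float
    sd_d_calpha: float
    fraction_closed_closed: float


def _validate_pdb_text(path: Path) -> None:
    """Minimal sanity pass over coordinate records before handing to gemmi.

    Rejects truncated ATOM/HETATM lines (shorter than the 54 columns needed
    for coordinates), naming the offending line number.
    """
    n_atom_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                n_atom_lines += 1
                stripped = line.rstrip("\n")
                if len(stripped) < 54:
                    raise PdbParseError(f"{path}: truncated {rec} record at line {lineno}")
                try:
                    [float(stripped[i:j]) for i, j in ((30, 38), (38, 46), (46, 54))]
                except ValueError as exc:
                    raise PdbParseError(
                        f"{path}: unparseable coordinates at line {lineno}"
                    ) from exc
    if n_atom_lines == 0:
        raise PdbParseError(f"{path}: no ATOM records (empty structure)")


def parse_pdb(path: str | Path) -> tuple[PdbStructure, list[tuple[ResidueKey, ResidueKey]]]:
    """Parse a PDB-format file into a structure record plus SSBOND declarations.

    First model only for multi-model (e.g. NMR) files; alternate locations
    resolved to the highest-occupancy atom, ties broken by altloc identifier
    order.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such PDB file: {path}")
    _validate_pdb_text(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise PdbParseError(f"{path}: no models")
    if len(st) > 1:
        logger.info("%s: %d models present; using the first only", path.name, len(st))
    model = st[0]

    atoms: dict[ResidueKey, dict[str, np.ndarray]] = {}
    res_names: dict[ResidueKey, str] = {}
    best: dict[tuple[ResidueKey, str], tuple[float, str]] = {}
    for chain in model:
        for res in chain:
            key = ResidueKey(chain.name, res.seqid.num, res.seqid.icode or " ")
            res_names.setdefault(key, res.name)
            store = atoms.setdefault(key, {})
            for atom in res:
                rank = (-(atom.occ if atom.occ > 0 else 1.0), atom.altloc or " ")
                prev = best.get((key, atom.name))
                if prev is None or rank < prev:
                    best[(key, atom.name)] = rank
                    store[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])

    declarations: list[tuple[ResidueKey, ResidueKey]] = []
    for con in st.connections:
        if con.type != gemmi.ConnectionType.Disulf:
            continue
        k1 = ResidueKey(con.partner1.chain_name, con.partner1.res_id.seqid.num,
                        con.partner1.res_id.seqid.icode or " ")
        k2 = ResidueKey(con.partner2.chain_name, con.partner2.res_id.seqid.num,
                        con.partner2.res_id.seqid.icode or " ")
        declarations.append(tuple(sorted((k1, k2))))
    return PdbStructure(pdb_id=st.name or path.stem, atoms=atoms, res_names=res_names), declarations


REQUIRED_ATOMS = ("CA", "CB", "SG")


def find_disulfides(
    structure: PdbStructure,
    declarations: list[tuple[ResidueKey, ResidueKey]] | None = None,
    sg_cutoff: float = DEFAULT_SG_CUTOFF,
) -> list[tuple[ResidueKey, ResidueKey]]:
    """Union of declared SSBOND pairs and geometric Sgamma-Sgamma contacts.

    Geometric detection pairs distinct CYS residues whose SG atoms lie within
    ``sg_cutoff`` Angstrom.  Pairs missing any of CA/CB/SG on either side are
    excluded with a warning.
    """
    pairs: set[tuple[ResidueKey, ResidueKey]] = set(tuple(sorted(p)) for p in (declarations or []))
    cys = [k for k, name in structure.res_names.items() if name == "CYS" and "SG" in structure.atoms[k]]
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = np.linalg.norm(structure.atoms[cys[i]]["SG"] - structure.atoms[cys[j]]["SG"])
            if d <= sg_cutoff:
                pairs.add(tuple(sorted((cys[i], cys[j]))))
    valid = []
    for a, b in sorted(pairs):
        ok = True
        for key in (a, b):
            missing = [at for at in REQUIRED_ATOMS if at not in structure.atoms.get(key, {})]
            if missing:
                logger.warning(
                    "%s: disulfide %s-%s skipped, residue %s missing %s",
                    structure.pdb_id, a, b, key, ",".join(missing),
                )
                ok = False
        if ok:
            valid.append((a, b))
    return valid


def classify(chi: float) -> str:
    """'closed' if the wrapped C-C-S-S dihedral lies in [130, 230] deg, else 'open'."""
    return "closed" if is_closed(chi) else "open"


def measure_disulfide(
    structure: PdbStructure, pair: tuple[ResidueKey, ResidueKey]
) -> DisulfideGeometry:
    """Measure chi1/chi2/chi3, Calpha-Calpha and S-S distances of one bridge.

    The pair is ordered by (chain, residue number); residue a supplies chi1
    (CAa-CBa-SGa-SGb) and residue b chi2 (CAb-CBb-SGb-SGa).
    """
    a, b = sorted(pair)
    coords = {}
    for key in (a, b):
        res = structure.atoms.get(key)
        if res is None:
            raise KeyError(f"{structure.pdb_id}: residue {key} not found")
        for at in REQUIRED_ATOMS:
            if at not in res:
                raise KeyError(f"{structure.pdb_id}: residue {key} missing atom {at}")
        coords[key] = res
    ca_a, cb_a, sg_a = (coords[a][x] for x in REQUIRED_ATOMS)
    ca_b, cb_b, sg_b = (coords[b][x] for x in REQUIRED_ATOMS)
    chi1 = dihedral(ca_a, cb_a, sg_a, sg_b)
    chi2 = dihedral(ca_b, cb_b, sg_b, sg_a)
    chi3 = dihedral(cb_a, sg_a, sg_b, cb_b)
    state_a = classify(chi1)
    state_b = classify(chi2)
    joint = "/".join(sorted((state_a, state_b), reverse=True)) if state_a != state_b else f"{state_a}/{state_b}"
    return DisulfideGeometry(
        chain_a=a.chain,
        res_a=a.seqid,
        chain_b=b.chain,
        res_b=b.seqid,
        chi1=chi1,
        chi2=chi2,
        chi3=chi3,
        d_calpha=float(np.linalg.norm(ca_a - ca_b)),
        ss_length=float(np.linalg.norm(sg_a - sg_b)),
        state_a=state_a,
        state_b=state_b,
        joint_state=joint,
        interchain=a.chain != b.chain,
        icode_a=a.icode,
        icode_b=b.icode,
    )


def summarize_class(records: list[DisulfideGeometry], class_label: str) -> ClassSummary:
    """Mean/SD Calpha-Calpha distance and closed/closed fraction for a class."""
    if not records:
        raise ValueError(f"class {class_label!r}: empty record list")
    d = np.array([r.d_calpha for r in records])
    frac = float(np.mean([r.joint_state == "closed/closed" for r in records]))
    return ClassSummary(
        class_label=class_label,
        n=len(records),
        mean_d_calpha=float(d.mean()),
        sd_d_calpha=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        fraction_closed_closed=frac,
    )


def records_to_frame(pdb_id: str, records: list[DisulfideGeometry]) -> pd.DataFrame:
    """Per-disulfide survey table; both the [0, 360) and the signed (-180, 180]
    representation of each dihedral are reported."""
    rows = []
    for r in records:
        rows.append(
            {
                "pdb_id": pdb_id,
                "chain_a": r.chain_a,
                "res_a": r.res_a,
                "chain_b": r.chain_b,
                "res_b": r.res_b,
                "chi1": r.chi1,
                "chi2": r.chi2,
                "chi3": r.chi3,
                "chi1_signed": to_signed(r.chi1),
                "chi2_signed": to_signed(r.chi2),
                "chi3_signed": to_signed(r.chi3),
                "d_calpha": r.d_calpha,
                "ss_length": r.ss_length,
                "joint_state": r.joint_state,
                "interchain": r.interchain,
            }
        )
    return pd.DataFrame(rows)


def survey(
    paths,
    class_map: dict[tuple[str, str, int, str, int], str] | None = None,
    sg_cutoff: float = DEFAULT_SG_CUTOFF,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full pipeline over PDB files: parse, locate, measure, classify.

    ``class_map`` optionally assigns protein-class labels keyed by
    ``(pdb_id, chain_a, res_a, chain_b, res_b)``; unmapped disulfides fall
    back to ``interchain``/``intrachain`` by chain identity.  Returns the
    per-disulfide table and the per-class summary table.
    """
    frames = []
    for path in paths:
        structure, decls = parse_pdb(path)
        pairs = find_disulfides(structure, decls, sg_cutoff=sg_cutoff)
        records = []
        for pair in pairs:
            rec = measure_disulfide(structure, pair)
            lo, hi = SS_LENGTH_RANGE
            if not lo <= rec.ss_length <= hi:
                logger.warning(
                    "%s: %s%d-%s%d S-S length %.2f A outside [%.1f, %.1f]; excluded",
                    structure.pdb_id, rec.chain_a, rec.res_a, rec.chain_b, rec.res_b,
                    rec.ss_length, lo, hi,
                )
                continue
            records.append(rec)
        frames.append(records_to_frame(structure.pdb_id, records))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if table.empty:
        return table, pd.DataFrame()

    def label_of(row):
        if class_map:
            key = (row.pdb_id, row.chain_a, row.res_a, row.chain_b, row.res_b)
            if key in class_map:
                return class_map[key]
        return "interchain" if row.interchain else "intrachain"

    table["class_label"] = [label_of(r) for r in table.itertuples()]
    summaries = []
    for label, sub in table.groupby("class_label"):
        summaries.append(
            {
                "class_label": label,
                "n": len(sub),
                "mean_d_calpha": sub.d_calpha.mean(),
                "sd_d_calpha": sub.d_calpha.std(ddof=1) if len(sub) > 1 else 0.0,
                "fraction_closed_closed": (sub.joint_state == "closed/closed").mean(),
            }
        )
    return table, pd.DataFrame(summaries)
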