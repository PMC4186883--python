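"""Synthetic inputs for the survey pipeline: cystine-fragment PDB files built
at prescribed dihedrals, and per-class (chi1, chi2, d_calpha) tables that
emulate the statistical structure of crystal-structure disulfide surveys.

Protein classes emulated (centers/spreads are emulation parameters, not
measured values):

* ``intrachain-Ig-like`` - a single wrapped-Gaussian component centred on the
  closed/closed state (180, 180), the strained-bridge signature.
* ``interchain-Ig-like``, ``TDi-like``, ``DO-like`` - mixtures centred on
  open-state combinations (gauche C-C-S-S wells near +-60/+-85 degrees),
  the unstrained, redox-ready signature.

Class sizes default to 927, 69, 40 and 27 members respectively, the sizes of
the four crystal-structure data sets the survey stage is modelled after.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Conformation, build_cartesian, wrap_angle
from .landscape import is_closed
from .models import builtin_model

__all__ = [
    "ClassSpec",
    "DEFAULT_CLASS_SPECS",
    "write_disulfide_pdb",
    "sample_class",
    "make_shipped_fixtures",
    "fragment_d_calpha",
]

logger = logging.getLogger(__name__)

#: (chi1 center, chi2 center) components of the open-state mixtures, degrees
_OPEN_CENTERS = [(300.0, 300.0), (60.0, 300.0), (300.0, 60.0), (60.0, 60.0), (275.0, 180.0)]


@dataclass(frozen=True)
class ClassSpec:
    """Recipe for one synthetic protein-class scatter table.

    ``components`` is a list of ``(center_chi1, center_chi2, spread, weight)``
    tuples (degrees); draws are wrapped Gaussians.  ``d_noise_sd`` is the
    Gaussian noise (Angstrom) added to the geometric Calpha-Calpha distance
    of a cystine fragment built at the drawn dihedrals.
    """

    label: str
    components: tuple[tuple[float, float, float, float], ...]
    n: int
    d_noise_sd: float = 0.15
    chi3_center: float = 90.0
    chi3_spread: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"class {self.label!r}: n must be >= 1")
        w = sum(c[3] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"class {self.label!r}: component weights sum to {w}, not 1")
        if any(c[2] <= 0 for c in self.components):
            raise ValueError(f"class {self.label!r}: spreads must be positive")

    def closed_closed_probability(self) -> float:
        """Analytic closed/closed probability of the wrapped-Gaussian mixture.

        For each component the per-axis closed probability is the Gaussian
        mass on [130, 230] summed over +-360-degree images (the spreads used
        make further images negligible).
        """
        from scipy.stats import norm

        p = 0.0
        for c1, c2, s, w in self.components:
            def axis_mass(center: float) -> float:
                m = 0.0
                for shift in (-360.0, 0.0, 360.0):
                    m += norm.cdf(230.0, center + shift, s) - norm.cdf(130.0, center + shift, s)
                return m

            p += w * axis_mass(c1) * axis_mass(c2)
        return p


def _specs(master_seed: int = 0) -> dict[str, ClassSpec]:
    return {
        "intrachain-Ig-like": ClassSpec(
            "intrachain-Ig-like", (((180.0, 180.0, 25.0, 1.0)),), n=927, seed=master_seed * 4 + 0
        ),
        "interchain-Ig-like": ClassSpec(
            "interchain-Ig-like",
            tuple((c1, c2, 30.0, 0.2) for c1, c2 in _OPEN_CENTERS),
            n=69,
            seed=master_seed * 4 + 1,
        ),
        "TDi-like": ClassSpec(
            "TDi-like",
            tuple((c1, c2, 28.0, 0.2) for c1, c2 in _OPEN_CENTERS),
            n=40,
            seed=master_seed * 4 + 2,
        ),
        "DO-like": ClassSpec(
            "DO-like",
            tuple((c1, c2, 28.0, 0.2) for c1, c2 in _OPEN_CENTERS),
            n=27,
            seed=master_seed * 4 + 3,
        ),
    }


DEFAULT_CLASS_SPECS = _specs(0)

_FRAGMENT = None


def _fragment_model():
    global _FRAGMENT
    if _FRAGMENT is None:
        _FRAGMENT = builtin_model("cystine")
    return _FRAGMENT


def _fragment_conformation(chi1: float, chi2: float, chi3: float) -> Conformation:
    # cystine torsion order: side1, chi1, chi3, chi2, side2; sides held trans
    return Conformation(np.array([180.0, chi1, chi3, chi2, 180.0]))


def fragment_d_calpha(chi1: float, chi2: float, chi3: float = 90.0) -> float:
    """Geometric Calpha-Calpha distance of a rigid cystine fragment (Angstrom)."""
    m = _fragment_model()
    s = build_cartesian(m, _fragment_conformation(chi1, chi2, chi3))
    return float(np.linalg.norm(s.coords[m.calpha_pair[0]] - s.coords[m.calpha_pair[1]]))


# fragment atom -> (residue index 0/1, PDB atom name)
_ATOM_MAP = [
    (0, "N"), (0, "CA"), (0, "CB"), (0, "SG"),
    (1, "SG"), (1, "CB"), (1, "CA"), (1, "C"),
]


def write_disulfide_pdb(chi1: float, chi2: float, chi3: float, path: str | Path) -> Path:
    """Write a two-cysteine disulfide fragment at prescribed dihedrals.

    The fragment is a rigid cystine (standard bond lengths: S-S 2.05, C-S
    1.81, C-C 1.53 Angstrom) realized at the given chi1/chi2/chi3 and written
    as ATOM records with an SSBOND declaration; re-parsing the file recovers
    the prescribed angles to well under 1e-3 degrees.
    """
    for name, val in (("chi1", chi1), ("chi2", chi2), ("chi3", chi3)):
        if not np.isfinite(val):
            raise ValueError(f"{name} must be finite")
    m = _fragment_model()
    s = build_cartesian(m, _fragment_conformation(wrap_angle(chi1), wrap_angle(chi2), wrap_angle(chi3)))

    # Fixed-column PDB records are emitted directly so coordinates carry five
    # decimals (centred on the fragment centroid, every |coordinate| < 10 A,
    # so the value still fits the 8-column x/y/z fields); the standard three
    # decimals would limit dihedral round-trips to ~5e-3 degrees, short of
    # the 1e-3 degree recovery this writer guarantees.
    coords = s.coords - s.coords.mean(axis=0)
    ss = np.linalg.norm(coords[3] - coords[4])
    lines = [
        f"SSBOND   1 CYS A    1    CYS A    2                          1555   1555 {ss:5.2f}",
        "CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1",
    ]
    serial = 0
    for (ires, at_name), spec, xyz in zip(_ATOM_MAP, m.atoms, coords):
        serial += 1
        x, y, z = xyz
        lines.append(
            f"ATOM  {serial:5d}  {at_name:<3s}{'CYS':>4s} A{ires + 1:4d}    "
            f"{x:8.5f}{y:8.5f}{z:8.5f}{1.00:6.2f}{0.00:6.2f}          {spec.element:>2s}"
        )
    lines += [f"TER   {serial + 1:5d}      CYS A   2", "END"]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path


def sample_class(spec: ClassSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a synthetic (chi1, chi2, chi3, d_calpha) table for one class.

    Wrapped-Gaussian mixture draws for the dihedrals; d_calpha is the rigid
    cystine-fragment distance at the drawn dihedrals plus Gaussian noise.
    Deterministic under the spec's seed when no generator is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    weights = np.array([c[3] for c in spec.components])
    comp = rng.choice(len(spec.components), size=spec.n, p=weights)
    centers = np.array([(c[0], c[1]) for c in spec.components])
    spreads = np.array([c[2] for c in spec.components])
    chi1 = wrap_angle(rng.normal(centers[comp, 0], spreads[comp]))
    chi2 = wrap_angle(rng.normal(centers[comp, 1], spreads[comp]))
    sign = rng.choice([-1.0, 1.0], size=spec.n)  # S-S minima at +-90
    chi3 = wrap_angle(sign * rng.normal(spec.chi3_center, spec.chi3_spread, size=spec.n))
    d = np.array(
        [fragment_d_calpha(a, b, c) for a, b, c in zip(chi1, chi2, chi3)]
    ) + rng.normal(0.0, spec.d_noise_sd, size=spec.n)
    closed = is_closed(chi1) & is_closed(chi2)
    return pd.DataFrame(
        {
            "class_label": spec.label,
            "chi1": chi1,
            "chi2": chi2,
            "chi3": chi3,
            "d_calpha": d,
            "closed_closed": closed,
        }
    )


#: (chi1, chi2) of the 12 shipped single-disulfide fixtures, spanning the
#: (open|closed)^2 grid with angles one degree inside/outside the closed-band
#: edges and a strained near-(165, 178) example
FIXTURE_ANGLES = [
    (180.0, 180.0, 90.0),
    (165.0, 178.0, 95.0),
    (131.0, 229.0, 90.0),
    (229.0, 131.0, 270.0),
    (180.0, 60.0, 90.0),
    (60.0, 180.0, 270.0),
    (200.0, 300.0, 90.0),
    (60.0, 300.0, 90.0),
    (300.0, 300.0, 270.0),
    (60.0, 60.0, 90.0),
    (300.0, 60.0, 85.0),
    (129.0, 231.0, 90.0),
]


def make_shipped_fixtures(out_dir: str | Path, master_seed: int = 1) -> dict:
    """Write the standard fixture set and return its manifest.

    Contents: 12 single-disulfide PDB fragments spanning the (open|closed)^2
    grid and band boundaries, four class tables (intrachain-Ig-like n=927,
    interchain-Ig-like n=69, TDi-like n=40, DO-like n=27), one malformed PDB
    for negative tests, and a JSON manifest with SHA-256 digests.
    Regeneration with the same master seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"master_seed": master_seed, "pdb_files": [], "class_tables": []}

    for i, (c1, c2, c3) in enumerate(FIXTURE_ANGLES):
        name = f"disulfide_{i:02d}.pdb"
        write_disulfide_pdb(c1, c2, c3, out_dir / name)
        manifest["pdb_files"].append(
            {
                "file": name,
                "chi1": c1,
                "chi2": c2,
                "chi3": c3,
                "joint_state": _joint_state(c1, c2),
                "sha256": _digest(out_dir / name),
            }
        )

    bad = out_dir / "malformed.pdb"
    bad.write_text("ATOM      1  CA  CYS A   1      12.3\nEND\n")
    manifest["malformed_pdb"] = {"file": bad.name, "sha256": _digest(bad)}

    for label, spec in _specs(master_seed).items():
        table = sample_class(spec)
        fname = f"class_{label}.tsv"
        table.to_csv(out_dir / fname, sep="\t", index=False, float_format="%.4f")
        manifest["class_tables"].append(
            {
                "file": fname,
                "label": label,
                "n": int(spec.n),
                "closed_closed_fraction": float(table.closed_closed.mean()),
                "analytic_closed_closed": spec.closed_closed_probability(),
                "sha256": _digest(out_dir / fname),
            }
        )

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _joint_state(chi1: float, chi2: float) -> str:
    a = "closed" if is_closed(chi1) else "open"
    b = "closed" if is_closed(chi2) else "open"
    return f"{a}/{b}" if a == b else "open/closed"


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
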