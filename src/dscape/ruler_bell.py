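"""Stress-strain "ruler" and Bell-model rate enhancement.

The mean Calpha-Calpha distance of a disulfide model compound rises
monotonically with the applied tensile force, so the simulated
(force, mean distance) curve can be inverted: an observed Calpha-Calpha
distance in a crystal structure maps back to the effective tensile force that
would produce it.  Bell's phenomenological law then converts a force into a
rate enhancement for the force-accelerated S-S redox chemistry:

    k(F) / k0 = exp(F * dx / kB T)

with dx the distance-to-transition-state length parameter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, isotonic_regression

from .force_clamp import KB, PN_ANGSTROM_TO_KJ_PER_MOL
from .landscape import ForceScan

__all__ = [
    "RulerCurve",
    "BellParams",
    "ForceEstimate",
    "CalibrationError",
    "calibrate_ruler",
    "infer_force",
    "rate_enhancement",
]


class CalibrationError(ValueError):
    """Raised when calibration points cannot support a monotone ruler."""


@dataclass
class ForceEstimate:
    """Inverted ruler reading: force in pN with propagated uncertainty.

    ``flag`` is ``"ok"`` inside the calibrated range and
    ``"compressive/unstrained"`` when the observed distance falls below the
    zero-force mean (force reported as 0).
    """

    force: float
    se: float
    flag: str = "ok"


@dataclass
class RulerCurve:
    """Monotone force <-> mean-Calpha-Calpha-distance calibration."""

    forces: np.ndarray  # pN, strictly increasing, forces[0] == 0
    mean_d: np.ndarray  # Angstrom, strictly increasing
    se: np.ndarray
    model_name: str = ""

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        self.mean_d = np.asarray(self.mean_d, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if np.any(np.diff(self.forces) <= 0):
            raise CalibrationError("forces must be strictly increasing")
        if np.any(np.diff(self.mean_d) <= 0):
            raise CalibrationError("mean distances must be strictly increasing")
        self._interp = PchipInterpolator(self.forces, self.mean_d)

    def __call__(self, force) -> float | np.ndarray:
        out = self._interp(force)
        return float(out) if np.ndim(force) == 0 else out

    def slope(self, force) -> float:
        return float(self._interp.derivative()(force))

    @property
    def valid_range(self) -> tuple[float, float]:
        return float(self.mean_d[0]), float(self.mean_d[-1])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "model_name": self.model_name,
                    "forces_pN": self.forces.tolist(),
                    "mean_d_angstrom": self.mean_d.tolist(),
                    "se_angstrom": self.se.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RulerCurve":
        raw = json.loads(Path(path).read_text())
        return cls(
            forces=np.array(raw["forces_pN"]),
            mean_d=np.array(raw["mean_d_angstrom"]),
            se=np.array(raw["se_angstrom"]),
            model_name=raw.get("model_name", ""),
        )


def calibrate_ruler(scan: ForceScan | None = None, *, forces=None, mean_d=None, se=None,
                    model_name: str = "") -> RulerCurve:
    """Build a monotone shape-preserving ruler from a force scan.

    Accepts either a :class:`ForceScan` or explicit ``forces``/``mean_d``
    (+ optional ``se``) arrays.  Requires at least 3 forces including 0.
    Adjacent pairs violating monotonicity by more than their combined 3 SE
    abort the calibration; smaller violations (Monte-Carlo noise) are
    repaired by isotonic regression followed by a strict-increase nudge well
    below the statistical resolution.
    """
    if scan is not None:
        forces, mean_d, se, model_name = (
            scan.forces, scan.mean_d_calpha, scan.mean_d_calpha_se, scan.model_name,
        )
    forces = np.asarray(forces, dtype=float)
    mean_d = np.asarray(mean_d, dtype=float)
    se = np.zeros_like(mean_d) if se is None else np.asarray(se, dtype=float)
    order = np.argsort(forces)
    forces, mean_d, se = forces[order], mean_d[order], se[order]
    if len(forces) < 3:
        raise CalibrationError("need at least 3 calibration forces")
    if forces[0] != 0.0:
        raise CalibrationError("calibration must include zero force")
    drops = np.diff(mean_d)
    tol = 3.0 * np.hypot(se[:-1], se[1:])
    if np.any(drops < -tol):
        i = int(np.argmin(drops + tol))
        raise CalibrationError(
            f"gross non-monotonicity between {forces[i]:.0f} and {forces[i + 1]:.0f} pN: "
            f"mean distance drops {-drops[i]:.3g} A (> 3 SE)"
        )
    if np.any(drops <= 0):
        mean_d = isotonic_regression(mean_d).x
        # break exact ties so PCHIP stays strictly monotone and invertible
        eps = max(1e-9, 1e-4 * float(np.ptp(mean_d) or 1.0))
        for i in range(1, len(mean_d)):
            if mean_d[i] <= mean_d[i - 1]:
                mean_d[i] = mean_d[i - 1] + eps
    return RulerCurve(forces=forces, mean_d=mean_d, se=se, model_name=model_name)


def infer_force(curve: RulerCurve, d_obs: float, tol: float = 0.1) -> ForceEstimate:
    """Invert the ruler: the force (pN) whose mean distance equals ``d_obs``.

    Root-finding to ``tol`` pN.  Distances below the zero-force mean report
    0 pN with a "compressive/unstrained" flag; distances above the maximal
    calibrated extension raise.  The uncertainty is the local calibration SE
    divided by the local slope.
    """
    lo, hi = curve.valid_range
    if d_obs < lo:
        slope = max(curve.slope(0.0), 1e-12)
        return ForceEstimate(force=0.0, se=float(curve.se[0] / slope), flag="compressive/unstrained")
    if d_obs > hi:
        raise ValueError(
            f"observed distance {d_obs:.3f} A exceeds the calibrated range "
            f"[{lo:.3f}, {hi:.3f}] A"
        )
    if d_obs == lo:
        f = 0.0
    elif d_obs == hi:
        f = float(curve.forces[-1])
    else:
        f = brentq(lambda x: curve(x) - d_obs, curve.forces[0], curve.forces[-1], xtol=tol / 2)
    k = int(np.clip(np.searchsorted(curve.forces, f), 0, len(curve.forces) - 1))
    slope = max(curve.slope(f), 1e-12)
    return ForceEstimate(force=float(f), se=float(curve.se[k] / slope), flag="ok")


@dataclass(frozen=True)
class BellParams:
    """Bell-model parameters: length parameter dx (Angstrom), temperature (K),
    and the zero-force reference rate k0 (1.0 when only the ratio matters)."""

    delta_x: float
    temperature: float = 300.0
    k0: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_x <= 0:
            raise ValueError("delta_x must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def rate_enhancement(force: float, params: BellParams) -> float:
    """Bell's law k(F)/k0 = exp(F * dx / kB T); exactly 1 at zero force."""
    if force < 0:
        raise ValueError("force must be non-negative")
    return math.exp(
        force * params.delta_x * PN_ANGSTROM_TO_KJ_PER_MOL / (KB * params.temperature)
    )
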