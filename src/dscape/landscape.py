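"""Landscape observables: periodic 2D (chi1, chi2) histograms, Boltzmann
inversion between probability and free energy, open-conformer statistics and
force scans.

The open/closed nomenclature follows disulfide mechanochemistry: a C-C-S-S
dihedral is *closed* when it lies within 180 +/- 50 degrees (trans-like,
blocking the collinear nucleophilic-attack cone on sulfur) and *open*
otherwise.  An ensemble member is an open conformer when at least one of its
two C-C-S-S dihedrals is open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .force_clamp import CLOSED_HI, CLOSED_LO, KB, ForceClampEnsemble, metropolis_sample
from .models import TorsionalModel

__all__ = [
    "Landscape2D",
    "ForceScan",
    "is_closed",
    "histogram2d",
    "boltzmann_invert",
    "fes_to_p",
    "open_fraction",
    "batch_means_se",
    "force_scan",
]


def is_closed(chi) -> np.ndarray | bool:
    """Closed-state test for C-C-S-S dihedrals: wrapped angle in [130, 230]."""
    w = np.mod(np.asarray(chi, dtype=float), 360.0)
    out = (w >= CLOSED_LO) & (w <= CLOSED_HI)
    if np.ndim(chi) == 0:
        return bool(out)
    return out


@dataclass
class Landscape2D:
    """Periodic (chi1, chi2) probability / free-energy surface on [0, 360)^2."""

    n_bins: int
    edges: np.ndarray  # (n_bins + 1,) shared by both axes
    counts: np.ndarray  # (n_bins, n_bins) integers, chi1 rows, chi2 columns
    P: np.ndarray  # normalized probabilities, sum = 1
    fes: np.ndarray  # -kB T ln P, min-shifted to 0; NaN where unsampled
    sampled: np.ndarray  # bool mask of sampled bins
    temperature: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self) -> pd.DataFrame:
        """Probability matrix as a DataFrame indexed by bin centers (degrees)."""
        c = self.centers
        return pd.DataFrame(self.P, index=pd.Index(c, name="chi1"), columns=pd.Index(c, name="chi2"))


def histogram2d(
    ensemble: ForceClampEnsemble,
    chi1_index: int | None = None,
    chi2_index: int | None = None,
    n_bins: int = 72,
    temperature: float | None = None,
) -> Landscape2D:
    """Periodic 2D histogram of two dihedrals of an ensemble.

    Default indices are the ensemble's chi1/chi2; 360 degrees wraps into bin
    0.  Counts sum to the sample count and P = counts/total.
    """
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    if ensemble.n_samples == 0:
        raise ValueError("empty ensemble")
    chi1_index = ensemble.chi1_index if chi1_index is None else chi1_index
    chi2_index = ensemble.chi2_index if chi2_index is None else chi2_index
    x = np.mod(ensemble.dihedrals[:, chi1_index], 360.0)
    y = np.mod(ensemble.dihedrals[:, chi2_index], 360.0)
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    ix = np.minimum((x / 360.0 * n_bins).astype(np.int64), n_bins - 1)
    iy = np.minimum((y / 360.0 * n_bins).astype(np.int64), n_bins - 1)
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    np.add.at(counts, (ix, iy), 1)
    p = counts / counts.sum()
    temp = ensemble.temperature if temperature is None else temperature
    fes, sampled = boltzmann_invert(p, temp)
    return Landscape2D(
        n_bins=n_bins, edges=edges, counts=counts, P=p, fes=fes, sampled=sampled, temperature=temp
    )


def boltzmann_invert(P, temperature: float):
    """Free energy per bin, F = -kB T ln P, min-shifted so the deepest bin is 0.

    Zero-probability (unsampled) bins are flagged ``False`` in the returned
    mask and carry NaN rather than an infinite energy.  Returns
    ``(fes, sampled_mask)``.
    """
    p = np.asarray(P, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    sampled = p > 0
    if not np.any(sampled):
        raise ValueError("all-zero probability array")
    fes = np.full(p.shape, np.nan)
    fes[sampled] = -KB * temperature * np.log(p[sampled])
    fes[sampled] -= np.nanmin(fes[sampled])
    return fes, sampled


def fes_to_p(fes, temperature: float) -> np.ndarray:
    """Invert a free-energy surface back to normalized probabilities.

    NaN (unsampled) bins get probability zero; the result sums to 1.
    """
    f = np.asarray(fes, dtype=float)
    w = np.where(np.isfinite(f), np.exp(-np.where(np.isfinite(f), f, 0.0) / (KB * temperature)), 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("free-energy surface has no finite bins")
    return w / total


def batch_means_se(values: np.ndarray, n_batches: int = 20) -> float:
    """Standard error by batch means (autocorrelation-robust for MC chains)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < n_batches:
        n_batches = max(2, n)
    m = n // n_batches
    batches = v[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))


def open_fraction(
    ensemble: ForceClampEnsemble,
    chi1_index: int | None = None,
    chi2_index: int | None = None,
) -> tuple[float, float]:
    """Fraction of samples with at least one C-C-S-S dihedral open, with SE.

    The complement of the closed/closed occupancy; SE by batch means over 20
    batches.
    """
    if ensemble.n_samples == 0:
        raise ValueError("empty ensemble")
    chi1_index = ensemble.chi1_index if chi1_index is None else chi1_index
    chi2_index = ensemble.chi2_index if chi2_index is None else chi2_index
    open_flags = ~(
        is_closed(ensemble.dihedrals[:, chi1_index]) & is_closed(ensemble.dihedrals[:, chi2_index])
    )
    frac = float(open_flags.mean())
    return frac, batch_means_se(open_flags.astype(float))


@dataclass
class ForceScan:
    """Force-resolved ensemble summaries (one row per applied force)."""

    model_name: str
    forces: np.ndarray  # pN
    open_fraction: np.ndarray
    open_fraction_se: np.ndarray
    closed_closed_fraction: np.ndarray
    closed_closed_se: np.ndarray
    mean_R: np.ndarray
    mean_R_se: np.ndarray
    mean_d_calpha: np.ndarray
    mean_d_calpha_se: np.ndarray
    chi3_dev: np.ndarray  # mean |chi3 - nearest of +-90 deg|
    chi3_dev_se: np.ndarray
    seeds: np.ndarray
    temperature: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "force_pN": self.forces,
                "open_fraction": self.open_fraction,
                "open_fraction_se": self.open_fraction_se,
                "closed_closed_fraction": self.closed_closed_fraction,
                "closed_closed_se": self.closed_closed_se,
                "mean_R": self.mean_R,
                "mean_R_se": self.mean_R_se,
                "mean_d_calpha": self.mean_d_calpha,
                "mean_d_calpha_se": self.mean_d_calpha_se,
                "chi3_dev": self.chi3_dev,
                "chi3_dev_se": self.chi3_dev_se,
                "seed": self.seeds,
            }
        )


def chi3_deviation(chi3: np.ndarray) -> np.ndarray:
    """Absolute deviation of the S-S torsion from its nearest unstrained
    minimum (+-90 degrees on the wrapped circle)."""
    w = np.mod(np.asarray(chi3, dtype=float), 360.0)
    return np.minimum.reduce([np.abs(w - 90.0), np.abs(w - 270.0)])


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-run seed below 2**31 from a master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def force_scan(
    model: TorsionalModel,
    forces,
    temperature: float = 300.0,
    n_steps: int = 500_000,
    master_seed: int = 7,
    step_width: float = 30.0,
    thinning: int = 10,
) -> ForceScan:
    """Run the sampler across a force ladder and summarize each ensemble.

    Per-force seeds are derived deterministically from ``master_seed`` and
    the force value itself, so identical ladders reproduce identical rows and
    a force repeated within one ladder yields identical rows.
    """
    forces = np.asarray(list(forces), dtype=float)
    if len(forces) < 2:
        raise ValueError("force_scan needs at least 2 forces")
    rows = {k: [] for k in (
        "of", "of_se", "cc", "cc_se", "r", "r_se", "d", "d_se", "x3", "x3_se", "seed")}
    for f in forces:
        seed = derive_seed(master_seed, int(round(f * 1024.0)))
        ens = metropolis_sample(
            model, float(f), temperature, n_steps=n_steps, seed=seed,
            step_width=step_width, thinning=thinning,
        )
        of, of_se = open_fraction(ens)
        cc_flags = (
            is_closed(ens.dihedrals[:, ens.chi1_index]) & is_closed(ens.dihedrals[:, ens.chi2_index])
        ).astype(float)
        x3 = chi3_deviation(ens.dihedrals[:, ens.chi3_index]) if ens.chi3_index >= 0 else np.zeros(1)
        for key, val, se in (
            ("of", of, of_se),
            ("cc", float(cc_flags.mean()), batch_means_se(cc_flags)),
            ("r", float(ens.R.mean()), batch_means_se(ens.R)),
            ("d", float(ens.d_calpha.mean()), batch_means_se(ens.d_calpha)),
            ("x3", float(x3.mean()), batch_means_se(x3)),
        ):
            rows[key].append(val)
            rows[key + "_se"].append(se)
        rows["seed"].append(seed)
    return ForceScan(
        model_name=model.name,
        forces=forces,
        open_fraction=np.array(rows["of"]),
        open_fraction_se=np.array(rows["of_se"]),
        closed_closed_fraction=np.array(rows["cc"]),
        closed_closed_se=np.array(rows["cc_se"]),
        mean_R=np.array(rows["r"]),
        mean_R_se=np.array(rows["r_se"]),
        mean_d_calpha=np.array(rows["d"]),
        mean_d_calpha_se=np.array(rows["d_se"]),
        chi3_dev=np.array(rows["x3"]),
        chi3_dev_se=np.array(rows["x3_se"]),
        seeds=np.array(rows["seed"], dtype=np.int64),
        temperature=temperature,
    )
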