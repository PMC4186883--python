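"""Constant-force (isotensional) torsional Monte Carlo.

The external tensile force F enters the energy as a mechanical work term
``-F * R`` where R, the mechanical coordinate, is the distance between the two
pulled atoms.  Sampling is single-dihedral-update Metropolis over the model's
rotatable dihedrals; an exact grid-quadrature oracle is provided for models
with at most three torsions.

Units: forces in pN, energies in kJ/mol, distances in Angstrom, temperature
in K.  1 pN * 1 Angstrom = 0.06022 kJ/mol; kB = 0.0083145 kJ/(mol K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import Conformation
from .models import TorsionalModel, builtin_model  # noqa: F401  (re-exported surface)

__all__ = [
    "KB",
    "PN_ANGSTROM_TO_KJ_PER_MOL",
    "ForceClampEnsemble",
    "QuadratureResult",
    "total_energy",
    "metropolis_sample",
    "quadrature_reference",
    "builtin_model",
    "TorsionalModel",
]

KB = 0.0083145  # kJ/(mol K)
PN_ANGSTROM_TO_KJ_PER_MOL = 0.06022

#: closed-state band for a C-C-S-S dihedral: 180 +/- 50 degrees, inclusive
CLOSED_LO = 130.0
CLOSED_HI = 230.0


@dataclass
class ForceClampEnsemble:
    """Thinned post-burn-in samples of a constant-force Metropolis run."""

    model_name: str
    force: float  # pN
    temperature: float  # K
    seed: int
    n_steps: int
    n_burnin: int
    thinning: int
    dihedrals: np.ndarray  # (n_samples, n_torsions), degrees in [0, 360)
    R: np.ndarray  # pull-pair distances, Angstrom
    d_calpha: np.ndarray
    energy: np.ndarray  # kJ/mol
    acceptance_rate: float
    chi1_index: int = -1
    chi2_index: int = -1
    chi3_index: int = -1

    def __post_init__(self) -> None:
        if np.any(self.R <= 0):
            raise ValueError("mechanical coordinate R must be positive for every sample")
        expected = (self.n_steps - self.n_burnin) // self.thinning
        if len(self.R) != expected:
            raise ValueError(
                f"sample count {len(self.R)} != (n_steps - n_burnin)/thinning = {expected}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.R)


@dataclass
class QuadratureResult:
    """Exact Boltzmann expectations from grid quadrature."""

    mean_R: float
    mean_d_calpha: float
    p_closed_closed: float
    p_open_open: float
    p_open_closed: float
    marginals: np.ndarray  # (n_torsions, n_grid) densities per degree
    grid_centers: np.ndarray  # degrees
    R_max: float


def total_energy(model: TorsionalModel, conf: Conformation, force: float, temperature: float = 300.0) -> float:
    """Isotensional energy (kJ/mol): torsional Fourier terms minus F*R.

    ``temperature`` is accepted for interface symmetry with the sampler; the
    energy itself is temperature-independent.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    r = model.pull_distance(conf)
    return model.torsion_energy(conf) - force * r * PN_ANGSTROM_TO_KJ_PER_MOL


def metropolis_sample(
    model: TorsionalModel,
    force: float,
    temperature: float = 300.0,
    n_steps: int = 2_000_000,
    seed: int = 0,
    step_width: float = 30.0,
    n_burnin: int | None = None,
    thinning: int = 10,
) -> ForceClampEnsemble:
    """Sample the isotensional ensemble at constant force (pN) and T (K).

    Proposals perturb one randomly chosen dihedral by a wrapped Gaussian of
    width ``step_width`` degrees; acceptance is Metropolis.  Burn-in defaults
    to 10% of ``n_steps``; the returned ensemble holds every ``thinning``-th
    post-burn-in state.  Runs are deterministic given ``seed``.
    """
    if not 0.0 < step_width <= 180.0:
        raise ValueError("step_width must lie in (0, 180] degrees")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if n_burnin is None:
        n_burnin = n_steps // 10
    if n_steps <= n_burnin:
        raise ValueError("n_steps must exceed n_burnin")
    packed = _kernels.pack_model(model)
    phi, r, dca, e, acc = _kernels.mc_run(
        *packed,
        force * PN_ANGSTROM_TO_KJ_PER_MOL,
        1.0 / (KB * temperature),
        n_steps,
        n_burnin,
        thinning,
        np.radians(step_width),
        seed % (2**32),
    )
    return ForceClampEnsemble(
        model_name=model.name,
        force=force,
        temperature=temperature,
        seed=seed,
        n_steps=n_steps,
        n_burnin=n_burnin,
        thinning=thinning,
        dihedrals=np.degrees(phi) % 360.0,
        R=r,
        d_calpha=dca,
        energy=e,
        acceptance_rate=acc,
        chi1_index=model.chi1_index,
        chi2_index=model.chi2_index,
        chi3_index=model.chi3_index,
    )


def quadrature_reference(
    model: TorsionalModel,
    force: float,
    temperature: float = 300.0,
    grid_points_per_dihedral: int = 120,
) -> QuadratureResult:
    """Exact Boltzmann expectations by dense grid quadrature.

    Refuses models with more than three rotatable dihedrals (the grid grows
    as ``n_grid**n_torsions``).  Joint open/closed probabilities use the
    model's chi1/chi2 indices and the 180 +/- 50 degree closed band.
    """
    if model.n_torsions > 3:
        raise ValueError(
            f"quadrature oracle limited to <= 3 dihedrals; model {model.name!r} has {model.n_torsions}"
        )
    if model.chi1_index < 0 or model.chi2_index < 0:
        raise ValueError("model must declare chi1/chi2 indices for joint-state probabilities")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    packed = _kernels.pack_model(model)
    mean_r, mean_dca, p_cc, p_oo, marg, r_max = _kernels.quadrature(
        *packed,
        force * PN_ANGSTROM_TO_KJ_PER_MOL,
        1.0 / (KB * temperature),
        grid_points_per_dihedral,
        model.chi1_index,
        model.chi2_index,
        np.radians(CLOSED_LO),
        np.radians(CLOSED_HI),
    )
    h = 360.0 / grid_points_per_dihedral
    centers = (np.arange(grid_points_per_dihedral) + 0.5) * h
    return QuadratureResult(
        mean_R=mean_r,
        mean_d_calpha=mean_dca,
        p_closed_closed=p_cc,
        p_open_open=p_oo,
        p_open_closed=1.0 - p_cc - p_oo,
        marginals=marg * (np.pi / 180.0),  # per-degree densities
        grid_centers=centers,
        R_max=r_max,
    )
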