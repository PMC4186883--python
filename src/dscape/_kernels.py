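"""Numba-jitted inner loops: NeRF chain building, torsional energies,
Metropolis sampling and grid quadrature.

A :class:`~dscape.models.TorsionalModel` is flattened to plain arrays by
:func:`pack_model` so the kernels stay nopython-compatible.  All angles inside
the kernels are radians; the public modules convert at the boundary.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .geometry import COLLINEAR_TOL


def pack_model(model):
    """Flatten a TorsionalModel into the array bundle the kernels consume."""
    n = len(model.atoms)
    refs = np.full((n, 3), -1, dtype=np.int64)
    blen = np.zeros(n)
    bang = np.zeros(n)
    tor_idx = np.full(n, -1, dtype=np.int64)
    tor_fixed = np.zeros(n)
    for i, a in enumerate(model.atoms):
        blen[i] = a.bond_length
        bang[i] = np.radians(a.bond_angle)
        if i >= 3:
            refs[i] = a.internal_refs
            if isinstance(a.dihedral_ref, (int, np.integer)):
                tor_idx[i] = int(a.dihedral_ref)
            else:
                tor_fixed[i] = np.radians(float(a.dihedral_ref))
    nt = model.n_torsions
    fv = np.zeros((nt, 3))
    fg = np.zeros((nt, 3))
    for t in model.torsions:
        fv[t.index] = t.v
        fg[t.index] = np.radians(np.asarray(t.gamma))
    return (
        refs,
        blen,
        bang,
        tor_idx,
        tor_fixed,
        fv,
        fg,
        np.array(model.pull_pair, dtype=np.int64),
        np.array(model.calpha_pair, dtype=np.int64),
    )


@njit(cache=True)
def _build(refs, blen, bang, tor_idx, tor_fixed, phi, coords):
    """NeRF chain construction; phi in radians; coords written in place."""
    coords[0, 0] = 0.0
    coords[0, 1] = 0.0
    coords[0, 2] = 0.0
    coords[1, 0] = blen[1]
    coords[1, 1] = 0.0
    coords[1, 2] = 0.0
    coords[2, 0] = blen[1] - blen[2] * np.cos(bang[2])
    coords[2, 1] = blen[2] * np.sin(bang[2])
    coords[2, 2] = 0.0
    n = refs.shape[0]
    for i in range(3, n):
        ia, ib, ic = refs[i, 0], refs[i, 1], refs[i, 2]
        if tor_idx[i] >= 0:
            tor = phi[tor_idx[i]]
        else:
            tor = tor_fixed[i]
        # bc unit vector
        bcx = coords[ic, 0] - coords[ib, 0]
        bcy = coords[ic, 1] - coords[ib, 1]
        bcz = coords[ic, 2] - coords[ib, 2]
        nbc = np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
        bcx /= nbc
        bcy /= nbc
        bcz /= nbc
        abx = coords[ib, 0] - coords[ia, 0]
        aby = coords[ib, 1] - coords[ia, 1]
        abz = coords[ib, 2] - coords[ia, 2]
        nx = aby * bcz - abz * bcy
        ny = abz * bcx - abx * bcz
        nz = abx * bcy - aby * bcx
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        nx /= nn
        ny /= nn
        nz /= nn
        mx = ny * bcz - nz * bcy
        my = nz * bcx - nx * bcz
        mz = nx * bcy - ny * bcx
        b = blen[i]
        ct = np.cos(bang[i])
        st = np.sin(bang[i])
        cp = np.cos(tor)
        sp = np.sin(tor)
        coords[i, 0] = coords[ic, 0] - b * ct * bcx + b * st * cp * mx + b * st * sp * nx
        coords[i, 1] = coords[ic, 1] - b * ct * bcy + b * st * cp * my + b * st * sp * ny
        coords[i, 2] = coords[ic, 2] - b * ct * bcz + b * st * cp * mz + b * st * sp * nz


@njit(cache=True)
def _dist(coords, i, j):
    dx = coords[i, 0] - coords[j, 0]
    dy = coords[i, 1] - coords[j, 1]
    dz = coords[i, 2] - coords[j, 2]
    return np.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True)
def _torsion_energy(fv, fg, phi):
    e = 0.0
    for k in range(fv.shape[0]):
        for n in range(1, 4):
            e += 0.5 * fv[k, n - 1] * (1.0 + np.cos(n * phi[k] - fg[k, n - 1]))
    return e


@njit(cache=True)
def mc_run(
    refs,
    blen,
    bang,
    tor_idx,
    tor_fixed,
    fv,
    fg,
    pull,
    calpha,
    f_kj,  # force in kJ/(mol Angstrom), i.e. pN * 0.06022
    beta,  # 1/(kB T) in mol/kJ
    n_steps,
    n_burnin,
    thinning,
    step_rad,
    seed,
):
    """Single-dihedral-update Metropolis sampling of the isotensional ensemble.

    Energy: sum of torsional Fourier terms minus f*R with R the pull-pair
    distance.  Returns thinned post-burn-in samples of (phi, R, d_calpha, E)
    and the overall acceptance rate.
    """
    np.random.seed(seed)
    n_tor = fv.shape[0]
    n_atoms = refs.shape[0]
    coords = np.zeros((n_atoms, 3))
    phi = np.random.uniform(0.0, 2.0 * np.pi, n_tor)
    _build(refs, blen, bang, tor_idx, tor_fixed, phi, coords)
    r = _dist(coords, pull[0], pull[1])
    e = _torsion_energy(fv, fg, phi) - f_kj * r
    n_out = (n_steps - n_burnin) // thinning
    out_phi = np.empty((n_out, n_tor))
    out_r = np.empty(n_out)
    out_dca = np.empty(n_out)
    out_e = np.empty(n_out)
    n_acc = 0
    idx = 0
    two_pi = 2.0 * np.pi
    for step in range(n_steps):
        k = np.random.randint(0, n_tor)
        old = phi[k]
        prop = old + step_rad * np.random.normal()
        prop = prop % two_pi
        if prop < 0.0:
            prop += two_pi
        phi[k] = prop
        _build(refs, blen, bang, tor_idx, tor_fixed, phi, coords)
        r_new = _dist(coords, pull[0], pull[1])
        e_new = _torsion_energy(fv, fg, phi) - f_kj * r_new
        de = e_new - e
        if de <= 0.0 or np.random.random() < np.exp(-beta * de):
            e = e_new
            r = r_new
            n_acc += 1
        else:
            phi[k] = old
        if step >= n_burnin and (step - n_burnin) % thinning == 0 and idx < n_out:
            # coords may hold a rejected proposal; rebuild at the current state
            _build(refs, blen, bang, tor_idx, tor_fixed, phi, coords)
            out_phi[idx] = phi
            out_r[idx] = r
            out_dca[idx] = _dist(coords, calpha[0], calpha[1])
            out_e[idx] = e
            idx += 1
    return out_phi[:idx], out_r[:idx], out_dca[:idx], out_e[:idx], n_acc / n_steps


@njit(cache=True)
def _band_fraction(center, h, lo, hi):
    """Fraction of the cell [center - h/2, center + h/2] inside [lo, hi]."""
    a = center - 0.5 * h
    b = center + 0.5 * h
    left = a if a > lo else lo
    right = b if b < hi else hi
    if right <= left:
        return 0.0
    return (right - left) / h


@njit(cache=True)
def quadrature(
    refs,
    blen,
    bang,
    tor_idx,
    tor_fixed,
    fv,
    fg,
    pull,
    calpha,
    f_kj,
    beta,
    n_grid,
    chi1,
    chi2,
    closed_lo,  # radians
    closed_hi,
):
    """Exact Boltzmann expectations on a periodic grid for <=3 torsions.

    Midpoint rule on the periodic torus (equivalent to the trapezoidal rule
    for periodic integrands).  Returns (Z-weighted) <R>, <d_calpha>,
    P(closed/closed), P(open/open), the per-torsion marginal densities and
    the maximum of R over the grid.  Energies are shifted by their grid
    minimum before exponentiation to avoid underflow.
    """
    n_tor = fv.shape[0]
    n_atoms = refs.shape[0]
    coords = np.zeros((n_atoms, 3))
    phi = np.zeros(n_tor)
    two_pi = 2.0 * np.pi
    h = two_pi / n_grid
    total = n_grid ** n_tor
    # first pass: minimum energy
    e_min = 1e300
    for flat in range(total):
        rem = flat
        for k in range(n_tor):
            phi[k] = (rem % n_grid + 0.5) * h
            rem //= n_grid
        _build(refs, blen, bang, tor_idx, tor_fixed, phi, coords)
        r = _dist(coords, pull[0], pull[1])
        e = _torsion_energy(fv, fg, phi) - f_kj * r
        if e < e_min:
            e_min = e
    z = 0.0
    mean_r = 0.0
    mean_dca = 0.0
    p_cc = 0.0
    p_oo = 0.0
    r_max = 0.0
    marginals = np.zeros((n_tor, n_grid))
    for flat in range(total):
        rem = flat
        for k in range(n_tor):
            phi[k] = (rem % n_grid + 0.5) * h
            rem //= n_grid
        _build(refs, blen, bang, tor_idx, tor_fixed, phi, coords)
        r = _dist(coords, pull[0], pull[1])
        if r > r_max:
            r_max = r
        dca = _dist(coords, calpha[0], calpha[1])
        e = _torsion_energy(fv, fg, phi) - f_kj * r
        w = np.exp(-beta * (e - e_min))
        z += w
        mean_r += w * r
        mean_dca += w * dca
        # exact overlap of each grid cell with the closed band, so the joint
        # probabilities are not biased by cells straddling the band edges
        f1 = _band_fraction(phi[chi1], h, closed_lo, closed_hi)
        f2 = _band_fraction(phi[chi2], h, closed_lo, closed_hi)
        p_cc += w * f1 * f2
        p_oo += w * (1.0 - f1) * (1.0 - f2)
        rem = flat
        for k in range(n_tor):
            marginals[k, rem % n_grid] += w
            rem //= n_grid
    mean_r /= z
    mean_dca /= z
    p_cc /= z
    p_oo /= z
    for k in range(n_tor):
        s = 0.0
        for g in range(n_grid):
            s += marginals[k, g]
        for g in range(n_grid):
            marginals[k, g] /= s * h  # density per radian
    return mean_r, mean_dca, p_cc, p_oo, marginals, r_max
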