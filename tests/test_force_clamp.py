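import numpy as np
import pytest
from scipy import stats

from dscape.force_clamp import (
    KB,
    PN_ANGSTROM_TO_KJ_PER_MOL,
    metropolis_sample,
    quadrature_reference,
    total_energy,
)
from dscape.geometry import AtomSpec, Conformation
from dscape.models import Torsion, TorsionalModel


def _zero_potential_deds(deds):
    return TorsionalModel(
        name="deds-flat",
        atoms=deds.atoms,
        torsions=[Torsion(t.index, (0.0, 0.0, 0.0), t.gamma, t.label) for t in deds.torsions],
        pull_pair=deds.pull_pair,
        calpha_pair=deds.calpha_pair,
        chi1_index=deds.chi1_index,
        chi2_index=deds.chi2_index,
        chi3_index=deds.chi3_index,
    )


def _single_torsion_model(v=(5.0, 0.0, 0.0)):
    atoms = [
        AtomSpec("A", "C"),
        AtomSpec("B", "C", (-1, -1, -1), 1.5, 0.0, 0.0),
        AtomSpec("C", "C", (-1, -1, -1), 1.5, 109.47, 0.0),
        AtomSpec("D", "C", (0, 1, 2), 1.5, 109.47, 0),
    ]
    return TorsionalModel(
        name="one-torsion",
        atoms=atoms,
        torsions=[Torsion(0, v)],
        pull_pair=(0, 3),
        calpha_pair=(0, 3),
        chi1_index=0,
        chi2_index=0,
        chi3_index=-1,
    )


def test_total_energy_zero_everywhere_for_flat_free_model(deds):
    flat = _zero_potential_deds(deds)
    rng = np.random.default_rng(0)
    for _ in range(5):
        conf = Conformation(rng.uniform(0, 360, 3))
        assert total_energy(flat, conf, force=0.0) == pytest.approx(0.0, abs=1e-12)


def test_total_energy_work_term_unit_conversion(deds):
    """At 100 pN the energy difference between two conformations is
    -100 * dR * 0.06022 kJ/mol; for dR = 2 A that is -12.044 kJ/mol."""
    flat = _zero_potential_deds(deds)
    c1 = Conformation(np.array([60.0, 90.0, 60.0]))
    c2 = Conformation(np.array([180.0, 180.0, 180.0]))
    r1, r2 = flat.pull_distance(c1), flat.pull_distance(c2)
    de = total_energy(flat, c2, 100.0) - total_energy(flat, c1, 100.0)
    assert de == pytest.approx(-100.0 * (r2 - r1) * 0.06022, abs=1e-9)
    # the work term per 2 A of extension at 100 pN
    assert 100.0 * 2.0 * PN_ANGSTROM_TO_KJ_PER_MOL == pytest.approx(12.044)


def test_total_energy_periodic_in_dihedrals(deds):
    phi = np.array([75.0, 200.0, 310.0])
    e1 = total_energy(deds, Conformation(phi.copy()), 250.0)
    e2 = total_energy(deds, Conformation(phi + np.array([360.0, 0.0, -360.0])), 250.0)
    assert e2 == pytest.approx(e1, abs=1e-9)


def test_metropolis_input_validation(deds):
    with pytest.raises(ValueError, match="step_width"):
        metropolis_sample(deds, 0.0, step_width=0.0, n_steps=1000)
    with pytest.raises(ValueError, match="temperature"):
        metropolis_sample(deds, 0.0, temperature=-1.0, n_steps=1000)
    with pytest.raises(ValueError, match="n_steps"):
        metropolis_sample(deds, 0.0, n_steps=100, n_burnin=100)


def test_flat_energy_sampler_is_uniform(deds):
    """With zero potential and zero force every dihedral marginal is uniform
    on [0, 360) (KS test at alpha = 0.01, n = 10000)."""
    flat = _zero_potential_deds(deds)
    ens = metropolis_sample(flat, 0.0, 300.0, n_steps=100_000, seed=2, thinning=10)
    assert ens.n_samples >= 9000
    for k in range(3):
        stat = stats.kstest(ens.dihedrals[:, k] / 360.0, "uniform")
        assert stat.pvalue > 0.01


def test_seed_determinism(deds):
    a = metropolis_sample(deds, 500.0, n_steps=50_000, seed=123)
    b = metropolis_sample(deds, 500.0, n_steps=50_000, seed=123)
    c = metropolis_sample(deds, 500.0, n_steps=50_000, seed=124)
    assert np.array_equal(a.dihedrals, b.dihedrals)
    assert np.array_equal(a.R, b.R)
    assert not np.array_equal(a.dihedrals, c.dihedrals)


def test_sample_count_contract(deds):
    ens = metropolis_sample(deds, 0.0, n_steps=50_000, n_burnin=10_000, thinning=7)
    assert ens.n_samples == (50_000 - 10_000) // 7


def test_two_state_occupancy_matches_boltzmann():
    """Detailed balance on a double-well torsion: MC occupancies of the two
    half-circles reproduce the exact Boltzmann ratio within 3 SE."""
    model = _single_torsion_model(v=(4.0, 0.0, 0.0))  # wells at 180 (deep) vs 0
    ens = metropolis_sample(model, 0.0, 300.0, n_steps=400_000, seed=9)
    q = quadrature_reference(model, 0.0, 300.0, 720)
    # exact probability of the half-circle [90, 270)
    centers = q.grid_centers
    mask = (centers >= 90.0) & (centers < 270.0)
    p_exact = q.marginals[0][mask].sum() * (360.0 / len(centers))
    flags = ((ens.dihedrals[:, 0] >= 90.0) & (ens.dihedrals[:, 0] < 270.0)).astype(float)
    from dscape.landscape import batch_means_se

    se = batch_means_se(flags)
    assert abs(flags.mean() - p_exact) < 3.0 * se


@pytest.mark.parametrize("force", [0.0, 2000.0])
def test_mc_agrees_with_quadrature(deds, force):
    """Mean R and closed/closed occupancy from Metropolis sampling agree with
    the exact quadrature oracle within 3 Monte-Carlo standard errors."""
    from dscape.landscape import batch_means_se, is_closed

    ens = metropolis_sample(deds, force, 300.0, n_steps=600_000, seed=31 + int(force))
    q = quadrature_reference(deds, force, 300.0, 90)
    se_r = batch_means_se(ens.R)
    assert abs(ens.R.mean() - q.mean_R) < 3.0 * se_r
    cc = (is_closed(ens.dihedrals[:, 0]) & is_closed(ens.dihedrals[:, 2])).astype(float)
    se_cc = batch_means_se(cc)
    assert abs(cc.mean() - q.p_closed_closed) < 3.0 * se_cc + 1e-4


def test_quadrature_band_measure_under_flat_density(deds):
    """Zero potential, zero force: P(closed/closed) is the squared closed-band
    measure (100/360)^2."""
    flat = _zero_potential_deds(deds)
    q = quadrature_reference(flat, 0.0, 300.0, 144)
    assert q.p_closed_closed == pytest.approx((100.0 / 360.0) ** 2, abs=1e-3)
    assert q.p_open_open == pytest.approx((260.0 / 360.0) ** 2, abs=1e-3)


def test_quadrature_large_force_concentrates_on_max_extension(deds):
    flat = _zero_potential_deds(deds)
    q = quadrature_reference(flat, 50_000.0, 300.0, 120)
    assert q.mean_R == pytest.approx(q.R_max, abs=0.05)


def test_quadrature_grid_convergence(deds):
    q1 = quadrature_reference(deds, 300.0, 300.0, 90)
    q2 = quadrature_reference(deds, 300.0, 300.0, 180)
    assert abs(q1.mean_R - q2.mean_R) < 1e-3


def test_quadrature_refuses_many_dihedrals(cystine):
    with pytest.raises(ValueError, match="<= 3 dihedrals"):
        quadrature_reference(cystine, 0.0)


def test_closed_closed_modal_at_300_pn(deds):
    """At 300 pN and 300 K the closed/closed conformer dominates the DEDS
    ensemble (it is the modal joint state)."""
    q = quadrature_reference(deds, 300.0, 300.0, 90)
    assert q.p_closed_closed > max(q.p_open_open, q.p_open_closed)
    assert q.p_closed_closed > 0.5


def test_deds_transposition_symmetry(deds_ensembles):
    """DEDS is symmetric under chi1 <-> chi2: circular moments of the two
    flanking dihedrals agree within 3 SE at every force."""
    from dscape.landscape import batch_means_se

    for ens in deds_ensembles.values():
        for f in (np.cos, np.sin):
            diff = f(np.radians(ens.dihedrals[:, 0])) - f(np.radians(ens.dihedrals[:, 2]))
            assert abs(diff.mean()) < 3.0 * batch_means_se(diff) + 5e-3
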