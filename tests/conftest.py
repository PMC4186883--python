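import numpy as np
import pytest

from dscape.models import builtin_model
from dscape.force_clamp import metropolis_sample
from dscape.synthetic import make_shipped_fixtures


@pytest.fixture(scope="session")
def deds():
    return builtin_model("DEDS")


@pytest.fixture(scope="session")
def cystine():
    return builtin_model("cystine")


@pytest.fixture(scope="session")
def polypeptide():
    return builtin_model("polypeptide-path")


@pytest.fixture(scope="session")
def fixtures_dir(tmp_path_factory):
    """The standard shipped fixture set (12 PDBs + 4 class tables + manifest)."""
    out = tmp_path_factory.mktemp("fixtures")
    manifest = make_shipped_fixtures(out, master_seed=1)
    return out, manifest


@pytest.fixture(scope="session")
def deds_ensembles(deds):
    """Shared DEDS ensembles at a small force ladder (500k steps each)."""
    return {
        f: metropolis_sample(deds, f, 300.0, n_steps=500_000, seed=11 + int(f))
        for f in (0.0, 300.0, 1000.0, 2000.0)
    }


def uniform_ensemble(n=10_000, seed=0, n_tor=3):
    """A synthetic ensemble with i.i.d. uniform dihedrals (helper, not a fixture)."""
    from dscape.force_clamp import ForceClampEnsemble

    rng = np.random.default_rng(seed)
    chi = rng.uniform(0.0, 360.0, size=(n, n_tor))
    return ForceClampEnsemble(
        model_name="uniform-test",
        force=0.0,
        temperature=300.0,
        seed=seed,
        n_steps=n,
        n_burnin=0,
        thinning=1,
        dihedrals=chi,
        R=np.ones(n),
        d_calpha=np.ones(n),
        energy=np.zeros(n),
        acceptance_rate=1.0,
        chi1_index=0,
        chi2_index=min(2, n_tor - 1),
        chi3_index=1 if n_tor > 2 else -1,
    )
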