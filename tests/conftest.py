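import numpy as np
import pytest

from qgclone import gfit, synth

TRAITS = ("AFR", "body_mass", "size_at_birth")


@pytest.fixture(scope="session")
def study_configs():
    """The three-population study design: 30/14/9 clonal families."""
    base_kwargs = dict(n_reps=5, mu=np.array([8.0, 300.0, 0.35]))
    G = np.array([[0.3, 0.05, 0.002], [0.05, 0.2, 0.003], [0.002, 0.003, 0.1]])
    E = np.diag([0.7, 0.8, 0.2])
    return [
        synth.PopulationSimConfig("Chile", n_clones=30, G_true=G, E_true=E,
                                  zones=("north", "central", "south"), **base_kwargs),
        synth.PopulationSimConfig("UK", n_clones=14, G_true=2 * G, E_true=E, **base_kwargs),
        synth.PopulationSimConfig("ME", n_clones=9, G_true=4 * G, E_true=E, **base_kwargs),
    ]


@pytest.fixture(scope="session")
def study_table(study_configs):
    return synth.simulate_study(study_configs, seed=20)


def wishart_posterior(G, n_samples=500, df=400, seed=0, population=""):
    """Synthetic 'posterior': Wishart draws centered on G with spread ~ 1/sqrt(df)."""
    rng = np.random.default_rng(seed)
    p = G.shape[0]
    L = np.linalg.cholesky(G + 1e-12 * np.eye(p))
    draws = np.empty((n_samples, p, p))
    for s in range(n_samples):
        Z = rng.standard_normal((df, p)) @ L.T
        draws[s] = Z.T @ Z / df
    return gfit.GPosterior.from_matrices(
        ["AFR", "body_mass", "size_at_birth"][:p], draws, population=population
    )


@pytest.fixture(scope="session")
def quick_posterior(study_table):
    """A real (short-chain) posterior for the Chile-like population."""
    settings = gfit.MCMCSettings(seed=3, burn_in=1500, sampling_iterations=1500,
                                 n_samples=150)
    return gfit.fit_clonal_model(study_table, traits=TRAITS, settings=settings,
                                 population="Chile")
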