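import numpy as np
import pandas as pd
import pytest

from qgclone import gfit, synth

TRAITS = ("AFR", "body_mass", "size_at_birth")


class TestSettings:
    def test_long_run_defaults(self):
        s = gfit.MCMCSettings()
        assert (s.burn_in, s.sampling_iterations, s.n_samples) == (500_000, 100_000, 1000)
        assert s.thin == 100

    def test_non_integral_thin_rejected(self):
        with pytest.raises(ValueError, match="thin"):
            gfit.MCMCSettings(sampling_iterations=1000, n_samples=301)

    def test_minimum_samples(self):
        with pytest.raises(ValueError):
            gfit.MCMCSettings(sampling_iterations=1000, n_samples=50)


class TestPosteriorMode:
    def test_constant(self):
        assert gfit.posterior_mode(np.full(200, 0.13)) == 0.13

    def test_standard_normal(self):
        x = np.random.default_rng(1).standard_normal(10_000)
        assert abs(gfit.posterior_mode(x)) < 0.1

    def test_lognormal_mode_below_median(self):
        x = np.exp(np.random.default_rng(2).standard_normal(10_000))
        assert gfit.posterior_mode(x) < np.median(x)


class TestHpdInterval:
    def test_uniform_width(self):
        x = np.random.default_rng(3).uniform(0, 1, 20_000)
        lo, hi = gfit.hpd_interval(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.02)

    def test_point_mass(self):
        lo, hi = gfit.hpd_interval(np.full(500, 2.0))
        assert lo == hi == 2.0

    def test_standard_normal(self):
        x = np.random.default_rng(4).standard_normal(10_000)
        lo, hi = gfit.hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.1)
        assert hi == pytest.approx(1.96, abs=0.1)

    def test_matches_arviz_on_skewed_sample(self):
        import arviz as az

        x = np.random.default_rng(5).gamma(2.0, size=5000)
        lo, hi = gfit.hpd_interval(x, 0.9)
        ref = az.hdi(x, hdi_prob=0.9)
        assert lo == pytest.approx(ref[0], abs=0.02)
        assert hi == pytest.approx(ref[1], abs=0.02)


class TestChainDiagnostics:
    @staticmethod
    def _as_posterior(x):
        n = len(x)
        G = np.zeros((n, 1, 1))
        G[:, 0, 0] = x
        return gfit.GPosterior.from_matrices(("t1",), G, np.ones((n, 1, 1)))

    def test_iid_ess_near_n(self):
        x = np.random.default_rng(6).standard_normal(1000)
        d = gfit.chain_diagnostics(self._as_posterior(x))
        assert d["ess"].iloc[0] == pytest.approx(1000, rel=0.2)

    def test_ar1_ess_collapses(self):
        rng = np.random.default_rng(7)
        rho, n = 0.9, 2000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + np.sqrt(1 - rho**2) * rng.standard_normal()
        d = gfit.chain_diagnostics(self._as_posterior(x))
        analytic = n * (1 - rho) / (1 + rho)  # ~105
        assert d["ess"].iloc[0] < n / 4
        assert d["ess"].iloc[0] == pytest.approx(analytic, rel=1.0)

    def test_constant_chain_flagged(self):
        d = gfit.chain_diagnostics(self._as_posterior(np.full(500, 1.0)))
        assert d["degenerate"].iloc[0]


def _simulate(G, E, n_clones, n_reps, seed, mu=(0.0, 0.0, 0.0)):
    cfg = synth.PopulationSimConfig(
        "sim", n_clones=n_clones, n_reps=n_reps, mu=np.asarray(mu),
        G_true=G, E_true=E,
    )
    return synth.simulate_clonal_population(cfg, seed=seed)


G_EXAMPLE = np.array([[0.5, 0.2, 0.0], [0.2, 0.5, 0.0], [0.0, 0.0, 0.3]])
E_EXAMPLE = np.eye(3) * 0.5


@pytest.fixture(scope="module")
def fitted():
    tab = _simulate(G_EXAMPLE, E_EXAMPLE, n_clones=100, n_reps=10, seed=8,
                    mu=(7.0, 300.0, 0.4))
    settings = gfit.MCMCSettings(seed=9, **gfit.PROFILES["test"])
    return tab, gfit.fit_clonal_model(tab, settings=settings)


class TestFitClonalModel:
    G = G_EXAMPLE
    E = E_EXAMPLE

    def test_recovers_moment_oracle(self, fitted):
        """Posterior means track the method-of-moments estimate of G from the
        same data (clone-mean covariance minus E_hat / n_reps)."""
        tab, post = fitted
        cols = list(TRAITS)
        fm = tab.groupby("clone_id")[cols].mean()
        resid = tab[cols] - tab.groupby("clone_id")[cols].transform("mean")
        n, r = 100, 10
        E_hat = resid.cov().to_numpy() * (n * r / (n * r - n))
        G_mom = fm.cov().to_numpy() - E_hat / r
        assert np.abs(post.G.mean(axis=0) - G_mom).max() < 0.06

    def test_recovers_truth(self, fitted):
        """Element-wise posterior modes land near the generating G."""
        _, post = fitted
        summ = gfit.summarize(post)
        assert np.abs(summ.G_mode - self.G).max() < 0.15

    def test_samples_symmetric_psd(self, fitted):
        _, post = fitted
        assert post.n_samples == 500
        assert np.allclose(post.G, np.swapaxes(post.G, 1, 2), atol=1e-8)
        for M in (post.G, post.E):
            assert np.linalg.eigvalsh(M).min() > -1e-8

    def test_posterior_concentrates_with_more_clones(self):
        """RMSE of the posterior-mode G shrinks from 25 to 200 clones."""
        errs = {}
        for n_clones in (25, 200):
            tab = _simulate(self.G, self.E, n_clones=n_clones, n_reps=5, seed=10)
            settings = gfit.MCMCSettings(seed=11, burn_in=2000,
                                         sampling_iterations=2000, n_samples=200)
            summ = gfit.summarize(gfit.fit_clonal_model(tab, settings=settings))
            errs[n_clones] = np.sqrt(np.mean((summ.G_mode - self.G) ** 2))
        assert errs[200] < errs[25]

    def test_trait_permutation_equivariance(self):
        tab = _simulate(self.G, self.E, n_clones=80, n_reps=6, seed=12)
        settings = gfit.MCMCSettings(seed=13, burn_in=2000,
                                     sampling_iterations=2000, n_samples=200)
        perm = [2, 0, 1]
        direct = gfit.summarize(gfit.fit_clonal_model(tab, settings=settings))
        permuted = gfit.summarize(
            gfit.fit_clonal_model(tab, traits=tuple(TRAITS[i] for i in perm),
                                  settings=settings)
        )
        assert np.abs(
            permuted.G_mode - direct.G_mode[np.ix_(perm, perm)]
        ).max() < 0.12

    def test_too_few_clones_rejected(self):
        tab = _simulate(self.G, self.E, n_clones=2, n_reps=3, seed=14)
        tab = tab[tab["clone_id"] == tab["clone_id"].iloc[0]]
        with pytest.raises(ValueError, match="clonal families"):
            gfit.fit_clonal_model(
                tab, settings=gfit.MCMCSettings(seed=0, burn_in=100,
                                                sampling_iterations=100, n_samples=100)
            )

    def test_zone_effect_runs(self, study_table):
        settings = gfit.MCMCSettings(seed=15, burn_in=1000,
                                     sampling_iterations=1000, n_samples=100)
        post = gfit.fit_clonal_model(study_table, settings=settings,
                                     population="Chile", zone_effect=True)
        assert post.n_samples == 100
        assert np.linalg.eigvalsh(post.G).min() > -1e-8


class TestSummarize:
    def test_equal_g_and_e_gives_half_heritability(self):
        G = np.broadcast_to(np.eye(3), (300, 3, 3)).copy()
        post = gfit.GPosterior.from_matrices(TRAITS, G, G.copy())
        summ = gfit.summarize(post)
        np.testing.assert_allclose(summ.H2, 0.5, atol=1e-9)

    def test_diagonal_g_gives_null_correlations(self):
        rng = np.random.default_rng(16)
        n = 400
        G = np.zeros((n, 3, 3))
        diag = rng.uniform(0.5, 1.5, (n, 3))
        G[:, np.arange(3), np.arange(3)] = diag
        # small symmetric off-diagonal noise around zero
        for a, b in ((0, 1), (0, 2), (1, 2)):
            off = rng.normal(0, 0.05, n)
            G[:, a, b] = G[:, b, a] = off
        post = gfit.GPosterior.from_matrices(TRAITS, G, np.broadcast_to(np.eye(3), (n, 3, 3)).copy())
        summ = gfit.summarize(post)
        off = summ.r_g[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.1
        for a, b in ((0, 1), (0, 2), (1, 2)):
            lo, hi = summ.r_g_hpd[a, b]
            assert lo < 0 < hi

    def test_report_cell_format(self):
        summ = gfit.GSummary(TRAITS, np.eye(3), np.zeros((3, 3, 2)), np.eye(3),
                             np.full(3, 0.14), np.zeros((3, 2)), np.eye(3),
                             np.zeros((3, 3, 2)))
        assert summ.format_cell(0.14, 0.05, 0.27) == "0.14 [0.05, 0.27]"


class TestSerialization:
    def test_round_trip(self, quick_posterior, tmp_path):
        quick_posterior.save(tmp_path / "post")
        back = gfit.GPosterior.load(tmp_path / "post")
        assert back.trait_names == quick_posterior.trait_names
        assert back.population == quick_posterior.population
        np.testing.assert_allclose(back.G, quick_posterior.G, rtol=1e-9)
        np.testing.assert_allclose(back.E, quick_posterior.E, rtol=1e-9)
        assert back.settings.seed == quick_posterior.settings.seed
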