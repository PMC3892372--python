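"""Bayesian estimation of broad-sense G-matrices from clonal replicate data.

Model, for trait vector y_ij of replicate j of clone i:

    y_ij = mu + g_i + e_ij,   g_i ~ MVN(0, G),   e_ij ~ MVN(0, E)

In a clonal design replicates within a family share the whole genome, so
the among-clone covariance G is the broad-sense genetic covariance matrix
and E the residual (environmental) covariance.  A Gibbs sampler with
inverse-Wishart full conditionals draws from the joint posterior; with
parameter expansion a redundant multiplicative working parameter (one
scale per trait, normal prior) is sampled alongside the underlying clone
covariance and folded into G each iteration, which greatly improves mixing
when variance components are near zero under weak priors.

Posterior point estimates are kernel-density modes and uncertainty is
reported as highest-posterior-density (HPD) intervals, the shortest
interval containing the requested posterior mass.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# settings and priors

@dataclass
class MCMCSettings:
    """Chain length bookkeeping.

    ``thin`` is derived: sampling_iterations / n_samples must be integral.
    Defaults follow the long-run profile (500k burn-in, 1000 stored samples
    from 100k further iterations); :data:`PROFILES` also ships a short
    profile for routine runs.
    """

    burn_in: int = 500_000
    sampling_iterations: int = 100_000
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_iterations % self.n_samples:
            raise ValueError(
                f"thin = {self.sampling_iterations}/{self.n_samples} is not integral"
            )
        if self.n_samples < 100:
            raise ValueError("need n_samples >= 100 for interval estimation")

    @property
    def thin(self) -> int:
        return self.sampling_iterations // self.n_samples


#: Named chain-length profiles: "paper" for final runs, "test" for routine runs.
PROFILES = {
    "paper": dict(burn_in=500_000, sampling_iterations=100_000, n_samples=1000),
    "test": dict(burn_in=5_000, sampling_iterations=5_000, n_samples=500),
}


@dataclass
class PriorSpec:
    """Inverse-Wishart priors on G and E, optionally parameter-expanded.

    Scale matrices default to 0.01 I with nu = p + 1 (weak); parameter
    expansion uses a N(0, 625 I) working-parameter prior (prior SD 25 on
    the per-trait scale), in the spirit of standard parameter-expanded
    variance-component priors.
    """

    V_g: np.ndarray
    V_e: np.ndarray
    nu_g: float
    nu_e: float
    parameter_expanded: bool = True
    alpha_mu: np.ndarray | None = None
    alpha_V: np.ndarray | None = None

    @classmethod
    def default(cls, p: int, parameter_expanded: bool = True) -> "PriorSpec":
        return cls(
            V_g=0.01 * np.eye(p),
            V_e=0.01 * np.eye(p),
            nu_g=p + 1,
            nu_e=p + 1,
            parameter_expanded=parameter_expanded,
            alpha_mu=np.zeros(p),
            alpha_V=625.0 * np.eye(p),
        )

    def validate(self, p: int) -> None:
        for name, V in (("V_g", self.V_g), ("V_e", self.V_e)):
            V = np.asarray(V, dtype=float)
            if V.shape != (p, p) or np.linalg.eigvalsh(V).min() < -1e-12:
                raise ValueError(f"{name} must be a {p}x{p} PSD matrix")
        if min(self.nu_g, self.nu_e) <= p - 1:
            raise ValueError("inverse-Wishart df must exceed p - 1")
        if self.parameter_expanded:
            if self.alpha_mu is None or self.alpha_V is None:
                raise ValueError("parameter expansion needs alpha_mu and alpha_V")


@dataclass
class GPosterior:
    """Ordered posterior samples of (G, E, mu) for one population."""

    trait_names: tuple[str, ...]
    G: np.ndarray  # (n_samples, p, p)
    E: np.ndarray  # (n_samples, p, p)
    mu: np.ndarray  # (n_samples, p)
    population: str = ""
    settings: MCMCSettings | None = None

    def __post_init__(self) -> None:
        self.trait_names = tuple(self.trait_names)
        if self.G.shape != self.E.shape or self.G.shape[0] != self.mu.shape[0]:
            raise ValueError("inconsistent posterior sample shapes")

    @property
    def n_samples(self) -> int:
        return self.G.shape[0]

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    # -- serialization: samples.csv + meta.json in a directory ------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        p = self.n_traits
        cols, data = [], []
        for a in range(p):
            for b in range(a, p):
                cols.append(f"g_{a + 1}{b + 1}")
                data.append(self.G[:, a, b])
        for a in range(p):
            for b in range(a, p):
                cols.append(f"e_{a + 1}{b + 1}")
                data.append(self.E[:, a, b])
        for a in range(p):
            cols.append(f"mu_{a + 1}")
            data.append(self.mu[:, a])
        pd.DataFrame(dict(zip(cols, data))).to_csv(directory / "samples.csv", index=False)
        meta = {
            "traits": list(self.trait_names),
            "population": self.population,
            "settings": None
            if self.settings is None
            else {
                "burn_in": self.settings.burn_in,
                "sampling_iterations": self.settings.sampling_iterations,
                "n_samples": self.settings.n_samples,
                "seed": self.settings.seed,
            },
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "GPosterior":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        df = pd.read_csv(directory / "samples.csv")
        traits = meta["traits"]
        p, n = len(traits), len(df)
        G = np.empty((n, p, p))
        E = np.empty((n, p, p))
        mu = np.empty((n, p))
        for a in range(p):
            for b in range(a, p):
                G[:, a, b] = G[:, b, a] = df[f"g_{a + 1}{b + 1}"]
                E[:, a, b] = E[:, b, a] = df[f"e_{a + 1}{b + 1}"]
            mu[:, a] = df[f"mu_{a + 1}"]
        settings = None
        if meta.get("settings"):
            settings = MCMCSettings(**meta["settings"])
        return cls(tuple(traits), G, E, mu, meta.get("population", ""), settings)

    @classmethod
    def from_matrices(
        cls,
        trait_names,
        G_samples,
        E_samples=None,
        mu_samples=None,
        population: str = "",
    ) -> "GPosterior":
        """Wrap externally constructed sample arrays (e.g. synthetic draws)."""
        G = np.asarray(G_samples, dtype=float)
        n, p, _ = G.shape
        E = np.asarray(E_samples, dtype=float) if E_samples is not None else np.zeros_like(G)
        mu = np.asarray(mu_samples, dtype=float) if mu_samples is not None else np.zeros((n, p))
        return cls(tuple(trait_names), G, E, mu, population)


@dataclass
class GSummary:
    """Posterior-mode summaries of a G posterior (Tables of the clonal analysis)."""

    trait_names: tuple[str, ...]
    G_mode: np.ndarray
    G_hpd: np.ndarray  # (p, p, 2)
    E_mode: np.ndarray
    H2: np.ndarray  # (p,)
    H2_hpd: np.ndarray  # (p, 2)
    r_g: np.ndarray  # (p, p), diagonal 1
    r_g_hpd: np.ndarray  # (p, p, 2)
    n_excluded: int = 0

    def format_cell(self, value: float, lo: float, hi: float) -> str:
        return f"{value:.2f} [{lo:.2f}, {hi:.2f}]"


# ---------------------------------------------------------------------------
# low-level samplers

_IW_IDX: dict[int, tuple] = {}


def _sample_invwishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """IW(df, scale) draw via Bartlett decomposition of the Wishart inverse."""
    p = scale.shape[0]
    if p not in _IW_IDX:
        _IW_IDX[p] = (np.diag_indices(p), np.tril_indices(p, -1), np.arange(p))
    dix, tix, ar = _IW_IDX[p]
    Ls = np.linalg.cholesky(scale)
    A = np.zeros((p, p))
    A[dix] = np.sqrt(rng.chisquare(df - ar))
    A[tix] = rng.standard_normal(p * (p - 1) // 2)
    # any square root B of inv(scale) gives W = (BA)(BA)' ~ Wishart(df, inv(scale))
    BA = np.linalg.inv(Ls).T @ A
    W = BA @ BA.T
    return np.linalg.inv(W)


def _chol_with_ridge(M: np.ndarray, label: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * max(np.trace(M) / M.shape[0], 1e-12)
        logger.warning("near-singular %s update; adding ridge %.2e", label, ridge)
        return np.linalg.cholesky(M + ridge * np.eye(M.shape[0]))


def _inv_pd(M: np.ndarray, label: str = "covariance") -> np.ndarray:
    L = _chol_with_ridge(M, label)
    Linv = np.linalg.inv(L)
    return Linv.T @ Linv


# ---------------------------------------------------------------------------
# the model fit

def fit_clonal_model(
    table: pd.DataFrame,
    traits=("AFR", "body_mass", "size_at_birth"),
    settings: MCMCSettings | None = None,
    prior: PriorSpec | None = None,
    zone_effect: bool = False,
    population: str | None = None,
) -> GPosterior:
    """Gibbs-sample the posterior of (G, E, mu) for one population.

    Parameters
    ----------
    table:
        Replicate-level records of a single population (or pass
        ``population`` to subset a combined table).
    traits:
        Ordered trait columns entering the multivariate model.
    settings, prior:
        Chain lengths and priors; defaults are the long-run profile and
        the weak parameter-expanded prior.
    zone_effect:
        Add a zero-mean per-trait random intercept for the ``zone``
        column (independent variances per trait).  Off by default.
    """
    settings = settings or MCMCSettings()
    if population is not None:
        table = table[table["population"] == population]
    elif table["population"].nunique() == 1:
        population = str(table["population"].iloc[0])
    else:
        raise ValueError("table spans several populations; pass population=")

    traits = tuple(traits)
    p = len(traits)
    sub = table.dropna(subset=list(traits))
    Y = sub.loc[:, list(traits)].to_numpy(dtype=float)
    clone_codes, clone_idx = np.unique(sub["clone_id"].to_numpy(), return_inverse=True)
    n_clones = len(clone_codes)
    if n_clones < 2:
        raise ValueError("need at least 2 clonal families")
    N = Y.shape[0]
    if n_clones < p:
        warnings.warn(
            f"only {n_clones} clones for {p} traits; posterior may be prior-dominated",
            RuntimeWarning,
        )

    prior = prior or PriorSpec.default(p)
    prior.validate(p)

    zone_idx = None
    n_zones = 0
    if zone_effect:
        if "zone" not in sub.columns or sub["zone"].isna().all():
            raise ValueError("zone_effect=True but no zone labels present")
        zone_codes, zone_idx = np.unique(sub["zone"].astype(str).to_numpy(), return_inverse=True)
        n_zones = len(zone_codes)
        if n_zones < 2:
            raise ValueError("zone_effect needs >= 2 zones")
        zone_counts = np.bincount(zone_idx, minlength=n_zones).astype(float)

    rng = np.random.default_rng(settings.seed)

    # sufficient statistics: per-clone sums and counts
    counts = np.bincount(clone_idx, minlength=n_clones).astype(float)
    S = np.zeros((n_clones, p))
    np.add.at(S, clone_idx, Y)
    y_total = Y.sum(axis=0)

    # grouping clones by replicate count lets the clone-effect update share
    # one conditional covariance per group (vectorized draw)
    count_groups = [
        (c, np.flatnonzero(counts == c)) for c in np.unique(counts)
    ]

    # initial values
    tot_var = np.var(Y, axis=0, ddof=1)
    tot_var[tot_var == 0] = 1e-6
    E = np.diag(tot_var / 2)
    V = np.diag(tot_var / 2)  # underlying clone covariance (G when not expanded)
    mu = Y.mean(axis=0)
    U = np.zeros((n_clones, p))
    alpha = np.ones(p)
    expanded = prior.parameter_expanded
    if expanded:
        alpha_mu = np.asarray(prior.alpha_mu, dtype=float)
        alpha_Vinv = _inv_pd(np.asarray(prior.alpha_V, dtype=float), "alpha prior")
    Z = np.zeros((n_zones, p)) if zone_effect else None
    s2_zone = np.full(p, tot_var.mean() / 10) if zone_effect else None

    V_g0 = np.asarray(prior.V_g, dtype=float)
    V_e0 = np.asarray(prior.V_e, dtype=float)

    n_store = settings.n_samples
    G_out = np.empty((n_store, p, p))
    E_out = np.empty((n_store, p, p))
    mu_out = np.empty((n_store, p))
    store_at = settings.burn_in + settings.thin * np.arange(1, n_store + 1)
    store_ptr = 0

    total_iter = settings.burn_in + settings.sampling_iterations
    D = np.diag(alpha)

    for it in range(1, total_iter + 1):
        Ei = _inv_pd(E, "E")
        Vi = _inv_pd(V, "G")

        # --- clone effects u_i | . ------------------------------------
        DEiD = (Ei * np.outer(alpha, alpha)) if expanded else Ei
        DEi = Ei * alpha[:, None] if expanded else Ei
        # residual totals per clone: S_i - n_i*mu - (zone sums)
        R = S - counts[:, None] * mu
        if zone_effect:
            zone_sum = np.zeros((n_clones, p))
            np.add.at(zone_sum, clone_idx, Z[zone_idx])
            R = R - zone_sum
        B = R @ DEi.T  # (n_clones, p): D Ei (S_i - n_i mu)
        for c, members in count_groups:
            prec = c * DEiD + Vi
            Lc = _chol_with_ridge(prec, "clone-effect precision")
            Lci = np.linalg.inv(Lc)
            cov = Lci.T @ Lci
            mean = B[members] @ cov.T
            U[members] = mean + rng.standard_normal((len(members), p)) @ Lci

        GU = U * alpha if expanded else U  # per-record genetic values D u_i

        # --- mu | . (flat prior) --------------------------------------
        resid_total = y_total - counts @ GU
        if zone_effect:
            resid_total = resid_total - zone_counts @ Z
        mu_mean = resid_total / N
        Le = _chol_with_ridge(E, "E")
        mu = mu_mean + (Le @ rng.standard_normal(p)) / np.sqrt(N)

        # --- zone effects and their variances -------------------------
        if zone_effect:
            Rz = np.zeros((n_zones, p))
            np.add.at(Rz, zone_idx, Y - mu - GU[clone_idx])
            for k in range(n_zones):
                prec = zone_counts[k] * Ei + np.diag(1.0 / s2_zone)
                Lk = _chol_with_ridge(prec, "zone precision")
                Lki = np.linalg.inv(Lk)
                cov = Lki.T @ Lki
                Z[k] = cov @ (Ei @ Rz[k]) + Lki.T @ rng.standard_normal(p)
            # conjugate IG update per trait (weak IG(0.501, 0.0005) prior)
            s2_zone = (0.001 + (Z**2).sum(axis=0)) / rng.chisquare(1.002 + n_zones, size=p)

        # --- working parameter alpha | . ------------------------------
        if expanded:
            UtU = (U.T * counts) @ U  # sum_i n_i u_i u_i^T
            A_prec = Ei * UtU + alpha_Vinv
            resid = S - counts[:, None] * mu
            if zone_effect:
                zone_sum = np.zeros((n_clones, p))
                np.add.at(zone_sum, clone_idx, Z[zone_idx])
                resid = resid - zone_sum
            b = (U * (resid @ Ei.T)).sum(axis=0) + alpha_Vinv @ alpha_mu
            La = _chol_with_ridge(A_prec, "alpha precision")
            Lai = np.linalg.inv(La)
            alpha = (Lai.T @ Lai) @ b + Lai.T @ rng.standard_normal(p)
            GU = U * alpha

        # --- covariance updates ---------------------------------------
        V = _sample_invwishart(rng, prior.nu_g + n_clones, V_g0 + U.T @ U)

        Eres = Y - mu - GU[clone_idx]
        if zone_effect:
            Eres = Eres - Z[zone_idx]
        E = _sample_invwishart(rng, prior.nu_e + N, V_e0 + Eres.T @ Eres)

        if store_ptr < n_store and it == store_at[store_ptr]:
            G_now = (V * np.outer(alpha, alpha)) if expanded else V
            G_out[store_ptr] = 0.5 * (G_now + G_now.T)
            E_out[store_ptr] = 0.5 * (E + E.T)
            mu_out[store_ptr] = mu
            store_ptr += 1

    return GPosterior(
        trait_names=traits,
        G=G_out,
        E=E_out,
        mu=mu_out,
        population=population or "",
        settings=settings,
    )


# ---------------------------------------------------------------------------
# posterior summaries

def posterior_mode(samples) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) on a 512-point grid."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2 or np.ptp(x) == 0:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ceil(prob * n) sorted samples."""
    if not 0 < prob < 1:
        raise ValueError("prob must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def _nearest_psd(M: np.ndarray) -> np.ndarray:
    w, Vm = np.linalg.eigh(M)
    if w.min() >= 0:
        return M
    logger.info("projecting summary matrix to nearest PSD (min eig %.2e)", w.min())
    w = np.clip(w, 0.0, None)
    return Vm @ np.diag(w) @ Vm.T


def summarize(post: GPosterior, prob: float = 0.95) -> GSummary:
    """Posterior modes + HPD intervals of G, heritabilities and genetic
    correlations.  H2 and r_g are computed per posterior sample (never as
    ratios of summary statistics) and then summarized."""
    p = post.n_traits
    G, E = post.G, post.E

    tot = np.einsum("naa->na", G) + np.einsum("naa->na", E)
    ok = (tot > 0).all(axis=1)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning("excluding %d samples with zero total variance", n_excluded)
    G, E, tot = G[ok], E[ok], tot[ok]

    gdiag = np.einsum("naa->na", G)
    H2_samp = gdiag / tot
    denom = np.sqrt(gdiag[:, :, None] * gdiag[:, None, :])
    rg_samp = G / denom

    G_mode = np.empty((p, p))
    G_hpd = np.empty((p, p, 2))
    E_mode = np.empty((p, p))
    rg_mode = np.eye(p)
    rg_hpd = np.zeros((p, p, 2))
    for a in range(p):
        for b in range(p):
            G_mode[a, b] = posterior_mode(G[:, a, b])
            G_hpd[a, b] = hpd_interval(G[:, a, b], prob)
            E_mode[a, b] = posterior_mode(E[:, a, b])
            if a != b:
                rg_mode[a, b] = posterior_mode(rg_samp[:, a, b])
                rg_hpd[a, b] = hpd_interval(rg_samp[:, a, b], prob)
            else:
                rg_hpd[a, b] = (1.0, 1.0)
    H2 = np.array([posterior_mode(H2_samp[:, t]) for t in range(p)])
    H2_hpd = np.array([hpd_interval(H2_samp[:, t], prob) for t in range(p)])

    return GSummary(
        trait_names=post.trait_names,
        G_mode=_nearest_psd(0.5 * (G_mode + G_mode.T)),
        G_hpd=G_hpd,
        E_mode=_nearest_psd(0.5 * (E_mode + E_mode.T)),
        H2=np.clip(H2, 0.0, 1.0),
        H2_hpd=np.clip(H2_hpd, 0.0, 1.0),
        r_g=np.clip(rg_mode, -1.0, 1.0),
        r_g_hpd=np.clip(rg_hpd, -1.0, 1.0),
        n_excluded=n_excluded,
    )


def chain_diagnostics(post: GPosterior) -> pd.DataFrame:
    """Effective sample size and lag-1 autocorrelation per G element."""
    import arviz as az

    rows = []
    p = post.n_traits
    for a in range(p):
        for b in range(a, p):
            x = post.G[:, a, b]
            if np.ptp(x) == 0:
                rows.append(
                    dict(element=f"g_{a + 1}{b + 1}", ess=np.nan, lag1=np.nan, degenerate=True)
                )
                logger.warning("constant chain for g_%d%d; ESS undefined", a + 1, b + 1)
                continue
            ess = float(az.ess(np.asarray(x)[None, :]))
            xc = x - x.mean()
            lag1 = float(np.dot(xc[:-1], xc[1:]) / np.dot(xc, xc))
            if ess < 100:
                logger.warning("low ESS %.0f for g_%d%d", ess, a + 1, b + 1)
            rows.append(
                dict(element=f"g_{a + 1}{b + 1}", ess=ess, lag1=lag1, degenerate=False)
            )
    return pd.DataFrame(rows)
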