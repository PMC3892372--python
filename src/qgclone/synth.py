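"""Synthetic clonal phenotype data with known genetic ground truth.

Emulates a common-garden clonal (parthenogenetic) breeding design: each
clonal family is one genotype, replicates within a family share the whole
genome, so the among-clone covariance of phenotypes is the broad-sense
genetic covariance matrix G and the within-clone covariance is the
residual (environmental) matrix E.  Three focal traits are simulated in a
fixed order: age at first reproduction (AFR, days), adult body mass
(micrograms) and mean offspring size at birth (mm, tibia length), plus an
offspring count used to derive the intrinsic rate of increase r_m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

TRAIT_NAMES = ("AFR", "body_mass", "size_at_birth")

#: CSV column order for clonal phenotype tables.
TABLE_COLUMNS = (
    "population",
    "zone",
    "clone_id",
    "replicate_id",
    "AFR",
    "ON",
    "body_mass",
    "size_at_birth",
    "r_m",
)


class CovarianceError(ValueError):
    """A supplied covariance matrix is not symmetric positive semi-definite."""


class DesignError(ValueError):
    """The simulated breeding design is degenerate (too few clones/replicates)."""


def _check_covariance(M: np.ndarray, name: str, p: int) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (p, p):
        raise CovarianceError(f"{name} must be {p}x{p}, got {M.shape}")
    if not np.allclose(M, M.T, atol=1e-10):
        raise CovarianceError(f"{name} is not symmetric within 1e-10")
    eigvals = np.linalg.eigvalsh(M)
    if eigvals.min() < -1e-10:
        raise CovarianceError(
            f"{name} has negative eigenvalue {eigvals.min():.3e}; not PSD"
        )
    return M


@dataclass
class PopulationSimConfig:
    """Ground-truth description of one simulated clonal population.

    Parameters
    ----------
    name:
        Population label (e.g. ``"Chile"``).
    n_clones:
        Number of clonal families (>= 2).
    n_reps:
        Replicates per clonal family (>= 1).
    mu:
        Trait means, ordered (AFR days, body mass ug, size at birth mm).
    G_true, E_true:
        Broad-sense genetic and residual covariance matrices (p x p,
        symmetric PSD) on the same trait order.
    on_mean:
        Mean offspring number; counts are drawn Poisson with this mean
        (values below 1 resampled so r_m is defined).
    zones:
        Optional zone labels; clones are assigned to zones round-robin.
    zone_shift:
        Optional per-zone additive shifts on the trait means, keyed by
        zone label (used to build clinal scenarios).
    """

    name: str
    n_clones: int
    n_reps: int
    mu: np.ndarray
    G_true: np.ndarray
    E_true: np.ndarray
    on_mean: float = 25.0
    zones: tuple[str, ...] = ()
    zone_shift: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        p = self.mu.shape[0]
        self.G_true = _check_covariance(self.G_true, "G_true", p)
        self.E_true = _check_covariance(self.E_true, "E_true", p)
        if self.n_clones < 2:
            raise DesignError("need at least 2 clonal families")
        if self.n_reps < 1:
            raise DesignError("need at least 1 replicate per clone")
        if self.on_mean <= 0:
            raise ValueError("on_mean must be positive")

    @property
    def n_traits(self) -> int:
        return self.mu.shape[0]


def _mvn(rng: np.random.Generator, cov: np.ndarray, n: int) -> np.ndarray:
    """Zero-mean MVN draws tolerating PSD (rank-deficient) covariance."""
    p = cov.shape[0]
    if not cov.any():
        return np.zeros((n, p))
    # eigh-based root: exact for PSD matrices incl. singular ones
    w, V = np.linalg.eigh(cov)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((n, p)) @ root.T


def population_rng(master_seed: int, pop_index: int) -> np.random.Generator:
    """One independent stream per population: adding populations later never
    perturbs the draws of earlier ones."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(pop_index)]))


def simulate_clonal_population(
    config: PopulationSimConfig,
    seed: int,
    pop_index: int = 0,
) -> pd.DataFrame:
    """Simulate replicate-level phenotypes for one clonal population.

    Clone effects g_i ~ MVN(0, G_true); replicate residuals e_ij ~
    MVN(0, E_true); phenotype y_ij = mu (+ zone shift) + g_i + e_ij.
    AFR is generated continuously, floored at 0.5 day, and reported at
    0.1-day resolution.  Offspring number is Poisson(on_mean) with zeros
    resampled; r_m = 0.74 ln(ON) / AFR.
    """
    rng = population_rng(seed, pop_index)
    n, r, p = config.n_clones, config.n_reps, config.n_traits

    g = _mvn(rng, config.G_true, n)
    e = _mvn(rng, config.E_true, n * r)
    clone_idx = np.repeat(np.arange(n), r)
    y = config.mu + g[clone_idx] + e

    zones: list[str | None]
    if config.zones:
        zone_of_clone = [config.zones[i % len(config.zones)] for i in range(n)]
        zones = [zone_of_clone[i] for i in clone_idx]
        shifts = np.array(
            [config.zone_shift.get(z, np.zeros(p)) for z in zones], dtype=float
        )
        y = y + shifts
    else:
        zones = [None] * (n * r)

    afr = np.round(np.maximum(y[:, 0], 0.5), 1)
    on = rng.poisson(config.on_mean, size=n * r)
    while (on < 1).any():  # resample so ln(ON) is defined
        bad = on < 1
        on[bad] = rng.poisson(config.on_mean, size=int(bad.sum()))

    table = pd.DataFrame(
        {
            "population": config.name,
            "zone": pd.array(zones, dtype="string"),
            "clone_id": [f"{config.name}_c{i + 1:03d}" for i in clone_idx],
            "replicate_id": [f"r{j + 1}" for _ in range(n) for j in range(r)],
            "AFR": afr,
            "ON": on,
            "body_mass": y[:, 1],
            "size_at_birth": y[:, 2],
        }
    )
    table["r_m"] = 0.74 * np.log(table["ON"].to_numpy(float)) / table["AFR"].to_numpy(float)
    return table


def simulate_study(
    configs: list[PopulationSimConfig], seed: int
) -> pd.DataFrame:
    """Simulate several populations into one combined long-format table."""
    parts = [
        simulate_clonal_population(cfg, seed, pop_index=k)
        for k, cfg in enumerate(configs)
    ]
    return pd.concat(parts, ignore_index=True)


def simulate_fitness_surface(
    table: pd.DataFrame,
    beta: np.ndarray,
    gamma: np.ndarray,
    noise_sd: float,
    seed: int,
    scale: float = 0.3,
) -> pd.DataFrame:
    """Overwrite r_m with a fitness surface of known selection gradients.

    Relative fitness w = 1 + beta'z + z'gamma z / 2 + eps with z the
    within-population standardized (body mass, size at birth) and
    eps ~ N(0, noise_sd^2); r_m is set to w * scale.  The true gradients
    are recorded in ``result.attrs["true_gradients"]``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if beta.shape != (2,) or gamma.shape != (2, 2):
        raise ValueError("beta must be length-2 and gamma 2x2 (BM, SB)")
    if not np.allclose(gamma, gamma.T):
        raise ValueError("gamma must be symmetric")

    rng = np.random.default_rng(seed)
    out = table.copy()
    z = np.empty((len(out), 2))
    for col, j in (("body_mass", 0), ("size_at_birth", 1)):
        grouped = out.groupby("population")[col]
        z[:, j] = ((out[col] - grouped.transform("mean")) / grouped.transform("std")).to_numpy()
    raw = z @ beta + 0.5 * np.einsum("ni,ij,nj->n", z, gamma, z)
    raw = raw + rng.normal(0.0, noise_sd, size=len(out))
    # recenter so mean(w) = 1 exactly: relative fitness then carries the
    # requested gradients without rescaling by the (quadratic-shifted) mean
    w = 1.0 + raw - raw.mean()
    out["r_m"] = w * scale
    out.attrs["true_gradients"] = {"beta": beta.copy(), "gamma": gamma.copy(), "scale": scale}
    return out


def make_g_family(
    base_G: np.ndarray,
    scenario: str,
    m: int,
    magnitude: float,
    trait: int = 2,
) -> list[np.ndarray]:
    """Families of G-matrices that vary along a gradient in a known way.

    ``scale``        G_k = base_G * (1 + k * magnitude)
    ``single_trait`` only the (trait, trait) variance changes, by
                     k * magnitude per step
    ``rotate``       the eigenbasis is rotated by k * magnitude degrees in
                     the plane of the two leading eigenvectors

    All outputs are symmetric PSD; k runs 0 .. m-1.
    """
    if m < 2:
        raise DesignError("a gradient needs at least 2 matrices")
    G0 = _check_covariance(base_G, "base_G", np.asarray(base_G).shape[0])
    if scenario == "scale":
        fam = [G0 * (1.0 + k * magnitude) for k in range(m)]
    elif scenario == "single_trait":
        fam = []
        for k in range(m):
            Gk = G0.copy()
            Gk[trait, trait] = G0[trait, trait] + k * magnitude
            fam.append(Gk)
    elif scenario == "rotate":
        w, V = np.linalg.eigh(G0)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        fam = []
        for k in range(m):
            theta = np.deg2rad(k * magnitude)
            R = np.eye(G0.shape[0])
            # rotation in the plane spanned by the two leading eigenvectors
            c, s = np.cos(theta), np.sin(theta)
            R2 = np.array([[c, -s], [s, c]])
            Vk = V.copy()
            Vk[:, :2] = V[:, :2] @ R2.T
            fam.append(Vk @ np.diag(w) @ Vk.T)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    for Gk in fam:
        if np.linalg.eigvalsh(Gk).min() < -1e-10:
            raise CovarianceError("constructed family member is not PSD")
    return fam


# ---------------------------------------------------------------------------
# config-file plumbing

def write_table(table: pd.DataFrame, path) -> None:
    """Write a clonal phenotype table as CSV (missing values empty)."""
    table.loc[:, list(TABLE_COLUMNS)].to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"population": str, "clone_id": str, "replicate_id": str})
    if "zone" in table.columns:
        table["zone"] = table["zone"].astype("string")
    return table


def configs_from_yaml(path_or_dict) -> list[PopulationSimConfig]:
    """Read per-population simulation configs from a nested YAML mapping."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh)
    pops = raw["populations"] if "populations" in raw else raw
    configs = []
    for name, block in pops.items():
        configs.append(
            PopulationSimConfig(
                name=name,
                n_clones=int(block["n_clones"]),
                n_reps=int(block["n_reps"]),
                mu=np.asarray(block["mu"], dtype=float),
                G_true=np.asarray(block["G_true"], dtype=float),
                E_true=np.asarray(block["E_true"], dtype=float),
                on_mean=float(block.get("on_mean", 25.0)),
                zones=tuple(block.get("zones", ())),
                zone_shift={
                    k: np.asarray(v, dtype=float)
                    for k, v in block.get("zone_shift", {}).items()
                },
            )
        )
    return configs
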