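"""Phenotypic-mean contrasts among regions and Lande-Arnold selection analysis.

Mean contrasts: a one-way linear model on clonal family means with all
pairwise Tukey contrasts (studentized-range / Tukey-Kramer adjustment),
reported as differences in standard deviations when traits are z-scored.

Selection: linear (beta) and quadratic/correlational (gamma) selection
gradients of relative fitness on standardized body mass and size at birth,
chosen by forward stepwise regression with partial F-tests.  Quadratic
gradients are reported as twice the fitted quadratic coefficient (the
standard correction so gamma matches the curvature of the fitness surface).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# family-mean contrasts

@dataclass
class MeansContrast:
    pair: tuple[str, str]
    difference: float  # A - B, in SD units when traits are standardized
    se: float
    t: float
    df: int
    p_adjusted: float


def compare_region_means(
    family_means: pd.DataFrame,
    trait: str,
    groups: str = "population",
) -> tuple[float, float, list[MeansContrast]]:
    """One-way linear model on family means with Tukey pairwise contrasts.

    Returns (overall F, overall p, contrasts).  Residual df is
    n_families - n_groups; adjusted p-values use the studentized-range
    distribution with the Tukey-Kramer allowance for unequal group sizes.
    """
    df = family_means.dropna(subset=[trait, groups])
    levels = sorted(df[groups].unique())
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = df.groupby(groups)[trait].size()
    if (sizes < 2).any():
        raise ValueError("need at least 2 families per group")
    n = len(df)
    dof = n - k

    means = df.groupby(groups)[trait].mean()
    sse = float(
        ((df[trait] - df[groups].map(means)) ** 2).sum()
    )
    if sse <= 0:
        raise ValueError("singular design: zero residual variance")
    mse = sse / dof
    grand = df[trait].mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    F = (ssb / (k - 1)) / mse
    p_overall = float(stats.f.sf(F, k - 1, dof))

    contrasts = []
    for a, b in itertools.combinations(levels, 2):
        diff = means[a] - means[b]
        se = float(np.sqrt(mse * (1.0 / sizes[a] + 1.0 / sizes[b])))
        t = diff / se
        # single-step adjustment: |t|*sqrt(2) referred to the studentized range
        p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, dof))
        contrasts.append(
            MeansContrast((a, b), float(diff), se, float(t), dof, min(p_adj, 1.0))
        )
    return float(F), p_overall, contrasts


def zone_cline_test(
    family_means: pd.DataFrame,
    traits=("AFR", "r_m", "body_mass", "size_at_birth"),
    zone_col: str = "zone",
) -> pd.DataFrame:
    """Per-trait one-way F test of family means across geographic zones.

    df = (n_zones - 1, n_families - n_zones); used to probe for a cline
    within one population's sampling transect.
    """
    df = family_means.dropna(subset=[zone_col])
    zones = df[zone_col].unique()
    if len(zones) < 2:
        raise ValueError("need at least 2 zones")
    rows = []
    for trait in traits:
        if trait not in df.columns:
            continue
        groups = [g[trait].dropna().to_numpy() for _, g in df.groupby(zone_col)]
        n = sum(len(g) for g in groups)
        df1, df2 = len(groups) - 1, n - len(groups)
        sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
        if sse <= 0:
            logger.warning("degenerate zone test for %s: zero residual variance", trait)
            rows.append(dict(trait=trait, F=np.inf, df1=df1, df2=df2, p=0.0, degenerate=True))
            continue
        F, p = stats.f_oneway(*groups)
        rows.append(dict(trait=trait, F=float(F), df1=df1, df2=df2, p=float(p), degenerate=False))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# selection gradients

def relative_fitness(r_m) -> np.ndarray:
    """Relative fitness w_i = r_m,i / mean(r_m); mean(w) = 1 by construction."""
    r = np.asarray(r_m, dtype=float)
    mean = r.mean()
    if mean <= 0:
        raise ValueError("mean fitness must be positive to form relative fitness")
    return r / mean


@dataclass
class SelectionTerm:
    name: str  # beta_BM, beta_SB, gamma_BM, gamma_SB, gamma_BMxSB
    estimate: float  # gamma terms already doubled
    se: float
    F: float
    df: tuple[int, int]
    p: float


@dataclass
class SelectionFit:
    population: str
    terms: list[SelectionTerm] = field(default_factory=list)
    alpha: float = 0.05
    n: int = 0

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    population=self.population,
                    term=t.name,
                    estimate=t.estimate,
                    se=t.se,
                    F=t.F,
                    df1=t.df[0],
                    df2=t.df[1],
                    p=t.p,
                )
                for t in self.terms
            ]
        )


_CANDIDATES = {
    "beta_BM": ("bm",),
    "beta_SB": ("sb",),
    "gamma_BM": ("bm2",),
    "gamma_SB": ("sb2",),
    "gamma_BMxSB": ("bmsb",),
}
_PARENTS = {
    "gamma_BM": {"beta_BM"},
    "gamma_SB": {"beta_SB"},
    "gamma_BMxSB": {"beta_BM", "beta_SB"},
}


def _ols(X: np.ndarray, y: np.ndarray):
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def selection_gradients_stepwise(
    table: pd.DataFrame,
    population: str | None = None,
    alpha: float = 0.05,
    fitness_col: str = "r_m",
    family_level: bool = False,
) -> SelectionFit:
    """Forward-stepwise Lande-Arnold selection gradients on (BM, SB).

    Candidate terms are the two linear gradients first; each quadratic or
    correlational term becomes eligible only once its linear parent(s) are
    in the model.  At each step the candidate with the largest partial F
    enters if its p-value is below ``alpha``.  Quadratic/correlational
    coefficients are reported as gamma = 2 x the regression coefficient.
    Traits are standardized and fitness made relative within the table
    passed in (pass one population, or use ``population=`` to subset).
    """
    if population is not None:
        table = table[table["population"] == population]
    else:
        pops = table["population"].unique()
        if len(pops) != 1:
            raise ValueError("table spans several populations; pass population=")
        population = str(pops[0])
    if family_level:
        from .traits import family_means

        table = family_means(table)
    table = table.dropna(subset=["body_mass", "size_at_birth", fitness_col])
    n = len(table)
    if n < 10:
        raise ValueError("need at least 10 records for selection analysis")

    w = relative_fitness(table[fitness_col].to_numpy(float))
    bm = table["body_mass"].to_numpy(float)
    sb = table["size_at_birth"].to_numpy(float)
    for name, x in (("body_mass", bm), ("size_at_birth", sb)):
        if np.std(x, ddof=1) == 0:
            raise ValueError(f"degenerate variance in {name}")
    bm = (bm - bm.mean()) / bm.std(ddof=1)
    sb = (sb - sb.mean()) / sb.std(ddof=1)

    columns = {
        "bm": bm,
        "sb": sb,
        "bm2": bm**2,
        "sb2": sb**2,
        "bmsb": bm * sb,
    }

    selected: list[str] = []
    fit = SelectionFit(population=population, alpha=alpha, n=n)

    def design(terms):
        cols = [np.ones(n)]
        for t in terms:
            cols.extend(columns[c] for c in _CANDIDATES[t])
        return np.column_stack(cols)

    _, rss_current = _ols(design(selected), w)
    linear_phase = True
    while True:
        if linear_phase:
            # linear gradients are offered first, one at a time
            steps = [[t] for t in ("beta_BM", "beta_SB") if t not in selected]
            if not steps:
                linear_phase = False
        if not linear_phase:
            # quadratic/correlational terms become candidates only once
            # their linear parent(s) are in the model (marginality); linear
            # terms stay on offer in case they turn significant later
            steps = [[t] for t in ("beta_BM", "beta_SB") if t not in selected]
            steps += [
                [t]
                for t in ("gamma_BM", "gamma_SB", "gamma_BMxSB")
                if t not in selected and _PARENTS[t] <= set(selected)
            ]
        best = None
        for step in steps:
            X1 = design(selected + step)
            k1 = X1.shape[1]
            _, rss1 = _ols(X1, w)
            df1, df2 = len(step), n - k1
            if df2 <= 0 or rss1 <= 0:
                continue
            F = ((rss_current - rss1) / df1) / (rss1 / df2)
            p = float(stats.f.sf(F, df1, df2))
            if best is None or p < best[2]:
                best = (step, F, p, rss1, (df1, df2))
        if best is None or best[2] >= alpha:
            if linear_phase:
                linear_phase = False
                continue
            break
        step, F, p, rss1, dfs = best
        selected.extend(step)
        rss_current = rss1

        # refit and record the entering term(s) with the step's F statistic
        X = design(selected)
        coef, rss = _ols(X, w)
        cov = rss / (n - X.shape[1]) * np.linalg.inv(X.T @ X)
        for t in step:
            j = 1 + sum(len(_CANDIDATES[s]) for s in selected[: selected.index(t)])
            scale = 2.0 if t in ("gamma_BM", "gamma_SB") else 1.0
            # the cross-product coefficient IS the correlational gradient;
            # pure quadratic coefficients are doubled
            fit.terms.append(
                SelectionTerm(
                    name=t,
                    estimate=float(coef[j] * scale),
                    se=float(np.sqrt(cov[j, j]) * scale),
                    F=float(F),
                    df=dfs,
                    p=p,
                )
            )

    # refresh estimates/SEs from the final model (entry F statistics kept)
    if selected:
        X = design(selected)
        coef, rss = _ols(X, w)
        cov = rss / (n - X.shape[1]) * np.linalg.inv(X.T @ X)
        for i, t in enumerate(selected):
            j = i + 1
            scale = 2.0 if t.startswith("gamma") and t != "gamma_BMxSB" else 1.0
            fit.terms[i].estimate = float(coef[j] * scale)
            fit.terms[i].se = float(np.sqrt(cov[j, j]) * scale)
    return fit
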