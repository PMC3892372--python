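"""Pairwise comparison of G-matrix posteriors.

Four derived statistics, each computed per posterior draw so that point
estimates (KDE modes) carry 95% HPD intervals:

* **Ovaskainen's D** — a [0, 1] measure of how distinguishable the two
  posterior distributions of G are.  Operationally: the probability P
  that a between-posterior Frobenius distance exceeds a within-posterior
  distance, mapped to D = 2 max(0, P - 1/2).  Identical distributions
  give P ~ 1/2 (D ~ 0); disjoint ones give P ~ 1 (D ~ 1).
* **Δ variance of Gmax** — difference (A - B) in the leading eigenvalue.
* **Krzanowski angle** — angle in [0°, 90°] between the leading
  eigenvectors (Gmax, the genetic line of least resistance).
* **Δ total variance (sum-volume)** — difference (A - B) in trace(G).

Significance for the Δ metrics is "95% HPD excludes 0"; the angle (which
cannot reach 0 by construction) and D are referred to permutation nulls
built by reshuffling the pooled posterior draws.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gfit import GPosterior, hpd_interval, posterior_mode

logger = logging.getLogger(__name__)


@dataclass
class MetricResult:
    estimate: float
    hpd: tuple[float, float]
    significant: bool


@dataclass
class PairwiseGComparison:
    """The four comparison metrics for one population pair (A, B)."""

    pair: tuple[str, str]
    D: MetricResult
    delta_var_gmax: MetricResult
    angle_gmax: MetricResult
    delta_total_variance: MetricResult

    def to_dict(self) -> dict:
        out = {"pair": list(self.pair)}
        for key in ("D", "delta_var_gmax", "angle_gmax", "delta_total_variance"):
            m: MetricResult = getattr(self, key)
            out[key] = {
                "estimate": m.estimate,
                "hpd": list(m.hpd),
                "significant": bool(m.significant),
            }
        return out

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


# ---------------------------------------------------------------------------

def gmax(G: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading eigenvector (unit norm, largest-|component| positive) and
    eigenvalue of a symmetric matrix.  Ties within 1e-12 are broken toward
    the lowest trait index with a warning."""
    G = np.asarray(G, dtype=float)
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("gmax needs a symmetric matrix")
    w, V = np.linalg.eigh(G)
    lead = w[-1]
    tied = np.flatnonzero(w >= lead - 1e-12)
    if len(tied) > 1:
        warnings.warn("tied leading eigenvalues; Gmax direction is degenerate", RuntimeWarning)
        # deterministic tie-break: among tied eigenvectors pick the one whose
        # largest-loading trait index is lowest
        cand = V[:, tied]
        idx = np.argmax(np.abs(cand), axis=0)
        pick = tied[np.argmin(idx)]
        v = V[:, pick]
    else:
        v = V[:, -1]
    j = np.argmax(np.abs(v))
    if v[j] < 0:
        v = -v
    return v, float(lead)


def _gmax_batch(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized gmax over a stack (n, p, p) -> unit vectors (n, p), eigenvalues (n,)."""
    w, V = np.linalg.eigh(G)
    vecs = V[..., -1]
    j = np.argmax(np.abs(vecs), axis=1)
    sign = np.sign(vecs[np.arange(len(vecs)), j])
    sign[sign == 0] = 1.0
    return vecs * sign[:, None], w[..., -1]


def _as_matrix_stack(x) -> np.ndarray:
    if isinstance(x, GPosterior):
        return x.G
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def _check_traits(A, B) -> None:
    if isinstance(A, GPosterior) and isinstance(B, GPosterior):
        if A.trait_names != B.trait_names:
            raise ValueError(
                f"trait mismatch: {A.trait_names} vs {B.trait_names}"
            )


def _pair_draws(A, B) -> tuple[np.ndarray, np.ndarray]:
    GA, GB = _as_matrix_stack(A), _as_matrix_stack(B)
    if GA.shape[0] != GB.shape[0]:
        n = min(GA.shape[0], GB.shape[0])
        warnings.warn(
            f"unequal sample counts ({GA.shape[0]} vs {GB.shape[0]}); truncating to {n}",
            RuntimeWarning,
        )
        GA, GB = GA[:n], GB[:n]
    return GA, GB


def krzanowski_angle(A, B, summary: bool = False):
    """Angle (degrees, in [0, 90]) between the Gmax axes of A and B.

    Matrix inputs give a scalar; posterior inputs give the per-draw-pair
    angle sequence (or its mode + HPD when ``summary=True``)."""
    _check_traits(A, B)
    GA, GB = _pair_draws(A, B)
    vA, _ = _gmax_batch(GA)
    vB, _ = _gmax_batch(GB)
    cosang = np.abs(np.einsum("np,np->n", vA, vB))
    theta = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
    if GA.shape[0] == 1:
        return float(theta[0])
    if summary:
        return posterior_mode(theta), hpd_interval(theta)
    return theta


def delta_var_gmax(A: GPosterior, B: GPosterior) -> np.ndarray:
    """Per-draw difference lambda1(A) - lambda1(B), paired by sample index."""
    _check_traits(A, B)
    GA, GB = _pair_draws(A, B)
    _, lA = _gmax_batch(GA)
    _, lB = _gmax_batch(GB)
    return lA - lB


def delta_total_variance(A: GPosterior, B: GPosterior) -> np.ndarray:
    """Per-draw difference trace(G_A) - trace(G_B) (sum-volume difference)."""
    _check_traits(A, B)
    GA, GB = _pair_draws(A, B)
    return np.einsum("naa->n", GA) - np.einsum("naa->n", GB)


def ovaskainen_d(
    A: GPosterior,
    B: GPosterior,
    n_pairs: int = 10_000,
    seed: int = 0,
    n_boot: int = 200,
) -> tuple[float, tuple[float, float]]:
    """Probabilistic distance D in [0, 1] between two G posteriors.

    D = 2 max(0, P - 1/2) where P is the probability that the Frobenius
    distance between one draw from A and one from B exceeds the distance
    between two distinct draws from one (randomly chosen) posterior.
    The interval is a bootstrap percentile interval over the draw pairs.
    """
    GA, GB = _as_matrix_stack(A), _as_matrix_stack(B)
    if min(GA.shape[0], GB.shape[0]) < 2:
        raise ValueError("need at least 2 posterior samples per side")
    rng = np.random.default_rng(seed)
    nA, nB = GA.shape[0], GB.shape[0]

    iA = rng.integers(nA, size=n_pairs)
    iB = rng.integers(nB, size=n_pairs)
    between = np.linalg.norm(
        (GA[iA] - GB[iB]).reshape(n_pairs, -1), axis=1
    )

    which = rng.integers(2, size=n_pairs).astype(bool)
    within = np.empty(n_pairs)
    for flag, Gs, n in ((True, GA, nA), (False, GB, nB)):
        m = which == flag
        k = int(m.sum())
        i1 = rng.integers(n, size=k)
        shift = rng.integers(1, n, size=k)
        i2 = (i1 + shift) % n  # distinct indices
        within[m] = np.linalg.norm((Gs[i1] - Gs[i2]).reshape(k, -1), axis=1)

    wins = (between > within).astype(float)
    ties = between == within
    wins[ties] = 0.5
    P = wins.mean()
    D = 2.0 * max(0.0, P - 0.5)

    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(n_pairs, size=n_pairs)
        boot[b] = 2.0 * max(0.0, wins[idx].mean() - 0.5)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return float(D), (float(lo), float(hi))


def _angle_null(GA: np.ndarray, GB: np.ndarray, rng: np.random.Generator,
                n_perm: int = 500) -> np.ndarray:
    """Null distribution of the angle mode under exchangeable posteriors:
    pooled draws are randomly reassigned to two groups of the original sizes."""
    pooled = np.concatenate([GA, GB])
    vecs, _ = _gmax_batch(pooled)
    nA = GA.shape[0]
    n = pooled.shape[0]
    nulls = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        va, vb = vecs[perm[:nA]], vecs[perm[nA:]]
        m = min(len(va), len(vb))
        cosang = np.abs(np.einsum("np,np->n", va[:m], vb[:m]))
        theta = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
        nulls[k] = np.median(theta)
    return nulls


def compare_pair(
    A: GPosterior,
    B: GPosterior,
    seed: int = 0,
    n_perm: int = 500,
    n_pairs: int = 10_000,
) -> PairwiseGComparison:
    """Assemble all four metrics with intervals and significance flags.

    Δ metrics are significant when the 95% HPD excludes 0.  The angle is
    significant when its posterior median exceeds the 95th percentile of a
    permutation null (pooled draws reshuffled); D likewise against its own
    permutation null.
    """
    _check_traits(A, B)
    rng = np.random.default_rng(seed)

    dvg = delta_var_gmax(A, B)
    dvg_hpd = hpd_interval(dvg)
    dtv = delta_total_variance(A, B)
    dtv_hpd = hpd_interval(dtv)

    ang = krzanowski_angle(A, B)
    ang_mode = posterior_mode(ang)
    ang_hpd = hpd_interval(ang)
    GA, GB = _pair_draws(A, B)
    ang_null = _angle_null(GA, GB, rng, n_perm)
    ang_sig = float(np.median(ang)) > float(np.percentile(ang_null, 95))

    D, D_int = ovaskainen_d(A, B, n_pairs=n_pairs, seed=int(rng.integers(2**31)))
    # permutation null for D: split the pooled draws at random
    pooled = np.concatenate([GA, GB])
    nulls = np.empty(100)
    for k in range(100):
        perm = rng.permutation(pooled.shape[0])
        half = pooled.shape[0] // 2
        PA = GPosterior.from_matrices(A.trait_names, pooled[perm[:half]])
        PB = GPosterior.from_matrices(A.trait_names, pooled[perm[half:]])
        nulls[k], _ = ovaskainen_d(PA, PB, n_pairs=2000, seed=int(rng.integers(2**31)))
    D_sig = D > float(np.percentile(nulls, 95))

    pops = (A.population or "A", B.population or "B")
    return PairwiseGComparison(
        pair=pops,
        D=MetricResult(D, D_int, D_sig),
        delta_var_gmax=MetricResult(
            posterior_mode(dvg), dvg_hpd, not (dvg_hpd[0] <= 0.0 <= dvg_hpd[1])
        ),
        angle_gmax=MetricResult(ang_mode, ang_hpd, ang_sig),
        delta_total_variance=MetricResult(
            posterior_mode(dtv), dtv_hpd, not (dtv_hpd[0] <= 0.0 <= dtv_hpd[1])
        ),
    )


def draws_frame(A: GPosterior, B: GPosterior) -> pd.DataFrame:
    """Flat per-draw metric values (for CSV export alongside the JSON report)."""
    return pd.DataFrame(
        {
            "angle_gmax": krzanowski_angle(A, B),
            "delta_var_gmax": delta_var_gmax(A, B),
            "delta_total_variance": delta_total_variance(A, B),
        }
    )
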