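"""Genetic covariance tensor analysis across an ordered population gradient.

A set of m G-matrices (p traits each) is embedded in the q = p(p+1)/2
dimensional space of symmetric matrices with a Frobenius-preserving
vectorization (off-diagonals scaled by sqrt(2)).  The sample covariance S
of the m embedded matrices is the matrix representation of the 4th-order
genetic covariance tensor; its eigenvectors, devectorized back into
symmetric matrices, are the *eigentensors* — independent axes along which
the G-matrices differ across the gradient — and its eigenvalues give the
proportion of among-population variance in G each axis explains (at most
m - 1 are nonzero).  The leading eigenvector of the first eigentensor is
the trait combination whose genetic variance changes most along the
gradient; projecting each population's G onto it gives per-site variances.

With posterior inputs the whole decomposition is repeated on every joint
posterior draw and summarized by KDE modes and 95% HPD intervals, with
eigentensor identity tracked across draws by maximal Frobenius overlap
with the decomposition of the posterior-mode matrices.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gfit import GPosterior, hpd_interval, posterior_mode

logger = logging.getLogger(__name__)


def vectorize_g(G: np.ndarray) -> np.ndarray:
    """Frobenius-preserving half-vectorization of a symmetric matrix."""
    G = np.asarray(G, dtype=float)
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("matrix is not symmetric within 1e-8")
    p = G.shape[0]
    iu = np.triu_indices(p)
    scale = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    return G[iu] * scale


def devectorize_g(v: np.ndarray, p: int) -> np.ndarray:
    """Inverse of :func:`vectorize_g`."""
    iu = np.triu_indices(p)
    scale = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    M = np.zeros((p, p))
    M[iu] = np.asarray(v, dtype=float) / scale
    return M + np.triu(M, 1).T


def build_s_tensor(Gs) -> np.ndarray:
    """Sample covariance (denominator m - 1) of the m vectorized G-matrices."""
    Gs = list(Gs)
    if len(Gs) < 2:
        raise ValueError("a gradient needs at least 2 G-matrices")
    V = np.stack([vectorize_g(G) for G in Gs])
    return np.cov(V.T, ddof=1)


def eigentensors(S: np.ndarray, p: int | None = None):
    """Eigen-decompose the tensor representation S.

    Returns ``(proportions, tensors)``: eigenvalue proportions (descending,
    clipped at 0) and the corresponding eigentensors as symmetric p x p
    matrices, orthonormal under the Frobenius inner product.
    """
    S = np.asarray(S, dtype=float)
    q = S.shape[0]
    if p is None:
        p = int(round((np.sqrt(8 * q + 1) - 1) / 2))
    w, V = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w, V = np.clip(w[order], 0.0, None), V[:, order]
    total = w.sum()
    if total <= 0:
        logger.warning("all-zero S tensor: no variation among G-matrices")
        return np.zeros(0), []
    props = w / total
    tensors = [devectorize_g(V[:, k], p) for k in range(q)]
    return props, tensors


def tensor_coordinates(G_j: np.ndarray, E_k: np.ndarray, mean_G: np.ndarray) -> float:
    """Frobenius projection of the (gradient-mean-centered) G_j onto E_k."""
    return float(np.sum((np.asarray(G_j) - np.asarray(mean_G)) * np.asarray(E_k)))


def site_variance(v: np.ndarray, G_j: np.ndarray) -> float:
    """Genetic variance of population j along the unit trait vector v."""
    v = np.asarray(v, dtype=float)
    if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-8):
        raise ValueError("v must be a unit vector")
    return float(v @ np.asarray(G_j, dtype=float) @ v)


def _leading_loadings(E1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-trait signed loadings of the first eigentensor.

    The eigenvector of E1 with the largest-|eigenvalue| gives the trait
    combination; it is signed by that eigenvalue, so a negative loading
    marks a trait whose variance decreases along the oriented tensor.
    Returns (signed loadings, unit direction vector v for site variances).
    """
    lam, vecs = np.linalg.eigh(E1)
    k = int(np.argmax(np.abs(lam)))
    v = vecs[:, k]
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        v = -v
    return v * np.sign(lam[k]), v


def _orient(E1: np.ndarray, Gs: list[np.ndarray]) -> np.ndarray:
    """Fix the arbitrary sign of the leading eigentensor.

    Oriented so its Frobenius projection onto (G_first - G_last) along the
    gradient order is non-negative: the tensor then describes change as
    seen moving *against* the gradient order (loss when variance grows
    along the order), matching the reading of loadings as directional
    change in variance."""
    ref = np.asarray(Gs[0]) - np.asarray(Gs[-1])
    if np.sum(E1 * ref) < 0:
        return -E1
    return E1


@dataclass
class TensorDecomposition:
    """Posterior summary of the covariance tensor across a gradient."""

    populations: tuple[str, ...]
    trait_names: tuple[str, ...]
    variance_proportions: np.ndarray  # (n_tensors,) modes
    variance_proportions_hpd: np.ndarray  # (n_tensors, 2)
    eigentensors: list[np.ndarray]  # reference (posterior-mode) eigentensors
    leading_loadings: np.ndarray  # (p,) modes, signed
    leading_loadings_hpd: np.ndarray  # (p, 2)
    site_variance_T1: np.ndarray  # (m,) modes
    site_variance_T1_hpd: np.ndarray  # (m, 2)
    coordinates: np.ndarray  # (m, n_tensors) from the reference decomposition
    n_unmatched: int = 0

    def to_dict(self) -> dict:
        return {
            "gradient": list(self.populations),
            "traits": list(self.trait_names),
            "A_variance_proportions": [
                {"tensor": k + 1, "mode": float(m), "lower": float(lo), "upper": float(hi)}
                for k, (m, (lo, hi)) in enumerate(
                    zip(self.variance_proportions, self.variance_proportions_hpd)
                )
            ],
            "B_delta_va_tensor1": [
                {"trait": t, "mode": float(m), "lower": float(lo), "upper": float(hi)}
                for t, m, (lo, hi) in zip(
                    self.trait_names, self.leading_loadings, self.leading_loadings_hpd
                )
            ],
            "C_site_variance_T1": [
                {"population": pop, "mode": float(m), "lower": float(lo), "upper": float(hi)}
                for pop, m, (lo, hi) in zip(
                    self.populations, self.site_variance_T1, self.site_variance_T1_hpd
                )
            ],
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def decompose_point(Gs, populations=None, trait_names=None) -> TensorDecomposition:
    """Point-estimate tensor decomposition for plain matrix inputs."""
    Gs = [np.asarray(G, dtype=float) for G in Gs]
    m = len(Gs)
    p = Gs[0].shape[0]
    S = build_s_tensor(Gs)
    props, tensors = eigentensors(S, p)
    n_keep = min(m - 1, len(props))
    props = props[:n_keep] / props[:n_keep].sum() if n_keep else props
    tensors = tensors[:n_keep]
    if tensors:
        tensors[0] = _orient(tensors[0], Gs)
        loadings, v = _leading_loadings(tensors[0])
        site = np.array([site_variance(v, G) for G in Gs])
    else:
        loadings = np.zeros(p)
        site = np.zeros(m)
    mean_G = np.mean(Gs, axis=0)
    coords = np.array(
        [[tensor_coordinates(G, Ek, mean_G) for Ek in tensors] for G in Gs]
    )
    zeros = np.zeros((len(props), 2))
    return TensorDecomposition(
        populations=tuple(populations or [f"pop{j + 1}" for j in range(m)]),
        trait_names=tuple(trait_names or [f"t{a + 1}" for a in range(p)]),
        variance_proportions=props,
        variance_proportions_hpd=np.column_stack([props, props]),
        eigentensors=tensors,
        leading_loadings=loadings,
        leading_loadings_hpd=np.column_stack([loadings, loadings]),
        site_variance_T1=site,
        site_variance_T1_hpd=np.column_stack([site, site]),
        coordinates=coords,
    )


def tensor_analysis(posteriors: list[GPosterior], seed: int = 0) -> TensorDecomposition:
    """Per-draw tensor decomposition across a gradient of G posteriors.

    For each joint posterior draw index the m G draws are assembled,
    decomposed, matched against the reference (posterior-mode) eigentensors
    by maximal |Frobenius overlap|, and the per-draw proportions, leading
    loadings and site variances are then summarized with modes and HPDs.
    """
    if len(posteriors) < 2:
        raise ValueError("a gradient needs at least 2 populations")
    traits = posteriors[0].trait_names
    for post in posteriors[1:]:
        if post.trait_names != traits:
            raise ValueError("trait mismatch across posteriors")
    n = min(post.n_samples for post in posteriors)
    m = len(posteriors)
    p = len(traits)
    n_keep = m - 1

    # reference decomposition from element-wise posterior means (stable)
    G_ref = [post.G[:n].mean(axis=0) for post in posteriors]
    ref = decompose_point(G_ref, [post.population for post in posteriors], traits)
    ref_tensors = ref.eigentensors

    props_draws = np.zeros((n, n_keep))
    load_draws = np.zeros((n, p))
    site_draws = np.zeros((n, m))
    n_unmatched = 0

    for s in range(n):
        Gs = [post.G[s] for post in posteriors]
        S = build_s_tensor(Gs)
        props, tensors = eigentensors(S, p)
        props = props[:n_keep]
        tensors = tensors[:n_keep]
        # label-switching: match draw tensors to the reference by overlap
        overlap = np.array(
            [[abs(np.sum(T * R)) for T in tensors] for R in ref_tensors]
        )
        assign = np.full(len(ref_tensors), -1)
        used = set()
        for r in np.argsort(-overlap.max(axis=1)):
            for c in np.argsort(-overlap[r]):
                if c not in used:
                    assign[r] = c
                    used.add(c)
                    break
        if len(tensors) and overlap.size and overlap[0, assign[0]] < 0.5:
            n_unmatched += 1
        matched_props = np.array(
            [props[assign[r]] if assign[r] >= 0 else 0.0 for r in range(n_keep)]
        )
        total = matched_props.sum()
        props_draws[s] = matched_props / total if total > 0 else matched_props
        T1 = tensors[assign[0]] if assign[0] >= 0 else np.zeros((p, p))
        T1 = _orient(T1, Gs)
        loadings, v = _leading_loadings(T1)
        load_draws[s] = loadings
        site_draws[s] = [site_variance(v, G) for G in Gs]

    return TensorDecomposition(
        populations=tuple(post.population or f"pop{j + 1}" for j, post in enumerate(posteriors)),
        trait_names=traits,
        variance_proportions=np.array(
            [posterior_mode(props_draws[:, k]) for k in range(n_keep)]
        ),
        variance_proportions_hpd=np.array(
            [hpd_interval(props_draws[:, k]) for k in range(n_keep)]
        ),
        eigentensors=ref_tensors,
        leading_loadings=np.array([posterior_mode(load_draws[:, a]) for a in range(p)]),
        leading_loadings_hpd=np.array([hpd_interval(load_draws[:, a]) for a in range(p)]),
        site_variance_T1=np.array([posterior_mode(site_draws[:, j]) for j in range(m)]),
        site_variance_T1_hpd=np.array([hpd_interval(site_draws[:, j]) for j in range(m)]),
        coordinates=ref.coordinates,
        n_unmatched=n_unmatched,
    )
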