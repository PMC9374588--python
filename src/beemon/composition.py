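"""Compositional analysis: Bray–Curtis dissimilarities, nonmetric
multidimensional scaling, and one-factor perMANOVA with permutation
inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

__all__ = [
    "bray_curtis",
    "nmds",
    "permanova",
    "Ordination",
    "PermanovaResult",
]


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity BC(x, y) = sum|x-y| / sum(x+y)
    between the rows of a unit x species count matrix.

    Raises if two all-zero units make an entry undefined, naming them.
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    zero_rows = np.where(x.sum(axis=1) == 0)[0]
    if len(zero_rows) >= 2:
        labels = [counts.index[i] for i in zero_rows]
        raise ValueError(
            f"Bray–Curtis undefined between all-zero units: {labels}"
        )
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=counts.index, columns=counts.index)


@dataclass
class Ordination:
    """NMDS result: unit x k coordinates and Kruskal stress-1."""

    coords: pd.DataFrame
    stress: float
    n_restarts: int
    converged: bool


def _kruskal_stress1(dvec: np.ndarray, config_dist: np.ndarray) -> float:
    """Stress-1 = sqrt(sum (d - dhat)^2 / sum d^2), with dhat the isotonic
    regression of configuration distances on the dissimilarities."""
    order = np.argsort(dvec, kind="stable")
    iso = IsotonicRegression()
    dhat = np.empty_like(config_dist)
    dhat[order] = iso.fit_transform(np.arange(len(order)), config_dist[order])
    denom = float(np.sum(config_dist ** 2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((config_dist - dhat) ** 2) / denom))


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical scaling start: eigendecomposition of the
    double-centered squared-distance matrix."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)


def nmds(
    dissim: pd.DataFrame,
    k: int = 2,
    n_restarts: int = 16,
    max_iter: int = 300,
    tol: float = 1e-9,
    rng: np.random.Generator | None = None,
) -> Ordination:
    """Nonmetric MDS minimizing Kruskal stress-1.

    Runs SMACOF with monotone regression from ``n_restarts`` random
    configurations plus one classical (metric) scaling start and keeps
    the lowest-stress solution. Deterministic given ``rng``.
    """
    d = dissim.to_numpy(dtype=float)
    n = d.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} units for a {k}-d ordination")
    rng = rng or np.random.default_rng()

    inits = [_classical_mds(d, k)]
    for _ in range(n_restarts):
        inits.append(rng.standard_normal((n, k)))

    best = None
    converged = False
    for x0 in inits:
        coords, _, n_iter = smacof(
            d,
            metric=False,
            n_components=k,
            init=x0,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            normalized_stress=False,
            return_n_iter=True,
        )
        cd = pdist(coords)
        stress1 = _kruskal_stress1(squareform(d, checks=False), cd)
        if best is None or stress1 < best[1]:
            best = (coords, stress1)
            converged = n_iter < max_iter
    coords, stress = best
    frame = pd.DataFrame(
        coords, index=dissim.index, columns=[f"axis{i + 1}" for i in range(k)]
    )
    return Ordination(coords=frame, stress=stress,
                      n_restarts=n_restarts, converged=converged)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_perm: int


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """Within-group and total sums of squared dissimilarities."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        members = np.nonzero(codes == g)[0]
        ng = len(members)
        if ng > 1:
            ss_within += d2[np.ix_(members, members)].sum() / (2.0 * ng)
    return ss_within, ss_total


def permanova(
    dissim: pd.DataFrame,
    groups,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> PermanovaResult:
    """One-factor perMANOVA on a dissimilarity matrix.

    Partitions the total sum of squared dissimilarities into among- and
    within-group components; pseudo-F = (SS_A/(a-1)) / (SS_W/(N-a));
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) under unrestricted label
    permutation; R² = SS_A / SS_T.
    """
    d = dissim.to_numpy(dtype=float)
    codes, uniques = pd.factorize(np.asarray(groups))
    if len(codes) != d.shape[0]:
        raise ValueError("group labels must match dissimilarity units")
    a = len(uniques)
    n = d.shape[0]
    if a < 2:
        raise ValueError("need at least 2 groups")
    if n <= a:
        raise ValueError("need more units than groups")
    rng = rng or np.random.default_rng()

    d2 = d ** 2

    def f_stat(c: np.ndarray) -> float:
        ss_w, ss_t = _permanova_ss(d2, c, a)
        ss_a = ss_t - ss_w
        return (ss_a / (a - 1)) / (ss_w / (n - a)) if ss_w > 0 else np.inf

    ss_w_obs, ss_t = _permanova_ss(d2, codes, a)
    ss_a_obs = ss_t - ss_w_obs
    f_obs = f_stat(codes)
    r2 = ss_a_obs / ss_t if ss_t > 0 else 0.0

    exceed = 0
    for _ in range(n_perm):
        if f_stat(codes[rng.permutation(n)]) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(pseudo_f=float(f_obs), r_squared=float(r2),
                           p_value=float(p), n_perm=n_perm)
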