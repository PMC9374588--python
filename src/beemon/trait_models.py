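"""Trait → trend models: phylogenetic generalized least squares under a
Brownian-motion covariance on the species tree, and ordinary least
squares for the no-phylogeny contrast. Single-predictor models by
default; a joint multiple-regression mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["PGLSFit", "brownian_cov", "pgls_fit", "ols_fit", "trait_model_table"]


@dataclass
class PGLSFit:
    """Single-trait regression of 5-year change on a trait."""

    trait: str
    coefficient: float
    t_statistic: float
    p_value: float
    method: str  # "pgls_brownian" | "ols"
    n: int
    std_error: float = float("nan")
    conf_int: tuple[float, float] = (float("nan"), float("nan"))
    jittered: bool = False


def brownian_cov(tree: dendropy.Tree, species: Sequence[str]) -> pd.DataFrame:
    """Brownian-motion covariance: cov(i, j) = depth of the MRCA of i and
    j (shared root-to-tip path length); diagonal = tip depth. Requires
    the requested species to be tips of the tree."""
    species = list(species)
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = [s for s in species if s not in tips]
    if missing:
        raise KeyError(f"species not in tree: {missing}")

    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    # root-to-tip node paths for MRCA depth lookups
    paths: dict[str, list] = {}
    for s in species:
        chain = []
        nd = tips[s]
        while nd is not None:
            chain.append(id(nd))
            nd = nd.parent_node
        paths[s] = chain[::-1]

    n = len(species)
    cov = np.zeros((n, n))
    for i in range(n):
        cov[i, i] = depth[paths[species[i]][-1]]
        for j in range(i + 1, n):
            pi, pj = paths[species[i]], paths[species[j]]
            shared = 0.0
            for a, b in zip(pi, pj):
                if a != b:
                    break
                shared = depth[a]
            cov[i, j] = cov[j, i] = shared
    return pd.DataFrame(cov, index=species, columns=species)


def _fit_gls(y: np.ndarray, X: np.ndarray, sigma: np.ndarray | None,
             trait: str, method: str, jittered: bool) -> PGLSFit:
    if sigma is None:
        model = sm.OLS(y, X)
    else:
        model = sm.GLS(y, X, sigma=sigma)
    res = model.fit()
    ci = res.conf_int(alpha=0.05)
    return PGLSFit(
        trait=trait,
        coefficient=float(res.params[1]),
        t_statistic=float(res.tvalues[1]),
        p_value=float(res.pvalues[1]),
        method=method,
        n=len(y),
        std_error=float(res.bse[1]),
        conf_int=(float(ci[1, 0]), float(ci[1, 1])),
        jittered=jittered,
    )


def pgls_fit(y, x, cov: pd.DataFrame, trait: str = "trait") -> PGLSFit:
    """PGLS of ``y`` (per-species change) on one trait with Brownian
    error covariance ``cov``: beta = (X' C^-1 X)^-1 X' C^-1 y with an
    intercept; two-sided t-test on the trait coefficient.

    A tiny ridge is added to a numerically singular covariance (flagged).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("need >= 3 paired species values")
    if np.std(x) == 0:
        raise ValueError("no variation in predictor")
    C = cov.to_numpy(dtype=float)
    if C.shape != (len(y), len(y)):
        raise ValueError("covariance dimension mismatch")
    jittered = False
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        C = C + np.eye(len(y)) * 1e-8 * np.trace(C) / len(y)
        jittered = True
    X = sm.add_constant(x)
    return _fit_gls(y, X, C, trait, "pgls_brownian", jittered)


def ols_fit(y, x, trait: str = "trait") -> PGLSFit:
    """Ordinary least squares with the same surface as :func:`pgls_fit`
    (the no-phylogeny comparison model)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("need >= 3 paired species values")
    if np.std(x) == 0:
        raise ValueError("no variation in predictor")
    X = sm.add_constant(x)
    return _fit_gls(y, X, None, trait, "ols", False)


def trait_model_table(
    change: pd.Series,
    traits: pd.DataFrame,
    cov: pd.DataFrame,
    log_body_length: bool = True,
) -> pd.DataFrame:
    """Fit PGLS and OLS for each trait column against per-species change.

    ``change`` is indexed by species; species are aligned across the
    three inputs (intersection). Body length is log-transformed unless
    disabled. Returns one row per (trait, method).
    """
    species = [s for s in change.index if s in traits.index and s in cov.index]
    if len(species) < 3:
        raise ValueError("fewer than 3 species shared across inputs")
    y = change.loc[species].to_numpy(float)
    C = cov.loc[species, species]
    rows = []
    for trait in traits.columns:
        x = traits.loc[species, trait].to_numpy(float)
        if trait == "body_length" and log_body_length:
            x = np.log(x)
        if np.std(x) == 0:
            continue
        for fitter in (pgls_fit, ols_fit):
            if fitter is pgls_fit:
                fit = pgls_fit(y, x, C, trait=trait)
            else:
                fit = ols_fit(y, x, trait=trait)
            rows.append({
                "trait": trait,
                "method": fit.method,
                "coefficient": fit.coefficient,
                "t": fit.t_statistic,
                "p_value": fit.p_value,
                "n": fit.n,
            })
    return pd.DataFrame(rows)
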