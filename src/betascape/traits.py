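"""Functional trait space: transforms, PCA, dendrogram, phylogenetic signal.

Traits (continuous, typically log-normally distributed) are log10- and
z-transformed, projected onto principal components, and species are clustered
by complete linkage on Euclidean distances between retained component scores.
The resulting ultrametric dendrogram is a weighted tree usable by the same
branch-based beta-diversity machinery as the phylogeny.

Pagel's lambda measures phylogenetic signal: the off-diagonal Brownian-motion
covariance is scaled by lambda in [0, 1] (0 = star-like independence,
1 = Brownian motion) and fitted by maximum likelihood, profiling out the root
state and rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from sklearn.decomposition import PCA

from .trees import phylo_vcv, tree_from_string


class TraitError(ValueError):
    pass


def read_traits(path) -> pd.DataFrame:
    """Species x traits CSV; first column is the species identifier."""
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "species"
    return df.astype(float)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, index_label="species")


def transform_traits(raw: pd.DataFrame, log10: bool | list[str] = True) -> pd.DataFrame:
    """log10 the tagged traits (all by default), then z-score each column.

    Log-tagged traits must be strictly positive; constant traits are rejected
    because they carry no information and break standardization.
    """
    df = raw.astype(float).copy()
    log_cols = list(df.columns) if log10 is True else ([] if log10 is False else list(log10))
    for col in log_cols:
        if (df[col] <= 0).any():
            raise TraitError(f"non-positive value in log-tagged trait {col!r}")
        df[col] = np.log10(df[col])
    sd = df.std(ddof=1)
    if (sd <= 0).any() or sd.isna().any():
        bad = sd.index[(sd <= 0) | sd.isna()].tolist()
        raise TraitError(f"zero-variance trait(s): {bad}")
    return (df - df.mean()) / sd


@dataclass
class PCScores:
    scores: pd.DataFrame  # species x retained components
    explained: np.ndarray  # explained-variance fractions, all components
    k: int


def trait_pca(transformed: pd.DataFrame, retain: int | float = 0.90) -> PCScores:
    """PCA of standardized traits.

    ``retain``: an int fixes the number of components; a float in (0, 1] keeps
    the smallest k whose cumulative explained variance reaches the threshold.
    Component signs are fixed by making each axis's largest-magnitude loading
    positive, so scores are reproducible across platforms.
    """
    X = transformed.to_numpy(float)
    n, p = X.shape
    pca = PCA(n_components=min(n, p), svd_solver="full")
    scores = pca.fit_transform(X)
    explained = pca.explained_variance_ratio_
    # deterministic sign convention
    flip = np.sign(pca.components_[np.arange(len(explained)), np.argmax(np.abs(pca.components_), axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip

    if isinstance(retain, (int, np.integer)) and not isinstance(retain, bool):
        k = int(retain)
        if not 1 <= k <= len(explained):
            raise TraitError(f"retain k={k} outside 1..{len(explained)}")
    else:
        thr = float(retain)
        if not 0 < thr <= 1:
            raise TraitError("variance threshold must be in (0, 1]")
        k = int(np.searchsorted(np.cumsum(explained), thr - 1e-12) + 1)
        k = min(k, len(explained))
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCScores(
        scores=pd.DataFrame(scores[:, :k], index=transformed.index, columns=cols),
        explained=explained,
        k=k,
    )


def _linkage_newick(node, names) -> str:
    """scipy cluster-node -> newick, branch length = parent height - height."""
    if node.is_leaf():
        return names[node.id], 0.0
    parts = []
    for child in (node.left, node.right):
        label, h = _linkage_newick(child, names)
        parts.append(f"{label}:{node.dist - h:.10g}")
    return "(" + ",".join(parts) + ")", node.dist


def build_functional_dendrogram(scores: PCScores | pd.DataFrame) -> dendropy.Tree:
    """Complete-linkage dendrogram on Euclidean distances between score rows.

    Merge heights become node depths, so the tree is ultrametric; cophenetic
    distances are >= the input distances (complete linkage takes the maximum).
    """
    df = scores.scores if isinstance(scores, PCScores) else scores
    if len(df) < 2:
        raise TraitError("need at least 2 species to build a dendrogram")
    names = list(df.index.astype(str))
    Z = linkage(df.to_numpy(float), method="complete", metric="euclidean")
    root = to_tree(Z)
    body, _ = _linkage_newick(root, names)
    return tree_from_string(body + ";")


@dataclass
class LambdaEstimate:
    lambda_hat: float
    loglik: float
    loglik_zero: float
    p_value: float  # likelihood-ratio test against lambda = 0


def _bm_loglik(y: np.ndarray, C: np.ndarray) -> float:
    """Profile log-likelihood of Brownian motion with covariance sigma^2 C,
    maximizing over the root state and sigma^2.

    A relative jitter keeps the factorization defined when zero-length
    terminal branches make tips exactly exchangeable (rank-deficient C).
    """
    n = len(y)
    C = C + (1e-9 * np.diag(C).mean()) * np.eye(n)
    cf = sla.cho_factor(C, lower=True)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    one = np.ones(n)
    Ci1 = sla.cho_solve(cf, one)
    mu = (Ci1 @ y) / (Ci1 @ one)
    r = y - mu
    sigma2 = (r @ sla.cho_solve(cf, r)) / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def pagels_lambda(tree: dendropy.Tree, values: pd.Series) -> LambdaEstimate:
    """Maximum-likelihood Pagel's lambda on [0, 1] for one trait.

    ``values`` is indexed by species matching the tree's tips (>= 4 required).
    """
    vals = pd.Series(values).astype(float)
    labels = list(vals.index.astype(str))
    if len(labels) < 4:
        raise TraitError("need >= 4 tips with trait values")
    y = vals.to_numpy()
    if np.std(y) == 0:
        raise TraitError("zero trait variance")
    C, _ = phylo_vcv(tree, order=labels)
    diag = np.diag(C).copy()
    if (diag <= 0).any():
        raise TraitError("tree has zero root-to-tip depth for some tips")
    off = C - np.diag(diag)

    def loglik(lam: float) -> float:
        return _bm_loglik(y, lam * off + np.diag(diag))

    res = minimize_scalar(
        lambda lam: -loglik(lam), bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-6},
    )
    lam_hat = float(np.clip(res.x, 0.0, 1.0))
    ll_hat = loglik(lam_hat)
    ll0 = loglik(0.0)
    # check the boundaries explicitly; the bounded search can sit just inside
    for lam_b, ll_b in ((0.0, ll0), (1.0, loglik(1.0))):
        if ll_b > ll_hat:
            lam_hat, ll_hat = lam_b, ll_b
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    return LambdaEstimate(lam_hat, ll_hat, ll0, float(chi2.sf(lr, df=1)))


def lambda_report(tree: dendropy.Tree, traits: pd.DataFrame) -> pd.DataFrame:
    """Per-trait lambda estimates as a tidy table."""
    rows = []
    for col in traits.columns:
        est = pagels_lambda(tree, traits[col])
        rows.append(
            {"trait": col, "lambda_hat": est.lambda_hat, "loglik": est.loglik,
             "p_value": est.p_value}
        )
    return pd.DataFrame(rows)
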