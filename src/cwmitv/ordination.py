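"""Ordination: PCA of trait and environment blocks, Bray-Curtis + NMDS of
overstory composition, and principal-axis rotation of NMDS scores."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .cwm import SpeciesMeans

logger = logging.getLogger("cwmitv.ordination")

__all__ = [
    "PcaResult",
    "NmdsResult",
    "pca",
    "pca_transform",
    "trait_pca_axes",
    "bray_curtis",
    "nmds",
    "rotate_scores",
    "wisconsin",
]


@dataclass
class PcaResult:
    """Loadings (variable x component), row scores, and explained variance (%).

    Components come from an eigendecomposition of the correlation matrix
    (``scale=True``, appropriate when variables mix units) or the covariance
    matrix.  Sign convention: each loading column is flipped so its
    largest-magnitude entry is positive, which makes axis interpretation
    reproducible across runs.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_pct: pd.Series
    center: pd.Series
    scale: pd.Series


def pca(table: pd.DataFrame, scale: bool = True) -> PcaResult:
    if table.isna().to_numpy().any():
        raise ValueError("PCA input contains missing values")
    if table.shape[0] < 3:
        raise ValueError("PCA needs at least 3 rows")
    X = table.to_numpy(float)
    center = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = [c for c, s in zip(table.columns, sd) if s == 0]
        if zero:
            raise ValueError(f"zero-variance column(s) with scale=True: {zero}")
    else:
        sd = np.ones(X.shape[1])
    Z = (X - center) / sd
    C = np.cov(Z, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic signs: largest-|loading| entry of each column positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] *= -1
    comps = [f"PC{j + 1}" for j in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=table.columns, columns=comps)
    scores = pd.DataFrame(Z @ eigvec, index=table.index, columns=comps)
    explained = pd.Series(100.0 * eigval / eigval.sum(), index=comps, name="explained_pct")
    return PcaResult(loadings=loadings, scores=scores, explained_pct=explained,
                     center=pd.Series(center, index=table.columns),
                     scale=pd.Series(sd, index=table.columns))


def pca_transform(result: PcaResult, newdata: pd.DataFrame) -> pd.DataFrame:
    """Project new rows into an existing PCA space (same centering/scaling)."""
    Z = (newdata[result.loadings.index] - result.center) / result.scale
    return pd.DataFrame(Z.to_numpy(float) @ result.loadings.to_numpy(),
                        index=newdata.index, columns=result.loadings.columns)


def trait_pca_axes(means: SpeciesMeans, n_axes: int = 2,
                   trait_cols: list[str] | None = None):
    """Species-level trait PCA, projected back onto fixed and plot-specific means.

    The PCA is fitted on the species x trait table of fixed means (the
    functional space is defined by species, so each species is one point
    regardless of how many plots it occupies).  Both x_i and x_im are then
    projected onto the same loadings, yielding per-species and per-(plot,
    species) axis scores that the CWM machinery treats as extra 'traits'.

    Returns (PcaResult, SpeciesMeans augmented with PC1..PCn columns).
    """
    cols = trait_cols or means.traits
    fit = pca(means.fixed[cols], scale=True)
    axes = list(fit.loadings.columns[:n_axes])
    fixed_axes = fit.scores[axes]
    specific_axes = pca_transform(fit, means.specific[cols])[axes]
    return fit, means.with_axes(fixed_axes, specific_axes)


def bray_curtis(community: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between plots.

    d(j,k) = sum_i |y_ij - y_ik| / sum_i (y_ij + y_ik).
    """
    Y = community.to_numpy(float)
    if (Y < 0).any():
        raise ValueError("negative abundances")
    empty = community.index[Y.sum(axis=1) == 0]
    if len(empty):
        raise ValueError(f"all-zero plots must be excluded before Bray-Curtis: {list(empty)}")
    D = squareform(pdist(Y, metric="braycurtis"))
    return pd.DataFrame(D, index=community.index, columns=community.index)


@dataclass
class NmdsResult:
    scores: pd.DataFrame      # plot x axis, principal-axis rotated, centered
    stress: float             # final Kruskal stress-1
    n_starts: int
    converged: bool
    seed: int


def kruskal_stress1(dissim: np.ndarray, scores: np.ndarray) -> float:
    """Stress-1 of a configuration: sqrt(sum (d - dhat)^2 / sum d^2), with
    dhat the monotone (isotonic) regression of configuration distances on the
    input dissimilarities."""
    iu = np.triu_indices(dissim.shape[0], 1)
    d_conf = squareform(pdist(scores))[iu]
    dhat = IsotonicRegression().fit_transform(dissim[iu], d_conf)
    denom = float(d_conf @ d_conf)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d_conf - dhat) ** 2) / denom))


def nmds(dissimilarity: pd.DataFrame, k: int = 2, n_starts: int = 50,
         seed: int = 0, max_iter: int = 500, eps: float = 1e-6) -> NmdsResult:
    """Non-metric multidimensional scaling with multiple random starts.

    Runs SMACOF-style stress minimization with monotone regression from
    ``n_starts`` random configurations, keeps the best, then rotates the
    configuration to its principal axes and centers it (so reported axes
    have mean 0 and axis 1 carries the largest score variance).  The
    returned stress is Kruskal stress-1 recomputed from the final
    configuration.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = np.asarray(dissimilarity, float)
    candidates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        # classical-scaling start (robust for well-embeddable inputs) plus
        # the requested number of random starts; best stress wins
        for init, n_init in (("classical_mds", 1), ("random", n_starts)):
            model = MDS(n_components=k, metric_mds=False, metric="precomputed",
                        n_init=n_init, init=init, random_state=seed,
                        max_iter=max_iter, eps=eps, normalized_stress=True)
            conf = model.fit_transform(D)
            candidates.append((kruskal_stress1(D, conf), conf, model.n_iter_))
    _, raw, n_iter = min(candidates, key=lambda c: c[0])
    converged = n_iter < max_iter
    if not converged:
        logger.warning("NMDS did not converge in %d iterations (best start kept)", max_iter)
    scores = pd.DataFrame(raw, index=dissimilarity.index,
                          columns=[f"NMDS{j + 1}" for j in range(k)])
    scores = rotate_scores(scores) if k >= 2 else scores - scores.mean()
    stress = kruskal_stress1(D, scores.to_numpy())
    return NmdsResult(scores=scores, stress=stress, n_starts=n_starts,
                      converged=bool(converged), seed=seed)


def rotate_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Rotate a score matrix to its principal axes (axis 1 = max variance).

    Centering plus orthogonal rotation: pairwise inter-point distances are
    unchanged.  Axis signs follow the same largest-entry-positive convention
    as :func:`pca`.
    """
    if scores.shape[1] < 2:
        return scores - scores.mean()
    Z = scores.to_numpy(float) - scores.to_numpy(float).mean(axis=0)
    C = np.cov(Z, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(C)
    eigvec = eigvec[:, np.argsort(eigval)[::-1]]
    R = Z @ eigvec
    for j in range(R.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            R[:, j] *= -1
    return pd.DataFrame(R, index=scores.index, columns=scores.columns)


def wisconsin(community: pd.DataFrame) -> pd.DataFrame:
    """Wisconsin double standardization (species maxima, then plot totals)."""
    Y = community / community.max(axis=0).replace(0, 1)
    totals = Y.sum(axis=1)
    return Y.div(totals.replace(0, 1), axis=0)
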