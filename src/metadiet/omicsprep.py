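"""Metabolome normalization/imputation and microbiome transforms.

Metabolite processing follows the canonical order: run-day block
normalization (each metabolite's within-day median scaled to 1), minimum
imputation with a 20% missingness exclusion rule, then a per-metabolite
rank-based inverse-normal transform. Microbiome utilities cover the
prevalence filter, the centred log-ratio transform, Shannon alpha
diversity, Bray-Curtis dissimilarity, and density-based flagging of
ecologically abnormal samples in principal-coordinate space.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .dietprep import inverse_rank_transform

__all__ = [
    "block_normalize",
    "impute_and_filter",
    "inverse_normal_metabolites",
    "process_metabolites",
    "prevalence_filter",
    "clr_transform",
    "shannon_index",
    "bray_curtis",
    "pcoa_embedding",
    "pcoa_outlier_flag",
]


def block_normalize(matrix: pd.DataFrame, run_day) -> pd.DataFrame:
    """Divide each metabolite by its run-day median (missing values ignored).

    After normalization every metabolite has within-day median 1 for each
    day where it was observed. A day in which a metabolite is entirely
    missing stays missing (no division by zero).
    """
    run_day = pd.Series(np.asarray(run_day), index=matrix.index)
    out = matrix.copy().astype(float)
    for _, idx in out.groupby(run_day.to_numpy()).groups.items():
        block = out.loc[idx]
        med = block.median(axis=0, skipna=True)
        med = med.replace(0.0, np.nan)
        out.loc[idx] = block / med
    return out


def impute_and_filter(matrix: pd.DataFrame, max_missing_frac: float = 0.20):
    """Minimum-impute metabolites below the missingness bound, drop the rest.

    Only metabolites strictly below ``max_missing_frac`` missingness are
    imputed (missing cells set to the metabolite's observed minimum); a
    metabolite at or above the bound is dropped. Returns (matrix,
    dropped list).
    """
    frac = matrix.isna().mean(axis=0)
    dropped = list(matrix.columns[frac >= max_missing_frac])
    kept = matrix.drop(columns=dropped).copy()
    mins = kept.min(axis=0, skipna=True)
    kept = kept.fillna(mins)
    return kept, dropped


def inverse_normal_metabolites(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-metabolite rank-based inverse-normal transform.

    Constant metabolites carry no ordering information and are dropped with
    a warning.
    """
    out = {}
    dropped = []
    for c in matrix.columns:
        col = matrix[c]
        try:
            out[c] = inverse_rank_transform(col)
        except ValueError:
            dropped.append(c)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} constant metabolites: {dropped[:5]}...")
    return pd.DataFrame(out, index=matrix.index)


def process_metabolites(raw: pd.DataFrame, run_day,
                        max_missing_frac: float = 0.20):
    """Canonical processing chain: block normalize -> impute/filter -> INT.

    Returns (transformed matrix, dropped metabolite list).
    """
    norm = block_normalize(raw, run_day)
    imputed, dropped = impute_and_filter(norm, max_missing_frac)
    return inverse_normal_metabolites(imputed), dropped


def prevalence_filter(species: pd.DataFrame, min_prev: float = 0.10) -> pd.DataFrame:
    """Retain species present (abundance > 0) in strictly more than
    ``min_prev`` of samples."""
    prev = (species > 0).mean(axis=0)
    return species.loc[:, prev > min_prev]


def close_composition(species: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample to relative abundances summing to 1."""
    total = species.sum(axis=1)
    if (total <= 0).any():
        raise ValueError("sample with non-positive total abundance")
    return species.div(total, axis=0)


def clr_transform(species: pd.DataFrame, pseudocount: float = None) -> pd.DataFrame:
    """Centred log-ratio transform of closed compositions.

    Zeros are replaced by ``pseudocount`` (default: half the smallest
    non-zero relative abundance in the matrix) before re-closing; each
    output row sums to zero.
    """
    X = species.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative abundances are not compositional")
    if pseudocount is None:
        nz = X[X > 0]
        if nz.size == 0:
            raise ValueError("all-zero composition matrix")
        pseudocount = nz.min() / 2.0
    X = np.where(X == 0, pseudocount, X)
    X = X / X.sum(axis=1, keepdims=True)
    logX = np.log(X)
    clr = logX - logX.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=species.index, columns=species.columns)


def shannon_index(abundances) -> float:
    """Shannon entropy H = -sum p ln p (nats) after renormalization."""
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundances")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_table(species: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [shannon_index(row) for row in species.to_numpy()],
        index=species.index, name="shannon",
    )


def bray_curtis(matrix) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity d(u,v) = sum|u-v| / sum(u+v)."""
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    totals = X.sum(axis=1)
    if (totals == 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between all-zero samples")
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        num = np.abs(X[i] - X[i + 1:]).sum(axis=1)
        den = totals[i] + totals[i + 1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = num / den
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return D


def pcoa_embedding(dist: np.ndarray, n_axes: int = 2):
    """Classical scaling of a dissimilarity matrix.

    Eigendecomposition of the Gower-centred matrix -0.5 J d^2 J; negative
    eigenvalues are dropped. Returns (coordinates, eigenvalues).
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    vals, vecs = vals[pos], vecs[:, pos]
    coords = vecs * np.sqrt(vals)
    return coords[:, :n_axes], vals


def _kdist_eps(coords, min_pts):
    """k-distance elbow: point of maximum curvature of sorted k-NN distance."""
    from scipy.spatial.distance import cdist

    d = cdist(coords, coords)
    kdist = np.sort(np.sort(d, axis=1)[:, min(min_pts, d.shape[0] - 1)])
    if kdist.size < 3 or kdist[-1] == 0:
        return max(kdist[-1], 1e-12)
    second = np.diff(kdist, 2)
    elbow = int(np.argmax(second)) + 1 if second.size else kdist.size - 1
    return max(kdist[elbow], 1e-12)


def pcoa_outlier_flag(dist, min_pts: int = 5, eps: float = None) -> pd.Series:
    """Flag ecologically abnormal samples.

    DBSCAN on the first two principal coordinates; anything outside the
    largest density cluster is flagged. With fewer than 4 samples no
    flagging is attempted.
    """
    index = dist.index if isinstance(dist, pd.DataFrame) else None
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if n < 4:
        return pd.Series(np.zeros(n, dtype=bool), index=index)
    coords, _ = pcoa_embedding(D, n_axes=2)
    if eps is None:
        eps = _kdist_eps(coords, min_pts)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(coords)
    clusters, counts = np.unique(labels[labels >= 0], return_counts=True)
    if clusters.size == 0:
        flags = np.ones(n, dtype=bool)
    else:
        main = clusters[np.argmax(counts)]
        flags = labels != main
    return pd.Series(flags, index=index, name="ecologically_abnormal")
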