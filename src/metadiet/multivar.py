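"""Community-level and set-level analyses.

PERMANOVA with sequential (order-dependent) sums of squares on a
dissimilarity matrix — covariates first, term of interest last, permutation
of the term only — plus sample-size-weighted pooling of R² across cohorts,
hypergeometric overrepresentation analysis of pathway sets, and
hierarchical clustering of signed association profiles under the Adjusted
Coefficient of Commonality (ACC) distance with silhouette-optimal cluster
number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

__all__ = [
    "PermanovaResult", "gower_center", "permanova", "dedup_twins",
    "weighted_r2", "ora_hypergeom", "acc_distance", "ward_cluster_optimal",
]


@dataclass
class PermanovaResult:
    term: str
    r2: float
    pseudo_f: float
    p_perm: float
    n_perm: int
    table: pd.DataFrame = None  # sequential SS for all terms + residual


def gower_center(dist: np.ndarray) -> np.ndarray:
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D ** 2) @ J


def _hat(X):
    Q, _ = np.linalg.qr(X)
    return Q


def dedup_twins(families, seed: int = 0):
    """Randomly keep one member per family; returns positional indices."""
    rng = np.random.default_rng(seed)
    fams = pd.Series(np.asarray(families))
    keep = []
    for _, idx in fams.groupby(fams.to_numpy()).groups.items():
        idx = np.asarray(idx)
        keep.append(int(rng.choice(idx)))
    return np.sort(np.array(keep))


def permanova(dist, covariates, term, term_name: str = "term",
              n_perm: int = 10000, seed: int = 0) -> PermanovaResult:
    """Sequential-SS PERMANOVA of one term conditional on covariates.

    The pseudo-F for the final term uses sums of squares of the
    Gower-centred dissimilarity matrix added after the covariate block;
    the permutation null shuffles the term rows only, covariates held
    fixed. R² is SS_term / SS_total.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if n_perm < 99:
        warnings.warn("fewer than 99 permutations gives a coarse p value")
    G = gower_center(D)
    ss_total = np.trace(G)

    t = np.asarray(term, dtype=float).reshape(n, -1)
    ones = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, dtype=float).reshape(n, -1)
        Xcov = np.hstack([ones, C])
    else:
        C = np.zeros((n, 0))
        Xcov = ones
    if np.linalg.matrix_rank(Xcov) < Xcov.shape[1]:
        raise ValueError("singular covariate design")

    Qc = _hat(Xcov)
    GQc = G @ Qc
    ss_cov_blocks = []
    # sequential SS per covariate column (intercept absorbs the grand mean)
    prev = _hat(ones)
    ss_prev = np.einsum("ij,ij->", prev, G @ prev)
    for k in range(C.shape[1]):
        cur = _hat(np.hstack([ones, C[:, : k + 1]]))
        ss_cur = np.einsum("ij,ij->", cur, G @ cur)
        ss_cov_blocks.append(ss_cur - ss_prev)
        ss_prev = ss_cur
    ss_after_cov = np.einsum("ij,ij->", Qc, GQc)

    # residualize the term against [1, covariates]
    resid = t - Qc @ (Qc.T @ t)
    df_term = t.shape[1]
    df_resid = n - Xcov.shape[1] - df_term

    def _ss_term(R):
        Qt, _ = np.linalg.qr(R)
        return np.einsum("ij,ij->", Qt, G @ Qt)

    ss_term = _ss_term(resid)
    ss_res = ss_total - ss_after_cov - ss_term
    f_obs = (ss_term / df_term) / (ss_res / df_resid)

    rng = np.random.default_rng(seed)
    if df_term == 1:
        # vectorised permutations for a single-column term
        perms = np.array([rng.permutation(n) for _ in range(n_perm)]).T
        T = t[perms[:, :], 0]  # (n, n_perm)
        R = T - Qc @ (Qc.T @ T)
        GR = G @ R
        num = np.einsum("ib,ib->b", R, GR)
        den = np.einsum("ib,ib->b", R, R)
        ss_perm = num / den
        ss_res_perm = ss_total - ss_after_cov - ss_perm
        f_perm = (ss_perm / df_term) / (ss_res_perm / df_resid)
    else:
        f_perm = np.empty(n_perm)
        for b in range(n_perm):
            tp = t[rng.permutation(n)]
            rp = tp - Qc @ (Qc.T @ tp)
            ssb = _ss_term(rp)
            f_perm[b] = (ssb / df_term) / ((ss_total - ss_after_cov - ssb) / df_resid)

    p = (1.0 + np.sum(f_perm >= f_obs)) / (n_perm + 1.0)

    cov_names = [f"covariate_{k}" for k in range(C.shape[1])]
    table = pd.DataFrame(
        {
            "term": cov_names + [term_name, "residual"],
            "ss": ss_cov_blocks + [ss_term, ss_res],
        }
    )
    table["r2"] = table["ss"] / ss_total
    return PermanovaResult(
        term=term_name, r2=float(ss_term / ss_total), pseudo_f=float(f_obs),
        p_perm=float(p), n_perm=n_perm, table=table,
    )


def weighted_r2(r2_per_cohort, n_per_cohort) -> float:
    """Sample-size weighted average of per-cohort R² values."""
    r2 = np.asarray(r2_per_cohort, dtype=float)
    n = np.asarray(n_per_cohort, dtype=float)
    if r2.shape != n.shape:
        raise ValueError("r2 and n lists must have equal length")
    if n.sum() <= 0:
        raise ValueError("total sample size must be positive")
    return float((r2 * n).sum() / n.sum())


def ora_hypergeom(hit_set, pathway_sets: dict, background) -> pd.DataFrame:
    """Overrepresentation analysis by the hypergeometric upper tail.

    For each pathway, p = P[X >= overlap] with X ~ Hypergeom(N=|background|,
    K=|pathway|, n=|hits|); Bonferroni correction over the tested pathways.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background set")
    hits = set(hit_set) & background
    rows = []
    for name, members in pathway_sets.items():
        members = set(members) & background
        overlap = len(hits & members)
        N, K, n = len(background), len(members), len(hits)
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
        rows.append({"pathway": name, "overlap": overlap,
                     "pathway_size": K, "p": p})
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_bonferroni"] = np.minimum(out["p"] * m, 1.0)
    out["significant"] = out["p_bonferroni"] < 0.05
    return out


def acc_distance(signed: pd.DataFrame, drop_empty: bool = True):
    """Adjusted-Coefficient-of-Commonality distance between signed profiles.

    Entries must be in {-1, 0, +1}. For items A, B with union support U
    (categories where either is nonzero), ACC = (n_same_sign -
    n_opposite_sign) / |U| in [-1, 1]; distance = (1 - ACC)/2. Items
    significant nowhere are excluded when ``drop_empty``; otherwise their
    presence raises.
    """
    M = signed.to_numpy(dtype=float)
    if not np.isin(M, [-1.0, 0.0, 1.0]).all():
        raise ValueError("signed matrix entries must be -1, 0 or +1")
    nonzero = (M != 0).any(axis=1)
    if drop_empty:
        signed = signed.loc[nonzero]
        M = M[nonzero]
    elif not nonzero.all():
        raise ValueError("all-zero signed rows present")
    same = M @ M.T  # same-sign minus opposite-sign counts
    support = (M != 0).astype(float)
    both = support @ support.T
    sizes = support.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - both
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.where(union > 0, same / union, 1.0)
    dist = (1.0 - acc) / 2.0
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=signed.index, columns=signed.index)


def ward_cluster_optimal(dist: pd.DataFrame, k_range=range(2, 7)):
    """Ward-linkage hierarchical clustering with silhouette-optimal k.

    Returns (labels Series, chosen k, linkage matrix, silhouette table).
    Silhouette ties (within 1e-12) and degenerate geometries resolve to the
    smallest k.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("clustering needs at least 3 items")
    Z = linkage(squareform(D, checks=False), method="ward")
    rows = []
    best_k, best_s = None, -np.inf
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        labels = fcluster(Z, t=k, criterion="maxclust")
        if np.unique(labels).size < 2:
            s = -np.inf
        else:
            try:
                s = silhouette_score(D, labels, metric="precomputed")
            except ValueError:
                s = -np.inf
        rows.append({"k": k, "silhouette": s})
        if s > best_s + 1e-12:
            best_s, best_k = s, k
    if best_k is None:
        best_k = min(k for k in k_range if 2 <= k <= n - 1)
    labels = fcluster(Z, t=best_k, criterion="maxclust")
    index = dist.index if isinstance(dist, pd.DataFrame) else None
    return (pd.Series(labels, index=index, name="cluster"), best_k, Z,
            pd.DataFrame(rows))
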