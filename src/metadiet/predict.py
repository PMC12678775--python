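"""Random-forest prediction of diet adherence from metabolite profiles.

The stack mirrors a two-cohort design: twin-aware train/test partitioning
of the discovery cohort (families never straddle the split; classifiers
keep exact class balance on both sides), Boruta shadow-feature selection on
the training partition, repeated-CV grid tuning of a random forest,
ROC/AUC or Spearman evaluation with bootstrap confidence intervals, paired
DeLong and cross-cohort bootstrap AUC comparisons, out-of-bag permutation
importance, mean-masking recursive feature elimination (features are
neutralised at their training mean, the model is never refit), and the
union panel of minimal feature subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import RepeatedKFold, RepeatedStratifiedKFold

__all__ = [
    "SplitPlan", "EvalResult", "RFEResult",
    "quartile_labels", "twin_aware_split", "boruta_select",
    "default_grid", "tune_and_fit", "evaluate", "delong_test",
    "bootstrap_auc_compare", "permutation_importance", "mean_mask_rfe",
    "build_panel", "run_diet_prediction",
]

COVARIATE_NAMES = ("age", "sex", "bmi")


@dataclass
class SplitPlan:
    train_ids: list
    test_ids: list
    family_map: dict

    def validate(self, labels=None):
        fam_train = {self.family_map[i] for i in self.train_ids}
        fam_test = {self.family_map[i] for i in self.test_ids}
        if fam_train & fam_test:
            raise AssertionError("family present on both sides of the split")
        if labels is not None:
            for ids in (self.train_ids, self.test_ids):
                vals = labels.loc[ids]
                counts = vals.value_counts()
                if counts.nunique() > 1:
                    raise AssertionError("class imbalance within split side")


@dataclass
class EvalResult:
    auc: float = np.nan
    auc_ci: tuple = (np.nan, np.nan)
    spearman_rho: float = np.nan
    rho_ci: tuple = (np.nan, np.nan)
    roc_points: tuple = None
    predictions: np.ndarray = None
    labels: np.ndarray = None


@dataclass
class RFEResult:
    importance_order: list
    trajectory: pd.DataFrame
    selected_features: list
    tolerance: float
    original_metrics: dict = field(default_factory=dict)


def quartile_labels(scores: pd.Series) -> pd.Series:
    """Binary labels for the top (1) and bottom (0) quartiles of a score.

    The middle half is dropped. Ties are resolved by a stable sort on the
    score, so assignment is deterministic.
    """
    s = pd.Series(scores)
    if s.nunique() < 2:
        raise ValueError("constant scores cannot be split into quartiles")
    n = len(s)
    if n < 8:
        raise ValueError("need at least 8 scores for quartile labelling")
    q = n // 4
    order = np.argsort(s.to_numpy(), kind="stable")
    bottom = s.index[order[:q]]
    top = s.index[order[-q:]]
    labels = pd.concat(
        [pd.Series(0, index=bottom), pd.Series(1, index=top)]
    )
    return labels.loc[[i for i in s.index if i in labels.index]]


def twin_aware_split(labels: pd.Series, families: pd.Series,
                     train_frac: float = 0.8, seed: int = 0,
                     balance: bool = True) -> SplitPlan:
    """Family-level randomized train/test split.

    Families are shuffled and assigned whole to one side. For binary
    labels with ``balance=True`` the majority class is first randomly
    down-sampled, and after assignment each side is trimmed (randomly) to
    exactly equal class counts.
    """
    rng = np.random.default_rng(seed)
    labels = pd.Series(labels)
    families = pd.Series(families).loc[labels.index]
    ids = labels.index.to_numpy()

    classes = np.unique(labels.to_numpy())
    is_binary = balance and classes.size == 2
    if is_binary:
        counts = labels.value_counts()
        n_min = counts.min()
        keep = []
        for cls in classes:
            members = labels.index[labels == cls].to_numpy()
            if members.size > n_min:
                members = rng.choice(members, n_min, replace=False)
            keep.extend(members)
        keep_set = set(keep)
        ids = np.array([i for i in ids if i in keep_set])
        labels = labels.loc[ids]
        families = families.loc[ids]
        if n_min < 5:
            raise ValueError("a class is too small to balance and split")

    fam_ids = families.to_numpy()
    unique_fams = np.unique(fam_ids)
    rng.shuffle(unique_fams)
    target = train_frac * ids.size
    train_ids, test_ids, assigned = [], [], 0
    members_of = {f: ids[np.where(fam_ids == f)[0]] for f in unique_fams}
    for f in unique_fams:
        m = members_of[f]
        if assigned < target:
            train_ids.extend(m); assigned += m.size
        else:
            test_ids.extend(m)

    if is_binary:
        def _trim(side):
            side = np.array(side, dtype=object)
            lab = labels.loc[side]
            counts = lab.value_counts()
            n_keep = counts.min()
            kept = []
            for cls in classes:
                members = side[(lab == cls).to_numpy()]
                if members.size > n_keep:
                    members = rng.choice(members, n_keep, replace=False)
                kept.extend(members)
            return list(kept)

        train_ids, test_ids = _trim(train_ids), _trim(test_ids)

    plan = SplitPlan(
        list(train_ids), list(test_ids),
        dict(zip(families.index, families.to_numpy())),
    )
    plan.validate(labels if is_binary else None)
    return plan


def _forest(task, seed, n_estimators=300, mtry=None, min_node=5,
            split_rule=None, n_features=None, oob=False):
    if mtry in (None, "sqrt"):
        max_features = "sqrt"
    else:
        max_features = max(1, int(round(mtry * n_features)))
    common = dict(
        n_estimators=n_estimators, max_features=max_features,
        min_samples_leaf=min_node, random_state=int(seed), n_jobs=1,
        oob_score=False, bootstrap=True,
    )
    if task == "classify":
        return RandomForestClassifier(
            criterion=split_rule or "gini", **common
        )
    return RandomForestRegressor(criterion=split_rule or "squared_error", **common)


def boruta_select(X: pd.DataFrame, y, task: str = "classify",
                  max_iter: int = 500, n_estimators: int = 64,
                  alpha: float = 0.05, round_iters: int = 40,
                  seed: int = 0):
    """Boruta shadow-feature selection with progressive elimination.

    Each iteration appends a column-permuted shadow copy of every still
    active feature, fits a forest, and scores a *hit* for each real
    feature whose importance exceeds the maximum shadow importance. After
    every ``round_iters`` iterations a two-sided binomial test against 0.5
    (Bonferroni-corrected over the starting feature count) is applied to
    that round's hit counts: features with significantly few hits are
    rejected and removed from subsequent forests — as in the original
    algorithm, which is what gives surviving features room to beat the
    shrinking shadow pool — and features with significantly many hits are
    confirmed. Iterations stop at ``max_iter`` or when every feature is
    decided. Returns (confirmed feature list, total hit counts).
    """
    if X.shape[1] < 2:
        raise ValueError("Boruta needs at least 2 candidate features")
    rng = np.random.default_rng(seed)
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = Xv.shape
    active = np.arange(p)
    confirmed = np.zeros(p, dtype=bool)
    total_hits = np.zeros(p, dtype=int)
    it = 0
    while it < max_iter and active.size:
        hits = np.zeros(active.size, dtype=int)
        this_round = min(round_iters, max_iter - it)
        for _ in range(this_round):
            Xa = Xv[:, active]
            shadow = Xa.copy()
            for j in range(active.size):
                shadow[:, j] = shadow[rng.permutation(n), j]
            model = _forest(task, rng.integers(2 ** 31),
                            n_estimators=n_estimators)
            model.fit(np.hstack([Xa, shadow]), y)
            imp = model.feature_importances_
            hits += imp[: active.size] > imp[active.size:].max()
        it += this_round
        total_hits[active] += hits
        pvals = np.array(
            [stats.binomtest(int(h), this_round, 0.5).pvalue for h in hits]
        )
        sig = pvals * p < alpha
        newly_confirmed = sig & (hits > this_round / 2)
        rejected = sig & (hits < this_round / 2)
        confirmed[active[newly_confirmed]] = True
        active = active[~(newly_confirmed | rejected)]
    out = list(X.columns[confirmed])
    return out, pd.Series(total_hits, index=X.columns)


def default_grid(task: str, n_features: int):
    """The full tuning grid: mtry in {sqrt, 10..50% of features},
    minimum node size {5, 10, 15}, and the natively available split rules."""
    mtries = ["sqrt", 0.1, 0.2, 0.3, 0.4, 0.5]
    nodes = [5, 10, 15]
    rules = ["gini", "entropy"] if task == "classify" else ["squared_error"]
    return [
        {"mtry": m, "min_node": s, "split_rule": r}
        for m in mtries for s in nodes for r in rules
    ]


def tune_and_fit(X: pd.DataFrame, y, task: str = "classify", grid=None,
                 cv_folds: int = 5, cv_repeats: int = 10, seed: int = 0,
                 n_estimators: int = 300):
    """Repeated k-fold grid search; refit on the full training set.

    Model selection is by mean CV accuracy (classification) or RMSE
    (regression); ties go to the earlier grid cell. Returns
    (fitted model, chosen cell, CV table).
    """
    y = np.asarray(y)
    if grid is None:
        grid = default_grid(task, X.shape[1])
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if task == "classify":
        splitter = RepeatedStratifiedKFold(
            n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed
        )
    else:
        splitter = RepeatedKFold(
            n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed
        )
    folds = list(splitter.split(X.to_numpy(), y))
    scores = []
    for cell in grid:
        fold_scores = []
        for tr, va in folds:
            # identical seeds across cells so equal cells score identically
            model = _forest(
                task, seed, n_estimators=n_estimators,
                n_features=X.shape[1], **cell,
            )
            model.fit(X.iloc[tr].to_numpy(), y[tr])
            pred = model.predict(X.iloc[va].to_numpy())
            if task == "classify":
                fold_scores.append(np.mean(pred == y[va]))
            else:
                fold_scores.append(-np.sqrt(np.mean((pred - y[va]) ** 2)))
        scores.append(np.mean(fold_scores))
    best = int(np.argmax(scores))  # argmax returns the first maximum
    model = _forest(
        task, seed, n_estimators=n_estimators, n_features=X.shape[1],
        **grid[best],
    )
    model.fit(X.to_numpy(), y)
    cv_table = pd.DataFrame(grid).assign(cv_score=scores)
    return model, grid[best], cv_table


def _predict(model, X, task):
    X = np.asarray(X, dtype=float)
    if task == "classify":
        return model.predict_proba(X)[:, 1]
    return model.predict(X)


def evaluate(model, X: pd.DataFrame, y, task: str = "classify",
             n_boot: int = 1000, seed: int = 0) -> EvalResult:
    """AUC (classification) or Spearman rho (regression) with 1000-resample
    bootstrap percentile confidence intervals; resampling is paired in
    (prediction, truth)."""
    y = np.asarray(y)
    preds = _predict(model, X, task)
    rng = np.random.default_rng(seed)
    res = EvalResult(predictions=preds, labels=y)
    if task == "classify":
        if np.unique(y).size < 2:
            raise ValueError("AUC undefined on a single-class evaluation set")
        res.auc = roc_auc_score(y, preds)
        fpr, tpr, _ = roc_curve(y, preds)
        res.roc_points = (fpr, tpr)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, y.size, y.size)
            if np.unique(y[idx]).size < 2:
                continue
            boots.append(roc_auc_score(y[idx], preds[idx]))
        if boots:
            res.auc_ci = tuple(np.percentile(boots, [2.5, 97.5]))
    else:
        res.spearman_rho = stats.spearmanr(y, preds).statistic
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, y.size, y.size)
            if np.unique(y[idx]).size > 1 and np.unique(preds[idx]).size > 1:
                boots.append(stats.spearmanr(y[idx], preds[idx]).statistic)
        if boots:
            res.rho_ci = tuple(np.percentile(boots, [2.5, 97.5]))
    return res


def _placements(probs, labels):
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    m, n = pos.size, neg.size
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    v10 = (ranks_all[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m
    return v10, v01


def delong_test(probs_a, probs_b, labels):
    """Paired DeLong test for equality of two correlated AUCs.

    Returns (auc_a, auc_b, two-sided p). Degenerate variance (e.g.
    identical probability vectors) yields p = 1 with a warning.
    """
    labels = np.asarray(labels)
    a, b = np.asarray(probs_a, float), np.asarray(probs_b, float)
    v10a, v01a = _placements(a, labels)
    v10b, v01b = _placements(b, labels)
    auc_a = v10a.mean()
    auc_b = v10b.mean()
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        import warnings

        warnings.warn("degenerate DeLong variance; returning p = 1")
        return float(auc_a), float(auc_b), 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(auc_a), float(auc_b), float(2 * stats.norm.sf(abs(z)))


def _bootstrap_aucs(probs, labels, n_boot, rng):
    """AUC of ``n_boot`` with-replacement resamples, rank-vectorised.

    Single-class resamples are redrawn (up to 100 rounds) so the number of
    iterations stays fixed.
    """
    probs = np.asarray(probs, float)
    labels = np.asarray(labels)
    n = labels.size
    idx = rng.integers(0, n, (n_boot, n))
    for _ in range(100):
        m = labels[idx].sum(axis=1)
        bad = (m == 0) | (m == n)
        if not bad.any():
            break
        idx[bad] = rng.integers(0, n, (int(bad.sum()), n))
    else:
        raise RuntimeError("could not draw two-class bootstrap resamples")
    ranks = stats.rankdata(probs[idx], axis=1)
    pos = labels[idx] == 1
    m = pos.sum(axis=1)
    sum_pos = np.where(pos, ranks, 0.0).sum(axis=1)
    return (sum_pos - m * (m + 1) / 2.0) / (m * (n - m))


def bootstrap_auc_compare(probs_a, labels_a, probs_b, labels_b,
                          n_boot: int = 1000, seed: int = 0):
    """Empirical two-sided bootstrap comparison of two independent AUCs.

    Each iteration resamples both evaluation sets with replacement and
    records the AUC difference, giving an empirical difference
    distribution. The two-sided p value is twice the smaller tail mass of
    that distribution at zero (capped at 1): equal AUCs leave the
    distribution straddling zero (p near 1, exactly 1 for identical
    sets), while a genuine difference pushes it off zero.
    """
    import warnings

    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap iterations is unreliable")
    rng = np.random.default_rng(seed)
    pa, la = np.asarray(probs_a, float), np.asarray(labels_a)
    pb, lb = np.asarray(probs_b, float), np.asarray(labels_b)
    obs = abs(roc_auc_score(la, pa) - roc_auc_score(lb, pb))
    diffs = _bootstrap_aucs(pa, la, n_boot, rng) \
        - _bootstrap_aucs(pb, lb, n_boot, rng)
    p = float(min(1.0, 2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean())))
    return p, obs, diffs


def permutation_importance(model, X: pd.DataFrame, y, task: str = "classify",
                           n_repeats: int = 10, seed: int = 0) -> pd.Series:
    """Out-of-bag permutation importance, averaged over permutation repeats.

    For every tree, performance on its out-of-bag samples is compared with
    performance after permuting one feature column; the importance of the
    feature is the mean degradation (error-rate increase for classifiers,
    MSE increase for regressors).
    """
    import inspect

    from sklearn.ensemble._forest import (
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )

    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y)
    n = Xv.shape[0]
    # the bootstrap helpers grew a sample_weight argument in newer sklearn
    if "sample_weight" in inspect.signature(_get_n_samples_bootstrap).parameters:
        n_boot = _get_n_samples_bootstrap(n, model.max_samples, None)
        _oob = lambda rs: _generate_unsampled_indices(rs, n, n_boot, None)
    else:
        n_boot = _get_n_samples_bootstrap(n, model.max_samples)
        _oob = lambda rs: _generate_unsampled_indices(rs, n, n_boot)
    imp = np.zeros(Xv.shape[1])
    n_trees = 0
    for tree in model.estimators_:
        oob = _oob(tree.random_state)
        if oob.size < 2:
            continue
        n_trees += 1
        Xo = Xv[oob]
        if task == "classify":
            base = np.mean(tree.predict(Xo) != y[oob])
        else:
            base = np.mean((tree.predict(Xo) - y[oob]) ** 2)
        for j in range(Xv.shape[1]):
            orig = Xo[:, j].copy()
            deg = 0.0
            for _ in range(n_repeats):
                Xo[:, j] = orig[rng.permutation(oob.size)]
                pred = tree.predict(Xo)
                if task == "classify":
                    deg += np.mean(pred != y[oob])
                else:
                    deg += np.mean((pred - y[oob]) ** 2)
            Xo[:, j] = orig
            imp[j] += deg / n_repeats - base
    imp /= max(n_trees, 1)
    return pd.Series(imp, index=X.columns).sort_values(ascending=False)


def mean_mask_rfe(model, train_means: pd.Series, eval_sets: dict,
                  importance_order, tolerance: float = 0.05,
                  task: str = "classify") -> RFEResult:
    """Mean-masking recursive feature elimination (no refitting).

    Starting from the least important feature, columns are cumulatively
    replaced by their training means and the metric (AUC or Spearman rho)
    recomputed on every evaluation set. The selected subset is the
    smallest retained set whose metric stays within ``tolerance`` of the
    unmasked metric on *all* evaluation sets; at least one feature is
    always retained.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    order = list(importance_order)  # most important first
    masked_order = order[::-1]

    def _metric(Xd, y):
        preds = _predict(model, Xd, task)
        if task == "classify":
            return roc_auc_score(np.asarray(y), preds)
        return stats.spearmanr(np.asarray(y), preds).statistic

    work = {name: (X.copy(), y) for name, (X, y) in eval_sets.items()}
    base = {name: _metric(X, y) for name, (X, y) in work.items()}
    rows = [{"n_masked": 0, "masked_feature": None,
             **{f"metric_{k}": v for k, v in base.items()}}]
    ok_sizes = [len(order)]
    for step, feat in enumerate(masked_order[:-1], start=1):
        for name, (X, y) in work.items():
            X[feat] = train_means[feat]
        metrics = {name: _metric(X, y) for name, (X, y) in work.items()}
        rows.append({"n_masked": step, "masked_feature": feat,
                     **{f"metric_{k}": v for k, v in metrics.items()}})
        if all(metrics[k] >= base[k] - tolerance for k in base):
            ok_sizes.append(len(order) - step)
    n_keep = min(ok_sizes)
    selected = order[:n_keep]
    return RFEResult(
        importance_order=order,
        trajectory=pd.DataFrame(rows),
        selected_features=selected,
        tolerance=tolerance,
        original_metrics=base,
    )


def build_panel(rfe_results, covariates=COVARIATE_NAMES) -> list:
    """Union of the minimal feature subsets, covariates excluded."""
    panel = set()
    for r in rfe_results:
        panel.update(r.selected_features)
    drop = {c.lower() for c in covariates}
    return sorted(f for f in panel if f.lower() not in drop)


def run_diet_prediction(features: pd.DataFrame, score: pd.Series,
                        families: pd.Series, validation=None,
                        task: str = "classify", covariate_cols=COVARIATE_NAMES,
                        boruta_iter: int = 500, boruta_trees: int = 64,
                        grid=None, cv_repeats: int = 10,
                        n_estimators: int = 300, rfe_tolerance: float = 0.05,
                        n_boot: int = 1000, seed: int = 0,
                        run_rfe: bool = True) -> dict:
    """Full prediction workflow for one dietary score.

    ``features`` holds metabolites plus covariate columns; ``validation``
    is an optional (features, score) pair from the replication cohort.
    Feature selection, tuning and RFE masking means use the training
    partition only. Returns a dict with the split, model, evaluations and
    (optionally) the RFE result.
    """
    covars = [c for c in covariate_cols if c in features.columns]
    if task == "classify":
        labels = quartile_labels(score)
    else:
        labels = score
    plan = twin_aware_split(labels, families, seed=seed,
                            balance=task == "classify")
    Xtr = features.loc[plan.train_ids]
    ytr = labels.loc[plan.train_ids].to_numpy()
    Xte = features.loc[plan.test_ids]
    yte = labels.loc[plan.test_ids].to_numpy()

    met_cols = [c for c in features.columns if c not in covars]
    confirmed, hits = boruta_select(
        Xtr[met_cols], ytr, task=task, max_iter=boruta_iter,
        n_estimators=boruta_trees, seed=seed,
    )
    selected = confirmed + covars
    if not confirmed:
        selected = covars or met_cols

    model, best_cell, cv_table = tune_and_fit(
        Xtr[selected], ytr, task=task, grid=grid, cv_repeats=cv_repeats,
        seed=seed, n_estimators=n_estimators,
    )
    test_eval = evaluate(model, Xte[selected], yte, task, n_boot=n_boot, seed=seed)
    out = {
        "plan": plan, "model": model, "selected_features": selected,
        "boruta_confirmed": confirmed, "boruta_hits": hits,
        "best_cell": best_cell, "cv_table": cv_table,
        "test_eval": test_eval, "labels": labels,
    }

    eval_sets = {"test": (Xte[selected], yte)}
    if validation is not None:
        vX, vscore = validation
        vlab = quartile_labels(vscore) if task == "classify" else vscore
        ids = vlab.index
        eval_sets["validation"] = (vX.loc[ids, selected], vlab.to_numpy())
        out["validation_eval"] = evaluate(
            model, vX.loc[ids, selected], vlab.to_numpy(), task,
            n_boot=n_boot, seed=seed,
        )
    if run_rfe:
        importance = permutation_importance(
            model, Xtr[selected], ytr, task=task, seed=seed
        )
        rfe = mean_mask_rfe(
            model, Xtr[selected].mean(), eval_sets,
            list(importance.index), tolerance=rfe_tolerance, task=task,
        )
        out["importance"] = importance
        out["rfe"] = rfe
    return out
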