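"""Random-forest category association and rank-sum differential abundance.

``rf_grid`` crosses host/technical categories with taxonomic levels and
normalisations, fitting one bagged-tree ensemble per crossing (500 trees,
sqrt-features per split) and recording the out-of-bag error — the screen the
meta-analysis used to find which factors structure the community.
``important_features`` ranks features by permutation importance and picks
the smallest feature count whose cross-validated error is within one pooled
standard deviation of the minimum (the point where the error curve
stabilises). ``differential_rank_sum`` is the two-sided Wilcoxon rank-sum
screen with Benjamini-Hochberg correction and log2 median fold changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .metadata import analysis_samples
from .normalization import clr_czm, rarefy, rra, tss
from .table import CountTable, collapse_taxonomy

__all__ = ["rf_grid", "important_features", "differential_rank_sum", "fit_forest"]

_NORMALISERS = {
    "RAR": lambda t, depth, seed: rarefy(t, depth=depth, seed=seed),
    "TSS": lambda t, depth, seed: tss(t),
    "RRA": lambda t, depth, seed: rra(t, depth=depth, seed=seed),
    "CLR": lambda t, depth, seed: clr_czm(t),
}


def _category_arrays(t, meta: pd.DataFrame, category: str):
    """Sample matrix X (samples x features) and labels for one category.

    Samples whose level is unknown (or pooled "others" for host categories)
    are excluded from this category's analysis.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    usable = analysis_samples(meta.reset_index(), category).set_index("sample_id")
    from .diversity import _matrix

    otu_ids, sample_ids, values = _matrix(t)
    keep = [i for i, s in enumerate(sample_ids) if s in usable.index]
    if not keep:
        raise ValueError(f"no usable samples for category {category!r}")
    X = values[:, keep].T
    y = usable.loc[[sample_ids[i] for i in keep], category].to_numpy()
    levels, counts = np.unique(y, return_counts=True)
    if len(levels) < 2:
        raise ValueError(f"category {category!r} has a single level after filtering")
    if counts.min() < 2:
        small = [l for l, c in zip(levels, counts) if c < 2]
        raise ValueError(f"category {category!r} level(s) with <2 samples: {small}")
    return X, y, otu_ids, [sample_ids[i] for i in keep]


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    seed: int | None = None,
    n_estimators: int = 500,
    oob: bool = True,
) -> RandomForestClassifier:
    """Fit the reference ensemble: ``n_estimators`` trees, sqrt-features splits."""
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        oob_score=oob,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def rf_grid(
    t: CountTable,
    meta: pd.DataFrame,
    tax: pd.DataFrame | None,
    categories: list[str],
    levels: list[str] = ("otu",),
    normalisations: list[str] = ("TSS",),
    seed: int | None = None,
    depth: int = 5000,
    n_estimators: int = 500,
) -> pd.DataFrame:
    """Out-of-bag error for every (category, level, normalisation) crossing.

    ``levels`` may include ``"otu"`` and any taxonomic rank (requires
    ``tax``). Returns one tidy row per crossing; deterministic for a fixed
    seed.
    """
    rows = []
    for level in levels:
        if level == "otu":
            t_level = t
        else:
            if tax is None:
                raise ValueError("taxonomy required for rank-level grids")
            t_level = collapse_taxonomy(t, tax, level)
        for norm in normalisations:
            if norm not in _NORMALISERS:
                raise ValueError(f"unknown normalisation {norm!r}")
            table = _NORMALISERS[norm](t_level, depth, seed)
            for category in categories:
                X, y, _, _ = _category_arrays(table, meta, category)
                forest = fit_forest(X, y, seed=seed, n_estimators=n_estimators)
                rows.append(
                    {
                        "category": category,
                        "taxonomic_level": level,
                        "normalisation": norm,
                        "oob_error": 1.0 - forest.oob_score_,
                        "n_samples": X.shape[0],
                        "n_features": X.shape[1],
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)


def _cv_feature_counts(n_features: int) -> list[int]:
    """Geometric halving grid of feature counts, rfcv-style."""
    counts = []
    k = n_features
    while k >= 1:
        counts.append(int(k))
        if k == 1:
            break
        k = int(np.ceil(k / 2))
        if counts and k == counts[-1]:
            k -= 1
    return counts


def important_features(
    t,
    meta: pd.DataFrame,
    category: str,
    k_folds: int = 10,
    repeats: int = 5,
    seed: int | None = None,
    n_estimators: int = 500,
    sd_factor: float = 1.0,
) -> dict:
    """Cross-validated selection of the features that matter for a category.

    Features are ranked by permutation importance (accuracy drop) of the
    full-data forest. The cross-validation curve evaluates geometrically
    reduced feature counts; within each training fold features are re-ranked
    so the curve is honest. The selected count is the smallest whose mean CV
    error is within ``sd_factor`` pooled standard deviations of the minimum
    — where the error curve stabilises — mapped back to the top of the
    full-data ranking.

    Returns a dict with ``ordered`` (feature ids by importance), ``selected``
    (the chosen prefix), and ``cv_curve`` (DataFrame: n_features, mean_error,
    sd_error).
    """
    X, y, feature_ids, _ = _category_arrays(t, meta, category)
    n = X.shape[0]
    if n < k_folds:
        raise ValueError(f"fewer samples ({n}) than folds ({k_folds})")
    rng = np.random.default_rng(seed)

    forest = fit_forest(X, y, seed=_subseed(rng), n_estimators=n_estimators)
    imp = permutation_importance(
        forest, X, y, n_repeats=5, random_state=_subseed(rng), scoring="accuracy"
    )
    order = np.argsort(-imp.importances_mean, kind="mergesort")
    ordered = [feature_ids[i] for i in order]

    counts = _cv_feature_counts(X.shape[1])
    errors = np.zeros((repeats * k_folds, len(counts)))
    row = 0
    for _ in range(repeats):
        folds = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=_subseed(rng))
        for train, test in folds.split(X, y):
            inner = fit_forest(
                X[train], y[train], seed=_subseed(rng),
                n_estimators=n_estimators, oob=False,
            )
            fold_imp = permutation_importance(
                inner, X[train], y[train], n_repeats=3,
                random_state=_subseed(rng), scoring="accuracy",
            )
            fold_order = np.argsort(-fold_imp.importances_mean, kind="mergesort")
            for c, k in enumerate(counts):
                cols = fold_order[:k]
                sub = fit_forest(
                    X[train][:, cols], y[train], seed=_subseed(rng),
                    n_estimators=n_estimators, oob=False,
                )
                errors[row, c] = np.mean(sub.predict(X[test][:, cols]) != y[test])
            row += 1

    mean_err = errors.mean(axis=0)
    sd_err = errors.std(axis=0, ddof=1)
    best = int(np.argmin(mean_err))
    tol = mean_err[best] + sd_factor * sd_err[best]
    admissible = [k for k, m in zip(counts, mean_err) if m <= tol + 1e-12]
    n_selected = min(admissible)
    curve = pd.DataFrame(
        {"n_features": counts, "mean_error": mean_err, "sd_error": sd_err}
    )
    return {
        "category": category,
        "ordered": ordered,
        "selected": ordered[:n_selected],
        "cv_curve": curve,
    }


def _subseed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def differential_rank_sum(
    t,
    meta: pd.DataFrame,
    category: str,
    pair: tuple[str, str],
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential abundance between two category levels.

    Taxa are compared on relative abundances (TSS applied to count input).
    Two-sided test with midranks; exact p-values when both groups have
    n <= 25 and the data are tie-free, normal approximation otherwise.
    Benjamini-Hochberg correction across taxa; fold change is
    log2((median_A + eps) / (median_B + eps)) with eps the smallest nonzero
    relative abundance in the table. Taxa all-zero in both groups are
    excluded.
    """
    from .diversity import _matrix

    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    if isinstance(t, CountTable):
        t = tss(t)
    taxa_ids, sample_ids, values = _matrix(t)
    level_a, level_b = pair
    ids_a = [s for s in sample_ids if s in meta.index and meta.loc[s, category] == level_a]
    ids_b = [s for s in sample_ids if s in meta.index and meta.loc[s, category] == level_b]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("both levels need at least 2 samples")
    col = {s: i for i, s in enumerate(sample_ids)}
    A = values[:, [col[s] for s in ids_a]]
    B = values[:, [col[s] for s in ids_b]]

    nonzero = values[values > 0]
    eps = float(nonzero.min()) if nonzero.size else 1.0

    rows = []
    for i, taxon in enumerate(taxa_ids):
        a, b = A[i], B[i]
        if not (a.any() or b.any()):
            continue
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        exact = len(a) <= 25 and len(b) <= 25 and not ties
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        fold = np.log2((np.median(a) + eps) / (np.median(b) + eps))
        rows.append((taxon, float(res.statistic), float(res.pvalue), float(fold)))

    out = pd.DataFrame(rows, columns=["taxon", "statistic", "p_value", "log2_fold"])
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["q_value"] = []
    return out.set_index("taxon")
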