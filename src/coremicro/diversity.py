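"""Alpha diversity, beta-diversity distance matrices, PCoA and PERMANOVA.

Distances are returned as :class:`skbio.DistanceMatrix`. Weighted UniFrac is
computed by a single post-order traversal that turns each sample into a
vector of per-branch subtree proportions; the raw distance between two
samples is the branch-length-weighted L1 difference of those vectors and the
normalised form divides by the weighted sum, bounding it to [0, 1].

PERMANOVA partitions the Gower-centred squared-distance matrix sequentially
(Type-I sums of squares), so "adjusting for the study" is expressed by
entering the study label as the first term. Permutation p-values come from
free relabelling, relabelling within strata blocks, or exhaustive
enumeration of all relabellings for small n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .normalization import NormalisedTable
from .table import CountTable

__all__ = [
    "alpha_diversity",
    "bray_curtis",
    "euclidean",
    "weighted_unifrac",
    "branch_embedding",
    "pcoa",
    "PcoaResult",
    "permanova",
]


def _matrix(t) -> tuple[list[str], list[str], np.ndarray]:
    if isinstance(t, CountTable):
        return list(t.otu_ids), list(t.sample_ids), t.counts.astype(np.float64)
    return list(t.otu_ids), list(t.sample_ids), np.asarray(t.values, dtype=np.float64)


# -- alpha diversity -------------------------------------------------------


def alpha_diversity(t, bias_corrected_chao1: bool = True) -> pd.DataFrame:
    """Chao1, Shannon (natural log) and Gini-Simpson per sample.

    Chao1 uses the bias-corrected estimator S_obs + F1(F1-1)/(2(F2+1)) by
    default (defined even when no doubletons exist); the classic form
    S_obs + F1^2/(2 F2) is available with ``bias_corrected_chao1=False``.
    Chao1 requires integer counts; Shannon and Simpson accept any
    non-negative table.
    """
    _, sample_ids, values = _matrix(t)
    if np.any(values < 0):
        raise ValueError("negative values in table")
    integral = np.all(np.equal(np.mod(values, 1), 0))

    records = []
    for j, sid in enumerate(sample_ids):
        col = values[:, j]
        total = col.sum()
        if total == 0:
            records.append((sid, np.nan, 0.0, 0.0))
            continue
        p = col[col > 0] / total
        shannon = float(-(p * np.log(p)).sum())
        simpson = float(1.0 - (p**2).sum())
        if integral:
            s_obs = int((col > 0).sum())
            f1 = int((col == 1).sum())
            f2 = int((col == 2).sum())
            if bias_corrected_chao1:
                chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
            else:
                chao1 = s_obs + (f1**2 / (2.0 * f2) if f2 > 0 else 0.0)
        else:
            chao1 = np.nan
        records.append((sid, chao1, shannon, simpson))

    out = pd.DataFrame(records, columns=["sample_id", "chao1", "shannon", "simpson"])
    if not integral:
        out = out.drop(columns="chao1")
    return out.set_index("sample_id")


def chao1_single(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness of one integer count vector."""
    counts = np.asarray(counts)
    if not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValueError("Chao1 requires integer counts")
    table = CountTable(
        [f"o{i}" for i in range(len(counts))], ["s"], np.asarray(counts).reshape(-1, 1)
    )
    return float(alpha_diversity(table, bias_corrected_chao1=bias_corrected)["chao1"].iloc[0])


# -- distance matrices -----------------------------------------------------


def bray_curtis(t) -> DistanceMatrix:
    """Bray-Curtis dissimilarity BC(x, y) = sum|x-y| / sum(x+y) between samples."""
    _, sample_ids, values = _matrix(t)
    if len(sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    if np.any(values.sum(axis=0) == 0):
        bad = [sample_ids[i] for i in np.flatnonzero(values.sum(axis=0) == 0)]
        raise ValueError(f"Bray-Curtis undefined for all-zero sample(s): {bad}")
    d = pdist(values.T, metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=sample_ids)


def euclidean(t) -> DistanceMatrix:
    """Euclidean distance between sample columns."""
    _, sample_ids, values = _matrix(t)
    if len(sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    d = pdist(values.T, metric="euclidean")
    return DistanceMatrix(squareform(d), ids=sample_ids)


def branch_embedding(tree: TreeNode, otu_ids: list[str]):
    """Per-branch structure of ``tree`` for weighted-UniFrac computations.

    Returns ``(lengths, paths)`` where ``lengths`` is the branch-length
    vector over all non-root branches (post-order) and ``paths[i]`` lists the
    branch indices on the root path of ``otu_ids[i]``'s leaf. A sample's
    per-branch subtree proportion vector is the sum of its leaf proportions
    over each branch's descendant leaves, i.e. scatter-add along ``paths``.
    """
    order = list(tree.postorder(include_self=False))
    index = {id(node): k for k, node in enumerate(order)}
    lengths = np.array([node.length or 0.0 for node in order])
    tip_paths: dict[str, list[int]] = {}
    for tip in tree.tips():
        path = []
        node = tip
        while node.parent is not None:
            path.append(index[id(node)])
            node = node.parent
        tip_paths[tip.name] = path
    missing = [o for o in otu_ids if o not in tip_paths]
    if missing:
        raise KeyError(f"OTUs absent from tree: {missing}")
    return lengths, [tip_paths[o] for o in otu_ids]


def _branch_proportions(values: np.ndarray, lengths, paths) -> np.ndarray:
    """Branch x sample matrix of subtree proportions (columns normalised)."""
    totals = values.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("all-zero sample; proportions undefined")
    props = values / totals
    P = np.zeros((len(lengths), values.shape[1]))
    for i, path in enumerate(paths):
        P[path] += props[i]
    return P


def weighted_unifrac(t, tree: TreeNode, normalised: bool = True) -> DistanceMatrix:
    """Weighted UniFrac distance between samples.

    raw(A, B)  = sum_j  b_j |P_j^A - P_j^B|
    norm(A, B) = raw / sum_j b_j (P_j^A + P_j^B)

    where the sum runs over branches, b_j is the branch length and P_j is the
    proportion of a sample's reads descending from branch j. Every OTU with a
    nonzero count must be a leaf of ``tree``.
    """
    otu_ids, sample_ids, values = _matrix(t)
    present = np.flatnonzero(values.sum(axis=1) > 0)
    tips = {tip.name for tip in tree.tips()}
    missing = [otu_ids[i] for i in present if otu_ids[i] not in tips]
    if missing:
        raise KeyError(f"OTUs with nonzero counts absent from tree: {missing}")
    in_tree = [i for i, o in enumerate(otu_ids) if o in tips]
    lengths, paths = branch_embedding(tree, [otu_ids[i] for i in in_tree])
    P = _branch_proportions(values[in_tree], lengths, paths)
    n = len(sample_ids)
    d = np.zeros((n, n))
    weighted = lengths[:, None] * P
    for i in range(n):
        diff = np.abs(weighted[:, i, None] - weighted[:, i + 1:]).sum(axis=0)
        if normalised:
            denom = (weighted[:, i, None] + weighted[:, i + 1:]).sum(axis=0)
            with np.errstate(invalid="ignore"):
                diff = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
        d[i, i + 1:] = diff
        d[i + 1:, i] = diff
    return DistanceMatrix(d, ids=sample_ids)


# -- PCoA ------------------------------------------------------------------


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a distance matrix."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray = field(repr=False)
    proportion_explained: np.ndarray = field(repr=False)


def pcoa(d: DistanceMatrix, k: int | None = None,
         negatives_in_denominator: bool = False) -> PcoaResult:
    """Classical scaling (PCoA) of a distance matrix.

    Eigendecomposes the Gower double-centred matrix -1/2 J D^2 J. Axes are
    ordered by descending eigenvalue; only positive-eigenvalue axes yield
    coordinates. Negative eigenvalues are reported and excluded from the
    proportion-explained denominator unless ``negatives_in_denominator``.
    """
    D = np.asarray(d.data, dtype=np.float64)
    n = D.shape[0]
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if k is None:
        k = n - 1
    if k > n - 1:
        raise ValueError("k must be <= n - 1")
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = np.clip(eigval, 0.0, None)
    coords = eigvec[:, :k] * np.sqrt(pos[:k])
    denom = np.abs(eigval).sum() if negatives_in_denominator else pos.sum()
    prop = pos / denom if denom > 0 else np.zeros_like(pos)
    frame = pd.DataFrame(
        coords, index=list(d.ids), columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PcoaResult(frame, eigval, prop)


# -- PERMANOVA -------------------------------------------------------------


def _dummy(levels: pd.Series) -> np.ndarray:
    cats = pd.Categorical(levels)
    if len(cats.categories) < 2:
        raise ValueError(f"term has a single level: {levels.name!r}")
    return pd.get_dummies(cats, drop_first=True, dtype=float).to_numpy()


def _projection(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projection onto the column span of X, and its rank."""
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


def permanova(
    d: DistanceMatrix,
    meta: pd.DataFrame,
    terms: list[str],
    n_perm: int | str = 999,
    seed: int | None = None,
    strata: str | None = None,
) -> pd.DataFrame:
    """Sequential (Type-I) PERMANOVA of a distance matrix on metadata terms.

    ``meta`` must carry ``sample_id`` plus every term (and ``strata``) as
    columns; rows are aligned to the distance matrix ids. Terms are fitted in
    order, so adjusting one factor for another means listing the adjuster
    first (study-adjusted analyses list ``"study"`` as the first term).
    ``n_perm`` is an integer for Monte-Carlo permutations or ``"exact"`` for
    exhaustive enumeration of all n! relabellings (n <= 8). ``strata``
    restricts permutations to within-block relabelling.

    Returns a tidy DataFrame (term, df, sum_of_squares, R2, pseudo_F,
    p_value) with residual and total rows; ``result.attrs["n_permutations"]``
    records the permutation count.
    """
    ids = list(d.ids)
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    missing = [s for s in ids if s not in meta.index]
    if missing:
        raise KeyError(f"metadata missing samples: {missing}")
    meta = meta.loc[ids]
    for term in terms:
        if meta[term].isna().any():
            raise ValueError(f"missing level in term {term!r}")

    n = len(ids)
    D2 = np.asarray(d.data) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    ss_total = float(np.trace(G))

    # sequential projections: intercept, then cumulative term blocks
    blocks = [np.ones((n, 1))]
    hats, ranks = [], []
    for term in terms:
        blocks.append(_dummy(meta[term]))
        H, rank = _projection(np.hstack(blocks))
        hats.append(H)
        ranks.append(rank)
    dfs = np.diff([1] + ranks)
    if np.any(dfs == 0):
        bad = [t for t, df_t in zip(terms, dfs) if df_t == 0]
        raise ValueError(f"term(s) collinear with earlier terms: {bad}")
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    scale = max(abs(ss_total), 1.0)

    def stats(Gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cum = np.array([np.sum(H * Gmat) for H in hats])  # tr(H G), H symmetric
        ss = np.diff(np.concatenate([[0.0], cum]))
        ss_res = np.trace(Gmat) - cum[-1]
        if ss_res < 1e-12 * scale:  # perfect fit: F is infinite where SS > 0
            F = np.where(ss > 1e-12 * scale, np.inf, 0.0)
        else:
            F = (ss / dfs) / (ss_res / df_res)
        return ss, F

    ss_obs, F_obs = stats(G)
    F_tol = np.where(np.isfinite(F_obs), 1e-9 * np.abs(F_obs) + 1e-12, 0.0)

    # permutations of sample labels
    if n_perm == "exact":
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        perms = np.array(list(itertools.permutations(range(n))))
        count = np.zeros(len(terms))
        for perm in perms:
            _, F_p = stats(G[np.ix_(perm, perm)])
            count += F_p >= F_obs - F_tol
        p = count / math.factorial(n)
        n_used = math.factorial(n)
    else:
        n_used = int(n_perm)
        rng = np.random.default_rng(seed)
        if strata is not None:
            groups = meta[strata].to_numpy()
            sizes = pd.Series(groups).value_counts()
            if (sizes == 1).any():
                import warnings

                warnings.warn("strata block(s) of size 1 cannot be permuted")
            block_idx = {g: np.flatnonzero(groups == g) for g in sizes.index}

        exceed = np.zeros(len(terms))
        chunk = max(1, min(n_used, int(4e7 // (n * n) + 1)))
        done = 0
        while done < n_used:
            m = min(chunk, n_used - done)
            perms = np.empty((m, n), dtype=np.int64)
            for r in range(m):
                if strata is None:
                    perms[r] = rng.permutation(n)
                else:
                    perm = np.arange(n)
                    for idx in block_idx.values():
                        perm[idx] = idx[rng.permutation(len(idx))]
                    perms[r] = perm
            Gp = G[perms[:, :, None], perms[:, None, :]]  # (m, n, n)
            cum = np.stack([np.einsum("ij,mij->m", H, Gp) for H in hats], axis=1)
            ss_p = np.diff(np.concatenate([np.zeros((m, 1)), cum], axis=1), axis=1)
            ss_res_p = np.einsum("mii->m", Gp) - cum[:, -1]
            F_p = (ss_p / dfs) / (ss_res_p / df_res)[:, None]
            exceed += (F_p >= F_obs - F_tol).sum(axis=0)
            done += m
        p = (1.0 + exceed) / (1.0 + n_used)

    ss_res = ss_total - ss_obs.sum()
    rows = [
        (term, int(df_t), ss_t, ss_t / ss_total, F_t, p_t)
        for term, df_t, ss_t, F_t, p_t in zip(terms, dfs, ss_obs, F_obs, p)
    ]
    rows.append(("Residual", int(df_res), ss_res, ss_res / ss_total, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    out = pd.DataFrame(
        rows, columns=["term", "df", "sum_of_squares", "R2", "pseudo_F", "p_value"]
    )
    out.attrs["n_permutations"] = n_used
    return out
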