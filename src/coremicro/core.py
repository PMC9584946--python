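"""Core-microbiome definition: threshold, ranked-contribution and consensus.

Three definitions of "core" taxa are computed from abundance-occupancy
statistics of a rarefied table:

* ``MRA_OCC`` — fixed thresholds: mean relative abundance above 0.1% and
  presence in more than 75% of samples, or 100% occupancy in more than ten
  studies.
* ``RANKED_BC`` / ``RANKED_WUF`` — occupancy-ranked prioritisation: OTUs are
  ranked by mean per-study occupancy and added one at a time; the fraction of
  overall beta diversity (Bray-Curtis or weighted UniFrac) explained by each
  prefix forms a contribution curve, and the core stops at the last rank
  whose marginal gain is at least 2% of the curve's total gain.
* ``CONSENSUS`` — the exact intersection of the above.

The contribution of a prefix to a sample pair's dissimilarity is the
prefix-restricted dissimilarity numerator over the full-table numerator
(for Bray-Curtis the numerator is sum|x_i - y_i| over the prefix OTUs; for
weighted UniFrac it is the branch-length-weighted L1 difference of the
prefix's subtree proportions), averaged over pairs. Holding the denominator
at its full-table value keeps the curve monotone, ending at exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .diversity import branch_embedding
from .normalization import rarefy, tss
from .table import CountTable

__all__ = [
    "abundance_occupancy",
    "core_by_threshold",
    "rank_by_occupancy",
    "ContributionCurve",
    "contribution_curve",
    "core_by_ranked_contribution",
    "consensus_core",
    "subgroup_profiles",
    "cluster_profiles",
    "CoreSet",
]


@dataclass
class CoreSet:
    """An ordered core-OTU list with per-member statistics.

    ``method`` is one of MRA_OCC, RANKED_BC, RANKED_WUF, CONSENSUS; ``stats``
    carries the abundance-occupancy rows of the members; ``params`` records
    the thresholds or stopping rule that produced the set.
    """

    method: str
    members: list[str]
    stats: pd.DataFrame = field(repr=False)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError("core members must be unique")

    def __len__(self):
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        out = self.stats.loc[self.members].copy()
        out.insert(0, "method", self.method)
        out["rank"] = np.arange(1, len(self.members) + 1)
        return out


def abundance_occupancy(
    t: CountTable,
    meta: pd.DataFrame,
    rarefy_depth: int = 5000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-OTU abundance-occupancy statistics on the rarefied table.

    Detection is a nonzero rarefied count; ``mra`` is the mean relative
    abundance over the TSS-scaled rarefied table; ``occ_samples`` is the
    detected fraction of all samples; ``mean_study_occupancy`` averages the
    per-study detected fractions; ``n_studies_full`` counts studies where the
    OTU is detected in every sample. The per-study occupancy matrix is
    attached as ``result.attrs["occ_by_study"]``.

    Studies whose samples all fall below the rarefaction depth are dropped
    with a warning.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    rar = rarefy(t, depth=rarefy_depth, seed=seed)
    missing = [s for s in rar.sample_ids if s not in meta.index]
    if missing:
        raise KeyError(f"metadata missing samples: {missing}")
    studies_before = set(meta["study"])
    meta = meta.loc[rar.sample_ids]
    dropped = studies_before - set(meta["study"])
    if dropped:
        warnings.warn(f"studies with no retained samples dropped: {sorted(dropped)}")

    rel = tss(rar).values
    detected = rar.values > 0
    study_labels = meta["study"].to_numpy()
    studies = list(dict.fromkeys(study_labels))
    occ_by_study = np.column_stack(
        [detected[:, study_labels == s].mean(axis=1) for s in studies]
    )

    out = pd.DataFrame(
        {
            "mra": rel.mean(axis=1),
            "occ_samples": detected.mean(axis=1),
            "mean_study_occupancy": occ_by_study.mean(axis=1),
            "n_studies_full": (occ_by_study == 1.0).sum(axis=1),
        },
        index=pd.Index(rar.otu_ids, name="otu_id"),
    )
    out.attrs["occ_by_study"] = pd.DataFrame(
        occ_by_study, index=out.index, columns=studies
    )
    out.attrs["n_studies"] = len(studies)
    return out


def core_by_threshold(
    ao: pd.DataFrame,
    mra_min: float = 0.001,
    occ_min: float = 0.75,
    full_study_min: int = 10,
) -> CoreSet:
    """Threshold core: MRA > ``mra_min`` and (overall occupancy > ``occ_min``
    or 100% occupancy in more than ``full_study_min`` studies).

    Both occupancy clauses are strict inequalities, as is the abundance
    clause. Members are ordered by descending MRA.
    """
    member = (ao["mra"] > mra_min) & (
        (ao["occ_samples"] > occ_min) | (ao["n_studies_full"] > full_study_min)
    )
    stats = ao[member].sort_values("mra", ascending=False, kind="mergesort")
    return CoreSet(
        method="MRA_OCC",
        members=list(stats.index),
        stats=ao,
        params={"mra_min": mra_min, "occ_min": occ_min, "full_study_min": full_study_min},
    )


def rank_by_occupancy(ao: pd.DataFrame) -> list[str]:
    """Rank OTUs by mean per-study occupancy (descending).

    Ties break by descending MRA, then lexicographic OTU id, so the ranking
    is deterministic.
    """
    if len(ao) == 0:
        raise ValueError("empty abundance-occupancy table")
    frame = ao.reset_index()
    frame = frame.sort_values(
        ["mean_study_occupancy", "mra", "otu_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return list(frame["otu_id"])


@dataclass
class ContributionCurve:
    """Explained beta-diversity fraction per prefix rank of a ranked OTU list."""

    explained: np.ndarray
    metric: str
    ranked: list[str] = field(default_factory=list, repr=False)

    def __len__(self):
        return len(self.explained)

    @property
    def gains(self) -> np.ndarray:
        return np.diff(np.concatenate([[0.0], self.explained]))


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def contribution_curve(
    t,
    ranked: list[str],
    metric: str = "bray_curtis",
    tree: TreeNode | None = None,
    max_samples: int | None = None,
    seed: int | None = None,
) -> ContributionCurve:
    """Explained beta-diversity fraction of every prefix of ``ranked``.

    ``explained[r-1]`` is the mean over sample pairs of the prefix-restricted
    dissimilarity numerator divided by the full-table numerator (pairs whose
    full numerator is zero are excluded). ``metric`` is ``bray_curtis`` or
    ``weighted_unifrac`` (the latter requires ``tree``). When ``max_samples``
    is given and the table is larger, the pair set is estimated on a seeded
    random subset of samples.
    """
    from .diversity import _matrix

    otu_ids, sample_ids, values = _matrix(t)
    extra = [o for o in ranked if o not in set(otu_ids)]
    if extra:
        raise KeyError(f"ranked OTUs absent from table: {extra}")
    if len(ranked) != len(otu_ids):
        # restrict the table to the ranked set: the curve is defined on it
        idx = pd.Index(otu_ids).get_indexer(ranked)
        values, otu_ids = values[idx], list(ranked)

    if max_samples is not None and len(sample_ids) > max_samples:
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(len(sample_ids), size=max_samples, replace=False))
        values = values[:, pick]
        sample_ids = [sample_ids[i] for i in pick]

    totals = values.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("all-zero sample in contribution computation")
    # Bray-Curtis shares use the table's values as given (rarefied counts in
    # the standard workflow); UniFrac subtree weights are defined on
    # proportions. With equalised column totals the two scalings coincide.
    props = values / totals
    order = pd.Index(otu_ids).get_indexer(ranked)
    n = len(sample_ids)
    if n < 2:
        raise ValueError("need at least 2 samples")
    ii, jj = _pair_indices(n)

    if metric == "bray_curtis":

        def numerators():
            num = np.zeros(len(ii))
            for o in order:
                num += np.abs(values[o, ii] - values[o, jj])
                yield num

    elif metric == "weighted_unifrac":
        if tree is None:
            raise ValueError("weighted_unifrac requires a tree")
        lengths, paths = branch_embedding(tree, list(otu_ids))

        def numerators():
            P = np.zeros((len(lengths), n))
            num = np.zeros(len(ii))
            for o in order:
                path = paths[o]
                old = np.abs(P[path][:, ii] - P[path][:, jj])
                P[path] += props[o]
                new = np.abs(P[path][:, ii] - P[path][:, jj])
                num += lengths[path] @ (new - old)
                yield num

    else:
        raise ValueError(f"unknown metric {metric!r}")

    # first pass establishes the full-table numerator, second normalises by it
    for num in numerators():
        pass
    full = num.copy()
    valid = full > 0
    explained = np.empty(len(ranked))
    for r, num in enumerate(numerators()):
        explained[r] = float(np.mean(num[valid] / full[valid])) if valid.any() else 1.0

    explained = np.clip(explained, 0.0, None)
    if valid.any():
        explained[-1] = 1.0  # exact by construction; guard rounding
    return ContributionCurve(explained=explained, metric=metric, ranked=list(ranked))


def core_by_ranked_contribution(
    curve: ContributionCurve,
    ranked: list[str] | None = None,
    gain_threshold: float = 0.02,
) -> CoreSet:
    """Ranked core: cut the contribution curve at its last substantial gain.

    The last included rank is the largest r whose marginal gain
    ``explained(r) - explained(r-1)`` is at least ``gain_threshold`` times the
    curve's total gain. If no rank qualifies (including the degenerate flat
    curve) the single rank with the largest gain is kept, with a warning for
    the flat case.
    """
    ranked = list(ranked) if ranked is not None else list(curve.ranked)
    if len(ranked) != len(curve):
        raise ValueError("curve and ranked list are not aligned")
    gains = curve.gains
    total = float(curve.explained[-1])
    if total <= 0:
        warnings.warn("flat contribution curve; degenerate core of one OTU")
        r = 1
    else:
        qualifying = np.flatnonzero(gains >= gain_threshold * total - 1e-12)
        if qualifying.size:
            r = int(qualifying[-1]) + 1
        else:
            r = int(np.argmax(gains)) + 1
    method = "RANKED_BC" if curve.metric == "bray_curtis" else "RANKED_WUF"
    return CoreSet(
        method=method,
        members=ranked[:r],
        stats=pd.DataFrame(index=pd.Index(ranked, name="otu_id")),
        params={"gain_threshold": gain_threshold, "last_rank": r, "metric": curve.metric},
    )


def consensus_core(cores: list[CoreSet]) -> CoreSet:
    """Exact set intersection of two or more core sets.

    Members keep the order of the first core's listing. Statistics are merged
    from whichever input carries them.
    """
    if len(cores) < 2:
        raise ValueError("consensus requires at least two core sets")
    common = set(cores[0].members)
    for core in cores[1:]:
        common &= set(core.members)
    members = [o for o in cores[0].members if o in common]
    if not members:
        warnings.warn("consensus core is empty")
    stats = None
    for core in cores:
        if not core.stats.empty and set(members) <= set(core.stats.index):
            stats = core.stats
            break
    if stats is None:
        stats = pd.DataFrame(index=pd.Index(members, name="otu_id"))
    return CoreSet(
        method="CONSENSUS",
        members=members,
        stats=stats,
        params={"inputs": [c.method for c in cores]},
    )


def subgroup_profiles(
    t,
    meta: pd.DataFrame,
    core: CoreSet,
    categories: list[str],
) -> pd.DataFrame:
    """Mean relative abundance of each core OTU at each category level.

    Returns a core-OTU x (category, level) frame of MRAs computed on the
    TSS-scaled table; levels with no samples are dropped, as are samples
    labelled unknown in the category at hand. The per-level cumulative core
    relative abundance (mean and SD over samples of the summed core fraction)
    is attached as ``result.attrs["cumulative_core"]``.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    rel = tss(t)
    frame = rel.to_dataframe()
    meta = meta.loc[[s for s in frame.columns if s in meta.index]]
    core_rows = frame.loc[[o for o in core.members if o in frame.index]]
    if core_rows.empty:
        raise ValueError("no core OTUs present in table")

    columns, cumulative = {}, {}
    for category in categories:
        levels = meta[category]
        for level in pd.unique(levels):
            if level in ("unknown",):
                continue
            samples = meta.index[levels == level]
            samples = [s for s in samples if s in frame.columns]
            if not samples:
                continue
            block = core_rows[samples]
            columns[(category, str(level))] = block.mean(axis=1)
            per_sample_total = block.sum(axis=0)
            cumulative[(category, str(level))] = (
                float(per_sample_total.mean()),
                float(per_sample_total.std(ddof=1)) if len(samples) > 1 else 0.0,
            )
    out = pd.DataFrame(columns)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["category", "level"])
    out.attrs["cumulative_core"] = cumulative
    return out


def cluster_profiles(matrix: pd.DataFrame, k: int = 4, eps: float = 1e-6) -> pd.Series:
    """Agglomerative (Ward, Euclidean) clustering of log10(MRA + eps) profiles.

    Returns integer cluster labels (1..k) indexed by OTU id.
    """
    from scipy.cluster.hierarchy import fcluster, linkage

    if k < 1 or k > len(matrix):
        raise ValueError("k must be between 1 and the number of profiles")
    logged = np.log10(matrix.to_numpy(dtype=float) + eps)
    Z = linkage(logged, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.index, name="cluster")
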