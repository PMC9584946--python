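"""Synthetic multi-study 16S count data with planted structure.

The generator emulates the statistical shape of a pooled multi-study oral
16S collection: a planted high-occupancy core carrying ~72% of reads, a
dominant multiplicative study (batch) effect, weaker host-factor effects,
a hypervariable-region detection artefact, and Dirichlet-multinomial
overdispersion at log-normal sequencing depths.

Taxa fall into three abundance-occupancy archetypes:

* **core** — high abundance, host prevalence drawn from U(0.90, 1.00);
  jointly scaled so the expected cumulative core relative abundance hits the
  target.
* **sub-core** — the oral community's "occasional dominants": individually
  abundant (~2% MRA each) but patchy (prevalence U(0.65, 0.74)), so they
  rank just below the core on occupancy and carry substantial beta-diversity
  mass without qualifying for an occupancy-threshold core.
* **rare tail** — everything else: low abundance, prevalence U(0.20, 0.70),
  and subject to region dropout (a taxon may be undetectable under one
  hypervariable-region label).

Ground truth records every planted choice so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .table import CountTable

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_tree",
    "generate_dataset",
    "random_sequences",
    "mutate_sequences",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic multi-study generator.

    ``category_effects`` maps a metadata category to (number of affected
    taxa, log2 effect size); each affected taxon is enriched by
    2**effect in one randomly chosen level of the category.
    """

    n_studies: int = 20
    samples_per_study: tuple[int, int] = (40, 40)
    n_otus: int = 900
    n_core: int = 68
    core_mra_target: float = 0.72
    n_subcore: int = 8
    subcore_mra_target: float = 0.18
    study_effect_sd: float = 0.7
    core_study_effect_sd: float = 0.25
    region_dropout: float = 0.6
    category_effects: dict = field(
        default_factory=lambda: {
            "location": (60, 2.0),
            "smoking": (30, 1.0),
            "drinking": (20, 0.5),
            "gender": (10, 0.25),
            "age_group": (20, 0.4),
        }
    )
    depth_lognormal: tuple[float, float] = (9.6, 0.35)
    concentration: float = 350.0
    core_prevalence: tuple[float, float] = (0.90, 1.00)
    subcore_prevalence: tuple[float, float] = (0.65, 0.74)
    tail_prevalence: tuple[float, float] = (0.20, 0.70)
    seed: int = 0

    def validate(self) -> None:
        if self.n_core + self.n_subcore > self.n_otus:
            raise ValueError("n_core + n_subcore must be <= n_otus")
        if not (0 <= self.region_dropout <= 1):
            raise ValueError("region_dropout must be a probability")
        n_tail = self.n_otus - self.n_core - self.n_subcore
        if self.core_mra_target + self.subcore_mra_target >= 1.0 and n_tail > 0:
            raise ValueError(
                "core and sub-core targets leave no mass for the remaining taxa"
            )
        if not (0 < self.core_mra_target <= 1):
            raise ValueError("core_mra_target must be in (0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator planted, for scoring recovery."""

    core_ids: list[str]
    subcore_ids: list[str]
    presence_prob: pd.Series = field(repr=False)
    base_composition: pd.Series = field(repr=False)
    study_bias: pd.DataFrame = field(repr=False)
    region_dropout: pd.Series = field(repr=False)
    category_effects: dict = field(repr=False)
    study_table: pd.DataFrame = field(repr=False)
    tree: TreeNode = field(repr=False)
    spec: SyntheticSpec = field(repr=False)


def generate_tree(n_leaves: int, seed: int | None = None, leaf_ids=None) -> TreeNode:
    """Random bifurcating rooted tree by sequential random attachment.

    Branch lengths are Exponential with rate 10 (mean 0.1). Deterministic for
    a fixed seed.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    if leaf_ids is None:
        leaf_ids = [f"OTU_{i + 1:04d}" for i in range(n_leaves)]
    if len(leaf_ids) != n_leaves:
        raise ValueError("leaf_ids length must equal n_leaves")

    a, b = TreeNode(name=leaf_ids[0]), TreeNode(name=leaf_ids[1])
    root = TreeNode(children=[a, b])
    attachable = [a, b]
    for name in leaf_ids[2:]:
        target = attachable[rng.integers(len(attachable))]
        parent = target.parent
        new_leaf = TreeNode(name=name)
        joint = TreeNode(children=[])
        parent.remove(target)
        joint.append(target)
        joint.append(new_leaf)
        parent.append(joint)
        attachable.extend([new_leaf, joint])
    for node in root.traverse(include_self=False):
        node.length = float(rng.exponential(scale=0.1))
    return root


def _pick_levels(rng, levels, p, size):
    return rng.choice(levels, size=size, p=p)


def _make_taxonomy(rng, otu_ids) -> pd.DataFrame:
    genus = rng.integers(0, 120, size=len(otu_ids))
    family, order = genus // 3, genus // 6
    klass, phylum = genus // 12, genus // 24
    tax = pd.DataFrame(
        {
            "phylum": [f"Phylum_{i}" for i in phylum],
            "class": [f"Class_{i}" for i in klass],
            "order": [f"Order_{i}" for i in order],
            "family": [f"Family_{i}" for i in family],
            "genus": [f"Genus_{i}" for i in genus],
            "species": [f"Species_{i}" for i in range(len(otu_ids))],
        },
        index=pd.Index(otu_ids, name="otu_id"),
    )
    unassigned = rng.random(len(otu_ids)) < 0.1
    tax.loc[unassigned, "species"] = np.nan
    return tax


def generate_dataset(spec: SyntheticSpec):
    """Generate (CountTable, metadata, taxonomy, tree, GroundTruth).

    Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_otus
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(n)]

    # archetype assignment over shuffled ids
    shuffled = rng.permutation(n)
    core_idx = np.sort(shuffled[: spec.n_core])
    subcore_idx = np.sort(shuffled[spec.n_core: spec.n_core + spec.n_subcore])
    tail_idx = np.sort(shuffled[spec.n_core + spec.n_subcore:])

    # block abundance draws; each block scaled so that, after the expected
    # host-prevalence thinning, its realised share matches its target
    base = np.zeros(n)
    base[core_idx] = rng.lognormal(0.0, 0.30, size=len(core_idx))
    base[subcore_idx] = rng.lognormal(0.0, 0.25, size=len(subcore_idx))
    if len(tail_idx):
        base[tail_idx] = rng.lognormal(0.0, 1.0, size=len(tail_idx))

    presence = np.ones(n)
    presence[core_idx] = rng.uniform(*spec.core_prevalence, size=len(core_idx))
    presence[subcore_idx] = rng.uniform(*spec.subcore_prevalence, size=len(subcore_idx))
    if len(tail_idx):
        presence[tail_idx] = rng.uniform(*spec.tail_prevalence, size=len(tail_idx))

    tail_target = 1.0 - spec.core_mra_target - spec.subcore_mra_target
    for idx, target in (
        (core_idx, spec.core_mra_target),
        (subcore_idx, spec.subcore_mra_target),
        (tail_idx, tail_target),
    ):
        if len(idx) == 0:
            continue
        effective = (base[idx] * presence[idx]).sum()
        base[idx] *= target / effective

    # study-level structure
    studies = [f"study_{i + 1:02d}" for i in range(spec.n_studies)]
    study_region = _pick_levels(
        rng, np.array(["V3V4", "V4", "others"]), [0.45, 0.45, 0.10], spec.n_studies
    )
    study_location = _pick_levels(
        rng,
        np.array(["NorthAmerica", "Europe", "China", "others"]),
        [0.35, 0.30, 0.25, 0.10],
        spec.n_studies,
    )
    study_sample_type = _pick_levels(
        rng,
        np.array(["spit", "mouthwash", "oral_rinse", "others"]),
        [0.5, 0.2, 0.2, 0.1],
        spec.n_studies,
    )
    study_table = pd.DataFrame(
        {
            "study": studies,
            "region": study_region,
            "location": study_location,
            "sample_type": study_sample_type,
        }
    ).set_index("study")
    # rare taxa feel the between-study (protocol/batch) effect much more
    # strongly than dominant ones; core taxa get a damped bias so their
    # detection stays near-certain in every study
    bias_sd = np.full(n, spec.study_effect_sd)
    bias_sd[core_idx] = spec.core_study_effect_sd
    study_bias = pd.DataFrame(
        np.exp(rng.normal(0.0, 1.0, size=(spec.n_studies, n)) * bias_sd),
        index=studies,
        columns=otu_ids,
    )

    # region dropout: a tail taxon may be undetectable under one region label
    dropout_region = pd.Series([None] * n, index=otu_ids, dtype=object)
    if len(tail_idx):
        hit = rng.random(len(tail_idx)) < spec.region_dropout
        choices = rng.choice(["V3V4", "V4"], size=len(tail_idx))
        for i, h, c in zip(tail_idx, hit, choices):
            if h:
                dropout_region.iloc[i] = c

    # planted host/technical category effects on detectable taxa
    level_space = {
        "location": ["NorthAmerica", "Europe", "China"],
        "smoking": ["smoker", "non_smoker"],
        "drinking": ["drinker", "non_drinker"],
        "gender": ["male", "female"],
        "age_group": ["18-30", "31-55", "56+"],
        "region": ["V3V4", "V4"],
        "sample_type": ["spit", "mouthwash", "oral_rinse"],
    }
    detectable = np.argsort(-base)[: min(300, n)]
    effects: dict[str, pd.DataFrame] = {}
    for category, (n_affected, log2_effect) in spec.category_effects.items():
        if category not in level_space:
            raise ValueError(f"no level space for category {category!r}")
        chosen = rng.choice(detectable, size=min(n_affected, len(detectable)), replace=False)
        levels = rng.choice(level_space[category], size=len(chosen))
        effects[category] = pd.DataFrame(
            {
                "otu_id": [otu_ids[i] for i in chosen],
                "level": levels,
                "multiplier": 2.0**log2_effect,
            }
        )

    # per-sample metadata
    lo, hi = spec.samples_per_study
    sizes = rng.integers(lo, hi + 1, size=spec.n_studies)
    rows = []
    for s, size in zip(studies, sizes):
        for k in range(size):
            rows.append(
                {
                    "sample_id": f"{s}.s{k + 1:03d}",
                    "study": s,
                    "location": study_table.loc[s, "location"],
                    "region": study_table.loc[s, "region"],
                    "sample_type": study_table.loc[s, "sample_type"],
                    "gender": rng.choice(
                        ["male", "female", "unknown"], p=[0.48, 0.48, 0.04]
                    ),
                    "age_group": rng.choice(
                        ["18-30", "31-55", "56+", "unknown"], p=[0.35, 0.40, 0.15, 0.10]
                    ),
                    "smoking": rng.choice(
                        ["smoker", "non_smoker", "unknown"], p=[0.25, 0.65, 0.10]
                    ),
                    "drinking": rng.choice(
                        ["drinker", "non_drinker", "unknown"], p=[0.35, 0.50, 0.15]
                    ),
                }
            )
    meta = pd.DataFrame(rows)

    # effect lookup: category -> level -> multiplier vector over taxa
    effect_vectors: dict[tuple[str, str], np.ndarray] = {}
    for category, frame in effects.items():
        for level in frame["level"].unique():
            vec = np.ones(n)
            sub = frame[frame["level"] == level]
            vec[[otu_ids.index(o) for o in sub["otu_id"]]] = sub["multiplier"].to_numpy()
            effect_vectors[(category, level)] = vec

    # expected per-sample mean vectors (host presence, study bias, planted
    # effects, region dropout all applied)
    region_mask = {}
    for region in ("V3V4", "V4"):
        region_mask[region] = (dropout_region == region).to_numpy()
    means = np.zeros((n, len(meta)))
    for j, row in enumerate(meta.itertuples(index=False)):
        mean = base * study_bias.loc[row.study].to_numpy()
        for category in effects:
            key = (category, getattr(row, category))
            if key in effect_vectors:
                mean = mean * effect_vectors[key]
        if row.region in region_mask:
            mean = np.where(region_mask[row.region], 0.0, mean)
        mask = rng.random(n) < presence
        means[:, j] = np.where(mask, mean, 0.0)

    # calibrate the core block so the expected cumulative core share equals
    # the target exactly under everything the mechanisms above did to it
    core_mass = means[core_idx].sum(axis=0)
    other_mass = means.sum(axis=0) - core_mass
    ok = (core_mass > 0) & (other_mass > 0)

    def mean_share(scale: float) -> float:
        return float(
            np.mean(scale * core_mass[ok] / (scale * core_mass[ok] + other_mass[ok]))
        )

    lo_s, hi_s = 1e-3, 1e3
    for _ in range(80):  # bisection; share is monotone in the scale
        mid = 0.5 * (lo_s + hi_s)
        if mean_share(mid) < spec.core_mra_target:
            lo_s = mid
        else:
            hi_s = mid
    means[core_idx] *= 0.5 * (lo_s + hi_s)
    base[core_idx] *= 0.5 * (lo_s + hi_s)
    composition = pd.Series(base, index=otu_ids, name="base_composition")

    # Dirichlet-multinomial draws at log-normal depths
    mu, sd = spec.depth_lognormal
    counts = np.zeros((n, len(meta)), dtype=np.int64)
    for j in range(len(meta)):
        alive = np.flatnonzero(means[:, j])
        if alive.size == 0:  # pragma: no cover - essentially impossible
            continue
        alpha = means[alive, j] / means[alive, j].sum() * spec.concentration
        p = rng.dirichlet(alpha)
        depth = max(1, int(round(float(rng.lognormal(mu, sd)))))
        counts[alive, j] = rng.multinomial(depth, p)

    table = CountTable(otu_ids, list(meta["sample_id"]), counts)
    taxonomy = _make_taxonomy(rng, otu_ids)
    tree = generate_tree(n, seed=int(rng.integers(0, 2**31 - 1)), leaf_ids=otu_ids)
    truth = GroundTruth(
        core_ids=[otu_ids[i] for i in core_idx],
        subcore_ids=[otu_ids[i] for i in subcore_idx],
        presence_prob=pd.Series(presence, index=otu_ids),
        base_composition=composition,
        study_bias=study_bias,
        region_dropout=dropout_region,
        category_effects=effects,
        study_table=study_table,
        tree=tree,
        spec=spec,
    )
    return table, meta, taxonomy, tree, truth


def random_sequences(ids, length: int = 250, seed: int | None = None) -> dict[str, str]:
    """Uniform-random nucleotide sequences keyed by ``ids``."""
    rng = np.random.default_rng(seed)
    return {i: "".join(rng.choice(_BASES, size=length)) for i in ids}


def mutate_sequences(
    refs: dict[str, str], divergence: float, seed: int | None = None
) -> dict[str, str]:
    """Substitute ``round(divergence * length)`` positions per sequence.

    Positions are chosen uniformly without replacement; each substituted base
    becomes one of the three other bases, uniformly.
    """
    if not (0.0 <= divergence <= 0.5):
        raise ValueError("divergence must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    out = {}
    for sid, seq in refs.items():
        chars = np.array(list(seq))
        k = int(round(divergence * len(chars)))
        if k:
            pos = rng.choice(len(chars), size=k, replace=False)
            for p in pos:
                alternatives = _BASES[_BASES != chars[p]]
                chars[p] = alternatives[rng.integers(3)]
        out[sid] = "".join(chars)
    return out
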