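"""The four normalisations compared throughout the meta-analysis.

RAR  — rarefaction: uniform subsampling without replacement to a fixed depth
       (multivariate hypergeometric, the QIIME2/vegan convention).
TSS  — total-sum scaling: per-sample relative abundance.
RRA  — rarefied total-sum scaling: TSS applied to the rarefied table.
CLR  — centred log-ratio after count-zero-multiplicative (CZM) zero
       replacement: zeros in a sample with total N are imputed as
       delta * (1/N) with delta = 0.65 (the zCompositions default), the
       non-zero parts are rescaled so the composition stays closed, and the
       result is log-ratio transformed against its geometric mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .table import CountTable

__all__ = ["NormalisedTable", "rarefy", "tss", "rra", "clr_czm"]


@dataclass
class NormalisedTable:
    """Real-valued OTU x sample matrix produced by one of the normalisations."""

    otu_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)
    method: str = "TSS"
    depth: int | None = None
    seed: int | None = None

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.sample_ids)


def _as_matrix(t) -> tuple[list[str], list[str], np.ndarray]:
    if isinstance(t, CountTable):
        return list(t.otu_ids), list(t.sample_ids), t.counts.astype(np.float64)
    return list(t.otu_ids), list(t.sample_ids), np.asarray(t.values, dtype=np.float64)


def rarefy(t: CountTable, depth: int = 5000, seed: int | None = None) -> NormalisedTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total falls below ``depth`` are dropped with a warning.
    Reproducible for a fixed ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = t.sample_sums()
    keep = totals >= depth
    dropped = [s for s, k in zip(t.sample_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"{len(dropped)} sample(s) below rarefaction depth {depth} dropped"
        )
    kept_ids = [s for s, k in zip(t.sample_ids, keep) if k]
    out = np.zeros((t.n_otus, len(kept_ids)), dtype=np.int64)
    j = 0
    for i, k in enumerate(keep):
        if not k:
            continue
        column = t.counts[:, i]
        if totals[i] == depth:
            out[:, j] = column
        else:
            out[:, j] = rng.multivariate_hypergeometric(column, depth)
        j += 1
    return NormalisedTable(
        list(t.otu_ids), kept_ids, out, method="RAR", depth=depth, seed=seed
    )


def tss(t) -> NormalisedTable:
    """Total-sum scaling: each column divided by its total."""
    otu_ids, sample_ids, values = _as_matrix(t)
    totals = values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"zero-sum sample(s): {[sample_ids[i] for i in zero]}")
    return NormalisedTable(otu_ids, sample_ids, values / totals, method="TSS")


def rra(t: CountTable, depth: int = 5000, seed: int | None = None) -> NormalisedTable:
    """Rarefied total-sum scaling: TSS of the rarefied table."""
    r = rarefy(t, depth=depth, seed=seed)
    out = tss(r)
    out.method = "RRA"
    out.depth = depth
    out.seed = seed
    return out


def clr_czm(t: CountTable, delta: float = 0.65) -> NormalisedTable:
    """Centred log-ratio transform with CZM zero replacement.

    Per sample with total N and Z zero entries: each zero becomes
    ``delta / N`` of the composition, the non-zero proportions are multiplied
    by ``1 - Z * delta / N``, and the column is then clr-transformed
    (log of each part over the column's geometric mean; columns sum to 0).
    """
    otu_ids, sample_ids, counts = _as_matrix(t)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        bad = [sample_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"all-zero sample(s): {bad}")
    props = counts / totals
    zeros = counts == 0
    repl = delta / totals  # per-column replacement value
    adjust = 1.0 - zeros.sum(axis=0) * repl
    if np.any(adjust <= 0):
        raise ValueError("zero replacement exceeds unit mass; lower delta")
    comp = np.where(zeros, repl[None, :], props * adjust[None, :])
    logc = np.log(comp)
    clr = logc - logc.mean(axis=0, keepdims=True)
    return NormalisedTable(otu_ids, sample_ids, clr, method="CLR")
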