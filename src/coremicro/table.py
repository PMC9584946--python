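"""OTU-by-sample count tables: container, I/O and count-level inclusion filters.

The count table is the central object of a multi-study 16S meta-analysis:
an integer matrix of OTU read counts (rows) per sample (columns), carrying
aligned identifier lists. Two on-disk dialects are supported — tab-separated
text (OTUs as rows, first column ``otu_id``, header row of sample ids) and
BIOM-JSON v1.0. The TSV orientation is fixed and never auto-detected, so a
table can never be silently transposed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "read_count_table",
    "write_count_table",
    "filter_samples_min_reads",
    "filter_features",
    "collapse_taxonomy",
    "RANKS",
    "UNASSIGNED",
]

#: taxonomic ranks accepted by :func:`collapse_taxonomy`
RANKS = ("phylum", "class", "order", "family", "genus", "species")

#: sentinel label that pools OTUs lacking an assignment at the collapsed rank
UNASSIGNED = "unassigned"


def _check_unique(ids, what):
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} ids: {dupes}")


@dataclass
class CountTable:
    """Integer OTU x sample count matrix with aligned identifier lists.

    Parameters
    ----------
    otu_ids : sequence of str
        Row identifiers, unique.
    sample_ids : sequence of str
        Column identifiers, unique.
    counts : ndarray of shape (n_otus, n_samples)
        Non-negative integer read counts.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.otu_ids = [str(i) for i in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.otu_ids, "OTU")
        _check_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integral")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)

    # -- basic accessors -------------------------------------------------

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def otu_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_otus(self, otu_ids) -> "CountTable":
        idx = pd.Index(self.otu_ids).get_indexer(list(otu_ids))
        if (idx < 0).any():
            missing = [o for o, i in zip(otu_ids, idx) if i < 0]
            raise KeyError(f"OTUs not in table: {missing}")
        return CountTable(list(otu_ids), list(self.sample_ids), self.counts[idx])

    def select_samples(self, sample_ids) -> "CountTable":
        idx = pd.Index(self.sample_ids).get_indexer(list(sample_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(sample_ids, idx) if i < 0]
            raise KeyError(f"samples not in table: {missing}")
        return CountTable(list(self.otu_ids), list(sample_ids), self.counts[:, idx])

    def __eq__(self, other):
        return (
            isinstance(other, CountTable)
            and self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


# -- I/O -----------------------------------------------------------------


def _read_tsv(path) -> CountTable:
    # check the header ourselves: pandas silently renames duplicate columns
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample")
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"malformed TSV count table {path!r}: {exc}") from exc
    _check_unique(df.index, "OTU")
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric count in {path!r}: {exc}") from exc
    if np.any(values < 0):
        bad = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at OTU {df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
        )
    if not np.all(np.equal(np.mod(values, 1), 0)):
        bad = np.argwhere(np.mod(values, 1) != 0)[0]
        raise ValueError(
            f"non-integer count at OTU {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r}"
        )
    return CountTable(list(df.index), list(df.columns), values.astype(np.int64))


def _read_biom_json(path) -> CountTable:
    import biom

    with open(path) as fh:
        payload = fh.read()
    try:
        tbl = biom.parse.parse_biom_table(payload)
    except Exception as exc:
        raise ValueError(f"malformed BIOM-JSON {path!r}: {exc}") from exc
    counts = np.asarray(tbl.matrix_data.todense())
    return CountTable(
        [str(i) for i in tbl.ids("observation")],
        [str(s) for s in tbl.ids("sample")],
        counts,
    )


def read_count_table(path, format: str = "tsv") -> CountTable:
    """Read a count table from ``path`` in the named dialect.

    ``format`` is ``"tsv"`` (OTUs as rows, samples as columns, header row of
    sample ids, first column ``otu_id``) or ``"biom_json"`` (BIOM v1.0).
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom_json":
        return _read_biom_json(path)
    raise ValueError(f"unknown count-table format {format!r}")


def write_count_table(t: CountTable, path, format: str = "tsv") -> None:
    """Write ``t`` to ``path`` in the named dialect (see read_count_table)."""
    if format == "tsv":
        df = t.to_dataframe()
        df.index.name = "otu_id"
        df.to_csv(path, sep="\t")
    elif format == "biom_json":
        import biom

        tbl = biom.Table(t.counts, t.otu_ids, t.sample_ids)
        with open(path, "w") as fh:
            fh.write(tbl.to_json("coremicro"))
    else:
        raise ValueError(f"unknown count-table format {format!r}")


# -- count-level inclusion filters ----------------------------------------


def filter_samples_min_reads(t: CountTable, floor: int = 2000) -> CountTable:
    """Drop samples with fewer than ``floor`` total reads.

    Samples with column sum >= ``floor`` are retained (OTU rows are kept even
    if they become all-zero). The 2000-read default is the usual floor for
    merged 16S study collections.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    keep = t.sample_sums() >= floor
    if not keep.any():
        warnings.warn("all samples fall below the read floor; returning empty table")
    kept = [s for s, k in zip(t.sample_ids, keep) if k]
    return CountTable(list(t.otu_ids), kept, t.counts[:, keep])


def filter_features(t: CountTable, min_total: int = 11, min_samples: int = 2) -> CountTable:
    """Drop low-frequency features.

    Retains OTUs whose total count across samples is >= ``min_total`` AND
    which are detected (count > 0) in >= ``min_samples`` samples. Defaults
    implement the "frequency <= 10 or detected in a single sample" exclusion:
    total >= 11 and detection in >= 2 samples.
    """
    if min_total < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    totals = t.otu_sums()
    prevalence = (t.counts > 0).sum(axis=1)
    keep = (totals >= min_total) & (prevalence >= min_samples)
    kept = [o for o, k in zip(t.otu_ids, keep) if k]
    return CountTable(kept, list(t.sample_ids), t.counts[keep])


def collapse_taxonomy(t: CountTable, tax: pd.DataFrame, rank: str) -> CountTable:
    """Sum OTU rows into taxa at ``rank``.

    ``tax`` is a DataFrame indexed by otu_id with columns for the six ranks
    (phylum..species); missing/NaN/empty entries at ``rank`` are pooled under
    the ``unassigned`` sentinel. Per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    missing = [o for o in t.otu_ids if o not in tax.index]
    if missing:
        raise KeyError(f"taxonomy missing OTUs: {missing}")
    labels = tax.loc[t.otu_ids, rank]
    labels = labels.where(labels.notna() & (labels.astype(str).str.len() > 0), UNASSIGNED)
    labels = labels.astype(str).to_numpy()
    order = list(dict.fromkeys(labels))  # first-appearance order, deterministic
    rows = np.zeros((len(order), t.n_samples), dtype=np.int64)
    index = {lab: i for i, lab in enumerate(order)}
    for lab, row in zip(labels, t.counts):
        rows[index[lab]] += row
    return CountTable(order, list(t.sample_ids), rows)
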