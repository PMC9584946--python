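"""Independent-cohort validation of a defined core.

A new cohort arrives as denoised exact sequence variants (ZOTUs). Each ZOTU
is affiliated to its originating core OTU by global pairwise alignment
identity; the cumulative relative abundance of the affiliated rows measures
how prevalent the previously defined core is in the new cohort; and a
classifier trained on the original genus-level profiles can be applied to
the new cohort after reconciling the feature spaces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import Align

from .normalization import tss
from .table import CountTable

__all__ = ["affiliate_zotus", "core_prevalence", "transfer_predict"]


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def alignment_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None):
    """Global-alignment identity: matches / alignment columns (gaps count)."""
    aligner = aligner or _aligner()
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns, columns


def affiliate_zotus(
    zotus: dict[str, str],
    core_refs: dict[str, str],
    identity_min: float = 0.97,
) -> pd.DataFrame:
    """Affiliate each ZOTU to its best-matching core reference sequence.

    Every ZOTU is globally aligned (match +1, mismatch -1, gap open -2,
    extend -1) against every reference; identity is matches over alignment
    columns. A ZOTU is assigned to the reference of highest identity if that
    identity reaches ``identity_min``; exact ties go to the lexicographically
    smallest reference id. Returns a frame indexed by zotu_id with columns
    assigned_otu_id (None when unassigned), identity and alignment_length.
    """
    if not core_refs:
        raise ValueError("empty core reference set")
    aligner = _aligner()
    ref_ids = sorted(core_refs)
    rows = []
    for zid, zseq in zotus.items():
        best_id, best_identity, best_len = None, -1.0, 0
        for rid in ref_ids:
            identity, columns = alignment_identity(zseq, core_refs[rid], aligner)
            if identity > best_identity + 1e-12:
                best_id, best_identity, best_len = rid, identity, columns
        assigned = best_id if best_identity >= identity_min - 1e-12 else None
        rows.append((zid, assigned, best_identity, best_len))
    return pd.DataFrame(
        rows, columns=["zotu_id", "assigned_otu_id", "identity", "alignment_length"]
    ).set_index("zotu_id")


def core_prevalence(t, core) -> pd.DataFrame:
    """Cumulative relative abundance of core-affiliated rows per sample.

    ``core`` is a CoreSet, an id list, or an affiliation frame from
    :func:`affiliate_zotus` (its assigned rows are used). Input counts are
    TSS-normalised internally, so raw and relative tables give identical
    results. Returns per-sample fractions; mean and SD are attached as
    ``result.attrs["mean"]`` / ``attrs["sd"]``.
    """
    if isinstance(t, CountTable):
        t = tss(t)
    frame = t.to_dataframe()
    if hasattr(core, "members"):
        wanted = list(core.members)
    elif isinstance(core, pd.DataFrame) and "assigned_otu_id" in core.columns:
        wanted = list(core.index[core["assigned_otu_id"].notna()])
    else:
        wanted = list(core)
    rows = [o for o in wanted if o in frame.index]
    if not rows:
        raise ValueError("no core-affiliated rows present in table")
    # guard against unnormalised numeric input (e.g. CLR): require proportions
    per_sample = frame.loc[rows].sum(axis=0) / frame.sum(axis=0)
    out = per_sample.rename("core_fraction").to_frame()
    out.attrs["mean"] = float(per_sample.mean())
    out.attrs["sd"] = float(per_sample.std(ddof=1)) if len(per_sample) > 1 else 0.0
    return out


def transfer_predict(model, train_features: list[str], test) -> dict:
    """Apply a classifier trained on one cohort to another cohort's table.

    ``test`` rows are reconciled to ``train_features``: taxa unseen in
    training are dropped, training taxa missing from the test cohort are
    zero-filled. Counts are TSS-normalised. Returns per-sample predicted
    labels, vote fractions, accuracy/AUC slots left as None until labels are
    supplied via :func:`score_transfer`.
    """
    if isinstance(test, CountTable):
        test = tss(test)
    frame = test.to_dataframe()
    overlap = [f for f in train_features if f in frame.index]
    if not overlap:
        raise ValueError("zero feature overlap between training and test tables")
    X = frame.reindex(train_features).fillna(0.0).to_numpy().T
    votes = model.predict_proba(X)
    labels = model.classes_[np.argmax(votes, axis=1)]
    return {
        "sample_ids": list(frame.columns),
        "predicted": pd.Series(labels, index=frame.columns, name="predicted"),
        "votes": pd.DataFrame(votes, index=frame.columns, columns=model.classes_),
        "n_features_overlap": len(overlap),
    }


def score_transfer(prediction: dict, truth: pd.Series) -> dict:
    """Accuracy and ROC AUC of a transfer prediction against true labels.

    AUC uses the positive-class vote fraction and is None when undefined
    (single-sample test set or a single true class).
    """
    from sklearn.metrics import roc_auc_score

    y_true = truth.loc[prediction["sample_ids"]]
    accuracy = float((prediction["predicted"] == y_true).mean())
    classes = list(prediction["votes"].columns)
    auc = None
    if len(y_true) > 1 and y_true.nunique() == 2 and len(classes) == 2:
        auc = float(roc_auc_score(y_true == classes[1], prediction["votes"][classes[1]]))
    return {"accuracy": accuracy, "auc": auc}
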