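"""Threshold-gated identification and consistency metrics.

A specimen is *assigned* to the group with its highest posterior
membership probability only when that probability strictly exceeds the
chosen threshold (0.95 or 0.99 in the standard protocol; ``None`` assigns
every specimen to its argmax). Specimens failing the threshold are
discarded, and by default still count in the denominator of the
consistency rate, so raising the threshold trades identified fraction for
confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import BandAreaVector, LandmarkConfiguration, ReferenceLibrary
from .dapc import posterior_memberships
from .procrustes import align_to_consensus

STANDARD_THRESHOLDS = (None, 0.95, 0.99)


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of thresholding one specimen's PGMP row."""

    specimen_id: str
    best_group: str
    best_pgmp: float
    threshold: float | None
    status: str  # 'assigned' | 'unassigned'
    consistent: bool | None = None  # vs. prior label, when known

    @property
    def assigned(self) -> bool:
        return self.status == "assigned"


def apply_threshold(pgmp_row, threshold: float | None) -> AssignmentResult:
    """Threshold one PGMP row (a pandas Series named by specimen, or a
    mapping group → probability).

    The best group is the argmax; assignment requires a strict ``>``
    against the threshold. An exact tie on the argmax leaves the specimen
    unassigned (no unique best group).
    """
    if not isinstance(pgmp_row, pd.Series):
        pgmp_row = pd.Series(pgmp_row)
    values = pgmp_row.to_numpy(dtype=float)
    best_idx = int(values.argmax())
    best = float(values[best_idx])
    tie = int(np.sum(values == best)) > 1
    ok = (threshold is None or best > threshold) and not tie
    return AssignmentResult(
        specimen_id=str(pgmp_row.name) if pgmp_row.name is not None else "",
        best_group=str(pgmp_row.index[best_idx]),
        best_pgmp=best,
        threshold=threshold,
        status="assigned" if ok else "unassigned",
    )


def assign_table(pgmp: pd.DataFrame, threshold: float | None) -> list[AssignmentResult]:
    """Apply :func:`apply_threshold` to every row of a PGMP table."""
    return [apply_threshold(row, threshold) for _, row in pgmp.iterrows()]


def consistency_rate(
    results,
    prior_labels,
    per_group: bool = False,
    denominator: str = "all",
):
    """Proportion of consistently assigned specimens.

    A specimen counts in the numerator when it is assigned *and* its best
    group matches the prior label. The default denominator is all
    specimens in the stratum, so discarded (unassigned) specimens count
    against the rate; ``denominator='assigned'`` restricts to assigned
    specimens only.

    With ``per_group=True`` returns a Series of rates by prior label.
    """
    if denominator not in ("all", "assigned"):
        raise ValueError("denominator must be 'all' or 'assigned'")
    results = list(results)
    if isinstance(prior_labels, pd.Series):
        labels = [prior_labels.loc[r.specimen_id] for r in results]
    else:
        labels = list(prior_labels)
    if len(labels) != len(results):
        raise ValueError("one prior label per result is required")
    if any(lab is None or (isinstance(lab, float) and np.isnan(lab)) for lab in labels):
        raise ValueError("missing prior label")

    rows = pd.DataFrame(
        {
            "prior": [str(lab) for lab in labels],
            "hit": [r.assigned and r.best_group == str(lab)
                    for r, lab in zip(results, labels)],
            "assigned": [r.assigned for r in results],
        }
    )
    if per_group:
        grouped = rows.groupby("prior")
        if denominator == "all":
            return grouped["hit"].mean()
        out = grouped.apply(
            lambda d: d["hit"].sum() / d["assigned"].sum() if d["assigned"].any() else 0.0,
            include_groups=False,
        )
        return out
    if denominator == "all":
        return float(rows["hit"].mean())
    n_assigned = int(rows["assigned"].sum())
    return float(rows["hit"].sum() / n_assigned) if n_assigned else 0.0


def consistency_by_threshold(
    pgmp: pd.DataFrame,
    prior_labels,
    thresholds=STANDARD_THRESHOLDS,
    per_group: bool = False,
) -> pd.DataFrame:
    """Consistency rates across assignment thresholds (diagnostic table)."""
    records = {}
    for thr in thresholds:
        res = assign_table(pgmp, thr)
        rate = consistency_rate(res, prior_labels, per_group=per_group)
        key = "none" if thr is None else f"{thr:g}"
        records[key] = rate
    if per_group:
        return pd.DataFrame(records)
    return pd.DataFrame({"threshold": list(records), "consistency": list(records.values())})


def identify(
    library: ReferenceLibrary,
    query,
    threshold: float | None = 0.95,
    sex: str | None = None,
) -> AssignmentResult:
    """Diagnose one unknown specimen against a frozen reference library.

    Landmark queries are normalized (left wings auto-reflected) and
    rotated onto the library's stored consensus — ordinary, not
    generalized, superimposition, so library features never change.
    Area queries are used as-is (the model centres internally). The query
    must match the library's feature kind, landmark count and sex stratum.
    """
    if sex is not None and sex != library.sex:
        raise ValueError(
            f"sex-stratum mismatch: query is {sex!r}, library is {library.sex!r}"
        )
    if isinstance(query, LandmarkConfiguration):
        if library.feature_kind != "landmarks":
            raise ValueError("landmark query against a non-landmark library")
        if library.consensus is None:
            raise ValueError("landmark library lacks a consensus configuration")
        aligned = align_to_consensus(query, library.consensus)
        features = aligned.reshape(1, -1)
        qid = query.specimen_id
    elif isinstance(query, BandAreaVector):
        if library.feature_kind != "areas":
            raise ValueError("area query against a non-area library")
        features = query.areas.reshape(1, -1)
        qid = query.specimen_id
    else:
        features = np.atleast_2d(np.asarray(query, dtype=float))
        qid = "query"
    pgmp = posterior_memberships(library.model, features, specimen_ids=[qid])
    return apply_threshold(pgmp.iloc[0], threshold)
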