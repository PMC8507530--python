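"""In-silico confirmation of internal DE calls against external datasets.

External studies of the same tumor type publish feature-level log2
tumor/normal ratios (or sample-level log2 matrices that reduce to a
median ratio).  A feature is externally 'up' when its ratio exceeds the
threshold (+1.0 by default), 'down' below the negative threshold, else
'unchanged'; an internal call is confirmed when the directions agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .differential import DEResult

__all__ = [
    "ConcordanceRecord",
    "classify_log2_ratio",
    "confirm_against_external",
    "summarize_external_matrix",
]


@dataclass
class ConcordanceRecord:
    feature_id: str
    internal_direction: str  # up | down
    external_log2_ratio: float
    external_call: str  # up | down | unchanged
    confirmed: bool


def classify_log2_ratio(value: float, threshold: float = 1.0) -> str:
    """'up' iff value > threshold, 'down' iff value < -threshold (strict),
    else 'unchanged'.  Exactly +-threshold is inside the unchanged band."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if not np.isfinite(value):
        raise ValueError(f"ratio must be finite, got {value!r}")
    if value > threshold:
        return "up"
    if value < -threshold:
        return "down"
    return "unchanged"


def confirm_against_external(
    internal: list[DEResult],
    external: Mapping[str, float],
    threshold: float = 1.0,
) -> tuple[list[ConcordanceRecord], dict]:
    """Check internal up/down calls against external log2 ratios.

    Only internally significant features (regulation != 'ns') are
    checked.  Returns the per-feature records plus a summary with
    confirmed counts by direction and the features absent from the
    external table.  Zero overlap is an error.
    """
    called = [r for r in internal if r.regulation in ("up", "down")]
    records: list[ConcordanceRecord] = []
    absent: list[str] = []
    for r in called:
        if r.feature_id not in external:
            absent.append(r.feature_id)
            continue
        ratio = float(external[r.feature_id])
        call = classify_log2_ratio(ratio, threshold)
        records.append(ConcordanceRecord(
            feature_id=r.feature_id,
            internal_direction=r.regulation,
            external_log2_ratio=ratio,
            external_call=call,
            confirmed=call == r.regulation,
        ))
    if not records:
        raise ValueError("no overlap between internal calls and external table")
    summary = {
        "n_checked": len(records),
        "confirmed_up": sum(1 for r in records
                            if r.confirmed and r.internal_direction == "up"),
        "confirmed_down": sum(1 for r in records
                              if r.confirmed and r.internal_direction == "down"),
        "checked_up": sum(1 for r in records if r.internal_direction == "up"),
        "checked_down": sum(1 for r in records if r.internal_direction == "down"),
        "absent_features": absent,
    }
    return records, summary


def summarize_external_matrix(
    external_expr: pd.DataFrame,
    reference: Mapping[str, float] | str = "pooled_reference",
    tumor_samples: list[str] | None = None,
) -> dict[str, float]:
    """Reduce a sample-level log2 matrix to one ratio per feature.

    With a mapping ``reference`` (feature -> pooled-reference log2 value),
    the ratio is median over tumor samples of (log2 tumor - log2
    reference).  With reference='per_sample_ratio' the matrix already
    holds per-sample log2 ratios and only the median is taken.
    """
    cols = tumor_samples if tumor_samples is not None else list(external_expr.columns)
    if not cols:
        raise ValueError("no tumor samples")
    sub = external_expr[cols]
    if isinstance(reference, str):
        if reference != "per_sample_ratio":
            raise ValueError(
                "reference must be a feature->log2 mapping or 'per_sample_ratio'"
            )
        med = sub.median(axis=1)
        return {f: float(v) for f, v in med.items() if np.isfinite(v)}
    out: dict[str, float] = {}
    for f in sub.index:
        if f not in reference:
            continue
        ratios = sub.loc[f] - float(reference[f])
        v = float(ratios.median())
        if np.isfinite(v):
            out[f] = v
    if not out:
        raise ValueError("reference covers no feature of the matrix")
    return out
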