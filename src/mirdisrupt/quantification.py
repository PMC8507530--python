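"""CT tables -> -dCT expression matrices and 2^-ddCT fold changes.

Covers the quantification chain of a paired qRT-PCR study: technical
replicate aggregation, the CT usability filter, model-based reference-gene
stability selection, endogenous-control normalisation (dCT) and the
comparative-CT (2^-ddCT) fold change per patient pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CtRecord, ExpressionMatrix, PairedDesign

__all__ = [
    "StabilityResult",
    "FoldChangeRecord",
    "aggregate_replicates",
    "filter_by_ct",
    "normfinder_stability",
    "delta_ct",
    "fold_change_ddct",
    "ct_records_to_frame",
]


@dataclass
class StabilityResult:
    """Model-based stability of one candidate reference gene.

    Lower stability_value = more stable.  intra_group_var holds the
    residual variance per group after removing the per-sample average
    across candidates; inter_group_dev is the gene's deviation of the
    between-group expression difference from the candidate average.
    """

    feature_id: str
    stability_value: float
    intra_group_var: dict[str, float]
    inter_group_dev: dict[str, float]
    rank: int = 0
    best_pair: tuple[str, str] | None = None


@dataclass
class FoldChangeRecord:
    """Per-feature comparative-CT fold change over patient pairs."""

    feature_id: str
    per_pair_fc: list[float]
    fc_mean: float
    fc_sd: float
    direction: str  # up | down

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.per_pair_fc) or self.fc_mean <= 0:
            raise ValueError("fold changes must be positive")


def ct_records_to_frame(records: list[CtRecord]) -> pd.DataFrame:
    """Aggregated-CT records -> assays x samples DataFrame (NaN = missing)."""
    cells: dict[str, dict[str, float]] = {}
    for r in records:
        cells.setdefault(r.assay_id, {})[r.sample_id] = (
            np.nan if r.aggregated_ct is None else r.aggregated_ct
        )
    return pd.DataFrame(cells).T.sort_index()


def aggregate_replicates(
    records: list[CtRecord], method: str = "mean"
) -> list[CtRecord]:
    """Fill aggregated_ct from the technical replicates (mean or median).

    Replicate values are retained for audit; records without replicates
    stay missing.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown aggregation method {method!r}")
    agg = np.mean if method == "mean" else np.median
    out: list[CtRecord] = []
    for r in records:
        value = float(agg(r.replicate_values)) if r.replicate_values else None
        out.append(
            CtRecord(r.assay_id, r.sample_id, list(r.replicate_values), value)
        )
    return out


def filter_by_ct(
    records: list[CtRecord], max_ct: float
) -> tuple[list[CtRecord], list[dict]]:
    """Keep records with aggregated CT strictly below max_ct.

    High CT means the transcript amplified too late to be quantified
    reliably; the cut is strict ("lower than"), so CT == max_ct drops.
    Missing aggregated CT also drops.  Returns (kept, dropped-with-reason).
    """
    kept: list[CtRecord] = []
    dropped: list[dict] = []
    for r in records:
        if r.aggregated_ct is None:
            dropped.append({"assay_id": r.assay_id, "sample_id": r.sample_id,
                            "reason": "missing aggregated CT"})
        elif r.aggregated_ct < max_ct:
            kept.append(r)
        else:
            dropped.append({"assay_id": r.assay_id, "sample_id": r.sample_id,
                            "reason": f"CT {r.aggregated_ct:.6g} >= {max_ct:.6g}"})
    return kept, dropped


def normfinder_stability(
    expr: ExpressionMatrix, design: PairedDesign
) -> list[StabilityResult]:
    """Rank candidate reference genes by a model-based stability value.

    Two-group variance decomposition on log-scale values: the per-sample
    mean across all candidates is removed (z = y - sample mean), giving
    each gene's expression relative to the candidate panel.  Then per
    gene i and group g:

    * intra-group variation  s2_ig = Var_j(z_igj)    (ddof 1)
    * inter-group deviation  d_ig  = zbar_ig - mean_g'(zbar_ig')
      (for two groups, half the gene's between-group difference relative
      to the candidate average, which is zero by construction)

    stability_i = mean_g( |d_ig| + sqrt(s2_ig / n_g) ) — the group-shift
    magnitude plus the sampling uncertainty of the gene's group mean.
    Lower is more stable.  best_pair minimises the same score for the
    average of two candidates (d and s2 averaged as for independent
    genes: d_pair = (d_a + d_b)/2, s2_pair = (s2_a + s2_b)/4).
    """
    candidates = expr.feature_ids
    if len(candidates) < 3:
        raise ValueError("need >= 3 candidate reference genes")
    groups = ("TT", "NNT")
    samples_by_group = {g: expr.samples_in_group(g) for g in groups}
    for g, ss in samples_by_group.items():
        if len(ss) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")

    d: dict[str, dict[str, float]] = {a: {} for a in candidates}
    s2: dict[str, dict[str, float]] = {a: {} for a in candidates}
    zbar: dict[str, dict[str, float]] = {a: {} for a in candidates}
    for g, ss in samples_by_group.items():
        sub = expr.values.loc[candidates, ss]
        if sub.isna().any().any():
            raise ValueError(f"missing values among candidates in group {g}")
        z = sub - sub.mean(axis=0)
        zb = z.mean(axis=1)
        vv = z.var(axis=1, ddof=1)
        for a in candidates:
            zbar[a][g] = float(zb[a])
            s2[a][g] = float(vv[a])
    for a in candidates:
        grand = np.mean([zbar[a][g] for g in groups])
        for g in groups:
            d[a][g] = zbar[a][g] - grand

    def score(d_of: dict[str, float], s2_of: dict[str, float]) -> float:
        return float(np.mean([
            abs(d_of[g]) + np.sqrt(max(s2_of[g], 0.0) / len(samples_by_group[g]))
            for g in groups
        ]))

    stab = {a: score(d[a], s2[a]) for a in candidates}
    best_pair, best_pair_score = None, np.inf
    for i, a in enumerate(candidates):
        for b in candidates[i + 1:]:
            pd_of = {g: (d[a][g] + d[b][g]) / 2 for g in groups}
            ps_of = {g: (s2[a][g] + s2[b][g]) / 4 for g in groups}
            sc = score(pd_of, ps_of)
            if sc < best_pair_score:
                best_pair, best_pair_score = (a, b), sc

    order = sorted(candidates, key=lambda a: (stab[a], a))
    rank_of = {a: i + 1 for i, a in enumerate(order)}
    return [
        StabilityResult(
            feature_id=a,
            stability_value=stab[a],
            intra_group_var={g: s2[a][g] for g in groups},
            inter_group_dev={g: d[a][g] for g in groups},
            rank=rank_of[a],
            best_pair=best_pair,
        )
        for a in order
    ]


def delta_ct(
    records: list[CtRecord], controls: list[str]
) -> tuple[ExpressionMatrix, list[dict]]:
    """Normalise aggregated CT to the endogenous controls.

    dCT(target t, sample s) = CT_t,s - mean(CT of controls in s); the
    matrix stores -dCT so that higher = more expressed.  Samples missing
    any control are excluded and reported.
    """
    if not controls:
        raise ValueError("no endogenous controls supplied")
    ct = ct_records_to_frame(records)
    missing_ctrl = [c for c in controls if c not in ct.index]
    if missing_ctrl:
        raise KeyError(f"controls absent from CT table: {missing_ctrl}")

    ctrl = ct.loc[controls]
    ok = ctrl.notna().all(axis=0)
    excluded = [
        {"sample_id": s, "reason": "missing control CT"}
        for s in ct.columns[~ok]
    ]
    use = ct.columns[ok]
    targets = [a for a in ct.index if a not in controls]
    neg_dct = -(ct.loc[targets, use] - ctrl[use].mean(axis=0))
    expr = ExpressionMatrix(values=neg_dct, group_of={}, scale_tag="neg_delta_ct")
    return expr, excluded


def fold_change_ddct(
    expr: ExpressionMatrix, design: PairedDesign, aggregation: str = "arithmetic"
) -> list[FoldChangeRecord]:
    """Comparative-CT fold change per feature over patient pairs.

    Per patient, ddCT = dCT_tumor - dCT_normal and the pair's fold change
    is 2^-ddCT; on the stored -dCT scale that is 2^(tumor - normal).
    fc_mean / fc_sd are the arithmetic mean and sample SD (ddof 1) of the
    per-pair fold changes; ``aggregation='geometric'`` switches the mean
    to geometric (SD then on log2 scale, re-exponentiated).  Patients with
    either tissue missing are skipped.
    """
    if expr.scale_tag != "neg_delta_ct":
        raise ValueError("fold_change_ddct expects a -dCT matrix")
    if aggregation not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    vals = expr.values
    out: list[FoldChangeRecord] = []
    for feat in expr.feature_ids:
        fcs: list[float] = []
        for p in design.patients:
            tt, nnt = design.tumor_of[p], design.normal_of[p]
            if tt not in vals.columns or nnt not in vals.columns:
                continue
            a, b = vals.at[feat, tt], vals.at[feat, nnt]
            if np.isnan(a) or np.isnan(b):
                continue
            fcs.append(float(2.0 ** (a - b)))  # -ddCT = (-dCT_tt) - (-dCT_nnt)
        if len(fcs) < 2:
            raise ValueError(
                f"feature {feat!r}: fewer than 2 contributing patient pairs"
            )
        arr = np.asarray(fcs)
        if aggregation == "arithmetic":
            mean, sd = float(arr.mean()), float(arr.std(ddof=1))
        else:
            logs = np.log2(arr)
            mean = float(2.0 ** logs.mean())
            sd = float(2.0 ** logs.std(ddof=1))
        out.append(FoldChangeRecord(
            feature_id=feat, per_pair_fc=fcs, fc_mean=mean, fc_sd=sd,
            direction="up" if mean > 1.0 else "down",
        ))
    return out
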