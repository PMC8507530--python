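"""Correlation-disruption detection for miRNA-mRNA pairs.

For every (miRNA, gene) pair the Pearson correlation of their -dCT
profiles is computed separately in tumor (TT) and matched normal (NNT)
samples.  Plotting each pair as a point (r_NNT, r_TT), concordant
regulation falls along a rising linear trend from (-1, -1) to (1, 1);
pairs whose tumor correlation departs from what their normal-tissue
correlation predicts — at a 99% band — are flagged as "disrupted"
(regulation lost or gained during carcinogenesis).  A sign flip
(r_TT * r_NNT < 0) is recorded separately so both outlier definitions
stay queryable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AnalysisConfig, ExpressionMatrix, PairedDesign
from .diagnostics import RocResult, pair_ratio_feature, roc_auc

__all__ = [
    "CorrelationRecord",
    "DisruptionRecord",
    "pairwise_correlations",
    "detect_disruption",
    "disruption_roc",
]


@dataclass
class CorrelationRecord:
    mirna_id: str
    gene_id: str
    group: str  # TT | NNT
    r: float
    p_value: float
    n_samples: int


@dataclass
class DisruptionRecord:
    mirna_id: str
    gene_id: str
    r_tt: float
    r_nnt: float
    fitted_value: float
    residual: float
    band_halfwidth: float
    flagged: bool
    sign_flip: bool


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Product-moment r on pairwise-complete values; two-sided p from the
    t-transform t = r * sqrt((n-2) / (1-r^2))."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(ddof=0), ys.std(ddof=0)
    if sx == 0 or sy == 0:
        return np.nan, np.nan, n
    r = float(np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p, n


def pairwise_correlations(
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    design: PairedDesign,
) -> list[CorrelationRecord]:
    """Per-group Pearson correlation for every (miRNA, gene) pair.

    Pairs with fewer than 3 complete observations in a group are skipped
    for that group.
    """
    group_of = design.group_of()
    shared = [s for s in mirna_expr.sample_ids
              if s in set(mrna_expr.sample_ids) and s in group_of]
    if not shared:
        raise ValueError("no shared samples between matrices and design")
    out: list[CorrelationRecord] = []
    for group in ("TT", "NNT"):
        samples = [s for s in shared if group_of[s] == group]
        mi = mirna_expr.values[samples].to_numpy(float)
        mr = mrna_expr.values[samples].to_numpy(float)
        for i, mirna in enumerate(mirna_expr.feature_ids):
            for j, gene in enumerate(mrna_expr.feature_ids):
                r, p, n = _pearson_with_p(mi[i], mr[j])
                if np.isnan(r):
                    continue
                out.append(CorrelationRecord(mirna, gene, group, r, p, n))
    return out


def detect_disruption(
    corr: list[CorrelationRecord],
    cfg: AnalysisConfig | None = None,
    mode: str = "regression",
) -> list[DisruptionRecord]:
    """Flag pairs leaving the linear (r_NNT, r_TT) band.

    regression mode (default): OLS of r_TT on r_NNT over all pairs, with
    a two-sided prediction interval at confidence cfg.disruption_ci —
    halfwidth_i = t_{1-a/2, n-2} * s * sqrt(1 + 1/n + (x_i - xbar)^2/Sxx).
    anchored mode: the identity line through (-1,-1) and (1,1), with a
    constant band = normal quantile(1 - a/2) * SD of the residuals.
    flagged = |residual| > halfwidth; records sorted by |residual|
    descending.
    """
    cfg = cfg or AnalysisConfig()
    if mode not in ("regression", "anchored"):
        raise ValueError(f"unknown mode {mode!r}")
    by_pair: dict[tuple[str, str], dict[str, float]] = {}
    for c in corr:
        by_pair.setdefault((c.mirna_id, c.gene_id), {})[c.group] = c.r
    pairs = sorted(k for k, v in by_pair.items() if {"TT", "NNT"} <= set(v))
    if len(pairs) < 10:
        raise ValueError("need >= 10 pairs present in both groups")
    x = np.array([by_pair[k]["NNT"] for k in pairs])
    y = np.array([by_pair[k]["TT"] for k in pairs])
    n = len(pairs)
    alpha = 1.0 - cfg.disruption_ci

    if mode == "regression":
        xbar = x.mean()
        sxx = float(((x - xbar) ** 2).sum())
        if sxx == 0:
            raise ValueError("degenerate r_NNT values: zero spread")
        slope = float(((x - xbar) * (y - y.mean())).sum() / sxx)
        intercept = float(y.mean() - slope * xbar)
        fitted = intercept + slope * x
        resid = y - fitted
        s2 = float((resid ** 2).sum() / (n - 2))
        tq = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
        half = tq * np.sqrt(s2 * (1.0 + 1.0 / n + (x - xbar) ** 2 / sxx))
    else:
        fitted = x.copy()
        resid = y - fitted
        sd = float(resid.std(ddof=1))
        if sd == 0:
            sd = np.finfo(float).tiny
        zq = stats.norm.ppf(1.0 - alpha / 2.0)
        half = np.full(n, zq * sd)

    records = [
        DisruptionRecord(
            mirna_id=m, gene_id=g,
            r_tt=float(yi), r_nnt=float(xi),
            fitted_value=float(fi), residual=float(ri),
            band_halfwidth=float(hi),
            flagged=bool(abs(ri) > hi),
            sign_flip=bool(xi * yi < 0),
        )
        for (m, g), xi, yi, fi, ri, hi in zip(pairs, x, y, fitted, resid, half)
    ]
    records.sort(key=lambda r: -abs(r.residual))
    return records


def disruption_roc(
    flagged: list[DisruptionRecord],
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    design: PairedDesign,
    epsilon: float = 1e-6,
    mode: str = "ratio",
) -> list[RocResult]:
    """ROC of the per-sample miRNA/mRNA -dCT ratio for each flagged pair."""
    group_of = design.group_of()
    shared = [s for s in mirna_expr.sample_ids
              if s in set(mrna_expr.sample_ids) and s in group_of]
    out: list[RocResult] = []
    for rec in flagged:
        if not rec.flagged:
            continue
        num = mirna_expr.values.loc[rec.mirna_id, shared].to_numpy(float)
        den = mrna_expr.values.loc[rec.gene_id, shared].to_numpy(float)
        scores, keep = pair_ratio_feature(num, den, epsilon=epsilon, mode=mode)
        labels = [group_of[s] for s, k in zip(shared, keep) if k]
        out.append(roc_auc(scores[keep], labels,
                           feature_label=f"{rec.mirna_id}/{rec.gene_id}"))
    return out
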