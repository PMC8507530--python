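"""Paired TT-vs-NNT differential expression calls.

The workhorse is a sign-flip permutation paired t-test (exhaustive when
the pair count allows, sampled otherwise) with Benjamini-Hochberg FDR,
plus the two threshold regimes used in this kind of study: a microarray
screen (|FC| >= 2, p < 0.01, FDR < 0.05) and a qRT-PCR validation call
(p < 0.05, FDR < 0.05).  A simplified empirical-Bayes moderated paired t
is provided for the microarray-style analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import AnalysisConfig, ExpressionMatrix, PairedDesign
from .quantification import FoldChangeRecord

__all__ = [
    "DEResult",
    "paired_differences",
    "paired_permutation_ttest",
    "benjamini_hochberg",
    "call_differential",
    "moderated_paired_t",
]


@dataclass
class DEResult:
    feature_id: str
    fc_mean: float
    t_stat: float
    p_value: float
    fdr: float
    regulation: str  # up | down | ns
    regime: str  # microarray | validation


def paired_differences(
    expr: ExpressionMatrix, design: PairedDesign
) -> pd.DataFrame:
    """Per-feature tumor-minus-normal differences, one column per patient.

    Patients with either tissue missing for a feature yield NaN there.
    """
    vals = expr.values
    cols = {}
    for p in design.patients:
        tt, nnt = design.tumor_of[p], design.normal_of[p]
        if tt in vals.columns and nnt in vals.columns:
            cols[p] = vals[tt] - vals[nnt]
    if not cols:
        raise ValueError("no complete patient pairs in expression matrix")
    return pd.DataFrame(cols)


def _t_from_diffs(d: np.ndarray) -> np.ndarray:
    """Row-wise paired t statistic mean(d) / (sd(d)/sqrt(n)); +-inf when
    the differences have zero variance but nonzero mean, 0 when all-zero."""
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0,
                     np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return t


def paired_permutation_ttest(
    expr: ExpressionMatrix,
    design: PairedDesign,
    n_perm: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-sided sign-flip permutation paired t-test per feature.

    The observed statistic is the ordinary paired t on per-patient
    differences.  Under the paired null the tumor/normal labels within a
    patient are exchangeable, so the reference distribution flips the
    sign of each patient's difference.  p = (#{|t_perm| >= |t_obs|} + 1)
    / (n_used + 1).  When 2^n_pairs <= n_perm the full 2^n enumeration is
    used instead of sampling (the identity flip is then the "+1").
    Features whose differences are all zero get p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    diffs = paired_differences(expr, design)
    complete = diffs.dropna(axis=0, how="any")
    if complete.shape[1] < 3:
        raise ValueError("need >= 3 complete patient pairs")
    d = complete.to_numpy(float)
    n_pairs = d.shape[1]
    t_obs = _t_from_diffs(d)

    if 2 ** n_pairs <= n_perm:
        signs = np.array(list(product((1.0, -1.0), repeat=n_pairs)))
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n_pairs))
        exhaustive = False

    abs_obs = np.abs(t_obs)
    exceed = np.zeros(d.shape[0], dtype=int)
    # chunk over permutations to bound memory at ~n_feat x chunk doubles
    chunk = max(1, int(2e6 / max(d.shape[0], 1)))
    for start in range(0, signs.shape[0], chunk):
        block = signs[start:start + chunk]
        # for each sign vector s, t = mean(d*s) / (sd(d*s)/sqrt(n))
        ds = d[None, :, :] * block[:, None, :]
        mean = ds.mean(axis=2)
        sd = ds.std(axis=2, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_p = mean / (sd / np.sqrt(n_pairs))
            t_p = np.where(sd == 0,
                           np.where(mean == 0, 0.0, np.sign(mean) * np.inf),
                           t_p)
        # >= with tolerance-free comparison; inf handled naturally
        exceed += (np.abs(t_p) >= abs_obs[None, :] - 1e-12).sum(axis=0)

    if exhaustive:
        # identity flip is included in the enumeration; p = exceed / total
        p = exceed / signs.shape[0]
    else:
        p = (exceed + 1) / (signs.shape[0] + 1)
    p = np.where(np.all(d == 0, axis=1), 1.0, p)

    return pd.DataFrame(
        {"t_stat": t_obs, "p_value": np.clip(p, 0.0, 1.0)},
        index=complete.index,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (clipped to 1, monotone in p rank)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    fc: list[FoldChangeRecord],
    stats_frame: pd.DataFrame,
    regime: str,
    cfg: AnalysisConfig | None = None,
) -> list[DEResult]:
    """Apply a threshold regime to fold changes + permutation statistics.

    microarray: |FC| beyond (threshold, 1/threshold) AND p < 0.01 AND
    FDR < 0.05.  validation: p < 0.05 AND FDR < 0.05.  Regulation is up
    iff fc_mean > 1 (only for features passing all thresholds; otherwise
    'ns').  FDR is computed here over the supplied feature set.
    """
    cfg = cfg or AnalysisConfig()
    if regime not in ("microarray", "validation"):
        raise ValueError(f"unknown regime {regime!r}")
    fc_by_id = {r.feature_id: r for r in fc}
    missing = [f for f in fc_by_id if f not in stats_frame.index]
    if missing:
        raise ValueError(f"features lacking statistics: {missing[:5]}")
    feats = [r.feature_id for r in fc]
    p = stats_frame.loc[feats, "p_value"].to_numpy(float)
    t = stats_frame.loc[feats, "t_stat"].to_numpy(float)
    fdr = benjamini_hochberg(p)

    out: list[DEResult] = []
    for feat, ti, pi, qi in zip(feats, t, p, fdr):
        m = fc_by_id[feat].fc_mean
        if regime == "microarray":
            passes = (
                (m > cfg.microarray_fc_threshold
                 or m < 1.0 / cfg.microarray_fc_threshold)
                and pi < cfg.microarray_p_threshold
                and qi < cfg.microarray_fdr_threshold
            )
        else:
            passes = (pi < cfg.p_threshold_validation
                      and qi < cfg.fdr_threshold_validation)
        regulation = ("up" if m > 1.0 else "down") if passes else "ns"
        out.append(DEResult(feat, m, float(ti), float(pi), float(qi),
                            regulation, regime))
    return out


def moderated_paired_t(
    expr: ExpressionMatrix,
    design: PairedDesign,
    prior_df: float = 4.0,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated paired t (two-group paired design only).

    Per-feature difference variances are shrunk toward a prior:
    s2_tilde = (d0 * s0^2 + d * s^2) / (d0 + d) with d = n_pairs - 1;
    t = mean(d) / sqrt(s2_tilde / n) referenced to t with d0 + d df.
    s0^2 defaults to the mean of the per-feature variances (a simplified
    prior; the full marginal-likelihood prior fit of the limma family is
    out of scope).  prior_df = 0 recovers the ordinary paired t.
    """
    if prior_df < 0:
        raise ValueError("prior_df must be >= 0")
    diffs = paired_differences(expr, design).dropna(axis=0, how="any")
    d = diffs.to_numpy(float)
    n = d.shape[1]
    df_resid = n - 1
    mean = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    s0sq = float(np.mean(s2)) if prior_var is None else float(prior_var)
    if prior_df == 0:
        s2_tilde = s2
    else:
        s2_tilde = (prior_df * s0sq + df_resid * s2) / (prior_df + df_resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s2_tilde / n)
    t = np.where(s2_tilde == 0, np.where(mean == 0, 0.0,
                                         np.sign(mean) * np.inf), t)
    df_total = prior_df + df_resid
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame({"t_stat": t, "p_value": p}, index=diffs.index)
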