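"""Synthetic paired tumor/normal CT data with known planted structure.

The generator emulates a paired two-group qRT-PCR study: per-assay CT
baselines, per-patient and per-sample offsets shared across assays (which
is exactly what endogenous-control normalisation removes), planted tumor
log2 fold changes encoded as group CT shifts (one PCR cycle = one log2
unit at ideal amplification efficiency), low-variance endogenous-control
assays, technical triplicates, and miRNA-mRNA pairs whose correlation is
forced to a target value separately in each group.  Every downstream
stage therefore has a ground-truth recovery test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import CtRecord, ExpressionMatrix, PairedDesign

__all__ = ["SyntheticTruth", "simulate_paired_ct", "simulate_correlated_pairs"]


@dataclass
class SyntheticTruth:
    """Planted effects for one simulated study.

    de_features maps feature -> planted log2 fold change (tumor - normal);
    control_assays have zero group effect and near-zero extra variance;
    disrupted_pairs are (miRNA, gene, r_NNT, r_TT) correlation targets.
    noise_sd is the technical replicate SD in CT cycles; patient_sd the SD
    of the shared per-patient offset (default 1.0 cycles); sample_sd a
    per-sample loading offset absorbed by control normalisation.
    """

    de_features: dict[str, float] = field(default_factory=dict)
    control_assays: list[str] = field(default_factory=list)
    disrupted_pairs: list[tuple[str, str, float, float]] = field(default_factory=list)
    noise_sd: float = 0.25
    patient_sd: float = 1.0
    sample_sd: float = 0.5
    baseline_low: float = 18.0
    baseline_high: float = 23.0
    n_patients: int = 24
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_patients < 3:
            raise ValueError("n_patients must be >= 3")
        overlap = set(self.control_assays) & set(self.de_features)
        if overlap:
            raise ValueError(f"control assays overlap DE features: {sorted(overlap)}")
        for m, g, r_nnt, r_tt in self.disrupted_pairs:
            if abs(r_nnt) > 1 or abs(r_tt) > 1:
                raise ValueError(f"correlation target out of [-1,1] for ({m}, {g})")

    @property
    def all_assays(self) -> list[str]:
        return list(self.de_features) + list(self.control_assays)


def simulate_paired_ct(
    truth: SyntheticTruth,
) -> tuple[list[CtRecord], PairedDesign, SyntheticTruth]:
    """Simulate triplicate CT tables for a paired TT/NNT design.

    CT(assay a, sample s of patient i in group g) =
        baseline_a + patient_i + sample_offset_s - shift(a, g) + eps,
    with shift = planted log2 FC for tumor samples of DE assays and 0
    otherwise.  Control assays track the patient and sample offsets, so
    dCT normalisation is exact in expectation.  Deterministic given seed.
    """
    rng = np.random.default_rng(truth.seed)
    assays = truth.all_assays
    if not assays:
        raise ValueError("truth defines no assays")

    patients = [f"P{i + 1:02d}" for i in range(truth.n_patients)]
    design = PairedDesign.from_records(
        (p, f"{p}_TT", f"{p}_NNT") for p in patients
    )

    baseline = {
        a: rng.uniform(truth.baseline_low, truth.baseline_high) for a in assays
    }
    patient_eff = {p: rng.normal(0.0, truth.patient_sd) for p in patients}
    sample_ids = design.tumor_samples + design.normal_samples
    sample_off = {s: rng.normal(0.0, truth.sample_sd) for s in sample_ids}
    group_of = design.group_of()

    records: list[CtRecord] = []
    for a in assays:
        shift_tt = truth.de_features.get(a, 0.0)
        for p in patients:
            for s in (design.tumor_of[p], design.normal_of[p]):
                mu = baseline[a] + patient_eff[p] + sample_off[s]
                if group_of[s] == "TT":
                    mu -= shift_tt
                reps = mu + rng.normal(0.0, truth.noise_sd, truth.n_replicates)
                reps = np.clip(reps, 0.0, None)
                records.append(
                    CtRecord(assay_id=a, sample_id=s,
                             replicate_values=[float(v) for v in reps])
                )
    return records, design, truth


def simulate_correlated_pairs(
    truth: SyntheticTruth,
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Re-draw gene values of each disrupted pair to hit target correlations.

    Within each group the gene column is rebuilt by the conditional-
    Gaussian construction gene = r * z(miRNA) + sqrt(1 - r^2) * eps on
    standardised values, then rescaled to the gene's original within-group
    mean and SD, so the target Pearson correlation holds in expectation.
    Non-disrupted features are untouched.
    """
    rng = np.random.default_rng(truth.seed + 1)
    mirna_vals = mirna_expr.values
    mrna_vals = mrna_expr.values.copy()

    for mirna, gene, r_nnt, r_tt in truth.disrupted_pairs:
        if mirna not in mirna_vals.index:
            raise KeyError(f"miRNA {mirna!r} absent from miRNA matrix")
        if gene not in mrna_vals.index:
            raise KeyError(f"gene {gene!r} absent from mRNA matrix")
        for group, r in (("NNT", r_nnt), ("TT", r_tt)):
            samples = [
                s for s in mrna_vals.columns
                if mrna_expr.group_of.get(s) == group and s in mirna_vals.columns
            ]
            if len(samples) < 3:
                raise ValueError(f"fewer than 3 shared {group} samples")
            x = mirna_vals.loc[mirna, samples].to_numpy(float)
            y = mrna_vals.loc[gene, samples].to_numpy(float)
            zx = (x - x.mean()) / (x.std(ddof=0) or 1.0)
            eps = rng.standard_normal(len(samples))
            eps -= eps.mean()
            eps /= eps.std(ddof=0) or 1.0
            # orthogonalise noise against the miRNA so sample r tracks target
            eps -= (eps @ zx) / (zx @ zx) * zx
            eps_sd = eps.std(ddof=0) or 1.0
            zy = r * zx + np.sqrt(max(0.0, 1.0 - r * r)) * (eps / eps_sd)
            y_sd = y.std(ddof=0) or 1.0
            mrna_vals.loc[gene, samples] = y.mean() + y_sd * zy
    return mirna_expr, ExpressionMatrix(
        values=mrna_vals, group_of=dict(mrna_expr.group_of),
        scale_tag=mrna_expr.scale_tag,
    )
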