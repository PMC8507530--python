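"""Shared fixtures: tiny on-disk inputs and a standard synthetic study."""

import numpy as np
import pandas as pd
import pytest

from mirdisrupt import (AnalysisConfig, PairedDesign, SyntheticTruth,
                        aggregate_replicates, delta_ct, fold_change_ddct,
                        simulate_paired_ct)
from mirdisrupt.core_io import ExpressionMatrix


@pytest.fixture
def tiny_design():
    return PairedDesign.from_records([
        ("P1", "P1_TT", "P1_NNT"),
        ("P2", "P2_TT", "P2_NNT"),
        ("P3", "P3_TT", "P3_NNT"),
        ("P4", "P4_TT", "P4_NNT"),
    ])


@pytest.fixture
def long_ct_file(tmp_path):
    path = tmp_path / "ct.tsv"
    rows = ["assay\tsample\treplicate\tct"]
    for rep, v in enumerate((20.0, 20.2, 20.4), start=1):
        rows.append(f"GENE1\tS1\t{rep}\t{v}")
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def design_file(tmp_path, tiny_design):
    path = tmp_path / "design.tsv"
    pd.DataFrame({
        "patient_id": tiny_design.patients,
        "tumor_sample": tiny_design.tumor_samples,
        "normal_sample": tiny_design.normal_samples,
    }).to_csv(path, sep="\t", index=False)
    return path


def make_expression(values, feature_ids, design, scale_tag="neg_delta_ct"):
    """Features x samples matrix over a design's TT then NNT samples."""
    cols = design.tumor_samples + design.normal_samples
    df = pd.DataFrame(np.asarray(values, float), index=feature_ids,
                      columns=cols)
    return ExpressionMatrix(df, design.group_of(), scale_tag)


@pytest.fixture
def synthetic_study():
    """12-patient study: 2 planted controls, 4 DE assays, 4 null assays."""
    truth = SyntheticTruth(
        de_features={"up2": 2.0, "up1": 1.0, "down1": -1.0, "down2": -2.0,
                     "null1": 0.0, "null2": 0.0, "null3": 0.0, "null4": 0.0},
        control_assays=["ctrlA", "ctrlB"],
        noise_sd=0.2,
        n_patients=12,
        seed=11,
    )
    records, design, _ = simulate_paired_ct(truth)
    expr, _ = delta_ct(aggregate_replicates(records),
                       ["ctrlA", "ctrlB"])
    expr.group_of.update(design.group_of())
    return truth, records, design, expr


@pytest.fixture
def cfg():
    return AnalysisConfig()
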