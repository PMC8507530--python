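"""Replicate aggregation, CT filtering, reference-gene stability and ddCT."""

import math

import numpy as np
import pytest

from mirdisrupt import (PairedDesign, aggregate_replicates, delta_ct,
                        filter_by_ct, fold_change_ddct, normfinder_stability)
from mirdisrupt.core_io import CtRecord
from tests.conftest import make_expression


class TestAggregateReplicates:
    @pytest.mark.parametrize("reps,method,expected", [
        ([20.0, 20.2, 20.4], "mean", 20.2),
        ([25.0], "mean", 25.0),
        ([20.0, 20.0, 30.0], "median", 20.0),
    ])
    def test_aggregation(self, reps, method, expected):
        rec = CtRecord("G", "S", replicate_values=reps)
        out = aggregate_replicates([rec], method)[0]
        assert out.aggregated_ct == pytest.approx(expected)
        assert out.replicate_values == reps  # audit trail retained


class TestFilterByCt:
    def test_strictly_below_kept_boundary_dropped(self):
        records = aggregate_replicates([
            CtRecord("G", "S1", [23.99]),
            CtRecord("G", "S2", [24.0]),
        ])
        kept, dropped = filter_by_ct(records, 24.0)
        assert [r.sample_id for r in kept] == ["S1"]
        assert dropped[0]["sample_id"] == "S2"

    def test_empty_input(self):
        assert filter_by_ct([], 24.0) == ([], [])


class TestDeltaCt:
    def _records(self, table):
        return aggregate_replicates([
            CtRecord(a, s, [v]) for (a, s), v in table.items()
        ])

    def test_neg_delta_ct_arithmetic(self):
        records = self._records({("T", "S1"): 25.0, ("C1", "S1"): 20.0,
                                 ("C2", "S1"): 22.0})
        expr, _ = delta_ct(records, ["C1", "C2"])
        assert expr.values.at["T", "S1"] == pytest.approx(-4.0)

    def test_target_equal_to_control_mean_gives_zero(self):
        records = self._records({("T", "S1"): 21.0, ("C1", "S1"): 20.0,
                                 ("C2", "S1"): 22.0})
        expr, _ = delta_ct(records, ["C1", "C2"])
        assert expr.values.at["T", "S1"] == 0.0

    def test_sample_missing_control_excluded_and_reported(self):
        records = self._records({("T", "S1"): 25.0, ("C1", "S1"): 20.0,
                                 ("T", "S2"): 25.0})
        records.append(CtRecord("C1", "S2", []))  # no replicate -> missing
        records = aggregate_replicates(records)
        expr, excluded = delta_ct(records, ["C1"])
        assert "S2" not in expr.sample_ids
        assert excluded == [{"sample_id": "S2",
                             "reason": "missing control CT"}]

    def test_no_controls_is_configuration_error(self):
        with pytest.raises(ValueError):
            delta_ct([], [])


class TestFoldChangeDdct:
    def test_zero_ddct_gives_unit_fc_zero_sd(self, tiny_design):
        expr = make_expression(np.ones((1, 8)), ["G"], tiny_design)
        rec = fold_change_ddct(expr, tiny_design)[0]
        assert rec.fc_mean == pytest.approx(1.0)
        assert rec.fc_sd == pytest.approx(0.0)

    def test_constant_minus_one_ddct_doubles(self, tiny_design):
        vals = np.zeros((1, 8))
        vals[0, :4] = 1.0  # tumor -dCT one unit higher -> ddCT = -1
        expr = make_expression(vals, ["G"], tiny_design)
        assert fold_change_ddct(expr, tiny_design)[0].fc_mean == pytest.approx(2.0)

    def test_swapping_labels_inverts_every_pair_fc(self, tiny_design):
        rng = np.random.default_rng(4)
        expr = make_expression(rng.normal(size=(2, 8)), ["G1", "G2"],
                               tiny_design)
        swapped = PairedDesign.from_records(
            (p, tiny_design.normal_of[p], tiny_design.tumor_of[p])
            for p in tiny_design.patients)
        fwd = fold_change_ddct(expr, tiny_design)
        rev = fold_change_ddct(expr, swapped)
        for a, b in zip(fwd, rev):
            assert np.allclose(sorted(a.per_pair_fc),
                               sorted(1.0 / np.array(b.per_pair_fc)))

    def test_geometric_mode_matches_mean_log(self, tiny_design):
        rng = np.random.default_rng(5)
        expr = make_expression(rng.normal(size=(1, 8)), ["G"], tiny_design)
        rec = fold_change_ddct(expr, tiny_design, aggregation="geometric")[0]
        logs = np.log2(rec.per_pair_fc)
        assert rec.fc_mean == pytest.approx(2.0 ** logs.mean())

    def test_single_pair_is_insufficient(self):
        design = PairedDesign.from_records([("P1", "T1", "N1"),
                                            ("P2", "T2", "N2")])
        vals = np.array([[1.0, np.nan, 0.0, np.nan]])
        expr = make_expression(vals, ["G"], design)
        with pytest.raises(ValueError, match="fewer than 2"):
            fold_change_ddct(expr, design)

    def test_noise_free_planted_minus_two_recovers_quarter(self):
        from mirdisrupt import SyntheticTruth, simulate_paired_ct
        truth = SyntheticTruth(de_features={"G": -2.0},
                               control_assays=["C1", "C2"],
                               noise_sd=1e-9, n_patients=5, seed=8)
        records, design, _ = simulate_paired_ct(truth)
        expr, _ = delta_ct(aggregate_replicates(records), ["C1", "C2"])
        rec = fold_change_ddct(expr, design)[0]
        assert rec.fc_mean == pytest.approx(0.25, abs=1e-6)


TOY = {  # candidates x (T1, T2, N1, N2)
    "A": [10.0, 10.0, 10.0, 10.0],
    "B": [12.0, 12.4, 11.0, 11.2],
    "C": [9.0, 8.8, 9.5, 9.9],
}


def _toy_oracle():
    """Spreadsheet-style re-evaluation of the stability decomposition on
    the 3x4 toy, written with plain Python arithmetic."""
    samples = ["T1", "T2", "N1", "N2"]
    groups = {"T1": "TT", "T2": "TT", "N1": "NNT", "N2": "NNT"}
    genes = list(TOY)
    col = {s: [TOY[g][i] for g in genes] for i, s in enumerate(samples)}
    sample_mean = {s: sum(col[s]) / len(genes) for s in samples}
    z = {g: {s: TOY[g][i] - sample_mean[s]
             for i, s in enumerate(samples)} for g in genes}
    out = {}
    for g in genes:
        stats = {}
        for grp in ("TT", "NNT"):
            ss = [s for s in samples if groups[s] == grp]
            vals = [z[g][s] for s in ss]
            m = sum(vals) / len(vals)
            v = sum((x - m) ** 2 for x in vals) / (len(vals) - 1)
            stats[grp] = (m, v, len(ss))
        grand = (stats["TT"][0] + stats["NNT"][0]) / 2
        score = 0.0
        for grp in ("TT", "NNT"):
            m, v, n = stats[grp]
            score += abs(m - grand) + math.sqrt(v / n)
        out[g] = score / 2
    return out


class TestNormfinderStability:
    def _toy_expr(self):
        design = PairedDesign.from_records([("P1", "T1", "N1"),
                                            ("P2", "T2", "N2")])
        import pandas as pd
        from mirdisrupt.core_io import ExpressionMatrix
        df = pd.DataFrame(TOY, index=["T1", "T2", "N1", "N2"]).T
        return ExpressionMatrix(df, design.group_of(), "log2"), design

    def test_toy_matches_spreadsheet_oracle_to_1e9(self):
        expr, design = self._toy_expr()
        results = {r.feature_id: r.stability_value
                   for r in normfinder_stability(expr, design)}
        oracle = _toy_oracle()
        for g in oracle:
            assert results[g] == pytest.approx(oracle[g], abs=1e-9)

    def test_constant_gene_ranks_first_on_toy(self):
        expr, design = self._toy_expr()
        best = min(normfinder_stability(expr, design), key=lambda r: r.rank)
        assert best.feature_id == "A"

    def test_ranks_are_a_permutation(self, synthetic_study):
        truth, records, design, _ = synthetic_study
        from mirdisrupt.quantification import ct_records_to_frame
        from mirdisrupt.core_io import ExpressionMatrix
        ct = ct_records_to_frame(aggregate_replicates(records))
        cands = ["ctrlA", "ctrlB", "up2", "down2", "up1"]
        expr = ExpressionMatrix(ct.loc[cands], design.group_of(), "log2")
        ranks = sorted(r.rank for r in normfinder_stability(expr, design))
        assert ranks == list(range(1, len(cands) + 1))

    def test_invariant_to_per_sample_constant(self):
        expr, design = self._toy_expr()
        shifted = expr.values + np.arange(4)[None, :] * 3.0
        from mirdisrupt.core_io import ExpressionMatrix
        expr2 = ExpressionMatrix(shifted, expr.group_of, "log2")
        a = {r.feature_id: r.stability_value
             for r in normfinder_stability(expr, design)}
        b = {r.feature_id: r.stability_value
             for r in normfinder_stability(expr2, design)}
        for g in a:
            assert a[g] == pytest.approx(b[g], abs=1e-12)

    def test_fewer_than_three_candidates_rejected(self, tiny_design):
        expr = make_expression(np.ones((2, 8)), ["A", "B"], tiny_design)
        with pytest.raises(ValueError, match=">= 3"):
            normfinder_stability(expr, tiny_design)

    def test_planted_controls_rank_top2_in_90pct_of_seeds(self):
        """The generator's low-variance, zero-shift controls should win
        the stability ranking against DE assays in >= 90% of 50 seeds."""
        from mirdisrupt import SyntheticTruth, simulate_paired_ct
        from mirdisrupt.quantification import ct_records_to_frame
        from mirdisrupt.core_io import ExpressionMatrix
        wins = 0
        for seed in range(50):
            truth = SyntheticTruth(
                de_features={"de1": 1.5, "de2": -1.5, "de3": 0.8,
                             "de4": -0.8},
                control_assays=["ctrlA", "ctrlB"],
                noise_sd=0.2, n_patients=12, seed=seed)
            records, design, _ = simulate_paired_ct(truth)
            ct = ct_records_to_frame(aggregate_replicates(records))
            expr = ExpressionMatrix(ct, design.group_of(), "log2")
            top2 = {r.feature_id
                    for r in normfinder_stability(expr, design)[:2]}
            wins += top2 == {"ctrlA", "ctrlB"}
        assert wins >= 45


class TestControlShiftEquivariance:
    def test_fold_changes_unchanged_by_per_sample_control_shift(self):
        """Adding a constant to every assay of one sample (a loading
        artefact) is absorbed by dCT normalisation."""
        table = {("T", "S1"): 25.0, ("T", "S2"): 24.0,
                 ("C1", "S1"): 20.0, ("C1", "S2"): 20.0,
                 ("C2", "S1"): 22.0, ("C2", "S2"): 22.0,
                 ("T", "S3"): 25.0, ("T", "S4"): 24.0,
                 ("C1", "S3"): 20.0, ("C1", "S4"): 20.0,
                 ("C2", "S3"): 22.0, ("C2", "S4"): 22.0}
        design = PairedDesign.from_records([("P1", "S1", "S2"),
                                            ("P2", "S3", "S4")])
        records = aggregate_replicates(
            [CtRecord(a, s, [v]) for (a, s), v in table.items()])
        shifted = aggregate_replicates(
            [CtRecord(a, s, [v + (3.0 if s == "S1" else 0.0)])
             for (a, s), v in table.items()])
        fc_a = fold_change_ddct(delta_ct(records, ["C1", "C2"])[0], design)
        fc_b = fold_change_ddct(delta_ct(shifted, ["C1", "C2"])[0], design)
        assert fc_a[0].per_pair_fc == pytest.approx(fc_b[0].per_pair_fc)
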