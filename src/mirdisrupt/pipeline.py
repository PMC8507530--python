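"""End-to-end orchestration: quantify -> DE -> ROC -> disruption ->
concordance -> enrichment, from one config, with a run manifest.

Stages communicate only via on-disk TSV/JSON, so any stage is
independently testable; a rerun with identical inputs, config and seed
is bitwise-identical on all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .concordance import confirm_against_external
from .core_io import (AnalysisConfig, PairedDesign, read_ct_table, read_design,
                      read_expression_matrix, read_gene_sets,
                      read_interactions, write_expression_matrix,
                      write_results)
from .differential import call_differential, paired_permutation_ttest
from .diagnostics import roc_auc
from .disruption import detect_disruption, disruption_roc, pairwise_correlations
from .enrichment import build_target_network, gsea_preranked, overrepresentation
from .quantification import (aggregate_replicates, delta_ct, filter_by_ct,
                             fold_change_ddct, normfinder_stability)

log = logging.getLogger("mirdisrupt")

__all__ = ["RunManifest", "run_pipeline", "quantify_stage"]

STAGES = ("quantify", "de", "roc", "disrupt", "confirm", "enrich")


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def quantify_stage(
    ct_path: str | Path,
    design: PairedDesign,
    controls: list[str],
    cfg: AnalysisConfig,
    apply_ct_filter: bool = True,
    na_999: bool = False,
):
    """CT table -> (-dCT ExpressionMatrix with groups, fold-change records)."""
    records = aggregate_replicates(read_ct_table(ct_path, na_999=na_999))
    if apply_ct_filter:
        records, dropped = filter_by_ct(records, cfg.max_ct)
        log.info("quantify: dropped %d records at CT >= %g",
                 len(dropped), cfg.max_ct)
    expr, excluded = delta_ct(records, controls)
    expr.group_of.update(design.group_of())
    if excluded:
        log.info("quantify: %d samples excluded (missing control)", len(excluded))
    fcs = fold_change_ddct(expr, design)
    return expr, fcs


def run_pipeline(
    cfg: AnalysisConfig,
    inputs: dict[str, str | Path],
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
    controls: list[str] | None = None,
) -> RunManifest:
    """Run the enabled stages in dependency order.

    ``inputs`` keys: design (always), ct_mirna and/or ct_mrna for
    quantify, external_ratios (feature\tlog2_ratio TSV) for confirm,
    interactions + gene_sets (GMT) for enrich.  Any stage failure raises
    with the stage name; outputs land in out_dir.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if "design" not in inputs:
        raise ValueError("inputs must name a 'design' sample sheet")
    need = {
        "quantify": ["design"], "de": ["design"], "roc": ["design"],
        "disrupt": ["design"],
        "confirm": ["external_ratios"],
        "enrich": ["interactions", "gene_sets"],
    }
    for st in stages:
        for key in need[st]:
            if key not in inputs:
                raise ValueError(f"stage {st!r} requires input {key!r}")
    if "quantify" in stages and not (
        "ct_mirna" in inputs or "ct_mrna" in inputs
    ):
        raise ValueError("stage 'quantify' requires ct_mirna and/or ct_mrna")

    manifest = RunManifest(
        config=cfg.to_dict(), seed=cfg.rng_seed, version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    for key, path in inputs.items():
        manifest.input_digests[key] = _digest(path)

    design = read_design(inputs["design"])
    exprs: dict[str, object] = {}
    fcs_by_kind: dict[str, list] = {}
    de_by_kind: dict[str, list] = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        counts = fn()
        log.info("stage %-8s %s  (%.2fs)", name, counts, time.perf_counter() - t0)
        manifest.stage_counts[name] = counts

    if "quantify" in stages:
        def _quantify():
            counts = {}
            for kind, key, default_controls in (
                ("mirna", "ct_mirna", ["miR-103a-3p", "miR-423-5p"]),
                ("mrna", "ct_mrna", ["ACTB", "RPLP0"]),
            ):
                if key not in inputs:
                    continue
                ctr = controls or default_controls
                expr, fcs = quantify_stage(
                    inputs[key], design, ctr, cfg,
                    apply_ct_filter=(kind == "mrna"),
                )
                exprs[kind] = expr
                fcs_by_kind[kind] = fcs
                write_expression_matrix(expr, out_dir / f"expr_{kind}.tsv")
                write_results(fcs, out_dir / f"fc_{kind}.tsv",
                              columns=["feature_id", "fc_mean", "fc_sd",
                                       "direction", "per_pair_fc"])
                counts[f"{kind}_features"] = len(fcs)
            return counts
        run_stage("quantify", _quantify)

    if "de" in stages:
        def _de():
            counts = {}
            for kind, expr in exprs.items():
                st = paired_permutation_ttest(
                    expr, design, cfg.n_permutations, cfg.rng_seed)
                de = call_differential(fcs_by_kind[kind], st, "validation", cfg)
                de_by_kind[kind] = de
                write_results(de, out_dir / f"de_{kind}.tsv")
                counts[f"{kind}_called"] = sum(
                    1 for r in de if r.regulation != "ns")
            return counts
        run_stage("de", _de)

    if "roc" in stages:
        def _roc():
            counts = {}
            group_of = design.group_of()
            for kind, expr in exprs.items():
                rocs = []
                for feat in expr.feature_ids:
                    row = expr.values.loc[feat]
                    ok = row.notna() & row.index.isin(group_of)
                    labels = [group_of[s] for s in row.index[ok]]
                    if len(set(labels)) < 2:
                        continue
                    rocs.append(roc_auc(row[ok].to_numpy(float), labels,
                                        feature_label=feat))
                write_results(rocs, out_dir / f"roc_{kind}.tsv",
                              columns=["feature_label", "auc", "orientation",
                                       "n_pos", "n_neg"])
                counts[f"{kind}_curves"] = len(rocs)
            return counts
        run_stage("roc", _roc)

    if "disrupt" in stages:
        def _disrupt():
            if "mirna" not in exprs or "mrna" not in exprs:
                raise ValueError("disrupt stage needs both miRNA and mRNA matrices")
            corr = pairwise_correlations(exprs["mirna"], exprs["mrna"], design)
            recs = detect_disruption(corr, cfg)
            write_results(corr, out_dir / "correlations.tsv")
            write_results(recs, out_dir / "disruption.tsv")
            flagged = [r for r in recs if r.flagged]
            rocs = disruption_roc(flagged, exprs["mirna"], exprs["mrna"], design)
            write_results(rocs, out_dir / "disruption_roc.tsv",
                          columns=["feature_label", "auc", "orientation",
                                   "n_pos", "n_neg"])
            return {"pairs": len(recs), "flagged": len(flagged)}
        run_stage("disrupt", _disrupt)

    if "confirm" in stages:
        def _confirm():
            import pandas as pd
            ext = pd.read_csv(inputs["external_ratios"], sep="\t")
            table = dict(zip(ext.iloc[:, 0].astype(str),
                             ext.iloc[:, 1].astype(float)))
            counts = {}
            for kind, de in de_by_kind.items():
                try:
                    recs, summary = confirm_against_external(
                        de, table, cfg.log2_ratio_threshold)
                except ValueError:
                    continue
                write_results(recs, out_dir / f"concordance_{kind}.tsv")
                counts[f"{kind}_confirmed"] = (
                    summary["confirmed_up"] + summary["confirmed_down"])
            return counts
        run_stage("confirm", _confirm)

    if "enrich" in stages:
        def _enrich():
            interactions = read_interactions(inputs["interactions"])
            sets = read_gene_sets(inputs["gene_sets"])
            de = de_by_kind.get("mirna", [])
            demirs = [r.feature_id for r in de if r.regulation != "ns"] or [
                e.mirna_id for e in interactions]
            net = build_target_network(demirs, interactions,
                                       cfg.top_interactions)
            targets = {n for n, d in net.nodes(data=True)
                       if d.get("bipartite") == "gene"}
            universe = {e.target_gene for e in interactions}
            ora = overrepresentation(targets & universe, sets, universe)
            write_results(ora, out_dir / "ora.tsv")
            counts = {"network_edges": net.number_of_edges(),
                      "ora_sets": len(ora)}
            if "mrna" in fcs_by_kind:
                ranking = {r.feature_id: float(np.log2(r.fc_mean))
                           for r in fcs_by_kind["mrna"]}
                gsea = gsea_preranked(ranking, sets, cfg,
                                      n_perm=min(cfg.n_permutations, 1000),
                                      seed=cfg.rng_seed)
                write_results(gsea, out_dir / "gsea.tsv")
                counts["gsea_sets"] = len(gsea)
            return counts
        run_stage("enrich", _enrich)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out_dir / "manifest.json")
    return manifest
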