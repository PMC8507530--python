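"""Shared data model, configuration and tabular I/O.

The pipeline's inputs are qRT-PCR cycle-threshold (CT) tables, a paired
tumor/normal sample sheet, log-scale expression matrices, miRNA-target
interaction tables and GMT gene sets.  Everything here is plain TSV/CSV,
GMT or JSON; parsing is strict — a file violating an invariant raises a
named error instead of being silently coerced.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CtRecord",
    "PairedDesign",
    "ExpressionMatrix",
    "AnalysisConfig",
    "GeneSet",
    "InteractionEdge",
    "ParseError",
    "DuplicateError",
    "FormatError",
    "read_ct_table",
    "read_design",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_interactions",
    "write_results",
    "read_results",
]


class ParseError(ValueError):
    """A cell failed to parse; the message names the offending line."""


class DuplicateError(ValueError):
    """A record that must be unique appeared twice."""


class FormatError(ValueError):
    """A structural problem with a file (wrong column count, empty set...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CtRecord:
    """Raw or aggregated PCR cycle values for one (assay, sample).

    CT is the cycle at which fluorescence crosses the detection threshold;
    lower CT means more template.  ``replicate_values`` preserves the
    technical replicates in input order; ``aggregated_ct`` is filled by
    :func:`mirdisrupt.quantification.aggregate_replicates`.
    """

    assay_id: str
    sample_id: str
    replicate_values: list[float] = field(default_factory=list)
    aggregated_ct: float | None = None

    def __post_init__(self) -> None:
        for v in self.replicate_values:
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"CT must be finite and >= 0, got {v!r} for "
                    f"({self.assay_id}, {self.sample_id})"
                )
        if self.aggregated_ct is not None and (
            not math.isfinite(self.aggregated_ct) or self.aggregated_ct < 0
        ):
            raise ValueError(
                f"aggregated CT must be finite and >= 0, got {self.aggregated_ct!r}"
            )


@dataclass
class PairedDesign:
    """Patient -> (tumor sample, normal sample) mapping.

    Each patient contributes exactly one tumor (TT) and one matched
    non-neoplastic (NNT) sample; no sample ID may appear twice.
    """

    patients: list[str]
    tumor_of: dict[str, str]
    normal_of: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.patients)) != len(self.patients):
            raise DuplicateError("duplicate patient IDs in design")
        seen: set[str] = set()
        for p in self.patients:
            if p not in self.tumor_of or p not in self.normal_of:
                raise FormatError(f"patient {p!r} lacks a tumor or normal sample")
            for s in (self.tumor_of[p], self.normal_of[p]):
                if s in seen:
                    raise DuplicateError(f"sample {s!r} appears twice in design")
                seen.add(s)

    @property
    def tumor_samples(self) -> list[str]:
        return [self.tumor_of[p] for p in self.patients]

    @property
    def normal_samples(self) -> list[str]:
        return [self.normal_of[p] for p in self.patients]

    def group_of(self) -> dict[str, str]:
        """Sample -> group label ('TT' tumor / 'NNT' non-neoplastic)."""
        out: dict[str, str] = {}
        for p in self.patients:
            out[self.tumor_of[p]] = "TT"
            out[self.normal_of[p]] = "NNT"
        return out

    @classmethod
    def from_records(cls, rows: Iterable[tuple[str, str, str]]) -> "PairedDesign":
        patients, tumor_of, normal_of = [], {}, {}
        for pid, tt, nnt in rows:
            patients.append(pid)
            tumor_of[pid] = tt
            normal_of[pid] = nnt
        return cls(patients, tumor_of, normal_of)


@dataclass
class ExpressionMatrix:
    """Features x samples on a log-like scale, with group labels.

    ``values`` rows are features, columns samples.  The scale tag records
    whether entries are -dCT (CT normalised to endogenous controls, sign
    flipped so higher = more expressed) or log2 intensities.  Missing
    values are NaN, never silent zeros.
    """

    values: pd.DataFrame  # index = feature_ids, columns = sample_ids
    group_of: dict[str, str]
    scale_tag: str = "neg_delta_ct"  # or "log2"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise DuplicateError("duplicate feature IDs in expression matrix")
        if self.values.columns.has_duplicates:
            raise DuplicateError("duplicate sample IDs in expression matrix")
        if self.scale_tag not in ("neg_delta_ct", "log2"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of.get(s) == group]


@dataclass
class AnalysisConfig:
    """Every threshold the pipeline applies, in one place.

    Defaults mirror the study design this package models: a strict CT < 24
    usability cut for the nanofluidic gene panel, 2000 sign-flip
    permutations with p < 0.05 and BH FDR < 0.05 for qRT-PCR validation,
    |FC| >= 2 with p < 0.01 and FDR < 0.05 for the microarray screen,
    |log2 ratio| > 1 for external concordance, a 99% band for
    correlation-disruption calls, the 100-edge target-network cut and the
    (10, 500) exclusive gene-set size window for GSEA.
    """

    max_ct: float = 24.0
    n_permutations: int = 2000
    p_threshold_validation: float = 0.05
    fdr_threshold_validation: float = 0.05
    microarray_fc_threshold: float = 2.0
    microarray_p_threshold: float = 0.01
    microarray_fdr_threshold: float = 0.05
    log2_ratio_threshold: float = 1.0
    disruption_ci: float = 0.99
    ora_fdr_down: float = 0.05
    ora_fdr_up: float = 0.10
    top_interactions: int = 100
    gsea_min_set: int = 10
    gsea_max_set: int = 500
    reactome_fdr: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "max_ct", "n_permutations", "p_threshold_validation",
            "fdr_threshold_validation", "microarray_fc_threshold",
            "microarray_p_threshold", "microarray_fdr_threshold",
            "log2_ratio_threshold", "ora_fdr_down", "ora_fdr_up",
            "top_interactions", "gsea_min_set", "gsea_max_set", "reactome_fdr",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.disruption_ci < 1.0:
            raise ValueError("disruption_ci must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GeneSet:
    name: str
    description: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} is empty")


@dataclass
class InteractionEdge:
    """One experimentally supported miRNA->target interaction.

    ``evidence`` distinguishes strong (reporter assay, western blot) from
    weak (high-throughput) support; ``support`` counts supporting
    experiments.
    """

    mirna_id: str
    target_gene: str
    evidence: str  # strong | weak
    support: int = 1

    def __post_init__(self) -> None:
        if self.evidence not in ("strong", "weak"):
            raise ValueError(f"evidence must be strong|weak, got {self.evidence!r}")
        if self.support < 1:
            raise ValueError("support must be >= 1")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_MISSING_STRINGS = {"", "na", "nan", "n/a", "null", "none"}


def _parse_ct_cell(cell: str, line_no: int, na_999: bool) -> float | None:
    token = cell.strip()
    if token.lower() in _MISSING_STRINGS:
        return None
    try:
        value = float(token)
    except ValueError:
        raise ParseError(f"line {line_no}: cannot parse CT value {cell!r}") from None
    if na_999 and value == 999.0:
        return None
    if not math.isfinite(value) or value < 0:
        raise ParseError(f"line {line_no}: CT value {value!r} out of range")
    return value


def _sniff_sep(path: Path) -> str:
    head = path.open().readline()
    return "," if ("," in head and "\t" not in head) else "\t"


def read_ct_table(
    path: str | Path,
    dialect: str = "auto",
    na_999: bool = False,
) -> list[CtRecord]:
    """Read a CT table in long or wide layout.

    Long layout has columns (assay, sample, replicate, ct); wide layout has
    assay IDs in the first column and sample IDs as the header, one CT per
    cell.  ``dialect='auto'`` sniffs the header.  With ``na_999`` the
    Fluidigm no-amplification code 999 maps to missing.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(sep)]
    lower = [h.lower() for h in header]

    if dialect == "auto":
        dialect = "long" if {"assay", "sample", "ct"} <= set(lower) else "wide"

    records: dict[tuple[str, str], CtRecord] = {}
    if dialect == "long":
        try:
            i_assay = lower.index("assay")
            i_sample = lower.index("sample")
            i_ct = lower.index("ct")
        except ValueError:
            raise FormatError(
                f"{path}: long dialect needs columns assay, sample, ct"
            ) from None
        i_rep = lower.index("replicate") if "replicate" in lower else None
        seen_rep: set[tuple[str, str, str]] = set()
        for line_no, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            cells = line.split(sep)
            if len(cells) < len(header):
                raise ParseError(f"line {line_no}: expected {len(header)} fields")
            assay, sample = cells[i_assay].strip(), cells[i_sample].strip()
            rep_label = cells[i_rep].strip() if i_rep is not None else str(line_no)
            key3 = (assay, sample, rep_label)
            if key3 in seen_rep:
                raise DuplicateError(
                    f"line {line_no}: duplicate replicate {rep_label!r} for "
                    f"({assay}, {sample})"
                )
            seen_rep.add(key3)
            value = _parse_ct_cell(cells[i_ct], line_no, na_999)
            rec = records.setdefault(
                (assay, sample), CtRecord(assay_id=assay, sample_id=sample)
            )
            if value is not None:
                rec.replicate_values.append(value)
    elif dialect == "wide":
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise DuplicateError(f"{path}: duplicate sample IDs in header")
        for line_no, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            cells = line.split(sep)
            if len(cells) != len(header):
                raise ParseError(f"line {line_no}: expected {len(header)} fields")
            assay = cells[0].strip()
            for sample, cell in zip(sample_ids, cells[1:]):
                if (assay, sample) in records:
                    raise DuplicateError(
                        f"line {line_no}: duplicate record for ({assay}, {sample})"
                    )
                value = _parse_ct_cell(cell, line_no, na_999)
                rec = CtRecord(assay_id=assay, sample_id=sample)
                if value is not None:
                    rec.replicate_values.append(value)
                records[(assay, sample)] = rec
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return list(records.values())


def read_design(path: str | Path) -> PairedDesign:
    """Read a paired-design sample sheet (patient_id, tumor_sample, normal_sample)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    required = {"patient_id", "tumor_sample", "normal_sample"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: needs columns {sorted(required)}")
    return PairedDesign.from_records(
        (r.patient_id, r.tumor_sample, r.normal_sample) for r in df.itertuples()
    )


def read_expression_matrix(
    path: str | Path,
    design: PairedDesign | None = None,
    scale_tag: str = "neg_delta_ct",
) -> ExpressionMatrix:
    """Read a features x samples TSV (first column = feature IDs)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    group_of = design.group_of() if design is not None else {}
    return ExpressionMatrix(values=df.astype(float), group_of=group_of,
                            scale_tag=scale_tag)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="feature_id",
                       float_format="%.10g")


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: name, description, then members, tab-separated.

    Duplicate members within a line are removed (first occurrence kept);
    a line with fewer than three fields is a format error.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {line_no}: GMT line needs >= 3 fields")
            name, desc, *members = fields
            dedup = list(dict.fromkeys(m for m in members if m.strip()))
            if not dedup:
                raise FormatError(f"line {line_no}: gene set {name!r} is empty")
            sets.append(GeneSet(name=name, description=desc, members=dedup))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_interactions(path: str | Path) -> list[InteractionEdge]:
    """Read a miRNA-target interaction TSV (mirna, target, evidence, support)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    required = {"mirna", "target", "evidence"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: needs columns {sorted(required)}")
    edges: list[InteractionEdge] = []
    seen: set[tuple[str, str, str]] = set()
    for line_no, row in enumerate(df.itertuples(), start=2):
        support = int(getattr(row, "support", 1) or 1)
        key = (row.mirna, row.target, row.evidence)
        if key in seen:
            raise DuplicateError(f"line {line_no}: duplicate edge {key}")
        seen.add(key)
        edges.append(InteractionEdge(row.mirna, row.target, row.evidence, support))
    return edges


# ---------------------------------------------------------------------------
# Generic result writer (dataclass records -> TSV / JSON, round-trip safe)
# ---------------------------------------------------------------------------

def _records_to_frame(records: Sequence) -> pd.DataFrame:
    if not records:
        return pd.DataFrame()
    first = records[0]
    if dataclasses.is_dataclass(first):
        if any(type(r) is not type(first) for r in records):
            raise TypeError("records must be homogeneous")
        return pd.DataFrame([dataclasses.asdict(r) for r in records])
    if isinstance(first, Mapping):
        return pd.DataFrame(list(records))
    raise TypeError(f"cannot serialise records of type {type(first).__name__}")


def write_results(
    records: Sequence,
    path: str | Path,
    format: str = "tsv",
    columns: Sequence[str] | None = None,
) -> None:
    """Write a homogeneous record collection as TSV (6 sig digits) or JSON
    (full double precision).  Lists inside records are JSON-encoded in TSV
    cells so the round trip is lossless at the stated precision.
    """
    df = _records_to_frame(records)
    if columns is not None and not df.empty:
        df = df[list(columns)]
    path = Path(path)
    if format == "tsv":
        enc = df.copy()
        for col in enc.columns:
            enc[col] = enc[col].map(
                lambda v: json.dumps(v) if isinstance(v, (list, tuple, dict)) else v
            )
        if columns is not None and enc.empty:
            enc = pd.DataFrame(columns=list(columns))
        enc.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1, default=float)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read back a file produced by :func:`write_results`."""
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        for col in df.columns:
            if df[col].dtype == object:
                df[col] = df[col].map(
                    lambda v: json.loads(v)
                    if isinstance(v, str) and v[:1] in "[{" else v
                )
        return df
    if format == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    raise ValueError(f"unknown format {format!r}")
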