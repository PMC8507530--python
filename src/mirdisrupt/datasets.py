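"""Published summary tables from the penile squamous-cell carcinoma study
this pipeline models, usable as worked-example inputs.

Three small tables: the nine microarray-selected miRNAs with their
microarray and qRT-PCR validation fold changes; the external log2
(normalized counts + 1) tumor/normal ratios for those miRNAs from the
ArrayExpress E-MTAB-3087 small-RNA comparison; and the 37 differentially
expressed genes of the 83-gene qRT-PCR panel with comparative-CT fold
changes (24 tumor/normal pairs).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "mirna_validation_table",
    "external_mirna_ratios",
    "gene_panel_fold_changes",
]

# miRNA, regulation on the array, microarray FC, microarray FDR,
# qRT-PCR validation FC, SD of per-pair FCs, validation FDR
_MIRNA_VALIDATION = [
    ("miR-432-5p", "down", 0.07, 0.0048, 0.41, 0.51, 0.004),
    ("miR-487b-3p", "down", 0.12, 0.0079, 0.44, 0.45, 0.004),
    ("miR-145-5p", "down", 0.18, 0.0088, 0.33, 0.37, 0.005),
    ("miR-30a-5p", "down", 0.21, 0.0067, 0.57, 0.32, 0.002),
    ("miR-149-5p", "down", 0.29, 0.0308, 0.79, 1.04, 0.097),
    ("miR-200a-5p", "up", 2.93, 0.0048, 3.48, 1.28, 0.004),
    ("miR-224-5p", "up", 6.59, 0.0083, 5.70, 3.19, 0.001),
    ("miR-31-3p", "up", 12.38, 0.0002, 41.62, 41.43, 0.004),
    ("miR-31-5p", "up", 38.32, 0.0048, 122.28, 127.75, 0.001),
]

# log2(normalized counts + 1) tumor/normal ratio, E-MTAB-3087
_EXTERNAL_MIRNA_RATIOS = {
    "miR-30a-5p": -8.165,
    "miR-432-5p": -7.947,
    "miR-487b-3p": -6.236,
    "miR-145-5p": -3.425,
    "miR-200a-5p": -0.551,
    "miR-224-5p": -5.815,
    "miR-31-3p": -3.342,
    "miR-31-5p": 2.914,
}

# gene, 2^-ddCT fold change TT vs NNT, FDR ("<0.001" coded as 0.0005)
_GENE_PANEL = [
    ("ABCB1", 0.24, 0.0005), ("ALDH1A1", 0.09, 0.0005), ("BCL2", 0.31, 0.0005),
    ("CCND1", 0.61, 0.007), ("EGR1", 0.19, 0.0005), ("FGF2", 0.18, 0.0005),
    ("FOS", 0.18, 0.0005), ("HOXA9", 0.51, 0.003), ("KAT6A", 0.47, 0.0005),
    ("KLF4", 0.22, 0.0005), ("KMT2A", 0.40, 0.0005), ("LATS2", 0.58, 0.004),
    ("MDM2", 0.71, 0.003), ("MLH1", 0.77, 0.007), ("NANOG", 0.33, 0.005),
    ("NRP1", 0.48, 0.0005), ("PEBP1", 0.53, 0.0005), ("PITX2", 0.30, 0.0005),
    ("PPARGC1A", 0.11, 0.0005), ("PTEN", 0.55, 0.0005), ("RECK", 0.24, 0.0005),
    ("RHOA", 0.66, 0.0005), ("RIPK3", 0.53, 0.0005), ("SAV1", 0.45, 0.0005),
    ("STAT3", 0.66, 0.0005), ("STK4", 0.65, 0.002), ("TCF7L2", 0.36, 0.0005),
    ("TLR4", 0.28, 0.0005), ("TP53", 0.57, 0.003), ("TWIST1", 0.18, 0.0005),
    ("ZEB1", 0.23, 0.0005),
    ("IL1A", 13.39, 0.0005), ("MCM2", 2.14, 0.0005), ("MMP1", 28.00, 0.0005),
    ("MMP12", 9.97, 0.0005), ("SFN", 4.26, 0.004), ("VEGFA", 2.06, 0.0005),
]


def mirna_validation_table() -> pd.DataFrame:
    """Nine microarray-selected miRNAs with validation-cohort fold changes."""
    return pd.DataFrame(
        _MIRNA_VALIDATION,
        columns=["mirna", "regulation", "microarray_fc", "microarray_fdr",
                 "qrtpcr_fc", "qrtpcr_sd", "qrtpcr_fdr"],
    )


def external_mirna_ratios() -> dict[str, float]:
    """External log2 tumor/normal ratios for the nine validated miRNAs."""
    return dict(_EXTERNAL_MIRNA_RATIOS)


def gene_panel_fold_changes() -> pd.DataFrame:
    """The 37 differentially expressed panel genes with 2^-ddCT fold changes."""
    return pd.DataFrame(_GENE_PANEL, columns=["gene", "fc", "fdr"])
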