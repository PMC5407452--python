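"""Curated reference gene panels for the fetal adrenal/testis system.

Small literature-derived lookup tables used in tests and examples: the
45-gene panel of known and candidate human steroidogenesis components
grouped by functional category, and the top differentially up-regulated
genes of the fetal adrenal (vs control) and of the post-onset ("late")
versus pre-onset ("early") fetal testis, with their published log2 and
absolute fold changes.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "steroidogenesis_candidate_panel",
    "top_adrenal_genes",
    "top_testis_late_genes",
]

_CANDIDATE_PANEL: dict[str, tuple[str, ...]] = {
    "Steroidogenesis": (
        "CYP17A1", "CYP11A1", "STAR", "FDX1P1", "FDX1", "PAPSS2",
        "HSD3B2", "POR",
    ),
    "Cholesterol metabolism & oxidative stress": (
        "SERPINA5", "SCARB1", "DHCR24", "APOA1", "APOC1", "MSMO1",
        "AS3MT", "LDLR", "DHCR7", "ACSS1", "NPC1", "PDK4", "ABCA5",
        "IDI1", "GPD1L", "HMGCR",
    ),
    "Oxidative stress": ("GSTA1", "MGST1", "SLC8B1", "GSTA3"),
    "Novel": (
        "MGARP", "MAP3K15", "HPGD", "C7", "MT2A", "DLK1", "INHA",
        "FOXO4", "GRAMD1B", "RMDN2", "SLC46A3", "SLC16A9", "COL15A1",
        "AVPI1", "FRRS1", "VCAM1", "FLJ38894",
    ),
}

# (gene, log2FC, absolute FC) — adrenal vs control, descending log2FC.
_TOP_ADRENAL = [
    ("CYP17A1", 7.91, 240.2), ("CYP11A1", 6.85, 115.4),
    ("SULT2A1", 6.60, 97.3), ("STAR", 6.20, 73.4), ("MC2R", 5.96, 62.3),
    ("CYP11B1", 5.58, 47.8), ("MGARP", 5.21, 37.1), ("GSTA1", 5.15, 35.5),
    ("MAP3K15", 5.11, 34.5), ("NPR3", 4.62, 24.6), ("ASB4", 4.60, 24.3),
    ("HPGD", 4.46, 22.0), ("GNRHR", 4.43, 21.6), ("C7", 4.34, 20.3),
    ("SERPINA5", 4.26, 19.2), ("FDX1P1", 4.26, 19.1), ("SCARB1", 4.15, 17.8),
    ("NRK", 4.09, 17.1), ("CYP21A2", 4.09, 17.1), ("FDX1", 4.03, 16.3),
]

# (gene, log2FC, absolute FC) — late vs early testis, descending log2FC.
_TOP_TESTIS_LATE = [
    ("CYP17A1", 5.27, 38.5), ("LHCGR", 3.47, 11.1), ("INSL3", 3.13, 8.8),
    ("CYP11A1", 3.08, 8.5), ("CALB2", 2.86, 7.3), ("SCARB1", 2.83, 7.1),
    ("STAR", 2.54, 5.8), ("DHCR24", 2.22, 4.6), ("ABCA10", 2.21, 4.6),
    ("MGARP", 2.16, 4.5), ("MSMO1", 2.12, 4.3), ("GRAMD1B", 2.04, 4.1),
    ("HSD17B6", 2.03, 4.1), ("EGFLAM", 2.02, 4.1), ("ABCA8", 2.02, 4.0),
    ("IDI1", 2.01, 4.0), ("LDLR", 1.95, 3.9), ("LUM", 1.95, 3.9),
    ("SPARCL1", 1.94, 3.8), ("HSD3B2", 1.92, 3.8), ("HSD17B3", 1.87, 3.7),
    ("INHA", 1.40, 2.6), ("AMH", 1.18, 2.3), ("POR", 1.07, 2.1),
]


def steroidogenesis_candidate_panel() -> dict[str, tuple[str, ...]]:
    """The 45-gene steroidogenesis candidate panel, by functional category.

    Eight established steroidogenic enzymes/cofactors, sixteen cholesterol
    metabolism genes, four oxidative-stress genes and seventeen candidates
    with no previously established steroidogenic role ("Novel").
    """
    return {k: tuple(v) for k, v in _CANDIDATE_PANEL.items()}


def top_adrenal_genes() -> pd.DataFrame:
    """Top differentially up-regulated fetal adrenal genes (vs control):
    columns gene, log2fc, abs_fc."""
    return pd.DataFrame(_TOP_ADRENAL, columns=["gene", "log2fc", "abs_fc"])


def top_testis_late_genes() -> pd.DataFrame:
    """Top differentially up-regulated late-testis genes (vs early testis):
    columns gene, log2fc, abs_fc."""
    return pd.DataFrame(_TOP_TESTIS_LATE, columns=["gene", "log2fc", "abs_fc"])
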