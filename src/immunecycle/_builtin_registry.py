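"""Reduced built-in cancer-immune gene registry.

The full 8-panel, 546-gene registry travels as a user-supplied two-column
file (see :func:`immunecycle.panels.load_panel_set`). This module ships a
reduced registry — the same 8 functional categories of the cancer-immunity
cycle, each with 10–20 representative marker genes — sufficient to exercise
every pipeline stage on synthetic data. Panel B (type I interferon) carries
"production"/"signaling" sub-tags because the two arms are scored
separately when phenotype labels are assigned.

Rows are (gene, panel, tag); tag is "" where no sub-tag applies.
"""

from __future__ import annotations

PANEL_NAMES: dict[str, str] = {
    "A": "ubiquitination/deubiquitination system",
    "B": "type I IFN production/signaling",
    "C": "antigen-processing/presenting machinery",
    "D": "TGF-beta signaling",
    "E": "NK cell activation",
    "F": "dendritic cell activation",
    "G": "tumor microenvironment",
    "H": "T cell activation/effector function",
}

BUILTIN_REGISTRY_ROWS: list[tuple[str, str, str]] = [
    # Panel A — ubiquitin ligases / deubiquitinases steering immune signaling
    ("UBE2L6", "A", ""), ("UBA7", "A", ""), ("TRIM21", "A", ""),
    ("TRIM25", "A", ""), ("RNF213", "A", ""), ("HERC5", "A", ""),
    ("HERC6", "A", ""), ("USP18", "A", ""), ("UBE2N", "A", ""),
    ("CBLB", "A", ""), ("ITCH", "A", ""), ("NEDD4", "A", ""),
    ("MDM2", "A", ""), ("FBXW7", "A", ""),
    # Panel B — type I IFN: nucleic-acid sensing / production arm ...
    ("TLR3", "B", "production"), ("DDX58", "B", "production"),
    ("IFIH1", "B", "production"), ("CGAS", "B", "production"),
    ("STING1", "B", "production"), ("TBK1", "B", "production"),
    ("IRF3", "B", "production"), ("IRF7", "B", "production"),
    ("MYD88", "B", "production"), ("MAVS", "B", "production"),
    ("IFI16", "B", "production"),
    # ... and the receptor/JAK-STAT signaling arm
    ("IFNAR1", "B", "signaling"), ("IFNAR2", "B", "signaling"),
    ("STAT1", "B", "signaling"), ("STAT2", "B", "signaling"),
    ("IRF9", "B", "signaling"), ("JAK1", "B", "signaling"),
    ("JAK2", "B", "signaling"), ("TYK2", "B", "signaling"),
    ("ISG15", "B", "signaling"), ("MX1", "B", "signaling"),
    # Panel C — proteasomal processing, peptide loading, MHC expression
    ("PSMB8", "C", ""), ("PSMB9", "C", ""), ("PSMB10", "C", ""),
    ("TAP1", "C", ""), ("TAP2", "C", ""), ("TAPBP", "C", ""),
    ("ERAP1", "C", ""), ("ERAP2", "C", ""), ("CANX", "C", ""),
    ("CALR", "C", ""), ("B2M", "C", ""), ("HLA-A", "C", ""),
    ("HLA-B", "C", ""), ("HLA-DRA", "C", ""), ("HLA-DQA1", "C", ""),
    ("CIITA", "C", ""), ("NLRC5", "C", ""),
    # Panel D — TGF-beta ligands, receptors, SMADs
    ("TGFB1", "D", ""), ("TGFB2", "D", ""), ("TGFB3", "D", ""),
    ("TGFBR1", "D", ""), ("TGFBR2", "D", ""), ("SMAD2", "D", ""),
    ("SMAD3", "D", ""), ("SMAD4", "D", ""), ("SMAD7", "D", ""),
    ("SKI", "D", ""), ("THBS1", "D", ""),
    # Panel E — NK activating/inhibitory receptors and their drivers
    ("NCR1", "E", ""), ("NCR2", "E", ""), ("NCR3", "E", ""),
    ("KLRK1", "E", ""), ("KLRC1", "E", ""), ("KLRD1", "E", ""),
    ("FCGR3A", "E", ""), ("IL15", "E", ""), ("IL18", "E", ""),
    ("ULBP1", "E", ""),
    # Panel F — DC maturation and lymph-node migration
    ("BATF3", "F", ""), ("IRF8", "F", ""), ("FLT3", "F", ""),
    ("FLT3LG", "F", ""), ("CD80", "F", ""), ("CD86", "F", ""),
    ("CD40", "F", ""), ("CCR7", "F", ""), ("CCL19", "F", ""),
    ("CCL21", "F", ""), ("ITGAX", "F", ""),
    # Panel G — TME: tumor-side interaction markers, myeloid recruitment,
    # angiogenesis
    ("IFNGR1", "G", ""), ("CD274", "G", ""), ("CXCL9", "G", ""),
    ("CXCL10", "G", ""), ("CXCL11", "G", ""), ("VEGFA", "G", ""),
    ("HIF1A", "G", ""), ("CCL2", "G", ""), ("CSF1", "G", ""),
    ("CSF1R", "G", ""), ("IL6", "G", ""), ("IL10", "G", ""),
    ("PTGS2", "G", ""), ("CXCL12", "G", ""),
    # Panel H — T cell activation, trafficking, recognition, killing
    ("CD3E", "H", ""), ("CD8A", "H", ""), ("CD4", "H", ""),
    ("GZMA", "H", ""), ("GZMB", "H", ""), ("PRF1", "H", ""),
    ("IFNG", "H", ""), ("PDCD1", "H", ""), ("CXCR3", "H", ""),
    ("CTLA4", "H", ""), ("LAG3", "H", ""), ("CD27", "H", ""),
    ("CD28", "H", ""), ("ZAP70", "H", ""), ("LCK", "H", ""),
    ("FOXP3", "H", ""), ("IL2RA", "H", ""),
]

# Replacement immune/stromal/cell-cycle marker sets for average-expression
# signature scoring. These are deliberately small, generic marker lists, not
# a reconstruction of any published score's gene set.
DEFAULT_SIGNATURE_SETS: dict[str, tuple[str, ...]] = {
    "immune": ("PTPRC", "CD3E", "CD8A", "CD4", "CD27", "FOXP3",
               "IL2RA", "GZMA", "PRF1", "CXCR3"),
    "stromal": ("COL1A1", "COL1A2", "COL3A1", "FAP", "PDGFRB",
                "ACTA2", "THBS1", "VIM"),
    "cell_cycle": ("MKI67", "CCNB1", "CDK1", "TOP2A", "BUB1", "PLK1"),
}
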