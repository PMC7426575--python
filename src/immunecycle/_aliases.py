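"""Static gene-symbol alias table.

Protein names commonly used in the immuno-oncology literature are mapped to
the HGNC symbols that expression matrices actually use. Applied at load time
everywhere gene identifiers enter the package; matching is case-insensitive
with the uppercase HGNC symbol as canonical form.
"""

from __future__ import annotations

GENE_ALIASES: dict[str, str] = {
    "PD-L1": "CD274",
    "PDL1": "CD274",
    "B7-H1": "CD274",
    "PD-1": "PDCD1",
    "PD1": "PDCD1",
    "IFNG": "IFNG",
    "IFN-G": "IFNG",
    "IFN-GAMMA": "IFNG",
    "IFNGAMMA": "IFNG",
    "IFNγ": "IFNG",  # IFNγ
    "CTLA-4": "CTLA4",
    "TIM-3": "HAVCR2",
    "TIM3": "HAVCR2",
    "NKP30": "NCR3",
    "NKP44": "NCR2",
    "NKP46": "NCR1",
    "NKG2D": "KLRK1",
    "NKG2A": "KLRC1",
    "CD94": "KLRD1",
    "STING": "STING1",
    "TMEM173": "STING1",
    "RIG-I": "DDX58",
    "MDA5": "IFIH1",
}


def canonical_symbol(symbol: str) -> str:
    """Return the canonical uppercase HGNC symbol for ``symbol``."""
    s = str(symbol).strip().upper()
    return GENE_ALIASES.get(s, s)
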