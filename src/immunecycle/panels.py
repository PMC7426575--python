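"""The 8-panel cancer-immune gene registry and named gene signatures.

Panels A–H cover the phases of the cancer-immunity cycle, from
ubiquitination-dependent signaling (A) and type I interferon
production/signaling (B), through antigen processing/presentation (C),
TGF-β signaling (D), NK-cell (E) and dendritic-cell (F) activation, to the
tumor microenvironment (G) and T-cell effector function (H). The full
registry (8 panels, 546 genes) is supplied by the user as a two-column
file; a reduced built-in registry ships for testing and synthetic cohorts.

Named signatures include the tumor-intrinsic classifier (TIC: IFI16, MYD88,
JAK2 from the type I IFN pathway plus TAP1, TAP2, PSMB9, HLA-DQA1 from the
antigen-presenting machinery), the immune response predictor (IRP: IFNGR1,
CD274, CXCL9, IFNG, PDCD1, CXCR3 — the tumor/T-cell interaction axis), and
cytolytic activity (CYT: GZMA, PRF1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._aliases import canonical_symbol
from ._builtin_registry import (BUILTIN_REGISTRY_ROWS, DEFAULT_SIGNATURE_SETS,
                                PANEL_NAMES)
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

VALID_PANEL_IDS = tuple("ABCDEFGH")

TIC_GENES = ("IFI16", "MYD88", "JAK2", "TAP1", "TAP2", "PSMB9", "HLA-DQA1")
IRP_GENES = ("IFNGR1", "CD274", "CXCL9", "IFNG", "PDCD1", "CXCR3")
CYT_GENES = ("GZMA", "PRF1")


@dataclass
class GenePanel:
    """One functional category of the cancer-immunity cycle."""

    panel_id: str
    name: str
    genes: tuple[str, ...]
    sub_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.panel_id not in VALID_PANEL_IDS:
            raise ValueError(f"panel id {self.panel_id!r} outside A-H")
        if not self.genes:
            raise ValueError(f"panel {self.panel_id}: empty gene list")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"panel {self.panel_id}: duplicate gene symbols")
        unknown = set(self.sub_tags) - set(self.genes)
        if unknown:
            raise ValueError(
                f"panel {self.panel_id}: sub_tag keys not in panel: {sorted(unknown)}")

    def tagged(self, tag: str) -> tuple[str, ...]:
        """Genes carrying sub-tag ``tag``, in panel order."""
        return tuple(g for g in self.genes if self.sub_tags.get(g) == tag)


@dataclass
class PanelSet:
    """A collection of gene panels forming one registry."""

    panels: tuple[GenePanel, ...]
    version: str = "0"
    source: str = "builtin-test"

    def __post_init__(self) -> None:
        ids = [p.panel_id for p in self.panels]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate panel ids")

    def __getitem__(self, panel_id: str) -> GenePanel:
        for p in self.panels:
            if p.panel_id == panel_id:
                return p
        raise KeyError(panel_id)

    def __contains__(self, panel_id: str) -> bool:
        return any(p.panel_id == panel_id for p in self.panels)

    @property
    def union_genes(self) -> tuple[str, ...]:
        """All registry genes, first-seen order, each counted once."""
        seen: dict[str, None] = {}
        for p in self.panels:
            for g in p.genes:
                seen.setdefault(g, None)
        return tuple(seen)

    def panel_of(self) -> dict[str, list[str]]:
        """gene -> list of panel ids containing it."""
        out: dict[str, list[str]] = {}
        for p in self.panels:
            for g in p.genes:
                out.setdefault(g, []).append(p.panel_id)
        return out


@dataclass
class GeneSignature:
    """A named gene set scored by (arithmetic or geometric) mean expression."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name}: empty gene list")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name}: duplicate genes")


def load_panel_set(path, source: str | None = None) -> PanelSet:
    """Load a panel registry from a tab-separated definition file.

    Format: header ``gene<TAB>panel<TAB>tag`` then one row per
    (gene, panel); the ``tag`` column is optional and may be empty. Gene
    symbols are canonicalized; duplicate (gene, panel) rows are collapsed
    with a logged warning; panel letters outside A-H are rejected.
    """
    rows: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty panel file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            gene = canonical_symbol(parts[0])
            panel = parts[1].strip().upper()
            tag = parts[2].strip() if len(parts) > 2 else ""
            if panel not in VALID_PANEL_IDS:
                raise ValueError(f"{path}:{lineno}: panel id {panel!r} outside A-H")
            if not gene:
                raise ValueError(f"{path}:{lineno}: empty gene symbol")
            rows.append((gene, panel, tag))
    if not rows:
        raise ValueError(f"{path}: no gene rows")
    return _panel_set_from_rows(rows, version="file",
                                source=source or str(path))


def _panel_set_from_rows(rows, version: str, source: str) -> PanelSet:
    by_panel: dict[str, dict[str, str]] = {}
    n_dupes = 0
    for gene, panel, tag in rows:
        bucket = by_panel.setdefault(panel, {})
        if gene in bucket:
            n_dupes += 1
            continue
        bucket[gene] = tag
    if n_dupes:
        logger.warning("collapsed %d duplicate (gene, panel) rows", n_dupes)
    panels = []
    for pid in sorted(by_panel):
        genes = tuple(by_panel[pid])
        sub_tags = {g: t for g, t in by_panel[pid].items() if t}
        panels.append(GenePanel(panel_id=pid, name=PANEL_NAMES.get(pid, pid),
                                genes=genes, sub_tags=sub_tags))
    return PanelSet(panels=tuple(panels), version=version, source=source)


def write_panel_set(panel_set: PanelSet, path) -> None:
    """Serialize a registry in the dialect :func:`load_panel_set` reads.

    Output is canonically ordered (panels A..H, genes in panel order) so a
    load/write cycle round-trips bit-identically.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tpanel\ttag\n")
        for panel in sorted(panel_set.panels, key=lambda p: p.panel_id):
            for gene in panel.genes:
                fh.write(f"{gene}\t{panel.panel_id}\t{panel.sub_tags.get(gene, '')}\n")


def builtin_panel_set() -> PanelSet:
    """The reduced 8-panel registry bundled for testing and simulation."""
    return _panel_set_from_rows(BUILTIN_REGISTRY_ROWS, version="builtin-0.1",
                                source="builtin-test")


def builtin_signatures(extra: dict[str, list[str]] | None = None
                       ) -> dict[str, GeneSignature]:
    """Bundled named signatures: TIC, IRP, CYT, immune, stromal, cell_cycle.

    ``extra`` entries (name -> gene list, e.g. from a signature config file)
    override or extend the defaults; symbols are canonicalized.
    """
    sigs = {
        "TIC": GeneSignature("TIC", tuple(canonical_symbol(g) for g in TIC_GENES)),
        "IRP": GeneSignature("IRP", tuple(canonical_symbol(g) for g in IRP_GENES)),
        "CYT": GeneSignature("CYT", tuple(canonical_symbol(g) for g in CYT_GENES)),
    }
    for name, genes in DEFAULT_SIGNATURE_SETS.items():
        sigs[name] = GeneSignature(name, tuple(canonical_symbol(g) for g in genes))
    for name, genes in (extra or {}).items():
        sigs[name] = GeneSignature(name, tuple(dict.fromkeys(
            canonical_symbol(g) for g in genes)))
    if set(sigs["TIC"].genes) & set(sigs["IRP"].genes):
        raise ValueError("TIC and IRP gene sets must be disjoint")
    return sigs


def subset_expression(panel_or_signature: GenePanel | GeneSignature | PanelSet,
                      expr: ExpressionMatrix) -> ExpressionMatrix:
    """Rows of ``expr`` for the genes of a panel, signature or whole registry.

    Preserves the panel's gene order, records the missing genes and the
    fraction present in the result's provenance, and errors if no gene
    overlaps.
    """
    if isinstance(panel_or_signature, PanelSet):
        genes = panel_or_signature.union_genes
        label = f"registry:{panel_or_signature.source}"
    else:
        genes = panel_or_signature.genes
        label = getattr(panel_or_signature, "panel_id", None) or panel_or_signature.name
    present = [g for g in genes if g in expr.values.index]
    missing = [g for g in genes if g not in expr.values.index]
    if not present:
        raise ValueError(f"no genes of {label} present in the expression matrix")
    if missing:
        logger.info("%s: %d/%d genes missing from matrix: %s",
                    label, len(missing), len(genes), missing[:10])
    frac = len(present) / len(genes)
    return ExpressionMatrix(
        values=expr.values.loc[present],
        state=expr.state,
        provenance=expr.provenance + [
            f"subset({label}, present={len(present)}/{len(genes)}, "
            f"fraction={frac:.3f}, missing={missing})"])
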