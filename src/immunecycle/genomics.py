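"""Exome-level summaries: TMB, arm-level copy-number burden, mutation landscape.

Mutation and copy-number calls are consumed, never produced: mutations
arrive as a MAF-like table (sample, gene, variant classification), arm-level
copy number as a SEG-like table (sample, chromosome arm, log2 ratio).
Tumor mutational burden counts small nonsynonymous variants (missense,
truncating, inframe) per megabase of capture; amplifications and deep
deletions appear in the mutation landscape but never in TMB. The somatic
copy-number burden is the mean absolute arm log2 ratio per sample, reported
both raw and as a cohort z-score; the signed per-arm means are kept for
subgroup amplification/deletion profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import zscore_vector

logger = logging.getLogger(__name__)

VARIANT_CLASSES = ("missense", "truncating", "inframe", "amplification",
                   "deep_deletion", "silent", "other")

TMB_DEFAULT_CLASSES = frozenset({"missense", "truncating", "inframe"})
DEFAULT_CAPTURE_MB = 30.0

# MAF Variant_Classification -> internal vocabulary
MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "truncating",
    "Frame_Shift_Del": "truncating",
    "Frame_Shift_Ins": "truncating",
    "Splice_Site": "truncating",
    "Nonstop_Mutation": "truncating",
    "Translation_Start_Site": "truncating",
    "In_Frame_Del": "inframe",
    "In_Frame_Ins": "inframe",
    "Silent": "silent",
    "Amplification": "amplification",
    "Deep_Deletion": "deep_deletion",
    "Homozygous_Deletion": "deep_deletion",
}
# canonical MAF spelling used on write
INTERNAL_TO_MAF = {
    "missense": "Missense_Mutation",
    "truncating": "Nonsense_Mutation",
    "inframe": "In_Frame_Del",
    "silent": "Silent",
    "amplification": "Amplification",
    "deep_deletion": "Deep_Deletion",
    "other": "Other",
}

# Canonical 39-arm vocabulary: 22 autosomes × (p, q) minus the five
# acrocentric p-arms conventionally excluded from arm-level calls.
ACROCENTRIC_P = frozenset({"13p", "14p", "15p", "21p", "22p"})
ARM_VOCABULARY = tuple(
    f"{chrom}{arm}" for chrom in range(1, 23) for arm in ("p", "q")
    if f"{chrom}{arm}" not in ACROCENTRIC_P)


@dataclass
class MutationTable:
    """Somatic mutation records: (sample_id, gene, variant_class)."""

    records: pd.DataFrame  # columns sample_id, gene, variant_class

    def __post_init__(self) -> None:
        need = {"sample_id", "gene", "variant_class"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"mutation table needs columns {sorted(need)}")
        bad = set(self.records["variant_class"]) - set(VARIANT_CLASSES)
        if bad:
            raise ValueError(f"unknown variant classes: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())


@dataclass
class ArmCNATable:
    """Arm-level copy-number records: (sample_id, arm, log2_ratio)."""

    records: pd.DataFrame  # columns sample_id, arm, log2_ratio

    def __post_init__(self) -> None:
        need = {"sample_id", "arm", "log2_ratio"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"CNA table needs columns {sorted(need)}")
        bad = set(self.records["arm"]) - set(ARM_VOCABULARY)
        if bad:
            raise ValueError(f"arm labels outside the canonical vocabulary: {sorted(bad)}")
        if self.records.duplicated(["sample_id", "arm"]).any():
            raise ValueError("multiple records for one (sample, arm)")

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())


def read_maf(path) -> MutationTable:
    """Read a MAF-like TSV (Tumor_Sample_Barcode, Hugo_Symbol,
    Variant_Classification); classes are collapsed to the internal
    vocabulary, unknown classes to ``other`` with a logged count."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {"Tumor_Sample_Barcode": "sample_id", "Hugo_Symbol": "gene",
            "Variant_Classification": "variant_class"}
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"MAF file missing columns {sorted(missing)}")
    df = df.rename(columns=cols)[list(cols.values())]
    mapped = df["variant_class"].map(MAF_CLASS_MAP)
    n_other = int(mapped.isna().sum())
    if n_other:
        logger.info("%d MAF records with unmapped classes -> 'other'", n_other)
    df["variant_class"] = mapped.fillna("other")
    return MutationTable(records=df)


def write_maf(muts: MutationTable, path) -> None:
    out = muts.records[["sample_id", "gene", "variant_class"]].copy()
    out["variant_class"] = out["variant_class"].map(INTERNAL_TO_MAF)
    out.columns = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]
    out.to_csv(path, sep="\t", index=False)


def read_seg(path) -> ArmCNATable:
    """Read a SEG-like TSV: sample, arm, log2_ratio."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"sample": str, "arm": str, "log2_ratio": float})
    need = {"sample", "arm", "log2_ratio"}
    if not need.issubset(df.columns):
        raise ValueError(f"SEG file missing columns {sorted(need - set(df.columns))}")
    df = df.rename(columns={"sample": "sample_id"})
    return ArmCNATable(records=df[["sample_id", "arm", "log2_ratio"]])


def write_seg(cna: ArmCNATable, path) -> None:
    out = cna.records.rename(columns={"sample_id": "sample"})
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def tmb(muts: MutationTable, capture_mb: float = DEFAULT_CAPTURE_MB,
        counted_classes=TMB_DEFAULT_CLASSES, sample_ids=None) -> pd.Series:
    """Per-sample tumor mutational burden, mutations per megabase.

    Counts records whose class is in ``counted_classes`` and divides by the
    capture size. ``sample_ids`` fixes the cohort so samples without
    records report 0.
    """
    if capture_mb <= 0:
        raise ValueError("capture_mb must be positive")
    counted = frozenset(counted_classes)
    if not counted:
        raise ValueError("counted_classes must be non-empty")
    bad = counted - set(VARIANT_CLASSES)
    if bad:
        raise ValueError(f"unknown counted classes: {sorted(bad)}")
    rec = muts.records
    hits = rec[rec["variant_class"].isin(counted)]
    counts = hits.groupby("sample_id").size()
    index = list(sample_ids) if sample_ids is not None else muts.sample_ids
    out = counts.reindex(index, fill_value=0).astype(float) / capture_mb
    out.name = "TMB"
    return out


def scna_burden(cna: ArmCNATable) -> pd.DataFrame:
    """Per-sample copy-number burden and its cohort-normalized score.

    burden = mean over arms of |log2 ratio|; scna_score = population
    z-score of burden across the cohort (all-zero if burden is constant).
    """
    rec = cna.records
    burden = rec.groupby("sample_id")["log2_ratio"].apply(
        lambda v: float(np.abs(v.to_numpy()).mean()))
    out = pd.DataFrame({"burden": burden})
    out["scna_score"] = zscore_vector(out["burden"].to_numpy())
    out.index.name = "sample_id"
    return out


def subgroup_arm_profile(cna: ArmCNATable, groups) -> pd.DataFrame:
    """Signed mean log2 ratio per (subgroup, arm); preserves amp/del sign."""
    groups = pd.Series(groups)
    rec = cna.records
    missing = set(rec["sample_id"]) - set(groups.index)
    if missing:
        raise ValueError(f"CNA samples without subgroup assignment: {sorted(missing)[:5]}")
    rec = rec.assign(subgroup=groups.loc[rec["sample_id"]].to_numpy())
    prof = rec.pivot_table(index="subgroup", columns="arm",
                           values="log2_ratio", aggfunc="mean")
    cols = [a for a in ARM_VOCABULARY if a in prof.columns]
    return prof[cols]


def mutation_landscape(muts: MutationTable, genes, groups
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Alteration frequencies per (gene, subgroup), plus a per-class breakdown.

    The frequency is the fraction of subgroup samples with at least one
    record of the gene (a sample with several variant classes in one gene
    counts once). Genes absent from the table report 0 everywhere.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    groups = pd.Series(groups)
    levels = sorted(groups.unique())
    sizes = {lev: int((groups == lev).sum()) for lev in levels}
    rec = muts.records[muts.records["gene"].isin(genes)]
    rec = rec[rec["sample_id"].isin(groups.index)]
    rec = rec.assign(subgroup=groups.loc[rec["sample_id"]].to_numpy())

    freq = pd.DataFrame(0.0, index=genes, columns=levels)
    altered = rec.drop_duplicates(["sample_id", "gene"])
    tally = altered.groupby(["gene", "subgroup"]).size()
    for (gene, lev), n in tally.items():
        freq.loc[gene, lev] = n / sizes[lev]

    by_class = (rec.drop_duplicates(["sample_id", "gene", "variant_class"])
                .groupby(["gene", "subgroup", "variant_class"]).size()
                .rename("n_samples").reset_index())
    freq.index.name = "gene"
    return freq, by_class
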