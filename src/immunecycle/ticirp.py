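"""Tumor-intrinsic classifier (TIC) and immune response predictor (IRP).

TIC summarizes the upstream immune-escape-initiating domains — three type I
IFN pathway genes (IFI16, MYD88, JAK2) and four antigen-presenting-machinery
genes (TAP1, TAP2, PSMB9, HLA-DQA1); IRP summarizes the tumor/T-cell
interaction axis (IFNGR1, CD274, CXCL9, IFNG, PDCD1, CXCR3). Each score is
the per-sample geometric mean of linear-scale expression (pseudocount 1),
normalized within the cohort by population z-score. Samples are placed in
quadrants of the (TIC, IRP) plane — quadrant 1 = both positive, where ICB
responders are expected to concentrate — and, when response labels are
available, the scores are tested between responders (PR) and
non-responders (NR/PD pooled) with Welch's t, alongside the Pearson
correlation between the two normalized scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, zscore_vector
from .panels import GeneSignature, builtin_signatures

logger = logging.getLogger(__name__)

RESPONSE_LABELS = ("PR", "NR", "PD", "NA")
MIN_TIC_GENES = 4  # of 7
MIN_IRP_GENES = 4  # of 6


@dataclass
class TicIrpResult:
    """Per-sample TIC/IRP scores, quadrants, and optional response labels."""

    sample_ids: list[str]
    tic_raw: np.ndarray
    irp_raw: np.ndarray
    tic_norm: np.ndarray
    irp_norm: np.ndarray
    quadrant: np.ndarray               # 1..4
    response: pd.Series | None = None  # PR / NR / PD / NA

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for name in ("tic_raw", "irp_raw", "tic_norm", "irp_norm", "quadrant"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name}: length mismatch")
        for name in ("tic_norm", "irp_norm"):
            if abs(getattr(self, name).mean()) > 1e-9:
                raise ValueError(f"{name} not centered")

    def quadrant_counts(self) -> dict[int, int]:
        return {q: int((self.quadrant == q).sum()) for q in (1, 2, 3, 4)}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "tic_raw": self.tic_raw, "irp_raw": self.irp_raw,
            "tic_norm": self.tic_norm, "irp_norm": self.irp_norm,
            "quadrant": self.quadrant,
        }, index=pd.Index(self.sample_ids, name="sample_id"))
        if self.response is not None:
            df["response"] = self.response.loc[self.sample_ids].to_numpy()
        return df


def geometric_mean_score(expr: ExpressionMatrix, genes: GeneSignature,
                         pseudocount: float = 1.0) -> pd.Series:
    """Per-sample geometric mean of linear-scale expression.

    exp(mean(log(x + pseudocount))) - pseudocount over the signature genes
    present in the matrix; missing genes are reported.
    """
    if expr.state != "raw":
        raise ValueError("geometric_mean_score requires linear-scale (raw) values")
    present = [g for g in genes.genes if g in expr.values.index]
    missing = [g for g in genes.genes if g not in expr.values.index]
    if not present:
        raise ValueError(f"no genes of {genes.name} in matrix")
    if missing:
        logger.info("%s: missing genes %s", genes.name, missing)
    vals = expr.values.loc[present].to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative expression values")
    out = np.exp(np.log(vals + pseudocount).mean(axis=0)) - pseudocount
    return pd.Series(out, index=expr.sample_ids, name=genes.name)


def _quadrants(tic_norm: np.ndarray, irp_norm: np.ndarray) -> np.ndarray:
    """Quadrant of the (TIC, IRP) plane; axis values of exactly 0 count as
    positive. 1 = (+,+), 2 = (-,+), 3 = (-,-), 4 = (+,-)."""
    tp = tic_norm >= 0
    ip = irp_norm >= 0
    q = np.empty(len(tic_norm), dtype=int)
    q[tp & ip] = 1
    q[~tp & ip] = 2
    q[~tp & ~ip] = 3
    q[tp & ~ip] = 4
    return q


def tic_irp_scores(expr: ExpressionMatrix, response=None,
                   pseudocount: float = 1.0) -> TicIrpResult:
    """Compute cohort-normalized TIC and IRP scores and quadrants.

    Requires at least 4 of the 7 TIC genes and 4 of the 6 IRP genes and a
    cohort of at least 3 samples (the within-cohort z-score is meaningless
    below that). ``response`` is an optional sample -> {PR, NR, PD} mapping;
    unlabelled samples become NA.
    """
    if expr.n_samples < 3:
        raise ValueError("cohort too small for within-cohort normalization (need >= 3)")
    sigs = builtin_signatures()
    for sig, lo in ((sigs["TIC"], MIN_TIC_GENES), (sigs["IRP"], MIN_IRP_GENES)):
        present = [g for g in sig.genes if g in expr.values.index]
        if len(present) < lo:
            missing = [g for g in sig.genes if g not in expr.values.index]
            raise ValueError(
                f"only {len(present)} of {len(sig.genes)} {sig.name} genes "
                f"present (need >= {lo}); missing: {missing}")
    tic_raw = geometric_mean_score(expr, sigs["TIC"], pseudocount).to_numpy()
    irp_raw = geometric_mean_score(expr, sigs["IRP"], pseudocount).to_numpy()
    tic_norm = zscore_vector(tic_raw)
    irp_norm = zscore_vector(irp_raw)
    resp = None
    if response is not None:
        resp = pd.Series(response).reindex(expr.sample_ids).fillna("NA")
        bad = set(resp.unique()) - set(RESPONSE_LABELS)
        if bad:
            raise ValueError(f"unknown response labels: {sorted(bad)}")
    return TicIrpResult(sample_ids=expr.sample_ids,
                        tic_raw=tic_raw, irp_raw=irp_raw,
                        tic_norm=tic_norm, irp_norm=irp_norm,
                        quadrant=_quadrants(tic_norm, irp_norm),
                        response=resp)


def response_association(result: TicIrpResult) -> dict:
    """Association of normalized TIC/IRP with ICB response.

    Welch t-tests of tic_norm and irp_norm between responders (PR) and
    non-responders (NR and PD pooled), the Pearson correlation between the
    two normalized scores, and the quadrant-1 responder count.
    """
    if result.response is None or (result.response == "NA").all():
        raise ValueError("no response labels available")
    resp = result.response.loc[result.sample_ids].to_numpy()
    is_pr = resp == "PR"
    is_non = np.isin(resp, ("NR", "PD"))
    if is_pr.sum() < 2 or is_non.sum() < 2:
        raise ValueError("need >= 2 responders and >= 2 non-responders")
    out: dict = {"n_pr": int(is_pr.sum()), "n_non_pr": int(is_non.sum())}
    for name, vec in (("tic", result.tic_norm), ("irp", result.irp_norm)):
        t = stats.ttest_ind(vec[is_pr], vec[is_non], equal_var=False)
        out[f"{name}_t"] = float(t.statistic)
        out[f"{name}_p"] = float(t.pvalue)
    r, rp = stats.pearsonr(result.tic_norm, result.irp_norm)
    out["pearson_r"] = float(r)
    out["pearson_p"] = float(rp)
    out["quadrant1_pr"] = int(((result.quadrant == 1) & is_pr).sum())
    out["quadrant1_pr_fraction"] = (out["quadrant1_pr"] / out["n_pr"]
                                    if out["n_pr"] else float("nan"))
    out["quadrant_counts"] = result.quadrant_counts()
    return out


def read_response(path) -> pd.Series:
    """Response TSV: sample_id <TAB> response with values PR/NR/PD."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "response"}.issubset(df.columns):
        raise ValueError("response file needs columns sample_id, response")
    s = df.set_index("sample_id")["response"]
    bad = set(s.unique()) - set(RESPONSE_LABELS)
    if bad:
        raise ValueError(f"unknown response labels: {sorted(bad)}")
    return s


class TicIrpModel:
    """ICB-response classifier over a cohort's linear-scale expression."""

    def __init__(self, expr: ExpressionMatrix, response=None,
                 pseudocount: float = 1.0):
        self.expr = expr
        self.response = response
        self.pseudocount = pseudocount

    def fit(self) -> "TicIrpResults":
        res = tic_irp_scores(self.expr, response=self.response,
                             pseudocount=self.pseudocount)
        return TicIrpResults(self, res)


class TicIrpResults:
    """Fitted TIC/IRP scores with response association on demand."""

    def __init__(self, model: TicIrpModel, result: TicIrpResult):
        self.model = model
        self.result = result

    def association(self) -> dict:
        return response_association(self.result)

    def to_frame(self) -> pd.DataFrame:
        return self.result.to_frame()

    def summary(self) -> str:
        counts = self.result.quadrant_counts()
        lines = [
            "TIC/IRP geometric-mean classifier",
            f"  samples: {len(self.result.sample_ids)}"
            f"   pseudocount: {self.model.pseudocount:g}",
            "  quadrant counts (1=TIC+/IRP+): "
            + ", ".join(f"Q{q}={counts[q]}" for q in (1, 2, 3, 4)),
        ]
        if self.result.response is not None and (self.result.response != "NA").any():
            try:
                a = self.association()
                lines += [
                    f"  PR vs non-PR Welch t: TIC t={a['tic_t']:.3f} "
                    f"p={a['tic_p']:.3g}; IRP t={a['irp_t']:.3f} p={a['irp_p']:.3g}",
                    f"  Pearson r(TIC, IRP) = {a['pearson_r']:.3f} "
                    f"(p={a['pearson_p']:.3g})",
                    f"  responders in quadrant 1: {a['quadrant1_pr']}/{a['n_pr']}",
                ]
            except ValueError as exc:
                lines.append(f"  response association unavailable: {exc}")
        return "\n".join(lines)
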