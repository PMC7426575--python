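"""Per-sample signature scores and subgroup comparison statistics.

Scoring follows the average-expression convention: a signature score is the
arithmetic mean of the signature genes' expression in the matrix's current
state. Cytolytic activity (CYT) is the geometric mean of GZMA and PRF1 on
the linear scale with a pseudocount of 1. High/low classes are cut at
configurable percentiles (>70th / <30th by default elsewhere in the
pipeline). Group comparisons offer Welch's t (a pooled-variance flag is
available) and the Mann-Whitney U test — normal approximation with tie
correction for groups of >= 8, full exact enumeration below that.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, zscore_vector
from .panels import GeneSignature, builtin_signatures

logger = logging.getLogger(__name__)

EXACT_MW_THRESHOLD = 8  # below this per-group size the exact test is used


@dataclass
class ScoreTable:
    """Named per-sample score vectors with normalization provenance."""

    sample_ids: list[str]
    scores: dict[str, np.ndarray] = field(default_factory=dict)
    normalization: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, values, normalization: str = "raw") -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.sample_ids),):
            raise ValueError(f"score {name}: length mismatch")
        if np.isnan(values).any():
            raise ValueError(f"score {name}: NaN values")
        self.scores[name] = values
        self.normalization[name] = normalization

    def __getitem__(self, name: str) -> pd.Series:
        return pd.Series(self.scores[name], index=self.sample_ids, name=name)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, index=self.sample_ids)
        df.index.name = "sample_id"
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class GroupComparison:
    """Two-group test result on one score."""

    score_name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    statistic_name: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("groups overlap")
        if not self.group_a or not self.group_b:
            raise ValueError("empty group")


def signature_score(expr: ExpressionMatrix, sig: GeneSignature) -> pd.Series:
    """Arithmetic-mean expression of the signature genes present in ``expr``."""
    present = [g for g in sig.genes if g in expr.values.index]
    if not present:
        raise ValueError(f"no genes of signature {sig.name} in matrix")
    missing = [g for g in sig.genes if g not in expr.values.index]
    if missing:
        logger.info("signature %s: missing genes %s", sig.name, missing)
    out = expr.values.loc[present].mean(axis=0)
    out.name = sig.name
    return out


def percentile_classes(score, hi: float = 70.0, lo: float = 30.0) -> pd.Series:
    """Classify samples as high (> hi-th pct), low (< lo-th pct), or mid.

    Percentiles use linear interpolation between order statistics; cut-offs
    are strict inequalities, so values equal to a percentile fall to mid.
    A constant vector yields all-mid with a logged warning.
    """
    if not (0 <= lo < hi <= 100):
        raise ValueError(f"need 0 <= lo < hi <= 100, got lo={lo} hi={hi}")
    s = pd.Series(score, dtype=float)
    vals = s.to_numpy()
    if np.ptp(vals) == 0:
        logger.warning("constant score vector: all samples classed mid")
        return pd.Series("mid", index=s.index)
    hi_cut = np.percentile(vals, hi, method="linear")
    lo_cut = np.percentile(vals, lo, method="linear")
    classes = np.where(vals > hi_cut, "high", np.where(vals < lo_cut, "low", "mid"))
    return pd.Series(classes, index=s.index)


def cytolytic_activity(expr: ExpressionMatrix) -> pd.Series:
    """CYT: geometric mean of (GZMA+1, PRF1+1) minus 1, on the linear scale."""
    if expr.state != "raw":
        raise ValueError("cytolytic_activity requires linear-scale (raw) values")
    sigs = builtin_signatures()
    cyt = sigs["CYT"]
    missing = [g for g in cyt.genes if g not in expr.values.index]
    if missing:
        raise ValueError(f"CYT genes absent from matrix: {missing}")
    vals = expr.values.loc[list(cyt.genes)].to_numpy(dtype=float)
    score = np.exp(np.log(vals + 1.0).mean(axis=0)) - 1.0
    return pd.Series(score, index=expr.sample_ids, name="CYT")


def subgroup_summary(scores: ScoreTable, groups) -> pd.DataFrame:
    """Per-subgroup mean of cohort-z-scored scores.

    Each score is z-scored (population) across all samples first, then
    averaged within each subgroup. ``groups`` is a sample -> subgroup
    mapping (e.g. ``SubgroupAssignment.subgroup_series()``).
    """
    groups = pd.Series(groups)
    missing = [s for s in scores.sample_ids if s not in groups.index]
    if missing:
        raise ValueError(f"samples without subgroup assignment: {missing[:5]}")
    g = groups.loc[scores.sample_ids]
    levels = sorted(g.unique())
    if not levels:
        raise ValueError("no subgroups in assignment")
    out = {}
    for name, vals in scores.scores.items():
        z = zscore_vector(vals)
        out[name] = [float(z[(g == lev).to_numpy()].mean()) for lev in levels]
    return pd.DataFrame(out, index=pd.Index(levels, name="subgroup")).T


def _rank_sum_distribution(ranks: np.ndarray, n1: int) -> dict[float, int]:
    """Null distribution of the group-1 rank sum over all assignments.

    Integer ranks (no ties) use a subset-sum dynamic program; midranks from
    ties fall back to explicit enumeration of combinations.
    """
    N = len(ranks)
    if np.allclose(ranks, np.round(ranks)):
        ints = np.round(ranks).astype(int)
        # dp[j] maps achievable rank-sum -> count for subsets of size j
        dp: list[dict[int, int]] = [dict() for _ in range(n1 + 1)]
        dp[0][0] = 1
        for r in ints:
            for j in range(min(n1, N) - 1, -1, -1):
                if not dp[j]:
                    continue
                nxt = dp[j + 1]
                for s, c in dp[j].items():
                    nxt[s + r] = nxt.get(s + r, 0) + c
        return {float(s): c for s, c in dp[n1].items()}
    counts: dict[float, int] = {}
    for comb in itertools.combinations(range(N), n1):
        s = float(ranks[list(comb)].sum())
        counts[s] = counts.get(s, 0) + 1
    return counts


def exact_mannwhitney(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U by full enumeration (tie-safe).

    Returns (U of the first group, p). The two-sided p-value is the null
    probability of a U at least as far from its mean n1*n2/2 as observed,
    which makes identical groups return exactly 1 and perfectly separated
    groups of size 3 return 2/20 = 0.1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    dist = _rank_sum_distribution(ranks, n1)
    total = sum(dist.values())
    mid = n1 * n2 / 2
    offset = n1 * (n1 + 1) / 2
    dev = abs(u_obs - mid)
    hits = sum(c for s, c in dist.items() if abs((s - offset) - mid) >= dev - 1e-12)
    return u_obs, hits / total


def compare_groups(values, group_a, group_b,
                   method: str = "welch_t", score_name: str = "",
                   pooled_variance: bool = False) -> GroupComparison:
    """Two-sided two-group comparison of a per-sample score.

    ``values`` is a pandas Series indexed by sample id; ``group_a`` and
    ``group_b`` are disjoint sample collections. ``method`` is ``welch_t``
    (Welch by default; ``pooled_variance=True`` gives the classical pooled
    t) or ``mann_whitney_u`` (exact enumeration when either group has fewer
    than 8 samples, normal approximation with tie correction otherwise).
    """
    values = pd.Series(values)
    a_ids, b_ids = tuple(group_a), tuple(group_b)
    if set(a_ids) & set(b_ids):
        raise ValueError("groups overlap")
    if not a_ids or not b_ids:
        raise ValueError("empty group")
    x = values.loc[list(a_ids)].to_numpy(dtype=float)
    y = values.loc[list(b_ids)].to_numpy(dtype=float)
    if method == "welch_t":
        if len(x) < 2 or len(y) < 2:
            raise ValueError("welch_t requires >= 2 samples per group")
        res = stats.ttest_ind(x, y, equal_var=pooled_variance)
        stat, p = float(res.statistic), float(res.pvalue)
        name = "student_t" if pooled_variance else "welch_t"
    elif method == "mann_whitney_u":
        if min(len(x), len(y)) < EXACT_MW_THRESHOLD:
            stat, p = exact_mannwhitney(x, y)
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
        name = "mann_whitney_u"
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(score_name=score_name or str(values.name or ""),
                           group_a=a_ids, group_b=b_ids,
                           statistic_name=name, statistic=stat,
                           p_value=min(p, 1.0))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values (optional flag on comparison tables)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def read_fraction_table(path) -> pd.DataFrame:
    """Immune-cell-fraction TSV (samples × cell types, deconvolution dialect).

    Values must lie in [0, 1] and each row must sum to at most 1.05; rows
    failing the sanity check are rejected with a report.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.astype(float)
    bad_range = df[((df < 0) | (df > 1)).any(axis=1)].index.tolist()
    bad_sum = df[df.sum(axis=1) > 1.05].index.tolist()
    bad = sorted(set(bad_range) | set(bad_sum))
    if bad:
        raise ValueError(
            f"fraction table rows failing sanity checks "
            f"(range [0,1], row sum <= 1.05): {bad}")
    return df
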