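"""Gaussian-mixture subgrouping and immune-escape phenotype labeling.

Samples are clustered on z-scored panel-gene expression with a diagonal-
covariance Gaussian mixture (samples are observations, genes features;
diagonal covariance because the feature count typically exceeds the sample
count). Each recovered cluster is then labeled along three immune-escape
axes — ubiquitination (panel A), type I IFN production/signaling (panel B
sub-tags), antigen presentation (panel C) — producing display strings such
as ``"UB+ IFN1p- AP-"``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .expression import ExpressionMatrix, log_transform, zscore_genes
from .panels import PanelSet, builtin_panel_set, subset_expression

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20180907
DEFAULT_N_INIT = 10


@dataclass
class SubgroupModel:
    """Fitted diagonal-covariance Gaussian mixture over panel genes."""

    k: int
    component_means: np.ndarray        # (k, d)
    component_variances: np.ndarray    # (k, d) diagonal
    mixing_weights: np.ndarray         # (k,)
    feature_genes: list[str]
    seed: int
    n_init: int
    converged: bool
    log_likelihood: float

    def __post_init__(self) -> None:
        self.component_means = np.asarray(self.component_means, dtype=float)
        self.component_variances = np.asarray(self.component_variances, dtype=float)
        self.mixing_weights = np.asarray(self.mixing_weights, dtype=float)
        if (self.mixing_weights < 0).any():
            raise ValueError("negative mixing weight")
        if abs(self.mixing_weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixing weights do not sum to 1")
        if (self.component_variances <= 0).any():
            raise ValueError("non-positive component variance")

    def to_json(self) -> str:
        return json.dumps({
            "k": self.k,
            "component_means": self.component_means.tolist(),
            "component_variances": self.component_variances.tolist(),
            "mixing_weights": self.mixing_weights.tolist(),
            "feature_genes": list(self.feature_genes),
            "seed": self.seed,
            "n_init": self.n_init,
            "converged": self.converged,
            "log_likelihood": self.log_likelihood,
        })

    @classmethod
    def from_json(cls, text: str) -> "SubgroupModel":
        return cls(**json.loads(text))


@dataclass
class PhenotypeLabel:
    """Three-axis immune-escape phenotype of one subgroup.

    ``ub`` and ``ap`` are "+" (functioning) or "-" (defective); ``ifn1``
    additionally distinguishes which type-I-IFN arm is defective:
    production ("p-"), signaling ("s-"), or unresolved ("-").
    """

    ub: str
    ifn1: str
    ap: str

    _UB_AP = ("+", "-")
    _IFN1 = ("+", "p-", "s-", "-")

    def __post_init__(self) -> None:
        if self.ub not in self._UB_AP or self.ap not in self._UB_AP:
            raise ValueError(f"invalid axis value: ub={self.ub!r} ap={self.ap!r}")
        if self.ifn1 not in self._IFN1:
            raise ValueError(f"invalid IFN1 value {self.ifn1!r}")

    @property
    def display(self) -> str:
        return f"UB{self.ub} IFN1{self.ifn1} AP{self.ap}"


@dataclass
class SubgroupAssignment:
    """Per-sample cluster assignment with posteriors and phenotype labels."""

    sample_ids: list[str]
    labels: np.ndarray                 # (n,) cluster index, argmax of posterior
    posteriors: pd.DataFrame           # samples x k
    phenotype_of: dict[int, PhenotypeLabel] = field(default_factory=dict)
    subgroup_number_of: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        post = self.posteriors.to_numpy()
        if np.abs(post.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("posterior rows do not sum to 1")
        if not np.array_equal(self.labels, post.argmax(axis=1)):
            raise ValueError("labels are not the argmax of the posteriors")

    @property
    def k(self) -> int:
        return self.posteriors.shape[1]

    @property
    def cluster_of(self) -> dict[str, int]:
        return dict(zip(self.sample_ids, (int(c) for c in self.labels)))

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.labels) if c == cluster]

    def sizes(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in range(self.k)}

    def subgroup_series(self) -> pd.Series:
        """sample -> reported subgroup number (falls back to cluster+1)."""
        num = self.subgroup_number_of or {c: c + 1 for c in range(self.k)}
        return pd.Series([num[int(c)] for c in self.labels],
                         index=self.sample_ids, name="subgroup")


def _observations(expr: ExpressionMatrix) -> np.ndarray:
    """samples x genes feature matrix for mixture fitting."""
    return expr.values.to_numpy(dtype=float).T


def fit_gmm(expr: ExpressionMatrix, k: int, seed: int = DEFAULT_SEED,
            n_init: int = DEFAULT_N_INIT, reg_covar: float = 1e-6,
            max_iter: int = 500) -> SubgroupModel:
    """Fit a diagonal-covariance GMM; best of ``n_init`` EM runs by log-likelihood."""
    if k < 2:
        raise ValueError("k must be at least 2")
    X = _observations(expr)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} samples, got {X.shape[0]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm = GaussianMixture(n_components=k, covariance_type="diag",
                             n_init=n_init, random_state=seed,
                             reg_covar=reg_covar, max_iter=max_iter).fit(X)
    if not gm.converged_:
        logger.warning("EM did not converge in any of %d inits "
                       "(max_iter=%d); best run reported", n_init, max_iter)
    return SubgroupModel(
        k=k,
        component_means=gm.means_,
        component_variances=gm.covariances_,
        mixing_weights=gm.weights_,
        feature_genes=expr.gene_ids,
        seed=seed, n_init=n_init,
        converged=bool(gm.converged_),
        log_likelihood=float(gm.score(X) * X.shape[0]),
    )


def n_parameters(k: int, d: int) -> int:
    """Free parameters of a k-component diagonal GMM in d dimensions."""
    return k * d + k * d + (k - 1)


def bic(model: SubgroupModel, n_samples: int) -> float:
    d = model.component_means.shape[1]
    return -2.0 * model.log_likelihood + n_parameters(model.k, d) * np.log(n_samples)


def select_k(expr: ExpressionMatrix, k_range, seed: int = DEFAULT_SEED,
             n_init: int = DEFAULT_N_INIT) -> int:
    """BIC scan over ``k_range``; returns the argmin (ties -> smallest k)."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    n = expr.n_samples
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    best_k, best_bic = None, np.inf
    for k in ks:
        b = bic(fit_gmm(expr, k, seed=seed, n_init=n_init), n)
        logger.info("select_k: k=%d BIC=%.2f", k, b)
        if b < best_bic - 1e-12:
            best_k, best_bic = k, b
    return best_k


def em_loglik_trace(expr: ExpressionMatrix, k: int, seed: int = DEFAULT_SEED,
                    n_steps: int = 50, reg_covar: float = 1e-6) -> list[float]:
    """Per-iteration EM lower-bound trace for a single seeded run.

    Used to verify the EM monotonicity property; steps one iteration at a
    time with warm starts.
    """
    X = _observations(expr)
    gm = GaussianMixture(n_components=k, covariance_type="diag", n_init=1,
                         random_state=seed, reg_covar=reg_covar, max_iter=1,
                         warm_start=True, tol=0.0)
    trace = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(n_steps):
            gm.fit(X)
            trace.append(float(gm.lower_bound_))
    return trace


def posterior_probabilities(model: SubgroupModel, X: np.ndarray) -> np.ndarray:
    """Component posteriors by Bayes' rule from the stored parameters."""
    mu = model.component_means[None, :, :]          # (1, k, d)
    var = model.component_variances[None, :, :]
    x = X[:, None, :]                               # (n, 1, d)
    log_pdf = -0.5 * (((x - mu) ** 2) / var + np.log(2.0 * np.pi * var)).sum(axis=2)
    log_joint = log_pdf + np.log(model.mixing_weights)[None, :]
    return np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))


def assign(model: SubgroupModel, expr: ExpressionMatrix) -> SubgroupAssignment:
    """Posterior-based hard assignment of samples to mixture components.

    Ties in the posterior argmax go to the lowest component index (numpy
    argmax convention). Phenotype labels are attached afterwards by
    :func:`label_phenotypes`.
    """
    if expr.gene_ids != list(model.feature_genes):
        raise ValueError("expression features do not match model.feature_genes")
    X = _observations(expr)
    post = posterior_probabilities(model, X)
    posteriors = pd.DataFrame(post, index=expr.sample_ids,
                              columns=[f"posterior_{c}" for c in range(model.k)])
    return SubgroupAssignment(sample_ids=expr.sample_ids,
                              labels=post.argmax(axis=1),
                              posteriors=posteriors)


# ---------------------------------------------------------------------------
# Phenotype labeling


def _cluster_panel_mean(expr_z: ExpressionMatrix, genes, members) -> float:
    present = [g for g in genes if g in expr_z.values.index]
    if not present:
        raise ValueError("no panel genes present in matrix")
    return float(expr_z.values.loc[present, members].to_numpy().mean())


def _axis_signs(scores: dict[int, float]) -> dict[int, str]:
    """Generic rank rule for one axis: best cluster "+", worst "-",
    middle clusters "+" iff their mean z is positive. Ties break on the
    lower cluster index (deterministic)."""
    order = sorted(scores, key=lambda c: (-scores[c], c))
    signs = {}
    for rank, c in enumerate(order):
        if rank == 0:
            signs[c] = "+"
        elif rank == len(order) - 1:
            signs[c] = "-"
        else:
            signs[c] = "+" if scores[c] > 0 else "-"
    return signs


def _severity(scores: dict[int, float], c: int) -> float:
    """Defect severity of cluster ``c`` on one axis: mean of the other
    clusters' scores minus its own (positive = below the rest)."""
    others = [scores[o] for o in scores if o != c]
    return float(np.mean(others) - scores[c])


def label_phenotypes(assignment: SubgroupAssignment, expr_z: ExpressionMatrix,
                     panels: PanelSet) -> SubgroupAssignment:
    """Attach three-axis phenotype labels to each cluster.

    Per cluster, mean z-scores are computed over the genes of panel A
    (ubiquitination), the production- and signaling-tagged genes of panel B
    (type I IFN), and panel C (antigen presentation). UB and AP use the
    generic rank rule. The IFN1 axis labels each arm separately and then
    combines: both arms functioning -> "+"; exactly one defective -> that
    arm's letter ("p-" / "s-"); both defective -> the arm with the larger
    defect severity relative to the other clusters (ties -> "-").

    Also fills ``subgroup_number_of``: the cluster with the highest panel
    B+C mean is reported last (the immune-functional, "subgroup 3"-like
    cluster); the remaining clusters are ordered by descending panel-A mean.
    """
    if expr_z.state != "zscore":
        raise ValueError("label_phenotypes requires a z-scored matrix")
    for pid in ("A", "B", "C"):
        if pid not in panels:
            raise ValueError(f"panel {pid} missing from registry")
    panel_b = panels["B"]
    prod_genes = panel_b.tagged("production")
    sig_genes = panel_b.tagged("signaling")
    if not prod_genes or not sig_genes:
        raise ValueError("panel B must carry production/signaling sub-tags")

    clusters = list(range(assignment.k))
    members = {c: assignment.members(c) for c in clusters}
    empty = [c for c in clusters if not members[c]]
    if empty:
        raise ValueError(f"clusters with zero samples: {empty}")

    ub_scores = {c: _cluster_panel_mean(expr_z, panels["A"].genes, members[c])
                 for c in clusters}
    prod_scores = {c: _cluster_panel_mean(expr_z, prod_genes, members[c])
                   for c in clusters}
    sig_scores = {c: _cluster_panel_mean(expr_z, sig_genes, members[c])
                  for c in clusters}
    ap_scores = {c: _cluster_panel_mean(expr_z, panels["C"].genes, members[c])
                 for c in clusters}

    ub_signs = _axis_signs(ub_scores)
    prod_signs = _axis_signs(prod_scores)
    sig_signs = _axis_signs(sig_scores)
    ap_signs = _axis_signs(ap_scores)

    phenotype_of = {}
    for c in clusters:
        if prod_signs[c] == "+" and sig_signs[c] == "+":
            ifn1 = "+"
        elif prod_signs[c] == "-" and sig_signs[c] == "+":
            ifn1 = "p-"
        elif sig_signs[c] == "-" and prod_signs[c] == "+":
            ifn1 = "s-"
        else:  # both arms defective: name the more severe one
            sp, ss = _severity(prod_scores, c), _severity(sig_scores, c)
            if sp > ss:
                ifn1 = "p-"
            elif ss > sp:
                ifn1 = "s-"
            else:
                ifn1 = "-"
        phenotype_of[c] = PhenotypeLabel(ub=ub_signs[c], ifn1=ifn1, ap=ap_signs[c])

    # Reporting order: most immune-functional cluster (highest B+C mean)
    # becomes the last subgroup number; the rest by descending panel-A mean.
    bc = {c: _cluster_panel_mean(expr_z,
                                 tuple(panel_b.genes) + tuple(panels["C"].genes),
                                 members[c])
          for c in clusters}
    last = max(clusters, key=lambda c: (bc[c], -c))
    rest = sorted((c for c in clusters if c != last),
                  key=lambda c: (-ub_scores[c], c))
    subgroup_number_of = {c: i + 1 for i, c in enumerate(rest + [last])}

    assignment.phenotype_of = phenotype_of
    assignment.subgroup_number_of = subgroup_number_of
    return assignment


def write_assignments(assignment: SubgroupAssignment, path) -> None:
    """Assignments TSV: sample, cluster, subgroup label, posteriors."""
    rows = assignment.posteriors.copy()
    rows.insert(0, "cluster", assignment.labels)
    labels = []
    for c in assignment.labels:
        ph = assignment.phenotype_of.get(int(c))
        labels.append(ph.display if ph else "")
    rows.insert(1, "subgroup_label", labels)
    rows.index.name = "sample_id"
    rows.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Model/Results facade


class ImmuneSubgroupModel:
    """Cancer-immunity-cycle subgrouping of a bulk expression cohort.

    Wraps the normalization chain (log2(x+1), per-gene z-score), the
    panel-gene subsetting, the diagonal-covariance Gaussian mixture and the
    three-axis phenotype labeling into a fit-once model object.

    Parameters
    ----------
    expr : ExpressionMatrix
        Cohort expression in raw, log, or zscore state; earlier states are
        normalized through the remaining chain.
    panels : PanelSet, optional
        Gene registry; the built-in reduced registry by default.
    k : int
        Number of mixture components (3 mirrors the reference cohort).
    """

    def __init__(self, expr: ExpressionMatrix, panels: PanelSet | None = None,
                 k: int = 3, log_offset: float = 1.0):
        if k < 2:
            raise ValueError("k must be at least 2")
        self.panels = panels if panels is not None else builtin_panel_set()
        self.k = k
        self.expr_raw = expr
        z = expr
        if z.state == "raw":
            z = log_transform(z, offset=log_offset)
        if z.state == "log":
            z = zscore_genes(z)
        self.expr_z = z
        self.features = subset_expression(self.panels, z)

    @classmethod
    def from_files(cls, expression_path, panel_path=None, k: int = 3
                   ) -> "ImmuneSubgroupModel":
        from .expression import read_expression
        from .panels import load_panel_set
        panels = load_panel_set(panel_path) if panel_path else None
        return cls(read_expression(expression_path), panels=panels, k=k)

    def fit(self, seed: int = DEFAULT_SEED, n_init: int = DEFAULT_N_INIT
            ) -> "ImmuneSubgroupResults":
        params = fit_gmm(self.features, self.k, seed=seed, n_init=n_init)
        assignment = assign(params, self.features)
        assignment = label_phenotypes(assignment, self.features, self.panels)
        return ImmuneSubgroupResults(self, params, assignment)

    def select_k(self, k_range, seed: int = DEFAULT_SEED,
                 n_init: int = DEFAULT_N_INIT) -> int:
        return select_k(self.features, k_range, seed=seed, n_init=n_init)


class ImmuneSubgroupResults:
    """Fitted subgroup model: assignments, phenotype labels, diagnostics."""

    def __init__(self, model: ImmuneSubgroupModel, params: SubgroupModel,
                 assignment: SubgroupAssignment):
        self.model = model
        self.params = params
        self.assignment = assignment

    @property
    def bic(self) -> float:
        return bic(self.params, self.model.features.n_samples)

    @property
    def converged(self) -> bool:
        return self.params.converged

    @property
    def log_likelihood(self) -> float:
        return self.params.log_likelihood

    def subgroup_sizes(self) -> dict[int, int]:
        """Reported-subgroup-number -> sample count."""
        series = self.assignment.subgroup_series()
        return series.value_counts().sort_index().to_dict()

    def phenotype_displays(self) -> dict[int, str]:
        """Reported-subgroup-number -> phenotype display string."""
        num = self.assignment.subgroup_number_of
        return {num[c]: ph.display
                for c, ph in sorted(self.assignment.phenotype_of.items())}

    def per_sample(self) -> pd.DataFrame:
        df = self.assignment.posteriors.copy()
        df.insert(0, "cluster", self.assignment.labels)
        df.insert(1, "subgroup", self.assignment.subgroup_series().to_numpy())
        df.insert(2, "subgroup_label", [
            self.assignment.phenotype_of[int(c)].display
            for c in self.assignment.labels])
        df.index.name = "sample_id"
        return df

    def summary(self) -> str:
        lines = [
            "Immune subgroup model (diagonal-covariance Gaussian mixture)",
            f"  samples: {self.model.features.n_samples}"
            f"   panel genes: {self.model.features.n_genes}"
            f"   components: {self.params.k}",
            f"  seed: {self.params.seed}   n_init: {self.params.n_init}"
            f"   converged: {self.converged}",
            f"  log-likelihood: {self.log_likelihood:.2f}   BIC: {self.bic:.2f}",
            "",
            "  subgroup   n    phenotype",
        ]
        sizes = self.subgroup_sizes()
        displays = self.phenotype_displays()
        for sg in sorted(sizes):
            lines.append(f"  {sg:>8} {sizes[sg]:>4}    {displays[sg]}")
        return "\n".join(lines)
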