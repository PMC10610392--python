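"""Tolerance-category classification: Ward clustering and LDA validation.

Genotype x trait index means are z-scored per trait and clustered with
Ward linkage on Euclidean distances; the tree is cut at k groups (k = 5 by
default) and categories are named HT, T, M, S, HS by descending cluster-mean
grain-yield index.  A pooled-covariance Gaussian linear discriminant model
then re-checks the categories: posterior ∝ prior * exp(-0.5 * Mahalanobis²),
with a Moore–Penrose pseudo-inverse when the pooled covariance is singular
(more predictors than residual degrees of freedom), and leave-one-out
cross-validation by exact refits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import MetselError

logger = logging.getLogger(__name__)

CATEGORY_NAMES = ["HT", "T", "M", "S", "HS"]  # best to worst


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: pd.Series               # genotype -> category name
    cluster_means: pd.DataFrame     # category x trait (raw index means)
    standardized: pd.DataFrame      # z-scores, computation scale
    heatmap: pd.DataFrame           # z-scores clipped at +/-3, display only
    row_order: list
    col_order: list


def ward_cluster(
    means: pd.DataFrame, k: int = 5, gy: str = "GY"
) -> ClusterResult:
    """Ward/Euclidean hierarchical clustering of z-scored trait indices.

    Heights are on the distance scale (Ward.D2 convention).  Categories are
    named HT..HS (for k = 5; C1..Ck otherwise) by descending cluster mean of
    the ``gy`` column.
    """
    if len(means) <= k:
        raise ValueError(f"need more than k={k} rows, got {len(means)}")
    z = (means - means.mean()) / means.std(ddof=1)
    if z.isna().any().any():
        const = list(means.columns[means.std(ddof=1) == 0])
        raise ValueError(f"constant trait columns: {const}")
    link = hierarchy.linkage(z.to_numpy(), method="ward",
                             metric="euclidean")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    if len(np.unique(raw)) < k:
        raise MetselError(
            f"only {len(np.unique(raw))} distinct clusters at k={k} "
            "(duplicate rows collapsed)"
        )
    raw = pd.Series(raw, index=means.index)
    if gy not in means.columns:
        raise KeyError(f"grain-yield column {gy!r} not in means table")
    order = (
        means.groupby(raw)[gy].mean().sort_values(ascending=False).index
    )
    names = CATEGORY_NAMES if k == 5 else [f"C{i + 1}" for i in range(k)]
    name_of = {c: names[i] for i, c in enumerate(order)}
    labels = raw.map(name_of)
    cluster_means = means.groupby(labels).mean().reindex(
        [n for n in names if n in set(labels)]
    )
    dend = hierarchy.dendrogram(link, no_plot=True)
    row_order = [means.index[i] for i in dend["leaves"]]
    col_link = hierarchy.linkage(z.to_numpy().T, method="ward")
    col_dend = hierarchy.dendrogram(col_link, no_plot=True)
    col_order = [means.columns[i] for i in col_dend["leaves"]]
    return ClusterResult(
        linkage=link,
        labels=labels,
        cluster_means=cluster_means,
        standardized=z,
        heatmap=z.clip(-3, 3),
        row_order=row_order,
        col_order=col_order,
    )


@dataclass
class LDAResults:
    """Fitted pooled-covariance linear discriminant model."""

    groups: list[str]
    means: pd.DataFrame             # group x predictor
    pooled_cov: pd.DataFrame
    cov_inverse: np.ndarray
    priors: pd.Series
    pseudo_inverted: bool
    labels: pd.Series
    X: pd.DataFrame = field(repr=False, default=None)
    prior_mode: str = "proportional"

    def posterior(self, X: pd.DataFrame) -> pd.DataFrame:
        """Membership probabilities per row; rows sum to 1."""
        Xv = X[self.means.columns].to_numpy(dtype=float)
        logp = np.empty((len(Xv), len(self.groups)))
        for j, g in enumerate(self.groups):
            d = Xv - self.means.loc[g].to_numpy()
            logp[:, j] = np.log(self.priors[g]) - 0.5 * np.einsum(
                "ij,jk,ik->i", d, self.cov_inverse, d
            )
        logp -= logp.max(axis=1, keepdims=True)
        w = np.exp(logp)
        w /= w.sum(axis=1, keepdims=True)
        return pd.DataFrame(w, index=X.index, columns=self.groups)

    def classify(self, X: pd.DataFrame,
                 prior_labels: pd.Series | None = None) -> "LDAReport":
        post = self.posterior(X)
        assigned = post.idxmax(axis=1)
        prior = (
            self.labels.reindex(X.index)
            if prior_labels is None
            else pd.Series(prior_labels, index=X.index)
        )
        return LDAReport.build(prior, assigned, post)

    def loo(self) -> "LDAReport":
        return lda_loo(self.X, self.labels, prior_mode=self.prior_mode)


@dataclass
class LDAReport:
    table: pd.DataFrame             # prior, posterior, per-group probs
    percent_correct: float
    misclassified: list[str]

    @classmethod
    def build(cls, prior: pd.Series, posterior: pd.Series,
              probs: pd.DataFrame) -> "LDAReport":
        tab = pd.concat(
            [prior.rename("prior"), posterior.rename("posterior"), probs],
            axis=1,
        )
        correct = prior == posterior
        return cls(
            table=tab,
            percent_correct=float(100.0 * correct.mean()),
            misclassified=list(prior.index[~correct]),
        )


def lda_fit(
    X: pd.DataFrame, labels: pd.Series, prior_mode: str = "proportional"
) -> LDAResults:
    """Fit the equal-covariance Gaussian discriminant model.

    ``prior_mode``: 'proportional' (group frequencies) or 'equal'.
    """
    labels = pd.Series(labels, index=X.index)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n, p = X.shape
    means = X.groupby(labels).mean().loc[groups]
    Sw = np.zeros((p, p))
    for g in groups:
        Xg = X[labels == g].to_numpy(dtype=float)
        if len(Xg) == 1 and p > 1:
            warnings.warn(f"group {g!r} has a single member")
        Sw += (Xg - means.loc[g].to_numpy()).T @ (
            Xg - means.loc[g].to_numpy()
        )
    dof = n - len(groups)
    if dof <= 0:
        raise ValueError("no residual degrees of freedom to pool covariance")
    Sw /= dof
    pseudo = p > dof or np.linalg.cond(Sw) > 1e12
    if pseudo:
        logger.info("singular pooled covariance; Moore-Penrose pseudo-inverse")
        inv = np.linalg.pinv(Sw)
    else:
        inv = np.linalg.inv(Sw)
    if prior_mode == "proportional":
        priors = labels.value_counts(normalize=True).reindex(groups)
    elif prior_mode == "equal":
        priors = pd.Series(1.0 / len(groups), index=groups)
    else:
        raise ValueError(f"unknown prior_mode {prior_mode!r}")
    return LDAResults(
        groups=groups,
        means=means,
        pooled_cov=pd.DataFrame(Sw, index=X.columns, columns=X.columns),
        cov_inverse=inv,
        priors=priors,
        pseudo_inverted=pseudo,
        labels=labels,
        X=X,
        prior_mode=prior_mode,
    )


def lda_loo(
    X: pd.DataFrame, labels: pd.Series, prior_mode: str = "proportional"
) -> LDAReport:
    """Leave-one-out cross-validation by exact per-fold refits."""
    labels = pd.Series(labels, index=X.index)
    rows = []
    probs = []
    for idx in X.index:
        mask = X.index != idx
        sub_labels = labels[mask]
        if labels[idx] not in set(sub_labels):
            warnings.warn(
                f"group {labels[idx]!r} vanishes when {idx!r} is held out; "
                "assigned among remaining groups"
            )
        model = lda_fit(X[mask], sub_labels, prior_mode=prior_mode)
        post = model.posterior(X.loc[[idx]])
        probs.append(post.reindex(columns=sorted(labels.unique()),
                                  fill_value=0.0))
        rows.append(post.idxmax(axis=1).iloc[0])
    posterior = pd.Series(rows, index=X.index)
    return LDAReport.build(labels, posterior, pd.concat(probs))


def agreement_table(prior: pd.Series, posterior: pd.Series) -> dict:
    """Confusion matrix, percent correct and the moved items."""
    prior = pd.Series(prior)
    posterior = pd.Series(posterior)
    if len(prior) != len(posterior):
        raise ValueError("label vectors differ in length")
    unknown = set(posterior.unique()) - set(prior.unique())
    if unknown:
        raise ValueError(f"posterior labels not in prior set: {unknown}")
    confusion = pd.crosstab(prior, posterior, dropna=False)
    correct = prior.to_numpy() == posterior.to_numpy()
    moved = [
        {"item": i, "from": a, "to": b}
        for i, a, b in zip(prior.index, prior, posterior)
        if a != b
    ]
    return {
        "confusion": confusion,
        "percent_correct": float(100.0 * correct.mean()),
        "moved": moved,
    }


class ToleranceLDA:
    """Model object for LDA validation of tolerance categories."""

    def __init__(self, X: pd.DataFrame, labels: pd.Series,
                 prior_mode: str = "proportional"):
        self.X = X
        self.labels = pd.Series(labels, index=X.index)
        self.prior_mode = prior_mode

    def fit(self) -> LDAResults:
        return lda_fit(self.X, self.labels, self.prior_mode)
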