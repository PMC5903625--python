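"""Sample-level multivariate analysis: log10 transform, Pearson/Ward
hierarchical clustering, and redundancy analysis (RDA) with a Monte Carlo
permutation test.

RDA is the constrained ordination used throughout community ecology: the
feature-centered response matrix is projected onto the column space of the
explanatory variables, and the canonical axes are the principal axes of the
fitted values. The constrained variance fraction is the share of total
response variance explained by the explanatory variables; its significance
is assessed by permuting sample rows of the explanatory table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "LinkageTree",
    "RdaResult",
    "log10_transform",
    "default_pseudocount",
    "pearson_ward_cluster",
    "rda_fit",
    "rda_permutation_test",
    "species_axis_filter",
]

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------- transform


def default_pseudocount(values: pd.DataFrame) -> float:
    """Half the smallest nonzero entry — scale-aware offset for log10."""
    arr = values.to_numpy(float)
    nz = arr[arr > 0]
    if nz.size == 0:
        raise ValueError("matrix has no positive entries; pseudocount undefined")
    return float(nz.min() / 2.0)


def log10_transform(values: pd.DataFrame, pseudocount: Optional[float] = None) -> pd.DataFrame:
    """Elementwise log10(x + pseudocount).

    ``pseudocount=None`` uses :func:`default_pseudocount` when zeros are
    present and 0 otherwise. A zero entry with pseudocount 0 is an error.
    """
    arr = values.to_numpy(float)
    if (arr < 0).any():
        raise ValueError("negative entries cannot be log-transformed")
    has_zero = bool((arr == 0).any())
    if pseudocount is None:
        pseudocount = default_pseudocount(values) if has_zero else 0.0
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if has_zero and pseudocount == 0:
        raise ValueError("matrix contains zeros; a positive pseudocount is required")
    return pd.DataFrame(
        np.log10(arr + pseudocount), index=values.index, columns=values.columns
    )


# ---------------------------------------------------------------- clustering


@dataclass
class LinkageTree:
    """A hierarchical merge sequence over samples.

    ``merges`` is a scipy-format linkage matrix (n−1 rows: left, right,
    height, size); heights are non-decreasing.
    """

    merges: np.ndarray
    labels: list[str]

    def cut(self, k: int) -> dict[str, int]:
        """sample -> cluster id for a cut into k clusters."""
        assignment = hierarchy.fcluster(self.merges, t=k, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assignment)}

    def to_newick(self) -> str:
        """Newick string with merge heights encoded as branch lengths."""
        tree = hierarchy.to_tree(self.merges)

        def recurse(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:g}"
            inner = ",".join(recurse(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{length:g}"

        root = tree
        inner = ",".join(recurse(c, root.dist) for c in (root.left, root.right))
        return f"({inner});"

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.merges, columns=["left", "right", "height", "size"]
        ).to_csv(path, sep="\t", index=False)


def pearson_ward_cluster(values: pd.DataFrame) -> LinkageTree:
    """Ward minimum-variance clustering of samples on Pearson distances.

    The distance between samples i and j is 1 − r(i, j), the Pearson
    correlation computed across features; Ward's update is applied to these
    dissimilarities directly (the ward.D2-style convention on given
    distances), which keeps the merge sequence deterministic and auditable.
    """
    if values.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    arr = values.to_numpy(float)
    sds = arr.std(axis=0)
    constant = [c for c, s in zip(values.columns, sds) if s == 0]
    if constant:
        raise ValueError(f"constant sample column(s): {constant}; Pearson undefined")
    corr = np.corrcoef(arr, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    condensed = squareform(dist, checks=False)
    merges = hierarchy.linkage(condensed, method="ward")
    return LinkageTree(merges=merges, labels=list(values.columns))


# ----------------------------------------------------------------------- RDA


@dataclass
class RdaResult:
    """Outcome of a redundancy analysis."""

    constrained_fraction: float
    axis_fractions: np.ndarray  # share of total variance per canonical axis
    sample_scores: pd.DataFrame  # samples × axes (U·S)
    feature_scores: pd.DataFrame  # features × axes (right singular vectors)
    explanatory_scores: pd.DataFrame  # variables × axes (correlations with axes)
    permutation_p: Optional[float] = None
    # internal state for the species-axis filter
    _centered_response: Optional[np.ndarray] = field(default=None, repr=False)
    _axes: Optional[np.ndarray] = field(default=None, repr=False)
    feature_ids: Optional[list] = field(default=None, repr=False)

    def write_tsv_triptych(self, prefix) -> None:
        self.sample_scores.to_csv(f"{prefix}_samples.tsv", sep="\t", index_label="sample")
        self.feature_scores.to_csv(f"{prefix}_features.tsv", sep="\t", index_label="feature")
        self.explanatory_scores.to_csv(
            f"{prefix}_variables.tsv", sep="\t", index_label="variable"
        )


def encode_explanatory(explanatory: pd.DataFrame) -> pd.DataFrame:
    """Canoco-style encoding: nominal columns as one-hot indicators (first
    level dropped), continuous columns standardized."""
    cols = {}
    for name in explanatory.columns:
        col = explanatory[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols[f"{name}={lev}"] = (col.astype(str) == lev).astype(float)
        else:
            v = col.to_numpy(float)
            sd = v.std(ddof=1)
            cols[name] = pd.Series(
                (v - v.mean()) / sd if sd > 0 else np.zeros_like(v), index=col.index
            )
    return pd.DataFrame(cols, index=explanatory.index)


def rda_fit(response: pd.DataFrame, explanatory: pd.DataFrame) -> RdaResult:
    """Redundancy analysis of a feature × sample response matrix.

    ``explanatory`` is sample × variable; rows must align with the response
    columns. Perfectly collinear explanatory columns are dropped with a
    warning. With ≥ n−1 independent explanatory columns the projection
    saturates and the constrained fraction is 1 (warned).
    """
    samples = list(response.columns)
    if list(explanatory.index) != samples:
        explanatory = explanatory.loc[samples]
    X_df = encode_explanatory(explanatory)
    n = len(samples)
    Y = response.to_numpy(float).T  # samples × features
    Y = Y - Y.mean(axis=0, keepdims=True)
    X = X_df.to_numpy(float)
    X = X - X.mean(axis=0, keepdims=True)

    # rank-revealing QR to drop collinear columns
    Q, R = np.linalg.qr(X, mode="reduced")
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    keep = diag > tol
    if not keep.all():
        dropped = [c for c, k in zip(X_df.columns, keep) if not k]
        warnings.warn(f"dropping collinear explanatory column(s): {dropped}")
        X = X[:, keep]
        X_df = X_df.loc[:, keep]
        Q = np.linalg.qr(X, mode="reduced")[0]
    rank = X.shape[1]
    if rank >= n - 1:
        warnings.warn(
            "explanatory variables span the sample space; constrained fraction saturates at 1"
        )

    total = float((Y**2).sum())
    if total == 0:
        raise ValueError("response matrix has zero total variance")
    Yhat = Q @ (Q.T @ Y)
    constrained = float((Yhat**2).sum())
    fraction = constrained / total

    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    n_axes = int((s > s.max() * 1e-12).sum()) if s.size and s.max() > 0 else 0
    U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes]
    axis_fractions = (s**2) / total
    axis_names = [f"RDA{i+1}" for i in range(n_axes)]
    sample_scores = pd.DataFrame(U * s, index=samples, columns=axis_names)
    feature_scores = pd.DataFrame(Vt.T, index=response.index, columns=axis_names)
    # biplot scores: correlation of each (centered) explanatory column with the axes
    expl_scores = np.zeros((X.shape[1], n_axes))
    for j in range(X.shape[1]):
        xj = X[:, j]
        for a in range(n_axes):
            denom = np.linalg.norm(xj) * np.linalg.norm(U[:, a])
            expl_scores[j, a] = float(xj @ U[:, a] / denom) if denom > 0 else 0.0
    explanatory_scores = pd.DataFrame(expl_scores, index=X_df.columns, columns=axis_names)
    return RdaResult(
        constrained_fraction=fraction,
        axis_fractions=axis_fractions,
        sample_scores=sample_scores,
        feature_scores=feature_scores,
        explanatory_scores=explanatory_scores,
        _centered_response=Y,
        _axes=U,
        feature_ids=list(response.index),
    )


def rda_permutation_test(
    response: pd.DataFrame,
    explanatory: pd.DataFrame,
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> tuple[float, RdaResult]:
    """Monte Carlo permutation test of the constrained variance fraction.

    Sample rows of the explanatory table are permuted jointly;
    p = (1 + #{permuted fraction ≥ observed}) / (1 + n_permutations), so the
    smallest attainable p is 1/(n_permutations + 1).
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    # canonical (sorted) sample order: the permutation stream then acts on the
    # same data regardless of input column order, so the Monte Carlo p-value
    # is exactly invariant to joint relabeling of samples
    samples = sorted(response.columns)
    response = response[samples]
    expl = explanatory.loc[samples]
    observed = rda_fit(response, expl)
    rng = np.random.default_rng(seed)
    # Permuting the rows of the (already centered) explanatory matrix permutes
    # the rows of its orthonormal basis Q, so the permuted constrained sum of
    # squares is ||Q[perm].T @ Y||^2 — identical to refitting, much cheaper.
    Y = observed._centered_response
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X_df = encode_explanatory(expl)
        X = X_df.to_numpy(float)
    X = X - X.mean(axis=0, keepdims=True)
    Q, R = np.linalg.qr(X, mode="reduced")
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    keep = diag > tol
    if not keep.all():
        Q = np.linalg.qr(X[:, keep], mode="reduced")[0]
    total = float((Y**2).sum())
    observed_ss = observed.constrained_fraction * total
    count = 0
    idx = np.arange(len(samples))
    for _ in range(n_permutations):
        perm = rng.permutation(idx)
        ss = float(((Q[perm].T @ Y) ** 2).sum())
        if ss >= observed_ss - 1e-9 * max(observed_ss, 1.0):
            count += 1
    p = (1 + count) / (1 + n_permutations)
    observed.permutation_p = p
    return p, observed


def species_axis_filter(result: RdaResult, threshold: float = 0.5) -> list:
    """Features with ≥ ``threshold`` of their variance on the first two axes.

    Per feature, the captured variance is the squared norm of the projection
    of its centered response profile onto the span of the first two
    canonical sample axes, relative to its total variance.
    """
    if result._centered_response is None or result._axes is None:
        raise ValueError("RdaResult lacks internal state; refit with rda_fit")
    if result._axes.shape[1] < 2:
        raise ValueError("species filter requires at least 2 canonical axes")
    Y = result._centered_response
    U2 = result._axes[:, :2]
    proj = U2 @ (U2.T @ Y)
    total = (Y**2).sum(axis=0)
    captured = (proj**2).sum(axis=0)
    keep = []
    for j, fid in enumerate(result.feature_ids):
        if total[j] == 0:
            continue
        if captured[j] / total[j] >= threshold - 1e-12:
            keep.append(fid)
    return keep
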