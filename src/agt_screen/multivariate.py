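"""Correlation, PCA, Gower distance, Ward.D2 clustering and cluster profiles.

All operations run on a genotype-indexed table of trait means. The PCA is a
correlation-matrix PCA (traits standardized to zero mean and unit variance
with divisor n), so the eigenvalues sum to the number of traits and the
cos^2 of a trait on a component is the squared correlation between them.

Phenotypic dissimilarity uses Gower's coefficient for numeric traits,

    d(i, j) = (1/m) * sum_k |x_ik - x_jk| / R_k,

with R_k the trait range over the panel, which keeps every entry in [0, 1].
Hierarchical clustering uses the Ward.D2 criterion via the Lance-Williams
update

    d(i u j, l) = sqrt(((n_i+n_l) d_il^2 + (n_j+n_l) d_jl^2
                        - n_l d_ij^2) / (n_i+n_j+n_l)),

which guarantees monotone merge heights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .group_compare import group_summary
from .traits import TRAIT_ORDER

#: Traits recorded under submergence, i.e. those directly expressing
#: anaerobic-germination potential (kernel morphology excluded).
AG_TRAITS: tuple[str, ...] = (
    "AGP", "AVI", "SL", "RL", "RI", "SRR", "NOL", "NOR", "FW", "DW",
)

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _numeric_block(frame: pd.DataFrame, traits: Sequence[str] | None) -> pd.DataFrame:
    if traits is None:
        traits = [t for t in TRAIT_ORDER if t in frame.columns]
    missing = [t for t in traits if t not in frame.columns]
    if missing:
        raise ValidationError(f"traits not in table: {', '.join(missing)}")
    block = frame.loc[:, list(traits)].astype(float)
    if block.isna().any().any():
        raise ValidationError("missing values in trait table")
    return block


# ---------------------------------------------------------------------------
# correlation


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    constant_traits: list[str] = field(default_factory=list)


def correlation_matrix(
    frame: pd.DataFrame, traits: Sequence[str] | None = None
) -> CorrelationResult:
    """Pairwise Pearson correlations with two-sided t-test p-values."""
    block = _numeric_block(frame, traits)
    n = len(block)
    if n < 3:
        raise ValidationError("need at least 3 genotypes for correlations")
    X = block.to_numpy()
    sd = X.std(axis=0)
    constant = [t for t, s in zip(block.columns, sd) if s == 0]

    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X.T)
    np.fill_diagonal(R, 1.0)
    for i, t in enumerate(block.columns):
        if t in constant:
            R[i, :] = np.nan
            R[:, i] = np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = R * np.sqrt((n - 2) / (1.0 - R ** 2))
        P = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(P, 0.0)

    cols = block.columns
    rdf = pd.DataFrame(R, index=cols, columns=cols)
    pdf = pd.DataFrame(P, index=cols, columns=cols)
    stars = pdf.map(_star)
    return CorrelationResult(rdf, pdf, stars, constant)


def _star(p: float) -> str:
    if np.isnan(p):
        return ""
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            return s
    return ""


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    cumulative_percent: np.ndarray
    loadings: pd.DataFrame     # correlation of each trait with each PC
    cos2: pd.DataFrame         # squared loadings
    scores: pd.DataFrame       # genotype coordinates

    @property
    def n_components_eigen_gt1(self) -> int:
        return int((self.eigenvalues > 1.0).sum())


def pca(frame: pd.DataFrame, traits: Sequence[str] | None = None) -> PcaResult:
    """Correlation-matrix PCA of the standardized trait table.

    Standardization uses the population variance (divisor n). Loadings are
    eigenvector entries scaled by sqrt(eigenvalue), i.e. trait-component
    correlations; cos^2 is their square, so each cos^2 column sums to its
    eigenvalue and each row sums to 1 over all components.
    """
    block = _numeric_block(frame, traits)
    sd = block.to_numpy().std(axis=0)
    constant = [t for t, s in zip(block.columns, sd) if s == 0]
    if constant:
        raise ValidationError(f"constant trait(s): {', '.join(constant)}")
    if len(block) <= len(block.columns):
        raise ValidationError("need more genotypes than traits")

    X = block.to_numpy()
    Z = (X - X.mean(axis=0)) / sd
    C = (Z.T @ Z) / len(Z)  # correlation matrix
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for j in range(V.shape[1]):
        i = int(np.abs(V[:, j]).argmax())
        if V[i, j] < 0:
            V[:, j] = -V[:, j]

    pcs = [f"PC{i + 1}" for i in range(len(w))]
    loadings = pd.DataFrame(
        V * np.sqrt(w), index=block.columns, columns=pcs
    )
    cos2 = loadings ** 2
    pct = 100.0 * w / w.sum()
    scores = pd.DataFrame(Z @ V, index=block.index, columns=pcs)
    return PcaResult(
        eigenvalues=w,
        percent_variance=pct,
        cumulative_percent=np.cumsum(pct),
        loadings=loadings,
        cos2=cos2,
        scores=scores,
    )


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        self.matrix = m

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.matrix[i, j])


def gower_distance(
    frame: pd.DataFrame, traits: Sequence[str] | None = None
) -> DistanceMatrix:
    """Range-normalized mean absolute difference over numeric traits."""
    block = _numeric_block(frame, traits)
    X = block.to_numpy()
    ranges = X.max(axis=0) - X.min(axis=0)
    keep = ranges > 0
    dropped = [t for t, k in zip(block.columns, keep) if not k]
    if dropped:
        warnings.warn(
            f"zero-range trait(s) excluded from Gower distance: "
            f"{', '.join(dropped)}",
            stacklevel=2,
        )
    if not keep.any():
        raise ValidationError("no trait with nonzero range")
    Xk = X[:, keep] / ranges[keep]
    diffs = np.abs(Xk[:, None, :] - Xk[None, :, :])
    D = diffs.mean(axis=2)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(block.index), D, "gower")


# ---------------------------------------------------------------------------
# Ward.D2 clustering


@dataclass
class ClusterTree:
    """Agglomerative merge sequence over a distance matrix."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix (n-1) x 4

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def assignments(self, k: int) -> pd.Series:
        """Cluster labels 1..k by cutting the tree at k clusters."""
        n = len(self.labels)
        if not 1 <= k <= n:
            raise ValidationError(f"k must be in [1, {n}]")
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                name = self.labels[node.id].replace(" ", "_")
                return f"{name}:{parent_height:.6g}"
            left = rec(node.get_left(), node.dist)
            right = rec(node.get_right(), node.dist)
            return f"({left},{right}):{max(length, 0.0):.6g}"

        body = rec(tree, tree.dist)
        return body.rsplit(":", 1)[0] + ";"


def ward_d2_cluster(
    distances: DistanceMatrix, k: int | None = None
) -> tuple[ClusterTree, pd.Series | None]:
    """Ward.D2 agglomeration of a precomputed distance matrix.

    Returns the merge tree and, when ``k`` is given, the flat assignment of
    genotypes to clusters 1..k (cut by descending merge height).
    """
    Z = hierarchy.linkage(distances.condensed(), method="ward")
    tree = ClusterTree(list(distances.labels), Z)
    assign = tree.assignments(k) if k is not None else None
    return tree, assign


# ---------------------------------------------------------------------------
# cluster profiling


def within_between_distances(
    assignments: pd.Series, distances: DistanceMatrix
) -> tuple[pd.Series, pd.DataFrame]:
    """Mean pairwise distance within each cluster and between cluster pairs.

    Singleton clusters have within-distance 0 (no pairs).
    """
    labels = sorted(assignments.unique())
    idx = {c: [distances.labels.index(g) for g in assignments.index[assignments == c]]
           for c in labels}
    M = distances.matrix
    within = {}
    for c, ii in idx.items():
        if len(ii) < 2:
            within[c] = 0.0
            continue
        sub = M[np.ix_(ii, ii)]
        within[c] = float(sub[np.triu_indices(len(ii), 1)].mean())
    between = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in labels:
        for b in labels:
            if a == b:
                between.loc[a, b] = within[a]
            else:
                between.loc[a, b] = float(M[np.ix_(idx[a], idx[b])].mean())
    return pd.Series(within, name="within"), between


def cluster_profile(
    assignments: pd.Series,
    records: pd.DataFrame,
    traits: Sequence[str] | None = None,
    distances: DistanceMatrix | None = None,
    alpha: float = 0.05,
) -> dict:
    """Per-cluster trait means with SNK letters plus distance summaries.

    ``assignments`` must cover every genotype in ``records``.
    """
    missing = [g for g in records.index if g not in assignments.index]
    if missing:
        raise ValidationError(
            f"assignments missing for: {', '.join(map(str, missing[:5]))}"
        )
    if traits is None:
        traits = [t for t in TRAIT_ORDER if t in records.columns]
    tab = records.copy()
    tab["cluster"] = assignments.reindex(tab.index)
    summary = group_summary(tab, by="cluster", traits=list(traits), alpha=alpha)
    sizes = tab["cluster"].value_counts().sort_index()
    out = {"summary": summary, "sizes": sizes}
    if distances is not None:
        within, between = within_between_distances(
            assignments.reindex(records.index), distances
        )
        out["within"] = within
        out["between"] = between
    return out
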