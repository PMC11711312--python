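"""Unsupervised afferent analysis: Gower dissimilarity, factor analysis of
mixed data (FAMD), Ward hierarchical clustering and club-like subtype
comparison.

The afferent record mixes continuous axonal parameters (terminal height,
fiber diameter, median Ranvier internode length, branch count) with binary
mechanically relevant flags (ringwulst apposition, root-sheath entry), so
pairwise dissimilarity uses Gower's coefficient — range-normalised absolute
difference for continuous variables, symmetric matching for binary ones,
equally weighted — and dimensionality reduction uses FAMD, the PCA/MCA hybrid
for mixed data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

__all__ = [
    "AXONAL_COLUMNS",
    "MORPHOLOGICAL_COLUMNS",
    "build_mixed_matrix",
    "GowerDissimilarity",
    "gower_matrix",
    "FAMD",
    "WardClusterer",
    "ward_cluster",
    "subtype_comparison",
    "club_subtype_split",
    "SubtypeComparison",
]

# Intrinsic axonal parameter set used for FAMD and the primary Gower matrix.
AXONAL_COLUMNS = {
    "continuous": (
        "terminal_height",
        "fiber_diameter",
        "median_internode_length",
        "branch_count",
    ),
    "binary": ("ringwulst_apposition", "root_sheath_entry"),
}

# Morphological score-sheet flags (the raster-plot view of each afferent).
MORPHOLOGICAL_COLUMNS = {
    "continuous": (),
    "binary": (
        "root_sheath_entry",
        "glassy_membrane_terminal",
        "ringwulst_apposition",
        "shaft_trajectory",
        "branched",
        "multibranch",
    ),
}


def build_mixed_matrix(features: pd.DataFrame, mode: str = "axonal") -> pd.DataFrame:
    """Select the mixed-type variable block for clustering/FAMD.

    mode="axonal" takes the continuous axonal parameters plus the two binary
    mechanical flags; mode="morphological" takes the binary score-sheet flags
    only (deriving ``branched`` from branch_count when absent).
    """
    if mode not in ("axonal", "morphological"):
        raise ValueError(f"unknown mode {mode!r}")
    spec = AXONAL_COLUMNS if mode == "axonal" else MORPHOLOGICAL_COLUMNS
    df = features.copy()
    if "branched" in spec["binary"] and "branched" not in df.columns:
        df["branched"] = df["branch_count"] > 0
    cols = list(spec["continuous"]) + list(spec["binary"])
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {', '.join(missing)}")
    out = df[cols].copy()
    for c in spec["continuous"]:
        out[c] = out[c].astype(float)
    for c in spec["binary"]:
        out[c] = out[c].astype(bool)
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"missing values in mixed feature matrix: {bad}")
    return out


def _split_types(X: pd.DataFrame):
    binary = [c for c in X.columns if X[c].dtype == bool]
    continuous = [c for c in X.columns if c not in binary]
    return continuous, binary


class GowerDissimilarity(TransformerMixin, BaseEstimator):
    """Pairwise Gower dissimilarity for mixed continuous/binary data.

    ``fit`` learns the per-column ranges from the reference data; ``transform``
    returns the square symmetric matrix of mean per-variable dissimilarities
    in [0, 1] (continuous: |xi - xj| / range, 0 when the range is 0; binary:
    symmetric matching 0/1), with equal variable weights.
    """

    def fit(self, X: pd.DataFrame, y=None):
        if len(X) < 2:
            raise ValueError("Gower dissimilarity needs at least 2 rows")
        self.continuous_, self.binary_ = _split_types(X)
        self.ranges_ = {
            c: float(np.ptp(X[c].to_numpy(dtype=float))) for c in self.continuous_
        }
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        n = len(X)
        parts = []
        for c in self.continuous_:
            v = X[c].to_numpy(dtype=float)[:, None]
            rng = self.ranges_[c]
            d = np.abs(v - v.T) / rng if rng > 0 else np.zeros((n, n))
            parts.append(d)
        for c in self.binary_:
            v = X[c].to_numpy(dtype=bool)[:, None]
            parts.append((v != v.T).astype(float))
        D = np.mean(parts, axis=0)
        np.fill_diagonal(D, 0.0)
        return D


def gower_matrix(X: pd.DataFrame) -> np.ndarray:
    """Square symmetric Gower dissimilarity matrix of a mixed-type table."""
    return GowerDissimilarity().fit(X).transform(X)


class FAMD(TransformerMixin, BaseEstimator):
    """Factor analysis of mixed data (principal components for mixed types).

    Continuous columns are standardised to zero mean and unit (population)
    variance. Each binary column contributes two indicator columns, scaled by
    1/sqrt(category proportion) and centered, so that with all-continuous
    input FAMD reduces exactly to PCA of the standardised matrix, and with
    all-binary input to multiple correspondence analysis. Row coordinates are
    the left singular vectors scaled by the singular values; explained
    inertia fractions come from the squared singular values.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    # -- construction of the scaled matrix --------------------------------
    def _build(self, X: pd.DataFrame, fitting: bool) -> np.ndarray:
        blocks = []
        for c in self.continuous_:
            v = X[c].to_numpy(dtype=float)
            blocks.append(((v - self.means_[c]) / self.sds_[c])[:, None])
        for c in self.binary_:
            v = X[c].to_numpy(dtype=bool)
            for level in (False, True):
                p = self.proportions_[(c, level)]
                ind = (v == level).astype(float)
                blocks.append((ind / np.sqrt(p) - self.centers_[(c, level)])[:, None])
        return np.hstack(blocks) if blocks else np.empty((len(X), 0))

    def fit(self, X: pd.DataFrame, y=None):
        if len(X) < self.n_components + 1:
            raise ValueError("FAMD needs at least n_components + 1 rows")
        continuous, binary = _split_types(X)
        self.means_, self.sds_ = {}, {}
        for c in continuous:
            v = X[c].to_numpy(dtype=float)
            sd = v.std(ddof=0)
            if sd == 0:
                raise ValueError(f"constant continuous column: {c!r}")
            self.means_[c], self.sds_[c] = v.mean(), sd
        kept_binary = []
        self.proportions_, self.centers_ = {}, {}
        for c in binary:
            v = X[c].to_numpy(dtype=bool)
            p_true = v.mean()
            if p_true in (0.0, 1.0):
                warnings.warn(
                    f"binary column {c!r} has a single category; dropped from FAMD"
                )
                continue
            kept_binary.append(c)
            for level, p in ((False, 1 - p_true), (True, p_true)):
                self.proportions_[(c, level)] = p
                # centered scaled indicator has mean p/sqrt(p) = sqrt(p)
                self.centers_[(c, level)] = np.sqrt(p)
        self.continuous_, self.binary_ = continuous, kept_binary
        Z = self._build(X, fitting=True)
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        self.singular_values_ = s
        self.components_ = Vt
        total = float((s**2).sum())
        self.explained_inertia_ = (s**2) / total if total > 0 else s * 0.0
        k = min(self.n_components, s.size)
        self.row_coordinates_ = U[:, :k] * s[:k]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        Z = self._build(X, fitting=False)
        k = min(self.n_components, self.singular_values_.size)
        return Z @ self.components_[:k].T

    def fit_transform(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).row_coordinates_


class WardClusterer(ClusterMixin, BaseEstimator):
    """Agglomerative clustering with Ward linkage on a precomputed
    dissimilarity matrix (Lance-Williams recurrence, Ward.D2 convention).

    ``fit`` expects the square symmetric matrix (e.g. Gower distances); the
    dendrogram is stored as ``linkage_`` (scipy format, merge heights
    nondecreasing) and flat labels at ``n_clusters`` as ``labels_``.
    """

    def __init__(self, n_clusters: int = 4):
        self.n_clusters = n_clusters

    def fit(self, D: np.ndarray, y=None):
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("D must be a square dissimilarity matrix")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        self.linkage_ = linkage(squareform(D, checks=False), method="ward")
        self.labels_ = fcluster(self.linkage_, t=self.n_clusters, criterion="maxclust") - 1
        return self

    def fit_predict(self, D: np.ndarray, y=None) -> np.ndarray:
        return self.fit(D).labels_


def ward_cluster(D: np.ndarray, n_clusters: int = 4):
    """Ward clustering of a dissimilarity matrix; returns (labels, linkage)."""
    model = WardClusterer(n_clusters=n_clusters).fit(D)
    return model.labels_, model.linkage_


@dataclass(frozen=True)
class SubtypeComparison:
    """Two-sample comparison of club-like subtypes on each axonal variable."""

    table: pd.DataFrame  # variable, mean_a, mean_b, sd_a, sd_b, t, p_value
    angle_histograms: dict | None = None


def subtype_comparison(
    labels,
    variables: dict[str, np.ndarray],
    angles=None,
    bins: int = 12,
) -> SubtypeComparison:
    """Compare two planted/recovered subtypes variable by variable.

    Two-sided two-sample t-tests on each variable, with per-group means and
    SDs; optionally angular histograms of each subtype around the shaft
    circumference.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"expected exactly 2 subtype labels, got {uniq.size}")
    mask_a = labels == uniq[0]
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValueError("each subtype needs at least 2 members")
    rows = []
    for name, v in variables.items():
        v = np.asarray(v, dtype=float)
        a, b = v[mask_a], v[~mask_a]
        t, p = sps.ttest_ind(a, b)
        rows.append(
            {
                "variable": name,
                "group_a": uniq[0],
                "group_b": uniq[1],
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "sd_a": a.std(ddof=1),
                "sd_b": b.std(ddof=1),
                "t": float(t),
                "p_value": float(p),
            }
        )
    hists = None
    if angles is not None:
        angles = np.asarray(angles, dtype=float)
        edges = np.linspace(0, 360, bins + 1)
        hists = {
            str(uniq[0]): np.histogram(angles[mask_a], bins=edges)[0],
            str(uniq[1]): np.histogram(angles[~mask_a], bins=edges)[0],
            "bin_edges": edges,
        }
    return SubtypeComparison(table=pd.DataFrame(rows), angle_histograms=hists)


def club_subtype_split(features: pd.DataFrame, type_column: str = "afferent_type"):
    """Find the two club-like sub-clusters within the club cluster.

    Restricts to afferents typed club-like, builds the axonal mixed matrix,
    computes Gower distances and cuts the Ward dendrogram at k = 2. Returns
    (club_subframe, subtype_labels).
    """
    club = features.loc[features[type_column] == "ClubLike"]
    if len(club) < 4:
        raise ValueError("need at least 4 club-like afferents for a subtype split")
    X = build_mixed_matrix(club, mode="axonal")
    labels = WardClusterer(n_clusters=2).fit_predict(gower_matrix(X))
    return club, labels
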