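"""Genomic kinship, principal-component covariates and kinship compression.

The kinship matrix K is the VanRaden (method 1) genomic relationship
matrix, K = M Mᵀ / c with M the 2p̂-centered dosage matrix and
c = Σ 2p̂(1 − p̂).  Compression replaces K by an n′ × n′ matrix of
between-group summaries together with an n × n′ incidence matrix Z, so the
mixed-model covariance Z K_g Zᵀ Vg acts at the group level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .genotype_io import GenotypeMatrix, GroupAssignment

VALID_LINKAGES = ("average", "complete", "ward")
VALID_OPERATORS = ("mean", "median", "max", "min")


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship must be square over sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class CompressedKinship:
    """Group-level kinship: labels (ordered), n′ × n′ values, n × n′ incidence."""

    group_labels: list[str]
    group_values: np.ndarray
    incidence: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.group_values = np.asarray(self.group_values, dtype=float)
        self.incidence = np.asarray(self.incidence, dtype=float)
        if self.incidence.shape != (len(self.sample_ids), len(self.group_labels)):
            raise ValueError("incidence shape mismatch")
        if not np.array_equal(self.incidence.sum(axis=1), np.ones(len(self.sample_ids))):
            raise ValueError("each sample must belong to exactly one group")

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    def individual_covariance(self) -> np.ndarray:
        """Z K_g Zᵀ — the n × n covariance structure seen by the model."""
        return self.incidence @ self.group_values @ self.incidence.T


@dataclass
class CovariateMatrix:
    """Intercept plus top principal-component scores as fixed covariates."""

    sample_ids: list[str]
    values: np.ndarray
    variance_explained: np.ndarray

    @property
    def n_components(self) -> int:
        return self.values.shape[1] - 1


def vanraden_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Requires imputed (complete) dosages and at least two polymorphic markers.
    """
    codes = g.codes
    if np.isnan(codes).any():
        raise ValueError("kinship requires complete dosages; impute first")
    p = codes.mean(axis=0) / 2.0
    c = float(np.sum(2.0 * p * (1.0 - p)))
    if c <= 0.0:
        raise ValueError("all markers monomorphic; kinship undefined")
    if int((p * (1 - p) > 0).sum()) < 2:
        raise ValueError("need >=2 polymorphic markers")
    m = codes - 2.0 * p
    k = m @ m.T / c
    k = (k + k.T) / 2.0
    return KinshipMatrix(list(g.sample_ids), k)


def pca_components(g: GenotypeMatrix, k: int = 3) -> CovariateMatrix:
    """Top-k principal components of the column-centered dosage matrix.

    Returns an intercept column followed by k score columns; the sign of
    each component is fixed so its largest-magnitude score is positive.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    codes = g.codes
    if np.isnan(codes).any():
        raise ValueError("PCA requires complete dosages; impute first")
    n, m = codes.shape
    if k >= min(n, m):
        raise ValueError(f"k={k} must be < min(n, m)={min(n, m)}")
    centered = codes - codes.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    if (s[:k] <= 1e-10 * s[0]).any():
        raise ValueError(f"matrix rank < k={k}")
    scores = u[:, :k] * s[:k]
    # deterministic sign: largest-|score| entry of each component positive
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    var_explained = (s**2 / np.sum(s**2))[:k]
    values = np.column_stack([np.ones(n), scores])
    return CovariateMatrix(list(g.sample_ids), values, var_explained)


def cluster_kinship(
    kin: KinshipMatrix, linkage: str = "average", n_groups: int = 1
) -> GroupAssignment:
    """Agglomerative clustering of individuals on kinship-derived distance.

    Distance is d_ij = max(K) − K_ij (monotone conversion); the dendrogram
    is cut at ``n_groups`` clusters.  Deterministic given its input.
    """
    if linkage not in VALID_LINKAGES:
        raise ValueError(f"linkage must be one of {VALID_LINKAGES}")
    n = len(kin.sample_ids)
    if not 1 <= n_groups <= n:
        raise ValueError("n_groups must be in [1, n]")
    if n_groups == n:
        labels = np.arange(1, n + 1)
    else:
        d = kin.values.max() - kin.values
        condensed = squareform(d, checks=False)
        z = scipy_linkage(condensed, method=linkage)
        labels = fcluster(z, t=n_groups, criterion="maxclust")
    return GroupAssignment(
        pd.Series([f"g{int(l)}" for l in labels], index=kin.sample_ids)
    )


def compress_kinship(
    kin: KinshipMatrix, groups: GroupAssignment, operator: str = "mean"
) -> CompressedKinship:
    """Summarise kinship between groups: group_values[a, b] = op over the block.

    Diagonal blocks include the i = j (self-kinship) terms.  With singleton
    groups the result reproduces ``kin`` exactly.
    """
    if operator not in VALID_OPERATORS:
        raise ValueError(f"operator must be one of {VALID_OPERATORS}")
    missing = [s for s in kin.sample_ids if s not in groups.labels.index]
    if missing:
        raise KeyError(f"samples without group label: {missing[:5]}")
    labels = groups.labels.loc[kin.sample_ids]
    order = []
    seen: set[str] = set()
    for lab in labels:
        if lab not in seen:
            seen.add(lab)
            order.append(lab)
    idx_of = {lab: np.flatnonzero((labels == lab).to_numpy()) for lab in order}
    op = {"mean": np.mean, "median": np.median, "max": np.max, "min": np.min}[operator]
    np_ = len(order)
    gv = np.empty((np_, np_))
    for a, la in enumerate(order):
        for b, lb in enumerate(order[: a + 1]):
            block = kin.values[np.ix_(idx_of[la], idx_of[lb])]
            gv[a, b] = gv[b, a] = op(block)
    incidence = np.zeros((len(kin.sample_ids), np_))
    for a, lab in enumerate(order):
        incidence[idx_of[lab], a] = 1.0
    return CompressedKinship(order, gv, incidence, list(kin.sample_ids))


def singleton_groups(sample_ids: list[str]) -> GroupAssignment:
    """One group per sample — the compression under which CMLM equals MLM."""
    return GroupAssignment(pd.Series(list(sample_ids), index=list(sample_ids)))


def write_kinship(path, kin: KinshipMatrix) -> None:
    kin.to_frame().to_csv(path, sep="\t")


def read_kinship(path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix(list(df.index.astype(str)), df.to_numpy())
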