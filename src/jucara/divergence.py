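"""Genotype divergence: distances, matrix fusion, UPGMA, Mojena cut, Mantel.

The genotypic distance is the standardized mean Euclidean distance (DEMP)
over SD-scaled trait values (typically BLUPs); the molecular distance is the
unweighted shared-allele index over SSR loci. After normalizing both to
[0, 1] they can be fused by the entrywise mean, clustered by average linkage
(UPGMA), cut with the Mojena criterion, and compared with a permutation
Mantel test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with aligned labels."""

    labels: list[str]
    values: np.ndarray
    kind: str = ""  # provenance: "demp" | "ssr-unweighted" | "fused" | ...

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.nanmin(self.values) < -1e-12:
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        if np.isnan(self.values).any():
            raise ValueError("distance matrix contains missing entries")
        return squareform(self.values, checks=False)

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(lbl) for lbl in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)


def demp_distance(blups: pd.DataFrame, scale: str = "sd") -> DistanceMatrix:
    """Standardized mean Euclidean distance among genotypes.

    d_ij = sqrt( (1/v) Σ_k ((x_ik - x_jk)/s_k)² ) over the v traits complete
    in both genotypes; s_k is the trait's sample SD across genotypes
    (``scale='range'`` divides by the trait range instead). Zero-spread
    traits are excluded with a warning.
    """
    if blups.shape[0] < 2 or blups.shape[1] < 1:
        raise ValueError("need >= 2 genotypes and >= 1 trait")
    X = blups.to_numpy(dtype=float)
    if scale == "sd":
        s = np.nanstd(X, axis=0, ddof=1)
    elif scale == "range":
        s = np.nanmax(X, axis=0) - np.nanmin(X, axis=0)
    else:
        raise ValueError("scale must be 'sd' or 'range'")
    keep = s > 0
    if not keep.all():
        dropped = list(blups.columns[~keep])
        warnings.warn(f"traits with zero spread excluded from DEMP: {dropped}", stacklevel=2)
    if not keep.any():
        raise ValueError("no trait with positive spread")
    Xs = X[:, keep] / s[keep]
    n = Xs.shape[0]
    D = np.zeros((n, n))
    if not np.isnan(Xs).any():
        sq = np.sum(Xs**2, axis=1)
        D2 = sq[:, None] + sq[None, :] - 2.0 * Xs @ Xs.T
        D = np.sqrt(np.clip(D2, 0.0, None) / Xs.shape[1])
    else:
        for i in range(n):
            for j in range(i + 1, n):
                both = np.isfinite(Xs[i]) & np.isfinite(Xs[j])
                if not both.any():
                    raise ValueError(
                        f"genotypes {blups.index[i]} and {blups.index[j]} share no trait"
                    )
                diff = Xs[i, both] - Xs[j, both]
                D[i, j] = D[j, i] = np.sqrt(np.mean(diff**2))
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(blups.index), D, kind="demp")


def _pair_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Shared-allele similarity of two diploid calls, counting multiplicity."""
    shared = 0
    used = [False, False]
    for x in a:
        for k in range(2):
            if not used[k] and b[k] == x:
                used[k] = True
                shared += 1
                break
    return shared / 2.0


def unweighted_ssr_distance(table: pd.DataFrame) -> DistanceMatrix:
    """Unweighted shared-allele distance over SSR loci.

    Per locus scored in both genotypes the similarity is (number of alleles
    in common, with multiplicity)/2 ∈ {0, 0.5, 1}; the distance is one minus
    the unweighted mean similarity over shared loci. A pair with no shared
    scored locus is an error (downstream clustering needs a complete matrix).
    """
    from jucara.diversity import locus_names

    loci = locus_names(table)
    n = len(table)
    calls = np.stack(
        [table[[f"{loc}.a", f"{loc}.b"] ].to_numpy(float) for loc in loci], axis=1
    )  # n × L × 2
    scored = np.isfinite(calls).all(axis=2)  # n × L
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = scored[i] & scored[j]
            if not both.any():
                raise ValueError(
                    f"genotypes {table.index[i]} and {table.index[j]} share no scored locus"
                )
            sims = [
                _pair_similarity(calls[i, locus_k], calls[j, locus_k])
                for locus_k in np.nonzero(both)[0]
            ]
            D[i, j] = D[j, i] = 1.0 - float(np.mean(sims))
    return DistanceMatrix(list(table.index), D, kind="ssr-unweighted")


def normalize01(D: DistanceMatrix, method: str = "max") -> DistanceMatrix:
    """Rescale distances to [0, 1].

    Default divides by the maximum off-diagonal entry, preserving the zero
    diagonal and proportionality; ``method='minmax'`` maps the off-diagonal
    minimum to 0 and maximum to 1 (destroys identity of indiscernibles for
    the closest pair — provided for compatibility).
    """
    vals = D.values.copy()
    off = vals[~np.eye(D.n, dtype=bool)]
    vmax = off.max()
    if vmax <= 0:
        raise ValueError("all distances are zero; cannot normalize")
    if method == "max":
        vals = vals / vmax
    elif method == "minmax":
        vmin = off.min()
        if vmax == vmin:
            raise ValueError("constant off-diagonal; min-max normalization undefined")
        vals = (vals - vmin) / (vmax - vmin)
        np.fill_diagonal(vals, 0.0)
        vals = np.clip(vals, 0.0, None)
    else:
        raise ValueError("method must be 'max' or 'minmax'")
    return DistanceMatrix(D.labels, vals, kind=f"{D.kind}-normalized")


def fuse_average(D1: DistanceMatrix, D2: DistanceMatrix) -> DistanceMatrix:
    """Entrywise mean of two normalized distance matrices (labels aligned)."""
    s1, s2 = set(D1.labels), set(D2.labels)
    if s1 != s2:
        raise ValueError(
            f"label mismatch: only in first {sorted(s1 - s2)}, only in second {sorted(s2 - s1)}"
        )
    D2a = D2.reorder(D1.labels)
    return DistanceMatrix(D1.labels, 0.5 * (D1.values + D2a.values), kind="fused")


@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    ``linkage`` is the scipy (n-1)×4 merge table; heights are nondecreasing
    for UPGMA (average linkage is monotone).
    """

    linkage: np.ndarray
    labels: list[str] = field(default_factory=list)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cophenetic(self) -> np.ndarray:
        """Square matrix of cophenetic (fusion-height) distances."""
        return squareform(hierarchy.cophenet(self.linkage), checks=False)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        inner = f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)})"
        return inner + ";"


def upgma(D: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a complete distance matrix."""
    Z = hierarchy.linkage(D.condensed(), method="average")
    return Dendrogram(linkage=Z, labels=list(D.labels))


def mojena_threshold(tree: Dendrogram, k: float = 1.25) -> float:
    """Mojena cut height: mean fusion height + k · sample SD of heights."""
    h = tree.heights
    sd = float(np.std(h, ddof=1)) if h.size > 1 else 0.0
    return float(np.mean(h) + k * sd)


def mojena_cut(tree: Dendrogram, k: float = 1.25) -> tuple[pd.Series, float]:
    """Group assignment from cutting the dendrogram at the Mojena threshold.

    Groups are the clusters existing just below the threshold (merges at
    heights strictly above it are undone). Returns (assignment, threshold).
    """
    thr = mojena_threshold(tree, k)
    flat = hierarchy.fcluster(tree.linkage, t=thr, criterion="distance")
    return pd.Series(flat, index=pd.Index(tree.labels, name="genotype"), name="group"), thr


@dataclass
class MantelResult:
    r: float
    permutations: int
    p_value: float
    seed: int


def mantel(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    permutations: int = 5000,
    seed: int = 0,
) -> MantelResult:
    """Mantel matrix-correlation test.

    r is the Pearson correlation of the lower-triangle vectors; the one-sided
    upper-tail p-value is (1 + #{r_perm >= r_obs}) / (B + 1) under joint
    row/column permutation of the second matrix.
    """
    if set(D1.labels) != set(D2.labels):
        raise ValueError("Mantel test requires matrices over the same labels")
    if permutations < 1:
        raise ValueError("need at least one permutation")
    D2a = D2.reorder(D1.labels)
    n = D1.n
    iu = np.tril_indices(n, k=-1)
    v1 = D1.values[iu]
    A2 = D2a.values
    v2 = A2[iu]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("constant distance vector; Mantel r undefined")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    v1c = v1 - v1.mean()
    denom1 = np.sqrt(np.sum(v1c**2))
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        vp = A2[np.ix_(perm, perm)][iu]
        vpc = vp - vp.mean()
        r_perm = float(np.dot(v1c, vpc) / (denom1 * np.sqrt(np.sum(vpc**2))))
        if r_perm >= r_obs:
            count += 1
    p = (1 + count) / (permutations + 1)
    return MantelResult(r=r_obs, permutations=permutations, p_value=float(p), seed=seed)
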