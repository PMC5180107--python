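"""Phylogenetic distance versus habitat-depth differentiation.

Consumes an ultrametric Newick tree whose tips are species abbreviations,
computes cophenetic distances (total branch length along the tip-to-tip
path), builds the pairwise habitat-depth difference matrix, and tests the
association between the two with a Mantel permutation test.  An exact
enumeration variant over all n! tip permutations serves as a small-n
reference for the Monte Carlo test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd


class TreeError(ValueError):
    """Raised for malformed or unusable input trees."""


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths; tip labels are species codes."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def root_to_tip_lengths(self) -> dict[str, float]:
        out = {}
        for leaf in self.tree.leaf_node_iter():
            out[leaf.taxon.label] = float(leaf.distance_from_root())
        return out

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = list(self.root_to_tip_lengths().values())
        return (max(depths) - min(depths)) <= tol

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def parse_newick(source: str, ultrametric_tol: float = 1e-6) -> PhyloTree:
    """Parse a Newick string (or path-like text already read) into a tree.

    Branch lengths are required on every non-root edge; duplicate tip
    labels raise; a non-ultrametric tree is accepted with a warning since
    downstream distances stay well defined.
    """
    try:
        tree = dendropy.Tree.get(
            data=source,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"Newick parse error: {exc}") from exc

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate tip labels: {dup}")
    if any(leaf.taxon is None for leaf in tree.leaf_node_iter()):
        raise TreeError("unlabelled tip in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise TreeError("missing branch length on an edge")
        if edge.length < 0:
            raise TreeError("negative branch length")

    pt = PhyloTree(tree=tree)
    if not pt.is_ultrametric(tol=ultrametric_tol):
        depths = pt.root_to_tip_lengths()
        spread = max(depths.values()) - min(depths.values())
        warnings.warn(
            f"tree is not ultrametric: root-to-tip spread {spread:.3g}", stacklevel=2
        )
    return pt


def read_newick(path, **kw) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read(), **kw)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative species-by-species distances, zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("matrix diagonal is not zero")
        if np.any(self.values < -1e-12):
            raise ValueError("negative distances")

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def subset(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels=list(labels), values=self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=list(df.columns), values=df.to_numpy(float))


def cophenetic_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Tip-to-tip path-length (cophenetic) distances."""
    pdm = tree.tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.tree.taxon_namespace)
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    n = len(labels)
    m = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = float(pdm.patristic_distance(taxa[a], taxa[labels[j]]))
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=labels, values=m)


def habitat_depth_distance(mean_depths: dict[str, float]) -> DistanceMatrix:
    """Pairwise absolute differences in species mean habitat depth.

    Species with undefined depth (None/NaN, e.g. zero census counts) are
    excluded with a warning.
    """
    usable = {k: v for k, v in mean_depths.items()
              if v is not None and math.isfinite(v)}
    dropped = sorted(set(mean_depths) - set(usable))
    if dropped:
        warnings.warn(f"species without defined mean depth excluded: {dropped}", stacklevel=2)
    if len(usable) < 3:
        raise ValueError("need at least 3 species with defined mean depth")
    labels = sorted(usable)
    d = np.array([usable[l] for l in labels])
    m = np.abs(d[:, None] - d[None, :])
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(labels=labels, values=m)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None
    tail: str

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n_perm": self.n_perm,
                "seed": self.seed, "tail": self.tail}


def _aligned(D1: DistanceMatrix, D2: DistanceMatrix):
    if set(D1.labels) != set(D2.labels):
        raise ValueError("distance matrices have different label sets")
    if D1.labels != D2.labels:
        D2 = D2.subset(D1.labels)
    return D1, D2


def _pearson_condensed(v1: np.ndarray, V2: np.ndarray) -> np.ndarray:
    """Pearson r of v1 against each row of V2 (vectorised)."""
    v1c = v1 - v1.mean()
    V2c = V2 - V2.mean(axis=1, keepdims=True)
    num = V2c @ v1c
    den = np.sqrt((v1c @ v1c) * np.sum(V2c * V2c, axis=1))
    return num / den


def mantel_test(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Mantel permutation test of association between two distance matrices.

    r is the Pearson correlation of the strictly-upper-triangle vectors.
    The null is built by jointly permuting rows and columns of the second
    matrix ``n_perm`` times; p = (#{r_perm >= r_obs} + 1) / (n_perm + 1)
    for ``tail='greater'``, mirrored for 'less', doubled smaller tail for
    'two-sided'.  Deterministic given ``seed``.
    """
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    D1, D2 = _aligned(D1, D2)
    n = len(D1.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    iu = np.triu_indices(n, k=1)
    v1 = D1.values[iu]
    v2 = D2.values[iu]
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("zero variance in a distance matrix triangle: r undefined")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    V2 = D2.values[perms[:, iu[0]], perms[:, iu[1]]]
    r_perm = _pearson_condensed(v1, V2)

    eps = 1e-12
    p_greater = (np.sum(r_perm >= r_obs - eps) + 1) / (n_perm + 1)
    p_less = (np.sum(r_perm <= r_obs + eps) + 1) / (n_perm + 1)
    if tail == "greater":
        p = p_greater
    elif tail == "less":
        p = p_less
    else:
        p = min(1.0, 2 * min(p_greater, p_less))
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, seed=seed, tail=tail)


def mantel_exact(D1: DistanceMatrix, D2: DistanceMatrix, tail: str = "greater") -> dict:
    """Exact Mantel p by enumerating all n! joint permutations (n <= 8)."""
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    D1, D2 = _aligned(D1, D2)
    n = len(D1.labels)
    if n > 8:
        raise ValueError("n > 8: exact enumeration infeasible, use mantel_test")
    if n < 3:
        raise ValueError("need at least 3 labels")
    iu = np.triu_indices(n, k=1)
    v1 = D1.values[iu]
    if v1.std() == 0 or D2.values[iu].std() == 0:
        raise ValueError("zero variance in a distance matrix triangle: r undefined")
    r_obs = float(np.corrcoef(v1, D2.values[iu])[0, 1])

    perms = np.array(list(itertools.permutations(range(n))))
    V2 = D2.values[perms[:, iu[0]], perms[:, iu[1]]]
    r_all = _pearson_condensed(v1, V2)
    eps = 1e-12
    p_greater = float(np.mean(r_all >= r_obs - eps))
    p_less = float(np.mean(r_all <= r_obs + eps))
    if tail == "greater":
        p = p_greater
    elif tail == "less":
        p = p_less
    else:
        p = min(1.0, 2 * min(p_greater, p_less))
    return {"r": r_obs, "p": p, "n_permutations": len(perms), "tail": tail}


def ultrametric_violation(dm: DistanceMatrix) -> float:
    """Largest violation of d(i,k) <= max(d(i,j), d(j,k)) over all triples."""
    v = dm.values
    n = len(dm.labels)
    worst = 0.0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if i == j or j == k or i == k:
                    continue
                worst = max(worst, v[i, k] - max(v[i, j], v[j, k]))
    return worst
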