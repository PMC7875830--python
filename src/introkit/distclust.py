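"""Genotype distance matrices and Neighbor-Joining sample clustering.

Distances are plain Euclidean distances on raw 0/1/2 alt-allele dosages (no
standardization).  Missing genotypes are handled pairwise-complete with an
L / L_complete rescaling inside the sum, so the distance is an unbiased
estimate of the value that would be obtained with no missing data (a
``complete-only`` mode restricts to loci typed in every sample instead).

The NJ implementation is the classic Saitou-Nei agglomeration with
deterministic tie-breaking (lowest index pair wins) and negative branch
lengths clamped to zero with the deficit moved onto the sibling branch, so a
given distance matrix always yields one well-defined tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .genio import GenotypeMatrix


class DistanceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, non-negative

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise DistanceError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0) or (v < 0).any():
            raise DistanceError("distance matrix must be symmetric, zero-diagonal, >= 0")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


def _quote_label(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class PhyloTree:
    """Unrooted tree over the samples; serialized with a trifurcating root."""

    root: TreeNode
    sample_ids: list[str]

    def to_newick(self) -> str:
        def render(node: TreeNode, length: float | None) -> str:
            if node.is_leaf():
                s = _quote_label(node.label or "")
            else:
                s = "(" + ",".join(render(c, l) for c, l in node.children) + ")"
            if length is not None:
                s += f":{length:.10g}"
            return s

        return render(self.root, None) + ";"

    def as_dendropy(
        self, taxon_namespace: dendropy.TaxonNamespace | None = None
    ) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            taxon_namespace=taxon_namespace,
            rooting="force-unrooted",
        )


def euclidean_distances(
    matrix: GenotypeMatrix, missing: str = "rescale"
) -> DistanceMatrix:
    """Pairwise Euclidean genotype distances between samples.

    d(i,j) = sqrt( L/L_ij * sum_l (x_il - x_jl)^2 ) over jointly non-missing
    loci (``missing="rescale"``), or over loci complete in every sample
    (``missing="complete-only"``).

    Raises
    ------
    DistanceError
        If a pair of samples shares no non-missing locus, naming the pair;
        or if multiallelic loci are still present.
    """
    if not matrix.is_biallelic.all():
        raise DistanceError("matrix contains multiallelic loci; run filter_biallelic first")
    if missing not in ("rescale", "complete-only"):
        raise DistanceError(f"unknown missing-data mode {missing!r}")
    x = matrix.dosages
    n_loci = x.shape[1]
    if missing == "complete-only":
        keep = ~np.isnan(x).any(axis=0)
        x = x[:, keep]
        if x.shape[1] == 0 and n_loci > 0:
            raise DistanceError("no locus is complete across all samples")
        n_loci = x.shape[1]
    s = matrix.n_samples
    d = np.zeros((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            ok = ~np.isnan(x[i]) & ~np.isnan(x[j])
            l_ij = int(ok.sum())
            if l_ij == 0:
                raise DistanceError(
                    f"samples {matrix.sample_ids[i]!r} and {matrix.sample_ids[j]!r} "
                    "share no non-missing locus"
                )
            ss = float(((x[i, ok] - x[j, ok]) ** 2).sum())
            if missing == "rescale":
                ss *= n_loci / l_ij
            d[i, j] = d[j, i] = np.sqrt(ss)
    return DistanceMatrix(list(matrix.sample_ids), d)


def _clamped(li: float, lj: float) -> tuple[float, float]:
    # clamp negative NJ branch estimates to 0, moving the deficit to the sibling
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return li, max(lj, 0.0)


def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei Neighbor-Joining.

    Iteratively joins the pair minimizing
    Q(i,j) = (n-2) d(i,j) - r_i - r_j (r = row sums), with limb lengths
    l_i = d(i,j)/2 + (r_i - r_j)/(2(n-2)).  Ties broken on the lowest
    (i, j) index pair; consistent (exact) on additive matrices.
    """
    n = len(dist.sample_ids)
    if n < 3:
        raise DistanceError(f"neighbor joining needs >= 3 samples, got {n}")
    if not np.isfinite(dist.values).all():
        raise DistanceError("non-finite distances")
    nodes: list[TreeNode] = [TreeNode(label=s) for s in dist.sample_ids]
    d = dist.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        # argmin over the upper triangle in row-major order -> lowest (i, j) tie-break
        k = int(np.argmin(q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamped(li, lj)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [t for t in range(m) if t not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        nodes = [nodes[t] for t in keep] + [parent]
        d = d2

    # resolve the final three nodes around a central trifurcation
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode(
        children=[
            (nodes[0], max(la, 0.0)),
            (nodes[1], max(lb, 0.0)),
            (nodes[2], max(lc, 0.0)),
        ]
    )
    return PhyloTree(root=root, sample_ids=list(dist.sample_ids))


def write_newick(tree: PhyloTree, path: str) -> None:
    """Write the tree in Newick with branch lengths (round-trip parseable)."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
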