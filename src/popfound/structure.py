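"""Population structure: genotype PCA, individual p-distances, neighbour joining.

PCA centres each site by its mean dosage (missing values mean-imputed) and
optionally applies Patterson scaling 1/sqrt(2*p(1-p)), the population-genetics
convention that whitens sites by their binomial standard deviation. The NJ
implementation is the Saitou–Nei agglomeration with the Studier–Keppler Q
criterion and a deterministic lowest-index tie-break; trees are returned as
scikit-bio ``TreeNode`` objects, so newick serialisation and tip-to-tip path
lengths come from the standard container.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .genotype_io import GenotypeMatrix

logger = logging.getLogger("popfound")


@dataclass
class PCAResult:
    """Sample scores and per-component variance fractions."""

    coordinates: np.ndarray  # (n_samples, k)
    variance_explained: np.ndarray  # (k,)
    sample_ids: list[str]


def pca(
    g: GenotypeMatrix, scaling: str = "patterson", n_components: int | None = None
) -> PCAResult:
    """Principal component analysis of the dosage matrix.

    Missing dosages are imputed to the per-site mean; monomorphic sites are
    dropped; ``scaling='patterson'`` divides each centred site by
    sqrt(2*p(1-p)) with p the mean dosage / 2. Scores come from the SVD of
    the centred matrix and ``variance_explained`` is each eigenvalue's share
    of the total variance.
    """
    if scaling not in ("patterson", "center_only"):
        raise ValueError("scaling must be 'patterson' or 'center_only'")
    if g.n_samples < 2 or g.n_sites < 2:
        raise ValueError("need >= 2 samples and >= 2 sites")

    x = g.dosages.astype(float)
    x[g.missing_mask] = np.nan
    mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(mean, inds[1])

    p_hat = mean / 2.0
    poly = (p_hat > 0.0) & (p_hat < 1.0) & (np.nanstd(x, axis=0) > 0)
    if not poly.any():
        raise ValueError("all sites monomorphic; PCA undefined")
    x = x[:, poly] - mean[poly]
    if scaling == "patterson":
        x /= np.sqrt(2.0 * p_hat[poly] * (1.0 - p_hat[poly]))

    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    k = n_components or min(g.n_samples, 10)
    k = min(k, s.size)
    return PCAResult(
        coordinates=u[:, :k] * s[:k],
        variance_explained=var[:k] / total,
        sample_ids=list(g.sample_ids),
    )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        finite = np.isfinite(self.d)
        if not np.allclose(self.d[finite & finite.T], self.d.T[finite & finite.T]):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_phylip(self, path: str) -> None:
        """Write the square PHYLIP format (interoperable with PHYLIP's NJ)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.d):
                name = label[:10].ljust(10)
                fh.write(name + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def p_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise allele-sharing p-distance between individuals.

    d(i,j) = sum_sites |dosage_i - dosage_j| / (2 * m_ij) with m_ij the count
    of sites called in both individuals. A pair with no shared called site
    gets a NaN entry and a warning.
    """
    n = g.n_samples
    x = g.dosages.astype(float)
    x[g.missing_mask] = np.nan
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1 :])  # NaN where either is missing
        m = np.sum(~np.isnan(diff), axis=1)
        total = np.nansum(diff, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(m > 0, total / (2.0 * m), np.nan)
        if np.isnan(row).any():
            logger.warning("p_distance: sample pair(s) share no called sites")
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return DistanceMatrix(labels=list(g.sample_ids), d=d)


def nj_tree(dm: DistanceMatrix) -> tuple[TreeNode, str]:
    """Neighbour-joining tree (Saitou–Nei, Studier–Keppler Q criterion).

    Negative branch lengths are clamped to 0 without redistributing the
    deficit; joins break ties on the lowest (i, j) index pair. Returns the
    tree (rooted at the final 3-way join, i.e. an unrooted topology) and its
    newick string.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    if not np.isfinite(dm.d).all():
        raise ValueError("distance matrix contains null entries")

    d = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among the minimisers, i < j
        iu = np.triu_indices(m, k=1)
        qu = q[iu]
        best = np.flatnonzero(qu == qu.min())[0]
        i, j = int(iu[0][best]), int(iu[1][best])

        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        parent = TreeNode(children=[child_i, child_j])

        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = new_row[keep]
        d_new[:-1, -1] = new_row[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]

    # terminal 3-taxon star: three-point formulas
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, length in zip((a, b, c), (la, lb, lc)):
        node.length = max(length, 0.0)
    tree = TreeNode(children=[a, b, c])

    buf = io.StringIO()
    tree.write(buf, format="newick")
    return tree, buf.getvalue().strip()
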