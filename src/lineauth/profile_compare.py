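"""Pairwise variant-profile comparison.

The variant set for a pair of cells <i, j> is

    V = { k : dp_i,k >= dp_min  and  dp_j,k >= dp_min
              and (freq_i,k > freq_min  or  freq_j,k > freq_min) }

(defaults dp_min = 10 reads, freq_min = 10 percent; the depth test is
non-strict and the frequency test strict).  The similarity of the pair is
the Pearson correlation of the two FREQ vectors over V.  Clustering of a
whole panel uses d = 1 - rho as the distance and unweighted average linkage
(UPGMA) with a deterministic lowest-index tie-break.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import ExpressionMatrix, Panel


@dataclass(frozen=True)
class ComparisonResult:
    """Pearson correlation of FREQ between two cells over their variant set.

    ``rho`` is NaN and ``defined`` False when fewer than 2 sites qualify or
    either FREQ vector is constant over V.  ``n_common`` counts sites with
    freq above the threshold in *both* cells (the shared-mutation count).
    """

    cell_i: str
    cell_j: str
    rho: float
    n_sites: int
    n_common: int

    @property
    def defined(self) -> bool:
        return math.isfinite(self.rho)


def select_variants(
    panel: Panel,
    i: str,
    j: str,
    dp_min: float = 10,
    freq_min: float = 10,
) -> np.ndarray:
    """Indices (panel site order) of the variant set V for the pair (i, j)."""
    if i == j:
        raise ValueError("select_variants needs two distinct cells")
    ci, cj = panel.cell_index(i), panel.cell_index(j)
    return _select(panel.freq[ci], panel.dp[ci], panel.freq[cj], panel.dp[cj], dp_min, freq_min)


def _select(fi, di, fj, dj, dp_min: float, freq_min: float) -> np.ndarray:
    mask = (di >= dp_min) & (dj >= dp_min) & ((fi > freq_min) | (fj > freq_min))
    return np.flatnonzero(mask)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN if undefined (n < 2 or a constant vector)."""
    if x.size < 2:
        return float("nan")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt(np.sum(xc**2)), np.sqrt(np.sum(yc**2))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))


def compare_vectors(
    fi, di, fj, dj, dp_min: float = 10, freq_min: float = 10
) -> tuple[float, int, int]:
    """(rho, n_sites, n_common) for two raw FREQ/DP vectors on shared sites."""
    sel = _select(np.asarray(fi, float), np.asarray(di, float),
                  np.asarray(fj, float), np.asarray(dj, float), dp_min, freq_min)
    x = np.asarray(fi, float)[sel]
    y = np.asarray(fj, float)[sel]
    n_common = int(np.sum((x > freq_min) & (y > freq_min)))
    return _pearson(x, y), int(sel.size), n_common


def pearson_freq_correlation(
    panel: Panel,
    i: str,
    j: str,
    dp_min: float = 10,
    freq_min: float = 10,
) -> ComparisonResult:
    """Pearson correlation of FREQ between cells i and j over V."""
    ci, cj = panel.cell_index(i), panel.cell_index(j)
    rho, n_sites, n_common = compare_vectors(
        panel.freq[ci], panel.dp[ci], panel.freq[cj], panel.dp[cj], dp_min, freq_min
    )
    return ComparisonResult(i, j, rho, n_sites, n_common)


@dataclass
class PairwiseMatrix:
    """Symmetric pairwise comparison of a whole panel (rho, n_sites, n_common)."""

    rho: pd.DataFrame
    n_sites: pd.DataFrame
    n_common: pd.DataFrame

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal rho values (each unordered pair once)."""
        m = self.rho.to_numpy()
        iu = np.triu_indices(m.shape[0], k=1)
        return m[iu]

    def to_tsv(self, prefix: str) -> None:
        for name in ("rho", "n_sites", "n_common"):
            getattr(self, name).to_csv(f"{prefix}.{name}.tsv", sep="\t")


def pairwise_matrix(panel: Panel, dp_min: float = 10, freq_min: float = 10) -> PairwiseMatrix:
    """All unordered pairwise comparisons; diagonal rho fixed at 1."""
    n = panel.n_cells
    if n < 2:
        raise ValueError("pairwise comparison needs at least 2 cells")
    rho = np.eye(n)
    n_sites = np.zeros((n, n), dtype=int)
    n_common = np.zeros((n, n), dtype=int)
    for i in range(n):
        sel_ii = _select(panel.freq[i], panel.dp[i], panel.freq[i], panel.dp[i], dp_min, freq_min)
        n_sites[i, i] = sel_ii.size
        n_common[i, i] = int(np.sum(panel.freq[i][sel_ii] > freq_min))
        for j in range(i + 1, n):
            r, ns, nc = compare_vectors(
                panel.freq[i], panel.dp[i], panel.freq[j], panel.dp[j], dp_min, freq_min
            )
            rho[i, j] = rho[j, i] = r
            n_sites[i, j] = n_sites[j, i] = ns
            n_common[i, j] = n_common[j, i] = nc
    ids = panel.cell_ids
    return PairwiseMatrix(
        pd.DataFrame(rho, index=ids, columns=ids),
        pd.DataFrame(n_sites, index=ids, columns=ids),
        pd.DataFrame(n_common, index=ids, columns=ids),
    )


def expression_correlation(
    expr: ExpressionMatrix,
    i: str,
    j: str,
    min_rpkm: float = 0.1,
    log_transform: bool = False,
) -> tuple[float, int]:
    """Pearson correlation of expression over genes with RPKM above
    ``min_rpkm`` in at least one of the two cells.

    Returns (rho, n_genes); rho is NaN when fewer than 2 genes qualify.
    With ``log_transform`` the correlation is computed on log2(RPKM + 1).
    """
    ci, cj = expr.cell_index(i), expr.cell_index(j)
    x, y = expr.rpkm[:, ci], expr.rpkm[:, cj]
    mask = (x > min_rpkm) | (y > min_rpkm)
    x, y = x[mask], y[mask]
    if log_transform:
        x, y = np.log2(x + 1.0), np.log2(y + 1.0)
    return _pearson(x, y), int(mask.sum())


# ---------------------------------------------------------------------------
# Hierarchical clustering (UPGMA on d = 1 - rho)


@dataclass
class Linkage:
    """Agglomerative merge tree in scipy linkage layout.

    ``merges`` is an (n-1) x 4 array: the two cluster ids merged (leaves are
    0..n-1, internal nodes n, n+1, ... in merge order), the merge height
    (average-linkage distance), and the new cluster's leaf count.
    """

    merges: np.ndarray
    labels: list[str]

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf ordering of the merge tree."""
        n = len(self.labels)

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            left, right = int(self.merges[node - n, 0]), int(self.merges[node - n, 1])
            return walk(left) + walk(right)

        return [self.labels[k] for k in walk(2 * n - 2)]

    def to_newick(self) -> str:
        """Newick string; leaf depths are half the merge height (ultrametric)."""
        n = len(self.labels)

        def height(node: int) -> float:
            return 0.0 if node < n else float(self.merges[node - n, 2]) / 2.0

        def walk(node: int) -> str:
            if node < n:
                return self.labels[node].replace(" ", "_")
            left, right = int(self.merges[node - n, 0]), int(self.merges[node - n, 1])
            h = height(node)
            return (
                f"({walk(left)}:{h - height(left):.6g},"
                f"{walk(right)}:{h - height(right):.6g})"
            )

        return walk(2 * n - 2) + ";"

    def to_merge_table(self, path: str) -> None:
        df = pd.DataFrame(self.merges, columns=["node_a", "node_b", "height", "size"])
        df.to_csv(path, sep="\t", index=False)


def hierarchical_cluster(corr, labels: list[str] | None = None) -> Linkage:
    """UPGMA clustering of a symmetric correlation matrix at distance 1 - rho.

    Ties are broken deterministically by the lowest pair of cluster ids, so
    the merge order is reproducible across platforms.
    """
    if isinstance(corr, pd.DataFrame):
        labels = [str(c) for c in corr.columns]
        corr = corr.to_numpy()
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.shape != (n, n) or not np.allclose(corr, corr.T, atol=1e-10, equal_nan=True):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("correlation matrix must have a unit diagonal")
    if labels is None:
        labels = [str(k) for k in range(n)]

    dist = {}
    active: dict[int, int] = {k: 1 for k in range(n)}  # cluster id -> leaf count
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = 1.0 - corr[i, j]

    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        # lowest distance; ties -> smallest (id_a, id_b)
        (ia, ib), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        size = active[ia] + active[ib]
        merges[step] = (ia, ib, h, size)
        del dist[(ia, ib)]
        new_dists = {}
        for other in active:
            if other in (ia, ib):
                continue
            da = dist.pop((min(ia, other), max(ia, other)))
            db = dist.pop((min(ib, other), max(ib, other)))
            new_dists[(other, next_id)] = (active[ia] * da + active[ib] * db) / size
        del active[ia], active[ib]
        active[next_id] = size
        dist.update(new_dists)
        next_id += 1
    return Linkage(merges, list(labels))
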