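"""Spatial weights, Moran's I, Dutilleul's modified t-test, and the
collinearity screen used before structural-equation fitting.

All schemes build a *symmetric* neighbour relation first and row-standardize
last, so a row of the weight matrix sums to 1 (or 0 for isolated cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .grid import GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialWeights",
    "build_weights",
    "morans_i",
    "CorrelationScreenResult",
    "dutilleul_test",
    "collinearity_screen",
]


@dataclass
class SpatialWeights:
    """Row-standardized spatial weights over a set of cells.

    ``W`` is the row-standardized sparse matrix; ``adjacency`` the symmetric
    binary (or distance-derived) relation before standardization.  Eigenvalues
    of ``W`` are computed lazily once and cached — the SAR log-Jacobian needs
    them for every candidate lambda.
    """

    cell_ids: np.ndarray
    adjacency: sp.csr_matrix
    scheme: str = "queen"
    _W: sp.csr_matrix | None = field(default=None, repr=False)
    _eigenvalues: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        A = self.adjacency
        if (A != A.T).nnz != 0:
            raise ValueError("neighbour relation must be symmetric before standardization")
        rs = np.asarray(A.sum(axis=1)).ravel()
        iso = int(np.sum(rs == 0))
        if iso:
            logger.warning("%d cells have no neighbours (isolated); their weight rows are zero", iso)
        inv = np.where(rs > 0, 1.0 / np.where(rs > 0, rs, 1.0), 0.0)
        self._W = sp.diags(inv) @ A.tocsr()

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    @property
    def W(self) -> sp.csr_matrix:
        return self._W

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of the row-standardized W.

        W = D^-1 A with A symmetric is similar to the symmetric
        D^-1/2 A D^-1/2, so its spectrum is real; isolated cells contribute
        zero rows and zero eigenvalues.
        """
        if self._eigenvalues is None:
            rs = np.asarray(self.adjacency.sum(axis=1)).ravel()
            if np.all(rs > 0):
                d = 1.0 / np.sqrt(rs)
                S = sp.diags(d) @ self.adjacency @ sp.diags(d)
                ev = np.linalg.eigvalsh(S.toarray())
            else:
                ev = np.linalg.eigvals(self._W.toarray())
                if np.max(np.abs(ev.imag)) > 1e-8:
                    raise RuntimeError("weight matrix has non-real eigenvalues")
                ev = np.sort(ev.real)
            self._eigenvalues = ev
        return self._eigenvalues

    def subset(self, mask: np.ndarray) -> "SpatialWeights":
        """Restrict to a boolean mask of cells (re-standardizes rows)."""
        mask = np.asarray(mask, dtype=bool)
        A = self.adjacency[mask][:, mask].tocsr()
        return SpatialWeights(cell_ids=self.cell_ids[mask], adjacency=A, scheme=self.scheme)

    def to_triplets(self) -> pd.DataFrame:
        """Row-standardized weights as a (from, to, weight) triplet table."""
        coo = self._W.tocoo()
        return pd.DataFrame({
            "from_cell": self.cell_ids[coo.row],
            "to_cell": self.cell_ids[coo.col],
            "weight": coo.data,
        })


def build_weights(
    grid: GridSpec,
    scheme: str = "queen",
    radius: float | None = None,
    k: int | None = None,
) -> SpatialWeights:
    """Build row-standardized weights over the grid's retained cells.

    Schemes: ``queen`` / ``rook`` contiguity on the grid; ``distance`` band
    (all pairs with centroid distance <= ``radius`` km); ``knn`` (k nearest
    centroids, symmetrized by union before standardization).
    """
    ids = grid.retained
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 retained cells")
    rows, cols = grid.rowcol(ids)
    if scheme in ("queen", "rook"):
        dr = rows[:, None] - rows[None, :]
        dc = cols[:, None] - cols[None, :]
        if scheme == "queen":
            adj = (np.abs(dr) <= 1) & (np.abs(dc) <= 1)
        else:
            adj = (np.abs(dr) + np.abs(dc)) == 1
        np.fill_diagonal(adj, False)
        A = sp.csr_matrix(adj.astype(float))
    elif scheme == "distance":
        if radius is None:
            raise ValueError("distance scheme requires a radius (km)")
        xy = grid.centroids(ids)
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        adj = d <= radius
        np.fill_diagonal(adj, False)
        A = sp.csr_matrix(adj.astype(float))
    elif scheme == "knn":
        if k is None:
            raise ValueError("knn scheme requires k")
        if k >= n:
            raise ValueError(f"k = {k} must be smaller than the number of cells ({n})")
        xy = grid.centroids(ids)
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        nearest = np.argsort(d, axis=1, kind="stable")[:, :k]
        adj = np.zeros((n, n), dtype=bool)
        adj[np.arange(n)[:, None], nearest] = True
        adj |= adj.T  # symmetrize by union
        A = sp.csr_matrix(adj.astype(float))
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")
    return SpatialWeights(cell_ids=ids.copy(), adjacency=A, scheme=scheme)


def morans_i(values: np.ndarray, weights: SpatialWeights) -> float:
    """Moran's I: (n/S0) * (z'Wz) / (z'z) with z the centred values."""
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("values have zero variance; Moran's I undefined")
    S0 = float(weights.W.sum())
    if S0 == 0.0:
        raise ValueError("weight matrix has no edges")
    n = weights.n
    return float(n / S0 * (z @ (weights.W @ z)) / denom)


@dataclass(frozen=True)
class CorrelationScreenResult:
    """Dutilleul modified correlation test for one variable pair."""

    x_name: str
    y_name: str
    r: float
    m_hat: float      # effective sample size
    f_stat: float
    p_value: float
    dropped: bool = False


def _distance_classes(coords: np.ndarray, n_classes: int | None) -> tuple[np.ndarray, int]:
    """Assign each (i, j) pair to an equal-width distance class.

    Class 0 is the diagonal (distance zero); off-diagonal pairs are binned
    into ``n_classes`` equal-width bins over (0, max distance].  Default
    class count follows Sturges' rule on the number of distinct pairs.
    """
    n = len(coords)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    if n_classes is None:
        n_pairs = n * (n - 1) // 2
        n_classes = int(np.ceil(np.log2(n_pairs))) + 1
    dmax = d.max()
    edges = np.linspace(0.0, dmax, n_classes + 1)
    cls = np.digitize(d, edges[1:-1], right=True) + 1
    cls[d == 0.0] = 0
    return cls, n_classes + 1


def _spatial_cov(z: np.ndarray, cls: np.ndarray, n_cls: int) -> np.ndarray:
    """Covariance matrix estimate: each distance class gets its empirical
    mean cross-product of centred values (isotropic, stationary)."""
    prod = np.outer(z, z)
    flat_cls = cls.ravel()
    sums = np.bincount(flat_cls, weights=prod.ravel(), minlength=n_cls)
    counts = np.bincount(flat_cls, minlength=n_cls)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return means[cls]


def dutilleul_test(
    x: np.ndarray,
    y: np.ndarray,
    coords: np.ndarray,
    n_distance_classes: int | None = None,
    threshold: float = 0.8,
    names: tuple[str, str] = ("x", "y"),
    _class_cache: tuple[np.ndarray, int] | None = None,
) -> CorrelationScreenResult:
    """Correlation test with spatially corrected degrees of freedom.

    The Pearson correlation is computed as usual; the effective sample size
    M is estimated from the spatial covariance of each field (binned by
    pairwise-distance class) as

        M = 1 + tr(B Sx) tr(B Sy) / tr(B Sx B Sy)

    with B the centering operator I - 11'/n.  The statistic
    F = (M - 2) r^2 / (1 - r^2) is referred to F(1, M - 2); p-values are
    two-sided.  When M <= 2 the pair carries too little effective
    information and p is reported as 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n or len(coords) != n:
        raise ValueError("x, y and coords must be defined on the same cells")
    if n < 10:
        raise ValueError("need at least 10 cells for the modified t-test")
    r = float(np.corrcoef(x, y)[0, 1])
    if _class_cache is not None:
        cls, n_cls = _class_cache
    else:
        cls, n_cls = _distance_classes(np.asarray(coords, dtype=float), n_distance_classes)
    zx = x - x.mean()
    zy = y - y.mean()
    Sx = _spatial_cov(zx, cls, n_cls)
    Sy = _spatial_cov(zy, cls, n_cls)
    # B M = M - colmean(M); tr computed without forming B explicitly
    BSx = Sx - Sx.mean(axis=0, keepdims=True)
    BSy = Sy - Sy.mean(axis=0, keepdims=True)
    tr_x = float(np.trace(BSx))
    tr_y = float(np.trace(BSy))
    tr_xy = float(np.sum(BSx * BSy.T))
    m_hat = 1.0 + tr_x * tr_y / tr_xy
    if m_hat <= 2.0:
        logger.warning(
            "effective sample size M = %.2f <= 2 for (%s, %s); insufficient "
            "effective information, reporting p = 1", m_hat, *names,
        )
        f_stat, p = 0.0, 1.0
    elif abs(r) >= 1.0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (m_hat - 2.0) * r * r / (1.0 - r * r)
        p = float(stats.f.sf(f_stat, 1, m_hat - 2.0))
    return CorrelationScreenResult(
        x_name=names[0], y_name=names[1], r=r, m_hat=m_hat,
        f_stat=f_stat, p_value=p, dropped=abs(r) > threshold,
    )


def distance_class_cache(coords: np.ndarray, n_distance_classes: int | None = None):
    """Precompute pair distance classes for repeated tests on one cell set."""
    return _distance_classes(np.asarray(coords, dtype=float), n_distance_classes)


def collinearity_screen(
    cell_table: pd.DataFrame,
    pathway_groups: dict[str, list[str]],
    coords: np.ndarray,
    threshold: float = 0.8,
    n_distance_classes: int | None = None,
) -> tuple[dict[str, list[str]], dict[str, list[str]], pd.DataFrame]:
    """Greedy within-pathway collinearity elimination.

    Within each pathway group, while any pair of remaining variables has
    |r| > ``threshold``, the member of the worst pair with the larger mean
    absolute correlation to the other remaining variables is dropped.  All
    pairwise modified-correlation results (across all variables in any
    group) are returned for reporting.

    Returns ``(kept, dropped, pairwise_table)`` where the first two map
    pathway name to variable lists.
    """
    all_vars = sorted({v for grp in pathway_groups.values() for v in grp})
    cache = distance_class_cache(coords, n_distance_classes)
    results = {}
    rows = []
    for i, a in enumerate(all_vars):
        for b in all_vars[i + 1:]:
            res = dutilleul_test(
                cell_table[a].to_numpy(), cell_table[b].to_numpy(), coords,
                threshold=threshold, names=(a, b), _class_cache=cache,
            )
            results[(a, b)] = results[(b, a)] = res
            rows.append({
                "var_x": a, "var_y": b, "r": res.r, "m_hat": res.m_hat,
                "f_stat": res.f_stat, "p_value": res.p_value,
                "above_threshold": res.dropped,
            })
    pairwise = pd.DataFrame(rows)
    kept: dict[str, list[str]] = {}
    dropped: dict[str, list[str]] = {}
    for group, members in pathway_groups.items():
        remaining = list(members)
        removed: list[str] = []
        while True:
            worst, worst_r = None, threshold
            for i, a in enumerate(remaining):
                for b in remaining[i + 1:]:
                    r = abs(results[(a, b)].r)
                    if r > worst_r:
                        worst, worst_r = (a, b), r
            if worst is None:
                break
            a, b = worst

            def mean_abs_r(v: str) -> float:
                others = [u for u in remaining if u != v]
                if not others:
                    return 0.0
                return float(np.mean([abs(results[(v, u)].r) for u in others]))

            victim = a if mean_abs_r(a) >= mean_abs_r(b) else b
            remaining.remove(victim)
            removed.append(victim)
            logger.info(
                "pathway %s: dropped %s (|r| = %.3f with %s)",
                group, victim, worst_r, a if victim == b else b,
            )
        kept[group] = remaining
        dropped[group] = removed
    return kept, dropped, pairwise
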