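"""Distance-band spatial weights and the inverse-distance autocovariate.

Weights connect every pair of units (patients) whose planar Euclidean
distance d_ij satisfies 0 < d_ij <= radius, with weight w_ij = 1 / d_ij.
The autocovariate of a binary outcome y is the weighted average of the
neighbours' outcomes,

    autocov_i = sum_j w_ij y_j / sum_j w_ij,

a convex combination of {y_j : j ~ i}, hence always in [0, 1].  It is the
spatial term gamma multiplies in the auto-logistic linear predictor.

Coordinates must be projected planar metres.  Longitude/latitude input can
be projected with :func:`autologit.io.lonlat_to_xy` first.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .exceptions import ValidationError

__all__ = [
    "DistanceBandWeights",
    "build_weights",
    "autocovariate",
    "jitter_points",
    "max_nearest_neighbor_distance",
]


def _as_coords(points) -> tuple[np.ndarray, np.ndarray]:
    """Coerce points to an (n, 2) float array plus an array of unit ids.

    Accepts a DataFrame with columns ``x``/``y`` (optionally ``unit_id``) or
    any (n, 2) array-like.
    """
    if isinstance(points, pd.DataFrame):
        missing = {"x", "y"} - set(points.columns)
        if missing:
            raise ValidationError(f"points frame lacks columns {sorted(missing)}")
        xy = points[["x", "y"]].to_numpy(dtype=float)
        if "unit_id" in points.columns:
            ids = points["unit_id"].to_numpy()
        else:
            ids = points.index.to_numpy()
    else:
        xy = np.asarray(points, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValidationError("points must be an (n, 2) array of x, y")
        ids = np.arange(xy.shape[0])
    if not np.all(np.isfinite(xy)):
        bad = np.where(~np.isfinite(xy).all(axis=1))[0]
        raise ValidationError(f"non-finite coordinates at rows {bad.tolist()[:10]}")
    if len(np.unique(ids)) != len(ids):
        raise ValidationError("unit_ids are not unique")
    if xy.shape[0] < 2:
        raise ValidationError("at least 2 points are required to build weights")
    return xy, ids


def max_nearest_neighbor_distance(points) -> float:
    """Maximum over units of the distance to the nearest other unit.

    Using this as the distance band guarantees every unit has at least one
    neighbour (no isolated units), the common default for distance-band
    autocovariate construction on irregular points.
    """
    xy, _ = _as_coords(points)
    tree = cKDTree(xy)
    d, _ = tree.query(xy, k=2)
    nn = d[:, 1]
    if np.any(nn == 0):
        i = int(np.argmin(nn + (nn > 0)))
        raise ValidationError(
            f"coincident points detected (e.g. unit index {i}); "
            "jitter_points() can break ties"
        )
    return float(nn.max())


class DistanceBandWeights:
    """Sparse symmetric inverse-distance weights within a distance band.

    Attributes
    ----------
    matrix : scipy.sparse.csr_array
        Symmetric (n, n) matrix with entries w_ij = 1/d_ij for pairs within
        the band; zero diagonal.
    radius : float
        Band radius in metres.
    unit_ids : ndarray
        Unit identifiers in row order.
    """

    def __init__(self, matrix, radius: float, unit_ids=None):
        matrix = sparse.csr_array(matrix)
        if matrix.shape[0] != matrix.shape[1]:
            raise ValidationError("weights matrix must be square")
        self.matrix = matrix
        self.radius = float(radius)
        self.unit_ids = (
            np.asarray(unit_ids) if unit_ids is not None else np.arange(matrix.shape[0])
        )

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def neighbor_counts(self) -> np.ndarray:
        return np.diff(self.matrix.indptr)

    @property
    def isolated(self) -> np.ndarray:
        """Boolean mask of units with no neighbour within the band."""
        return self.neighbor_counts == 0

    @property
    def row_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    @property
    def s0(self) -> float:
        """Sum of all weights (the S0 normaliser of Moran's I)."""
        return float(self.matrix.sum())

    def row_standardized(self) -> sparse.csr_array:
        """Row-standardised copy; isolated rows remain all-zero."""
        rs = self.row_sums
        inv = np.divide(1.0, rs, out=np.zeros_like(rs), where=rs > 0)
        d = sparse.dia_array((inv[None, :], [0]), shape=(self.n, self.n))
        return sparse.csr_array(d @ self.matrix)

    def pairs(self) -> pd.DataFrame:
        """Stored (i, j, w_ij) triples as a tidy frame (both orientations)."""
        coo = self.matrix.tocoo()
        return pd.DataFrame(
            {
                "i": self.unit_ids[coo.row],
                "j": self.unit_ids[coo.col],
                "w": coo.data,
            }
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"DistanceBandWeights(n={self.n}, radius={self.radius:.1f} m, "
            f"pairs={self.matrix.nnz}, isolated={int(self.isolated.sum())})"
        )


def build_weights(points, radius: float | None = None) -> DistanceBandWeights:
    """Build inverse-distance weights for all pairs within ``radius`` metres.

    Parameters
    ----------
    points : DataFrame with x, y (metres) or (n, 2) array
    radius : float, optional
        Band radius; defaults to the maximum nearest-neighbour distance,
        which guarantees no isolated units.

    Raises
    ------
    ValidationError
        On coincident points within the band (1/d undefined; the message
        names the offending pair so the caller may jitter), non-finite
        coordinates, or radius <= 0.
    """
    xy, ids = _as_coords(points)
    if radius is None:
        # tiny relative bump so the unit attaining the max is not excluded
        # by floating-point round-off at the band boundary
        radius = max_nearest_neighbor_distance(points) * (1.0 + 1e-9)
    radius = float(radius)
    if not radius > 0:
        raise ValidationError("radius must be > 0")

    tree = cKDTree(xy)
    pair_idx = np.array(sorted(tree.query_pairs(radius)), dtype=np.int64)
    n = xy.shape[0]
    if pair_idx.size == 0:
        mat = sparse.csr_array((n, n))
        w = DistanceBandWeights(mat, radius, ids)
        warnings.warn(
            f"all {n} units are isolated at radius {radius:g} m", stacklevel=2
        )
        return w
    d = np.hypot(
        xy[pair_idx[:, 0], 0] - xy[pair_idx[:, 1], 0],
        xy[pair_idx[:, 0], 1] - xy[pair_idx[:, 1], 1],
    )
    if np.any(d == 0):
        k = int(np.argmax(d == 0))
        a, b = ids[pair_idx[k, 0]], ids[pair_idx[k, 1]]
        raise ValidationError(
            f"coincident points within band: units {a!r} and {b!r} have "
            "d_ij = 0 (1/d undefined); use jitter_points() to break ties"
        )
    w = 1.0 / d
    rows = np.concatenate([pair_idx[:, 0], pair_idx[:, 1]])
    cols = np.concatenate([pair_idx[:, 1], pair_idx[:, 0]])
    data = np.concatenate([w, w])
    mat = sparse.csr_array(
        sparse.coo_array((data, (rows, cols)), shape=(n, n))
    )
    out = DistanceBandWeights(mat, radius, ids)
    n_iso = int(out.isolated.sum())
    if n_iso:
        warnings.warn(
            f"{n_iso} unit(s) have no neighbour within {radius:g} m and are "
            "flagged isolated",
            stacklevel=2,
        )
    return out


def autocovariate(
    weights: DistanceBandWeights,
    outcome,
    isolated_fallback: str | float = "prevalence",
) -> np.ndarray:
    """Inverse-distance-weighted average of neighbours' binary outcomes.

    For unit i with at least one neighbour this is
    ``sum_j w_ij y_j / sum_j w_ij`` and lies in [0, 1].  Isolated units
    receive the fallback: the overall outcome prevalence (default, keeps the
    design matrix complete without injecting spatial signal) or a fixed
    number.

    Raises
    ------
    ValidationError
        If the outcome length does not match the weights, or the outcome is
        not binary 0/1.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    if y.shape[0] != weights.n:
        raise ValidationError(
            f"outcome length {y.shape[0]} does not match {weights.n} units"
        )
    vals = np.unique(y)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValidationError(f"outcome must be binary 0/1; saw values {vals[:5]}")
    num = weights.matrix @ y
    den = weights.row_sums
    iso = weights.isolated
    ac = np.divide(num, den, out=np.zeros_like(num), where=~iso)
    if iso.any():
        fb = float(y.mean()) if isolated_fallback == "prevalence" else float(
            isolated_fallback
        )
        ac[iso] = fb
        warnings.warn(
            f"{int(iso.sum())} isolated unit(s) assigned autocovariate "
            f"fallback {fb:.4g}",
            stacklevel=2,
        )
    return ac


def jitter_points(points, scale: float = 0.5, seed: int | None = None):
    """Break coincident coordinates with uniform noise in (-scale, scale) m.

    Returns an object of the same kind as the input with perturbed x/y.
    """
    rng = np.random.default_rng(seed)
    if isinstance(points, pd.DataFrame):
        out = points.copy()
        out["x"] = out["x"] + rng.uniform(-scale, scale, len(out))
        out["y"] = out["y"] + rng.uniform(-scale, scale, len(out))
        return out
    xy = np.asarray(points, dtype=float).copy()
    xy += rng.uniform(-scale, scale, xy.shape)
    return xy
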