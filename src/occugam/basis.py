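"""Low-rank 2-D thin-plate regression spline basis for the occupancy surface.

The occupancy surface f_t(lat, lon) is expanded in K basis functions
g_1 .. g_K with coefficients nu_{k,t}.  The basis is a standard low-rank
eigen-reduction of the full thin-plate spline: the radial kernel
eta(r) = r^2 log(r) / (8 pi) is evaluated between all pairs of sites, the K
leading eigenvectors (by absolute eigenvalue) are retained, the thin-plate
side constraint is absorbed, and the unpenalised polynomial null space
{1, lat, lon} is appended.  Wiggliness is penalised through a quadratic
form nu' S nu whose null space is exactly the affine functions of the
(scaled) coordinates, so a smoothing parameter lambda -> infinity shrinks
the fitted surface to the ordinary least-squares plane.

Coordinates are centred and divided by a single common scale (the larger
of the latitude/longitude ranges) before kernel evaluation; the transform
is stored on the basis so the identical basis functions can be evaluated
at prediction locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class SiteCoordinates:
    """Survey-site locations in decimal degrees (WGS-84, unprojected)."""

    site_id: np.ndarray
    latitude: np.ndarray
    longitude: np.ndarray

    def __post_init__(self) -> None:
        sid = np.asarray(self.site_id)
        lat = np.asarray(self.latitude, dtype=float)
        lon = np.asarray(self.longitude, dtype=float)
        if not (sid.shape == lat.shape == lon.shape) or lat.ndim != 1:
            raise ValueError("site_id, latitude, longitude must be equal-length 1-D arrays")
        if len(np.unique(sid)) != sid.size:
            raise ValueError("site_ids must be unique")
        if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
            raise ValueError("coordinates must be finite")
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude must lie in [-90, 90]")
        if np.any(np.abs(lon) > 180.0):
            raise ValueError("longitude must lie in [-180, 180]")
        object.__setattr__(self, "site_id", sid)
        object.__setattr__(self, "latitude", lat)
        object.__setattr__(self, "longitude", lon)

    def __len__(self) -> int:
        return self.latitude.size

    @property
    def xy(self) -> np.ndarray:
        """(N, 2) array of (latitude, longitude) pairs."""
        return np.column_stack([self.latitude, self.longitude])


@dataclass(frozen=True)
class SplineBasis:
    """A fitted thin-plate regression spline basis.

    Attributes
    ----------
    basis_matrix : (N, K) design matrix; the last ``null_space_dim``
        columns span {constant, lat, lon} and are unpenalised.
    penalty_matrix : (K, K) symmetric PSD wiggliness penalty S.
    null_space_dim : dimension of the penalty null space (3 for
        non-degenerate 2-D site sets).
    transform : centring/scaling constants applied to coordinates
        before kernel evaluation.
    """

    basis_matrix: np.ndarray
    penalty_matrix: np.ndarray
    null_space_dim: int
    transform: dict
    # internals needed to evaluate the same basis functions at new points
    _train_scaled: np.ndarray = field(repr=False, default=None)
    _kernel_weights: np.ndarray = field(repr=False, default=None)

    @property
    def K(self) -> int:
        return self.basis_matrix.shape[1]

    @property
    def n_sites(self) -> int:
        return self.basis_matrix.shape[0]


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    """2-D thin-plate radial kernel eta(r) = r^2 log(r) / (8 pi), eta(0) = 0."""
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos]) / (8.0 * np.pi)
    return out


def _scale_coords(xy: np.ndarray, transform: dict) -> np.ndarray:
    return (xy - transform["center"]) / transform["scale"]


def build_tprs_basis(coords: SiteCoordinates, K: int) -> SplineBasis:
    """Construct a rank-K thin-plate regression spline basis at the sites.

    Parameters
    ----------
    coords : site locations (must contain at least K distinct,
        non-collinear coordinate pairs).
    K : total basis dimension, including the 3-dimensional null space
        (constant + linear latitude + linear longitude).

    Returns
    -------
    SplineBasis with full-column-rank design, symmetric PSD penalty whose
    null space is exactly the affine functions, and the stored coordinate
    transform.
    """
    if K < 4:
        raise ValueError("K must be at least 4 (null space dimension 3 plus one smooth term)")
    xy = coords.xy
    uniq = np.unique(xy, axis=0)
    if uniq.shape[0] < K:
        raise ValueError(
            f"need at least K={K} distinct coordinate pairs, found {uniq.shape[0]}"
        )
    # collinearity check on the distinct locations
    centered = uniq - uniq.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-10 * max(sv[0], 1.0):
        raise ValueError("sites are collinear: the thin-plate null space is degenerate")

    center = xy.mean(axis=0)
    rng_lat = np.ptp(xy[:, 0])
    rng_lon = np.ptp(xy[:, 1])
    scale = max(rng_lat, rng_lon)
    if scale <= 0:
        raise ValueError("degenerate site set: zero coordinate range")
    transform = {"center": center, "scale": scale}
    s = _scale_coords(xy, transform)

    E = _tps_kernel(cdist(s, s))
    T = np.column_stack([np.ones(len(s)), s[:, 0], s[:, 1]])

    # leading-|eigenvalue| eigen-reduction of the kernel
    evals, evecs = np.linalg.eigh(E)
    order = np.argsort(np.abs(evals))[::-1][:K]
    U = evecs[:, order]          # (N, K)
    D = evals[order]             # (K,)

    # absorb the thin-plate side constraint T' delta = 0 with delta = U delta_k
    C = T.T @ U                  # (3, K)
    _, _, Vt = np.linalg.svd(C, full_matrices=True)
    Z = Vt[3:].T                 # (K, K-3) orthonormal null basis of C

    X_pen = (U * D) @ Z          # (N, K-3): rows of E U Z
    S_pen = Z.T @ (Z * D[:, None])  # Z' diag(D) Z, PSD on the constrained space
    S_pen = 0.5 * (S_pen + S_pen.T)

    X = np.column_stack([X_pen, T])
    S = np.zeros((K, K))
    S[: K - 3, : K - 3] = S_pen

    if np.linalg.matrix_rank(X) < K:
        raise ValueError("basis matrix is rank deficient for this site set")

    return SplineBasis(
        basis_matrix=X,
        penalty_matrix=S,
        null_space_dim=3,
        transform=transform,
        _train_scaled=s,
        _kernel_weights=U @ Z,   # (N, K-3): delta = (U Z) beta_pen
    )


def affine_basis(coords: SiteCoordinates) -> SplineBasis:
    """Degenerate K = 3 basis: the unpenalised plane {1, lat, lon} only.

    Useful for site sets too small to carry a thin-plate smooth and for
    collapsing the model onto a plain logistic occupancy fit; the penalty
    matrix is zero.
    """
    xy = coords.xy
    center = xy.mean(axis=0)
    scale = max(np.ptp(xy[:, 0]), np.ptp(xy[:, 1]))
    if scale <= 0:
        raise ValueError("degenerate site set: zero coordinate range")
    transform = {"center": center, "scale": scale}
    s = _scale_coords(xy, transform)
    T = np.column_stack([np.ones(len(s)), s[:, 0], s[:, 1]])
    return SplineBasis(
        basis_matrix=T, penalty_matrix=np.zeros((3, 3)), null_space_dim=3,
        transform=transform, _train_scaled=s, _kernel_weights=np.zeros((len(s), 0)),
    )


def evaluate_basis(
    basis: SplineBasis,
    new_coords: SiteCoordinates,
    return_extrapolation_mask: bool = False,
):
    """Evaluate the stored basis functions at new locations.

    Returns an (M, K) matrix; evaluating at the training coordinates
    reproduces ``basis.basis_matrix``.  With ``return_extrapolation_mask``
    also returns a boolean mask marking points outside the training
    bounding box (extrapolation is permitted but flagged).
    """
    xy = new_coords.xy
    s = _scale_coords(xy, basis.transform)
    E_new = _tps_kernel(cdist(s, basis._train_scaled))
    X_pen = E_new @ basis._kernel_weights
    T_new = np.column_stack([np.ones(len(s)), s[:, 0], s[:, 1]])
    X = np.column_stack([X_pen, T_new])
    if not return_extrapolation_mask:
        return X
    lo = basis._train_scaled.min(axis=0)
    hi = basis._train_scaled.max(axis=0)
    outside = np.any((s < lo) | (s > hi), axis=1)
    return X, outside
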