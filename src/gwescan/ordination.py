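"""Constrained ordination and geographic predictors.

Redundancy analysis (RDA) regresses a multivariate response (centered SNP
dosages) on environmental predictors and eigen-decomposes the fitted values;
the constrained axes are the directions of SNP variation that the predictors
can explain.  Inertia is reported as raw sums of squares — the ratio
constrained/total (R^2) is identical to the variance-based convention.

Also here: Ezekiel adjusted R^2, permutation tests for the pseudo-F,
stepwise forward selection with the double stopping rule (permutation alpha
and the full-model adjusted R^2 ceiling), two-block variance partitioning,
Vincenty geodesic distances on the WGS-84 ellipsoid, and classical
principal-coordinates analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "RDA",
    "fit_rda",
    "adjusted_r2",
    "permutation_test",
    "ForwardSelector",
    "forward_select",
    "VarpartResult",
    "varpart",
    "geodesic_distance",
    "geodesic_distance_matrix",
    "pcoa",
    "geography_predictors",
]


def _as_2d(A) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    return A


def _orthonormal_basis(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column span of X (rank-revealing)."""
    if X.shape[1] == 0:
        return np.empty((X.shape[0], 0))
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    r = int(np.sum(S > S[0] * tol)) if S.size and S[0] > 0 else 0
    return U[:, :r]


def _residualize(A: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residuals of A after projection onto the orthonormal basis Q."""
    if Q.shape[1] == 0:
        return A
    return A - Q @ (Q.T @ A)


class RDA(BaseEstimator):
    """Redundancy analysis of a response matrix on predictor variables.

    Parameters
    ----------
    scale : bool, default False
        Standardize response columns to unit variance before the analysis.
        Dosage columns share units, so the default ordination is on the
        covariance (centering only).
    n_axes : int or None
        Number of constrained axes to retain; ``None`` keeps all axes with
        non-null eigenvalue.

    Attributes (after :meth:`fit`)
    ------------------------------
    eigenvalues_ : constrained sums of squares per axis.
    total_inertia_ : total sum of squares of the (conditioned) response.
    r2_, adj_r2_ : constrained fraction and its Ezekiel adjustment.
    site_scores_ : n x k sample scores (U * S).
    loadings_ : p x k response (SNP) loadings, unit norm per axis.
    biplot_scores_ : predictor correlations with the site scores.
    """

    def __init__(self, scale: bool = False, n_axes: int | None = None):
        self.scale = scale
        self.n_axes = n_axes

    def fit(self, X, Y, condition=None):
        X = _as_2d(X)
        Y = _as_2d(Y)
        n = Y.shape[0]
        if X.shape[0] != n:
            raise ValueError("X and Y must have the same number of rows")
        names = getattr(X, "columns", None)
        Yc = Y - Y.mean(axis=0)
        if self.scale:
            sd = Yc.std(axis=0, ddof=1)
            Yc = Yc / np.where(sd == 0, 1.0, sd)
        Xc = X - X.mean(axis=0)
        n_cond = 0
        if condition is not None:
            Z = _as_2d(condition)
            Zc = Z - Z.mean(axis=0)
            Qz = _orthonormal_basis(Zc)
            n_cond = Qz.shape[1]
            Yc = _residualize(Yc, Qz)
            Xc = _residualize(Xc, Qz)
        rank = np.linalg.matrix_rank(Xc)
        if rank < Xc.shape[1]:
            bad = self._collinear_columns(Xc)
            raise ValueError(
                "predictors are rank-deficient after conditioning; "
                f"collinear columns: {bad}"
            )
        if n < Xc.shape[1] + n_cond + 2:
            raise ValueError("need n_samples >= n_predictors + 2")
        Qx = _orthonormal_basis(Xc)
        fitted = Qx @ (Qx.T @ Yc)
        U, S, Vt = np.linalg.svd(fitted, full_matrices=False)
        tol = S[0] * 1e-12 if S.size and S[0] > 0 else 0.0
        k = int(np.sum(S > tol))
        if self.n_axes is not None:
            k = min(k, self.n_axes)
        total = float(np.sum(Yc * Yc))
        constrained = float(np.sum(S[: int(np.sum(S > tol))] ** 2))
        self.n_samples_ = n
        self.n_predictors_ = Xc.shape[1]
        self.eigenvalues_ = S[:k] ** 2
        self.total_inertia_ = total
        self.constrained_inertia_ = constrained
        self.r2_ = constrained / total if total > 0 else 0.0
        self.adj_r2_ = adjusted_r2(self.r2_, n, Xc.shape[1])
        self.site_scores_ = U[:, :k] * S[:k]
        self.loadings_ = Vt[:k].T
        with np.errstate(invalid="ignore", divide="ignore"):
            bs = np.array(
                [
                    [_safe_corr(Xc[:, j], self.site_scores_[:, a]) for a in range(k)]
                    for j in range(Xc.shape[1])
                ]
            )
        self.biplot_scores_ = bs
        self.predictor_names_ = (
            list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
        )
        return self

    @staticmethod
    def _collinear_columns(Xc: np.ndarray) -> list[int]:
        from scipy.linalg import qr

        _, R, piv = qr(Xc, mode="economic", pivoting=True)
        d = np.abs(np.diag(R))
        thresh = d[0] * 1e-10 if d.size and d[0] > 0 else 0.0
        return sorted(int(piv[i]) for i in range(len(d)) if d[i] <= thresh)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def fit_rda(Y, X, condition=None, scale: bool = False, n_axes: int | None = None) -> RDA:
    """Functional wrapper: fit an :class:`RDA` of ``Y`` on ``X``."""
    return RDA(scale=scale, n_axes=n_axes).fit(X, Y, condition=condition)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel correction: 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 needs n > p + 1 (n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _r2_project(Yc: np.ndarray, Q: np.ndarray, total: float) -> float:
    if total <= 0:
        return 0.0
    return float(np.sum((Q.T @ Yc) ** 2)) / total


def _reduce_response(Yc: np.ndarray) -> np.ndarray:
    """Replace a wide centered response by U*S from its thin SVD.

    Row permutations and projections only see Y through Frobenius norms of
    Q' P Y, which are invariant to the right-orthogonal factor, so a wide
    SNP matrix (p >> n) can be collapsed to n columns without changing any
    R^2, pseudo-F or permutation p-value.
    """
    n, p = Yc.shape
    if p <= n:
        return Yc
    U, S, _ = np.linalg.svd(Yc, full_matrices=False)
    return U * S


def permutation_test(
    Y,
    X,
    condition=None,
    n_perm: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation test of the RDA pseudo-F.

    Without conditioning the rows of the centered response are permuted;
    with conditioning, residuals under the reduced (condition-only) model
    are permuted.  p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so the
    smallest attainable p is 1/(n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if rng is None:
        rng = np.random.default_rng(seed)
    Y = _as_2d(Y)
    X = _as_2d(X)
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    n_cond = 0
    if condition is not None:
        Z = _as_2d(condition)
        Qz = _orthonormal_basis(Z - Z.mean(axis=0))
        n_cond = Qz.shape[1]
        Yc = _residualize(Yc, Qz)
        Xc = _residualize(Xc, Qz)
    Yc = _reduce_response(Yc)
    Qx = _orthonormal_basis(Xc)
    r = Qx.shape[1]
    if r == 0:
        raise ValueError("predictors have no variation")
    df_res = n - 1 - r - n_cond
    total = float(np.sum(Yc * Yc))

    def pseudo_f(Yp: np.ndarray) -> float:
        ss_fit = float(np.sum((Qx.T @ Yp) ** 2))
        ss_res = max(total - ss_fit, 0.0)
        if ss_res == 0.0:
            return np.inf
        return (ss_fit / r) / (ss_res / df_res)

    f_obs = pseudo_f(Yc)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if pseudo_f(Yc[perm]) >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return float(f_obs), float(p)


@dataclass
class ForwardSelectionResult:
    steps: list[dict] = field(default_factory=list)
    stopping_reason: str = ""

    @property
    def selected(self) -> list[str]:
        return [s["variable"] for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["variable", "cum_adj_r2", "pseudo_f", "p_value"]
        )


class ForwardSelector(BaseEstimator):
    """Stepwise forward selection of ordination predictors.

    At each step the candidate with the largest adjusted-R^2 gain is tested
    by a permutation test conditioned on the already-selected variables;
    it enters only if p <= ``alpha`` AND the new cumulative adjusted R^2
    does not exceed the full-model adjusted R^2 (double stopping rule that
    controls the type-1 error of stepwise ordination).
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_perm: int = 999,
        full_adj_r2: float | None = None,
        seed: int | None = None,
        condition=None,
    ):
        self.alpha = alpha
        self.n_perm = n_perm
        self.full_adj_r2 = full_adj_r2
        self.seed = seed
        self.condition = condition

    def fit(self, X: pd.DataFrame, Y):
        X = pd.DataFrame(X)
        if X.shape[1] < 1:
            raise ValueError("need at least one candidate")
        Y = _as_2d(Y)
        n = Y.shape[0]
        Yc = Y - Y.mean(axis=0)
        Xall = X.to_numpy(dtype=float)
        Xall = Xall - Xall.mean(axis=0)
        if self.condition is not None:
            Z = _as_2d(self.condition)
            Qz = _orthonormal_basis(Z - Z.mean(axis=0))
            Yc = _residualize(Yc, Qz)
            Xall = _residualize(Xall, Qz)
        Yc = _reduce_response(Yc)
        total = float(np.sum(Yc * Yc))
        full_adj = self.full_adj_r2
        if full_adj is None:
            Qf = _orthonormal_basis(Xall)
            full_adj = adjusted_r2(_r2_project(Yc, Qf, total), n, Qf.shape[1])
        rng = np.random.default_rng(self.seed)
        cols = list(X.columns)
        selected: list[int] = []
        result = ForwardSelectionResult()
        while True:
            remaining = [j for j in range(len(cols)) if j not in selected]
            if not remaining:
                result.stopping_reason = "exhausted"
                break
            best_j, best_adj = None, -np.inf
            for j in remaining:
                Q = _orthonormal_basis(Xall[:, selected + [j]])
                adj = adjusted_r2(
                    _r2_project(Yc, Q, total), n, len(selected) + 1
                )
                if adj > best_adj:
                    best_adj, best_j = adj, j
            prev_adj = result.steps[-1]["cum_adj_r2"] if result.steps else 0.0
            if best_adj <= prev_adj:
                result.stopping_reason = "no_gain"
                break
            if best_adj > full_adj:
                result.stopping_reason = "adj_r2_ceiling"
                break
            cond = Xall[:, selected] if selected else None
            f, p = permutation_test(
                Yc, Xall[:, [best_j]], condition=cond, n_perm=self.n_perm, rng=rng
            )
            if p > self.alpha:
                result.stopping_reason = "alpha"
                break
            selected.append(best_j)
            result.steps.append(
                {
                    "variable": cols[best_j],
                    "cum_adj_r2": best_adj,
                    "pseudo_f": f,
                    "p_value": p,
                }
            )
        self.result_ = result
        self.selected_ = result.selected
        self.full_adj_r2_ = full_adj
        return self


def forward_select(
    Y,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    full_adj_r2: float | None = None,
    seed: int | None = None,
    condition=None,
) -> ForwardSelectionResult:
    """Functional wrapper over :class:`ForwardSelector`."""
    sel = ForwardSelector(
        alpha=alpha, n_perm=n_perm, full_adj_r2=full_adj_r2, seed=seed,
        condition=condition,
    ).fit(candidates, Y)
    return sel.result_


@dataclass
class VarpartResult:
    """Two-block variance partition on the adjusted-R^2 scale.

    a = unique to block 1 (climate), c = unique to block 2 (geography),
    b = shared, d = residual; a + b + c + d = 1 by construction.
    """

    a: float
    b: float
    c: float
    d: float
    adj_r2_block1: float
    adj_r2_block2: float
    adj_r2_full: float

    @property
    def climate_total(self) -> float:
        return self.a + self.b

    @property
    def geography_total(self) -> float:
        return self.b + self.c


def varpart(Y, X_block1, X_block2) -> VarpartResult:
    """Partition response variance between two predictor blocks.

    Adjusted R^2 of the block-1-only, block-2-only and joint models combine
    by inclusion-exclusion: a = adjR2(full) - adjR2(block2), etc.
    """
    Y = _as_2d(Y)
    X1 = _as_2d(X_block1)
    X2 = _as_2d(X_block2)
    if X1.shape[1] == 0 or X2.shape[1] == 0:
        raise ValueError("both predictor blocks must be nonempty")
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    total = float(np.sum(Yc * Yc))

    def adj(Xb: np.ndarray) -> float:
        Q = _orthonormal_basis(Xb - Xb.mean(axis=0))
        if Q.shape[1] == 0:
            raise ValueError("predictor block has no variation")
        return adjusted_r2(_r2_project(Yc, Q, total), n, Q.shape[1])

    a1 = adj(X1)
    a2 = adj(X2)
    Xf = np.column_stack([X1, X2])
    Qf = _orthonormal_basis(Xf - Xf.mean(axis=0))
    if Qf.shape[1] >= n - 1:
        raise ValueError("joint model is saturated/rank-deficient")
    afull = adj(Xf)
    a = afull - a2
    c = afull - a1
    b = a1 + a2 - afull
    d = 1.0 - afull
    return VarpartResult(a=a, b=b, c=c, d=d, adj_r2_block1=a1, adj_r2_block2=a2, adj_r2_full=afull)


# ---------------------------------------------------------------------------
# Geodesy and principal coordinates

_WGS84_A = 6378137.0
_WGS84_F = 1 / 298.257223563
_WGS84_B = _WGS84_A * (1 - _WGS84_F)


def geodesic_distance(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Vincenty inverse geodesic distance (meters) on the WGS-84 ellipsoid.

    Falls back to the spherical great-circle formula (with a warning) in
    the rare non-convergent near-antipodal case.
    """
    if lon1 == lon2 and lat1 == lat2:
        return 0.0
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - _WGS84_F) * math.tan(phi1))
    U2 = math.atan((1 - _WGS84_F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)
    lam = L
    for _ in range(200):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(
            cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        )
        if sin_sigma == 0.0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha * sin_alpha
        cos_2sigma_m = (
            cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha if cos2_alpha != 0 else 0.0
        )
        C = _WGS84_F / 16.0 * cos2_alpha * (4 + _WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * _WGS84_F * sin_alpha * (
            sigma
            + C
            * sin_sigma
            * (cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < 1e-12:
            break
    else:
        warnings.warn(
            "Vincenty iteration did not converge (near-antipodal points); "
            "falling back to spherical distance",
            RuntimeWarning,
            stacklevel=2,
        )
        r = (2 * _WGS84_A + _WGS84_B) / 3.0
        d = math.acos(
            min(1.0, max(-1.0, math.sin(phi1) * math.sin(phi2)
                         + math.cos(phi1) * math.cos(phi2) * math.cos(L)))
        )
        return r * d
    u2 = cos2_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos_2sigma_m
            + B
            / 4
            * (
                cos_sigma * (-1 + 2 * cos_2sigma_m**2)
                - B
                / 6
                * cos_2sigma_m
                * (-3 + 4 * sin_sigma**2)
                * (-3 + 4 * cos_2sigma_m**2)
            )
        )
    )
    return _WGS84_B * A * (sigma - delta_sigma)


def geodesic_distance_matrix(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Symmetric pairwise Vincenty distance matrix (meters)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = len(lon)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = geodesic_distance(lon[i], lat[i], lon[j], lat[j])
    return D


def pcoa(D: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centers -D^2/2, keeps the top-k positive eigenvalues and returns
    coordinates scaled by sqrt(eigenvalue), plus all eigenvalues sorted
    descending.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D * D) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(k, int(np.sum(vals > 0)))
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    return coords, vals


def geography_predictors(
    lon: np.ndarray, lat: np.ndarray, min_inertia: float = 0.95
) -> np.ndarray:
    """Geography block for variance partitioning.

    Principal coordinates of the pairwise Vincenty distance matrix, keeping
    the leading axes with positive eigenvalue covering at least
    ``min_inertia`` of the positive inertia.
    """
    D = geodesic_distance_matrix(lon, lat)
    coords, vals = pcoa(D, k=len(lon) - 1)
    pos = vals[vals > 0]
    cum = np.cumsum(pos) / pos.sum()
    k = int(np.searchsorted(cum, min_inertia) + 1)
    return coords[:, : min(k, coords.shape[1])]
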