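"""Operations on symmetric positive-definite (SPD) matrices under the
affine-invariant (Fisher) metric.

A 1-s epoch of an n-channel EEG recording is summarised by its spatial
covariance matrix, a point on the SPD manifold.  Under the affine-invariant
metric the distance between two covariance matrices is invariant to any
congruence transformation (re-referencing, linear mixing), which is what
makes the geometry suitable for EEG spatial patterns.  This module provides
the metric distance, the geometric (Frechet/Karcher) mean computed by
fixed-point iteration, and the geometric dispersion statistics used to
standardize distances of a training set to its centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "DistanceStats",
    "GeometricMeanResult",
    "InvalidMatrixError",
    "ConvergenceError",
    "validate_spd",
    "riemannian_distance",
    "pairwise_distances",
    "distances_to_reference",
    "geometric_mean",
    "distance_stats",
    "standardize_distance",
]

# Relative eigenvalue floor below which a matrix is considered singular.
EIG_RTOL = 1e-12


class InvalidMatrixError(ValueError):
    """Input matrix is not symmetric positive-definite."""


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach tolerance.

    Carries the last residual in ``residual``.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class DistanceStats:
    """Geometric mean and geometric standard deviation of a distance set.

    ``mu`` is the geometric mean exp(mean(ln d_k)); ``sigma`` the geometric
    standard deviation exp(sqrt(mean(ln(d_k/mu)^2))) (multiplicative, >= 1);
    ``count`` the number of distances the statistics summarise.
    """

    mu: float
    sigma: float
    count: int


@dataclass(frozen=True)
class GeometricMeanResult:
    mean: np.ndarray
    iterations: int
    final_residual: float


def validate_spd(C: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Check symmetry and strict positive-definiteness.

    Returns the eigenvalues.  Eigenvalues below EIG_RTOL times the largest
    raise InvalidMatrixError rather than being clipped silently.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise InvalidMatrixError(f"{name} must be square, got shape {C.shape}")
    if not np.allclose(C, C.T, rtol=1e-8, atol=1e-10):
        raise InvalidMatrixError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(C)
    if w[0] <= EIG_RTOL * max(w[-1], 0.0) or w[-1] <= 0:
        raise InvalidMatrixError(
            f"{name} is not positive-definite (eigenvalue range "
            f"[{w[0]:.3e}, {w[-1]:.3e}]); consider covariance shrinkage"
        )
    return w


def _eig_fun(C: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to a symmetric matrix via eigendecomposition."""
    w, V = np.linalg.eigh(C)
    return (V * fun(w)) @ V.T


def _isqrtm(C: np.ndarray) -> np.ndarray:
    return _eig_fun(C, lambda w: 1.0 / np.sqrt(w))


def _sqrtm(C: np.ndarray) -> np.ndarray:
    return _eig_fun(C, np.sqrt)


def riemannian_distance(a: np.ndarray, b: np.ndarray, *, validate: bool = True) -> float:
    """Affine-invariant distance sqrt(sum_i log^2 lambda_i).

    The lambda_i are the generalized eigenvalues of the pencil (a, b),
    i.e. the eigenvalues of b^{-1} a; the distance is symmetric because
    inverting the eigenvalues only flips the sign of their logs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidMatrixError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if validate:
        validate_spd(a, "a")
        validate_spd(b, "b")
    w = scipy.linalg.eigvalsh(a, b)
    if w[0] <= 0:
        raise InvalidMatrixError("generalized eigenvalues not all positive")
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def distances_to_reference(covs: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Distances from a stack of SPD matrices (N, n, n) to one reference.

    Uses the congruence by ref^{-1/2} so the whole stack reduces to one
    batched symmetric eigendecomposition.
    """
    covs = np.asarray(covs, dtype=float)
    K = _isqrtm(np.asarray(ref, dtype=float))
    M = K @ covs @ K
    M = 0.5 * (M + np.swapaxes(M, -1, -2))
    w = np.linalg.eigvalsh(M)
    if np.any(w <= 0):
        raise InvalidMatrixError("non-SPD matrix in stack")
    return np.sqrt(np.sum(np.log(w) ** 2, axis=-1))


def pairwise_distances(covs: np.ndarray) -> np.ndarray:
    """Full symmetric N x N distance matrix for a stack of SPD matrices.

    Precomputes each inverse square root once; row i is then a single
    batched eigendecomposition over the remaining matrices.
    """
    covs = np.asarray(covs, dtype=float)
    N = covs.shape[0]
    D = np.zeros((N, N))
    isqrts = np.empty_like(covs)
    for i in range(N):
        isqrts[i] = _isqrtm(covs[i])
    for i in range(N - 1):
        K = isqrts[i]
        M = K @ covs[i + 1 :] @ K
        M = 0.5 * (M + np.swapaxes(M, -1, -2))
        w = np.linalg.eigvalsh(M)
        if np.any(w <= 0):
            raise InvalidMatrixError("non-SPD matrix in stack")
        d = np.sqrt(np.sum(np.log(w) ** 2, axis=-1))
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return D


def geometric_mean(
    covs,
    tol: float = 1e-7,
    max_iter: int = 100,
) -> GeometricMeanResult:
    """Geometric (Frechet) mean of a set of SPD matrices.

    Initialized at the arithmetic mean, then the fixed-point iteration

        M <- M^{1/2} exp[(1/k) sum_k ln(M^{-1/2} C_k M^{-1/2})] M^{1/2}

    is repeated until the Frobenius norm of the bracketed mean-log term
    falls below ``tol``.  Raises ConvergenceError (carrying the last
    residual) after ``max_iter`` iterations.
    """
    covs = np.asarray(covs, dtype=float)
    if covs.ndim == 2:
        covs = covs[None]
    if covs.shape[0] == 0:
        raise ValueError("geometric_mean of an empty set")
    if covs.shape[0] == 1:
        return GeometricMeanResult(mean=covs[0].copy(), iterations=0, final_residual=0.0)

    def mean_log(M: np.ndarray) -> np.ndarray:
        K = _isqrtm(M)
        inner = K @ covs @ K
        inner = 0.5 * (inner + np.swapaxes(inner, -1, -2))
        w, V = np.linalg.eigh(inner)
        if np.any(w <= 0):
            raise InvalidMatrixError("non-SPD matrix in geometric mean input")
        logs = (V * np.log(w)[..., None, :]) @ np.swapaxes(V, -1, -2)
        return logs.mean(axis=0)

    M = covs.mean(axis=0)
    J = mean_log(M)
    residual = float(np.linalg.norm(J, "fro"))
    step = 1.0
    for it in range(1, max_iter + 1):
        if residual < tol:
            return GeometricMeanResult(mean=M, iterations=it - 1, final_residual=residual)
        # the unit-step fixed point is not contractive for widely dispersed
        # sets; halve the step until the residual decreases
        while True:
            S = _sqrtm(M)
            M_new = S @ _eig_fun(0.5 * step * (J + J.T), np.exp) @ S
            M_new = 0.5 * (M_new + M_new.T)
            J_new = mean_log(M_new)
            r_new = float(np.linalg.norm(J_new, "fro"))
            if r_new < residual or step < 1e-4:
                break
            step *= 0.5
        M, J, residual = M_new, J_new, r_new
        if step < 1.0:
            step = min(step * 2.0, 1.0)
    if residual < tol:
        return GeometricMeanResult(mean=M, iterations=max_iter, final_residual=residual)
    raise ConvergenceError(
        f"geometric mean did not converge in {max_iter} iterations "
        f"(residual {residual:.3e})",
        residual,
    )


def distance_stats(distances) -> DistanceStats:
    """Geometric mean and geometric standard deviation of a distance set.

    mu = exp(mean(ln d_k)); sigma = exp(sqrt(mean(ln(d_k/mu)^2))).
    The square root makes sigma the conventional geometric SD, so that
    d = mu * sigma lies exactly one (multiplicative) SD from the center.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two distances")
    if np.any(d <= 0):
        raise ValueError(
            "distances must be strictly positive (a zero distance means a "
            "training epoch identical to the centroid; jitter or drop it)"
        )
    logs = np.log(d)
    mu = float(np.exp(logs.mean()))
    sigma = float(np.exp(np.sqrt(np.mean((logs - logs.mean()) ** 2))))
    return DistanceStats(mu=mu, sigma=sigma, count=int(d.size))


def standardize_distance(delta, stats: DistanceStats):
    """Standardized distance ln(delta/mu) / ln(sigma).

    Accepts a scalar or an array of distances; raises for the degenerate
    case sigma <= 1 (no dispersion to standardize by).
    """
    if stats.sigma <= 1.0:
        raise ValueError(f"degenerate dispersion sigma={stats.sigma}")
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0):
        raise ValueError("distance must be strictly positive")
    out = np.log(delta / stats.mu) / np.log(stats.sigma)
    return float(out) if out.ndim == 0 else out
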