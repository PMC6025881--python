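"""Toy emission-tomography forward model, Poisson data and MLEM.

A linear system operator H maps a nonnegative voxelized field to mean
detector-bin counts; the measured data are independent Poisson draws around
those means.  Reconstruction is classical MLEM (maximum-likelihood
expectation-maximization), the standard multiplicative iteration

    x <- (x / s) * H^T (g / (H x)),     s = H^T 1,

which preserves nonnegativity, never decreases the Poisson log-likelihood and,
after the first iteration, projects to the total observed counts.  The default
toy system is a separable Gaussian blur followed by block downsampling — the
low-pass-plus-sampling essence of ECT without attenuation, scatter or detector
physics.  Reconstruction covariance is estimated by Monte Carlo over
independent noise realizations (a Fisher-information approximation is offered
as a fast, clearly non-reference alternative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp

from .exceptions import ModelError
from .fields import Grid, ScalarField, TemporalField, _as_rng

__all__ = [
    "SystemOperator",
    "CountData",
    "Reconstruction",
    "blur_downsample_operator",
    "identity_operator",
    "forward_project",
    "sample_counts",
    "poisson_loglik",
    "mlem_reconstruct",
    "recon_covariance",
    "fisher_covariance",
]


class SystemOperator:
    """Explicit nonnegative matrix H: voxels -> detector bins.

    ``sensitivity`` (the column sums H^T 1) must be strictly positive on the
    reconstruction support.
    """

    def __init__(self, matrix):
        if sp.issparse(matrix):
            self.matrix = matrix.tocsr()
            if self.matrix.nnz and self.matrix.min() < 0:
                raise ValueError("system matrix entries must be nonnegative")
        else:
            self.matrix = np.asarray(matrix, dtype=float)
            if self.matrix.size and self.matrix.min() < 0:
                raise ValueError("system matrix entries must be nonnegative")
        self.n_detectors, self.n_voxels = self.matrix.shape
        s = np.asarray(self.matrix.sum(axis=0)).ravel()
        self.sensitivity = s

    def apply(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.matrix @ x).ravel()

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(self.matrix.T @ y).ravel()


@dataclass
class CountData:
    """Nonnegative integer counts per detector bin."""

    counts: np.ndarray
    exposure: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class Reconstruction:
    """MLEM output: the estimate, its iteration count and log-likelihood
    trace, and (optionally) a voxel covariance estimate."""

    values: np.ndarray  # flat voxel vector
    n_iter: int
    loglik_trace: np.ndarray
    covariance: np.ndarray | None = None

    def as_field(self, grid: Grid, **kw) -> ScalarField:
        return ScalarField(grid, self.values.reshape(grid.shape), nonnegative=True, **kw)


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------


def _blur_matrix_1d(n: int, fwhm: float) -> np.ndarray:
    """Row-normalized truncated-Gaussian blur (FWHM in voxels)."""
    if fwhm <= 0:
        return np.eye(n)
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    half = max(1, int(math.ceil(4.0 * sigma)))
    offs = np.arange(-half, half + 1)
    ker = np.exp(-0.5 * (offs / sigma) ** 2)
    B = np.zeros((n, n))
    for i in range(n):
        j = i + offs
        ok = (j >= 0) & (j < n)
        B[i, j[ok]] = ker[ok]
    B /= B.sum(axis=1, keepdims=True)
    return B


def _pool_matrix_1d(n: int, k: int) -> np.ndarray:
    """k-fold average pooling; n must be divisible by k."""
    if n % k:
        raise ValueError(f"axis size {n} not divisible by downsampling factor {k}")
    P = np.zeros((n // k, n))
    for i in range(n // k):
        P[i, i * k : (i + 1) * k] = 1.0 / k
    return P


def blur_downsample_operator(
    shape, fwhm_voxels: float = 1.5, factor: int = 1, gain: float = 1.0
) -> SystemOperator:
    """Separable Gaussian blur + block-average downsampling as an explicit
    sparse matrix; ``gain`` scales mean counts per unit activity."""
    mats = []
    for n in shape:
        if n == 1:
            mats.append(np.eye(1))
            continue
        M = _pool_matrix_1d(n, factor if n % factor == 0 else 1) @ _blur_matrix_1d(n, fwhm_voxels)
        mats.append(M)
    H = sp.kron(sp.kron(sp.csr_matrix(mats[0]), sp.csr_matrix(mats[1])), sp.csr_matrix(mats[2]))
    return SystemOperator(gain * H.tocsr())


def identity_operator(n_voxels: int, gain: float = 1.0) -> SystemOperator:
    return SystemOperator(gain * sp.identity(n_voxels, format="csr"))


# ---------------------------------------------------------------------------
# Forward model and likelihood
# ---------------------------------------------------------------------------


def forward_project(H: SystemOperator, field) -> np.ndarray:
    """Mean detector counts H f for a nonnegative field (or flat vector)."""
    x = field.values.ravel() if hasattr(field, "values") else np.asarray(field, dtype=float).ravel()
    if x.min() < 0:
        raise ValueError("field must be nonnegative")
    return H.apply(x)


def sample_counts(means: np.ndarray, seed) -> CountData:
    """Independent Poisson draws per detector bin."""
    means = np.asarray(means, dtype=float)
    if means.size and means.min() < 0:
        raise ValueError("Poisson means must be nonnegative")
    rng = _as_rng(seed)
    return CountData(rng.poisson(means))


def poisson_loglik(H: SystemOperator, g: CountData, field) -> float:
    """Poisson log-likelihood sum_m [g_m ln(Hf)_m - (Hf)_m], constants
    dropped; 0 ln 0 = 0, and -inf where a zero mean meets a positive count."""
    hf = forward_project(H, field)
    g_ = g.counts.astype(float)
    with np.errstate(divide="ignore"):
        lg = np.where(g_ > 0, g_ * np.log(np.where(hf > 0, hf, 1.0)), 0.0)
    if np.any((hf == 0) & (g_ > 0)):
        return -math.inf
    return float(np.sum(lg - hf))


def mlem_reconstruct(
    H: SystemOperator,
    g: CountData,
    n_iter: int = 50,
    init: np.ndarray | None = None,
    track_loglik: bool = True,
) -> Reconstruction:
    """MLEM with the standard multiplicative update.

    Stopping is a fixed iteration count (a bias/variance trade-off knob, not
    a convergence criterion).  Requires a strictly positive initial estimate
    and strictly positive sensitivity.
    """
    s = H.sensitivity
    if s.min() <= 0:
        raise ModelError("zero-sensitivity voxel: H cannot reconstruct there")
    g_ = g.counts.astype(float)
    if g_.shape != (H.n_detectors,):
        raise ValueError("count vector length != number of detector bins")
    if init is None:
        x = np.full(H.n_voxels, max(g_.sum(), 1.0) / s.sum())
    else:
        x = np.asarray(init, dtype=float).copy()
        if x.min() <= 0:
            raise ValueError("initial estimate must be strictly positive")
    trace = []
    for _ in range(n_iter):
        hx = H.apply(x)
        ratio = np.divide(g_, hx, out=np.ones_like(g_), where=hx > 0)
        x = (x / s) * H.adjoint(ratio)
        if track_loglik:
            trace.append(poisson_loglik(H, g, x))
    return Reconstruction(x, n_iter, np.asarray(trace))


def recon_covariance(
    H: SystemOperator,
    truth: np.ndarray,
    n_iter: int,
    n_noise: int,
    seed,
):
    """Monte-Carlo covariance of the MLEM estimator at a fixed truth.

    Draws ``n_noise`` independent Poisson data realizations around H(truth),
    reconstructs each, and returns (sample covariance, sample mean).  The
    covariance is symmetric PSD by construction.
    """
    if n_noise < 2:
        raise ValueError("need at least 2 noise realizations")
    rng = _as_rng(seed)
    truth = np.asarray(truth, dtype=float).ravel()
    means = H.apply(truth)
    ests = np.empty((n_noise, H.n_voxels))
    for i in range(n_noise):
        g = sample_counts(means, rng)
        ests[i] = mlem_reconstruct(H, g, n_iter=n_iter, track_loglik=False).values
    cov = np.cov(ests, rowvar=False)
    cov = np.atleast_2d(cov)
    return 0.5 * (cov + cov.T), ests.mean(axis=0)


def fisher_covariance(H: SystemOperator, truth: np.ndarray) -> np.ndarray:
    """Fisher-information (CRB) covariance approximation at the truth:
    pinv(H^T diag(1/Hf) H).  Fast, but NOT the reference: it ignores the
    early-stopping bias/variance of MLEM."""
    truth = np.asarray(truth, dtype=float).ravel()
    hf = H.apply(truth)
    if hf.min() <= 0:
        raise ModelError("Fisher covariance needs strictly positive means")
    Hd = H.matrix.toarray() if sp.issparse(H.matrix) else H.matrix
    F = Hd.T @ (Hd / hf[:, None])
    return np.linalg.pinv(F)
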