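"""Patient-specific log-kill estimation, TCP and the TOC curve.

Plugging MLEM reconstructions of the sensitivity and drug fields into the
integrated log-kill gives the patient-specific estimate

    Yhat = -<alpha_hat, AUC_hat>,

asymptotically normal with variance propagated from the reconstruction
covariances of the two (statistically independent) ECT data sets.  Two
variance modes are provided:

* ``"as-printed"``: the literal double sum with prefactor eps^3 dt,
  Var = eps^3 dt * sum_{n n'} K_alpha(n, n') sum_{m m'} K_c(n m; n' m').
* ``"quadrature-consistent"``: the variance of the discrete quadrature
  Yhat = -eps^3 sum_n alpha_n (dt sum_m c_{n m}) for independent estimates,
  Var = eps^6 [ sum K_alpha o K_AUC + abar^T K_AUC abar + AUC^T K_alpha AUC ],
  with K_AUC = dt^2 sum_{m m'} K_c.  Dimensional analysis of the quadrature
  supports the latter; both are computed and the Monte-Carlo oracle
  arbitrates in the test suite.

The estimated TCP is the Gaussian lower tail at the control threshold Y_c
(an error function).  Sweeping administered mass M against a normal-tissue
complication model (probit in ln M — a conventional sigmoid stand-in, since
whole-body dose-complication data are scarce) traces the Therapy Operating
Characteristic curve; its area AUTOC is the scalar figure of merit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import GridMismatchError, ModelError
from .fields import ScalarField, TemporalField, _same_grid
from .logkill import AUCField, compute_auc, integrated_logkill

__all__ = [
    "PatientEstimates",
    "YEstimate",
    "NTCPModel",
    "TOCCurve",
    "estimate_Y",
    "variance_Y",
    "tcp_estimate",
    "ntcp",
    "toc_curve",
]

PSD_TOL = 1e-10


def _check_psd(K: np.ndarray, name: str) -> None:
    if not np.allclose(K, K.T, atol=1e-8 * max(1.0, np.abs(K).max())):
        raise ModelError(f"{name} covariance must be symmetric")
    w = np.linalg.eigvalsh(K)
    if w.min() < -PSD_TOL * max(np.trace(K), 1.0):
        raise ModelError(f"{name} covariance not PSD (min eig {w.min():.3e})")


@dataclass
class PatientEstimates:
    """Reconstructed sensitivity/drug fields and their covariances.

    ``cov_c`` is a list of per-frame voxel covariance matrices (dynamic
    frames are imaged independently, so cross-frame covariances vanish).
    """

    alpha_hat: ScalarField
    c_hat: TemporalField
    cov_alpha: np.ndarray
    cov_c: list[np.ndarray]

    def __post_init__(self):
        if not _same_grid(self.alpha_hat.grid, self.c_hat.grid):
            raise GridMismatchError("alpha and c estimates on different grids")
        nv = self.alpha_hat.grid.n_voxels
        self.cov_alpha = np.asarray(self.cov_alpha, dtype=float)
        if self.cov_alpha.shape != (nv, nv):
            raise ValueError("cov_alpha must be n_voxels x n_voxels")
        _check_psd(self.cov_alpha, "alpha")
        self.cov_c = [np.asarray(K, dtype=float) for K in self.cov_c]
        if len(self.cov_c) != self.c_hat.n_times:
            raise ValueError("need one c covariance per time frame")
        for K in self.cov_c:
            if K.shape != (nv, nv):
                raise ValueError("each cov_c entry must be n_voxels x n_voxels")


@dataclass
class YEstimate:
    y_hat: float
    variance: float
    method: str = "quadrature-consistent"

    def __post_init__(self):
        if self.variance < 0:
            raise ValueError("variance must be nonnegative")


def estimate_Y(est: PatientEstimates, t0: float, T: float) -> float:
    """Yhat = -<alpha_hat, AUC_hat> with AUC_hat integrated from c_hat."""
    auc = compute_auc(est.c_hat, t0, T)
    return integrated_logkill(est.alpha_hat, auc)


def variance_Y(est: PatientEstimates, mode: str = "quadrature-consistent",
               t0: float | None = None, T: float | None = None) -> float:
    """Variance of Yhat propagated from the reconstruction covariances.

    See the module docstring for the two modes.  ``t0``/``T`` restrict the
    quadrature-consistent mode to the AUC window (default: all frames).
    """
    grid = est.alpha_hat.grid
    eps3 = grid.voxel_volume
    dt = est.c_hat.dt
    if t0 is None:
        sel = np.ones(est.c_hat.n_times, dtype=bool)
    else:
        tiny = 1e-9 * dt
        sel = (est.c_hat.times >= t0 - tiny) & (est.c_hat.times < t0 + (T or 0.0) - tiny)
    # frames independent: sum over m, m' of K_c collapses to a single sum
    s_c = np.zeros_like(est.cov_alpha)
    for m, K in enumerate(est.cov_c):
        if sel[m]:
            s_c = s_c + K
    if mode == "as-printed":
        return float(eps3 * dt * np.sum(est.cov_alpha * s_c))
    if mode != "quadrature-consistent":
        raise ValueError(f"unknown variance mode {mode!r}")
    k_auc = dt**2 * s_c
    abar = est.alpha_hat.values.ravel()
    if t0 is None:
        auc = est.c_hat.values.reshape(est.c_hat.n_times, -1)[sel].sum(axis=0) * dt
    else:
        auc = compute_auc(est.c_hat, t0, T).values.ravel()
    var = (
        np.sum(est.cov_alpha * k_auc)
        + abar @ k_auc @ abar
        + auc @ est.cov_alpha @ auc
    )
    return float(eps3**2 * max(var, 0.0))


def tcp_estimate(y_hat: float, variance: float, yc: float) -> float:
    """Estimated TCP = Pr(Yhat < Yc) under the asymptotic Gaussian:
    the error-function form Phi((Yc - Yhat) / sd).  Zero variance degenerates
    to the indicator of Yhat < Yc."""
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    if variance == 0:
        return 1.0 if y_hat < yc else 0.0
    return float(norm.cdf((yc - y_hat) / math.sqrt(variance)))


@dataclass(frozen=True)
class NTCPModel:
    """Normal-tissue complication probability vs administered mass:
    a probit in ln M with NTCP(M50) = 1/2 and slope sigma (log-mass units).
    A conventional sigmoid shape; not calibrated to any drug."""

    m50: float
    sigma: float

    def __post_init__(self):
        if self.m50 <= 0 or self.sigma <= 0:
            raise ValueError("require M50 > 0 and sigma > 0")


def ntcp(model: NTCPModel, mass) -> np.ndarray | float:
    """NTCP(M) = Phi((ln M - ln M50) / sigma); 0 at M = 0, strictly
    increasing, range (0, 1)."""
    m = np.asarray(mass, dtype=float)
    if np.any(m < 0):
        raise ValueError("administered mass must be nonnegative")
    with np.errstate(divide="ignore"):
        z = np.where(m > 0, (np.log(np.where(m > 0, m, 1.0)) - math.log(model.m50)) / model.sigma, -np.inf)
    out = norm.cdf(z)
    return float(out) if np.isscalar(mass) else out


@dataclass
class TOCCurve:
    """TCP/NTCP pairs swept over administered mass, with the area under the
    TCP-vs-NTCP curve (AUTOC) over NTCP in [0, 1]."""

    table: pd.DataFrame  # columns M, TCP, NTCP
    autoc: float


def toc_curve(
    masses,
    tcp_values,
    ntcp_model: NTCPModel,
    tcp_limits: tuple[float, float] | None = None,
) -> TOCCurve:
    """Construct the TOC curve and its area.

    ``tcp_limits`` are the M -> 0 and M -> infinity limits of TCP used to
    extend the curve to the endpoints NTCP = 0 and NTCP = 1 before the
    trapezoid rule; by default the first/last sampled TCP values are carried
    out flat.
    """
    masses = np.asarray(masses, dtype=float)
    tcp_values = np.asarray(tcp_values, dtype=float)
    if masses.size == 0:
        raise ValueError("mass grid must be nonempty")
    if masses.size != tcp_values.size:
        raise ValueError("masses and TCP values must align")
    order = np.argsort(masses)
    masses, tcp_values = masses[order], tcp_values[order]
    nt = ntcp(ntcp_model, masses)
    table = pd.DataFrame({"M": masses, "TCP": tcp_values, "NTCP": nt})
    lo, hi = tcp_limits if tcp_limits is not None else (tcp_values[0], tcp_values[-1])
    x = np.concatenate([[0.0], nt, [1.0]])
    y = np.concatenate([[lo], tcp_values, [hi]])
    keep = np.concatenate([[True], np.diff(x) > 0])
    autoc = float(np.trapezoid(y[keep], x[keep]))
    return TOCCurve(table, autoc)
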