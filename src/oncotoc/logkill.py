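"""Log-kill statistics and tumor-control probability.

Under linear log-kill the post/pre-treatment density ratio at a voxel is
exp(y(r)) with pointwise log-kill y(r) = -alpha(r) AUC(r), where AUC(r) is
the time-integrated drug concentration (total local exposure).  Its volume
integral, the integrated log-kill

    Y = -<alpha, AUC> = -integral alpha(r) AUC(r) d^3r,

is a scalar random variable whose conditional characteristic function is a
single evaluation of the sensitivity field's characteristic functional at the
test function -xi AUC(r):

    psi_{Y|c}(xi) = Psi_alpha[-xi AUC(r)].

Fourier inversion (pr(Y|c) = integral psi(xi) e^{+2 pi i xi Y} d xi) yields
the PDF of Y, and tumor control is the event Y < Y_c (e.g. Y_c = -3 for an
e^3 ~ 20-fold reduction), so

    Pr(TC | c) = integral_{-inf}^{Yc} pr(Y|c) dY.

The Fourier convention is fixed: psi(xi) = <exp(-2 pi i xi Y)>, inversion
kernel exp(+2 pi i xi Y); no angular-frequency variants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import map_coordinates

from .exceptions import (
    CapabilityError,
    GridMismatchError,
    ResolutionError,
)
from .fields import (
    GaussianFieldModel,
    Grid,
    LumpyFieldModel,
    ScalarField,
    TemporalField,
    _as_rng,
    _same_grid,
    inner_product,
)

__all__ = [
    "AUCField",
    "LogKillDistribution",
    "ResponseKernel",
    "compute_auc",
    "pointwise_logkill",
    "integrated_logkill",
    "cf_Y_given_c",
    "pdf_Y_given_c",
    "prob_tumor_control",
    "tcp_vs_mass",
    "marginal_tcp",
    "nonlocal_cf_Y",
    "sample_integrated_logkill",
]

CF_DECAY_TOL = 1e-8  # |psi(xi_max)| required before inversion
CLIP_MASS_TOL = 1e-4  # clipped negative-ripple mass above which we error
DEGENERATE_SIGMA = 1e-5  # below this (relative) Y-std the PDF is a delta


# ---------------------------------------------------------------------------
# AUC and log-kill functionals
# ---------------------------------------------------------------------------


@dataclass
class AUCField:
    """Area under the concentration-time curve per voxel (conc * h >= 0).

    ``mass`` records the administered mass for the linear delivery model, in
    which AUC(r) = M * auc(r) with auc the unit-mass exposure.
    """

    field: ScalarField
    t0: float = 0.0
    T: float = 0.0
    mass: float = 1.0

    def __post_init__(self):
        if self.field.values.min() < 0:
            raise ValueError("AUC must be nonnegative")

    @property
    def grid(self) -> Grid:
        return self.field.grid

    @property
    def values(self) -> np.ndarray:
        return self.field.values

    def scaled(self, mass: float) -> "AUCField":
        """AUC for administered mass ``mass``, treating self as the unit field."""
        if mass < 0:
            raise ValueError("administered mass must be nonnegative")
        f = ScalarField(self.grid, self.values * mass, self.field.units, True)
        return AUCField(f, self.t0, self.T, mass=self.mass * mass)


def compute_auc(c: TemporalField, t0: float, T: float) -> AUCField:
    """Rectangle-rule time integral of c(r, t) over [t0, t0 + T] per voxel."""
    if T <= 0:
        raise ValueError("integration window T must be positive")
    dt = c.dt
    tiny = 1e-9 * dt
    if t0 < c.times[0] - tiny or t0 + T > c.times[-1] + dt + tiny:
        raise ValueError(
            f"window [{t0}, {t0 + T}] outside sampled span "
            f"[{c.times[0]}, {c.times[-1] + dt}]"
        )
    sel = (c.times >= t0 - tiny) & (c.times < t0 + T - tiny)
    vals = np.sum(c.values[sel], axis=0) * dt
    f = ScalarField(c.grid, vals, units=(c.units + "*h").lstrip("*"), nonnegative=c.values.min() >= 0)
    return AUCField(f, t0=t0, T=T)


def pointwise_logkill(alpha: ScalarField, auc: AUCField) -> ScalarField:
    """y(r) = -alpha(r) AUC(r); the density update is n -> n exp(y)."""
    if not _same_grid(alpha.grid, auc.grid):
        raise GridMismatchError("alpha and AUC on different grids")
    return ScalarField(alpha.grid, -alpha.values * auc.values)


def integrated_logkill(
    alpha: ScalarField, auc: AUCField, mask: np.ndarray | None = None
) -> float:
    """Y = -<alpha, AUC> over the (masked) volume by midpoint quadrature."""
    if not _same_grid(alpha.grid, auc.grid):
        raise GridMismatchError("alpha and AUC on different grids")
    prod = alpha.values * auc.values
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != alpha.grid.shape:
            raise GridMismatchError("mask shape != grid shape")
        prod = prod * mask.astype(bool)
    return float(-np.sum(prod) * alpha.grid.voxel_volume)


# ---------------------------------------------------------------------------
# Conditional characteristic function of Y
# ---------------------------------------------------------------------------


def _cf_Y_gaussian(model: GaussianFieldModel, auc: AUCField, xi: np.ndarray):
    """psi(xi) = exp(2 pi i xi <mean, AUC> - 2 pi^2 xi^2 <AUC, K AUC>)."""
    m = inner_product(model.mean_field(auc.grid), auc.field)
    q = model.quadratic_form(auc.field)
    return np.exp(2j * math.pi * xi * m - 2.0 * math.pi**2 * xi**2 * q)


def _cf_Y_lumpy(model: LumpyFieldModel, auc: AUCField, xi: np.ndarray, chunk=256):
    """Lumpy-alpha psi(xi): the Poisson-point CF of lump centers composed with
    the lump-smoothed AUC; an exactly known non-Gaussian characteristic
    function, evaluated by midpoint quadrature over the center coordinate."""
    grid = auc.grid
    u = float(np.sum(auc.values) * grid.voxel_volume)  # <AUC, 1>
    g = model.smoothed_test(auc.field).values.ravel()  # unit lump-smoothed AUC
    xi = np.atleast_1d(np.asarray(xi, dtype=float))
    out = np.empty(xi.shape, dtype=complex)
    dens = grid.voxel_volume * model.kbar / grid.fov_volume
    for i0 in range(0, xi.size, chunk):
        x = xi[i0 : i0 + chunk, None]
        integrand = np.exp(2j * math.pi * model.amplitude * x * g[None, :]) - 1.0
        lam = dens * integrand.sum(axis=1)
        out[i0 : i0 + chunk] = np.exp(2j * math.pi * x[:, 0] * model.offset * u + lam)
    return out


def cf_Y_given_c(model, auc: AUCField, xi):
    """Conditional characteristic function psi_{Y|c}(xi) = Psi_alpha[-xi AUC].

    Vectorized over ``xi``.  Only models with an analytic characteristic
    functional are supported; for anything else sample alpha fields and use
    the empirical route.
    """
    scalar = np.isscalar(xi)
    xi_arr = np.atleast_1d(np.asarray(xi, dtype=float))
    if isinstance(model, GaussianFieldModel):
        out = _cf_Y_gaussian(model, auc, xi_arr)
    elif isinstance(model, LumpyFieldModel):
        out = _cf_Y_lumpy(model, auc, xi_arr)
    else:
        raise CapabilityError(
            f"{type(model).__name__} has no analytic characteristic functional; "
            "use sample_integrated_logkill + an empirical CF instead"
        )
    return complex(out[0]) if scalar else out


def _moments_from_cf(psi, scale_guess: float) -> tuple[float, float]:
    """Mean and std of Y from the cumulant expansion of log psi near 0.

    log psi(xi) = -2 pi i mu xi - 2 pi^2 sigma^2 xi^2 + O(xi^3); the step h is
    adapted so the phase stays small but above roundoff.
    """
    h = 0.1 / max(scale_guess, 1e-12)
    for _ in range(60):
        val = psi(np.array([h]))[0]
        if abs(val) < 1e-12:
            h /= 4.0
            continue
        lp = np.log(val)
        mu = -lp.imag / (2.0 * math.pi * h)
        var = max(-lp.real, 0.0) / (2.0 * math.pi**2 * h**2)
        sig = math.sqrt(var)
        width = 2.0 * math.pi * h * (abs(mu) + 4.0 * sig)
        if width > 0.5:
            h /= 4.0
        elif 0 < width < 0.02:
            # keep the probe comfortably above roundoff in log psi
            h *= 4.0
        else:
            return mu, sig
    return mu, sig


@dataclass
class LogKillDistribution:
    """psi_{Y|c} sampled on a symmetric xi grid and the Fourier-inverted PDF.

    ``clipped_mass`` is the (absolute) probability mass removed when clipping
    negative truncation ripple before renormalization.
    """

    xi: np.ndarray
    psi: np.ndarray
    y: np.ndarray
    pdf: np.ndarray
    clipped_mass: float = 0.0

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])

    def cdf(self, yc: float) -> float:
        c = np.concatenate([[0.0], cumulative_trapezoid(self.pdf, self.y)])
        c /= c[-1] if c[-1] > 0 else 1.0
        return float(np.interp(yc, self.y, c))

    def mean(self) -> float:
        return float(np.trapezoid(self.y * self.pdf, self.y))

    def std(self) -> float:
        m = self.mean()
        v = float(np.trapezoid((self.y - m) ** 2 * self.pdf, self.y))
        return math.sqrt(max(v, 0.0))


def _invert_cf(psi_fn, mu: float, sigma: float, n_xi: int, xi_max: float):
    """Discrete Fourier inversion on a symmetric xi grid centered PDF at mu.

    xi_k = (k - n/2) dxi, Y_m = mu + (m - n/2) dY with dY = 1/(n dxi); the
    modulation by exp(2 pi i xi mu) recenters the grid, and for n divisible
    by 4 the double sum reduces to a single length-n inverse FFT with
    alternating-sign twiddles.
    """
    n = int(n_xi)
    dxi = 2.0 * xi_max / n
    k = np.arange(n)
    xi = (k - n // 2) * dxi
    psi = psi_fn(xi)
    mod = psi * np.exp(2j * math.pi * xi * mu)
    sign = np.where(k % 2 == 0, 1.0, -1.0)
    pdf_c = dxi * sign * n * np.fft.ifft(mod * sign)
    dy = 1.0 / (n * dxi)
    y = mu + (k - n // 2) * dy
    return xi, psi, y, pdf_c


def pdf_Y_given_c(
    model,
    auc: AUCField,
    xi_max: float | None = None,
    n_xi: int = 4096,
    max_doublings: int = 20,
) -> LogKillDistribution:
    """PDF of the integrated log-kill by Fourier inversion of psi_{Y|c}.

    The xi half-width is grown (doubling) until |psi| < 1e-8 at the grid edge;
    negative ripple is clipped at zero and the PDF renormalized, erroring if
    the clipped mass exceeds 1e-4.  A (near-)degenerate Y collapses to a
    single-bin delta, which the mean-centered inversion resolves exactly.
    """
    if n_xi < 4 or n_xi % 4:
        raise ValueError("n_xi must be a multiple of 4 (power of two recommended)")
    psi_fn = lambda x: np.atleast_1d(cf_Y_given_c(model, auc, x))

    scale0 = float(np.max(np.abs(auc.values)) * auc.grid.fov_volume) or 1.0
    mu, sigma = _moments_from_cf(psi_fn, scale0)

    if sigma <= DEGENERATE_SIGMA * max(abs(mu), 1e-6 * scale0, 1e-300):
        # deterministic limit: all mass in one Y bin at the mean
        dy = max(abs(mu), 1.0) * 1e-6
        k = np.arange(n_xi)
        y = mu + (k - n_xi // 2) * dy
        pdf = np.zeros(n_xi)
        pdf[n_xi // 2] = 1.0 / dy
        xi = (k - n_xi // 2) / (n_xi * dy)
        return LogKillDistribution(xi, psi_fn(xi), y, pdf, 0.0)

    if xi_max is None:
        xi_max = 1.0 / (2.0 * math.pi * sigma)
    for _ in range(max_doublings):
        edge = np.abs(psi_fn(np.linspace(0.92, 1.0, 8) * xi_max)).max()
        if edge < CF_DECAY_TOL:
            break
        xi_max *= 2.0
    else:
        raise ResolutionError(
            f"|psi| = {edge:.2e} at xi_max = {xi_max:.3g}; characteristic "
            "function does not decay (try a larger xi_max or more doublings)"
        )

    # refine the Y grid (dY = 1/(2 xi_max)) well below the distribution width;
    # psi is ~0 beyond the decay point so this is plain zero-padding
    xi_max = max(xi_max, 32.0 / sigma)
    # ensure the Y window (span 1/dxi = n/(2 xi_max)) covers the bulk
    n = n_xi
    while n / (2.0 * xi_max) < 30.0 * sigma and n < 2**22:
        n *= 2

    _, _, y, pdf_c = _invert_cf(psi_fn, mu, sigma, n, xi_max)
    pdf = pdf_c.real
    dy = y[1] - y[0]
    clipped = float(-np.sum(pdf[pdf < 0]) * dy)
    if clipped > CLIP_MASS_TOL:
        raise ResolutionError(
            f"clipped negative PDF mass {clipped:.2e} exceeds {CLIP_MASS_TOL}; "
            "increase xi_max / n_xi"
        )
    pdf = np.clip(pdf, 0.0, None)
    norm = np.sum(pdf) * dy
    if norm <= 0:
        raise ResolutionError("inverted PDF has no positive mass")
    pdf /= norm
    xi_full = (np.arange(n) - n // 2) * (2.0 * xi_max / n)
    return LogKillDistribution(xi_full, psi_fn(xi_full), y, pdf, clipped)


# ---------------------------------------------------------------------------
# Tumor-control probabilities
# ---------------------------------------------------------------------------


def prob_tumor_control(dist: LogKillDistribution, yc: float) -> float:
    """Pr(TC) = Pr(Y < Yc), the lower tail of the inverted PDF."""
    if yc < dist.y[0] or yc > dist.y[-1]:
        warnings.warn(
            f"Yc = {yc} outside the tabulated Y grid "
            f"[{dist.y[0]:.3g}, {dist.y[-1]:.3g}]; clamping",
            stacklevel=2,
        )
    p = dist.cdf(float(np.clip(yc, dist.y[0], dist.y[-1])))
    return float(np.clip(p, 0.0, 1.0))


def tcp_vs_mass(model, auc_unit: AUCField, masses, yc: float, **pdf_kw):
    """TCP as a function of administered mass M, with AUC = M * auc.

    Returns a ``pandas.DataFrame`` with columns ``M`` and ``TCP``.  For
    nonnegative sensitivity and exposure TCP is nondecreasing in M.
    """
    import pandas as pd

    masses = np.asarray(masses, dtype=float)
    if masses.size and masses.min() < 0:
        raise ValueError("administered mass must be nonnegative")
    tcp = np.empty(masses.size)
    for i, m in enumerate(masses):
        if m == 0.0 or auc_unit.values.max() == 0.0:
            tcp[i] = 1.0 if 0.0 < yc else 0.0  # Y is identically zero
            continue
        dist = pdf_Y_given_c(model, auc_unit.scaled(m), **pdf_kw)
        tcp[i] = prob_tumor_control(dist, yc)
    return pd.DataFrame({"M": masses, "TCP": tcp})


def marginal_tcp(model, c_samples, yc: float, t0: float, T: float, **pdf_kw) -> float:
    """Population-marginal Pr(TC): average the conditional TCP over sampled
    drug distributions c."""
    c_samples = list(c_samples)
    if not c_samples:
        raise ValueError("need at least one drug-field sample")
    vals = []
    for c in c_samples:
        auc = compute_auc(c, t0, T)
        dist = pdf_Y_given_c(model, auc, **pdf_kw)
        vals.append(prob_tumor_control(dist, yc))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Nonlocal response
# ---------------------------------------------------------------------------


class ResponseKernel:
    """Linear nonlocal-response operator L with kernel L(r, r').

    Either an explicit nonnegative matrix over voxels (applied with the eps^3
    quadrature weight) or an isotropic Gaussian profile of RMS range
    ``range_mm``, row-normalized so constants are preserved.  Models dose
    deposited at a distance from the binding site (e.g. charged-particle range
    in targeted radionuclide therapy).
    """

    def __init__(
        self,
        matrix: np.ndarray | None = None,
        range_mm: float | None = None,
    ):
        if (matrix is None) == (range_mm is None):
            raise ValueError("provide exactly one of matrix / range_mm")
        if matrix is not None:
            matrix = np.asarray(matrix, dtype=float)
            if matrix.min() < 0:
                raise ValueError("kernel must be nonnegative")
        if range_mm is not None and range_mm <= 0:
            raise ValueError("range_mm must be positive")
        self.matrix = matrix
        self.range_mm = range_mm

    @classmethod
    def identity(cls, grid: Grid) -> "ResponseKernel":
        """Delta kernel: L AUC = AUC (local response)."""
        return cls(matrix=np.eye(grid.n_voxels) / grid.voxel_volume)

    def apply(self, f: ScalarField) -> ScalarField:
        grid = f.grid
        if self.matrix is not None:
            if self.matrix.shape[0] != grid.n_voxels:
                raise GridMismatchError("kernel matrix size != number of voxels")
            out = (self.matrix @ f.values.ravel()) * grid.voxel_volume
            return ScalarField(grid, out.reshape(grid.shape))
        # row-normalized Gaussian profile; boundary renormalization via the
        # smoothed indicator so constants are preserved exactly
        from .fields import _se_kernel_block
        from scipy.signal import fftconvolve

        full = tuple(2 * n - 1 for n in grid.shape)
        ker = np.fft.fftshift(_se_kernel_block(grid, full, self.range_mm))
        num = fftconvolve(f.values, ker, mode="same")
        den = fftconvolve(np.ones(grid.shape), ker, mode="same")
        return ScalarField(grid, num / den)


def nonlocal_cf_Y(model, kernel: ResponseKernel, auc: AUCField, xi):
    """psi_{Y|c}(xi) for the nonlocal response: Psi_alpha[-xi (L AUC)(r)].

    The smoothed exposure is purely spatial (AUC is already time-integrated).
    An identity kernel reproduces the local characteristic function.
    """
    sm = kernel.apply(auc.field)
    sm_auc = AUCField(
        ScalarField(auc.grid, np.clip(sm.values, 0.0, None)), auc.t0, auc.T, auc.mass
    )
    return cf_Y_given_c(model, sm_auc, xi)


# ---------------------------------------------------------------------------
# Monte-Carlo sampling of Y (oracle route for tests and calibration)
# ---------------------------------------------------------------------------


def sample_integrated_logkill(model, auc: AUCField, n_samples: int, seed) -> np.ndarray:
    """Draw Y = -<alpha, AUC> for ``n_samples`` independent alpha realizations.

    Gaussian/lognormal models sample full fields.  The lumpy model uses the
    equivalent projection form: Y depends on a realization only through the
    baseline term and the lump-smoothed AUC evaluated at the (continuous,
    uniform) lump centers, so fields need not be materialized.  The resulting
    distribution is identical to sampling fields and taking inner products.
    """
    rng = _as_rng(seed)
    grid = auc.grid
    if isinstance(model, LumpyFieldModel):
        u = float(np.sum(auc.values) * grid.voxel_volume)
        g = model.smoothed_test(auc.field).values * model.amplitude
        ks = rng.poisson(model.kbar, size=n_samples)
        total = int(ks.sum())
        # continuous uniform centers, trilinear interpolation of the smoothed AUC
        frac = rng.random((total, 3)) * np.asarray(grid.shape)
        coords = (frac - 0.5).T
        vals = map_coordinates(g, coords, order=1, mode="nearest")
        edges = np.concatenate([[0], np.cumsum(ks)])
        sums = np.add.reduceat(np.concatenate([vals, [0.0]]), edges[:-1])
        sums[ks == 0] = 0.0
        return -(model.offset * u + sums)
    ys = np.empty(n_samples)
    for i in range(n_samples):
        f = model.sample(grid, rng)
        ys[i] = -inner_product(f, auc.field)
    return ys
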