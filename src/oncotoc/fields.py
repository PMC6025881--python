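"""Regular-grid fields, random-field ensembles and characteristic functionals.

Physiological quantities (cell density, drug concentration, drug sensitivity,
vascular permeability, ...) are carried on a regular 3D voxel lattice, either
as a static :class:`ScalarField` or as a uniformly time-sampled
:class:`TemporalField`.  Each quantity is one realization of a random process;
the ensembles implemented here (Gaussian, lumpy, lognormal, spatiotemporal
Poisson point process) are the standard object models of statistical image
science.  The complete spatial statistics of a random field ``f`` are encoded
by its characteristic functional

    Psi_f[phi] = < exp(-2 pi i <phi, f>) >,

the expectation running over realizations, with ``phi`` an arbitrary
real-valued test function and ``<.,.>`` the volume (or volume-time) integral.
All integrals are midpoint (voxel-center) quadrature with rectangle-rule time
steps.

Every sampler takes an explicit integer seed or :class:`numpy.random.Generator`;
there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .exceptions import (
    CapabilityError,
    CapacityError,
    GridMismatchError,
    ModelError,
)

__all__ = [
    "Grid",
    "ScalarField",
    "TemporalField",
    "PointEventSet",
    "GaussianFieldModel",
    "LumpyFieldModel",
    "LognormalFieldModel",
    "PoissonPointModel",
    "sample_field",
    "sample_point_process",
    "inner_product",
    "point_inner_product",
    "cf_gaussian",
    "cf_lumpy",
    "cf_poisson_point",
    "cf_empirical",
]

# Dense-covariance sampling is refused above this voxel count.
DENSE_VOXEL_CAP = 20_000

# Eigenvalues of an explicit covariance below -PSD_TOL * trace raise ModelError;
# small negative eigenvalues above that floor are clipped to zero.
PSD_TOL = 1e-10


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Grids and fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Grid:
    """Regular 3D voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along each axis (positive integers).
    spacing
        Voxel edge lengths in mm.
    origin
        Physical coordinate (mm) of the low corner of the volume.  Voxel
        centers sit at ``origin + (index + 1/2) * spacing``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(s) for s in self.origin)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three positive integers, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive lengths, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        """Voxel volume eps^3 in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size of the field of view along each axis (mm)."""
        return tuple(n * d for n, d in zip(self.shape, self.spacing))

    @property
    def fov_volume(self) -> float:
        return float(np.prod(self.extent))

    def axes(self) -> list[np.ndarray]:
        """Voxel-center coordinates along each axis."""
        return [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        ]

    def centers(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel-center coordinates (C order)."""
        ax = self.axes()
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    def contains(self, positions: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(positions)
        lo = np.asarray(self.origin)
        hi = lo + np.asarray(self.extent)
        return np.all((pos >= lo) & (pos <= hi), axis=1)


def _check_values(values: np.ndarray, nonnegative: bool) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError("field values must be finite")
    if nonnegative and values.size and values.min() < 0:
        raise ValueError("field flagged nonnegative has negative values")


@dataclass
class ScalarField:
    """Scalar quantity on a :class:`Grid`: one real value per voxel."""

    grid: Grid
    values: np.ndarray
    units: str = ""
    nonnegative: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        _check_values(self.values, self.nonnegative)

    @classmethod
    def constant(cls, grid: Grid, value: float, **kw) -> "ScalarField":
        return cls(grid, np.full(grid.shape, float(value)), **kw)

    @classmethod
    def from_function(cls, grid: Grid, fn, **kw) -> "ScalarField":
        ax = grid.axes()
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return cls(grid, np.asarray(fn(xx, yy, zz), dtype=float), **kw)

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy(), self.units, self.nonnegative)


@dataclass
class TemporalField:
    """Time-sampled scalar field: values[k] is the field at ``times[k]``.

    Times must be uniformly spaced; ``dt`` is the rectangle-rule step used in
    all time quadratures.
    """

    grid: Grid
    times: np.ndarray
    values: np.ndarray
    units: str = ""
    nonnegative: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError("times must be a 1D sequence")
        if self.times.size > 1:
            steps = np.diff(self.times)
            if steps.min() <= 0:
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
                raise ValueError("times must be uniformly spaced")
        if self.values.shape != (self.times.size, *self.grid.shape):
            raise GridMismatchError(
                f"values shape {self.values.shape} != (n_times, *grid.shape)"
            )
        _check_values(self.values, self.nonnegative)

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            return 1.0
        return float(self.times[1] - self.times[0])

    @property
    def n_times(self) -> int:
        return int(self.times.size)

    @classmethod
    def constant(cls, grid: Grid, times, value: float, **kw) -> "TemporalField":
        times = np.asarray(times, dtype=float)
        return cls(grid, times, np.full((times.size, *grid.shape), float(value)), **kw)

    def frame(self, k: int) -> ScalarField:
        return ScalarField(self.grid, self.values[k], self.units, self.nonnegative)

    def copy(self) -> "TemporalField":
        return TemporalField(
            self.grid, self.times.copy(), self.values.copy(), self.units, self.nonnegative
        )


@dataclass
class PointEventSet:
    """Realization of a spatiotemporal point process: J events (r_j, t_j)."""

    grid: Grid
    positions: np.ndarray  # (J, 3) mm
    times: np.ndarray  # (J,) h

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        if self.positions.shape[0] != self.times.shape[0]:
            raise ValueError("positions and times must have equal length")
        if self.count and not np.all(self.grid.contains(self.positions)):
            raise ValueError("all events must lie inside the grid volume")

    @property
    def count(self) -> int:
        return int(self.times.size)

    def voxel_indices(self) -> np.ndarray:
        """(J, 3) integer indices of the voxel containing each event."""
        rel = (self.positions - np.asarray(self.grid.origin)) / np.asarray(
            self.grid.spacing
        )
        idx = np.floor(rel).astype(int)
        return np.clip(idx, 0, np.asarray(self.grid.shape) - 1)

    def time_indices(self, times: np.ndarray) -> np.ndarray:
        """Index of the rectangle-rule time bin [t_k, t_k + dt) per event."""
        times = np.asarray(times, dtype=float)
        dt = times[1] - times[0] if times.size > 1 else 1.0
        idx = np.floor((self.times - times[0]) / dt).astype(int)
        return np.clip(idx, 0, times.size - 1)


# ---------------------------------------------------------------------------
# Quadrature inner products
# ---------------------------------------------------------------------------


def _same_grid(a: Grid, b: Grid) -> bool:
    return a.shape == b.shape and np.allclose(a.spacing, b.spacing) and np.allclose(
        a.origin, b.origin
    )


def inner_product(field, test) -> float:
    """Midpoint-quadrature inner product <test, field>.

    ``integral phi f d^3r`` (times ``dt`` summed over frames for temporal
    fields).  Both arguments must share the grid, and for temporal fields the
    time sampling.
    """
    if not _same_grid(field.grid, test.grid):
        raise GridMismatchError("inner_product: fields on different grids")
    if isinstance(field, TemporalField) or isinstance(test, TemporalField):
        if not (isinstance(field, TemporalField) and isinstance(test, TemporalField)):
            raise GridMismatchError("cannot mix spatial and temporal fields")
        if field.times.shape != test.times.shape or not np.allclose(
            field.times, test.times
        ):
            raise GridMismatchError("inner_product: different time sampling")
        return float(
            np.sum(field.values * test.values) * field.grid.voxel_volume * field.dt
        )
    return float(np.sum(field.values * test.values) * field.grid.voxel_volume)


def point_inner_product(events: PointEventSet, test: TemporalField) -> float:
    """<test, s> for a point-process realization s = sum_j delta(r-r_j)delta(t-t_j).

    The deltas integrate the test function at the event locations; with a
    voxelwise/framewise-constant test this is the value at the containing bin.
    """
    if events.count == 0:
        return 0.0
    if not _same_grid(events.grid, test.grid):
        raise GridMismatchError("point_inner_product: grid mismatch")
    vi = events.voxel_indices()
    ti = events.time_indices(test.times)
    return float(np.sum(test.values[ti, vi[:, 0], vi[:, 1], vi[:, 2]]))


# ---------------------------------------------------------------------------
# Random-field models
# ---------------------------------------------------------------------------


def _se_kernel_block(grid: Grid, shape: Sequence[int], corr_length: float) -> np.ndarray:
    """Squared-exponential kernel evaluated at signed voxel offsets.

    Returns an array of the given (odd or embedding) shape whose entry at
    multi-index k is exp(-|d_k|^2 / (2 l^2)) with d_k the *toroidal* offset,
    used both for convolution quadrature and circulant embedding.
    """
    d2 = np.zeros(tuple(shape))
    for a in range(3):
        n = shape[a]
        k = np.arange(n)
        off = np.minimum(k, n - k) * grid.spacing[a]
        sl = [None, None, None]
        sl[a] = slice(None)
        d2 = d2 + (off**2)[tuple(sl)]
    return np.exp(-d2 / (2.0 * corr_length**2))


class GaussianFieldModel:
    """Gaussian random field with either a stationary squared-exponential
    covariance (variance ``sigma2``, correlation length ``corr_length`` in mm)
    or an explicit symmetric covariance matrix over voxels.

    The characteristic functional is the standard Gaussian closed form

        Psi[phi] = exp(-2 pi i <phi, mean> - 2 pi^2 <phi, K phi>).
    """

    def __init__(
        self,
        mean: float | ScalarField = 0.0,
        sigma2: float | None = None,
        corr_length: float | None = None,
        cov_matrix: np.ndarray | None = None,
    ):
        if cov_matrix is None:
            if sigma2 is None or corr_length is None:
                raise ModelError(
                    "provide either (sigma2, corr_length) or an explicit cov_matrix"
                )
            if sigma2 < 0 or corr_length <= 0:
                raise ModelError("require sigma2 >= 0 and corr_length > 0")
        else:
            cov_matrix = np.asarray(cov_matrix, dtype=float)
            if cov_matrix.ndim != 2 or cov_matrix.shape[0] != cov_matrix.shape[1]:
                raise ModelError("cov_matrix must be square")
            if not np.allclose(cov_matrix, cov_matrix.T, atol=1e-10):
                raise ModelError("cov_matrix must be symmetric")
        self.mean = mean
        self.sigma2 = None if sigma2 is None else float(sigma2)
        self.corr_length = None if corr_length is None else float(corr_length)
        self.cov_matrix = cov_matrix
        self._factor_cache: dict = {}

    # -- covariance machinery ------------------------------------------------

    @property
    def stationary(self) -> bool:
        return self.cov_matrix is None

    def mean_field(self, grid: Grid) -> ScalarField:
        if isinstance(self.mean, ScalarField):
            if not _same_grid(self.mean.grid, grid):
                raise GridMismatchError("model mean lives on a different grid")
            return self.mean
        return ScalarField.constant(grid, float(self.mean))

    def covariance_matrix(self, grid: Grid) -> np.ndarray:
        """Dense voxel-pair covariance matrix (capacity-limited)."""
        if not self.stationary:
            if self.cov_matrix.shape[0] != grid.n_voxels:
                raise GridMismatchError("cov_matrix size != number of voxels")
            return self.cov_matrix
        if grid.n_voxels > DENSE_VOXEL_CAP:
            raise CapacityError(
                f"dense covariance refused for {grid.n_voxels} voxels "
                f"(cap {DENSE_VOXEL_CAP})"
            )
        r = grid.centers()
        d2 = np.sum((r[:, None, :] - r[None, :, :]) ** 2, axis=-1)
        return self.sigma2 * np.exp(-d2 / (2.0 * self.corr_length**2))

    def apply_covariance(self, test: ScalarField) -> ScalarField:
        """(K phi)(r) = integral K(r, r') phi(r') d^3r', midpoint quadrature.

        For the stationary kernel this is an exact discrete convolution with
        the kernel evaluated at all voxel offsets (no truncation).
        """
        grid = test.grid
        if self.stationary:
            full = tuple(2 * n - 1 for n in grid.shape)
            ker = np.fft.fftshift(_se_kernel_block(grid, full, self.corr_length))
            out = fftconvolve(test.values, ker, mode="same")
            vals = self.sigma2 * out * grid.voxel_volume
        else:
            K = self.covariance_matrix(grid)
            vals = (K @ test.values.ravel()).reshape(grid.shape) * grid.voxel_volume
        return ScalarField(grid, vals)

    def quadratic_form(self, test: ScalarField) -> float:
        """<phi, K phi> = eps^6 phi^T K phi (always >= 0 up to roundoff)."""
        q = inner_product(self.apply_covariance(test), test)
        return max(q, 0.0)

    # -- sampling ------------------------------------------------------------

    def _dense_factor(self, grid: Grid) -> np.ndarray:
        key = (grid.shape, grid.spacing, grid.origin)
        if key not in self._factor_cache:
            K = self.covariance_matrix(grid)
            w, Q = np.linalg.eigh(K)
            floor = -PSD_TOL * max(np.trace(K), 1.0)
            if w.min() < floor:
                raise ModelError(
                    f"covariance not PSD: min eigenvalue {w.min():.3e} below "
                    f"tolerance {floor:.3e}"
                )
            w = np.clip(w, 0.0, None)
            self._factor_cache[key] = Q * np.sqrt(w)
        return self._factor_cache[key]

    def _embedding(self, grid: Grid):
        key = ("emb", grid.shape, grid.spacing)
        if key not in self._factor_cache:
            # pad each axis so wrap-around correlation is negligible
            emb_shape = []
            for a in range(3):
                need = grid.shape[a] + int(np.ceil(6 * self.corr_length / grid.spacing[a]))
                n = 1
                while n < need:
                    n *= 2
                emb_shape.append(n)
            ker = self.sigma2 * _se_kernel_block(grid, emb_shape, self.corr_length)
            spec = np.fft.fftn(ker).real
            spec = np.clip(spec, 0.0, None)
            self._factor_cache[key] = (tuple(emb_shape), np.sqrt(spec))
        return self._factor_cache[key]

    def sample(self, grid: Grid, seed) -> ScalarField:
        """Draw one realization.

        Stationary kernels use an FFT circulant-embedding sampler (periodic
        embedding with padding >= 6 correlation lengths, so the covariance of
        the retained block matches the kernel to high accuracy).  Explicit
        covariance matrices use a dense eigendecomposition, refused above
        ``DENSE_VOXEL_CAP`` voxels.
        """
        rng = _as_rng(seed)
        mean = self.mean_field(grid).values
        if self.stationary:
            if self.sigma2 == 0.0:
                return ScalarField(grid, mean.copy())
            emb_shape, amp = self._embedding(grid)
            n_emb = int(np.prod(emb_shape))
            eps = rng.standard_normal(emb_shape) + 1j * rng.standard_normal(emb_shape)
            z = np.fft.ifftn(amp * eps * math.sqrt(n_emb / 2.0) * math.sqrt(2.0))
            # Re and Im are each a valid draw; use Re
            block = z.real[tuple(slice(0, n) for n in grid.shape)]
            return ScalarField(grid, mean + block)
        F = self._dense_factor(grid)
        z = rng.standard_normal(F.shape[1])
        return ScalarField(grid, mean + (F @ z).reshape(grid.shape))


class LumpyFieldModel:
    """Lumpy background: baseline offset plus a Poisson-distributed number of
    isotropic Gaussian blobs with uniformly random centers.

        f(r) = b0 + sum_k a0 exp(-|r - r_k|^2 / (2 s^2)),   K ~ Poisson(kbar)

    A standard non-Gaussian object model; it is a filtered Poisson point
    process, so its characteristic functional is known exactly:

        Psi[phi] = exp(-2 pi i b0 <phi, 1>)
                   * exp( (kbar/V) * integral [exp(-2 pi i a0 g(rc)) - 1] d^3 rc ),

    with g(rc) = integral phi(r) exp(-|r - rc|^2/(2 s^2)) d^3r the
    lump-smoothed test function and V the field-of-view volume.
    """

    def __init__(self, kbar: float, amplitude: float, width: float, offset: float = 0.0):
        if kbar < 0 or width <= 0:
            raise ModelError("require kbar >= 0 and width > 0")
        if offset < 0:
            raise ModelError("baseline offset must be >= 0")
        self.kbar = float(kbar)
        self.amplitude = float(amplitude)
        self.width = float(width)
        self.offset = float(offset)

    def mean_value(self, grid: Grid) -> float:
        """Idealized expected field value b0 + kbar * (lump integral) / V_fov.

        Neglects boundary truncation: lumps centered near the field-of-view
        edge contribute less inside the volume, so the realized mean is lower
        when the lump width is not small compared to the extent.  Use
        :meth:`mean_field` for the exact finite-volume expectation.
        """
        lump_integral = self.amplitude * (2 * math.pi * self.width**2) ** 1.5
        return self.offset + self.kbar * lump_integral / grid.fov_volume

    def mean_field(self, grid: Grid) -> ScalarField:
        """Exact voxelwise expectation
        b0 + (kbar/V) * integral_FOV a0 exp(-|r - rc|^2/(2 s^2)) d^3 rc."""
        full = tuple(2 * n - 1 for n in grid.shape)
        ker = np.fft.fftshift(_se_kernel_block(grid, full, self.width))
        conv = fftconvolve(np.ones(grid.shape), ker, mode="same") * grid.voxel_volume
        vals = self.offset + (self.kbar / grid.fov_volume) * self.amplitude * conv
        return ScalarField(grid, vals)

    def _lump_values(self, grid: Grid, centers: np.ndarray) -> np.ndarray:
        ax = grid.axes()
        out = np.zeros(grid.shape)
        two_s2 = 2.0 * self.width**2
        for c in centers:
            d2 = (
                ((ax[0] - c[0]) ** 2)[:, None, None]
                + ((ax[1] - c[1]) ** 2)[None, :, None]
                + ((ax[2] - c[2]) ** 2)[None, None, :]
            )
            out += np.exp(-d2 / two_s2)
        return out

    def sample(self, grid: Grid, seed) -> ScalarField:
        rng = _as_rng(seed)
        k = rng.poisson(self.kbar)
        lo = np.asarray(grid.origin)
        centers = lo + rng.random((k, 3)) * np.asarray(grid.extent)
        vals = self.offset + self.amplitude * self._lump_values(grid, centers)
        return ScalarField(grid, vals, nonnegative=self.amplitude >= 0 <= self.offset)

    def smoothed_test(self, test: ScalarField) -> ScalarField:
        """g(rc) = integral phi(r) exp(-|r-rc|^2/(2 s^2)) d^3r on the grid."""
        grid = test.grid
        full = tuple(2 * n - 1 for n in grid.shape)
        ker = np.fft.fftshift(_se_kernel_block(grid, full, self.width))
        vals = fftconvolve(test.values, ker, mode="same") * grid.voxel_volume
        return ScalarField(grid, vals)


class LognormalFieldModel:
    """Strictly positive field: exp of an underlying Gaussian random field."""

    def __init__(self, log_model: GaussianFieldModel):
        self.log_model = log_model

    def sample(self, grid: Grid, seed) -> ScalarField:
        g = self.log_model.sample(grid, seed)
        return ScalarField(grid, np.exp(g.values), nonnegative=True)


class PoissonPointModel:
    """Spatiotemporal Poisson point process with mean function sbar(r, t)
    (events per mm^3 per h).  Fully determined by its mean function; the
    characteristic functional is

        Psi[phi] = exp( integral sbar (exp(-2 pi i phi) - 1) d^3r dt ).
    """

    def __init__(self, mean_fn: TemporalField):
        if mean_fn.values.min() < 0:
            raise ModelError("Poisson point-process mean function must be >= 0")
        self.mean_fn = mean_fn

    @property
    def total_rate(self) -> float:
        """Expected total number of events = integral sbar d^3r dt."""
        f = self.mean_fn
        return float(np.sum(f.values) * f.grid.voxel_volume * f.dt)

    def sample(self, seed) -> PointEventSet:
        """Draw one event set: J ~ Poisson(total), bins chosen proportional to
        sbar, positions uniform within the voxel and times uniform within the
        time step."""
        rng = _as_rng(seed)
        f = self.mean_fn
        grid = f.grid
        lam = self.total_rate
        j = rng.poisson(lam) if lam > 0 else 0
        if j == 0:
            return PointEventSet(grid, np.empty((0, 3)), np.empty(0))
        w = f.values.reshape(f.n_times, -1).ravel()
        p = w / w.sum()
        flat = rng.choice(w.size, size=j, p=p)
        t_idx, v_idx = np.divmod(flat, grid.n_voxels)
        vi = np.stack(np.unravel_index(v_idx, grid.shape), axis=1)
        pos = (
            np.asarray(grid.origin)
            + (vi + rng.random((j, 3))) * np.asarray(grid.spacing)
        )
        dt = f.dt
        times = f.times[t_idx] + rng.random(j) * dt
        return PointEventSet(grid, pos, times)


# ---------------------------------------------------------------------------
# Characteristic functionals
# ---------------------------------------------------------------------------


def cf_gaussian(model: GaussianFieldModel, test: ScalarField) -> complex:
    """Gaussian characteristic functional
    exp(-2 pi i <phi, mean> - 2 pi^2 <phi, K phi>)."""
    m = inner_product(model.mean_field(test.grid), test)
    q = model.quadratic_form(test)
    return complex(np.exp(-2j * math.pi * m - 2.0 * math.pi**2 * q))


def cf_lumpy(model: LumpyFieldModel, test: ScalarField) -> complex:
    """Exact characteristic functional of the lumpy background (filtered
    Poisson point process of lump centers), by midpoint quadrature over the
    center coordinate."""
    grid = test.grid
    ones = ScalarField.constant(grid, 1.0)
    phase = -2j * math.pi * model.offset * inner_product(ones, test)
    g = model.smoothed_test(test).values
    integrand = np.exp(-2j * math.pi * model.amplitude * g) - 1.0
    lam = (model.kbar / grid.fov_volume) * np.sum(integrand) * grid.voxel_volume
    return complex(np.exp(phase + lam))


def cf_poisson_point(model: PoissonPointModel, test: TemporalField) -> complex:
    """Poisson point-process characteristic functional
    exp( integral sbar (e^{-2 pi i phi} - 1) d^3r dt )."""
    f = model.mean_fn
    if not _same_grid(f.grid, test.grid) or f.times.shape != test.times.shape or not np.allclose(f.times, test.times):
        raise GridMismatchError("test function must share the mean function's sampling")
    integrand = f.values * (np.exp(-2j * math.pi * test.values) - 1.0)
    return complex(np.exp(np.sum(integrand) * f.grid.voxel_volume * f.dt))


def cf_empirical(samples, test) -> complex:
    """Empirical characteristic functional: the sample average of
    exp(-2 pi i <phi, f>) over realizations (fields or point-event sets)."""
    samples = list(samples)
    if not samples:
        raise ValueError("cf_empirical requires at least one sample")
    vals = np.empty(len(samples), dtype=complex)
    for i, s in enumerate(samples):
        if isinstance(s, PointEventSet):
            ip = point_inner_product(s, test)
        else:
            ip = inner_product(s, test)
        vals[i] = np.exp(-2j * math.pi * ip)
    return complex(vals.mean())


# ---------------------------------------------------------------------------
# Functional wrappers (module-level operation surface)
# ---------------------------------------------------------------------------


def sample_field(model, grid: Grid, seed) -> ScalarField:
    """Draw one realization of a Gaussian, lumpy or lognormal field model."""
    if isinstance(model, (GaussianFieldModel, LumpyFieldModel, LognormalFieldModel)):
        return model.sample(grid, seed)
    raise CapabilityError(f"no sampler for model type {type(model).__name__}")


def sample_point_process(model: PoissonPointModel, seed) -> PointEventSet:
    return model.sample(seed)


def characteristic_functional(model, test) -> complex:
    """Dispatch to the analytic characteristic functional of a model."""
    if isinstance(model, GaussianFieldModel):
        return cf_gaussian(model, test)
    if isinstance(model, LumpyFieldModel):
        return cf_lumpy(model, test)
    if isinstance(model, PoissonPointModel):
        return cf_poisson_point(model, test)
    raise CapabilityError(
        f"{type(model).__name__} has no analytic characteristic functional; "
        "use cf_empirical with sampled realizations"
    )
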