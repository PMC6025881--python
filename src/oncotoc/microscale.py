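"""Microscale drug-delivery cascade.

The intratumoral drug distribution decomposes into capillary, diffusing,
receptor-bound and internalized components,

    c = c_cap + c_diff + c_bound + c_int,

linked causally: molecules extravasate through capillary fenestrations (a
spatiotemporal Poisson point process with mean function
sbar(r, t) = c_cap(r, t) v(r)), diffuse through the interstitium with a
spatially varying coefficient D(r) (zero initial condition, zero-flux
boundary), bind to cell-surface receptors (Michaelis-Menten at local dynamic
equilibrium, with a weak-binding linearization) and are internalized at an
endocytotic rate K_e.

The diffusion operator is a symmetric finite-volume discretization of
-div(D grad .) with arithmetic-mean face diffusivities; it is self-adjoint,
so the adjoint semigroup in the characteristic-functional propagation rule

    Psi_cdiff[phi, t] = < Psi_s[ exp((t' - t) D) phi ] >_D

equals the forward one.  Units: mm, h, molecules/mm^3; D in mm^2/h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .exceptions import CapacityError, GridMismatchError
from .fields import (
    Grid,
    PointEventSet,
    PoissonPointModel,
    ScalarField,
    TemporalField,
    _as_rng,
    _same_grid,
    cf_poisson_point,
)

__all__ = [
    "DeliveryParams",
    "BindingParams",
    "InternalizationParams",
    "DrugComponents",
    "mean_source",
    "diffusion_operator",
    "solve_diffusion",
    "propagate_events_exact",
    "cf_cdiff",
    "cf_cbound",
    "bind_mm",
    "bind_weak",
    "internalize",
    "compose_components",
]

DENSE_OPERATOR_CAP = 2500  # unknowns above which dense eigendecomposition is refused


@dataclass
class DeliveryParams:
    """Extravasation inputs: capillary concentration c_cap(r, t) >= 0,
    vascular permeability v(r) >= 0 (1/h per unit concentration ratio) and
    interstitial diffusion coefficient D(r) > 0 (mm^2/h)."""

    c_cap: TemporalField
    v: ScalarField
    D: ScalarField

    def __post_init__(self):
        if not (_same_grid(self.c_cap.grid, self.v.grid) and _same_grid(self.v.grid, self.D.grid)):
            raise GridMismatchError("delivery parameter fields on different grids")
        if self.c_cap.values.min() < 0 or self.v.values.min() < 0:
            raise ValueError("c_cap and v must be nonnegative")
        if self.D.values.min() <= 0:
            raise ValueError("diffusion coefficient must be strictly positive")


@dataclass
class BindingParams:
    """Receptor binding: mean receptors per cell Nbar_rec, dissociation
    constant K_d (same units as concentration).  With cell density n the
    receptor concentration is B_max = n * N_rec and the binding potential is
    BP = B_max / K_d.  ``poisson_receptors`` draws N_rec ~ Poisson(Nbar_rec)
    per realization (tumor cells are near-clonal, so a Poisson count is the
    natural receptor-number model)."""

    n_rec_mean: float
    k_d: float
    poisson_receptors: bool = False
    receptor_unit: float = 1.0  # receptors-per-cell -> concentration conversion

    def __post_init__(self):
        if self.n_rec_mean <= 0 or self.k_d <= 0:
            raise ValueError("require Nbar_rec > 0 and K_d > 0")


@dataclass
class InternalizationParams:
    """Endocytosis: rate constant K_e >= 0 (1/h)."""

    k_e: float

    def __post_init__(self):
        if self.k_e < 0:
            raise ValueError("endocytotic rate constant must be nonnegative")


@dataclass
class DrugComponents:
    """The four-compartment decomposition on a shared grid/time sampling."""

    c_cap: TemporalField
    c_diff: TemporalField
    c_bound: TemporalField
    c_int: TemporalField

    def __post_init__(self):
        ref = self.c_cap
        for f in (self.c_diff, self.c_bound, self.c_int):
            if not _same_grid(f.grid, ref.grid) or f.times.shape != ref.times.shape:
                raise GridMismatchError("drug components on different samplings")
            if f.values.min() < 0:
                raise ValueError("drug components must be nonnegative")


def mean_source(params: DeliveryParams) -> TemporalField:
    """sbar(r, t) = c_cap(r, t) v(r): the Poisson fenestration mean function
    (a simple product when secretion has no nonlinearities)."""
    vals = params.c_cap.values * params.v.values[None]
    return TemporalField(
        params.c_cap.grid, params.c_cap.times, vals,
        units="molecules/mm^3/h", nonnegative=True,
    )


# ---------------------------------------------------------------------------
# Finite-volume diffusion operator
# ---------------------------------------------------------------------------


def diffusion_operator(D: ScalarField, sparse: bool = True):
    """Symmetric finite-volume discretization of -div(D grad .) with zero-flux
    boundaries on a uniform grid.

    Face diffusivity is the arithmetic mean of the adjacent voxel values.
    The matrix has zero row sums (constants are in the null space) and is
    positive semidefinite.  Returned dense when ``sparse=False`` (capacity
    limited to ``DENSE_OPERATOR_CAP`` unknowns).
    """
    grid = D.grid
    if D.values.min() <= 0:
        raise ValueError("diffusion coefficient must be strictly positive")
    n = grid.n_voxels
    if not sparse and n > DENSE_OPERATOR_CAP:
        raise CapacityError(
            f"dense diffusion operator refused for {n} unknowns (cap {DENSE_OPERATOR_CAP})"
        )
    shape = grid.shape
    idx = np.arange(n).reshape(shape)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for a in range(3):
        if shape[a] < 2:
            continue
        h2 = grid.spacing[a] ** 2
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[a] = slice(0, shape[a] - 1)
        sl_hi[a] = slice(1, shape[a])
        i_lo = idx[tuple(sl_lo)].ravel()
        i_hi = idx[tuple(sl_hi)].ravel()
        d_face = 0.5 * (
            D.values[tuple(sl_lo)].ravel() + D.values[tuple(sl_hi)].ravel()
        )
        w = d_face / h2
        rows.extend([i_lo, i_hi])
        cols.extend([i_hi, i_lo])
        vals.extend([-w, -w])
        np.add.at(diag, i_lo, w)
        np.add.at(diag, i_hi, w)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return A if sparse else A.toarray()


def _deposit_events(events: PointEventSet, times: np.ndarray, grid: Grid) -> np.ndarray:
    """Per-time-step concentration deposits: each molecule adds 1/eps^3 to its
    containing voxel at the nearest time step (delta-in-space convention)."""
    n_t = times.size
    dep = np.zeros((n_t, grid.n_voxels))
    if events.count:
        vi = events.voxel_indices()
        flat = np.ravel_multi_index((vi[:, 0], vi[:, 1], vi[:, 2]), grid.shape)
        dt = times[1] - times[0] if n_t > 1 else 1.0
        ti = np.clip(np.round((events.times - times[0]) / dt).astype(int), 0, n_t - 1)
        np.add.at(dep, (ti, flat), 1.0 / grid.voxel_volume)
    return dep


def solve_diffusion(
    D: ScalarField,
    source,
    tgrid,
    verbose: bool = False,
) -> TemporalField:
    """Backward-Euler finite-volume solution of dc/dt + A c = s, c(r,0) = 0.

    ``source`` is either a :class:`PointEventSet` (molecules deposited into
    their containing voxel at the nearest time step, 1/eps^3 each) or a
    :class:`TemporalField` volumetric rate (molecules/mm^3/h, rectangle rule).
    Zero-flux boundaries conserve mass exactly: the volume integral of c at
    time t equals the cumulative injected amount.
    """
    grid = D.grid
    tgrid = np.asarray(tgrid, dtype=float)
    if tgrid.size < 2:
        raise ValueError("tgrid needs at least two times")
    dt = float(tgrid[1] - tgrid[0])
    if not np.allclose(np.diff(tgrid), dt):
        raise ValueError("tgrid must be uniform")
    A = diffusion_operator(D, sparse=True)
    n = grid.n_voxels
    lu = splu((sp.identity(n, format="csc") + dt * A.tocsc()))

    if isinstance(source, PointEventSet):
        dep = _deposit_events(source, tgrid, grid)
        rate = None
    else:
        if not _same_grid(source.grid, grid):
            raise GridMismatchError("source grid != D grid")
        rate = source
        dep = None

    c = np.zeros(n)
    out = np.empty((tgrid.size, *grid.shape))
    if dep is not None:
        c = c + dep[0]
    out[0] = c.reshape(grid.shape)
    for k in range(tgrid.size - 1):
        b = c.copy()
        if rate is not None:
            # rectangle rule: the source over [t_k, t_k+dt) at the frame value
            ks = min(k, rate.n_times - 1)
            b += dt * rate.values[ks].ravel()
        c = lu.solve(b)
        if dep is not None:
            c = c + dep[k + 1]
        out[k + 1] = c.reshape(grid.shape)
    out = np.clip(out, 0.0, None)  # roundoff guard; backward Euler is positivity-preserving
    return TemporalField(grid, tgrid, out, units="molecules/mm^3", nonnegative=True)


def _dense_eig(D: ScalarField):
    A = diffusion_operator(D, sparse=False)
    w, Q = np.linalg.eigh(A)
    return np.clip(w, 0.0, None), Q


def propagate_events_exact(
    D: ScalarField, events: PointEventSet, tgrid
) -> TemporalField:
    """Exact-in-time semigroup solution for point deposits on the spatial
    discretization: c(t) = sum_j exp(-(t - t_j) A) delta_j / eps^3 for
    t >= t_j.  Dense eigendecomposition; capacity-limited."""
    grid = D.grid
    tgrid = np.asarray(tgrid, dtype=float)
    w, Q = _dense_eig(D)
    out = np.zeros((tgrid.size, grid.n_voxels))
    if events.count:
        vi = events.voxel_indices()
        flat = np.ravel_multi_index((vi[:, 0], vi[:, 1], vi[:, 2]), grid.shape)
        qj = Q[flat, :] / grid.voxel_volume  # modal weights per event
        for k, t in enumerate(tgrid):
            active = events.times <= t
            if not np.any(active):
                continue
            phases = np.exp(-np.outer(t - events.times[active], w))
            # sum_j Q exp(-(t - t_j) Lambda) Q^T delta_j
            out[k] = (np.einsum("jm,jm->m", phases, qj[active])) @ Q.T
    return TemporalField(
        grid, tgrid, np.clip(out.reshape((-1, *grid.shape)), 0.0, None),
        nonnegative=True,
    )


def cf_cdiff(
    source_model: PoissonPointModel,
    D_samples,
    test: ScalarField,
    t: float,
) -> complex:
    """Characteristic functional of the diffusing drug component at time t.

    For each diffusivity realization, the spatial test function is propagated
    backwards by the (self-adjoint) diffusion semigroup to form the
    spatiotemporal effective test phi_eff(r, t') = [exp((t' - t) A) phi](r)
    for t' <= t (zero after t), the source-process characteristic functional
    is evaluated there, and the results are averaged over the D samples.

    The within-bin time integral uses the midpoint t' = t_m + dt/2 of each
    source bin, consistent with event times being uniform within a bin;
    ``t`` should coincide with a bin boundary of the source sampling.
    """
    D_samples = list(D_samples)
    if not D_samples:
        raise ValueError("need at least one diffusivity sample")
    mean_fn = source_model.mean_fn
    grid = mean_fn.grid
    if not _same_grid(test.grid, grid):
        raise GridMismatchError("test function grid != source grid")
    times = mean_fn.times
    dt = mean_fn.dt
    vals = []
    for D in D_samples:
        w, Q = _dense_eig(D)
        phi_modal = Q.T @ test.values.ravel()
        eff = np.zeros((times.size, *grid.shape))
        for m, tp in enumerate(times):
            tm = tp + 0.5 * dt  # bin midpoint
            if tm > t:
                break
            eff[m] = (Q @ (np.exp((tm - t) * w) * phi_modal)).reshape(grid.shape)
        eff_tf = TemporalField(grid, times, eff)
        vals.append(cf_poisson_point(source_model, eff_tf))
    return complex(np.mean(vals))


def cf_cbound(
    source_model: PoissonPointModel,
    D_samples,
    n_samples,
    params: BindingParams,
    test: ScalarField,
    t: float,
    seed=0,
) -> complex:
    """Characteristic functional of the bound component in the weak-binding
    (linearized) regime: cf_cdiff at the scaled test (N_rec / K_d) n(r) phi(r),
    averaged over sampled receptor counts and cell-density fields."""
    n_samples = list(n_samples)
    if not n_samples:
        raise ValueError("need at least one cell-density sample")
    rng = _as_rng(seed)
    vals = []
    for n_field in n_samples:
        if params.poisson_receptors:
            n_rec = float(rng.poisson(params.n_rec_mean))
        else:
            n_rec = params.n_rec_mean
        scale = params.receptor_unit * n_rec / params.k_d
        scaled = ScalarField(test.grid, scale * n_field.values * test.values)
        vals.append(cf_cdiff(source_model, D_samples, scaled, t))
    return complex(np.mean(vals))


# ---------------------------------------------------------------------------
# Binding and internalization
# ---------------------------------------------------------------------------


def _receptor_conc(n: TemporalField, params: BindingParams) -> np.ndarray:
    return params.receptor_unit * params.n_rec_mean * n.values


def bind_mm(n: TemporalField, c_diff: TemporalField, params: BindingParams) -> TemporalField:
    """Michaelis-Menten equilibrium binding:
    c_bound = B_max c_diff / (K_d + c_diff) with B_max = n N_rec,
    saturating at the receptor concentration."""
    if not _same_grid(n.grid, c_diff.grid) or n.times.shape != c_diff.times.shape:
        raise GridMismatchError("n and c_diff on different samplings")
    if c_diff.values.min() < 0 or n.values.min() < 0:
        raise ValueError("concentrations and densities must be nonnegative")
    bmax = _receptor_conc(n, params)
    vals = bmax * c_diff.values / (params.k_d + c_diff.values)
    return TemporalField(n.grid, n.times, vals, units=c_diff.units, nonnegative=True)


def bind_weak(n: TemporalField, c_diff: TemporalField, params: BindingParams) -> TemporalField:
    """Weak-binding linearization c_bound ~ B_max c_diff / K_d, valid when
    c_diff << K_d (relative error vs the full law is at most max(c_diff)/K_d)."""
    if not _same_grid(n.grid, c_diff.grid) or n.times.shape != c_diff.times.shape:
        raise GridMismatchError("n and c_diff on different samplings")
    if c_diff.values.min() < 0 or n.values.min() < 0:
        raise ValueError("concentrations and densities must be nonnegative")
    bmax = _receptor_conc(n, params)
    vals = bmax * c_diff.values / params.k_d
    return TemporalField(n.grid, n.times, vals, units=c_diff.units, nonnegative=True)


def internalize(c_bound: TemporalField, params: InternalizationParams) -> TemporalField:
    """c_int(r, t) = K_e * integral_0^t c_bound(r, t') dt' (running rectangle
    rule, administration at t = 0); nondecreasing in t at every voxel."""
    if c_bound.values.min() < 0:
        raise ValueError("bound concentration must be nonnegative")
    dt = c_bound.dt
    run = np.concatenate(
        [np.zeros((1, *c_bound.grid.shape)), np.cumsum(c_bound.values[:-1], axis=0) * dt]
    )
    return TemporalField(
        c_bound.grid, c_bound.times, params.k_e * run,
        units=c_bound.units, nonnegative=True,
    )


def compose_components(components: DrugComponents) -> TemporalField:
    """Total drug distribution: the voxelwise sum of the four components."""
    vals = (
        components.c_cap.values
        + components.c_diff.values
        + components.c_bound.values
        + components.c_int.values
    )
    ref = components.c_cap
    return TemporalField(ref.grid, ref.times, vals, units=ref.units, nonnegative=True)
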