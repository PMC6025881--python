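"""Delivery cascade: source, diffusion, CF propagation, binding, uptake."""

import numpy as np
import pytest
from scipy.fft import dct

from oncotoc.exceptions import CapacityError, GridMismatchError
from oncotoc.fields import (
    Grid,
    PointEventSet,
    PoissonPointModel,
    ScalarField,
    TemporalField,
    inner_product,
)
from oncotoc.microscale import (
    BindingParams,
    DeliveryParams,
    DrugComponents,
    InternalizationParams,
    bind_mm,
    bind_weak,
    cf_cbound,
    cf_cdiff,
    compose_components,
    diffusion_operator,
    internalize,
    mean_source,
    propagate_events_exact,
    solve_diffusion,
)

from conftest import make_temporal


class TestMeanSource:
    def test_product_form(self, grid2d):
        ccap = make_temporal(grid2d, value=2.0)
        v = ScalarField.constant(grid2d, 3.0, nonnegative=True)
        D = ScalarField.constant(grid2d, 0.1)
        s = mean_source(DeliveryParams(ccap, v, D))
        assert np.allclose(s.values, 6.0)
        # bilinear: doubling v doubles sbar
        s2 = mean_source(DeliveryParams(ccap, ScalarField.constant(grid2d, 6.0, nonnegative=True), D))
        assert np.allclose(s2.values, 2 * s.values)

    def test_zero_permeability(self, grid2d):
        ccap = make_temporal(grid2d, value=2.0)
        s = mean_source(DeliveryParams(ccap, ScalarField.constant(grid2d, 0.0, nonnegative=True),
                                       ScalarField.constant(grid2d, 0.1)))
        assert np.allclose(s.values, 0.0)

    def test_nonpositive_diffusivity_rejected(self, grid2d):
        with pytest.raises(ValueError):
            DeliveryParams(make_temporal(grid2d, value=1.0),
                           ScalarField.constant(grid2d, 1.0, nonnegative=True),
                           ScalarField.constant(grid2d, 0.0))


class TestDiffusionOperator:
    def test_symmetric_zero_rowsum_psd(self):
        g = Grid((5, 4, 3), (0.5, 1.0, 2.0))
        rng = np.random.default_rng(1)
        D = ScalarField(g, 0.1 + rng.random(g.shape))
        A = diffusion_operator(D, sparse=False)
        assert np.max(np.abs(A - A.T)) == 0.0
        assert np.allclose(A.sum(axis=1), 0.0, atol=1e-12)
        assert np.linalg.eigvalsh(A).min() > -1e-10
        # constants in the null space (zero flux)
        assert np.allclose(A @ np.ones(g.n_voxels), 0.0, atol=1e-12)

    def test_1d_constant_D_is_tridiagonal_laplacian(self):
        g = Grid((5, 1, 1), (0.5, 1.0, 1.0))
        D0 = 0.7
        A = diffusion_operator(ScalarField.constant(g, D0), sparse=False)
        h2 = 0.25
        expect = (D0 / h2) * (
            np.diag([1.0, 2.0, 2.0, 2.0, 1.0])
            - np.diag(np.ones(4), 1)
            - np.diag(np.ones(4), -1)
        )
        assert np.allclose(A, expect)

    def test_dense_capacity(self):
        g = Grid((20, 20, 10))
        with pytest.raises(CapacityError):
            diffusion_operator(ScalarField.constant(g, 1.0), sparse=False)


class TestSolveDiffusion:
    def test_zero_source_stays_zero(self, grid1d):
        D = ScalarField.constant(grid1d, 0.5)
        ev = PointEventSet(grid1d, np.empty((0, 3)), np.empty(0))
        c = solve_diffusion(D, ev, np.linspace(0, 1, 11))
        assert np.allclose(c.values, 0.0)

    def test_mass_conservation_events(self):
        g = Grid((16, 16, 1), (0.5, 0.5, 1.0))
        rng = np.random.default_rng(4)
        D = ScalarField(g, 0.2 + 0.3 * rng.random(g.shape))
        pos = np.column_stack([rng.uniform(0, 8, 30), rng.uniform(0, 8, 30), rng.uniform(0, 1, 30)])
        ev = PointEventSet(g, pos, rng.uniform(0, 0.5, 30))
        tg = np.linspace(0, 1.0, 41)
        c = solve_diffusion(D, ev, tg)
        total = c.values[-1].sum() * g.voxel_volume
        assert total == pytest.approx(30.0, rel=1e-8)

    def test_mass_conservation_rate_source(self, grid1d):
        D = ScalarField.constant(grid1d, 0.5)
        tg = np.linspace(0, 2.0, 21)
        rate = make_temporal(grid1d, n_t=21, dt=0.1, value=1.0)
        rate = TemporalField(grid1d, tg, rate.values, nonnegative=True)
        c = solve_diffusion(D, rate, tg)
        injected = 1.0 * grid1d.fov_volume * 2.0  # rate * volume * time
        total = c.values[-1].sum() * grid1d.voxel_volume
        assert total == pytest.approx(injected, rel=1e-8)

    def test_early_impulse_matches_green_function(self):
        """Free-space Gaussian Green's function within 2% L2 before the
        boundary is felt (impulse at a voxel center)."""
        n, L = 400, 20.0
        g = Grid((n, 1, 1), (L / n, 1.0, 1.0))
        D = ScalarField.constant(g, 1.0)
        x = g.axes()[0]
        x0 = x[n // 2]
        ev = PointEventSet(g, np.array([[x0, 0.5, 0.5]]), np.array([0.0]))
        t_end = 0.05
        c = solve_diffusion(D, ev, np.linspace(0, t_end, 201))
        green = np.exp(-((x - x0) ** 2) / (4 * t_end)) / np.sqrt(4 * np.pi * t_end)
        prof = c.values[-1, :, 0, 0]
        l2 = np.sqrt(np.sum((prof - green) ** 2) / np.sum(green**2))
        assert l2 < 0.02

    def test_low_pass_mode_decay(self):
        """Spatial Fourier modes of the impulse response decay at
        4 pi^2 D nu^2 (within 5%), faster for higher frequencies."""
        n, L, D0 = 64, 16.0, 0.5
        g = Grid((n, 1, 1), (L / n, 1, 1))
        A = diffusion_operator(ScalarField.constant(g, D0), sparse=False)
        w, Q = np.linalg.eigh(A)
        e = np.zeros(n)
        e[n // 2] = 1.0
        t1, t2 = 0.5, 1.0
        c1 = Q @ (np.exp(-w * t1) * (Q.T @ e))
        c2 = Q @ (np.exp(-w * t2) * (Q.T @ e))
        a1 = dct(c1, type=2, norm="ortho")
        a2 = dct(c2, type=2, norm="ortho")
        rates = []
        for m in (1, 2, 3, 4):
            nu = m / (2 * L)  # cosine mode m: nu cycles per mm
            rate = -np.log(abs(a2[m] / a1[m])) / (t2 - t1)
            assert rate == pytest.approx(4 * np.pi**2 * D0 * nu**2, rel=0.05)
            rates.append(rate)
        assert np.all(np.diff(rates) > 0)


class TestCfCdiff:
    def _setup(self, n_t=16, dt=0.125):
        g = Grid((24, 1, 1), (0.5, 1, 1))
        times = dt * np.arange(n_t)
        vals = np.zeros((n_t, *g.shape))
        vals[:, 8:11] = 1.0
        sbar = TemporalField(g, times, vals, nonnegative=True)
        model = PoissonPointModel(sbar)
        D = ScalarField.constant(g, 0.3)
        phi = ScalarField(g, 0.05 * np.cos(np.arange(24) / 3.0)[:, None, None] * np.ones(g.shape))
        return g, model, D, phi, n_t * dt

    def test_unity_at_zero_test_function(self):
        g, model, D, _, t = self._setup()
        zero = ScalarField.constant(g, 0.0)
        assert cf_cdiff(model, [D], zero, t) == pytest.approx(1.0)

    def test_unity_at_time_zero(self):
        g, model, D, phi, _ = self._setup()
        assert cf_cdiff(model, [D], phi, 0.0) == pytest.approx(1.0)

    def test_matches_monte_carlo(self):
        """CF propagation rule vs empirical CF over simulated source events
        propagated by the exact semigroup (3 MC standard errors)."""
        g, model, D, phi, t = self._setup()
        ana = cf_cdiff(model, [D], phi, t)
        rng = np.random.default_rng(3)
        n = 3000
        vals = np.empty(n, dtype=complex)
        for i in range(n):
            ev = model.sample(rng)
            c = propagate_events_exact(D, ev, np.array([0.0, t]))
            vals[i] = np.exp(-2j * np.pi * inner_product(c.frame(1), phi))
        emp = vals.mean()
        se = np.sqrt((1 - abs(ana) ** 2) / n)
        assert abs(emp - ana) <= 3 * se + 1e-3

    def test_mean_field_consistency(self):
        """First functional moment of the CF equals the PDE mean field driven
        by sbar, within 1% (numerical differentiation at small amplitude)."""
        g, model, D, phi, t = self._setup(n_t=256, dt=1.0 / 128.0)
        h = 1e-4
        scaled = ScalarField(g, h * phi.values)
        val_p = cf_cdiff(model, [D], scaled, t)
        val_m = cf_cdiff(model, [D], ScalarField(g, -h * phi.values), t)
        # d/du <e^{-2 pi i u <phi,c>}>|_0 = -2 pi i <<phi, c>>
        mean_ip_cf = (val_p - val_m).imag / (-4 * np.pi * h)
        c_mean = solve_diffusion(D, model.mean_fn, model.mean_fn.times)
        mean_ip_pde = inner_product(c_mean.frame(-1), phi)
        assert mean_ip_cf == pytest.approx(mean_ip_pde, rel=0.01)

    def test_empty_sample_list_rejected(self):
        g, model, D, phi, t = self._setup()
        with pytest.raises(ValueError):
            cf_cdiff(model, [], phi, t)


class TestBinding:
    def _fields(self, grid, cdiff_level, n_level=100.0):
        n = make_temporal(grid, value=n_level)
        c = make_temporal(grid, value=cdiff_level)
        return n, c

    def test_half_saturation(self, grid2d):
        p = BindingParams(n_rec_mean=50.0, k_d=2.0)
        n, c = self._fields(grid2d, cdiff_level=2.0)
        b = bind_mm(n, c, p)
        assert np.allclose(b.values, 100.0 * 50.0 / 2.0)

    def test_saturation_limit(self, grid2d):
        p = BindingParams(n_rec_mean=50.0, k_d=2.0)
        n, c = self._fields(grid2d, cdiff_level=2e6)
        b = bind_mm(n, c, p)
        assert np.allclose(b.values, 100.0 * 50.0, rtol=1e-5)
        assert np.all(b.values <= 100.0 * 50.0)

    def test_zero_concentration(self, grid2d):
        p = BindingParams(n_rec_mean=50.0, k_d=2.0)
        n, c = self._fields(grid2d, cdiff_level=0.0)
        assert np.allclose(bind_mm(n, c, p).values, 0.0)
        assert np.allclose(bind_weak(n, c, p).values, 0.0)

    def test_weak_binding_error_bound(self, grid2d):
        """|weak - mm| / mm <= max(c_diff)/K_d, and ~1% at c_diff = 0.01 K_d."""
        p = BindingParams(n_rec_mean=50.0, k_d=2.0)
        n, c = self._fields(grid2d, cdiff_level=0.02)  # 0.01 K_d
        mm = bind_mm(n, c, p).values
        wk = bind_weak(n, c, p).values
        rel = np.max(np.abs(wk - mm) / mm)
        assert rel <= 0.01 + 1e-12
        rng = np.random.default_rng(2)
        cv = rng.uniform(0, 1.0, (4, *grid2d.shape))
        c2 = TemporalField(grid2d, 0.5 * np.arange(4), cv, nonnegative=True)
        mm2 = bind_mm(n, c2, p).values
        wk2 = bind_weak(n, c2, p).values
        mask = mm2 > 0
        assert np.max(np.abs(wk2 - mm2)[mask] / mm2[mask]) <= cv.max() / p.k_d + 1e-12

    def test_weak_binding_linearity(self, grid2d):
        p = BindingParams(n_rec_mean=50.0, k_d=2.0)
        n, c = self._fields(grid2d, cdiff_level=0.1)
        b1 = bind_weak(n, c, p).values
        c2 = TemporalField(grid2d, c.times, 2 * c.values, nonnegative=True)
        assert np.allclose(bind_weak(n, c2, p).values, 2 * b1)


class TestInternalization:
    def test_zero_rate(self, grid2d):
        c = make_temporal(grid2d, value=3.0)
        assert np.allclose(internalize(c, InternalizationParams(0.0)).values, 0.0)

    def test_constant_bound_gives_linear_uptake(self, grid2d):
        dt = 0.5
        c = make_temporal(grid2d, n_t=6, dt=dt, value=4.0)
        ci = internalize(c, InternalizationParams(0.3))
        expect = 0.3 * 4.0 * c.times  # K_e * b * t (rectangle rule is exact here)
        assert np.allclose(ci.values, expect[:, None, None, None] * np.ones_like(ci.values))
        assert np.all(np.diff(ci.values, axis=0) >= 0)

    def test_refinement_convergence(self, grid2d):
        """Rectangle-rule uptake converges at O(dt) to the fine-grid result."""
        k_e = 0.4

        def uptake(n_t):
            dt = 2.0 / n_t
            times = dt * np.arange(n_t + 1)
            vals = np.exp(-times)[:, None, None, None] * np.ones((n_t + 1, *grid2d.shape))
            c = TemporalField(grid2d, times, vals, nonnegative=True)
            return internalize(c, InternalizationParams(k_e)).values[-1, 0, 0, 0]

        exact = k_e * (1 - np.exp(-2.0))
        e1 = abs(uptake(20) - exact)
        e2 = abs(uptake(40) - exact)
        assert e2 < 0.6 * e1
        assert e2 < 0.05 * exact

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            InternalizationParams(-0.1)


class TestComposition:
    def test_sum_of_components(self, grid2d):
        zero = make_temporal(grid2d, value=0.0)
        cap = make_temporal(grid2d, value=2.0)
        comp = DrugComponents(cap, zero, zero, zero)
        assert np.allclose(compose_components(comp).values, cap.values)

    def test_linearity(self, grid2d):
        rng = np.random.default_rng(0)
        fs = [TemporalField(grid2d, 0.5 * np.arange(4), rng.random((4, *grid2d.shape)),
                            nonnegative=True) for _ in range(4)]
        total = compose_components(DrugComponents(*fs))
        assert np.allclose(total.values, sum(f.values for f in fs))

    def test_pipeline_nonnegative(self, grid2d):
        """End-to-end cascade output is nonnegative everywhere."""
        times = 0.25 * np.arange(8)
        ccap = TemporalField(grid2d, times,
                             np.exp(-times)[:, None, None, None] * np.ones((8, *grid2d.shape)),
                             nonnegative=True)
        v = ScalarField.constant(grid2d, 0.5, nonnegative=True)
        D = ScalarField.constant(grid2d, 0.2)
        params = DeliveryParams(ccap, v, D)
        cdiff = solve_diffusion(D, mean_source(params), times)
        n = make_temporal(grid2d, n_t=8, dt=0.25, value=100.0)
        bp = BindingParams(n_rec_mean=20.0, k_d=50.0)
        cbound = bind_mm(n, cdiff, bp)
        cint = internalize(cbound, InternalizationParams(0.1))
        total = compose_components(DrugComponents(ccap, cdiff, cbound, cint))
        assert total.values.min() >= 0.0


class TestCfCbound:
    def test_unity_at_zero(self, ):
        g = Grid((12, 1, 1), (0.5, 1, 1))
        times = 0.25 * np.arange(8)
        sbar = TemporalField(g, times, np.full((8, *g.shape), 0.2), nonnegative=True)
        model = PoissonPointModel(sbar)
        D = ScalarField.constant(g, 0.3)
        n = ScalarField.constant(g, 100.0, nonnegative=True)
        p = BindingParams(n_rec_mean=10.0, k_d=50.0)
        zero = ScalarField.constant(g, 0.0)
        assert cf_cbound(model, [D], [n], p, zero, 2.0) == pytest.approx(1.0)

    def test_deterministic_inputs_reduce_to_scaled_cdiff(self):
        g = Grid((12, 1, 1), (0.5, 1, 1))
        times = 0.25 * np.arange(8)
        sbar = TemporalField(g, times, np.full((8, *g.shape), 0.2), nonnegative=True)
        model = PoissonPointModel(sbar)
        D = ScalarField.constant(g, 0.3)
        n = ScalarField.constant(g, 100.0, nonnegative=True)
        p = BindingParams(n_rec_mean=10.0, k_d=50.0, poisson_receptors=False)
        phi = ScalarField(g, 0.01 * np.ones(g.shape))
        scaled = ScalarField(g, (p.n_rec_mean / p.k_d) * n.values * phi.values)
        assert cf_cbound(model, [D], [n], p, phi, 2.0) == pytest.approx(
            cf_cdiff(model, [D], scaled, 2.0)
        )

    def test_matches_simulated_cbound_mc(self):
        """Weak-binding CF vs empirical CF of simulated bound fields (1D)."""
        g = Grid((12, 1, 1), (0.5, 1, 1))
        n_t, dt = 16, 0.125
        times = dt * np.arange(n_t)
        sbar = TemporalField(g, times, np.full((n_t, *g.shape), 0.6), nonnegative=True)
        model = PoissonPointModel(sbar)
        D = ScalarField.constant(g, 0.3)
        n_field = ScalarField.constant(g, 100.0, nonnegative=True)
        p = BindingParams(n_rec_mean=10.0, k_d=5000.0)
        phi = ScalarField(g, 0.02 * np.cos(np.arange(12))[:, None, None] * np.ones(g.shape))
        t = n_t * dt
        ana = cf_cbound(model, [D], [n_field], p, phi, t)
        rng = np.random.default_rng(9)
        n_mc = 2000
        scale = p.n_rec_mean / p.k_d * 100.0
        vals = np.empty(n_mc, dtype=complex)
        for i in range(n_mc):
            ev = model.sample(rng)
            c = propagate_events_exact(D, ev, np.array([0.0, t]))
            cb = scale * c.values[1]  # weak-binding bound field at time t
            ip = float(np.sum(cb * phi.values) * g.voxel_volume)
            vals[i] = np.exp(-2j * np.pi * ip)
        emp = vals.mean()
        se = np.sqrt((1 - abs(ana) ** 2) / n_mc)
        assert abs(emp - ana) <= 3 * se + 1e-3
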