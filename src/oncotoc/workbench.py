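"""End-to-end "digital patient" experiments.

Wires the modules into a reproducible forward chain: sample ground-truth
sensitivity and drug fields, image both with the toy ECT model under Poisson
noise, reconstruct with MLEM, propagate to the patient-specific integrated
log-kill, its variance and TCP, and sweep administered mass into a TOC curve.
Every stochastic stage takes its own explicit seed from the configuration, so
a run is reproducible from its manifest alone.

The default drug truth is separable, c(r, t) = M * shape(r) * w(t) with a
normalized exponential washout w(t) = k exp(-k t): linear in the administered
mass M, which is what makes the unit-mass exposure auc(r) well defined.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field

import numpy as np

from .exceptions import ConfigError
from .fields import Grid, ScalarField, TemporalField, _as_rng
from .imaging import (
    SystemOperator,
    blur_downsample_operator,
    forward_project,
    mlem_reconstruct,
    recon_covariance,
    sample_counts,
)
from .io import model_from_dict
from .logkill import AUCField, compute_auc, integrated_logkill
from .precision import (
    NTCPModel,
    PatientEstimates,
    estimate_Y,
    ntcp,
    tcp_estimate,
    toc_curve,
    variance_Y,
)

__all__ = [
    "ExperimentConfig",
    "DigitalPatient",
    "default_config",
    "generate_patient",
    "run_experiment",
    "sample_Y_estimates",
]


def default_config() -> dict:
    """A small, fast demo configuration (32x32x1 voxels, 6 frames)."""
    return {
        "grid": {"shape": [32, 32, 1], "spacing": [1.0, 1.0, 1.0], "origin": [0.0, 0.0, 0.0]},
        "alpha_model": {"type": "lumpy", "kbar": 15.0, "amplitude": 0.003,
                        "width": 3.0, "offset": 0.0015},
        "drug": {"auc_model": {"type": "lumpy", "kbar": 20.0, "amplitude": 0.5,
                               "width": 4.0, "offset": 0.5},
                 "washout_rate": 0.5, "n_frames": 6, "dt": 1.0, "mass": 1.0},
        "imaging": {"fwhm_voxels": 1.5, "factor": 1, "gain_alpha": 4e4,
                    "gain_c": 200.0, "n_iter": 40, "n_cov": 200},
        "therapy": {"yc": -3.0, "masses": [0.25, 0.5, 1.0, 2.0, 4.0, 8.0],
                    "ntcp_m50": 4.0, "ntcp_sigma": 0.5},
        "seeds": {"alpha_field": 11, "c_field": 12, "alpha_noise": 13,
                  "c_noise": 14, "cov": 15},
    }


@dataclass
class ExperimentConfig:
    """Validated experiment configuration; see :func:`default_config`."""

    raw: dict

    def __post_init__(self):
        c = self.raw
        for key in ("grid", "alpha_model", "drug", "imaging", "therapy", "seeds"):
            if key not in c:
                raise ConfigError(f"missing config section: {key}")
        g = c["grid"]
        try:
            self.grid = Grid(tuple(g["shape"]), tuple(g.get("spacing", (1, 1, 1))),
                             tuple(g.get("origin", (0, 0, 0))))
        except (KeyError, ValueError, TypeError) as e:
            raise ConfigError(f"grid: {e}") from e
        try:
            self.alpha_model = model_from_dict(c["alpha_model"])
            self.auc_model = model_from_dict(c["drug"]["auc_model"])
        except (KeyError, ValueError) as e:
            raise ConfigError(f"model spec: {e}") from e
        d = c["drug"]
        self.washout_rate = float(d.get("washout_rate", 0.5))
        self.n_frames = int(d.get("n_frames", 6))
        self.dt = float(d.get("dt", 1.0))
        self.mass = float(d.get("mass", 1.0))
        if self.washout_rate <= 0 or self.n_frames < 1 or self.dt <= 0 or self.mass < 0:
            raise ConfigError("drug: washout_rate, n_frames, dt must be positive; mass >= 0")
        im = c["imaging"]
        self.fwhm_voxels = float(im.get("fwhm_voxels", 1.5))
        self.factor = int(im.get("factor", 1))
        self.gain_alpha = float(im.get("gain_alpha", im.get("gain", 100.0)))
        self.gain_c = float(im.get("gain_c", im.get("gain", 100.0)))
        self.n_iter = int(im.get("n_iter", 40))
        self.n_cov = int(im.get("n_cov", 200))
        th = c["therapy"]
        self.yc = float(th.get("yc", -3.0))
        self.masses = np.asarray(th.get("masses", [1.0]), dtype=float)
        self.ntcp = NTCPModel(float(th.get("ntcp_m50", 4.0)), float(th.get("ntcp_sigma", 0.5)))
        seeds = c["seeds"]
        for k in ("alpha_field", "c_field", "alpha_noise", "c_noise", "cov"):
            if k not in seeds:
                raise ConfigError(f"seeds: missing {k}")
        self.seeds = {k: int(v) for k, v in seeds.items()}

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_frames)

    @property
    def t0(self) -> float:
        return float(self.raw["therapy"].get("t0", 0.0))

    @property
    def T(self) -> float:
        return float(self.raw["therapy"].get("T", self.n_frames * self.dt))

    def manifest(self) -> dict:
        blob = json.dumps(self.raw, sort_keys=True)
        return {"config": self.raw,
                "config_sha256": hashlib.sha256(blob.encode()).hexdigest()}


@dataclass
class DigitalPatient:
    """Ground truth, imaging data, reconstructions and derived estimates."""

    config: ExperimentConfig
    alpha_true: ScalarField
    c_true: TemporalField
    auc_true: AUCField
    y_true: float
    counts_alpha: np.ndarray
    counts_c: np.ndarray  # (n_frames, n_det)
    estimates: PatientEstimates
    y_hat: float
    var_y: float
    var_y_printed: float
    tcp_hat: float
    manifest: dict = dc_field(default_factory=dict)


def _drug_truth(cfg: ExperimentConfig, mass: float | None = None) -> TemporalField:
    shape = cfg.auc_model.sample(cfg.grid, cfg.seeds["c_field"]).values
    shape = np.clip(shape, 0.0, None)
    k = cfg.washout_rate
    w = k * np.exp(-k * cfg.times)
    m = cfg.mass if mass is None else mass
    vals = m * w[:, None, None, None] * shape[None]
    return TemporalField(cfg.grid, cfg.times, vals, units="molecules/mm^3",
                         nonnegative=True)


def _reconstruct_patient(
    cfg: ExperimentConfig,
    H_alpha: SystemOperator,
    H_c: SystemOperator,
    alpha_true: ScalarField,
    c_true: TemporalField,
    with_covariance: bool = True,
) -> tuple[PatientEstimates, np.ndarray, np.ndarray]:
    # two statistically independent ECT studies: separate operators and seeds
    rng_a = _as_rng(cfg.seeds["alpha_noise"])
    rng_c = _as_rng(cfg.seeds["c_noise"])
    g_a = sample_counts(forward_project(H_alpha, alpha_true), rng_a)
    alpha_hat = mlem_reconstruct(H_alpha, g_a, n_iter=cfg.n_iter, track_loglik=False)
    counts_c = np.empty((c_true.n_times, H_c.n_detectors), dtype=np.int64)
    c_vals = np.empty_like(c_true.values)
    for m in range(c_true.n_times):
        g_m = sample_counts(forward_project(H_c, c_true.frame(m)), rng_c)
        counts_c[m] = g_m.counts
        rec = mlem_reconstruct(H_c, g_m, n_iter=cfg.n_iter, track_loglik=False)
        c_vals[m] = rec.values.reshape(cfg.grid.shape)
    c_hat = TemporalField(cfg.grid, cfg.times, c_vals, nonnegative=True)
    nv = cfg.grid.n_voxels
    if with_covariance:
        rng_cov = _as_rng(cfg.seeds["cov"])
        cov_a, _ = recon_covariance(H_alpha, alpha_true.values.ravel(), cfg.n_iter,
                                    cfg.n_cov, rng_cov)
        cov_c = []
        for m in range(c_true.n_times):
            K, _ = recon_covariance(H_c, c_true.values[m].ravel(), cfg.n_iter,
                                    cfg.n_cov, rng_cov)
            cov_c.append(K)
    else:
        cov_a = np.zeros((nv, nv))
        cov_c = [np.zeros((nv, nv))] * c_true.n_times
    est = PatientEstimates(
        alpha_hat.as_field(cfg.grid), c_hat, cov_a, cov_c
    )
    return est, np.asarray(g_a.counts), counts_c


def generate_patient(config: dict | ExperimentConfig) -> DigitalPatient:
    """Run the full forward chain for one digital patient."""
    cfg = config if isinstance(config, ExperimentConfig) else ExperimentConfig(config)
    alpha_true = cfg.alpha_model.sample(cfg.grid, cfg.seeds["alpha_field"])
    alpha_true = ScalarField(cfg.grid, np.clip(alpha_true.values, 0.0, None),
                             nonnegative=True)
    c_true = _drug_truth(cfg)
    auc_true = compute_auc(c_true, cfg.t0, cfg.T)
    y_true = integrated_logkill(alpha_true, auc_true)
    H_a = blur_downsample_operator(cfg.grid.shape, cfg.fwhm_voxels, cfg.factor, cfg.gain_alpha)
    H_c = blur_downsample_operator(cfg.grid.shape, cfg.fwhm_voxels, cfg.factor, cfg.gain_c)
    est, g_a, g_c = _reconstruct_patient(cfg, H_a, H_c, alpha_true, c_true)
    y_hat = estimate_Y(est, cfg.t0, cfg.T)
    var_q = variance_Y(est, "quadrature-consistent", cfg.t0, cfg.T)
    var_p = variance_Y(est, "as-printed")
    tcp_hat = tcp_estimate(y_hat, var_q, cfg.yc)
    return DigitalPatient(
        cfg, alpha_true, c_true, auc_true, y_true, g_a, g_c, est,
        y_hat, var_q, var_p, tcp_hat, cfg.manifest(),
    )


def run_experiment(config: dict | ExperimentConfig, stages=("all",)) -> dict:
    """Execute the pipeline and return a JSON-ready report of all scalars."""
    cfg = config if isinstance(config, ExperimentConfig) else ExperimentConfig(config)
    stages = set(stages)
    report = dict(cfg.manifest())
    if stages == {"fields"}:
        alpha = cfg.alpha_model.sample(cfg.grid, cfg.seeds["alpha_field"])
        report["alpha_mean"] = float(alpha.values.mean())
        return report
    patient = generate_patient(cfg)
    report.update(
        y_true=patient.y_true,
        y_hat=patient.y_hat,
        var_y=patient.var_y,
        var_y_printed=patient.var_y_printed,
        tcp_hat=patient.tcp_hat,
        yc=cfg.yc,
    )
    # TOC sweep on the true unit-mass exposure with the Gaussian plug-in TCP
    auc_unit = AUCField(
        ScalarField(cfg.grid, patient.auc_true.values / max(cfg.mass, 1e-300),
                    nonnegative=True),
        cfg.t0, cfg.T,
    )
    sd = np.sqrt(max(patient.var_y, 0.0))
    tcps = []
    for m in cfg.masses:
        y_m = patient.y_hat * m / max(cfg.mass, 1e-300)
        tcps.append(tcp_estimate(y_m, (sd * m / max(cfg.mass, 1e-300)) ** 2, cfg.yc))
    toc = toc_curve(cfg.masses, tcps, cfg.ntcp, tcp_limits=(0.0, 1.0))
    report["autoc"] = toc.autoc
    report["toc"] = toc.table.to_dict(orient="list")
    return report


def sample_Y_estimates(
    alpha_true: ScalarField,
    c_true: TemporalField,
    H: SystemOperator,
    n_iter: int,
    n_real: int,
    seed,
    t0: float,
    T: float,
) -> np.ndarray:
    """Yhat over independent imaging-noise realizations at fixed truth.

    Each realization draws independent Poisson data for the sensitivity and
    for every drug frame (two statistically independent ECT studies),
    reconstructs with MLEM and evaluates Yhat; used to calibrate and verify
    the variance propagation and interval coverage.
    """
    rng = _as_rng(seed)
    means_a = forward_project(H, alpha_true)
    means_c = [forward_project(H, c_true.frame(m)) for m in range(c_true.n_times)]
    grid = alpha_true.grid
    out = np.empty(n_real)
    for i in range(n_real):
        g_a = sample_counts(means_a, rng)
        a_hat = mlem_reconstruct(H, g_a, n_iter=n_iter, track_loglik=False)
        c_vals = np.empty_like(c_true.values)
        for m, mu in enumerate(means_c):
            g_m = sample_counts(mu, rng)
            rec = mlem_reconstruct(H, g_m, n_iter=n_iter, track_loglik=False)
            c_vals[m] = rec.values.reshape(grid.shape)
        c_hat = TemporalField(grid, c_true.times, c_vals, nonnegative=True)
        auc = compute_auc(c_hat, t0, T)
        out[i] = integrated_logkill(a_hat.as_field(grid), auc)
    return out
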