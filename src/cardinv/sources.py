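"""Transmembrane-potential template, source timing and ECG synthesis.

The EDL source strength at a myocardial node is a template transmembrane
potential (TMP) waveform shifted and stretched to the node's activation
time tau and repolarization time rho.  The template is a product of two
logistic ramps,

    D(t; tau, rho) = resting + amplitude * F((t - tau)/w_d) * F((rho - t)/w_r)

with F the logistic function: a monotone upstroke of width ``w_d`` at
activation, a plateau, and a monotone recovery of width ``w_r`` around
repolarization.  The form is smooth in tau and rho, so the Jacobian of
the forward ECG exists analytically.  The dipole-layer strength is
``d = D - resting``; a closed layer of uniform strength is externally
silent, so the ECG is driven only by timing dispersion across the wall.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import geometry as geo
from . import forward as fwd

__all__ = [
    "TMPTemplate",
    "SourceTiming",
    "SignalSet",
    "template_waveform",
    "assign_repolarization",
    "forward_ecg",
    "add_noise",
    "DatasetConfig",
    "generate_dataset",
]


def _logistic(x):
    # numerically safe logistic
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class TMPTemplate:
    """Template transmembrane potential (mV, ms)."""

    resting_mv: float = -85.0
    amplitude_mv: float = 100.0
    upstroke_ms: float = 1.5
    recovery_ms: float = 30.0

    def __post_init__(self):
        if self.amplitude_mv <= 0 or self.upstroke_ms <= 0 or self.recovery_ms <= 0:
            raise ValueError("template amplitude and widths must be positive")

    def waveform(self, t, tau, rho):
        """TMP value D(t; tau, rho) in mV; broadcasts over inputs."""
        t, tau, rho = np.asarray(t, float), np.asarray(tau, float), np.asarray(rho, float)
        if np.any(rho <= tau):
            raise ValueError("repolarization must follow activation (rho > tau)")
        return self.resting_mv + self.amplitude_mv * (
            _logistic((t - tau) / self.upstroke_ms)
            * _logistic((rho - t) / self.recovery_ms))

    def strength(self, t, tau, rho):
        """Dipole-layer strength d = D - resting (mV)."""
        return self.waveform(t, tau, rho) - self.resting_mv

    def strength_grid(self, tau, rho, t):
        """d on a (nodes, time) grid for vectors tau, rho and time axis t."""
        return self.strength(t[None, :], np.asarray(tau)[:, None],
                             np.asarray(rho)[:, None])

    def d_dtau(self, tau, rho, t):
        """Analytic (nodes, time) derivative of the strength w.r.t. tau."""
        x = (t[None, :] - np.asarray(tau)[:, None]) / self.upstroke_ms
        y = (np.asarray(rho)[:, None] - t[None, :]) / self.recovery_ms
        fx, fy = _logistic(x), _logistic(y)
        return -self.amplitude_mv / self.upstroke_ms * fx * (1 - fx) * fy

    def d_drho(self, tau, rho, t):
        """Analytic (nodes, time) derivative of the strength w.r.t. rho."""
        x = (t[None, :] - np.asarray(tau)[:, None]) / self.upstroke_ms
        y = (np.asarray(rho)[:, None] - t[None, :]) / self.recovery_ms
        fx, fy = _logistic(x), _logistic(y)
        return self.amplitude_mv / self.recovery_ms * fx * fy * (1 - fy)


def template_waveform(t, tau, rho, template: TMPTemplate = None):
    """TMP template evaluated at time(s) t for one (tau, rho) pair."""
    template = template or TMPTemplate()
    return template.waveform(t, tau, rho)


@dataclass
class SourceTiming:
    """Per-node activation (tau) and repolarization (rho) times, ms."""

    tau: np.ndarray
    rho: np.ndarray

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.tau.shape != self.rho.shape:
            raise ValueError("tau and rho must have the same length")
        ok = np.isfinite(self.tau) & np.isfinite(self.rho)
        if np.any(self.rho[ok] <= self.tau[ok]):
            raise ValueError("rho must exceed tau at every (non-missing) node")

    @property
    def n_nodes(self):
        return len(self.tau)

    def missing(self):
        return ~(np.isfinite(self.tau) & np.isfinite(self.rho))

    def save_csv(self, path):
        with open(path, "w") as fh:
            fh.write("node_id,tau_ms,rho_ms\n")
            for j, (a, b) in enumerate(zip(self.tau, self.rho)):
                fh.write(f"{j},{float(a):.17g},{float(b):.17g}\n")

    @classmethod
    def load_csv(cls, path):
        data = np.genfromtxt(path, delimiter=",", skip_header=1)
        return cls(tau=data[:, 1], rho=data[:, 2])


@dataclass
class SignalSet:
    """Labeled multichannel time series (channels x samples, mV)."""

    labels: list
    rate_hz: float
    samples: np.ndarray
    start_ms: float = 0.0
    kind: str = "ECG"   # ECG | EGM | TMP

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or len(self.labels) != self.samples.shape[0]:
            raise ValueError("label count must equal channel count")
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("missing/non-finite samples")

    @property
    def n_channels(self):
        return self.samples.shape[0]

    @property
    def n_samples(self):
        return self.samples.shape[1]

    def time_axis(self):
        return self.start_ms + np.arange(self.n_samples) * 1000.0 / self.rate_hz

    def save_csv(self, path):
        with open(path, "w") as fh:
            fh.write(f"# kind: {self.kind}\n")
            fh.write(f"# rate_hz: {float(self.rate_hz):.17g}\n")
            fh.write(f"# start_ms: {float(self.start_ms):.17g}\n")
            fh.write("# units: mV\n")
            fh.write("label," + ",".join(f"s{k}" for k in range(self.n_samples)) + "\n")
            for lab, row in zip(self.labels, self.samples):
                fh.write(lab + "," + ",".join(f"{float(x):.17g}" for x in row) + "\n")

    @classmethod
    def load_csv(cls, path):
        meta = {}
        labels, rows = [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    k, _, v = line[1:].partition(":")
                    meta[k.strip()] = v.strip()
                elif line.startswith("label,"):
                    continue
                elif line:
                    parts = line.split(",")
                    labels.append(parts[0])
                    rows.append([float(x) for x in parts[1:]])
        return cls(labels=labels, rate_hz=float(meta["rate_hz"]),
                   samples=np.array(rows), start_ms=float(meta.get("start_ms", 0.0)),
                   kind=meta.get("kind", "ECG"))


def template_electrograms(timing: SourceTiming, template: TMPTemplate, t,
                          gain: float = 0.15, labels=None) -> SignalSet:
    """Template-shaped local electrogram surrogate per node.

    A unipolar electrogram shows its steepest downslope at local
    activation and steepest upslope at local repolarization, i.e. the
    mirror image of the local TMP:  phi_j(t) = -gain * d(tau_j, rho_j, t).
    The default gain maps the 100 mV template to a 15 mV deflection,
    a typical epicardial electrogram scale.
    """
    t = np.asarray(t, dtype=float)
    phi = -gain * template.strength_grid(timing.tau, timing.rho, t)
    rate = 1000.0 / (t[1] - t[0])
    labels = list(labels or (f"N{j:04d}" for j in range(timing.n_nodes)))
    return SignalSet(labels=labels, rate_hz=rate, samples=phi,
                     start_ms=float(t[0]), kind="EGM")


# ---------------------------------------------------------------------------
# timing construction

def assign_repolarization(tau, mode: str = "electrotonic", apd0: float = 220.0,
                          slope: float = 0.25):
    """Repolarization times from activation times.

    ``uniform``: rho = tau + apd0.  ``electrotonic``: early-activated sites
    get longer action potentials, rho = tau + apd0 - slope*(tau - mean(tau)),
    clipped to keep rho > tau (a warning is printed to the run log when
    more than 5% of nodes need clipping).
    """
    tau = np.asarray(tau, dtype=float)
    if apd0 <= 0:
        raise ValueError("apd0 must be positive")
    if not (0 <= slope < 1):
        raise ValueError("slope must be in [0, 1)")
    if mode == "uniform":
        return tau + apd0
    if mode != "electrotonic":
        raise ValueError(f"unknown repolarization mode {mode!r}")
    apd = apd0 - slope * (tau - tau.mean())
    floor = 1.0  # ms, minimum APD after clipping
    clipped = apd < floor
    if clipped.mean() > 0.05:
        import warnings
        warnings.warn(f"APD clipped at {int(clipped.sum())} nodes "
                      f"({100*clipped.mean():.1f}%)")
    return tau + np.maximum(apd, floor)


def forward_ecg(A: "fwd.TransferMatrix", timing: SourceTiming,
                template: TMPTemplate, t=None, rate_hz: float = 1000.0,
                labels=None) -> SignalSet:
    """Body-surface ECG V(t) = A d(tau, rho, t) on a time axis (default 1 kHz)."""
    if A.flavor != "edl":
        raise ValueError("forward ECG requires the EDL transfer matrix")
    if timing.n_nodes != A.n_sources:
        raise ValueError("timing registry does not match the transfer matrix")
    if t is None:
        t = np.arange(0.0, 450.0, 1000.0 / rate_hz)
    t = np.asarray(t, dtype=float)
    if timing.tau.min() < t[0] - 50 or timing.rho.max() > t[-1] + 50:
        raise ValueError("timing lies outside the requested time axis")
    d = template.strength_grid(timing.tau, timing.rho, t)
    V = A.matrix @ d
    rate = 1000.0 / (t[1] - t[0])
    return SignalSet(labels=list(labels or A.electrode_labels), rate_hz=rate,
                     samples=V, start_ms=float(t[0]), kind="ECG")


def add_noise(signals: SignalSet, sigma_uv: float, seed) -> SignalSet:
    """Additive i.i.d. zero-mean Gaussian sensor noise, reproducible by seed."""
    if sigma_uv < 0:
        raise ValueError("noise level must be nonnegative")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma_uv / 1000.0, size=signals.samples.shape)
    return SignalSet(labels=list(signals.labels), rate_hz=signals.rate_hz,
                     samples=signals.samples + noise,
                     start_ms=signals.start_ms, kind=signals.kind)


# ---------------------------------------------------------------------------
# synthetic dataset generation

@dataclass
class DatasetConfig:
    """Study conditions for the synthetic fixture.

    Defaults: nested-sphere torso/heart geometry; focal (paced) activation
    spread by the fastest route at a physiological ventricular velocity;
    electrotonic APD shortening with activation delay; 1 kHz sampling over
    a 0-450 ms QRST window; 20 uV additive sensor noise.
    """

    torso_radius: float = 200.0
    epi_radius: float = 50.0
    endo_radius: float = 35.0
    heart_center: tuple = (-40.0, 0.0, 0.0)
    torso_refinement: int = 3
    heart_refinement: int = 2
    conductivity: float = 0.2
    n_electrodes: int = 400
    pacing_node: int | None = None     # myocardial node index; None = epi apex
    pacing_onset_ms: float = 10.0
    velocity_mm_ms: float = 1.0
    apd_mode: str = "electrotonic"
    apd0_ms: float = 220.0
    apd_slope: float = 0.25
    noise_uv: float = 20.0
    rate_hz: float = 1000.0
    window_ms: tuple = (0.0, 450.0)
    edl_scale: float = fwd.DEFAULT_EDL_SCALE
    template: TMPTemplate = field(default_factory=TMPTemplate)

    def validate(self):
        problems = []
        if not (0 < self.endo_radius < self.epi_radius < self.torso_radius):
            problems.append("radii must nest: endo < epi < torso")
        if self.velocity_mm_ms <= 0:
            problems.append("velocity must be positive")
        if self.apd0_ms <= 0:
            problems.append("apd0 must be positive")
        if not (0 <= self.apd_slope < 1):
            problems.append("apd slope must be in [0, 1)")
        if self.noise_uv < 0:
            problems.append("noise level must be nonnegative")
        if self.rate_hz <= 0:
            problems.append("sampling rate must be positive")
        if self.window_ms[1] <= self.window_ms[0]:
            problems.append("window must have positive length")
        if self.apd_mode not in ("electrotonic", "uniform"):
            problems.append(f"unknown apd mode {self.apd_mode!r}")
        if problems:
            raise ValueError("invalid dataset config:\n  - " + "\n  - ".join(problems))


@dataclass
class DatasetBundle:
    """In-memory fixture: geometry, transfer matrices, truth and signals."""

    config: DatasetConfig
    model: geo.ConductorModel
    myocardial: geo.TriSurface
    tm_ep: "fwd.TransferMatrix"
    tm_edl: "fwd.TransferMatrix"
    truth: SourceTiming
    ecg_clean: SignalSet
    ecg_noisy: SignalSet
    pacing_node: int
    seed: int
    manifest: dict = field(default_factory=dict)


def _hash_array(a) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def build_fixture_geometry(cfg: DatasetConfig):
    model = geo.make_nested_spheres(
        torso_radius=cfg.torso_radius, epi_radius=cfg.epi_radius,
        endo_radius=cfg.endo_radius, heart_center=cfg.heart_center,
        torso_refinement=cfg.torso_refinement,
        heart_refinement=cfg.heart_refinement,
        conductivity=cfg.conductivity, n_electrodes=cfg.n_electrodes)
    myo = geo.make_myocardial_surface(model.epicardium, model.endocardium)
    return model, myo


def generate_dataset(config: DatasetConfig = None, seed: int = 0,
                     outdir=None) -> DatasetBundle:
    """Generate the full synthetic fixture bundle.

    Builds geometry and both transfer matrices, simulates a focal
    activation with the fastest-route model, synthesizes clean and noisy
    ECGs through the EDL forward model, and (optionally) writes the bundle
    with a manifest of seeds and content hashes to ``outdir``.
    """
    cfg = config or DatasetConfig()
    cfg.validate()
    model, myo = build_fixture_geometry(cfg)
    tm_ep = fwd.build_ep_transfer(model)
    tm_edl = fwd.build_edl_transfer(model, myo, edl_scale=cfg.edl_scale)

    if cfg.pacing_node is None:
        # default pacing site: epicardial node nearest the torso free wall
        pace = int(np.argmin(myo.vertices[: model.epicardium.n_vertices, 0]))
    else:
        pace = int(cfg.pacing_node)
    tau = geo.fastest_route_times(myo, {pace: cfg.pacing_onset_ms},
                                  cfg.velocity_mm_ms)
    rho = assign_repolarization(tau, cfg.apd_mode, cfg.apd0_ms, cfg.apd_slope)
    truth = SourceTiming(tau=tau, rho=rho)

    t = np.arange(cfg.window_ms[0], cfg.window_ms[1], 1000.0 / cfg.rate_hz)
    ecg_clean = forward_ecg(tm_edl, truth, cfg.template, t)
    ecg_noisy = add_noise(ecg_clean, cfg.noise_uv, seed)

    manifest = {
        "seed": int(seed),
        "pacing_node": pace,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items() if k != "template"},
        "template": asdict(cfg.template),
        "hashes": {
            "tm_ep": _hash_array(tm_ep.matrix),
            "tm_edl": _hash_array(tm_edl.matrix),
            "truth_tau": _hash_array(truth.tau),
            "truth_rho": _hash_array(truth.rho),
            "ecg_clean": _hash_array(ecg_clean.samples),
            "ecg_noisy": _hash_array(ecg_noisy.samples),
        },
    }
    bundle = DatasetBundle(config=cfg, model=model, myocardial=myo,
                           tm_ep=tm_ep, tm_edl=tm_edl, truth=truth,
                           ecg_clean=ecg_clean, ecg_noisy=ecg_noisy,
                           pacing_node=pace, seed=int(seed), manifest=manifest)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        geo.save_surface(model.torso, out / "torso.off")
        geo.save_surface(model.epicardium, out / "epicardium.off")
        geo.save_surface(model.endocardium, out / "endocardium.off")
        fwd.save_transfer(tm_ep, out / "transfer_ep")
        fwd.save_transfer(tm_edl, out / "transfer_edl")
        truth.save_csv(out / "truth_timing.csv")
        ecg_clean.save_csv(out / "ecg_clean.csv")
        ecg_noisy.save_csv(out / "ecg_noisy.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return bundle
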