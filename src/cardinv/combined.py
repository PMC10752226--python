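"""Combining the EP and EDL inverses: sequential and merged procedures.

*Sequential*: the EP inverse provides epicardial activation/repolarization
times (from the reconstructed electrograms); endocardial timing is then
initialized by a focal fastest-route scan with the epicardial values held
fixed, and the full myocardial timing is refined by the EDL
Levenberg-Marquardt optimization.  The main gain over EP alone is that
endocardial timing is produced.

*Merged*: a single objective combines both data terms,

    sum_t ||V - T phi||^2 + lam^2 ||phi||^2
  + sum_t ||V - A d(tau,rho,t)||^2 + lam_tau^2 ||L tau||^2 + lam_rho^2 ||L rho||^2
  + mu * sum_{j in epi} sum_t (phi_j(t) - gamma_j s_j(tau_j, rho_j, t))^2

The two printed data terms share no variable; the epicardial-consistency
penalty (weight ``mu``, with ``s_j`` the template-shaped local electrogram
surrogate and ``gamma_j`` a per-node fitted gain) is the explicit coupling
that makes the minimization simultaneous.  At ``mu = 0`` the objective
decouples exactly into the two standalone inverses.  The solver is block
coordinate descent: the phi-block and the gain fit are linear, the
(tau, rho)-block is a Marquardt solve with the coupling rows appended, so
the joint objective never increases across outer iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .edl_inverse import (EDLConfig, EDLSolution, _EDLProblem, _fit_grid,
                          marquardt_optimize)
from .ep_inverse import TikhonovConfig, extract_timing, reconstruct_egms, select_lambda
from .forward import TransferMatrix
from .geometry import TriSurface, fastest_route_times, mesh_laplacian
from .sources import SignalSet, SourceTiming, TMPTemplate

__all__ = [
    "CombinedConfig",
    "MergedResult",
    "sequential_inverse",
    "merged_inverse",
]


@dataclass
class CombinedConfig:
    mode: str = "sequential"           # sequential | merged
    mu: float = 1e-2                   # epicardial-consistency weight (merged)
    ep: TikhonovConfig = field(default_factory=TikhonovConfig)
    edl: EDLConfig = field(default_factory=EDLConfig)
    qrs_window: tuple = (0.0, 170.0)
    t_window: tuple = (170.0, 445.0)
    onset_grid_ms: tuple = (0.0, -10.0, -20.0, -30.0)
    max_outer: int = 8
    outer_tol: float = 1e-4            # relative joint-objective decrease

    def __post_init__(self):
        if self.mode not in ("sequential", "merged"):
            raise ValueError(f"unknown combined mode {self.mode!r}")
        if self.mu < 0:
            raise ValueError("coupling weight mu must be nonnegative")


def _check_registries(tm_ep: TransferMatrix, tm_edl: TransferMatrix,
                      surface: TriSurface):
    n_epi = tm_ep.n_sources
    if tm_ep.source_sheet is not None and (tm_ep.source_sheet == "endo").any():
        n_epi = int((tm_ep.source_sheet == "epi").sum())
    if tm_edl.source_sheet is None or surface.sheet is None:
        raise ValueError("EDL registry must label epi/endo sheets")
    if not (tm_edl.source_sheet[:n_epi] == "epi").all():
        raise ValueError("epicardial nodes of T are not a prefix of A's registry")
    if list(tm_ep.electrode_labels) != list(tm_edl.electrode_labels):
        raise ValueError("transfer matrices use different electrode registries")
    return n_epi


def _fill_missing(timing: SourceTiming, surface: TriSurface, n: int) -> SourceTiming:
    """Replace missing-flagged nodes by iterated neighbour means."""
    tau, rho = timing.tau.copy(), timing.rho.copy()
    e = surface.edges()
    e = e[(e[:, 0] < n) & (e[:, 1] < n)]
    for x in (tau, rho):
        for _ in range(n):
            bad = np.flatnonzero(~np.isfinite(x))
            if not bad.size:
                break
            for j in bad:
                nb = np.concatenate([e[e[:, 0] == j, 1], e[e[:, 1] == j, 0]])
                vals = x[nb]
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    x[j] = vals.mean()
    bad = (rho <= tau) | ~np.isfinite(tau) | ~np.isfinite(rho)
    rho[bad] = tau[bad] + 1.0 if np.isfinite(tau[bad]).all() else rho[bad]
    return SourceTiming(tau=tau, rho=rho)


def _endocardial_scan(V_fit, fit_t, tm_edl: TransferMatrix, template: TMPTemplate,
                      surface: TriSurface, epi_timing: SourceTiming, n_epi: int,
                      config: EDLConfig, onset_grid) -> SourceTiming:
    """Focal endocardial candidates with the epicardial timing held fixed.

    Every endocardial node is tried as a focus with onsets relative to the
    earliest epicardial activation; travel times propagate both from the
    focus and from the fixed epicardial front (through the transmural
    links), and the candidate whose forward ECG best matches the recording
    wins.  Epicardial values are returned untouched.
    """
    n = surface.n_vertices
    n_endo = n - n_epi
    epi_sources = {j: float(epi_timing.tau[j]) for j in range(n_epi)}
    t0_epi = float(epi_timing.tau.min())
    nv = max(np.linalg.norm(V_fit), 1e-300)
    A_epi = tm_edl.matrix[:, :n_epi]
    A_endo = tm_edl.matrix[:, n_epi:]
    d_epi = template.strength_grid(epi_timing.tau, epi_timing.rho, fit_t)
    W_epi = A_epi @ d_epi                       # fixed epicardial contribution
    # unit-velocity travel times from every endocardial focus to endo nodes
    dist = np.stack([fastest_route_times(surface, {f: 0.0}, 1.0)[n_epi:]
                     for f in range(n_epi, n)])
    best = (np.inf, None)
    for v in config.velocities:
        # spread of the fixed epicardial front into the endocardium
        tau_base = fastest_route_times(surface, epi_sources, v)[n_epi:]
        for onset in onset_grid:
            tau_c = np.minimum(tau_base[None, :],
                               dist / v + t0_epi + float(onset))  # (foci, endo)
            if config.apd_mode == "uniform":
                rho_c = tau_c + config.apd0_ms
            else:
                full_mean = (epi_timing.tau.sum() + tau_c.sum(axis=1)) / n
                rho_c = tau_c + config.apd0_ms \
                    - config.apd_slope * (tau_c - full_mean[:, None])
            rho_c = np.maximum(rho_c, tau_c + 1.0)
            d = template.strength(fit_t[None, None, :], tau_c[:, :, None],
                                  rho_c[:, :, None])
            W = W_epi[None] + np.einsum("ej,fjt->fet", A_endo, d, optimize=True)
            fits = np.linalg.norm(W - V_fit[None], axis=(1, 2)) / nv
            k = int(np.argmin(fits))
            if fits[k] < best[0]:
                tau = np.concatenate([epi_timing.tau, tau_c[k]])
                rho = np.concatenate([epi_timing.rho, rho_c[k]])
                best = (float(fits[k]), SourceTiming(tau=tau, rho=rho))
    return best[1]


def sequential_inverse(ecg: SignalSet, tm_ep: TransferMatrix,
                       tm_edl: TransferMatrix, surface: TriSurface,
                       template: TMPTemplate, config: CombinedConfig = None):
    """EP-initialized EDL inverse.

    Returns ``(solution, composite_start, ep_info)``: the refined EDL
    solution over all myocardial nodes, the composite initial timing
    (epicardial values exactly the EP-derived AT/RT), and the EP stage
    report.
    """
    config = config or CombinedConfig()
    n_epi = _check_registries(tm_ep, tm_edl, surface)
    egms, ep_info = reconstruct_egms(ecg, tm_ep, config.ep)
    epi_timing = extract_timing(egms, config.qrs_window, config.t_window)
    n_missing = int(epi_timing.missing().sum())
    epi_timing = _fill_missing(epi_timing, surface, n_epi)
    ep_info = dict(ep_info, missing_filled=n_missing)

    fit_t, V_fit = _fit_grid(ecg, config.edl.stride_ms)
    composite = _endocardial_scan(V_fit, fit_t, tm_edl, template, surface,
                                  epi_timing, n_epi, config.edl,
                                  config.onset_grid_ms)
    L = mesh_laplacian(surface)
    solution = marquardt_optimize(composite, ecg, tm_edl, template,
                                  config.edl, L=L)
    return solution, composite, ep_info


# ---------------------------------------------------------------------------
# merged inverse

@dataclass
class MergedResult:
    phi: SignalSet                     # epicardial potentials on the fit grid
    solution: EDLSolution              # timing with EDL-side decomposition
    gains: np.ndarray
    components: dict                   # six objective components + total
    history: list                      # total objective per outer iteration
    converged: bool


def _merged_components(phi, V, T, lam, prob: _EDLProblem, tau, rho, mu,
                       gains, s_epi, n_epi):
    ep_data = float(((V - T @ phi) ** 2).sum())
    ep_reg = float(lam**2 * (phi**2).sum())
    edl_data, rt, rr, _, _ = prob.terms(tau, rho)
    raw = float(((phi[:n_epi] - gains[:, None] * s_epi) ** 2).sum())
    coup = mu * raw
    total = ep_data + ep_reg + edl_data + rt + rr + coup
    return {"ep_data": ep_data, "ep_reg": ep_reg, "edl_data": edl_data,
            "edl_reg_tau": rt, "edl_reg_rho": rr, "coupling": coup,
            "coupling_raw": raw, "total": total}


def merged_inverse(ecg: SignalSet, tm_ep: TransferMatrix,
                   tm_edl: TransferMatrix, surface: TriSurface,
                   template: TMPTemplate, config: CombinedConfig = None,
                   init_timing: SourceTiming = None) -> MergedResult:
    """Joint EP+EDL inverse by block coordinate descent.

    The epicardial-potential block and the per-node gains are linear
    updates; the timing block is a Marquardt solve with the coupling
    residuals appended.  Initial timing defaults to the sequential
    composite start.  With ``mu = 0`` the objective decouples and a single
    outer pass returns exactly the two standalone solutions.
    """
    config = config or CombinedConfig()
    mu = float(config.mu)
    n_epi = _check_registries(tm_ep, tm_edl, surface)
    T = tm_ep.matrix[:, :n_epi] if tm_ep.n_sources > n_epi else tm_ep.matrix
    fit_t, V = _fit_grid(ecg, config.edl.stride_ms)

    # fixed EP regularization weight for the joint objective
    if config.ep.lam == "auto":
        lam = select_lambda(V, T, config.ep)
    else:
        lam = float(config.ep.lam)

    if init_timing is None:
        _, init_timing, _ = sequential_inverse(ecg, tm_ep, tm_edl, surface,
                                               template, config)
    tau = init_timing.tau.copy()
    rho = init_timing.rho.copy()

    L = mesh_laplacian(surface)
    Ld = L.toarray()
    ecfg = config.edl
    prob = _EDLProblem(V, fit_t, tm_edl.matrix, template,
                       float(ecfg.lam_tau), float(ecfg.lam_rho), Ld)

    # eigendecomposition of T^T T for the phi-block solves at any (lam, mu)
    TtT = T.T @ T
    evals, evecs = linalg.eigh(TtT)
    TtV = T.T @ V

    def phi_block(g_surr):
        rhs = TtV + mu * g_surr
        return evecs @ ((evecs.T @ rhs) / (evals + lam**2 + mu)[:, None])

    def surrogate(tau, rho):
        return -template.strength_grid(tau[:n_epi], rho[:n_epi], fit_t)

    gains = np.zeros(n_epi)
    s_epi = surrogate(tau, rho)
    g_surr = np.zeros((n_epi, V.shape[1]))
    history = []
    best = None
    converged = False
    n_outer = 1 if mu == 0.0 else config.max_outer
    for outer in range(n_outer):
        # 1) linear phi-block given (tau, rho, gains)
        full_g = np.zeros((T.shape[1], V.shape[1]))
        full_g[:n_epi] = gains[:, None] * s_epi
        phi = phi_block(full_g)
        # 2) per-node gain refit given phi
        denom = (s_epi**2).sum(axis=1)
        gains = np.where(denom > 0, (phi[:n_epi] * s_epi).sum(axis=1)
                         / np.maximum(denom, 1e-300), 0.0)
        # 3) timing block: LM with coupling rows appended
        sol = _coupled_marquardt(prob, tau, rho, mu, gains, phi[:n_epi],
                                 template, ecfg, n_epi)
        tau, rho = sol.timing.tau, sol.timing.rho
        s_epi = surrogate(tau, rho)
        comp = _merged_components(phi, V, T, lam, prob, tau, rho, mu,
                                  gains, s_epi, n_epi)
        history.append(comp["total"])
        if best is not None and comp["total"] > best[0] * (1 + 1e-12):
            warnings.warn("joint objective increased; returning best iterate")
            break
        best = (comp["total"], phi.copy(), tau.copy(), rho.copy(),
                gains.copy(), comp, sol)
        if len(history) > 1 and (history[-2] - history[-1]) \
                < config.outer_tol * max(history[-2], 1e-300):
            converged = True
            break
    if mu == 0.0:
        converged = True
    total, phi, tau, rho, gains, comp, sol = best
    labels = [f"N{j:04d}" for j in range(phi.shape[0])]
    phi_set = SignalSet(labels=labels, rate_hz=1000.0 / (fit_t[1] - fit_t[0]),
                        samples=phi, start_ms=float(fit_t[0]), kind="EGM")
    return MergedResult(phi=phi_set, solution=sol, gains=gains,
                        components=comp, history=history, converged=converged)


def _coupled_marquardt(prob: _EDLProblem, tau0, rho0, mu, gains, phi_epi,
                       template: TMPTemplate, config: EDLConfig,
                       n_epi: int) -> EDLSolution:
    """LM on the EDL terms plus the epicardial coupling rows.

    Coupling residuals sqrt(mu) * (gamma_j s_j(t) - phi_j(t)) depend only
    on node j's own (tau_j, rho_j): their normal-matrix contribution is
    block-diagonal and is added to the separable data-block assembly.
    """
    tau = tau0.copy()
    gap = rho0 - tau0
    z = np.log(np.maximum(gap, 1e-6))
    n = prob.n
    mu_lm = config.mu0

    def eval_all(tau, z):
        ez = np.exp(z)
        rho = tau + ez
        JtJ, g, total, parts = prob.normal_system(tau, z)
        if mu > 0:
            s = -template.strength_grid(tau[:n_epi], rho[:n_epi], prob.t)
            r_c = phi_epi - gains[:, None] * s          # residual of coupling fit
            # d s/d tau (at fixed z) and d s/d z
            dst = -(template.d_dtau(tau[:n_epi], rho[:n_epi], prob.t)
                    + template.d_drho(tau[:n_epi], rho[:n_epi], prob.t))
            dsz = -template.d_drho(tau[:n_epi], rho[:n_epi], prob.t) \
                * ez[:n_epi, None]
            # model m = gamma * s; J rows per (j, t)
            jt = gains[:, None] * dst
            jz = gains[:, None] * dsz
            idx = np.arange(n_epi)
            JtJ[idx, idx] += mu * (jt * jt).sum(axis=1)
            JtJ[idx, n + idx] += mu * (jt * jz).sum(axis=1)
            JtJ[n + idx, idx] += mu * (jt * jz).sum(axis=1)
            JtJ[n + idx, n + idx] += mu * (jz * jz).sum(axis=1)
            g[:n_epi] += mu * (jt * r_c).sum(axis=1)
            g[n:][:n_epi] += mu * (jz * r_c).sum(axis=1)
            total += mu * float((r_c**2).sum())
        return JtJ, g, total, parts

    def objective(tau, rho):
        total, data, rt, rr = prob.objective(tau, rho)
        if mu > 0:
            s = -template.strength_grid(tau[:n_epi], rho[:n_epi], prob.t)
            total += mu * float(((phi_epi - gains[:, None] * s) ** 2).sum())
        return total, (data, rt, rr)

    JtJ, g, obj, parts = eval_all(tau, z)
    accepted = 0
    it = 0
    for it in range(1, config.max_iter + 1):
        diag = np.clip(np.diag(JtJ), 1e-12, None)
        try:
            step = linalg.solve(JtJ + mu_lm * np.diag(diag), g, assume_a="pos")
        except linalg.LinAlgError:
            mu_lm *= config.mu_factor
            continue
        tau_new = tau + step[:n]
        z_new = np.clip(z + step[n:], -20.0, 20.0)
        obj_new, parts_new = objective(tau_new, tau_new + np.exp(z_new))
        if not np.isfinite(obj_new):
            raise FloatingPointError(f"non-finite objective at iteration {it}")
        if obj_new <= obj:
            rel_dec = (obj - obj_new) / max(obj, 1e-300)
            tau, z = tau_new, z_new
            accepted += 1
            mu_lm = max(mu_lm / config.mu_factor, 1e-14)
            JtJ, g, obj, parts = eval_all(tau, z)
            if rel_dec < config.obj_tol or np.abs(step).max() < config.step_tol:
                break
        else:
            mu_lm *= config.mu_factor
            if mu_lm > 1e12:
                break
    rho = tau + np.exp(z)
    data, rt, rr = parts
    return EDLSolution(timing=SourceTiming(tau=tau, rho=rho),
                       objective=obj, data_term=data, reg_tau=rt, reg_rho=rr,
                       iterations=it, accepted_steps=accepted, converged=True,
                       lam_tau=float(config.lam_tau), lam_rho=float(config.lam_rho))
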