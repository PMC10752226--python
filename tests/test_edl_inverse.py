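"""EDL inverse: objective, initial estimates, Marquardt recovery."""

import numpy as np
import pytest

from cardinv import edl_inverse as EDL
from cardinv import sources as S
from cardinv.edl_inverse import _fit_grid
from cardinv.geometry import fastest_route_times, mesh_laplacian
from cardinv.sources import SourceTiming, add_noise, assign_repolarization


@pytest.fixture(scope="module")
def L(myocardial):
    return mesh_laplacian(myocardial)


@pytest.fixture(scope="module")
def top_candidate(dataset, tm_edl, template, myocardial, candidate_scan):
    cands = EDL.initial_estimate(dataset.ecg_clean, tm_edl, template,
                                 myocardial, EDL.EDLConfig(),
                                 scan=candidate_scan)
    return cands


class TestObjective:
    def test_truth_attains_data_floor(self, dataset, tm_edl, template,
                                      myocardial):
        total, parts = EDL.edl_objective(dataset.truth.tau, dataset.truth.rho,
                                         dataset.ecg_clean, tm_edl, template,
                                         0.0, 0.0, L=myocardial)
        energy = (dataset.ecg_clean.samples ** 2).sum()
        assert parts["data"] <= 1e-12 * energy

    def test_uniform_timing_has_zero_regularization(self, dataset, tm_edl,
                                                    template, myocardial):
        n = tm_edl.n_sources
        total, parts = EDL.edl_objective(np.full(n, 50.0), np.full(n, 250.0),
                                         dataset.ecg_clean, tm_edl, template,
                                         0.7, 0.9, L=myocardial)
        # cotangent row sums cancel to ~1e-13; squared leaves ~1e-26
        assert parts["reg_tau"] <= 1e-18
        assert parts["reg_rho"] <= 1e-18

    def test_rho_not_above_tau_rejected(self, dataset, tm_edl, template):
        n = tm_edl.n_sources
        with pytest.raises(ValueError, match="rho"):
            EDL.edl_objective(np.full(n, 250.0), np.full(n, 50.0),
                              dataset.ecg_clean, tm_edl, template, 0.0, 0.0)

    def test_gradient_matches_finite_differences(self, dataset, tm_edl,
                                                 template, myocardial, rng):
        tau = dataset.truth.tau + rng.normal(0, 5, tm_edl.n_sources)
        rho = dataset.truth.rho + rng.normal(0, 5, tm_edl.n_sources)
        args = (dataset.ecg_noisy, tm_edl, template, 0.05, 0.05)
        gt, gr = EDL.edl_gradient(tau, rho, *args, L=myocardial)
        h = 1e-3
        for j in rng.integers(0, tm_edl.n_sources, 5):
            for vec, grad in ((tau, gt), (rho, gr)):
                up, dn = vec.copy(), vec.copy()
                up[j] += h
                dn[j] -= h
                if vec is tau:
                    fp, _ = EDL.edl_objective(up, rho, *args, L=myocardial)
                    fm, _ = EDL.edl_objective(dn, rho, *args, L=myocardial)
                else:
                    fp, _ = EDL.edl_objective(tau, up, *args, L=myocardial)
                    fm, _ = EDL.edl_objective(tau, dn, *args, L=myocardial)
                fd = (fp - fm) / (2 * h)
                assert abs(fd - grad[j]) <= 1e-4 * max(abs(fd), 1.0)


class TestInitialEstimate:
    def test_generating_candidate_ranks_first(self, dataset, top_candidate):
        best = top_candidate[0]
        assert best.focus == dataset.pacing_node
        assert best.velocity == dataset.config.velocity_mm_ms
        assert best.shift_ms == pytest.approx(dataset.config.pacing_onset_ms)
        assert best.fit < 1e-10

    def test_candidates_ranked_ascending(self, top_candidate):
        fits = [c.fit for c in top_candidate]
        assert fits == sorted(fits)

    def test_noisy_top_candidate_near_truth(self, dataset, tm_edl, template,
                                            myocardial, candidate_scan):
        cfg = EDL.EDLConfig()
        noisy = [add_noise(dataset.ecg_clean, 20.0, 300 + s)
                 for s in range(20)]
        Vs = [_fit_grid(V, cfg.stride_ms)[1] for V in noisy]
        ranked = candidate_scan.rank_many(Vs, top=1)
        # graph distance 1 = within one edge of the true pacing node
        e = myocardial.edges()
        nbrs = {dataset.pacing_node}
        for a, b in e:
            if a == dataset.pacing_node:
                nbrs.add(int(b))
            if b == dataset.pacing_node:
                nbrs.add(int(a))
        hits = sum(r[0].focus in nbrs for r in ranked)
        assert hits >= 18    # >= 90% of 20 seeded repeats


class TestMarquardt:
    def test_started_at_truth_terminates_immediately(self, dataset, tm_edl,
                                                     template, L):
        cfg = EDL.EDLConfig(lam_tau=0.0, lam_rho=0.0)
        sol = EDL.marquardt_optimize(dataset.truth, dataset.ecg_clean, tm_edl,
                                     template, cfg, L=L)
        assert sol.accepted_steps <= 1
        assert sol.objective <= 1e-10

    def test_objective_decomposition_consistent(self, dataset, tm_edl,
                                                template, L, top_candidate):
        c = top_candidate[0]
        sol = EDL.marquardt_optimize(SourceTiming(c.tau, c.rho),
                                     dataset.ecg_noisy, tm_edl, template,
                                     EDL.EDLConfig(), L=L)
        assert sol.decomposition_check() < 1e-9

    def test_noiseless_recovery(self, dataset, tm_edl, template, myocardial,
                                L, top_candidate):
        c = top_candidate[0]
        sol = EDL.marquardt_optimize(SourceTiming(c.tau, c.rho),
                                     dataset.ecg_clean, tm_edl, template,
                                     EDL.EDLConfig(), L=L)
        cc_tau = np.corrcoef(sol.timing.tau, dataset.truth.tau)[0, 1]
        cc_rho = np.corrcoef(sol.timing.rho, dataset.truth.rho)[0, 1]
        loc = np.linalg.norm(
            myocardial.vertices[np.argmin(sol.timing.tau)]
            - myocardial.vertices[dataset.pacing_node])
        assert cc_tau >= 0.95
        assert cc_rho >= 0.90
        assert loc <= 2 * myocardial.mean_edge_length()

    def test_perturbed_truth_recovery(self, dataset, tm_edl, template, L, rng):
        pt = dataset.truth.tau + rng.choice([-10.0, 10.0],
                                            dataset.truth.n_nodes)
        pr = dataset.truth.rho + rng.choice([-10.0, 10.0],
                                            dataset.truth.n_nodes)
        sol = EDL.marquardt_optimize(SourceTiming(pt, pr), dataset.ecg_clean,
                                     tm_edl, template, EDL.EDLConfig(), L=L)
        assert np.abs(sol.timing.tau - dataset.truth.tau).mean() <= 2.0
        assert np.abs(sol.timing.rho - dataset.truth.rho).mean() <= 4.0

    def test_invalid_initial_timing_rejected(self, dataset, tm_edl, template):
        n = tm_edl.n_sources
        bad = SourceTiming(np.full(n, 50.0), np.full(n, 250.0))
        bad.rho = bad.tau - 1.0     # bypass the constructor check
        with pytest.raises(ValueError, match="rho > tau"):
            EDL.marquardt_optimize(bad, dataset.ecg_clean, tm_edl, template)


class TestSolveEDL:
    def test_noisy_recovery_over_seeds(self, dataset, tm_edl, template,
                                       myocardial, candidate_scan, L):
        cfg = EDL.EDLConfig()
        noisy = [add_noise(dataset.ecg_clean, 20.0, 100 + s)
                 for s in range(10)]
        Vs = [_fit_grid(V, cfg.stride_ms)[1] for V in noisy]
        ranked = candidate_scan.rank_many(Vs, top=1)
        ccs = []
        for sig, cands in zip(noisy, ranked):
            c = cands[0]
            sol = EDL.marquardt_optimize(SourceTiming(c.tau, c.rho), sig,
                                         tm_edl, template, cfg, L=L)
            ccs.append(np.corrcoef(sol.timing.tau, dataset.truth.tau)[0, 1])
        assert np.median(ccs) >= 0.80

    def test_single_start_equals_marquardt_on_top(self, dataset, tm_edl,
                                                  template, myocardial,
                                                  candidate_scan, L,
                                                  top_candidate):
        cfg = EDL.EDLConfig(multi_start=1)
        sol = EDL.solve_edl(dataset.ecg_clean, tm_edl, template, myocardial,
                            cfg, scan=candidate_scan)
        c = top_candidate[0]
        ref = EDL.marquardt_optimize(SourceTiming(c.tau, c.rho),
                                     dataset.ecg_clean, tm_edl, template,
                                     cfg, L=L)
        assert np.allclose(sol.timing.tau, ref.timing.tau, atol=1e-12)
        assert sol.alternatives == []

    def test_best_data_term_selected(self, dataset, tm_edl, template,
                                     myocardial, candidate_scan):
        sol = EDL.solve_edl(dataset.ecg_noisy, tm_edl, template, myocardial,
                            EDL.EDLConfig(), scan=candidate_scan)
        for alt in sol.alternatives:
            assert sol.data_term <= alt.data_term

    def test_multistart_beats_wrong_symmetric_start(self, dataset, tm_edl,
                                                    template, myocardial,
                                                    candidate_scan, L):
        # mirror focus through the heart centre: a near-symmetric competitor
        cfg = dataset.config
        hc = np.array(cfg.heart_center)
        mirror_pos = 2 * hc - myocardial.vertices[dataset.pacing_node]
        nepi = 162
        mirror = int(np.argmin(np.linalg.norm(
            myocardial.vertices[:nepi] - mirror_pos, axis=1)))
        tau_m = fastest_route_times(myocardial, {mirror: 10.0},
                                    cfg.velocity_mm_ms)
        rho_m = assign_repolarization(tau_m, cfg.apd_mode, cfg.apd0_ms,
                                      cfg.apd_slope)
        wrong = EDL.marquardt_optimize(SourceTiming(tau_m, rho_m),
                                       dataset.ecg_clean, tm_edl, template,
                                       EDL.EDLConfig(), L=L)
        multi = EDL.solve_edl(dataset.ecg_clean, tm_edl, template, myocardial,
                              EDL.EDLConfig(), scan=candidate_scan)
        pace_v = myocardial.vertices[dataset.pacing_node]
        loc_wrong = np.linalg.norm(
            myocardial.vertices[np.argmin(wrong.timing.tau)] - pace_v)
        loc_multi = np.linalg.norm(
            myocardial.vertices[np.argmin(multi.timing.tau)] - pace_v)
        assert loc_wrong - loc_multi > 3 * myocardial.mean_edge_length()
        assert multi.data_term < wrong.data_term


class TestAutoLambda:
    def test_laplacian_level_monotone_in_lambda(self, dataset, tm_edl,
                                                template, myocardial,
                                                candidate_scan):
        Ld = mesh_laplacian(myocardial).toarray()
        levels = []
        for lt in (0.003, 0.03, 0.3):
            cfg = EDL.EDLConfig(lam_tau=lt, lam_rho=0.005, multi_start=1)
            sol = EDL.solve_edl(dataset.ecg_noisy, tm_edl, template,
                                myocardial, cfg, scan=candidate_scan)
            levels.append(np.linalg.norm(Ld @ sol.timing.tau))
        assert levels[0] * 1.01 >= levels[1] >= levels[2] / 1.01

    def test_truth_target_reaches_default_accuracy(self, dataset, tm_edl,
                                                   template, myocardial,
                                                   candidate_scan):
        Ld = mesh_laplacian(myocardial).toarray()
        target = float(np.linalg.norm(Ld @ dataset.truth.tau))
        cfg = EDL.EDLConfig(lam_tau="auto", lam_rho=0.005,
                            smoothness_target=target, multi_start=1)
        lt, lr = EDL.auto_lambda(dataset.ecg_noisy, tm_edl, template,
                                 myocardial, cfg)
        sol_auto = EDL.solve_edl(
            dataset.ecg_noisy, tm_edl, template, myocardial,
            EDL.EDLConfig(lam_tau=lt, lam_rho=lr, multi_start=1),
            scan=candidate_scan)
        sol_def = EDL.solve_edl(dataset.ecg_noisy, tm_edl, template,
                                myocardial, EDL.EDLConfig(multi_start=1),
                                scan=candidate_scan)
        mae_auto = np.abs(sol_auto.timing.tau - dataset.truth.tau).mean()
        mae_def = np.abs(sol_def.timing.tau - dataset.truth.tau).mean()
        assert mae_auto <= mae_def * 1.5 + 0.5   # comparable accuracy

    def test_explicit_zero_lambda_reduces_to_data_term(self, dataset, tm_edl,
                                                       template, myocardial,
                                                       candidate_scan):
        cfg = EDL.EDLConfig(lam_tau=0.0, lam_rho=0.0, multi_start=1)
        sol = EDL.solve_edl(dataset.ecg_noisy, tm_edl, template, myocardial,
                            cfg, scan=candidate_scan)
        assert sol.reg_tau == 0.0
        assert sol.reg_rho == 0.0
        assert sol.objective == pytest.approx(sol.data_term)


class TestEndocardialRecoverability:
    def test_endocardial_pacing_stays_endocardial(self, dataset, template,
                                                  myocardial, candidate_scan):
        nepi = 162
        cfg2 = S.DatasetConfig(pacing_node=nepi + 60)
        b2 = S.generate_dataset(cfg2, seed=2)
        econf = EDL.EDLConfig()
        L2 = mesh_laplacian(myocardial)
        noisy = [add_noise(b2.ecg_clean, 20.0, 200 + s) for s in range(10)]
        Vs = [_fit_grid(V, econf.stride_ms)[1] for V in noisy]
        ranked = candidate_scan.rank_many(Vs, top=1)
        hits = 0
        for sig, cands in zip(noisy, ranked):
            c = cands[0]
            sol = EDL.marquardt_optimize(SourceTiming(c.tau, c.rho), sig,
                                         b2.tm_edl, template, econf, L=L2)
            hits += int(np.argmin(sol.timing.tau) >= nepi)
        assert hits >= 8
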