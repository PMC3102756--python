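"""Tests for MFPT, thermodynamics and transition-path flux decomposition."""

import numpy as np
import pytest

import msmbind as mb
from msmbind.kinetics import GAS_CONSTANT_KCAL


def mc_first_passage_oracle(T, sources, targets, n_walkers, seed, pi=None):
    """Monte Carlo mean first passage (in lag units) from stationary-weighted sources."""
    rng = np.random.default_rng(seed)
    n = T.shape[0]
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    if pi is None:
        pi = mb.stationary_distribution(T)
    w = pi[sources] / pi[sources].sum()
    pos = rng.choice(sources, size=n_walkers, p=w)
    steps = np.zeros(n_walkers, dtype=np.int64)
    active = ~np.isin(pos, targets)
    t = 0
    while active.any():
        t += 1
        idx = np.flatnonzero(active)
        u = rng.random(idx.size)
        nxt = np.empty(idx.size, dtype=np.int64)
        for s in np.unique(pos[idx]):
            m = pos[idx] == s
            nxt[m] = np.searchsorted(cum[s], u[m], side="right")
        pos[idx] = nxt
        arrived = np.isin(nxt, targets)
        steps[idx[arrived]] = t
        active[idx[arrived]] = False
        if t > 10**6:
            raise RuntimeError("walkers failed to absorb")
    return steps.mean()


class TestMFPT:
    def test_source_inside_target_is_zero(self):
        T = np.array([[0.5, 0.5], [0.5, 0.5]])
        res = mb.mfpt(T, 6.0, [0], [0, 1])
        assert res.value_us == 0.0

    def test_two_state_closed_form_lag_over_p(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        res = mb.mfpt(T, 6.0, [0], [1])
        assert res.value_us * 1000 == pytest.approx(60.0)

    def test_matches_monte_carlo_first_passage(self):
        rng = np.random.default_rng(77)
        T = rng.dirichlet(np.ones(5) * 0.7, size=5)
        res = mb.mfpt(T, 1.0, [0], [4])
        want = mc_first_passage_oracle(T, np.array([0]), np.array([4]),
                                       200_000, seed=7)
        assert res.value_us * 1000 == pytest.approx(want, rel=0.02)

    def test_additive_on_directed_chain(self):
        # b separates a from c: MFPT(a->c) = MFPT(a->b) + MFPT(b->c)
        T = np.array([[0.8, 0.2, 0.0],
                      [0.1, 0.7, 0.2],
                      [0.0, 0.3, 0.7]])
        ab = mb.mfpt(T, 1.0, [0], [1]).value_us
        bc = mb.mfpt(T, 1.0, [1], [2]).value_us
        ac = mb.mfpt(T, 1.0, [0], [2]).value_us
        assert ac == pytest.approx(ab + bc, rel=1e-10)

    def test_unreachable_target_flagged_infinite(self):
        T = np.array([[1.0, 0.0], [0.5, 0.5]])
        with pytest.warns(UserWarning, match="unreachable"):
            res = mb.mfpt(T, 1.0, [0], [1])
        assert np.isinf(res.value_us)

    def test_multi_source_stationary_weighting(self):
        rng = np.random.default_rng(3)
        T = rng.dirichlet(np.ones(4), size=4)
        pi = mb.stationary_distribution(T)
        res = mb.mfpt(T, 1.0, [0, 1], [3], pi=pi)
        w = pi[[0, 1]] / pi[[0, 1]].sum()
        per = np.array([res.per_source_us[0], res.per_source_us[1]])
        assert res.value_us == pytest.approx(float(w @ per))


class TestBootstrap:
    def test_constant_statistic_zero_sd(self):
        mean, sd = mb.bootstrap_statistic([1, 2, 3, 4], lambda t: 5.0, n_boot=20)
        assert (mean, sd) == (5.0, 0.0)

    def test_trajectory_count_statistic(self):
        mean, sd = mb.bootstrap_statistic(list(range(6)), len, n_boot=30, n_draw=4)
        assert mean == 4.0 and sd == 0.0

    def test_bootstrap_sd_tracks_analytic_standard_error(self):
        rng = np.random.default_rng(11)
        values = rng.normal(10.0, 2.0, size=200)
        mean, sd = mb.bootstrap_statistic(
            values.tolist(), lambda t: float(np.mean(t)), n_boot=100, seed=1)
        analytic_se = values.std(ddof=0) / np.sqrt(len(values))
        assert abs(sd / analytic_se - 1.0) < 0.30

    def test_failing_resamples_skipped_with_warning(self):
        calls = {"n": 0}

        def flaky(t):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("boom")
            return 1.0

        with pytest.warns(UserWarning, match="resample"):
            mean, _ = mb.bootstrap_statistic([1, 2, 3], flaky, n_boot=9)
        assert mean == 1.0

    def test_needs_two_trajectories(self):
        with pytest.raises(ValueError):
            mb.bootstrap_statistic([1], lambda t: 0.0)


class TestThermodynamics:
    def test_printed_binding_free_energy(self):
        # 1.75% free species at 4.9 mM box concentration and 318 K
        dG = mb.binding_free_energy(0.0175, 0.0049, 318.0)
        assert dG == pytest.approx(-8.46, abs=0.01)

    def test_golden_ratio_free_fraction_gives_zero(self):
        alpha = (np.sqrt(5.0) - 1.0) / 2.0
        assert mb.binding_free_energy(alpha, 1.0, 300.0) == pytest.approx(0.0, abs=1e-10)

    def test_monotone_in_free_fraction(self):
        alphas = np.linspace(0.01, 0.99, 25)
        vals = [mb.binding_free_energy(a, 0.0049, 318.0) for a in alphas]
        assert np.all(np.diff(vals) > 0)   # less free species => more negative dG

    def test_degenerate_fraction_rejected(self):
        for a in (0.0, 1.0):
            with pytest.raises(ValueError):
                mb.binding_free_energy(a, 0.0049, 318.0)

    def test_printed_reference_free_energy_from_kd(self):
        assert mb.dG_from_Kd(14e-9, 277.0) == pytest.approx(-9.95, abs=0.01)

    def test_unit_kd_gives_zero(self):
        assert mb.dG_from_Kd(1.0, 298.0) == 0.0

    def test_halving_kd_shifts_by_rt_ln2(self):
        T = 300.0
        d = mb.dG_from_Kd(1e-9, T) - mb.dG_from_Kd(2e-9, T)
        assert d == pytest.approx(-GAS_CONSTANT_KCAL * T * np.log(2.0))

    def test_association_timescale_examples(self):
        assert mb.association_timescale(np.log(2.0), 1.0) == pytest.approx(1.0)
        assert mb.association_timescale(1e7, 0.0049) == pytest.approx(1.414e-5, rel=1e-3)
        t1 = mb.association_timescale(5e6, 0.002)
        t2 = mb.association_timescale(5e6, 0.004)
        assert t1 == pytest.approx(2 * t2)


class TestCommittor:
    def test_boundary_values(self):
        rng = np.random.default_rng(5)
        T = rng.dirichlet(np.ones(6), size=6)
        q = mb.committor(T, [0], [5])
        assert q[0] == 0.0 and q[5] == 1.0

    def test_gamblers_ruin_profile(self):
        # symmetric nearest-neighbor walk on 0..N: q_i = i/N
        N = 10
        T = np.zeros((N + 1, N + 1))
        T[0, 0] = T[N, N] = 1.0
        for i in range(1, N):
            T[i, i - 1] = T[i, i + 1] = 0.5
        q = mb.committor(T, [0], [N])
        assert np.allclose(q, np.arange(N + 1) / N, atol=1e-10)

    def test_fixed_point_residual(self):
        rng = np.random.default_rng(6)
        T = rng.dirichlet(np.ones(7), size=7)
        q = mb.committor(T, [0, 1], [6])
        inter = np.arange(2, 6)
        assert np.linalg.norm(q[inter] - T[inter] @ q, np.inf) < 1e-10

    def test_states_cut_off_from_sink_get_zero(self):
        T = np.array([[0.5, 0.5, 0.0, 0.0],
                      [0.5, 0.5, 0.0, 0.0],
                      [0.0, 0.0, 1.0, 0.0],
                      [0.0, 0.5, 0.0, 0.5]])
        with pytest.warns(UserWarning, match="cannot reach"):
            q = mb.committor(T, [0], [1])
        assert q[2] == 0.0

    def test_overlapping_sets_rejected(self):
        T = np.eye(2)
        with pytest.raises(ValueError):
            mb.committor(T, [0], [0, 1])


def linear_chain(n, p=0.2):
    T = np.zeros((n, n))
    for i in range(n):
        if i + 1 < n:
            T[i, i + 1] = p
        if i - 1 >= 0:
            T[i, i - 1] = p / 2
        T[i, i] = 1.0 - T[i].sum()
    return T


class TestNetFlux:
    def test_linear_chain_carries_identical_edge_flux(self):
        T = linear_chain(4)
        pi = mb.stationary_distribution(T)
        q = mb.committor(T, [0], [3])
        F, total = mb.net_flux(T, pi, q, [0], [3])
        edges = [F[0, 1], F[1, 2], F[2, 3]]
        assert np.allclose(edges, edges[0])
        assert total == pytest.approx(edges[0])

    def test_flux_conservation_source_to_sink(self):
        rng = np.random.default_rng(8)
        T = rng.dirichlet(np.ones(6), size=6)
        pi = mb.stationary_distribution(T)
        q = mb.committor(T, [0], [5])
        F, total = mb.net_flux(T, pi, q, [0], [5])
        out_src = F[0, :].sum() - F[:, 0].sum()
        in_sink = F[:, 5].sum() - F[5, :].sum()
        assert out_src == pytest.approx(in_sink, abs=1e-10)
        assert total == pytest.approx(in_sink, abs=1e-10)

    def test_no_flux_leaves_the_sink(self):
        rng = np.random.default_rng(9)
        T = rng.dirichlet(np.ones(5), size=5)
        pi = mb.stationary_distribution(T)
        q = mb.committor(T, [0], [4])
        F, _ = mb.net_flux(T, pi, q, [0], [4])
        assert np.all(F[4, :] == 0.0)


class TestTopFluxPaths:
    def test_linear_chain_single_path_all_flux(self):
        T = linear_chain(4)
        pi = mb.stationary_distribution(T)
        q = mb.committor(T, [0], [3])
        F, total = mb.net_flux(T, pi, q, [0], [3])
        paths = mb.top_flux_paths(F, [0], [3], n_paths=5, total_flux=total)
        assert len(paths) == 1
        assert paths[0][0] == [0, 1, 2, 3]
        assert paths[0][2] == pytest.approx(1.0)

    def test_planted_parallel_branches_recovered_in_order(self):
        # hand-built net flux: source 0 -> {1 (0.7), 2 (0.3)} -> sink 3
        F = np.zeros((4, 4))
        F[0, 1] = F[1, 3] = 0.7
        F[0, 2] = F[2, 3] = 0.3
        paths = mb.top_flux_paths(F, [0], [3], n_paths=10, total_flux=1.0)
        assert [p[0] for p in paths] == [[0, 1, 3], [0, 2, 3]]
        assert paths[0][1] == pytest.approx(0.7)
        assert paths[1][1] == pytest.approx(0.3)
        assert [p[2] for p in paths] == [pytest.approx(0.7), pytest.approx(0.3)]

    def test_path_flux_sum_bounded_by_total(self):
        rng = np.random.default_rng(10)
        T = rng.dirichlet(np.ones(7), size=7)
        pi = mb.stationary_distribution(T)
        q = mb.committor(T, [0], [6])
        F, total = mb.net_flux(T, pi, q, [0], [6])
        paths = mb.top_flux_paths(F, [0], [6], n_paths=10, total_flux=total)
        assert sum(p[1] for p in paths) <= total + 1e-10


class TestTransitionEvents:
    def test_hand_built_sequence_one_valid_event(self):
        #                 0  1  2  3  4  5  6  7
        labels = np.array([0, 1, 0, 0, 1, 1, 1, 1])
        feats = np.arange(8, dtype=float)
        ev = mb.transition_event_features(labels, feats, 0, 1,
                                          min_residence_frames=3)
        # the blip at frame 1 is rejected; the event at frame 4 persists
        assert ev.ravel().tolist() == [4.0]

    def test_no_transitions_empty(self):
        ev = mb.transition_event_features(np.zeros(5, dtype=int),
                                          np.zeros(5), 0, 1)
        assert len(ev) == 0

    def test_event_count_bounded_by_raw_changes(self):
        rng = np.random.default_rng(12)
        labels = rng.integers(0, 2, size=300)
        feats = rng.standard_normal(300)
        raw = np.sum((labels[:-1] == 0) & (labels[1:] == 1))
        ev = mb.transition_event_features(labels, feats, 0, 1,
                                          min_residence_frames=2)
        assert len(ev) <= raw


class TestFreeEnergySurface:
    def test_single_bin_zero(self):
        xe, ye, F = mb.free_energy_surface(np.zeros(10), np.zeros(10), 1.0, 1.0)
        vals = F[np.isfinite(F)]
        assert len(vals) == 1 and vals[0] == 0.0

    def test_count_ratio_e_gives_one_kt(self):
        n = 1000
        x = np.concatenate([np.zeros(int(round(np.e * n))), np.ones(n) * 5.0])
        y = np.zeros_like(x)
        _, _, F = mb.free_energy_surface(x, y, 1.0, 1.0, kT=1.0)
        vals = np.sort(F[np.isfinite(F)])
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(1.0, abs=2e-3)

    def test_gaussian_sample_quadratic_radial_profile(self):
        rng = np.random.default_rng(13)
        pts = rng.standard_normal((10**6, 2))
        xe, ye, F = mb.free_energy_surface(pts[:, 0], pts[:, 1], 0.25, 0.25)
        xc = 0.5 * (xe[:-1] + xe[1:])
        yc = 0.5 * (ye[:-1] + ye[1:])
        X, Y = np.meshgrid(xc, yc, indexing="ij")
        r2 = X**2 + Y**2
        sel = (r2 < 4.0) & np.isfinite(F) & (r2 > 0.2)
        # Boltzmann inversion of a standard Gaussian: F = r^2/2 (+ const)
        ratio = F[sel] / (r2[sel] / 2.0)
        assert np.median(np.abs(ratio - 1.0)) < 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mb.free_energy_surface(np.array([]), np.array([]), 1.0, 1.0)


class TestMedoids:
    def test_identical_conformations_lowest_indices(self):
        X = np.tile(np.arange(12.0).reshape(4, 3), (6, 1, 1))
        assert mb.medoid_conformations(X, n=3).tolist() == [0, 1, 2]

    def test_outlier_never_selected(self):
        rng = np.random.default_rng(14)
        base = rng.standard_normal((5, 3))
        # the outlier differs in shape (not just pose, which superposition removes)
        X = np.stack([base + rng.standard_normal((5, 3)) * 1e-3 for _ in range(9)]
                     + [base * 3.0])
        assert 9 not in mb.medoid_conformations(X, n=3)

    def test_matches_exhaustive_pairwise_oracle(self):
        from msmbind.featurize import superpose
        rng = np.random.default_rng(15)
        X = rng.standard_normal((10, 6, 3)) * 2
        D = np.zeros((10, 10))
        for i in range(10):
            for j in range(10):
                if i != j:
                    D[i, j] = superpose(X[j], X[i])[1]
        want = np.argsort(D.mean(axis=1) * 10 / 9)[:3]
        got = mb.medoid_conformations(X, n=3)
        assert sorted(got) == sorted(want)

    def test_needs_enough_conformations(self):
        with pytest.raises(ValueError):
            mb.medoid_conformations(np.zeros((2, 3, 3)), n=3)
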