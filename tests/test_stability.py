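"""Jury classification, bifurcation thresholds, scans, Lyapunov exponents."""

import math

import numpy as np
import pytest

from sivs import (
    FixtureSpec,
    ModelParams,
    basic_reproduction_number,
    bifurcation_scan,
    classify_dfe,
    classify_endemic,
    detect_period,
    disease_free_equilibrium,
    endemic_equilibrium,
    generate_fixtures,
    jacobian_reduced,
    jury_stable,
    lyapunov_exponents,
    no_neimark_sacker_certificate,
    period_doubling_beta,
    simulate,
    transcritical_beta,
)
from sivs.model import CompartmentState, _step_reduced_xy


class TestJacobian:
    def test_matches_central_differences(self, disc_params):
        params = disc_params.with_(beta=2.7)
        I, S = 0.4, 0.8
        J = jacobian_reduced((I, S), params)
        h = 1e-7
        fd = np.empty((2, 2))
        for j, (dI, dS) in enumerate(((h, 0.0), (0.0, h))):
            hi = _step_reduced_xy(I + dI, S + dS, params)
            lo = _step_reduced_xy(I - dI, S - dS, params)
            fd[0, j] = (hi[0] - lo[0]) / (2 * h)
            fd[1, j] = (hi[1] - lo[1]) / (2 * h)
        assert np.allclose(J.as_array(), fd, atol=1e-6)

    def test_triangular_at_disease_free_point(self, disc_params):
        r0 = basic_reproduction_number(disc_params)
        J = jacobian_reduced(disease_free_equilibrium(disc_params), disc_params)
        assert J.a12 == 0.0
        lams = sorted(lam.real for lam in J.eigenvalues)
        assert lams[1] == pytest.approx(1 - 0.25 + 0.25 * r0, rel=1e-12)
        assert lams[0] == pytest.approx(1 - 0.55, rel=1e-12)

    def test_unit_top_left_entry_at_endemic_point(self, disc_params):
        params = disc_params.with_(beta=2.7)
        J = jacobian_reduced(endemic_equilibrium(params), params)
        assert J.a11 == pytest.approx(1.0, rel=1e-12)

    def test_eigenvalues_satisfy_characteristic_polynomial(self, disc_params):
        J = jacobian_reduced((0.3, 0.9), disc_params.with_(beta=2.0))
        for lam in J.eigenvalues:
            assert abs(lam * lam - J.trace * lam + J.det) < 1e-10


class TestJuryCriterion:
    def test_origin_is_stable(self):
        assert jury_stable(0.0, 0.0)

    def test_double_root_at_one_is_not(self):
        assert not jury_stable(2.0, 1.0)

    def test_agrees_with_root_moduli_on_grid(self):
        """Brute-force oracle: roots of lambda^2 - tr lambda + det inside the
        unit disk, over a 100x100 (trace, det) grid."""
        for tr in np.linspace(-3, 3, 100):
            for det in np.linspace(-2, 2, 100):
                if abs(abs(tr) - (1 + det)) < 1e-9 or abs(det - 1) < 1e-9:
                    continue  # on the stability boundary the root oracle is ill-conditioned
                roots = np.roots([1.0, -tr, det])
                inside = bool(np.all(np.abs(roots) < 1))
                assert jury_stable(tr, det) == inside


class TestClassification:
    def test_dfe_stable_below_threshold(self, disc_params):
        rep = classify_dfe(disc_params)
        assert rep.verdict == "stable"
        assert rep.jury_satisfied

    def test_dfe_unstable_above_threshold(self, disc_params):
        rep = classify_dfe(disc_params.with_(beta=0.55))
        assert rep.verdict == "unstable"
        assert round(rep.R0, 4) == 1.2400

    def test_dfe_marginal_at_transcritical_point(self, disc_params):
        params = disc_params.with_(beta=transcritical_beta(disc_params))
        assert classify_dfe(params).verdict == "marginal"

    @pytest.mark.parametrize("beta, verdict", [(0.55, "stable"), (2.0, "stable"), (2.5, "unstable")])
    def test_endemic_verdicts(self, disc_params, beta, verdict):
        rep = classify_endemic(disc_params.with_(beta=beta))
        assert rep is not None
        assert rep.verdict == verdict
        assert rep.jury_satisfied == (verdict == "stable")

    def test_endemic_absent_below_threshold(self, disc_params):
        assert classify_endemic(disc_params) is None

    def test_endemic_trace_det_identities(self, disc_params):
        # tr = 2 - b1, det = 1 - b1 + b2 with b1, b2 from the endemic point
        params = disc_params.with_(beta=2.7)
        rep = classify_endemic(params)
        J = jacobian_reduced(rep.point, params)
        assert J.trace == pytest.approx(2 - rep.b1, abs=1e-12)
        assert J.det == pytest.approx(1 - rep.b1 + rep.b2, abs=1e-12)

    def test_dfe_verdict_iff_r0_below_one_over_fixtures(self):
        """Disease-free point stable <=> R0 < 1 under the nonnegativity
        conditions (randomized)."""
        for params, _ in generate_fixtures(FixtureSpec(n=500, regime="conditions-3-satisfied", seed=29)):
            rep = classify_dfe(params)
            r0 = basic_reproduction_number(params)
            if abs(r0 - 1) > 1e-9:
                assert (rep.verdict == "stable") == (r0 < 1)

    def test_endemic_always_stable_under_conditions_over_fixtures(self):
        """Under the nonnegativity conditions the endemic point is stable
        whenever it exists (randomized)."""
        for params, _ in generate_fixtures(FixtureSpec(n=500, regime="R0-above-1", seed=31)):
            rep = classify_endemic(params)
            assert rep is not None and rep.verdict == "stable"


class TestAnalyticThresholds:
    def test_transcritical_worked_value(self, disc_params):
        assert round(transcritical_beta(disc_params), 4) == 0.4435

    def test_transcritical_classical_sis_limit(self):
        p = ModelParams(mu=0.1, beta=0.4, gamma=0.15, epsilon=0.0, p=0.0, q=0.0, N=1.0)
        assert transcritical_beta(p) == pytest.approx(0.25, rel=1e-14)

    def test_r0_is_one_at_transcritical_beta(self, disc_params):
        beta_c = transcritical_beta(disc_params)
        assert basic_reproduction_number(disc_params.with_(beta=beta_c)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_period_doubling_worked_value(self, disc_params):
        assert round(period_doubling_beta(disc_params), 4) == 2.4279

    def test_eigenvalue_minus_one_at_flip_beta(self, disc_params):
        """P(-1) = 0 of the endemic characteristic polynomial at the flip
        threshold: 4 - 2 b1 + b2 = 0."""
        params = disc_params.with_(beta=period_doubling_beta(disc_params))
        rep = classify_endemic(params)
        assert 4 - 2 * rep.b1 + rep.b2 == pytest.approx(0.0, abs=1e-10)
        J = jacobian_reduced(rep.point, params)
        P_minus1 = 1 + J.trace + J.det
        assert P_minus1 == pytest.approx(0.0, abs=1e-10)

    def test_flip_beta_matches_bisection_oracle(self, disc_params):
        """Root-bracketing on the P(-1) sign change of the endemic Jacobian."""

        def p_minus1(beta):
            params = disc_params.with_(beta=beta)
            J = jacobian_reduced(endemic_equilibrium(params), params)
            return 1 + J.trace + J.det

        lo, hi = 2.0, 3.0
        assert p_minus1(lo) > 0 > p_minus1(hi)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if p_minus1(mid) > 0:
                lo = mid
            else:
                hi = mid
        assert period_doubling_beta(disc_params) == pytest.approx(0.5 * (lo + hi), abs=1e-9)


class TestNeimarkSackerCertificate:
    def test_worked_parameter_set(self, disc_params):
        # b1^2 - 4 b2 evaluated from the printed closed forms at beta=2.7
        params = disc_params.with_(beta=2.7)
        beta_i = 0.1375 / 0.35 * (basic_reproduction_number(params) - 1)
        b1, b2 = 0.55 + beta_i, 0.35 * beta_i
        assert b1 * b1 - 4 * b2 > 0
        assert no_neimark_sacker_certificate(params)

    def test_real_eigenvalues_over_random_fixtures(self):
        for params, _ in generate_fixtures(FixtureSpec(n=200, regime="R0-above-1", seed=37)):
            assert no_neimark_sacker_certificate(params)
            J = jacobian_reduced(endemic_equilibrium(params), params)
            assert all(abs(lam.imag) < 1e-12 for lam in J.eigenvalues)


class TestPeriodDetection:
    def test_fixed_point_orbit(self):
        assert detect_period(np.full(50, 0.7), 1e-6) == 1

    def test_two_cycle(self):
        assert detect_period(np.array([0.2, 0.9] * 25), 1e-6) == 2

    def test_aperiodic_returns_none(self):
        rng = np.random.default_rng(1)
        assert detect_period(rng.uniform(0, 1, 100), 1e-9) is None


class TestBifurcationScan:
    def test_single_point_grid_reproduces_simulate_tail(self, disc_params, disc_init_reduced):
        res = bifurcation_scan(disc_params, "beta", [0.55], disc_init_reduced,
                               n_transient=100, n_sample=20)
        traj = simulate(disc_params.with_(beta=0.55),
                        CompartmentState(I=0.4, S=0.8), 120)
        assert res.points[0].samples == pytest.approx([s.I for s in traj[101:]], rel=1e-15)

    def test_rejects_unsorted_grid(self, disc_params, disc_init_reduced):
        with pytest.raises(ValueError):
            bifurcation_scan(disc_params, "beta", [0.5, 0.4], disc_init_reduced)

    def test_transcritical_bracket_contains_analytic_threshold(self, disc_params, disc_init_reduced):
        """Coarse scan around R0 = 1: the detected positive-infection onset
        brackets the analytic transcritical beta."""
        grid = np.round(np.arange(0.42, 0.4701, 0.005), 5)
        res = bifurcation_scan(disc_params, "beta", grid, disc_init_reduced,
                               n_transient=20_000, n_sample=100)
        beta_c = transcritical_beta(disc_params)
        assert res.positive_I_onset is not None
        assert res.positive_I_onset - 0.005 <= beta_c <= res.positive_I_onset

    def test_flip_bracket_contains_analytic_threshold(self, disc_params, disc_init_reduced):
        grid = np.round(np.arange(2.40, 2.4601, 0.005), 5)
        res = bifurcation_scan(disc_params, "beta", grid, disc_init_reduced,
                               n_transient=20_000, n_sample=100)
        beta_f = period_doubling_beta(disc_params)
        assert res.period2_onset is not None
        assert res.period2_onset - 0.005 <= beta_f <= res.period2_onset

    def test_divergent_orbit_flagged_scan_continues(self, disc_params, disc_init_reduced):
        grid = [3.0, 30.0]  # second value blows up
        res = bifurcation_scan(disc_params, "beta", grid, disc_init_reduced,
                               n_transient=200, n_sample=20)
        assert not res.points[0].diverged
        assert res.points[1].diverged


class TestLyapunovExponents:
    def test_equals_log_spectral_radius_at_stable_endemic_point(self, disc_params, disc_init_reduced):
        params = disc_params.with_(beta=0.55)
        J = jacobian_reduced(endemic_equilibrium(params), params)
        lead, _ = lyapunov_exponents(params, disc_init_reduced, n_transient=5000, n_iter=2000)
        assert lead == pytest.approx(math.log(J.spectral_radius), abs=1e-3)
        assert lead < 0

    def test_equals_dfe_eigenvalue_log_below_threshold(self, disc_params, disc_init_reduced):
        r0 = basic_reproduction_number(disc_params)
        lead, _ = lyapunov_exponents(disc_params, disc_init_reduced, n_transient=5000, n_iter=2000)
        assert lead == pytest.approx(math.log(1 - 0.25 + 0.25 * r0), abs=1e-3)

    def test_positive_in_chaotic_band(self, disc_params, disc_init_reduced):
        lead, _ = lyapunov_exponents(disc_params.with_(beta=3.48), disc_init_reduced,
                                     n_transient=5000, n_iter=10_000)
        assert lead > 0

    def test_exponents_sorted_descending(self, disc_params, disc_init_reduced):
        lead, second = lyapunov_exponents(disc_params, disc_init_reduced,
                                          n_transient=1000, n_iter=500)
        assert lead >= second

    def test_divergent_orbit_raises(self, disc_params):
        with pytest.raises(ValueError):
            lyapunov_exponents(disc_params.with_(beta=30.0), (0.4, 0.8),
                               n_transient=1000, n_iter=200)
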