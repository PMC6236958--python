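"""Grid construction, OLS fitting, Nash-Sutcliffe scoring, the estimator."""

import numpy as np
import pytest

from cscompliance import (
    CardiacCycleData,
    DegenerateInputError,
    DiscreteQuartet,
    EstimatorConfig,
    InvalidConfigError,
    NoSolutionError,
    UndefinedEError,
    WaveformSpec,
    build_stability_grid,
    continuous_transfer_function,
    discretize_pole_zero_matched,
    estimate_compliance_distribution,
    fit_pq_ols,
    generate_subject,
    nash_sutcliffe,
    poles_of,
    predict_csf,
    sensitivity_report,
    simulate_csf_response,
)


def brute_force_stable_pairs(step):
    """Independent enumeration of stable lattice points via the pole oracle."""
    pairs = []
    j = -int(2 // step) - 2
    vals = np.arange(-int(np.ceil(2 / step)), int(np.ceil(2 / step)) + 1) * step
    for q2 in vals:
        if not -1 + 1e-12 < q2 < 1 - 1e-12:
            continue
        for q1 in vals:
            if not -2 + 1e-12 < q1 < 2 - 1e-12:
                continue
            if max(abs(z) for z in poles_of(q1, q2)) < 1 - 1e-9:
                pairs.append((q1, q2))
    return pairs


class TestStabilityGrid:
    @pytest.mark.parametrize("step, expected_n", [(0.5, 9), (1.0, 1)])
    def test_counts_against_enumeration(self, step, expected_n):
        grid = build_stability_grid(step)
        assert len(grid) == expected_n
        assert len(brute_force_stable_pairs(step)) == expected_n

    def test_step_one_is_origin(self):
        assert build_stability_grid(1.0).tolist() == [[0.0, 0.0]]

    def test_all_returned_pairs_stable(self):
        grid = build_stability_grid(0.05)
        for q1, q2 in grid:
            assert max(abs(z) for z in poles_of(q1, q2)) < 1.0

    def test_ordering_q2_major(self):
        grid = build_stability_grid(0.25)
        order = np.lexsort((grid[:, 0], grid[:, 1]))
        assert np.array_equal(order, np.arange(len(grid)))

    def test_invalid_step(self):
        with pytest.raises(InvalidConfigError):
            build_stability_grid(0.0)


class TestFitPQ:
    def test_exact_recovery_at_generating_pair(self, clean_subject):
        """Noise-free refit at the true (q1, q2) recovers (p1, p2) and E=1."""
        cyc = clean_subject.cycle
        tf = continuous_transfer_function(clean_subject.truth_params)
        quartet = discretize_pole_zero_matched(tf, cyc.sampling_interval)
        p1, p2 = fit_pq_ols(quartet.q1, quartet.q2, cyc)
        assert p1 == pytest.approx(quartet.p1, abs=1e-8)
        assert p2 == pytest.approx(quartet.p2, abs=1e-8)
        pred = predict_csf(DiscreteQuartet(p1, p2, quartet.q1, quartet.q2), cyc)
        assert nash_sutcliffe(cyc.q_csf, pred) == pytest.approx(1.0, abs=1e-10)

    def test_zero_input_degenerate(self):
        cyc = CardiacCycleData(
            q_av=np.zeros(32), q_csf=np.random.default_rng(0).normal(size=32),
            cycle_duration=1.0,
        )
        with pytest.raises(DegenerateInputError):
            fit_pq_ols(-0.5, 0.1, cyc)

    def test_matches_brute_force_grid(self, rng):
        """OLS equals an exhaustive search of the cyclic equation-error
        objective on an 8-frame toy (coarse-to-fine p grid, 1e-3 final)."""
        u = rng.normal(size=8)
        y = rng.normal(size=8)
        cyc = CardiacCycleData(q_av=u, q_csf=y, cycle_duration=1.0)
        q1, q2 = -0.3, 0.2

        def sse(p1, p2):
            resid = (
                y + q1 * np.roll(y, 1) + q2 * np.roll(y, 2)
                - p1 * np.roll(u, 1) - p2 * np.roll(u, 2)
            )
            return np.sum(resid**2)

        # coarse pass over [-5, 5], then refine around the winner at 1e-3
        coarse = np.arange(-5, 5.0001, 0.01)
        P1, P2 = np.meshgrid(coarse, coarse, indexing="ij")
        S = np.array([[sse(a, b) for b in coarse] for a in coarse])
        i, j = np.unravel_index(np.argmin(S), S.shape)
        fine1 = coarse[i] + np.arange(-0.02, 0.0201, 1e-3)
        fine2 = coarse[j] + np.arange(-0.02, 0.0201, 1e-3)
        S2 = np.array([[sse(a, b) for b in fine2] for a in fine1])
        i2, j2 = np.unravel_index(np.argmin(S2), S2.shape)
        best = (fine1[i2], fine2[j2])

        p = fit_pq_ols(q1, q2, cyc)
        assert p[0] == pytest.approx(best[0], abs=1.5e-3)
        assert p[1] == pytest.approx(best[1], abs=1.5e-3)


class TestNashSutcliffe:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=32)
        assert nash_sutcliffe(y, y) == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self, rng):
        y = rng.normal(size=32)
        assert nash_sutcliffe(y, np.full(32, y.mean())) == pytest.approx(0.0)

    def test_constant_observed_undefined(self):
        with pytest.raises(UndefinedEError):
            nash_sutcliffe(np.ones(32), np.zeros(32))


class TestPredict:
    def test_identity_with_simulator(self, clean_subject):
        cyc = clean_subject.cycle
        tf = continuous_transfer_function(clean_subject.truth_params)
        quartet = discretize_pole_zero_matched(tf, cyc.sampling_interval)
        assert np.array_equal(
            predict_csf(quartet, cyc), simulate_csf_response(quartet, cyc.q_av)
        )

    def test_zero_input_zero_output(self):
        cyc = CardiacCycleData(
            q_av=np.zeros(32), q_csf=np.ones(32), cycle_duration=1.0
        )
        out = predict_csf(DiscreteQuartet(0.3, 0.2, -0.5, 0.1), cyc)
        assert out.shape == (32,)
        assert np.allclose(out, 0.0)


class TestEstimator:
    def test_histogram_conservation(self, clean_subject):
        res = estimate_compliance_distribution(clean_subject.cycle)
        in_range = (res.accepted_gain >= 0) & (res.accepted_gain <= 1)
        assert res.histogram.counts.sum() == in_range.sum()
        assert res.n_accepted == len(res.accepted_e)
        assert (res.accepted_e > 0.7).all()
        assert res.spinal_percent + res.cranial_percent == 100
        assert res.spinal_percent in res.tie_bins

    def test_deterministic(self, clean_subject):
        r1 = estimate_compliance_distribution(clean_subject.cycle)
        r2 = estimate_compliance_distribution(clean_subject.cycle)
        assert r1.spinal_percent == r2.spinal_percent
        assert np.array_equal(r1.histogram.counts, r2.histogram.counts)

    def test_best_fit_gain_recovers_truth(self, clean_subject):
        """The dc gain of the argmax-E quartet matches the generating
        circuit's compliance ratio closely on noise-free data (the histogram
        mode is a coarser statistic; see the methods note)."""
        res = estimate_compliance_distribution(clean_subject.cycle)
        assert res.best_e > 0.999
        assert 100 * res.best_fit_gain == pytest.approx(
            clean_subject.truth_spinal_percent, abs=2.0
        )

    def test_scale_invariance(self, clean_subject):
        """Scaling both waveforms by the same constant leaves the
        distribution unchanged (the dc gain is a ratio)."""
        cyc = clean_subject.cycle
        scaled = CardiacCycleData(
            q_av=3.7 * cyc.q_av, q_csf=3.7 * cyc.q_csf,
            cycle_duration=cyc.cycle_duration,
        )
        r1 = estimate_compliance_distribution(cyc)
        r2 = estimate_compliance_distribution(scaled)
        assert r1.spinal_percent == r2.spinal_percent
        assert np.array_equal(r1.histogram.counts, r2.histogram.counts)

    def test_white_noise_output_has_no_solution(self, clean_subject, rng):
        """CSF flow uncorrelated with blood flow fits no stable quartet."""
        cyc = clean_subject.cycle
        noisy = CardiacCycleData(
            q_av=cyc.q_av, q_csf=rng.normal(size=cyc.frame_count),
            cycle_duration=cyc.cycle_duration,
        )
        with pytest.raises(NoSolutionError) as exc:
            estimate_compliance_distribution(noisy)
        assert exc.value.best_e < 0.7

    def test_config_validation(self):
        with pytest.raises(InvalidConfigError):
            EstimatorConfig(grid_step=0.5)
        with pytest.raises(InvalidConfigError):
            EstimatorConfig(e_threshold=1.0)


class TestSensitivity:
    def test_report_structure_and_determinism(self, clean_subject):
        rep1 = sensitivity_report(
            clean_subject.cycle, steps=(0.01, 0.005)
        )
        rep2 = sensitivity_report(
            clean_subject.cycle, steps=(0.01, 0.005)
        )
        assert rep1 == rep2
        assert set(rep1.spinal_by_threshold) == {0.7, 0.6}
        assert set(rep1.spinal_by_step) == {0.01, 0.005}
        assert rep1.step_diff == abs(
            rep1.spinal_by_step[0.01] - rep1.spinal_by_step[0.005]
        )
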