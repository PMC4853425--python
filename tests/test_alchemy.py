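import math

import numpy as np
import pytest
from scipy.integrate import quad

from c60kit import alchemy, mc, synth
from c60kit.constants import AVOGADRO, R_KCAL
from c60kit.errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)

T = 298.15
RT = R_KCAL * T


class TestZwanzig:
    def test_constant_perturbation_is_exact(self):
        assert alchemy.zwanzig(np.full(50, 1.7), T) == pytest.approx(1.7, abs=1e-12)

    def test_gaussian_work_distribution(self, rng):
        mu, sigma, n = 2.0, 0.8, 10 ** 5
        du = rng.normal(mu, sigma, n)
        expected = mu - sigma ** 2 / (2 * RT)
        batches = np.array_split(du, 10)
        est = np.array([alchemy.zwanzig(b, T) for b in batches])
        se = est.std(ddof=1) / math.sqrt(len(est))
        assert abs(alchemy.zwanzig(du, T) - expected) <= 3 * max(se, 1e-3)

    def test_gaussian_bias_decreases_with_n(self, rng):
        mu, sigma = 0.0, 1.2
        expected = mu - sigma ** 2 / (2 * RT)
        errors = []
        for n in (10 ** 3, 10 ** 4, 10 ** 5):
            reps = [abs(alchemy.zwanzig(rng.normal(mu, sigma, n), T) - expected)
                    for _ in range(8)]
            errors.append(np.mean(reps))
        assert errors[2] < errors[0]

    def test_extreme_outlier_stays_finite(self):
        du = np.array([0.1, 0.2, -1e6])
        assert np.isfinite(alchemy.zwanzig(du, T))

    def test_empty_and_bad_temperature(self):
        with pytest.raises(InsufficientDataError):
            alchemy.zwanzig([], T)
        with pytest.raises(InvalidParameterError):
            alchemy.zwanzig([1.0], -1.0)

    def test_bar_on_crooks_consistent_gaussian_work(self, rng):
        # forward work N(mu, s^2) implies dG = mu - s^2/2RT and, by Crooks,
        # reverse work N(-mu + s^2/RT, s^2)
        mu, sigma, n = 1.0, 0.5, 40000
        dg_true = mu - sigma ** 2 / (2 * RT)
        wf = rng.normal(mu, sigma, n)
        wr = rng.normal(-mu + sigma ** 2 / RT, sigma, n)
        dg = alchemy.bar(wf, wr, T)
        assert abs(dg - dg_true) < 0.02


class TestRestraintSchedule:
    def test_endpoints_and_linear_midpoint(self):
        assert alchemy.restraint_schedule(0.0) == 0.0
        assert alchemy.restraint_schedule(1.0) == 10.0
        assert alchemy.restraint_schedule(0.5) == 5.0

    def test_monotone_non_decreasing(self):
        grid = np.linspace(0, 1, 101)
        vals = [alchemy.restraint_schedule(l) for l in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            alchemy.restraint_schedule(1.2)


class TestStandardState:
    def test_volume_matches_quadrature_to_six_digits(self):
        k = 10.0
        v_k = alchemy.restrained_volume(k, T)
        # 3-D integral of exp(-k r^2/2RT), radially: 4 pi r^2 weight
        integral = quad(lambda r: 4 * math.pi * r * r * math.exp(-k * r * r / (2 * RT)),
                        0, 20)[0]
        assert abs(v_k - integral) / integral < 1e-6

    def test_doubling_concentration_shifts_by_rt_ln2(self):
        a = alchemy.standard_state_correction(10.0, T, 1.0)
        b = alchemy.standard_state_correction(10.0, T, 2.0)
        assert a - b == pytest.approx(RT * math.log(2.0), abs=1e-12)

    def test_finite_for_small_k_divergent_at_zero(self):
        for k in (1e-3, 1e-1, 10.0, 1e4):
            assert np.isfinite(alchemy.standard_state_correction(k, T))
        with pytest.raises(InvalidParameterError):
            alchemy.standard_state_correction(0.0, T)

    def test_correction_grows_logarithmically_with_k(self):
        ks = [1.0, 10.0, 100.0]
        vals = [alchemy.standard_state_correction(k, T) for k in ks]
        step1 = vals[1] - vals[0]
        step2 = vals[2] - vals[1]
        assert step1 > 0 and abs(step1 - step2) < 1e-9  # 1.5 RT ln 10 each

    def test_kd_dg_round_trip(self):
        dg = -9.8
        kd = alchemy.kd_from_dg(dg, T)
        assert abs(alchemy.dg_from_kd(kd, T) - dg) < 1e-12


class TestImportanceReweight:
    def test_zero_and_constant_bias_reduce_to_mean(self, rng):
        a = rng.normal(size=200)
        assert alchemy.importance_reweight(a, np.zeros(200), T) == pytest.approx(a.mean())
        assert alchemy.importance_reweight(a, np.full(200, 3.3), T) == pytest.approx(a.mean())

    def test_harmonically_biased_gaussian_moments(self, rng):
        # target density  exp(-x^2 / 2 s^2); bias U_b = kb x^2 / 2 added during
        # sampling, so draws come from variance (1/s^2 + kb/RT)^-1
        s2, kb, n = 0.8, 1.5, 200000
        var_biased = 1.0 / (1.0 / s2 + kb / RT)
        x = rng.normal(0.0, math.sqrt(var_biased), n)
        est = alchemy.importance_reweight(x * x, 0.5 * kb * x * x, T)
        batches = np.array_split(np.arange(n), 10)
        reps = [alchemy.importance_reweight(x[b] ** 2, 0.5 * kb * x[b] ** 2, T)
                for b in batches]
        se = np.std(reps, ddof=1) / math.sqrt(len(reps))
        assert abs(est - s2) <= 3 * se

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            alchemy.importance_reweight([1.0], [1.0, 2.0], T)


def null_factory(tid, sid):
    system = mc.ParticleSystem(
        positions=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
        epsilon=np.zeros(2), r_min=np.ones(2),
        box=np.full(3, 10.0), coupling={}, temperature=T, fixed=frozenset({0}))
    return alchemy.StepSpec(system=system, step_size=0.5)


class TestRunTransformation:
    def test_null_transformation_is_exactly_zero(self):
        sched = alchemy.LambdaSchedule(4, 50, 200)
        res = alchemy.run_transformation(null_factory, sched, 1, 1, "forward", seed=1)
        assert res.cumulative_dg == 0.0
        assert np.all(res.per_window_dg == 0.0)

    def test_cumulative_equals_window_sum_and_negation(self):
        sched = alchemy.LambdaSchedule(4, 50, 200)
        fwd = alchemy.run_transformation(null_factory, sched, 1, 1, "forward", seed=1)
        assert fwd.cumulative_dg == pytest.approx(fwd.per_window_dg.sum(), abs=1e-10)
        rev = alchemy.run_transformation(null_factory, sched, 1, 1, "reverse", seed=1)
        assert rev.dg_decoupling == -rev.cumulative_dg

    def test_harmonic_decoupling_matches_partition_function_ratio(self):
        fx = synth.generate_fep_fixture("harmonic", synth.GeneratorConfig(seed=2))
        sched = alchemy.LambdaSchedule(20, 500, 5000)
        vals = [alchemy.run_transformation(fx.factory, sched, 1, 1, "forward",
                                           seed=s).dg_decoupling for s in (1, 2, 3)]
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        analytic = fx.metadata["analytic_dg_decouple"]
        assert abs(np.mean(vals) - analytic) <= 3 * max(se, 0.02)

    def test_forward_reverse_consistency(self):
        fx = synth.generate_fep_fixture("harmonic", synth.GeneratorConfig(seed=2))
        sched = alchemy.LambdaSchedule(20, 500, 5000)
        fwd = [alchemy.run_transformation(fx.factory, sched, 1, 1, "forward",
                                          seed=s).dg_decoupling for s in (4, 5, 6)]
        rev = [alchemy.run_transformation(fx.factory, sched, 1, 1, "reverse",
                                          seed=s).dg_decoupling for s in (7, 8, 9)]
        se = math.sqrt(np.var(fwd, ddof=1) / 3 + np.var(rev, ddof=1) / 3)
        assert abs(np.mean(fwd) - np.mean(rev)) <= 3 * max(se, 0.02)

    def test_bad_direction_rejected(self):
        with pytest.raises(ConfigurationError):
            alchemy.run_transformation(null_factory, alchemy.LambdaSchedule(2, 10, 50),
                                       1, 1, "sideways", seed=0)


def fake_result(tid, sid, direction, seed, dgs):
    dgs = np.asarray(dgs, dtype=float)
    return alchemy.TransformationResult(
        tid, sid, direction, seed, np.linspace(0, 1, len(dgs) + 1), dgs)


class TestCombineCycle:
    def test_bookkeeping_and_error_propagation(self):
        t1 = [fake_result(1, 1, "forward", s, [1.0, 1.0 + 0.1 * s]) for s in range(4)]
        t1 += [fake_result(1, 2, "forward", s, [0.5]) for s in range(4)]
        t2 = [fake_result(2, 1, "forward", s, [0.2]) for s in range(4)]
        t2 += [fake_result(2, 2, "forward", s, [0.1]) for s in range(4)]
        corr = 5.0
        cycle = alchemy.combine_cycle(t1, t2, corr, T)
        dg11 = np.mean([2.0 + 0.1 * s for s in range(4)])
        assert cycle.dg_transformation_1 == pytest.approx(dg11 + 0.5)
        assert cycle.dg_transformation_2 == pytest.approx(0.3)
        assert cycle.dg_bind == pytest.approx(0.3 - (dg11 + 0.5) + corr)
        se11 = np.std([2.0 + 0.1 * s for s in range(4)], ddof=1) / 2.0
        assert cycle.se == pytest.approx(se11)
        assert cycle.kd == pytest.approx(math.exp(cycle.dg_bind / RT))

    def test_reverse_results_negated_when_pooled(self):
        t1 = [fake_result(1, 1, "forward", 0, [2.0]),
              fake_result(1, 1, "reverse", 1, [-2.0]),
              fake_result(1, 2, "forward", 0, [1.0])]
        t2 = [fake_result(2, 1, "forward", 0, [0.0]),
              fake_result(2, 2, "forward", 0, [0.0])]
        cycle = alchemy.combine_cycle(t1, t2, 0.0, T)
        # the negated reverse (-(-2.0)) pools with the forward 2.0
        assert cycle.step_summary[(1, 1)][0] == pytest.approx(2.0)

    def test_missing_step_is_an_incomplete_cycle(self):
        t1 = [fake_result(1, 1, "forward", 0, [1.0])]
        t2 = [fake_result(2, 1, "forward", 0, [0.0]),
              fake_result(2, 2, "forward", 0, [0.0])]
        with pytest.raises(ConfigurationError):
            alchemy.combine_cycle(t1, t2, 0.0, T)

    def test_cycle_closure_with_no_interactions(self):
        # every decoupling dG vanishes: dG_bind reduces to the correction
        sched = alchemy.LambdaSchedule(3, 20, 100)
        results = [alchemy.run_transformation(null_factory, sched, tid, sid,
                                              "forward", seed=tid * 10 + sid)
                   for tid in (1, 2) for sid in (1, 2)]
        corr = alchemy.standard_state_correction(10.0, T)
        cycle = alchemy.combine_cycle([r for r in results if r.transformation_id == 1],
                                      [r for r in results if r.transformation_id == 2],
                                      corr, T)
        assert cycle.dg_bind == pytest.approx(corr, abs=1e-12)

    def test_printed_binding_energy_maps_into_kd_band(self):
        kd = alchemy.kd_from_dg(-9.8, T)
        assert 40e-9 <= kd <= 100e-9


class TestHysteresisReport:
    def test_identical_directions_zero_discrepancy(self):
        results = [fake_result(1, 1, "forward", 0, [1.5]),
                   fake_result(1, 1, "reverse", 1, [-1.5])]
        report = alchemy.hysteresis_report(results)
        assert report.loc[0, "discrepancy"] == pytest.approx(0.0)
        assert not report.loc[0, "flagged"]

    def test_reported_se_is_standard_error_of_replicates(self, rng):
        vals = rng.normal(3.0, 0.2, 10)
        results = [fake_result(1, 1, "forward", i, [v]) for i, v in enumerate(vals)]
        results += [fake_result(1, 1, "reverse", 20 + i, [-v])
                    for i, v in enumerate(vals)]
        report = alchemy.hysteresis_report(results)
        assert report.loc[0, "se_forward"] == pytest.approx(
            vals.std(ddof=1) / math.sqrt(10))

    def test_divergent_step_is_flagged(self, rng):
        fwd = [fake_result(1, 1, "forward", i, [3.0 + 0.01 * e])
               for i, e in enumerate(rng.normal(size=5))]
        rev = [fake_result(1, 1, "reverse", 10 + i, [-(2.0 + 0.01 * e)])
               for i, e in enumerate(rng.normal(size=5))]
        report = alchemy.hysteresis_report(fwd + rev)
        assert report.loc[0, "flagged"]

    def test_missing_direction_raises(self):
        with pytest.raises(InsufficientDataError):
            alchemy.hysteresis_report([fake_result(1, 1, "forward", 0, [1.0])])


class TestProtocolArithmetic:
    def test_stated_protocol_totals_336_ns(self):
        assert alchemy.campaign_time_ns() == pytest.approx(336.0, abs=1e-12)

    def test_scales_linearly_with_replicates(self):
        assert alchemy.campaign_time_ns(replicates=5) == pytest.approx(168.0)


class TestOccupancyConversion:
    def test_bound_fraction_dg_identity(self):
        v_unb = 10000.0
        f = 0.8
        dg = alchemy.dg_from_bound_fraction(f, v_unb, T)
        z = v_unb / (1 - f)
        assert dg == pytest.approx(-RT * math.log(z * AVOGADRO / 1e27))

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(InvalidParameterError):
            alchemy.dg_from_bound_fraction(1.0, 100.0, T)
        with pytest.raises(InvalidParameterError):
            alchemy.dg_from_bound_fraction(0.0, 100.0, T)
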