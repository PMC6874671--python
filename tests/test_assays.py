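import numpy as np
import pytest

from carasr.assays import (
    FitError,
    KineticDataset,
    PlateTrace,
    StandardCurve,
    activity_significance,
    activity_threshold,
    catalytic_efficiency,
    dsf_tm,
    fit_kinetics,
    fit_ph_profile,
    fit_standard_curve,
    half_life,
    initial_rate,
    michaelis_menten,
    ph_rate_model,
    significance_stars,
)
from carasr.simulate import (
    AssayTruth,
    dilution_series,
    simulate_condition_profiles,
    simulate_plate_assay,
)
from oracles import welch_t

CURVE = StandardCurve(slope=0.005, intercept=0.04, r_squared=1.0)


def rates_from_run(run, curve=CURVE):
    S = np.array([t.concentration for t in run.traces])
    v = np.array([initial_rate(t, curve, run.blanks[0]).rate for t in run.traces])
    return S, v


class TestStandardCurve:
    def test_exact_line(self):
        c = np.arange(0, 120, 10.0)
        fit = fit_standard_curve(c, 0.005 * c + 0.04)
        assert fit.slope == pytest.approx(0.005)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_slope_within_3se(self):
        rng = np.random.default_rng(0)
        c = np.linspace(0, 250, 12)
        a = 0.005 * c + 0.04 + rng.normal(0, 0.003, c.size)
        fit = fit_standard_curve(c, a)
        assert abs(fit.slope - 0.005) < 3 * 0.003 / np.std(c) / np.sqrt(c.size - 2) * 3

    def test_two_points_error(self):
        with pytest.raises(ValueError):
            fit_standard_curve([0, 100], [0.04, 0.54])


class TestInitialRate:
    def test_exact_linear_depletion(self):
        t = np.arange(0, 301, 30.0)
        nadph = 250.0 - 50.0 * t / 60.0
        trace = PlateTrace(t, CURVE.slope * nadph + CURVE.intercept)
        res = initial_rate(trace, CURVE)
        assert res.rate == pytest.approx(50.0, abs=1e-9)
        assert not res.low_confidence

    def test_blank_equals_trace_gives_zero(self):
        t = np.arange(0, 301, 30.0)
        a = CURVE.intercept + 0.001 * np.sin(t / 50)
        trace = PlateTrace(t, a)
        blank = PlateTrace(t, a.copy(), blank=True)
        res = initial_rate(trace, CURVE, blank)
        assert res.rate == pytest.approx(0.0, abs=1e-12)

    def test_exponential_progress_recovers_v0(self):
        # closed-form progress curve: S depletes first-order, v0 = k*S0
        t = np.arange(0, 601, 15.0)
        k = 0.002  # per second
        S0 = 200.0
        nadph = 50.0 + S0 * np.exp(-k * t)  # consumption tracks substrate
        v0_true = k * S0 * 60.0  # µM/min at t=0
        trace = PlateTrace(t, CURVE.slope * nadph + CURVE.intercept)
        res = initial_rate(trace, CURVE)
        assert abs(res.rate - v0_true) / v0_true < 0.05

    def test_garbage_trace_flags_low_confidence(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 301, 30.0)
        trace = PlateTrace(t, rng.normal(0.5, 0.2, t.size))
        res = initial_rate(trace, CURVE)
        assert res.low_confidence


class TestKinetics:
    def test_noiseless_recovery(self):
        truth = AssayTruth(kcat=340.0, KM=76.8, enzyme_uM=0.05, noise_sd=0.0)
        run = simulate_plate_assay(truth, dilution_series(800.0), seed=1)
        S, v = rates_from_run(run)
        fit = fit_kinetics(KineticDataset(S, v, enzyme_uM=0.05))
        assert abs(fit.kcat - 340.0) / 340.0 < 0.001
        assert abs(fit.KM - 76.8) / 76.8 < 0.001
        assert fit.efficiency == pytest.approx(fit.kcat / fit.KM, abs=1e-9)

    def test_half_max_at_km_identity(self):
        truth = AssayTruth(kcat=340.0, KM=76.8, enzyme_uM=0.05)
        run = simulate_plate_assay(truth, dilution_series(800.0), seed=1)
        S, v = rates_from_run(run)
        fit = fit_kinetics(KineticDataset(S, v, enzyme_uM=0.05))
        assert michaelis_menten(fit.KM, fit.Vmax, fit.KM) == pytest.approx(fit.Vmax / 2)

    def test_substrate_inhibition_trimming(self):
        truth = AssayTruth(kcat=300.0, KM=50.0, Ki=2000.0, enzyme_uM=0.05)
        run = simulate_plate_assay(truth, dilution_series(2000.0), seed=2)
        S, v = rates_from_run(run)
        fit = fit_kinetics(KineticDataset(S, v, enzyme_uM=0.05), trim_inhibited=True)
        assert fit.trimmed and max(fit.trimmed) == pytest.approx(2000.0)
        assert abs(fit.KM - 50.0) / 50.0 < 0.10

    def test_explicit_substrate_inhibition_model(self):
        truth = AssayTruth(kcat=300.0, KM=50.0, Ki=400.0, enzyme_uM=0.05)
        run = simulate_plate_assay(truth, dilution_series(2000.0, n=10), seed=2)
        S, v = rates_from_run(run)
        fit = fit_kinetics(KineticDataset(S, v, enzyme_uM=0.05), model="MM+SI")
        assert fit.Ki == pytest.approx(400.0, rel=0.02)
        assert fit.KM == pytest.approx(50.0, rel=0.02)

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_kinetics(KineticDataset([1, 2, 3, 4], [1, 2, 2, 2], enzyme_uM=1.0))

    def test_all_zero_rates(self):
        with pytest.raises(ValueError, match="zero"):
            fit_kinetics(KineticDataset([1, 2, 3, 4, 5], [0, 0, 0, 0, 0], enzyme_uM=1.0))

    @pytest.mark.parametrize(
        "kcat,KM,expected",
        [(340.0, 76.8, 4.4), (203.5, 0.9, 226.1), (1.0, 1.0, 1.0)],
    )
    def test_catalytic_efficiency(self, kcat, KM, expected):
        assert round(catalytic_efficiency(kcat, KM), 1) == pytest.approx(expected)


class TestPHProfile:
    def test_fifty_percent_identity_at_k1(self):
        # at h = K1 with well-separated pKs the bell model sits at 50%
        v = ph_rate_model(5.0, 100.0, 5.0, 11.0)
        assert v == pytest.approx(100.0 / (2.0 + 1e-6), abs=1e-9)
        assert round(float(v)) == 50

    def test_noiseless_recovery(self):
        df = simulate_condition_profiles("pH", np.arange(3, 11.1, 0.5),
                                         pK1=5.0, pK2=11.0)
        fit = fit_ph_profile(df["condition"], df["value"])
        assert fit.pK1 == pytest.approx(5.0, abs=0.01)
        assert fit.pK2 == pytest.approx(11.0, abs=0.01)

    def test_rescaling_invariance(self):
        df = simulate_condition_profiles("pH", np.arange(3, 11.1, 0.5),
                                         pK1=5.12, pK2=11.11)
        f1 = fit_ph_profile(df["condition"], df["value"])
        f2 = fit_ph_profile(df["condition"], df["value"] * 7.3)
        assert f2.pK1 == pytest.approx(f1.pK1, abs=1e-6)
        assert f2.V100 == pytest.approx(7.3 * f1.V100, rel=1e-6)

    def test_flat_profile_warns(self):
        fit = fit_ph_profile(np.arange(3, 11.1, 1.0), np.full(9, 80.0))
        assert fit.warnings and fit.pK1 == 3.0 and fit.pK2 == 11.0

    def test_one_sided_profile(self):
        pH = np.arange(6.0, 11.1, 0.5)
        act = ph_rate_model(pH, 100.0, 2.0, 9.0)  # acidic flank out of range
        fit = fit_ph_profile(pH, act)
        assert any("acidic" in w for w in fit.warnings)
        assert fit.pK1 == pytest.approx(6.0)


class TestStability:
    def test_midpoint_interpolation(self):
        res = activity_threshold([62, 64, 66], [100, 100, 0])
        assert res.value == pytest.approx(65.0)

    def test_unbounded_marker(self):
        res = activity_threshold([30, 50, 70], [100, 90, 80])
        assert res.value is None and res.marker == ">70"

    def test_logistic_recovery(self):
        df = simulate_condition_profiles("temperature-A50",
                                         np.arange(30, 72, 2.0), midpoint=67.5)
        res = activity_threshold(df["condition"], df["value"])
        assert res.value == pytest.approx(67.5, abs=0.3)

    def test_reorder_invariance(self):
        x = np.array([30.0, 50, 60, 70, 40])
        y = np.array([100.0, 90, 45, 5, 98])
        r1 = activity_threshold(x, y)
        order = [3, 0, 4, 1, 2]
        r2 = activity_threshold(x[order], y[order])
        assert r1.value == pytest.approx(r2.value)

    def test_half_life_exponential(self):
        t = np.arange(0, 241, 24.0)
        a = 100.0 * np.exp(-np.log(2) / 41.0 * t)
        res = half_life(t, a)
        assert res.value == pytest.approx(41.0, abs=1e-6)

    def test_half_life_interpolation_bracket(self):
        res = half_life([0, 100, 200], [100, 60, 40], method="interpolation")
        assert res.value == pytest.approx(150.0)

    def test_half_life_noisy_within_15pct(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 500, 10)
        a = 100.0 * np.exp(-np.log(2) / 200.0 * t) + rng.normal(0, 5, 10)
        a[0] = 100.0
        res = half_life(t, a)
        assert abs(res.value - 200.0) / 200.0 < 0.15

    def test_no_decay_error(self):
        with pytest.raises(FitError, match="decay"):
            half_life([0, 10, 20], [100, 100, 110])


class TestDSF:
    def test_clean_sigmoid(self):
        df = simulate_condition_profiles("melt", np.arange(25, 99, 0.25),
                                         midpoint=67.5)
        res = dsf_tm(df["condition"], df["value"])
        assert res.value == pytest.approx(67.5, abs=0.1)

    def test_noisy_sigmoid_within_half_degree(self):
        df = simulate_condition_profiles("melt", np.arange(25, 99, 0.25),
                                         midpoint=67.5, noise_sd=10.0, seed=4)
        res = dsf_tm(df["condition"], df["value"])
        assert res.value == pytest.approx(67.5, abs=0.5)

    def test_linear_curve_errors(self):
        T = np.arange(25, 99, 1.0)
        with pytest.raises(FitError, match="interior"):
            dsf_tm(T, 2.0 * T + 5.0)


class TestSignificance:
    def test_identical_groups(self):
        res = activity_significance([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0) and res.stars == "ns"

    def test_zero_variance_equal(self):
        res = activity_significance([5, 5, 5], [5, 5, 5])
        assert res.p == 1.0 and res.stars == "ns"

    @pytest.mark.parametrize(
        "p,stars",
        [(0.5, "ns"), (5e-4, "*"), (5e-5, "**"), (5e-6, "***"), (5e-7, "****"),
         (1e-3, "*"), (1e-6, "****")],
    )
    def test_banding(self, p, stars):
        assert significance_stars(p) == stars

    def test_t_statistic_matches_textbook_formula(self):
        a, b = [1.0, 2.0, 3.0], [101.0, 102.0, 103.5]
        res = activity_significance(a, b)
        assert res.t == pytest.approx(welch_t(a, b), abs=1e-12)
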