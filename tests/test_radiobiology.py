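"""LQ dose-rate kinetics, protraction factor, BED/OER/SF/TCP stack."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq, minimize_scalar

from cscrit import (
    DoseSchedule,
    EffectiveTimes,
    LQParams,
    OERParams,
    RepopulationParams,
    TumorBurden,
    bed,
    dose_rate,
    dose_response_table,
    oer,
    peak_dose_rate,
    protraction_lambda,
    relative_effectiveness,
    rit_rate,
    surviving_fraction_integrated,
    surviving_fraction_point,
    tcp,
    total_dose,
)
from cscrit.radiobiology import tcp_saturation_dose

from conftest import RADIONUCLIDES

LN2 = math.log(2)


def lambda_quadrature_oracle(times: EffectiveTimes, T_mu: float) -> float:
    """Protraction factor from the LQ dose-protraction double integral.

    RE - 1 = (2/(D*(a/b))) * Int r(t) Int r(t') e^{-mu (t-t')} dt' dt must
    equal r0*Lambda/(ln2*(a/b)); solve for Lambda with r0 = 1.  The inner
    integral is done analytically (plain exponentials), the outer numerically.
    """
    le, lu, mu = LN2 / times.Te, LN2 / times.Teu, LN2 / T_mu

    def r(t):
        return np.exp(-le * t) - np.exp(-lu * t)

    def inner(t):
        return (np.exp(-le * t) - np.exp(-mu * t)) / (mu - le) - (
            np.exp(-lu * t) - np.exp(-mu * t)
        ) / (mu - lu)

    I, _ = quad(lambda t: r(t) * inner(t), 0, 60 * times.Te, limit=400)
    D = times.tau_e / LN2  # total dose at r0 = 1
    return 2.0 * I * LN2 / D


class TestDoseRate:
    def test_zero_at_time_zero(self, schedule):
        assert dose_rate(0.0, schedule("90Y")) == 0.0

    def test_negative_time_rejected(self, schedule):
        with pytest.raises(ValueError, match="t >= 0"):
            dose_rate(-0.1, schedule("90Y"))

    def test_printed_peak_values(self, schedule):
        # maxima of the bi-exponential curve at r0 = 2 Gy/day
        assert dose_rate(2.424, schedule("90Y")) == pytest.approx(0.2552, rel=5e-4)
        _, r_peak = peak_dose_rate(schedule("131I"))
        assert r_peak == pytest.approx(0.4362, rel=5e-4)

    def test_nonnegative_everywhere(self, schedule):
        t = np.linspace(0, 100, 2000)
        for name in RADIONUCLIDES:
            assert np.all(dose_rate(t, schedule(name)) >= 0)

    @pytest.mark.parametrize("name", RADIONUCLIDES)
    def test_peak_matches_numeric_maximizer(self, schedule, name):
        # oracle: stationary point of the rate curve, located by root-finding
        # the derivative of the bi-exponential directly
        sched = schedule(name)
        t_peak, r_peak = peak_dose_rate(sched)
        Te, Teu = sched.times.Te, sched.times.Teu

        def drdt(t):
            return -(LN2 / Te) * 2.0 ** (-t / Te) + (LN2 / Teu) * 2.0 ** (-t / Teu)

        t_oracle = brentq(drdt, 1e-6, 20 * Te, xtol=1e-12)
        assert t_peak == pytest.approx(t_oracle, abs=1e-8)
        # and the coarse numeric maximizer never beats the closed form
        res = minimize_scalar(
            lambda t: -dose_rate(t, sched), bounds=(0.0, 20 * Te), method="bounded"
        )
        assert r_peak >= -res.fun - 1e-12

    def test_zero_rate_convention(self, registry):
        from cscrit import effective_times

        sched = DoseSchedule(r0=0.0, times=effective_times(registry["90Y"]))
        assert peak_dose_rate(sched) == (0.0, 0.0)


class TestTotalDose:
    def test_zero_rate(self, schedule):
        sched = DoseSchedule(r0=0.0, times=schedule("90Y").times)
        assert total_dose(sched) == 0.0

    def test_ac225_value(self, schedule):
        # D = r0 * tau_e / ln2 with tau_e = 4.8718 - 2.4242 days
        assert total_dose(schedule("225Ac")) == pytest.approx(7.063, abs=1e-3)

    @pytest.mark.parametrize("name", RADIONUCLIDES)
    @pytest.mark.parametrize("r0", [0.1, 2.0, 10.0])
    def test_matches_quadrature(self, schedule, name, r0):
        sched = DoseSchedule.for_radionuclide(name, r0)
        numeric, _ = quad(lambda t: dose_rate(t, sched), 0, 50 * sched.times.Te, limit=200)
        assert total_dose(sched) == pytest.approx(numeric, rel=1e-6)


class TestProtractionLambda:
    @pytest.mark.parametrize(
        "name, expected",
        [("225Ac", 0.0207922), ("131I", 0.0180803)],  # frozen from the oracle
    )
    def test_oracle_values(self, schedule, name, expected):
        lam = protraction_lambda(0.062, schedule(name).times)
        assert lam == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("name", RADIONUCLIDES)
    def test_closed_form_matches_double_integral(self, schedule, name):
        times = schedule(name).times
        lam = protraction_lambda(0.062, times)
        assert lam == pytest.approx(lambda_quadrature_oracle(times, 0.062), rel=1e-5)

    def test_instant_repair_limit(self, schedule):
        # T_mu -> 0: repair outruns delivery, no quadratic protraction
        assert protraction_lambda(1e-5, schedule("225Ac").times) < 1e-4

    def test_pole_rejected(self, schedule):
        times = schedule("90Y").times
        with pytest.raises(ValueError, match="singular"):
            protraction_lambda(times.Te, times)


class TestRelativeEffectiveness:
    def test_unity_at_zero_rate(self, schedule, lq):
        sched = DoseSchedule(r0=0.0, times=schedule("225Ac").times)
        assert relative_effectiveness(sched, lq) == 1.0

    def test_composition_from_lambda(self, schedule, lq):
        sched = schedule("225Ac")
        lam = protraction_lambda(lq.T_mu, sched.times)
        expected = 1.0 + 2.0 * lam / (LN2 * (0.46 / 0.30))
        assert relative_effectiveness(sched, lq) == pytest.approx(expected)

    def test_oxygenation_pulls_re_toward_one(self, schedule, lq):
        sched = schedule("225Ac")
        assert 1.0 < relative_effectiveness(sched, lq, 2.0) < relative_effectiveness(sched, lq, 1.0)

    def test_monotone_in_rate(self, lq):
        times = DoseSchedule.for_radionuclide("131I", 1.0).times
        res = [relative_effectiveness(DoseSchedule(r, times), lq) for r in (0.5, 1, 2, 4)]
        assert res == sorted(res)

    def test_plain_convention_exposed(self, schedule, lq):
        sched = schedule("225Ac")
        plain = relative_effectiveness(sched, lq, re_convention="plain")
        lam = protraction_lambda(lq.T_mu, sched.times)
        assert plain == pytest.approx(1.0 + 2.0 * lam / LN2)


class TestOER:
    def test_anoxic_limit_is_max(self, oer_params):
        assert oer(0.0, oer_params) == 3.0

    def test_half_effect_at_km(self, oer_params):
        # OER(K_m) = 2*OER_max/(OER_max + 1)
        assert oer(3.28, oer_params) == pytest.approx(1.5, abs=1e-15)

    def test_normoxic_value(self, oer_params):
        assert oer(40.0, oer_params) == pytest.approx(3 * 43.28 / 123.28, rel=1e-12)

    def test_strictly_decreasing(self, oer_params):
        P = np.linspace(0, 100, 500)
        assert np.all(np.diff(oer(P, oer_params)) < 0)

    def test_negative_pressure_rejected(self, oer_params):
        with pytest.raises(ValueError, match="non-negative"):
            oer(-1.0, oer_params)


class TestBED:
    def test_zero_rate_zero_bed(self, schedule, lq):
        sched = DoseSchedule(r0=0.0, times=schedule("90Y").times)
        assert bed(sched, lq) == 0.0

    def test_oxygen_free_identity(self, schedule, lq):
        sched = schedule("225Ac")
        assert bed(sched, lq) == pytest.approx(
            total_dose(sched) * relative_effectiveness(sched, lq)
        )
        assert rit_rate(sched, lq) == pytest.approx(lq.alpha_c * bed(sched, lq))

    def test_hypoxia_scaling(self, schedule, lq, oer_params):
        sched = schedule("225Ac")
        o = oer(40.0, oer_params)
        assert bed(sched, lq, o) == pytest.approx(
            total_dose(sched) / o * relative_effectiveness(sched, lq, o)
        )

    def test_repopulation_branches(self, schedule, lq):
        sched = schedule("225Ac")
        base = bed(sched, lq)
        off = bed(sched, lq, repop=RepopulationParams(T=5.0, T_k=10.0, T_d=3.0))
        on = bed(sched, lq, repop=RepopulationParams(T=15.0, T_k=10.0, T_d=3.0))
        assert off == base
        assert on == pytest.approx(base - LN2 * 5.0 / (lq.alpha_c * 3.0))
        with pytest.raises(ZeroDivisionError):
            bed(sched, lq, repop=RepopulationParams(T=15.0, T_k=10.0, T_d=0.0))

    def test_rit_rate_orderings(self, lq):
        rates = {
            n: rit_rate(DoseSchedule.for_radionuclide(n, 2.0), lq) for n in RADIONUCLIDES
        }
        assert rates["225Ac"] > rates["90Y"]  # longer effective time, larger dose
        increasing = [rit_rate(DoseSchedule.for_radionuclide("90Y", r), lq) for r in (1, 2, 4)]
        assert increasing == sorted(increasing)


class TestSurvivingFraction:
    def test_unity_without_dose(self, schedule, lq):
        sched = DoseSchedule(r0=0.0, times=schedule("90Y").times)
        assert surviving_fraction_point(sched, lq, 40.0) == 1.0

    def test_oxygen_sensitizes_all_radionuclides(self, schedule, lq):
        for name in RADIONUCLIDES:
            sched = schedule(name)
            assert surviving_fraction_point(sched, lq, 40.0) < surviving_fraction_point(
                sched, lq, 1.0
            )

    def test_ac225_most_effective(self, schedule, lq):
        sfs = {n: surviving_fraction_point(schedule(n), lq, 40.0) for n in RADIONUCLIDES}
        assert min(sfs, key=sfs.get) == "225Ac"

    def test_point_mass_collapse(self, schedule, lq):
        sched = schedule("177Lu")
        point = surviving_fraction_point(sched, lq, 11.0)
        assert surviving_fraction_integrated(sched, lq, [11.0], [1.0]) == point

    def test_uniform_density_bounded_by_extremes(self, schedule, lq):
        sched = schedule("225Ac")
        P = np.linspace(1.0, 40.0, 400)
        w = np.full(P.size, 1.0 / P.size)
        sf = surviving_fraction_integrated(sched, lq, P, w)
        assert surviving_fraction_point(sched, lq, 40.0) < sf < surviving_fraction_point(sched, lq, 1.0)

    def test_quadrature_matches_monte_carlo(self, schedule, lq):
        sched = schedule("225Ac")
        rng = np.random.default_rng(7)
        samples = rng.uniform(1.0, 40.0, 50_000)
        mc = np.mean([math.exp(-rit_rate(sched, lq, o)) for o in oer(samples)])
        P = np.linspace(1.0, 40.0, 2000)
        w = np.full(P.size, 1.0 / P.size)
        sf = surviving_fraction_integrated(sched, lq, P, w)
        assert sf == pytest.approx(mc, abs=2e-3)

    def test_unnormalized_density_rejected(self, schedule, lq):
        with pytest.raises(ValueError, match="sum to 1"):
            surviving_fraction_integrated(schedule("90Y"), lq, [1.0, 2.0], [0.7, 0.6])


class TestTCP:
    def test_empty_burden_controls(self, schedule, lq):
        assert tcp(schedule("90Y"), lq, TumorBurden(0.0, 1e5), P_o=40.0) == 1.0

    def test_reference_burden_product(self):
        burden = TumorBurden(varsigma=0.004576, V=1e5)
        assert burden.N == pytest.approx(457.6)

    def test_composition_is_exact(self, schedule, lq):
        sched = schedule("225Ac")
        burden = TumorBurden(0.004576, 1e5)
        sf = surviving_fraction_point(sched, lq, 40.0)
        assert tcp(sched, lq, burden, P_o=40.0) == math.exp(-burden.N * sf)

    def test_high_dose_limit(self, lq):
        sched = DoseSchedule.for_radionuclide("225Ac", 50.0)
        assert tcp(sched, lq, TumorBurden(0.004576, 1e5), P_o=40.0) == pytest.approx(1.0, abs=1e-6)


class TestDoseResponseTable:
    def test_single_cell_matches_scalar_ops(self, lq):
        table = dose_response_table(["225Ac"], [2.0], lq, burden=TumorBurden(0.004576, 1e5))
        assert len(table) == 1
        row = table.iloc[0]
        sched = DoseSchedule.for_radionuclide("225Ac", 2.0)
        assert row["D_gy"] == total_dose(sched)
        assert row["BED_gy"] == pytest.approx(bed(sched, lq))
        assert row["SF"] == pytest.approx(math.exp(-rit_rate(sched, lq)))

    def test_bed_hierarchy(self, lq):
        table = dose_response_table(RADIONUCLIDES, [2.0], lq).set_index("radionuclide")
        order = list(table["BED_gy"].sort_values(ascending=False).index)
        assert order == ["225Ac", "177Lu", "131I", "90Y"]

    def test_tcp_monotone_along_grid(self, lq):
        table = dose_response_table(
            RADIONUCLIDES, np.linspace(0.1, 5, 20), lq, burden=TumorBurden(0.004576, 1e5)
        )
        for name in RADIONUCLIDES:
            tcps = table[table["radionuclide"] == name]["TCP"].to_numpy()
            assert np.all(np.diff(tcps) >= -1e-12)

    def test_saturation_dose_reported(self, lq):
        table = dose_response_table(
            ["225Ac"], np.linspace(0.1, 8, 80), lq, burden=TumorBurden(0.004576, 1e5)
        )
        r_sat = tcp_saturation_dose(table, "225Ac")
        assert r_sat is not None
        sub = table.set_index("r0_gy_per_day")
        assert sub.loc[r_sat, "TCP"] >= 1 - 1e-3

    def test_empty_grid_rejected(self, lq):
        with pytest.raises(ValueError, match="non-empty"):
            dose_response_table(["90Y"], [], lq)

    def test_unit_roundtrip_invariance(self, lq):
        day = dose_response_table(["131I"], [2.0], lq, unit="Gy/day")
        year = dose_response_table(["131I"], [2.0 * 365.0], lq, unit="Gy/year")
        assert day["BED_gy"].iloc[0] == pytest.approx(year["BED_gy"].iloc[0], rel=1e-12)
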