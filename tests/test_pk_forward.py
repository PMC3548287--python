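"""Forward-model unit and property tests: dose-to-mass stoichiometry,
exact exponential updates, mass conservation, linearity, void behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dehprecon.constants import METABOLITES, MW_DEHP, MW_METABOLITE
from dehprecon.pk_forward import (
    DoseEvent,
    MetaboliteSpec,
    SimConfig,
    SimulationState,
    Subject,
    VoidRecord,
    cumulative_molar_fraction,
    default_specs,
    dose_input_mass,
    expand_spread,
    simulate,
    step,
)

# independently hand-computed formula masses (C 12.011, H 1.008, O 15.999)
HAND_MW = {"DEHP": 390.564, "MEHP": 278.348, "MEHHP": 294.347, "MEOHP": 292.331, "MECPP": 308.330}


def test_molecular_weights_match_hand_computed_formula_masses():
    assert MW_DEHP == pytest.approx(HAND_MW["DEHP"], abs=1e-9)
    for name in METABOLITES:
        assert MW_METABOLITE[name] == pytest.approx(HAND_MW[name], abs=1e-9)


class TestDoseInputMass:
    def test_zero_dose_gives_zero_mass(self, subject70, specs4):
        assert dose_input_mass(0.0, subject70, specs4[0]) == 0.0

    def test_hand_arithmetic_oracle_mehp(self, subject70, specs4):
        # 10 µg/kg × 70 kg = 700 µg DEHP = 700/390.564 µmol;
        # ×0.059 molar fraction ×278.348 g/mol → 29.434 µg MEHP
        expected = 0.059 * (700.0 / 390.564) * 278.348
        assert expected == pytest.approx(29.434, abs=5e-4)  # arithmetic cross-check
        assert dose_input_mass(10.0, subject70, specs4[0]) == pytest.approx(expected, rel=1e-9)

    def test_linearity_in_dose_for_every_metabolite(self, subject70, specs4):
        for spec in specs4:
            assert dose_input_mass(14.0, subject70, spec) == pytest.approx(
                2.0 * dose_input_mass(7.0, subject70, spec), rel=1e-12
            )

    def test_negative_dose_rejected(self, subject70, specs4):
        with pytest.raises(ValueError):
            dose_input_mass(-1.0, subject70, specs4[0])


class TestStep:
    def test_zero_state_stays_zero(self, specs4):
        s = SimulationState.initial(4)
        s2 = step(s, 15.0, np.zeros(4), specs4)
        assert np.all(s2.P == 0) and np.all(s2.B == 0)

    def test_single_input_all_mass_reaches_bladder_eventually(self, specs4):
        s = SimulationState.initial(4)
        s = step(s, 15.0, np.array([10.0, 20.0, 5.0, 8.0]), specs4)
        for _ in range(4 * 24 * 30):  # 30 days
            s = step(s, 15.0, np.zeros(4), specs4)
        assert np.allclose(s.B, [10, 20, 5, 8], rtol=1e-6)

    def test_discrete_bladder_matches_closed_form_instant_appearance(self, subject70):
        spec = default_specs(k_a=math.inf)[0]
        km = spec.k_m
        s = SimulationState.initial(1)
        s = step(s, 0.0, np.array([100.0]), (spec,))
        t_hr = 0.0
        for _ in range(40):
            s = step(s, 15.0, np.zeros(1), (spec,))
            t_hr += 0.25
            assert s.B[0] == pytest.approx(100.0 * (1 - math.exp(-km * t_hr)), rel=1e-12)

    def test_total_mass_conserved_through_steps(self, specs4):
        rng = np.random.default_rng(7)
        s = SimulationState.initial(4)
        total_in = np.zeros(4)
        for _ in range(50):
            inp = rng.exponential(5.0, 4)
            total_in += inp
            s = step(s, float(rng.choice([15.0, 30.0, 60.0])), inp, specs4)
        assert np.allclose(s.total, total_in, rtol=1e-12)


class TestSimulate:
    def test_no_dose_events_give_zero_concentrations(self, subject70, specs4):
        pred = simulate(subject70, [], [(60.0, 0.2), (240.0, 0.3)], specs4)
        assert all(np.all(p.conc == 0) for p in pred)

    def test_terminal_phase_half_life_is_five_hours(self, subject70, specs4):
        voids = [(60.0 * h, 0.1) for h in range(1, 49)]
        pred = simulate(subject70, [DoseEvent(time=0.0, dose=10.0)], voids, specs4)
        t = np.array([p.time / 60.0 for p in pred])
        m = np.array([p.mass[0] for p in pred])  # MEHP
        sel = (t >= 6) & (t <= 24)
        slope = np.polyfit(t[sel], np.log(m[sel]), 1)[0]
        assert math.log(2.0) / -slope == pytest.approx(5.0, rel=0.02)

    def test_total_excreted_mass_independent_of_void_schedule(self, subject70, specs4):
        doses = [DoseEvent(time=120.0, dose=8.0), DoseEvent(time=900.0, dose=3.0)]
        dense = [(240.0 * k, 0.2) for k in range(1, 19)]
        sparse = [(4320.0, 1.5)]
        tot_dense = sum(p.mass for p in simulate(subject70, doses, dense, specs4))
        tot_sparse = sum(p.mass for p in simulate(subject70, doses, sparse, specs4))
        assert np.allclose(tot_dense, tot_sparse, rtol=1e-9)

    def test_concentration_equals_mass_over_volume(self, subject70, specs4):
        pred = simulate(subject70, [DoseEvent(time=0.0, dose=5.0)], [(300.0, 0.37)], specs4)
        assert np.allclose(pred[0].conc, pred[0].mass / 0.37, rtol=0, atol=0)

    def test_void_idempotence_second_void_at_same_time_is_zero(self, subject70, specs4):
        pred = simulate(
            subject70, [DoseEvent(time=0.0, dose=5.0)], [(300.0, 0.3), (300.0, 0.1)], specs4
        )
        assert np.all(pred[1].conc == 0)

    def test_unsorted_voids_rejected(self, subject70, specs4):
        with pytest.raises(ValueError):
            simulate(subject70, [], [(300.0, 0.3), (200.0, 0.3)], specs4)

    def test_nonpositive_volume_rejected(self, subject70, specs4):
        with pytest.raises(ValueError):
            simulate(subject70, [], [(300.0, 0.0)], specs4)

    def test_bladder_accumulation_between_voids_matches_closed_form(self, subject70):
        # with instantaneous appearance, mass in void 2 is I(e^{-k t1} - e^{-k t2})
        spec = default_specs(k_a=math.inf)[0]
        I = dose_input_mass(10.0, subject70, spec)
        km = spec.k_m
        pred = simulate(subject70, [DoseEvent(time=0.0, dose=10.0)], [(180.0, 0.2), (420.0, 0.2)], (spec,))
        assert pred[1].mass[0] == pytest.approx(
            I * (math.exp(-km * 3.0) - math.exp(-km * 7.0)), rel=1e-12
        )

    def test_second_phase_releases_delayed_fraction(self, subject70):
        spec = default_specs(second_phase=True, g_m=0.2, tau_m=24.0)[0]
        pred = simulate(subject70, [DoseEvent(time=0.0, dose=10.0)], [(20160.0, 1.0)], (spec,))
        base = dose_input_mass(10.0, subject70, spec)
        assert pred[0].mass[0] == pytest.approx(1.2 * base, rel=1e-4)


class TestCumulativeMolarFraction:
    def test_mehp_reaches_5_9_percent_at_72_hours(self, subject70, specs4):
        frac = cumulative_molar_fraction(subject70, DoseEvent(time=0.0, dose=10.0), specs4[0], 72.0)
        assert frac == pytest.approx(0.059, abs=1e-3)

    def test_short_horizon_fraction_vanishes(self, subject70, specs4):
        frac = cumulative_molar_fraction(subject70, DoseEvent(time=0.0, dose=10.0), specs4[0], 0.01)
        assert frac < 1e-4

    def test_finite_horizon_closed_form_instant_appearance(self, subject70):
        spec = default_specs(k_a=math.inf)[0]
        for T in (6.0, 24.0, 48.0):
            frac = cumulative_molar_fraction(subject70, DoseEvent(time=0.0, dose=5.0), spec, T)
            assert frac == pytest.approx(spec.f_m * (1 - math.exp(-spec.k_m * T)), rel=1e-10)

    def test_zero_dose_is_domain_error(self, subject70, specs4):
        with pytest.raises(ValueError):
            cumulative_molar_fraction(
                subject70, DoseEvent(time=0.0, dose=1.0), specs4[0], 0.0
            )


class TestSpecValidation:
    def test_molar_fractions_sum_below_one(self, specs4):
        assert sum(s.f_m for s in specs4) < 1.0

    @pytest.mark.parametrize(
        "kw",
        [
            dict(f_m=0.0),
            dict(f_m=1.5),
            dict(k_m=-0.1),
            dict(mw=0.0),
            dict(k_a=0.01),  # slower than k_m: terminal phase would flip
            dict(g_m=1.0),
            dict(tau_m=-1.0),
        ],
    )
    def test_invalid_constants_rejected(self, kw):
        base = dict(name="MEHP", f_m=0.059, k_m=math.log(2) / 5, mw=278.348)
        base.update(kw)
        with pytest.raises(ValueError):
            MetaboliteSpec(**base)


def test_expand_spread_two_hours_gives_eight_equal_subboluses():
    subs = expand_spread(DoseEvent(time=600.0, dose=8.0, spread=120.0))
    assert len(subs) == 8
    assert all(s.dose == pytest.approx(1.0) for s in subs)
    assert sum(s.dose for s in subs) == pytest.approx(8.0, rel=1e-12)
    # impulse train centred on the nominal time, half before and half after
    assert np.mean([s.time for s in subs]) == pytest.approx(600.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    dose=st.floats(0.5, 60.0),
    t_event=st.floats(0.0, 1440.0),
    seed=st.integers(0, 10_000),
)
def test_mass_conservation_and_linearity_properties(dose, t_event, seed):
    """For random bolus/void schedules: total excreted mass never exceeds the
    input, equals it in the long-collection limit, and predictions are
    homogeneous of degree 1 in the dose."""
    subject = Subject(id="P", sex="M")
    specs = default_specs()
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(t_event + 1.0, t_event + 4000.0, 6))
    voids = [(float(t), float(v)) for t, v in zip(times, rng.uniform(0.05, 0.6, 6))]
    voids.append((t_event + 20000.0, 1.0))  # collect-all terminal void
    ev = [DoseEvent(time=t_event, dose=dose)]
    pred = simulate(subject, ev, voids, specs)
    total = sum(p.mass for p in pred)
    expected = np.array([dose_input_mass(dose, subject, s) for s in specs])
    assert np.allclose(total, expected, rtol=1e-6)
    pred2 = simulate(subject, [DoseEvent(time=t_event, dose=2 * dose)], voids, specs)
    for p, q in zip(pred, pred2):
        assert np.allclose(2 * p.conc, q.conc, rtol=1e-12, atol=1e-12)
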