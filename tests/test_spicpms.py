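"""Unit and property tests for the spICP-MS trace-processing chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanopartchar import spicpms as sp
from conftest import iterative_trim_oracle


def make_trace(readings, dwell=0.003, **kw):
    return sp.TimeTrace(readings=np.asarray(readings, dtype=float), dwell_time=dwell, **kw)


class TestDetectEvents:
    def test_constant_background_yields_no_events(self):
        es = sp.detect_events(make_trace(np.full(1000, 10.0)))
        assert es.n_events == 0
        assert es.background_mean == 10.0
        assert es.background_sd == 0.0
        assert es.threshold == 10.0

    def test_isolated_spikes_match_trim_oracle(self, rng):
        readings = rng.poisson(10.0, 1000).astype(float)
        spike_idx = rng.choice(1000, 10, replace=False)
        # keep spikes isolated so each is its own event
        spike_idx = spike_idx[np.argsort(spike_idx)]
        readings[spike_idx] = 1000.0
        es = sp.detect_events(make_trace(readings))
        mu, sd, thr, outliers = iterative_trim_oracle(readings)
        assert es.background_mean == pytest.approx(mu)
        assert es.background_sd == pytest.approx(sd)
        assert es.threshold == pytest.approx(thr)
        # all 10 spikes recovered (some Poisson readings may also exceed 5 sigma)
        assert set(spike_idx).issubset(set(outliers))
        assert es.n_events == len(_runs(outliers))

    @pytest.mark.parametrize(
        "policy,expected_n,expected_net",
        [("merge", 1, 1180.0), ("drop", 0, None), ("keep", 2, 590.0)],
    )
    def test_split_plume_merge_policy(self, policy, expected_n, expected_net):
        readings = np.full(1000, 10.0)
        readings[500:502] = 600.0
        es = sp.detect_events(make_trace(readings), merge_policy=policy)
        assert es.n_events == expected_n
        if expected_n:
            assert es.events[0] == pytest.approx(expected_net, rel=1e-3)

    def test_oracle_agreement_random_traces(self, rng):
        """Event detection equals the literal pure-Python trim oracle."""
        for _ in range(20):
            n = int(rng.integers(200, 2000))
            readings = rng.poisson(rng.uniform(1, 30), n).astype(float)
            n_spikes = int(rng.integers(0, 10))
            if n_spikes:
                readings[rng.choice(n, n_spikes, replace=False)] += rng.uniform(100, 5000, n_spikes)
            es = sp.detect_events(make_trace(readings), merge_policy="keep")
            mu, sd, thr, outliers = iterative_trim_oracle(readings)
            assert es.background_mean == pytest.approx(mu)
            assert es.threshold == pytest.approx(thr)
            assert es.n_events == len(outliers)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            make_trace([])

    def test_every_event_exceeds_threshold_net(self, rng):
        readings = rng.poisson(5.0, 5000).astype(float)
        readings[rng.choice(5000, 20, replace=False)] += 300.0
        es = sp.detect_events(make_trace(readings), merge_policy="keep")
        assert np.all(es.events + es.background_mean > es.threshold)


def _runs(sorted_indices):
    runs, cur = [], []
    for i in sorted_indices:
        if cur and i == cur[-1] + 1:
            cur.append(i)
        else:
            cur = [i]
            runs.append(cur)
    return runs


class TestCalibration:
    def test_exact_line(self):
        cal = sp.fit_ionic_calibration([(0, 0), (1, 10), (2, 20)])
        assert cal.slope == pytest.approx(10.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)
        assert cal.r_squared == pytest.approx(1.0)

    def test_noisy_line_recovers_slope(self, rng):
        conc = np.arange(6.0)
        inten = 10.0 * conc + rng.normal(0, 0.1, 6)
        cal = sp.fit_ionic_calibration(list(zip(conc, inten)))
        assert cal.slope == pytest.approx(10.0, abs=0.3)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            sp.fit_ionic_calibration([(1.0, 10.0)])
        with pytest.raises(ValueError):
            sp.fit_ionic_calibration([(1.0, 10.0), (1.0, 11.0)])


class TestSensitivity:
    def test_unit_mass_flux_arithmetic(self):
        # eta 4.8%, 0.47 mL/min, 3 ms dwell: 1 ug/L delivers
        # 0.048 * (0.47/60 mL/s) * 0.003 s * 1e6 fg/mL = 1.128 fg per dwell
        acq = sp.AcquisitionConfig()
        cal = sp.IonicCalibration([], slope=0.1, intercept=0.0, r_squared=1.0)
        S = sp.sensitivity_from_calibration(cal, acq)
        assert S == pytest.approx(0.1 / 1.128, rel=1e-6)

    def test_doubling_transport_efficiency_halves_sensitivity(self):
        cal = sp.IonicCalibration([], slope=0.1, intercept=0.0, r_squared=1.0)
        s1 = sp.sensitivity_from_calibration(cal, sp.AcquisitionConfig(transport_efficiency=0.048))
        s2 = sp.sensitivity_from_calibration(cal, sp.AcquisitionConfig(transport_efficiency=0.096))
        assert s1 == pytest.approx(2 * s2)

    def test_nonpositive_slope_rejected(self):
        cal = sp.IonicCalibration([], slope=-1.0, intercept=0.0, r_squared=1.0)
        with pytest.raises(ValueError):
            sp.sensitivity_from_calibration(cal, sp.AcquisitionConfig())


class TestTransportEfficiency:
    def test_gold_reference_frequency_method(self):
        """30 nm gold at 12.5 ng/L, 1033 events in 1 min at 0.47 mL/min -> 4.8 %."""
        acq = sp.AcquisitionConfig(duration=60.0)
        eta = sp.transport_efficiency_frequency(1033, acq, 30.0, 19.3, 12.5)
        assert eta == pytest.approx(0.048, abs=0.001)

    def test_detecting_all_nebulized_gives_unity(self):
        acq = sp.AcquisitionConfig(duration=60.0)
        single_mass_g = sp.esd_to_mass(30.0, 19.3) * 1e-15
        nebulized = 12.5e-9 / single_mass_g * (0.47 / 1000 / 60) * 60.0
        eta = sp.transport_efficiency_frequency(round(nebulized), acq, 30.0, 19.3, 12.5)
        assert eta == pytest.approx(1.0, rel=1e-3)

    def test_zero_detected_warns(self):
        acq = sp.AcquisitionConfig()
        with pytest.warns(UserWarning):
            assert sp.transport_efficiency_frequency(0, acq, 30.0, 19.3, 12.5) == 0.0


class TestMassAndESD:
    def test_compound_mass_from_counts(self):
        assert sp.event_mass(100.0, 1.0, sp.TIO2_ANALYTE) == pytest.approx(167.0)
        assert sp.event_mass(0.0, 1.0, sp.TIO2_ANALYTE) == 0.0

    def test_mass_to_esd_reference_points(self):
        # 2.215 fg of TiO2 (rho 4.23) is a 100 nm sphere; 0.2728 fg of gold a 30 nm sphere
        assert sp.mass_to_esd(2.2148, 4.23) == pytest.approx(100.0, rel=1e-4)
        assert sp.mass_to_esd(0.27285, 19.3) == pytest.approx(30.0, rel=1e-4)
        assert sp.mass_to_esd(0.0, 4.23) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(mass=st.floats(min_value=1e-3, max_value=1e6))
    def test_esd_mass_round_trip(self, mass):
        d = sp.mass_to_esd(mass, 4.23)
        assert sp.esd_to_mass(d, 4.23) == pytest.approx(mass, rel=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            sp.event_mass(-1.0, 1.0, sp.TIO2_ANALYTE)
        with pytest.raises(ValueError):
            sp.mass_to_esd(1.0, -4.23)


class TestSizeLimits:
    @staticmethod
    def _paper_sensitivity():
        # 4 counts correspond to a 39 nm TiO2 particle: S = 4 counts over
        # the Ti mass of a 39 nm sphere
        m_tio2 = sp.esd_to_mass(39.0, 4.23)
        return 4.0 / (m_tio2 / 1.67)

    def test_clean_background_uses_four_count_floor(self):
        es = sp.ParticleEventSet(0.0, 0.0, 0.0, np.array([]), 1)
        lod, loq = sp.size_limits(es, self._paper_sensitivity(), sp.TIO2_ANALYTE)
        assert lod == pytest.approx(39.0, abs=0.5)
        assert loq == pytest.approx(39.0, abs=0.5)

    def test_sigma_term_scales_linearly_above_floor(self):
        S = self._paper_sensitivity()
        es1 = sp.ParticleEventSet(2.0, 4.0, 0.0, np.array([]), 1)
        es2 = sp.ParticleEventSet(2.0, 8.0, 0.0, np.array([]), 1)
        m1 = sp.event_mass(2.0 + 3 * 4.0, S, sp.TIO2_ANALYTE)
        d1 = sp.mass_to_esd(m1, 4.23)
        lod1, _ = sp.size_limits(es1, S, sp.TIO2_ANALYTE)
        lod2, _ = sp.size_limits(es2, S, sp.TIO2_ANALYTE)
        assert lod1 == pytest.approx(d1)
        # intensity doubles its sigma term: 2 + 24 counts vs 2 + 12
        m2 = sp.event_mass(2.0 + 3 * 8.0, S, sp.TIO2_ANALYTE)
        assert lod2 == pytest.approx(sp.mass_to_esd(m2, 4.23))

    def test_loq_never_below_lod(self, rng):
        S = self._paper_sensitivity()
        for _ in range(20):
            es = sp.ParticleEventSet(rng.uniform(0, 5), rng.uniform(0, 3), 0.0, np.array([]), 1)
            lod, loq = sp.size_limits(es, S, sp.TIO2_ANALYTE)
            assert loq >= lod


class TestConcentrations:
    def test_effective_volume_arithmetic(self):
        # 200 events, eta 4.8%, 0.47 mL/min, 60 s -> V_eff 0.02256 mL
        es = sp.ParticleEventSet(0, 0, 0, np.ones(200), 1)
        acq = sp.AcquisitionConfig(duration=60.0)
        out = sp.concentrations(es, np.ones(200), acq)
        v_eff_mL = 0.048 * 0.47 * 1.0
        assert v_eff_mL == pytest.approx(0.02256)
        assert out["number_concentration_per_L"] == pytest.approx(200 / (v_eff_mL / 1000))

    def test_zero_events_zero_concentrations(self):
        es = sp.ParticleEventSet(0, 0, 0, np.array([]), 1)
        out = sp.concentrations(es, np.array([]), sp.AcquisitionConfig())
        assert out["number_concentration_per_L"] == 0.0
        assert out["mass_concentration_g_per_L"] == 0.0

    def test_dilution_factor_scales_linearly(self):
        es = sp.ParticleEventSet(0, 0, 0, np.ones(100), 1)
        out1 = sp.concentrations(es, np.ones(100), sp.AcquisitionConfig(dilution_factor=1))
        out10 = sp.concentrations(es, np.ones(100), sp.AcquisitionConfig(dilution_factor=10))
        assert out10["number_concentration_per_L"] == pytest.approx(
            10 * out1["number_concentration_per_L"]
        )

    def test_transport_efficiency_inverse_scaling(self):
        es = sp.ParticleEventSet(0, 0, 0, np.ones(100), 1)
        o1 = sp.concentrations(es, np.ones(100), sp.AcquisitionConfig(transport_efficiency=0.048))
        o2 = sp.concentrations(es, np.ones(100), sp.AcquisitionConfig(transport_efficiency=0.096))
        assert o1["mass_concentration_g_per_L"] == pytest.approx(
            2 * o2["mass_concentration_g_per_L"]
        )

    def test_powder_normalization(self):
        es = sp.ParticleEventSet(0, 0, 0, np.ones(100), 1)
        out = sp.concentrations(es, np.ones(100), sp.AcquisitionConfig(),
                                powder_loading_g_per_L=0.37)
        assert out["mass_concentration_kg_per_kg_powder"] == pytest.approx(
            out["mass_concentration_g_per_L"] / 0.37
        )


class TestDilutionSeries:
    def test_proportional_series_passes(self):
        rep = sp.check_dilution_series([(10, 2000, 90.0), (20, 1000, 90.0)])
        assert rep.all_pass

    def test_nonproportional_counts_fail(self):
        rep = sp.check_dilution_series([(10, 2000, 90.0), (20, 1800, 90.0)])
        assert not rep.proportionality_pass

    def test_count_below_working_range_fails(self):
        rep = sp.check_dilution_series([(10, 300, 90.0), (20, 150, 90.0)])
        assert not rep.count_range_pass

    def test_single_entry_rejected(self):
        with pytest.raises(ValueError):
            sp.check_dilution_series([(10, 2000, 90.0)])


class TestSummarize:
    def test_single_event_median_is_that_particle(self):
        readings = np.full(2000, 2.0)
        readings[1000] = 500.0
        cal = sp.fit_ionic_calibration([(0, 0), (1, 10)])
        acq = sp.AcquisitionConfig(duration=2000 * 0.003)
        res = sp.summarize_spicpms(make_trace(readings), cal, acq)
        assert res.n_events == 1
        assert res.median_esd_nm == pytest.approx(res.esds_nm[0])

    def test_background_only_trace_reports_limits(self, rng):
        readings = rng.poisson(2.0, 5000).astype(float)
        cal = sp.fit_ionic_calibration([(0, 0), (1, 10)])
        acq = sp.AcquisitionConfig(duration=5000 * 0.003)
        res = sp.summarize_spicpms(make_trace(readings), cal, acq)
        if res.n_events == 0:
            assert res.number_concentration_per_L == 0.0
            assert math.isnan(res.median_esd_nm)
        assert res.size_lod_nm > 0
        assert res.size_loq_nm >= res.size_lod_nm
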