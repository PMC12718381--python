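"""Histograms, Gaussian-mixture fits, occupancy, Förster conversion, transitions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stimfret as sf
from stimfret.qc import FretSeries
from stimfret.states import (DEFAULT_BIN_EDGES, ForsterCalibration,
                             MixtureComponent, MixtureFit, build_histogram,
                             count_transitions, distance_to_fret, fit_mixture,
                             fret_to_distance, match_mixture_to_reference,
                             occupancy)

from oracles import bisect_fret_distance


def series_of(e_values, mol_id="m0", frame_interval=0.1):
    e = np.asarray(e_values, dtype=float)
    return FretSeries(molecule_id=mol_id, efficiencies=e,
                      efficiencies_clipped=np.clip(e, -0.1, 1.1),
                      window=(0, len(e)), gamma_used=1.0,
                      frame_interval=frame_interval)


class TestHistogram:
    def test_point_mass_density(self):
        h = build_histogram([series_of([0.5] * 20)])
        occupied = h.density > 0
        assert occupied.sum() == 1
        assert h.density[occupied][0] == pytest.approx(1.0 / 0.02)

    def test_per_molecule_weighting_equalizes_long_traces(self):
        """Molecules of 10 and 1,000 frames at E=0.2 and 0.8 each carry
        half the mass."""
        h = build_histogram([series_of([0.2] * 10, "a"),
                             series_of([0.8] * 1000, "b")])
        mass = h.density * h.widths
        lo = mass[h.centers < 0.5].sum()
        hi = mass[h.centers > 0.5].sum()
        assert lo == pytest.approx(0.5)
        assert hi == pytest.approx(0.5)

    def test_density_integrates_to_one(self, static_two_state_traces):
        records, _ = sf.qc_filter(static_two_state_traces)
        series = sf.qc.fret_series_from_records(records)
        h = build_histogram(series)
        assert np.sum(h.density * h.widths) == pytest.approx(1.0, abs=1e-9)

    def test_mode_near_low_fret_peak(self, static_two_state_traces):
        """Ensemble generated from the Ca²⁺ two-state parameters peaks near
        E = 0.28."""
        records, _ = sf.qc_filter(static_two_state_traces)
        series = sf.qc.fret_series_from_records(records)
        h = build_histogram(series)
        assert abs(h.centers[np.argmax(h.density)] - 0.28) < 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([series_of([np.nan, np.nan])])


class TestMixtureFit:
    def test_single_gaussian_recovery(self):
        """μ=0.5, σ=0.06, 300 molecules: k=1 selected, μ within 0.02, w=1."""
        rng = np.random.default_rng(13)
        series = [series_of(np.clip(0.5 + 0.06 * rng.standard_normal()
                                    + 0.02 * rng.standard_normal(40), 0, 1),
                            f"m{i}") for i in range(300)]
        fit = fit_mixture(build_histogram(series), k_range=(1, 2, 3), seed=0)
        assert fit.n_components == 1
        assert abs(fit.components[0].mean - 0.5) <= 0.02
        assert fit.components[0].area == pytest.approx(1.0)

    def test_two_state_selection_and_recovery(self, static_two_state_traces):
        """Ca²⁺-like two-state ensemble: k=2 selected; areas within ±5 pp,
        means within ±0.03."""
        records, _ = sf.qc_filter(static_two_state_traces)
        series = sf.qc.fret_series_from_records(records)
        fit = fit_mixture(build_histogram(series), k_range=(1, 2, 3, 4), seed=0)
        assert fit.n_components == 2
        areas, means = match_mixture_to_reference(fit, [0.28, 0.68])
        # compare against the realized accepted composition, not the
        # asymptotic 70/30, to keep the check sharp at n=150
        truth = np.array([t.truth.state_fret[0]
                          for t in static_two_state_traces])
        accepted_ids = {r.trace.molecule_id
                        for r in sf.qc_filter(static_two_state_traces)[0]}
        acc = np.array([t.truth.state_fret[0] for t in static_two_state_traces
                        if t.molecule_id in accepted_ids])
        frac_low = np.mean(acc < 0.5)
        assert abs(areas[0] - frac_low) < 0.05
        assert abs(means[0] - 0.28) < 0.03 and abs(means[1] - 0.68) < 0.03

    def test_three_state_selection_egta_like(self):
        """EGTA-condition generator at n=450: three components detected and
        areas recovered within ±6 pp."""
        traces = sf.simulate_state_ensemble([(0.29, .25), (0.65, .67),
                                             (0.88, .08)], 450, seed=33)
        res = sf.analyze_ensemble(traces, k_range=(1, 2, 3, 4), seed=0)
        assert res.fit.n_components == 3
        areas, _ = match_mixture_to_reference(res.fit, [0.29, 0.65, 0.88])
        np.testing.assert_allclose(areas, [0.25, 0.67, 0.08], atol=0.06)

    def test_invalid_k_range(self):
        h = build_histogram([series_of([0.5] * 10)])
        with pytest.raises(ValueError):
            fit_mixture(h, k_range=(0, 7))

    def test_areas_sum_to_one(self, static_two_state_traces):
        records, _ = sf.qc_filter(static_two_state_traces)
        series = sf.qc.fret_series_from_records(records)
        fit = fit_mixture(build_histogram(series), seed=3)
        assert fit.areas.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(fit.means) > 0)


class TestOccupancy:
    def _fit(self, comps):
        return MixtureFit([MixtureComponent(*c) for c in comps],
                          rss=0.0, bic=0.0, n_bins=60)

    def test_lowest_component_area_reported(self):
        fit = self._fit([(0.28, 0.06, 0.70), (0.68, 0.08, 0.30)])
        assert occupancy(fit).low_fret_occupancy == pytest.approx(0.70)

    def test_single_component_is_unity(self):
        fit = self._fit([(0.5, 0.07, 1.0)])
        assert occupancy(fit).low_fret_occupancy == 1.0

    def test_three_component_lowest(self):
        fit = self._fit([(0.25, 0.05, 0.17), (0.58, 0.07, 0.47),
                         (0.81, 0.06, 0.36)])
        assert occupancy(fit).low_fret_occupancy == pytest.approx(0.17)

    def test_highest_rule_for_inverted_pairs(self):
        fit = self._fit([(0.3, 0.06, 0.4), (0.8, 0.06, 0.6)])
        assert occupancy(fit, rule="highest").low_fret_occupancy == \
            pytest.approx(0.6)

    def test_empty_fit_rejected(self):
        with pytest.raises(ValueError):
            occupancy(MixtureFit([], 0.0, 0.0, 0))


class TestForster:
    def test_half_efficiency_returns_r0(self):
        assert fret_to_distance(0.5, ForsterCalibration(5.8)) == \
            pytest.approx(5.8, rel=1e-12)

    def test_high_efficiency_limit(self):
        assert fret_to_distance(0.999999, ForsterCalibration(5.8)) < 0.6

    def test_low_fret_peak_distance_matches_bisection(self):
        """R(E=0.28) agrees with an independent bisection solve of the
        inverse relation."""
        r = fret_to_distance(0.28, ForsterCalibration(5.8))
        r_oracle = bisect_fret_distance(0.28, 5.8)
        assert r == pytest.approx(r_oracle, rel=1e-9)

    def test_domain_errors(self):
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                fret_to_distance(bad)
        with pytest.raises(ValueError):
            distance_to_fret(0.0)

    @given(e=st.floats(min_value=1e-3, max_value=1 - 1e-3))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, e):
        cal = ForsterCalibration(5.8)
        assert distance_to_fret(fret_to_distance(e, cal), cal) == \
            pytest.approx(e, rel=1e-12)

    def test_strictly_decreasing(self):
        es = np.linspace(0.01, 0.99, 200)
        rs = fret_to_distance(es, ForsterCalibration(5.8))
        assert np.all(np.diff(rs) < 0)


class TestTransitions:
    def _fit_two_state(self, mu=(0.3, 0.8), sg=0.05):
        return MixtureFit([MixtureComponent(m, sg, 0.5) for m in mu],
                          rss=0.0, bic=0.0, n_bins=60)

    def test_constant_series_zero_transitions(self):
        stats = count_transitions([series_of([0.3] * 100)],
                                  self._fit_two_state(), window_seconds=5.0)
        assert stats.per_molecule_counts.tolist() == [0]

    def test_square_wave_counted_exactly(self):
        """Noiseless 0.3/0.8 square wave with 4 switches in-window."""
        e = np.r_[[0.3] * 10, [0.8] * 10, [0.3] * 10, [0.8] * 10, [0.3] * 10]
        stats = count_transitions([series_of(e)], self._fit_two_state(),
                                  window_seconds=5.0)
        assert stats.per_molecule_counts.tolist() == [4]

    def test_single_component_fit_gives_zero(self):
        fit = MixtureFit([MixtureComponent(0.5, 0.06, 1.0)], 0.0, 0.0, 60)
        e = np.r_[[0.3] * 20, [0.8] * 20]
        stats = count_transitions([series_of(e)], fit, window_seconds=3.0)
        assert stats.per_molecule_counts.tolist() == [0]

    def test_noise_below_hysteresis_band_ignored(self):
        rng = np.random.default_rng(2)
        e = np.r_[[0.3] * 25, [0.8] * 25] + 0.02 * rng.standard_normal(50)
        stats = count_transitions([series_of(e)], self._fit_two_state(),
                                  window_seconds=5.0)
        assert stats.per_molecule_counts.tolist() == [1]

    def test_counts_non_increasing_in_dwell_threshold(self):
        """Minimum-dwell filtering can only remove transitions."""
        rng = np.random.default_rng(5)
        model = sf.StateModel(state_fret=(0.3, 0.8), state_probs=(0.5, 0.5),
                              transition_rates=np.array([[0, 2.0], [2.0, 0]]))
        photo = sf.PhotoModel(total_intensity=400, noise_sd=6.0)
        traces = sf.simulate_ensemble(model, photo, 50, 60, seed=14)
        series = [sf.compute_fret(t, 1.0, window=(0, 60)) for t in traces]
        fit = self._fit_two_state()
        means = [count_transitions(series, fit, 5.0, min_dwell_frames=d)
                 .mean_count for d in (1, 2, 3, 5)]
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_short_molecules_excluded(self):
        stats = count_transitions([series_of([0.3] * 10)],
                                  self._fit_two_state(), window_seconds=5.0)
        assert stats.n_excluded == 1
        assert len(stats.per_molecule_counts) == 0

    def test_distribution_sums_to_one(self):
        e1 = np.r_[[0.3] * 25, [0.8] * 25]
        stats = count_transitions([series_of(e1), series_of([0.3] * 50, "b")],
                                  self._fit_two_state(), window_seconds=5.0)
        assert stats.frequency_distribution["probability"].sum() == \
            pytest.approx(1.0)
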