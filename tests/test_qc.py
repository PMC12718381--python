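"""Trace QC: change-point detection, γ estimation, FRET computation, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stimfret as sf
from stimfret.qc import (BleachEvents, GammaEstimate, QCPolicy, compute_fret,
                         detect_steps, estimate_gamma, qc_filter,
                         robust_noise_sd)

from conftest import make_clean_trace
from oracles import brute_force_change_points


class TestDetectSteps:
    def test_single_noiseless_shift_found_exactly(self):
        y = np.r_[np.full(100, 200.0), np.full(100, 50.0)]
        assert detect_steps(y) == [(100, -150.0)]

    def test_constant_series_has_no_steps(self):
        assert detect_steps(np.full(60, 7.0)) == []

    def test_pure_noise_has_no_steps(self):
        rng = np.random.default_rng(0)
        y = 100 + 5 * rng.standard_normal(200)
        assert detect_steps(y, max_steps=2) == []

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_steps(np.ones(6), min_segment=4)

    @pytest.mark.parametrize("seed", range(12))
    def test_two_step_staircase_matches_exhaustive_oracle(self, seed):
        """Noisy staircases with ≥100-count steps: the detector recovers the
        exact change-point pair found by brute-force least squares."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(40, 200))
        c1 = int(rng.integers(8, n // 2))
        c2 = int(rng.integers(c1 + 8, n - 8))
        levels = rng.choice([-1, 1], size=2) * rng.uniform(100, 300, size=2)
        y = np.full(n, 500.0)
        y[c1:] += levels[0]
        y[c2:] += levels[1]
        y += 5.0 * rng.standard_normal(n)
        penalty = 10.0 * 25.0 * np.log(n)
        found = [f for f, _ in detect_steps(y, max_steps=2, penalty=penalty)]
        assert found == brute_force_change_points(y, penalty)
        assert found == [c1, c2]

    @pytest.mark.parametrize("n_steps", [0, 1, 2])
    @pytest.mark.parametrize("trial", range(6))
    def test_agrees_with_oracle_on_random_series(self, n_steps, trial):
        """Optimal-partition DP equals exhaustive search on arbitrary series
        of length ≤ 200 with ≤ 2 steps, including ambiguous small steps."""
        rng = np.random.default_rng(1000 * n_steps + trial)
        n = int(rng.integers(24, 200))
        y = 50.0 + 8.0 * rng.standard_normal(n)
        cps = np.sort(rng.choice(np.arange(6, n - 6), size=n_steps,
                                 replace=False)) if n_steps else []
        for c in cps:
            y[c:] += rng.uniform(-60, 60)
        penalty = 10.0 * 64.0 * np.log(n)
        found = [f for f, _ in detect_steps(y, max_steps=2, penalty=penalty)]
        assert found == brute_force_change_points(y, penalty)

    def test_step_sizes_are_segment_mean_differences(self):
        y = np.r_[np.full(50, 10.0), np.full(50, 110.0), np.full(50, 60.0)]
        steps = detect_steps(y, max_steps=2)
        assert [(f, round(s)) for f, s in steps] == [(50, 100), (100, -50)]


class TestRobustNoise:
    def test_estimates_gaussian_noise_despite_steps(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.zeros(150), np.full(150, 500.0)]
        y += 10.0 * rng.standard_normal(300)
        assert abs(robust_noise_sd(y) - 10.0) < 1.5


class TestEstimateGamma:
    def _events(self, ab, db=None):
        return BleachEvents(acceptor_bleach_frame=ab, donor_bleach_frame=db)

    def test_equal_steps_give_unit_gamma(self):
        tr = make_clean_trace(e=2 / 3, gamma=2.0, total=150.0, ab=100, db=None)
        # acceptor 100→0, donor 50→... engineered via explicit arrays instead
        donor = np.r_[np.full(100, 50.0), np.full(100, 150.0)]
        acceptor = np.r_[np.full(100, 100.0), np.full(100, 0.0)]
        tr = sf.Trace("g1", 0.1, donor, acceptor)
        g = estimate_gamma(tr, self._events(100))
        assert g.method == "per-molecule-step"
        assert g.gamma == pytest.approx(1.0)

    def test_ratio_of_step_magnitudes(self):
        donor = np.r_[np.full(80, 40.0), np.full(80, 90.0)]
        acceptor = np.r_[np.full(80, 120.0), np.full(80, 20.0)]
        tr = sf.Trace("g2", 0.1, donor, acceptor)
        g = estimate_gamma(tr, self._events(80))
        assert g.gamma == pytest.approx(2.0)  # 100 / 50

    def test_noisy_recovery_within_tolerance(self):
        """True γ = 1.4 with noise sd 5: recovered within ±0.1."""
        tr = make_clean_trace(e=0.45, gamma=1.4, total=400.0, ab=150, db=280,
                              noise_sd=5.0, seed=11)
        g = estimate_gamma(tr, self._events(150, 280), window=10)
        assert g.method == "per-molecule-step"
        assert abs(g.gamma - 1.4) < 0.1

    def test_negative_donor_rise_falls_back(self):
        donor = np.r_[np.full(50, 90.0), np.full(50, 40.0)]
        acceptor = np.r_[np.full(50, 120.0), np.full(50, 20.0)]
        tr = sf.Trace("g3", 0.1, donor, acceptor)
        g = estimate_gamma(tr, self._events(50))
        assert g.method == "ensemble-fallback"
        assert np.isnan(g.gamma)

    def test_missing_bleach_falls_back(self):
        tr = sf.Trace("g4", 0.1, np.full(40, 50.0), np.full(40, 50.0))
        assert estimate_gamma(tr, self._events(None)).method == "ensemble-fallback"

    @given(scale=st.floats(min_value=0.01, max_value=100.0,
                           allow_nan=False, allow_infinity=False))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale):
        """Multiplying both channels by c > 0 leaves γ unchanged."""
        donor = np.r_[np.full(60, 40.0), np.full(60, 90.0)]
        acceptor = np.r_[np.full(60, 120.0), np.full(60, 20.0)]
        g0 = estimate_gamma(sf.Trace("s", 0.1, donor, acceptor),
                            self._events(60)).gamma
        g1 = estimate_gamma(sf.Trace("s", 0.1, scale * donor, scale * acceptor),
                            self._events(60)).gamma
        assert g1 == pytest.approx(g0, rel=1e-9)


class TestComputeFret:
    @pytest.mark.parametrize("ia,idn,gamma,expected", [
        (50.0, 50.0, 1.0, 0.5),
        (0.0, 80.0, 1.0, 0.0),
        (60.0, 20.0, 2.0, 0.6),
    ])
    def test_ratio_formula_examples(self, ia, idn, gamma, expected):
        tr = sf.Trace("f", 0.1, np.full(10, idn), np.full(10, ia))
        fs = compute_fret(tr, gamma, window=(0, 10))
        np.testing.assert_allclose(fs.efficiencies, expected, atol=1e-12)

    def test_matches_generating_state_fret_prebleach(self):
        """compute_fret ∘ simulate_trace with matching γ and zero noise is
        exact at every pre-bleach frame."""
        model = sf.StateModel(state_fret=(0.3, 0.8), state_probs=(0.5, 0.5),
                              transition_rates=np.array([[0, 1.0], [1.0, 0]]))
        photo = sf.PhotoModel(total_intensity=350, gamma=1.6,
                              acceptor_bleach_rate=0.01, background=20.0)
        tr = sf.simulate_trace(model, photo, 300, seed=6)
        ab = tr.truth.acceptor_bleach_frame
        fs = compute_fret(tr, 1.6, window=(0, ab), background=20.0)
        truth_e = np.asarray(model.state_fret)[tr.truth.states[:ab]]
        np.testing.assert_allclose(fs.efficiencies, truth_e, rtol=1e-10)

    def test_nonpositive_denominator_excluded_and_counted(self):
        donor = np.array([50.0, -100.0, 50.0])
        acceptor = np.array([50.0, 20.0, 50.0])
        fs = compute_fret(sf.Trace("d", 0.1, donor, acceptor), 1.0,
                          window=(0, 3))
        assert fs.n_excluded == 1
        assert np.isnan(fs.efficiencies[1])

    def test_clipping_preserves_raw(self):
        donor = np.full(5, 10.0)
        acceptor = np.full(5, -5.0)
        fs = compute_fret(sf.Trace("c", 0.1, donor, acceptor), 1.0,
                          window=(0, 5))
        assert np.all(fs.efficiencies < -0.1)
        assert np.all(fs.efficiencies_clipped == -0.1)


class TestQCFilter:
    def test_clean_ensemble_fully_accepted(self):
        traces = [make_clean_trace(f"m{i}", e=0.3 + 0.001 * i, noise_sd=4.0,
                                   seed=i) for i in range(100)]
        records, report = qc_filter(traces)
        assert len(records) == 100
        assert report["accepted"].all()

    def test_donor_first_rejected(self):
        n = 200
        donor = np.r_[np.full(100, 200.0), np.full(100, 0.0)]
        acceptor = np.r_[np.full(100, 150.0), np.full(100, 0.0)]
        tr = sf.Trace("df", 0.1, donor, acceptor)
        _, report = qc_filter([tr])
        assert report.loc[0, "reason"] == "donor-first"

    def test_no_bleach_rejected(self):
        tr = sf.Trace("nb", 0.1, np.full(120, 80.0), np.full(120, 90.0))
        _, report = qc_filter([tr])
        assert report.loc[0, "reason"] == "no-acceptor-bleach"

    def test_short_prebleach_rejected(self):
        tr = make_clean_trace("sp", ab=10, db=200)
        _, report = qc_filter([tr])
        assert report.loc[0, "reason"] == "short-prebleach"

    def test_fallback_gamma_is_ensemble_median(self):
        from stimfret.qc import QCRecord, apply_gamma_fallback

        good = [make_clean_trace(f"g{i}", e=0.4, gamma=g, ab=150, db=280)
                for i, g in enumerate((1.0, 1.2, 1.4))]
        records, _ = qc_filter(good)
        # a molecule whose γ step was unusable carries a NaN placeholder
        bad = make_clean_trace("fb", e=0.4, gamma=2.5, ab=150, db=151)
        records.append(QCRecord(bad,
                                BleachEvents(150, 151),
                                GammaEstimate(np.nan, "ensemble-fallback"),
                                (0.0, 0.0)))
        used = apply_gamma_fallback(records)
        by_id = {r.trace.molecule_id: r for r in records}
        assert by_id["fb"].gamma.gamma == pytest.approx(used)
        assert used == pytest.approx(1.2, abs=0.05)

    def test_median_gamma_recovery_on_population(self):
        """Median recovered γ within 2% of the log-normal population median."""
        traces = sf.simulate_state_ensemble([(0.45, 1.0)], 300, seed=77)
        records, _ = qc_filter(traces)
        gammas = np.array([r.gamma.gamma for r in records
                           if r.gamma.method == "per-molecule-step"])
        assert len(gammas) > 100
        assert abs(np.median(gammas) - 1.0) < 0.02
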