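"""Time-resolved peak tracking, onset/completion detection, d(t)."""

import numpy as np
import pytest

from mesosaxs.io import SAXSPattern
from mesosaxs.kinetics import (
    detect_completion,
    detect_onset,
    track_d_spacing,
    track_series,
)
from mesosaxs.phases import Reflection
from mesosaxs.synthetic import (
    KineticSpec,
    NoiseSpec,
    PhaseSpec,
    generate_kinetic_series,
)

LATTICES = {"lamellar": 6.9, "Pn3m": 11.6, "Im3m": 12.7}


class TestTrackSeries:
    def test_noiseless_traces_match_generator(self, noiseless_series,
                                              tracked_reflections, im3m_reference):
        tr = track_series(noiseless_series, tracked_reflections,
                          im3m_reference, LATTICES)
        # spectator reference trace is identically 1
        np.testing.assert_allclose(tr.intensity["Im3m_211"], 1.0, atol=1e-9)
        # lamellar trace follows the generator's linear ramp
        ramp = np.array([1 - min(max((t - 30) / 90, 0.0), 1.0) for t in tr.times])
        got = tr.intensity["lamellar_100"] / tr.intensity["lamellar_100"][0]
        np.testing.assert_allclose(got, ramp, atol=5e-3)
        # Pn3m grows from its delayed onset
        grow = np.array([min(max((t - 50) / 70, 0.0), 1.0) for t in tr.times])
        pn = tr.intensity["Pn3m_110"] / tr.intensity["Pn3m_110"][-1]
        np.testing.assert_allclose(pn, grow, atol=5e-3)

    def test_identical_frames_give_constant_traces(self, tracked_reflections,
                                                   im3m_reference):
        spec = KineticSpec(
            initial=[PhaseSpec("lamellar", 6.9, 2000), PhaseSpec("Im3m", 12.7, 800)],
            final=[PhaseSpec("lamellar", 6.9, 2000), PhaseSpec("Im3m", 12.7, 800)],
        )
        frames = generate_kinetic_series(spec, NoiseSpec(model="none"))
        tr = track_series(frames, [("lamellar", Reflection.lamellar(1))],
                          im3m_reference, {"lamellar": 6.9, "Im3m": 12.7})
        lam = tr.intensity["lamellar_100"]
        np.testing.assert_allclose(lam, lam[0], rtol=1e-6)
        assert tr.onsets["lamellar_100"] is None

    def test_normalization_invariance(self, noiseless_series, tracked_reflections,
                                      im3m_reference):
        """Arbitrary positive per-frame scale factors cancel exactly."""
        rng = np.random.default_rng(8)
        scales = rng.uniform(0.5, 2.0, len(noiseless_series))
        scaled = [SAXSPattern(f.q, f.I * c, None, dict(f.metadata))
                  for f, c in zip(noiseless_series, scales)]
        a = track_series(noiseless_series, tracked_reflections, im3m_reference,
                         LATTICES)
        b = track_series(scaled, tracked_reflections, im3m_reference, LATTICES)
        for key in a.intensity:
            np.testing.assert_allclose(b.intensity[key], a.intensity[key],
                                       rtol=1e-9, atol=1e-12)

    def test_reverse_direction_mirrors_forward(self, transition_spec,
                                               tracked_reflections, im3m_reference):
        frames = generate_kinetic_series(transition_spec, NoiseSpec(model="none"))
        reversed_frames = []
        times = [f.time_s for f in frames]
        for f, t in zip(reversed(frames), times):
            g = SAXSPattern(f.q, f.I, f.sigma, dict(f.metadata))
            g.metadata["time_s"] = t
            reversed_frames.append(g)
        tr = track_series(reversed_frames, tracked_reflections, im3m_reference,
                          LATTICES)
        lam = tr.intensity["lamellar_100"]
        pn = tr.intensity["Pn3m_110"]
        assert lam[-1] > lam[0]  # lamellar rises
        assert pn[0] > pn[-1]    # Pn3m falls

    def test_missing_reference_raises_with_frame(self, transition_spec,
                                                 tracked_reflections):
        # Pn3m has zero amplitude in the early frames, so demanding it as
        # the reference must fail loudly, naming the frame
        frames = generate_kinetic_series(
            transition_spec,
            NoiseSpec(model="gaussian-fractional", fractional=0.02, seed=0))
        with pytest.raises(ValueError, match="frame"):
            track_series(frames, [("lamellar", Reflection.lamellar(1))],
                         ("Pn3m", Reflection.cubic(1, 1, 0)), LATTICES)

    def test_onset_completion_recovery_with_noise(self, transition_spec,
                                                  tracked_reflections,
                                                  im3m_reference):
        """30/50/120 s timing recovered within one 10 s frame, >=90% of seeds."""
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            frames = generate_kinetic_series(
                transition_spec,
                NoiseSpec(model="gaussian-fractional", fractional=0.02, seed=seed))
            tr = track_series(frames, tracked_reflections, im3m_reference, LATTICES)
            good = (
                tr.onsets["lamellar_100"] is not None
                and abs(tr.onsets["lamellar_100"] - 30) <= 10
                and tr.onsets["Pn3m_110"] is not None
                and abs(tr.onsets["Pn3m_110"] - 50) <= 10
                and isinstance(tr.completions["lamellar_100"], float)
                and abs(tr.completions["lamellar_100"] - 120) <= 10
                and isinstance(tr.completions["Pn3m_110"], float)
                and abs(tr.completions["Pn3m_110"] - 120) <= 10
            )
            ok += good
        assert ok >= 0.9 * n_seeds


class TestDetectors:
    def test_step_change_detected_at_step_frame(self):
        t = np.arange(0, 120, 10.0)
        v = np.where(t >= 60, 5.0, 1.0)
        assert detect_onset(t, v) == 60.0

    def test_flat_noiseless_trace_gives_none(self):
        t = np.arange(0, 120, 10.0)
        assert detect_onset(t, np.ones_like(t)) is None

    def test_false_positive_rate_on_constant_noise(self):
        fp = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            v = 1.0 + 0.02 * rng.standard_normal(19)
            if detect_onset(np.arange(0, 190, 10.0), v) is not None:
                fp += 1
        assert fp <= 1

    def test_logistic_onset_recovered_within_one_frame(self):
        spec = KineticSpec(initial=[PhaseSpec("lamellar", 6.9)],
                           final=[PhaseSpec("Pn3m", 11.6)],
                           t_on_growth=50, t_end=120, shape="logistic")
        t = np.arange(0, 190, 10.0)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            v = np.array([spec.progress(ti, 50) for ti in t])
            v = v + 0.02 * rng.standard_normal(t.size)
            got = detect_onset(t, v, sigma=np.full(t.size, 0.02))
            hits += got is not None and abs(got - 50) <= 10
        assert hits >= 9

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            detect_onset(np.array([0.0, 10.0, 20.0]), np.array([1.0, 1.0, 2.0]),
                         baseline=3)

    def test_completion_of_piecewise_linear_ramp(self):
        t = np.arange(0, 190, 10.0)
        v = np.clip((t - 30) / 90, 0, 1)
        assert detect_completion(t, v, t_onset=40.0) == 120.0

    def test_still_rising_not_reached(self):
        t = np.arange(0, 100, 10.0)
        v = t / 100.0
        assert detect_completion(t, v, t_onset=10.0) == "not reached"

    def test_step_completes_at_first_post_step_frame(self):
        t = np.arange(0, 120, 10.0)
        v = np.where(t >= 60, 5.0, 1.0)
        assert detect_completion(t, v, t_onset=60.0) == 60.0

    def test_grid_recovery_invariant(self):
        """Onsets 10-60 s, ends 80-150 s, 10 s frames, 2% noise: both times
        within one frame spacing in >=90% of seeded runs."""
        rng = np.random.default_rng(7)
        ok = n = 0
        t = np.arange(0, 190, 10.0)
        for t_on in (10, 20, 30, 40, 50, 60):
            for t_end in (80, 100, 120, 150):
                for _ in range(4):
                    v = np.clip((t - t_on) / (t_end - t_on), 0, 1)
                    v = v + 0.02 * rng.standard_normal(t.size)
                    k = min(max(2, int(np.searchsorted(t, t_on)) + 1), 3)
                    d_on = detect_onset(t, v, baseline=k)
                    d_c = detect_completion(t, v, d_on,
                                            sigma=np.full(t.size, 0.02))
                    n += 2
                    ok += d_on is not None and abs(d_on - t_on) <= 10
                    ok += isinstance(d_c, float) and abs(d_c - t_end) <= 10
        assert ok / n >= 0.9

    def test_direction_symmetry(self):
        t = np.arange(0, 190, 10.0)
        v = np.clip((t - 50) / 70, 0, 1)
        fwd_on = detect_onset(t, v)
        rev_on = detect_onset(t, v[::-1])
        fwd_c = detect_completion(t, v, fwd_on)
        rev_c = detect_completion(t, v[::-1], rev_on)
        # reversing swaps the roles: reverse onset mirrors forward completion
        assert fwd_on is not None and rev_on is not None
        assert rev_on == pytest.approx(t[-1] - fwd_c, abs=10)
        assert rev_c == pytest.approx(t[-1] - fwd_on, abs=10)


class TestDSpacing:
    def _drift_spec(self):
        return KineticSpec(
            initial=[PhaseSpec("lamellar", 6.51, 2000)],
            final=[PhaseSpec("lamellar", 6.51, 2000)],
            d_drift={"phase": "lamellar", "a_final": 6.47})

    def test_drift_endpoints_recovered(self):
        frames = generate_kinetic_series(self._drift_spec(), NoiseSpec(model="none"))
        _, d, sd = track_d_spacing(frames, 6.51)
        assert d[0] == pytest.approx(6.51, abs=1e-3)
        assert d[-1] == pytest.approx(6.47, abs=1e-3)

    def test_drift_with_noise_within_tolerance(self):
        diffs = []
        for seed in range(5):
            frames = generate_kinetic_series(
                self._drift_spec(),
                NoiseSpec(model="gaussian-fractional", fractional=0.02, seed=seed))
            _, d, _ = track_d_spacing(frames, 6.51)
            diffs.append(d[-1] - d[0])
        assert np.mean(diffs) == pytest.approx(-0.04, abs=0.02)

    def test_constant_d_gives_no_onset(self):
        spec = KineticSpec(initial=[PhaseSpec("lamellar", 6.5, 2000)],
                           final=[PhaseSpec("lamellar", 6.5, 2000)])
        frames = generate_kinetic_series(spec, NoiseSpec(model="none"))
        t, d, _ = track_d_spacing(frames, 6.5)
        assert detect_onset(t, d) is None

    def test_sigma_calibration(self):
        """2% noise: reported sigma_d consistent with empirical scatter
        within a factor of 2."""
        spec = KineticSpec(initial=[PhaseSpec("lamellar", 6.5, 2000)],
                           final=[PhaseSpec("lamellar", 6.5, 2000)],
                           frame_times=(0.0, 10.0, 20.0, 30.0))
        ds, sds = [], []
        for seed in range(20):
            frames = generate_kinetic_series(
                spec, NoiseSpec(model="gaussian-fractional", fractional=0.02,
                                seed=seed))
            _, d, sd = track_d_spacing(frames, 6.5)
            ds.append(d[0])
            sds.append(sd[0])
        scatter = np.std(ds, ddof=1)
        assert 0.5 * scatter <= np.median(sds) <= 2.0 * scatter
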