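import numpy as np
import pytest

from vmadapt import preprocess as P


def make_samples(t, xy):
    xy = np.asarray(xy, dtype=float)
    return np.column_stack([t, xy, xy])


class TestDetectGlitches:
    def test_constant_velocity_clean(self):
        t = np.arange(50) * 0.01
        xy = np.outer(t, [1.0, 0.5])
        assert not P.detect_glitches(make_samples(t, xy))

    def test_single_frame_jump_flagged(self):
        t = np.arange(50) * 0.01
        xy = np.zeros((50, 2))
        xy[25] = [0.5, 0.0]  # 50 au/s for one 10 ms frame
        assert P.detect_glitches(make_samples(t, xy))

    def test_exact_threshold_passes(self):
        """A speed change of exactly 40 au/s is not a glitch (strict >)."""
        t = np.arange(10) * 0.25  # dyadic timestamps keep speeds exact
        xy = np.zeros((10, 2))
        xy[5:, 0] = np.cumsum(np.full(5, 10.0))  # speed steps 0 -> 40 au/s
        samples = make_samples(t, xy)
        assert not P.detect_glitches(samples, threshold=40.0)
        assert P.detect_glitches(samples, threshold=39.9)

    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            P.detect_glitches(make_samples([0.0, 0.01], [[0, 0], [0, 0]]))


class TestResample:
    def test_identity_on_grid(self):
        t = np.arange(30) / 100.0
        xy = np.column_stack([np.sin(t), np.cos(t)])
        out = P.resample_uniform(make_samples(t, xy), 100.0)
        assert np.allclose(out, make_samples(t, xy), atol=1e-12)

    def test_linear_ramp_exact(self):
        """Linear interpolation is exact on affine signals regardless of the
        source rate."""
        t = np.arange(40) / 60.0
        xy = np.outer(t, [2.0, -1.0]) + [0.3, 0.1]
        out = P.resample_uniform(make_samples(t, xy), 100.0)
        expected = np.outer(out[:, 0], [2.0, -1.0]) + [0.3, 0.1]
        assert np.abs(out[:, 1:3] - expected).max() < 1e-12

    def test_sinusoid_error_bound(self):
        """Standard linear-interpolation error bound: (2*pi*f*dt)^2 / 8."""
        f, fs = 2.0, 144.0
        t = np.arange(200) / fs
        xy = np.column_stack([np.sin(2 * np.pi * f * t), np.zeros_like(t)])
        out = P.resample_uniform(make_samples(t, xy), 100.0)
        truth = np.sin(2 * np.pi * f * out[:, 0])
        bound = (2 * np.pi * f / fs) ** 2 / 8
        assert np.abs(out[:, 1] - truth).max() <= bound

    def test_no_extrapolation(self):
        t = np.array([0.0, 0.013, 0.029, 0.041])
        out = P.resample_uniform(make_samples(t, np.ones((4, 2))), 100.0)
        assert out[-1, 0] <= t[-1]

    def test_non_monotone_rejected(self):
        t = np.array([0.0, 0.02, 0.01, 0.03])
        with pytest.raises(ValueError):
            P.resample_uniform(make_samples(t, np.zeros((4, 2))), 100.0)


def _filtered_amplitude(freq_hz, n=400, cfg=P.PreprocessConfig()):
    t = np.arange(n) / cfg.resample_hz
    sig = np.sin(2 * np.pi * freq_hz * t)
    samples = make_samples(t, np.column_stack([sig, np.zeros_like(sig)]))
    out = P.lowpass_zero_phase(samples, cfg)
    interior = slice(n // 4, 3 * n // 4)
    basis = np.column_stack([np.sin(2 * np.pi * freq_hz * t), np.cos(2 * np.pi * freq_hz * t)])
    coef, *_ = np.linalg.lstsq(basis[interior], out[interior, 1], rcond=None)
    return float(np.hypot(*coef))


class TestLowpass:
    def test_dc_gain_unity(self):
        t = np.arange(100) / 100.0
        samples = make_samples(t, np.full((100, 2), 0.7))
        out = P.lowpass_zero_phase(samples)
        assert np.allclose(out[:, 1:], 0.7, atol=1e-9)

    @pytest.mark.parametrize(
        "freq, rtol",
        [(2.0, 0.01), (30.0, 0.05)],
    )
    def test_two_pass_butterworth_magnitude(self, freq, rtol):
        """Forward-backward filtering squares the single-pass magnitude:
        |H(f)|^2 = 1 / (1 + (f/15)^4) for a 2nd-order 15 Hz Butterworth."""
        expected = 1.0 / (1.0 + (freq / 15.0) ** 4)
        measured = _filtered_amplitude(freq)
        assert abs(measured - expected) <= rtol * expected

    def test_zero_phase_no_lag(self):
        t = np.arange(400) / 100.0
        sig = np.sin(2 * np.pi * 3.0 * t)
        out = P.lowpass_zero_phase(make_samples(t, np.column_stack([sig, sig])))
        xc = np.correlate(out[:, 1], sig, mode="full")
        assert np.argmax(xc) == len(sig) - 1  # peak at lag 0

    def test_time_reversal_symmetry(self, rng):
        t = np.arange(200) / 100.0
        sig = rng.normal(0, 1, 200).cumsum()
        samples = make_samples(t, np.column_stack([sig, sig]))
        fwd = P.lowpass_zero_phase(samples)[:, 1]
        reversed_samples = make_samples(t, np.column_stack([sig[::-1], sig[::-1]]))
        rev = P.lowpass_zero_phase(reversed_samples)[:, 1]
        assert np.allclose(fwd, rev[::-1], atol=1e-8)

    def test_monotone_magnitude_response(self):
        amps = [_filtered_amplitude(f) for f in (1.0, 5.0, 10.0, 15.0, 25.0, 40.0)]
        assert all(a > b for a, b in zip(amps, amps[1:]))

    def test_short_trial_rejected(self):
        t = np.arange(10) / 100.0
        with pytest.raises(ValueError):
            P.lowpass_zero_phase(make_samples(t, np.zeros((10, 2))))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            P.PreprocessConfig(cutoff_hz=60.0)
        with pytest.raises(ValueError):
            P.PreprocessConfig(pad_samples=3)


class TestPreprocessTrials:
    def test_exclusion_log(self, rng):
        t = np.arange(60) / 100.0
        good = np.column_stack([t, np.outer(t, [1, 0]), np.outer(t, [1, 0])])
        glitchy = good.copy()
        glitchy[30, 1:] += 1.0
        short = good[:5]
        import pandas as pd

        frames = []
        for i, arr in enumerate([good, glitchy, short]):
            df = pd.DataFrame(arr, columns=["t", "input_x", "input_y", "cursor_x", "cursor_y"])
            df.insert(0, "trial_index", i)
            df.insert(0, "participant_id", "p0")
            frames.append(df)
        clean, exclusions = P.preprocess_trials(pd.concat(frames))
        assert set(clean["trial_index"]) == {0}
        assert exclusions.set_index("trial_index")["reason"].to_dict() == {
            1: "glitch",
            2: "too-short",
        }
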