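"""Stimulus construction: filter gains, scrambling, moment equalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfcode import stimgen
from sfcode.stimgen import (
    BandSpec,
    DegenerateImageError,
    INTACT,
    NormTargets,
    apply_sf_filter,
    build_stimulus_set,
    butterworth_bandpass_gain,
    default_bands,
    normalize_luminance_contrast,
    phase_scramble,
    records_manifest,
    sf_power,
)

R4 = BandSpec("R4", 18.0, 45.0, 4)


def _grating(side, cycles):
    x = np.arange(side)
    return np.tile(np.cos(2 * np.pi * cycles * x / side), (side, 1))


class TestBandpassGain:
    def test_zero_at_dc(self):
        for band in default_bands():
            assert butterworth_bandpass_gain(0.0, band) == 0.0

    def test_half_power_at_upper_cutoff(self):
        # high-pass factor is ~1 at f_hi when f_lo << f_hi, so the product
        # sits at the low-pass half-power value
        assert butterworth_bandpass_gain(45.0, R4) == pytest.approx(0.5, abs=1e-2)

    def test_value_at_geometric_mean_matches_formula(self):
        r = np.sqrt(18.0 * 45.0)
        expected = (1 / (1 + (r / 45.0) ** 8)) * (1 / (1 + (18.0 / r) ** 8))
        assert butterworth_bandpass_gain(r, R4) == pytest.approx(expected, rel=1e-12)

    def test_intact_rejected(self):
        with pytest.raises(ValueError):
            butterworth_bandpass_gain(10.0, INTACT)

    @given(st.floats(min_value=0.0, max_value=300.0))
    @settings(max_examples=50, deadline=None)
    def test_gain_bounded(self, r):
        g = butterworth_bandpass_gain(r, R4)
        assert 0.0 <= g <= 1.0

    def test_unimodal_rising_then_falling(self):
        r = np.linspace(0.0, 120.0, 500)
        g = butterworth_bandpass_gain(r, R4)
        peak = int(np.argmax(g))
        assert np.all(np.diff(g[: peak + 1]) >= -1e-12)
        assert np.all(np.diff(g[peak:]) <= 1e-12)


class TestApplySfFilter:
    def test_grating_attenuated_by_scalar_gain(self):
        side = 128
        img = _grating(side, 12)
        out = apply_sf_filter(img, BandSpec("R3", 10, 18, 4))
        gain = butterworth_bandpass_gain(12.0, BandSpec("R3", 10, 18, 4))
        assert out.std() == pytest.approx(gain * img.std(), rel=1e-9)

    def test_constant_image_maps_to_zero(self):
        out = apply_sf_filter(np.full((64, 64), 0.7), R4)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_out_of_band_grating_suppressed(self):
        side = 256
        img = _grating(side, 100)
        out = apply_sf_filter(img, BandSpec("R1", 1, 5, 4))
        assert out.std() < 0.01 * img.std()

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.random((64, 64))
        y = rng.random((64, 64))
        lhs = apply_sf_filter(2.0 * x - 0.5 * y, R4)
        rhs = 2.0 * apply_sf_filter(x, R4) - 0.5 * apply_sf_filter(y, R4)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_band_output_is_zero_mean(self):
        rng = np.random.default_rng(1)
        out = apply_sf_filter(rng.random((64, 64)), R4)
        assert abs(out.mean()) < 1e-10


class TestPhaseScramble:
    def test_amplitude_spectrum_preserved(self):
        rng = np.random.default_rng(2)
        img = rng.random((64, 64))
        out = phase_scramble(img, np.random.default_rng(3))
        amp_in = np.abs(np.fft.fft2(img))
        amp_out = np.abs(np.fft.fft2(out))
        assert np.allclose(amp_in, amp_out, rtol=1e-8, atol=1e-8)

    def test_power_preserved_within_one_percent(self):
        rng = np.random.default_rng(4)
        img = rng.random((64, 64))
        out = phase_scramble(img, np.random.default_rng(5))
        assert sf_power(out) == pytest.approx(sf_power(img), rel=0.01)

    def test_deterministic_given_seed(self):
        img = np.random.default_rng(6).random((32, 32))
        a = phase_scramble(img, np.random.default_rng(7))
        b = phase_scramble(img, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_decorrelates_broadband_image(self):
        # broadband (1/f) texture: phase randomization rotates many
        # independent components, so pixel-wise correlation collapses
        img = stimgen.make_texture_bases(1, 64, np.random.default_rng(20),
                                         n_face=1, n_nonface=0)[0][2]
        cors = []
        for seed in range(5):
            out = phase_scramble(img, np.random.default_rng(seed))
            cors.append(np.corrcoef(img.ravel(), out.ravel())[0, 1])
        assert np.mean(np.abs(cors)) < 0.25


class TestNormalization:
    def test_default_targets_hit_exactly(self):
        img = np.random.default_rng(8).random((100, 100))
        out = normalize_luminance_contrast(img)
        assert out.mean() == pytest.approx(0.5, abs=1e-6)
        assert out.std() == pytest.approx(0.0314, abs=1e-6)

    def test_identity_on_already_normalized(self):
        img = np.random.default_rng(9).random((50, 50))
        once = normalize_luminance_contrast(img)
        twice = normalize_luminance_contrast(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            normalize_luminance_contrast(np.full((32, 32), 0.3))

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            NormTargets(L=0.0)
        with pytest.raises(ValueError):
            NormTargets(C=-1.0)


class TestSfPower:
    def test_zero_image(self):
        assert sf_power(np.zeros((32, 32))) == 0.0

    def test_parseval_identity(self):
        img = np.random.default_rng(10).random((48, 48))
        spatial = float(np.sum(img**2)) * img.size
        assert sf_power(img) == pytest.approx(spatial, rel=1e-10)

    def test_quadratic_scaling(self):
        img = np.random.default_rng(11).random((32, 32))
        assert sf_power(2 * img) == pytest.approx(4 * sf_power(img), rel=1e-10)


class TestBuildStimulusSet:
    @pytest.fixture(scope="class")
    def small_set(self):
        rng = np.random.default_rng(12)
        bases = stimgen.make_texture_bases(3, 64, rng, n_face=1, n_nonface=1)
        return build_stimulus_set(bases, rng=rng)

    def test_twelve_records_per_base(self, small_set):
        assert len(small_set) == 36

    def test_all_moments_equalized(self, small_set):
        man = records_manifest(small_set)
        assert np.allclose(man["mean"], 0.5, atol=1e-6)
        assert np.allclose(man["std"], 0.0314, atol=1e-6)

    def test_unique_stim_ids(self, small_set):
        ids = [r.stim_id for r in small_set]
        assert len(set(ids)) == len(ids)

    def test_duplicate_base_ids_rejected(self):
        rng = np.random.default_rng(13)
        img = rng.random((32, 32))
        with pytest.raises(ValueError, match="duplicate"):
            build_stimulus_set(
                [("a", "face", img), ("a", "face", img)], rng=rng
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_stimulus_set([], rng=np.random.default_rng(0))

    def test_scrambled_sibling_shares_band_content(self, small_set):
        # scrambling happens before filtering, so sibling band variants
        # carry similar (not identical) AC power in their band
        man = records_manifest(small_set)
        uns = man[(man.band == "R2") & ~man.scrambled].set_index("base_id")
        scr = man[(man.band == "R2") & man.scrambled].set_index("base_id")
        # moments forced equal => AC power forced equal
        assert np.allclose(
            uns["band_power"], scr.loc[uns.index, "band_power"], rtol=1e-6
        )


def test_png_roundtrip(tmp_path):
    img = np.random.default_rng(14).random((32, 32))
    path = tmp_path / "x.png"
    stimgen.save_grayscale_png(img, path)
    back = stimgen.load_grayscale_png(path)
    assert back.shape == (32, 32)
    assert np.abs(back - img).max() <= 1.0 / 255.0 + 1e-9
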