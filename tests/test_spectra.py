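import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slowosc.exceptions import DegenerateSeriesError, ParameterError, ValidationError
from slowosc.spectra import (
    ComponentSpectrum,
    amplitude_spectrum,
    band_falff,
    combine_component_spectra,
    falff_table,
    make_bin_grid,
    resample_to_bins,
    slow5_share,
    smooth_spectrum,
)

TR = 2.6
T = 220


def _flat_spectrum(value=1.0, smoothed=True):
    freqs = np.fft.rfftfreq(T, d=TR)
    amp = np.full_like(freqs, value)
    spec = ComponentSpectrum(freqs=freqs, amplitude=amp, tr_seconds=TR)
    return smooth_spectrum(spec) if smoothed else spec


class TestAmplitudeSpectrum:
    def test_frequency_grid_from_scan_parameters(self):
        spec = amplitude_spectrum(np.random.default_rng(0).normal(size=T), TR)
        assert len(spec.freqs) == T // 2 + 1
        assert spec.freqs[1] == pytest.approx(1.0 / (T * TR))  # ~0.001748 Hz
        assert spec.nyquist == pytest.approx(0.19230769, abs=1e-8)

    def test_on_grid_sinusoid_concentrates_at_its_frequency(self):
        k = 11
        t = np.arange(T) * TR
        f0 = k / (T * TR)
        series = np.sin(2 * np.pi * f0 * t)
        spec = amplitude_spectrum(series - series.mean(), TR)
        peak = spec.amplitude[k]
        off = np.delete(spec.amplitude, k)
        assert peak == pytest.approx(T / 2, rel=1e-9)
        assert off.max() < 1e-9 * peak

    def test_zero_series_gives_zero_spectrum(self):
        spec = amplitude_spectrum(np.zeros(T), TR)
        assert np.all(spec.amplitude == 0)

    def test_nan_rejected(self):
        x = np.zeros(T)
        x[5] = np.nan
        with pytest.raises(ValidationError):
            amplitude_spectrum(x, TR)

    def test_parseval_energy_identity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=T)
        x -= x.mean()
        spec = amplitude_spectrum(x, TR)
        a2 = spec.amplitude**2
        # one-sided doubling: interior bins count twice (even length)
        total = a2[0] + a2[-1] + 2 * a2[1:-1].sum()
        assert total == pytest.approx(T * (x**2).sum(), rel=1e-8)


class TestSmoothing:
    def test_impulse_response_is_gaussian(self):
        freqs = np.fft.rfftfreq(T, d=TR)
        amp = np.zeros_like(freqs)
        amp[50] = 1.0
        spec = smooth_spectrum(ComponentSpectrum(freqs=freqs, amplitude=amp, tr_seconds=TR))
        sm = spec.smoothed_amplitude
        k = np.arange(len(freqs))
        expected = np.exp(-((k - 50) ** 2) / (2 * 2.0**2))
        expected /= expected.sum()
        assert np.allclose(sm, expected, atol=1e-4)

    def test_flat_stays_flat_and_mass_conserved(self):
        spec = _flat_spectrum(3.0)
        assert np.allclose(spec.smoothed_amplitude, 3.0, rtol=1e-12)
        rng = np.random.default_rng(1)
        raw = amplitude_spectrum(rng.normal(size=T), TR)
        sm = smooth_spectrum(raw)
        n = len(raw.freqs)
        interior = slice(int(0.05 * n), int(0.95 * n))
        before = raw.amplitude[interior].sum()
        after = sm.smoothed_amplitude[interior].sum()
        assert after == pytest.approx(before, rel=0.01)

    def test_bad_sigma_rejected(self):
        with pytest.raises(ParameterError):
            smooth_spectrum(_flat_spectrum(smoothed=False), sigma_bins=0)


class TestBinGrid:
    def test_default_grid_has_34_bins(self):
        grid = make_bin_grid()
        assert grid.n_bins == 34
        assert grid.edges[0] == pytest.approx(0.009)
        assert grid.edges[-1] == pytest.approx(0.060)
        assert np.allclose(np.diff(grid.edges), 0.0015)

    def test_flat_spectrum_resamples_to_constant(self):
        vals = resample_to_bins(_flat_spectrum(2.5), make_bin_grid())
        assert vals.shape == (34,)
        assert np.allclose(vals, 2.5)

    def test_linear_spectrum_interpolates_exactly(self):
        freqs = np.fft.rfftfreq(T, d=TR)
        amp = 7.0 * freqs + 0.3
        spec = ComponentSpectrum(freqs=freqs, amplitude=amp, tr_seconds=TR)
        grid = make_bin_grid()
        vals = resample_to_bins(spec, grid, use_smoothed=False)
        assert np.allclose(vals, 7.0 * grid.centers + 0.3, atol=1e-12)

    def test_grid_outside_nyquist_rejected(self):
        short = ComponentSpectrum(
            freqs=np.linspace(0, 0.05, 50), amplitude=np.ones(50), tr_seconds=10.0
        )
        with pytest.raises(ParameterError):
            resample_to_bins(short, make_bin_grid(), use_smoothed=False)


class TestBandFalff:
    def test_flat_spectrum_equals_band_bin_fraction(self, scheme):
        spec = _flat_spectrum()
        s5 = scheme["slow5"].mask(spec.freqs).sum()
        full = scheme["full"].mask(spec.freqs).sum()
        v = band_falff(spec, scheme["slow5"], scheme["full"])
        assert v == pytest.approx(s5 / full, rel=1e-12)
        # discrete value sits within 2% of the continuous bandwidth ratio
        assert v == pytest.approx(0.017 / spec.nyquist, rel=0.02)

    def test_narrowband_sinusoid_dominates_slow5(self, scheme):
        t = np.arange(T) * TR
        f0 = 11 / (T * TR)  # on-grid, inside slow-5
        rng = np.random.default_rng(0)
        series = np.sin(2 * np.pi * f0 * t) + 1e-4 * rng.normal(size=T)
        spec = smooth_spectrum(amplitude_spectrum(series - series.mean(), TR))
        assert band_falff(spec, scheme["slow5"], scheme["full"]) > 0.9

    def test_numerator_equals_denominator_gives_one(self, scheme):
        spec = _flat_spectrum()
        assert band_falff(spec, scheme["full"], scheme["full"]) == 1.0

    def test_zero_mass_denominator_raises(self, scheme):
        freqs = np.fft.rfftfreq(T, d=TR)
        spec = ComponentSpectrum(freqs=freqs, amplitude=np.zeros_like(freqs), tr_seconds=TR)
        with pytest.raises(DegenerateSeriesError):
            band_falff(spec, scheme["slow5"], scheme["full"], use_smoothed=False)

    def test_numerator_outside_denominator_rejected(self, scheme):
        with pytest.raises(ParameterError):
            band_falff(_flat_spectrum(), scheme["full"], scheme["slow5"])

    def test_disjoint_band_additivity(self, scheme):
        rng = np.random.default_rng(2)
        spec = smooth_spectrum(amplitude_spectrum(rng.normal(size=T), TR))
        s5 = band_falff(spec, scheme["slow5"], scheme["full"])
        s4 = band_falff(spec, scheme["slow4"], scheme["full"])
        rest = band_falff(spec, scheme["resting"], scheme["full"])
        assert s5 + s4 == pytest.approx(rest, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-6, max_value=1e6), seed=st.integers(0, 100))
    def test_scale_invariance(self, scheme, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=T)
        a = smooth_spectrum(amplitude_spectrum(x, TR))
        b = smooth_spectrum(amplitude_spectrum(scale * x, TR))
        va = band_falff(a, scheme["slow5"], scheme["full"])
        vb = band_falff(b, scheme["slow5"], scheme["full"])
        assert va == pytest.approx(vb, rel=1e-9)
        assert 0.0 <= va <= 1.0


class TestSlow5Share:
    def test_all_mass_in_slow5_gives_one(self, scheme):
        freqs = np.fft.rfftfreq(T, d=TR)
        amp = np.where(scheme["slow5"].mask(freqs), 1.0, 0.0)
        spec = ComponentSpectrum(freqs=freqs, amplitude=amp, tr_seconds=TR)
        assert slow5_share(spec, scheme, use_smoothed=False) == 1.0

    def test_all_mass_in_slow4_gives_zero(self, scheme):
        freqs = np.fft.rfftfreq(T, d=TR)
        amp = np.where(scheme["slow4"].mask(freqs), 1.0, 0.0)
        spec = ComponentSpectrum(freqs=freqs, amplitude=amp, tr_seconds=TR)
        assert slow5_share(spec, scheme, use_smoothed=False) == 0.0

    def test_flat_spectrum_share_equals_bin_fraction(self, scheme):
        spec = _flat_spectrum()
        s5 = scheme["slow5"].mask(spec.freqs).sum()
        rest = scheme["resting"].mask(spec.freqs).sum()
        assert slow5_share(spec, scheme) == pytest.approx(s5 / rest, rel=1e-12)
        # close to the continuous bandwidth ratio 0.017/0.063
        assert slow5_share(spec, scheme) == pytest.approx(0.017 / 0.063, abs=0.02)


class TestCombine:
    def test_identical_spectra_unchanged(self):
        spec = _flat_spectrum(2.0)
        comb = combine_component_spectra([spec, spec, spec])
        assert np.allclose(comb.smoothed_amplitude, spec.smoothed_amplitude)

    def test_two_flat_spectra_average(self):
        comb = combine_component_spectra([_flat_spectrum(1.0), _flat_spectrum(3.0)])
        assert np.allclose(comb.amplitude, 2.0)

    def test_composite_falff_is_mean_of_members_when_denominators_match(self, scheme):
        # equal total mass in members -> composite fALFF = mean of member fALFFs
        rng = np.random.default_rng(4)
        specs = []
        for _ in range(3):
            x = rng.normal(size=T)
            s = smooth_spectrum(amplitude_spectrum(x, TR))
            scale = 1.0 / s.smoothed_amplitude.sum()
            specs.append(
                ComponentSpectrum(
                    freqs=s.freqs,
                    amplitude=s.amplitude * scale,
                    smoothed_amplitude=s.smoothed_amplitude * scale,
                    tr_seconds=TR,
                )
            )
        comb = combine_component_spectra(specs)
        v = band_falff(comb, scheme["slow5"], scheme["full"])
        member = np.mean([band_falff(s, scheme["slow5"], scheme["full"]) for s in specs])
        assert v == pytest.approx(member, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        a = _flat_spectrum()
        freqs = np.fft.rfftfreq(100, d=TR)
        b = ComponentSpectrum(freqs=freqs, amplitude=np.ones_like(freqs), tr_seconds=TR)
        with pytest.raises(ValidationError):
            combine_component_spectra([a, b])


def test_falff_table_builds_composites_and_bounded_values(scheme):
    rng = np.random.default_rng(9)
    specs = []
    for sid in ("s0", "s1"):
        for comp in ("pDMN", "aDMN", "vDMN", "visual", "motor"):
            specs.append(
                smooth_spectrum(
                    amplitude_spectrum(rng.normal(size=T), TR, subject_id=sid, component=comp)
                )
            )
    table = falff_table(specs, scheme, groups={"s0": "old", "s1": "young"})
    comps = set(table["component"])
    assert {"DMN", "visual-sensorimotor"} <= comps
    assert ((table["falff"] >= 0) & (table["falff"] <= 1)).all()
    # per subject/component: slow5 + slow4 = resting over the same denominator
    for (sid, comp), sl in table.groupby(["subject_id", "component"]):
        vals = sl.set_index("band")["falff"]
        assert vals["slow5"] + vals["slow4"] == pytest.approx(vals["resting"], abs=1e-12)
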