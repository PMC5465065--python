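"""Equivalent-circuit impedance: analytic limits, fitting, band evaluation."""

import numpy as np
import pytest

from zfeeg.impedance import (
    EEG_BAND_FREQS,
    circuit_impedance,
    evaluate_band_frequencies,
    fit_circuit,
    load_spectrum_csv,
    reference_skin_spectrum,
)
from zfeeg.types import CircuitParams, EISSpectrum, InvalidArgumentError


def _random_params(rng):
    return CircuitParams(
        R_s=float(rng.uniform(1e3, 1e5)),
        R_ct=float(rng.uniform(1e5, 1e8)),
        Q=float(10 ** rng.uniform(-9, -5)),
        n=float(rng.uniform(0.5, 1.0)),
    )


class TestCircuitImpedance:
    def test_cpe_with_n_one_is_a_capacitor(self):
        # R_ct huge so the parallel block is pure CPE; |Z - R_s| = 1/(wC)
        C = 1e-6
        p = CircuitParams(R_s=100.0, R_ct=1e15, Q=C, n=1.0)
        for f in (1.0, 10.0, 100.0):
            z = circuit_impedance(p, f)
            assert abs(z - p.R_s) == pytest.approx(
                1.0 / (2 * np.pi * f * C), rel=1e-6
            )

    def test_high_frequency_limit_is_series_resistance(self):
        # both parallel blocks short out as omega -> inf; at 1e9 Hz the
        # CPE impedance is negligible for interface-like (Q, n) values
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = CircuitParams(
                R_s=float(rng.uniform(1e3, 1e5)),
                R_ct=float(rng.uniform(1e5, 1e8)),
                Q=float(10 ** rng.uniform(-8, -6)),
                n=float(rng.uniform(0.8, 1.0)),
            )
            z = circuit_impedance(p, 1e9)
            assert abs(z) == pytest.approx(p.R_s, rel=0.01)

    def test_matches_direct_complex_arithmetic(self):
        # independent oracle: literal parallel/series complex arithmetic
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = _random_params(rng)
            f = float(10 ** rng.uniform(-1, 5))
            w = 2 * np.pi * f
            z_cpe = 1.0 / (p.Q * (1j * w) ** p.n)
            expected = p.R_s + (p.R_ct * z_cpe) / (p.R_ct + z_cpe)
            assert circuit_impedance(p, f) == pytest.approx(expected, rel=1e-10)

    def test_full_model_adds_subcutaneous_block(self):
        p = CircuitParams(
            R_s=1e3, R_ct=1e6, Q=1e-7, n=0.9, R_sub=5e4, C_sub=1e-8
        )
        f = 10.0
        w = 2 * np.pi * f
        z_cpe = 1.0 / (p.Q * (1j * w) ** p.n)
        z_c = 1.0 / (1j * w * p.C_sub)
        expected = (
            p.R_s
            + (p.R_sub * z_c) / (p.R_sub + z_c)
            + (p.R_ct * z_cpe) / (p.R_ct + z_cpe)
        )
        assert circuit_impedance(p, f) == pytest.approx(expected, rel=1e-10)

    def test_nonpositive_frequency_rejected(self):
        p = CircuitParams(R_s=1e3, R_ct=1e6, Q=1e-7, n=0.9)
        with pytest.raises(InvalidArgumentError):
            circuit_impedance(p, 0.0)

    def test_magnitude_monotone_nonincreasing(self):
        rng = np.random.default_rng(2)
        freqs = np.geomspace(0.1, 1e5, 200)
        for _ in range(20):
            mags = np.abs(circuit_impedance(_random_params(rng), freqs))
            assert np.all(np.diff(mags) <= 1e-9 * mags[:-1])

    def test_phase_between_minus_ninety_and_zero(self):
        rng = np.random.default_rng(3)
        freqs = np.geomspace(0.1, 1e5, 100)
        for _ in range(20):
            z = circuit_impedance(_random_params(rng), freqs)
            phase = np.angle(z, deg=True)
            assert np.all(phase <= 1e-9) and np.all(phase >= -90.0 - 1e-9)


class TestFitCircuit:
    def test_selfconsistency_on_noiseless_data(self):
        true = CircuitParams(R_s=2e4, R_ct=5e6, Q=8e-8, n=0.9)
        freqs = np.geomspace(0.5, 100.0, 12)
        mags = np.abs(circuit_impedance(true, freqs))
        fit = fit_circuit(
            EISSpectrum(freqs=freqs, magnitude=mags), model="reduced"
        )
        assert fit.max_abs_residual <= 1e-6

    def test_parameter_recovery_noiseless(self):
        # identifiable subset (Q, n, R_s) recovered within 10%
        rng = np.random.default_rng(4)
        for _ in range(5):
            true = CircuitParams(
                R_s=float(rng.uniform(1e4, 5e4)),
                R_ct=float(rng.uniform(1e6, 1e7)),
                Q=float(10 ** rng.uniform(-8, -7)),
                n=float(rng.uniform(0.7, 0.95)),
            )
            freqs = np.geomspace(0.1, 1e4, 25)
            mags = np.abs(circuit_impedance(true, freqs))
            fit = fit_circuit(
                EISSpectrum(freqs=freqs, magnitude=mags), model="reduced"
            )
            assert fit.params.n == pytest.approx(true.n, rel=0.1)
            assert fit.params.Q == pytest.approx(true.Q, rel=0.1)
            assert fit.params.R_s == pytest.approx(true.R_s, rel=0.1)

    def test_recovery_with_one_percent_noise(self):
        rng = np.random.default_rng(5)
        true = CircuitParams(R_s=3e4, R_ct=8e6, Q=7e-8, n=0.9)
        freqs = np.geomspace(0.1, 1e4, 30)
        mags = np.abs(circuit_impedance(true, freqs))
        noisy = mags * (1.0 + 0.01 * rng.standard_normal(len(mags)))
        fit = fit_circuit(
            EISSpectrum(freqs=freqs, magnitude=noisy), model="reduced"
        )
        assert fit.params.n == pytest.approx(true.n, rel=0.1)
        assert fit.params.Q == pytest.approx(true.Q, rel=0.1)

    def test_reference_spectrum_fit_quality(self):
        fit = fit_circuit(reference_skin_spectrum())
        assert fit.model == "reduced"
        assert fit.max_abs_residual <= 0.05  # dex

    def test_too_few_points_rejected(self):
        spec = EISSpectrum(
            freqs=np.array([1.0, 10.0, 100.0]),
            magnitude=np.array([1e6, 1e5, 1e4]),
        )
        with pytest.raises(InvalidArgumentError):
            fit_circuit(spec, model="reduced")


class TestBandEvaluation:
    def test_band_frequencies_cover_the_five_eeg_bands(self):
        assert list(EEG_BAND_FREQS.values()) == [1.0, 5.0, 10.0, 30.0, 50.0]

    def test_magnitudes_decrease_across_bands(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            mags = list(evaluate_band_frequencies(_random_params(rng)).values())
            assert all(a >= b for a, b in zip(mags, mags[1:]))

    def test_spectrum_csv_roundtrip(self, tmp_path):
        ref = reference_skin_spectrum()
        path = tmp_path / "spec.csv"
        import pandas as pd

        pd.DataFrame(
            {"freq_hz": ref.freqs, "z_mag_ohm": ref.magnitude}
        ).to_csv(path, index=False)
        back = load_spectrum_csv(path)
        np.testing.assert_allclose(back.magnitude, ref.magnitude)
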