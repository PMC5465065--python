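"""Skin-electrode equivalent-circuit impedance with a constant phase element.

The interface between a dry gold electrode and mucous fish skin does not
behave as an ideal capacitor, so the electrode block is modelled as a
charge-transfer resistance in parallel with a constant phase element
(CPE), Z_CPE = 1 / (Q (jω)^n) with n ∈ [0, 1]. The full series chain is

    Z(ω) = R_s + (R_sub ∥ 1/(jωC_sub)) + (R_ct ∥ Z_CPE)

where the middle block lumps the subcutaneous layers (epidermis, scales,
skull). With only a handful of magnitude points the subcutaneous block is
not identifiable and a reduced 4-parameter chain R_s + (R_ct ∥ Z_CPE) is
fitted instead; the full model is used for dense spectra.

Fits minimise residuals of log10|Z| (magnitudes span MΩ to kΩ across the
EEG band, so a linear objective would be dominated by the lowest
frequency), with phase residuals added when the spectrum carries phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd

from .types import CircuitParams, EISSpectrum, FittingError, InvalidArgumentError

#: Representative frequencies of the five classical EEG bands.
EEG_BAND_FREQS = {
    "delta": 1.0,
    "theta": 5.0,
    "alpha": 10.0,
    "beta": 30.0,
    "gamma": 50.0,
}

#: Minimum number of points to fit the reduced (4-parameter) model.
MIN_POINTS_REDUCED = 4
#: Minimum number of points before the full 6-parameter model is attempted.
MIN_POINTS_FULL = 8


def circuit_impedance(
    params: CircuitParams, freq: float | np.ndarray
) -> complex | np.ndarray:
    """Complex impedance of the equivalent circuit at ``freq`` (Hz)."""
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0):
        raise InvalidArgumentError("frequency must be positive")
    w = 2 * np.pi * f
    z_cpe = 1.0 / (params.Q * (1j * w) ** params.n)
    z = params.R_s + 1.0 / (1.0 / params.R_ct + 1.0 / z_cpe)
    if params.R_sub is not None:
        z_c = 1.0 / (1j * w * params.C_sub)
        z = z + 1.0 / (1.0 / params.R_sub + 1.0 / z_c)
    return complex(z) if np.isscalar(freq) else z


@dataclass(frozen=True)
class FitResult:
    params: CircuitParams
    residuals: np.ndarray  # per-point log10|Z| residuals (dex)
    chi_square: float
    reduced_chi_square: float
    n_points: int
    n_free: int
    model: str  # "reduced" or "full"

    @property
    def max_abs_residual(self) -> float:
        return float(np.max(np.abs(self.residuals)))


def _to_circuit(p: lmfit.Parameters, model: str) -> CircuitParams:
    kw = dict(
        R_s=p["R_s"].value, R_ct=p["R_ct"].value, Q=p["Q"].value, n=p["n"].value
    )
    if model == "full":
        kw.update(R_sub=p["R_sub"].value, C_sub=p["C_sub"].value)
    return CircuitParams(**kw)


def fit_circuit(
    spectrum: EISSpectrum,
    init: CircuitParams | None = None,
    model: str | None = None,
) -> FitResult:
    """Least-squares fit of the equivalent circuit to a magnitude spectrum.

    ``model`` is "reduced" (4 parameters) or "full" (6 parameters); by
    default the full model is used only when the spectrum has at least 8
    points. Phase residuals (scaled to match the log-magnitude range) are
    included when the spectrum provides phase.
    """
    order = np.argsort(spectrum.freqs)
    f = spectrum.freqs[order]
    mag = spectrum.magnitude[order]
    phase = None if spectrum.phase is None else np.asarray(spectrum.phase)[order]
    if model is None:
        model = "full" if len(f) >= MIN_POINTS_FULL else "reduced"
    min_pts = MIN_POINTS_REDUCED if model == "reduced" else MIN_POINTS_FULL
    if len(f) < min_pts:
        raise InvalidArgumentError(
            f"{model} model needs at least {min_pts} frequency points"
        )

    def make_params(n0: float) -> lmfit.Parameters:
        p = lmfit.Parameters()
        if init is not None:
            p.add("R_s", init.R_s, min=1e-3)
            p.add("R_ct", init.R_ct, min=1e-3)
            p.add("Q", init.Q, min=1e-15)
            p.add("n", init.n, min=0.0, max=1.0)
            if model == "full":
                p.add("R_sub", init.R_sub or mag[-1], min=1e-3)
                p.add("C_sub", init.C_sub or 1e-7, min=1e-15)
            return p
        # heuristics: |Z| flattens to R_s at high f and the CPE dominates
        # the low-f rise; Q from the mid-band magnitude given a trial n0
        p.add("R_s", 0.5 * mag[-1], min=1e-3)
        p.add("R_ct", 20.0 * mag[0], min=1e-3)
        f_mid = f[len(f) // 2]
        q0 = 1.0 / (mag[len(f) // 2] * (2 * np.pi * f_mid) ** n0)
        p.add("Q", q0, min=1e-15)
        p.add("n", n0, min=0.0, max=1.0)
        if model == "full":
            p.add("R_sub", mag[len(f) // 3], min=1e-3)
            p.add("C_sub", 1e-7, min=1e-15)
        return p

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        cp = _to_circuit(pars, model)
        z = circuit_impedance(cp, f)
        res = np.log10(np.abs(z)) - np.log10(mag)
        if phase is not None:
            res = np.concatenate([res, (np.angle(z, deg=True) - phase) / 90.0])
        return res

    # the CPE exponent creates shallow local minima; multistart over n0
    starts = [0.6, 0.7, 0.8, 0.9] if init is None else [init.n]
    out = None
    for n0 in starts:
        try:
            cand = lmfit.minimize(residual, make_params(n0), method="least_squares")
        except Exception:
            continue
        if cand.success and (out is None or cand.chisqr < out.chisqr):
            out = cand
    if out is None:
        raise FittingError("circuit fit did not converge from any start point")
    fitted = _to_circuit(out.params, model)
    res = np.log10(np.abs(circuit_impedance(fitted, f))) - np.log10(mag)
    return FitResult(
        params=fitted,
        residuals=res,
        chi_square=float(out.chisqr),
        reduced_chi_square=float(out.redchi),
        n_points=len(f),
        n_free=int(out.nfree) if out.nfree else len(f) - out.nvarys,
        model=model,
    )


def evaluate_band_frequencies(params: CircuitParams) -> dict[str, float]:
    """|Z| (Ω) at the representative frequency of each EEG band."""
    return {
        band: float(np.abs(circuit_impedance(params, f)))
        for band, f in EEG_BAND_FREQS.items()
    }


def load_spectrum_csv(path: str | Path) -> EISSpectrum:
    """Read a spectrum CSV with columns freq_hz, z_mag_ohm[, phase_deg]."""
    df = pd.read_csv(path)
    if not {"freq_hz", "z_mag_ohm"} <= set(df.columns):
        raise InvalidArgumentError(
            f"{path}: expected columns freq_hz, z_mag_ohm[, phase_deg]"
        )
    phase = df["phase_deg"].to_numpy() if "phase_deg" in df.columns else None
    return EISSpectrum(
        freqs=df["freq_hz"].to_numpy(dtype=float),
        magnitude=df["z_mag_ohm"].to_numpy(dtype=float),
        phase=phase,
    )


def reference_skin_spectrum() -> EISSpectrum:
    """The bundled five-point skin-electrode magnitude spectrum measured
    on adult zebrafish at the representative EEG-band frequencies."""
    with resources.files("zfeeg").joinpath("data/paper_impedance.csv").open() as fh:
        df = pd.read_csv(fh)
    return EISSpectrum(
        freqs=df["freq_hz"].to_numpy(dtype=float),
        magnitude=df["z_mag_ohm"].to_numpy(dtype=float),
    )
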