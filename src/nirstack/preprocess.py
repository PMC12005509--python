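"""Raw optical intensities to hemoglobin concentration changes.

The chain is: absorbance change relative to a rest baseline (log-ratio),
the modified Beer-Lambert law (a 2x2 linear solve per channel and sample
mapping absorbance at two wavelengths onto dHbO/dHbR in uM), a zero-phase
Butterworth bandpass (0.01-0.2 Hz by default) that removes drift, Mayer
waves leakage, respiration and cardiac pulsation, and mean subtraction over
the rest padding as baseline correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import Paradigm, RawIntensityRecording, ValidationError

__all__ = [
    "ExtinctionTable",
    "HemoTimeSeries",
    "FilterSpec",
    "default_extinction_table",
    "absorbance_change",
    "mbll_convert",
    "bandpass",
    "baseline_correct",
    "preprocess_recording",
]

#: condition-number ceiling above which the extinction matrix is rejected
COND_TOL = 1e8


@dataclass(frozen=True)
class ExtinctionTable:
    """Extinction coefficients and differential path length factor.

    ``alpha`` is the 2x2 matrix ``[[aHbO(l1), aHbR(l1)], [aHbO(l2),
    aHbR(l2)]]`` in uM^-1 cm^-1; ``dpf`` is the dimensionless path-length
    correction ``d``.  These are instrument/physiology constants, not method
    content, so they are fully overridable.
    """

    alpha: np.ndarray
    dpf: float
    wavelengths_nm: tuple[float, float]

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.shape != (2, 2):
            raise ValidationError(f"alpha must be 2x2, got {alpha.shape}")
        if not np.all(alpha > 0):
            raise ValidationError("extinction coefficients must be positive")
        cond = np.linalg.cond(alpha)
        if cond > COND_TOL:
            raise ValidationError(
                f"extinction matrix is numerically singular (condition number {cond:.3g} "
                f"> {COND_TOL:.0e})"
            )
        if self.dpf <= 0:
            raise ValidationError("dpf must be positive")
        object.__setattr__(self, "alpha", alpha)


def default_extinction_table(wavelengths_nm: tuple[float, float] = (760.0, 850.0),
                             dpf: float = 6.0) -> ExtinctionTable:
    """Default coefficients for the common 760/850 nm wavelength pair.

    Molar extinction values from the standard compiled hemoglobin spectra,
    converted to uM^-1 cm^-1.  Only the 760/850 pair is tabulated; other
    pairs must supply their own table.
    """
    table = {
        760.0: (0.000586, 0.00154852),   # (aHbO, aHbR)
        850.0: (0.001058, 0.00069132),
    }
    try:
        row1 = table[float(wavelengths_nm[0])]
        row2 = table[float(wavelengths_nm[1])]
    except KeyError as exc:
        raise ValidationError(
            f"no built-in extinction coefficients for {exc} nm; supply an ExtinctionTable"
        ) from exc
    alpha = np.array([row1, row2], dtype=float)
    return ExtinctionTable(alpha, dpf, tuple(float(w) for w in wavelengths_nm))


@dataclass
class HemoTimeSeries:
    """Concentration changes dHbO/dHbR/dHbT in uM, channels x samples."""

    dHbO: np.ndarray
    dHbR: np.ndarray
    dHbT: np.ndarray
    fs_hz: float
    montage: object = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dHbO = np.asarray(self.dHbO, dtype=float)
        self.dHbR = np.asarray(self.dHbR, dtype=float)
        self.dHbT = np.asarray(self.dHbT, dtype=float)
        if not (self.dHbO.shape == self.dHbR.shape == self.dHbT.shape):
            raise ValidationError("dHbO/dHbR/dHbT must share one shape")
        if self.dHbO.ndim != 2:
            raise ValidationError("chromophore arrays must be 2D (channels x samples)")
        if not np.allclose(self.dHbT, self.dHbO + self.dHbR, atol=1e-9, rtol=1e-7):
            raise ValidationError("dHbT must equal dHbO + dHbR")
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.dHbO.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dHbO.shape[1]

    def chromophore(self, name: str) -> np.ndarray:
        try:
            return {"HbO": self.dHbO, "HbR": self.dHbR, "HbT": self.dHbT}[name]
        except KeyError:
            raise ValidationError(f"unknown chromophore {name!r}; expected HbO/HbR/HbT")

    def with_data(self, dHbO: np.ndarray, dHbR: np.ndarray, note: str) -> "HemoTimeSeries":
        return HemoTimeSeries(
            dHbO, dHbR, dHbO + dHbR, self.fs_hz, self.montage,
            provenance=[*self.provenance, note],
        )


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass filter parameters; defaults keep the 0.01-0.2 Hz band."""

    low_cut_hz: float = 0.01
    high_cut_hz: float = 0.2
    order: int = 3
    design: str = "butter_zero_phase"

    def __post_init__(self) -> None:
        if not (0 < self.low_cut_hz < self.high_cut_hz):
            raise ValidationError("need 0 < low_cut_hz < high_cut_hz")
        if self.order < 1:
            raise ValidationError("order must be a positive integer")
        if self.design != "butter_zero_phase":
            raise ValidationError(f"unknown filter design {self.design!r}")


def absorbance_change(rec: RawIntensityRecording,
                      baseline: tuple[int, int] | None = None) -> np.ndarray:
    """Absorbance change dA(t; wavelength) relative to a baseline window.

    ``dA = -log10(I(t) / mean(I over baseline))`` per channel and
    wavelength.  ``baseline`` is a half-open sample range; by default the
    first 30 s (or the whole recording if shorter).
    """
    if baseline is None:
        baseline = (0, min(rec.n_samples, int(round(30.0 * rec.fs_hz))))
    lo, hi = baseline
    if not (0 <= lo < hi <= rec.n_samples):
        raise ValueError(
            f"baseline range [{lo}, {hi}) is empty or outside the recording "
            f"of {rec.n_samples} samples"
        )
    ref = rec.intensities[:, lo:hi, :].mean(axis=1, keepdims=True)
    return -np.log10(rec.intensities / ref)


def mbll_convert(dA: np.ndarray, ext: ExtinctionTable, separation_cm: float,
                 fs_hz: float, montage=None) -> HemoTimeSeries:
    """Modified Beer-Lambert law: absorbance changes to concentration changes.

    Per channel and time point solves ``alpha @ [dHbO, dHbR] * l * d = dA``
    for the two chromophores; total hemoglobin is their sum.  Units are uM
    when ``alpha`` is in uM^-1 cm^-1 and ``separation_cm`` in cm.
    """
    dA = np.asarray(dA, dtype=float)
    if dA.ndim != 3 or dA.shape[2] != 2:
        raise ValidationError(f"dA must be (channels, samples, 2); got {dA.shape}")
    if separation_cm <= 0:
        raise ValidationError("separation_cm must be positive")
    cond = np.linalg.cond(ext.alpha)
    if cond > COND_TOL:
        raise np.linalg.LinAlgError(
            f"extinction matrix condition number {cond:.3g} exceeds {COND_TOL:.0e}"
        )
    inv = np.linalg.inv(ext.alpha)
    scale = 1.0 / (separation_cm * ext.dpf)
    # concentrations[c, t, :] = inv @ dA[c, t, :] * scale
    conc = np.einsum("ij,ctj->cti", inv, dA) * scale
    dHbO, dHbR = conc[..., 0], conc[..., 1]
    return HemoTimeSeries(
        dHbO, dHbR, dHbO + dHbR, fs_hz, montage,
        provenance=[f"mbll(l={separation_cm} cm, dpf={ext.dpf})"],
    )


def _sos(spec: FilterSpec, fs_hz: float) -> np.ndarray:
    if fs_hz <= 2 * spec.high_cut_hz:
        raise ValidationError(
            f"sampling rate {fs_hz} Hz too low for high cutoff {spec.high_cut_hz} Hz"
        )
    return signal.butter(spec.order, [spec.low_cut_hz, spec.high_cut_hz],
                         btype="bandpass", fs=fs_hz, output="sos")


def bandpass(series: HemoTimeSeries, spec: FilterSpec | None = None) -> HemoTimeSeries:
    """Zero-phase Butterworth bandpass applied to every channel and chromophore.

    Forward-backward filtering preserves event timing for epoching; output
    length equals input length.
    """
    spec = spec or FilterSpec()
    sos = _sos(spec, series.fs_hz)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if series.n_samples <= padlen:
        min_s = (padlen + 1) / series.fs_hz
        raise ValidationError(
            f"series of {series.n_samples} samples is shorter than the filter warm-up; "
            f"need at least {padlen + 1} samples ({min_s:.1f} s at {series.fs_hz} Hz)"
        )
    dHbO = signal.sosfiltfilt(sos, series.dHbO, axis=1)
    dHbR = signal.sosfiltfilt(sos, series.dHbR, axis=1)
    return series.with_data(
        dHbO, dHbR,
        f"bandpass({spec.low_cut_hz}-{spec.high_cut_hz} Hz, order {spec.order}, zero-phase)",
    )


def baseline_correct(series: HemoTimeSeries, paradigm: Paradigm) -> HemoTimeSeries:
    """Subtract the mean over the initial and final rest windows.

    After correction the mean of every channel/chromophore over those rest
    windows is zero to floating tolerance.
    """
    n = series.n_samples
    total = paradigm.total_duration_s()
    if (n + 1) / series.fs_hz < total:
        raise ValidationError(
            f"recording of {n / series.fs_hz:.1f} s is shorter than the paradigm "
            f"({total:.1f} s)"
        )
    idx_init = np.arange(0, int(round(paradigm.initial_rest_s * series.fs_hz)))
    t_final = paradigm.total_duration_s() - paradigm.final_rest_s
    idx_final = np.arange(int(round(t_final * series.fs_hz)), min(n, int(round(total * series.fs_hz))))
    idx = np.concatenate([idx_init, idx_final])
    if idx.size == 0:
        return series.with_data(series.dHbO, series.dHbR, "baseline_correct(no rest padding)")
    dHbO = series.dHbO - series.dHbO[:, idx].mean(axis=1, keepdims=True)
    dHbR = series.dHbR - series.dHbR[:, idx].mean(axis=1, keepdims=True)
    return series.with_data(dHbO, dHbR, "baseline_correct(initial+final rest mean)")


def preprocess_recording(rec: RawIntensityRecording, paradigm: Paradigm,
                         ext: ExtinctionTable | None = None,
                         filter_spec: FilterSpec | None = None) -> HemoTimeSeries:
    """Full preprocessing chain: absorbance, Beer-Lambert, bandpass, baseline."""
    ext = ext or default_extinction_table(rec.wavelengths_nm)
    dA = absorbance_change(rec)
    series = mbll_convert(dA, ext, rec.montage.separation_cm, rec.fs_hz, rec.montage)
    series = bandpass(series, filter_spec)
    return baseline_correct(series, paradigm)
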