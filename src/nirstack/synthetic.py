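"""Synthetic labeled fNIRS recordings with the structure the pipeline assumes.

A double-gamma hemodynamic response convolved with the task boxcar drives
dHbO up (and dHbR down, scaled by a negative ratio) on a subset of
channels; every channel additionally carries cardiac (~1 Hz), respiratory
(~0.3 Hz) and Mayer-wave (~0.1 Hz) oscillations, white noise and slow
drift.  A forward Beer-Lambert model converts concentration changes back
into dual-wavelength light intensities, so the generator and the converter
are exact inverses of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .io import Montage, Paradigm, RawIntensityRecording, ValidationError, motor_cortex_20ch
from .preprocess import ExtinctionTable, HemoTimeSeries, default_extinction_table

__all__ = [
    "NoiseSpec",
    "SimulationConfig",
    "canonical_hrf",
    "simulate_hemo",
    "simulate_raw",
    "simulate_cohort",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes (uM) and frequencies (Hz) of the physiological confounds.

    Cardiac and respiration sit above the 0.2 Hz cutoff and are largely
    removed by the bandpass; Mayer waves at ~0.1 Hz fall inside the band and
    are the main in-band confound, as in real recordings.
    """

    cardiac_amp: float = 0.3
    cardiac_hz: float = 1.0
    respiration_amp: float = 0.2
    respiration_hz: float = 0.3
    mayer_amp: float = 0.5
    mayer_hz: float = 0.1
    white_sd: float = 0.8
    drift_amp: float = 0.5

    def __post_init__(self) -> None:
        for name in ("cardiac_amp", "respiration_amp", "mayer_amp", "white_sd", "drift_amp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(0.0, 1.0, 0.0, 0.3, 0.0, 0.1, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated participant.

    Defaults emulate the acquisition the pipeline targets: 20 channels at
    10.1725 Hz, 30 s rest, 10 trials of 10 s task + 20 s rest, 30 s final
    rest.  Task-evoked dHbO rides on spatially coherent physiological
    oscillations and sensor noise; amplitudes are calibrated so that
    decoding is challenging but clearly above chance, the regime the
    pipeline is built for.  dHbR follows dHbO scaled by a negative ratio.
    """

    paradigm: Paradigm = field(default_factory=Paradigm)
    n_channels: int = 20
    fs_hz: float = 10.1725
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    activation_amp_uM: float = 0.06
    hbr_ratio: float = -0.35
    active_channel_fraction: float = 0.5
    trial_gain_sd: float = 0.3
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValidationError("n_channels must be at least 1")
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz must be positive")
        if not (0 < self.active_channel_fraction <= 1):
            raise ValidationError("active_channel_fraction must be in (0, 1]")
        if self.activation_amp_uM < 0:
            raise ValidationError("activation_amp_uM must be non-negative")
        if self.trial_gain_sd < 0:
            raise ValidationError("trial_gain_sd must be non-negative")


def canonical_hrf(fs_hz: float, peak_s: float = 6.0, undershoot_s: float = 16.0,
                  duration_s: float = 32.0, undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Unit-peak double-gamma hemodynamic response kernel.

    A positive gamma density peaking near ``peak_s`` minus a shallower one
    peaking near ``undershoot_s``, evaluated on the sample grid and divided
    by its maximum so the kernel peak is exactly 1.
    """
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    if not peak_s < undershoot_s:
        raise ValueError("peak_s must precede undershoot_s")
    duration_s = max(duration_s, 30.0)
    t = np.arange(int(round(duration_s * fs_hz))) / fs_hz

    def gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
        tt = np.maximum(t, 1e-12)
        logp = (shape - 1) * np.log(tt) - tt / scale - gammaln(shape) - shape * np.log(scale)
        out = np.exp(logp)
        out[t <= 0] = 0.0
        return out

    # shape*scale is the gamma mode + scale; use scale 1 s so mode ~= peak
    scale = 1.0
    h = gamma_pdf(t, peak_s / scale + 1, scale) - undershoot_ratio * gamma_pdf(
        t, undershoot_s / scale + 1, scale
    )
    return h / h.max()


def _boxcar(paradigm: Paradigm, fs_hz: float, n_samples: int) -> np.ndarray:
    return paradigm.task_mask(fs_hz, n_samples).astype(float)


def simulate_hemo(cfg: SimulationConfig) -> tuple[HemoTimeSeries, np.ndarray]:
    """Simulate one participant's hemoglobin series and the task boxcar.

    The boxcar marks neural truth; the hemodynamic response it drives is
    delayed by the HRF, so task labels and peak response are offset --
    label-shift policy belongs to epoching, not here.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.paradigm.total_duration_s() * cfg.fs_hz))
    t = np.arange(n) / cfg.fs_hz
    boxcar = _boxcar(cfg.paradigm, cfg.fs_hz, n)
    hrf = canonical_hrf(cfg.fs_hz, cfg.hrf_peak_s, cfg.hrf_undershoot_s)
    # trial-to-trial response variability (attention/habituation): each task
    # block gets a multiplicative gain around 1, truncated to stay positive
    neural = boxcar.copy()
    if cfg.trial_gain_sd > 0:
        t_sec = np.arange(n) / cfg.fs_hz
        for a, b in cfg.paradigm.task_intervals_s():
            gain = max(0.1, rng.normal(1.0, cfg.trial_gain_sd))
            neural[(t_sec >= a) & (t_sec < b)] *= gain
    response = np.convolve(neural, hrf)[:n]

    n_active = max(1, int(round(cfg.active_channel_fraction * cfg.n_channels)))
    active = np.zeros(cfg.n_channels, dtype=bool)
    active[rng.choice(cfg.n_channels, size=n_active, replace=False)] = True

    dHbO = np.zeros((cfg.n_channels, n))
    dHbR = np.zeros((cfg.n_channels, n))
    dHbO[active] = response * cfg.activation_amp_uM
    dHbR[active] = response * cfg.activation_amp_uM * cfg.hbr_ratio

    # systemic physiological oscillations are spatially coherent: one global
    # phase per component and subject, with mild per-channel amplitude and
    # phase jitter -- this is what keeps channel averaging from removing them
    ns = cfg.noise
    components = [(ns.cardiac_amp, ns.cardiac_hz),
                  (ns.respiration_amp, ns.respiration_hz),
                  (ns.mayer_amp, ns.mayer_hz)]
    global_phases = rng.uniform(0, 2 * np.pi, size=len(components))
    for ch in range(cfg.n_channels):
        osc = np.zeros(n)
        for (amp, freq), phase in zip(components, global_phases):
            if amp > 0:
                ch_amp = amp * rng.uniform(0.6, 1.4)
                ch_phase = phase + rng.normal(0.0, 0.3)
                osc += ch_amp * np.sin(2 * np.pi * freq * t + ch_phase)
        drift = np.zeros(n)
        if ns.drift_amp > 0:
            walk = np.cumsum(rng.standard_normal(n))
            walk -= walk.mean()
            peak = np.abs(walk).max()
            if peak > 0:
                drift = walk / peak * ns.drift_amp
        white_o = rng.standard_normal(n) * ns.white_sd
        white_r = rng.standard_normal(n) * ns.white_sd * 0.5
        dHbO[ch] += osc + drift + white_o
        dHbR[ch] += -0.35 * (osc + drift) + white_r

    series = HemoTimeSeries(
        dHbO, dHbR, dHbO + dHbR, cfg.fs_hz,
        montage=None, provenance=[f"simulate_hemo(seed={cfg.seed})"],
    )
    return series, boxcar


def simulate_raw(cfg: SimulationConfig, ext: ExtinctionTable | None = None,
                 separation_cm: float = 3.0, montage: Montage | None = None,
                 baseline_intensity: float = 1000.0,
                 subject_id: str = "sim") -> RawIntensityRecording:
    """Forward Beer-Lambert model: concentration changes to light intensities.

    ``I(t; wavelength) = I0 * 10^(-alpha @ dC * l * d)`` -- the exact inverse
    of the conversion applied during preprocessing, so a round trip through
    the converter recovers the simulated concentrations.
    """
    ext = ext or default_extinction_table()
    if montage is None:
        montage = motor_cortex_20ch(separation_cm)
        if cfg.n_channels != montage.n_channels:
            raise ValidationError(
                f"default montage has {montage.n_channels} channels; config asks for "
                f"{cfg.n_channels} -- pass a matching montage"
            )
    series, _ = simulate_hemo(cfg)
    conc = np.stack([series.dHbO, series.dHbR], axis=-1)  # (ch, t, 2)
    dA = np.einsum("ij,ctj->cti", ext.alpha, conc) * (separation_cm * ext.dpf)
    intensities = baseline_intensity * 10.0 ** (-dA)
    return RawIntensityRecording(intensities, ext.wavelengths_nm, cfg.fs_hz,
                                 montage, subject_id)


def simulate_cohort(n_subjects: int, cfg: SimulationConfig | None = None,
                    between_subject_sd: float = 0.02,
                    return_amplitudes: bool = False):
    """Simulate a cohort with subject-level variation in evoked amplitude.

    Per-subject activation amplitudes are drawn around the config value
    (truncated at zero); subject seeds derive deterministically from the
    master seed so the whole cohort is reproducible.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    if between_subject_sd < 0:
        raise ValueError("between_subject_sd must be non-negative")
    cfg = cfg or SimulationConfig()
    children = np.random.SeedSequence(cfg.seed).spawn(n_subjects + 1)
    amp_rng = np.random.default_rng(children[0])
    subject_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children[1:]]
    recordings = []
    amplitudes = []
    for i in range(n_subjects):
        amp = max(0.0, amp_rng.normal(cfg.activation_amp_uM, between_subject_sd))
        amplitudes.append(amp)
        sub_cfg = replace(cfg, activation_amp_uM=amp, seed=subject_seeds[i])
        rec = simulate_raw(sub_cfg, subject_id=f"sub-{i + 1:02d}")
        recordings.append(rec)
    if return_amplitudes:
        return recordings, np.array(amplitudes)
    return recordings
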