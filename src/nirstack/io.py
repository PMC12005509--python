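"""On-disk representations for the pipeline.

Raw dual-wavelength intensities travel as delimited tables (one column per
channel/wavelength pair, header ``S<i>_D<j>_<nm>``), montages and task
paradigms as small key-value text files, and feature matrices / evaluation
reports as JSON.  A read-only adapter for SNIRF-layout HDF5 containers is
provided for interoperability with standard acquisition software.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Montage",
    "Paradigm",
    "RawIntensityRecording",
    "ValidationError",
    "FormatError",
    "motor_cortex_20ch",
    "read_intensity_table",
    "write_intensity_table",
    "read_snirf_like",
    "read_montage",
    "write_montage",
    "read_paradigm",
    "write_paradigm",
]


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class FormatError(ValueError):
    """A file does not follow the documented on-disk layout."""


@dataclass(frozen=True)
class Montage:
    """Optode layout: sources, detectors and the source-detector channels.

    Positions are 2D scalp coordinates in arbitrary units and serve as
    metadata for plotting and fixtures only; no pipeline computation uses
    them.  ``separation_cm`` is the source-detector distance ``l`` entering
    the Beer-Lambert conversion.
    """

    sources: dict[str, tuple[float, float]]
    detectors: dict[str, tuple[float, float]]
    channels: tuple[tuple[str, str], ...]
    separation_cm: float = 3.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("montage must define at least one channel")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("montage channels contain duplicate pairs")
        for src, det in self.channels:
            if src not in self.sources:
                raise ValidationError(f"channel references unknown source {src!r}")
            if det not in self.detectors:
                raise ValidationError(f"channel references unknown detector {det!r}")
        if self.separation_cm <= 0:
            raise ValidationError("separation_cm must be positive")
        object.__setattr__(self, "channels", tuple(tuple(c) for c in self.channels))

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_names(self) -> list[str]:
        return [f"{s}_{d}" for s, d in self.channels]


@dataclass(frozen=True)
class Paradigm:
    """Block design of the motor task.

    An initial rest, ``n_trials`` repetitions of task followed by
    inter-trial rest, and a final rest used for baseline correction.
    Defaults mirror a 30 s / 10 x (10 s task + 20 s rest) / 30 s session.
    """

    initial_rest_s: float = 30.0
    task_s: float = 10.0
    inter_trial_rest_s: float = 20.0
    final_rest_s: float = 30.0
    n_trials: int = 10

    def __post_init__(self) -> None:
        for name in ("initial_rest_s", "inter_trial_rest_s", "final_rest_s"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.task_s <= 0:
            raise ValidationError("task_s must be positive")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be at least 1")

    def total_duration_s(self, include_rest_padding: bool = True) -> float:
        core = self.n_trials * (self.task_s + self.inter_trial_rest_s)
        if include_rest_padding:
            return self.initial_rest_s + core + self.final_rest_s
        return core

    def task_intervals_s(self, shift_s: float = 0.0) -> list[tuple[float, float]]:
        """Start/stop times in seconds of each task block, optionally delayed."""
        out = []
        t = self.initial_rest_s
        for _ in range(self.n_trials):
            out.append((t + shift_s, t + self.task_s + shift_s))
            t += self.task_s + self.inter_trial_rest_s
        return out

    def task_mask(self, fs_hz: float, n_samples: int, shift_s: float = 0.0) -> np.ndarray:
        """Boolean per-sample mask of task periods (sample n at time n/fs)."""
        t = np.arange(n_samples) / fs_hz
        mask = np.zeros(n_samples, dtype=bool)
        for a, b in self.task_intervals_s(shift_s):
            mask |= (t >= a) & (t < b)
        return mask


@dataclass
class RawIntensityRecording:
    """Dual-wavelength optical intensities, channels x samples x 2.

    Intensities are strictly positive detector units; the log-ratio against
    a baseline window is taken during conversion to absorbance changes.
    """

    intensities: np.ndarray
    wavelengths_nm: tuple[float, float]
    fs_hz: float
    montage: Montage
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or self.intensities.shape[2] != 2:
            raise ValidationError(
                "intensities must have shape (n_channels, n_samples, 2); got "
                f"{self.intensities.shape}"
            )
        if self.intensities.shape[0] != self.montage.n_channels:
            raise ValidationError(
                f"recording has {self.intensities.shape[0]} channels but montage "
                f"defines {self.montage.n_channels}"
            )
        if not np.all(self.intensities > 0):
            raise ValidationError("intensities must be strictly positive")
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz must be positive")
        lo, hi = self.wavelengths_nm
        if lo == hi:
            raise ValidationError("the two wavelengths must differ")
        for w in (lo, hi):
            if not (700.0 <= w <= 1000.0):
                raise ValidationError(f"wavelength {w} nm outside the NIR window 700-1000 nm")

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]


def motor_cortex_20ch(separation_cm: float = 3.0) -> Montage:
    """A named 20-channel bilateral motor-cortex montage.

    Eight sources and eight detectors, ten channels per hemisphere.  The
    coordinates approximate a standard 10-20 motor grid and are documented
    as approximate; they are metadata only.
    """
    sources: dict[str, tuple[float, float]] = {}
    detectors: dict[str, tuple[float, float]] = {}
    channels: list[tuple[str, str]] = []
    for hemi, x0 in (("L", -4.0), ("R", 4.0)):
        base_s = 4 * (0 if hemi == "L" else 1)
        src_pos = [(x0 - 1, 1), (x0 + 1, 1), (x0 - 1, -1), (x0 + 1, -1)]
        det_pos = [(x0, 2), (x0 - 2, 0), (x0 + 2, 0), (x0, -2)]
        for i, p in enumerate(src_pos):
            sources[f"S{base_s + i + 1}"] = p
        for i, p in enumerate(det_pos):
            detectors[f"D{base_s + i + 1}"] = p
        s = [f"S{base_s + i + 1}" for i in range(4)]
        d = [f"D{base_s + i + 1}" for i in range(4)]
        pairs = [
            (s[0], d[0]), (s[0], d[1]), (s[1], d[0]), (s[1], d[2]),
            (s[2], d[1]), (s[2], d[3]), (s[3], d[2]), (s[3], d[3]),
            (s[0], d[3]), (s[3], d[0]),
        ]
        channels.extend(pairs)
    return Montage(sources, detectors, tuple(channels), separation_cm)


# ---------------------------------------------------------------------------
# intensity tables


def _column_name(src: str, det: str, wavelength_nm: float) -> str:
    wl = int(round(wavelength_nm))
    return f"{src}_{det}_{wl}"


def write_intensity_table(rec: RawIntensityRecording, path: str | Path, sep: str = ",") -> None:
    """Write a recording as a delimited table, one row per sample.

    Columns follow ``S<i>_D<j>_<nm>`` for every montage channel and both
    wavelengths; :func:`read_intensity_table` inverts the layout exactly.
    """
    cols = {}
    for ci, (src, det) in enumerate(rec.montage.channels):
        for wi, wl in enumerate(rec.wavelengths_nm):
            cols[_column_name(src, det, wl)] = rec.intensities[ci, :, wi]
    df = pd.DataFrame(cols)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_intensity_table(
    path: str | Path,
    montage: Montage,
    fs_hz: float,
    wavelengths_nm: tuple[float, float],
    subject_id: str = "unknown",
) -> RawIntensityRecording:
    """Read a delimited intensity table into a recording.

    The channel ordering of the result always follows ``montage.channels``,
    regardless of the column order on disk.  Delimiter (comma or tab) is
    auto-detected from the header line.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except ValueError as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            raise FormatError(
                f"non-numeric cell in column {col!r} at row {int(np.flatnonzero(bad)[0])}"
            )
    n_samples = len(df)
    data = np.empty((montage.n_channels, n_samples, 2), dtype=float)
    for ci, (src, det) in enumerate(montage.channels):
        for wi, wl in enumerate(wavelengths_nm):
            name = _column_name(src, det, wl)
            if name not in df.columns:
                raise FormatError(
                    f"table {path} is missing column {name!r} for channel {src}_{det}"
                )
            data[ci, :, wi] = df[name].to_numpy(dtype=float)
    if not np.all(data > 0):
        raise ValidationError(f"non-positive intensity value in {path}")
    return RawIntensityRecording(data, tuple(wavelengths_nm), fs_hz, montage, subject_id)


# ---------------------------------------------------------------------------
# SNIRF-layout HDF5 (read-only)


def read_snirf_like(path: str | Path, montage: Montage | None = None) -> RawIntensityRecording:
    """Read a SNIRF-layout HDF5 container into a recording.

    Expects ``/nirs/data1/dataTimeSeries``, per-column ``measurementList<k>``
    groups and a ``/nirs/probe`` with wavelengths.  Only continuous-wave
    intensity channels at the first two wavelengths are used; auxiliary
    channels or extra wavelengths are skipped with a logged warning.
    """
    import h5py

    path = Path(path)
    with h5py.File(path, "r") as f:
        if "nirs" not in f or "data1" not in f["nirs"]:
            raise FormatError(f"{path} lacks the mandatory /nirs/data1 group")
        nirs = f["nirs"]
        if "probe" not in nirs:
            raise FormatError(f"{path} lacks the mandatory /nirs/probe group")
        data1 = nirs["data1"]
        if "dataTimeSeries" not in data1:
            raise FormatError(f"{path} lacks /nirs/data1/dataTimeSeries")
        ts = np.asarray(data1["dataTimeSeries"], dtype=float)  # time x measurements
        wavelengths = np.asarray(nirs["probe"]["wavelengths"], dtype=float).ravel()
        if len(wavelengths) > 2:
            logger.warning(
                "%s declares %d wavelengths; using the first two", path, len(wavelengths)
            )
        wl_pair = (float(wavelengths[0]), float(wavelengths[1]))
        time = np.asarray(data1["time"], dtype=float).ravel()
        if len(time) > 1:
            fs_hz = float(1.0 / np.median(np.diff(time)))
        else:
            fs_hz = 1.0

        entries: dict[tuple[int, int, int], int] = {}
        for key in data1:
            if not key.startswith("measurementList"):
                continue
            ml = data1[key]
            col = int(key[len("measurementList"):]) - 1
            si = int(np.asarray(ml["sourceIndex"]).item())
            di = int(np.asarray(ml["detectorIndex"]).item())
            wi = int(np.asarray(ml["wavelengthIndex"]).item())
            if wi > 2:
                logger.warning("skipping measurement %s at wavelength index %d", key, wi)
                continue
            entries[(si, di, wi)] = col

        pairs = sorted({(si, di) for si, di, _ in entries})
        if montage is None:
            sources = {f"S{si}": (float(si), 0.0) for si, _ in pairs}
            detectors = {f"D{di}": (float(di), 1.0) for _, di in pairs}
            channels = tuple((f"S{si}", f"D{di}") for si, di in pairs)
            montage = Montage(sources, detectors, channels)
        data = np.empty((len(pairs), ts.shape[0], 2), dtype=float)
        for ci, (si, di) in enumerate(pairs):
            for wi in (1, 2):
                if (si, di, wi) not in entries:
                    raise FormatError(
                        f"{path} lacks wavelength {wi} for source {si} / detector {di}"
                    )
                data[ci, :, wi - 1] = ts[:, entries[(si, di, wi)]]
    return RawIntensityRecording(data, wl_pair, fs_hz, montage, subject_id=path.stem)


# ---------------------------------------------------------------------------
# key-value sidecars


def write_montage(montage: Montage, path: str | Path) -> None:
    lines = [f"separation_cm: {montage.separation_cm!r}"]
    for name, (x, y) in montage.sources.items():
        lines.append(f"source: {name} {x!r} {y!r}")
    for name, (x, y) in montage.detectors.items():
        lines.append(f"detector: {name} {x!r} {y!r}")
    for src, det in montage.channels:
        lines.append(f"channel: {src} {det}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_montage(path: str | Path) -> Montage:
    sources: dict[str, tuple[float, float]] = {}
    detectors: dict[str, tuple[float, float]] = {}
    channels: list[tuple[str, str]] = []
    separation_cm = 3.0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            key, rest = line.split(":", 1)
            parts = rest.split()
            key = key.strip()
            if key == "separation_cm":
                separation_cm = float(parts[0])
            elif key == "source":
                sources[parts[0]] = (float(parts[1]), float(parts[2]))
            elif key == "detector":
                detectors[parts[0]] = (float(parts[1]), float(parts[2]))
            elif key == "channel":
                channels.append((parts[0], parts[1]))
            else:
                raise ValueError(f"unknown key {key!r}")
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return Montage(sources, detectors, tuple(channels), separation_cm)


def write_paradigm(paradigm: Paradigm, path: str | Path) -> None:
    lines = [
        f"initial_rest_s: {paradigm.initial_rest_s!r}",
        f"task_s: {paradigm.task_s!r}",
        f"inter_trial_rest_s: {paradigm.inter_trial_rest_s!r}",
        f"final_rest_s: {paradigm.final_rest_s!r}",
        f"n_trials: {paradigm.n_trials}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_paradigm(path: str | Path) -> Paradigm:
    kv: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key: value'")
        key, val = line.split(":", 1)
        kv[key.strip()] = val.strip()
    try:
        return Paradigm(
            initial_rest_s=float(kv["initial_rest_s"]),
            task_s=float(kv["task_s"]),
            inter_trial_rest_s=float(kv["inter_trial_rest_s"]),
            final_rest_s=float(kv["final_rest_s"]),
            n_trials=int(kv["n_trials"]),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing paradigm key {exc}") from exc


# ---------------------------------------------------------------------------
# JSON containers


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
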