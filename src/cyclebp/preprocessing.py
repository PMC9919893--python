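"""Four-step input preparation and its exact inversion.

The pipeline, in order: (1) convert luminal area from m² to cm²; (2) fix a
common time-window equal to the longest cardiac cycle in the full cohort and
tile each subject's pulse periodically to fill it; (3) MinMax-normalize
pressures and areas to [−1, 1] with ranges fitted on the training cohort
only; (4) resample from the source rate (500 Hz) to the target rate (256 Hz)
with a polyphase anti-aliased resampler.

Normalization uses one global pressure range shared by all three pressure
channels and one area range, so cross-channel calibration relationships
(e.g. peripheral systolic pressure exceeding central systolic pressure)
survive the transform and can be exploited by the model.  Because every step
is affine or linear, denormalizing a prediction recovers physical units
exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from fractions import Fraction
from pathlib import Path
from typing import List

import numpy as np
from scipy.signal import resample_poly

from .records import AreaUnits, Cohort, WaveformRecord, convert_record_area

PRESSURE_CHANNELS = ("p_brachial", "p_radial", "p_abdominal")


@dataclass
class NormalizationSpec:
    """Global MinMax [−1, 1] ranges, fitted on training data only."""

    pressure_min: float
    pressure_max: float
    area_min: float  # cm²
    area_max: float  # cm²
    fit_scope: str = "train_only"

    def __post_init__(self):
        if self.pressure_max <= self.pressure_min:
            raise ValueError("degenerate pressure range (max <= min)")
        if self.area_max <= self.area_min:
            raise ValueError("degenerate area range (max <= min)")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NormalizationSpec":
        return cls(**json.loads(s))


@dataclass
class WindowSpec:
    """Fixed analysis window: the longest pulse in the cohort, at both rates."""

    window_len_source: int
    window_len_target: int
    fs_source: float
    fs_target: float

    def __post_init__(self):
        expected = int(round(self.window_len_source * self.fs_target / self.fs_source))
        if self.window_len_target != expected:
            raise ValueError(
                f"window_len_target {self.window_len_target} inconsistent with "
                f"rates (expected {expected})"
            )

    @classmethod
    def from_cohort(
        cls, cohort: Cohort, fs_target: float = 256.0
    ) -> "WindowSpec":
        if len(cohort) == 0:
            raise ValueError("empty cohort")
        fs_source = cohort.records[0].fs
        win = max(r.pulse_samples for r in cohort)
        return cls(
            window_len_source=win,
            window_len_target=int(round(win * fs_target / fs_source)),
            fs_source=fs_source,
            fs_target=fs_target,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "WindowSpec":
        return cls(**json.loads(s))


@dataclass
class PairedSample:
    """One subject's model-ready tensors.

    ``x``: (2, T) peripheral pressures (brachial, radial); ``y``: (2, T)
    central pressure and area — all in normalized units, T at the target
    rate.  ``pulse_len_target`` is the length of one cardiac cycle at the
    target rate, used later to delimit pulses.
    """

    subject_id: str
    x: np.ndarray
    y: np.ndarray
    pulse_len_target: int

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.shape[0] != 2 or self.y.shape[0] != 2:
            raise ValueError("x and y must have exactly 2 channels each")
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must share the window length")


def convert_area_to_cm2(record: WaveformRecord) -> WaveformRecord:
    """Area m² → cm² (× 10⁴); guarded against double conversion."""
    return convert_record_area(record)


def tile_pulse(signal: np.ndarray, pulse_len: int, window_len: int) -> np.ndarray:
    """Repeat one pulse periodically until the window is filled.

    The signal is assumed stationary, so ``out[j] = signal[j mod pulse_len]``.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if pulse_len < 2:
        raise ValueError("pulse_len must be >= 2")
    if pulse_len > window_len:
        raise ValueError("pulse_len exceeds window_len")
    if len(signal) < pulse_len:
        raise ValueError("signal shorter than pulse_len")
    pulse = signal[:pulse_len]
    reps = int(np.ceil(window_len / pulse_len))
    return np.tile(pulse, reps)[:window_len]


def resample_signal(signal: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Band-limited rational resampling (polyphase, Kaiser-windowed filter)."""
    signal = np.asarray(signal, dtype=np.float64)
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if fs_in == fs_out:
        return signal.copy()
    ratio = Fraction(fs_out / fs_in).limit_denominator(1000)
    # resample the zero-mean component and restore the mean: the polyphase
    # branches have slightly unequal DC gains, so this keeps constants (and
    # hence affine rescalings such as the MinMax map) exactly invariant
    mu = signal.mean()
    return resample_poly(signal - mu, ratio.numerator, ratio.denominator) + mu


def resample_tiled(
    signal: np.ndarray,
    pulse_len: int,
    window_len: int,
    fs_in: float,
    fs_out: float,
    window_len_target: int,
) -> np.ndarray:
    """Resample a periodically tiled window without edge transients.

    The tiled signal continues ``signal[j mod pulse_len]`` on both sides of
    the window, so the anti-aliasing filter is fed the true periodic
    extension instead of zero padding; the exact target window is then cut
    out at an integer sample offset.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if fs_in == fs_out:
        return tile_pulse(signal, pulse_len, window_len)[:window_len_target]
    ratio = Fraction(fs_out / fs_in).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    margin = 10 * down  # covers the polyphase filter transient
    idx = np.arange(-margin, window_len + margin) % pulse_len
    extended = signal[:pulse_len][idx]
    mu = extended.mean()  # see resample_signal: keeps affine maps exact
    res = resample_poly(extended - mu, up, down) + mu
    offset = margin * up // down  # integer because margin is a multiple of down
    return res[offset : offset + window_len_target]


def fit_minmax(train: Cohort) -> NormalizationSpec:
    """Global ranges over the training cohort (areas must already be in cm²)."""
    if len(train) == 0:
        raise ValueError("empty training cohort")
    p_min, p_max = np.inf, -np.inf
    a_min, a_max = np.inf, -np.inf
    for rec in train:
        if rec.units_area is not AreaUnits.cm2:
            raise ValueError(f"{rec.subject_id}: convert area to cm² before fitting")
        for c in PRESSURE_CHANNELS:
            s = getattr(rec, c)
            p_min, p_max = min(p_min, s.min()), max(p_max, s.max())
        a_min, a_max = min(a_min, rec.a_abdominal.min()), max(a_max, rec.a_abdominal.max())
    return NormalizationSpec(
        pressure_min=float(p_min),
        pressure_max=float(p_max),
        area_min=float(a_min),
        area_max=float(a_max),
    )


def normalize(
    values: np.ndarray,
    spec: NormalizationSpec,
    magnitude: str,
    invert: bool = False,
) -> np.ndarray:
    """Affine map to/from [−1, 1]; no clipping, exact round trip."""
    if magnitude == "pressure":
        lo, hi = spec.pressure_min, spec.pressure_max
    elif magnitude == "area":
        lo, hi = spec.area_min, spec.area_max
    else:
        raise ValueError(f"unknown magnitude {magnitude!r}")
    values = np.asarray(values, dtype=np.float64)
    if invert:
        return (values + 1.0) * (hi - lo) / 2.0 + lo
    return 2.0 * (values - lo) / (hi - lo) - 1.0


def build_dataset(
    cohort: Cohort, spec: NormalizationSpec, window: WindowSpec
) -> List[PairedSample]:
    """Apply the four preparation steps to every subject of a cohort."""
    samples = []
    for rec in cohort:
        if rec.units_area is AreaUnits.m2:
            rec = convert_area_to_cm2(rec)
        pulse_len = rec.pulse_samples
        channels = {}
        for name, series in rec.channels().items():
            tiled = tile_pulse(series, pulse_len, window.window_len_source)
            magnitude = "area" if name == "a_abdominal" else "pressure"
            norm = normalize(tiled, spec, magnitude)
            channels[name] = resample_tiled(
                norm,
                pulse_len,
                window.window_len_source,
                window.fs_source,
                window.fs_target,
                window.window_len_target,
            )
        pulse_len_target = int(
            round(pulse_len * window.fs_target / window.fs_source)
        )
        samples.append(
            PairedSample(
                subject_id=rec.subject_id,
                x=np.stack([channels["p_brachial"], channels["p_radial"]]),
                y=np.stack([channels["p_abdominal"], channels["a_abdominal"]]),
                pulse_len_target=pulse_len_target,
            )
        )
    return samples


def save_sidecar(path, norm: NormalizationSpec, window: WindowSpec) -> None:
    """Persist the specs next to processed tensors so inversion is exact."""
    Path(path).write_text(
        json.dumps({"normalization": asdict(norm), "window": asdict(window)}, indent=2)
    )


def load_sidecar(path):
    blob = json.loads(Path(path).read_text())
    return (
        NormalizationSpec(**blob["normalization"]),
        WindowSpec(**blob["window"]),
    )
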