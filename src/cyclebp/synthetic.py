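"""Synthetic paired peripheral/central waveform cohorts with known mechanics.

The generator emulates the structure of the virtual pulse-wave database the
package is designed for: per subject, two peripheral pressure channels
(brachial, radial) and a central pair (abdominal-aortic pressure and luminal
area), sampled at 500 Hz, with heart period varying across subjects.

Three physiological features are reproduced by construction:

* **Peripheral systolic amplification** — peripheral systolic pressure is
  strictly above central systolic pressure (gain on the pulsatile component).
* **Pressure–strain hysteresis** — the arterial wall is a Voigt
  (spring–dashpot) viscoelastic element, ``P(t) − DBP = E·ε(t) + η·dε/dt``,
  so strain lags pressure and the P–ε loop encloses a positive area.  The
  elastic modulus ``E`` (mmHg per % strain) and viscosity ``η``
  (mmHg·s per % strain) are the per-subject ground truth.
* **Variable heart period** — drawn per subject from a heart-rate range.

The central pressure pulse is a smooth parametric shape: a raised-cosine
systolic upstroke followed by an exponential diastolic decay closed exactly
at the pulse foot.  Peripheral pressures are amplitude-amplified, delayed
copies of the central pulse; radial amplification is a fixed monotone
function of brachial amplification so the peripheral pair determines the
central pressure (an invertible X↔Y mapping a model can learn).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd

from .records import AreaUnits, Cohort, CohortRole, WaveformRecord

#: radial-over-brachial pulsatile gain relation: amp_rad = 1 + RADIAL_GAIN*(amp_bra - 1)
RADIAL_GAIN = 1.6
#: radial delay relative to brachial delay (radial site is more distal)
RADIAL_DELAY_RATIO = 1.8
#: fraction of the cardiac period from foot to systolic peak
SYSTOLIC_PEAK_FRACTION = 0.3
#: beats stored per subject record
N_BEATS = 4


@dataclass
class SyntheticConfig:
    """Cohort-level generation parameters (uniform per-subject draws)."""

    n_subjects: int = 64
    fs: float = 500.0
    heart_rate_range: Tuple[float, float] = (60.0, 100.0)  # beats/min
    dbp_range: Tuple[float, float] = (60.0, 90.0)  # mmHg
    pp_range: Tuple[float, float] = (30.0, 60.0)  # mmHg
    e_modulus_range: Tuple[float, float] = (8.0, 12.0)  # mmHg per % strain
    viscosity_range: Tuple[float, float] = (0.05, 0.3)  # mmHg*s per % strain
    diastolic_diameter_range: Tuple[float, float] = (1.2, 2.2)  # cm
    peripheral_amplification_range: Tuple[float, float] = (1.08, 1.25)
    peripheral_delay_range: Tuple[float, float] = (0.04, 0.1)  # s
    noise_sd: float = 0.0  # fraction of pulse amplitude; source data is noiseless
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        ranges = {
            "heart_rate_range": self.heart_rate_range,
            "dbp_range": self.dbp_range,
            "pp_range": self.pp_range,
            "e_modulus_range": self.e_modulus_range,
            "viscosity_range": self.viscosity_range,
            "diastolic_diameter_range": self.diastolic_diameter_range,
            "peripheral_amplification_range": self.peripheral_amplification_range,
            "peripheral_delay_range": self.peripheral_delay_range,
        }
        for name, (lo, hi) in ranges.items():
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")
        if self.peripheral_amplification_range[0] <= 1.0:
            raise ValueError(
                "peripheral amplification must exceed 1 (peripheral SBP > central SBP)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def voigt_strain_response(
    pressure: np.ndarray,
    dbp: float,
    e_modulus: float,
    viscosity: float,
    fs: float,
) -> np.ndarray:
    """Periodic steady-state strain of a Voigt wall driven by one pressure cycle.

    Solves ``P(t) − DBP = E·ε(t) + η·dε/dt`` on the periodic extension of the
    input pulse, exactly, in the Fourier domain: each harmonic of the driving
    pressure is scaled by ``1/(E + iωη)``.  For a sinusoidal drive of angular
    frequency ω this reproduces the closed form — amplitude ``1/√(E²+ω²η²)``
    and phase lag ``arctan(ωη/E)``.  Output is percent strain, same length as
    the input.
    """
    pressure = np.asarray(pressure, dtype=np.float64)
    if pressure.ndim != 1 or len(pressure) < 2:
        raise ValueError("pressure must be a 1-D series of length >= 2")
    if not np.all(np.isfinite(pressure)):
        raise ValueError("pressure contains NaN or infinite values")
    if e_modulus <= 0:
        raise ValueError("e_modulus must be positive")
    if viscosity < 0:
        raise ValueError("viscosity must be non-negative")
    drive = pressure - dbp
    n = len(drive)
    spec = np.fft.rfft(drive)
    omega = 2.0 * np.pi * np.fft.rfftfreq(n, d=1.0 / fs)
    strain_spec = spec / (e_modulus + 1j * omega * viscosity)
    return np.fft.irfft(strain_spec, n=n)


def central_pressure_pulse(
    n_samples: int, fs: float, dbp: float, pp: float
) -> np.ndarray:
    """One smooth central pressure cycle starting at the diastolic foot.

    Raised-cosine upstroke from DBP to SBP over the systolic fraction of the
    period, then an exponential decay back to DBP; a small linear correction
    closes the pulse exactly at the foot so tiling is seamless.
    """
    if n_samples < 4:
        raise ValueError("pulse must have at least 4 samples")
    t = np.arange(n_samples) / fs
    period = n_samples / fs
    t_peak = SYSTOLIC_PEAK_FRACTION * period
    tau = (period - t_peak) / 4.0
    p = np.empty(n_samples)
    up = t <= t_peak
    p[up] = dbp + pp * 0.5 * (1.0 - np.cos(np.pi * t[up] / t_peak))
    td = t[~up] - t_peak
    tail = period - t_peak
    end_val = np.exp(-tail / tau)
    p[~up] = dbp + pp * (np.exp(-td / tau) - end_val * td / tail)
    return p


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(subject_index,)))
    )


@dataclass
class SubjectTruth:
    subject_id: str
    e_true: float
    eta_true: float
    amp_brachial: float
    amp_radial: float
    dbp: float
    pp: float
    d_diastolic: float
    heart_rate: float


def synth_subject(
    config: SyntheticConfig, subject_index: int
) -> Tuple[WaveformRecord, SubjectTruth]:
    """Generate one virtual subject; reproducible from (config.seed, index)."""
    rng = _subject_rng(config.seed, subject_index)
    hr = rng.uniform(*config.heart_rate_range)
    dbp = rng.uniform(*config.dbp_range)
    pp = rng.uniform(*config.pp_range)
    e_mod = rng.uniform(*config.e_modulus_range)
    eta = rng.uniform(*config.viscosity_range)
    d_d = rng.uniform(*config.diastolic_diameter_range)
    amp_bra = rng.uniform(*config.peripheral_amplification_range)
    amp_rad = 1.0 + RADIAL_GAIN * (amp_bra - 1.0)
    delay_bra = rng.uniform(*config.peripheral_delay_range)
    delay_rad = RADIAL_DELAY_RATIO * delay_bra

    fs = config.fs
    n_pulse = int(round(60.0 / hr * fs))
    period = n_pulse / fs

    p_central = central_pressure_pulse(n_pulse, fs, dbp, pp)
    strain = voigt_strain_response(p_central, dbp, e_mod, eta, fs)
    diameter = d_d * (1.0 + strain / 100.0)  # cm
    area_cm2 = np.pi * diameter**2 / 4.0
    area_m2 = area_cm2 * 1.0e-4

    def periph(amp: float, delay: float) -> np.ndarray:
        shift = int(round(delay * fs)) % n_pulse
        return dbp + amp * (np.roll(p_central, shift) - dbp)

    p_bra = periph(amp_bra, delay_bra)
    p_rad = periph(amp_rad, delay_rad)

    def tile(sig: np.ndarray) -> np.ndarray:
        out = np.tile(sig, N_BEATS)
        if config.noise_sd > 0:
            out = out + rng.normal(0.0, config.noise_sd * pp, size=out.shape)
        return out

    sid = f"synth{subject_index:04d}"
    record = WaveformRecord(
        subject_id=sid,
        fs=fs,
        p_brachial=tile(p_bra),
        p_radial=tile(p_rad),
        p_abdominal=tile(p_central),
        a_abdominal=np.tile(area_m2, N_BEATS)
        if config.noise_sd == 0
        else np.tile(area_m2, N_BEATS)
        * (1.0 + rng.normal(0.0, config.noise_sd, size=n_pulse * N_BEATS) * 0.01),
        pulse_period=period,
        units_area=AreaUnits.m2,
    )
    truth = SubjectTruth(
        subject_id=sid,
        e_true=e_mod,
        eta_true=eta,
        amp_brachial=amp_bra,
        amp_radial=amp_rad,
        dbp=dbp,
        pp=pp,
        d_diastolic=d_d,
        heart_rate=hr,
    )
    return record, truth


def synth_cohort(config: SyntheticConfig) -> Tuple[Cohort, pd.DataFrame]:
    """Generate a full cohort plus the aligned ground-truth table."""
    records, truths = [], []
    for i in range(config.n_subjects):
        rec, truth = synth_subject(config, i)
        records.append(rec)
        truths.append(vars(truth))
    return Cohort(records, role=CohortRole.full), pd.DataFrame(truths)
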