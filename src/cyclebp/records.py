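"""Canonical in-memory representation of the virtual pulse-wave database.

One :class:`WaveformRecord` holds a virtual subject's pressure series at the
brachial, radial and abdominal-aortic sites together with the abdominal
luminal-area series, the sampling frequency and the cardiac period.  A
:class:`Cohort` is an ordered collection of records that can be split into
train/test subsets and round-tripped through an HDF5 archive
(``/subject_id/{channel}`` datasets with ``fs`` and ``pulse_period``
attributes) or a directory of per-subject CSV files.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Tuple

import h5py
import numpy as np
import pandas as pd

CANONICAL_CHANNELS = ("p_brachial", "p_radial", "p_abdominal", "a_abdominal")


class AreaUnits(str, enum.Enum):
    m2 = "m2"
    cm2 = "cm2"


class ChannelNotFoundError(KeyError):
    """A required channel is absent from the source file."""


class FormatError(ValueError):
    """The source file cannot be parsed as a waveform archive."""


@dataclass
class WaveformRecord:
    """Multichannel signals of one virtual subject.

    Pressures are in mmHg; the luminal area is in m² as loaded from the
    database and in cm² after unit conversion (tracked by ``units_area``).
    """

    subject_id: str
    fs: float
    p_brachial: np.ndarray
    p_radial: np.ndarray
    p_abdominal: np.ndarray
    a_abdominal: np.ndarray
    pulse_period: float
    units_area: AreaUnits = AreaUnits.m2

    def __post_init__(self):
        for name in CANONICAL_CHANNELS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        self.units_area = AreaUnits(self.units_area)
        n = len(self.p_brachial)
        if any(len(getattr(self, c)) != n for c in CANONICAL_CHANNELS):
            raise ValueError(f"{self.subject_id}: signal lengths differ")
        if self.fs <= 0:
            raise ValueError(f"{self.subject_id}: fs must be positive")
        if self.pulse_period <= 0:
            raise ValueError(f"{self.subject_id}: pulse_period must be positive")
        if round(self.pulse_period * self.fs) > n:
            raise ValueError(
                f"{self.subject_id}: pulse_period exceeds the stored series"
            )
        for c in ("p_brachial", "p_radial", "p_abdominal"):
            if np.any(getattr(self, c) <= 0):
                raise ValueError(f"{self.subject_id}: non-positive pressure in {c}")
        if np.any(self.a_abdominal <= 0):
            raise ValueError(f"{self.subject_id}: non-positive luminal area")

    @property
    def n_samples(self) -> int:
        return len(self.p_brachial)

    @property
    def pulse_samples(self) -> int:
        return int(round(self.pulse_period * self.fs))

    def channels(self) -> Dict[str, np.ndarray]:
        return {c: getattr(self, c) for c in CANONICAL_CHANNELS}


class CohortRole(str, enum.Enum):
    full = "full"
    train = "train"
    test = "test"


@dataclass
class Cohort:
    records: List[WaveformRecord] = field(default_factory=list)
    role: CohortRole = CohortRole.full

    def __post_init__(self):
        self.role = CohortRole(self.role)
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_ids in cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subject_ids(self) -> List[str]:
        return [r.subject_id for r in self.records]


def load_database(path, site_map: Mapping[str, str] | None = None) -> Cohort:
    """Read a converted database archive into a :class:`Cohort`.

    ``path`` may be an HDF5 file (one group per subject, a dataset per
    channel, ``fs``/``pulse_period`` attributes on the group) or a directory
    of per-subject CSV files (one column per channel, a header row).
    ``site_map`` maps the four canonical channel names to the channel names
    used inside the archive; by default they coincide.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    site_map = dict(site_map or {c: c for c in CANONICAL_CHANNELS})
    missing = [c for c in CANONICAL_CHANNELS if c not in site_map]
    if missing:
        raise ChannelNotFoundError(f"site_map lacks canonical channels: {missing}")
    if path.is_dir():
        return _load_csv_dir(path, site_map)
    return _load_hdf5(path, site_map)


def _load_hdf5(path: Path, site_map: Mapping[str, str]) -> Cohort:
    records = []
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"cannot open {path} as HDF5: {exc}") from exc
    with f:
        for sid in sorted(f.keys()):
            grp = f[sid]
            series = {}
            for canonical, stored in site_map.items():
                if stored not in grp:
                    raise ChannelNotFoundError(
                        f"subject {sid}: channel '{stored}' not found"
                    )
                series[canonical] = np.asarray(grp[stored], dtype=np.float64)
            records.append(
                WaveformRecord(
                    subject_id=sid,
                    fs=float(grp.attrs["fs"]),
                    pulse_period=float(
                        grp.attrs.get("pulse_period")
                        if "pulse_period" in grp.attrs
                        else _estimate_pulse_period(
                            series["p_abdominal"], float(grp.attrs["fs"])
                        )
                    ),
                    units_area=AreaUnits(grp.attrs.get("units_area", "m2")),
                    **series,
                )
            )
    return Cohort(records=records, role=CohortRole.full)


def _load_csv_dir(path: Path, site_map: Mapping[str, str]) -> Cohort:
    records = []
    files = sorted(path.glob("*.csv"))
    if not files:
        raise FormatError(f"no per-subject CSV files found in {path}")
    for fp in files:
        try:
            df = pd.read_csv(fp)
        except Exception as exc:  # noqa: BLE001 - surfaced as format error
            raise FormatError(f"cannot parse {fp}: {exc}") from exc
        series = {}
        for canonical, stored in site_map.items():
            if stored not in df.columns:
                raise ChannelNotFoundError(
                    f"subject file {fp.name}: channel '{stored}' not found"
                )
            series[canonical] = df[stored].to_numpy(dtype=np.float64)
        meta = _read_csv_meta(fp)
        fs = float(meta.get("fs", 500.0))
        period = meta.get("pulse_period")
        if period is None:
            period = _estimate_pulse_period(series["p_abdominal"], fs)
        records.append(
            WaveformRecord(
                subject_id=fp.stem,
                fs=fs,
                pulse_period=float(period),
                units_area=AreaUnits(meta.get("units_area", "m2")),
                **series,
            )
        )
    return Cohort(records=records, role=CohortRole.full)


def _read_csv_meta(fp: Path) -> Dict[str, object]:
    """Sidecar metadata: '<stem>.meta.json' next to the CSV, if present."""
    import json

    meta_fp = fp.with_suffix("").with_suffix(".meta.json")
    alt = fp.parent / (fp.stem + ".meta.json")
    for candidate in (meta_fp, alt):
        if candidate.exists():
            return json.loads(candidate.read_text())
    return {}


def _estimate_pulse_period(pressure: np.ndarray, fs: float) -> float:
    """Fallback period estimate: spacing of the first two detected pulse feet."""
    from .evaluation import detect_pulse_feet

    feet = detect_pulse_feet(pressure, fs)
    if len(feet) < 2:
        raise FormatError("cannot estimate pulse_period: fewer than two pulse feet")
    return (feet[1] - feet[0]) / fs


def save_archive(cohort: Cohort, path) -> None:
    """Write a cohort to the internal HDF5 processed-archive layout."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["role"] = cohort.role.value
        for rec in cohort:
            grp = f.create_group(rec.subject_id)
            grp.attrs["fs"] = rec.fs
            grp.attrs["pulse_period"] = rec.pulse_period
            grp.attrs["units_area"] = rec.units_area.value
            for name, series in rec.channels().items():
                grp.create_dataset(name, data=series)


def split_cohort(
    cohort: Cohort, test_fraction: float, seed: int
) -> Tuple[Cohort, Cohort]:
    """Random subject-level split into (train, test).

    The train size is ``round(n * (1 - test_fraction))``; the remaining
    subjects form the test cohort.  Membership is deterministic given
    ``seed`` and the two cohorts partition the input.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(cohort)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.Generator(np.random.PCG64(seed))
    order = rng.permutation(n)
    n_train = int(round(n * (1.0 - test_fraction)))
    n_train = min(max(n_train, 1), n - 1)  # both sides non-empty
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    train = Cohort([cohort.records[i] for i in train_idx], role=CohortRole.train)
    test = Cohort([cohort.records[i] for i in test_idx], role=CohortRole.test)
    return train, test


def convert_record_area(rec: WaveformRecord) -> WaveformRecord:
    """Return a copy of ``rec`` with the area converted from m² to cm²."""
    if rec.units_area is AreaUnits.cm2:
        raise ValueError(f"{rec.subject_id}: area already in cm² (double conversion)")
    return replace(rec, a_abdominal=rec.a_abdominal * 1.0e4, units_area=AreaUnits.cm2)
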