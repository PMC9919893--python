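"""Physical-unit inversion and clinical evaluation of central predictions.

Predictions of the X→Y generator are denormalized back to mmHg and cm²,
then compared with the ground truth over the *first completed pulse* of each
signal (delimited by successive pulse feet).  Metrics:

* per-pulse RMSE of pressure and area, reported as mean ± SD over subjects;
* the pressure–strain elastic modulus ``E_P-ε`` — the ordinary
  least-squares slope β of pressure on percent strain over the pulse — with
  mean error ``ME = mean(β − β̂)`` and
  ``MAPE = 100·mean(|β − β̂| / β)`` across subjects;
* hysteresis-loop geometry (signed loop area, systolic/diastolic pressure,
  max/min diameter);
* Bland–Altman agreement (mean difference, SD, limits of agreement
  mean ± 1.96·SD) for SBP, DBP and the diameter extremes.

Strain is referenced to the minimum (diastolic) diameter of the pulse,
``ε_j = 100·(D_j − D_min)/D_min``, with diameter from a circular lumen,
``D = 2·√(A/π)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .preprocessing import NormalizationSpec, PairedSample, normalize

logger = logging.getLogger(__name__)

#: minimum foot prominence, as a fraction of the signal range
FOOT_PROMINENCE = 0.05
#: minimum spacing between successive feet, seconds
FOOT_MIN_SPACING = 0.25


class NoPulseError(ValueError):
    """Fewer than two pulse feet were found in the signal."""


@dataclass
class PulseWindow:
    start: int
    end: int  # half-open [start, end)
    fs: float

    def __post_init__(self):
        if self.end <= self.start + 1:
            raise ValueError("pulse window must span more than one sample")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LoopMetrics:
    """Per-pulse derived quantities of the pressure–strain loop."""

    beta: float  # E_P-eps slope, mmHg/%
    loop_area: float  # signed, mmHg·%
    sbp: float
    dbp: float
    d_max: float  # cm
    d_min: float  # cm


@dataclass
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float


@dataclass
class EvalReport:
    n_subjects: int
    n_excluded: int
    rmse_pressure_mean: float
    rmse_pressure_sd: float
    rmse_area_mean: float
    rmse_area_sd: float
    me_beta: float
    me_beta_sd: float
    mape_beta: float
    mape_beta_sd: float
    bland_altman: Dict[str, BlandAltman] = field(default_factory=dict)
    per_subject: pd.DataFrame = field(default=None, repr=False)

    def to_json(self) -> str:
        blob = {k: v for k, v in asdict(self).items() if k != "per_subject"}
        blob["bland_altman"] = {k: asdict(v) if isinstance(v, BlandAltman) else v
                                for k, v in self.bland_altman.items()}
        return json.dumps(blob, indent=2)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "Pressure RMSE [mmHg]": f"{self.rmse_pressure_mean:.2f} ± {self.rmse_pressure_sd:.2f}",
                    "Area RMSE [cm²]": f"{self.rmse_area_mean:.3f} ± {self.rmse_area_sd:.3f}",
                    "E_P-ε ME [mmHg/%]": f"{self.me_beta:.2f} ± {self.me_beta_sd:.2f}",
                    "E_P-ε MAPE [%]": f"{self.mape_beta:.1f} ± {self.mape_beta_sd:.1f}",
                }
            ]
        )


# ---------------------------------------------------------------------------
# pulse delimitation
# ---------------------------------------------------------------------------


def detect_pulse_feet(signal: np.ndarray, fs: float) -> np.ndarray:
    """Indices of pulse feet: prominent local minima, plus the start sample
    when the signal opens on a rising foot (tiled windows start at a foot)."""
    signal = np.asarray(signal, dtype=np.float64)
    rng_ = signal.max() - signal.min()
    if rng_ <= 0:
        return np.array([], dtype=int)
    distance = max(1, int(round(FOOT_MIN_SPACING * fs)))
    feet, _ = find_peaks(-signal, prominence=FOOT_PROMINENCE * rng_, distance=distance)
    if len(signal) > 1 and signal[0] < signal[1]:
        threshold = signal.min() + FOOT_PROMINENCE * rng_
        if signal[0] <= threshold and (len(feet) == 0 or feet[0] >= distance):
            feet = np.concatenate(([0], feet))
    return feet.astype(int)


def detect_first_pulse(signal: np.ndarray, fs: float) -> PulseWindow:
    """Window of the first completed pulse: the first two successive feet."""
    signal = np.asarray(signal, dtype=np.float64)
    if len(signal) < 3:
        raise NoPulseError("signal too short for pulse detection")
    feet = detect_pulse_feet(signal, fs)
    if len(feet) < 2:
        raise NoPulseError(f"found {len(feet)} pulse feet; need at least 2")
    return PulseWindow(start=int(feet[0]), end=int(feet[1]), fs=fs)


# ---------------------------------------------------------------------------
# loop quantities
# ---------------------------------------------------------------------------


def area_to_diameter(area):
    """Circular-lumen diameter (cm) from luminal area (cm²): D = 2·√(A/π)."""
    area = np.asarray(area, dtype=np.float64)
    if np.any(area <= 0):
        raise ValueError("area must be positive")
    return 2.0 * np.sqrt(area / np.pi)


def strain_from_area(area_pulse: np.ndarray) -> np.ndarray:
    """Percent strain referenced to the minimum (diastolic) diameter."""
    d = area_to_diameter(area_pulse)
    d_ref = d.min()
    if d_ref <= 0:
        raise ValueError("degenerate diameter reference")
    return 100.0 * (d - d_ref) / d_ref


def pe_modulus(pressure_pulse: np.ndarray, strain_pulse: np.ndarray) -> float:
    """OLS slope of pressure on strain: β = Σ(ε−ε̄)(P−P̄) / Σ(ε−ε̄)²."""
    p = np.asarray(pressure_pulse, dtype=np.float64)
    e = np.asarray(strain_pulse, dtype=np.float64)
    if len(p) != len(e) or len(p) < 2:
        raise ValueError("pressure and strain must have equal length >= 2")
    de = e - e.mean()
    denom = np.dot(de, de)
    if denom == 0:
        raise ValueError("zero strain variance; slope undefined")
    return float(np.dot(de, p - p.mean()) / denom)


def loop_area(pressure_pulse: np.ndarray, strain_pulse: np.ndarray) -> float:
    """Signed shoelace area of the closed (ε, P) loop, as ∮ P dε (mmHg·%).

    Positive when strain lags pressure (viscous hysteresis); reversing the
    traversal direction flips the sign.
    """
    p = np.asarray(pressure_pulse, dtype=np.float64)
    e = np.asarray(strain_pulse, dtype=np.float64)
    if len(p) != len(e) or len(p) < 3:
        raise ValueError("need at least 3 points to close a loop")
    e_next = np.roll(e, -1)
    p_next = np.roll(p, -1)
    return float(0.5 * np.sum((e_next - e) * (p_next + p)))


def pulse_loop_metrics(pressure_pulse: np.ndarray, area_pulse: np.ndarray) -> LoopMetrics:
    strain = strain_from_area(area_pulse)
    d = area_to_diameter(area_pulse)
    return LoopMetrics(
        beta=pe_modulus(pressure_pulse, strain),
        loop_area=loop_area(pressure_pulse, strain),
        sbp=float(np.max(pressure_pulse)),
        dbp=float(np.min(pressure_pulse)),
        d_max=float(np.max(d)),
        d_min=float(np.min(d)),
    )


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------


def pulse_rmse(true_pulse: np.ndarray, est_pulse: np.ndarray) -> float:
    """RMSE over the common (shorter) length of the two pulses."""
    a = np.asarray(true_pulse, dtype=np.float64)
    b = np.asarray(est_pulse, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty pulse")
    t = min(len(a), len(b))
    d = a[:t] - b[:t]
    return float(np.sqrt(np.mean(d * d)))


def beta_errors(
    beta_true: Sequence[float], beta_est: Sequence[float]
) -> Tuple[float, float]:
    """(ME, MAPE) of the elastic modulus across subjects."""
    bt = np.asarray(beta_true, dtype=np.float64)
    be = np.asarray(beta_est, dtype=np.float64)
    if bt.shape != be.shape or bt.size == 0:
        raise ValueError("beta arrays must be non-empty and equal-length")
    if np.any(bt == 0):
        raise ZeroDivisionError("zero true modulus; MAPE undefined")
    me = float(np.mean(bt - be))
    mape = float(100.0 * np.mean(np.abs(bt - be) / bt))
    return me, mape


def bland_altman(true_values, est_values) -> BlandAltman:
    """Agreement summary with differences true − estimated and 1.96·SD LOA."""
    t = np.asarray(true_values, dtype=np.float64)
    e = np.asarray(est_values, dtype=np.float64)
    if t.shape != e.shape or t.size < 2:
        raise ValueError("need at least two paired values")
    diff = t - e
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(
        mean_diff=mean, sd_diff=sd, loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd
    )


# ---------------------------------------------------------------------------
# cohort-level evaluation
# ---------------------------------------------------------------------------


def _denormalize_y(y: np.ndarray, spec: NormalizationSpec) -> Tuple[np.ndarray, np.ndarray]:
    pressure = normalize(y[0], spec, "pressure", invert=True)
    area = normalize(y[1], spec, "area", invert=True)
    return pressure, area


def rmse_against_truth(
    gxy, samples: Sequence[PairedSample], spec: NormalizationSpec
) -> Tuple[float, float]:
    """Whole-window denormalized RMSE (pressure, area), averaged over
    subjects — the ranking criterion of the hyperparameter search."""
    ps, as_ = [], []
    for s in samples:
        pred = gxy.predict(s.x)
        p_true, a_true = _denormalize_y(s.y, spec)
        p_est, a_est = _denormalize_y(pred, spec)
        ps.append(pulse_rmse(p_true, p_est))
        as_.append(pulse_rmse(a_true, a_est))
    return float(np.mean(ps)), float(np.mean(as_))


def evaluate(
    gxy,
    samples: Sequence[PairedSample],
    spec: NormalizationSpec,
    fs: float = 256.0,
    identity: bool = False,
) -> EvalReport:
    """Full clinical evaluation of the X→Y generator on a cohort.

    ``identity=True`` replaces the prediction by the ground truth (an oracle
    model), which must produce exactly zero errors — an end-to-end check of
    the inversion chain.  Subjects whose first pulse cannot be delimited in
    either signal are excluded with a warning.
    """
    rows = []
    n_excluded = 0
    for s in samples:
        pred = s.y.copy() if identity else gxy.predict(s.x)
        p_true, a_true = _denormalize_y(s.y, spec)
        p_est, a_est = _denormalize_y(pred, spec)
        try:
            w_true = detect_first_pulse(p_true, fs)
            w_est = detect_first_pulse(p_est, fs)
        except NoPulseError as exc:
            n_excluded += 1
            logger.warning("subject %s excluded: %s", s.subject_id, exc)
            continue
        t = min(w_true.length, w_est.length)
        pt = p_true[w_true.start : w_true.start + t]
        at = a_true[w_true.start : w_true.start + t]
        pe = p_est[w_est.start : w_est.start + t]
        ae = a_est[w_est.start : w_est.start + t]
        try:
            m_true = pulse_loop_metrics(pt, at)
            m_est = pulse_loop_metrics(pe, ae)
        except ValueError as exc:
            n_excluded += 1
            logger.warning("subject %s excluded: %s", s.subject_id, exc)
            continue
        rows.append(
            {
                "subject_id": s.subject_id,
                "rmse_p": pulse_rmse(pt, pe),
                "rmse_a": pulse_rmse(at, ae),
                "beta_true": m_true.beta,
                "beta_est": m_est.beta,
                "loop_area_true": m_true.loop_area,
                "loop_area_est": m_est.loop_area,
                "sbp_true": m_true.sbp,
                "sbp_est": m_est.sbp,
                "dbp_true": m_true.dbp,
                "dbp_est": m_est.dbp,
                "dmax_true": m_true.d_max,
                "dmax_est": m_est.d_max,
                "dmin_true": m_true.d_min,
                "dmin_est": m_est.d_min,
            }
        )
    if not rows:
        raise NoPulseError("no subject produced a usable pulse")
    df = pd.DataFrame(rows)
    diffs_beta = df.beta_true - df.beta_est
    ape = 100.0 * np.abs(diffs_beta) / df.beta_true
    ba = {}
    for name, (tc, ec) in {
        "sbp": ("sbp_true", "sbp_est"),
        "dbp": ("dbp_true", "dbp_est"),
        "d_max": ("dmax_true", "dmax_est"),
        "d_min": ("dmin_true", "dmin_est"),
    }.items():
        if len(df) >= 2:
            ba[name] = bland_altman(df[tc].to_numpy(), df[ec].to_numpy())
    return EvalReport(
        n_subjects=len(df),
        n_excluded=n_excluded,
        rmse_pressure_mean=float(df.rmse_p.mean()),
        rmse_pressure_sd=float(df.rmse_p.std(ddof=1)) if len(df) > 1 else 0.0,
        rmse_area_mean=float(df.rmse_a.mean()),
        rmse_area_sd=float(df.rmse_a.std(ddof=1)) if len(df) > 1 else 0.0,
        me_beta=float(diffs_beta.mean()),
        me_beta_sd=float(diffs_beta.std(ddof=1)) if len(df) > 1 else 0.0,
        mape_beta=float(ape.mean()),
        mape_beta_sd=float(ape.std(ddof=1)) if len(df) > 1 else 0.0,
        bland_altman=ba,
        per_subject=df,
    )
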