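"""Quantification of trot movement asymmetry from marker trajectories.

At trot the pelvis (tubera sacrale marker) describes two vertical
oscillations per stride, one per diagonal stance, and reaches a lower
position during the sound hindlimb stance.  Hindlimb lameness therefore
shows up as a difference between the two vertical-displacement minima of
each stride; the same logic applies to the poll marker for horses that
shift weight forward.  This module implements the processing chain:

1. zero-phase Butterworth low-pass filtering with the cut-off adjusted to
   the horse's stride frequency,
2. stride segmentation by peak detection on the pelvis signal,
3. left/right half-stride assignment from pelvic roll,
4. per-stride minima differences ``HDmin`` (head) and ``PDmin`` (pelvis),
   signed so that negative values denote left-sided asymmetry,
5. total asymmetry ``|HDmin/2| + |PDmin|`` and the *total asymmetry
   score*, its change from the horse's baseline measurement.

All displacements are in mm, vertical axis positive up, angles in degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "MarkerTrajectorySet",
    "StrideSegmentation",
    "AsymmetryMeasurement",
    "TotalAsymmetryScore",
    "DegenerateInputError",
    "ParameterError",
    "lowpass_filter",
    "estimate_stride_frequency",
    "segment_strides",
    "assign_sides",
    "compute_min_diff",
    "total_asymmetry",
    "asymmetry_score",
    "measure_asymmetry",
]

TRAJECTORY_COLUMNS = [
    "time_s",
    "poll_z_mm",
    "sacrale_z_mm",
    "left_tc_z_mm",
    "right_tc_z_mm",
    "roll_deg",
    "yaw_deg",
]


class ParameterError(ValueError):
    """Invalid analysis parameter (e.g. cut-off at or above Nyquist)."""


class DegenerateInputError(ValueError):
    """Signal does not contain the structure the operation requires."""


@dataclass
class MarkerTrajectorySet:
    """Synchronized vertical-displacement time series for the analyzed markers.

    ``poll_z`` and ``sacrale_z`` drive the asymmetry computation;
    ``left_tc_z``/``right_tc_z`` (tubera coxae) and ``roll``/``yaw`` support
    side detection.  All series share one uniform time grid.
    """

    time: np.ndarray          # s
    poll_z: np.ndarray        # mm
    sacrale_z: np.ndarray     # mm
    roll: np.ndarray          # deg
    yaw: np.ndarray           # deg
    sampling_rate: float      # Hz
    left_tc_z: np.ndarray | None = None
    right_tc_z: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        series = [self.poll_z, self.sacrale_z, self.roll, self.yaw]
        if self.left_tc_z is not None:
            series.append(self.left_tc_z)
        if self.right_tc_z is not None:
            series.append(self.right_tc_z)
        if any(len(s) != n for s in series):
            raise ParameterError("all trajectory series must have equal length")
        for s in [self.time, *series]:
            if not np.all(np.isfinite(s)):
                raise ParameterError("trajectories must not contain missing values")
        if n >= 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, 1.0 / self.sampling_rate, rtol=1e-6, atol=1e-9):
                raise ParameterError("time grid inconsistent with sampling_rate")

    def to_frame(self) -> pd.DataFrame:
        zeros = np.zeros_like(self.time)
        return pd.DataFrame(
            {
                "time_s": self.time,
                "poll_z_mm": self.poll_z,
                "sacrale_z_mm": self.sacrale_z,
                "left_tc_z_mm": self.left_tc_z if self.left_tc_z is not None else zeros,
                "right_tc_z_mm": self.right_tc_z if self.right_tc_z is not None else zeros,
                "roll_deg": self.roll,
                "yaw_deg": self.yaw,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerTrajectorySet":
        missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
        if missing:
            raise ParameterError(f"trajectory table lacks columns {missing}")
        t = df["time_s"].to_numpy(float)
        if len(t) < 2:
            raise DegenerateInputError("trajectory too short")
        fs = 1.0 / np.median(np.diff(t))
        return cls(
            time=t,
            poll_z=df["poll_z_mm"].to_numpy(float),
            sacrale_z=df["sacrale_z_mm"].to_numpy(float),
            left_tc_z=df["left_tc_z_mm"].to_numpy(float),
            right_tc_z=df["right_tc_z_mm"].to_numpy(float),
            roll=df["roll_deg"].to_numpy(float),
            yaw=df["yaw_deg"].to_numpy(float),
            sampling_rate=fs,
        )


@dataclass
class StrideSegmentation:
    """Stride windows on the pelvis signal.

    ``peaks`` are pelvis-displacement peak indices (two per stride); stride
    ``i`` spans ``peaks[2i] .. peaks[2i+2]`` with its two half-strides split
    at ``peaks[2i+1]``.  ``half_sides`` labels each inter-peak half-stride
    'left' or 'right' once :func:`assign_sides` has run.
    """

    peaks: np.ndarray
    stride_frequency_hz: float
    half_sides: list[str] = field(default_factory=list)
    side_warning: str | None = None

    @property
    def n_strides(self) -> int:
        return max(0, (len(self.peaks) - 1) // 2)

    def stride_halves(self, i: int) -> tuple[tuple[int, int], tuple[int, int]]:
        a, b, c = self.peaks[2 * i], self.peaks[2 * i + 1], self.peaks[2 * i + 2]
        return (a, b), (b, c)


@dataclass
class AsymmetryMeasurement:
    """Mean per-stride asymmetry for one straight-line trot measurement."""

    hd_min_mm: float
    pd_min_mm: float
    total_asymmetry_mm: float
    n_strides_used: int
    n_strides_dropped: int = 0
    stride_hd_mm: np.ndarray | None = None
    stride_pd_mm: np.ndarray | None = None


@dataclass(frozen=True)
class TotalAsymmetryScore:
    """Change in total movement asymmetry from the horse's baseline."""

    horse: str
    occasion: str
    score_mm: float


def lowpass_filter(
    x: np.ndarray,
    sampling_rate: float,
    stride_frequency: float,
    order: int = 4,
    cutoff_multiplier: float = 6.0,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass with stride-frequency-adjusted cut-off.

    The cut-off is ``cutoff_multiplier * stride_frequency`` (default 6x,
    which keeps at least three harmonics of the dominant two-per-stride
    displacement component).  Forward-backward filtering gives zero phase
    lag; output length equals input length.
    """
    x = np.asarray(x, float)
    if len(x) <= 6 * order:
        raise DegenerateInputError("signal too short to filter")
    cutoff = cutoff_multiplier * stride_frequency
    nyq = sampling_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ParameterError(f"cut-off {cutoff} Hz not below Nyquist {nyq} Hz")
    sos = sps.butter(order, cutoff, btype="low", fs=sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def estimate_stride_frequency(
    pelvis_signal: np.ndarray,
    sampling_rate: float,
    f_bounds: tuple[float, float] = (0.5, 2.5),
) -> float:
    """Estimate stride frequency from the pelvis vertical displacement.

    At trot the pelvis oscillates twice per stride, so the dominant
    spectral peak of the mean-removed signal sits at twice the stride
    frequency.  The peak location is refined by parabolic interpolation of
    the log-magnitude spectrum.
    """
    x = np.asarray(pelvis_signal, float)
    x = x - x.mean()
    if len(x) < 16 or np.std(x) < 1e-9:
        raise DegenerateInputError("pelvis signal flat or too short")
    nfft = int(2 ** np.ceil(np.log2(len(x) * 8)))
    spec = np.abs(np.fft.rfft(x * np.hanning(len(x)), nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sampling_rate)
    lo, hi = 2 * f_bounds[0], 2 * f_bounds[1]
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any() or spec[mask].max() <= 0:
        raise DegenerateInputError("no spectral peak in physiologic bounds")
    idx = np.flatnonzero(mask)[np.argmax(spec[mask])]
    # parabolic refinement on log magnitude
    if 0 < idx < len(spec) - 1 and spec[idx - 1] > 0 and spec[idx + 1] > 0:
        la, lb, lc = np.log(spec[idx - 1 : idx + 2])
        denom = la - 2 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom < 0 else 0.0
    else:
        delta = 0.0
    f2 = freqs[idx] + delta * (freqs[1] - freqs[0])
    f = f2 / 2.0
    if not f_bounds[0] <= f <= f_bounds[1]:
        raise DegenerateInputError(f"estimated stride frequency {f:.3f} Hz out of bounds")
    return float(f)


def segment_strides(
    filtered_pelvis: np.ndarray,
    sampling_rate: float,
    stride_frequency: float,
    prominence_fraction: float = 0.2,
) -> StrideSegmentation:
    """Segment strides by peak detection on the filtered pelvis signal.

    Peaks (two per stride at trot) must be separated by at least
    ``0.4 / stride_frequency`` seconds and have prominence of at least
    ``prominence_fraction`` of the signal's interquartile range; a stride
    spans three successive peaks.  Partial strides at the edges are
    implicitly discarded.
    """
    x = np.asarray(filtered_pelvis, float)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    min_dist = max(1, int(round(0.4 / stride_frequency * sampling_rate)))
    peaks, _ = sps.find_peaks(x, distance=min_dist, prominence=prominence_fraction * iqr)
    seg = StrideSegmentation(peaks=peaks, stride_frequency_hz=stride_frequency)
    if seg.n_strides < 1:
        raise DegenerateInputError("fewer than one complete stride detected")
    return seg


def assign_sides(
    segmentation: StrideSegmentation,
    roll: np.ndarray,
    yaw: np.ndarray | None = None,
    ambiguity_threshold_deg: float = 0.1,
) -> StrideSegmentation:
    """Label each half-stride 'left' or 'right' from pelvic roll.

    Convention (shared with the synthetic gait generator): mean pelvic roll
    is positive during the right-stance-associated half-stride.  The label
    pattern must alternate, so the alternation phase is chosen to best
    match the per-half mean-roll signs; if every half-stride's mean roll
    magnitude is below ``ambiguity_threshold_deg`` a warning is emitted and
    plain alternation starting 'right' is used.  ``yaw`` is accepted for
    interface completeness but not used by the default rule.
    """
    roll = np.asarray(roll, float)
    peaks = segmentation.peaks
    n_half = len(peaks) - 1
    if n_half < 1:
        raise DegenerateInputError("segmentation has no half-strides")
    means = np.array([roll[peaks[k] : peaks[k + 1] + 1].mean() for k in range(n_half)])
    parity = np.where(np.arange(n_half) % 2 == 0, 1.0, -1.0)
    score = float(np.sum(parity * means))
    warning = None
    if np.all(np.abs(means) < ambiguity_threshold_deg):
        warning = (
            "pelvic roll amplitude below ambiguity threshold; "
            "falling back to alternation starting 'right'"
        )
        warnings.warn(warning, stacklevel=2)
        even_side = "right" if score >= 0 else "left"
    else:
        even_side = "right" if score > 0 else "left"
    odd_side = "left" if even_side == "right" else "right"
    segmentation.half_sides = [even_side if k % 2 == 0 else odd_side for k in range(n_half)]
    segmentation.side_warning = warning
    return segmentation


def _refined_min(x: np.ndarray, a: int, b: int) -> float | None:
    """Interior minimum of ``x[a:b+1]`` with 3-point parabolic refinement.

    Returns None when the minimum sits on the window edge (no proper
    displacement minimum inside the half-stride).  Ties take the earliest
    sample.
    """
    window = x[a : b + 1]
    if len(window) < 3:
        return None
    i = int(np.argmin(window))
    if i == 0 or i == len(window) - 1:
        return None
    y0, y1, y2 = window[i - 1], window[i], window[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom > 0:
        return float(y1 - (y0 - y2) ** 2 / (8 * denom))
    return float(y1)


def compute_min_diff(
    filtered_signal: np.ndarray,
    segmentation: StrideSegmentation,
) -> tuple[np.ndarray, float, int]:
    """Per-stride signed difference between the two displacement minima.

    For each stride the minimum during the right-associated half and the
    minimum during the left-associated half are located (within the
    pelvis-defined stride windows) and the signed difference
    ``min_right - min_left`` is taken, so that left-sided asymmetries (a
    shallower left-stance minimum) come out negative.  Strides lacking an
    interior minimum in either half are excluded and counted.

    Returns ``(per_stride_values, mean, n_dropped)``.
    """
    if not segmentation.half_sides:
        raise ParameterError("segmentation has no side labels; run assign_sides first")
    x = np.asarray(filtered_signal, float)
    values = []
    dropped = 0
    for i in range(segmentation.n_strides):
        (a1, b1), (a2, b2) = segmentation.stride_halves(i)
        side1 = segmentation.half_sides[2 * i]
        m1 = _refined_min(x, a1, b1)
        m2 = _refined_min(x, a2, b2)
        if m1 is None or m2 is None:
            dropped += 1
            continue
        if side1 == "right":
            values.append(m1 - m2)
        else:
            values.append(m2 - m1)
    if not values:
        raise DegenerateInputError("no stride yielded two interior minima")
    arr = np.array(values)
    return arr, float(arr.mean()), dropped


def total_asymmetry(hd_min_mm: float, pd_min_mm: float) -> float:
    """Total movement asymmetry ``|HDmin/2| + |PDmin|`` in mm."""
    if not (np.isfinite(hd_min_mm) and np.isfinite(pd_min_mm)):
        raise ParameterError("hd_min_mm and pd_min_mm must be finite")
    return abs(hd_min_mm) / 2.0 + abs(pd_min_mm)


def measure_asymmetry(
    traj: MarkerTrajectorySet,
    stride_frequency: float | None = None,
    cutoff_multiplier: float = 6.0,
    prominence_fraction: float = 0.2,
) -> AsymmetryMeasurement:
    """Full processing chain for one measurement: filter, segment, assign
    sides, and average per-stride HDmin/PDmin into a total asymmetry.
    """
    if stride_frequency is None:
        stride_frequency = estimate_stride_frequency(traj.sacrale_z, traj.sampling_rate)
    pelvis = lowpass_filter(
        traj.sacrale_z, traj.sampling_rate, stride_frequency, cutoff_multiplier=cutoff_multiplier
    )
    poll = lowpass_filter(
        traj.poll_z, traj.sampling_rate, stride_frequency, cutoff_multiplier=cutoff_multiplier
    )
    seg = segment_strides(pelvis, traj.sampling_rate, stride_frequency, prominence_fraction)
    seg = assign_sides(seg, traj.roll, traj.yaw)
    pd_vals, pd_mean, pd_drop = compute_min_diff(pelvis, seg)
    hd_vals, hd_mean, hd_drop = compute_min_diff(poll, seg)
    return AsymmetryMeasurement(
        hd_min_mm=hd_mean,
        pd_min_mm=pd_mean,
        total_asymmetry_mm=total_asymmetry(hd_mean, pd_mean),
        n_strides_used=min(len(pd_vals), len(hd_vals)),
        n_strides_dropped=max(pd_drop, hd_drop),
        stride_hd_mm=hd_vals,
        stride_pd_mm=pd_vals,
    )


def asymmetry_score(
    measurements: dict[str, AsymmetryMeasurement],
    baseline_occasion: str,
    horse: str = "",
) -> list[TotalAsymmetryScore]:
    """Total asymmetry score per occasion: change from the baseline occasion.

    The baseline occasion scores 0 by construction; scores may be negative
    when an induced measurement is more symmetric than baseline.
    """
    if baseline_occasion not in measurements:
        raise ParameterError(f"baseline occasion {baseline_occasion!r} missing")
    base = measurements[baseline_occasion].total_asymmetry_mm
    return [
        TotalAsymmetryScore(horse=horse, occasion=occ, score_mm=m.total_asymmetry_mm - base)
        for occ, m in measurements.items()
    ]
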