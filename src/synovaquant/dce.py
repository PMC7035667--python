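"""Semiquantitative DCE-MRI perfusion parameters.

Given a 4D dynamic series and ROI masks, this module extracts
time-intensity curves (TICs) and computes the five heuristic perfusion
parameters commonly reported for synovitis:

* wash-in   -- average signal slope over the initial 30 s (a.u./min)
* wash-out  -- average signal slope over the final 30 s (a.u./min)
* TTP       -- time to peak enhancement, from acquisition start (s)
* PE        -- peak enhancement ratio, (S_max - S0) / S0
* iAUC      -- initial area under the enhancement curve, first 60 s
               (a.u.·min)

No pharmacokinetic (Tofts-type) modelling is performed: slopes are OLS
fits, the integral is trapezoidal, and all quantities are defined
directly on the sampled curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ROI names used in the knee synovitis protocol (three synovial sites
#: plus the arterial and muscular reference curves).
KNOWN_ROIS = (
    "infrapatellar",
    "intercondylar",
    "prefemoral",
    "popliteal_artery",
    "gastrocnemius_muscle",
    "custom",
)

PARAM_NAMES = ("wash_in", "wash_out", "ttp", "pe", "iauc")


@dataclass(frozen=True)
class TimeIntensityCurve:
    """Mean ROI signal versus acquisition time.

    Parameters
    ----------
    times
        Acquisition times in seconds, strictly increasing. The first
        element defines the acquisition start.
    signals
        Mean ROI signal (arbitrary units), same length as ``times``,
        finite and non-negative.
    roi_name
        One of :data:`KNOWN_ROIS`.
    """

    times: np.ndarray
    signals: np.ndarray
    roi_name: str = "custom"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        signals = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "signals", signals)
        if times.ndim != 1 or signals.ndim != 1:
            raise ValueError("times and signals must be 1-D")
        if times.size != signals.size:
            raise ValueError("times and signals must have equal length")
        if times.size < 2:
            raise ValueError("a time-intensity curve needs at least 2 samples")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(signals)) or np.any(signals < 0):
            raise ValueError("signals must be finite and non-negative")
        if self.roi_name not in KNOWN_ROIS:
            raise ValueError(
                f"unknown roi_name {self.roi_name!r}; expected one of {KNOWN_ROIS}"
            )

    @property
    def duration(self) -> float:
        """Total acquisition time span in seconds."""
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class PerfusionParams:
    """The five semiquantitative parameters for one ROI, plus S0/Smax."""

    s0: float
    s_max: float
    wash_in: float
    wash_out: float
    ttp: float
    pe: float
    iauc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "s0": self.s0,
            "s_max": self.s_max,
            "wash_in": self.wash_in,
            "wash_out": self.wash_out,
            "ttp": self.ttp,
            "pe": self.pe,
            "iauc": self.iauc,
        }


@dataclass(frozen=True)
class PatientDceSummary:
    """Per-parameter mean and SD across a patient's included ROIs.

    SD uses the n-1 denominator; with fewer than two included ROIs the
    SD is reported missing (NaN).
    """

    patient_id: str
    roi_params: dict[str, PerfusionParams]
    roi_inclusion: tuple[str, ...]
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)


def extract_tic(
    volume4d: np.ndarray,
    roi: np.ndarray,
    frame_times: np.ndarray,
    roi_name: str = "custom",
    roi_label: int | None = None,
) -> TimeIntensityCurve:
    """Reduce a 4D series to the mean-signal curve of one ROI.

    Parameters
    ----------
    volume4d
        Array of shape (x, y, z, t).
    roi
        Either a boolean/binary mask of shape (x, y, z) or, when
        ``roi_label`` is given, an integer label volume from which the
        mask ``roi == roi_label`` is taken.
    frame_times
        Acquisition time of each frame (s); length must equal the
        series' fourth dimension.
    """
    volume4d = np.asarray(volume4d)
    if volume4d.ndim != 4:
        raise ValueError(f"expected a 4D series, got shape {volume4d.shape}")
    roi = np.asarray(roi)
    if roi.shape != volume4d.shape[:3]:
        raise ValueError(
            f"ROI shape {roi.shape} does not match spatial shape {volume4d.shape[:3]}"
        )
    mask = (roi == roi_label) if roi_label is not None else roi.astype(bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size != volume4d.shape[3]:
        raise ValueError(
            f"{frame_times.size} frame times for {volume4d.shape[3]} frames"
        )
    signals = volume4d[mask].mean(axis=0)
    return TimeIntensityCurve(times=frame_times, signals=signals, roi_name=roi_name)


def baseline_s0(tic: TimeIntensityCurve, n_baseline_frames: int = 1) -> float:
    """Pre-contrast signal S0: mean of the first ``n_baseline_frames`` samples.

    The contrast injection in the emulated protocol starts just before
    the first measurement, so only frame 0 is reliably pre-contrast;
    hence the default window of one frame.
    """
    n = len(tic.signals)
    if not 1 <= n_baseline_frames < n:
        raise ValueError(
            f"n_baseline_frames must be in [1, {n - 1}], got {n_baseline_frames}"
        )
    return float(tic.signals[:n_baseline_frames].mean())


def window_slope(
    tic: TimeIntensityCurve,
    window: str,
    window_len_s: float = 30.0,
    method: str = "ols",
) -> float:
    """Average slope over the initial or final window, in a.u./min.

    ``window='initial'`` fits over samples with
    t in [t_first, t_first + window_len_s]; ``'final'`` over
    [t_last - window_len_s, t_last]; both ends closed, no interpolation
    to the window boundary. The default estimator is an ordinary
    least-squares fit of signal on time; ``method='endpoint'`` uses the
    difference quotient between the first and last in-window samples
    for sensitivity checks.
    """
    t, y = tic.times, tic.signals
    if window == "initial":
        sel = t <= t[0] + window_len_s
    elif window == "final":
        sel = t >= t[-1] - window_len_s
    else:
        raise ValueError(f"window must be 'initial' or 'final', got {window!r}")
    if sel.sum() < 2:
        raise ValueError(
            f"fewer than 2 samples in the {window} {window_len_s:g} s window"
        )
    tw, yw = t[sel], y[sel]
    if np.all(yw == yw[0]):  # exactly flat window: slope 0 without fit residue
        return 0.0
    if method == "ols":
        slope = float(np.polyfit(tw, yw, 1)[0])
    elif method == "endpoint":
        slope = float((yw[-1] - yw[0]) / (tw[-1] - tw[0]))
    else:
        raise ValueError(f"unknown slope method {method!r}")
    return slope * 60.0  # a.u./s -> a.u./min


def time_to_peak(tic: TimeIntensityCurve) -> float:
    """Time from acquisition start to maximum signal, in seconds.

    Ties resolve to the earliest frame attaining the maximum.
    """
    return float(tic.times[int(np.argmax(tic.signals))] - tic.times[0])


def peak_enhancement(tic: TimeIntensityCurve, s0: float) -> float:
    """Peak enhancement ratio PE = (S_max - S0) / S0. Requires S0 > 0."""
    if s0 <= 0:
        raise ValueError(f"peak enhancement requires s0 > 0, got {s0}")
    return float((tic.signals.max() - s0) / s0)


def iauc(
    tic: TimeIntensityCurve,
    s0: float,
    window_len_s: float = 60.0,
    clip_negative: bool = False,
) -> float:
    """Initial area under the enhancement curve, in a.u.·min.

    Trapezoidal integral of (signal - s0) over samples with
    t - t_first <= window_len_s; no extrapolation beyond the last
    in-window sample. Negative excursions are kept by default so the
    integral is linear in the enhancement; ``clip_negative=True``
    floors the integrand at zero.
    """
    t, y = tic.times, tic.signals
    sel = t - t[0] <= window_len_s
    if sel.sum() < 2:
        raise ValueError(
            f"fewer than 2 samples in the first {window_len_s:g} s for iAUC"
        )
    enh = y[sel] - s0
    if clip_negative:
        enh = np.maximum(enh, 0.0)
    return float(np.trapezoid(enh, t[sel]) / 60.0)


def perfusion_params(
    tic: TimeIntensityCurve,
    n_baseline_frames: int = 1,
    slope_window_s: float = 30.0,
    iauc_window_s: float = 60.0,
    clip_negative_iauc: bool = False,
) -> PerfusionParams:
    """All five semiquantitative parameters for one curve."""
    s0 = baseline_s0(tic, n_baseline_frames)
    return PerfusionParams(
        s0=s0,
        s_max=float(tic.signals.max()),
        wash_in=window_slope(tic, "initial", slope_window_s),
        wash_out=window_slope(tic, "final", slope_window_s),
        ttp=time_to_peak(tic),
        pe=peak_enhancement(tic, s0),
        iauc=iauc(tic, s0, iauc_window_s, clip_negative_iauc),
    )


def iauc_map(
    volume4d: np.ndarray,
    frame_times: np.ndarray,
    mask: np.ndarray | None = None,
    n_baseline_frames: int = 1,
    window_len_s: float = 60.0,
) -> np.ndarray:
    """Voxelwise iAUC parametric map (a.u.·min), NaN outside the mask.

    Per-voxel S0 is the mean of the first ``n_baseline_frames`` frames.
    """
    volume4d = np.asarray(volume4d, dtype=float)
    if volume4d.ndim != 4:
        raise ValueError(f"expected a 4D series, got shape {volume4d.shape}")
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size != volume4d.shape[3]:
        raise ValueError(
            f"{frame_times.size} frame times for {volume4d.shape[3]} frames"
        )
    sel = frame_times - frame_times[0] <= window_len_s
    if sel.sum() < 2:
        raise ValueError("fewer than 2 frames in the iAUC window")
    s0 = volume4d[..., :n_baseline_frames].mean(axis=3)
    enh = volume4d[..., sel] - s0[..., None]
    out = np.trapezoid(enh, frame_times[sel], axis=3) / 60.0
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != volume4d.shape[:3]:
            raise ValueError(
                f"mask shape {mask.shape} does not match spatial shape "
                f"{volume4d.shape[:3]}"
            )
        excluded = int((~mask.astype(bool)).sum())
        out[~mask.astype(bool)] = np.nan
        logger.info("iauc_map: %d voxels outside mask set to NaN", excluded)
    return out


def summarize_patient(
    patient_id: str,
    roi_params: dict[str, PerfusionParams],
    roi_inclusion: tuple[str, ...] | list[str] | None = None,
) -> PatientDceSummary:
    """Per-parameter mean and SD (n-1) across the included ROIs.

    Which ROIs enter a patient-level summary (all five, or only the
    synovial three) is a reporting choice, so the inclusion set is an
    explicit argument and is recorded in the output.
    """
    if not roi_params:
        raise ValueError("at least one ROI is required")
    if roi_inclusion is None:
        roi_inclusion = tuple(roi_params)
    unknown = set(roi_inclusion) - set(roi_params)
    if unknown:
        raise ValueError(f"roi_inclusion names not present: {sorted(unknown)}")
    included = [roi_params[name] for name in roi_inclusion]
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for p in PARAM_NAMES:
        vals = np.array([getattr(rp, p) for rp in included], dtype=float)
        means[p] = float(vals.mean())
        sds[p] = float(vals.std(ddof=1)) if len(vals) >= 2 else float("nan")
    return PatientDceSummary(
        patient_id=patient_id,
        roi_params=dict(roi_params),
        roi_inclusion=tuple(roi_inclusion),
        means=means,
        sds=sds,
    )


def tic_to_frame(tics: dict[str, TimeIntensityCurve], patient_id: str) -> pd.DataFrame:
    """Long-format TIC table: patient, roi, time_s, signal."""
    rows = []
    for roi_name, tic in tics.items():
        for t, s in zip(tic.times, tic.signals):
            rows.append(
                {"patient": patient_id, "roi": roi_name, "time_s": t, "signal": s}
            )
    return pd.DataFrame(rows)
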