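"""Digital DCE phantom and rater simulator.

Every downstream stage of the toolkit (curve extraction, perfusion
parameters, volumetry, agreement statistics) is testable without real
images by generating:

* a 4D dynamic series in which each tissue compartment follows a
  piecewise-linear three-segment enhancement curve (baseline, uptake,
  late phase) with known, closed-form parameters,
* a pair of segmentation masks (contrast-enhanced vs. FLAIR-like) with
  a controllable volume ratio, the FLAIR mask a strict subset of the
  CE mask, and
* a pair of ordinal readers with a controllable disagreement rate.

The default acquisition emulates a 22-frame dynamic series at 9.8 s
intervals (200 s total); signal levels are arbitrary units. The
piecewise-linear kinetics reproduce the qualitative morphology of
synovial enhancement — steep uptake between roughly 20 and 40 s after
injection, then continued but much slower enhancement — while keeping
every truth parameter exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .dce import PerfusionParams, TimeIntensityCurve, perfusion_params

logger = logging.getLogger(__name__)

COMPARTMENT_NAMES = (
    "synovium",
    "effusion",
    "artery",
    "muscle",
    "fat",
    "background",
)

#: Compartments that do not enhance (flat curves).
NON_ENHANCING = ("effusion", "background")


@dataclass(frozen=True)
class CompartmentSpec:
    """One tissue compartment of the phantom.

    The noiseless signal is the three-segment piecewise-linear curve

        S(t) = s0                                          t < arrival
        S(t) = s0 + uptake_slope * (t - arrival)           arrival <= t < peak
        S(t) = S(peak) + late_slope * (t - peak)           t >= peak

    with ``late_slope`` possibly negative (washout).
    """

    label: int
    name: str
    s0: float
    arrival_time: float = 0.0
    uptake_slope: float = 0.0
    peak_time: float = 0.0
    late_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise ValueError("compartment label must be a positive integer")
        if self.name not in COMPARTMENT_NAMES:
            raise ValueError(
                f"unknown compartment name {self.name!r}; "
                f"expected one of {COMPARTMENT_NAMES}"
            )
        if self.s0 < 0:
            raise ValueError("baseline signal s0 must be non-negative")
        if self.arrival_time > self.peak_time:
            raise ValueError("arrival_time must not exceed peak_time")
        if self.name in NON_ENHANCING and self.uptake_slope != 0:
            raise ValueError(f"{self.name} is non-enhancing: uptake_slope must be 0")

    def signal_at(self, t: np.ndarray | float) -> np.ndarray:
        """Noiseless piecewise-linear signal at time(s) ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        peak_sig = self.s0 + self.uptake_slope * (self.peak_time - self.arrival_time)
        return np.where(
            t < self.arrival_time,
            self.s0,
            np.where(
                t < self.peak_time,
                self.s0 + self.uptake_slope * (t - self.arrival_time),
                peak_sig + self.late_slope * (t - self.peak_time),
            ),
        )


def default_compartments() -> list[CompartmentSpec]:
    """Knee-like compartment set with arbitrary-unit signal levels.

    Synovium enhances steeply between ~20 and ~40 s then slowly; the
    artery enhances earlier and washes out; muscle enhances weakly;
    effusion and background are flat. No raw signal scale is implied by
    the emulated protocol, so the levels are arbitrary units chosen to
    give enhancement ratios of the order seen in inflamed synovium.
    """
    return [
        CompartmentSpec(1, "synovium", s0=100.0, arrival_time=19.6,
                        uptake_slope=4.0, peak_time=39.2, late_slope=0.5),
        CompartmentSpec(2, "artery", s0=100.0, arrival_time=9.8,
                        uptake_slope=12.0, peak_time=29.4, late_slope=-0.6),
        CompartmentSpec(3, "muscle", s0=80.0, arrival_time=19.6,
                        uptake_slope=0.4, peak_time=117.6, late_slope=0.1),
        CompartmentSpec(4, "effusion", s0=120.0),
        CompartmentSpec(5, "background", s0=20.0),
    ]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, timing and noise of the digital phantom."""

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size: tuple[float, float, float] = (1.1, 1.1, 1.1)
    n_frames: int = 22
    frame_interval: float = 9.8
    noise_sd: float = 0.0
    seed: int = 0
    noise_model: str = "gaussian"
    compartments: list[CompartmentSpec] = field(default_factory=default_compartments)

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        labels = [c.label for c in self.compartments]
        if len(labels) != len(set(labels)):
            raise ValueError("compartment labels must be unique")
        total = self.total_time
        for c in self.compartments:
            if c.peak_time > total:
                raise ValueError(
                    f"compartment {c.name!r} peaks at {c.peak_time} s, after the "
                    f"acquisition ends ({total} s)"
                )

    @property
    def total_time(self) -> float:
        """Total acquisition time (n_frames - 1) * frame_interval, s."""
        return (self.n_frames - 1) * self.frame_interval

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class PhantomTruth:
    """Ground truth accompanying one generated phantom.

    Truth perfusion parameters are computed by applying the estimator
    formulas to the noiseless piecewise curve sampled at the frame
    times — exact up to floating point, with no sampling noise and no
    voxel averaging.
    """

    curves: dict[str, TimeIntensityCurve]
    params: dict[str, PerfusionParams]
    volumes_cm3: dict[str, float]
    ce_flair_ratio: float | None = None


def compartment_labels(config: PhantomConfig) -> np.ndarray:
    """Deterministic label volume: compartments as slabs along the x-axis."""
    nx = config.grid_shape[0]
    n_comp = len(config.compartments)
    labels = np.zeros(config.grid_shape, dtype=np.int16)
    edges = np.linspace(0, nx, n_comp + 1).round().astype(int)
    for comp, lo, hi in zip(config.compartments, edges[:-1], edges[1:]):
        labels[lo:hi, :, :] = comp.label
    return labels


def generate_dce_phantom(
    config: PhantomConfig,
) -> tuple[np.ndarray, np.ndarray, PhantomTruth]:
    """Generate the 4D signal series, label volume and ground truth.

    The same seed always reproduces a bit-identical series. Negative
    signals after noise are clipped at zero and the clip count logged.
    """
    labels = compartment_labels(config)
    times = config.frame_times
    signal = np.zeros(config.grid_shape + (config.n_frames,), dtype=float)
    curves: dict[str, TimeIntensityCurve] = {}
    params: dict[str, PerfusionParams] = {}
    volumes: dict[str, float] = {}
    for comp in config.compartments:
        clean = comp.signal_at(times)
        signal[labels == comp.label] = clean
        curves[comp.name] = TimeIntensityCurve(times, clean, "custom")
        params[comp.name] = perfusion_params(curves[comp.name])
        volumes[comp.name] = float(
            (labels == comp.label).sum() * config.voxel_volume_mm3 / 1000.0
        )
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        if config.noise_model == "gaussian":
            signal = signal + rng.normal(0.0, config.noise_sd, signal.shape)
        else:  # rician: magnitude of a complex signal with Gaussian channels
            n1 = rng.normal(0.0, config.noise_sd, signal.shape)
            n2 = rng.normal(0.0, config.noise_sd, signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)
        n_clipped = int((signal < 0).sum())
        if n_clipped:
            logger.warning(
                "phantom: %d voxel-frames clipped at 0 after noise", n_clipped
            )
            signal = np.clip(signal, 0.0, None)
    truth = PhantomTruth(curves=curves, params=params, volumes_cm3=volumes)
    return signal, labels, truth


def _trim_boundary(mask: np.ndarray, n_remove: int, structure: np.ndarray) -> None:
    """Remove ``n_remove`` boundary voxels in lexicographic order, in place."""
    while n_remove > 0:
        interior = ndimage.binary_erosion(mask, structure=structure)
        shell = np.argwhere(mask & ~interior)  # argwhere is lexicographic
        if shell.size == 0:
            shell = np.argwhere(mask)
        for idx in shell[:n_remove]:
            mask[tuple(idx)] = False
        n_remove -= min(n_remove, len(shell))


def erode_to_ratio(
    mask_ce: np.ndarray, target_ratio: float
) -> tuple[np.ndarray, float]:
    """Shrink a binary mask toward ``target_ratio`` of its volume.

    Iterative 6-connectivity morphological erosion, then removal of
    individual boundary voxels in lexicographic order until the voxel
    count equals round(target_ratio * N). Deterministic. Returns the
    shrunken mask and the achieved ratio; a warning is logged whenever
    the achieved ratio is not exactly the target.
    """
    if not 0 < target_ratio <= 1:
        raise ValueError("target_ratio must be in (0, 1]")
    mask_ce = mask_ce.astype(bool)
    n_total = int(mask_ce.sum())
    if n_total == 0:
        raise ValueError("CE mask is empty")
    if target_ratio == 1.0:
        return mask_ce.copy(), 1.0
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    target_count = max(1, int(round(target_ratio * n_total)))
    mask = mask_ce.copy()
    while True:
        eroded = ndimage.binary_erosion(mask, structure=structure)
        if int(eroded.sum()) < target_count:
            break
        mask = eroded
    _trim_boundary(mask, int(mask.sum()) - target_count, structure)
    achieved = int(mask.sum()) / n_total
    if achieved != target_ratio:
        logger.warning(
            "paired masks: target ratio %.6g not exactly achievable on %d voxels; "
            "achieved %.6g",
            target_ratio,
            n_total,
            achieved,
        )
    return mask, achieved


def generate_paired_masks(
    config: PhantomConfig, target_ratio: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """CE and FLAIR-like synovium masks with a controlled volume ratio.

    Emulates the systematic under-segmentation of synovium on
    non-enhanced FLAIR images relative to contrast-enhanced images: the
    FLAIR mask is a voxelwise subset of the CE mask with
    |FLAIR| / |CE| as close to ``target_ratio`` as the voxel grid
    allows.
    """
    synovium = [c for c in config.compartments if c.name == "synovium"]
    if not synovium:
        raise ValueError("config has no synovium compartment")
    labels = compartment_labels(config)
    mask_ce = labels == synovium[0].label
    mask_flair, achieved = erode_to_ratio(mask_ce, target_ratio)
    return mask_ce, mask_flair, achieved


def simulate_reader_pair(
    true_scores: list[int] | np.ndarray,
    disagreement_prob: float,
    seed: int,
    max_grade: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Two ordinal readers with a known item-wise disagreement rate.

    Reader 1 returns the true grades. Reader 2 differs at each item
    with probability ``disagreement_prob`` by one grade step: direction
    uniform for interior grades, inward at the scale boundaries (so a
    drawn disagreement always changes the grade).
    """
    if not 0 <= disagreement_prob <= 1:
        raise ValueError("disagreement_prob must be in [0, 1]")
    true_scores = np.asarray(true_scores, dtype=int)
    if np.any(true_scores < 0) or np.any(true_scores > max_grade):
        raise ValueError(f"grades must lie in 0..{max_grade}")
    rng = np.random.default_rng(seed)
    flip = rng.random(true_scores.shape) < disagreement_prob
    step = rng.choice([-1, 1], size=true_scores.shape)
    step[true_scores == 0] = 1
    step[true_scores == max_grade] = -1
    reader2 = true_scores + np.where(flip, step, 0)
    return true_scores.copy(), reader2


def make_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    """RAS+ affine with the given voxel spacing (mm), origin at zero."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_phantom(
    outdir: str | Path,
    config: PhantomConfig,
    signal: np.ndarray,
    labels: np.ndarray,
    truth: PhantomTruth,
) -> dict[str, Path]:
    """Write signal/labels as NIfTI and truth as CSV + JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = make_affine(config.voxel_size)
    paths = {
        "signal": outdir / "dce_signal.nii.gz",
        "labels": outdir / "labels.nii.gz",
        "truth_csv": outdir / "truth_params.csv",
        "truth_json": outdir / "truth.json",
    }
    nib.save(nib.Nifti1Image(signal.astype(np.float32), aff), paths["signal"])
    nib.save(nib.Nifti1Image(labels.astype(np.int16), aff), paths["labels"])
    rows = []
    for name, p in truth.params.items():
        row = {"compartment": name, "volume_cm3": truth.volumes_cm3[name]}
        row.update(p.as_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(paths["truth_csv"], index=False)
    sidecar = {
        "n_frames": config.n_frames,
        "frame_interval_s": config.frame_interval,
        "voxel_size_mm": list(config.voxel_size),
        "noise_sd": config.noise_sd,
        "noise_model": config.noise_model,
        "seed": config.seed,
        "ce_flair_ratio": truth.ce_flair_ratio,
        "compartment_labels": {c.name: c.label for c in config.compartments},
    }
    paths["truth_json"].write_text(json.dumps(sidecar, indent=2))
    return paths
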