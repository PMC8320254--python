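"""From a two-channel image stack plus ROI masks to per-cell traces.

Drift correction is translation-only: each frame is registered to a
reference frame by cross-correlation and shifted back. Excessive axial
(Z) movement cannot be corrected in a single-plane recording, so it is
flagged instead, using the per-frame Pearson correlation to the reference
as a surrogate metric. ROI masks are label images (0 = background) drawn
externally; segmentation is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
from skimage.registration import phase_cross_correlation

from .config import AnalysisConfig

__all__ = [
    "RoiTrace",
    "BackgroundRedStats",
    "QcReport",
    "register_stack",
    "qc_z_movement",
    "extract_roi_traces",
    "measure_background_red",
]


@dataclass
class RoiTrace:
    """One cell's raw green-channel time series plus static measurements.

    ``green`` holds mean pixel intensity over the ROI per frame (arbitrary
    units); ``area_um2`` the soma cross-sectional area; ``red_mean`` the mean
    red-channel intensity over the ROI on the reference frame (NaN when no
    red channel was recorded).
    """

    cell_id: str
    area_um2: float
    green: np.ndarray
    time_s: np.ndarray
    red_mean: float = float("nan")

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.area_um2 <= 0:
            raise ValueError(f"area_um2 must be positive, got {self.area_um2!r}")
        if self.green.shape != self.time_s.shape:
            raise ValueError("green and time_s must have equal length")
        if self.time_s.size >= 2 and not (np.diff(self.time_s) > 0).all():
            raise ValueError("time_s must be strictly increasing")


@dataclass(frozen=True)
class BackgroundRedStats:
    """Mean and SD of the per-ROI mean red intensities in background regions."""

    mean: float
    sd: float
    n_rois: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")


@dataclass
class QcReport:
    """Per-frame registration quality and the stack-level verdict."""

    correlations: np.ndarray
    failing_frames: list[int] = field(default_factory=list)
    passed: bool = True
    corr_min: float = 0.6


def register_stack(
    stack: np.ndarray,
    reference: int | str = "mean",
    upsample_factor: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Translation-only registration of every frame to a reference.

    Parameters
    ----------
    stack:
        Array of shape (frames, y, x).
    reference:
        Frame index, or ``"mean"`` for the mean image.
    upsample_factor:
        1 gives integer-pixel shifts (cross-correlation argmax); larger
        values enable subpixel refinement.

    Returns
    -------
    (corrected, shifts):
        The corrected stack and the estimated per-frame (dy, dx) shifts.
        Each frame is translated by the negative of its estimated shift.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be 3-D with at least 2 frames")
    if stack.shape[1] < 8 or stack.shape[2] < 8:
        raise ValueError("frames must be at least 8x8 pixels")
    ref = stack.mean(axis=0) if reference == "mean" else stack[int(reference)]

    shifts = np.zeros((stack.shape[0], 2))
    corrected = np.empty_like(stack)
    for i, frame in enumerate(stack):
        shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor, normalization=None
        )
        # phase_cross_correlation returns the shift that maps frame onto ref,
        # i.e. the correction; the frame's displacement is its negative.
        shifts[i] = -shift
        if np.allclose(shift, np.round(shift)):
            corrected[i] = np.roll(frame, tuple(int(s) for s in shift), axis=(0, 1))
        else:
            corrected[i] = scipy.ndimage.shift(frame, shift, order=1, mode="nearest")
    return corrected, shifts


def qc_z_movement(stack: np.ndarray, config: AnalysisConfig) -> QcReport:
    """Flag frames that decorrelate from the reference (axial-movement proxy).

    Computes the Pearson correlation of every frame with the mean image of
    the registered stack; the stack fails when more than
    ``config.qc_fail_frac`` of frames fall below ``config.qc_corr_min``.
    """
    stack = np.asarray(stack, dtype=float)
    ref = stack.mean(axis=0)
    ref_flat = ref.ravel() - ref.mean()
    ref_norm = np.linalg.norm(ref_flat)
    corrs = np.empty(stack.shape[0])
    for i, frame in enumerate(stack):
        f = frame.ravel() - frame.mean()
        denom = ref_norm * np.linalg.norm(f)
        corrs[i] = 1.0 if denom == 0 else float(ref_flat @ f) / denom
    failing = [int(i) for i in np.nonzero(corrs < config.qc_corr_min)[0]]
    passed = len(failing) <= config.qc_fail_frac * stack.shape[0]
    return QcReport(
        correlations=corrs,
        failing_frames=failing,
        passed=passed,
        corr_min=config.qc_corr_min,
    )


def extract_roi_traces(
    stack: np.ndarray,
    mask: np.ndarray,
    pixel_size_um: float,
    frame_rate_hz: float = 1.55,
    red_frame: np.ndarray | None = None,
) -> list[RoiTrace]:
    """Mean-intensity time series and areas for every labelled ROI.

    ``mask`` is a label image (0 = background); each nonzero label yields one
    :class:`RoiTrace` with ``green[t]`` the mean pixel intensity over the
    label in frame ``t`` and ``area_um2 = pixel count × pixel_size_um²``.
    When ``red_frame`` is given, ``red_mean`` is the ROI mean on it.
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask)
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if stack.shape[1:] != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {stack.shape[1:]}"
        )
    labels = [int(v) for v in np.unique(mask) if v != 0]
    time_s = np.arange(stack.shape[0]) / frame_rate_hz
    traces: list[RoiTrace] = []
    for label in labels:
        sel = mask == label
        n_px = int(sel.sum())
        if n_px == 0:
            warnings.warn(f"ROI label {label} has no pixels; skipped")
            continue
        green = stack[:, sel].mean(axis=1)
        red = float(red_frame[sel].mean()) if red_frame is not None else float("nan")
        traces.append(
            RoiTrace(
                cell_id=f"cell{label:04d}",
                area_um2=n_px * pixel_size_um**2,
                green=green,
                time_s=time_s,
                red_mean=red,
            )
        )
    return traces


def measure_background_red(
    red_frame: np.ndarray, background_mask: np.ndarray
) -> BackgroundRedStats:
    """Background red-fluorescence statistics from labelled background ROIs.

    The mean and SD are taken across the per-ROI mean intensities (sample
    SD, n−1 denominator), not across pooled pixels.
    """
    red_frame = np.asarray(red_frame, dtype=float)
    background_mask = np.asarray(background_mask)
    labels = [int(v) for v in np.unique(background_mask) if v != 0]
    if len(labels) < 2:
        raise ValueError(f"need >= 2 background ROIs, got {len(labels)}")
    means = np.array([red_frame[background_mask == lab].mean() for lab in labels])
    return BackgroundRedStats(
        mean=float(means.mean()), sd=float(means.std(ddof=1)), n_rois=len(labels)
    )
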