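"""Analysis configuration: every numeric constant of the pipeline in one place.

The defaults encode the published analysis: acquisition at 1.55 Hz, a four
time-point moving average, a 10 s pre-stimulus baseline, a 30 s response
window, a derivative z-score cutoff of 5, a minimum ΔF/F₀ of 0.25, 80 µm²
area-histogram bins, a mean + 3 SD silent-cell cutoff, and a z > 5 rule for
tdTomato positivity against five background ROIs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Numeric constants of the responder-detection and classification pipeline.

    Attributes
    ----------
    frame_rate_hz:
        Acquisition frequency in frames per second.
    smooth_points:
        Width of the trailing moving average applied to each trace, in frames.
    baseline_s:
        Duration of the pre-stimulus baseline window, seconds.
    response_window_s:
        Duration of the post-stimulus search window, seconds.
    z_threshold:
        Minimum derivative z-score for a responder call.
    dff_min:
        Minimum ΔF/F₀; responses below this are discarded.
    bin_width_um2:
        Histogram bin width for soma-area Gaussian fits, µm².
    sd_multiplier:
        Silent-classification cutoff is fit mean + sd_multiplier × fit SD.
    red_z_threshold:
        tdTomato positivity requires red z-score strictly above this.
    n_background_rois:
        Number of background ROIs used for red-channel statistics.
    ci_level:
        Confidence level for Wilson proportion intervals.
    qc_corr_min:
        Minimum frame-to-reference Pearson correlation before a frame is
        flagged by the Z-movement QC.
    qc_fail_frac:
        Stack fails QC when more than this fraction of frames is flagged.
    rng_seed:
        Seed for any randomness routed through the pipeline.
    """

    frame_rate_hz: float = 1.55
    smooth_points: int = 4
    baseline_s: float = 10.0
    response_window_s: float = 30.0
    z_threshold: float = 5.0
    dff_min: float = 0.25
    bin_width_um2: float = 80.0
    sd_multiplier: float = 3.0
    red_z_threshold: float = 5.0
    n_background_rois: int = 5
    ci_level: float = 0.95
    qc_corr_min: float = 0.6
    qc_fail_frac: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "frame_rate_hz",
            "baseline_s",
            "response_window_s",
            "z_threshold",
            "dff_min",
            "bin_width_um2",
            "sd_multiplier",
            "red_z_threshold",
        )
        for name in positive:
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value!r}")
        if self.smooth_points < 1:
            raise ValueError(f"smooth_points must be >= 1, got {self.smooth_points!r}")
        if self.n_background_rois < 2:
            raise ValueError(
                f"n_background_rois must be >= 2, got {self.n_background_rois!r}"
            )
        if not 0 < self.ci_level < 1:
            raise ValueError(f"ci_level must lie in (0, 1), got {self.ci_level!r}")
        if not 0 <= self.qc_fail_frac <= 1:
            raise ValueError(
                f"qc_fail_frac must lie in [0, 1], got {self.qc_fail_frac!r}"
            )
        if self.baseline_frames < 2 or self.response_frames < 2:
            raise ValueError(
                "baseline_s and response_window_s must each span >= 2 frames "
                f"at {self.frame_rate_hz} Hz"
            )

    # Windows are stated in seconds and converted to frames with floor();
    # at the defaults this gives 15 baseline and 46 response frames.
    @property
    def baseline_frames(self) -> int:
        return max(2, math.floor(self.baseline_s * self.frame_rate_hz))

    @property
    def response_frames(self) -> int:
        return max(2, math.floor(self.response_window_s * self.frame_rate_hz))

    @property
    def frame_interval_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    def replace(self, **changes) -> "AnalysisConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a flat YAML key-value file.

    Unspecified keys take the defaults; an empty file yields the full default
    configuration. Unknown keys and invariant violations raise ``ValueError``
    naming the offending key.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    return AnalysisConfig(**data)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    """Write a config as flat YAML; ``load_config`` round-trips it exactly."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
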