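"""Stimulus-locked responder calling on GCaMP traces.

A cell is called a responder to a stimulus when, within the response window
after stimulus onset, the derivative of its smoothed trace exceeds the
pre-stimulus baseline derivative by at least ``z_threshold`` standard
deviations AND the response amplitude ΔF/F₀ = (F_peak − F₀)/F₀ reaches
``dff_min``. The pipeline is: trailing moving average → first-difference
derivative → baseline z-scoring → amplitude gate.

Window conventions: the baseline covers [onset − baseline_s, onset) and the
response window (onset, onset + response_window_s], truncated at the next
stimulus onset; the onset frame itself belongs to neither. A derivative
sample is timestamped at the end of its frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .imaging import RoiTrace

__all__ = [
    "MODALITIES",
    "COLD_MODALITIES",
    "Stimulus",
    "ResponseCall",
    "smooth_trace",
    "derivative",
    "call_response",
    "threshold_temperature",
    "call_session",
    "modality_group",
]

MODALITIES = (
    "cold_ice_water",
    "cold_acetone",
    "cold_peltier",
    "heat_55C",
    "pinch",
    "brush",
    "von_frey_2g",
)

#: Stimulus modalities that count toward the pooled "cold" modality.
COLD_MODALITIES = frozenset({"cold_ice_water", "cold_acetone", "cold_peltier"})


def modality_group(modality: str) -> str:
    """Collapse cold sub-modalities into the pooled ``cold`` group."""
    return "cold" if modality in COLD_MODALITIES else modality


@dataclass(frozen=True)
class Stimulus:
    """One stimulus application to the hind paw.

    ``temperature_profile`` is an optional (time_s, °C) array for
    Peltier-controlled ramps; times are absolute (same clock as the traces).
    """

    stimulus_id: str
    modality: str
    onset_s: float
    duration_s: float = 5.0
    temperature_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )


@dataclass
class ResponseCall:
    """The verdict of the responder algorithm for one (cell, stimulus) pair."""

    cell_id: str
    stimulus_id: str
    z_max: float
    dff: float
    is_responder: bool
    discard_reason: str | None = None  # None | below_z | below_dff | qc
    onset_s: float | None = None
    threshold_temp_C: float | None = None
    flags: list[str] = field(default_factory=list)


def smooth_trace(green: np.ndarray, smooth_points: int) -> np.ndarray:
    """Trailing (causal) moving average of width ``smooth_points``.

    The first ``smooth_points − 1`` samples average over the available
    prefix, so output length equals input length and no post-stimulus
    sample leaks into the pre-stimulus baseline.
    """
    green = np.asarray(green, dtype=float)
    if smooth_points < 1:
        raise ValueError("smooth_points must be >= 1")
    if green.size < smooth_points:
        raise ValueError(
            f"trace length {green.size} shorter than smooth_points {smooth_points}"
        )
    if smooth_points == 1:
        return green.copy()
    csum = np.concatenate([[0.0], np.cumsum(green)])
    out = np.empty_like(green)
    n = green.size
    widths = np.minimum(np.arange(1, n + 1), smooth_points)
    starts = np.arange(1, n + 1) - widths
    out = (csum[np.arange(1, n + 1)] - csum[starts]) / widths
    return out


def derivative(smoothed: np.ndarray, time_s: np.ndarray) -> np.ndarray:
    """First difference divided by the frame interval (intensity per second).

    Output index ``i`` is the slope over the interval ending at frame
    ``i + 1``; length is ``len(smoothed) − 1``.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    if smoothed.size != time_s.size or smoothed.size < 2:
        raise ValueError("need equal-length series with >= 2 samples")
    dt = np.diff(time_s)
    if not (dt > 0).all():
        raise ValueError("time_s must be strictly increasing")
    return np.diff(smoothed) / dt


def call_response(
    trace: RoiTrace,
    stim: Stimulus,
    config: AnalysisConfig,
    next_onset_s: float | None = None,
) -> ResponseCall:
    """Apply the derivative z-score and ΔF/F₀ gates to one (cell, stimulus).

    Baseline statistics (mean, sample SD) are computed on derivative samples
    in [onset − baseline_s, onset); the z-score is evaluated on derivative
    samples in (onset, onset + response_window_s], truncated at
    ``next_onset_s`` when that is nearer. F₀ is the mean of the *raw* trace
    over the baseline frames; F_peak the max of the *smoothed* trace in the
    response window.

    A zero baseline SD (noise-free input) is handled by a strict-exceedance
    rule plus a ``degenerate_baseline`` flag rather than an error.
    """
    t = trace.time_s
    onset = stim.onset_s
    if t[0] > onset - config.baseline_s:
        raise ValueError(
            f"trace starts at {t[0]:.2f}s; needs {config.baseline_s}s of "
            f"pre-stimulus data before onset {onset:.2f}s"
        )
    window_end = onset + config.response_window_s
    if next_onset_s is not None:
        window_end = min(window_end, next_onset_s)

    smoothed = smooth_trace(trace.green, config.smooth_points)
    deriv = derivative(smoothed, t)
    t_deriv = t[1:]  # derivative sample timestamped at interval end

    base_d = deriv[(t_deriv >= onset - config.baseline_s) & (t_deriv < onset)]
    resp_d = deriv[(t_deriv > onset) & (t_deriv <= window_end)]
    base_raw = trace.green[(t >= onset - config.baseline_s) & (t < onset)]
    resp_sm = smoothed[(t > onset) & (t <= window_end)]
    if base_d.size < 2 or resp_d.size < 1 or base_raw.size < 1:
        raise ValueError(
            f"insufficient data around stimulus {stim.stimulus_id} at {onset}s"
        )

    flags: list[str] = []
    if window_end < onset + config.response_window_s:
        flags.append("truncated_window")

    mu, sd = float(base_d.mean()), float(base_d.std(ddof=1))
    if sd == 0:
        flags.append("degenerate_baseline")
        z = np.where(resp_d > mu, np.inf, np.where(resp_d < mu, -np.inf, 0.0))
        z_gate_idx = np.nonzero(resp_d > mu)[0]
    else:
        z = (resp_d - mu) / sd
        z_gate_idx = np.nonzero(z >= config.z_threshold)[0]
    z_max = float(np.max(z))

    f0 = float(base_raw.mean())
    f_peak = float(resp_sm.max())
    dff = (f_peak - f0) / f0

    z_ok = z_gate_idx.size > 0
    dff_ok = dff >= config.dff_min
    is_responder = z_ok and dff_ok
    if is_responder:
        reason = None
    elif not z_ok:
        reason = "below_z"
    else:
        reason = "below_dff"

    onset_time: float | None = None
    temp_c: float | None = None
    if is_responder:
        # response onset = start of the first supra-threshold derivative
        # interval (the rise began somewhere inside it)
        resp_sel = np.nonzero((t_deriv > onset) & (t_deriv <= window_end))[0]
        onset_time = float(t[resp_sel[z_gate_idx[0]]])
        if stim.temperature_profile is not None:
            temp_c, _ = threshold_temperature_at(onset_time, stim)

    return ResponseCall(
        cell_id=trace.cell_id,
        stimulus_id=stim.stimulus_id,
        z_max=z_max,
        dff=dff,
        is_responder=is_responder,
        discard_reason=reason,
        onset_s=onset_time,
        threshold_temp_C=temp_c,
        flags=flags,
    )


def threshold_temperature_at(onset_s: float, stim: Stimulus) -> tuple[float, float]:
    """Stimulus temperature at ``onset_s`` and the drop from the ramp start."""
    profile = stim.temperature_profile
    if profile is None:
        raise ValueError("stimulus has no temperature profile")
    profile = np.asarray(profile, dtype=float)
    times, temps = profile[:, 0], profile[:, 1]
    if not times[0] <= onset_s <= times[-1]:
        raise ValueError(
            f"onset {onset_s}s outside temperature profile span "
            f"[{times[0]}, {times[-1]}]s"
        )
    temp = float(np.interp(onset_s, times, temps))
    return temp, float(temps[0] - temp)


def threshold_temperature(call: ResponseCall, stim: Stimulus) -> tuple[float, float]:
    """Thermal activation threshold (°C) of a responder and its drop from start."""
    if not call.is_responder or call.onset_s is None:
        raise ValueError("threshold temperature is defined only for responders")
    return threshold_temperature_at(call.onset_s, stim)


def call_session(
    traces: list[RoiTrace],
    stimuli: list[Stimulus],
    config: AnalysisConfig,
) -> tuple[list[ResponseCall], dict[str, set[str]]]:
    """Run the responder algorithm over every (cell, stimulus) pair.

    Returns all calls plus, per cell, the set of responded modality groups
    (cold sub-modalities pooled into ``cold``). Cells with an empty set did
    not respond to any stimulus and are outside the responding population.
    """
    stimuli = sorted(stimuli, key=lambda s: s.onset_s)
    calls: list[ResponseCall] = []
    modalities: dict[str, set[str]] = {tr.cell_id: set() for tr in traces}
    for trace in traces:
        for i, stim in enumerate(stimuli):
            nxt = stimuli[i + 1].onset_s if i + 1 < len(stimuli) else None
            call = call_response(trace, stim, config, next_onset_s=nxt)
            calls.append(call)
            if call.is_responder:
                modalities[trace.cell_id].add(modality_group(stim.modality))
    return calls, modalities
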