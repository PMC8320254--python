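"""Synthetic DRG calcium-imaging datasets with known ground truth.

Emulates the population structure the analysis assumes: a small-soma basal
cold-sensing population (area ~ N(214.9, 77.29²) µm², truncated > 0), a
large-soma normally cold-insensitive "silent" population (~ N(820.1, 200²))
that acquires cold responses with probability ``unmask_prob`` in the
neuropathic condition, and a remainder responding only to other modalities.
Traces are a constant baseline plus Gaussian noise, with stimulus-locked
transients (linear rise, brief plateau, exponential decay) for every
stimulus the cell truly responds to. Transient kinetics are a modelling
choice — real GCaMP3 kinetics are not reproduced — and are configurable.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import AnalysisConfig
from .detection import COLD_MODALITIES, MODALITIES, Stimulus
from .imaging import RoiTrace

__all__ = [
    "PopulationSpec",
    "CellTruth",
    "SyntheticDataset",
    "generate_population",
    "synthesize_trace",
    "synthesize_stack",
    "simulate_dataset",
    "default_stimulus_battery",
    "peltier_ramp_stimulus",
    "write_dataset",
    "read_traces_csv",
    "read_stimuli_csv",
]

#: Default per-class probabilities of responding to each non-cold modality.
DEFAULT_MODALITY_PROBS: dict[str, dict[str, float]] = {
    "basal_cold": {"heat_55C": 0.10, "pinch": 0.16, "brush": 0.02, "von_frey_2g": 0.05},
    "silent": {"heat_55C": 0.05, "pinch": 0.35, "brush": 0.00, "von_frey_2g": 0.08},
    "other": {"heat_55C": 0.50, "pinch": 0.60, "brush": 0.40, "von_frey_2g": 0.30},
}

#: Default per-class probability of tdTomato positivity (Na_v_1.8-style marker).
DEFAULT_MARKER_PROBS: dict[str, float] = {
    "basal_cold": 0.14,
    "silent": 0.68,
    "other": 0.30,
}


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of the simulated sensory-neuron population.

    ``unmask_prob`` is the probability that a silent (large-soma) cell
    carries a true cold response; it is 0 in the control condition and is
    the dial that turns the simulation "neuropathic".
    """

    n_cells: int = 500
    frac_basal_cold: float = 0.20
    frac_silent: float = 0.24
    unmask_prob: float = 0.0
    area_basal_mean_um2: float = 214.9
    area_basal_sd_um2: float = 77.29
    area_silent_mean_um2: float = 820.1
    area_silent_sd_um2: float = 200.0
    modality_probs: dict = field(default_factory=lambda: DEFAULT_MODALITY_PROBS)
    marker_prob: dict = field(default_factory=lambda: DEFAULT_MARKER_PROBS)
    dff_amp_range: tuple[float, float] = (0.3, 3.0)
    noise_sd_frac: float = 0.02
    cold_submodality_prob: float = 0.8
    condition: str = "control"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("frac_basal_cold", "frac_silent", "unmask_prob",
                     "cold_submodality_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.frac_basal_cold + self.frac_silent > 1:
            raise ValueError("frac_basal_cold + frac_silent must be <= 1")
        for name in ("area_basal_mean_um2", "area_basal_sd_um2",
                     "area_silent_mean_um2", "area_silent_sd_um2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.dff_amp_range
        if not (0 <= lo <= hi):
            raise ValueError("dff_amp_range must satisfy 0 <= min <= max")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")
        for cls, probs in self.modality_probs.items():
            for mod, p in probs.items():
                if mod not in MODALITIES:
                    raise ValueError(f"modality_probs[{cls!r}]: unknown modality {mod!r}")
                if not 0 <= p <= 1:
                    raise ValueError(f"modality_probs[{cls!r}][{mod!r}] out of [0, 1]")
        for cls, p in self.marker_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"marker_prob[{cls!r}] out of [0, 1]")


@dataclass
class CellTruth:
    """Ground truth for one simulated cell."""

    cell_id: str
    cell_class: str            # basal_cold | silent | other
    area_um2: float
    responds: set[str]         # concrete stimulus modalities
    tdtomato: bool
    dff_true: dict[str, float]  # modality -> true ΔF/F0 amplitude
    cold_threshold_C: float | None = None

    @property
    def is_cold_true(self) -> bool:
        return bool(self.responds & COLD_MODALITIES)


@dataclass
class SyntheticDataset:
    """A complete simulated session: traces, stimuli, truth, config, seed."""

    traces: list[RoiTrace]
    stimuli: list[Stimulus]
    truth: list[CellTruth]
    config: AnalysisConfig
    spec: PopulationSpec
    seed: int

    def truth_by_id(self) -> dict[str, CellTruth]:
        return {c.cell_id: c for c in self.truth}


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Normal draws with values <= 0 rejected and redrawn."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def generate_population(spec: PopulationSpec, seed: int) -> list[CellTruth]:
    """Draw a labelled cell population from a :class:`PopulationSpec`.

    Classes are assigned by the stated fractions (deterministic counts,
    rounded), soma areas from the class Gaussian truncated at > 0, cold
    responses to all basal-cold cells and to silent cells with probability
    ``unmask_prob``, other modalities and the tdTomato marker from the
    per-class probability tables. Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_cells
    n_basal = round(n * spec.frac_basal_cold)
    n_silent = round(n * spec.frac_silent)
    classes = (["basal_cold"] * n_basal + ["silent"] * n_silent
               + ["other"] * (n - n_basal - n_silent))
    rng.shuffle(classes)

    cells: list[CellTruth] = []
    for i, cls in enumerate(classes):
        if cls == "silent":
            area = float(_truncated_normal(
                rng, spec.area_silent_mean_um2, spec.area_silent_sd_um2, 1)[0])
        else:
            area = float(_truncated_normal(
                rng, spec.area_basal_mean_um2, spec.area_basal_sd_um2, 1)[0])
        responds: set[str] = set()
        cold_true = (cls == "basal_cold") or (
            cls == "silent" and rng.random() < spec.unmask_prob)
        if cold_true:
            subs = [m for m in sorted(COLD_MODALITIES)
                    if rng.random() < spec.cold_submodality_prob]
            if not subs:
                subs = [sorted(COLD_MODALITIES)[rng.integers(len(COLD_MODALITIES))]]
            responds.update(subs)
        for mod, p in spec.modality_probs.get(cls, {}).items():
            if rng.random() < p:
                responds.add(mod)
        lo, hi = spec.dff_amp_range
        dff_true = {m: float(rng.uniform(lo, hi)) for m in sorted(responds)}
        marker = rng.random() < spec.marker_prob.get(cls, 0.0)
        cells.append(CellTruth(
            cell_id=f"cell{i + 1:04d}",
            cell_class=cls,
            area_um2=area,
            responds=responds,
            tdtomato=bool(marker),
            dff_true=dff_true,
            cold_threshold_C=float(rng.uniform(8, 28)) if cold_true else None,
        ))
    return cells


def default_stimulus_battery(first_onset_s: float = 15.0,
                             spacing_s: float = 45.0) -> list[Stimulus]:
    """The six-stimulus session used throughout: two cold stimuli, heat,
    pinch, brush and a 2 g von Frey hair, separated by ``spacing_s``."""
    order = ["cold_ice_water", "cold_acetone", "heat_55C", "pinch",
             "brush", "von_frey_2g"]
    return [
        Stimulus(stimulus_id=f"stim{i + 1}", modality=mod,
                 onset_s=first_onset_s + i * spacing_s, duration_s=5.0)
        for i, mod in enumerate(order)
    ]


def peltier_ramp_stimulus(onset_s: float, start_C: float = 32.0,
                          end_C: float = 2.0, ramp_s: float = 60.0,
                          stimulus_id: str = "peltier1") -> Stimulus:
    """A Peltier-thermode cooling ramp with a linear temperature profile."""
    times = np.linspace(onset_s, onset_s + ramp_s, 121)
    temps = np.linspace(start_C, end_C, 121)
    return Stimulus(stimulus_id=stimulus_id, modality="cold_peltier",
                    onset_s=onset_s, duration_s=ramp_s,
                    temperature_profile=np.column_stack([times, temps]))


def _transient(t: np.ndarray, t_start: float, amp: float, rise_s: float,
               plateau_s: float, decay_tau_s: float) -> np.ndarray:
    """Unit-baseline transient: linear rise, plateau, exponential decay."""
    out = np.zeros_like(t)
    rel = t - t_start
    rising = (rel >= 0) & (rel < rise_s)
    out[rising] = amp * rel[rising] / rise_s
    top = (rel >= rise_s) & (rel < rise_s + plateau_s)
    out[top] = amp
    tail = rel >= rise_s + plateau_s
    out[tail] = amp * np.exp(-(rel[tail] - rise_s - plateau_s) / decay_tau_s)
    return out


def synthesize_trace(
    cell: CellTruth,
    stimuli: list[Stimulus],
    config: AnalysisConfig,
    seed: int,
    f0: float = 100.0,
    noise_sd_frac: float = 0.02,
    rise_s: float = 1.0,
    plateau_s: float = 3.0,
    decay_tau_s: float = 5.0,
    onset_delay_range: tuple[float, float] = (0.0, 2.0),
    long_decay: bool = False,
    n_frames: int | None = None,
) -> RoiTrace:
    """Simulate one cell's green-channel trace for a stimulus session.

    For every stimulus whose modality the cell truly responds to, a transient
    of peak amplitude ``dff_true × f0`` starts 0–2 s after onset (or, on a
    Peltier ramp for a cell with a ``cold_threshold_C``, when the ramp
    crosses that threshold). ``long_decay=True`` switches the decay constant
    to 30 s, emulating the prolonged acetone-type responses.
    """
    stims = sorted(stimuli, key=lambda s: s.onset_s)
    for a, b in zip(stims, stims[1:]):
        if b.onset_s - a.onset_s < 30.0:
            raise ValueError(
                f"stimuli {a.stimulus_id} and {b.stimulus_id} are separated by "
                f"{b.onset_s - a.onset_s:.1f}s; need >= 30 s"
            )
    rng = np.random.default_rng(seed)
    if n_frames is None:
        t_end = stims[-1].onset_s + config.response_window_s + 10.0
        n_frames = int(np.ceil(t_end * config.frame_rate_hz)) + 1
    t = np.arange(n_frames) / config.frame_rate_hz

    tau = 30.0 if long_decay else decay_tau_s
    signal = np.zeros_like(t)
    for stim in stims:
        if stim.modality not in cell.responds:
            continue
        amp = cell.dff_true[stim.modality] * f0
        t_start = None
        if stim.temperature_profile is not None and cell.cold_threshold_C is not None:
            prof = np.asarray(stim.temperature_profile, dtype=float)
            below = prof[:, 1] <= cell.cold_threshold_C
            if below.any():
                t_start = float(prof[np.argmax(below), 0])
        if t_start is None:
            t_start = stim.onset_s + rng.uniform(*onset_delay_range)
        signal += _transient(t, t_start, amp, rise_s, plateau_s, tau)

    noise = rng.normal(0.0, noise_sd_frac * f0, t.size) if noise_sd_frac > 0 else 0.0
    green = f0 + signal + noise
    return RoiTrace(cell_id=cell.cell_id, area_um2=cell.area_um2,
                    green=green, time_s=t, red_mean=float("nan"))


# red-channel generation: positives sit 20 background SDs above the mean so
# the z > 5 call recovers truth with margin; negatives scatter ~1 SD
RED_BG_MEAN = 50.0
RED_BG_SD = 2.0
RED_POS_Z = 20.0


def _red_intensity(cell: CellTruth, rng: np.random.Generator) -> float:
    if cell.tdtomato:
        return RED_BG_MEAN + RED_POS_Z * RED_BG_SD + rng.normal(0, RED_BG_SD)
    return RED_BG_MEAN + rng.normal(0, RED_BG_SD)


def simulate_dataset(
    spec: PopulationSpec,
    config: AnalysisConfig,
    seed: int,
    stimuli: list[Stimulus] | None = None,
    **trace_kwargs,
) -> SyntheticDataset:
    """Generate a full labelled session: population, traces, red channel.

    Per-cell seeds are derived from ``seed`` so the dataset is reproducible
    as a whole while cells remain independent.
    """
    if stimuli is None:
        stimuli = default_stimulus_battery()
    truth = generate_population(spec, seed)
    root = np.random.default_rng(seed)
    red_rng = np.random.default_rng(root.integers(2**31))
    cell_seeds = root.integers(2**31, size=len(truth))
    trace_kwargs.setdefault("noise_sd_frac", spec.noise_sd_frac)
    traces = []
    for cell, cs in zip(truth, cell_seeds):
        tr = synthesize_trace(cell, stimuli, config, int(cs), **trace_kwargs)
        tr.red_mean = _red_intensity(cell, red_rng)
        traces.append(tr)
    return SyntheticDataset(traces=traces, stimuli=stimuli, truth=truth,
                            config=config, spec=spec, seed=seed)


def synthesize_stack(
    dataset: SyntheticDataset,
    drift: np.ndarray,
    seed: int,
    pixel_size_um: float = 1.0,
    noise_scale: float = 0.0,
    field_px: int | None = None,
    n_background_rois: int = 5,
    max_tries: int = 2000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Render a dataset as a two-channel image stack plus label masks.

    Cells become filled discs whose pixel count matches their area at
    ``pixel_size_um``; the green channel inside a disc equals the cell's
    trace value frame by frame, the red channel is constant per cell. Every
    frame is then rolled by the integer ``drift`` vector for that frame and
    optionally corrupted with shot-like (intensity-scaled) Gaussian noise.

    Returns ``(green_stack, red_frame, roi_mask, background_mask)``.
    """
    n_frames = dataset.traces[0].time_s.size
    drift = np.asarray(drift)
    if drift.shape != (n_frames, 2):
        raise ValueError(f"drift must have shape ({n_frames}, 2)")
    rng = np.random.default_rng(seed)
    n_cells = len(dataset.traces)
    if field_px is None:
        # generous packing so random placement terminates
        area_px = sum(tr.area_um2 for tr in dataset.traces) / pixel_size_um**2
        field_px = max(64, int(np.sqrt(area_px * 8)))

    mask = np.zeros((field_px, field_px), dtype=np.uint16)
    yy, xx = np.mgrid[0:field_px, 0:field_px]
    for label, tr in enumerate(dataset.traces, start=1):
        r = max(1.0, np.sqrt(tr.area_um2 / np.pi) / pixel_size_um)
        placed = False
        for _ in range(max_tries):
            cy = rng.integers(int(r) + 2, field_px - int(r) - 2)
            cx = rng.integers(int(r) + 2, field_px - int(r) - 2)
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            if not mask[disc].any():
                mask[disc] = label
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {tr.cell_id} without overlap after "
                f"{max_tries} tries; increase field_px"
            )

    bg_mask = np.zeros_like(mask)
    free = mask == 0
    for b in range(1, n_background_rois + 1):
        for _ in range(max_tries):
            cy = rng.integers(4, field_px - 4)
            cx = rng.integers(4, field_px - 4)
            patch = (slice(cy - 2, cy + 2), slice(cx - 2, cx + 2))
            if free[patch].all() and not bg_mask[patch].any():
                bg_mask[patch] = b
                break
        else:
            raise RuntimeError("could not place background ROIs")

    green = np.zeros((n_frames, field_px, field_px), dtype=float)
    red = RED_BG_MEAN + rng.normal(0, RED_BG_SD, (field_px, field_px))
    for label, tr in enumerate(dataset.traces, start=1):
        sel = mask == label
        green[:, sel] = tr.green[:, None]
        red[sel] = tr.red_mean

    for i in range(n_frames):
        dy, dx = int(drift[i, 0]), int(drift[i, 1])
        frame = np.roll(green[i], (dy, dx), axis=(0, 1))
        if noise_scale > 0:
            frame = frame + rng.normal(0, noise_scale * np.sqrt(np.abs(frame) + 1))
        green[i] = frame
    return green, red, mask, bg_mask


# ---------------------------------------------------------------------------
# plain-text writers/readers shared with the imaging pipeline

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write traces, per-cell metadata, stimulus log and truth to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": outdir / "traces.csv",
        "cells": outdir / "cells_meta.csv",
        "stimuli": outdir / "stimuli.csv",
        "truth": outdir / "truth.json",
    }
    df = pd.DataFrame({"time_s": dataset.traces[0].time_s})
    for tr in dataset.traces:
        df[tr.cell_id] = tr.green
    df.to_csv(paths["traces"], index=False)

    pd.DataFrame(
        [{"cell_id": tr.cell_id, "area_um2": tr.area_um2, "red_mean": tr.red_mean}
         for tr in dataset.traces]
    ).to_csv(paths["cells"], index=False)

    rows = []
    for s in dataset.stimuli:
        row = {"stimulus_id": s.stimulus_id, "modality": s.modality,
               "onset_s": s.onset_s, "duration_s": s.duration_s,
               "temperature_profile": ""}
        if s.temperature_profile is not None:
            prof_path = outdir / f"profile_{s.stimulus_id}.csv"
            pd.DataFrame(s.temperature_profile,
                         columns=["time_s", "temp_C"]).to_csv(prof_path, index=False)
            row["temperature_profile"] = prof_path.name
        rows.append(row)
    pd.DataFrame(rows).to_csv(paths["stimuli"], index=False)

    truth_records = []
    for c in dataset.truth:
        rec = asdict(c)
        rec["responds"] = sorted(c.responds)
        truth_records.append(rec)
    paths["truth"].write_text(json.dumps(
        {"seed": dataset.seed, "condition": dataset.spec.condition,
         "cells": truth_records}, indent=1))
    return paths


def read_traces_csv(traces_path: str | Path,
                    cells_path: str | Path | None = None) -> list[RoiTrace]:
    """Read the traces CSV (plus optional per-cell metadata) back to traces."""
    df = pd.read_csv(traces_path)
    if df.columns[0] != "time_s":
        raise ValueError("first column of a traces CSV must be time_s")
    meta = {}
    if cells_path is not None:
        mdf = pd.read_csv(cells_path)
        meta = {r.cell_id: (r.area_um2, r.red_mean) for r in mdf.itertuples()}
    t = df["time_s"].to_numpy()
    traces = []
    for col in df.columns[1:]:
        area, red = meta.get(col, (1.0, float("nan")))
        traces.append(RoiTrace(cell_id=col, area_um2=float(area),
                               green=df[col].to_numpy(), time_s=t,
                               red_mean=float(red)))
    return traces


def read_stimuli_csv(path: str | Path) -> list[Stimulus]:
    """Read a stimulus log written by :func:`write_dataset`."""
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    stimuli = []
    for r in df.itertuples():
        profile = None
        if r.temperature_profile:
            pdf = pd.read_csv(path.parent / r.temperature_profile)
            profile = pdf[["time_s", "temp_C"]].to_numpy()
        stimuli.append(Stimulus(
            stimulus_id=str(r.stimulus_id), modality=str(r.modality),
            onset_s=float(r.onset_s), duration_s=float(r.duration_s),
            temperature_profile=profile))
    return stimuli


def write_stack_tiffs(green: np.ndarray, red: np.ndarray, mask: np.ndarray,
                      bg_mask: np.ndarray, outdir: str | Path) -> dict[str, Path]:
    """Write the rendered stack and masks as TIFFs (green as multi-page)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "green": outdir / "green_stack.tif",
        "red": outdir / "red_reference.tif",
        "mask": outdir / "roi_mask.tif",
        "bg_mask": outdir / "background_mask.tif",
    }
    tifffile.imwrite(paths["green"], green.astype(np.float32))
    tifffile.imwrite(paths["red"], red.astype(np.float32))
    tifffile.imwrite(paths["mask"], mask.astype(np.uint16))
    tifffile.imwrite(paths["bg_mask"], bg_mask.astype(np.uint16))
    return paths
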