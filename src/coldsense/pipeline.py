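"""End-to-end runs: simulate or load a session, detect responders, classify
populations and write paper-style summary tables.

Outputs per run directory: ``calls.csv`` (one row per cell × stimulus),
``cells.csv`` (per-cell class/modalities/marker), ``fits.json`` (Gaussian
area fits), ``polymodality.csv``, ``recruitment.csv``, ``proportions.csv``
(key proportions with Wilson CIs) and ``manifest.json``. Every run is fully
determined by its seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig, load_config
from .detection import COLD_MODALITIES, Stimulus, call_session, threshold_temperature
from .imaging import BackgroundRedStats, RoiTrace
from .population import (
    CellRecord,
    GaussianFit,
    classify_cells,
    fit_area_gaussian,
    polymodality_table,
    recruitment_curve,
    tdtomato_positive,
)
from .stats import wilson_ci
from .synthetic import (
    PopulationSpec,
    SyntheticDataset,
    read_stimuli_csv,
    read_traces_csv,
    simulate_dataset,
)

__all__ = ["run_pipeline", "make_figures", "analyze_session", "SessionResult"]

log = logging.getLogger("coldsense")


class SessionResult:
    """In-memory results of one analysed session."""

    def __init__(self, calls, cells, control_fit, session_fit, stimuli):
        self.calls = calls
        self.cells: list[CellRecord] = cells
        self.control_fit: GaussianFit = control_fit
        self.session_fit: GaussianFit | None = session_fit
        self.stimuli: list[Stimulus] = stimuli

    @property
    def responding(self) -> list[CellRecord]:
        return [c for c in self.cells if c.modalities]

    def silent_fraction(self) -> tuple[int, int]:
        resp = self.responding
        k = sum(1 for c in resp if c.cell_class == "silent")
        return k, len(resp)


def analyze_session(
    traces: list[RoiTrace],
    stimuli: list[Stimulus],
    config: AnalysisConfig,
    control_fit: GaussianFit | None = None,
    background_red: BackgroundRedStats | None = None,
    condition: str = "",
) -> SessionResult:
    """Run responder detection and population classification on one session.

    When ``control_fit`` is None the Gaussian is fit to this session's own
    cold-responder areas (appropriate for a control/vehicle session); a
    neuropathic session must be classified against its matched control fit.
    """
    calls, modality_sets = call_session(traces, stimuli, config)
    cells = []
    for tr in traces:
        rec = CellRecord(cell_id=tr.cell_id, area_um2=tr.area_um2,
                         modalities=modality_sets[tr.cell_id],
                         condition=condition)
        if background_red is not None and np.isfinite(tr.red_mean):
            pos, z, _ = tdtomato_positive(tr.red_mean, background_red, config)
            rec.tdtomato = "positive" if pos else "negative"
            rec.red_z = z
        cells.append(rec)

    cold_areas = [c.area_um2 for c in cells if c.is_cold]
    session_fit = None
    if len(cold_areas) >= 20:
        try:
            session_fit = fit_area_gaussian(cold_areas, config)
        except (ValueError, RuntimeError) as exc:
            log.warning("session area fit failed: %s", exc)
    if session_fit is None and len(cold_areas) >= 2:
        # too few cold responders for a histogram fit: fall back to sample
        # moments so small sessions remain classifiable
        log.warning("using moment-based area fit (%d cold responders)",
                    len(cold_areas))
        session_fit = GaussianFit.from_params(
            float(np.mean(cold_areas)), float(np.std(cold_areas, ddof=1)),
            sd_multiplier=config.sd_multiplier,
            n_cells=len(cold_areas), bin_width_um2=config.bin_width_um2)
    if control_fit is None:
        if session_fit is None:
            raise ValueError(
                "no control fit supplied and the session's own cold-responder "
                "areas could not be fit")
        control_fit = session_fit

    cells = classify_cells(cells, control_fit)

    # per-cell thermal threshold drops from any Peltier ramp stimuli
    ramp_stims = {s.stimulus_id: s for s in stimuli
                  if s.temperature_profile is not None}
    if ramp_stims:
        drops: dict[str, float] = {}
        for call in calls:
            if call.is_responder and call.stimulus_id in ramp_stims:
                _, drop = threshold_temperature(call, ramp_stims[call.stimulus_id])
                drops.setdefault(call.cell_id, drop)
        for cell in cells:
            cell.threshold_drop_C = drops.get(cell.cell_id)

    return SessionResult(calls, cells, control_fit, session_fit, stimuli)


def _calls_frame(calls) -> pd.DataFrame:
    return pd.DataFrame.from_records([
        {"cell_id": c.cell_id, "stimulus_id": c.stimulus_id,
         "z_max": c.z_max, "dff": c.dff, "is_responder": c.is_responder,
         "discard_reason": c.discard_reason or "",
         "onset_s": "" if c.onset_s is None else c.onset_s,
         "threshold_temp_C": "" if c.threshold_temp_C is None else c.threshold_temp_C,
         "flags": ";".join(c.flags)}
        for c in calls])


def _cells_frame(cells) -> pd.DataFrame:
    return pd.DataFrame.from_records([
        {"cell_id": c.cell_id, "area_um2": c.area_um2,
         "modalities": ";".join(sorted(c.modalities)),
         "cell_class": c.cell_class, "tdtomato": c.tdtomato,
         "condition": c.condition,
         "threshold_drop_C": "" if c.threshold_drop_C is None
         else c.threshold_drop_C}
        for c in cells])


def run_pipeline(
    config: AnalysisConfig | str | Path,
    outdir: str | Path,
    seed: int = 0,
    synthetic_spec: PopulationSpec | None = None,
    traces_path: str | Path | None = None,
    cells_meta_path: str | Path | None = None,
    stimuli_path: str | Path | None = None,
    control_fit: GaussianFit | None = None,
    condition: str | None = None,
    plots: bool = False,
) -> Path:
    """Config-driven end-to-end run; returns the output directory.

    Input is either a :class:`PopulationSpec` (synthetic session) or paths
    to a traces CSV (+ optional per-cell metadata CSV) and a stimulus log.
    For a synthetic neuropathic session without an explicit ``control_fit``,
    a matched control session (``unmask_prob = 0``, derived seed) is
    simulated and fit, mirroring the vehicle group of the experiment.
    """
    t0 = time.time()
    if not isinstance(config, AnalysisConfig):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    dataset: SyntheticDataset | None = None
    if synthetic_spec is not None:
        condition = condition or synthetic_spec.condition
        dataset = simulate_dataset(synthetic_spec, config, seed)
        traces, stimuli = dataset.traces, dataset.stimuli
        from .synthetic import RED_BG_MEAN, RED_BG_SD
        bg = BackgroundRedStats(mean=RED_BG_MEAN, sd=RED_BG_SD,
                                n_rois=config.n_background_rois)
        if control_fit is None and synthetic_spec.unmask_prob > 0:
            log.info("simulating matched control session for the area fit")
            control_spec = PopulationSpec(**{
                **asdict_spec(synthetic_spec), "unmask_prob": 0.0,
                "condition": "control"})
            control_res = analyze_session(
                simulate_dataset(control_spec, config, seed + 1).traces,
                stimuli, config, condition="control")
            control_fit = control_res.control_fit
    elif traces_path is not None and stimuli_path is not None:
        traces = read_traces_csv(traces_path, cells_meta_path)
        stimuli = read_stimuli_csv(stimuli_path)
        bg = None
        condition = condition or ""
    else:
        raise ValueError(
            "provide either synthetic_spec or traces_path + stimuli_path")

    result = analyze_session(traces, stimuli, config, control_fit=control_fit,
                             background_red=bg, condition=condition)

    _calls_frame(result.calls).to_csv(outdir / "calls.csv", index=False)
    _cells_frame(result.cells).to_csv(outdir / "cells.csv", index=False)

    fits = {"control_fit": asdict(result.control_fit)}
    if result.session_fit is not None:
        fits["session_fit"] = asdict(result.session_fit)
    (outdir / "fits.json").write_text(json.dumps(fits, indent=1))

    submods = {}
    for sub in sorted(COLD_MODALITIES):
        ids = {c.cell_id for c in result.calls
               if c.is_responder and any(
                   s.stimulus_id == c.stimulus_id and s.modality == sub
                   for s in stimuli)}
        if ids:
            submods[sub] = ids
    poly = polymodality_table(result.cells, cold_submodalities=submods,
                              ci_level=config.ci_level, by_class=True)
    poly.to_csv(outdir / "polymodality.csv", index=False)

    drops = [c.threshold_drop_C for c in result.cells
             if c.threshold_drop_C is not None]
    if len(drops) >= 2:
        x, y, line = recruitment_curve(drops, fit=True)
        rec = pd.DataFrame({"drop_C": x, "percent_recruited_above": y})
        rec.to_csv(outdir / "recruitment.csv", index=False)
        fits["recruitment_line"] = line._asdict()
        (outdir / "fits.json").write_text(json.dumps(fits, indent=1))
    else:
        pd.DataFrame(columns=["drop_C", "percent_recruited_above"]).to_csv(
            outdir / "recruitment.csv", index=False)

    k, n = result.silent_fraction()
    rows = []
    if n > 0:
        ci = wilson_ci(k, n, config.ci_level)
        rows.append({"quantity": "silent_fraction_of_responders", "k": k,
                     "n": n, "proportion": k / n, "ci_low": ci.ci_low,
                     "ci_high": ci.ci_high})
    n_cold = sum(1 for c in result.cells if c.is_cold)
    if len(result.responding) > 0:
        ci = wilson_ci(n_cold, len(result.responding), config.ci_level)
        rows.append({"quantity": "cold_fraction_of_responders", "k": n_cold,
                     "n": len(result.responding), "proportion":
                     n_cold / len(result.responding), "ci_low": ci.ci_low,
                     "ci_high": ci.ci_high})
    pd.DataFrame(rows).to_csv(outdir / "proportions.csv", index=False)

    qc_flags = sorted({f for c in result.calls for f in c.flags})
    manifest = {
        "seed": seed,
        "condition": condition,
        "config": config.to_dict(),
        "synthetic_spec": asdict_spec(synthetic_spec) if synthetic_spec else None,
        "inputs": {"traces": str(traces_path) if traces_path else None,
                   "stimuli": str(stimuli_path) if stimuli_path else None},
        "counts": {"cells": len(result.cells),
                   "stimuli": len(stimuli),
                   "calls": len(result.calls),
                   "responding": len(result.responding),
                   "cold_responders": n_cold,
                   "silent": k},
        "qc_flags": qc_flags,
        "outputs": ["calls.csv", "cells.csv", "fits.json", "polymodality.csv",
                    "recruitment.csv", "proportions.csv", "manifest.json"],
        "runtime_s": round(time.time() - t0, 3),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    if plots:
        make_figures(outdir)

    # ground truth alongside, for benchmarking synthetic runs
    if dataset is not None:
        truth = pd.DataFrame.from_records([
            {"cell_id": c.cell_id, "cell_class": c.cell_class,
             "area_um2": c.area_um2, "cold_true": c.is_cold_true,
             "tdtomato": c.tdtomato, "responds": ";".join(sorted(c.responds))}
            for c in dataset.truth])
        truth.to_csv(outdir / "truth.csv", index=False)

    log.info("pipeline finished in %.2fs -> %s", time.time() - t0, outdir)
    return outdir


def asdict_spec(spec: PopulationSpec) -> dict:
    d = asdict(spec)
    d["dff_amp_range"] = list(spec.dff_amp_range)
    return d


def make_figures(outdir: str | Path) -> list[Path]:
    """Plot the area histogram with its Gaussian fit and cutoff, the
    recruitment curve, and a responder heat map, from a run directory."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    cells = pd.read_csv(outdir / "cells.csv")
    calls = pd.read_csv(outdir / "calls.csv")
    fits = json.loads((outdir / "fits.json").read_text())
    made: list[Path] = []

    fit = fits["control_fit"]
    cold = cells[cells["modalities"].fillna("").str.contains("cold")]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if len(cold):
        w = fit["bin_width_um2"]
        edges = np.arange(0, cold["area_um2"].max() + w, w)
        ax.hist(cold["area_um2"], bins=edges, color="#7f9fc4",
                edgecolor="white", label="cold responders")
        xs = np.linspace(0, edges[-1], 300)
        if np.isfinite(fit["amplitude"]):
            ax.plot(xs, fit["amplitude"] * np.exp(
                -((xs - fit["mean_um2"]) ** 2) / (2 * fit["sd_um2"] ** 2)),
                "k-", label="control Gaussian")
        ax.axvline(fit["cutoff_um2"], ls="--", color="crimson",
                   label=f"mean + {fit['sd_multiplier']:.0f} SD")
        ax.legend(fontsize=8)
    else:
        ax.text(0.5, 0.5, "no cold responders", ha="center", va="center",
                transform=ax.transAxes)
    ax.set_xlabel("soma area (µm²)")
    ax.set_ylabel("cells")
    fig.tight_layout()
    p = outdir / "area_histogram.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    made.append(p)

    rec = pd.read_csv(outdir / "recruitment.csv")
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    if len(rec):
        ax.plot(rec["drop_C"], rec["percent_recruited_above"], "o-", ms=3)
        line = fits.get("recruitment_line")
        if line:
            xs = rec["drop_C"].to_numpy(dtype=float)
            ax.plot(xs, line["slope"] * xs + line["intercept"], "k--",
                    label=f"y = {line['slope']:.2f}x + {line['intercept']:.1f}")
            ax.legend(fontsize=8)
    else:
        ax.text(0.5, 0.5, "no thermal thresholds", ha="center", va="center",
                transform=ax.transAxes)
    ax.set_xlabel("temperature drop (°C)")
    ax.set_ylabel("% cells recruited above")
    fig.tight_layout()
    p = outdir / "recruitment.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    made.append(p)

    resp = calls[calls["is_responder"]]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if len(resp):
        pivot = calls.pivot_table(index="cell_id", columns="stimulus_id",
                                  values="z_max", aggfunc="first")
        order = resp.sort_values("onset_s")["cell_id"].unique()
        keep = [c for c in order if c in pivot.index]
        ax.imshow(np.clip(pivot.loc[keep].to_numpy(dtype=float), 0, 20),
                  aspect="auto", cmap="magma")
        ax.set_xlabel("stimulus")
        ax.set_ylabel("responding cells (ordered by onset)")
    else:
        ax.text(0.5, 0.5, "no responders", ha="center", va="center",
                transform=ax.transAxes)
    fig.tight_layout()
    p = outdir / "responder_heatmap.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    made.append(p)
    return made
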