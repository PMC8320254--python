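"""Basal/silent classification, marker scoring and population summaries.

The central rule: fit a least-squares Gaussian to the control-condition
histogram of cold-responder soma areas (bin width 80 µm², anchored at 0) and
classify any cold responder whose area lies strictly above mean + 3 SD of
that fit as a silent cold-sensing neuron. At the published control fit
(µ = 214.9 µm², σ = 77.29 µm²) the cutoff is 446.77 µm².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .config import AnalysisConfig
from .imaging import BackgroundRedStats
from .stats import wilson_ci, ols_line, LineFit

__all__ = [
    "GaussianFit",
    "CellRecord",
    "fit_area_gaussian",
    "classify_cells",
    "tdtomato_positive",
    "polymodality_table",
    "recruitment_curve",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero toward +inf.

    Reproduces how the published percentages are printed (e.g. 45/291 → 15%,
    27/81 → 33%); Python's built-in banker's rounding does not.
    """
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class GaussianFit:
    """Least-squares Gaussian on an area histogram and the derived cutoff."""

    amplitude: float
    mean_um2: float
    sd_um2: float
    cutoff_um2: float
    rss: float
    n_cells: int
    bin_width_um2: float
    sd_multiplier: float = 3.0

    @classmethod
    def from_params(cls, mean_um2: float, sd_um2: float,
                    sd_multiplier: float = 3.0, amplitude: float = float("nan"),
                    rss: float = float("nan"), n_cells: int = 0,
                    bin_width_um2: float = 80.0) -> "GaussianFit":
        """Build a fit object from (µ, σ) alone; cutoff = µ + multiplier·σ."""
        if sd_um2 <= 0:
            raise ValueError("sd_um2 must be positive")
        return cls(amplitude=amplitude, mean_um2=mean_um2, sd_um2=sd_um2,
                   cutoff_um2=mean_um2 + sd_multiplier * sd_um2, rss=rss,
                   n_cells=n_cells, bin_width_um2=bin_width_um2,
                   sd_multiplier=sd_multiplier)


@dataclass
class CellRecord:
    """Per-cell aggregate used by the classification and summary layers."""

    cell_id: str
    area_um2: float
    modalities: set[str] = field(default_factory=set)
    cell_class: str = "non_responder"   # basal | silent | non_responder
    tdtomato: str = "unknown"           # positive | negative | unknown
    condition: str = ""
    red_z: float = float("nan")
    threshold_drop_C: float | None = None

    @property
    def is_cold(self) -> bool:
        return "cold" in self.modalities


def _gauss(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2 * sigma**2))


def fit_area_gaussian(areas, config: AnalysisConfig,
                      min_cells: int = 20) -> GaussianFit:
    """Least-squares Gaussian fit to a soma-area histogram.

    The histogram uses ``config.bin_width_um2`` bins anchored at 0; the
    Gaussian ``a·exp(−(x−µ)²/2σ²)`` is fit to (bin centre, count) pairs by
    nonlinear least squares, initialised from the sample mean and SD. The
    silent-classification cutoff is µ + ``config.sd_multiplier``·σ.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size < min_cells:
        raise ValueError(f"need >= {min_cells} areas, got {areas.size}")
    if (areas <= 0).any():
        raise ValueError("all areas must be positive")
    w = config.bin_width_um2
    edges = np.arange(0, areas.max() + w, w)
    counts, edges = np.histogram(areas, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    if int((counts > 0).sum()) < 3:
        raise ValueError("histogram has fewer than 3 nonempty bins")

    p0 = (float(counts.max()), float(areas.mean()), float(areas.std(ddof=1)))
    try:
        popt, _ = scipy.optimize.curve_fit(
            _gauss, centers, counts, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"Gaussian fit did not converge (init a={p0[0]:.3g}, "
            f"mu={p0[1]:.3g}, sigma={p0[2]:.3g})") from exc
    a, mu, sigma = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    rss = float(np.sum((counts - _gauss(centers, a, mu, sigma)) ** 2))
    # Sheppard's correction: fitting bin counts at bin centres inflates the
    # width by ~w²/12 in variance (4-5% at w=80, sigma~77); undo it so the
    # estimator is unbiased for the underlying population SD
    if sigma**2 > w**2 / 12:
        sigma = float(np.sqrt(sigma**2 - w**2 / 12))
    return GaussianFit(
        amplitude=a, mean_um2=mu, sd_um2=sigma,
        cutoff_um2=mu + config.sd_multiplier * sigma, rss=rss,
        n_cells=int(areas.size), bin_width_um2=w,
        sd_multiplier=config.sd_multiplier)


def classify_cells(cells: list[CellRecord],
                   control_fit: GaussianFit) -> list[CellRecord]:
    """Split cold responders into basal and silent by the control cutoff.

    Cold-responding cells with area strictly above ``control_fit.cutoff_um2``
    become ``silent``; other cold responders ``basal``; cells without a cold
    response keep ``non_responder`` (for cold) regardless of size.
    """
    out = []
    for cell in cells:
        if cell.is_cold:
            cls = "silent" if cell.area_um2 > control_fit.cutoff_um2 else "basal"
        else:
            cls = "non_responder"
        out.append(replace_class(cell, cls))
    return out


def replace_class(cell: CellRecord, cls: str) -> CellRecord:
    new = CellRecord(**{**cell.__dict__})
    new.cell_class = cls
    return new


def tdtomato_positive(red_mean: float, bg: BackgroundRedStats,
                      config: AnalysisConfig) -> tuple[bool, float, bool]:
    """Call marker positivity by z-scoring red intensity against background.

    Returns ``(positive, z, degenerate)``; positivity requires z strictly
    above ``config.red_z_threshold``. A zero background SD falls back to a
    strict mean comparison with the degenerate flag set.
    """
    if bg.sd == 0:
        return red_mean > bg.mean, float("nan"), True
    z = (red_mean - bg.mean) / bg.sd
    return z > config.red_z_threshold, float(z), False


def polymodality_table(cells: list[CellRecord],
                       cold_submodalities: dict[str, set[str]] | None = None,
                       ci_level: float = 0.95,
                       by_class: bool = False) -> pd.DataFrame:
    """Cross-tabulate cold responders against second modalities.

    For each cold group (pooled ``cold`` plus any sub-modality sets passed
    in ``cold_submodalities``, mapping cold group name -> cell ids) and each
    second modality, reports k responders to both, n cold responders, the
    half-up-rounded percentage and the Wilson CI. Rows with n = 0 carry a
    NaN percentage.
    """
    second = ["heat_55C", "pinch", "brush", "von_frey_2g"]
    groups: dict[str, list[CellRecord]] = {
        "cold": [c for c in cells if c.is_cold]}
    if cold_submodalities:
        by_id = {c.cell_id: c for c in cells}
        for name, ids in cold_submodalities.items():
            groups[name] = [by_id[i] for i in sorted(ids) if i in by_id]

    def rows_for(name: str, members: list[CellRecord], klass: str | None):
        sel = [c for c in members if klass is None or c.cell_class == klass]
        n = len(sel)
        for mod in second:
            k = sum(1 for c in sel if mod in c.modalities)
            if n == 0:
                pct, lo, hi = float("nan"), float("nan"), float("nan")
            else:
                ci = wilson_ci(k, n, ci_level)
                pct, lo, hi = round_half_up(100 * k / n), ci.ci_low, ci.ci_high
            yield {"cold_group": name, "cell_class": klass or "all",
                   "second_modality": mod, "k": k, "n": n,
                   "percent": pct, "ci_low": lo, "ci_high": hi}

    records = []
    for name, members in groups.items():
        records.extend(rows_for(name, members, None))
        if by_class:
            for klass in ("basal", "silent"):
                records.extend(rows_for(name, members, klass))
    return pd.DataFrame.from_records(records)


def recruitment_curve(threshold_drops, fit: bool = True
                      ) -> tuple[np.ndarray, np.ndarray, LineFit | None]:
    """Survival curve of cells versus temperature drop, in percent.

    ``y(x)`` is the percentage of cells whose thermal-activation threshold
    drop exceeds ``x`` °C, evaluated at integer drops 0..⌈max⌉; it starts
    near 100 and falls as the ramp deepens. With ``fit=True`` an ordinary
    least-squares line (slope in %/°C) is attached.
    """
    drops = np.asarray(list(threshold_drops), dtype=float)
    if drops.size == 0:
        raise ValueError("need at least one threshold drop")
    x = np.arange(0, int(np.ceil(drops.max())) + 1, dtype=float)
    y = 100.0 * (drops[None, :] > x[:, None]).mean(axis=1)
    line = None
    if fit:
        if drops.size < 2:
            raise ValueError("need >= 2 thresholds to fit a line")
        line = ols_line(x, y)
    return x, y, line
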