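"""a-c plots and lesion pattern discrimination plots (LDP).

The a-c plot scatters ln(range) versus ln(sill) with one symbol per axis
per pattern: X red squares, Y green triangles, Z blue diamonds.  The LDP
collapses each pattern to its mean center, classes the symbol by standard
distance (anisotropy), and carries a secondary axis translating the sill
into total lesion load (mm³).  Follow-up mode connects one patient's exams
chronologically with arrows.

Every figure gets a sidecar CSV holding exactly the coordinates plotted, so
figures and tables cannot drift apart.  Rendering is deterministic: a fixed
SVG hash salt and stripped date metadata make repeated calls byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .masks import MNI_GRID, GridSpec
from .models import VariogramModelFit
from .summary import PatternSummary

#: Axis-limit defaults of the a-c plot / LDP; realistic normalized lesion
#: patterns fall within ln(a) in [0, 3] and ln(c) in [-12, -3].
DEFAULT_LN_A_LIMITS = (0.0, 3.0)
DEFAULT_LN_C_LIMITS = (-12.0, -3.0)

_AXIS_STYLE = {
    "X": {"marker": "s", "color": "red"},
    "Y": {"marker": "^", "color": "green"},
    "Z": {"marker": "D", "color": "blue"},
}
_SD_CLASS_MARKERS = ("o", "s", "^", "D", "*")


@dataclass(frozen=True)
class PlotConfig:
    ln_a_limits: tuple[float, float] = DEFAULT_LN_A_LIMITS
    ln_c_limits: tuple[float, float] = DEFAULT_LN_C_LIMITS
    axis_symbols: dict = field(default_factory=lambda: dict(_AXIS_STYLE))
    sd_class_symbols: tuple[str, ...] = _SD_CLASS_MARKERS
    show_nomogram: bool = True
    path_arrows: bool = True
    grid: GridSpec = MNI_GRID
    dpi: int = 150

    def __post_init__(self) -> None:
        for lo, hi in (self.ln_a_limits, self.ln_c_limits):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"axis limits must be finite with min < max, got ({lo}, {hi})")


def _new_figure(config: PlotConfig):
    plt.rcParams["svg.hashsalt"] = "lesionvario"
    fig, ax = plt.subplots(figsize=(6.4, 5.6), dpi=config.dpi)
    ax.set_xlim(*config.ln_a_limits)
    ax.set_ylim(*config.ln_c_limits)
    ax.set_xlabel("ln(a)  [range, mm]")
    ax.set_ylabel("ln(c)  [sill]")
    return fig, ax


def _save(fig, path: Path, config: PlotConfig) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
    plt.close(fig)
    return path


def _sidecar(path: Path, frame: pd.DataFrame) -> Path:
    sidecar = Path(path).with_suffix(".csv")
    frame.to_csv(sidecar, index=False)
    return sidecar


def _add_nomogram(ax, config: PlotConfig) -> None:
    n_vox, vol = config.grid.n_voxels, config.grid.voxel_volume_mm3

    def lnc_to_tll(lnc):
        return np.exp(lnc) * n_vox * vol

    def tll_to_lnc(tll):
        return np.log(np.maximum(np.asarray(tll, dtype=float), 1e-300) / (n_vox * vol))

    secax = ax.secondary_yaxis("right", functions=(lnc_to_tll, tll_to_lnc))
    secax.set_yscale("log")
    secax.set_ylabel("TLL (mm³)")


def ac_plot(
    fit_triples: Sequence[tuple[str, Sequence[VariogramModelFit]]],
    path: str | Path,
    config: PlotConfig = PlotConfig(),
    show_mean_centers: bool = False,
) -> Path:
    """Scatter ln(a) vs ln(c), one symbol per axis per pattern."""
    rows = []
    for pattern_id, fits in fit_triples:
        for f in fits:
            if f.converged:
                rows.append(
                    {"id": pattern_id, "axis": f.axis, "ln_a": f.ln_a, "ln_c": f.ln_c}
                )
    if not rows:
        raise ValueError("no converged fits to plot")
    frame = pd.DataFrame(rows)

    fig, ax = _new_figure(config)
    for axis, style in config.axis_symbols.items():
        sub = frame[frame["axis"] == axis]
        ax.scatter(sub["ln_a"], sub["ln_c"], s=28, alpha=0.8, label=axis, **style)
    if show_mean_centers:
        for axis, style in config.axis_symbols.items():
            sub = frame[frame["axis"] == axis]
            if len(sub):
                ax.scatter(
                    sub["ln_a"].mean(), sub["ln_c"].mean(),
                    s=220, marker=style["marker"], facecolors="none",
                    edgecolors=style["color"], linewidths=2,
                )
    ax.legend(title="direction", loc="lower right")
    ax.set_title("a-c plot")
    out = _save(fig, Path(path), config)
    _sidecar(out, frame)
    return out


def ldp_plot(
    summaries: Sequence[PatternSummary],
    path: str | Path,
    config: PlotConfig = PlotConfig(),
) -> Path:
    """Lesion pattern discrimination plot: mean centers classed by SD."""
    if not summaries:
        raise ValueError("no summaries to plot")
    frame = pd.DataFrame(
        {
            "id": [s.id for s in summaries],
            "mean_ln_a": [s.mean_ln_a for s in summaries],
            "mean_ln_c": [s.mean_ln_c for s in summaries],
            "sd": [s.sd for s in summaries],
            "sd_class": [s.sd_class if s.sd_class is not None else 1 for s in summaries],
        }
    )
    fig, ax = _new_figure(config)
    for cls in sorted(frame["sd_class"].unique()):
        sub = frame[frame["sd_class"] == cls]
        marker = config.sd_class_symbols[(int(cls) - 1) % len(config.sd_class_symbols)]
        ax.scatter(
            sub["mean_ln_a"], sub["mean_ln_c"],
            marker=marker, s=36, alpha=0.85, label=f"SD class {int(cls)}",
        )
    if config.show_nomogram:
        _add_nomogram(ax, config)
    ax.legend(loc="lower right", fontsize=8)
    ax.set_title("Lesion pattern discrimination plot")
    out = _save(fig, Path(path), config)
    _sidecar(out, frame)
    return out


def ldp_followup(
    series: Sequence[PatternSummary],
    path: str | Path,
    config: PlotConfig = PlotConfig(),
) -> Path:
    """LDP evolution path for one patient's chronologically ordered exams."""
    if len(series) < 2:
        raise ValueError("a follow-up path needs >= 2 exams")
    dates = [s.exam_date for s in series]
    if any(d is None for d in dates):
        raise ValueError("all exams in a follow-up series need dates")
    if any(d1 >= d2 for d1, d2 in zip(dates, dates[1:])):
        raise ValueError("exam dates must be strictly ascending")

    frame = pd.DataFrame(
        {
            "id": [s.id for s in series],
            "date": [d.isoformat() for d in dates],
            "mean_ln_a": [s.mean_ln_a for s in series],
            "mean_ln_c": [s.mean_ln_c for s in series],
            "sd": [s.sd for s in series],
        }
    )
    fig, ax = _new_figure(config)
    xs, ys = frame["mean_ln_a"].to_numpy(), frame["mean_ln_c"].to_numpy()
    ax.plot(xs, ys, "-", color="0.6", lw=1, zorder=1)
    ax.scatter(xs, ys, s=40, c=range(len(xs)), cmap="viridis", zorder=2)
    if config.path_arrows:
        for i in range(len(xs) - 1):
            ax.annotate(
                "",
                xy=(xs[i + 1], ys[i + 1]),
                xytext=(xs[i], ys[i]),
                arrowprops={"arrowstyle": "->", "color": "0.3"},
            )
    for i, row in frame.iterrows():
        ax.annotate(
            f"{row['id']} ({row['date']})",
            (xs[i], ys[i]),
            textcoords="offset points",
            xytext=(5, 5),
            fontsize=7,
        )
    if config.show_nomogram:
        _add_nomogram(ax, config)
    ax.set_title("LDP follow-up path")
    out = _save(fig, Path(path), config)
    _sidecar(out, frame)
    return out
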