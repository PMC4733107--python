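"""Single-pattern, batch and longitudinal pipelines with tabular outputs.

Each run writes CSV tables (variograms, fits, morphometry, summaries) and,
for batch/follow-up modes, the a-c plot and LDP figures.  Identical inputs,
configuration and seed produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .errors import DegeneratePatternError, SmallPatternWarning
from .masks import LesionMask, ManifestEntry, read_manifest, read_mask
from .models import fit_exponential, fits_to_frame
from .morphometry import morphometry
from .plots import PlotConfig, ac_plot, ldp_followup, ldp_plot
from .summary import (
    PatternSummary,
    sd_quartile_thresholds,
    summaries_to_frame,
    summarize,
)
from .variogram import DEFAULT_CUTOFF_MM, variogram_set, variograms_to_frame

logger = logging.getLogger("lesionvario")

#: Patterns with fewer foreground voxels than this trigger an aliasing warning.
SMALL_PATTERN_VOXELS = 16


@dataclass
class RunConfig:
    """Pipeline configuration; defaults mirror the documented method."""

    cutoff_mm: float = DEFAULT_CUTOFF_MM
    connectivity: int = 26
    log_space: bool = True
    sd_class_thresholds: tuple[float, ...] | None = None  # None -> batch quartiles
    axis_order: str = "XYZ"
    output_dir: str = "lesionvario_out"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = dataclasses.asdict(self)
        if data["sd_class_thresholds"] is not None:
            data["sd_class_thresholds"] = list(data["sd_class_thresholds"])
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if data.get("sd_class_thresholds") is not None:
            data["sd_class_thresholds"] = tuple(data["sd_class_thresholds"])
        return cls(**data)


def _warn_small(mask: LesionMask) -> None:
    if 0 < mask.n_foreground < SMALL_PATTERN_VOXELS:
        warnings.warn(
            f"pattern {mask.id!r} has only {mask.n_foreground} foreground voxel(s); "
            "variogram parameters are aliasing-prone and SD may be inflated",
            SmallPatternWarning,
            stacklevel=3,
        )


def process_mask(
    mask: LesionMask,
    config: RunConfig,
    sd_thresholds: tuple[float, ...] | None = None,
):
    """Run variography, fitting, morphometry and summary for one mask.

    Returns (variograms, fits, report, summary).  Raises
    :class:`DegeneratePatternError` for empty/constant masks.
    """
    t0 = time.perf_counter()
    _warn_small(mask)
    vgs = variogram_set(mask, config.cutoff_mm)
    fits = tuple(fit_exponential(vg) for vg in vgs)
    report = morphometry(mask, config.connectivity)
    thresholds = sd_thresholds if sd_thresholds is not None else config.sd_class_thresholds
    summ = summarize(
        fits,
        mask.grid,
        pattern_id=mask.id,
        log_space=config.log_space,
        sd_thresholds=thresholds,
        exam_date=mask.exam_date,
    )
    logger.info("processed %s in %.2f s", mask.id, time.perf_counter() - t0)
    return vgs, fits, report, summ


def run_single(mask_path: str | Path, config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Full pipeline for one mask file; writes the four stage CSVs."""
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    mask = read_mask(mask_path, axis_order=config.axis_order)
    vgs, fits, report, summ = process_mask(mask, config)

    paths = {
        "variograms": outdir / f"{mask.id}_variograms.csv",
        "fits": outdir / f"{mask.id}_fits.csv",
        "morphometry": outdir / f"{mask.id}_morphometry.csv",
        "summary": outdir / f"{mask.id}_summary.csv",
    }
    variograms_to_frame(vgs).to_csv(paths["variograms"], index=False)
    fits_to_frame(mask.id, fits).to_csv(paths["fits"], index=False)
    report.to_frame().to_csv(paths["morphometry"], index=False)
    summaries_to_frame([summ]).to_csv(paths["summary"], index=False)
    return paths


def _process_entries(
    entries: list[ManifestEntry], config: RunConfig
) -> tuple[list, list, list[PatternSummary]]:
    """Process manifest entries, logging and skipping failures."""
    fit_rows, morph_rows, summaries = [], [], []
    for entry in entries:
        try:
            mask = read_mask(
                entry.path, axis_order=config.axis_order, id=entry.id, exam_date=entry.exam_date
            )
            _, fits, report, summ = process_mask(mask, config)
        except (DegeneratePatternError, ValueError, OSError) as exc:
            logger.error("pattern %s failed: %s", entry.id, exc)
            continue
        fit_rows.append((entry.id, fits))
        morph_rows.append(report)
        summaries.append(summ)
    return fit_rows, morph_rows, summaries


def _reclass_summaries(summaries: list[PatternSummary], config: RunConfig) -> list[PatternSummary]:
    """Assign SD classes: fixed thresholds if configured, else batch quartiles."""
    if config.sd_class_thresholds is not None:
        thresholds = config.sd_class_thresholds
    elif len(summaries) >= 4:
        thresholds = sd_quartile_thresholds([s.sd for s in summaries])
    else:
        return summaries
    from .summary import classify_sd

    return [dataclasses.replace(s, sd_class=classify_sd(s.sd, thresholds)) for s in summaries]


def run_batch(manifest_path: str | Path, config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Cross-sectional batch: per-pattern tables plus a-c plot and LDP."""
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = read_manifest(manifest_path)
    fit_rows, morph_rows, summaries = _process_entries(entries, config)
    if not summaries:
        raise DegeneratePatternError("all patterns in the batch failed")
    summaries = _reclass_summaries(summaries, config)

    plot_cfg = PlotConfig()
    paths = {
        "fits": outdir / "batch_fits.csv",
        "morphometry": outdir / "batch_morphometry.csv",
        "summary": outdir / "batch_summary.csv",
        "ac_plot": outdir / "ac_plot.svg",
        "ldp": outdir / "ldp.svg",
    }
    pd.concat([fits_to_frame(pid, fits) for pid, fits in fit_rows], ignore_index=True).to_csv(
        paths["fits"], index=False
    )
    pd.concat([r.to_frame() for r in morph_rows], ignore_index=True).to_csv(
        paths["morphometry"], index=False
    )
    summaries_to_frame(summaries).to_csv(paths["summary"], index=False)
    ac_plot(fit_rows, paths["ac_plot"], plot_cfg, show_mean_centers=True)
    ldp_plot(summaries, paths["ldp"], plot_cfg)
    return paths


def run_followup(manifest_path: str | Path, config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Longitudinal series for one patient: summary table plus LDP path."""
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = read_manifest(manifest_path)
    if len(entries) < 2:
        raise ValueError("a follow-up series needs >= 2 dated exams")
    if any(e.exam_date is None for e in entries):
        raise ValueError("all follow-up manifest rows need dates")
    dates = [e.exam_date for e in entries]
    if any(d1 >= d2 for d1, d2 in zip(dates, dates[1:])):
        raise ValueError("follow-up exam dates must be strictly ascending")

    _, _, summaries = _process_entries(entries, config)
    if len(summaries) < 2:
        raise DegeneratePatternError("fewer than two exams survived processing")
    summaries = _reclass_summaries(summaries, config)

    paths = {
        "summary": outdir / "followup_summary.csv",
        "ldp_path": outdir / "followup_ldp.svg",
    }
    summaries_to_frame(summaries).to_csv(paths["summary"], index=False)
    ldp_followup(summaries, paths["ldp_path"], PlotConfig())
    return paths
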