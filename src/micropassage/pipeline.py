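"""End-to-end measurement drivers and the full-pipeline runner.

Everything here operates on rendered movies only — ground truth is never
consulted — so the cohort statistics these drivers return are genuine
recoveries by the measurement chain (segmentation -> tracking -> event
classification -> quantification).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import find_contours

from . import __version__
from .actinquant import (EnrichmentParams, enrichment_flag,
                         normalized_perinuclear_actin, actin_around_bead,
                         series_enrichment_flag)
from .errors import (ConfigError, MicropassageError, NoCellDetected,
                     NotEncountered, TrackTooShort, UndefinedBaseline)
from .events import EventParams, PassageEvent, classify_passage, \
    cohort_passage_stats
from .laminaquant import (LaminaParams, angular_intensity_profile,
                          detect_rupture, tip_localization)
from .microdevice import ChannelGeometry
from .movieio import Movie
from .segment import (FrameMasks, SegmentationParams, cortex_mask,
                      device_interior_mask, perinuclear_cortex_mask,
                      segment_beads, segment_cell, segment_nucleus)
from .synthgen import (SynthConfig, default_geometry, render_bead_transit,
                       render_lamina_panel, render_movie, sample_cohort)
from .track import (build_track, instantaneous_velocity,
                    nuclear_transit_slowdown)

__all__ = ["AnalysisParams", "CellAnalysis", "analyze_movie",
           "measure_mean_speed", "measure_passage", "measure_slowdown",
           "measure_enrichment", "measure_lamina_condition", "measure_beads",
           "run_pipeline", "synth_config_from_dict", "straight_channel_config"]


@dataclass(frozen=True)
class AnalysisParams:
    """Bundle of all measurement-chain tunables."""
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    events: EventParams = field(default_factory=EventParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    lamina: LaminaParams = field(default_factory=LaminaParams)
    measure_nucleus: bool = True
    measure_actin: bool = False
    early_stop: bool = True


@dataclass
class CellAnalysis:
    """Measurement output for one movie."""
    track: pd.DataFrame | None
    event: PassageEvent | None
    perinuclear: pd.Series | None = None
    enriched: bool | None = None
    enrichment_peak: float = float("nan")
    error: str | None = None


def _resolved(cell_front_s, cell_back_s, entered, entrance_s, exit_s,
              eps) -> bool:
    if cell_back_s >= exit_s:
        return True
    return entered and cell_front_s < entrance_s - eps


def analyze_movie(movie: Movie, geometry: ChannelGeometry,
                  params: AnalysisParams = AnalysisParams()) -> CellAnalysis:
    """Segment, track and classify one single-cell movie.

    With ``early_stop`` the per-frame segmentation halts once the passage
    outcome is confirmed (the classification of the truncated track is
    identical because only the first resolved engagement is scored).
    """
    actin = movie.channel("actin")
    d = geometry.migration_direction
    entrance_s = geometry.entrance_x_um * d
    exit_s = geometry.exit_x_um * d
    px = geometry.pixel_size_um
    eps = params.events.reversal_margin_um

    lumen = device_interior_mask(geometry, actin.shape[1:])
    masks: list[FrameMasks | None] = [None] * movie.n_frames
    peri_vals: dict[int, float] = {}
    entered = False
    for t in range(movie.n_frames):
        try:
            cell = segment_cell(actin[t], params.segmentation) & lumen
        except NoCellDetected:
            continue
        if not cell.any():
            continue
        fm = FrameMasks(cell=cell)
        if params.measure_nucleus and "dna" in movie.channel_map:
            try:
                fm.nucleus = segment_nucleus(movie.frame(t, "dna"), cell,
                                             params.segmentation) & lumen
            except MicropassageError:
                fm.nucleus = None
        if params.measure_actin and fm.nucleus is not None:
            try:
                fm.cortex = cortex_mask(
                    cell, connectivity=params.segmentation.connectivity)
                fm.perinuclear_cortex = perinuclear_cortex_mask(
                    fm.cortex, fm.nucleus)
                peri_vals[t] = normalized_perinuclear_actin(actin[t], fm)
            except MicropassageError:
                pass
        masks[t] = fm
        if params.early_stop:
            xs = np.flatnonzero(cell.any(axis=0))
            coords = (xs + 0.5) * px * d
            front_s, back_s = coords.max(), coords.min()
            entered = entered or front_s >= entrance_s
            if _resolved(front_s, back_s, entered, entrance_s, exit_s, eps):
                break

    try:
        track = build_track(masks, movie, geometry)
    except TrackTooShort as exc:
        return CellAnalysis(track=None, event=None, error=str(exc))
    try:
        event = classify_passage(track, geometry, movie.frame_interval_min,
                                 params.events)
    except NotEncountered as exc:
        return CellAnalysis(track=track, event=None, error=str(exc))

    out = CellAnalysis(track=track, event=event)
    if params.measure_actin:
        out.perinuclear = pd.Series(peri_vals, dtype=float).reindex(
            range(movie.n_frames))
        try:
            out.enriched, out.enrichment_peak = enrichment_flag(
                out.perinuclear, event, movie.frame_interval_min,
                params.enrichment)
        except UndefinedBaseline as exc:
            out.error = str(exc)
    return out


# --------------------------------------------------------------------------
# cohort measurement drivers

def straight_channel_config(**overrides) -> SynthConfig:
    """Configuration for free migration in a channel with no narrowing."""
    geom = default_geometry(constriction_width_um=7.0)
    return SynthConfig(geometry=geom, **overrides)


def _iter_cohort(config: SynthConfig, renderer=render_movie):
    for lat in sample_cohort(config):
        yield renderer(lat, config)


def measure_mean_speed(config: SynthConfig,
                       params: AnalysisParams | None = None) -> dict:
    """Cohort mean of per-cell mean instantaneous speeds (um/min).

    Per-cell means use only displacements between frames where the cell
    mask does not touch the axial image border (edge-clipped masks bias the
    centroid).  The cohort statistic averages cells, not frames, so slow
    cells (which stay longer in the field) are not over-weighted.
    """
    if params is None:
        params = AnalysisParams(measure_nucleus=False, early_stop=False)
    per_cell = []
    for movie, _truth in _iter_cohort(config):
        res = analyze_movie(movie, config.geometry, params)
        if res.track is None:
            continue
        v = instantaneous_velocity(res.track, movie.frame_interval_min,
                                   direction=config.geometry.migration_direction)
        border = res.track["cell_touches_xborder"].astype(bool)
        clean = v[~border & ~border.shift(1, fill_value=True)].dropna()
        if len(clean):
            per_cell.append(float(clean.mean()))
    return {"mean_speed_um_min": float(np.mean(per_cell)),
            "sd": float(np.std(per_cell, ddof=1)),
            "n_cells": len(per_cell),
            "per_cell": per_cell}


def measure_passage(config: SynthConfig,
                    params: AnalysisParams | None = None) -> dict:
    """Percentage of passage (and event summary) for one cohort."""
    if params is None:
        params = AnalysisParams(measure_nucleus=True)
    events, truths = [], []
    for movie, truth in _iter_cohort(config):
        res = analyze_movie(movie, config.geometry, params)
        if res.event is not None:
            events.append(res.event)
            truths.append(truth)
    stats = cohort_passage_stats(events)
    stats["truth_outcomes"] = [t.outcome for t in truths]
    stats["measured_outcomes"] = [e.outcome for e in events]
    return stats


def measure_slowdown(config: SynthConfig,
                     params: AnalysisParams | None = None) -> dict:
    """Mean normalized velocity variation during nuclear transit."""
    if params is None:
        params = AnalysisParams(measure_nucleus=True)
    per_cell = []
    for movie, _truth in _iter_cohort(config):
        res = analyze_movie(movie, config.geometry, params)
        if res.track is None or res.event is None:
            continue
        if res.event.outcome != "passed":
            continue
        try:
            per_cell.append(nuclear_transit_slowdown(
                res.track, config.geometry, movie.frame_interval_min))
        except UndefinedBaseline:
            continue
    if not per_cell:
        raise UndefinedBaseline("no cell yielded a clean transit window")
    return {"mean_normalized_velocity_variation": float(np.mean(per_cell)),
            "sd": float(np.std(per_cell, ddof=1)) if len(per_cell) > 1 else 0.0,
            "n_cells": len(per_cell),
            "per_cell": per_cell}


def measure_enrichment(config: SynthConfig,
                       params: AnalysisParams | None = None,
                       outcome_filter: str | None = None) -> dict:
    """Fraction of cells flagged by the perinuclear enrichment detector.

    Cells without a defined flag (no nuclear entry, or too few baseline
    frames for the adaptive criterion) are excluded from the denominator.
    """
    if params is None:
        params = AnalysisParams(measure_actin=True)
    flags = []
    n_undefined = 0
    for movie, _truth in _iter_cohort(config):
        res = analyze_movie(movie, config.geometry, params)
        if res.event is None:
            n_undefined += 1
            continue
        if outcome_filter is not None and res.event.outcome != outcome_filter:
            continue
        if res.enriched is None:
            n_undefined += 1
            continue
        flags.append(res.enriched)
    if not flags:
        raise UndefinedBaseline("no cell had a defined enrichment flag")
    return {"fraction_enriched": float(np.mean(flags)),
            "n_cells": len(flags),
            "n_undefined": n_undefined}


def measure_lamina_condition(config: SynthConfig, condition: str,
                             n: int | None = None,
                             params: AnalysisParams | None = None) -> dict:
    """Rupture statistics of one rendered still-image condition panel."""
    if params is None:
        params = AnalysisParams()
    lp = params.lamina
    reports = []
    for frames, _truth in render_lamina_panel(config, condition, n=n):
        try:
            nuc = segment_cell(frames["dna"], params.segmentation)
        except NoCellDetected:
            continue
        profile = angular_intensity_profile(frames["lamina"], nuc, lp.n_bins)
        boundary = 0.0
        for contour in find_contours(nuc.astype(float), 0.5):
            boundary += float(np.hypot(*np.diff(contour, axis=0).T).sum()) \
                * config.geometry.pixel_size_um
        report = detect_rupture(profile, boundary, lp)
        if report.ruptured:
            report.tip_localized = tip_localization(report, nuc,
                                                    config.geometry, lp)
        reports.append(report)
    n_rupt = sum(r.ruptured for r in reports)
    tip_known = [r for r in reports if r.ruptured]
    return {
        "condition": condition,
        "n": len(reports),
        "fraction_ruptured": n_rupt / len(reports) if reports else float("nan"),
        "fraction_tip_localized": (
            float(np.mean([r.tip_localized for r in tip_known]))
            if tip_known else None),
        "rupture_perimeters_um": [r.rupture_perimeter_um
                                  for r in tip_known],
    }


def measure_beads(config: SynthConfig,
                  params: AnalysisParams | None = None) -> dict:
    """Fraction of bead transits flagged for peribead actin accumulation.

    Per frame: segment the cell and the bead, measure the normalized
    annulus intensity, then score the bead with the same adaptive
    baseline-vs-window criterion as the perinuclear detector, gated on the
    measured bead center being inside the constriction.
    """
    if params is None:
        params = AnalysisParams(measure_nucleus=False, early_stop=False)
    if config.bead_params is None:
        raise ConfigError("bead_params not configured")
    geom = config.geometry
    d = geom.migration_direction
    entrance_s, exit_s = geom.entrance_x_um * d, geom.exit_x_um * d
    r_um = config.bead_params.diameter_um / 2.0
    flags = []
    n_undefined = 0
    for movie, _truth in _iter_cohort(config, renderer=render_bead_transit):
        actin = movie.channel("actin")
        bead_ch = movie.channel("bead")
        vals, inside, before = {}, {}, {}
        for t in range(movie.n_frames):
            try:
                cell = segment_cell(actin[t], params.segmentation)
            except NoCellDetected:
                continue
            labeled = segment_beads(bead_ch[t], r_um, geom)
            if labeled.max() == 0:
                continue
            ys, xs = np.nonzero(labeled == 1)
            center_s = (xs.mean() + 0.5) * geom.pixel_size_um * d
            try:
                vals[t] = actin_around_bead(actin[t], labeled, 1, cell)
            except MicropassageError:
                continue
            inside[t] = entrance_s <= center_s < exit_s
            before[t] = center_s < entrance_s
        series = pd.Series(vals, dtype=float)
        baseline = [t for t, b in before.items() if b]
        window = [t for t, b in inside.items() if b]
        if not window:
            n_undefined += 1
            continue
        try:
            flag, _peak = series_enrichment_flag(series, baseline, window,
                                                 params.enrichment)
        except UndefinedBaseline:
            n_undefined += 1
            continue
        flags.append(flag)
    return {"fraction_accumulating": float(np.mean(flags)) if flags
            else float("nan"),
            "n_cells": len(flags),
            "n_undefined": n_undefined}


# --------------------------------------------------------------------------
# config plumbing and the full pipeline

_GEOMETRY_KEYS = ("channel_width_um", "channel_height_um",
                  "constriction_width_um", "constriction_length_um",
                  "constriction_center_x_um", "pixel_size_um",
                  "migration_direction")


def synth_config_from_dict(d: dict) -> SynthConfig:
    """Build a SynthConfig from a flat configuration dictionary."""
    d = dict(d)
    geom_kwargs = {k: d.pop(k) for k in list(d) if k in _GEOMETRY_KEYS}
    if geom_kwargs:
        base = default_geometry()
        merged = {k: getattr(base, k) for k in _GEOMETRY_KEYS}
        merged.update(geom_kwargs)
        d["geometry"] = ChannelGeometry(**merged)
    known = set(SynthConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
    return SynthConfig(**d)


def run_pipeline(config: dict, output_dir: str | Path | None = None) -> dict:
    """Run simulate -> segment -> track -> events -> quantify on a cohort.

    ``config`` mirrors the module structure::

        {"condition": "W1.5",
         "simulate": {"n_cells": 4, "seed": 3, "constriction_width_um": 1.5},
         "analysis": {"measure_actin": true},
         "output_dir": "out"}

    Per-cell failures are recorded and never abort the cohort.  Writes
    events.csv, tracks.csv, summary.json and manifest.json; reruns with the
    same config produce byte-identical outputs.
    """
    sim = config.get("simulate")
    if not sim:
        raise ConfigError("config must contain a 'simulate' block")
    if sim.get("n_cells", 0) < 1:
        raise ConfigError("simulate.n_cells must be >= 1")
    synth = synth_config_from_dict(sim)
    analysis_kwargs = dict(config.get("analysis", {}))
    params = AnalysisParams(**analysis_kwargs)
    condition = config.get("condition", "default")
    if output_dir is None:
        output_dir = config.get("output_dir")

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]

    event_rows, track_frames, errors = [], [], []
    for i, (movie, _truth) in enumerate(_iter_cohort(synth)):
        res = analyze_movie(movie, synth.geometry, params)
        cell_id = f"cell{i:04d}"
        if res.error is not None and res.event is None:
            errors.append({"cell_id": cell_id, "error": res.error})
            continue
        ev = res.event
        event_rows.append({
            "cell_id": cell_id, "condition": condition,
            "config_hash": cfg_hash,
            "outcome": ev.outcome,
            "t_cell_entry_min": ev.t_cell_entry_min,
            "t_nuc_entry_min": ev.t_nuc_entry_min,
            "t_nuc_exit_min": ev.t_nuc_exit_min,
            "t_cell_exit_min": ev.t_cell_exit_min,
            "cell_passage_time_min": ev.cell_passage_time_min,
            "nuc_passage_time_min": ev.nuc_passage_time_min,
            "non_passage_time_min": ev.non_passage_time_min,
            "nuclear_entry": ev.nuclear_entry_flag,
            "enriched": res.enriched,
        })
        if res.track is not None:
            tr = res.track.copy()
            tr.insert(0, "cell_id", cell_id)
            tr.insert(1, "condition", condition)
            tr.insert(2, "config_hash", cfg_hash)
            track_frames.append(tr)

    events_df = pd.DataFrame(event_rows)
    summary = {
        "condition": condition,
        "config_hash": cfg_hash,
        "seed": synth.seed,
        "version": __version__,
        "n_cells": synth.n_cells,
        "n_analyzed": len(event_rows),
        "n_failed": len(errors),
        "passage": (cohort_passage_stats(
            [PassageEvent(r["t_cell_entry_min"], r["t_nuc_entry_min"],
                          r["t_nuc_exit_min"], r["t_cell_exit_min"],
                          r["outcome"], bool(r["nuclear_entry"]),
                          r["cell_passage_time_min"],
                          r["nuc_passage_time_min"],
                          r["non_passage_time_min"])
             for r in event_rows]) if event_rows else None),
        "errors": errors,
    }
    if summary["passage"]:
        summary["passage"].pop("truth_outcomes", None)

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        events_df.to_csv(out / "events.csv", index=False)
        if track_frames:
            pd.concat(track_frames).to_csv(out / "tracks.csv")
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=str))
        (out / "manifest.json").write_text(json.dumps({
            "config": config, "config_hash": cfg_hash,
            "seed": synth.seed, "version": __version__,
            "n_cells": synth.n_cells, "n_analyzed": len(event_rows),
            "n_failed": len(errors),
        }, indent=2, sort_keys=True))
    return summary
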