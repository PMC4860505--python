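"""End-to-end runner: simulate -> render -> trace -> extract -> quantify -> stats.

The pipeline writes every intermediate table so each stage can be audited,
and finishes with a manifest of checksums. A ``bypass_imaging`` mode feeds
simulator ground truth straight into quantification, skipping rendering and
image analysis entirely — the reference path against which the imaging
stages are validated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig
from .extract import SpotParams, assign_spots_to_fibers, detect_spots, segment_tracts
from .io import RunManifest, write_imageset, write_table
from .quantify import (
    CATEGORIES,
    FiberRecord,
    classify_fiber,
    encounter_proportions,
    records_from_ground_truth,
    records_to_frame,
    summarize,
)
from .render import ImageSet, RenderedField, render_images
from .simulate import simulate_fibers
from .stats import StatsError, two_proportion_z
from .trace import TraceParams, segment_fibers

log = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """Parameters of the image-analysis stages, shared across fields."""

    trace: TraceParams = field(default_factory=TraceParams)
    spots: SpotParams = field(default_factory=SpotParams)
    max_assign_dist_px: float = 3.0
    tract_threshold: float | str = "otsu"
    gap_close_kb: float = 2.0
    min_tract_kb: float = 1.0
    adjacency_kb: float = 2.0


def analyze_imageset(
    image_set: ImageSet,
    params: AnalysisParams | None = None,
    experiment_label: str = "",
    id_offset: int = 0,
) -> dict:
    """Run tracing, spot detection/assignment and tract segmentation on one
    field; returns records plus the stage tables.

    Edge-touching traces are excluded from the records entirely (their
    length is truncated by the field of view); crossing fibers were already
    discarded during tracing.
    """
    params = params or AnalysisParams()
    trace_res = segment_fibers(image_set, params.trace)
    clean = [t for t in trace_res.traces if not t.edge_touching]
    for i, tr in enumerate(clean):
        tr.id = id_offset + i

    spots = detect_spots(image_set.channels["qdot"], params.spots)
    kb_per_px = params.trace.pixel_um * params.trace.kb_per_um
    assign = assign_spots_to_fibers(spots, clean, params.max_assign_dist_px, kb_per_px)

    signals_by_fiber: dict[int, list[float]] = {}
    for sig in assign.signals:
        signals_by_fiber.setdefault(sig.fiber_id, []).append(sig.arc_kb)

    records: list[FiberRecord] = []
    tract_rows = []
    for tr in clean:
        tracts = segment_tracts(
            tr.arc_kb,
            tr.profiles.get("idU", np.zeros_like(tr.arc_kb)),
            threshold=params.tract_threshold,
            gap_close_kb=params.gap_close_kb,
            min_tract_kb=params.min_tract_kb,
            fiber_id=tr.id,
        )
        for t in tracts:
            tract_rows.append(
                {"fiber_id": t.fiber_id, "start_kb": t.start_kb, "end_kb": t.end_kb, "label": t.label}
            )
        rec = FiberRecord(
            fiber_id=tr.id,
            experiment_label=experiment_label,
            length_kb=tr.length_kb,
            signals=signals_by_fiber.get(tr.id, []),
            idu_tracts=[(t.start_kb, t.end_kb) for t in tracts],
        )
        classify_fiber(rec, params.adjacency_kb)
        records.append(rec)

    signal_rows = [
        {
            "fiber_id": s.fiber_id,
            "arc_kb": s.arc_kb,
            "row": s.row,
            "col": s.col,
            "peak": s.peak_intensity,
            "snr": s.snr,
        }
        for s in assign.signals
    ]
    fiber_rows = [
        {
            "fiber_id": tr.id,
            "length_px": tr.length_px,
            "length_kb": tr.length_kb,
            "edge_touching": tr.edge_touching,
        }
        for tr in clean
    ]
    return {
        "records": records,
        "traces": clean,
        "fibers": pd.DataFrame(fiber_rows, columns=["fiber_id", "length_px", "length_kb", "edge_touching"]),
        "signals": pd.DataFrame(signal_rows, columns=["fiber_id", "arc_kb", "row", "col", "peak", "snr"]),
        "tracts": pd.DataFrame(tract_rows, columns=["fiber_id", "start_kb", "end_kb", "label"]),
        "n_crossing_discarded": trace_res.n_crossing_discarded,
        "n_edge_excluded": trace_res.n_edge_flagged,
        "n_unassigned_spots": assign.n_unassigned,
        "n_assignment_ties": assign.n_ties,
    }


def analyze_fields(
    fields: list[RenderedField] | list[ImageSet],
    params: AnalysisParams | None = None,
    experiment_label: str = "",
) -> dict:
    """Analyze several fields, concatenating records with unique fiber ids."""
    params = params or AnalysisParams()
    records: list[FiberRecord] = []
    fibers_df, signals_df, tracts_df = [], [], []
    counters = {"n_crossing_discarded": 0, "n_edge_excluded": 0, "n_unassigned_spots": 0, "n_assignment_ties": 0}
    offset = 0
    for fld in fields:
        image_set = fld.image_set if isinstance(fld, RenderedField) else fld
        res = analyze_imageset(image_set, params, experiment_label, id_offset=offset)
        offset += len(res["records"]) + 1
        records.extend(res["records"])
        fibers_df.append(res["fibers"])
        signals_df.append(res["signals"])
        tracts_df.append(res["tracts"])
        for k in counters:
            counters[k] += res[k]
    empty = {
        "fibers": pd.DataFrame(columns=["fiber_id", "length_px", "length_kb", "edge_touching"]),
        "signals": pd.DataFrame(columns=["fiber_id", "arc_kb", "row", "col", "peak", "snr"]),
        "tracts": pd.DataFrame(columns=["fiber_id", "start_kb", "end_kb", "label"]),
    }
    return {
        "records": records,
        "fibers": pd.concat(fibers_df, ignore_index=True) if fibers_df else empty["fibers"],
        "signals": pd.concat(signals_df, ignore_index=True) if signals_df else empty["signals"],
        "tracts": pd.concat(tracts_df, ignore_index=True) if tracts_df else empty["tracts"],
        **counters,
    }


def summary_frame(records, label: str) -> pd.DataFrame:
    s = summarize(records, label)
    row = {
        "experiment_label": s.experiment_label,
        "n_fibers": s.n_fibers,
        "n_fibers_with_signal": s.n_fibers_with_signal,
        "fraction_with_signal": (s.n_fibers_with_signal / s.n_fibers) if s.n_fibers else float("nan"),
        "total_length_kb": s.total_length_kb,
        "n_signals": s.n_signals,
        "density_per_1000kb": s.density_per_1000kb,
        "n_distances": len(s.distances_kb),
        "mean_distance_kb": float(np.mean(s.distances_kb)) if s.distances_kb else float("nan"),
    }
    for cat in CATEGORIES:
        row[f"n_{cat.lower()}"] = s.category_counts[cat]
    return pd.DataFrame([row])


def run_pipeline(
    config: SimulationConfig,
    out_dir,
    bypass_imaging: bool = False,
    write_images: bool = False,
    analysis: AnalysisParams | None = None,
) -> RunManifest:
    """Execute the full pipeline into ``out_dir`` and return the manifest.

    With ``bypass_imaging`` the quantification consumes simulator ground
    truth directly (no rendering). Deterministic for a fixed config + seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rc = config.render
    calib = {"kb_per_um": rc.kb_per_um, "pixel_um": rc.pixel_um}
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed, version=__version__)

    def _stage(name):
        manifest.stages.append(name)
        log.info("stage: %s", name)

    try:
        _stage("simulate")
        fibers, truth = simulate_fibers(config)
        write_table(truth["fibers"], out / "ground_truth_fibers.csv", units={"length_kb": "kb"}, calibration=calib)
        write_table(truth["adducts"], out / "ground_truth_adducts.csv", units={"position_kb": "kb"}, calibration=calib)
        write_table(
            truth["tracts"], out / "ground_truth_tracts.csv", units={"start_kb": "kb", "end_kb": "kb"}, calibration=calib
        )

        analysis = analysis or AnalysisParams(
            trace=TraceParams(pixel_um=rc.pixel_um, kb_per_um=rc.kb_per_um)
        )
        if bypass_imaging:
            _stage("quantify(bypass)")
            records = records_from_ground_truth(fibers, analysis.adjacency_kb)
            tables = None
        else:
            _stage("render")
            render_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
            fields = render_images(fibers, rc, render_rng)
            if write_images:
                for i, fld in enumerate(fields):
                    write_imageset(fld.image_set, out / f"field_{i:03d}.tif")
            _stage("trace+extract+quantify")
            tables = analyze_fields(fields, analysis, config.experiment_label)
            records = tables["records"]
            write_table(tables["fibers"], out / "fibers.csv", units={"length_px": "px", "length_kb": "kb"}, calibration=calib)
            write_table(tables["signals"], out / "signals.csv", units={"arc_kb": "kb", "row": "px", "col": "px"}, calibration=calib)
            write_table(tables["tracts"], out / "tracts.csv", units={"start_kb": "kb", "end_kb": "kb"}, calibration=calib)

        write_table(records_to_frame(records), out / "records.csv", units={"length_kb": "kb"}, calibration=calib)
        summary = summary_frame(records, config.experiment_label)
        write_table(summary, out / "summary.csv", units={"total_length_kb": "kb", "density_per_1000kb": "per 10^3 kb"}, calibration=calib)

        _stage("stats")
        test_rows = []
        if not records:
            log.info("zero fibers: statistics stage skipped")
        else:
            try:
                f_single, f_double, n_enc = encounter_proportions(records)
                k_double = round(f_double * n_enc)
                res = two_proportion_z(n_enc - k_double, k_double)
                test_rows.append(
                    {"method": res.method, "statistic": res.statistic, "df": res.df, "p_value": res.p_value}
                )
            except (StatsError, ValueError) as exc:  # quantification may lack encounters
                log.info("encounter-proportion test skipped: %s", exc)
        tests_df = pd.DataFrame(test_rows, columns=["method", "statistic", "df", "p_value"])
        write_table(tests_df, out / "tests.csv")

        _stage("manifest")
        for p in sorted(out.iterdir()):
            if p.is_file() and p.name != "manifest.json":
                manifest.add_output(out, p)
        manifest.write(out / "manifest.json")
        return manifest
    except Exception:
        log.exception("pipeline aborted during stage %s; partial outputs kept in %s", manifest.stages[-1] if manifest.stages else "?", out)
        raise
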