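"""End-to-end orchestration: simulate/load -> wear -> segment ->
profile -> tune/fit -> evaluate, with per-stage seeds derived
deterministically from one master seed."""

from __future__ import annotations

import json
import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from funcprofile import io_epoch
from funcprofile.evaluation import (
    MEASURES,
    CohortData,
    cv_tune_width,
    holdout_evaluate,
)
from funcprofile.segmentation import (
    SEGMENT_COLUMNS,
    SegmentationConfig,
    segment_bout,
    summarize_segment,
)
from funcprofile.synthetic import SimulationConfig, simulate_cohort
from funcprofile.wear import detect_nonwear, extract_bouts, valid_day

logger = logging.getLogger(__name__)


def _derived_seed(*parts) -> int:
    ss = np.random.SeedSequence([int(p) % (2**31) for p in parts])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def wear_mask_table(epochs: pd.DataFrame) -> pd.DataFrame:
    """Per-minute wear flags for every subject-day."""
    frames = []
    for (sid, day), grp in epochs.groupby(["subject_id", "day"], sort=True):
        mask = detect_nonwear(grp["count"].to_numpy())
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "timestamp": grp["timestamp"].to_numpy(),
                    "wear": mask.astype(np.int8),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def segment_cohort(
    epochs: pd.DataFrame,
    seg_config: SegmentationConfig,
    master_seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Wear-filter and segment every valid subject-day.

    Returns (segments, valid_days): segments on valid days only, and a
    subject_id -> K series restricted to subjects with K >= 1.  Each
    bout gets its own seed derived from (master seed, subject, day,
    bout), so the result is independent of processing order.
    """
    master = seg_config.seed if master_seed is None else master_seed
    subject_index = {
        sid: i for i, sid in enumerate(sorted(epochs["subject_id"].unique()))
    }
    rows = []
    k_counts: dict[str, int] = {}
    n_invalid = 0
    for (sid, day), grp in epochs.groupby(["subject_id", "day"], sort=True):
        counts = grp["count"].to_numpy()
        mask = detect_nonwear(counts)
        if not valid_day(mask):
            n_invalid += 1
            continue
        si = subject_index[sid]
        di = k_counts.get(sid, 0)
        k_counts[sid] = di + 1
        for bi, bout in enumerate(extract_bouts(counts, mask, sid, day)):
            cfg = replace(seg_config, seed=_derived_seed(master, si, di, bi))
            for lo, hi in segment_bout(bout.counts, cfg):
                mean, sd, dur = summarize_segment(bout.counts, lo, hi)
                rows.append(
                    (sid, day, bout.start + lo, bout.start + hi, mean, sd, dur)
                )
    if n_invalid:
        logger.info("excluded %d invalid days (<600 wear minutes)", n_invalid)
    segments = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    valid_days = pd.Series(k_counts, name="K").sort_index()
    valid_days.index.name = "subject_id"
    return segments, valid_days


def build_cohort_data(
    epochs: pd.DataFrame,
    covariates: pd.DataFrame,
    capacity: pd.DataFrame,
    seg_config: SegmentationConfig,
    master_seed: int | None = None,
) -> CohortData:
    segments, valid_days = segment_cohort(epochs, seg_config, master_seed)
    dropped = set(covariates["subject_id"]) - set(valid_days.index)
    if dropped:
        logger.info("%d subjects have no valid days", len(dropped))
    return CohortData(segments, valid_days, covariates, capacity)


def run_pipeline(config: dict) -> dict:
    """Run the whole workflow from a flat JSON-style config.

    Recognized keys (all optional unless noted): ``seed`` (master),
    ``simulate`` (SimulationConfig field overrides; when absent,
    ``epochs``/``covariates``/``capacity`` CSV paths are required),
    ``segmentation`` (SegmentationConfig overrides), ``width``,
    ``tune_widths`` (list; triggers cross-validated width selection),
    ``folds``, ``repeats``, ``measures``, ``split_fraction``,
    ``min_support``, ``model`` (OrdinalGAM kwargs), ``outdir``.
    """
    seed = int(config.get("seed", 0))
    outdir = config.get("outdir")
    if "simulate" in config:
        sim = SimulationConfig(**{"seed": _derived_seed(seed, 11), **config["simulate"]})
        cohort_sim = simulate_cohort(sim)
        epochs, covariates, capacity = (
            cohort_sim.epochs, cohort_sim.covariates, cohort_sim.capacity,
        )
    else:
        for key in ("epochs", "covariates", "capacity"):
            if key not in config:
                raise ValueError(
                    f"config needs {key!r} (or a 'simulate' preset)"
                )
        epochs = io_epoch.read_epochs(config["epochs"])
        covariates = io_epoch.read_covariates(config["covariates"])
        capacity = io_epoch.read_capacity(config["capacity"])

    seg_config = SegmentationConfig(
        **{"seed": _derived_seed(seed, 22), **config.get("segmentation", {})}
    )
    cohort = build_cohort_data(epochs, covariates, capacity, seg_config)
    logger.info(
        "%d subjects with valid days, %d segments",
        cohort.valid_days.size, len(cohort.segments),
    )

    measures = config.get("measures", list(MEASURES))
    model_kwargs = config.get("model", {})
    min_support = int(config.get("min_support", 10))
    report: dict = {"seed": seed, "measures": {}}
    for measure in measures:
        if "tune_widths" in config:
            width, cv_results = cv_tune_width(
                cohort, measure, config["tune_widths"],
                folds=int(config.get("folds", 5)),
                repeats=int(config.get("repeats", 10)),
                seed=_derived_seed(seed, 33),
                min_support=min_support,
                model_kwargs=model_kwargs,
            )
            curve = (
                cv_results.groupby("width")["gamma"].mean().to_dict()
            )
        else:
            width = float(config.get("width", 700.0))
            curve = None
        ev = holdout_evaluate(
            cohort, measure, width,
            split_fraction=float(config.get("split_fraction", 0.8)),
            seed=_derived_seed(seed, 44),
            min_support=min_support,
            model_kwargs=model_kwargs,
        )
        entry = ev.to_dict()
        if curve is not None:
            entry["cv_gamma_by_width"] = curve
        report["measures"][measure] = entry

    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        io_epoch.write_table(
            cohort.segments, os.path.join(outdir, "segments.csv"), allow_empty=True
        )
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
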