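"""Orchestration: simulate → render → read → morphometry → lineage → stats.

``run_simulate`` writes a fixture bundle (SVG segmentations plus ground-truth
lineage CSVs) for all nine experimental conditions — intact controls (CT) and
apical/basal ablations (AE/BE) at the 2-, 4- and 8-cell stages. ``run_analyze``
consumes a directory of segmentation SVGs and emits the full analysis tables.
Both are deterministic given the seed; every CSV starts with a comment header
recording the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .core import EmbryoTimeSeries
from .lineage import first_longitudinal_stage, track_series
from .morphometry import blade_metrics, cell_metrics
from .segio import read_segmentation, validate_series
from .simulator import (
    AblationPlan,
    SimulationConfig,
    render_snapshots,
    simulate_embryo,
)
from .stats import ALPHA, compare_conditions

log = logging.getLogger("kelpmorph")

STAGES = (2, 4, 8)
ABLATION_TARGET = {"AE": "apical", "BE": "basal"}


@dataclass
class RunConfig:
    """Shared knobs of the pipeline verbs."""

    out_dir: Path
    seed: int = 0
    calibration: float = 1.0
    alpha: float = ALPHA
    endpoint_day: int = 6
    n_replicates: int = 5
    days: int = 9
    noise_growth_cv: float = 0.0
    vertex_jitter_sd: float = 0.0
    replicate_rate_cv: float = 0.0  # between-embryo growth-rate variability
    iou_threshold: float = 0.3
    base_config: SimulationConfig = field(default_factory=SimulationConfig)


def _condition_config(
    run: RunConfig, condition: str, replicate: int, rng: np.random.Generator
) -> SimulationConfig:
    prefix, stage = condition[:2], int(condition[2:])
    ablation = (
        None
        if prefix == "CT"
        else AblationPlan(target=ABLATION_TARGET[prefix], stage=stage)
    )
    scale = 1.0
    if run.replicate_rate_cv > 0:
        sigma2 = np.log(1.0 + run.replicate_rate_cv**2)
        scale = float(rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2)))
    base = run.base_config
    return dataclasses.replace(
        base,
        growth_rate_basal=base.growth_rate_basal * scale,
        growth_rate_apical=base.growth_rate_apical * scale,
        ablation=ablation,
        days=run.days,
        noise_growth_cv=run.noise_growth_cv,
        vertex_jitter_sd=run.vertex_jitter_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def run_simulate(run: RunConfig) -> list[Path]:
    """Generate the nine-condition fixture bundle; returns written SVG paths."""
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(run.seed)
    written = []
    for prefix in ("CT", "AE", "BE"):
        for stage in STAGES:
            condition = f"{prefix}{stage}"
            for rep in range(run.n_replicates):
                cfg = _condition_config(run, condition, rep, rng)
                embryo_id = f"{condition}_r{rep:02d}"
                series = simulate_embryo(cfg)
                svg_path = out / f"{embryo_id}.svg"
                render_snapshots(
                    series,
                    calibration=run.calibration,
                    embryo_id=embryo_id,
                    condition=condition,
                    path=svg_path,
                )
                truth = pd.DataFrame(
                    [dataclasses.asdict(r) for r in series.lineage_truth]
                )
                _write_csv(truth, out / f"{embryo_id}_truth.csv", run.seed)
                written.append(svg_path)
                log.info("simulated %s (%d divisions)", embryo_id,
                         len(series.lineage_truth))
    _write_metadata(out, run, mode="simulate")
    return written


def _write_csv(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kelpmorph {__version__} seed={seed}\n")
        df.to_csv(fh, index=False)


def _write_metadata(out: Path, run: RunConfig, mode: str) -> None:
    meta = {
        "tool": "kelpmorph",
        "version": __version__,
        "mode": mode,
        "seed": run.seed,
        "alpha": run.alpha,
        "calibration": run.calibration,
        "endpoint_day": run.endpoint_day,
        "n_replicates": run.n_replicates,
        "noise_growth_cv": run.noise_growth_cv,
        "vertex_jitter_sd": run.vertex_jitter_sd,
        "replicate_rate_cv": run.replicate_rate_cv,
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_series_dir(
    input_dir: Path, calibration: float
) -> list[EmbryoTimeSeries]:
    """Read every segmentation SVG in a directory (sorted, deterministic)."""
    paths = sorted(Path(input_dir).glob("*.svg"))
    if not paths:
        raise FileNotFoundError(f"no segmentation SVGs in {input_dir}")
    series = []
    from lxml import etree

    for p in paths:
        root = etree.parse(str(p)).getroot()
        condition = root.get("data-condition") or "CT8"
        embryo_id = root.get("data-embryo-id") or p.stem
        series.append(
            read_segmentation(str(p), calibration, condition, embryo_id)
        )
    return series


def analyze_series(
    all_series: list[EmbryoTimeSeries],
    run: RunConfig,
) -> dict[str, pd.DataFrame]:
    """Compute every analysis table from in-memory series."""
    cals = {ts.calibration for ts in all_series}
    if len(cals) > 1:
        raise ValueError(f"mixed calibrations in one comparison: {sorted(cals)}")
    cell_rows, blade_rows, event_rows, stage_rows, tidy_rows = [], [], [], [], []
    for ts in all_series:
        report = validate_series(ts)
        for v in report.errors():
            log.warning("%s: %s", ts.embryo_id, v.message)
        for snap in ts.snapshots:
            bm = blade_metrics(snap)
            blade_rows.append(
                dict(embryo_id=ts.embryo_id, condition=ts.condition,
                     day=snap.day, blade_area=bm.blade_area, length=bm.length,
                     width=bm.width, lwr=bm.lwr,
                     main_axis_orientation=bm.main_axis_orientation,
                     n_cells_alive=bm.n_cells_alive)
            )
            for measure, value in (
                ("blade_area", bm.blade_area),
                ("n_cells", float(bm.n_cells_alive)),
                ("blade_lwr", bm.lwr),
            ):
                tidy_rows.append(
                    dict(embryo_id=ts.embryo_id, condition=ts.condition,
                         day=snap.day, measure=measure, value=value)
                )
            for cell in snap.alive_cells:
                cm = cell_metrics(cell)
                cell_rows.append(
                    dict(embryo_id=ts.embryo_id, condition=ts.condition,
                         day=snap.day, cell_id=cm.cell_id, area=cm.area,
                         lwr=cm.lwr, mbr_length=cm.mbr_length,
                         mbr_width=cm.mbr_width,
                         mbr_orientation=cm.mbr_orientation)
                )
        maps = track_series(ts, iou_threshold=run.iou_threshold)
        for lm in maps:
            for ev in lm.divisions:
                event_rows.append(
                    dict(embryo_id=ts.embryo_id, condition=ts.condition,
                         day_before=ev.day_before, day_after=ev.day_after,
                         parent_id=ev.parent_id,
                         daughter1_id=ev.daughter_ids[0],
                         daughter2_id=ev.daughter_ids[1],
                         orientation=ev.orientation,
                         cells_before=ev.cells_before,
                         wall_angle_deg=ev.wall_angle_deg)
                )
            for an in lm.anomalies:
                log.warning("%s d%02d->d%02d anomaly %s: %s", ts.embryo_id,
                            an.day_before, an.day_after, an.code, an.detail)
        stage = first_longitudinal_stage(maps)
        ablation_days = [
            snap.day
            for snap in ts.snapshots
            if any(not c.alive for c in snap.cells)
        ]
        stage_rows.append(
            dict(embryo_id=ts.embryo_id, condition=ts.condition,
                 first_longitudinal_stage=stage,
                 ablation_day=min(ablation_days) if ablation_days else None)
        )
    tables = {
        "cell_metrics": pd.DataFrame(cell_rows),
        "blade_metrics": pd.DataFrame(blade_rows),
        "division_events": pd.DataFrame(event_rows),
        "first_longitudinal_stage": pd.DataFrame(stage_rows),
        "tidy_measures": pd.DataFrame(tidy_rows),
    }
    tables["comparisons"] = _condition_comparisons(
        tables["tidy_measures"], tables["first_longitudinal_stage"], run
    )
    return tables


def _condition_comparisons(
    tidy: pd.DataFrame, stage_table: pd.DataFrame, run: RunConfig
) -> pd.DataFrame:
    """Each ablated condition vs its stage-matched control, for each measure
    and endpoint. A single CT series set serves as comparator for multiple
    ablation stages (control reuse); rate fits start at the treated group's
    ablation day so both groups cover the same post-ablation window."""
    rows = []
    present = set(tidy["condition"].unique()) if len(tidy) else set()
    for prefix in ("AE", "BE"):
        for stage in STAGES:
            treated, control = f"{prefix}{stage}", f"CT{stage}"
            if treated not in present or control not in present:
                continue
            abl = stage_table.loc[
                stage_table["condition"] == treated, "ablation_day"
            ].dropna()
            start_day = int(abl.median()) if len(abl) else 0
            for measure in ("blade_area", "n_cells", "blade_lwr"):
                for endpoint in ("day6", "rate"):
                    try:
                        cmp_, _ = compare_conditions(
                            tidy, measure, endpoint, treated, control,
                            endpoint_day=run.endpoint_day, alpha=run.alpha,
                            start_day=start_day if endpoint == "rate" else 0,
                        )
                    except ValueError as exc:
                        log.warning("%s vs %s %s/%s skipped: %s", treated,
                                    control, measure, endpoint, exc)
                        continue
                    rows.append(
                        dict(treated=treated, control=control, measure=measure,
                             endpoint=endpoint, test=cmp_.test,
                             statistic=cmp_.statistic, p_value=cmp_.p_value,
                             alternative=cmp_.alternative, n_treated=cmp_.n_a,
                             n_control=cmp_.n_b,
                             significant=cmp_.significant)
                    )
    return pd.DataFrame(rows)


def run_analyze(input_dir: Path, run: RunConfig) -> dict[str, pd.DataFrame]:
    """Analyze a directory of segmentation SVGs; write all tables to
    ``run.out_dir`` and return them."""
    all_series = load_series_dir(input_dir, run.calibration)
    tables = analyze_series(all_series, run)
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        _write_csv(df, out / f"{name}.csv", run.seed)
    _write_metadata(out, run, mode="analyze")
    return tables


def run_end_to_end(run: RunConfig) -> dict[str, pd.DataFrame]:
    """simulate into ``out_dir/fixtures`` then analyze into ``out_dir``."""
    fixtures = Path(run.out_dir) / "fixtures"
    sim_run = dataclasses.replace(run, out_dir=fixtures)
    run_simulate(sim_run)
    return run_analyze(fixtures, run)
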