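"""End-to-end orchestration: simulate -> segment -> track -> fit -> summarize.

Positions are processed one at a time so a full 49-position experiment never
holds more than one position's stack in memory.  A single root seed fans out
to per-stage child seeds through ``numpy.random.SeedSequence`` with fixed
keys, so each stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baranyi import FitResult, fit_baranyi
from .config import AnalysisConfig
from .io import TimelapseDataset, save_timelapse, write_results
from .segmentation import measure_objects, pi_positive_pixels, segment_brightfield
from .simulate import FateRecord, PositionRenderer, SimulationParams, sample_population
from .stats import SpatialDeathTest, dead_cell_spatial_test, summarize_condition
from .tracking import (Founder, Lineage, build_growth_series, classify_founders,
                       link_frames, register_founders)

__all__ = ["PositionResult", "RunManifest", "analyze_position",
           "analyze_dataset", "simulate_and_analyze", "run_all"]


@dataclass
class PositionResult:
    position: str
    founders: list[Founder]
    lineages: list[Lineage]
    classifications: list
    fits: dict[int, FitResult]
    spatial_tests: list[SpatialDeathTest] = field(default_factory=list)


def analyze_position(bf_stack, pi_stack, frame_times, config: AnalysisConfig,
                     position: str = "", seed: int | None = None) -> PositionResult:
    """Run segmentation, tracking, classification, fitting and the dead-cell
    spatial test for one imaging position."""
    masks = [segment_brightfield(f, config) for f in bf_stack]
    measures_t0 = measure_objects(masks[0], pi_stack[0], config)
    founders = register_founders(masks[0], measures_t0)
    if not founders:
        return PositionResult(position, [], [], [], {})
    lineages = link_frames(masks, founders=founders)
    classifications = classify_founders(lineages, founders, config)
    fits: dict[int, FitResult] = {}
    for lin in lineages:
        series = build_growth_series(lin, np.asarray(frame_times))
        fits[lin.founder_id] = fit_baranyi(series, config.fit)

    # dead-cell spatial analysis on the final frame
    spatial: list[SpatialDeathTest] = []
    final_mask, final_pi = masks[-1], pi_stack[-1]
    if final_mask.max() > 0:
        from scipy import ndimage as ndi
        dead = pi_positive_pixels(np.asarray(final_pi, dtype=float), k=config.pi_k,
                                  background=final_mask == 0)
        dead &= final_mask > 0
        spot_lbl, n_spots = ndi.label(dead, structure=np.ones((3, 3)))
        if n_spots:
            # drop 1-2 px specks (shot noise); rendered dead cells are larger
            sizes = np.bincount(spot_lbl.ravel())
            small = np.flatnonzero(sizes < 3)
            spot_lbl[np.isin(spot_lbl, small)] = 0
            labs = np.unique(spot_lbl)
            labs = labs[labs > 0]
            centroids = ndi.center_of_mass(dead, spot_lbl, labs) if len(labs) else []
            by_colony: dict[int, list] = {}
            for cen in centroids:
                lab = int(final_mask[int(round(cen[0])), int(round(cen[1]))])
                if lab > 0:
                    by_colony.setdefault(lab, []).append(cen)
            rng = np.random.default_rng(seed)
            for lab, cents in sorted(by_colony.items()):
                if len(cents) < config.stats.spatial_min_dead:
                    continue
                sub_seed = int(rng.integers(0, 2**31 - 1))
                spatial.append(dead_cell_spatial_test(
                    final_mask == lab, np.asarray(cents),
                    B=config.stats.mc_replicates, seed=sub_seed))
    return PositionResult(position, founders, lineages, classifications, fits,
                          spatial)


def _founder_table(results: list[PositionResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        cls = {c.founder_id: c for c in res.classifications}
        for f in res.founders:
            c = cls[f.founder_id]
            lin = next(l for l in res.lineages if l.founder_id == f.founder_id)
            fit = res.fits.get(f.founder_id)
            p = fit.params if fit is not None and fit.params is not None else None
            rows.append({
                "founder_id": f"{res.position}:{f.founder_id}",
                "position": res.position,
                "centroid_row": f.centroid[0],
                "centroid_col": f.centroid[1],
                "area_t0": f.area_t0,
                "label_class": c.label_class,
                "pi_positive_t0": f.pi_positive_t0,
                "max_area_ratio": c.max_area_ratio,
                "censored": lin.censored_at_frame is not None,
                "fittable": bool(fit.fittable) if fit is not None else False,
                "lag_h": p.lag if p is not None else np.nan,
                "mu_max": p.mu_max if p is not None else np.nan,
                "y0": p.y0 if p is not None else np.nan,
                "ymax": p.ymax if p is not None else np.nan,
                "h0": p.h0 if p is not None else np.nan,
                "rmse": fit.rmse if fit is not None else np.nan,
                "n_points": fit.n_points if fit is not None else 0,
            })
    return pd.DataFrame(rows)


def _merge_results(results: list[PositionResult], config: AnalysisConfig,
                   condition: str, cfu_table=None, seed: int | None = None):
    """Pool per-position results into (summary, founder table)."""
    all_cls, all_fits, all_spatial = [], {}, []
    offset = 0
    for res in results:
        for c in res.classifications:
            all_cls.append(type(c)(founder_id=c.founder_id + offset,
                                   label_class=c.label_class,
                                   pi_positive_t0=c.pi_positive_t0,
                                   max_area_ratio=c.max_area_ratio))
        for fid, fit in res.fits.items():
            all_fits[fid + offset] = fit
        all_spatial.extend(res.spatial_tests)
        offset += len(res.founders)
    summary = summarize_condition(all_cls, all_fits, config, cfu_table=cfu_table,
                                  spatial_tests=all_spatial, condition=condition,
                                  seed=seed)
    return summary, _founder_table(results)


def analyze_dataset(dataset: TimelapseDataset, config: AnalysisConfig,
                    condition: str = "", cfu_table=None):
    """Analyze a loaded experiment; returns (ConditionSummary, founder table)."""
    results = []
    ss = np.random.SeedSequence([config.seed, 2])
    seeds = ss.generate_state(len(dataset.positions))
    for pos, pos_seed in zip(dataset.positions, seeds):
        bf = [f for f in dataset.stack(pos, "brightfield") if f is not None]
        pi = [f for f in dataset.stack(pos, "pi") if f is not None]
        if not bf:
            continue
        results.append(analyze_position(bf, pi, dataset.frame_times[: len(bf)],
                                        config, position=pos, seed=int(pos_seed)))
    return _merge_results(results, config, condition, cfu_table,
                          seed=int(ss.generate_state(1)[0]) % 2**31)


def simulate_and_analyze(params: SimulationParams, config: AnalysisConfig,
                         condition: str = "", cfu_table=None):
    """Simulate and analyze an experiment position-by-position (streaming).

    Returns (summary, founder_table, fate_records).  Frames are rendered,
    analyzed and discarded one position at a time, so memory stays flat
    regardless of grid size.
    """
    records = sample_population(params)
    times = params.frame_times
    by_pos: dict[str, list[FateRecord]] = {p: [] for p in params.position_ids()}
    for rec in records:
        by_pos[rec.position].append(rec)
    results = []
    ss = np.random.SeedSequence([config.seed, 2])
    pos_seeds = ss.generate_state(params.n_positions)
    for p_idx, pos in enumerate(params.position_ids()):
        if not by_pos[pos]:
            continue
        rend = PositionRenderer(by_pos[pos], params)
        bf, pi = [], []
        for t_idx, t in enumerate(times):
            sbf = np.random.SeedSequence([params.seed, 1 + p_idx, t_idx, 0])
            spi = np.random.SeedSequence([params.seed, 1 + p_idx, t_idx, 1])
            bf.append(rend.render(float(t), "brightfield", seed=sbf.generate_state(1)[0])[0])
            pi.append(rend.render(float(t), "pi", seed=spi.generate_state(1)[0])[0])
        results.append(analyze_position(bf, pi, times, config, position=pos,
                                        seed=int(pos_seeds[p_idx])))
    summary, table = _merge_results(results, config, condition, cfu_table,
                                    seed=int(ss.generate_state(1)[0]) % 2**31)
    return summary, table, records


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stage_timings: dict[str, float]
    outputs: dict[str, str]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _config_hash(params: SimulationParams, config: AnalysisConfig) -> str:
    blob = json.dumps({"sim": params.model_dump(), "analysis": config.model_dump()},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(params: SimulationParams, config: AnalysisConfig, out_dir: str | Path,
            condition: str = "run", save_images: bool = False,
            cfu_table=None) -> RunManifest:
    """Run the full pipeline and write every artifact under ``out_dir``.

    Artifacts: ``truth.json`` (simulator ground truth), ``founders.csv``,
    ``summary.json``, ``manifest.json`` and, when ``save_images`` is set,
    the rendered TIFF stacks.  Identical (params, config) reproduce every
    artifact bit-for-bit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}

    t0 = time.perf_counter()
    if save_images:
        from .simulate import simulate_experiment
        dataset, records = simulate_experiment(params)
        save_timelapse(dataset, out / "images")
        outputs["images"] = str(out / "images")
        timings["simulate"] = time.perf_counter() - t0
        t0 = time.perf_counter()
        summary, table = analyze_dataset(dataset, config, condition=condition,
                                         cfu_table=cfu_table)
        timings["analyze"] = time.perf_counter() - t0
    else:
        summary, table, records = simulate_and_analyze(
            params, config, condition=condition, cfu_table=cfu_table)
        timings["simulate_and_analyze"] = time.perf_counter() - t0

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps([r.to_dict() for r in records],
                                     indent=1, sort_keys=True))
    outputs["truth"] = str(truth_path)
    paths = write_results(table, summary.to_dict(), out)
    outputs.update({k: str(v) for k, v in paths.items()})

    manifest = RunManifest(
        config_hash=_config_hash(params, config),
        seed=params.seed,
        version=__version__,
        stage_timings=timings,
        outputs=outputs,
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=1, sort_keys=True))
    return manifest
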