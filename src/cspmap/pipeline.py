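"""End-to-end orchestration: simulate -> transfer -> track -> csp -> fit -> map.

A run is fully described by a :class:`RunConfig`; everything it produces
lands in one output directory with a machine-readable ``summary.json``
(pooled K_D, significant residues, every parameter and the seed), so two
runs with the same config are identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from cspmap.defaults import (
    ALPHA_N,
    MAX_STEP_PPM,
    NOISE_SIGMA_PPM,
    OVERLAP_TOL_PPM,
    TRANSFER_TOL_PPM,
)
from cspmap.fitting import FitError, fit_global, select_reporters
from cspmap.peaklists import (
    PeakList,
    TitrationSeries,
    read_peak_list,
    transfer_assignments,
    write_csp_table,
    write_peak_list,
)
from cspmap.stats import csp_table_from_tracks
from cspmap.synth import default_scenario, simulate_titration
from cspmap.tracking import flag_overlap, track_series
from cspmap.structure import paint_csp, read_structure

log = logging.getLogger("cspmap")

__all__ = ["RunConfig", "run_pipeline", "run_recovery", "load_series"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; flags override config-file values."""

    out_dir: str
    scenario: str | None = None  # synthetic scenario name, or None
    peak_list_paths: tuple[str, ...] = ()  # measured input instead of scenario
    kd: float | None = None  # mM, scenario override
    final_ratio: float | None = None
    n_binders: int | None = None
    noise_sigma: float = NOISE_SIGMA_PPM
    decoy_count: int = 20
    alpha: float = ALPHA_N
    max_step: float = MAX_STEP_PPM
    overlap_tol: float = OVERLAP_TOL_PPM
    transfer_tol: float = TRANSFER_TOL_PPM
    rule: str = "ksigma"
    fit_mode: str = "per_residue_average"
    structure_path: str | None = None
    chain: str = "B"
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha", "max_step", "overlap_tol", "transfer_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.scenario is None and not self.peak_list_paths:
            raise ValueError("either a scenario or peak-list paths are required")


def load_series(paths: list[str | Path]) -> TitrationSeries:
    """Read per-point peak-list files (metadata in their headers)."""
    points = [read_peak_list(p) for p in paths]
    points.sort(key=lambda pl: pl.point_index)
    return TitrationSeries(points=tuple(points))


class StageError(RuntimeError):
    """Pipeline stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _stage(name, fn, *args, **kwargs):
    log.info("stage=%s start", name)
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(name, str(exc)) from exc
    log.info("stage=%s done", name)
    return result


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages; returns the output directory.

    Synthetic runs also write the per-point peak lists and the ground truth.
    The map stage is skipped when no structure is given.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.scenario is not None:
        truth = _stage(
            "simulate",
            default_scenario,
            config.scenario,
            seed=config.seed,
            kd=config.kd,
            final_ratio=config.final_ratio,
            n_binders=config.n_binders,
            noise_sigma=config.noise_sigma,
            decoy_count=config.decoy_count,
            alpha=config.alpha,
        )
        series = _stage("simulate", simulate_titration, truth, alpha=config.alpha)
        truth.to_json(out / "ground_truth.json")
        for pl in series.points:
            write_peak_list(pl, out / f"point_{pl.point_index:02d}.list")
        reference = truth.assignment_table().to_peak_list(truth.model.protein_total)
    else:
        series = _stage("load", load_series, list(config.peak_list_paths))
        reference = series.points[0]  # measured apo list must carry assignments

    apo = _stage(
        "transfer",
        transfer_assignments,
        reference,
        series.points[0],
        alpha=config.alpha,
        tol=config.transfer_tol,
    )
    series = TitrationSeries(points=(apo,) + series.points[1:])

    tracks = _stage("track", track_series, series, alpha=config.alpha, max_step=config.max_step)
    tracks = _stage(
        "track", flag_overlap, series, tracks, alpha=config.alpha, overlap_tol=config.overlap_tol
    )

    unassigned = truth.missing_residues if truth is not None else ()
    table = _stage(
        "csp",
        csp_table_from_tracks,
        tracks,
        alpha=config.alpha,
        rule=config.rule,
        unassigned=unassigned,
    )
    write_csp_table(table, out / "csp_table.tsv")

    reporters = select_reporters(table, tracks)
    by_res = {tr.residue_number: tr for tr in tracks}
    summary: dict = {
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "csp_mean_ppm": table.mean,
        "csp_sigma_ppm": table.sigma,
        "rule": table.rule,
        "significant_1sigma": table.significant("1sigma"),
        "significant_2sigma": table.significant("2sigma"),
        "reporters": reporters,
    }
    try:
        fit = _stage(
            "fit",
            fit_global,
            [by_res[r] for r in reporters],
            series.protein_total,
            series.ligand_schedule,
            mode=config.fit_mode,
            alpha=config.alpha,
        )
        fit.per_residue.to_csv(out / "fit_per_residue.tsv", sep="\t", index=False)
        fit.curve.to_csv(out / "normalized_curve.tsv", sep="\t", index=False)
        summary.update(fit.summary())
    except StageError as exc:
        if not isinstance(exc.__cause__, FitError):
            raise
        summary["fit_error"] = str(exc)

    if config.structure_path:
        model = _stage("map", read_structure, config.structure_path)
        suffix = Path(config.structure_path).suffix or ".pdb"
        _, report = _stage(
            "map", paint_csp, model, table, config.chain, out / f"painted{suffix}"
        )
        (out / "paint_report.txt").write_text("\n".join(report) + "\n", encoding="utf-8")
        summary["painted"] = True
    else:
        summary["painted"] = False

    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=str), encoding="utf-8"
    )
    return out


def run_recovery(
    scenario: str,
    kd: float,
    seeds: range,
    final_ratio: float | None = None,
    n_binders: int | None = None,
    mode: str = "per_residue_average",
    noise_sigma: float = NOISE_SIGMA_PPM,
) -> np.ndarray:
    """Pooled K_D (uM) recovered from one synthetic scenario per seed.

    The in-memory analogue of run_pipeline's simulate->transfer->track->csp->
    fit chain, used by the recovery studies; returns an array of pooled K_D
    means, NaN where a seed yielded too few reporters.
    """
    out = np.full(len(seeds), np.nan)
    for i, seed in enumerate(seeds):
        truth = default_scenario(
            scenario,
            seed=seed,
            kd=kd,
            final_ratio=final_ratio,
            n_binders=n_binders,
            noise_sigma=noise_sigma,
        )
        series = simulate_titration(truth)
        apo = transfer_assignments(
            truth.assignment_table().to_peak_list(truth.model.protein_total),
            series.points[0],
        )
        series = TitrationSeries(points=(apo,) + series.points[1:])
        tracks = track_series(series)
        tracks = flag_overlap(series, tracks)
        table = csp_table_from_tracks(tracks)
        reporters = select_reporters(table, tracks)
        by_res = {tr.residue_number: tr for tr in tracks}
        try:
            fit = fit_global(
                [by_res[r] for r in reporters],
                series.protein_total,
                series.ligand_schedule,
                mode=mode,
            )
        except FitError:
            continue
        out[i] = fit.kd_mean_uM
    return out
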