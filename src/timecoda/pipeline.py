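"""End-to-end orchestration: inputs -> cohort -> model -> reallocation.

A run takes one of three input modes — a ready cohort CSV, a minute-epoch
CSV plus a participant table with pre/post weights, or a synthetic cohort
drawn in-process — then screens covariates, fits the ILR outcome model,
tests the overall composition, and (if the test is significant at alpha,
or forced) builds the reallocation table and figure. Outputs are fully
reproducible from config + seed and every file carries both.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .coda import BEHAVIORS, pivot_basis
from .epochs import process_epochs
from .reallocation import (
    CompositionNotSignificantError,
    ReallocationGrid,
    build_reallocation_table,
    format_reallocation_table,
    plot_reallocation_grid,
    reference_point,
)
from .regression import (
    DEFAULT_CANDIDATES,
    fit_coda_model,
    percent_total_weight_loss,
)
from .synthetic import CohortSimConfig, simulate_cohort

log = logging.getLogger("timecoda")


class PipelineError(RuntimeError):
    """Validation failure that aborts a run (e.g. too few participants)."""


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""
    cohort_csv: str | None = None
    epoch_csv: str | None = None
    participants_csv: str | None = None
    simulate: dict | None = None        # CohortSimConfig overrides
    pivot: str = "sleep"
    screening_alpha: float = 0.05
    alpha: float = 0.05
    grid_deltas: tuple = (-60, -45, -30, -15, 15, 30, 45, 60)
    min_wear_hours: float = 16.0
    min_valid_days: int = 4
    zero_replacement: float = 0.5
    force_reallocation: bool = False
    make_figure: bool = True
    seed: int = 0
    out_dir: str = "timecoda_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = io.load_config(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.grid_deltas, list):
            cfg.grid_deltas = tuple(cfg.grid_deltas)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def analysis_dict(self) -> dict:
        """Config fields that determine the numbers (paths of record stay;
        the output destination does not)."""
        d = self.to_dict()
        d.pop("out_dir")
        d.pop("make_figure")
        return d


@dataclass
class RunResult:
    cohort: pd.DataFrame
    model: object
    reference: np.ndarray
    table: pd.DataFrame | None
    reallocation_skipped: bool
    summary: dict
    out_dir: Path | None = None


def _assemble_cohort(config: RunConfig) -> pd.DataFrame:
    """Resolve the input mode into a cohort table with twl_pct."""
    if config.cohort_csv:
        cohort = io.read_table(config.cohort_csv)
        if "twl_pct" not in cohort.columns:
            cohort["twl_pct"] = percent_total_weight_loss(
                cohort["pre_kg"], cohort["post_kg"])
        return cohort
    if config.epoch_csv:
        if not config.participants_csv:
            raise PipelineError(
                "epoch input requires a participants_csv with weights")
        epochs = io.read_epochs(config.epoch_csv)
        participants, exclusions = process_epochs(
            epochs, config.min_wear_hours, config.min_valid_days,
            config.zero_replacement)
        for line in exclusions:
            log.warning("exclusion: %s", line)
        meta = io.read_table(config.participants_csv)
        cohort = participants.merge(meta, on="participant_id", how="inner")
        cohort["twl_pct"] = percent_total_weight_loss(
            cohort["pre_kg"], cohort["post_kg"])
        return cohort
    sim_kwargs = dict(config.simulate or {})
    sim_kwargs.setdefault("seed", config.seed)
    sim = CohortSimConfig(**sim_kwargs)
    return simulate_cohort(sim)


def run_full(config: RunConfig, write_outputs: bool = True) -> RunResult:
    """Execute the whole pipeline and (optionally) write the report bundle."""
    cohort = _assemble_cohort(config)
    n = len(cohort)
    log.info("cohort assembled: %d participants enter the model", n)
    if n < 4:
        raise PipelineError(
            f"only {n} valid participants after filtering; need >= 4")

    basis = pivot_basis(config.pivot)
    candidates = [c for c in DEFAULT_CANDIDATES if c in cohort.columns]
    model = fit_coda_model(cohort, basis, alpha=config.screening_alpha,
                           candidates=candidates)
    reference, cov_means = reference_point(cohort)

    table = None
    skipped = False
    try:
        table = build_reallocation_table(
            model.fit, reference, ReallocationGrid(tuple(config.grid_deltas)),
            alpha=config.alpha, composition_p=model.test.p_value,
            force=config.force_reallocation)
    except CompositionNotSignificantError as exc:
        skipped = True
        log.warning("%s", exc)

    summary = {
        "seed": config.seed,
        "config_hash": io.config_hash(config.analysis_dict()),
        "n_participants": n,
        "mean_minutes": {f"{b}_min": float(cohort[f"{b}_min"].mean())
                         for b in BEHAVIORS},
        "reference_composition": {b: float(v) for b, v in
                                  zip(BEHAVIORS, reference)},
        "mean_twl_pct": float(cohort["twl_pct"].mean()),
        "sd_twl_pct": float(cohort["twl_pct"].std(ddof=1)),
        "retained_covariates": model.retained_covariates,
        "f_stat": model.test.f_stat,
        "df": [model.test.df_num, model.test.df_den],
        "p_value": model.test.p_value,
        "reallocation_skipped": skipped,
    }
    if table is not None:
        sig = table["feasible"] & ((table["ci_low"] > 0) | (table["ci_high"] < 0))
        summary["n_feasible_cells"] = int(table["feasible"].sum())
        summary["n_significant_cells"] = int(sig.sum())

    result = RunResult(cohort=cohort, model=model, reference=reference,
                       table=table, reallocation_skipped=skipped,
                       summary=summary)
    if write_outputs:
        result.out_dir = _write_bundle(config, result)
    return result


def _render_report(config: RunConfig, result: RunResult) -> str:
    s = result.summary
    lines = [
        "timecoda run report",
        f"seed={s['seed']} config={s['config_hash']}",
        f"n = {s['n_participants']} participants",
        "mean daily minutes: " + ", ".join(
            f"{b}={s['mean_minutes'][f'{b}_min']:.1f}" for b in BEHAVIORS),
        f"mean %TWL = {s['mean_twl_pct']:.1f} (SD {s['sd_twl_pct']:.1f})",
        f"retained covariates: {s['retained_covariates'] or 'none'}",
        f"composition test: F({s['df'][0]}, {s['df'][1]}) = "
        f"{s['f_stat']:.2f}, p = {s['p_value']:.3f}",
    ]
    if result.reallocation_skipped:
        lines.append("reallocation stage skipped: overall composition not "
                     f"significant at alpha = {config.alpha:g}")
    elif result.table is not None:
        lines.append("")
        lines.append(format_reallocation_table(result.table))
    return "\n".join(lines) + "\n"


def _write_bundle(config: RunConfig, result: RunResult) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = result.summary["config_hash"]
    io.write_table(result.cohort, out / "cohort.csv",
                   seed=config.seed, cfg_hash=h)
    io.write_table(result.model.fit.summary_frame().reset_index(names="term"),
                   out / "model_summary.csv", seed=config.seed, cfg_hash=h)
    if result.table is not None:
        io.write_table(result.table, out / "reallocation_long.csv",
                       seed=config.seed, cfg_hash=h)
        (out / "reallocation_table.txt").write_text(
            f"# seed={config.seed} config={h}\n"
            + format_reallocation_table(result.table))
        if config.make_figure:
            plot_reallocation_grid(result.table,
                                   out / "reallocation_grid.png")
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2))
    (out / "report.txt").write_text(_render_report(config, result))
    io.save_config(config.to_dict(), out / "run_config.yaml")
    return out
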