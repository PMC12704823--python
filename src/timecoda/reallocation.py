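"""Isotemporal reallocation: estimated %TWL change for time shifts.

Given a fitted composition model, the estimated outcome difference for
moving ``delta`` minutes from one behavior to another — holding the other
two behaviors and the 1440-min day constant — is the contrast
``d' beta_comp`` where ``d`` is the difference in ILR coordinates between
the reallocated and the reference composition and ``beta_comp`` the ILR
coefficient block. Covariate terms cancel in the difference; the variance
is ``d' Sigma_comp d`` and the confidence interval uses the t distribution
on the fit's residual df. The reference composition is the cohort's
geometric-mean (compositional mean) time use.

The default grid spans -60 to +60 min in 15-min steps over all 12 ordered
behavior pairs; a reallocation is infeasible when it would exhaust the
displaced behavior (e.g. taking 45 min from a 42.6-min MVPA reference),
and such cells are rendered as dashes in the wide table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coda import (
    BEHAVIORS,
    InfeasibleReallocationError,
    geometric_mean_composition,
    ilr,
    reallocate,
)
from .regression import PART_COLUMNS, CodaFit


class CompositionNotSignificantError(RuntimeError):
    """Raised when the reallocation stage is gated off by the F-test."""


@dataclass(frozen=True)
class ReallocationGrid:
    """Deltas (minutes) and the 12 ordered behavior pairs to evaluate."""
    deltas: tuple = (-60, -45, -30, -15, 15, 30, 45, 60)

    def __post_init__(self) -> None:
        d = np.asarray(self.deltas, dtype=float)
        if d.size == 0 or np.any(d == 0):
            raise ValueError("grid deltas must be non-zero")
        if not np.allclose(np.sort(d), np.sort(-d)):
            raise ValueError("grid deltas must be symmetric about 0")

    @property
    def pairs(self):
        return [(a, b) for a in BEHAVIORS for b in BEHAVIORS if a != b]


@dataclass(frozen=True)
class ReallocationEstimate:
    frm: str
    to: str
    delta: float
    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    se: float | None
    feasible: bool


def reference_point(cohort: pd.DataFrame):
    """Cohort-representative prediction point.

    Returns ``(composition, covariate_means)``: the geometric-mean
    composition (equivalently the ILR-inverse of the mean ILR coordinates)
    and the sample means of the numeric covariates with observed
    proportions for categorical ones. Only the composition enters the
    reallocation contrasts — covariates cancel in differences — but the
    point is reported for completeness.
    """
    comps = cohort[PART_COLUMNS].to_numpy(dtype=float)
    ref = geometric_mean_composition(comps)
    cov_means = {}
    for col in cohort.columns:
        if col in PART_COLUMNS or col in ("participant_id", "twl_pct"):
            continue
        s = cohort[col]
        if pd.api.types.is_numeric_dtype(s):
            cov_means[col] = float(s.mean())
        else:
            cov_means[col] = s.value_counts(normalize=True).to_dict()
    return ref, cov_means


def estimate_reallocation(fit: CodaFit, reference, frm: str, to: str,
                          delta: float,
                          alpha: float = 0.05) -> ReallocationEstimate:
    """Point estimate and CI for one (from, to, delta) reallocation."""
    if fit.basis is None or not fit.ilr_terms:
        raise ValueError("fit must carry its ILR basis and term names")
    ref = np.asarray(reference, dtype=float)
    if delta == 0:
        if frm == to:
            raise ValueError("source and destination behaviors must differ")
        return ReallocationEstimate(frm, to, 0.0, 0.0, 0.0, 0.0, 0.0, True)
    try:
        new = reallocate(ref, frm, to, delta)
    except InfeasibleReallocationError:
        return ReallocationEstimate(frm, to, float(delta),
                                    None, None, None, None, False)
    d = ilr(new, fit.basis) - ilr(ref, fit.basis)
    beta = fit.params[fit.ilr_terms].to_numpy()
    sigma = fit.cov.loc[fit.ilr_terms, fit.ilr_terms].to_numpy()
    est = float(d @ beta)
    se = float(np.sqrt(d @ sigma @ d))
    tcrit = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    return ReallocationEstimate(frm, to, float(delta), est,
                                est - tcrit * se, est + tcrit * se,
                                se, True)


def build_reallocation_table(fit: CodaFit, reference,
                             grid: ReallocationGrid | None = None,
                             alpha: float = 0.05,
                             composition_p: float | None = None,
                             force: bool = False) -> pd.DataFrame:
    """All pairs x deltas as a long table (one row per cell).

    When ``composition_p`` is supplied the stage is gated: estimates are
    only produced if the overall composition test is significant at
    ``alpha`` (pass ``force=True`` to override, e.g. in simulation
    studies). Columns: ``from, to, delta_min, estimate_pct_twl, ci_low,
    ci_high, feasible``.
    """
    if (composition_p is not None and composition_p >= alpha and not force):
        raise CompositionNotSignificantError(
            f"overall composition p = {composition_p:.3f} >= {alpha:g}; "
            "reallocation stage skipped (use force=True to override)")
    grid = grid or ReallocationGrid()
    rows = []
    for frm, to in grid.pairs:
        for delta in grid.deltas:
            e = estimate_reallocation(fit, reference, frm, to, delta, alpha)
            rows.append({"from": frm, "to": to, "delta_min": e.delta,
                         "estimate_pct_twl": e.estimate,
                         "ci_low": e.ci_low, "ci_high": e.ci_high,
                         "feasible": e.feasible})
    return pd.DataFrame(rows)


def format_reallocation_table(table: pd.DataFrame) -> str:
    """Wide text rendering grouped by |delta|, dashes for infeasible cells.

    Rows are the behavior time is displaced from, columns the behavior it
    is reallocated to, matching the published layout for positive shifts.
    """
    lines = []
    mags = sorted({abs(d) for d in table["delta_min"]})
    width = 22
    for mag in mags:
        lines.append(f"Reallocation of {mag:g} min "
                     f"(rows: displaced from; columns: reallocated to)")
        header = "".ljust(8) + "".join(b.upper().ljust(width)
                                       for b in BEHAVIORS)
        lines.append(header)
        for frm in BEHAVIORS:
            cells = []
            for to in BEHAVIORS:
                if frm == to:
                    cells.append("NA".ljust(width))
                    continue
                row = table[(table["from"] == frm) & (table["to"] == to)
                            & (table["delta_min"] == mag)].iloc[0]
                if not row["feasible"]:
                    cells.append("-".ljust(width))
                else:
                    cells.append((f"{row['estimate_pct_twl']:.2f} "
                                  f"({row['ci_low']:.2f}, "
                                  f"{row['ci_high']:.2f})").ljust(width))
            lines.append(frm.upper().ljust(8) + "".join(cells))
        lines.append("")
    lines.append("- : magnitude of time reallocation exceeds the time "
                 "available in the displaced behavior")
    return "\n".join(lines)


def plot_reallocation_grid(table: pd.DataFrame, path):
    """4x4 panel figure: estimate vs delta with 95% CI band per pair.

    Rows index the behavior displaced (from), columns the behavior
    increased (to); diagonal panels are blank. Deterministic: identical
    tables render byte-identical files.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if table.empty:
        missing = [(a, b) for a in BEHAVIORS for b in BEHAVIORS if a != b]
        raise ValueError(f"reallocation table is empty; missing pairs: "
                         f"{missing}")

    fig, axes = plt.subplots(4, 4, figsize=(11, 9), sharex=True)
    for i, frm in enumerate(BEHAVIORS):
        for j, to in enumerate(BEHAVIORS):
            ax = axes[i, j]
            if frm == to:
                ax.axis("off")
                continue
            sub = table[(table["from"] == frm) & (table["to"] == to)
                        & table["feasible"]].sort_values("delta_min")
            ax.axhline(0.0, color="0.7", lw=0.8)
            if not sub.empty:
                ax.fill_between(sub["delta_min"], sub["ci_low"],
                                sub["ci_high"], alpha=0.25)
                ax.plot(sub["delta_min"], sub["estimate_pct_twl"],
                        marker="o", ms=3)
            if i == 0:
                ax.set_title(f"to {to.upper()}", fontsize=9)
            if j == 3 or (j == 2 and i == 3):
                ax.yaxis.set_label_position("right")
            if j == 0:
                ax.set_ylabel("Δ %TWL", fontsize=8)
            ax.tick_params(labelsize=7)
        axes[i, 3 if frm != BEHAVIORS[3] else 2].text(
            1.12, 0.5, f"from {frm.upper()}", rotation=270, fontsize=9,
            transform=axes[i, 3 if frm != BEHAVIORS[3] else 2].transAxes,
            va="center")
    for ax in axes[3, :]:
        ax.set_xlabel("reallocated minutes", fontsize=8)
    fig.suptitle("Estimated change in 6-month %TWL per time reallocation")
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": None})
    plt.close(fig)
    return path
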