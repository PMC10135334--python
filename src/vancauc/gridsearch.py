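"""Sampling-time grid search and evaluation reports.

For every cohort, model and candidate (C1-time, C2-time) pair, pairs the
two-point AUC estimate with the noncompartmental reference per subject,
computes the agreement panel, flags cells whose absolute percent mean
difference is strictly below the acceptability threshold (default 5%),
intersects acceptable sampling windows across cohorts, pools per-subject
pairs over the intersection, and writes tabular reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import nca, sparse_auc
from .agreement import AgreementSummary, summarize
from .simcohort import ConcProfile

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateTimes",
    "EvaluationConfig",
    "GridCell",
    "WindowIntersection",
    "SelectionReport",
    "evaluate_cell",
    "run_grid",
    "select_and_intersect",
    "pooled_regression",
    "report",
]

ADULT_CANDIDATES_MIN = ((0, 10, 20, 40, 60, 90, 120), (240,))
PEDIATRIC_CANDIDATES_MIN = ((0, 15, 30, 60, 120, 180, 240), (240, 300))


@dataclass(frozen=True)
class CandidateTimes:
    """Candidate C1/C2 offsets (minutes after end of infusion) for one cohort."""

    c1_min: tuple[float, ...]
    c2_min: tuple[float, ...]

    def pairs(self) -> list[tuple[float, float]]:
        return [(t1, t2) for t2 in self.c2_min for t1 in self.c1_min if t1 < t2]


DEFAULT_CANDIDATES = {
    "adult": CandidateTimes(*ADULT_CANDIDATES_MIN),
    "pediatric": CandidateTimes(*PEDIATRIC_CANDIDATES_MIN),
}


@dataclass(frozen=True)
class EvaluationConfig:
    threshold_pct: float = 5.0
    models: tuple[str, ...] = ("model1", "model2")
    candidates: Mapping[str, CandidateTimes] = field(
        default_factory=lambda: dict(DEFAULT_CANDIDATES)
    )
    n_lambda_points: int = 3
    auc_mode: str = "inf"

    def __post_init__(self) -> None:
        if not self.threshold_pct > 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class GridCell:
    """One (cohort, model, t1, t2) evaluation: agreement panel + per-subject pairs."""

    cohort: str
    model: str
    t1_min: float
    t2_min: float
    n_used: int
    n_excluded: int
    summary: AgreementSummary
    acceptable: bool
    data: pd.DataFrame  # subject_id, ref_auc, est_auc, ke, cl, vd, t_half


def _is_acceptable(pct_mean_diff: float, threshold: float) -> bool:
    # strict inequality: a bias of exactly the threshold is not acceptable
    return abs(pct_mean_diff) < threshold


def evaluate_cell(
    profiles: Sequence[ConcProfile],
    nca_results: Mapping[str, nca.NcaResult],
    model: str,
    t1_min: float,
    t2_min: float,
    threshold: float = 5.0,
    cohort: str = "",
) -> GridCell:
    """Evaluate one sampling-time pair for one model across a cohort.

    Subjects whose (C1, C2) pair does not decline are excluded from the cell
    and counted; fewer than 3 usable subjects is an error.
    """
    rows = []
    n_excluded = 0
    for p in profiles:
        try:
            obs = sparse_auc.two_point_from_profile(p, t1_min, t2_min)
        except KeyError as e:
            raise KeyError(f"time pair ({t1_min}, {t2_min}) min not in schedule") from e
        try:
            est = sparse_auc.estimate(obs, model)
        except sparse_auc.NonDecliningPair:
            n_excluded += 1
            continue
        ref = nca_results.get(p.subject_id)
        if ref is None:  # subject had no usable reference terminal phase
            n_excluded += 1
            continue
        rows.append(
            {
                "subject_id": p.subject_id,
                "ref_auc": ref.auc_ref,
                "est_auc": est.auc_f,
                "ke": est.ke,
                "cl": est.cl,
                "vd": est.vd,
                "t_half": est.t_half,
            }
        )
    if n_excluded:
        logger.info(
            "cell %s/%s t1=%g t2=%g: excluded %d non-declining pair(s)",
            cohort, model, t1_min, t2_min, n_excluded,
        )
    if len(rows) < 3:
        raise ValueError(
            f"cell {model} ({t1_min},{t2_min}) min: only {len(rows)} usable subjects"
        )
    data = pd.DataFrame(rows)
    summary = summarize(data["ref_auc"].to_numpy(), data["est_auc"].to_numpy())
    return GridCell(
        cohort=cohort,
        model=model,
        t1_min=float(t1_min),
        t2_min=float(t2_min),
        n_used=len(rows),
        n_excluded=n_excluded,
        summary=summary,
        acceptable=_is_acceptable(summary.pct_mean_diff, threshold),
        data=data,
    )


def reference_nca(
    profiles: Sequence[ConcProfile], config: EvaluationConfig
) -> dict[str, nca.NcaResult]:
    """Reference NCA per subject, computed once per cohort.

    Subjects whose terminal samples do not decline (possible under assay
    noise) get no reference and are excluded from every cell, with a log line.
    """
    refs: dict[str, nca.NcaResult] = {}
    for p in profiles:
        try:
            refs[p.subject_id] = nca.auc_inf(p, config.n_lambda_points, config.auc_mode)
        except nca.TerminalPhaseError as e:
            logger.warning("subject %s: no usable reference (%s)", p.subject_id, e)
    return refs


def run_grid(
    cohorts: Mapping[str, Sequence[ConcProfile]],
    config: EvaluationConfig | None = None,
) -> list[GridCell]:
    """Evaluate the full model x C1 x C2 grid for every cohort."""
    config = config or EvaluationConfig()
    cells: list[GridCell] = []
    for name, profiles in cohorts.items():
        cand = config.candidates.get(name)
        if cand is None:
            raise KeyError(f"no candidate times configured for cohort {name!r}")
        refs = reference_nca(profiles, config)
        for model in config.models:
            for t1, t2 in cand.pairs():
                cells.append(
                    evaluate_cell(
                        profiles, refs, model, t1, t2, config.threshold_pct, name
                    )
                )
    return cells


@dataclass(frozen=True)
class WindowIntersection:
    """A model's sampling windows acceptable in every cohort."""

    model: str
    t1_window: tuple[float, float]  # (lo, hi) minutes post-infusion
    t2_window: tuple[float, float]
    cells: tuple[GridCell, ...]  # acceptable cells inside the windows


@dataclass(frozen=True)
class SelectionReport:
    acceptable: tuple[GridCell, ...]
    intersections: tuple[WindowIntersection, ...]


def _cohort_window(values: set[float], candidates: Sequence[float]) -> tuple[float, float]:
    """Acceptable-time window for one cohort and axis.

    The window is [min, max] of the acceptable times, opened to +/-inf at an
    end that coincides with the cohort's candidate-set extreme: a cohort
    cannot constrain the window beyond the times it actually tested.
    """
    lo, hi = min(values), max(values)
    if lo == min(candidates):
        lo = -np.inf
    if hi == max(candidates):
        hi = np.inf
    return lo, hi


def select_and_intersect(
    cells: Sequence[GridCell], config: EvaluationConfig | None = None
) -> SelectionReport:
    """Acceptable cells per cohort plus cross-cohort window intersections.

    For each model present in every cohort's acceptable set, intersects the
    per-cohort C1 and C2 windows and clips them to the union candidate grid.
    An empty intersection is a valid result.
    """
    config = config or EvaluationConfig()
    acceptable = tuple(c for c in cells if c.acceptable)
    cohorts = sorted({c.cohort for c in cells})
    intersections = []
    for model in sorted({c.model for c in cells}):
        per_cohort = {
            name: [c for c in acceptable if c.model == model and c.cohort == name]
            for name in cohorts
        }
        if any(not v for v in per_cohort.values()):
            continue  # model must be acceptable somewhere in every cohort
        t1_lo, t1_hi = -np.inf, np.inf
        t2_lo, t2_hi = -np.inf, np.inf
        for name, acc in per_cohort.items():
            cand = config.candidates[name]
            c1_valid = [t1 for t1, _ in cand.pairs()]
            c2_valid = [t2 for _, t2 in cand.pairs()]
            lo, hi = _cohort_window({c.t1_min for c in acc}, c1_valid)
            t1_lo, t1_hi = max(t1_lo, lo), min(t1_hi, hi)
            lo, hi = _cohort_window({c.t2_min for c in acc}, c2_valid)
            t2_lo, t2_hi = max(t2_lo, lo), min(t2_hi, hi)
        # clip to the union grid of tested times
        union_c1 = sorted({t for n in cohorts for t, _ in config.candidates[n].pairs()})
        union_c2 = sorted({t for n in cohorts for _, t in config.candidates[n].pairs()})
        c1_in = [t for t in union_c1 if t1_lo <= t <= t1_hi]
        c2_in = [t for t in union_c2 if t2_lo <= t <= t2_hi]
        if not c1_in or not c2_in:
            continue
        t1_w = (min(c1_in), max(c1_in))
        t2_w = (min(c2_in), max(c2_in))
        selected = tuple(
            c
            for c in acceptable
            if c.model == model
            and t1_w[0] <= c.t1_min <= t1_w[1]
            and t2_w[0] <= c.t2_min <= t2_w[1]
        )
        if selected:
            intersections.append(
                WindowIntersection(model=model, t1_window=t1_w, t2_window=t2_w, cells=selected)
            )
    return SelectionReport(acceptable=acceptable, intersections=tuple(intersections))


def pooled_regression(cells: Sequence[GridCell]) -> tuple[float, float, float]:
    """OLS and Pearson r on per-subject pairs pooled over selected cells.

    Returns (slope, intercept, r) of est on ref across the pooled data.
    """
    if not cells:
        raise ValueError("no cells to pool")
    ref = np.concatenate([c.data["ref_auc"].to_numpy() for c in cells])
    est = np.concatenate([c.data["est_auc"].to_numpy() for c in cells])
    from .agreement import ols_fit, pearson

    slope, intercept, _ = ols_fit(ref, est)
    r, _ = pearson(ref, est)
    return slope, intercept, r


# ---------------------------------------------------------------------------
# reports

_CELL_COLUMNS = [
    "cohort", "model", "c1_min", "c2_min", "n_used", "n_excluded",
    "mean", "mean_diff", "pct_mean_diff", "sd_diff", "loa_low", "loa_high",
    "pearson_r", "pearson_p", "lin_ccc", "lin_p",
    "ols_slope", "ols_intercept", "ols_r2", "acceptable",
]


def _cell_row(c: GridCell) -> dict:
    s = c.summary
    return {
        "cohort": c.cohort,
        "model": c.model,
        "c1_min": c.t1_min,
        "c2_min": c.t2_min,
        "n_used": c.n_used,
        "n_excluded": c.n_excluded,
        "mean": s.grand_mean,
        "mean_diff": s.mean_diff,
        "pct_mean_diff": s.pct_mean_diff,
        "sd_diff": s.sd_diff,
        "loa_low": s.loa_low,
        "loa_high": s.loa_high,
        "pearson_r": s.pearson_r,
        "pearson_p": s.pearson_p,
        "lin_ccc": s.lin_ccc,
        "lin_p": s.lin_p,
        "ols_slope": s.ols_slope,
        "ols_intercept": s.ols_intercept,
        "ols_r2": s.ols_r2,
        "acceptable": c.acceptable,
    }


def cells_to_frame(cells: Sequence[GridCell]) -> pd.DataFrame:
    return pd.DataFrame([_cell_row(c) for c in cells], columns=_CELL_COLUMNS)


def _pk_summary(
    cells: Sequence[GridCell],
    nca_by_cohort: Mapping[str, Mapping[str, nca.NcaResult]],
) -> pd.DataFrame:
    """Mean +/- SD of AUC, CL, Vd and t1/2: reference and each selected cell."""
    rows = []
    for name, refs in nca_by_cohort.items():
        vals = list(refs.values())
        rows.append(
            {
                "cohort": name,
                "source": "reference",
                "c1_min": np.nan,
                "c2_min": np.nan,
                "auc_mean": np.mean([v.auc_ref for v in vals]),
                "auc_sd": np.std([v.auc_ref for v in vals], ddof=1),
                "cl_mean": np.mean([v.cl_ref for v in vals]),
                "cl_sd": np.std([v.cl_ref for v in vals], ddof=1),
                "vd_mean": np.mean([v.vd_ref for v in vals]),
                "vd_sd": np.std([v.vd_ref for v in vals], ddof=1),
                "t_half_mean": np.mean([v.t_half_ref for v in vals]),
                "t_half_sd": np.std([v.t_half_ref for v in vals], ddof=1),
            }
        )
    for c in cells:
        d = c.data
        rows.append(
            {
                "cohort": c.cohort,
                "source": c.model,
                "c1_min": c.t1_min,
                "c2_min": c.t2_min,
                "auc_mean": d["est_auc"].mean(),
                "auc_sd": d["est_auc"].std(ddof=1),
                "cl_mean": d["cl"].mean(),
                "cl_sd": d["cl"].std(ddof=1),
                "vd_mean": d["vd"].mean(),
                "vd_sd": d["vd"].std(ddof=1),
                "t_half_mean": d["t_half"].mean(),
                "t_half_sd": d["t_half"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


def report(
    cells: Sequence[GridCell],
    selection: SelectionReport,
    outdir: str | Path,
    nca_by_cohort: Mapping[str, Mapping[str, nca.NcaResult]] | None = None,
    plots: bool = False,
) -> dict[str, Path]:
    """Write grid.csv, selected.csv, pk_summary.csv, pooled_regression.txt.

    Optionally renders Bland-Altman plots for the selected cells and a pooled
    regression scatter.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["grid"] = outdir / "grid.csv"
    cells_to_frame(cells).to_csv(paths["grid"], index=False)

    selected_cells = [c for w in selection.intersections for c in w.cells]
    paths["selected"] = outdir / "selected.csv"
    cells_to_frame(selected_cells).to_csv(paths["selected"], index=False)

    paths["pk_summary"] = outdir / "pk_summary.csv"
    _pk_summary(selected_cells, nca_by_cohort or {}).to_csv(
        paths["pk_summary"], index=False
    )

    paths["pooled"] = outdir / "pooled_regression.txt"
    with open(paths["pooled"], "w") as fh:
        if not selection.intersections:
            fh.write("no intersected acceptable sampling windows\n")
        for w in selection.intersections:
            slope, intercept, r = pooled_regression(w.cells)
            fh.write(
                f"model={w.model} C1 window {w.t1_window[0]:g}-{w.t1_window[1]:g} min, "
                f"C2 window {w.t2_window[0]:g}-{w.t2_window[1]:g} min: "
                f"est = {intercept:.3f} + {slope:.3f} * ref, r = {r:.4f}, "
                f"n = {sum(c.n_used for c in w.cells)}\n"
            )

    if plots and selected_cells:
        paths.update(_render_plots(selected_cells, selection, outdir))
    return paths


def _render_plots(
    selected_cells: Sequence[GridCell], selection: SelectionReport, outdir: Path
) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths: dict[str, Path] = {}
    fig, axes = plt.subplots(
        1, len(selected_cells), figsize=(4 * len(selected_cells), 3.5), squeeze=False
    )
    for ax, c in zip(axes[0], selected_cells):
        d = c.data
        mean = (d["ref_auc"] + d["est_auc"]) / 2
        diff = d["est_auc"] - d["ref_auc"]
        s = c.summary
        ax.scatter(mean, diff, s=12)
        for y, ls in ((s.mean_diff, "-"), (s.loa_low, "--"), (s.loa_high, "--")):
            ax.axhline(y, ls=ls, c="gray", lw=0.8)
        ax.set_title(f"{c.cohort} {c.model} {c.t1_min:g}/{c.t2_min:g} min", fontsize=8)
        ax.set_xlabel("mean AUC (mg·h/L)")
        ax.set_ylabel("est − ref")
    fig.tight_layout()
    paths["bland_altman_plot"] = outdir / "bland_altman.png"
    fig.savefig(paths["bland_altman_plot"], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    for w in selection.intersections:
        ref = np.concatenate([c.data["ref_auc"].to_numpy() for c in w.cells])
        est = np.concatenate([c.data["est_auc"].to_numpy() for c in w.cells])
        ax.scatter(ref, est, s=10, label=w.model)
        slope, intercept, r = pooled_regression(w.cells)
        xs = np.linspace(ref.min(), ref.max(), 10)
        ax.plot(xs, intercept + slope * xs, lw=1)
    ax.plot(*(2 * [ax.get_xlim()]), ls=":", c="k", lw=0.8)
    ax.set_xlabel("reference AUC (mg·h/L)")
    ax.set_ylabel("two-point AUC (mg·h/L)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    paths["regression_plot"] = outdir / "pooled_regression.png"
    fig.savefig(paths["regression_plot"], dpi=120)
    plt.close(fig)
    return paths
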