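"""Ordered hazard-ratio series over percentage-of-involved-nodes cutoffs.

For each cutoff t the cohort is dichotomised at ``pct >= t`` ("high"
involvement, with strictly-below as reference) and an adjusted Cox model is
refit with the indicator plus the adjustment covariates; the series of
``exp(beta_indicator)`` values, ordered by t, is the H_t input to the
random-walk stage. Cutoffs with too few events in either arm, a degenerate
design, separation or non-convergence are recorded as skipped with a reason
rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cox_core import fit_cox, hazard_ratio_ci
from .errors import DataIntegrityError, DegenerateDesignError, NumericalError

__all__ = [
    "DEFAULT_ADJUSTMENT",
    "HazardRatioSeries",
    "compute_percentage",
    "sweep_cutoffs",
]

#: Default adjustment set: the registry covariates (area, year, race, marital
#: status, age, histology, grade, hormone receptors, location, size) without
#: any node-count variable.
DEFAULT_ADJUSTMENT: tuple[str, ...] = (
    "area_central",
    "area_west",
    "year_dx",
    "black",
    "married",
    "age_years",
    "ductal",
    "grade_high",
    "er_negative",
    "pr_negative",
    "medial",
    "tumor_size_mm",
)

SERIES_COLUMNS = ("cutoff_pct", "hr", "lo95", "hi95", "n_high", "events_high", "events_low")


def compute_percentage(nodes_positive, nodes_examined):
    """Percentage of involved nodes, ``100 * positive / examined``.

    Accepts scalars or arrays. Raises :class:`DataIntegrityError` when any
    record has more involved nodes than examined, or examined < 1.
    """
    pos = np.asarray(nodes_positive, dtype=float)
    exam = np.asarray(nodes_examined, dtype=float)
    if np.any(exam < 1):
        raise DataIntegrityError("nodes_examined must be >= 1")
    if np.any(pos > exam):
        raise DataIntegrityError("more involved nodes than examined")
    pct = 100.0 * pos / exam
    return float(pct) if pct.ndim == 0 else pct


@dataclass(frozen=True)
class HazardRatioSeries:
    """The ordered (t, H_t) points of one cutoff sweep, plus skipped cutoffs."""

    points: pd.DataFrame  # columns SERIES_COLUMNS, sorted by cutoff_pct
    skipped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["cutoff_pct", "reason"])
    )
    adjustment: tuple[str, ...] = DEFAULT_ADJUSTMENT
    min_events: int = 10

    @property
    def cutoffs(self) -> np.ndarray:
        return self.points["cutoff_pct"].to_numpy()

    @property
    def hr(self) -> np.ndarray:
        return self.points["hr"].to_numpy()

    def __len__(self) -> int:
        return len(self.points)

    def to_csv(self, path, skipped_path=None) -> None:
        self.points.to_csv(path, index=False)
        if skipped_path is not None:
            self.skipped.to_csv(skipped_path, index=False)

    @classmethod
    def from_csv(cls, path, skipped_path=None) -> "HazardRatioSeries":
        points = pd.read_csv(path)
        missing = set(SERIES_COLUMNS) - set(points.columns)
        if missing:
            raise DataIntegrityError(f"series file missing columns: {sorted(missing)}")
        skipped = (
            pd.read_csv(skipped_path)
            if skipped_path is not None and Path(skipped_path).exists()
            else pd.DataFrame(columns=["cutoff_pct", "reason"])
        )
        return cls(points=points, skipped=skipped)


def _candidate_cutoffs(pct: np.ndarray, cutoffs) -> list[int]:
    """Integer cutoffs 1..100, collapsed so each retained t changes the split.

    Dichotomising at t and at t' give the same high/low partition unless some
    observed percentage lies in [min(t,t'), max(t,t')); only the first cutoff
    of each run of identical partitions is kept.
    """
    if cutoffs is None:
        grid = np.arange(1, 101)
    else:
        grid = np.unique(np.asarray(list(cutoffs), dtype=float))
    kept = []
    prev_high = None
    for t in grid:
        n_high = int(np.count_nonzero(pct >= t))
        if prev_high is not None and n_high == prev_high:
            continue
        kept.append(t)
        prev_high = n_high
    return kept


def sweep_cutoffs(
    cohort: pd.DataFrame,
    adjustment=DEFAULT_ADJUSTMENT,
    cutoffs=None,
    min_events: int = 10,
    ties: str = "efron",
    level: float = 0.95,
) -> HazardRatioSeries:
    """Fit the adjusted Cox model at every cutoff of the percentage grid.

    Parameters
    ----------
    cohort
        Patient table with time, event, node counts and the adjustment
        covariates.
    adjustment
        Covariate names entering every model beside the cutoff indicator.
    cutoffs
        Explicit grid, or None for integers 1..100 restricted to splits the
        cohort can distinguish.
    min_events
        Minimum deaths required in each arm for a cutoff to be retained.

    Raises
    ------
    NumericalError
        If no cutoff survives the exclusion rules (no series to model).
    """
    adjustment = tuple(adjustment)
    missing = [c for c in ("time", "event", "nodes_positive", "nodes_examined") + adjustment
               if c not in cohort.columns]
    if missing:
        raise DataIntegrityError(f"cohort missing columns: {missing}")

    pct = compute_percentage(
        cohort["nodes_positive"].to_numpy(), cohort["nodes_examined"].to_numpy()
    )
    times = cohort["time"].to_numpy(dtype=float)
    events = cohort["event"].to_numpy()
    X_adj = cohort[list(adjustment)].to_numpy(dtype=float)

    rows = []
    skipped = []
    beta_warm = None
    for t in _candidate_cutoffs(pct, cutoffs):
        high = (pct >= t).astype(float)
        n_high = int(high.sum())
        ev_high = int(events[high == 1].sum())
        ev_low = int(events[high == 0].sum())
        if n_high == 0 or n_high == len(high):
            skipped.append((t, "no contrast: all patients on one side"))
            beta_warm = None
            continue
        if ev_high < min_events or ev_low < min_events:
            skipped.append((t, f"fewer than {min_events} events in one arm"))
            beta_warm = None
            continue
        X = np.column_stack([high, X_adj])
        try:
            fit = fit_cox(times, events, X, ties=ties, beta_init=beta_warm)
        except DegenerateDesignError:
            skipped.append((t, "degenerate design"))
            beta_warm = None
            continue
        if fit.monotone_flags.any():
            skipped.append((t, "monotone likelihood (separation)"))
            beta_warm = None
            continue
        if not fit.converged:
            skipped.append((t, "did not converge"))
            beta_warm = None
            continue
        ci = hazard_ratio_ci(fit, 0, level)
        rows.append((float(t), ci.hr, ci.lo, ci.hi, n_high, ev_high, ev_low))
        beta_warm = fit.beta
    if not rows:
        raise NumericalError("every cutoff was skipped: no hazard-ratio series to model")

    points = pd.DataFrame(rows, columns=list(SERIES_COLUMNS)).sort_values(
        "cutoff_pct", ignore_index=True
    )
    skipped_df = pd.DataFrame(skipped, columns=["cutoff_pct", "reason"])
    return HazardRatioSeries(
        points=points, skipped=skipped_df, adjustment=adjustment, min_events=min_events
    )
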