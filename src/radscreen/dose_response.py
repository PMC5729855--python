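"""The dose-response screen: condition means, fold changes, linear selection.

The screen asks, per gene and per timepoint, whether expression fold change
(mean normalized count at a dose divided by the mean in the unirradiated
control at the same timepoint) is a linear function of dose in roentgen.
Low-expression fold changes are ignored via a present/absent filter: a fold
change is dropped when both the experimental and the control condition mean
fall below a bottom-quartile cutoff computed per timepoint. A gene is called
linear at a timepoint when at least ``min_doses`` of its fold changes are
defined and the ordinary least-squares fit of fold change on dose has
R^2 strictly greater than ``r2_min`` (default 0.9). Gene sets are compared
across timepoints through their full overlap (Venn) structure; the genes
linear at every timepoint are the dosimeter candidates.

Conventions, stated to make results reproducible:

* the control point (dose 0, fold change 1 by construction) is not a
  regression point unless ``include_control`` is set; including it would
  inflate R^2 with a constant-by-construction observation;
* dose enters the fit on the linear roentgen scale and fold changes as plain
  ratios (no log transform on either axis);
* the bottom-quartile cutoff is the linear-interpolation quantile of the
  per-(gene, condition) mean-expression distribution of the timepoint;
* a fold change whose control mean is zero while the experimental mean
  passes the cutoff is undefined (infinite ratio) and counts as a
  non-passing dose;
* R^2 comparisons are strict (> r2_min), and R^2 is undefined when the fold
  changes have zero variance -- such genes are never selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .counts_io import CountMatrix, DesignError, SampleTable

__all__ = [
    "STATUS_DEFINED",
    "STATUS_ABSENT",
    "STATUS_ZERO_CONTROL",
    "LinearFit",
    "ScreenResult",
    "condition_means",
    "presence_cutoff",
    "presence_cutoffs",
    "fold_change_table",
    "linear_r2",
    "select_linear_genes",
    "overlap_sets",
]

STATUS_DEFINED = "defined"
STATUS_ABSENT = "absent_below_cutoff"
STATUS_ZERO_CONTROL = "undefined_zero_control"


class LinearFit(NamedTuple):
    """OLS fit of fold change on dose for one gene at one timepoint."""

    n_doses_used: int
    slope: float
    intercept: float
    r_squared: float  # NaN when undefined (zero variance or too few points)


@dataclass
class ScreenResult:
    """Selected gene sets per timepoint plus their full overlap structure.

    ``overlaps`` maps every non-empty subset of timepoints to the
    intersection of the corresponding selected sets; ``exclusive`` maps the
    same subsets to the genes selected in exactly those timepoints (the
    Venn regions). ``dose_groups`` is populated by the spike screen only.
    """

    kind: str  # "linear" | "spike"
    label: str  # e.g. "all-doses" | "lowest-dose-excluded"
    selected: dict[int, set[str]]
    records: pd.DataFrame
    overlaps: dict[frozenset, set[str]] = field(default_factory=dict)
    exclusive: dict[frozenset, set[str]] = field(default_factory=dict)
    dose_groups: dict | None = None

    def __post_init__(self) -> None:
        if not self.overlaps:
            self.overlaps, self.exclusive = overlap_sets(self.selected)

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.selected)

    def full_overlap(self) -> set[str]:
        """Genes selected at every timepoint."""
        return set(self.overlaps[frozenset(self.selected)])


def condition_means(counts: CountMatrix, samples: SampleTable) -> pd.DataFrame:
    """Mean expression per (gene, timepoint, dose) over the replicates present.

    Handles unbalanced designs (e.g. a control condition with one failed
    replicate) by averaging whatever replicates exist. Returns a long table
    with columns gene_id, timepoint_days, dose_roentgen, mean_expression,
    n_replicates.
    """
    samples.cross_validate(counts)
    sdf = samples.data
    if sdf.empty:
        raise DesignError("sample table is empty")
    frames = []
    for (tp, dose), grp in sdf.groupby(["timepoint_days", "dose_roentgen"]):
        cols = grp["sample_id"].tolist()
        if not cols:
            raise DesignError(f"condition ({tp} d, {dose} R) has no samples")
        means = counts.data[cols].mean(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": counts.data.index,
                    "timepoint_days": tp,
                    "dose_roentgen": dose,
                    "mean_expression": means.to_numpy(),
                    "n_replicates": len(cols),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def presence_cutoff(
    means: pd.DataFrame, timepoint: int, quantile: float = 0.25
) -> float:
    """Bottom-quantile present/absent cutoff for one timepoint.

    The cutoff is the q-quantile (linear-interpolation convention) of the
    distribution of per-(gene, condition) mean expression values over all
    conditions of the timepoint, control included.
    """
    values = means.loc[
        means["timepoint_days"] == timepoint, "mean_expression"
    ].to_numpy()
    if values.size == 0:
        raise ValueError(f"no mean-expression values for timepoint {timepoint}")
    return float(np.quantile(values, quantile))


def presence_cutoffs(means: pd.DataFrame, quantile: float = 0.25) -> dict[int, float]:
    """Per-timepoint cutoffs for every timepoint in the mean table."""
    return {
        int(tp): presence_cutoff(means, tp, quantile)
        for tp in sorted(means["timepoint_days"].unique())
    }


def fold_change_table(
    means: pd.DataFrame, cutoffs: Mapping[int, float]
) -> pd.DataFrame:
    """Fold changes vs. the dose-0 control, with present/absent status.

    For each gene, timepoint and dose > 0 the fold change is
    mean(dose)/mean(0). Status is ``absent_below_cutoff`` when both means
    fall below the timepoint's cutoff, ``undefined_zero_control`` when the
    control mean is zero but the experimental mean passes the cutoff, and
    ``defined`` otherwise (fold_change is NaN unless defined).
    """
    wide = means.pivot_table(
        index=["gene_id", "timepoint_days"],
        columns="dose_roentgen",
        values="mean_expression",
        sort=False,
    )
    if 0 not in wide.columns:
        raise DesignError("no dose-0 control condition in the mean table")
    control = wide[0]
    rows = []
    doses = [d for d in wide.columns if d > 0]
    for dose in doses:
        exp = wide[dose]
        tp_index = wide.index.get_level_values("timepoint_days")
        cut = np.array([cutoffs[int(tp)] for tp in tp_index])
        both_below = (exp.to_numpy() < cut) & (control.to_numpy() < cut)
        zero_ctrl = (control.to_numpy() == 0) & ~both_below
        status = np.where(
            both_below, STATUS_ABSENT, np.where(zero_ctrl, STATUS_ZERO_CONTROL, STATUS_DEFINED)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = exp.to_numpy() / control.to_numpy()
        fc = np.where(status == STATUS_DEFINED, fc, np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": wide.index.get_level_values("gene_id"),
                    "timepoint_days": tp_index,
                    "dose_roentgen": dose,
                    "fold_change": fc,
                    "status": status,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(
        ["timepoint_days", "gene_id", "dose_roentgen"], ignore_index=True, kind="stable"
    )


def linear_r2(doses: np.ndarray, fold_changes: np.ndarray) -> LinearFit:
    """OLS of fold change on dose (linear roentgen scale) with intercept.

    Returns slope, intercept and R^2 = 1 - SSresid/SStotal. R^2 is NaN when
    fewer than two points are supplied or when the fold changes have zero
    total variance (SStotal = 0), in which case the gene is unselectable.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(fold_changes, dtype=float)
    n = x.size
    if n < 2:
        return LinearFit(n, np.nan, np.nan, np.nan)
    if np.ptp(y) <= 1e-12 * np.max(np.abs(y)):
        # flat response (up to float rounding): slope 0, intercept the common
        # value, R^2 undefined -- a zero-variance ratio carries no dose signal
        return LinearFit(n, 0.0, float(y[0]), np.nan)
    res = stats.linregress(x, y)
    return LinearFit(n, float(res.slope), float(res.intercept), float(res.rvalue**2))


def _fits_by_gene(
    fc: pd.DataFrame,
    exclude_doses: Iterable[float],
    include_control: bool,
) -> pd.DataFrame:
    exclude = set(float(d) for d in exclude_doses)
    all_doses = set(fc["dose_roentgen"].unique())
    if all_doses and not (all_doses - exclude):
        raise DesignError("exclude_doses removes every radiation dose")
    sub = fc[~fc["dose_roentgen"].isin(exclude)]
    rows = []
    for (tp, gene), grp in sub.groupby(["timepoint_days", "gene_id"], sort=True):
        defined = grp[grp["status"] == STATUS_DEFINED]
        x = defined["dose_roentgen"].to_numpy(dtype=float)
        y = defined["fold_change"].to_numpy(dtype=float)
        n_defined = x.size
        if include_control and n_defined:
            x = np.append(x, 0.0)
            y = np.append(y, 1.0)
        fit = linear_r2(x, y) if n_defined >= 2 else LinearFit(n_defined, np.nan, np.nan, np.nan)
        rows.append(
            {
                "gene_id": gene,
                "timepoint_days": tp,
                "n_doses_used": n_defined,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "timepoint_days",
            "n_doses_used",
            "slope",
            "intercept",
            "r_squared",
        ],
    )


def select_linear_genes(
    fc: pd.DataFrame,
    r2_min: float = 0.9,
    min_doses: int = 4,
    exclude_doses: Iterable[float] = (),
    include_control: bool = False,
    label: str | None = None,
) -> ScreenResult:
    """Run the linear screen over a fold-change table.

    A gene is selected at a timepoint iff, after removing ``exclude_doses``,
    it has at least ``min_doses`` defined fold changes and the OLS fit of
    fold change on dose has R^2 strictly greater than ``r2_min``. Genes with
    undefined R^2 (zero fold-change variance) are never selected.
    """
    records = _fits_by_gene(fc, exclude_doses, include_control)
    records["selected"] = (
        (records["n_doses_used"] >= min_doses)
        & records["r_squared"].notna()
        & (records["r_squared"] > r2_min)
    )
    selected: dict[int, set[str]] = {}
    for tp in sorted(fc["timepoint_days"].unique()):
        mask = (records["timepoint_days"] == tp) & records["selected"]
        selected[int(tp)] = set(records.loc[mask, "gene_id"])
    if label is None:
        label = "lowest-dose-excluded" if set(exclude_doses) else "all-doses"
    return ScreenResult(kind="linear", label=label, selected=selected, records=records)


def overlap_sets(
    per_timepoint_sets: Mapping[int, set[str]],
) -> tuple[dict[frozenset, set[str]], dict[frozenset, set[str]]]:
    """Intersections and exclusive (Venn) regions for all timepoint subsets.

    Returns ``(overlaps, exclusive)``: for every non-empty subset S of
    timepoints, ``overlaps[S]`` is the intersection of the selected sets of
    S, and ``exclusive[S]`` the genes selected in exactly the timepoints of
    S and no others.
    """
    if not per_timepoint_sets:
        raise ValueError("at least one timepoint required")
    tps = sorted(per_timepoint_sets)
    overlaps: dict[frozenset, set[str]] = {}
    exclusive: dict[frozenset, set[str]] = {}
    for r in range(1, len(tps) + 1):
        for combo in combinations(tps, r):
            key = frozenset(combo)
            inter = set.intersection(*(set(per_timepoint_sets[t]) for t in combo))
            overlaps[key] = inter
            outside = set().union(
                *(set(per_timepoint_sets[t]) for t in tps if t not in key)
            )
            exclusive[key] = inter - outside
    return overlaps, exclusive
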