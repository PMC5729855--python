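"""Spike detection: genes whose fold change bursts at a single dose.

A gene "spikes" at a timepoint when its largest fold change across doses is
at least ``ratio_min`` (default 5) times the second largest AND the largest
fold change itself exceeds 1 (expression at the spike dose above control).
Ties for the maximum give ratio 1 and can never spike. The same
present/absent-filtered fold-change table as the linear screen is used, so
the low-expression cutoff applies identically.

For reporting spikes grouped by the dose at which they occur, spikes sitting
at the highest analyzed dose are omitted by default: a maximum at the top
dose is more plausibly a gene that is simply increasing with dose than a
single-dose burst. Such genes still count as spike genes for the per-
timepoint sets and overlaps, which are computed before dose grouping.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .counts_io import DesignError
from .dose_response import STATUS_DEFINED, ScreenResult

__all__ = ["SpikeCall", "spike_statistic", "select_spike_genes"]


class SpikeCall(NamedTuple):
    """Spike statistics for one gene at one timepoint (NaN fields = too few data)."""

    n_defined: int
    spike_dose: float
    max_fold_change: float
    second_fold_change: float
    ratio: float
    is_spike: bool


def spike_statistic(
    doses: np.ndarray,
    fold_changes: np.ndarray,
    ratio_min: float = 5.0,
    min_defined: int = 3,
) -> SpikeCall:
    """Largest vs. second-largest fold change and the spike decision.

    ``doses`` and ``fold_changes`` hold the defined fold changes only. With
    fewer than ``min_defined`` points the call is insufficient-data (all
    statistics NaN, never a spike); "second largest" is degenerate below
    three points, hence the default gate.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(fold_changes, dtype=float)
    n = y.size
    if n < min_defined or n < 2:
        return SpikeCall(n, np.nan, np.nan, np.nan, np.nan, False)
    order = np.argsort(y)[::-1]
    max_fc = float(y[order[0]])
    second = float(y[order[1]])
    spike_dose = float(x[order[0]])
    if second > 0:
        ratio = max_fc / second
    else:
        ratio = np.inf if max_fc > 0 else 1.0
    is_spike = bool(ratio >= ratio_min and max_fc > 1)
    return SpikeCall(n, spike_dose, max_fc, second, ratio, is_spike)


def select_spike_genes(
    fc: pd.DataFrame,
    ratio_min: float = 5.0,
    min_defined: int = 3,
    exclude_doses: Iterable[float] = (),
    drop_top_dose_spikes_for_grouping: bool = True,
    label: str | None = None,
) -> ScreenResult:
    """Run the spike screen over a fold-change table.

    Returns a :class:`~radscreen.dose_response.ScreenResult` with kind
    ``"spike"``: per-timepoint spike gene sets, overlap structure, per-gene
    records (spike dose, max/second fold change, ratio, top-dose flag) and a
    ``dose_groups`` report mapping timepoint -> spike dose -> genes, which
    omits spikes at the highest analyzed dose when the flag is set.
    """
    exclude = set(float(d) for d in exclude_doses)
    all_doses = set(fc["dose_roentgen"].unique())
    kept = all_doses - exclude
    if all_doses and not kept:
        raise DesignError("exclude_doses removes every radiation dose")
    top_dose = max(kept)
    sub = fc[~fc["dose_roentgen"].isin(exclude)]
    rows = []
    selected: dict[int, set[str]] = {int(tp): set() for tp in sub["timepoint_days"].unique()}
    dose_groups: dict[int, dict[float, set[str]]] = {tp: {} for tp in selected}
    for (tp, gene), grp in sub.groupby(["timepoint_days", "gene_id"], sort=True):
        defined = grp[grp["status"] == STATUS_DEFINED]
        call = spike_statistic(
            defined["dose_roentgen"].to_numpy(),
            defined["fold_change"].to_numpy(),
            ratio_min=ratio_min,
            min_defined=min_defined,
        )
        at_top = bool(call.is_spike and call.spike_dose == top_dose)
        rows.append(
            {
                "gene_id": gene,
                "timepoint_days": tp,
                "spike_dose": call.spike_dose,
                "max_fc": call.max_fold_change,
                "second_fc": call.second_fold_change,
                "ratio": call.ratio,
                "is_spike": call.is_spike,
                "at_top_dose": at_top,
            }
        )
        if call.is_spike:
            selected[int(tp)].add(gene)
            if not (drop_top_dose_spikes_for_grouping and at_top):
                dose_groups[int(tp)].setdefault(call.spike_dose, set()).add(gene)
    records = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "timepoint_days",
            "spike_dose",
            "max_fc",
            "second_fc",
            "ratio",
            "is_spike",
            "at_top_dose",
        ],
    )
    if label is None:
        label = "lowest-dose-excluded" if exclude else "all-doses"
    return ScreenResult(
        kind="spike",
        label=label,
        selected=selected,
        records=records,
        dose_groups=dose_groups,
    )
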