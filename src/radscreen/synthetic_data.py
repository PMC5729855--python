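"""Synthetic count datasets with planted dose-response ground truth.

The generator emulates the study design the screen was built for: three
timepoints (2, 10, 20 days post-irradiation) x six X-ray exposures (0, 10,
1000, 5000, 10,000, 20,000 roentgen) x three replicates, with one control
replicate dropped at (20 d, 0 R) to mirror a failed quality check. Genes
fall into three classes:

* ``linear`` -- expected fold change 1 + slope*dose (floored at 0.05), i.e.
  the screen's target quantity is linear in dose by construction;
* ``spike``  -- expected fold change = amplitude at one planted dose and 1
  elsewhere;
* ``null``   -- flat expected expression at the gene's baseline.

Baselines are log-normal. Each sample gets a log-normal depth multiplier
(what size-factor normalization must undo), and counts are drawn from a
negative binomial with variance mean + dispersion * mean^2 (dispersion 0
falls back to Poisson; ``zero_noise`` emits the expected values exactly, so
every screen stage can be checked for exact parameter recovery).

Planted linear and spike genes receive a baseline log-mean boost over null
genes so that planted signals sit above the bottom-quartile present/absent
cutoff: the generator plants signals that are detectable in principle, and
the cutoff's behaviour on low-expression genes is exercised separately by
direct unit tests. A single RNG stream with a fixed draw order (gene-level
parameters, then sample depths, then counts row by row in gene order, each
row in sample order) makes outputs bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .counts_io import (
    ConsistencyError,
    CountMatrix,
    SampleTable,
    write_count_matrix,
    write_sample_table,
)
from .dose_response import ScreenResult

__all__ = [
    "SimConfig",
    "ConfigError",
    "simulate_dataset",
    "expected_expression",
    "recovery_metrics",
    "write_dataset",
]


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the screen's study conditions: the 3 x 6 x 3 design
    with one dropped control replicate, a log-normal baseline whose bottom
    quartile sits near 18-20 counts, moderate replicate overdispersion and
    modest depth variation between samples.
    """

    n_genes: int = 1000
    timepoints: Sequence[int] = (2, 10, 20)
    doses: Sequence[float] = (0, 10, 1000, 5000, 10000, 20000)
    replicates: int = 3
    #: (timepoint, dose, replicate) triples removed from the design
    dropped_samples: Sequence[tuple[int, float, int]] = ((20, 0, 3),)
    baseline_log_mean: float = 3.6
    baseline_log_sd: float = 1.0
    #: negative-binomial dispersion alpha in var = mu + alpha*mu^2; 0 = Poisson
    nb_dispersion: float = 0.05
    #: emit expected values exactly instead of drawing counts
    zero_noise: bool = False
    frac_linear: float = 0.05
    frac_spike: float = 0.01
    #: fold-change slope per roentgen; negative slopes are admissible, the
    #: expected fold change is floored at 0.05
    slope_range: tuple[float, float] = (5e-5, 1.5e-4)
    spike_amplitude_range: tuple[float, float] = (8.0, 25.0)
    #: doses eligible for planted spikes; None = interior positive doses
    spike_dose_choices: Sequence[float] | None = None
    #: log-mean baseline boost for planted (non-null) genes
    signal_log_mean_shift: float = 2.0
    #: log-scale spread of per-sample depth multipliers
    size_factor_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.replicates < 1:
            raise ConfigError("n_genes and replicates must be positive")
        if self.frac_linear < 0 or self.frac_spike < 0:
            raise ConfigError("class fractions must be non-negative")
        if self.frac_linear + self.frac_spike > 1:
            raise ConfigError("frac_linear + frac_spike must not exceed 1")
        doses = list(self.doses)
        if 0 not in doses:
            raise ConfigError("doses must include the 0 R control")
        positive = [d for d in doses if d > 0]
        if any(d < 0 for d in doses) or len(set(doses)) != len(doses):
            raise ConfigError("doses must be distinct and non-negative")
        if not positive:
            raise ConfigError("at least one positive dose required")
        if self.nb_dispersion < 0 or self.size_factor_sd < 0:
            raise ConfigError("dispersion and size_factor_sd must be non-negative")
        if self.spike_dose_choices is not None:
            bad = set(self.spike_dose_choices) - set(positive)
            if bad:
                raise ConfigError(f"spike_dose_choices not in the dose ladder: {bad}")

    @property
    def n_linear(self) -> int:
        return int(round(self.n_genes * self.frac_linear))

    @property
    def n_spike(self) -> int:
        return int(round(self.n_genes * self.frac_spike))

    def spike_doses(self) -> list[float]:
        if self.spike_dose_choices is not None:
            return list(self.spike_dose_choices)
        positive = sorted(d for d in self.doses if d > 0)
        # interior doses: a spike at the lowest dose disappears when that dose
        # is excluded, and one at the top dose is indistinguishable from a
        # monotone increase (it is dropped from the dose-grouping report)
        return positive[1:-1] if len(positive) > 2 else positive

    def sample_design(self) -> pd.DataFrame:
        dropped = set(
            (int(tp), float(d), int(r)) for tp, d, r in self.dropped_samples
        )
        rows = []
        for tp in self.timepoints:
            for dose in self.doses:
                for rep in range(1, self.replicates + 1):
                    if (int(tp), float(dose), rep) in dropped:
                        continue
                    rows.append(
                        {
                            "sample_id": f"t{tp}_d{int(dose)}_r{rep}",
                            "timepoint_days": int(tp),
                            "dose_roentgen": float(dose),
                            "replicate": rep,
                        }
                    )
        return pd.DataFrame(rows)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _truth_and_baselines(config: SimConfig, rng: np.random.Generator):
    n = config.n_genes
    genes = _gene_ids(n)
    classes = np.array(
        ["linear"] * config.n_linear
        + ["spike"] * config.n_spike
        + ["null"] * (n - config.n_linear - config.n_spike)
    )
    log_mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    log_mu[classes != "null"] += config.signal_log_mean_shift
    baselines = np.exp(log_mu)
    slopes = np.full(n, np.nan)
    if config.n_linear:
        slopes[: config.n_linear] = rng.uniform(
            config.slope_range[0], config.slope_range[1], size=config.n_linear
        )
    spike_dose = np.full(n, np.nan)
    spike_amp = np.full(n, np.nan)
    if config.n_spike:
        lo = config.n_linear
        hi = lo + config.n_spike
        spike_dose[lo:hi] = rng.choice(config.spike_doses(), size=config.n_spike)
        spike_amp[lo:hi] = rng.uniform(
            config.spike_amplitude_range[0],
            config.spike_amplitude_range[1],
            size=config.n_spike,
        )
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "class": classes,
            "slope": slopes,
            "spike_dose": spike_dose,
            "spike_amplitude": spike_amp,
            "baseline": baselines,
        }
    )
    return truth


def _fold_change_columns(truth: pd.DataFrame, doses: Sequence[float]) -> np.ndarray:
    """Expected fold-change matrix, genes x len(doses)."""
    classes = truth["class"].to_numpy()
    slopes = truth["slope"].to_numpy()
    spike_dose = truth["spike_dose"].to_numpy()
    spike_amp = truth["spike_amplitude"].to_numpy()
    out = np.ones((len(truth), len(doses)))
    is_linear = classes == "linear"
    is_spike = classes == "spike"
    for j, dose in enumerate(doses):
        if dose == 0:
            continue
        col = out[:, j]
        col[is_linear] = np.maximum(1.0 + slopes[is_linear] * dose, 0.05)
        hit = is_spike & (spike_dose == dose)
        col[hit] = spike_amp[hit]
    return out


def expected_expression(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noise-free expected expression per gene and condition.

    Returns ``(expected, truth)`` where ``expected`` has genes in rows and a
    (timepoint, dose) MultiIndex in columns; depth multipliers are not
    applied. Uses the same RNG draws as :func:`simulate_dataset` for the
    gene-level parameters, so the two agree for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    truth = _truth_and_baselines(config, rng)
    cols = pd.MultiIndex.from_product(
        [list(config.timepoints), list(config.doses)], names=["timepoint_days", "dose_roentgen"]
    )
    fc = _fold_change_columns(truth, [dose for _tp, dose in cols])
    expected = pd.DataFrame(
        fc * truth["baseline"].to_numpy()[:, None],
        index=truth["gene_id"],
        columns=cols,
    )
    return expected, truth


def simulate_dataset(
    config: SimConfig,
) -> tuple[CountMatrix, SampleTable, pd.DataFrame]:
    """Draw a full synthetic dataset.

    Returns the raw count matrix, the sample table and the truth table
    (columns gene_id, class, slope, spike_dose, spike_amplitude, baseline).
    Bit-identical outputs for identical configs.
    """
    rng = np.random.default_rng(config.seed)
    truth = _truth_and_baselines(config, rng)
    design = config.sample_design()
    depths = np.exp(rng.normal(0.0, config.size_factor_sd, size=len(design)))

    fc = _fold_change_columns(truth, design["dose_roentgen"].tolist())
    means = truth["baseline"].to_numpy()[:, None] * fc * depths[None, :]
    values = np.empty((config.n_genes, len(design)))
    alpha = config.nb_dispersion
    # one row of draws per gene, samples in design order: fixed draw order
    for i in range(config.n_genes):
        mean = means[i]
        if config.zero_noise:
            values[i] = mean
        elif alpha == 0:
            values[i] = rng.poisson(mean)
        else:
            size = 1.0 / alpha
            p = size / (size + mean)
            values[i] = rng.negative_binomial(size, p)

    counts = CountMatrix(
        pd.DataFrame(values, index=truth["gene_id"].to_numpy(), columns=design["sample_id"]),
        normalized=False,
    )
    counts.data.index.name = "gene_id"
    samples = SampleTable(design)
    return counts, samples, truth.drop(columns="baseline")


def recovery_metrics(truth: pd.DataFrame, result: ScreenResult) -> pd.DataFrame:
    """Score a screen result against the planted truth.

    For each timepoint and for the full (all-timepoint) overlap, reports the
    sensitivity on the class matching the screen kind (linear screen scored
    on planted linear genes, spike screen on planted spike genes), the
    false-positive rate among null genes, and the cross-class confusion
    (planted genes of the other signal class entering this screen).
    """
    truth_genes = set(truth["gene_id"])
    result_genes = set(result.records["gene_id"])
    if not result_genes <= truth_genes:
        raise ConsistencyError(
            f"screened genes absent from truth: {sorted(result_genes - truth_genes)[:5]}"
        )
    target_class = "linear" if result.kind == "linear" else "spike"
    other_class = "spike" if result.kind == "linear" else "linear"
    target = set(truth.loc[truth["class"] == target_class, "gene_id"])
    other = set(truth.loc[truth["class"] == other_class, "gene_id"])
    null = set(truth.loc[truth["class"] == "null", "gene_id"])

    def _score(label, genes):
        genes = set(genes)
        return {
            "timepoint": label,
            "n_selected": len(genes),
            "sensitivity": len(genes & target) / len(target) if target else np.nan,
            "null_fpr": len(genes & null) / len(null) if null else np.nan,
            "cross_class_rate": len(genes & other) / len(other) if other else np.nan,
        }

    rows = [_score(str(tp), result.selected[tp]) for tp in result.timepoints]
    rows.append(_score("all", result.full_overlap()))
    return pd.DataFrame(rows)


def write_dataset(
    counts: CountMatrix,
    samples: SampleTable,
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write counts.tsv, samples.tsv and truth.tsv into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out_dir / "counts.tsv",
        "samples": out_dir / "samples.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_count_matrix(counts, paths["counts"])
    write_sample_table(samples, paths["samples"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
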