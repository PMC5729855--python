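"""Configuration-driven end-to-end runner for the dosimetry screen.

A single run executes: (optional) median-of-ratios normalization ->
condition means -> per-timepoint bottom-quartile cutoffs -> fold changes ->
the linear screen with and without the excluded doses -> the spike screen in
the same two variants -> overlap summaries and TSV outputs. Four named
analyses are always emitted, each in its own subdirectory:

* ``linear``           -- linear screen, all doses
* ``linear_excluded``  -- linear screen without the excluded doses
* ``spike``            -- spike screen, all doses
* ``spike_excluded``   -- spike screen without the excluded doses

When no excluded doses are configured, the ``*_excluded`` analyses drop the
lowest positive dose present (the dose most likely to sit at the level of
noise). A run manifest (JSON) records every threshold, the seed, and input
checksums so that manifest + inputs determine all outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import counts_io, normalization, synthetic_data
from .counts_io import ConsistencyError, CountMatrix, SampleTable
from .dose_response import (
    ScreenResult,
    condition_means,
    fold_change_table,
    presence_cutoffs,
    select_linear_genes,
)
from .spike_screen import select_spike_genes
from .synthetic_data import SimConfig

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("radscreen")

ANALYSES = ("linear", "linear_excluded", "spike", "spike_excluded")


@dataclass
class PipelineConfig:
    """Everything a screen run depends on.

    Exactly one of (``counts_path`` + ``samples_path``) or ``simulate`` must
    be provided. Thresholds default to the screen's canonical values:
    R^2 > 0.9, at least 4 defined doses, bottom-quartile (0.25) presence
    cutoff, spike ratio >= 5.
    """

    counts_path: str | None = None
    samples_path: str | None = None
    simulate: SimConfig | None = None
    normalized_input: bool = False
    r2_min: float = 0.9
    min_doses: int = 4
    presence_quantile: float = 0.25
    spike_ratio_min: float = 5.0
    spike_min_defined: int = 3
    exclude_doses: tuple[float, ...] = ()
    include_control_in_fit: bool = False
    out_dir: str = "radscreen_out"

    def __post_init__(self) -> None:
        has_paths = self.counts_path is not None or self.samples_path is not None
        if has_paths and self.simulate is not None:
            raise ConsistencyError(
                "config must provide input paths or a simulate block, not both"
            )
        if not has_paths and self.simulate is None:
            raise ConsistencyError(
                "config must provide input paths or a simulate block"
            )
        if has_paths and (self.counts_path is None or self.samples_path is None):
            raise ConsistencyError("both counts_path and samples_path are required")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a PipelineConfig from a JSON file (keys mirror the field names)."""
    with open(path) as fh:
        raw = json.load(fh)
    if "simulate" in raw and raw["simulate"] is not None:
        sim = raw["simulate"]
        for key in ("timepoints", "doses", "slope_range", "spike_amplitude_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        if "dropped_samples" in sim:
            sim["dropped_samples"] = tuple(tuple(x) for x in sim["dropped_samples"])
        raw["simulate"] = SimConfig(**sim)
    if "exclude_doses" in raw:
        raw["exclude_doses"] = tuple(raw["exclude_doses"])
    return PipelineConfig(**raw)


def _stage(name: str, message: str, *args) -> None:
    logger.info("[%s] " + message, name, *args)


def run_pipeline(config: PipelineConfig) -> dict[str, ScreenResult]:
    """Execute the full screen and write all result tables.

    Returns the four ScreenResults keyed by analysis name and writes, under
    ``config.out_dir``: normalized counts and size factors (when
    normalization ran), per-analysis screen and overlap tables, recovery
    metrics against the truth table (simulated inputs only), and
    ``manifest.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "thresholds": {
            "r2_min": config.r2_min,
            "min_doses": config.min_doses,
            "presence_quantile": config.presence_quantile,
            "spike_ratio_min": config.spike_ratio_min,
            "spike_min_defined": config.spike_min_defined,
            "include_control_in_fit": config.include_control_in_fit,
        }
    }

    truth: pd.DataFrame | None = None
    try:
        if config.simulate is not None:
            _stage("simulate", "generating %d genes (seed %d)",
                   config.simulate.n_genes, config.simulate.seed)
            counts, samples, truth = synthetic_data.simulate_dataset(config.simulate)
            paths = synthetic_data.write_dataset(counts, samples, truth, out_dir / "inputs")
            manifest["simulate"] = dataclasses.asdict(config.simulate)
            manifest["inputs"] = {
                k: counts_io.file_checksum(p) for k, p in paths.items()
            }
            counts.normalized = False
        else:
            _stage("read", "loading %s / %s", config.counts_path, config.samples_path)
            counts = counts_io.read_count_matrix(
                config.counts_path, normalized=config.normalized_input
            )
            samples = counts_io.read_sample_table(config.samples_path)
            samples.cross_validate(counts)
            manifest["inputs"] = {
                "counts": counts_io.file_checksum(config.counts_path),
                "samples": counts_io.file_checksum(config.samples_path),
            }
    except Exception as exc:
        raise type(exc)(f"[input stage] {exc}") from exc

    try:
        if not counts.normalized:
            _stage("normalize", "median-of-ratios size factors")
            factors = normalization.size_factors(counts)
            normalization.write_size_factors(factors, out_dir / "size_factors.tsv")
            counts = normalization.normalize_counts(counts, factors)
        else:
            _stage("normalize", "input flagged normalized; skipping")
    except Exception as exc:
        raise type(exc)(f"[normalize stage] {exc}") from exc

    try:
        means = condition_means(counts, samples)
        cutoffs = presence_cutoffs(means, config.presence_quantile)
        _stage("cutoff", "per-timepoint presence cutoffs: %s",
               {k: round(v, 3) for k, v in cutoffs.items()})
        fc = fold_change_table(means, cutoffs)
        n_defined = int((fc["status"] == "defined").sum())
        _stage("fold-change", "%d/%d fold changes defined", n_defined, len(fc))
        manifest["cutoffs"] = cutoffs
    except Exception as exc:
        raise type(exc)(f"[fold-change stage] {exc}") from exc

    excluded = tuple(config.exclude_doses)
    if not excluded:
        positive = sorted(d for d in samples.doses if d > 0)
        excluded = (positive[0],)
    manifest["excluded_doses"] = list(excluded)

    results: dict[str, ScreenResult] = {}
    try:
        results["linear"] = select_linear_genes(
            fc,
            r2_min=config.r2_min,
            min_doses=config.min_doses,
            include_control=config.include_control_in_fit,
            label="all-doses",
        )
        results["linear_excluded"] = select_linear_genes(
            fc,
            r2_min=config.r2_min,
            min_doses=config.min_doses,
            exclude_doses=excluded,
            include_control=config.include_control_in_fit,
            label="lowest-dose-excluded",
        )
        results["spike"] = select_spike_genes(
            fc,
            ratio_min=config.spike_ratio_min,
            min_defined=config.spike_min_defined,
            label="all-doses",
        )
        results["spike_excluded"] = select_spike_genes(
            fc,
            ratio_min=config.spike_ratio_min,
            min_defined=config.spike_min_defined,
            exclude_doses=excluded,
            label="lowest-dose-excluded",
        )
    except Exception as exc:
        raise type(exc)(f"[screen stage] {exc}") from exc

    manifest["selected_counts"] = {}
    for name, result in results.items():
        counts_io.write_result_tables(result, out_dir / name)
        per_tp = {str(tp): len(result.selected[tp]) for tp in result.timepoints}
        per_tp["all"] = len(result.full_overlap())
        manifest["selected_counts"][name] = per_tp
        _stage("screen", "%s: %s", name, per_tp)
        if truth is not None:
            metrics = synthetic_data.recovery_metrics(truth, result)
            metrics.to_csv(out_dir / name / "recovery.tsv", sep="\t", index=False)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return results
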