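"""Reading, validating and writing count matrices, sample tables and screen results.

The on-disk formats are plain tab-separated text in the style of GEO series
supplementary files: a count matrix has genes in rows and samples in columns
(header row of sample identifiers, first column of gene identifiers), and a
sample table maps each sample to its experimental condition (timepoint in
days post-irradiation, dose in roentgen, replicate index).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleTable",
    "IdentifierError",
    "FormatError",
    "DesignError",
    "ConsistencyError",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_table",
    "write_sample_table",
    "write_result_tables",
]

SAMPLE_COLUMNS = ("sample_id", "timepoint_days", "dose_roentgen", "replicate")


class IdentifierError(ValueError):
    """Duplicate or unknown gene/sample identifier."""


class FormatError(ValueError):
    """Malformed input file (empty matrix, missing columns ...)."""


class DesignError(ValueError):
    """Experimental design violates the screen's requirements (e.g. no control)."""


class ConsistencyError(ValueError):
    """Two inputs that must describe the same samples disagree."""


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative expression values.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as the index and sample identifiers
        as columns; values are raw or normalized counts, all >= 0.
    normalized
        Whether the values have already been depth-normalized.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise FormatError("count matrix is empty")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate gene identifiers: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate sample identifiers: {dupes}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("count matrix contains non-numeric cells")
        if np.isnan(values).any():
            raise ValueError("count matrix contains missing values")
        if (values < 0).any():
            raise ValueError("count matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class SampleTable:
    """Per-sample experimental labels for a dose x timepoint x replicate design."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"sample table lacks columns: {missing}")
        df = self.data.loc[:, list(SAMPLE_COLUMNS)].reset_index(drop=True)
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise IdentifierError(f"duplicate sample identifiers: {dupes}")
        for col in ("timepoint_days", "replicate"):
            try:
                as_int = df[col].astype(float)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"column {col!r} is not numeric") from exc
            if not np.all(as_int == np.round(as_int)) or (as_int <= 0).any():
                raise ValueError(f"column {col!r} must hold positive integers")
            df[col] = as_int.astype(int)
        try:
            df["dose_roentgen"] = df["dose_roentgen"].astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError("column 'dose_roentgen' is not numeric") from exc
        if (df["dose_roentgen"] < 0).any():
            raise ValueError("doses must be non-negative")
        for tp, grp in df.groupby("timepoint_days"):
            if not (grp["dose_roentgen"] == 0).any():
                raise DesignError(f"timepoint {tp} d has no dose-0 control samples")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.data["timepoint_days"].unique().tolist())

    @property
    def doses(self) -> list[float]:
        return sorted(self.data["dose_roentgen"].unique().tolist())

    def census(self) -> pd.DataFrame:
        """Samples available per (timepoint, dose) condition."""
        return (
            self.data.groupby(["timepoint_days", "dose_roentgen"])
            .size()
            .rename("n_samples")
            .reset_index()
        )

    def cross_validate(self, counts: CountMatrix) -> None:
        """Raise ConsistencyError unless every sample here is a matrix column."""
        missing = set(self.data["sample_id"]) - set(counts.sample_ids)
        if missing:
            raise ConsistencyError(
                f"samples absent from the count matrix: {sorted(missing)}"
            )


def _read_header(path: Path) -> list[str]:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if not first:
        raise FormatError(f"{path}: empty file")
    return first.split("\t")


def read_count_matrix(path: str | Path, normalized: bool = False) -> CountMatrix:
    """Read a TSV count matrix (genes in rows, samples in columns).

    The first column holds gene identifiers; its header cell may be empty,
    ``gene_id`` or any other label. Raises :class:`IdentifierError` on
    duplicate identifiers, :class:`ValueError` on negative or non-numeric
    cells and :class:`FormatError` on an empty matrix.
    """
    path = Path(path)
    header = _read_header(path)
    sample_ids = header[1:]
    if len(sample_ids) != len(set(sample_ids)):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise IdentifierError(f"duplicate sample identifiers in header: {dupes}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: matrix has no genes or no samples")
    df.columns = sample_ids
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    try:
        numeric = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in count matrix") from exc
    return CountMatrix(numeric, normalized=normalized)


def write_count_matrix(counts: CountMatrix, path: str | Path) -> Path:
    """Write a CountMatrix as TSV, preserving row and column order."""
    path = Path(path)
    out = counts.data.copy()
    out.index.name = "gene_id"
    # 17 significant digits: the TSV round-trips doubles exactly
    out.to_csv(path, sep="\t", float_format="%.17g")
    return path


def read_sample_table(path: str | Path) -> SampleTable:
    """Read and validate a TSV sample table (see :data:`SAMPLE_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path: str | Path) -> Path:
    path = Path(path)
    samples.data.to_csv(path, sep="\t", index=False)
    return path


def _subset_label(timepoints: Iterable[int]) -> str:
    return "&".join(f"d{tp}" for tp in sorted(timepoints))


def write_result_tables(result, out_dir: str | Path) -> dict[str, Path]:
    """Write a ScreenResult's per-gene records and overlap summary as TSVs.

    Produces ``<kind>_screen.tsv`` with the per-gene statistics and
    ``overlap_summary.tsv`` with one row per non-empty timepoint subset:
    subset label (``d2&d10&d20`` style), intersection size, exclusive-region
    size and the semicolon-joined member genes.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}

        records = result.records.copy()
        if result.kind == "linear":
            for col in ("slope", "intercept", "r_squared"):
                records[col] = records[col].map(
                    lambda v: "" if pd.isna(v) else f"{v:.6f}"
                )
            records["selected"] = records["selected"].astype(int)
        else:
            for col in ("max_fc", "second_fc", "ratio"):
                records[col] = records[col].map(
                    lambda v: "" if pd.isna(v) else f"{v:.4f}"
                )
            records["is_spike"] = records["is_spike"].astype(int)
            records["at_top_dose"] = records["at_top_dose"].astype(int)
        screen_path = out_dir / f"{result.kind}_screen.tsv"
        records.to_csv(screen_path, sep="\t", index=False)
        written["screen"] = screen_path

        rows = []
        for subset in sorted(result.overlaps, key=lambda s: (len(s), sorted(s))):
            inter = result.overlaps[subset]
            excl = result.exclusive.get(subset, set())
            rows.append(
                {
                    "subset": _subset_label(subset),
                    "intersection_size": len(inter),
                    "exclusive_size": len(excl),
                    "genes": ";".join(sorted(inter)),
                }
            )
        overlap_path = out_dir / "overlap_summary.tsv"
        pd.DataFrame(
            rows, columns=["subset", "intersection_size", "exclusive_size", "genes"]
        ).to_csv(overlap_path, sep="\t", index=False)
        written["overlap"] = overlap_path

        if getattr(result, "dose_groups", None) is not None:
            grows = []
            for tp in sorted(result.dose_groups):
                for dose in sorted(result.dose_groups[tp]):
                    genes = result.dose_groups[tp][dose]
                    grows.append(
                        {
                            "timepoint_days": tp,
                            "spike_dose": dose,
                            "n_genes": len(genes),
                            "genes": ";".join(sorted(genes)),
                        }
                    )
            group_path = out_dir / "spike_dose_groups.tsv"
            pd.DataFrame(
                grows, columns=["timepoint_days", "spike_dose", "n_genes", "genes"]
            ).to_csv(group_path, sep="\t", index=False)
            written["dose_groups"] = group_path
        return written
    except OSError as exc:
        raise IOError(f"cannot write result tables to {out_dir}: {exc}") from exc


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file, for run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
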