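"""Reading, writing and reshaping of DIA quantification reports.

The pipeline starts from a long-format precursor report (one row per
(run, precursor) as exported by DIA extraction software), a per-run sample
design table, and an optional YAML/JSON configuration.  Internally the
quantitative data live in a :class:`QuantMatrix` oriented runs × precursors
(samples × features, the scikit-learn convention); on disk matrices are
written features × runs with the feature id in the first column, the layout
proteomics tools exchange.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: canonical column names of a long report
CANONICAL_COLUMNS = (
    "run_id",
    "precursor_id",
    "protein_id",
    "intensity",
    "qvalue",
    "rt_observed",
    "is_standard",
)

MANDATORY_COLUMNS = ("run_id", "precursor_id", "protein_id", "intensity", "qvalue")

#: named column dialects for common DIA report layouts
DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {c: c for c in CANONICAL_COLUMNS},
    "spectronaut": {
        "run_id": "R.FileName",
        "precursor_id": "EG.PrecursorId",
        "protein_id": "PG.ProteinAccessions",
        "intensity": "FG.Quantity",
        "qvalue": "EG.Qvalue",
        "rt_observed": "EG.ApexRT",
        "is_standard": "EG.IsIRT",
    },
}


class InputError(ValueError):
    """Malformed or empty input data."""


class ConfigurationError(ValueError):
    """Invalid configuration (missing columns, unknown modes, bad ranges)."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class LongReport:
    """Tidy (run, precursor) records with intensity, q-value and RT."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"long report lacks mandatory columns: {missing}")
        if len(self.data) == 0:
            raise InputError("long report is empty")
        if self.data.duplicated(["run_id", "precursor_id"]).any():
            dup = self.data[self.data.duplicated(["run_id", "precursor_id"])]
            raise InputError(
                f"duplicate (run, precursor) pairs, e.g. "
                f"{dup[['run_id', 'precursor_id']].iloc[0].tolist()}"
            )
        neg = self.data["intensity"].dropna() < 0
        if neg.any():
            raise InputError("negative intensities in long report")
        if "rt_observed" not in self.data.columns:
            self.data["rt_observed"] = np.nan
        if "is_standard" not in self.data.columns:
            self.data["is_standard"] = False

    @property
    def runs(self) -> list[str]:
        return list(pd.unique(self.data["run_id"]))

    @property
    def precursors(self) -> list[str]:
        return list(pd.unique(self.data["precursor_id"]))

    @property
    def precursor_to_protein(self) -> dict[str, str]:
        m = self.data.drop_duplicates("precursor_id")
        return dict(zip(m["precursor_id"], m["protein_id"]))


@dataclass
class QuantMatrix:
    """Runs × precursors intensity matrix with a precursor → protein map.

    ``values`` is indexed by run id with one column per precursor; missing
    entries are NaN.  ``scale`` is ``"linear"`` (non-negative) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str
    precursor_to_protein: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        if self.values.columns.duplicated().any():
            raise InputError("duplicate precursor ids in matrix")
        if self.values.index.duplicated().any():
            raise InputError("duplicate run ids in matrix")
        if self.scale == "linear":
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise InputError("linear-scale matrix contains negative values")

    def to_log2(self) -> "QuantMatrix":
        """Log2-transform a linear matrix; zeros become missing."""
        if self.scale == "log2":
            return self
        vals = self.values.to_numpy(dtype=float).copy()
        n_zero = int((vals == 0).sum())
        if n_zero:
            logger.info("log2 transform: %d zero intensities set to missing", n_zero)
        vals[vals <= 0] = np.nan
        out = pd.DataFrame(np.log2(vals), index=self.values.index, columns=self.values.columns)
        return QuantMatrix(out, "log2", dict(self.precursor_to_protein))

    def to_linear(self) -> "QuantMatrix":
        if self.scale == "linear":
            return self
        out = np.exp2(self.values)
        return QuantMatrix(out, "linear", dict(self.precursor_to_protein))

    @property
    def n_runs(self) -> int:
        return self.values.shape[0]

    @property
    def n_precursors(self) -> int:
        return self.values.shape[1]


@dataclass
class SampleDesign:
    """Per-run acquisition metadata: batch, order, QC flag, covariates.

    ``data`` is indexed by run id with mandatory columns ``batch``,
    ``acq_order`` and ``sample_type`` (``"QC"`` or ``"study"``); further
    columns are biological covariates (e.g. strain) or ``replicate_id``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for c in ("batch", "acq_order", "sample_type"):
            if c not in self.data.columns:
                raise ConfigurationError(f"sample design lacks column {c!r}")
        if self.data.index.duplicated().any():
            raise InputError("duplicate run ids in sample design")
        bad = set(self.data["sample_type"]) - {"QC", "study"}
        if bad:
            raise InputError(f"unknown sample types: {sorted(bad)}")

    @property
    def runs(self) -> list[str]:
        return list(self.data.index)

    @property
    def batches(self) -> list:
        return list(pd.unique(self.data["batch"]))

    def batch_sizes(self) -> pd.Series:
        return self.data["batch"].value_counts()

    def qc_runs(self) -> list[str]:
        return list(self.data.index[self.data["sample_type"] == "QC"])

    def require_qc_per_batch(self, minimum: int = 2) -> None:
        counts = (
            self.data[self.data["sample_type"] == "QC"].groupby("batch").size()
        )
        for b in self.batches:
            if counts.get(b, 0) < minimum:
                raise InputError(f"batch {b!r} has fewer than {minimum} QC runs")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _resolve_dialect(dialect: str | Mapping[str, str] | None) -> dict[str, str]:
    if dialect is None:
        return DIALECTS["canonical"]
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError:
            raise ConfigurationError(
                f"unknown dialect {dialect!r}; available: {sorted(DIALECTS)}"
            ) from None
    return {**DIALECTS["canonical"], **dict(dialect)}


def read_long_report(
    path: str | Path, dialect: str | Mapping[str, str] | None = None
) -> LongReport:
    """Read a tab-separated long-format precursor report.

    ``dialect`` maps canonical column names to the file's header names (or
    names a shipped preset such as ``"spectronaut"``).  Rows whose intensity
    or q-value does not parse as a number are dropped and counted; empty
    strings and ``NA`` are read as missing.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    colmap = _resolve_dialect(dialect)
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", ""], keep_default_na=False)
    if len(raw) == 0:
        raise InputError(f"empty long report: {path}")
    for canonical in MANDATORY_COLUMNS:
        if colmap[canonical] not in raw.columns:
            raise ConfigurationError(
                f"long report lacks mandatory column {colmap[canonical]!r} "
                f"(canonical {canonical!r})"
            )
    df = pd.DataFrame(index=raw.index)
    for canonical in CANONICAL_COLUMNS:
        src = colmap.get(canonical)
        if src in raw.columns:
            df[canonical] = raw[src]
    n_in = len(df)
    for col in ("intensity", "qvalue", "rt_observed"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    # a row is unparseable if q-value is absent where intensity is present
    bad = df["intensity"].notna() & df["qvalue"].isna()
    n_dropped = int(bad.sum())
    df = df[~bad].reset_index(drop=True)
    if "is_standard" in df.columns:
        df["is_standard"] = (
            df["is_standard"].astype(str).str.lower().isin(["true", "1", "yes", "t"])
        )
    else:
        df["is_standard"] = False
    report = LongReport(df)
    logger.info(
        "read %s: %d rows kept, %d dropped, %d runs, %d precursors",
        path, len(df), n_dropped, len(report.runs), len(report.precursors),
    )
    return report


def read_sample_design(path: str | Path) -> SampleDesign:
    """Read a tab-separated sample-design table indexed by run id."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"run_id": str}, na_values=["NA", ""],
                     keep_default_na=False)
    if "run_id" not in df.columns:
        raise ConfigurationError("sample design lacks column 'run_id'")
    df = df.set_index("run_id")
    df["acq_order"] = pd.to_numeric(df["acq_order"])
    return SampleDesign(df)


def pivot_to_matrix(report: LongReport, scale: str = "linear") -> QuantMatrix:
    """Pivot a tidy report to a runs × precursors :class:`QuantMatrix`.

    With ``scale="log2"`` the transform is applied after pivoting; zero
    intensities become missing (non-detections, not −∞).
    """
    wide = report.data.pivot(index="run_id", columns="precursor_id", values="intensity")
    wide = wide.sort_index(axis=1)
    mat = QuantMatrix(wide, "linear", report.precursor_to_protein)
    if scale == "log2":
        mat = mat.to_log2()
    elif scale != "linear":
        raise ConfigurationError(f"unknown scale {scale!r}")
    return mat


def pivot_qvalues(report: LongReport) -> pd.DataFrame:
    """Runs × precursors q-value matrix aligned with :func:`pivot_to_matrix`."""
    q = report.data.pivot(index="run_id", columns="precursor_id", values="qvalue")
    return q.sort_index(axis=1)


def unpivot(matrix: QuantMatrix) -> pd.DataFrame:
    """Melt a matrix back to tidy (run_id, precursor_id, intensity) rows."""
    tidy = (
        matrix.values.reset_index(names="run_id")
        .melt(id_vars="run_id", var_name="precursor_id", value_name="intensity")
        .dropna(subset=["intensity"])
        .reset_index(drop=True)
    )
    return tidy


def write_matrix(matrix: QuantMatrix | pd.DataFrame, path: str | Path,
                 feature_axis: str = "columns") -> None:
    """Write a matrix as TSV, features × runs, feature id in the first column.

    Missing values are written as ``NA``.  ``feature_axis`` says which axis of
    the in-memory frame holds the features (``"columns"`` for the internal
    runs × precursors orientation).
    """
    df = matrix.values if isinstance(matrix, QuantMatrix) else matrix
    out = df.T if feature_axis == "columns" else df
    out = out.rename_axis("feature_id")
    # %.17g keeps float64 values exact across the text round trip
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_matrix(path: str | Path, scale: str = "linear") -> QuantMatrix:
    """Read a features × runs TSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""],
                     keep_default_na=False, float_precision="round_trip")
    return QuantMatrix(df.T, scale)


def read_config(path: str | Path) -> dict:
    """Read a YAML or JSON pipeline configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping, for provenance records."""
    import hashlib

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
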