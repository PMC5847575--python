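"""End-to-end post-processing pipeline.

Fixed stage order: q-value filter → pivot/log → robust-sum normalization →
RT stability (side channel) → batch correction → peptide selection →
geometric rollup → QC metrics → report.  Each stage is an estimator from
the corresponding module; :func:`run_pipeline` wires them together, records
feature counts per stage and writes artifacts plus a provenance record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as dio
from .batch import ComBat, SurrogateVariableCorrector, fit_combat
from .filtering import QValueFilter, RobustSumNormalizer, filter_audit
from .qc import batch_diagnostics, cv_table, variability_reduction
from .report import render_report, write_report
from .rollup import CorrelationPeptideSelector, GeometricProteinRollup
from .rt import RTCalibrator, rt_stability

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage toggles and parameters of the post-processing pipeline."""

    filter_enabled: bool = True
    filter_mode: str = "median"
    qvalue_cutoff: float = 0.01
    percentile_fraction: float = 0.1
    normalize_enabled: bool = True
    pool_fraction: float = 0.10
    rt_enabled: bool = True
    correction: str = "combat"          # combat | sva | none
    shrink: bool = True
    sva_k: int | str = 1
    control_fraction: float = 0.5
    selection_enabled: bool = True
    rho_min: float = 0.5
    min_overlap: int = 6
    min_present_fraction: float = 0.5
    qc_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("percentile_fraction", "pool_fraction", "control_fraction",
                     "min_present_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise dio.ConfigurationError(f"{name} must be in (0, 1)")
        if not 0 < self.qvalue_cutoff <= 1:
            raise dio.ConfigurationError("qvalue_cutoff must be in (0, 1]")
        if self.correction not in ("combat", "sva", "none"):
            raise dio.ConfigurationError(
                f"unknown correction mode {self.correction!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise dio.ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


@dataclass
class PipelineResult:
    protein_matrix: pd.DataFrame                 # runs × proteins, log2
    peptide_matrix: dio.QuantMatrix              # corrected, log2
    qc_report: dict
    dossier: str
    provenance: dict
    models: dict = field(default_factory=dict)


class _Stage:
    """Context manager that re-raises with the failing stage's name."""

    def __init__(self, name: str, counts: dict):
        self.name, self.counts = name, counts

    def __enter__(self):
        logger.info("stage %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        return False


def run_pipeline(report: dio.LongReport, design: dio.SampleDesign,
                 config: PipelineConfig | dict | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full post-processing pipeline on a long report."""
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)

    missing_runs = [r for r in report.runs if r not in set(design.runs)]
    if missing_runs:
        raise dio.InputError(
            f"runs in report but not in design: {missing_runs[:5]}")

    counts: dict[str, dict] = {}
    models: dict = {}
    stages: dict = {s: None for s in
                    ("rt", "filter", "normalize", "correct", "cv", "batch")}

    quant_rows = report.data[~report.data["is_standard"]]
    quant = dio.LongReport(quant_rows.reset_index(drop=True))
    counts["input"] = {"rows": len(report.data), "runs": len(report.runs),
                       "precursors": len(quant.precursors)}

    # --- q-value filter ----------------------------------------------------
    qvalues = dio.pivot_qvalues(quant)
    with _Stage("filter", counts):
        if config.filter_enabled:
            filt = QValueFilter(config.filter_mode, config.qvalue_cutoff,
                                config.percentile_fraction).fit(qvalues)
            kept = filt.kept_precursors_
            models["filter"] = filt
            audit = filter_audit(qvalues, config.qvalue_cutoff,
                                 config.percentile_fraction)
            stages["filter"] = {
                "mode": config.filter_mode,
                "cutoff": config.qvalue_cutoff,
                "kept": int(len(kept)),
                "total": int(qvalues.shape[1]),
                "kept_per_mode": {m: int(audit[m].sum()) for m in audit.columns},
            }
        else:
            kept = qvalues.columns
    counts["filter"] = {"precursors": int(len(kept))}

    # --- pivot + normalization (linear scale) ------------------------------
    with _Stage("pivot", counts):
        matrix = dio.pivot_to_matrix(quant, scale="linear")
        matrix = dio.QuantMatrix(matrix.values.loc[:, kept], "linear",
                                 {p: matrix.precursor_to_protein[p] for p in kept})
    with _Stage("normalize", counts):
        if config.normalize_enabled:
            norm = RobustSumNormalizer(config.pool_fraction).fit(matrix)
            matrix = norm.transform(matrix)
            models["normalize"] = norm
            stages["normalize"] = {
                "pool_size": int(len(norm.pool_)),
                "factor_min": float(norm.factors_.min()),
                "factor_max": float(norm.factors_.max()),
                "target_sum": float(norm.target_sum_),
            }
    counts["normalize"] = {"precursors": matrix.n_precursors}

    # --- RT stability (side channel, uses the standards) --------------------
    with _Stage("rt", counts):
        if config.rt_enabled and report.data["is_standard"].any():
            cal = RTCalibrator().fit(report)
            stab = rt_stability(report, cal)
            models["rt"] = cal
            stages["rt"] = stab.to_dict()

    # --- batch correction (log2 scale) --------------------------------------
    log2 = matrix.to_log2()
    uncorrected = log2
    with _Stage("correct", counts):
        if config.correction == "combat":
            cb = fit_combat(log2, design, shrink=config.shrink)
            log2 = cb.transform(log2)
            models["correct"] = cb
            stages["correct"] = {
                "mode": "combat", "shrink": config.shrink,
                "n_batches": len(cb.batch_levels_),
                "n_iter": int(cb.n_iter_), "converged": bool(cb.converged_),
                "uncorrected_features": int(len(cb.uncorrected_features_)),
            }
        elif config.correction == "sva":
            sva = SurrogateVariableCorrector(
                control_fraction=config.control_fraction, k=config.sva_k,
                random_state=config.seed).fit(log2)
            log2 = sva.transform(log2)
            models["correct"] = sva
            stages["correct"] = {"mode": "sva", "k": int(sva.k_),
                                 "n_controls": int(len(sva.controls_))}
    counts["correct"] = {"precursors": log2.n_precursors}

    # --- peptide selection + rollup -----------------------------------------
    with _Stage("select", counts):
        if config.selection_enabled:
            sel = CorrelationPeptideSelector(
                config.rho_min, config.min_overlap).fit(log2)
            selected = sel.transform(log2)
            models["select"] = sel
        else:
            selected = log2
    counts["select"] = {"precursors": selected.n_precursors}
    with _Stage("rollup", counts):
        roll = GeometricProteinRollup(config.min_present_fraction).fit(
            selected, groups=getattr(models.get("select"), "groups_", None))
        proteins = roll.transform(selected)
    counts["rollup"] = {"proteins": int(proteins.shape[1])}

    # --- QC metrics ----------------------------------------------------------
    with _Stage("qc", counts):
        if config.qc_enabled:
            has_qc = len(design.qc_runs()) >= 2
            grouping = "qc" if has_qc else "replicates"
            cv_before = cv_table(uncorrected, design, grouping)
            cv_after = cv_table(log2, design, grouping)
            cv_section = {
                "grouping": grouping,
                "medians_before": cv_before.medians.to_dict(),
                "medians_after": cv_after.medians.to_dict(),
            }
            if "QC_all" in cv_before.medians.index:
                cv_section["cv.inter_batch_median"] = float(
                    cv_after.medians["QC_all"])
                intra = [g for g in cv_after.medians.index
                         if g.startswith("QC_intra_")]
                cv_section["cv.intra_batch_median"] = float(
                    cv_after.medians[intra].median())
                cv_section["cv.reduction_percent"] = variability_reduction(
                    cv_before, cv_after, "QC_all")
            stages["cv"] = cv_section
            if len(design.batches) >= 2:
                diag_before = batch_diagnostics(uncorrected, design)
                diag_after = batch_diagnostics(log2, design)
                stages["batch"] = {
                    "silhouette_before": diag_before.silhouette,
                    "silhouette_after": diag_after.silhouette,
                    "median_batch_r2_before": float(
                        diag_before.batch_r2.median()),
                    "median_batch_r2_after": float(diag_after.batch_r2.median()),
                }

    stages["counts"] = counts
    summary, dossier = render_report(stages)
    provenance = {
        "config": asdict(config),
        "config_hash": dio.config_hash(asdict(config)),
        "stage_counts": counts,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_matrix(log2, out / "peptide_matrix.tsv")
        dio.write_matrix(proteins, out / "protein_matrix.tsv")
        if "select" in models:
            models["select"].audit_table().to_csv(
                out / "selection_audit.tsv", sep="\t", index=False)
        write_report(summary, dossier, out)
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True) + "\n")

    return PipelineResult(proteins, log2, summary, dossier, provenance, models)
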