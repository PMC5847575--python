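"""Precision and batch-effect diagnostics.

The precision currency is the coefficient of variation (CV = sample SD /
mean, in percent) computed on *linear-scale* intensities per feature within
a replicate group: QC injections within one batch (intra-batch), all QC
injections pooled (inter-batch), or the biological replicates of each
condition.  Batch structure is diagnosed by the per-feature variance
explained by batch, and by the silhouette of batch labels in the first two
principal components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .io import InputError, QuantMatrix, SampleDesign


@dataclass
class CVReport:
    """Per-feature CVs per group plus cohort medians."""

    per_feature: pd.DataFrame        # features × groups, CV in percent
    group_sizes: pd.Series           # runs per group
    medians: pd.Series               # cohort median CV per group, percent

    def median_over(self, groups: list[str]) -> float:
        """Median of the per-group median CVs over a set of groups."""
        return float(self.medians.loc[groups].median())


@dataclass
class BatchDiagnostics:
    batch_r2: pd.Series              # per-feature variance explained by batch
    silhouette: float                # batch labels in PC1/PC2 space
    explained_variance_ratio: tuple[float, float]
    scores: pd.DataFrame             # runs × 2 principal components


def _linear_values(matrix) -> pd.DataFrame:
    if isinstance(matrix, QuantMatrix):
        return matrix.to_linear().values
    return pd.DataFrame(matrix)


def _log2_values(matrix) -> pd.DataFrame:
    if isinstance(matrix, QuantMatrix):
        return matrix.to_log2().values
    return pd.DataFrame(matrix)


def _group_cv(V: pd.DataFrame, runs: list) -> pd.Series:
    sub = V.loc[runs]
    n = sub.notna().sum(axis=0)
    sd = sub.std(axis=0, ddof=1)
    mean = sub.mean(axis=0)
    cv = sd / mean * 100.0
    cv[n < 2] = np.nan                   # <2 present values: missing, never 0
    return cv


def cv_table(matrix, design: SampleDesign, grouping: str = "qc") -> CVReport:
    """CVs per feature per replicate group.

    ``grouping="qc"`` builds one group per batch from that batch's QC runs
    (``QC_intra_<batch>``) plus the pooled group ``QC_all``;
    ``grouping="replicates"`` groups study runs by their biological
    covariate (cross-batch replicate groups, one per condition).
    """
    V = _linear_values(matrix)
    d = design.data.loc[V.index]
    groups: dict[str, list] = {}
    if grouping == "qc":
        qc = d[d["sample_type"] == "QC"]
        for b, sub in qc.groupby("batch"):
            groups[f"QC_intra_{b}"] = list(sub.index)
        groups["QC_all"] = list(qc.index)
    elif grouping == "replicates":
        study = d[d["sample_type"] == "study"]
        covariate = [c for c in study.columns
                     if c not in ("batch", "acq_order", "sample_type",
                                  "replicate_id")]
        if not covariate:
            raise InputError("no covariate column to group replicates by")
        for level, sub in study.groupby(covariate[0]):
            groups[str(level)] = list(sub.index)
    else:
        raise InputError(f"unknown grouping {grouping!r}")
    groups = {name: runs for name, runs in groups.items() if len(runs) >= 2}
    if not groups:
        raise InputError("no group with >= 2 runs")
    per_feature = pd.DataFrame({name: _group_cv(V, runs)
                                for name, runs in groups.items()})
    return CVReport(
        per_feature=per_feature,
        group_sizes=pd.Series({n: len(r) for n, r in groups.items()}),
        medians=per_feature.median(axis=0, skipna=True),
    )


def variability_reduction(before: CVReport, after: CVReport,
                          group: str | list[str] | None = None) -> float:
    """Percent reduction of the total (cross-batch) median CV.

    100 × (median_before − median_after) / median_before.  Negative when
    correction made things worse — a signal, not an error.
    """
    if not before.per_feature.columns.equals(after.per_feature.columns):
        raise InputError("before/after reports have different groupings")
    if group is None:
        group = ("QC_all" if "QC_all" in before.medians.index
                 else list(before.medians.index))
    if isinstance(group, str):
        m_before = float(before.medians.loc[group])
        m_after = float(after.medians.loc[group])
    else:
        m_before = before.median_over(list(group))
        m_after = after.median_over(list(group))
    if m_before == 0:
        raise InputError("median CV before correction is zero; reduction undefined")
    return 100.0 * (m_before - m_after) / m_before


def batch_diagnostics(matrix, design: SampleDesign) -> BatchDiagnostics:
    """Batch R² per feature and batch silhouette in PC1/PC2."""
    V = _log2_values(matrix)
    d = design.data.loc[V.index]
    batches = d["batch"]
    if len(V) < 3 or batches.nunique() < 2:
        raise InputError("diagnostics need >= 3 runs and >= 2 batches")

    # one-way variance explained by batch, per feature
    Y = V.to_numpy(dtype=float)
    obs = ~np.isnan(Y)
    grand = np.nanmean(np.where(obs, Y, np.nan), axis=0)
    ss_tot = np.nansum((Y - grand) ** 2, axis=0)
    ss_between = np.zeros(Y.shape[1])
    for b in batches.unique():
        rows = (batches == b).to_numpy()
        with np.errstate(invalid="ignore"):
            mean_b = np.nanmean(np.where(obs[rows], Y[rows], np.nan), axis=0)
        n_b = obs[rows].sum(axis=0)
        ss_between += np.where(n_b > 0, n_b * (mean_b - grand) ** 2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, ss_between / ss_tot, np.nan)

    complete = V.dropna(axis=1)
    if complete.shape[1] < 2:
        raise InputError("fewer than 2 complete features for PCA")
    centered = complete - complete.mean(axis=0)
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(centered.to_numpy())
    sil = float(silhouette_score(scores, batches.to_numpy()))
    return BatchDiagnostics(
        batch_r2=pd.Series(r2, index=V.columns),
        silhouette=sil,
        explained_variance_ratio=tuple(pca.explained_variance_ratio_[:2]),
        scores=pd.DataFrame(scores, index=V.index, columns=["PC1", "PC2"]),
    )
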