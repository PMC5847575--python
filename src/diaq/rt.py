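"""Per-run linear retention-time calibration against spiked iRT standards.

Each run's observed apex retention times (seconds) of the standard peptides
are regressed on their reference iRT values, ``rt = a_r * irt + b_r``;
mapping back, ``irt = (rt - b_r) / a_r``.  Cohort-level stability metrics
(per-standard apex SD across runs, RT CV, per-run calibration R²) summarise
chromatographic drift over a campaign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import InputError, LongReport
from .simulate import load_irt_reference


@dataclass
class RTStabilityReport:
    """Cohort retention-time stability summary."""

    per_standard: pd.DataFrame     # sd_seconds, cv_percent, n_runs per standard
    per_run_r2: pd.Series          # calibration R² per run
    mean_sd_seconds: float
    max_cv_percent: float
    n_standards: int

    def to_dict(self) -> dict:
        return {
            "rt.mean_sd_seconds": float(self.mean_sd_seconds),
            "rt.max_cv_percent": float(self.max_cv_percent),
            "rt.n_standards": int(self.n_standards),
            "rt.per_run_r2_median": float(self.per_run_r2.median()),
        }


class RTCalibrator(BaseEstimator):
    """Fit per-run linear RT ↔ iRT maps from standard peptides.

    Parameters
    ----------
    reference : pd.Series, optional
        Standard peptide id → reference iRT.  Defaults to the shipped
        11-peptide table.
    robust : bool, default False
        Use the median of pairwise slopes (Theil–Sen) instead of ordinary
        least squares; resistant to a single outlier standard.
    min_standards : int, default 2
        Runs with fewer detected standards are flagged unfit, not dropped.

    Attributes
    ----------
    calibration_ : pd.DataFrame
        Per run: ``slope``, ``intercept``, ``residual_sd``, ``n_standards``,
        ``fitted`` (bool).
    """

    def __init__(self, reference: pd.Series | None = None, robust: bool = False,
                 min_standards: int = 2):
        self.reference = reference
        self.robust = robust
        self.min_standards = min_standards

    def _ref(self) -> pd.Series:
        return self.reference if self.reference is not None else load_irt_reference()

    def fit(self, report: LongReport, y=None) -> "RTCalibrator":
        ref = self._ref()
        std = report.data[report.data["is_standard"]
                          & report.data["precursor_id"].isin(ref.index)]
        rows = {}
        for run in report.runs:
            sub = std[std["run_id"] == run].dropna(subset=["rt_observed"])
            n = len(sub)
            if n < max(2, self.min_standards):
                rows[run] = dict(slope=np.nan, intercept=np.nan,
                                 residual_sd=np.nan, n_standards=n, fitted=False)
                continue
            x = ref.loc[sub["precursor_id"]].to_numpy(dtype=float)
            t = sub["rt_observed"].to_numpy(dtype=float)
            if self.robust and n >= 3:
                ii, jj = np.triu_indices(n, k=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    slopes = (t[jj] - t[ii]) / (x[jj] - x[ii])
                slope = float(np.nanmedian(slopes))
                intercept = float(np.median(t - slope * x))
            else:
                slope, intercept = np.polyfit(x, t, 1)
            resid = t - (slope * x + intercept)
            dof = max(n - 2, 1)
            rows[run] = dict(
                slope=float(slope), intercept=float(intercept),
                residual_sd=float(np.sqrt((resid**2).sum() / dof)),
                n_standards=n, fitted=True,
            )
        self.calibration_ = pd.DataFrame.from_dict(rows, orient="index")
        if not self.calibration_["fitted"].any():
            raise InputError("no run could be calibrated (standards missing)")
        return self

    def _params_for(self, run_id: str) -> tuple[float, float]:
        try:
            row = self.calibration_.loc[run_id]
        except KeyError:
            raise InputError(f"run {run_id!r} not in calibration") from None
        if not bool(row["fitted"]):
            raise InputError(f"run {run_id!r} was flagged unfit (too few standards)")
        return float(row["slope"]), float(row["intercept"])

    def to_irt(self, run_id: str, rt_observed) -> np.ndarray | float:
        """Map observed RT (seconds) to iRT units: (rt − b_r) / a_r."""
        a, b = self._params_for(run_id)
        rt = np.asarray(rt_observed, dtype=float)
        out = (rt - b) / a
        return float(out) if out.ndim == 0 else out

    def from_irt(self, run_id: str, irt) -> np.ndarray | float:
        """Inverse map: iRT units to observed-RT seconds."""
        a, b = self._params_for(run_id)
        v = np.asarray(irt, dtype=float)
        out = a * v + b
        return float(out) if out.ndim == 0 else out

    def transform(self, report: LongReport) -> pd.DataFrame:
        """Return the tidy report with an ``irt`` column added per row."""
        cal = self.calibration_
        df = report.data.copy()
        slope = df["run_id"].map(cal["slope"])
        intercept = df["run_id"].map(cal["intercept"])
        df["irt"] = (df["rt_observed"] - intercept) / slope
        return df


def fit_run_calibration(report: LongReport, reference: pd.Series | None = None,
                        robust: bool = False) -> RTCalibrator:
    """Functional wrapper over :class:`RTCalibrator`."""
    return RTCalibrator(reference=reference, robust=robust).fit(report)


def rt_stability(report: LongReport, calibrator: RTCalibrator | None = None,
                 reference: pd.Series | None = None) -> RTStabilityReport:
    """Cohort RT-stability metrics.

    Per standard peptide: sample SD (seconds) and CV (%) of raw apex RTs
    across runs.  Per run: R² between observed RT and the RT predicted by
    that run's calibration for all rows with a usable iRT (the standards, or
    any peptide with a library iRT attached upstream).
    """
    ref = (reference if reference is not None
           else (calibrator._ref() if calibrator is not None else load_irt_reference()))
    if len(report.runs) < 2:
        raise InputError("RT stability needs at least 2 runs")
    std = report.data[report.data["is_standard"]
                      & report.data["precursor_id"].isin(ref.index)]
    g = std.groupby("precursor_id")["rt_observed"]
    per_standard = pd.DataFrame(
        {
            "sd_seconds": g.std(ddof=1),
            "cv_percent": g.std(ddof=1) / g.mean() * 100.0,
            "n_runs": g.count(),
        }
    ).dropna(subset=["sd_seconds"])

    per_run_r2 = pd.Series(dtype=float)
    if calibrator is not None:
        cal = calibrator.calibration_
        r2 = {}
        for run, sub in std.groupby("run_id"):
            if run not in cal.index or not bool(cal.loc[run, "fitted"]):
                continue
            a, b = cal.loc[run, "slope"], cal.loc[run, "intercept"]
            t = sub["rt_observed"].to_numpy(dtype=float)
            pred = a * ref.loc[sub["precursor_id"]].to_numpy(dtype=float) + b
            ss_res = float(((t - pred) ** 2).sum())
            ss_tot = float(((t - t.mean()) ** 2).sum())
            r2[run] = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        per_run_r2 = pd.Series(r2)

    return RTStabilityReport(
        per_standard=per_standard,
        per_run_r2=per_run_r2,
        mean_sd_seconds=float(per_standard["sd_seconds"].mean()),
        max_cv_percent=float(per_standard["cv_percent"].max()),
        n_standards=int(len(per_standard)),
    )
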