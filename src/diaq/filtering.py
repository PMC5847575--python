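"""Q-value filtering policies and robust-sum injection normalization.

Large DIA matrices face a completeness/depth trade-off: demanding a
confident identification in *every* run (complete filtering) discards most
of the matrix, while keeping any precursor ever identified (sparse) inflates
it with unreliable features.  Intermediate policies — a q-value percentile
or the median q-value across runs — retain precursors whose identification
is reproducible without over-weighting single bad runs.  Filtering acts at
the precursor level: a kept precursor keeps its intensities in all runs.

Injection-amount differences between runs are corrected by a robust sum:
precursors are ranked by cross-run median intensity, the most and least
intense tails are excluded, and each run is scaled so its summed intensity
over the remaining reference pool matches the cohort median.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ConfigurationError, InputError, QuantMatrix

FILTER_MODES = ("sparse", "complete", "percentile", "median")


class QValueFilter(BaseEstimator, TransformerMixin):
    """Precursor-level identification-confidence filter.

    A precursor is kept iff, at cutoff ``c`` (default 0.01):

    - ``sparse``:     at least one run has q ≤ c;
    - ``complete``:   measured in every run and q ≤ c in all of them;
    - ``percentile``: the fraction of runs with q ≤ c is ≥ ``percentile_fraction``;
    - ``median``:     the median q across runs is ≤ c.

    Missing q-values count as failing (q = 1).  The median is the lower
    median (no interpolation between order statistics), which makes median
    filtering exactly the percentile policy at fraction 0.5.  For a fixed
    cutoff the kept sets nest: complete ⊆ median ⊆ percentile(p ≤ 0.5) ⊆
    sparse.

    Parameters
    ----------
    mode : str
        One of ``sparse | complete | percentile | median``.
    qvalue_cutoff : float in (0, 1], default 0.01
    percentile_fraction : float in (0, 1), default 0.1
        Only used by ``percentile`` mode.

    Attributes
    ----------
    kept_precursors_ : pd.Index
    verdict_ : pd.Series  (bool per precursor)
    """

    def __init__(self, mode: str = "median", qvalue_cutoff: float = 0.01,
                 percentile_fraction: float = 0.1):
        self.mode = mode
        self.qvalue_cutoff = qvalue_cutoff
        self.percentile_fraction = percentile_fraction

    def _validate(self) -> None:
        if self.mode not in FILTER_MODES:
            raise ConfigurationError(
                f"unknown filter mode {self.mode!r}; choose from {FILTER_MODES}")
        if not 0 < self.qvalue_cutoff <= 1:
            raise ConfigurationError("qvalue_cutoff must be in (0, 1]")
        if self.mode == "percentile" and not 0 < self.percentile_fraction < 1:
            raise ConfigurationError("percentile_fraction must be in (0, 1)")

    def fit(self, X, y=None, *, qvalues: pd.DataFrame | None = None):
        """Decide the kept precursor set.

        ``X`` may itself be the runs × precursors q-value matrix, or the
        intensity matrix with ``qvalues`` given separately (aligned columns).
        """
        self._validate()
        q = qvalues if qvalues is not None else X
        if isinstance(q, QuantMatrix):
            raise ConfigurationError("pass the q-value matrix, not intensities")
        q = pd.DataFrame(q)
        qv = q.to_numpy(dtype=float)
        qv = np.where(np.isnan(qv), 1.0, qv)        # missing q fails
        passing = qv <= self.qvalue_cutoff
        measured_everywhere = ~np.isnan(q.to_numpy(dtype=float))
        if self.mode == "sparse":
            keep = passing.any(axis=0)
        elif self.mode == "complete":
            keep = passing.all(axis=0) & measured_everywhere.all(axis=0)
        elif self.mode == "percentile":
            keep = passing.mean(axis=0) >= self.percentile_fraction
        else:  # median (lower order statistic, so that median ≡ percentile(0.5))
            keep = np.quantile(qv, 0.5, axis=0, method="lower") <= self.qvalue_cutoff
        self.verdict_ = pd.Series(keep, index=q.columns)
        self.kept_precursors_ = q.columns[keep]
        self.n_features_in_ = q.shape[1]
        return self

    def transform(self, X):
        """Restrict an intensity matrix (or q-value frame) to kept precursors."""
        check_is_fitted(self, "kept_precursors_")
        if isinstance(X, QuantMatrix):
            return QuantMatrix(
                X.values.loc[:, self.kept_precursors_], X.scale,
                {p: X.precursor_to_protein[p] for p in self.kept_precursors_
                 if p in X.precursor_to_protein},
            )
        return pd.DataFrame(X).loc[:, self.kept_precursors_]


def qvalue_filter(data, qvalues: pd.DataFrame, mode: str = "median",
                  qvalue_cutoff: float = 0.01, percentile_fraction: float = 0.1):
    """Functional wrapper: returns (filtered data, kept precursor Index)."""
    f = QValueFilter(mode, qvalue_cutoff, percentile_fraction).fit(
        qvalues, qvalues=qvalues)
    return f.transform(data), f.kept_precursors_


def filter_audit(qvalues: pd.DataFrame, qvalue_cutoff: float = 0.01,
                 percentile_fraction: float = 0.1) -> pd.DataFrame:
    """Per-precursor verdict under every policy (for completeness curves)."""
    out = {}
    for mode in FILTER_MODES:
        f = QValueFilter(mode, qvalue_cutoff, percentile_fraction)
        out[mode] = f.fit(qvalues).verdict_
    return pd.DataFrame(out)


class RobustSumNormalizer(BaseEstimator, TransformerMixin):
    """Per-run scaling to a trimmed-sum reference pool.

    Operates on linear-scale intensities.  Precursors are ranked by their
    cross-run median intensity after dividing each run by its own median
    (so the ranking — hence the pool — is invariant to per-run injection
    scale, which makes the procedure exactly idempotent and equivariant to
    rescaling any run).  The top and bottom ``pool_fraction`` of the ranking
    are excluded and the pool is restricted to precursors present in every
    run, so each run's robust sum S_r adds identical members.  Run r is
    multiplied by f_r = median_r'(S_r') / S_r; afterwards all robust sums
    equal the cohort median.

    Attributes
    ----------
    pool_ : pd.Index           reference-pool precursor ids
    robust_sums_ : pd.Series   S_r per run (pre-scaling)
    factors_ : pd.Series       f_r per run
    target_sum_ : float        median robust sum
    """

    def __init__(self, pool_fraction: float = 0.10):
        self.pool_fraction = pool_fraction

    def fit(self, X, y=None):
        if not 0 < self.pool_fraction < 0.5:
            raise ConfigurationError("pool_fraction must be in (0, 0.5)")
        V = X.values if isinstance(X, QuantMatrix) else pd.DataFrame(X)
        if isinstance(X, QuantMatrix) and X.scale != "linear":
            raise ConfigurationError("robust-sum normalization expects linear scale")
        n = V.shape[1]
        present_half = (V.notna().mean(axis=0) >= 0.5).sum()
        if n < 10 or present_half < 10:
            raise InputError("need >= 10 precursors quantified in >= 50% of runs")
        run_median = V.median(axis=1, skipna=True)
        med = V.div(run_median, axis=0).median(axis=0, skipna=True)
        # deterministic ranking: median, ties broken by precursor id
        order = med.to_frame("m").assign(pid=med.index.astype(str)) \
                   .sort_values(["m", "pid"], kind="mergesort").index
        n_tail = int(np.floor(n * self.pool_fraction))
        middle = order[n_tail: n - n_tail] if n_tail > 0 else order
        complete = V.columns[V.notna().all(axis=0)]
        pool = pd.Index([p for p in middle if p in set(complete)])
        if len(pool) == 0:
            raise InputError(
                "reference pool is empty after removing incomplete precursors; "
                "use a smaller pool_fraction or filter for completeness first")
        self.pool_ = pool
        sums = V.loc[:, pool].sum(axis=1)
        self.robust_sums_ = sums
        self.target_sum_ = float(sums.median())
        self.factors_ = self.target_sum_ / sums
        return self

    def transform(self, X):
        check_is_fitted(self, "factors_")
        V = X.values if isinstance(X, QuantMatrix) else pd.DataFrame(X)
        missing_pool = [p for p in self.pool_ if p not in V.columns]
        if missing_pool:
            raise InputError(f"pool precursors absent from matrix: {missing_pool[:3]}")
        sums = V.loc[:, self.pool_].sum(axis=1)
        factors = self.target_sum_ / sums
        out = V.mul(factors, axis=0)
        if isinstance(X, QuantMatrix):
            return QuantMatrix(out, X.scale, dict(X.precursor_to_protein))
        return out


def robust_sum_normalize(matrix, pool_fraction: float = 0.10):
    """Functional wrapper: returns (normalized matrix, fitted normalizer)."""
    norm = RobustSumNormalizer(pool_fraction).fit(matrix)
    return norm.transform(matrix), norm
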