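"""Batch-effect correction for large acquisition campaigns.

Two complementary correctors, both operating on log2 runs × features
matrices:

:class:`ComBat`
    QC-anchored empirical-Bayes correction of additive and multiplicative
    per-(batch, feature) effects.  The signal of feature *g* in run *j* of
    batch *i* is modelled as

        y_ijg = alpha_g + X_j beta_g + gamma_ig + delta_ig eps_ijg

    where X carries the biological covariates (with the QC pool as one level
    of the condition factor, so QC runs anchor every batch), gamma_ig is the
    additive and delta_ig the multiplicative batch effect.  Per-feature
    estimates are shrunk towards batch-level priors (normal for gamma,
    inverse-gamma for delta²) whose hyperparameters are moment-matched
    across features, then removed:  y* = sigma_g/delta*_ig (z - gamma*_ig)
    + alpha_g + X beta_g.

:class:`SurrogateVariableCorrector`
    A supervised surrogate-variable approach: the least-variable half of the
    features serve as controls assumed free of biology; the dominant
    right-singular vectors of the row-centred control submatrix estimate
    unmodelled systematic variation, which is regressed out of every
    feature.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ConfigurationError, InputError, QuantMatrix


class ConvergenceError(RuntimeError):
    """Empirical-Bayes fixed-point iteration failed to converge."""


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, QuantMatrix):
        if X.scale != "log2":
            raise ConfigurationError("batch correction expects a log2-scale matrix")
        return X.values
    return pd.DataFrame(X)


def _wrap_like(X, values: pd.DataFrame):
    if isinstance(X, QuantMatrix):
        return QuantMatrix(values, X.scale, dict(X.precursor_to_protein))
    return values


def _covariate_matrix(covariates: pd.DataFrame | None, index) -> pd.DataFrame:
    """Expand covariates to a numeric design block (one-hot, first level dropped)."""
    if covariates is None or covariates.shape[1] == 0:
        return pd.DataFrame(index=index)
    cov = pd.DataFrame(covariates).loc[index]
    blocks = []
    for col in cov.columns:
        if pd.api.types.is_numeric_dtype(cov[col]):
            blocks.append(cov[[col]].astype(float))
        else:
            blocks.append(pd.get_dummies(cov[col], prefix=col, drop_first=True,
                                         dtype=float))
    return pd.concat(blocks, axis=1)


class ComBat(BaseEstimator, TransformerMixin):
    """Empirical-Bayes additive/multiplicative batch correction.

    Parameters
    ----------
    shrink : bool, default True
        Shrink per-feature batch estimates towards moment-matched priors
        (parametric adjustment).  With ``shrink=False`` the raw per-batch
        location/scale estimates are removed instead.
    tol : float, default 1e-4
        Convergence tolerance of the fixed-point iteration (max absolute
        change in gamma*, max relative change in delta²*).
    max_iter : int, default 100

    Fit requires ``batch`` (per-run labels) and optionally ``covariates``
    (per-run DataFrame; categorical columns are one-hot encoded).  Features
    with fewer than 2 observed values in any batch cannot be corrected and
    are passed through unchanged (``uncorrected_features_``).

    Attributes
    ----------
    alpha_ : pd.Series            per-feature grand intercept
    beta_ : pd.DataFrame          covariate coefficients (columns × features)
    sigma_ : pd.Series            pooled residual SD per feature
    gamma_hat_, gamma_star_ : pd.DataFrame   batches × features
    delta_sq_hat_, delta_sq_star_ : pd.DataFrame
    priors_ : pd.DataFrame        gamma_bar, tau_sq, lambda_bar, theta_bar per batch
    n_iter_, converged_ : iteration diagnostics
    """

    def __init__(self, shrink: bool = True, tol: float = 1e-4, max_iter: int = 100):
        self.shrink = shrink
        self.tol = tol
        self.max_iter = max_iter

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None, *, batch, covariates: pd.DataFrame | None = None):
        V = _as_frame(X)
        runs = V.index
        batch = pd.Series(np.asarray(batch), index=runs) if not isinstance(batch, pd.Series) else batch.loc[runs]
        levels = list(pd.unique(batch))
        K = len(levels)
        sizes = batch.value_counts()
        if (sizes < 2).any() and K > 1:
            small = sizes[sizes < 2].index.tolist()
            raise InputError(f"batches with fewer than 2 runs: {small}")

        B = pd.get_dummies(batch, dtype=float)[levels]          # n × K
        C = _covariate_matrix(covariates, runs)                 # n × p
        D = pd.concat([B, C], axis=1)
        self._check_rank(B, C)

        Y = V.to_numpy(dtype=float)
        n_runs, G = Y.shape
        obs = ~np.isnan(Y)
        b_idx = np.array([levels.index(b) for b in batch])

        # correctable: >= 2 observed values in every batch
        ok = np.ones(G, dtype=bool)
        for i in range(K):
            ok &= obs[b_idx == i].sum(axis=0) >= 2
        self.uncorrected_features_ = V.columns[~ok]

        Dm = D.to_numpy(dtype=float)
        P = Dm.shape[1]
        coef = np.full((P, G), np.nan)
        # solve feature-wise least squares, grouping identical missing patterns
        patterns: dict[bytes, list[int]] = {}
        for g in np.nonzero(ok)[0]:
            patterns.setdefault(obs[:, g].tobytes(), []).append(g)
        for key, feats in patterns.items():
            mask = np.frombuffer(key, dtype=bool)
            pinv = np.linalg.pinv(Dm[mask])
            coef[:, feats] = pinv @ np.where(obs[mask][:, feats],
                                             Y[mask][:, feats], 0.0)

        n_i = sizes.reindex(levels).to_numpy(dtype=float)
        w = n_i / n_i.sum()
        alpha = w @ coef[:K]                                    # grand mean
        beta = coef[K:]
        cov_term = Dm[:, K:] @ beta if P > K else np.zeros((n_runs, G))
        stand_mean = alpha[None, :] + cov_term                  # n × G
        resid = Y - (Dm @ coef)
        with warnings.catch_warnings():
            # features already flagged uncorrectable yield empty slices here
            warnings.simplefilter("ignore", RuntimeWarning)
            sigma_sq = np.nanmean(np.where(obs, resid, np.nan) ** 2, axis=0)
        sigma_sq = np.where(ok, sigma_sq, np.nan)
        if np.any(sigma_sq[ok] <= 0):
            # strictly constant features carry no batch information
            degenerate = V.columns[(sigma_sq <= 0) & ok]
            ok = ok & (sigma_sq > 0)
            self.uncorrected_features_ = self.uncorrected_features_.union(degenerate)
        sigma = np.sqrt(sigma_sq)

        Z = (Y - stand_mean) / sigma[None, :]
        gamma_hat = np.full((K, G), np.nan)
        delta_sq_hat = np.full((K, G), np.nan)
        counts = np.zeros((K, G))
        for i in range(K):
            zi = np.where(obs[b_idx == i], Z[b_idx == i], np.nan)
            counts[i] = (~np.isnan(zi)).sum(axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                gamma_hat[i] = np.nanmean(zi, axis=0)
                delta_sq_hat[i] = np.nanvar(zi, axis=0, ddof=1)

        priors = {}
        gamma_star = gamma_hat.copy()
        delta_sq_star = delta_sq_hat.copy()
        self.n_iter_, self.converged_, self.last_delta_ = 0, True, 0.0
        if K == 1:
            # a single batch carries no batch contrast: identity correction
            gamma_star = np.zeros_like(gamma_hat)
            delta_sq_star = np.ones_like(delta_sq_hat)
        elif self.shrink:
            for i in range(K):
                g = gamma_hat[i, ok]
                d = delta_sq_hat[i, ok]
                gamma_bar = float(np.mean(g))
                tau_sq = float(np.var(g, ddof=1))
                m = float(np.mean(d))
                s2 = float(np.var(d, ddof=1))
                if s2 <= 0:
                    lam, theta = np.inf, np.inf
                else:
                    lam = (m**2 + 2 * s2) / s2
                    theta = (m**3 + m * s2) / s2
                priors[levels[i]] = dict(gamma_bar=gamma_bar, tau_sq=tau_sq,
                                         lambda_bar=lam, theta_bar=theta)
                g_star, d_star, it, delta = self._iterate(
                    Z[b_idx == i][:, ok], obs[b_idx == i][:, ok],
                    gamma_hat[i, ok], delta_sq_hat[i, ok], counts[i, ok],
                    gamma_bar, tau_sq, lam, theta)
                gamma_star[i, ok] = g_star
                delta_sq_star[i, ok] = d_star
                self.n_iter_ = max(self.n_iter_, it)
                self.last_delta_ = max(self.last_delta_, delta)

        cols = V.columns
        self.batch_levels_ = levels
        self.batch_ = batch
        self.batch_sizes_ = sizes.reindex(levels)
        self.feature_names_in_ = cols
        self.alpha_ = pd.Series(alpha, index=cols)
        self.beta_ = pd.DataFrame(beta, index=D.columns[K:], columns=cols)
        self.sigma_ = pd.Series(sigma, index=cols)
        self.gamma_hat_ = pd.DataFrame(gamma_hat, index=levels, columns=cols)
        self.delta_sq_hat_ = pd.DataFrame(delta_sq_hat, index=levels, columns=cols)
        self.gamma_star_ = pd.DataFrame(gamma_star, index=levels, columns=cols)
        self.delta_sq_star_ = pd.DataFrame(delta_sq_star, index=levels, columns=cols)
        self.priors_ = pd.DataFrame(priors).T if priors else pd.DataFrame()
        self.stand_mean_ = pd.DataFrame(stand_mean, index=runs, columns=cols)
        self.corrected_mask_ = pd.Series(ok, index=cols)
        return self

    def _iterate(self, Zb, obs_b, g_hat, d_hat, n, gamma_bar, tau_sq, lam, theta):
        """Fixed-point iteration of the parametric posterior estimates."""
        g_old, d_old = g_hat.copy(), d_hat.copy()
        if not np.isfinite(lam):                    # degenerate spread: full shrink
            return np.full_like(g_hat, gamma_bar), d_hat.copy(), 0, 0.0
        Zb = np.where(obs_b, Zb, np.nan)
        for it in range(1, self.max_iter + 1):
            if tau_sq > 0:
                g_new = (n * tau_sq * g_hat + d_old * gamma_bar) / (n * tau_sq + d_old)
            else:
                g_new = np.full_like(g_hat, gamma_bar)
            with np.errstate(invalid="ignore"):
                sum2 = np.nansum((Zb - g_new[None, :]) ** 2, axis=0)
            d_new = (theta + 0.5 * sum2) / (n / 2.0 + lam - 1.0)
            delta = max(np.max(np.abs(g_new - g_old)),
                        np.max(np.abs(d_new - d_old) / np.maximum(d_old, 1e-12)))
            g_old, d_old = g_new, d_new
            if delta < self.tol:
                return g_old, d_old, it, float(delta)
        raise ConvergenceError(
            f"empirical-Bayes iteration did not converge in {self.max_iter} "
            f"steps (last delta {delta:.3g})")

    def _check_rank(self, B: pd.DataFrame, C: pd.DataFrame) -> None:
        M = B.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(M)
        confounded = []
        for col in C.columns:
            cand = np.column_stack([M, C[col].to_numpy(dtype=float)])
            r = np.linalg.matrix_rank(cand)
            if r == rank:
                confounded.append(col)
            else:
                M, rank = cand, r
        if confounded:
            raise InputError(
                "design matrix is rank deficient; covariate columns confounded "
                f"with batch (or each other): {confounded}")

    # -- application --------------------------------------------------------

    def transform(self, X):
        check_is_fitted(self, "gamma_star_")
        V = _as_frame(X)
        unknown = V.index.difference(self.stand_mean_.index)
        if len(unknown):
            raise InputError(f"runs absent from fitted design: {list(unknown)[:3]}")
        cols = self.feature_names_in_
        Y = V.loc[:, cols].to_numpy(dtype=float)
        stand = self.stand_mean_.loc[V.index].to_numpy()
        sigma = self.sigma_.to_numpy()
        b_idx = np.array([self.batch_levels_.index(b)
                          for b in self.batch_.loc[V.index]])
        gamma = self.gamma_star_.to_numpy()[b_idx]              # n × G
        delta = np.sqrt(self.delta_sq_star_.to_numpy())[b_idx]
        Z = (Y - stand) / sigma[None, :]
        out = (sigma[None, :] / delta) * (Z - gamma) + stand
        keep_raw = ~self.corrected_mask_.to_numpy()
        out[:, keep_raw] = Y[:, keep_raw]
        out_df = pd.DataFrame(out, index=V.index, columns=cols)
        return _wrap_like(X, out_df)

    def to_json_dict(self) -> dict:
        """Serializable per-feature model parameters for audit/re-application."""
        check_is_fitted(self, "gamma_star_")
        return {
            "batch_levels": list(map(str, self.batch_levels_)),
            "features": list(map(str, self.feature_names_in_)),
            "alpha": self.alpha_.tolist(),
            "sigma": self.sigma_.tolist(),
            "gamma_star": self.gamma_star_.to_numpy().tolist(),
            "delta_sq_star": self.delta_sq_star_.to_numpy().tolist(),
            "priors": self.priors_.to_dict() if len(self.priors_) else {},
            "n_iter": int(self.n_iter_),
        }


def fit_combat(matrix, design, shrink: bool = True, tol: float = 1e-4,
               max_iter: int = 100, covariate_columns: tuple[str, ...] | None = None
               ) -> ComBat:
    """Fit :class:`ComBat` from a matrix and a :class:`~diaq.io.SampleDesign`.

    QC anchoring: the condition factor passed as covariate is the design's
    ``strain`` (or first covariate) column, in which QC runs form their own
    level — QC profiles then inform the batch estimates in every batch
    without being treated as a biological group of interest.
    """
    d = design.data
    if covariate_columns is None:
        candidates = [c for c in d.columns
                      if c not in ("batch", "acq_order", "sample_type", "replicate_id")]
        covariate_columns = tuple(candidates)
    cov = d[list(covariate_columns)] if covariate_columns else None
    V = _as_frame(matrix)
    return ComBat(shrink=shrink, tol=tol, max_iter=max_iter).fit(
        matrix, batch=d.loc[V.index, "batch"], covariates=cov)


def apply_combat(matrix, model: ComBat):
    """Apply a fitted :class:`ComBat` model (functional wrapper)."""
    return model.transform(matrix)


class SurrogateVariableCorrector(BaseEstimator, TransformerMixin):
    """Supervised surrogate-variable estimation and removal.

    Features are ranked by variance across runs; the least-variable
    ``control_fraction`` form the control set, assumed to carry technical
    but not biological variation.  The top right-singular vectors of the
    row-centred control submatrix are the surrogate vectors; ``transform``
    regresses every feature on them (with intercept) and subtracts the
    fitted surrogate component.

    ``k="auto"`` keeps components while the singular value exceeds the 95th
    percentile of the matching singular value under row-wise permutation of
    the controls (``n_permutations`` draws, seeded by ``random_state``).

    Attributes
    ----------
    controls_ : pd.Index
    surrogates_ : pd.DataFrame   runs × k, orthonormal columns
    singular_values_ : np.ndarray
    k_ : int
    """

    def __init__(self, control_fraction: float = 0.5, k: int | str = 1,
                 n_permutations: int = 19, random_state: int = 0):
        self.control_fraction = control_fraction
        self.k = k
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y=None):
        V = _as_frame(X)
        n_runs, G = V.shape
        if n_runs < 3:
            raise InputError("surrogate estimation needs >= 3 runs")
        if not 0 < self.control_fraction <= 1:
            raise ConfigurationError("control_fraction must be in (0, 1]")
        if isinstance(self.k, int) and self.k >= n_runs:
            raise InputError("k must be smaller than the number of runs")
        variances = V.var(axis=0, ddof=1, skipna=True)
        rank = variances.to_frame("v").assign(pid=variances.index.astype(str)) \
                        .sort_values(["v", "pid"], kind="mergesort")
        n_ctrl = max(int(np.floor(self.control_fraction * G)), 1)
        controls = pd.Index(rank.index[:n_ctrl])
        M = V.loc[:, controls].to_numpy(dtype=float).T          # controls × runs
        # mean-impute residual missingness so the SVD is defined
        row_mean = np.nanmean(np.where(np.isnan(M), np.nan, M), axis=1)
        row_mean = np.where(np.isfinite(row_mean), row_mean, 0.0)
        M = np.where(np.isnan(M), row_mean[:, None], M)
        M = M - M.mean(axis=1, keepdims=True)                   # row-centre
        U, S, Vt = np.linalg.svd(M, full_matrices=False)

        if self.k == "auto":
            rng = np.random.default_rng(self.random_state)
            if not np.any(S > 0):
                k = 0
            else:
                perm_s = np.empty((self.n_permutations, len(S)))
                for p in range(self.n_permutations):
                    Mp = np.array([rng.permutation(row) for row in M])
                    Mp = Mp - Mp.mean(axis=1, keepdims=True)
                    perm_s[p] = np.linalg.svd(Mp, compute_uv=False)
                thresh = np.percentile(perm_s, 95, axis=0)
                k = 0
                while k < min(len(S), n_runs - 1) and S[k] > thresh[k]:
                    k += 1
        else:
            k = int(self.k) if np.any(S > 0) else 0
        self.controls_ = controls
        self.singular_values_ = S
        self.k_ = k
        self.surrogates_ = pd.DataFrame(
            Vt[:k].T, index=V.index, columns=[f"SV{i + 1}" for i in range(k)])
        self.feature_names_in_ = V.columns
        return self

    def transform(self, X):
        check_is_fitted(self, "surrogates_")
        V = _as_frame(X)
        if self.k_ == 0:
            return _wrap_like(X, V.copy())
        if not V.index.equals(self.surrogates_.index):
            if len(V) != len(self.surrogates_):
                raise InputError("run dimension does not match fitted surrogates")
            sv = self.surrogates_.reindex(V.index)
            if sv.isna().any().any():
                raise InputError("runs absent from fitted surrogates")
        else:
            sv = self.surrogates_
        Y = V.to_numpy(dtype=float)
        D = np.column_stack([np.ones(len(V)), sv.to_numpy()])
        obs = ~np.isnan(Y)
        out = Y.copy()
        patterns: dict[bytes, list[int]] = {}
        for g in range(Y.shape[1]):
            if obs[:, g].sum() > self.k_ + 1:
                patterns.setdefault(obs[:, g].tobytes(), []).append(g)
        for key, feats in patterns.items():
            mask = np.frombuffer(key, dtype=bool)
            coef = np.linalg.pinv(D[mask]) @ Y[mask][:, feats]
            surr_part = D[mask][:, 1:] @ coef[1:]
            block = out[np.ix_(mask, feats)]
            out[np.ix_(mask, feats)] = block - surr_part
        return _wrap_like(X, pd.DataFrame(out, index=V.index, columns=V.columns))


def estimate_surrogates(matrix, control_fraction: float = 0.5,
                        k: int | str = 1, random_state: int = 0
                        ) -> SurrogateVariableCorrector:
    """Functional wrapper over :class:`SurrogateVariableCorrector`."""
    return SurrogateVariableCorrector(
        control_fraction=control_fraction, k=k, random_state=random_state
    ).fit(matrix)


def regress_out_surrogates(matrix, model: SurrogateVariableCorrector):
    """Remove fitted surrogate components from a matrix."""
    return model.transform(matrix)
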