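"""Correlation-based quantifier-peptide selection and geometric protein rollup.

Not every peptide of a protein tracks the protein's abundance — peptides may
be differentially modified, mis-assigned or poorly extracted.  Rather than
picking quantifier peptides by abundance, members of each protein group are
scored by their mean pairwise Pearson correlation across runs and the
inconsistent ones are removed by greedy backward elimination.  The surviving
peptides are geometrically averaged into the protein quantity (equivalently,
their log2 intensities are arithmetically averaged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ConfigurationError, InputError, QuantMatrix


@dataclass
class PeptideGroup:
    """Selection outcome for one protein."""

    protein_id: str
    members: list[str]
    selected: list[str]
    scores: dict[str, float]            # mean pairwise correlation at final round
    removals: list[tuple[str, float, int]] = field(default_factory=list)
    flagged: bool = False               # too few members for selection


def _mean_pairwise_scores(sub: pd.DataFrame, method: str, min_overlap: int
                          ) -> pd.Series:
    """Mean pairwise correlation of each member with the others.

    Pairs sharing fewer than ``min_overlap`` runs contribute a missing score.
    """
    corr = sub.corr(method=method, min_periods=min_overlap)
    np.fill_diagonal(corr.values, np.nan)
    return corr.mean(axis=1, skipna=True)


class CorrelationPeptideSelector(BaseEstimator, TransformerMixin):
    """Greedy backward elimination of inconsistent peptides per protein.

    While the worst member's mean pairwise correlation is below ``rho_min``
    and more than two members remain, the worst member is removed and scores
    are recomputed.  Proteins with two or fewer members keep all members and
    are flagged.  Ties break deterministically on (score, precursor id).

    Parameters
    ----------
    rho_min : float, default 0.5
    min_overlap : int, default 6
        Minimum shared runs for a pair to contribute a correlation.
    method : {"pearson", "spearman"}, default "pearson"

    Attributes
    ----------
    groups_ : dict[str, PeptideGroup]
    selected_precursors_ : pd.Index
    """

    def __init__(self, rho_min: float = 0.5, min_overlap: int = 6,
                 method: str = "pearson"):
        self.rho_min = rho_min
        self.min_overlap = min_overlap
        self.method = method

    def fit(self, X, y=None, *, mapping: dict[str, str] | None = None):
        V = X.values if isinstance(X, QuantMatrix) else pd.DataFrame(X)
        if mapping is None and isinstance(X, QuantMatrix):
            mapping = X.precursor_to_protein
        if not mapping:
            raise InputError("empty precursor-to-protein mapping")
        missing = [p for p in V.columns if p not in mapping]
        if missing:
            raise InputError(f"precursors without protein mapping: {missing[:3]}")
        if self.method not in ("pearson", "spearman"):
            raise ConfigurationError(f"unknown correlation method {self.method!r}")

        groups: dict[str, PeptideGroup] = {}
        by_protein: dict[str, list[str]] = {}
        for pid in V.columns:
            by_protein.setdefault(mapping[pid], []).append(pid)
        for prot in sorted(by_protein):
            members = sorted(by_protein[prot])
            if len(members) <= 2:
                scores = {}
                if len(members) == 2:
                    s = _mean_pairwise_scores(V[members], self.method,
                                              self.min_overlap)
                    scores = {m: float(s[m]) for m in members}
                groups[prot] = PeptideGroup(prot, members, list(members),
                                            scores, flagged=True)
                continue
            selected = list(members)
            removals = []
            rnd = 0
            while len(selected) > 2:
                scores = _mean_pairwise_scores(V[selected], self.method,
                                               self.min_overlap)
                # worst member: lowest score, ties by precursor id; a missing
                # score (insufficient overlap everywhere) counts as worst
                ranked = sorted(selected,
                                key=lambda m: (not np.isnan(scores[m]),
                                               scores[m], m))
                worst = ranked[0]
                worst_score = float(scores[worst])
                if not np.isnan(worst_score) and worst_score >= self.rho_min:
                    break
                rnd += 1
                removals.append((worst, worst_score, rnd))
                selected.remove(worst)
            final_scores = _mean_pairwise_scores(V[selected], self.method,
                                                 self.min_overlap)
            groups[prot] = PeptideGroup(
                prot, members, selected,
                {m: float(final_scores[m]) for m in selected},
                removals=removals)
        self.groups_ = groups
        self.selected_precursors_ = pd.Index(
            [m for g in groups.values() for m in g.selected])
        return self

    def transform(self, X):
        """Restrict the matrix to selected quantifier peptides."""
        check_is_fitted(self, "groups_")
        V = X.values if isinstance(X, QuantMatrix) else pd.DataFrame(X)
        keep = [c for c in V.columns if c in set(self.selected_precursors_)]
        out = V.loc[:, keep]
        if isinstance(X, QuantMatrix):
            return QuantMatrix(out, X.scale,
                               {p: X.precursor_to_protein[p] for p in keep})
        return out

    def audit_table(self) -> pd.DataFrame:
        """Selection audit: one row per (protein, peptide) with verdicts."""
        check_is_fitted(self, "groups_")
        rows = []
        for g in self.groups_.values():
            removed = {m: (s, r) for m, s, r in g.removals}
            for m in g.members:
                kept = m in g.selected
                score = g.scores.get(m, removed.get(m, (np.nan,))[0])
                rows.append({"protein_id": g.protein_id, "precursor_id": m,
                             "score": score, "kept": kept,
                             "removal_round": removed.get(m, (None, None))[1],
                             "flagged": g.flagged})
        return pd.DataFrame(rows)


class GeometricProteinRollup(BaseEstimator, TransformerMixin):
    """Geometric averaging of selected peptides into protein quantities.

    For each (protein, run): if at least ``min_present_fraction`` of the
    selected members are present, the protein value is the geometric mean of
    the present members (on linear scale; equivalently the arithmetic mean
    of their log2 values); otherwise missing.  Output scale matches input.
    """

    def __init__(self, min_present_fraction: float = 0.5):
        self.min_present_fraction = min_present_fraction

    def fit(self, X, y=None, *, groups: dict[str, PeptideGroup] | None = None,
            mapping: dict[str, str] | None = None):
        if groups is None:
            if mapping is None and isinstance(X, QuantMatrix):
                mapping = X.precursor_to_protein
            if not mapping:
                raise InputError("provide peptide groups or a mapping")
            groups = {}
            by_protein: dict[str, list[str]] = {}
            for pid, prot in mapping.items():
                by_protein.setdefault(prot, []).append(pid)
            for prot, members in sorted(by_protein.items()):
                groups[prot] = PeptideGroup(prot, sorted(members),
                                            sorted(members), {})
        self.groups_ = groups
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "groups_")
        V = X.values if isinstance(X, QuantMatrix) else pd.DataFrame(X)
        scale = X.scale if isinstance(X, QuantMatrix) else "log2"
        cols = set(V.columns)
        out = {}
        self.n_peptides_used_ = {}
        for prot, g in self.groups_.items():
            absent = [m for m in g.selected if m not in cols]
            if absent:
                raise InputError(
                    f"group {prot} references precursors absent from the "
                    f"matrix: {absent[:3]}")
            sub = V[g.selected]
            logs = sub if scale == "log2" else np.log2(sub.where(sub > 0))
            frac = logs.notna().mean(axis=1)
            mean_log = logs.mean(axis=1, skipna=True)
            mean_log[frac < self.min_present_fraction] = np.nan
            out[prot] = mean_log if scale == "log2" else np.exp2(mean_log)
            self.n_peptides_used_[prot] = len(g.selected)
        return pd.DataFrame(out, index=V.index)


def select_peptides(matrix, mapping: dict[str, str] | None = None,
                    rho_min: float = 0.5, min_overlap: int = 6,
                    method: str = "pearson") -> CorrelationPeptideSelector:
    """Functional wrapper over :class:`CorrelationPeptideSelector`."""
    return CorrelationPeptideSelector(rho_min, min_overlap, method).fit(
        matrix, mapping=mapping)


def rollup_geometric(matrix, groups=None, mapping=None,
                     min_present_fraction: float = 0.5) -> pd.DataFrame:
    """Roll a peptide matrix up to proteins (runs × proteins DataFrame)."""
    r = GeometricProteinRollup(min_present_fraction).fit(
        matrix, groups=groups, mapping=mapping)
    return r.transform(matrix)
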