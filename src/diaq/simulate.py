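"""Synthetic DIA precursor reports with known ground truth.

The generator emulates the structure of a large SWATH acquisition campaign:
tens of strains measured in replicates, acquired in a few batches with a
pooled QC sample injected every 10–12 runs, additive and multiplicative
per-(batch, feature) effects, per-run injection-amount offsets,
abundance-dependent dropout, a small rate of false identifications carrying
large q-values, and per-run linear retention-time drift around spiked iRT
standards.  Every planted quantity is returned alongside the report so each
pipeline stage can be scored against truth.

The generative model on the log2 scale, for feature ``g`` in run ``j`` of
batch ``i`` and strain ``s``::

    y_jg = base_g + effect_{g,s} + inj_j + a_{i,g} + d_{i,g} * eps_jg

with ``eps_jg ~ N(0, sigma_tech^2)``, ``a_{i,g} ~ N(0, batch_add_sd^2)`` and
``d_{i,g}^2`` inverse-gamma with mean 1 — the same additive/multiplicative
family the empirical-Bayes corrector estimates, so parameter recovery can be
tested exactly.  QC runs carry the pooled mean of all strain profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import LongReport, SampleDesign

LN2 = float(np.log(2.0))


def lognormal_cv(sigma_log2: float | np.ndarray) -> float | np.ndarray:
    """Linear-scale CV of a log2-normal variable with log2 SD ``sigma_log2``.

    CV = sqrt(exp((sigma * ln 2)^2) - 1).
    """
    return np.sqrt(np.expm1((np.asarray(sigma_log2, dtype=float) * LN2) ** 2))


def cv_to_sigma_log2(cv: float) -> float:
    """Inverse of :func:`lognormal_cv`: log2 SD giving linear CV ``cv``."""
    return float(np.sqrt(np.log1p(cv**2)) / LN2)


def load_irt_reference() -> pd.Series:
    """The shipped iRT standard table (peptide id → reference iRT)."""
    with resources.files("diaq.data").joinpath("irt_reference.tsv").open() as fh:
        tab = pd.read_csv(fh, sep="\t")
    return tab.set_index("peptide_id")["irt"]


@dataclass
class TruthParams:
    """Parameters of the synthetic campaign.

    Defaults reproduce the scale of the reference study design: 38 strains
    with 8 replicates balanced over 3 batches (~304 study runs), a pooled QC
    every 10–12 injections (≥10 per batch, ~330 runs total), ~7.5% technical
    CV, additive batch offsets of 0.18 log2 units (≈17% cross-batch CV),
    60-min gradients with 17.7 s apex RT jitter, and 1% false identifications.
    """

    n_proteins: int = 250
    peptides_per_protein: tuple[int, int, int] = (2, 4, 8)  # (min, mode, max)
    n_strains: int = 38
    replicates_per_strain: int = 8
    n_batches: int = 3
    qc_every: tuple[int, int] = (10, 12)
    tech_cv: float = 0.075
    batch_add_sd: float = 0.18            # log2 units
    batch_mult_shape: float = 40.0        # inverse-gamma shape of delta^2
    effect_sd: float = 0.30               # log2 units, strain effects
    injection_sd: float = 0.15            # log2 units, per-run scale offsets
    missing_logit_slope: float = 0.8      # per log2 unit
    missing_logit_mid: float = 9.0        # log2 a.u.
    false_id_rate: float = 0.01
    rt_gradient_min: float = 60.0
    rt_jitter_sd: float = 17.7            # seconds
    rt_slope_sd: float = 0.002            # relative SD of per-run slope
    rt_intercept_sd: float = 5.0          # seconds
    base_mean: float = 13.0               # log2 a.u., protein abundance centre
    base_sd: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_strains", "replicates_per_strain", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("tech_cv", "false_id_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if min(self.qc_every) < 2:
            raise ValueError("qc_every interval must be >= 2")
        if self.batch_mult_shape <= 2:
            raise ValueError("batch_mult_shape must exceed 2 (finite variance)")

    @property
    def sigma_tech_log2(self) -> float:
        return cv_to_sigma_log2(self.tech_cv) if self.tech_cv > 0 else 0.0


@dataclass
class SyntheticDataset:
    """A generated report + design + the planted truth."""

    report: LongReport
    design: SampleDesign
    truth: dict = field(default_factory=dict)
    params: TruthParams = field(default_factory=TruthParams)


def _design_table(params: TruthParams, rng: np.random.Generator) -> pd.DataFrame:
    """Acquisition plan: batched study runs with interspersed QC injections.

    Replicates of every strain are balanced across batches; each batch opens
    with a QC injection, a further QC follows every k study runs with k drawn
    uniformly from the ``qc_every`` interval, and each batch closes with a QC.
    """
    # replicate counts per batch, e.g. 8 replicates over 3 batches -> 3,3,2
    base, extra = divmod(params.replicates_per_strain, params.n_batches)
    rows = []
    qc_lo, qc_hi = min(params.qc_every), max(params.qc_every)
    order = 0
    qc_counter = 0
    for b in range(params.n_batches):
        n_rep_b = base + (1 if b < extra else 0)
        study = [
            (s, r) for s in range(params.n_strains) for r in range(n_rep_b)
        ]
        perm = rng.permutation(len(study))
        study = [study[p] for p in perm]

        def add_qc():
            nonlocal order, qc_counter
            order += 1
            qc_counter += 1
            rows.append(
                {"run_id": f"R{order:03d}", "acq_order": order, "batch": f"B{b + 1}",
                 "sample_type": "QC", "strain": "QC",
                 "replicate_id": f"QC{qc_counter:02d}"}
            )

        add_qc()
        until_qc = int(rng.integers(qc_lo, qc_hi + 1))
        since_qc = 0
        for s, r in study:
            order += 1
            rep_index = b * (base + 1) + r  # unique within strain
            rows.append(
                {"run_id": f"R{order:03d}", "acq_order": order, "batch": f"B{b + 1}",
                 "sample_type": "study", "strain": f"S{s + 1:02d}",
                 "replicate_id": f"rep{rep_index + 1}"}
            )
            since_qc += 1
            if since_qc >= until_qc:
                add_qc()
                since_qc = 0
                until_qc = int(rng.integers(qc_lo, qc_hi + 1))
        if since_qc > 0:
            add_qc()
    return pd.DataFrame(rows).set_index("run_id")


def simulate(params: TruthParams | None = None) -> SyntheticDataset:
    """Generate a synthetic precursor report with full ground truth."""
    params = params or TruthParams()
    rng = np.random.default_rng(params.seed)

    design_df = _design_table(params, rng)
    runs = design_df.index.to_numpy()
    n_runs = len(runs)
    batches = design_df["batch"].to_numpy()
    batch_levels = [f"B{i + 1}" for i in range(params.n_batches)]
    strains = design_df["strain"].to_numpy()

    # feature roster
    lo, mode, hi = params.peptides_per_protein
    n_pep = np.clip(
        np.rint(rng.triangular(lo, mode, hi + 1, size=params.n_proteins)).astype(int),
        lo, hi,
    )
    protein_ids = np.repeat(
        [f"PROT{p + 1:04d}" for p in range(params.n_proteins)], n_pep
    )
    precursor_ids = np.array(
        [f"{prot}_PEP{k + 1:02d}.2"
         for prot, cnt in zip([f"PROT{p + 1:04d}" for p in range(params.n_proteins)], n_pep)
         for k in range(cnt)]
    )
    n_feat = len(precursor_ids)
    prot_index = np.repeat(np.arange(params.n_proteins), n_pep)

    # planted signal components (log2)
    protein_base = rng.normal(params.base_mean, params.base_sd, params.n_proteins)
    peptide_offset = rng.normal(0.0, 1.0, n_feat)
    base = protein_base[prot_index] + peptide_offset
    # strain effects act at the protein level, shared by sibling peptides
    protein_effect = rng.normal(0.0, params.effect_sd,
                                (params.n_proteins, params.n_strains))
    effect = protein_effect[prot_index, :]          # features × strains
    batch_add = rng.normal(0.0, params.batch_add_sd,
                           (params.n_batches, n_feat))
    if params.batch_add_sd == 0:
        batch_add[:] = 0.0
    shape = params.batch_mult_shape
    # inverse-gamma(shape, shape-1): mean 1, dispersion shrinks as shape grows
    delta_sq = (shape - 1.0) / rng.gamma(shape, 1.0, (params.n_batches, n_feat))
    batch_mult = np.sqrt(delta_sq)
    injection = rng.normal(0.0, params.injection_sd, n_runs)

    strain_levels = [f"S{s + 1:02d}" for s in range(params.n_strains)]
    strain_idx = {s: i for i, s in enumerate(strain_levels)}
    batch_idx_map = {b: i for i, b in enumerate(batch_levels)}
    b_of_run = np.array([batch_idx_map[b] for b in batches])

    pooled_effect = effect.mean(axis=1)             # QC = mixture of all samples
    cond = np.where(
        strains == "QC",
        -1,
        [strain_idx.get(s, -1) for s in strains],
    )
    mean_term = np.empty((n_runs, n_feat))
    for j in range(n_runs):
        eff = pooled_effect if cond[j] < 0 else effect[:, cond[j]]
        mean_term[j] = base + eff + batch_add[b_of_run[j]] + injection[j]
    eps = rng.normal(0.0, 1.0, (n_runs, n_feat))
    sigma = params.sigma_tech_log2
    y_log2 = mean_term + batch_mult[b_of_run] * (sigma * eps)

    # abundance-dependent dropout
    p_present = expit(params.missing_logit_slope * (y_log2 - params.missing_logit_mid))
    present = rng.random((n_runs, n_feat)) < p_present

    # q-values: ~false_id_rate of present cells are false IDs with large q
    false_cell = rng.random((n_runs, n_feat)) < params.false_id_rate
    q_true = rng.uniform(1e-5, 0.01, (n_runs, n_feat))
    q_false = rng.uniform(0.02, 1.0, (n_runs, n_feat))
    qvalues = np.where(false_cell, q_false, q_true)

    # retention times: per-run linear map of reference iRT plus apex jitter
    irt_ref = load_irt_reference()
    gradient_s = params.rt_gradient_min * 60.0
    slope0 = 0.8 * gradient_s / 130.0               # maps iRT -25..105 into gradient
    intercept0 = 0.1 * gradient_s + 25.0 * slope0
    feat_irt = rng.uniform(-25.0, 105.0, n_feat)
    run_slope = slope0 * rng.normal(1.0, params.rt_slope_sd, n_runs)
    run_intercept = intercept0 + rng.normal(0.0, params.rt_intercept_sd, n_runs)
    rt_feat = (run_slope[:, None] * feat_irt[None, :] + run_intercept[:, None]
               + rng.normal(0.0, params.rt_jitter_sd, (n_runs, n_feat)))

    # assemble tidy rows (vectorised over the present mask)
    jj, gg = np.nonzero(present)
    rows = pd.DataFrame(
        {
            "run_id": runs[jj],
            "precursor_id": precursor_ids[gg],
            "protein_id": protein_ids[gg],
            "intensity": np.exp2(y_log2[jj, gg]),
            "qvalue": qvalues[jj, gg],
            "rt_observed": rt_feat[jj, gg],
            "is_standard": False,
        }
    )

    # iRT standards: present in every run, confidently identified, abundant
    std_ids = irt_ref.index.to_numpy()
    n_std = len(std_ids)
    std_y = (15.0 + rng.normal(0.0, 0.2, n_std)[None, :]
             + injection[:, None]
             + rng.normal(0.0, sigma if sigma > 0 else 0.0, (n_runs, n_std)))
    std_rt = (run_slope[:, None] * irt_ref.to_numpy()[None, :]
              + run_intercept[:, None]
              + rng.normal(0.0, params.rt_jitter_sd, (n_runs, n_std)))
    std_rows = pd.DataFrame(
        {
            "run_id": np.repeat(runs, n_std),
            "precursor_id": np.tile(std_ids, n_runs),
            "protein_id": "IRT_STANDARD",
            "intensity": np.exp2(std_y).ravel(),
            "qvalue": rng.uniform(1e-5, 0.001, n_runs * n_std),
            "rt_observed": std_rt.ravel(),
            "is_standard": True,
        }
    )

    report = LongReport(
        pd.concat([rows, std_rows], ignore_index=True).reset_index(drop=True)
    )
    truth = {
        "base": pd.Series(base, index=precursor_ids),
        "protein_base": pd.Series(
            protein_base, index=[f"PROT{p + 1:04d}" for p in range(params.n_proteins)]
        ),
        "effects": pd.DataFrame(effect, index=precursor_ids, columns=strain_levels),
        "batch_additive": pd.DataFrame(batch_add, index=batch_levels,
                                       columns=precursor_ids),
        "batch_mult": pd.DataFrame(batch_mult, index=batch_levels,
                                   columns=precursor_ids),
        "injection": pd.Series(injection, index=runs),
        "rt_slope": pd.Series(run_slope, index=runs),
        "rt_intercept": pd.Series(run_intercept, index=runs),
        "feature_irt": pd.Series(feat_irt, index=precursor_ids),
        "false_id": pd.DataFrame(false_cell & present, index=runs,
                                 columns=precursor_ids),
        "params": asdict(params),
    }
    return SyntheticDataset(report, SampleDesign(design_df), truth, params)


def truth_cv(dataset: SyntheticDataset) -> pd.DataFrame:
    """Closed-form expected linear-scale QC CVs implied by the planted SDs.

    Per feature: ``intra_cv`` is the QC-count-weighted mean over batches of
    the within-batch CV (multiplicative factor × technical SD), ``cross_cv``
    adds the between-batch spread of the additive offsets.  Per-run injection
    offsets are excluded — normalization removes them before CVs are read.
    """
    params = dataset.params
    design = dataset.design.data
    qc = design[design["sample_type"] == "QC"]
    if len(qc) < 2:
        raise ValueError("dataset has fewer than 2 QC runs")
    sigma = params.sigma_tech_log2
    add = dataset.truth["batch_additive"]           # batches × features
    mult = dataset.truth["batch_mult"]
    n_qc = qc.groupby("batch").size().reindex(add.index).fillna(0).to_numpy()
    w = n_qc / n_qc.sum()
    within_sd = mult.to_numpy() * sigma             # batches × features
    intra_cv = lognormal_cv(within_sd)
    intra = (w[:, None] * intra_cv).sum(axis=0)
    a = add.to_numpy()
    mean_a = (w[:, None] * a).sum(axis=0)
    between_var = (w[:, None] * (a - mean_a) ** 2).sum(axis=0)
    within_var = (w[:, None] * within_sd**2).sum(axis=0)
    cross = lognormal_cv(np.sqrt(between_var + within_var))
    return pd.DataFrame(
        {"intra_cv": intra, "cross_cv": cross}, index=add.columns
    )
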