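"""BS-BOLD coupling: per-run GLM and covariate-adjusted group test.

Each parcel's preprocessed time series is regressed on the HRF-convolved
burst-suppression regressor; the per-parcel beta measures how strongly that
parcel's BOLD signal follows the burst/suppression alternation.  At the group
level the betas are tested against zero with a one-sample model that includes
subject indicator covariates (runs are repeated measures within animals), with
Bonferroni correction across parcels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._glm import DesignError, check_full_rank, ols_contrast_t, subject_dummies
from .bspattern import VolumeRegressor
from .preproc import BOLDRun


@dataclass
class CouplingResult:
    """Per-parcel coupling betas and t statistics for one run."""

    betas: np.ndarray
    tstats: np.ndarray
    region_labels: list[str]
    run_id: str = ""
    subject: str = ""

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.tstats = np.asarray(self.tstats, dtype=float)
        if not (len(self.betas) == len(self.tstats) == len(self.region_labels)):
            raise ValueError("betas, tstats and labels must have equal length")
        if not (np.isfinite(self.betas).all() and np.isfinite(self.tstats).all()):
            raise ValueError("coupling estimates must be finite")


@dataclass
class GroupCouplingResult:
    """Group-level coupling inference per parcel."""

    tstats: np.ndarray
    pvalues: np.ndarray
    significant: np.ndarray
    mean_betas: np.ndarray
    region_labels: list[str]
    n_runs: int
    alpha: float
    covariates: list[str]


def fit_coupling_glm(run: BOLDRun, regressor: VolumeRegressor | None = None) -> CouplingResult:
    """Per-parcel OLS of the run's series on [intercept, BS regressor].

    Uses the run's attached regressor when none is passed.  The regressor is
    mean-centered, so betas are invariant to intercept shifts.
    """
    regressor = regressor if regressor is not None else run.bs_regressor
    if regressor is None:
        raise ValueError(f"run {run.run_id or run.subject}: no BS regressor available")
    r = np.asarray(regressor.values, dtype=float)
    if r.size != run.n_volumes:
        raise ValueError(
            f"regressor length {r.size} does not match {run.n_volumes} volumes"
        )
    if r.std() == 0:
        raise DesignError("degenerate design: BS regressor has zero variance")
    X = np.column_stack([np.ones_like(r), r - r.mean()])
    beta, t, _, _ = ols_contrast_t(X, run.data.T, coef_index=1)
    return CouplingResult(
        betas=beta,
        tstats=t,
        region_labels=list(run.region_labels),
        run_id=run.run_id,
        subject=run.subject,
    )


def group_coupling_test(
    results: list[CouplingResult],
    subjects: list[str] | None = None,
    alpha: float = 0.05,
) -> GroupCouplingResult:
    """Covariate-adjusted one-sample test of coupling betas across runs.

    Per parcel, betas are modeled on [intercept, subject indicators]; the
    intercept t-statistic tests the (reference-subject-adjusted) group mean
    against zero.  Bonferroni correction across parcels at ``alpha``.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 runs for a group test")
    labels = results[0].region_labels
    for r in results:
        if r.region_labels != labels:
            raise ValueError("all runs must share the same parcellation")
    subjects = subjects if subjects is not None else [r.subject for r in results]
    if len(subjects) != len(results):
        raise ValueError("one subject label per run is required")
    B = np.stack([r.betas for r in results])  # runs x parcels
    dummies, names = subject_dummies(subjects)
    X = np.column_stack([np.ones(len(results)), dummies])
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError(
            f"insufficient data: {X.shape[0]} runs for {X.shape[1]} model columns"
        )
    check_full_rank(X, ["intercept", *names])
    _, t, p, _ = ols_contrast_t(X, B, coef_index=0)
    sig = p < alpha / len(labels)
    return GroupCouplingResult(
        tstats=t,
        pvalues=p,
        significant=sig,
        mean_betas=B.mean(axis=0),
        region_labels=list(labels),
        n_runs=len(results),
        alpha=alpha,
        covariates=names,
    )
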