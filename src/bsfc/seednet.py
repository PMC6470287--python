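"""Seed-based connectivity: PCC-like (default-mode) and thalamic seeds.

The seed regressor is the mean preprocessed time course over the seed
regions; every other parcel is regressed on it, and the beta coefficient is
the connectivity strength.  Group inference mirrors the edgewise analysis:
covariate-adjusted one-sample tests within each group and a two-group linear
model with subject indicators for the BS-vs-SW difference, Bonferroni
corrected across target parcels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._glm import check_full_rank, ols_contrast_t, subject_dummies
from .preproc import BOLDRun

# default seeds on the packaged parcellation
PCC_SEED_REGIONS = ("L_CCp", "R_CCp")
THALAMUS_SEED_REGIONS = ("L_Thal", "R_Thal")


@dataclass(frozen=True)
class SeedSpec:
    """A named set of seed regions (e.g. bilateral PCC)."""

    name: str
    seed_regions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.seed_regions:
            raise ValueError("seed_regions must be non-empty")


def default_seeds() -> list[SeedSpec]:
    return [
        SeedSpec("PCC", PCC_SEED_REGIONS),
        SeedSpec("thalamus", THALAMUS_SEED_REGIONS),
    ]


@dataclass
class SeedMap:
    """Per-target connectivity betas for one run and one seed."""

    seed_name: str
    target_labels: list[str]
    betas: np.ndarray
    tstats: np.ndarray
    subject: str = ""
    group: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.tstats = np.asarray(self.tstats, dtype=float)
        if not (len(self.betas) == len(self.tstats) == len(self.target_labels)):
            raise ValueError("betas, tstats, target_labels must align")
        if not np.isfinite(self.betas).all():
            raise ValueError("betas must be finite")


def seed_connectivity(run: BOLDRun, seed: SeedSpec) -> SeedMap:
    """Per-target OLS of each non-seed parcel on the mean seed time course."""
    missing = [r for r in seed.seed_regions if r not in run.region_labels]
    if missing:
        raise ValueError(f"seed regions not in parcellation: {missing}")
    idx = [run.region_labels.index(r) for r in seed.seed_regions]
    seed_ts = run.data[idx].mean(axis=0)
    if seed_ts.std() == 0:
        raise ValueError(f"degenerate seed {seed.name!r}: constant mean time course")
    targets = [i for i in range(run.n_parcels) if i not in idx]
    X = np.column_stack([np.ones_like(seed_ts), seed_ts - seed_ts.mean()])
    beta, t, _, _ = ols_contrast_t(X, run.data[targets].T, coef_index=1)
    return SeedMap(
        seed_name=seed.name,
        target_labels=[run.region_labels[i] for i in targets],
        betas=beta,
        tstats=t,
        subject=run.subject,
        group=run.group,
        run_id=run.run_id,
    )


def seed_group_compare(
    maps: list[SeedMap],
    groups: list[str] | None = None,
    subjects: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Within-group one-sample tests and BS-vs-SW comparison per target.

    Within each group, target betas are tested against zero with subject
    covariates; between groups, betas are modeled on [intercept, group,
    subject indicators] and the group coefficient tested.  All tests are
    Bonferroni corrected across targets at ``alpha``.
    """
    groups = groups if groups is not None else [m.group for m in maps]
    subjects = subjects if subjects is not None else [m.subject for m in maps]
    if len({*groups}) < 2:
        raise ValueError("both groups must be present")
    labels = maps[0].target_labels
    for m in maps:
        if m.target_labels != labels:
            raise ValueError("all maps must share the same targets")
    B = np.stack([m.betas for m in maps])
    groups_a = np.asarray(groups, dtype=object)
    n_targets = len(labels)
    out = pd.DataFrame({"target": labels})

    for gname in ("BS", "SW"):
        rows = np.flatnonzero(groups_a == gname)
        if rows.size < 3:
            raise ValueError(f"insufficient runs in group {gname} (need >= 3)")
        subj_g = [subjects[r] for r in rows]
        dummies, names = subject_dummies(subj_g)
        X = np.column_stack([np.ones(rows.size), dummies])
        if X.shape[0] < X.shape[1] + 2:
            raise ValueError(f"insufficient runs in group {gname} for covariates")
        check_full_rank(X, ["intercept", *names])
        _, t, p, _ = ols_contrast_t(X, B[rows], coef_index=0)
        out[f"{gname.lower()}_mean_beta"] = B[rows].mean(axis=0)
        out[f"{gname.lower()}_t"] = t
        out[f"{gname.lower()}_p"] = p
        out[f"{gname.lower()}_significant"] = p < alpha / n_targets

    g = np.asarray([1.0 if x == "BS" else 0.0 for x in groups])
    dummies, names = subject_dummies(list(subjects))
    X = np.column_stack([np.ones(len(maps)), g, dummies])
    check_full_rank(X, ["intercept", "group", *names])
    _, t, p, _ = ols_contrast_t(X, B, coef_index=1)
    out["diff_t"] = t
    out["diff_p"] = p
    out["diff_significant"] = p < alpha / n_targets
    return out
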