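"""End-to-end orchestration of the two analysis pipelines.

``run_full_analysis`` ties the stages together for a cohort manifest:
suppression detection (or regressor loading) for BS runs, both preprocessing
variants (with and without the burst-suppression regressor in the nuisance
design), per-run and group coupling statistics, whole-brain edgewise
comparison with NBS correction, the lobe-block distribution of significant
edges, seed-based maps, and the physiology summary when per-run physiology is
available.  Everything is deterministic given the configured seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .bspattern import (
    DetectionParams,
    HRFParams,
    build_bs_regressor,
    detect_suppressions,
    make_binary_pattern,
)
from .coupling import fit_coupling_glm, group_coupling_test
from .netstats import (
    fc_matrix,
    load_partition,
    lobe_block_permutation,
    mean_offdiag_fc,
    nbs_correction,
)
from .physio import load_physiology_table, physio_report
from .preproc import PreprocConfig, preprocess
from .seednet import default_seeds, seed_connectivity, seed_group_compare

log = logging.getLogger("bsfc")


@dataclass
class PipelineConfig:
    """All paper-facing parameters of the full analysis in one place."""

    detection: DetectionParams = field(default_factory=DetectionParams)
    hrf: HRFParams = field(default_factory=HRFParams)
    band: tuple[float, float] = (0.01, 0.1)
    filter_order: int = 4
    order: str = "regress_then_filter"
    n_drop: int = 10
    edge_alpha: float = 0.001
    cluster_alpha: float = 0.05
    n_perm: int = 5000
    alpha: float = 0.05
    seed: int = 0
    partition_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        det = DetectionParams(**raw.pop("detection", {}))
        hrf = HRFParams(**raw.pop("hrf", {}))
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        return cls(detection=det, hrf=hrf, **raw)


def _regressor_for_run(row, run, config: PipelineConfig, root: Path):
    """Attach a BS regressor to a BS run: from file if given, else from EEG."""
    n_volumes = run.n_volumes + config.n_drop
    if isinstance(row.get("regressor_path"), str) and row["regressor_path"]:
        return bio.read_regressor(root / row["regressor_path"])
    if isinstance(row.get("eeg_path"), str) and row["eeg_path"]:
        eeg = bio.read_eeg(root / row["eeg_path"])
        intervals = detect_suppressions(eeg, config.detection)
        pattern = make_binary_pattern(intervals, eeg.duration, eeg.sample_rate)
        return build_bs_regressor(pattern, run.tr, n_volumes, config.n_drop, config.hrf)
    raise ValueError(f"BS run {row['run']} has neither regressor nor EEG file")


def run_full_analysis(
    manifest: pd.DataFrame,
    config: PipelineConfig | None = None,
    root: Path | str = ".",
    physio_table: pd.DataFrame | None = None,
) -> dict:
    """Execute both pipelines over a cohort manifest.

    Returns a results bundle with the group coupling table, edge statistics
    (NBS-corrected), lobe-block statistics, seed-map group comparisons, the
    mean off-diagonal FC of each pipeline variant, and the physiology report.
    """
    config = config or PipelineConfig()
    root = Path(root)
    log.info(
        "full analysis: edge_alpha=%g cluster_alpha=%g n_perm=%d band=%s seed=%d",
        config.edge_alpha, config.cluster_alpha, config.n_perm, config.band, config.seed,
    )

    # validation first: every referenced file must resolve before any compute
    for _, row in manifest.iterrows():
        for col in ("eeg_path", "bold_path", "nuisance_path", "regressor_path"):
            v = row.get(col)
            if isinstance(v, str) and v and not (root / v).exists():
                raise FileNotFoundError(f"run {row['run']}: missing file {v}")

    runs, regs = [], []
    for _, row in manifest.iterrows():
        run = bio.read_bold_run(
            root / row["bold_path"],
            root / row["nuisance_path"] if isinstance(row.get("nuisance_path"), str) and row["nuisance_path"] else None,
        )
        run.run_id = run.run_id or f"{row['subject']}-{row['session']}-{row['run']}"
        if row["group"] == "BS":
            run.bs_regressor = _regressor_for_run(row, run, config, root)
        runs.append(run)

    cfg_plain = PreprocConfig(order=config.order, band=config.band,
                              include_bs_regressor=False, filter_order=config.filter_order)
    cfg_bs = PreprocConfig(order=config.order, band=config.band,
                           include_bs_regressor=True, filter_order=config.filter_order)

    pre_plain, pre_bs = [], []
    for run in runs:
        try:
            pre_plain.append(preprocess(run, cfg_plain))
            pre_bs.append(preprocess(run, cfg_bs if run.group == "BS" else cfg_plain))
        except Exception as exc:
            raise RuntimeError(f"preprocess failed for run {run.run_id}: {exc}") from exc

    bs_idx = [i for i, r in enumerate(runs) if r.group == "BS"]
    coupling_runs = [fit_coupling_glm(pre_plain[i]) for i in bs_idx]
    group_coupling = group_coupling_test(coupling_runs, alpha=config.alpha)

    fc_plain = [fc_matrix(r) for r in pre_plain]
    fc_corrected = [fc_matrix(r) for r in pre_bs]
    groups = [r.group for r in runs]
    subjects = [r.subject for r in runs]

    edge_stats = nbs_correction(
        fc_corrected, groups, subjects,
        edge_alpha=config.edge_alpha, cluster_alpha=config.cluster_alpha,
        n_perm=config.n_perm, seed=config.seed,
    )

    partition = load_partition(config.partition_path)
    if edge_stats.significant.any():
        block_stats = lobe_block_permutation(
            edge_stats.significant, partition, edge_stats.region_labels,
            n_perm=config.n_perm, seed=config.seed + 1, alpha=config.alpha,
        )
    else:
        block_stats = None

    seed_results = {}
    for spec in default_seeds():
        if all(r in runs[0].region_labels for r in spec.seed_regions):
            maps = [seed_connectivity(r, spec) for r in pre_bs]
            seed_results[spec.name] = seed_group_compare(
                maps, groups, subjects, alpha=config.alpha
            )

    fc_bs_plain = [m for m in fc_plain if m.group == "BS"]
    fc_bs_corr = [m for m in fc_corrected if m.group == "BS"]
    report = physio_report(physio_table) if physio_table is not None else None

    return {
        "group_coupling": group_coupling,
        "coupling_runs": coupling_runs,
        "edge_stats": edge_stats,
        "block_stats": block_stats,
        "seed_results": seed_results,
        "mean_fc_bs_uncorrected": mean_offdiag_fc(fc_bs_plain) if fc_bs_plain else np.nan,
        "mean_fc_bs_corrected": mean_offdiag_fc(fc_bs_corr) if fc_bs_corr else np.nan,
        "physio_report": report,
        "n_runs": len(runs),
    }


def write_results(results: dict, out_dir) -> None:
    """Write the results bundle as delimiter-separated tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gc = results["group_coupling"]
    pd.DataFrame(
        {
            "region": gc.region_labels,
            "mean_beta": gc.mean_betas,
            "t": gc.tstats,
            "p": gc.pvalues,
            "significant": gc.significant,
        }
    ).to_csv(out / "group_coupling.tsv", sep="\t", index=False)
    results["edge_stats"].to_frame().to_csv(out / "edge_stats.tsv", sep="\t", index=False)
    if results["block_stats"] is not None:
        results["block_stats"].to_csv(out / "block_stats.tsv", sep="\t", index=False)
    for name, table in results["seed_results"].items():
        table.to_csv(out / f"seed_{name}.tsv", sep="\t", index=False)
    if results["physio_report"] is not None:
        results["physio_report"].to_csv(out / "physio_report.tsv", sep="\t", index=False)
    summary = pd.DataFrame(
        {
            "metric": ["mean_fc_bs_uncorrected", "mean_fc_bs_corrected", "n_runs"],
            "value": [
                results["mean_fc_bs_uncorrected"],
                results["mean_fc_bs_corrected"],
                results["n_runs"],
            ],
        }
    )
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
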