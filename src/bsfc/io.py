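"""Text-first file formats for every pipeline artifact.

All artifacts are delimiter-separated text with headers, for auditability:
EEG as one column per channel with a small YAML sidecar (sample rate, channel
names), parcel BOLD as volumes x regions with region labels as header,
suppression intervals as 3-column text (onset s, offset s, label), regressors
as single-column tables with a sidecar, FC matrices as square labeled tables,
and cohort manifests mirroring the physiology-table layout.  Floats are
written with 17 significant digits so read(write(x)) round-trips exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bspattern import BSPattern, EEGRecording, VolumeRegressor, make_binary_pattern
from .netstats import FCMatrix
from .preproc import NUISANCE_COLUMNS, BOLDRun

FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """Malformed artifact file."""


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".meta.yaml")


def _write_meta(path: Path, meta: dict) -> None:
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def _read_meta(path: Path) -> dict:
    sc = _sidecar(path)
    if not sc.exists():
        raise FormatError(f"missing metadata sidecar {sc}")
    return yaml.safe_load(sc.read_text())


# --- EEG -------------------------------------------------------------------

def write_eeg(eeg: EEGRecording, path) -> None:
    path = Path(path)
    df = pd.DataFrame(eeg.data.T, columns=eeg.channel_names)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    _write_meta(path, {"sample_rate": float(eeg.sample_rate),
                       "channel_names": list(eeg.channel_names)})


def read_eeg(path) -> EEGRecording:
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns) != list(meta["channel_names"]):
        raise FormatError(f"{path}: channel header does not match sidecar")
    return EEGRecording(
        data=df.to_numpy().T,
        sample_rate=float(meta["sample_rate"]),
        channel_names=list(meta["channel_names"]),
    )


# --- intervals and patterns ------------------------------------------------

def write_intervals(intervals, path, label: str = "suppression") -> None:
    path = Path(path)
    with path.open("w") as f:
        f.write("onset_s\toffset_s\tlabel\n")
        for onset, offset in intervals:
            f.write(f"{onset:.17g}\t{offset:.17g}\t{label}\n")


def read_intervals(path) -> list[tuple[float, float]]:
    path = Path(path)
    intervals = []
    with path.open() as f:
        header = f.readline().strip().split("\t")
        if header[:2] != ["onset_s", "offset_s"]:
            raise FormatError(f"{path}:1: expected 'onset_s\\toffset_s\\tlabel' header")
        for ln, line in enumerate(f, start=2):
            parts = line.strip().split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected at least 2 columns")
            try:
                onset, offset = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-numeric interval bound") from exc
            intervals.append((onset, offset))
    intervals.sort()
    for (a0, b0), (a1, _) in zip(intervals, intervals[1:]):
        if a1 < b0:
            raise FormatError(f"{path}: overlapping intervals at onset {a1}")
    return intervals


def write_pattern(pattern: BSPattern, path) -> None:
    write_intervals(pattern.intervals, path)
    _write_meta(Path(path), {"sample_rate": float(pattern.sample_rate),
                             "duration": float(pattern.duration)})


def read_pattern(path) -> BSPattern:
    meta = _read_meta(Path(path))
    intervals = read_intervals(path)
    return make_binary_pattern(intervals, float(meta["duration"]), float(meta["sample_rate"]))


# --- regressors ------------------------------------------------------------

def write_regressor(reg: VolumeRegressor, path) -> None:
    path = Path(path)
    pd.DataFrame({"bs_regressor": reg.values}).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    _write_meta(path, {"tr": float(reg.tr),
                       "n_dropped_leading_volumes": int(reg.n_dropped_leading_volumes)})


def read_regressor(path) -> VolumeRegressor:
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "bs_regressor" not in df.columns:
        raise FormatError(f"{path}: missing 'bs_regressor' column")
    return VolumeRegressor(
        values=df["bs_regressor"].to_numpy(),
        tr=float(meta["tr"]),
        n_dropped_leading_volumes=int(meta["n_dropped_leading_volumes"]),
    )


# --- parcel matrices and runs ---------------------------------------------

def write_parcel_matrix(data: np.ndarray, region_labels, path) -> None:
    """Write a parcel x volume matrix as volumes x regions with labeled header."""
    pd.DataFrame(np.asarray(data).T, columns=list(region_labels)).to_csv(
        Path(path), sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_parcel_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least 2 region columns")
    return df.to_numpy().T, [str(c) for c in df.columns]


def write_nuisance(nuisance: pd.DataFrame, path) -> None:
    nuisance.to_csv(Path(path), sep="\t", index=False, float_format=FLOAT_FMT)


def read_nuisance(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    missing = set(NUISANCE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing nuisance columns {sorted(missing)}")
    return df[NUISANCE_COLUMNS]


def write_bold_run(run: BOLDRun, bold_path, nuisance_path=None, regressor_path=None) -> None:
    write_parcel_matrix(run.data, run.region_labels, bold_path)
    _write_meta(Path(bold_path), {"tr": float(run.tr), "subject": run.subject,
                                  "group": run.group, "run_id": run.run_id})
    if nuisance_path is not None and run.nuisance is not None:
        write_nuisance(run.nuisance, nuisance_path)
    if regressor_path is not None and run.bs_regressor is not None:
        write_regressor(run.bs_regressor, regressor_path)


def read_bold_run(bold_path, nuisance_path=None, regressor_path=None) -> BOLDRun:
    data, labels = read_parcel_matrix(bold_path)
    meta = _read_meta(Path(bold_path))
    nuisance = read_nuisance(nuisance_path) if nuisance_path else None
    reg = read_regressor(regressor_path) if regressor_path else None
    return BOLDRun(
        data=data,
        region_labels=labels,
        tr=float(meta["tr"]),
        subject=str(meta["subject"]),
        group=str(meta["group"]),
        nuisance=nuisance,
        bs_regressor=reg,
        run_id=str(meta.get("run_id", "")),
    )


# --- FC matrices -----------------------------------------------------------

def write_fc_matrix(m: FCMatrix, path) -> None:
    df = pd.DataFrame(m.values, index=m.region_labels, columns=m.region_labels)
    df.to_csv(Path(path), sep="\t", float_format=FLOAT_FMT, index_label="region")
    _write_meta(Path(path), {"scale": m.scale, "subject": m.subject,
                             "group": m.group, "run_id": m.run_id})


def read_fc_matrix(path) -> FCMatrix:
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", index_col="region", float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column labels differ")
    return FCMatrix(
        values=df.to_numpy(),
        region_labels=[str(c) for c in df.columns],
        scale=str(meta["scale"]),
        subject=str(meta.get("subject", "")),
        group=str(meta.get("group", "")),
        run_id=str(meta.get("run_id", "")),
    )


# --- cohort manifest -------------------------------------------------------

MANIFEST_COLUMNS = [
    "subject", "session", "run", "group",
    "eeg_path", "bold_path", "nuisance_path", "regressor_path", "bsr_pct",
]


def write_manifest(manifest: pd.DataFrame, path) -> None:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise FormatError(f"manifest lacks columns {sorted(missing)}")
    manifest.to_csv(Path(path), sep="\t", index=False)


def read_manifest(path, check_paths: bool = True) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "session": str, "run": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest lacks columns {sorted(missing)}")
    keys = df[["subject", "session", "run"]].apply(tuple, axis=1)
    if keys.duplicated().any():
        raise FormatError(f"{path}: duplicate (subject, session, run) keys")
    if check_paths:
        root = path.parent
        for col in ("eeg_path", "bold_path", "nuisance_path", "regressor_path"):
            for v in df[col].dropna():
                if str(v) and not (root / str(v)).exists():
                    raise FormatError(f"{path}: referenced file not found: {v}")
    return df
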