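"""Readers and writers: tab-delimited panels and feature matrices with a
YAML run manifest carrying labels, metadata and provenance.

Everything is plain text and byte-deterministic for a fixed seed: floats are
written with 17 significant digits (lossless for doubles), and manifests
carry no timestamps.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import CorrMatrix, DtwMatrix, LaggedCorrResult, LeadMatrix
from .panel import Record, TimeSeriesPanel

FLOAT_FMT = "%.17g"

MANIFEST_NAME = "manifest.yaml"


def _record_filename(rec: Record) -> str:
    return f"{rec.subject_id}_visit-{rec.visit_id}_run-{rec.run_id}.tsv"


def write_panel(panel: TimeSeriesPanel, directory) -> Path:
    """One TSV per record (ROI rows, time columns) plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in panel.records:
        fname = _record_filename(rec)
        df = pd.DataFrame(
            rec.matrix,
            index=pd.Index(panel.roi_names, name="roi"),
            columns=[f"t{i}" for i in range(rec.matrix.shape[1])],
        )
        df.to_csv(directory / fname, sep="\t", float_format=FLOAT_FMT)
        entries.append(
            {
                "subject_id": rec.subject_id,
                "visit_id": int(rec.visit_id),
                "run_id": int(rec.run_id),
                "path": fname,
            }
        )
    manifest = {
        "tr": float(panel.tr),
        "n_rois": panel.n_rois,
        "n_time": panel.n_time,
        "roi_names": list(panel.roi_names),
        "records": entries,
        "labels": dict(panel.labels),
        "metadata": {k: dict(v) for k, v in panel.metadata.items()},
        "provenance": list(panel.provenance),
    }
    path = directory / MANIFEST_NAME
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def read_panel(manifest_path) -> TimeSeriesPanel:
    """Load a panel, enforcing shape and ROI-order consistency per record."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    manifest = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    roi_names = list(manifest["roi_names"])
    n_time = int(manifest["n_time"])
    records = []
    for entry in manifest["records"]:
        key = (entry["subject_id"], entry["visit_id"], entry["run_id"])
        path = base / entry["path"]
        if not path.exists():
            raise FileNotFoundError(f"record {key}: missing file {path}")
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
        if list(df.index) != roi_names:
            raise ValueError(
                f"record {key}: ROI names/order differ from the manifest"
            )
        if df.shape[1] != n_time:
            raise ValueError(
                f"record {key}: {df.shape[1]} time points, manifest says {n_time}"
            )
        matrix = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(matrix)):
            bad = np.argwhere(~np.isfinite(matrix))[0]
            raise ValueError(
                f"record {key}: non-numeric cell at row {roi_names[bad[0]]}, "
                f"column t{bad[1]}"
            )
        records.append(Record(entry["subject_id"], int(entry["visit_id"]),
                              int(entry["run_id"]), matrix))
    return TimeSeriesPanel(
        roi_names=roi_names,
        records=records,
        labels=dict(manifest.get("labels", {})),
        tr=float(manifest["tr"]),
        metadata={k: dict(v) for k, v in manifest.get("metadata", {}).items()},
        provenance=list(manifest.get("provenance", [])),
    )


_KIND_CLASSES = {
    "lead": LeadMatrix,
    "corr": CorrMatrix,
    "dtw": DtwMatrix,
}


def write_feature(feature, path, provenance=None) -> Path:
    """Delimited table plus sidecar metadata (kind, units, provenance)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(feature, LaggedCorrResult):
        frames = {"lcm": feature.lcm, "tdm": feature.tdm}
        meta = {"kind": "lagged_corr", "units": {"lcm": "correlation",
                                                 "tdm": "seconds"},
                "max_lag_s": float(feature.max_lag_s)}
    else:
        frames = {"values": feature.values}
        meta = {"kind": feature.kind, "units": "dimensionless"}
    names = feature.roi_names or [
        f"ROI{i + 1:02d}" for i in range(next(iter(frames.values())).shape[0])
    ]
    written = []
    for tag, values in frames.items():
        target = path if len(frames) == 1 else path.with_suffix(f".{tag}.tsv")
        pd.DataFrame(values, index=pd.Index(names, name="roi"),
                     columns=names).to_csv(target, sep="\t",
                                           float_format=FLOAT_FMT)
        written.append(target.name)
    meta["roi_names"] = names
    meta["files"] = written
    meta["provenance"] = list(provenance or [])
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_feature(path):
    """Load a feature matrix and re-validate its symmetry invariants."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    kind = meta["kind"]
    names = list(meta["roi_names"])

    def load(p):
        return pd.read_csv(
            p, sep="\t", index_col=0, float_precision="round_trip"
        ).to_numpy(dtype=float)

    try:
        if kind == "lagged_corr":
            lcm = load(path.with_suffix(".lcm.tsv"))
            tdm = load(path.with_suffix(".tdm.tsv"))
            return LaggedCorrResult(lcm, tdm, float(meta["max_lag_s"]), names)
        cls = _KIND_CLASSES[kind]
        return cls(load(path), names)
    except ValueError as err:
        raise ValueError(f"feature file {path} violates its invariants: {err}")


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path
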