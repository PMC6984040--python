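"""Cohort container: ROI x time matrices indexed by subject, visit and run."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Record:
    """One scan: a single subject/visit/run ROI-by-time matrix."""

    subject_id: str
    visit_id: int
    run_id: int
    matrix: np.ndarray  # shape (n_rois, n_time)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.subject_id, self.visit_id, self.run_id)


@dataclass
class TimeSeriesPanel:
    """A cohort of ROI-by-time BOLD-like matrices with group labels.

    All records share ``roi_names`` (same order) and the number of time
    points; ``labels`` maps subject id to group (``"patient"``/``"control"``),
    ``metadata`` holds optional per-subject attributes (age, sex, hearing
    status), ``tr`` is the sampling interval in seconds.
    """

    roi_names: list[str]
    records: list[Record]
    labels: dict[str, str]
    tr: float
    metadata: dict[str, dict] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n_rois = len(self.roi_names)
        n_time = None
        for rec in self.records:
            if rec.matrix.shape[0] != n_rois:
                raise ValueError(
                    f"record {rec.key}: {rec.matrix.shape[0]} rows, "
                    f"expected {n_rois} ROIs"
                )
            if n_time is None:
                n_time = rec.matrix.shape[1]
            elif rec.matrix.shape[1] != n_time:
                raise ValueError(
                    f"record {rec.key}: {rec.matrix.shape[1]} time points, "
                    f"expected {n_time}"
                )
            if not np.all(np.isfinite(rec.matrix)):
                raise ValueError(f"record {rec.key}: non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def n_time(self) -> int:
        return self.records[0].matrix.shape[1] if self.records else 0

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.subject_id, None)
        return list(seen)

    @property
    def visits(self) -> list[int]:
        return sorted({rec.visit_id for rec in self.records})

    def get(self, subject_id: str, visit_id: int, run_id: int = 1) -> Record:
        for rec in self.records:
            if rec.key == (subject_id, visit_id, run_id):
                return rec
        raise KeyError(f"no record for {(subject_id, visit_id, run_id)}")

    def records_for_visit(self, visit_id: int) -> list[Record]:
        return [r for r in self.records if r.visit_id == visit_id]

    def map_matrices(self, func, note: str | None = None) -> "TimeSeriesPanel":
        """Return a new panel with ``func`` applied to every matrix."""
        new_records = [
            Record(r.subject_id, r.visit_id, r.run_id, func(r.matrix))
            for r in self.records
        ]
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return TimeSeriesPanel(
            roi_names=list(self.roi_names),
            records=new_records,
            labels=dict(self.labels),
            tr=self.tr,
            metadata={k: dict(v) for k, v in self.metadata.items()},
            provenance=prov,
        )
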