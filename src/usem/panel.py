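"""Cohort-grouped collections of per-subject ROI time series.

A :class:`TimeSeriesPanel` is the interchange container for the whole
pipeline: every subject carries a ``(T, n_nodes)`` data matrix, a boolean
censoring mask of length ``T`` (``True`` = usable time point) and cohort /
sex metadata.  Panels round-trip through a plain-text directory format
(one TSV per subject plus a JSON manifest) so that user-supplied
ROI-extracted data can enter the pipeline the same way simulated data do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Subject", "TimeSeriesPanel"]


@dataclass
class Subject:
    """One subject's ROI time series with its censoring mask."""

    subject_id: str
    cohort: str
    sex: str
    data: np.ndarray  # (T, n_nodes) float
    mask: np.ndarray = None  # (T,) bool, True = usable

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"subject {self.subject_id}: data must be 2-D (time x ROI)")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[0], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.data.shape[0],):
            raise ValueError(
                f"subject {self.subject_id}: mask length {self.mask.shape} "
                f"does not match time dimension {self.data.shape[0]}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_uncensored(self) -> int:
        return int(self.mask.sum())


@dataclass
class TimeSeriesPanel:
    """Cohort-grouped collection of subjects sharing one node set."""

    node_names: list[str]
    subjects: list[Subject]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.node_names)
        for s in self.subjects:
            if s.data.shape[1] != n:
                raise ValueError(
                    f"subject {s.subject_id}: {s.data.shape[1]} columns, "
                    f"panel defines {n} nodes"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def cohorts(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subjects:
            seen.setdefault(s.cohort, None)
        return list(seen)

    def by_cohort(self, cohort: str) -> list[Subject]:
        return [s for s in self.subjects if s.cohort == cohort]

    @property
    def n_uncensored(self) -> int:
        """Total usable time points across all subjects."""
        return sum(s.n_uncensored for s in self.subjects)

    def copy(self) -> "TimeSeriesPanel":
        return TimeSeriesPanel(
            node_names=list(self.node_names),
            subjects=[
                replace(s, data=s.data.copy(), mask=s.mask.copy())
                for s in self.subjects
            ],
            meta=dict(self.meta),
        )

    # ------------------------------------------------------------------
    # plain-text interchange format: one TSV per subject + JSON manifest
    # ------------------------------------------------------------------
    def to_dir(self, path: str | Path) -> Path:
        """Write the panel as ``manifest.json`` + one TSV per subject."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        entries = []
        for s in self.subjects:
            fname = f"{s.subject_id}.tsv"
            df = pd.DataFrame(s.data, columns=self.node_names)
            df.to_csv(path / fname, sep="\t", index=False, float_format="%.10g")
            entries.append(
                {
                    "id": s.subject_id,
                    "cohort": s.cohort,
                    "sex": s.sex,
                    "file": fname,
                    "censored": np.flatnonzero(~s.mask).tolist(),
                }
            )
        manifest = {
            "node_names": self.node_names,
            "subjects": entries,
            "meta": self.meta,
        }
        with open(path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "TimeSeriesPanel":
        path = Path(path)
        with open(path / "manifest.json") as fh:
            manifest = json.load(fh)
        node_names = list(manifest["node_names"])
        subjects = []
        for e in manifest["subjects"]:
            df = pd.read_csv(path / e["file"], sep="\t")
            if list(df.columns) != node_names:
                raise ValueError(
                    f"subject {e['id']}: TSV columns {list(df.columns)} "
                    f"do not match manifest node_names"
                )
            data = df.to_numpy(dtype=float)
            mask = np.ones(data.shape[0], dtype=bool)
            mask[np.asarray(e.get("censored", []), dtype=int)] = False
            subjects.append(
                Subject(e["id"], e["cohort"], e.get("sex", "?"), data, mask)
            )
        return cls(node_names, subjects, dict(manifest.get("meta", {})))
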