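"""Time-series preparation: spike censoring, standardization, lagged-pair
construction, AR-order assessment and cohort covariance assembly.

The spike filter implements a multi-ROI threshold ladder on sudden
point-to-point signal change: a jump is artifactual when it exceeds
7 SDs in at least 2 ROIs, 6 SDs in 3, 5 SDs in 4, 4 SDs in 5, or
3 SDs in at least 6 ROIs simultaneously.  Deviation units are each
subject's full-series per-ROI standard deviation (single pass, so the
mask depends only on the input data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import Subject, TimeSeriesPanel

__all__ = [
    "CENSOR_LADDER",
    "censor_spikes",
    "standardize",
    "build_lagged",
    "assess_ar_order",
    "cohort_covariances",
    "LaggedSubject",
    "LaggedDataset",
    "CohortCovariances",
]

#: (threshold in SD units, minimum number of ROIs exceeding it)
CENSOR_LADDER: tuple[tuple[float, int], ...] = ((7, 2), (6, 3), (5, 4), (4, 5), (3, 6))


def _check_nonconstant(subject: Subject, sd: np.ndarray, node_names: list[str]) -> None:
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(node_names[i] for i in bad)
        raise ValueError(
            f"subject {subject.subject_id}: constant series (zero SD) in ROI(s) {names}"
        )


def censor_spikes(
    panel: TimeSeriesPanel,
    ladder: tuple[tuple[float, int], ...] = CENSOR_LADDER,
    mode: str = "difference",
) -> TimeSeriesPanel:
    """Mark artifact time points; data are left untouched.

    ``mode="difference"`` (default) applies the ladder to first
    differences |x_t - x_{t-1}| in per-ROI SD units; the censored point of
    a qualifying jump is whichever endpoint lies farther from the series
    mean (averaged over the offending ROIs), so an impulse artifact is
    censored exactly once.  ``mode="level"`` applies the ladder to
    |x_t - mean| directly.
    """
    if mode not in ("difference", "level"):
        raise ValueError(f"unknown censoring mode {mode!r}")
    out = panel.copy()
    min_thr = min(thr for thr, _ in ladder)
    for s in out.subjects:
        if s.n_timepoints < 2:
            raise ValueError(f"subject {s.subject_id}: need >= 2 time points")
        sd = s.data.std(axis=0)
        _check_nonconstant(s, sd, out.node_names)
        z = (s.data - s.data.mean(axis=0)) / sd  # deviation from series mean
        if mode == "level":
            absz = np.abs(z)
            for t in range(s.n_timepoints):
                if any((absz[t] > thr).sum() >= m for thr, m in ladder):
                    s.mask[t] = False
            continue
        jump = np.abs(np.diff(s.data, axis=0)) / sd  # (T-1, n); row t-1 = jump into t
        for t in range(1, s.n_timepoints):
            j = jump[t - 1]
            if not any((j > thr).sum() >= m for thr, m in ladder):
                continue
            offending = j > min_thr
            # censor the endpoint farther from the series mean
            if np.abs(z[t, offending]).mean() >= np.abs(z[t - 1, offending]).mean():
                s.mask[t] = False
            else:
                s.mask[t - 1] = False
    return out


def standardize(panel: TimeSeriesPanel) -> TimeSeriesPanel:
    """Normalize each subject x ROI series to mean 0, variance 1
    (population convention, divisor n) over its uncensored points."""
    out = panel.copy()
    for s in out.subjects:
        if s.mask.sum() < 2:
            raise ValueError(f"subject {s.subject_id}: < 2 uncensored time points")
        kept = s.data[s.mask]
        mean = kept.mean(axis=0)
        sd = kept.std(axis=0)  # ddof=0
        _check_nonconstant(s, sd, out.node_names)
        s.data = (s.data - mean) / sd
    return out


@dataclass
class LaggedSubject:
    """Paired (unlagged, lagged) observation blocks for one subject."""

    subject_id: str
    cohort: str
    sex: str
    unlagged: np.ndarray  # (n_pairs, n_nodes) = x_t
    lagged: np.ndarray  # (n_pairs, n_nodes) = x_{t+1}

    @property
    def n_pairs(self) -> int:
        return self.unlagged.shape[0]


@dataclass
class LaggedDataset:
    """Per-subject lagged pairs; the 2n-variable sample for SEM fitting.

    Variable order is [x_1 .. x_n (unlagged), x_1' .. x_n' (lagged)].
    """

    node_names: list[str]
    subjects: list[LaggedSubject]
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def variable_names(self) -> list[str]:
        return list(self.node_names) + [f"{n}_lag" for n in self.node_names]

    @property
    def cohorts(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subjects:
            seen.setdefault(s.cohort, None)
        return list(seen)

    def counts(self) -> dict[str, int]:
        """Effective observation count N^(g) per cohort."""
        out: dict[str, int] = {}
        for s in self.subjects:
            out[s.cohort] = out.get(s.cohort, 0) + s.n_pairs
        return out

    @property
    def n_total(self) -> int:
        return sum(s.n_pairs for s in self.subjects)

    def stacked(self, cohort: str, sex: str | None = None) -> np.ndarray:
        """Pooled (N^(g), 2n) observation matrix for one cohort."""
        blocks = [
            np.hstack([s.unlagged, s.lagged])
            for s in self.subjects
            if s.cohort == cohort and (sex is None or s.sex == sex)
        ]
        if not blocks:
            raise ValueError(f"no observations for cohort {cohort!r}"
                             + (f" sex {sex!r}" if sex else ""))
        return np.vstack(blocks)


def build_lagged(panel: TimeSeriesPanel) -> LaggedDataset:
    """Form within-subject (x_t, x_{t+1}) pairs; no pair spans a censored
    time point or a subject boundary."""
    subjects = []
    for s in panel.subjects:
        ok = s.mask[:-1] & s.mask[1:]
        subjects.append(
            LaggedSubject(
                s.subject_id, s.cohort, s.sex,
                unlagged=s.data[:-1][ok].copy(),
                lagged=s.data[1:][ok].copy(),
            )
        )
    return LaggedDataset(list(panel.node_names), subjects, dict(panel.meta))


@dataclass
class CohortCovariances:
    """Per-cohort sample covariance (divisor N-1) over the 2n variables."""

    variable_names: list[str]
    matrices: dict[str, np.ndarray]
    counts: dict[str, int]

    @property
    def n_variables(self) -> int:
        return len(self.variable_names)

    @property
    def cohorts(self) -> list[str]:
        return list(self.matrices)

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


def cohort_covariances(
    data: LaggedDataset, sex: str | None = None
) -> CohortCovariances:
    """Sample covariance of the stacked (unlagged, lagged) vectors per
    cohort.  Warns when N^(g) is too small for a full-rank covariance."""
    p = 2 * data.n_nodes
    mats: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for cohort in data.cohorts:
        Z = data.stacked(cohort, sex=sex)
        N = Z.shape[0]
        if N < p + 1:
            warnings.warn(
                f"cohort {cohort}: N={N} <= {p} variables; covariance may be singular",
                stacklevel=2,
            )
        if N < 2:
            raise ValueError(f"cohort {cohort}: need >= 2 observations")
        mats[cohort] = np.cov(Z, rowvar=False, ddof=1)
        counts[cohort] = N
    return CohortCovariances(data.variable_names, mats, counts)


def assess_ar_order(panel: TimeSeriesPanel, max_lag: int = 5) -> pd.DataFrame:
    """Incremental variance explained by AR(k) over AR(k-1) per ROI.

    AR models are fitted by least squares on within-subject lagged rows
    pooled over subjects (rows with any censored lag are dropped).
    Returns a DataFrame indexed by ROI with columns ``lag1..lag<max_lag>``
    holding R^2 increments.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    shortest = min(s.n_timepoints for s in panel.subjects)
    if max_lag >= shortest:
        raise ValueError(
            f"max_lag {max_lag} >= shortest usable series length {shortest}"
        )
    n = panel.n_nodes
    rows = np.zeros((n, max_lag))
    for j in range(n):
        ys, Xs = [], []
        for s in panel.subjects:
            x = s.data[:, j]
            T = x.size
            if T <= max_lag:
                continue
            ok = np.ones(T - max_lag, dtype=bool)
            for k in range(max_lag + 1):
                ok &= s.mask[k : T - max_lag + k]
            t0 = np.arange(max_lag, T)[ok]
            ys.append(x[t0])
            Xs.append(np.column_stack([x[t0 - k] for k in range(1, max_lag + 1)]))
        y = np.concatenate(ys)
        X = np.vstack(Xs)
        y = y - y.mean()
        X = X - X.mean(axis=0)
        tss = float(y @ y)
        prev = 0.0
        for k in range(1, max_lag + 1):
            beta, *_ = np.linalg.lstsq(X[:, :k], y, rcond=None)
            resid = y - X[:, :k] @ beta
            r2 = 1.0 - float(resid @ resid) / tss
            rows[j, k - 1] = r2 - prev
            prev = r2
    return pd.DataFrame(
        rows, index=panel.node_names, columns=[f"lag{k}" for k in range(1, max_lag + 1)]
    )
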