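"""Synthetic cohort-structured multivariate time series from a known
contemporaneous + lag-1 structural model.

The generative model for one subject is the structural VAR

    y_t = C y_t + (L + diag(a)) y_{t-1} + eps_t,    eps_t ~ N(0, diag(sd^2))

where ``C`` holds contemporaneous path coefficients (target row, source
column, zero diagonal), ``L`` cross-lag coefficients, and ``a`` per-node
lag-1 autoregression.  Solving the simultaneous system gives the reduced
form ``y_t = M y_{t-1} + u_t`` with ``M = (I-C)^{-1}(L + diag(a))`` and
``u_t = (I-C)^{-1} eps_t``, whose stationary covariance solves the
discrete Lyapunov equation ``Sigma = M Sigma M' + Q``.

Coefficients may differ by cohort (and optionally by sex), which is how
age-related drift in connectivity is injected.  Because downstream model
fitting standardizes every series, innovation variances can be calibrated
so that each node's stationary variance is exactly 1; the generating
coefficients are then directly comparable to standardized path estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import linalg

from .panel import Subject, TimeSeriesPanel

__all__ = [
    "SpikeSpec",
    "SimConfig",
    "NonStationaryError",
    "reduced_form",
    "stationary_covariance",
    "unit_variance_innovations",
    "standardized_coefficients",
    "simulate_panel",
    "default_dmn_scenario",
    "load_dmn_nodes",
    "load_exploratory_edges",
]


class NonStationaryError(ValueError):
    """Raised when a cohort's coefficient set induces a non-stationary VAR."""


@dataclass(frozen=True)
class SpikeSpec:
    """An artifact spike: additive offset at one time point of one subject.

    ``amplitude`` is expressed in units of the affected series' standard
    deviation, so a 8-SD spike is recoverable by a 7-SD censoring rule.
    """

    subject_id: str
    timepoint: int
    rois: tuple[str, ...]
    amplitude: float


@dataclass
class SimConfig:
    """Generating model for a cohort-grouped panel.

    Coefficient tables are (target row, source column).  Each of
    ``contemporaneous``, ``crosslag`` may be a single (n, n) table shared
    by all cohorts or a (G, n, n) stack; ``auto`` and ``innovation_sd``
    may be (n,) or (G, n).  ``cohort_schedule`` is an optional linear
    drift {(source, target): (intercept, slope)} applied on top of the
    shared contemporaneous table, evaluated as intercept + slope*(g-1)
    for cohort g = 1..G.
    """

    node_names: list[str]
    contemporaneous: np.ndarray
    crosslag: np.ndarray | None = None
    auto: np.ndarray | None = None
    innovation_sd: np.ndarray | None = None
    cohort_schedule: dict[tuple[str, str], tuple[float, float]] | None = None
    n_cohorts: int = 1
    cohort_labels: list[str] | None = None
    subjects_per_cohort: int = 20
    timepoints_per_subject: int = 150
    burn_in: int = 200
    spike_spec: list[SpikeSpec] = field(default_factory=list)
    seed: int = 0
    calibrate_unit_variance: bool = False
    contemporaneous_by_sex: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        n = len(self.node_names)
        self.contemporaneous = np.asarray(self.contemporaneous, dtype=float)
        if self.crosslag is None:
            self.crosslag = np.zeros((n, n))
        self.crosslag = np.asarray(self.crosslag, dtype=float)
        if self.auto is None:
            self.auto = np.zeros(n)
        self.auto = np.asarray(self.auto, dtype=float)
        if self.innovation_sd is None:
            self.innovation_sd = np.ones(n)
        self.innovation_sd = np.asarray(self.innovation_sd, dtype=float)
        if self.cohort_labels is None:
            self.cohort_labels = [f"c{g+1}" for g in range(self.n_cohorts)]
        if len(self.cohort_labels) != self.n_cohorts:
            raise ValueError("cohort_labels length must equal n_cohorts")
        if self.timepoints_per_subject < 1 or self.subjects_per_cohort < 1:
            raise ValueError("subjects_per_cohort and timepoints_per_subject must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if np.any(self.innovation_sd <= 0):
            raise ValueError("innovation_sd must be positive")
        self.validate()

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def _per_cohort(self, table: np.ndarray, g: int, square: bool) -> np.ndarray:
        table = np.asarray(table, dtype=float)
        want_ndim = 2 if square else 1
        if table.ndim == want_ndim:
            return table
        if table.ndim == want_ndim + 1 and table.shape[0] == self.n_cohorts:
            return table[g]
        raise ValueError(f"coefficient table has unexpected shape {table.shape}")

    def coefficients(self, cohort_index: int, sex: str | None = None):
        """Resolve (C, L, a, sd) for a 0-based cohort index (and sex)."""
        base = self.contemporaneous
        if sex is not None and self.contemporaneous_by_sex and sex in self.contemporaneous_by_sex:
            base = self.contemporaneous_by_sex[sex]
        C = self._per_cohort(base, cohort_index, square=True).copy()
        if self.cohort_schedule:
            idx = {name: i for i, name in enumerate(self.node_names)}
            for (src, dst), (b0, b1) in self.cohort_schedule.items():
                C[idx[dst], idx[src]] = b0 + b1 * cohort_index
        L = self._per_cohort(self.crosslag, cohort_index, square=True)
        a = self._per_cohort(self.auto, cohort_index, square=False)
        sd = self._per_cohort(self.innovation_sd, cohort_index, square=False)
        if self.calibrate_unit_variance:
            sd = unit_variance_innovations(C, L, a)
        return C, L, a, sd

    def validate(self) -> None:
        """Check stationarity and identifiability for every cohort (and sex)."""
        sexes: list[str | None] = [None]
        if self.contemporaneous_by_sex:
            sexes = list(self.contemporaneous_by_sex)
        for g in range(self.n_cohorts):
            for sex in sexes:
                C, L, a, _ = self.coefficients(g, sex)
                if np.any(np.diag(C) != 0.0):
                    raise ValueError("contemporaneous coefficient matrix must have zero diagonal")
                if np.any(a < 0) or np.any(a >= 1):
                    raise ValueError("auto coefficients must lie in [0, 1)")
                M, _ = reduced_form(C, L, a)
                rho = np.max(np.abs(np.linalg.eigvals(M)))
                if rho >= 1.0:
                    raise NonStationaryError(
                        f"cohort {self.cohort_labels[g]}"
                        + (f" (sex {sex})" if sex else "")
                        + f": VAR(1) companion spectral radius {rho:.4f} >= 1"
                    )


def reduced_form(C: np.ndarray, L: np.ndarray, a: np.ndarray):
    """Reduced-form transition M and structural solve B = (I-C)^{-1}."""
    n = C.shape[0]
    ImC = np.eye(n) - C
    if abs(np.linalg.det(ImC)) < 1e-12:
        raise ValueError("(I - C) is singular; contemporaneous system has no solution")
    B = np.linalg.inv(ImC)
    M = B @ (L + np.diag(a))
    return M, B


def stationary_covariance(C, L, a, sd) -> np.ndarray:
    """Stationary covariance of the induced VAR(1), via the discrete
    Lyapunov equation Sigma = M Sigma M' + Q."""
    M, B = reduced_form(np.asarray(C, float), np.asarray(L, float), np.asarray(a, float))
    D = np.diag(np.asarray(sd, float) ** 2)
    Q = B @ D @ B.T
    return linalg.solve_discrete_lyapunov(M, Q)


def unit_variance_innovations(C, L, a) -> np.ndarray:
    """Innovation SDs such that every node's stationary variance is 1.

    The stationary variance vector is linear in the innovation variance
    vector d:  diag(Sigma) = T d, with column j of T obtained from the
    Lyapunov solution for a unit innovation on node j alone.
    """
    n = C.shape[0]
    M, B = reduced_form(np.asarray(C, float), np.asarray(L, float), np.asarray(a, float))
    T = np.empty((n, n))
    for j in range(n):
        Qj = np.outer(B[:, j], B[:, j])
        T[:, j] = np.diag(linalg.solve_discrete_lyapunov(M, Qj))
    d = np.linalg.solve(T, np.ones(n))
    if np.any(d <= 0):
        raise ValueError(
            "no positive innovation variances yield unit stationary variances "
            "for this coefficient set"
        )
    return np.sqrt(d)


def standardized_coefficients(config: SimConfig, cohort_index: int, sex: str | None = None):
    """Generating coefficients on the standardized (unit-variance) scale.

    Downstream fitting standardizes every series, so the estimable
    coefficient for a path A -> B is the structural coefficient times
    sd(A)/sd(B) under the stationary law.  Returns (C_std, L_std, a);
    the autoregressive coefficient relates a node to itself and is scale
    free.  This is the ground truth that standardized path estimates
    recover.
    """
    C, L, a, sd = config.coefficients(cohort_index, sex)
    sigma = stationary_covariance(C, L, a, sd)
    s = np.sqrt(np.diag(sigma))
    scale = s[None, :] / s[:, None]  # [target, source] -> sd_src / sd_tgt
    return C * scale, L * scale, a.copy()


def simulate_panel(config: SimConfig) -> TimeSeriesPanel:
    """Generate a cohort-grouped panel from the structural model.

    Subjects within a cohort are i.i.d. given their sex; the first half
    of each cohort is male, the second female (even split).  Spikes from
    ``config.spike_spec`` are added after generation, scaled by each
    affected series' own SD.  Bit-reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    T = config.timepoints_per_subject
    half = config.subjects_per_cohort // 2
    subjects = []
    for g, label in enumerate(config.cohort_labels):
        for j in range(config.subjects_per_cohort):
            sex = "M" if j < half else "F"
            C, L, a, sd = config.coefficients(g, sex)
            M, B = reduced_form(C, L, a)
            total = T + config.burn_in
            eps = rng.standard_normal((total, n)) * sd
            y = np.zeros(n)
            out = np.empty((total, n))
            for t in range(total):
                y = M @ y + B @ eps[t]
                out[t] = y
            data = out[config.burn_in:]
            subjects.append(
                Subject(f"{label}_s{j+1:02d}", label, sex, data)
            )
    panel = TimeSeriesPanel(
        node_names=list(config.node_names),
        subjects=subjects,
        meta={
            "generator": "usem.simulate",
            "seed": int(config.seed),
            "n_cohorts": config.n_cohorts,
            "subjects_per_cohort": config.subjects_per_cohort,
            "timepoints_per_subject": T,
            "burn_in": config.burn_in,
            "unit_variance_calibrated": bool(config.calibrate_unit_variance),
            "innovation_model": "independent Gaussian innovations"
            + (", variances calibrated to unit stationary variance"
               if config.calibrate_unit_variance else ""),
        },
    )
    by_id = {s.subject_id: s for s in panel.subjects}
    idx = {name: i for i, name in enumerate(config.node_names)}
    # amplitudes are in units of the clean (pre-spike) series SD
    base_sd = {s.subject_id: s.data.std(axis=0) for s in panel.subjects}
    for spike in config.spike_spec:
        s = by_id[spike.subject_id]
        for roi in spike.rois:
            col = idx[roi]
            s.data[spike.timepoint, col] += spike.amplitude * base_sd[s.subject_id][col]
    return panel


# ----------------------------------------------------------------------
# packaged DMN scenario
# ----------------------------------------------------------------------

def _load_json(name: str) -> dict:
    with resources.files("usem.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_dmn_nodes() -> list[dict]:
    """Packaged 9-node DMN node set (names, labels, Talairach coordinates)."""
    return _load_json("dmn_nodes.json")["nodes"]


def load_exploratory_edges() -> dict:
    """Packaged 13-edge exploratory DMN model with per-decade coefficients."""
    return _load_json("exploratory_model.json")


def default_dmn_scenario(
    seed: int,
    subjects_per_cohort: int = 20,
    timepoints_per_subject: int = 600,
    auto: float = 0.6,
) -> SimConfig:
    """The packaged 9-node, 6-cohort DMN scenario.

    The contemporaneous (lagged->lagged analog) coefficient of each of the
    13 published edges at cohort k equals the published decade-k value;
    all unlisted paths are zero.  Cross-lag coefficients are zero and the
    lag-1 autoregression is 0.6 for every node (so an AR(1)-only node has
    lag-1 R^2 of 0.36, the magnitude reported for resting-state BOLD).
    Innovations are unit-variance Gaussians; because the published values
    are standardized estimates of an imperfectly fitting model, no jointly
    realizable process has both these structural coefficients and unit
    stationary variances, so ground truth on the standardized scale that
    fitting sees is given by :func:`standardized_coefficients`.
    """
    node_names = [nd["name"] for nd in load_dmn_nodes()]
    spec = load_exploratory_edges()
    G = spec["n_cohorts"]
    n = len(node_names)
    idx = {name: i for i, name in enumerate(node_names)}
    C = np.zeros((G, n, n))
    for e in spec["edges"]:
        for g, coef in enumerate(e["coefficients"]):
            C[g, idx[e["target"]], idx[e["source"]]] = coef
    return SimConfig(
        node_names=node_names,
        contemporaneous=C,
        auto=np.full(n, auto),
        n_cohorts=G,
        cohort_labels=list(spec["cohort_labels"]),
        subjects_per_cohort=subjects_per_cohort,
        timepoints_per_subject=timepoints_per_subject,
        seed=seed,
    )
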