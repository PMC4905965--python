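"""Age-related trend analysis of path coefficients.

Connectivity change across decade cohorts is quantified by the Pearson
correlation of each edge's lagged->lagged path coefficient (the
connectivity-strength measure, net of autocorrelation and delayed
effects) with the cohort axis, tested two-sided with G-2 degrees of
freedom.  Significant edges are classified rising or falling and grouped
by receiving node, where age-related increases and decreases have been
observed to arrive in pairs.  The chance level of agreement between two
edge sets on the same nodes is an exact hypergeometric tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .fit import GroupFitResult, fit_ml
from .model import Edge, UsemModel
from .panel import TimeSeriesPanel
from .prep import build_lagged, cohort_covariances

__all__ = [
    "trend_from_coefficients",
    "decade_trends",
    "sex_split_trends",
    "per_subject_coefficients",
    "pair_by_receiver",
    "OverlapResult",
    "edge_overlap_probability",
]


def trend_from_coefficients(
    coeffs: pd.DataFrame,
    cohort_axis: np.ndarray | list[float] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson trend of per-cohort coefficients against the cohort axis.

    ``coeffs`` is an edges x cohorts table.  The default axis is the
    cohort index 1..G; Pearson r is invariant under any affine rescaling
    of the axis, so index and mean-cohort-age axes agree.  Returns a
    TrendTable: one row per edge with the coefficient vector, r, the
    two-sided p (t test, G-2 df), and class rising / falling / flat.
    A zero-variance coefficient vector has undefined r and is flat.
    """
    G = coeffs.shape[1]
    if G < 3:
        raise ValueError("need >= 3 cohorts for a trend test")
    x = np.arange(1, G + 1, dtype=float) if cohort_axis is None else np.asarray(
        cohort_axis, dtype=float
    )
    if x.size != G:
        raise ValueError("cohort_axis length must match number of cohorts")
    rows = []
    for edge, vec in coeffs.iterrows():
        y = vec.to_numpy(dtype=float)
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, y)
        if np.isnan(r) or p >= alpha:
            cls = "flat"
        else:
            cls = "rising" if r > 0 else "falling"
        row = {"edge": edge, "r": r, "p": p, "class": cls,
               "significant": cls != "flat"}
        for k, c in enumerate(coeffs.columns):
            row[str(c)] = y[k]
        rows.append(row)
    return pd.DataFrame(rows).set_index("edge")


def decade_trends(
    fits: GroupFitResult,
    cohort_axis: np.ndarray | list[float] | None = None,
    alpha: float = 0.05,
    kind: str = "lagged",
) -> pd.DataFrame:
    """TrendTable from a fitted multi-group model (per-cohort free
    parameters); the trend statistic is the lagged->lagged coefficient."""
    if fits.grouping != "free":
        raise ValueError("decade trends need per-cohort free parameters")
    if len(fits.cohorts) < 3:
        raise ValueError("need >= 3 cohorts")
    return trend_from_coefficients(
        fits.coefficient_matrix(kind=kind), cohort_axis=cohort_axis, alpha=alpha
    )


def sex_split_trends(
    panel: TimeSeriesPanel,
    model: UsemModel,
    cohort_axis: np.ndarray | list[float] | None = None,
    alpha: float = 0.05,
    **fit_kw,
) -> dict:
    """Refit per cohort x sex and compare trends between sexes.

    ``panel`` must already be censored and standardized.  Returns
    ``{"F": TrendTable, "M": TrendTable, "divergent": [edge, ...]}``
    where an edge is divergent when significant in exactly one sex.
    """
    sexes = sorted({s.sex for s in panel.subjects})
    if len(sexes) != 2:
        raise ValueError(f"expected exactly 2 sex levels, found {sexes}")
    for cohort in panel.cohorts:
        present = {s.sex for s in panel.by_cohort(cohort)}
        if present != set(sexes):
            raise ValueError(f"cohort {cohort}: missing sex level {set(sexes) - present}")
    lagged = build_lagged(panel)
    tables = {}
    for sex in sexes:
        covs = cohort_covariances(lagged, sex=sex)
        fit = fit_ml(model, covs, grouping="free", **fit_kw)
        tables[sex] = decade_trends(fit, cohort_axis=cohort_axis, alpha=alpha)
    a, b = sexes
    sig_a = tables[a]["significant"]
    sig_b = tables[b]["significant"]
    divergent = sorted(sig_a.index[(sig_a != sig_b)])
    return {**tables, "divergent": divergent}


def per_subject_coefficients(
    panel: TimeSeriesPanel, model: UsemModel, kind: str = "lagged", **fit_kw
) -> pd.DataFrame:
    """Per-subject path coefficients (each subject fit alone).

    Secondary to the per-cohort analysis: single-subject estimates carry
    much larger standard errors, but allow subject-level trend checks.
    """
    from .prep import CohortCovariances

    lagged = build_lagged(panel)
    rows = []
    for s in lagged.subjects:
        Z = np.hstack([s.unlagged, s.lagged])
        covs = CohortCovariances(
            lagged.variable_names,
            {s.cohort: np.cov(Z, rowvar=False, ddof=1)},
            {s.cohort: Z.shape[0]},
        )
        fit = fit_ml(model, covs, grouping="free", compute_indices=False,
                     compute_se=False, **fit_kw)
        tab = fit.path_table()
        tab = tab[tab["kind"] == kind]
        for _, r in tab.iterrows():
            rows.append(
                {
                    "subject": s.subject_id,
                    "cohort": s.cohort,
                    "sex": s.sex,
                    "edge": f"{r['source']}->{r['target']}",
                    "estimate": r["estimate"],
                }
            )
    return pd.DataFrame(rows)


def pair_by_receiver(trends: pd.DataFrame, model: UsemModel) -> dict:
    """Group significant edges by receiving node.

    Returns ``{"paired": {node: {"rising": [...], "falling": [...]}},
    "unpaired": {node: {...}}}`` — a node is paired when it receives at
    least one rising and one falling significant edge.
    """
    by_target: dict[str, dict[str, list[str]]] = {}
    for e in model.edges:
        label = e.label
        if label not in trends.index:
            continue
        cls = trends.loc[label, "class"]
        if cls == "flat":
            continue
        by_target.setdefault(e.target, {"rising": [], "falling": []})[cls].append(label)
    paired, unpaired = {}, {}
    for node, d in sorted(by_target.items()):
        (paired if d["rising"] and d["falling"] else unpaired)[node] = d
    return {"paired": paired, "unpaired": unpaired}


# ----------------------------------------------------------------------
# edge-set overlap
# ----------------------------------------------------------------------

@dataclass
class OverlapResult:
    """Chance-agreement summary of two undirected edge sets."""

    n_possible: int
    size_a: int
    size_b: int
    overlap: int
    probability: float  # exact P(X >= overlap)
    probability_exact: Fraction

    def to_dict(self) -> dict:
        return {
            "n_possible": self.n_possible,
            "size_a": self.size_a,
            "size_b": self.size_b,
            "overlap": self.overlap,
            "probability": self.probability,
        }


def _undirected(edges) -> set[frozenset]:
    out = set()
    for e in edges:
        if isinstance(e, Edge):
            pair = frozenset((e.source, e.target))
        else:
            pair = frozenset(tuple(e)[:2])
        if len(pair) != 2:
            raise ValueError(f"self-edge {e!r} has no undirected form")
        out.add(pair)
    return out


def edge_overlap_probability(set_a, set_b, n_nodes: int) -> OverlapResult:
    """Exact hypergeometric tail P(overlap >= observed), directions ignored.

    With C(n_nodes, 2) possible undirected edges, |A| of them marked and
    |B| drawn at random, the overlap is hypergeometric; the tail is
    evaluated in exact rational arithmetic.
    """
    N = n_nodes * (n_nodes - 1) // 2
    A, B = _undirected(set_a), _undirected(set_b)
    if len(A) > N or len(B) > N:
        raise ValueError(f"edge set larger than the {N} possible undirected edges")
    k = len(A & B)
    K, n = len(A), len(B)
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return OverlapResult(
        n_possible=N,
        size_a=K,
        size_b=n,
        overlap=k,
        probability=float(total),
        probability_exact=total,
    )
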