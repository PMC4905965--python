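"""Exploratory specification search.

Starting from the null model (each ROI's unlagged variable loading on its
lagged copy and nothing else), candidate connections are scored by
modification indices — univariate score-test estimates of the chi-square
improvement from freeing one fixed path, a lower bound on the refit
improvement.  Each iteration tests the top five candidate region pairs as
full three-path additions in both orientations, accepts the single
addition that most improves the Browne-Cudeck criterion, and stops when
the per-cohort RMSEA upper confidence bound is acceptable for at least
half the cohorts, when no candidate improves the BCC, or at an edge cap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fit import GroupFitResult, RamSystem, fit_ml, single_cohort
from .model import Edge, UsemModel, build_usem
from .prep import CohortCovariances

__all__ = [
    "SearchSettings",
    "SearchTrace",
    "modification_indices",
    "explore",
    "fit_prior_model",
]


@dataclass
class SearchSettings:
    """Tunables of the exploratory search."""

    rmsea_hi_threshold: float = 0.08
    min_groups: int | None = None  # default ceil(G/2)
    max_edges: int = 25
    top_k: int = 5
    mi_aggregation: str = "sum"  # "sum" | "max" over the three paths
    seed: int = 0

    def resolve_min_groups(self, n_groups: int) -> int:
        return self.min_groups if self.min_groups is not None else math.ceil(n_groups / 2)


# ----------------------------------------------------------------------
# modification indices
# ----------------------------------------------------------------------

def _candidate_paths(model: UsemModel, source: str, target: str):
    from .model import PathParam

    return (
        PathParam("contemporaneous", source, target),
        PathParam("lagged", source, target),
        PathParam("crosslag", source, target),
    )


def modification_indices(
    model: UsemModel,
    fit: GroupFitResult,
    covs: CohortCovariances,
    aggregation: str = "sum",
) -> pd.DataFrame:
    """Score-test MI for every absent edge, per direction.

    For a fixed parameter with chi-square-scale score s and effective
    information (after partialling out the free parameters) h, the MI is
    s^2 / h per cohort; cohort contributions add.  The edge-level MI
    aggregates the three path MIs by ``aggregation`` ("sum" or "max").
    Returns a DataFrame with columns source, target, mi and the per-path
    breakdown, sorted by mi descending; empty for a saturated model.
    """
    if aggregation not in ("sum", "max"):
        raise ValueError(f"unknown MI aggregation {aggregation!r}")
    pairs = [
        (a, b)
        for i, a in enumerate(model.node_names)
        for b in model.node_names[i + 1 :]
        if not model.has_pair(a, b)
    ]
    if not pairs:
        return pd.DataFrame(columns=["source", "target", "mi"])

    system = RamSystem(model)
    cand: list[tuple[str, str]] = []
    cand_pos: list[tuple[int, int]] = []
    for a, b in pairs:
        for s_, t_ in ((a, b), (b, a)):
            for p in _candidate_paths(model, s_, t_):
                cand.append((s_, t_))
                cand_pos.append(model.path_indices(p))
    n_free = system.n_params
    n_cand = len(cand_pos)
    mi_path = np.zeros(n_cand)

    for label in fit.cohorts:
        S_samp = covs.matrices[label]
        theta = fit.theta[label]
        N = covs.counts[label]
        sigma = system.implied(theta)
        sig_inv = np.linalg.inv(sigma)
        W = sig_inv - sig_inv @ S_samp @ sig_inv
        A, S = system.unpack(theta)
        B = system._solve(A)

        # dSigma for free params then candidates (candidate value is 0,
        # so the same outer-product formula applies at the current point)
        derivs = np.empty((n_free + n_cand, system.n_var, system.n_var))
        derivs[:n_free] = system.sigma_derivatives(theta)
        for j, (t_, s_) in enumerate(cand_pos):
            half = np.outer(B[:, t_], sigma[s_, :])
            derivs[n_free + j] = half + half.T

        D = np.einsum("ij,kjl->kil", sig_inv, derivs)
        m = n_free + n_cand
        H = np.einsum("ipq,jqp->ij", D, D).reshape(m, m)
        grad_c = np.einsum("ij,kij->k", W, derivs[n_free:])

        H_ff = H[:n_free, :n_free]
        H_fc = H[:n_free, n_free:]
        try:
            X = np.linalg.solve(H_ff, H_fc)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"cohort {label}: singular information matrix; using pseudo-inverse",
                stacklevel=2,
            )
            X = np.linalg.pinv(H_ff) @ H_fc
        h_eff = np.diag(H[n_free:, n_free:]) - np.einsum("ij,ij->j", H_fc, X)
        # second-order drop in chi^2 from freeing one parameter:
        # chi2(tau) ~ chi2(0) + (N-1) g tau + (N-1) h tau^2 / 2,
        # minimized at tau* = -g/h  =>  MI = (N-1) g^2 / (2 h)
        ok = h_eff > 1e-10
        contrib = np.zeros(n_cand)
        contrib[ok] = (N - 1) * grad_c[ok] ** 2 / (2.0 * h_eff[ok])
        if not ok.all():
            warnings.warn(
                f"cohort {label}: dropped {int((~ok).sum())} candidates with "
                "degenerate effective information",
                stacklevel=2,
            )
        mi_path += contrib

    rows = []
    for j in range(0, n_cand, 3):
        s_, t_ = cand[j]
        per_path = mi_path[j : j + 3]
        rows.append(
            {
                "source": s_,
                "target": t_,
                "mi": float(per_path.sum() if aggregation == "sum" else per_path.max()),
                "mi_contemporaneous": float(per_path[0]),
                "mi_lagged": float(per_path[1]),
                "mi_crosslag": float(per_path[2]),
            }
        )
    table = pd.DataFrame(rows).sort_values("mi", ascending=False, ignore_index=True)
    return table


# ----------------------------------------------------------------------
# search trace
# ----------------------------------------------------------------------

@dataclass
class IterationRecord:
    index: int
    candidates: pd.DataFrame  # tested additions with chi2, df, rmsea, bcc, mi
    accepted: str | None
    chi_square: float
    df: int
    rmsea: float
    bcc: float


@dataclass
class SearchTrace:
    """Ordered record of the exploratory-search iterations."""

    start_chi_square: float
    start_df: int
    start_rmsea: float
    start_bcc: float
    iterations: list[IterationRecord] = field(default_factory=list)
    stop_reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Flat table mirroring the iterative-build report: one row per
        tested addition, plus a marker row for each accepted edge."""
        rows = [
            {
                "iteration": 0,
                "addition": "None",
                "accepted": False,
                "chi_square": self.start_chi_square,
                "df": self.start_df,
                "rmsea": self.start_rmsea,
                "bcc": self.start_bcc,
                "mi": np.nan,
            }
        ]
        for it in self.iterations:
            for _, c in it.candidates.iterrows():
                rows.append(
                    {
                        "iteration": it.index,
                        "addition": c["addition"],
                        "accepted": bool(c["addition"] == it.accepted),
                        "chi_square": c["chi_square"],
                        "df": c["df"],
                        "rmsea": c["rmsea"],
                        "bcc": c["bcc"],
                        "mi": c["mi"],
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


# ----------------------------------------------------------------------
# the search proper
# ----------------------------------------------------------------------

def _rmsea_criterion_met(
    fit: GroupFitResult, threshold: float, min_groups: int
) -> bool:
    hi = [g["rmsea_hi90"] for g in fit.fit.groups.values()]
    return sum(h <= threshold for h in hi) >= min_groups


def explore(
    nodes: list[str],
    covs: CohortCovariances,
    settings: SearchSettings | None = None,
) -> tuple[UsemModel, SearchTrace, GroupFitResult]:
    """Forward specification search from the null model.

    Returns the final model, the search trace, and the final fit.
    Deterministic given covariances and settings.
    """
    settings = settings or SearchSettings()
    G = len(covs.cohorts)
    min_groups = settings.resolve_min_groups(G)

    model = build_usem(nodes, [])
    fit = fit_ml(model, covs, grouping="free", seed=settings.seed)
    trace = SearchTrace(
        start_chi_square=fit.chi_square,
        start_df=fit.df,
        start_rmsea=fit.fit.rmsea,
        start_bcc=fit.fit.bcc,
    )
    if _rmsea_criterion_met(fit, settings.rmsea_hi_threshold, min_groups):
        trace.stop_reason = "rmsea criterion met by null model"
        return model, trace, fit

    while len(model.edges) < settings.max_edges:
        mi_table = modification_indices(
            model, fit, covs, aggregation=settings.mi_aggregation
        )
        if mi_table.empty:
            trace.stop_reason = "model saturated"
            break
        # rank unordered pairs by their better direction's MI
        mi_table["pair"] = [
            frozenset((s, t)) for s, t in zip(mi_table["source"], mi_table["target"])
        ]
        pair_rank = (
            mi_table.groupby("pair", sort=False)["mi"].max().sort_values(ascending=False)
        )
        top_pairs = list(pair_rank.index[: settings.top_k])

        tested = []
        for pair in top_pairs:
            for _, row in mi_table[mi_table["pair"] == pair].iterrows():
                edge = Edge(row["source"], row["target"])
                cand_fit = fit_ml(
                    model.with_edge(edge), covs, grouping="free", seed=settings.seed
                )
                tested.append(
                    {
                        "addition": edge.label,
                        "edge": edge,
                        "mi": float(row["mi"]),
                        "chi_square": cand_fit.chi_square,
                        "df": cand_fit.df,
                        "rmsea": cand_fit.fit.rmsea,
                        "bcc": cand_fit.fit.bcc,
                        "fit": cand_fit,
                    }
                )
        tested.sort(key=lambda r: (r["bcc"], r["rmsea"], r["addition"]))
        best = tested[0]
        current_bcc = trace.iterations[-1].bcc if trace.iterations else trace.start_bcc
        if best["bcc"] >= current_bcc:
            trace.stop_reason = "no candidate improves BCC"
            break

        model = model.with_edge(best["edge"])
        fit = best["fit"]
        trace.iterations.append(
            IterationRecord(
                index=len(trace.iterations) + 1,
                candidates=pd.DataFrame(
                    [{k: v for k, v in r.items() if k not in ("fit", "edge")} for r in tested]
                ),
                accepted=best["addition"],
                chi_square=fit.chi_square,
                df=fit.df,
                rmsea=fit.fit.rmsea,
                bcc=fit.fit.bcc,
            )
        )
        if _rmsea_criterion_met(fit, settings.rmsea_hi_threshold, min_groups):
            trace.stop_reason = (
                f"per-cohort RMSEA hi90 <= {settings.rmsea_hi_threshold} "
                f"for >= {min_groups} of {G} cohorts"
            )
            break
    else:
        trace.stop_reason = f"max_edges ({settings.max_edges}) reached"
    if not trace.stop_reason:
        trace.stop_reason = f"max_edges ({settings.max_edges}) reached"
    return model, trace, fit


def fit_prior_model(
    model: UsemModel, covs: CohortCovariances, **fit_kw
) -> dict:
    """Fit a user-supplied prior model pooled (multi-group) and per cohort.

    Returns ``{"pooled": GroupFitResult, "per_cohort": {label: GroupFitResult}}``
    for side-by-side reporting against an exploratory model.
    """
    pooled = fit_ml(model, covs, grouping="free", **fit_kw)
    per = {
        label: fit_ml(model, single_cohort(covs, label), grouping="free", **fit_kw)
        for label in covs.cohorts
    }
    return {"pooled": pooled, "per_cohort": per}
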