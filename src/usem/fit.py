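"""Maximum-likelihood fitting of unified-SEM models to cohort covariances.

The model-implied covariance follows the reticular action model (RAM):
``Sigma(theta) = (I-A)^{-1} S (I-A)^{-T}`` with ``A`` the directed path
matrix over the 2n observed variables and ``S`` the diagonal matrix of
residual variances.  Fitting minimizes the Wishart ML discrepancy

    F = ln|Sigma| - ln|S_g| + tr(S_g Sigma^{-1}) - p

per cohort, with chi^2 = sum_g (N_g - 1) F_g.

Two routes are provided.  Recursive models (no feedback loops) with
per-cohort-free parameters have an exact solution: the Gaussian
likelihood of an acyclic path system with uncorrelated errors factorizes
into one regression per endogenous variable, so each equation is solved
directly from the sample covariance.  Non-recursive variants and
cross-cohort equality constraints fall back to L-BFGS with the analytic
gradient.  Standard errors come from the inverse expected information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize

from . import indices
from .model import Edge, PathParam, UsemModel
from .prep import CohortCovariances

__all__ = [
    "RamSystem",
    "GroupFitResult",
    "implied_covariance",
    "fit_ml",
    "fit_bidirectional_variants",
    "independence_chi_square",
    "single_cohort",
]


class RamSystem:
    """RAM parameterization bound to one :class:`UsemModel`.

    The free-parameter vector is ``[path coefficients..., residual
    variances...]`` in the order of ``model.paths`` then variables.
    """

    def __init__(self, model: UsemModel):
        self.model = model
        self.paths = model.paths
        self.n_var = model.n_variables
        self.path_pos = np.array(
            [model.path_indices(p) for p in self.paths], dtype=int
        ).reshape(-1, 2)  # rows of (target, source)
        self.n_paths = len(self.paths)
        self.n_params = self.n_paths + self.n_var

    # ------------------------------------------------------------------
    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = np.zeros((self.n_var, self.n_var))
        if self.n_paths:
            A[self.path_pos[:, 0], self.path_pos[:, 1]] = theta[: self.n_paths]
        S = np.asarray(theta[self.n_paths :], dtype=float)
        return A, S

    def _solve(self, A: np.ndarray) -> np.ndarray:
        ImA = np.eye(self.n_var) - A
        try:
            return np.linalg.inv(ImA)
        except np.linalg.LinAlgError:
            raise ValueError(self._cycle_message(A)) from None

    def _cycle_message(self, A: np.ndarray) -> str:
        g = nx.DiGraph(zip(*np.nonzero(A.T)))
        try:
            cyc = nx.find_cycle(g)
            names = self.model.variable_names
            loop = " -> ".join(names[u] for u, _ in cyc) + f" -> {names[cyc[0][0]]}"
            return f"(I - A) is singular; feedback loop {loop} has unit gain"
        except nx.NetworkXNoCycle:
            return "(I - A) is singular"

    def implied(self, theta: np.ndarray) -> np.ndarray:
        A, S = self.unpack(theta)
        B = self._solve(A)
        sig = (B * S) @ B.T
        return 0.5 * (sig + sig.T)

    # ------------------------------------------------------------------
    def discrepancy(self, theta: np.ndarray, S_samp: np.ndarray) -> float:
        sigma = self.implied(theta)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return np.inf
        sign_s, logdet_s = np.linalg.slogdet(S_samp)
        if sign_s <= 0:
            raise ValueError("sample covariance is not positive definite")
        return float(
            logdet - logdet_s + np.trace(np.linalg.solve(sigma, S_samp)) - self.n_var
        )

    def gradient(self, theta: np.ndarray, S_samp: np.ndarray) -> np.ndarray:
        """Analytic gradient of F with respect to theta."""
        A, S = self.unpack(theta)
        B = self._solve(A)
        sigma = (B * S) @ B.T
        sig_inv = np.linalg.inv(sigma)
        W = sig_inv - sig_inv @ S_samp @ sig_inv  # dF/dSigma
        g = np.empty(self.n_params)
        if self.n_paths:
            G_A = 2.0 * (sigma @ W @ B)  # indexed [source, target]
            g[: self.n_paths] = G_A[self.path_pos[:, 1], self.path_pos[:, 0]]
        g[self.n_paths :] = np.einsum("ji,jk,ki->i", B, W, B)
        return g

    def sigma_derivatives(self, theta: np.ndarray) -> np.ndarray:
        """Stack of dSigma/dtheta_i, shape (n_params, p, p)."""
        A, S = self.unpack(theta)
        B = self._solve(A)
        sigma = (B * S) @ B.T
        out = np.empty((self.n_params, self.n_var, self.n_var))
        for k in range(self.n_paths):
            t, s = self.path_pos[k]
            half = np.outer(B[:, t], sigma[s, :])
            out[k] = half + half.T
        for i in range(self.n_var):
            out[self.n_paths + i] = np.outer(B[:, i], B[:, i])
        return out

    def information(self, theta: np.ndarray, derivs: np.ndarray | None = None) -> np.ndarray:
        """Expected information of F: H_ij = tr(Sig^-1 dSig_i Sig^-1 dSig_j)."""
        sigma = self.implied(theta)
        sig_inv = np.linalg.inv(sigma)
        if derivs is None:
            derivs = self.sigma_derivatives(theta)
        D = np.einsum("ij,kjl->kil", sig_inv, derivs)  # Sig^-1 dSig_k
        m = D.shape[0]
        return np.einsum("ipq,jqp->ij", D, D).reshape(m, m)


def implied_covariance(system: RamSystem, params: np.ndarray) -> np.ndarray:
    """Model-implied covariance Sigma = (I-A)^{-1} S (I-A)^{-T}."""
    return system.implied(np.asarray(params, dtype=float))


# ----------------------------------------------------------------------
# results container
# ----------------------------------------------------------------------

@dataclass
class GroupFitResult:
    """Per-cohort and pooled ML fit of one unified-SEM model."""

    model: UsemModel
    grouping: str
    cohorts: list[str]
    counts: dict[str, int]
    theta: dict[str, np.ndarray]  # per-cohort parameter vector
    se: dict[str, np.ndarray]  # per-cohort SE vector (same layout)
    discrepancies: dict[str, float]  # minimized F per cohort
    chi_square: float
    df: int
    q: int
    converged: bool
    grad_norm: float
    n_total: int
    fit: "indices.FitIndexBundle | None" = None
    diagnostics: dict = field(default_factory=dict)

    # -- accessors ------------------------------------------------------
    def _system(self) -> RamSystem:
        return RamSystem(self.model)

    def estimate(self, cohort: str, path: PathParam) -> float:
        k = self.model.paths.index(path)
        return float(self.theta[cohort][k])

    def standard_error(self, cohort: str, path: PathParam) -> float:
        k = self.model.paths.index(path)
        return float(self.se[cohort][k])

    def group_chi_square(self, cohort: str) -> float:
        return (self.counts[cohort] - 1) * self.discrepancies[cohort]

    def group_df(self) -> int:
        p = self.model.n_variables
        return p * (p + 1) // 2 - self.model.q_per_group()

    def path_table(self) -> pd.DataFrame:
        """Long table of (cohort, source, target, kind, estimate, se)."""
        rows = []
        for cohort in self.cohorts:
            th, se = self.theta[cohort], self.se[cohort]
            for k, p in enumerate(self.model.paths):
                rows.append(
                    {
                        "cohort": cohort,
                        "source": p.source,
                        "target": p.target,
                        "kind": p.kind,
                        "estimate": float(th[k]),
                        "se": float(se[k]) if se is not None else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def coefficient_matrix(self, kind: str = "lagged") -> pd.DataFrame:
        """Edges x cohorts table of path coefficients of one kind."""
        tab = self.path_table()
        tab = tab[tab["kind"] == kind]
        tab["edge"] = tab["source"] + "->" + tab["target"]
        return tab.pivot(index="edge", columns="cohort", values="estimate")[self.cohorts]

    def to_dict(self) -> dict:
        out = {
            "model": self.model.to_json(grouping=self.grouping),
            "chi_square": self.chi_square,
            "df": self.df,
            "q": self.q,
            "n_total": self.n_total,
            "counts": dict(self.counts),
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "parameters": self.path_table().to_dict(orient="records"),
        }
        if self.fit is not None:
            out["fit_indices"] = self.fit.to_dict()
        return out


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

def _check_pd(S: np.ndarray, label: str) -> None:
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        raise ValueError(f"cohort {label}: sample covariance is not positive definite")


def _fit_group_recursive(system: RamSystem, S_samp: np.ndarray) -> np.ndarray:
    """Exact ML for an acyclic path system: one regression per variable."""
    parents: dict[int, list[tuple[int, int]]] = {i: [] for i in range(system.n_var)}
    for k in range(system.n_paths):
        t, s = system.path_pos[k]
        parents[t].append((k, s))
    theta = np.zeros(system.n_params)
    for i in range(system.n_var):
        ps = parents[i]
        if not ps:
            theta[system.n_paths + i] = S_samp[i, i]
            continue
        src = [s for _, s in ps]
        b = np.linalg.solve(S_samp[np.ix_(src, src)], S_samp[src, i])
        for (k, _), bk in zip(ps, b):
            theta[k] = bk
        theta[system.n_paths + i] = S_samp[i, i] - S_samp[src, i] @ b
    return theta


def _start_values(system: RamSystem, S_samp: np.ndarray) -> np.ndarray:
    theta = np.zeros(system.n_params)
    theta[: system.n_paths] = 0.1
    theta[system.n_paths :] = np.diag(S_samp)
    return theta


def _fit_group_optimize(
    system: RamSystem,
    S_samp: np.ndarray,
    seed: int,
    max_iter: int,
    n_restarts: int,
) -> tuple[np.ndarray, bool]:
    """Quasi-Newton minimization with analytic gradient, seeded restarts."""
    bounds = [(None, None)] * system.n_paths + [(1e-8, None)] * system.n_var

    def obj(th):
        f = system.discrepancy(th, S_samp)
        if not np.isfinite(f):
            return 1e12, np.zeros_like(th)
        return f, system.gradient(th, S_samp)

    rng = np.random.default_rng(seed)
    start = _start_values(system, S_samp)
    best = None
    for attempt in range(n_restarts + 1):
        th0 = start.copy()
        if attempt > 0:
            th0[: system.n_paths] += 0.1 * rng.standard_normal(system.n_paths)
        res = optimize.minimize(
            obj,
            th0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
        if np.max(np.abs(system.gradient(best.x, S_samp))) < 1e-6:
            break
    grad = np.max(np.abs(system.gradient(best.x, S_samp)))
    return best.x, bool(grad < 1e-4)


def _standard_errors(
    system: RamSystem, theta: np.ndarray, n_obs: int
) -> np.ndarray:
    """SEs from the inverse expected information: acov = 2 H^{-1}/(N-1)."""
    H = system.information(theta)
    try:
        cov = 2.0 * np.linalg.inv(H) / (n_obs - 1)
    except np.linalg.LinAlgError:
        warnings.warn("information matrix singular; using pseudo-inverse", stacklevel=2)
        cov = 2.0 * np.linalg.pinv(H) / (n_obs - 1)
    d = np.diag(cov).copy()
    d[d < 0] = np.nan
    return np.sqrt(d)


def independence_chi_square(covs: CohortCovariances) -> tuple[float, int]:
    """chi^2 and df of the independence model (all 2n variables mutually
    uncorrelated, variances free) — the comparison baseline for CFI."""
    chi2 = 0.0
    p = covs.n_variables
    for label, S in covs.matrices.items():
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError(f"cohort {label}: sample covariance not positive definite")
        F = float(np.sum(np.log(np.diag(S))) - logdet)
        chi2 += (covs.counts[label] - 1) * F
    df = len(covs.matrices) * (p * (p + 1) // 2 - p)
    return chi2, df


def single_cohort(covs: CohortCovariances, label: str) -> CohortCovariances:
    """Restrict a covariance set to one cohort (for per-cohort fits)."""
    return CohortCovariances(
        list(covs.variable_names), {label: covs.matrices[label]}, {label: covs.counts[label]}
    )


def fit_ml(
    model: UsemModel,
    covs: CohortCovariances,
    grouping: str = "free",
    method: str = "auto",
    seed: int = 0,
    max_iter: int = 500,
    n_restarts: int = 5,
    compute_se: bool = True,
    compute_indices: bool = True,
) -> GroupFitResult:
    """Fit a unified-SEM model to per-cohort sample covariances.

    ``grouping="free"`` estimates every parameter separately per cohort;
    ``"equal"`` constrains all parameters equal across cohorts.
    ``method`` is ``"auto"`` (exact per-equation solution for recursive
    models with free grouping, optimizer otherwise), ``"closed"`` or
    ``"optimize"``.  Deterministic given inputs and ``seed``.
    """
    if model.node_names != covs.variable_names[: model.n_nodes]:
        # allow plain name match only; lagged block is derived
        raise ValueError("model node_names do not match covariance variables")
    system = RamSystem(model)
    labels = covs.cohorts
    G = len(labels)
    for label in labels:
        _check_pd(covs.matrices[label], label)

    recursive = model.is_recursive()
    if method == "auto":
        method = "closed" if (recursive and grouping == "free") else "optimize"
    if method == "closed" and not (recursive and grouping == "free"):
        raise ValueError("closed-form solution requires a recursive model with free grouping")

    theta: dict[str, np.ndarray] = {}
    converged = True
    if method == "closed":
        for label in labels:
            theta[label] = _fit_group_recursive(system, covs.matrices[label])
    elif grouping == "free":
        for i, label in enumerate(labels):
            th, ok = _fit_group_optimize(
                system, covs.matrices[label], seed + i, max_iter, n_restarts
            )
            theta[label] = th
            converged &= ok
    elif grouping == "equal":
        weights = {g: covs.counts[g] - 1 for g in labels}
        bounds = [(None, None)] * system.n_paths + [(1e-8, None)] * system.n_var

        def obj(th):
            f, g = 0.0, np.zeros_like(th)
            for label in labels:
                fg = system.discrepancy(th, covs.matrices[label])
                if not np.isfinite(fg):
                    return 1e12, np.zeros_like(th)
                f += weights[label] * fg
                g += weights[label] * system.gradient(th, covs.matrices[label])
            return f, g

        S_mean = sum(weights[g] * covs.matrices[g] for g in labels) / sum(weights.values())
        th0 = _start_values(system, S_mean)
        if recursive:
            th0 = _fit_group_recursive(system, S_mean)
        res = optimize.minimize(
            obj, th0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-8},
        )
        converged = bool(np.max(np.abs(res.jac)) < 1e-3)
        for label in labels:
            theta[label] = res.x
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    discrepancies = {
        label: system.discrepancy(theta[label], covs.matrices[label]) for label in labels
    }
    chi_square = float(
        sum((covs.counts[g] - 1) * discrepancies[g] for g in labels)
    )
    q = model.q(G, grouping)
    df = model.df(G, grouping)
    grad_norm = max(
        float(np.max(np.abs(system.gradient(theta[g], covs.matrices[g]))))
        for g in labels
    ) if grouping == "free" else float(np.max(np.abs(
        sum((covs.counts[g] - 1) * system.gradient(theta[g], covs.matrices[g]) for g in labels)
    ))) / max(covs.n_total - G, 1)

    se: dict[str, np.ndarray] = {}
    if compute_se:
        if grouping == "free":
            for label in labels:
                se[label] = _standard_errors(system, theta[label], covs.counts[label])
        else:
            H = sum(
                (covs.counts[g] - 1) * system.information(theta[g]) for g in labels
            )
            try:
                cov = 2.0 * np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov = 2.0 * np.linalg.pinv(H)
            s = np.sqrt(np.clip(np.diag(cov), 0, None))
            for label in labels:
                se[label] = s
    else:
        for label in labels:
            se[label] = np.full(system.n_params, np.nan)

    result = GroupFitResult(
        model=model,
        grouping=grouping,
        cohorts=labels,
        counts=dict(covs.counts),
        theta=theta,
        se=se,
        discrepancies=discrepancies,
        chi_square=chi_square,
        df=df,
        q=q,
        converged=converged,
        grad_norm=grad_norm,
        n_total=covs.n_total,
    )
    if compute_indices:
        null_chi2, null_df = independence_chi_square(covs)
        group_sizes = [covs.counts[g] for g in labels]
        result.fit = indices.bundle(
            chi_square=chi_square,
            df=df,
            n_total=covs.n_total,
            q=q,
            group_sizes=group_sizes,
            p_per_group=[covs.n_variables] * G,
            null_chi_square=null_chi2,
            null_df=null_df,
            groups={
                g: (result.group_chi_square(g), result.group_df(), covs.counts[g])
                for g in labels
            },
        )
    return result


def fit_bidirectional_variants(
    model: UsemModel,
    covs: CohortCovariances,
    bidirectional_edges: list[Edge | tuple],
    **fit_kw,
) -> dict:
    """Compare feedback-loop vs unidirectional treatments of ambiguous edges.

    Fits (a) the non-recursive variant in which every listed edge carries
    both direction triples and (b) every assignment of a single
    orientation to each listed edge, ranking all fits by RMSEA (primary)
    and CFI (secondary).
    """
    from itertools import product

    listed = []
    for e in bidirectional_edges:
        e = e if isinstance(e, Edge) else Edge(*e)
        match = [m for m in model.edges if m.pair == e.pair]
        if not match:
            raise ValueError(f"edge {e.label} not in model")
        listed.append(match[0])
    rest = [e for e in model.edges if e not in listed]

    variants: list[tuple[str, UsemModel]] = []
    fb_edges = rest + [Edge(e.source, e.target, bidirectional=True) for e in listed]
    variants.append(("feedback:" + "+".join(e.label for e in listed),
                     UsemModel(list(model.node_names), fb_edges)))
    for orient in product(*[(e, e.reversed()) for e in listed]):
        uni = [Edge(o.source, o.target, False) for o in orient]
        label = "+".join(o.label for o in uni)
        variants.append((label, UsemModel(list(model.node_names), rest + uni)))

    records = []
    for label, m in variants:
        res = fit_ml(m, covs, **fit_kw)
        records.append(
            {
                "variant": label,
                "non_recursive": not m.is_recursive(),
                "chi_square": res.chi_square,
                "df": res.df,
                "rmsea": res.fit.rmsea,
                "cfi": res.fit.cfi,
                "bcc": res.fit.bcc,
                "result": res,
            }
        )
    records.sort(key=lambda r: (round(r["rmsea"], 12), -round(r["cfi"], 12), r["variant"]))
    return {"variants": records, "best": records[0]}
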