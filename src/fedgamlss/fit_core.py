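"""The RS fitting algorithm for distributional regression with P-splines.

Three nested iterations:

* the **outer** iteration cycles over the distribution parameters
  (mu, sigma, nu, tau);
* the **inner** iteration performs a Newton-type step for one parameter: the
  family supplies a score ``u`` and iterative weight ``w`` on the predictor
  scale, the working response ``z = eta + u/w`` turns the likelihood step into
  a penalized weighted least-squares problem;
* the **backfitting** iteration fits the parametric part and each P-spline
  term to its partial residuals in turn until the joint predictor stabilizes,
  updating smoothing parameters in place (local ML).

Every least-squares solve consumes only additive sufficient statistics —
cross-products ``C'WC``, ``C'Wr`` and a handful of scalars — obtained through
a *cluster* abstraction. The pooled fitter drives a single in-memory node;
the federated driver (``fedgamlss.federation``) drives several nodes through
a serializing message channel. Both run this exact engine, which is why the
two yield identical estimates up to floating-point summation order.

Each accepted inner step must not increase the penalized deviance
(global deviance plus the quadratic P-spline penalty at the step's smoothing
parameters); proposals that do are step-halved toward the previous state.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from ._exceptions import (
    ConvergenceError,
    ProtocolError,
    RankDeficiencyError,
    SpecificationError,
)
from .families import get_family, score_and_weight as _family_score_and_weight
from .model import (
    Control,
    ModelSpec,
    build_param_design,
    merge_schemas,
    penalty_matrix,
    plan_df,
    resolve_plan,
    schema_of,
)
from .smoothers import estimate_lambda, greville_abscissae, lambda_for_df, effective_df

__all__ = [
    "SuffStats",
    "NodeWorker",
    "PooledCluster",
    "FittedModel",
    "global_deviance",
    "pwls_solve",
    "backfit_cycle",
    "inner_iteration",
    "fit_pooled",
    "rs_fit",
]


# ---------------------------------------------------------------------------
# sufficient statistics
# ---------------------------------------------------------------------------

@dataclass
class SuffStats:
    """Additive per-node message for one term's weighted least-squares problem.

    ``ctwc`` is C'WC (term df x term df), ``ctwr`` is C'Wr against the term's
    partial residual r, ``rtwr`` the weighted partial-residual sum of squares,
    ``n`` the node's observation count and ``loglik`` an optional log-likelihood
    contribution. Statistics of a union of datasets are the elementwise sums of
    the parts; dimensions depend only on the model, never on n.
    """

    ctwc: np.ndarray
    ctwr: np.ndarray
    rtwr: float
    n: int
    loglik: float = 0.0

    def __add__(self, other: "SuffStats") -> "SuffStats":
        if self.ctwc.shape != other.ctwc.shape or self.ctwr.shape != other.ctwr.shape:
            raise ProtocolError(
                f"non-conformable sufficient statistics: "
                f"{self.ctwc.shape} vs {other.ctwc.shape}"
            )
        return SuffStats(
            ctwc=self.ctwc + other.ctwc,
            ctwr=self.ctwr + other.ctwr,
            rtwr=self.rtwr + other.rtwr,
            n=self.n + other.n,
            loglik=self.loglik + other.loglik,
        )

    def to_wire(self) -> dict:
        return {
            "ctwc": self.ctwc.tolist(),
            "ctwr": self.ctwr.tolist(),
            "rtwr": float(self.rtwr),
            "n": int(self.n),
            "loglik": float(self.loglik),
        }

    @classmethod
    def from_wire(cls, d: dict) -> "SuffStats":
        return cls(
            ctwc=np.asarray(d["ctwc"], dtype=float),
            ctwr=np.asarray(d["ctwr"], dtype=float),
            rtwr=float(d["rtwr"]),
            n=int(d["n"]),
            loglik=float(d.get("loglik", 0.0)),
        )


# ---------------------------------------------------------------------------
# coefficient containers (plain dicts so they serialize trivially)
# ---------------------------------------------------------------------------

def _zero_coefs(pparam: dict) -> dict:
    n_beta = 0
    for t in pparam["linear"]:
        n_beta += len(t["levels"]) - 1 if t["kind"] == "factor" else 1
    gammas = [np.zeros(len(sm["knots"]) - sm["degree"] - 1) for sm in pparam["smooths"]]
    return {"beta": np.zeros(n_beta), "gamma": gammas}


def _copy_coefs(c: dict) -> dict:
    return {"beta": c["beta"].copy(), "gamma": [g.copy() for g in c["gamma"]]}


def _blend_coefs(old: dict, new: dict, alpha: float) -> dict:
    return {
        "beta": old["beta"] + alpha * (new["beta"] - old["beta"]),
        "gamma": [og + alpha * (ng - og) for og, ng in zip(old["gamma"], new["gamma"])],
    }


def coefs_to_wire(c: dict) -> dict:
    return {"beta": list(map(float, c["beta"])),
            "gamma": [list(map(float, g)) for g in c["gamma"]]}


def coefs_from_wire(d: dict) -> dict:
    return {"beta": np.asarray(d["beta"], dtype=float),
            "gamma": [np.asarray(g, dtype=float) for g in d["gamma"]]}


def _beta_offsets(lin_terms) -> list:
    """Column offset of each linear term within the beta vector."""
    offsets, pos = [], 0
    for t in lin_terms:
        offsets.append(pos)
        pos += len(t["levels"]) - 1 if t["kind"] == "factor" else 1
    return offsets


# ---------------------------------------------------------------------------
# node-side computation
# ---------------------------------------------------------------------------

class _ParamDesign:
    """One distribution parameter's design blocks on one node."""

    def __init__(self, X: np.ndarray, Zs: list, names: list):
        self.X = X
        self.Zs = Zs
        self.names = names

    def assemble(self, coefs: dict) -> np.ndarray:
        eta = self.X @ coefs["beta"]
        for Z, g in zip(self.Zs, coefs["gamma"]):
            eta = eta + Z @ g
        return eta

    def term_matrix(self, term):
        if term == "linear":
            return self.X
        kind, j = term
        return self.Zs[j]

    def term_fit(self, term, coefs):
        if term == "linear":
            return self.X @ coefs["beta"]
        kind, j = term
        return self.Zs[j] @ coefs["gamma"][j]


class NodeWorker:
    """Holds one node's private data and performs all per-observation work.

    Only low-dimensional cross-products, scalar aggregates and counts ever
    leave this object; vectors of length n stay inside.
    """

    def __init__(self, node_id: str, data: pd.DataFrame):
        self.node_id = str(node_id)
        self.data = data.reset_index(drop=True)
        self.n = len(data)
        self.family = None
        self.designs: dict = {}
        self.y = None
        self.eta: dict = {}
        self.theta: dict = {}
        self._wz: dict = {}
        self._ctwc_cache: dict = {}
        self._weights_version = 0

    # -- protocol -----------------------------------------------------------
    def describe(self) -> dict:
        return schema_of(self.data)

    def build(self, plan: dict) -> dict:
        self.family = get_family(plan["family"], links=plan["links"])
        resp = plan["response"]
        if resp not in self.data.columns:
            raise ProtocolError(f"response column {resp!r} missing on node {self.node_id!r}")
        self.y = self.family.validate_y(np.asarray(self.data[resp], dtype=float))
        self.designs = {}
        for k, pparam in plan["params"].items():
            X, Zs, names = build_param_design(self.data, pparam,
                                              where=f"node {self.node_id!r}")
            self.designs[k] = _ParamDesign(X, Zs, names)
        return {"n": self.n, "df": plan_df(plan)}

    def init_stats(self) -> dict:
        y = self.y
        return {"n": self.n, "sum_y": float(y.sum()), "sum_y2": float((y * y).sum())}

    def set_initial(self, coefs_all: dict) -> dict:
        for k, c in coefs_all.items():
            self._set_eta(k, self.designs[k].assemble(self._coerce(c)))
        return {}

    def _set_eta(self, k, eta_k):
        self.eta[k] = np.asarray(eta_k, dtype=float)
        self.theta[k] = self.family.clip_param(
            k, self.family.links[k].inverse(self.eta[k])
        )

    def begin_inner(self, k: str) -> dict:
        u, w = _family_score_and_weight(self.family, k, self.y, self.theta)
        z = self.eta[k] + u / w
        self._wz[k] = (w, z)
        self._weights_version += 1
        self._ctwc_cache = {}
        return {}

    def term_stats(self, k: str, term, coefs_k: dict) -> SuffStats:
        coefs_k = self._coerce(coefs_k)
        w, z = self._wz[k]
        d = self.designs[k]
        C = d.term_matrix(term)
        eta = d.assemble(coefs_k)
        r = z - eta + d.term_fit(term, coefs_k)
        key = (k, "linear" if term == "linear" else ("smooth", term[1]))
        ctwc = self._ctwc_cache.get(key)
        if ctwc is None:
            ctwc = C.T @ (w[:, None] * C)
            self._ctwc_cache[key] = ctwc
        wr = w * r
        return SuffStats(ctwc=ctwc, ctwr=C.T @ wr, rtwr=float(r @ wr), n=self.n)

    def delta_eta(self, k: str, coefs_a: dict, coefs_b: dict) -> dict:
        d = self.designs[k]
        delta = d.assemble(self._coerce(coefs_a)) - d.assemble(self._coerce(coefs_b))
        return {"max_abs": float(np.max(np.abs(delta))) if self.n else 0.0}

    def loglik(self, trial: dict | None = None) -> dict:
        theta = self.theta
        if trial is not None:
            k = trial["k"]
            eta_k = self.designs[k].assemble(self._coerce(trial["coefs"]))
            theta = dict(theta)
            theta[k] = self.family.clip_param(k, self.family.links[k].inverse(eta_k))
        ll = float(self.family.log_density(self.y, theta).sum())
        return {"loglik": ll, "n": self.n}

    def accept(self, k: str, coefs_k: dict) -> dict:
        self._set_eta(k, self.designs[k].assemble(self._coerce(coefs_k)))
        return {}

    @staticmethod
    def _coerce(coefs):
        if isinstance(coefs["beta"], np.ndarray):
            return coefs
        return coefs_from_wire(coefs)

    # -- convenience (pooled fits only) -------------------------------------
    def fitted_theta(self) -> pd.DataFrame:
        return pd.DataFrame({k: v for k, v in self.theta.items()})


class PooledCluster:
    """Single in-memory node; the degenerate (D = 1) cluster with no transport."""

    def __init__(self, worker: NodeWorker):
        self.worker = worker

    def init_stats(self):
        return self.worker.init_stats()

    def set_initial(self, coefs_all):
        self.worker.set_initial({k: c for k, c in coefs_all.items()})

    def begin_inner(self, k):
        self.worker.begin_inner(k)

    def term_stats(self, k, term, coefs_k) -> SuffStats:
        return self.worker.term_stats(k, term, coefs_k)

    def max_delta(self, k, coefs_a, coefs_b) -> float:
        return self.worker.delta_eta(k, coefs_a, coefs_b)["max_abs"]

    def loglik(self, trial=None) -> float:
        return self.worker.loglik(trial)["loglik"]

    def accept(self, k, coefs_k):
        self.worker.accept(k, coefs_k)


# ---------------------------------------------------------------------------
# client-side linear algebra
# ---------------------------------------------------------------------------

def global_deviance(family, y, theta) -> float:
    """Global deviance: -2 x sum of per-observation log-densities."""
    if isinstance(family, str):
        family = get_family(family)
    return float(-2.0 * np.sum(family.log_density(y, theta)))


def pwls_solve(ctwc, ctwz, penalty=None, cond_limit: float = 1e12,
               names=None) -> np.ndarray:
    """Solve the penalized weighted least-squares system (C'WC + P) b = C'Wz.

    Uses a QR factorization of the (small, aggregated) penalized cross-product;
    a Jacobi-scaled condition number above ``cond_limit`` raises
    :class:`RankDeficiencyError` naming the most collinear columns.
    """
    M = np.asarray(ctwc, dtype=float)
    r = np.asarray(ctwz, dtype=float)
    if penalty is not None:
        M = M + np.asarray(penalty, dtype=float)
    d = np.sqrt(np.abs(np.diag(M)))
    if np.any(d == 0.0):
        idx = np.flatnonzero(np.diag(M) == 0.0)
        label = [names[i] for i in idx] if names else list(map(int, idx))
        raise RankDeficiencyError(f"zero-information column(s): {label}")
    Ms = M / np.outer(d, d)
    sv = np.linalg.svd(Ms, compute_uv=False)
    # a dominant penalty legitimately inflates the condition number (the
    # solution is still well determined in the data directions), so the
    # collinearity guard applies to unpenalized (linear-term) systems only
    effective_limit = cond_limit if penalty is None else np.inf
    if sv[-1] <= 0 or sv[0] / sv[-1] > effective_limit:
        _, _, Vt = np.linalg.svd(Ms)
        heavy = np.argsort(-np.abs(Vt[-1]))[:2]
        label = [names[i] for i in heavy] if names else list(map(int, heavy))
        raise RankDeficiencyError(
            f"ill-conditioned system (scaled condition number "
            f"{sv[0] / max(sv[-1], 1e-300):.2e}); near-collinear columns: {label}"
        )
    Q, R = np.linalg.qr(M)
    x = scipy.linalg.solve_triangular(R, Q.T @ r)
    # iterative refinement with extended-precision residuals: cheap on these
    # small systems, and keeps stiff (dominant-penalty) solves accurate
    Ml, rl = M.astype(np.longdouble), r.astype(np.longdouble)
    for _ in range(2):
        resid = np.asarray(rl - Ml @ x.astype(np.longdouble), dtype=float)
        x = x + scipy.linalg.solve_triangular(R, Q.T @ resid)
    return x


# ---------------------------------------------------------------------------
# shared backfitting loop (client side)
# ---------------------------------------------------------------------------

@dataclass
class _SmoothLayout:
    G: np.ndarray
    order: int
    policy: object           # "ml" | float | ["df", float]
    transfer_N: np.ndarray   # q x m null-space basis shared with the linear part
    beta_targets: list       # beta indices absorbing the transferred components
    q: int = 0


@dataclass
class _ParamLayout:
    smooths: list
    lin_names: list = field(default_factory=list)


def _layout_from_plan(pparam: dict) -> _ParamLayout:
    offsets = _beta_offsets(pparam["linear"])
    smooths = []
    for sm in pparam["smooths"]:
        G = penalty_matrix(sm)
        q = G.shape[0]
        cols = [np.ones(q)]
        targets = [0]  # intercept is always the first linear column
        if sm["order"] >= 2 and sm["degree"] >= 1:
            cols.append(greville_abscissae(sm["knots"], sm["degree"]))
            targets.append(offsets[sm["x_linear_index"]])
        N = np.column_stack(cols)
        smooths.append(_SmoothLayout(G=G, order=sm["order"], policy=sm["lambda"],
                                     transfer_N=N, beta_targets=targets, q=q))
    names = []
    for t in pparam["linear"]:
        if t["kind"] == "intercept":
            names.append("(Intercept)")
        elif t["kind"] == "numeric":
            names.append(t["name"])
        else:
            names.extend(f"{t['name']}[{lev}]" for lev in t["levels"][1:])
    return _ParamLayout(smooths=smooths, lin_names=names)


def _transfer_nullspace(gamma: np.ndarray, sl: _SmoothLayout):
    """Move the smooth's exactly-linear content into the parametric part.

    The transfer directions lie in the penalty null space, so the penalty
    value and the assembled predictor are both unchanged; it merely makes the
    decomposition between X beta and the smooth identified.
    """
    N = sl.transfer_N
    if N.shape[1] == 0:
        return gamma, np.zeros(0)
    a = np.linalg.solve(N.T @ N, N.T @ gamma)
    return gamma - N @ a, a


def _run_backfit(term_stats, max_delta, layout: _ParamLayout, lam_k: list,
                 control: Control, n_total: float, coefs_k: dict,
                 notes: list, label: str):
    """Cycle linear + smooth solves until the predictor stabilizes.

    ``term_stats(term, coefs_k) -> SuffStats`` and
    ``max_delta(coefs_a, coefs_b) -> float`` abstract over pooled/federated.
    Returns (coefs_k, cycles, last_ctwc_per_smooth).
    """
    n_sm = len(layout.smooths)
    last_ctwc = [None] * n_sm
    cycles = 0
    while True:
        cycles += 1
        prev = _copy_coefs(coefs_k)
        st = term_stats("linear", coefs_k)
        coefs_k["beta"] = pwls_solve(st.ctwc, st.ctwr, cond_limit=control.cond_limit,
                                     names=layout.lin_names)
        for j, sl in enumerate(layout.smooths):
            st = term_stats(("smooth", j), coefs_k)
            last_ctwc[j] = st.ctwc
            if sl.policy == "ml":
                lam_k[j], capped = estimate_lambda(
                    st.ctwc, st.ctwr, st.rtwr, sl.G, n_total, lam_k[j], sl.order,
                    max_iter=control.lambda_max_iter, rtol=control.lambda_rtol,
                )
                if capped:
                    msg = f"lambda at bound for smooth {j} of {label}"
                    if msg not in notes:
                        notes.append(msg)
            elif isinstance(sl.policy, (list, tuple)):
                lam_k[j] = lambda_for_df(st.ctwc, sl.G, float(sl.policy[1]))
            else:
                lam_k[j] = float(sl.policy)
            gamma = pwls_solve(st.ctwc, st.ctwr, lam_k[j] * sl.G,
                               cond_limit=control.cond_limit)
            gamma, a = _transfer_nullspace(gamma, sl)
            coefs_k["gamma"][j] = gamma
            for idx, val in zip(sl.beta_targets, a):
                coefs_k["beta"][idx] += val
        if n_sm == 0:
            break
        if max_delta(coefs_k, prev) < control.backfit_tol:
            break
        if cycles >= control.max_backfit:
            notes.append(f"backfitting hit max_backfit={control.max_backfit} for {label}")
            break
    return coefs_k, cycles, last_ctwc


def _penalty_value(coefs_k: dict, lam_k: list, layout: _ParamLayout) -> float:
    return float(sum(l * (g @ sl.G @ g)
                     for l, g, sl in zip(lam_k, coefs_k["gamma"], layout.smooths)))


# ---------------------------------------------------------------------------
# the RS engine
# ---------------------------------------------------------------------------

def rs_fit(cluster, plan: dict, control: Control) -> dict:
    """Run the nested RS iterations against a cluster of nodes."""
    fam = get_family(plan["family"], links=plan["links"])
    params = list(fam.param_names)
    layouts = {k: _layout_from_plan(plan["params"][k]) for k in params}

    lam = {}
    for k in params:
        lam[k] = []
        for sl in layouts[k].smooths:
            if isinstance(sl.policy, (int, float)) and not isinstance(sl.policy, bool):
                lam[k].append(float(sl.policy))
            else:
                lam[k].append(float(control.lambda_init))

    stats0 = cluster.init_stats()
    n_total = float(stats0["n"])
    eta0 = fam.initial_eta(stats0)
    coefs = {}
    for k in params:
        c = _zero_coefs(plan["params"][k])
        c["beta"][0] = float(eta0[k])
        coefs[k] = c
    cluster.set_initial(coefs)

    dev = -2.0 * cluster.loglik(None)
    notes: list = []
    pen_trace: list = []
    inner_total = 0
    backfit_total = 0
    converged = False
    outer_used = 0

    for outer in range(1, control.max_outer + 1):
        outer_used = outer
        dev_outer_start = dev
        for k in params:
            layout = layouts[k]
            for _ in range(control.max_inner):
                inner_total += 1
                cluster.begin_inner(k)
                old = _copy_coefs(coefs[k])
                dev_old = dev

                def _stats(term, c, _k=k):
                    return cluster.term_stats(_k, term, c)

                def _delta(a, b, _k=k):
                    return cluster.max_delta(_k, a, b)

                new, cycles, last_ctwc = _run_backfit(
                    _stats, _delta, layout, lam[k], control, n_total,
                    _copy_coefs(coefs[k]), notes, label=f"parameter {k!r}",
                )
                backfit_total += cycles
                layouts[k].last_ctwc = last_ctwc

                pen_others = sum(_penalty_value(coefs[k2], lam[k2], layouts[k2])
                                 for k2 in params if k2 != k)
                pen_old = dev_old + _penalty_value(old, lam[k], layout)
                alpha, accepted = 1.0, False
                tol_pad = 1e-10 * (abs(pen_old) + 1.0)
                for _h in range(control.max_halvings + 1):
                    trial = _blend_coefs(old, new, alpha)
                    dev_trial = -2.0 * cluster.loglik({"k": k, "coefs": trial})
                    pen_trial = dev_trial + _penalty_value(trial, lam[k], layout)
                    if np.isfinite(pen_trial) and pen_trial <= pen_old + tol_pad:
                        accepted = True
                        break
                    alpha *= 0.5
                if not accepted:
                    trial, dev_trial, pen_trial = old, dev_old, pen_old
                    notes.append(f"step for parameter {k!r} rejected (outer {outer})")
                coefs[k] = trial
                cluster.accept(k, trial)
                dev = dev_trial
                pen_trace.append(pen_trial + pen_others)
                if abs(dev - dev_old) < control.inner_tol:
                    break
        if abs(dev - dev_outer_start) < control.outer_tol:
            converged = True
            break
    if not converged:
        notes.append(f"outer iterations exhausted (max_outer={control.max_outer})")

    edf = {}
    pen_total = 0.0
    for k in params:
        edf[k] = []
        for j, sl in enumerate(layouts[k].smooths):
            ctwc = getattr(layouts[k], "last_ctwc", [None] * len(layouts[k].smooths))[j]
            edf[k].append(effective_df(ctwc, sl.G, lam[k][j]) if ctwc is not None else float("nan"))
        pen_total += _penalty_value(coefs[k], lam[k], layouts[k])

    return {
        "coefficients": coefs,
        "lambdas": lam,
        "edf": edf,
        "deviance": dev,
        "penalized_deviance": dev + pen_total,
        "iterations": {"outer": outer_used, "inner": inner_total,
                       "backfit_cycles": backfit_total},
        "converged": converged,
        "warnings": notes,
        "pen_trace": pen_trace,
        "n_obs": int(n_total),
    }


# ---------------------------------------------------------------------------
# public single-table operations
# ---------------------------------------------------------------------------

def backfit_cycle(X, smooths, w, z, coefs=None, control: Control | None = None,
                  n_eff: float | None = None, lambdas: list | None = None):
    """Pooled, in-memory backfitting for one working WLS problem.

    ``smooths`` is a list of dicts with keys ``Z`` (basis matrix), ``G``
    (penalty), ``order``, ``lambda`` ("ml" | float | ("df", v)) and optionally
    ``transfer_N``/``beta_targets`` for null-space identification. Returns
    ``(coefs, lambdas, n_cycles)``.
    """
    control = control or Control()
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    design = _ParamDesign(X, [np.asarray(s["Z"], float) for s in smooths],
                          [f"x{i}" for i in range(X.shape[1])])
    layout = _ParamLayout(smooths=[], lin_names=design.names)
    for s in smooths:
        G = np.asarray(s["G"], dtype=float)
        q = G.shape[0]
        N = np.asarray(s.get("transfer_N", np.ones((q, 1))), dtype=float)
        layout.smooths.append(_SmoothLayout(
            G=G, order=int(s.get("order", 2)), policy=s.get("lambda", "ml"),
            transfer_N=N, beta_targets=list(s.get("beta_targets", [0]))[: N.shape[1]],
            q=q,
        ))
    if coefs is None:
        coefs = {"beta": np.zeros(X.shape[1]),
                 "gamma": [np.zeros(sl.q) for sl in layout.smooths]}
    else:
        coefs = _copy_coefs(coefs)
    lam_k = list(lambdas) if lambdas is not None else [control.lambda_init] * len(layout.smooths)

    def term_stats(term, c):
        C = design.term_matrix(term)
        r = z - design.assemble(c) + design.term_fit(term, c)
        wr = w * r
        return SuffStats(ctwc=C.T @ (w[:, None] * C), ctwr=C.T @ wr,
                         rtwr=float(r @ wr), n=len(z))

    def max_delta(a, b):
        return float(np.max(np.abs(design.assemble(a) - design.assemble(b))))

    notes: list = []
    coefs, cycles, _ = _run_backfit(term_stats, max_delta, layout, lam_k, control,
                                    n_eff if n_eff is not None else float(len(z)),
                                    coefs, notes, label="backfit_cycle")
    return coefs, lam_k, cycles


def inner_iteration(family, k, y, X, smooths, theta, control: Control | None = None,
                    coefs_k: dict | None = None, lambdas: list | None = None):
    """One parameter's Newton/backfitting loop on pooled in-memory data.

    ``theta`` holds all parameters' current natural-scale vectors; parameters
    other than ``k`` stay fixed. Returns ``(coefs_k, eta_k, deviance_trace)``.
    """
    if isinstance(family, str):
        family = get_family(family)
    control = control or Control()
    y = np.asarray(y, dtype=float)
    theta = {kk: np.asarray(v, dtype=float) for kk, v in
             (theta.theta if hasattr(theta, "theta") else theta).items()}
    X = np.asarray(X, dtype=float)
    design = _ParamDesign(X, [np.asarray(s["Z"], float) for s in smooths], [])
    if coefs_k is None:
        # start from the current eta_k projected onto the parametric part
        coefs_k = {"beta": np.zeros(X.shape[1]),
                   "gamma": [np.zeros(np.asarray(s["G"]).shape[0]) for s in smooths]}
        eta_k = family.links[k].apply(theta[k])
        coefs_k["beta"][0] = float(np.mean(eta_k))
    eta_k = design.assemble(coefs_k)
    theta[k] = family.clip_param(k, family.links[k].inverse(eta_k))
    dev = global_deviance(family, y, theta)
    trace = [dev]
    lam_k = lambdas
    for _ in range(control.max_inner):
        u, w = family.score_and_weight(k, y, theta)
        z = eta_k + u / w
        old = _copy_coefs(coefs_k)
        new, lam_k, _ = backfit_cycle(X, smooths, w, z, coefs=coefs_k,
                                      control=control, lambdas=lam_k)
        alpha, accepted = 1.0, False
        for _h in range(control.max_halvings + 1):
            trial = _blend_coefs(old, new, alpha)
            eta_try = design.assemble(trial)
            th_try = dict(theta)
            th_try[k] = family.clip_param(k, family.links[k].inverse(eta_try))
            dev_try = global_deviance(family, y, th_try)
            if np.isfinite(dev_try) and dev_try <= dev + 1e-10 * (abs(dev) + 1.0):
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            raise ConvergenceError(
                f"inner iteration for {k!r} could not decrease the deviance"
            )
        coefs_k = trial
        eta_k = design.assemble(coefs_k)
        theta[k] = family.clip_param(k, family.links[k].inverse(eta_k))
        prev, dev = dev, dev_try
        trace.append(dev)
        if abs(dev - prev) < control.inner_tol:
            break
    return coefs_k, eta_k, trace


# ---------------------------------------------------------------------------
# fitted-model container and the pooled driver
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """Converged coefficients, smoothing parameters and fit diagnostics."""

    plan: dict
    control: dict
    coefficients: dict
    lambdas: dict
    edf: dict
    deviance: float
    penalized_deviance: float
    iterations: dict
    converged: bool
    warnings: list
    n_obs: int
    comm_log: list | None = None
    fitted: object = None      # pooled fits only; never serialized

    @property
    def family_name(self) -> str:
        return self.plan["family"]

    def make_family(self):
        return get_family(self.plan["family"], links=self.plan["links"])

    def coef_vector(self, k: str) -> np.ndarray:
        c = self.coefficients[k]
        parts = [np.asarray(c["beta"], float)]
        parts += [np.asarray(g, float) for g in c["gamma"]]
        return np.concatenate(parts)

    def coef_table(self) -> dict:
        return {k: self.coef_vector(k) for k in self.plan["params"]}

    def to_dict(self) -> dict:
        return {
            "plan": self.plan,
            "control": self.control,
            "coefficients": {k: coefs_to_wire(NodeWorker._coerce(c))
                             for k, c in self.coefficients.items()},
            "lambdas": {k: list(map(float, v)) for k, v in self.lambdas.items()},
            "edf": {k: list(map(float, v)) for k, v in self.edf.items()},
            "deviance": float(self.deviance),
            "penalized_deviance": float(self.penalized_deviance),
            "iterations": self.iterations,
            "converged": bool(self.converged),
            "warnings": list(self.warnings),
            "n_obs": int(self.n_obs),
            "comm_log": self.comm_log,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            plan=d["plan"], control=d["control"],
            coefficients={k: coefs_from_wire(c) for k, c in d["coefficients"].items()},
            lambdas=d["lambdas"], edf=d["edf"],
            deviance=d["deviance"], penalized_deviance=d["penalized_deviance"],
            iterations=d["iterations"], converged=d["converged"],
            warnings=d["warnings"], n_obs=d["n_obs"],
            comm_log=d.get("comm_log"),
        )

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _result_to_model(plan, control, res, comm_log=None, fitted=None) -> FittedModel:
    res = dict(res)
    res.pop("pen_trace", None)
    return FittedModel(plan=plan, control=control.to_dict(), comm_log=comm_log,
                       fitted=fitted, **res)


def _check_identifiable(plan: dict, n: int) -> None:
    """Each parameter's WLS problem needs more observations than coefficients."""
    for k, pparam in plan["params"].items():
        df_k = sum(len(t["levels"]) - 1 if t["kind"] == "factor" else 1
                   for t in pparam["linear"])
        df_k += sum(len(sm["knots"]) - sm["degree"] - 1 for sm in pparam["smooths"])
        if n <= df_k:
            raise SpecificationError(
                f"n = {n} observations cannot identify the {df_k} coefficients "
                f"of parameter {k!r}"
            )


def fit_pooled(spec: ModelSpec, data: pd.DataFrame, control: Control | None = None,
               knots: dict | None = None) -> FittedModel:
    """Fit the model to a single physically pooled table (the reference path)."""
    control = control or spec.control
    schema = merge_schemas({"pooled": schema_of(data)})
    plan = resolve_plan(spec, schema, knots=knots)
    _check_identifiable(plan, len(data))
    worker = NodeWorker("pooled", data)
    worker.build(plan)
    cluster = PooledCluster(worker)
    res = rs_fit(cluster, plan, control)
    model = _result_to_model(plan, control, res, comm_log=None,
                             fitted=worker.fitted_theta())
    model._pen_trace = res.get("pen_trace")
    return model


def pooled_knots(spec: ModelSpec, data: pd.DataFrame) -> dict:
    """Knot vectors a pooled fit would use (for shared-knot federated fits)."""
    schema = merge_schemas({"pooled": schema_of(data)})
    plan = resolve_plan(spec, schema)
    out = {}
    for pparam in plan["params"].values():
        for sm in pparam["smooths"]:
            out[sm["name"]] = np.asarray(sm["knots"], dtype=float)
    return out
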