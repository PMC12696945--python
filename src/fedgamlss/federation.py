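"""Federated fitting: nodes, wire serialization, aggregation and disclosure guards.

Each node holds a private table behind a :class:`Node` wrapper. The client
(the fitting driver) broadcasts the compiled model plan and current
coefficients, and every per-term least-squares solve consumes only the
elementwise sum of per-node sufficient statistics (cross-products, scalars,
counts). All traffic crosses an explicit JSON wire format, so only plain
numbers of model-sized dimension can leave a node — never a vector of
length n — and every exchange is recorded in a communication log.

Because the federated driver runs the exact same RS engine as the pooled
fitter, merely sourcing each solve's cross-products from a sum over nodes
instead of one matrix product, the two paths produce identical estimates up
to floating-point summation order (the additivity of matrix multiplication
across row blocks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import DisclosureError, HarmonizationError, ProtocolError
from .fit_core import (
    FittedModel,
    NodeWorker,
    SuffStats,
    _check_identifiable,
    _result_to_model,
    rs_fit,
)
from .model import Control, ModelSpec, merge_schemas, plan_df, resolve_plan
from .smoothers import anonymized_range

__all__ = [
    "Thresholds",
    "CommLog",
    "Node",
    "FederatedSession",
    "broadcast_spec",
    "node_suffstats",
    "aggregate",
    "disclosure_guard",
    "fit_federated",
]


@dataclass
class Thresholds:
    """Data-owner privacy settings (DataSHIELD-style defaults, all configurable)."""

    k_anonymity: int = 3
    category_min: int = 3
    df_ratio: float = 0.33

    def to_dict(self):
        return {"k_anonymity": self.k_anonymity, "category_min": self.category_min,
                "df_ratio": self.df_ratio}


class CommLog:
    """Ordered record of client<->node exchanges.

    One *round* is a single request/response pair with one node; each entry
    stores the payload kind and its scalar count, which must be independent of
    any node's sample size.
    """

    def __init__(self):
        self.entries: list = []
        self._round = 0

    def record(self, node_id: str, kind: str, n_request: int, n_response: int):
        self._round += 1
        self.entries.append({"round": self._round, "node": node_id, "kind": kind,
                             "request_scalars": n_request,
                             "response_scalars": n_response})

    @property
    def total_rounds(self) -> int:
        return self._round

    def max_payload(self, kind: str | None = None) -> int:
        sel = [e for e in self.entries if kind is None or e["kind"] == kind]
        if not sel:
            return 0
        return max(max(e["request_scalars"], e["response_scalars"]) for e in sel)

    def to_records(self) -> list:
        return list(self.entries)


def _count_scalars(obj) -> int:
    if isinstance(obj, (int, float, bool)):
        return 1
    if isinstance(obj, (list, tuple)):
        return sum(_count_scalars(v) for v in obj)
    if isinstance(obj, dict):
        return sum(_count_scalars(v) for v in obj.values())
    return 0


def disclosure_guard(model_df: int, node_meta: dict, thresholds: Thresholds) -> list:
    """Evaluate the data-owner rules for one node; returns violation strings.

    Rules: the requested model degrees of freedom must stay below
    ``df_ratio * n_node``; every factor-category count must reach
    ``category_min``; and the node itself must hold at least ``k_anonymity``
    observations.
    """
    violations = []
    n = int(node_meta["n"])
    if n < thresholds.k_anonymity:
        violations.append(
            f"k-anonymity: node has n={n} < {thresholds.k_anonymity}"
        )
    if model_df > thresholds.df_ratio * n:
        violations.append(
            f"degrees of freedom: model df={model_df} exceeds "
            f"{thresholds.df_ratio} x n={n}"
        )
    for col, meta in node_meta.get("columns", {}).items():
        if meta.get("kind") != "factor":
            continue
        for lev, cnt in meta["levels"].items():
            if cnt < thresholds.category_min:
                violations.append(
                    f"category count: {col!r} level {lev!r} has {cnt} < "
                    f"{thresholds.category_min} observations"
                )
    return violations


class Node:
    """A data holder: private table plus a guarded, serialized message endpoint."""

    def __init__(self, node_id: str, data: pd.DataFrame,
                 thresholds: Thresholds | None = None):
        self.node_id = str(node_id)
        self.thresholds = thresholds or Thresholds()
        self._worker = NodeWorker(node_id, data)
        self._guarded_columns: set = set()

    @property
    def n(self) -> int:
        return self._worker.n

    def handle_json(self, request: str) -> str:
        """The node's sole entry point: JSON in, JSON out."""
        msg = json.loads(request)
        kind = msg.get("kind")
        w = self._worker
        if kind == "describe":
            resp = w.describe()
        elif kind == "build":
            plan = msg["plan"]
            meta = w.describe()
            used = {plan["response"]}
            for pparam in plan["params"].values():
                for t in pparam["linear"]:
                    if t["kind"] != "intercept":
                        used.add(t["name"])
                for sm in pparam["smooths"]:
                    used.add(sm["name"])
            meta_used = {"n": meta["n"],
                         "columns": {c: m for c, m in meta["columns"].items()
                                     if c in used}}
            violations = disclosure_guard(plan_df(plan), meta_used, self.thresholds)
            if violations:
                resp = {"ok": False, "violations": violations}
            else:
                resp = {"ok": True, **w.build(plan)}
        elif kind == "init_stats":
            resp = w.init_stats()
        elif kind == "set_initial":
            resp = w.set_initial(msg["coefs"])
        elif kind == "begin_inner":
            resp = w.begin_inner(msg["k"])
        elif kind == "term_stats":
            term = msg["term"]
            term = "linear" if term == "linear" else ("smooth", int(term[1]))
            resp = w.term_stats(msg["k"], term, msg["coefs"]).to_wire()
        elif kind == "delta_eta":
            resp = w.delta_eta(msg["k"], msg["coefs_a"], msg["coefs_b"])
        elif kind == "loglik":
            resp = w.loglik(msg.get("trial"))
        elif kind == "accept":
            resp = w.accept(msg["k"], msg["coefs"])
        else:
            raise ProtocolError(f"unknown message kind {kind!r}")
        return json.dumps(resp)


class FederatedSession:
    """A client connected to a set of nodes, with a shared communication log."""

    def __init__(self, node_data, thresholds: Thresholds | None = None):
        if isinstance(node_data, dict):
            items = sorted(node_data.items())
        else:
            items = [(f"node{i}", df) for i, df in enumerate(node_data)]
        if not items:
            raise ProtocolError("a federated session needs at least one node")
        self.thresholds = thresholds or Thresholds()
        self.nodes = [Node(nid, df, self.thresholds) for nid, df in items]
        self.comm = CommLog()
        self.plan = None

    # -- transport ----------------------------------------------------------
    def request(self, node: Node, msg: dict) -> dict:
        payload = json.dumps(msg)
        reply = node.handle_json(payload)
        resp = json.loads(reply)
        self.comm.record(node.node_id, msg.get("kind", "?"),
                         _count_scalars(msg), _count_scalars(resp))
        return resp

    def request_all(self, msg: dict) -> list:
        return [self.request(node, msg) for node in self.nodes]

    # -- cluster interface consumed by the RS engine -------------------------
    def init_stats(self):
        parts = self.request_all({"kind": "init_stats"})
        return {"n": sum(p["n"] for p in parts),
                "sum_y": sum(p["sum_y"] for p in parts),
                "sum_y2": sum(p["sum_y2"] for p in parts)}

    def set_initial(self, coefs_all):
        wire = {k: _wire_coefs(c) for k, c in coefs_all.items()}
        self.request_all({"kind": "set_initial", "coefs": wire})

    def begin_inner(self, k):
        self.request_all({"kind": "begin_inner", "k": k})

    def term_stats(self, k, term, coefs_k) -> SuffStats:
        wire_term = "linear" if term == "linear" else ["smooth", term[1]]
        msg = {"kind": "term_stats", "k": k, "term": wire_term,
               "coefs": _wire_coefs(coefs_k)}
        stats = [SuffStats.from_wire(r) for r in self.request_all(msg)]
        return aggregate(stats)

    def max_delta(self, k, coefs_a, coefs_b) -> float:
        msg = {"kind": "delta_eta", "k": k, "coefs_a": _wire_coefs(coefs_a),
               "coefs_b": _wire_coefs(coefs_b)}
        return max(r["max_abs"] for r in self.request_all(msg))

    def loglik(self, trial=None) -> float:
        msg = {"kind": "loglik"}
        if trial is not None:
            msg["trial"] = {"k": trial["k"], "coefs": _wire_coefs(trial["coefs"])}
        return sum(r["loglik"] for r in self.request_all(msg))

    def accept(self, k, coefs_k):
        self.request_all({"kind": "accept", "k": k, "coefs": _wire_coefs(coefs_k)})


def _wire_coefs(c) -> dict:
    if isinstance(c["beta"], list):
        return c
    return {"beta": [float(v) for v in c["beta"]],
            "gamma": [[float(v) for v in g] for g in c["gamma"]]}


def aggregate(stats_list) -> SuffStats:
    """Elementwise sum of per-node sufficient statistics."""
    stats_list = list(stats_list)
    if not stats_list:
        raise ProtocolError("nothing to aggregate")
    total = stats_list[0]
    for s in stats_list[1:]:
        total = total + s
    return total


def node_suffstats(node, k, term, coefs_k) -> SuffStats:
    """One node's sufficient statistics for a term (test/audit entry point).

    Goes through the node's serialized endpoint, so the disclosure properties
    of the wire format apply.
    """
    if isinstance(node, Node):
        wire_term = "linear" if term == "linear" else ["smooth", term[1]]
        reply = node.handle_json(json.dumps(
            {"kind": "term_stats", "k": k, "term": wire_term,
             "coefs": _wire_coefs(coefs_k)}))
        return SuffStats.from_wire(json.loads(reply))
    return node.term_stats(k, term, coefs_k)


def broadcast_spec(session: FederatedSession, spec: ModelSpec,
                   knots: dict | None = None, granularity: float | None = None):
    """Harmonize schemas, fix session-wide knots, build designs, run guards.

    Returns the resolved plan. Knots for every smooth covariate are shared
    across nodes; unless supplied explicitly they span an anonymized range
    (outward-rounded per-node extremes) so no node's exact minimum or maximum
    is used.
    """
    schemas = {node.node_id: session.request(node, {"kind": "describe"})
               for node in session.nodes}
    merged = merge_schemas(schemas)
    if knots is None:
        knots = {}
        for cov in spec.covariates():
            meta = merged["columns"].get(cov)
            if meta is None or meta["kind"] != "numeric":
                continue
            smooth_covs = {sm.covariate for _, smooths in spec.parsed().values()
                           for sm in smooths}
            if cov not in smooth_covs:
                continue
            amin, amax = anonymized_range(
                meta["per_node_range"].values(), granularity=granularity,
                k_anonymity=session.thresholds.k_anonymity)
            # store the anonymized bounds; interval counts come from the term spec
            meta["min"], meta["max"] = amin, amax
        plan = resolve_plan(spec, merged)
    else:
        plan = resolve_plan(spec, merged, knots=knots)
    acks = session.request_all({"kind": "build", "plan": plan})
    failures = {node.node_id: r["violations"]
                for node, r in zip(session.nodes, acks) if not r.get("ok")}
    if failures:
        lines = "; ".join(f"node {nid!r}: {v}" for nid, v in failures.items())
        raise DisclosureError(f"disclosure guard blocked the fit: {lines}")
    _check_identifiable(plan, merged["n"])
    session.plan = plan
    return plan


def fit_federated(spec: ModelSpec, nodes, control: Control | None = None,
                  knots: dict | None = None, thresholds: Thresholds | None = None,
                  granularity: float | None = None) -> FittedModel:
    """Fit the model across nodes; estimates match ``fit_pooled`` on the union.

    ``nodes`` may be a :class:`FederatedSession`, a mapping of node id to
    DataFrame, or a list of DataFrames. Explicit ``knots`` (e.g. from
    :func:`fedgamlss.fit_core.pooled_knots`) reproduce a pooled fit exactly;
    otherwise knots span the anonymized range.
    """
    session = nodes if isinstance(nodes, FederatedSession) else \
        FederatedSession(nodes, thresholds=thresholds)
    control = control or spec.control
    plan = broadcast_spec(session, spec, knots=knots, granularity=granularity)
    res = rs_fit(session, plan, control)
    model = _result_to_model(plan, control, res,
                             comm_log=session.comm.to_records(), fitted=None)
    model._pen_trace = res.get("pen_trace")
    model._comm = session.comm
    return model
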