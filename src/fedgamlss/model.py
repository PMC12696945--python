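"""Model specification: per-parameter formulas, links and control settings.

A model is declared with one formula string per distribution parameter, e.g.::

    ModelSpec(
        family="BCPE",
        formulas={
            "mu":    "1 + age + pb(age)",
            "sigma": "1 + age + pb(age)",
            "nu":    "1 + age + pb(age)",
            "tau":   "1 + age + pb(age)",
        },
    )

Grammar: terms separated by ``+``; ``1`` is the intercept (always included),
a bare name is a linear term (numeric column, or factor expanded to
reference-coded dummies with the alphabetically first level as reference),
and ``pb(x, ...)`` is a P-spline smooth with optional keywords
``lambda=<float>`` (fixed), ``df=<float>`` (target effective df),
``n_intervals=<int>``, ``degree=<int>``, ``order=<int>``; without a lambda
policy keyword the smoothing parameter is estimated by local ML. As in the
reference GAMLSS software, ``pb(x)`` implies a linear ``x`` term in the
parametric part, which is added automatically when absent.

``resolve_plan`` turns a spec plus a (possibly merged, multi-node) data schema
into a plain serializable *plan* — concrete factor encodings and knot vectors —
that every node uses to build identical design matrices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._exceptions import HarmonizationError, SpecificationError
from .families import get_family
from .smoothers import default_knots, bspline_basis, difference_penalty

__all__ = ["Control", "SmoothTermSpec", "ModelSpec", "merge_schemas", "schema_of",
           "resolve_plan", "build_param_design", "plan_df"]

DEFAULT_N_INTERVALS = 20
DEFAULT_DEGREE = 3
DEFAULT_ORDER = 2


@dataclass
class Control:
    """Convergence tolerances and iteration caps for the RS algorithm."""

    outer_tol: float = 1e-3        # |change in global deviance| across an outer cycle
    inner_tol: float = 1e-3        # |change in global deviance| per inner step
    backfit_tol: float = 1e-6      # max |change in eta| per backfitting cycle
    max_outer: int = 50
    max_inner: int = 30
    max_backfit: int = 30
    max_halvings: int = 10
    lambda_init: float = 10.0
    lambda_rtol: float = 1e-3
    lambda_max_iter: int = 30
    cond_limit: float = 1e12

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise SpecificationError(f"unknown control option(s): {sorted(bad)}")
        return cls(**d)


@dataclass
class SmoothTermSpec:
    covariate: str
    n_intervals: int = DEFAULT_N_INTERVALS
    degree: int = DEFAULT_DEGREE
    order: int = DEFAULT_ORDER
    lam: object = "ml"          # "ml" | float | ("df", float)
    knots: object = None        # resolved later

    @property
    def q(self) -> int:
        return self.n_intervals + self.degree


_PB_RE = re.compile(r"^pb\((?P<args>.*)\)$")
_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")


def _parse_pb(expr: str) -> SmoothTermSpec:
    m = _PB_RE.match(expr)
    args = [a.strip() for a in m.group("args").split(",") if a.strip()]
    if not args or "=" in args[0]:
        raise SpecificationError(f"pb() needs a covariate name first: {expr!r}")
    spec = SmoothTermSpec(covariate=args[0])
    for a in args[1:]:
        if "=" not in a:
            raise SpecificationError(f"unexpected pb() argument {a!r} in {expr!r}")
        key, val = (s.strip() for s in a.split("=", 1))
        if key == "lambda":
            spec.lam = float(val)
        elif key == "df":
            spec.lam = ("df", float(val))
        elif key in ("n_intervals", "inter"):
            spec.n_intervals = int(val)
        elif key == "degree":
            spec.degree = int(val)
        elif key == "order":
            spec.order = int(val)
        else:
            raise SpecificationError(f"unknown pb() option {key!r} in {expr!r}")
    if spec.order >= spec.q:
        raise SpecificationError(f"penalty order >= basis dimension in {expr!r}")
    return spec


def parse_formula(formula: str):
    """Return (linear_names, smooths) from a formula string."""
    linear: list[str] = []
    smooths: list[SmoothTermSpec] = []
    for raw in str(formula).split("+"):
        term = raw.strip()
        if not term:
            raise SpecificationError(f"empty term in formula {formula!r}")
        if term == "1":
            continue
        if term.startswith("pb(") :
            smooths.append(_parse_pb(term))
        elif _NAME_RE.match(term):
            if term not in linear:
                linear.append(term)
        else:
            raise SpecificationError(f"cannot parse term {term!r} in formula {formula!r}")
    # pb(x) implies a linear x term (the smooth models the deviation from it)
    for sm in smooths:
        if sm.covariate not in linear:
            linear.append(sm.covariate)
    return linear, smooths


@dataclass
class ModelSpec:
    """Response family plus per-distribution-parameter formulas and links."""

    family: str
    formulas: dict
    links: dict | None = None
    control: Control = field(default_factory=Control)
    response: str | None = None   # inferred as the first non-covariate column if None

    def __post_init__(self):
        if isinstance(self.control, dict):
            self.control = Control.from_dict(self.control)
        fam = get_family(self.family, links=self.links)
        unknown = set(self.formulas) - set(fam.param_names)
        if unknown:
            raise SpecificationError(
                f"formulas given for {sorted(unknown)} but family {fam.name} "
                f"has parameters {list(fam.param_names)}"
            )

    def make_family(self):
        return get_family(self.family, links=self.links)

    def parsed(self):
        fam = self.make_family()
        out = {}
        for k in fam.param_names:
            formula = self.formulas.get(k, "1")
            out[k] = parse_formula(formula)
        return out

    def covariates(self):
        names = []
        for linear, smooths in self.parsed().values():
            for nm in linear:
                if nm not in names:
                    names.append(nm)
            for sm in smooths:
                if sm.covariate not in names:
                    names.append(sm.covariate)
        return names

    @classmethod
    def from_config(cls, cfg: dict) -> "ModelSpec":
        family = cfg["family"]
        if family is False:
            family = "NO"   # YAML 1.1 reads a bare NO as boolean false
        return cls(
            family=family,
            formulas=dict(cfg.get("formulas", {})),
            links=cfg.get("links"),
            control=Control.from_dict(cfg.get("control", {})),
            response=cfg.get("response"),
        )


# ---------------------------------------------------------------------------
# schemas (per-node metadata) and plan resolution
# ---------------------------------------------------------------------------

def schema_of(data: pd.DataFrame) -> dict:
    """Column metadata of one table: kind, level counts, numeric range."""
    cols = {}
    for name in data.columns:
        s = data[name]
        if pd.api.types.is_numeric_dtype(s):
            cols[name] = {"kind": "numeric", "min": float(s.min()), "max": float(s.max())}
        else:
            counts = s.astype(str).value_counts().to_dict()
            cols[name] = {"kind": "factor",
                          "levels": {str(k): int(v) for k, v in counts.items()}}
    return {"n": int(len(data)), "columns": cols}


def merge_schemas(schemas: dict) -> dict:
    """Merge per-node schemas; inconsistent column kinds are a harmonization error."""
    merged: dict = {"n": 0, "columns": {}, "per_node_n": {}}
    for node_id, sch in schemas.items():
        merged["n"] += sch["n"]
        merged["per_node_n"][node_id] = sch["n"]
        for name, meta in sch["columns"].items():
            if name not in merged["columns"]:
                merged["columns"][name] = {"kind": meta["kind"]}
                if meta["kind"] == "numeric":
                    merged["columns"][name].update(min=meta["min"], max=meta["max"],
                                                   per_node_range={})
                else:
                    merged["columns"][name]["levels"] = {}
            tgt = merged["columns"][name]
            if tgt["kind"] != meta["kind"]:
                raise HarmonizationError(
                    f"column {name!r} is {meta['kind']} on node {node_id!r} but "
                    f"{tgt['kind']} elsewhere"
                )
            if meta["kind"] == "numeric":
                tgt["min"] = min(tgt["min"], meta["min"])
                tgt["max"] = max(tgt["max"], meta["max"])
                tgt["per_node_range"][node_id] = (meta["min"], meta["max"], sch["n"])
            else:
                for lev, cnt in meta["levels"].items():
                    tgt["levels"][lev] = tgt["levels"].get(lev, 0) + cnt
    return merged


def resolve_plan(spec: ModelSpec, schema: dict, knots: dict | None = None) -> dict:
    """Compile a spec against a merged schema into a serializable build plan.

    ``knots`` optionally maps covariate name -> explicit knot vector; smooths
    without an entry get equally spaced knots over the schema's [min, max].
    """
    fam = spec.make_family()
    parsed = spec.parsed()
    response = spec.response
    if response is None:
        # convention: response is the single column not referenced as covariate
        used = set(spec.covariates())
        candidates = [c for c in schema["columns"] if c not in used]
        if len(candidates) != 1:
            raise SpecificationError(
                "cannot infer the response column; set ModelSpec.response "
                f"(unreferenced columns: {candidates})"
            )
        response = candidates[0]
    if response not in schema["columns"]:
        raise HarmonizationError(f"response column {response!r} not present in data")

    plan = {"family": fam.name, "links": dict(fam.link_names),
            "response": response, "params": {}}
    for k in fam.param_names:
        linear, smooths = parsed[k]
        lin_terms = [{"kind": "intercept"}]
        for name in linear:
            meta = schema["columns"].get(name)
            if meta is None:
                raise HarmonizationError(f"covariate {name!r} missing from data schema")
            if meta["kind"] == "numeric":
                lin_terms.append({"kind": "numeric", "name": name})
            else:
                levels = sorted(meta["levels"])
                if len(levels) < 2:
                    raise SpecificationError(
                        f"factor {name!r} has a single level {levels}"
                    )
                lin_terms.append({"kind": "factor", "name": name, "levels": levels})
        sm_plans = []
        for sm in smooths:
            meta = schema["columns"].get(sm.covariate)
            if meta is None:
                raise HarmonizationError(
                    f"smooth covariate {sm.covariate!r} missing from data schema"
                )
            if meta["kind"] != "numeric":
                raise SpecificationError(f"pb({sm.covariate}) needs a numeric covariate")
            if knots is not None and sm.covariate in knots:
                kv = np.asarray(knots[sm.covariate], dtype=float)
            else:
                kv = default_knots(meta["min"], meta["max"], sm.n_intervals, sm.degree)
            x_index = next(
                i for i, t in enumerate(lin_terms)
                if t["kind"] == "numeric" and t["name"] == sm.covariate
            )
            lam = sm.lam
            if isinstance(lam, tuple):
                lam = list(lam)
            sm_plans.append({
                "name": sm.covariate, "knots": [float(v) for v in kv],
                "degree": sm.degree, "order": sm.order, "lambda": lam,
                "x_linear_index": x_index,
            })
        plan["params"][k] = {"link": fam.link_names[k], "linear": lin_terms,
                             "smooths": sm_plans}
    return plan


def plan_df(plan: dict) -> int:
    """Total coefficient count of a plan (the model's nominal df)."""
    total = 0
    for p in plan["params"].values():
        for t in p["linear"]:
            total += len(t["levels"]) - 1 if t["kind"] == "factor" else 1
        for sm in p["smooths"]:
            total += len(sm["knots"]) - sm["degree"] - 1
    return total


def _linear_columns(data: pd.DataFrame, terms, where: str):
    cols = []
    names = []
    n = len(data)
    for t in terms:
        if t["kind"] == "intercept":
            cols.append(np.ones(n))
            names.append("(Intercept)")
        elif t["kind"] == "numeric":
            if t["name"] not in data.columns:
                raise HarmonizationError(f"column {t['name']!r} missing on {where}")
            cols.append(np.asarray(data[t["name"]], dtype=float))
            names.append(t["name"])
        else:
            if t["name"] not in data.columns:
                raise HarmonizationError(f"column {t['name']!r} missing on {where}")
            vals = data[t["name"]].astype(str).to_numpy()
            unknown = set(vals) - set(t["levels"])
            if unknown:
                raise HarmonizationError(
                    f"factor {t['name']!r} on {where} has level(s) {sorted(unknown)} "
                    f"not in the harmonized encoding {t['levels']}"
                )
            for lev in t["levels"][1:]:   # first (alphabetical) level = reference
                cols.append((vals == lev).astype(float))
                names.append(f"{t['name']}[{lev}]")
    return np.column_stack(cols), names


def build_param_design(data: pd.DataFrame, param_plan: dict, where: str = "data"):
    """Build (X, [Z_j], column_names) for one distribution parameter."""
    X, names = _linear_columns(data, param_plan["linear"], where)
    Zs = []
    for sm in param_plan["smooths"]:
        if sm["name"] not in data.columns:
            raise HarmonizationError(f"column {sm['name']!r} missing on {where}")
        x = np.asarray(data[sm["name"]], dtype=float)
        Zs.append(bspline_basis(x, sm["knots"], sm["degree"]))
    return X, Zs, names


def penalty_matrix(sm_plan: dict) -> np.ndarray:
    q = len(sm_plan["knots"]) - sm_plan["degree"] - 1
    return difference_penalty(q, sm_plan["order"])
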