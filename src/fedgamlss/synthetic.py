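"""Synthetic datasets with the statistical structure of the package's two
flagship use cases, so every component is testable without any data access.

``simulate_growth``
    Age/height data for centile-curve estimation. Ages are uniform on
    [2, 18] years rounded to one decimal (mimicking field-collected age), and
    height is drawn from the scenario's response distribution — normal
    (``growth_NO``), Box-Cox Cole-Green (``growth_BCCG``) or Box-Cox power
    exponential (``growth_BCPE``) — with smoothly age-varying parameters.
    The default truth curves give heights around 90 cm at age 2 rising,
    decelerating, to ~155 cm at 18 with a ~4% coefficient of variation and
    mild age-varying skewness: the shape of a pediatric growth reference.

``simulate_sbp``
    A heteroscedastic linear-regression analogue: systolic blood pressure
    (mmHg) regressed on sex and BMI with a country-specific residual standard
    deviation, one country per node. Default coefficients are
    mu = 80 - 0.7*female + 1.3*bmi and log(sigma) = 2.0 + 0.1*spain.

Every generator is deterministic under its seed and returns the generating
truth alongside the data, so recovery tests can compare estimates against
the exact data-generating process. What these generators deliberately do not
emulate: multi-wave sampling designs, within-person repeated measures, or
measurement error structure of a real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import SpecificationError
from .families import get_family

__all__ = ["SimConfig", "simulate_ages", "simulate_growth", "simulate_sbp",
           "growth_truth_theta", "write_node_csvs"]

SCENARIOS = ("growth_NO", "growth_BCCG", "growth_BCPE", "sbp_hetero")

# truth curves for the growth scenarios (age in years, height in cm)
_GROWTH_TRUTH = {
    # decelerating cubic median growth: ~90 cm at 2y, ~155 cm at 18y
    "mu_poly": [70.0, 11.0, -0.55, 0.011],
    # mild age trend in the coefficient of variation (BCCG/BCPE sigma)
    "log_sigma_cv": [np.log(0.04) - 0.01 * 10.0, 0.01],
    # absolute residual SD for the normal scenario (cm)
    "sigma_abs": [4.5, 0.25],
    "nu": [1.2, -0.04],      # mild, age-decreasing right skew
    "log_tau": [np.log(2.2), 0.0],
}

_SBP_TRUTH = {"beta10": 80.0, "beta11_female": -0.7, "beta12_bmi": 1.3,
              "beta20": 2.0, "beta21_spain": 0.1,
              "bmi_mean": 16.7, "bmi_sd": 2.7}


@dataclass
class SimConfig:
    """Scenario, per-node sample sizes, seed and (optional) truth overrides."""

    scenario: str
    n_per_node: list
    seed: int
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise SpecificationError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if isinstance(self.n_per_node, int):
            self.n_per_node = [self.n_per_node]
        if self.seed is None:
            raise SpecificationError("a seed is mandatory")


def simulate_ages(n: int, seed) -> np.ndarray:
    """Ages uniform on [2, 18] years, rounded to one decimal digit."""
    if n < 1:
        raise SpecificationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return np.round(rng.uniform(2.0, 18.0, n), 1)


def _polyval(coef, x):
    out = np.zeros_like(np.asarray(x, dtype=float))
    for p, c in enumerate(coef):
        out = out + c * np.asarray(x, dtype=float) ** p
    return out


def growth_truth_theta(scenario: str, age, truth: dict | None = None) -> dict:
    """The generating distribution parameters at the given ages."""
    t = dict(_GROWTH_TRUTH)
    if truth:
        t.update(truth)
    age = np.asarray(age, dtype=float)
    mu = _polyval(t["mu_poly"], age)
    if scenario == "growth_NO":
        sigma = _polyval(t["sigma_abs"], age)
        if np.any(sigma <= 0):
            raise SpecificationError("truth sigma must be positive everywhere")
        return {"mu": mu, "sigma": sigma}
    sigma = np.exp(_polyval(t["log_sigma_cv"], age))
    nu = _polyval(t["nu"], age)
    if scenario == "growth_BCCG":
        return {"mu": mu, "sigma": sigma, "nu": nu}
    tau = np.exp(_polyval(t["log_tau"], age))
    return {"mu": mu, "sigma": sigma, "nu": nu, "tau": tau}


def simulate_growth(config: SimConfig):
    """Per-node (age, height) tables plus the generating truth record."""
    if not config.scenario.startswith("growth_"):
        raise SpecificationError(f"not a growth scenario: {config.scenario!r}")
    fam = get_family(config.scenario.split("_", 1)[1])
    rng = np.random.default_rng(config.seed)
    tables = {}
    for i, n_d in enumerate(config.n_per_node):
        age = np.round(rng.uniform(2.0, 18.0, n_d), 1)
        theta = growth_truth_theta(config.scenario, age, config.truth)
        height = fam.ppf(rng.random(n_d), theta)
        tables[f"node{i}"] = pd.DataFrame({"age": age, "height": height})
    truth = dict(_GROWTH_TRUTH)
    truth.update(config.truth)
    truth = {k: (list(v) if isinstance(v, (list, tuple)) else v)
             for k, v in truth.items()}
    truth["scenario"] = config.scenario
    return tables, truth


def simulate_sbp(config: SimConfig):
    """Per-node (sbp, sex, bmi, country) tables; one country per node."""
    if config.scenario != "sbp_hetero":
        raise SpecificationError(f"not the sbp scenario: {config.scenario!r}")
    t = dict(_SBP_TRUTH)
    t.update(config.truth)
    rng = np.random.default_rng(config.seed)
    countries = ["Germany", "Spain"]
    tables = {}
    for i, n_d in enumerate(config.n_per_node):
        country = countries[i % len(countries)]
        sex = np.where(rng.random(n_d) < 0.5, "female", "male")
        bmi = np.clip(rng.normal(t["bmi_mean"], t["bmi_sd"], n_d), 11.0, None)
        mu = t["beta10"] + t["beta11_female"] * (sex == "female") + t["beta12_bmi"] * bmi
        sigma = np.exp(t["beta20"] + t["beta21_spain"] * (country == "Spain"))
        sbp = rng.normal(mu, sigma)
        tables[f"node{i}"] = pd.DataFrame(
            {"sbp": sbp, "sex": sex, "bmi": bmi,
             "country": np.repeat(country, n_d)})
    truth = dict(t)
    truth["scenario"] = config.scenario
    return tables, truth


def write_node_csvs(tables: dict, out_dir, prefix: str = "") -> list:
    """One CSV per node; returns the written paths (sorted by node id)."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for node_id in sorted(tables):
        p = out / f"{prefix}{node_id}.csv"
        tables[node_id].to_csv(p, index=False, float_format="%.12g")
        paths.append(p)
    return paths
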