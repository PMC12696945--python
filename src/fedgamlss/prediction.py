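"""Prediction, centile (percentile) curves and z-scores from a fitted model.

Centiles are covariate-indexed quantiles of the fitted conditional
distribution: the distribution parameters are predicted at each grid point
and the family's quantile function is applied. Because a quantile function is
strictly increasing in the probability, centile curves from one fitted model
can never cross. z-scores are the normal-deviate transform of the fitted
conditional CDF, z = Phi^-1(F_Y(y | theta(x))).

Prediction outside the knot-supported domain of any smooth raises
:class:`ExtrapolationError`: P-spline extrapolation is undefined and a silent
linear extension would produce confidently wrong curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from ._exceptions import ExtrapolationError, RangeError, SpecificationError
from .fit_core import FittedModel
from .model import build_param_design

__all__ = ["CentileTable", "predict_parameters", "centiles", "z_scores",
           "plot_centiles", "DEFAULT_PROBS"]

# the conventional growth-reference percentile set
DEFAULT_PROBS = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)


def _as_frame(new_covariates) -> pd.DataFrame:
    if isinstance(new_covariates, pd.DataFrame):
        return new_covariates.reset_index(drop=True)
    return pd.DataFrame({k: np.asarray(v) for k, v in dict(new_covariates).items()})


def predict_parameters(model: FittedModel, new_covariates) -> pd.DataFrame:
    """Distribution parameters theta at new covariate values.

    Predictors are assembled from the stored coefficients and re-evaluated
    bases; ``theta_k = g_k^{-1}(eta_k)``.
    """
    data = _as_frame(new_covariates)
    fam = model.make_family()
    out = {}
    for k, pparam in model.plan["params"].items():
        try:
            X, Zs, _ = build_param_design(data, pparam, where="prediction data")
        except RangeError as err:
            raise ExtrapolationError(
                f"prediction for parameter {k!r} outside the fitted knot "
                f"domain: {err}"
            ) from err
        c = model.coefficients[k]
        eta = X @ np.asarray(c["beta"], float)
        for Z, g in zip(Zs, c["gamma"]):
            eta = eta + Z @ np.asarray(g, float)
        out[k] = fam.clip_param(k, fam.links[k].inverse(eta))
    return pd.DataFrame(out)


@dataclass
class CentileTable:
    """Grid of covariate values with fitted theta and centile curves."""

    grid: pd.DataFrame
    theta: pd.DataFrame
    probs: tuple
    values: np.ndarray          # (n_grid, n_probs)

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.concat([self.grid.reset_index(drop=True),
                        self.theta.reset_index(drop=True)], axis=1)
        for i, p in enumerate(self.probs):
            df[f"P{100 * p:g}"] = self.values[:, i]
        return df

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.12g")


def centiles(model: FittedModel, new_covariates, probs=DEFAULT_PROBS) -> CentileTable:
    """Centile curves at the requested probabilities over a covariate grid."""
    probs = tuple(float(p) for p in probs)
    if any(b <= a for a, b in zip(probs, probs[1:])):
        raise SpecificationError("probs must be strictly increasing")
    grid = _as_frame(new_covariates)
    theta = predict_parameters(model, grid)
    fam = model.make_family()
    th = {k: theta[k].to_numpy() for k in theta.columns}
    vals = np.column_stack([fam.ppf(np.full(len(grid), p), th) for p in probs])
    return CentileTable(grid=grid, theta=theta, probs=probs, values=vals)


def z_scores(model: FittedModel, y, covariates) -> np.ndarray:
    """z = Phi^-1(F_Y(y | theta(x))): the fitted-distribution normal deviate."""
    data = _as_frame(covariates)
    theta = predict_parameters(model, data)
    fam = model.make_family()
    th = {k: theta[k].to_numpy() for k in theta.columns}
    u = fam.cdf(np.asarray(y, dtype=float), th)
    eps = 1e-15
    return special.ndtri(np.clip(u, eps, 1.0 - eps))


def plot_centiles(table: CentileTable, covariate: str | None = None, ax=None,
                  response_label: str = "response"):
    """Line chart of the centile curves over the grid (no data points are
    drawn: from a federated fit only grid curves leave the client)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if covariate is None:
        if table.grid.shape[1] != 1:
            raise SpecificationError("specify which covariate to plot")
        covariate = table.grid.columns[0]
    x = table.grid[covariate].to_numpy()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    for i, p in enumerate(table.probs):
        ax.plot(x, table.values[:, i], label=f"P{100 * p:g}",
                lw=2 if abs(p - 0.5) < 1e-9 else 1)
    ax.set_xlabel(covariate)
    ax.set_ylabel(response_label)
    ax.legend(fontsize=8)
    return ax
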