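"""Response-distribution families for distributional regression.

Three families are provided:

``NO``
    Normal distribution, parameterized by mean ``mu`` and standard deviation
    ``sigma``.
``BCCG``
    Box-Cox Cole-Green (the "LMS" family): a Box-Cox power transform of a
    positive response to approximate normality, with median-like location
    ``mu``, approximate coefficient of variation ``sigma`` and Box-Cox power
    ``nu`` controlling skewness.
``BCPE``
    Box-Cox power exponential: BCCG with an additional kurtosis parameter
    ``tau`` (power-exponential kernel). ``tau = 2`` recovers BCCG exactly, and
    both BCCG routines delegate to the shared power-exponential code path so
    the nesting holds to machine precision (densities, quantiles and samplers
    alike).

The Box-Cox transform is ``z = ((y/mu)**nu - 1) / (sigma*nu)`` for ``nu != 0``
and ``z = log(y/mu)/sigma`` for ``nu = 0``. The transformed variable follows a
standardized (zero-mean, unit-variance) power exponential distribution,
truncated to the region compatible with ``y > 0``; the truncation normalizer
``F_T(1/(sigma*|nu|))`` is included in the density, and quantiles invert the
full truncated CDF, so every family integrates to one over its support.

Scores are analytic first derivatives of the log-density with respect to the
*predictor* (link) scale. Iterative weights use minus the expected second
derivative where a closed form exists (NO both parameters; BCCG mu and sigma)
and squared-score quasi-Newton weights otherwise, floored at ``WEIGHT_FLOOR``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from ._exceptions import DomainError, NumericalStabilityError, SpecificationError
from .links import get_link

__all__ = [
    "Family",
    "ThetaState",
    "get_family",
    "log_density",
    "score_and_weight",
    "quantile",
    "cdf",
    "sample",
    "WEIGHT_FLOOR",
]

WEIGHT_FLOOR = 1e-10
# Domain floors preventing division blow-ups during transient extreme predictors.
PARAM_FLOORS = {"sigma": 1e-8, "tau": 1e-8, "mu_positive": 1e-8}
_NU_EPS = 1e-10  # |nu| below this is treated as the log-transform limit


# ---------------------------------------------------------------------------
# standardized power exponential helpers (zero mean, unit variance)
# ---------------------------------------------------------------------------

def _pe_log_c(tau):
    """log of the scale constant c with c^2 = 2^(-2/tau) Gamma(1/tau)/Gamma(3/tau)."""
    tau = np.asarray(tau, dtype=float)
    return 0.5 * (
        -(2.0 / tau) * np.log(2.0)
        + special.gammaln(1.0 / tau)
        - special.gammaln(3.0 / tau)
    )


def _pe_logpdf(t, tau, log_c):
    c = np.exp(log_c)
    return (
        np.log(tau)
        - log_c
        - (1.0 + 1.0 / tau) * np.log(2.0)
        - special.gammaln(1.0 / tau)
        - 0.5 * np.abs(t / c) ** tau
    )


def _pe_cdf(t, tau, log_c):
    c = np.exp(log_c)
    t = np.asarray(t, dtype=float)
    inner = special.gammainc(1.0 / tau, 0.5 * np.abs(t / c) ** tau)
    return 0.5 * (1.0 + np.sign(t) * inner)


def _pe_ppf(u, tau, log_c):
    c = np.exp(log_c)
    u = np.asarray(u, dtype=float)
    s = 2.0 * u - 1.0
    mag = c * (2.0 * special.gammaincinv(1.0 / tau, np.abs(s))) ** (1.0 / tau)
    return np.sign(s) * mag


# ---------------------------------------------------------------------------
# theta container
# ---------------------------------------------------------------------------

@dataclass
class ThetaState:
    """Per-parameter natural-scale (``theta``) and predictor-scale (``eta``) vectors.

    The invariant ``theta_k = g_k^{-1}(eta_k)`` (after domain clipping) is
    maintained by constructing instances through :meth:`from_eta` or
    :meth:`from_theta`.
    """

    family: "Family"
    eta: dict = field(default_factory=dict)
    theta: dict = field(default_factory=dict)

    @classmethod
    def from_eta(cls, family: "Family", eta: dict) -> "ThetaState":
        theta = {}
        for k in family.param_names:
            link = family.links[k]
            theta[k] = family.clip_param(k, link.inverse(np.asarray(eta[k], float)))
        return cls(family=family, eta={k: np.asarray(eta[k], float) for k in family.param_names}, theta=theta)

    @classmethod
    def from_theta(cls, family: "Family", **theta) -> "ThetaState":
        th = {}
        eta = {}
        for k in family.param_names:
            v = family.clip_param(k, np.asarray(theta[k], dtype=float))
            th[k] = v
            eta[k] = family.links[k].apply(v)
        return cls(family=family, eta=eta, theta=th)

    def replace_eta(self, k: str, eta_k) -> None:
        eta_k = np.asarray(eta_k, dtype=float)
        self.eta[k] = eta_k
        self.theta[k] = self.family.clip_param(k, self.family.links[k].inverse(eta_k))

    def broadcast_n(self, n: int) -> "ThetaState":
        """Return a state with every parameter vector broadcast to length n."""
        eta = {k: np.broadcast_to(np.asarray(v, float), (n,)).copy() for k, v in self.eta.items()}
        return ThetaState.from_eta(self.family, eta)


def _coerce_theta(family, theta):
    if isinstance(theta, ThetaState):
        theta = theta.theta
    out = {k: np.asarray(v, dtype=float) for k, v in theta.items()}
    missing = [k for k in family.param_names if k not in out]
    if missing:
        raise SpecificationError(f"theta is missing parameter(s) {missing} for {family.name}")
    return out


# ---------------------------------------------------------------------------
# family base class
# ---------------------------------------------------------------------------

class Family:
    name: str = ""
    param_names: tuple = ()
    default_links: dict = {}
    positive_support: bool = False

    def __init__(self, links: dict | None = None):
        chosen = dict(self.default_links)
        if links:
            for k, v in links.items():
                if k not in self.param_names:
                    raise SpecificationError(
                        f"family {self.name} has no parameter {k!r}"
                    )
                chosen[k] = v
        self.link_names = chosen
        self.links = {k: get_link(v) for k, v in chosen.items()}

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    # -- domain -------------------------------------------------------------
    def clip_param(self, k, value):
        value = np.asarray(value, dtype=float)
        if k in ("sigma", "tau"):
            return np.maximum(value, PARAM_FLOORS[k])
        if k == "mu" and self.positive_support:
            return np.maximum(value, PARAM_FLOORS["mu_positive"])
        return value

    def validate_y(self, y):
        y = np.asarray(y, dtype=float)
        if self.positive_support:
            bad = np.flatnonzero(~(y > 0.0))
            if bad.size:
                raise DomainError(
                    f"{self.name} requires y > 0; offending index {int(bad[0])} "
                    f"(value {y[bad[0]]!r})"
                )
        if not np.all(np.isfinite(y)):
            bad = int(np.flatnonzero(~np.isfinite(y))[0])
            raise DomainError(f"non-finite response at index {bad}")
        return y

    # -- interface ----------------------------------------------------------
    def log_density(self, y, theta) -> np.ndarray:
        raise NotImplementedError

    def score(self, k, y, theta) -> np.ndarray:
        """d log f / d theta_k (natural parameter scale)."""
        raise NotImplementedError

    def score_eta(self, k, y, theta) -> np.ndarray:
        th = _coerce_theta(self, theta)
        u = self.score(k, y, th)
        return u * self.links[k].dtheta_deta(th[k])

    def weight(self, k, y, theta, u_eta) -> np.ndarray:
        """Iterative weight on the predictor scale (quasi-Newton default)."""
        return np.maximum(u_eta * u_eta, WEIGHT_FLOOR)

    def score_and_weight(self, k, y, theta):
        y = self.validate_y(y)
        th = _coerce_theta(self, theta)
        u = self.score_eta(k, y, th)
        if not np.all(np.isfinite(u)):
            raise NumericalStabilityError(
                f"non-finite score for parameter {k!r} of family {self.name}"
            )
        w = self.weight(k, y, th, u)
        w = np.maximum(w, WEIGHT_FLOOR)
        if not np.all(np.isfinite(w)):
            raise NumericalStabilityError(
                f"non-finite weight for parameter {k!r} of family {self.name}"
            )
        return u, w

    def cdf(self, y, theta) -> np.ndarray:
        raise NotImplementedError

    def ppf(self, prob, theta) -> np.ndarray:
        raise NotImplementedError

    def rvs(self, theta, n_draws: int, seed) -> np.ndarray:
        """Inverse-CDF sampling; shared path across nested families."""
        rng = np.random.default_rng(seed)
        u = rng.random(n_draws)
        th = _coerce_theta(self, theta)
        th = {k: np.broadcast_to(v, (n_draws,)) if np.ndim(v) and np.size(v) == n_draws else v
              for k, v in th.items()}
        return np.asarray(self.ppf(u, th), dtype=float)

    def initial_eta(self, stats: dict) -> dict:
        """Intercept-scale starting values from aggregated response moments."""
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Normal
# ---------------------------------------------------------------------------

class NormalFamily(Family):
    name = "NO"
    param_names = ("mu", "sigma")
    default_links = {"mu": "identity", "sigma": "log"}
    positive_support = False

    def log_density(self, y, theta):
        y = self.validate_y(y)
        th = _coerce_theta(self, theta)
        mu, sigma = th["mu"], th["sigma"]
        z = (y - mu) / sigma
        return -0.5 * np.log(2.0 * np.pi) - np.log(sigma) - 0.5 * z * z

    def score(self, k, y, theta):
        th = _coerce_theta(self, theta)
        mu, sigma = th["mu"], th["sigma"]
        y = np.asarray(y, dtype=float)
        if k == "mu":
            return (y - mu) / sigma**2
        if k == "sigma":
            return ((y - mu) ** 2 - sigma**2) / sigma**3
        raise SpecificationError(f"NO has no parameter {k!r}")

    def weight(self, k, y, theta, u_eta):
        th = _coerce_theta(self, theta)
        n = np.broadcast_shapes(np.shape(y), np.shape(th["mu"]))
        if k == "mu":
            # identity link: expected information 1/sigma^2
            return np.broadcast_to(1.0 / th["sigma"] ** 2, n).copy()
        # log link: u_eta = z^2 - 1 with E[u^2] = 2
        return np.full(n, 2.0)

    def cdf(self, y, theta):
        th = _coerce_theta(self, theta)
        z = (np.asarray(y, float) - th["mu"]) / th["sigma"]
        return special.ndtr(z)

    def ppf(self, prob, theta):
        th = _coerce_theta(self, theta)
        prob = _check_prob(prob)
        return th["mu"] + th["sigma"] * special.ndtri(prob)

    def initial_eta(self, stats):
        ybar, s = _moments(stats)
        return {"mu": self.links["mu"].apply(ybar), "sigma": self.links["sigma"].apply(s)}


# ---------------------------------------------------------------------------
# Box-Cox power exponential (and Cole-Green as its tau = 2 section)
# ---------------------------------------------------------------------------

def _boxcox_z(y, mu, sigma, nu):
    """z and log(y/mu); stable near nu = 0 via expm1."""
    L = np.log(y / mu)
    small = np.abs(nu) < _NU_EPS
    nu_safe = np.where(small, 1.0, nu)
    z = np.where(small, L / sigma, np.expm1(nu_safe * L) / (sigma * nu_safe))
    return z, L


def _dz_dnu(z, L, sigma, nu):
    """d z / d nu, with the analytic nu -> 0 limit handled by series."""
    enuL = 1.0 + sigma * nu * z  # = (y/mu)^nu
    small = np.abs(nu * L) < 1e-4
    nu_safe = np.where(np.abs(nu) < _NU_EPS, 1.0, nu)
    exact = (L * enuL * nu - sigma * nu * z) / (sigma * nu_safe**2)
    series = L * L / (2.0 * sigma) + nu * L**3 / (3.0 * sigma)
    return np.where(small, series, exact)


class BCPEFamily(Family):
    name = "BCPE"
    param_names = ("mu", "sigma", "nu", "tau")
    default_links = {"mu": "identity", "sigma": "log", "nu": "identity", "tau": "log"}
    positive_support = True

    _TAU_FD_STEP = 1e-5  # relative step for the truncation-constant tau derivative

    # -- internals ----------------------------------------------------------
    def _parts(self, y, th):
        mu, sigma, nu, tau = th["mu"], th["sigma"], th["nu"], th["tau"]
        log_c = _pe_log_c(tau)
        z, L = _boxcox_z(y, mu, sigma, nu)
        return mu, sigma, nu, tau, log_c, z, L

    @staticmethod
    def _trunc_bound(sigma, nu):
        """b = 1/(sigma |nu|); inf when nu = 0 (no truncation)."""
        absnu = np.abs(nu)
        with np.errstate(divide="ignore"):
            return np.where(absnu < _NU_EPS, np.inf, 1.0 / (sigma * np.maximum(absnu, _NU_EPS)))

    def _log_trunc_const(self, sigma, nu, tau, log_c=None):
        if log_c is None:
            log_c = _pe_log_c(tau)
        b = self._trunc_bound(sigma, nu)
        C = np.where(np.isinf(b), 1.0, _pe_cdf(np.where(np.isinf(b), 1.0, b), tau, log_c))
        return np.log(C), b, C

    def log_density(self, y, theta):
        y = self.validate_y(y)
        th = _coerce_theta(self, theta)
        mu, sigma, nu, tau, log_c, z, L = self._parts(y, th)
        logC, _, _ = self._log_trunc_const(sigma, nu, tau, log_c)
        return (
            (nu - 1.0) * np.log(y)
            - nu * np.log(mu)
            - np.log(sigma)
            + _pe_logpdf(z, tau, log_c)
            - logC
        )

    def score(self, k, y, theta):
        y = np.asarray(y, dtype=float)
        th = _coerce_theta(self, theta)
        mu, sigma, nu, tau, log_c, z, L = self._parts(y, th)
        c = np.exp(log_c)
        # g = d log f_T / d z
        absz = np.abs(z)
        g = -(tau / (2.0 * c**tau)) * np.sign(z) * absz ** np.where(absz > 0, tau - 1.0, 1.0)
        g = np.where(absz > 0, g, 0.0)
        enuL = 1.0 + sigma * nu * z  # (y/mu)^nu

        if k == "mu":
            # truncation constant does not depend on mu
            return -nu / mu - g * enuL / (sigma * mu)

        logC, b, C = self._log_trunc_const(sigma, nu, tau, log_c)
        finite_b = np.isfinite(b)
        fb = np.where(finite_b, np.exp(_pe_logpdf(np.where(finite_b, b, 1.0), tau, log_c)), 0.0)
        hazard = np.where(finite_b, fb / C, 0.0)

        if k == "sigma":
            dlogC = np.where(finite_b, -hazard * b / sigma, 0.0)
            return -1.0 / sigma - g * z / sigma - dlogC
        if k == "nu":
            nu_safe = np.where(np.abs(nu) < _NU_EPS, 1.0, nu)
            dlogC = np.where(finite_b & (np.abs(nu) >= _NU_EPS), -hazard * b / nu_safe, 0.0)
            return L + g * _dz_dnu(z, L, sigma, nu) - dlogC
        if k == "tau":
            dlogc = (2.0 * np.log(2.0) - special.polygamma(0, 1.0 / tau)
                     + 3.0 * special.polygamma(0, 3.0 / tau)) / (2.0 * tau**2)
            A = np.where(absz > 0, (absz / c) ** tau, 0.0)
            log_ratio = np.where(absz > 0, np.log(np.where(absz > 0, absz, 1.0) / c), 0.0)
            dldt = (
                1.0 / tau
                + np.log(2.0) / tau**2
                + special.polygamma(0, 1.0 / tau) / tau**2
                - dlogc
                - 0.5 * A * (log_ratio - tau * dlogc)
            )
            # truncation-normalizer tau-derivative via central difference of the
            # analytic log-normalizer (incomplete gamma in tau); tiny in practice
            h = self._TAU_FD_STEP * tau
            lp, _, _ = self._log_trunc_const(sigma, nu, tau + h)
            lm, _, _ = self._log_trunc_const(sigma, nu, tau - h)
            dlogC = np.where(finite_b, (lp - lm) / (2.0 * h), 0.0)
            return dldt - dlogC
        raise SpecificationError(f"BCPE has no parameter {k!r}")

    def cdf(self, y, theta):
        y = self.validate_y(y)
        th = _coerce_theta(self, theta)
        mu, sigma, nu, tau, log_c, z, L = self._parts(y, th)
        _, b, C = self._log_trunc_const(sigma, nu, tau, log_c)
        Ft = _pe_cdf(z, tau, log_c)
        pos = nu > _NU_EPS
        neg = nu < -_NU_EPS
        out = Ft  # nu == 0 case
        out = np.where(pos, (Ft - (1.0 - C)) / C, out)
        out = np.where(neg, Ft / C, out)
        return np.clip(out, 0.0, 1.0)

    def ppf(self, prob, theta):
        prob = _check_prob(prob)
        th = _coerce_theta(self, theta)
        mu, sigma, nu, tau = th["mu"], th["sigma"], th["nu"], th["tau"]
        log_c = _pe_log_c(tau)
        _, b, C = self._log_trunc_const(sigma, nu, tau, log_c)
        pos = nu > _NU_EPS
        neg = nu < -_NU_EPS
        u = np.where(pos, 1.0 - C + prob * C, np.where(neg, prob * C, prob))
        z = _pe_ppf(u, tau, log_c)
        nu_safe = np.where(np.abs(nu) < _NU_EPS, 1.0, nu)
        core = np.maximum(1.0 + sigma * nu * z, 1e-300)
        y = np.where(
            np.abs(nu) < _NU_EPS,
            mu * np.exp(sigma * z),
            mu * core ** (1.0 / nu_safe),
        )
        return y

    def initial_eta(self, stats):
        ybar, s = _moments(stats)
        cv = float(np.clip(s / max(ybar, 1e-8), 1e-4, 0.5))
        return {
            "mu": self.links["mu"].apply(ybar),
            "sigma": self.links["sigma"].apply(cv),
            "nu": self.links["nu"].apply(1.0),
            "tau": self.links["tau"].apply(2.0),
        }


class BCCGFamily(BCPEFamily):
    """Box-Cox Cole-Green: the tau = 2 section of BCPE (normal kernel).

    Shares the full BCPE code path with tau pinned to 2, so densities,
    quantiles and samplers nest exactly; mu/sigma use closed-form expected
    information weights (truncation ignored, standard LMS practice).
    """

    name = "BCCG"
    param_names = ("mu", "sigma", "nu")
    default_links = {"mu": "identity", "sigma": "log", "nu": "identity"}
    positive_support = True

    @staticmethod
    def _with_tau(th):
        out = dict(th)
        shape = np.broadcast_shapes(*[np.shape(v) for v in th.values()]) or ()
        out["tau"] = np.broadcast_to(2.0, shape).copy() if shape else np.float64(2.0)
        return out

    def log_density(self, y, theta):
        return BCPEFamily.log_density(self, y, self._with_tau(_coerce_theta(self, theta)))

    def score(self, k, y, theta):
        return BCPEFamily.score(self, k, y, self._with_tau(_coerce_theta(self, theta)))

    def cdf(self, y, theta):
        return BCPEFamily.cdf(self, y, self._with_tau(_coerce_theta(self, theta)))

    def ppf(self, prob, theta):
        return BCPEFamily.ppf(self, prob, self._with_tau(_coerce_theta(self, theta)))

    def weight(self, k, y, theta, u_eta):
        th = _coerce_theta(self, theta)
        mu, sigma, nu = th["mu"], th["sigma"], th["nu"]
        shape = np.broadcast_shapes(np.shape(y), np.shape(mu))
        if k == "mu":
            return np.broadcast_to((1.0 + 2.0 * sigma**2 * nu**2) / (sigma**2 * mu**2), shape).copy()
        if k == "sigma":
            return np.full(shape, 2.0)
        return np.maximum(u_eta * u_eta, WEIGHT_FLOOR)

    def initial_eta(self, stats):
        ybar, s = _moments(stats)
        cv = float(np.clip(s / max(ybar, 1e-8), 1e-4, 0.5))
        return {
            "mu": self.links["mu"].apply(ybar),
            "sigma": self.links["sigma"].apply(cv),
            "nu": self.links["nu"].apply(1.0),
        }


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

_FAMILIES = {"NO": NormalFamily, "BCCG": BCCGFamily, "BCPE": BCPEFamily}


def get_family(name: str, links: dict | None = None) -> Family:
    """Look up a family by its name string ("NO", "BCCG", "BCPE")."""
    key = str(name).upper()
    if key not in _FAMILIES:
        raise SpecificationError(f"unknown family {name!r}; available: {sorted(_FAMILIES)}")
    return _FAMILIES[key](links=links)


def log_density(family: Family, y, theta) -> np.ndarray:
    """Per-observation log-density; the sum is the unpenalized log-likelihood."""
    return family.log_density(y, theta)


def score_and_weight(family: Family, k, y, theta):
    """Score d log f / d eta_k and iterative weight vector for parameter k."""
    if isinstance(k, int):
        k = family.param_names[k]
    return family.score_and_weight(k, y, theta)


def quantile(family: Family, prob, theta_row) -> np.ndarray:
    """Quantile of the response distribution at probability ``prob``."""
    return family.ppf(prob, theta_row)


def cdf(family: Family, y, theta) -> np.ndarray:
    return family.cdf(y, theta)


def sample(family: Family, theta_row, n_draws: int, seed) -> np.ndarray:
    """Reproducible inverse-CDF draws from the response distribution."""
    return family.rvs(theta_row, n_draws, seed)


def _check_prob(prob):
    prob = np.asarray(prob, dtype=float)
    if np.any(prob <= 0.0) or np.any(prob >= 1.0):
        raise SpecificationError("probabilities must lie strictly inside (0, 1)")
    return prob


def _moments(stats):
    n = float(stats["n"])
    ybar = stats["sum_y"] / n
    var = max((stats["sum_y2"] - n * ybar**2) / max(n - 1.0, 1.0), 1e-12)
    return ybar, float(np.sqrt(var))
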