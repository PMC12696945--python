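"""Monotone link functions mapping distribution parameters to predictor scale.

Each link provides ``apply`` (theta -> eta), ``inverse`` (eta -> theta) and
``dtheta_deta`` (the Jacobian d theta / d eta used to move scores from the
parameter scale to the predictor scale).
"""

from __future__ import annotations

import numpy as np

from ._exceptions import SpecificationError

# Bounds keeping exp() finite during transient extreme predictor values.
_ETA_EXP_MAX = 700.0


class IdentityLink:
    name = "identity"

    @staticmethod
    def apply(theta):
        return np.asarray(theta, dtype=float)

    @staticmethod
    def inverse(eta):
        return np.asarray(eta, dtype=float)

    @staticmethod
    def dtheta_deta(theta):
        return np.ones_like(np.asarray(theta, dtype=float))


class LogLink:
    name = "log"

    @staticmethod
    def apply(theta):
        return np.log(np.asarray(theta, dtype=float))

    @staticmethod
    def inverse(eta):
        return np.exp(np.clip(np.asarray(eta, dtype=float), -_ETA_EXP_MAX, _ETA_EXP_MAX))

    @staticmethod
    def dtheta_deta(theta):
        # d theta / d eta = theta for theta = exp(eta)
        return np.asarray(theta, dtype=float)


_LINKS = {"identity": IdentityLink(), "log": LogLink()}


def get_link(name: str):
    try:
        return _LINKS[name]
    except KeyError:
        raise SpecificationError(
            f"unknown link {name!r}; available: {sorted(_LINKS)}"
        ) from None
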