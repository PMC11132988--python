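"""Bijective maps between unconstrained and constrained parameter spaces.

Every phenotype parameter is modelled on the real line and pushed through a
monotone bijection before it enters a task likelihood:

* ``log``    — positive-only parameters (effect sizes, noise scales, rates);
* ``logit``  — unit-interval parameters (learning rate, lapse rate);
* ``identity`` — unbounded parameters (biases, regression weights).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Transform", "TRANSFORMS", "get_transform"]


class Transform:
    """A monotone bijection R -> constrained domain with derivative info."""

    def __init__(self, name: str):
        if name not in ("identity", "log", "logit"):
            raise ValueError(f"unknown transform {name!r}")
        self.name = name

    def constrain(self, u):
        u = np.asarray(u, dtype=float)
        if self.name == "identity":
            return u + 0.0
        if self.name == "log":
            return np.exp(u)
        # logit-parameterized: u is the log-odds, constrained value in (0,1)
        return 1.0 / (1.0 + np.exp(-u))

    def unconstrain(self, x):
        x = np.asarray(x, dtype=float)
        if self.name == "identity":
            return x + 0.0
        if self.name == "log":
            return np.log(x)
        return np.log(x) - np.log1p(-x)

    def dconstrain_du(self, u):
        """d constrained / d unconstrained, evaluated at unconstrained u."""
        u = np.asarray(u, dtype=float)
        if self.name == "identity":
            return np.ones_like(u)
        if self.name == "log":
            return np.exp(u)
        s = 1.0 / (1.0 + np.exp(-u))
        return s * (1.0 - s)


TRANSFORMS = {
    "identity": Transform("identity"),
    "log": Transform("log"),
    "logit": Transform("logit"),
}


def get_transform(name: str) -> Transform:
    return TRANSFORMS[name]
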