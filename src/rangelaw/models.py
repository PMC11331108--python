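"""The three canonical decay models and their survival probabilities.

Type I (linear): N_t = N0 - c*t — a constant number of taxa is lost per
step, so the per-step survival probability falls with age ("aging").
Type II (exponential): N_t = N0*exp(-lam*t) — a constant fraction is lost
per step; survival probability is independent of age (the law of constant
extinction, memoryless decay).
Type III (power): N_t = b*t**-k — survival probability rises with age
("rich get richer").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KINDS = ("linear", "exponential", "power")


@dataclass(frozen=True)
class DecayModel:
    """A decay model ``kind`` with its two shape parameters.

    params meaning by kind:
      linear      (c, N0):  N_t = N0 - c*t
      exponential (N0, lam): N_t = N0 * exp(-lam*t)
      power       (b, k):   N_t = b * t**-k
    """

    kind: str
    params: tuple[float, float]

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")

    def evaluate(self, x):
        x = np.asarray(x, dtype=float)
        p, q = self.params
        if self.kind == "linear":
            return q - p * x
        if self.kind == "exponential":
            return p * np.exp(-q * x)
        return p * np.power(x, -q)


def survival_probability(model: DecayModel, t: float) -> float:
    """Probability of persisting from step ``t`` to step ``t + 1``.

    Computed as N_{t+1}/N_t under the model.  For the exponential model the
    ratio is exp(-lam), independent of t; for the linear model it decreases
    with t; for the power model it increases with t.
    """
    if model.kind == "exponential":
        _, lam = model.params
        return float(np.exp(-lam))
    if model.kind == "linear":
        c, n0 = model.params
        n_t = n0 - c * t
        n_next = n0 - c * (t + 1)
        if n_t <= 0 or n_next <= 0:
            raise ValueError(f"population nonpositive at t={t}")
        return 1.0 - c / n_t
    # power
    _, k = model.params
    if t <= 0:
        raise ValueError("power-law survival probability undefined at t <= 0")
    return float(((t + 1) / t) ** (-k))
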