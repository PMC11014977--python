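"""Depth-1 theory-of-mind (1-ToM) learners.

A level-0 learner is a Gaussian-approximate Bayesian filter on the log-odds
of the opponent's next choice: the log-odds x has a Gaussian belief
(mu, var) that diffuses by a volatility ``vol`` each trial and is updated by
a Laplace (Newton) step on the Bernoulli-logit likelihood.  Its predictive
choice probability moderates the mean by the posterior spread (probit-style
correction).

A level-1 learner simulates the AA as a level-0 observer of the
participant's own choices.  The simulated AA best-responds (softly) under a
hard-coded payoff tag: a cooperative AA is rewarded on a match and so moves
toward the participant's predicted card, a competitive AA is rewarded on a
mismatch and moves away from it.
"""

from __future__ import annotations

import math

from .base import Model, ParamDef, sigmoid, softmax2

#: variance moderation of the predictive probability, sigma(mu / sqrt(1 + a*var))
_MODERATION = math.pi / 8.0
#: softmax sharpness of the simulated opponent's best response
OPPONENT_BETA = 3.0


class Tom0Tracker:
    """Volatile Gaussian-approximate log-odds tracker of a binary sequence."""

    __slots__ = ("mu", "var", "vol")

    def __init__(self, vol: float, mu: float = 0.0, var: float = 1.0):
        if vol < 0:
            raise ValueError("volatility must be >= 0")
        self.mu = float(mu)
        self.var = float(var)
        self.vol = float(vol)

    def predict(self) -> float:
        """Posterior-predictive probability of observing a 1."""
        return sigmoid(self.mu / math.sqrt(1.0 + _MODERATION * self.var))

    def update(self, obs: int) -> None:
        """Laplace update after observing ``obs`` in {0, 1}."""
        prior_var = self.var + self.vol
        prior_prec = 1.0 / prior_var
        mu = self.mu
        x = mu
        # Newton iterations to the posterior mode of N(mu, prior_var) x Bern-logit
        for _ in range(3):
            p = sigmoid(x)
            grad = (obs - p) - prior_prec * (x - mu)
            hess = -p * (1.0 - p) - prior_prec
            x -= grad / hess
        p = sigmoid(x)
        self.mu = x
        self.var = 1.0 / (prior_prec + p * (1.0 - p))


class OneToMExpert:
    """Level-1 mentalizer over the AA, with a fixed payoff tag.

    ``tag`` is "COOP" (opponent rewarded on match) or "COMP" (on mismatch).
    Action values follow the participant's own match payoff, V1 = P(AA=1).
    """

    __slots__ = ("tag", "self_model")

    def __init__(self, tag: str, vol: float):
        if tag not in ("COOP", "COMP"):
            raise ValueError("payoff tag must be COOP or COMP")
        self.tag = tag
        self.self_model = Tom0Tracker(vol)

    def predict_opponent(self) -> float:
        """Probability that the AA plays card 1."""
        q = self.self_model.predict()  # AA's level-0 estimate of me playing 1
        drive = 2.0 * q - 1.0
        if self.tag == "COMP":
            drive = -drive
        return sigmoid(OPPONENT_BETA * drive)

    def values(self) -> tuple[float, float]:
        p = self.predict_opponent()
        return (1.0 - p, p)

    def update(self, a_self: int, a_aa: int, outcome: int | None = None) -> None:
        # the simulated AA observes the participant's action
        self.self_model.update(a_self)


class SingleToMModel(Model):
    """1-ToM with a single payoff prior (cooperative or competitive)."""

    param_defs = (
        ParamDef("vol", "log"),
        ParamDef("beta", "log"),
    )

    def __init__(self, tag: str):
        self.tag = tag
        self.name = "TOM1_COOP" if tag == "COOP" else "TOM1_COMP"

    def start(self, params: dict):
        return {
            "expert": OneToMExpert(self.tag, params["vol"]),
            "beta": float(params["beta"]),
        }

    def act(self, state) -> float:
        v0, v1 = state["expert"].values()
        return softmax2(v0, v1, state["beta"])

    def update(self, state, a_self, a_aa, outcome) -> None:
        state["expert"].update(a_self, a_aa, outcome)
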