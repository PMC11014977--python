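"""Bayesian Sequence Learner (BSL).

Tracks the probability that the AA selects card 1 after each specific
history of its own last ``k`` choices, with an independent conjugate
Beta(1, 1) prior per history context.  The posterior-mean prediction for a
context with counts (n1, n0) is ``(n1 + 1) / (n1 + n0 + 2)``; an unseen
context therefore predicts 0.5, and a history shorter than ``k`` falls back
to the marginal choice frequency (same smoothing).
"""

from __future__ import annotations

from .base import Model, ParamDef, softmax2


def bsl_predict(counts: dict, history: tuple, k: int, marginal=(0, 0)) -> float:
    """Posterior-mean probability that the AA picks card 1 next."""
    if len(history) >= k:
        ctx = tuple(history[-k:])
        n0, n1 = counts.get(ctx, (0, 0))
    else:
        n0, n1 = marginal
    return (n1 + 1.0) / (n0 + n1 + 2.0)


class BayesianSequenceLearner(Model):
    def __init__(self, k: int):
        if k not in (2, 3):
            raise ValueError("sequence depth k must be 2 or 3")
        self.k = k
        self.name = f"BSL{k}"

    param_defs = (ParamDef("beta", "log"),)

    def start(self, params: dict):
        return {
            "beta": float(params["beta"]),
            "counts": {},
            "hist": [],
            "marg": [0, 0],
        }

    def _predict(self, state) -> float:
        return bsl_predict(
            state["counts"], tuple(state["hist"]), self.k, tuple(state["marg"])
        )

    def act(self, state) -> float:
        p = self._predict(state)
        # match payoff: value of card c is the probability the AA plays c
        return softmax2(1.0 - p, p, state["beta"])

    def update(self, state, a_self, a_aa, outcome) -> None:
        hist = state["hist"]
        if len(hist) >= self.k:
            ctx = tuple(hist[-self.k:])
            n0, n1 = state["counts"].get(ctx, (0, 0))
            state["counts"][ctx] = (n0 + (a_aa == 0), n1 + (a_aa == 1))
        state["marg"][a_aa] += 1
        hist.append(a_aa)
        if len(hist) > self.k:
            hist.pop(0)
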