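"""Plain reinforcement learning (delta-rule Q-learning) over the two cards.

Only the chosen card's value is updated; the unchosen value is left
untouched, which is the defining contrast with the influence-expert models
where both options' values move every trial.
"""

from __future__ import annotations

from .base import Model, ParamDef, softmax2


class QLearning(Model):
    name = "RL"
    param_defs = (
        ParamDef("alpha", "logit"),
        ParamDef("beta", "log"),
    )

    #: initial action values (uninformative for a 0/1 payoff)
    q_init = 0.5

    def start(self, params: dict):
        return {
            "alpha": float(params["alpha"]),
            "beta": float(params["beta"]),
            "Q": [self.q_init, self.q_init],
        }

    def act(self, state) -> float:
        q = state["Q"]
        return softmax2(q[0], q[1], state["beta"])

    def update(self, state, a_self, a_aa, outcome) -> None:
        q = state["Q"]
        q[a_self] += state["alpha"] * (outcome - q[a_self])
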