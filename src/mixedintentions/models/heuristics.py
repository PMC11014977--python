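"""Heuristic baseline models: Random Bias and Win-Stay / Lose-Switch."""

from __future__ import annotations

from .base import Model, ParamDef


class RandomBias(Model):
    """Constant choice bias: picks card 1 with a fixed probability ``b``."""

    name = "RB"
    param_defs = (ParamDef("b", "logit"),)

    def start(self, params: dict):
        return {"b": float(params["b"])}

    def act(self, state) -> float:
        return state["b"]

    def update(self, state, a_self, a_aa, outcome) -> None:
        pass


class WinStayLoseSwitch(Model):
    """Win-stay / lose-switch with lapse rate ``epsilon``.

    After a win the previous card is repeated with probability
    ``1 - epsilon``; after a loss with probability ``epsilon``.  The first
    trial is random.  ``epsilon = 0.5`` is behaviorally identical to
    ``RandomBias(b=0.5)``.
    """

    name = "WSLS"
    param_defs = (ParamDef("epsilon", "logit"),)

    def start(self, params: dict):
        return {"eps": float(params["epsilon"]), "prev": None, "won": None}

    def act(self, state) -> float:
        if state["prev"] is None:
            return 0.5
        p_stay = 1.0 - state["eps"] if state["won"] else state["eps"]
        return p_stay if state["prev"] == 1 else 1.0 - p_stay

    def update(self, state, a_self, a_aa, outcome) -> None:
        state["prev"] = a_self
        state["won"] = outcome
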