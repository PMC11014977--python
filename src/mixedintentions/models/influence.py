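"""Influence-learning experts: reinforcement learning plus second-order mentalizing.

Each expert tracks ``p_opp``, its estimate of the probability that the AA
plays card 1, with a delta rule (rate ``eta``) *plus* an influence term: the
expert also tracks ``q_self``, the AA's presumed estimate of the
participant's own choice probability (rate ``eta_self``), and assumes its own
action shifts the AA's next move by ``kappa`` times its own belief prediction
error.  The cooperative expert (sign +1) expects the AA to move *toward* the
participant's action, the competitive expert (sign -1) *away* from it; the
sign of this second-order term is the only difference between the two.

With a match payoff of R = 1 (win) / 0 (loss), the action values are simply
``V1 = p_opp`` and ``V0 = 1 - p_opp``.
"""

from __future__ import annotations

from .base import Model, ParamDef, softmax2

#: payoff for a matching trial (losses pay 0)
R_WIN = 1.0


class InfluenceExpert:
    """One influence learner with a fixed mentalizing sign (+1 coop, -1 comp)."""

    __slots__ = ("sign", "eta", "kappa", "eta_self", "p_opp", "q_self")

    def __init__(self, sign: int, eta: float, kappa: float, eta_self: float):
        if sign not in (+1, -1):
            raise ValueError("sign must be +1 (cooperative) or -1 (competitive)")
        self.sign = sign
        self.eta = float(eta)
        self.kappa = float(kappa)
        self.eta_self = float(eta_self)
        self.p_opp = 0.5
        self.q_self = 0.5

    def values(self) -> tuple[float, float]:
        """(V0, V1) action values under the match payoff R_WIN."""
        return ((1.0 - self.p_opp) * R_WIN, self.p_opp * R_WIN)

    def update(self, a_self: int, a_aa: int, outcome: int | None = None) -> None:
        p = self.p_opp
        p += self.eta * ((1.0 if a_aa == 1 else 0.0) - p)
        p += self.sign * self.kappa * ((1.0 if a_self == 1 else 0.0) - self.q_self)
        self.p_opp = min(max(p, 0.0), 1.0)
        self.q_self += self.eta_self * ((1.0 if a_self == 1 else 0.0) - self.q_self)


def expert_values(p_opp: float, reward: float = R_WIN) -> tuple[float, float]:
    """Functional form of the expert's action values for a given payoff."""
    return ((1.0 - p_opp) * reward, p_opp * reward)


class SingleInfluenceModel(Model):
    """One influence expert driving choice directly through the softmax.

    ``sign=+1`` is the cooperative influence model, ``sign=-1`` the
    competitive one.  The self-model learning rate is tied to ``eta``.
    """

    param_defs = (
        ParamDef("eta", "logit"),
        ParamDef("kappa", "log"),
        ParamDef("beta", "log"),
    )

    def __init__(self, sign: int):
        self.sign = sign
        self.name = "INF_COOP" if sign == +1 else "INF_COMP"

    def start(self, params: dict):
        expert = InfluenceExpert(
            self.sign,
            params["eta"],
            params["kappa"],
            params.get("eta_self", params["eta"]),
        )
        return {"expert": expert, "beta": float(params["beta"])}

    def act(self, state) -> float:
        v0, v1 = state["expert"].values()
        return softmax2(v0, v1, state["beta"])

    def update(self, state, a_self, a_aa, outcome) -> None:
        state["expert"].update(a_self, a_aa, outcome)
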