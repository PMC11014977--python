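"""Mixed-intentions controller: reliability-based arbitration between experts.

Two experts — one assuming the other player cooperates, one assuming it
competes — learn in parallel.  Each expert's *reliability* is the unsigned
difference between its two action values (a decisive expert has high
reliability).  A controller turns the reliability difference

    Delta = rel_coop - rel_comp

into the arbitration weight ``omega = sigmoid(slope * (Delta - delta_bias))``,
interpreted as the probability that the other is cooperating; ``delta_bias``
(the competitive bias, delta) captures an individual's tendency to attribute
competitive (delta > 0) or cooperative (delta < 0) intentions.  The combined
decision value is the omega-weighted mixture of the experts' values, choice
follows a softmax on the decision-value difference, and the reward
prediction error is the outcome minus the combined value of the chosen card.

A trial is classified COOPERATIVE when ``Delta - delta_bias > 0`` and
COMPETITIVE otherwise (ties competitive); a ``Delta``-only variant is
available behind ``use_bias_in_classification``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..task import SessionData
from .base import Model, ParamDef, sigmoid, softmax2, _P_FLOOR
from .influence import InfluenceExpert
from .tom import OneToMExpert

COOPERATIVE = "COOPERATIVE"
COMPETITIVE = "COMPETITIVE"


def reliability(v0: float, v1: float) -> float:
    """Unsigned value difference: how decisive an expert's prediction is."""
    return abs(v0 - v1)


def arbitrate(rel_coop: float, rel_comp: float, slope: float, delta_bias: float) -> float:
    """Probability that the other is cooperating, from the reliability gap."""
    return sigmoid(slope * ((rel_coop - rel_comp) - delta_bias))


def combine_values(
    v_coop: tuple[float, float], v_comp: tuple[float, float], omega: float
) -> tuple[float, float]:
    return (
        omega * v_coop[0] + (1.0 - omega) * v_comp[0],
        omega * v_coop[1] + (1.0 - omega) * v_comp[1],
    )


def combine_and_choose(
    v_coop: tuple[float, float],
    v_comp: tuple[float, float],
    omega: float,
    beta: float,
) -> tuple[float, float, float]:
    """(DV0, DV1, p_choice1) from the omega-weighted mixture of expert values."""
    dv0, dv1 = combine_values(v_coop, v_comp, omega)
    return dv0, dv1, softmax2(dv0, dv1, beta)


def model_pe(dv_chosen: float, reward: float) -> float:
    """Reward prediction error of the combined valuation."""
    return reward - dv_chosen


def classify_trial(delta: float, delta_bias: float, use_bias: bool = True) -> str:
    """COOPERATIVE iff the bias-adjusted reliability difference is positive."""
    margin = delta - delta_bias if use_bias else delta
    return COOPERATIVE if margin > 0 else COMPETITIVE


@dataclass
class ControllerTrace:
    """Per-trial latent variables of the controller over one session."""

    delta: np.ndarray  # rel_coop - rel_comp at choice time
    rel_coop: np.ndarray
    rel_comp: np.ndarray
    omega: np.ndarray
    classification: np.ndarray  # COOPERATIVE / COMPETITIVE strings
    dv0: np.ndarray
    dv1: np.ndarray
    dv_chosen: np.ndarray
    dv_stay: np.ndarray  # DV of repeating the previous card (nan on trial 1)
    p_choice1: np.ndarray
    rpe: np.ndarray
    trial_loglik: np.ndarray

    @property
    def loglik(self) -> float:
        return float(self.trial_loglik.sum())

    def __len__(self) -> int:
        return len(self.delta)


class MixtureModel(Model):
    """Generic two-expert mixture: arbitration controller over any expert pair.

    ``expert_factory(params) -> (coop_expert, comp_expert)`` builds experts
    exposing ``values() -> (V0, V1)`` and ``update(a_self, a_aa, outcome)``.
    """

    def __init__(
        self,
        name: str,
        expert_factory,
        expert_param_defs: tuple[ParamDef, ...],
        use_bias_in_classification: bool = True,
    ):
        self.name = name
        self._factory = expert_factory
        self.param_defs = expert_param_defs + (
            ParamDef("beta", "log"),
            ParamDef("slope", "log"),
            ParamDef("delta_bias", "id", 0.0, 1.0),
        )
        self.use_bias_in_classification = use_bias_in_classification

    def start(self, params: dict):
        coop, comp = self._factory(params)
        return {
            "coop": coop,
            "comp": comp,
            "beta": float(params["beta"]),
            "slope": float(params["slope"]),
            "delta_bias": float(params["delta_bias"]),
        }

    # fast scalar path used by act()/update() during simulation and fitting
    def _step_values(self, state):
        vc = state["coop"].values()
        vk = state["comp"].values()
        omega = arbitrate(
            reliability(*vc), reliability(*vk), state["slope"], state["delta_bias"]
        )
        return vc, vk, omega

    def act(self, state) -> float:
        vc, vk, omega = self._step_values(state)
        _, _, p1 = combine_and_choose(vc, vk, omega, state["beta"])
        return p1

    def update(self, state, a_self, a_aa, outcome) -> None:
        state["coop"].update(a_self, a_aa, outcome)
        state["comp"].update(a_self, a_aa, outcome)

    # -- full trace -------------------------------------------------------

    def run(self, params: dict, session: SessionData) -> ControllerTrace:
        """Replay a session, returning every controller latent per trial."""
        choices, aa_choices, outcomes = session.columns()
        n = len(choices)
        state = self.start(params)
        delta = np.empty(n)
        rel_c = np.empty(n)
        rel_k = np.empty(n)
        omega_arr = np.empty(n)
        cls = np.empty(n, dtype=object)
        dv0_arr = np.empty(n)
        dv1_arr = np.empty(n)
        dv_ch = np.empty(n)
        dv_stay = np.full(n, np.nan)
        p1_arr = np.empty(n)
        rpe = np.empty(n)
        tll = np.empty(n)
        prev_choice = None
        for t in range(n):
            vc, vk, omega = self._step_values(state)
            rc, rk = reliability(*vc), reliability(*vk)
            d = rc - rk
            dv0, dv1, p1 = combine_and_choose(vc, vk, omega, state["beta"])
            a = choices[t]
            dv_a = dv1 if a == 1 else dv0
            p = p1 if a == 1 else 1.0 - p1
            p = min(max(p, _P_FLOOR), 1.0 - _P_FLOOR)
            delta[t] = d
            rel_c[t] = rc
            rel_k[t] = rk
            omega_arr[t] = omega
            cls[t] = classify_trial(
                d, state["delta_bias"], self.use_bias_in_classification
            )
            dv0_arr[t] = dv0
            dv1_arr[t] = dv1
            dv_ch[t] = dv_a
            if prev_choice is not None:
                dv_stay[t] = dv1 if prev_choice == 1 else dv0
            p1_arr[t] = p1
            rpe[t] = model_pe(dv_a, outcomes[t])
            tll[t] = math.log(p)
            self.update(state, a, aa_choices[t], outcomes[t])
            prev_choice = a
        return ControllerTrace(
            delta=delta,
            rel_coop=rel_c,
            rel_comp=rel_k,
            omega=omega_arr,
            classification=cls,
            dv0=dv0_arr,
            dv1=dv1_arr,
            dv_chosen=dv_ch,
            dv_stay=dv_stay,
            p_choice1=p1_arr,
            rpe=rpe,
            trial_loglik=tll,
        )


def _influence_pair(params: dict):
    eta_self = params.get("eta_self", params["eta"])
    return (
        InfluenceExpert(+1, params["eta"], params["kappa"], eta_self),
        InfluenceExpert(-1, params["eta"], params["kappa"], eta_self),
    )


def _tom_pair(params: dict):
    return (OneToMExpert("COOP", params["vol"]), OneToMExpert("COMP", params["vol"]))


def make_mixed_influence(use_bias_in_classification: bool = True) -> MixtureModel:
    """The mixed-intentions influence model (two influence experts)."""
    return MixtureModel(
        "INF_MIXED",
        _influence_pair,
        (ParamDef("eta", "logit"), ParamDef("kappa", "log")),
        use_bias_in_classification,
    )


def make_mixed_tom(use_bias_in_classification: bool = True) -> MixtureModel:
    """The 1-ToM two-expert mixture."""
    return MixtureModel(
        "TOM1_MIXED",
        _tom_pair,
        (ParamDef("vol", "log"),),
        use_bias_in_classification,
    )
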