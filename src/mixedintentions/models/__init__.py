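"""Model zoo: every candidate learner addressable by name.

The comparison set spans heuristics (RB, WSLS), plain reinforcement learning
(RL), Bayesian sequence learners at depths 2 and 3 (BSL2, BSL3), single
influence experts (INF_COOP, INF_COMP), the mixed-intentions influence model
(INF_MIXED), depth-1 theory-of-mind learners (TOM1_COOP, TOM1_COMP), and the
two-expert 1-ToM mixture (TOM1_MIXED).
"""

from __future__ import annotations

from .base import Model, ParamDef, sigmoid, softmax2
from .bsl import BayesianSequenceLearner, bsl_predict
from .heuristics import RandomBias, WinStayLoseSwitch
from .influence import InfluenceExpert, SingleInfluenceModel, expert_values
from .mixture import (
    COMPETITIVE,
    COOPERATIVE,
    ControllerTrace,
    MixtureModel,
    arbitrate,
    classify_trial,
    combine_and_choose,
    combine_values,
    make_mixed_influence,
    make_mixed_tom,
    model_pe,
    reliability,
)
from .rl import QLearning
from .tom import OneToMExpert, SingleToMModel, Tom0Tracker

_FACTORIES = {
    "RB": RandomBias,
    "WSLS": WinStayLoseSwitch,
    "RL": QLearning,
    "BSL2": lambda: BayesianSequenceLearner(2),
    "BSL3": lambda: BayesianSequenceLearner(3),
    "INF_COOP": lambda: SingleInfluenceModel(+1),
    "INF_COMP": lambda: SingleInfluenceModel(-1),
    "INF_MIXED": make_mixed_influence,
    "TOM1_COOP": lambda: SingleToMModel("COOP"),
    "TOM1_COMP": lambda: SingleToMModel("COMP"),
    "TOM1_MIXED": make_mixed_tom,
}

MODEL_NAMES = tuple(_FACTORIES)


def get_model(name: str) -> Model:
    """Instantiate a model from the registry by its exact name."""
    try:
        return _FACTORIES[name]()
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {', '.join(MODEL_NAMES)}"
        ) from None


__all__ = [
    "Model",
    "ParamDef",
    "sigmoid",
    "softmax2",
    "RandomBias",
    "WinStayLoseSwitch",
    "QLearning",
    "BayesianSequenceLearner",
    "bsl_predict",
    "InfluenceExpert",
    "SingleInfluenceModel",
    "expert_values",
    "OneToMExpert",
    "SingleToMModel",
    "Tom0Tracker",
    "MixtureModel",
    "ControllerTrace",
    "make_mixed_influence",
    "make_mixed_tom",
    "reliability",
    "arbitrate",
    "combine_values",
    "combine_and_choose",
    "model_pe",
    "classify_trial",
    "COOPERATIVE",
    "COMPETITIVE",
    "MODEL_NAMES",
    "get_model",
]
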