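"""Common agent interface shared by every learning model.

A model is a stateless *specification*; per-session mutable state is created
by :meth:`Model.start` and threaded through :meth:`act` / :meth:`update`.
All value-based models emit choices through the same two-option softmax so
that model comparison is not confounded by the choice rule.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from typing import Any, NamedTuple

from ..task import SessionData

_P_FLOOR = 1e-9  # machine-safe floor for per-trial choice probabilities


class ParamDef(NamedTuple):
    """One free parameter: its natural-scale meaning and unconstrained prior."""

    name: str
    transform: str  # 'logit' -> (0,1), 'log' -> (0,inf), 'id' -> R
    prior_mean: float = 0.0
    prior_sd: float = 3.0


def sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def softmax2(v0: float, v1: float, beta: float) -> float:
    """P(choose option 1) under a two-option softmax with inverse temperature."""
    return sigmoid(beta * (v1 - v0))


class Model(ABC):
    """Abstract learning agent with an act/update/likelihood interface."""

    name: str = ""
    param_defs: tuple[ParamDef, ...] = ()

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.param_defs)

    @abstractmethod
    def start(self, params: dict) -> Any:
        """Create fresh per-session state from natural-scale parameters."""

    @abstractmethod
    def act(self, state: Any) -> float:
        """Probability of choosing card 1 on the current trial."""

    @abstractmethod
    def update(self, state: Any, a_self: int, a_aa: int, outcome: int) -> None:
        """Learn from one completed trial (mutates ``state``)."""

    # -- likelihood -------------------------------------------------------

    def trial_likelihoods(self, params: dict, session: SessionData) -> list[float]:
        """Per-trial probability assigned to the participant's actual choice."""
        choices, aa_choices, outcomes = session.columns()
        state = self.start(params)
        out = []
        for t in range(len(choices)):
            p1 = self.act(state)
            a = choices[t]
            p = p1 if a == 1 else 1.0 - p1
            out.append(min(max(p, _P_FLOOR), 1.0 - _P_FLOOR))
            self.update(state, a, aa_choices[t], outcomes[t])
        return out

    def loglik(self, params: dict, session: SessionData) -> float:
        """Session log-likelihood of the participant's choices."""
        choices, aa_choices, outcomes = session.columns()
        state = self.start(params)
        ll = 0.0
        log = math.log
        act = self.act
        update = self.update
        for t in range(len(choices)):
            p1 = act(state)
            a = choices[t]
            p = p1 if a == 1 else 1.0 - p1
            if p < _P_FLOOR:
                p = _P_FLOOR
            elif p > 1.0 - _P_FLOOR:
                p = 1.0 - _P_FLOOR
            ll += log(p)
            update(state, a, aa_choices[t], outcomes[t])
        return ll
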