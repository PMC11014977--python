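"""Mixed-intentions task engine.

The task is an iterated two-card game against an adaptive artificial agent
(AA).  The participant wins a trial when both players pick the same card.
Unbeknownst to the participant, the AA alternates between Competitive blocks
(matching-pennies payoffs: the AA tries to *mismatch* the participant's
predicted card) and Cooperative blocks (coordination payoffs: the AA tries to
*match* it), after a short random initialization phase.

Cards are coded ``{0, 1}``.  "Stay" means repeating one's own previous card.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Mode",
    "ScheduleEntry",
    "BlockSchedule",
    "build_schedule",
    "AdaptiveOpponent",
    "aa_choose",
    "TrialRecord",
    "SessionData",
    "play_session",
    "session_rng",
    "InvalidConfigError",
    "ContractViolationError",
]


class InvalidConfigError(ValueError):
    """Raised when a task configuration violates its preconditions."""


class ContractViolationError(RuntimeError):
    """Raised when an agent returns an invalid choice probability."""


class Mode(str, Enum):
    INIT = "INIT"
    COMPETITIVE = "COMPETITIVE"
    COOPERATIVE = "COOPERATIVE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ScheduleEntry:
    trial: int  # 1-based
    mode: Mode
    block_id: int


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered block structure of one session."""

    entries: tuple[ScheduleEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def modes(self) -> list[Mode]:
        return [e.mode for e in self.entries]

    def mode_counts(self) -> dict[Mode, int]:
        counts = {m: 0 for m in Mode}
        for e in self.entries:
            counts[e.mode] += 1
        return counts

    def block_lengths(self) -> list[tuple[Mode, int]]:
        """Run-length encoding of the schedule as (mode, length) pairs."""
        out: list[tuple[Mode, int]] = []
        for e in self.entries:
            if out and out[-1][0] is e.mode:
                out[-1] = (e.mode, out[-1][1] + 1)
            else:
                out.append((e.mode, 1))
        return out


def build_schedule(
    n_trials: int = 163,
    init_len: int = 5,
    comp_len: int = 13,
    coop_len: int = 10,
    start_mode: Mode = Mode.COMPETITIVE,
) -> BlockSchedule:
    """Build the deterministic block schedule.

    ``init_len`` random-initialization trials are followed by alternating
    Competitive (``comp_len``) and Cooperative (``coop_len``) blocks, starting
    with ``start_mode``; the final block is truncated so the schedule holds
    exactly ``n_trials`` trials.
    """
    start_mode = Mode(start_mode)
    if comp_len < 1 or coop_len < 1:
        raise InvalidConfigError("block lengths must be >= 1")
    if init_len < 0 or n_trials < init_len:
        raise InvalidConfigError("need n_trials >= init_len >= 0")
    if start_mode not in (Mode.COMPETITIVE, Mode.COOPERATIVE):
        raise InvalidConfigError("start_mode must be COMPETITIVE or COOPERATIVE")

    entries: list[ScheduleEntry] = []
    trial = 1
    for _ in range(init_len):
        entries.append(ScheduleEntry(trial, Mode.INIT, 0))
        trial += 1
    mode = start_mode
    block_id = 1
    lengths = {Mode.COMPETITIVE: comp_len, Mode.COOPERATIVE: coop_len}
    while trial <= n_trials:
        for _ in range(lengths[mode]):
            if trial > n_trials:
                break
            entries.append(ScheduleEntry(trial, mode, block_id))
            trial += 1
        mode = Mode.COOPERATIVE if mode is Mode.COMPETITIVE else Mode.COMPETITIVE
        block_id += 1
    return BlockSchedule(tuple(entries))


class AdaptiveOpponent:
    """The adaptive artificial agent's predictor of the participant's choice.

    Estimates the probability ``p`` that the participant picks card 1 next,
    from running add-one-smoothed conditional frequencies keyed by the
    previous one or two (choice, outcome) pairs, falling back to the marginal
    choice frequency when a conditioning context is unseen.  With an empty
    history ``p = 0.5``.
    """

    def __init__(self) -> None:
        self._hist: list[tuple[int, int]] = []  # last two (choice, outcome)
        self._counts2: dict[tuple, list[int]] = {}
        self._counts1: dict[tuple, list[int]] = {}
        self._marg: list[int] = [0, 0]

    @property
    def history(self) -> tuple[tuple[int, int], ...]:
        return tuple(self._hist)

    @staticmethod
    def _posterior(counts: Sequence[int]) -> float:
        # Beta(1,1)-smoothed frequency of choice 1
        return (counts[1] + 1.0) / (counts[0] + counts[1] + 2.0)

    def predict(self) -> float:
        """Probability that the participant selects card 1 on the next trial."""
        if not self._hist:
            return 0.5
        if len(self._hist) == 2:
            c2 = self._counts2.get(tuple(self._hist))
            if c2 is not None and sum(c2) > 0:
                return self._posterior(c2)
        c1 = self._counts1.get(self._hist[-1])
        if c1 is not None and sum(c1) > 0:
            return self._posterior(c1)
        return self._posterior(self._marg)

    def observe(self, participant_choice: int, outcome: int) -> None:
        """Record one completed trial and credit its conditioning contexts."""
        if participant_choice not in (0, 1) or outcome not in (0, 1):
            raise ValueError("choice and outcome must be binary")
        if self._hist:
            key1 = self._hist[-1]
            self._counts1.setdefault(key1, [0, 0])[participant_choice] += 1
            if len(self._hist) == 2:
                key2 = tuple(self._hist)
                self._counts2.setdefault(key2, [0, 0])[participant_choice] += 1
        self._marg[participant_choice] += 1
        self._hist.append((participant_choice, outcome))
        if len(self._hist) > 2:
            self._hist.pop(0)


def aa_choose(p: float, mode: Mode, rng: np.random.Generator) -> int:
    """Draw the AA's card given its prediction ``p`` and the block mode.

    In Cooperative mode the AA plays the card it predicts with probability
    equal to the prediction's weight (so ``P(aa=1) = p``); in Competitive
    mode it avoids it (``P(aa=1) = 1 - p``); in INIT mode it plays randomly.
    """
    if not (0.0 <= p <= 1.0) or math.isnan(p):
        raise ValueError(f"prediction p={p!r} outside [0, 1]")
    mode = Mode(mode)
    if mode is Mode.INIT:
        q = 0.5
    elif mode is Mode.COOPERATIVE:
        q = p
    else:
        q = 1.0 - p
    return int(rng.random() < q)


@dataclass(frozen=True)
class TrialRecord:
    trial: int
    mode: Mode
    participant_choice: int
    aa_choice: int
    outcome: int  # 1 = match = participant win
    participant_stay: Optional[int] = None  # undefined on trial 1
    aa_stay: Optional[int] = None

    def __post_init__(self) -> None:
        if self.outcome != int(self.participant_choice == self.aa_choice):
            raise ValueError(
                f"trial {self.trial}: outcome must be 1 iff the choices match"
            )


@dataclass
class SessionData:
    """Ordered trial records of one participant-AA game."""

    subject_id: str
    records: tuple[TrialRecord, ...]
    schedule: BlockSchedule
    seed: int = 0
    # cached plain-list views used by the likelihood loops
    _cols: Optional[tuple[list, list, list]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if len(self.records) != len(self.schedule):
            raise ValueError("session length must equal schedule length")
        for rec, ent in zip(self.records, self.schedule.entries):
            if rec.mode is not ent.mode or rec.trial != ent.trial:
                raise ValueError(
                    f"trial {rec.trial}: record mode/index disagrees with schedule"
                )

    def __len__(self) -> int:
        return len(self.records)

    def columns(self) -> tuple[list, list, list]:
        """(choices, aa_choices, outcomes) as plain lists (fast inner loops)."""
        if self._cols is None:
            self._cols = (
                [r.participant_choice for r in self.records],
                [r.aa_choice for r in self.records],
                [r.outcome for r in self.records],
            )
        return self._cols

    @property
    def win_rate(self) -> float:
        return float(np.mean([r.outcome for r in self.records]))

    def win_rate_by_mode(self) -> dict[Mode, float]:
        out: dict[Mode, float] = {}
        for m in Mode:
            o = [r.outcome for r in self.records if r.mode is m]
            if o:
                out[m] = float(np.mean(o))
        return out


def session_rng(subject_id: str, seed: int) -> np.random.Generator:
    """One RNG stream per session, keyed by (subject_id, global seed)."""
    h = zlib.crc32(str(subject_id).encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, h])


def _stays(prev: Optional[int], cur: int) -> Optional[int]:
    return None if prev is None else int(prev == cur)


def play_session(
    model,
    params: dict,
    schedule: BlockSchedule,
    seed: int = 0,
    subject_id: str = "sim",
) -> SessionData:
    """Play one full session of ``model`` against a live adaptive AA.

    Simultaneous-move semantics: on each trial the AA's card is drawn from its
    prediction of the participant *before* seeing the current choice, and the
    agent's card is drawn from its own policy before seeing the AA's card.
    """
    rng = session_rng(subject_id, seed)
    aa = AdaptiveOpponent()
    state = model.start(params)
    records: list[TrialRecord] = []
    prev_pc: Optional[int] = None
    prev_aa: Optional[int] = None
    for entry in schedule.entries:
        p_pred = aa.predict()
        aa_card = aa_choose(p_pred, entry.mode, rng)
        p1 = model.act(state)
        if not (0.0 <= p1 <= 1.0) or math.isnan(p1):
            raise ContractViolationError(
                f"{model.name}: choice probability {p1!r} outside [0, 1]"
            )
        pc = int(rng.random() < p1)
        outcome = int(pc == aa_card)
        records.append(
            TrialRecord(
                trial=entry.trial,
                mode=entry.mode,
                participant_choice=pc,
                aa_choice=aa_card,
                outcome=outcome,
                participant_stay=_stays(prev_pc, pc),
                aa_stay=_stays(prev_aa, aa_card),
            )
        )
        aa.observe(pc, outcome)
        model.update(state, pc, aa_card, outcome)
        prev_pc, prev_aa = pc, aa_card
    return SessionData(
        subject_id=subject_id, records=tuple(records), schedule=schedule, seed=seed
    )
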