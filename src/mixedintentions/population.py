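"""Synthetic populations, replay against fixed opponents, and recovery analyses.

The default population emulates the study design: 31 subjects, 163 trials
each, 5 random initialization trials followed by alternating 13-trial
Competitive and 10-trial Cooperative blocks against the live adaptive agent.
Per-subject parameters are drawn from normal distributions on the
unconstrained scale.  Replay runs a model against a *fixed* AA choice
sequence (a non-contingent opponent), the design used for the generative
signature analyses; replay banks are produced by simulating lapsing
win-stay/lose-switch agents against the live AA, which yields realistic
block-structured opponent sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .inference import FitResult, fit_map, to_natural
from .models import get_model
from .selection import BMSResult, bms
from .task import (
    BlockSchedule,
    Mode,
    SessionData,
    TrialRecord,
    build_schedule,
    play_session,
    session_rng,
)

__all__ = [
    "PopulationSpec",
    "DEFAULT_POPULATIONS",
    "simulate_population",
    "ReplayBank",
    "replay_model",
    "parameter_recovery",
    "model_recovery",
    "expert_signature_analysis",
    "generative_signature_analysis",
    "fit_population",
    "default_spec",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Population distribution of one generating model.

    ``param_dists`` maps parameter names to (mean, sd) on the unconstrained
    scale (logit / log / identity per the model's definitions).
    """

    model: str = "INF_MIXED"
    n_subjects: int = 31
    param_dists: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_trials: int = 163
    init_len: int = 5
    comp_len: int = 13
    coop_len: int = 10
    start_mode: Mode = Mode.COMPETITIVE
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        for name, (_, sd) in self.param_dists.items():
            if sd < 0:
                raise ValueError(f"negative SD for parameter {name!r}")

    def schedule(self) -> BlockSchedule:
        return build_schedule(
            self.n_trials, self.init_len, self.comp_len, self.coop_len,
            self.start_mode,
        )

    def draw_params(self, rng: np.random.Generator) -> dict[str, float]:
        model = get_model(self.model)
        theta = np.empty(len(model.param_defs))
        for i, d in enumerate(model.param_defs):
            mean, sd = self.param_dists.get(d.name, (d.prior_mean, 0.5))
            theta[i] = rng.normal(mean, sd)
        return to_natural(model.param_defs, theta)


def _d(**kw) -> dict[str, tuple[float, float]]:
    return kw


#: Study-shaped population distributions on the unconstrained scale.
#: Means/SDs were calibrated once so that simulated mixed-intentions
#: populations reproduce the task's qualitative operating point (win rate
#: clearly above chance in Cooperative blocks and below chance in Competitive
#: blocks, stay probability near 0.5, roughly half of trials classified
#: competitive) and then frozen.
DEFAULT_POPULATIONS: dict[str, dict[str, tuple[float, float]]] = {
    "INF_MIXED": _d(
        eta=(-1.0, 0.4),        # learning rate ~0.27
        kappa=(-0.5, 0.3),      # influence weight ~0.6
        beta=(1.25, 0.3),       # inverse temperature ~3.5
        slope=(2.5, 0.3),       # arbitration steepness ~12
        delta_bias=(0.1, 0.15), # slight population-level competitive bias
    ),
    "INF_COOP": _d(eta=(-1.0, 0.4), kappa=(-0.5, 0.3), beta=(1.25, 0.3)),
    "INF_COMP": _d(eta=(-1.0, 0.4), kappa=(-0.5, 0.3), beta=(1.25, 0.3)),
    "RL": _d(alpha=(-1.0, 0.4), beta=(1.25, 0.3)),
    "WSLS": _d(epsilon=(-1.7, 0.5)),
    "RB": _d(b=(0.0, 0.5)),
    "BSL2": _d(beta=(1.25, 0.3)),
    "BSL3": _d(beta=(1.25, 0.3)),
    "TOM1_COOP": _d(vol=(-1.2, 0.4), beta=(1.25, 0.3)),
    "TOM1_COMP": _d(vol=(-1.2, 0.4), beta=(1.25, 0.3)),
    "TOM1_MIXED": _d(
        vol=(-1.2, 0.4), beta=(1.25, 0.3), slope=(2.5, 0.3), delta_bias=(0.1, 0.15)
    ),
}


def default_spec(model: str = "INF_MIXED", **overrides) -> PopulationSpec:
    dists = overrides.pop("param_dists", dict(DEFAULT_POPULATIONS[model]))
    return PopulationSpec(model=model, param_dists=dists, **overrides)


def simulate_population(
    spec: PopulationSpec,
) -> tuple[list[SessionData], list[dict[str, float]]]:
    """Simulate one population against the live AA; returns (sessions, truths)."""
    model = get_model(spec.model)
    schedule = spec.schedule()
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 0x505])
    sessions, truths = [], []
    for i in range(spec.n_subjects):
        params = spec.draw_params(rng)
        sid = f"{spec.model}_s{i + 1:03d}"
        sessions.append(
            play_session(model, params, schedule, seed=spec.seed, subject_id=sid)
        )
        truths.append(params)
    return sessions, truths


# ---------------------------------------------------------------------------
# replay against fixed opponent sequences


@dataclass(frozen=True)
class ReplayBank:
    """Stored AA choice sequences used as non-contingent opponents."""

    sequences: tuple[tuple[int, ...], ...]
    schedule: BlockSchedule

    def __post_init__(self):
        for s in self.sequences:
            if len(s) != len(self.schedule):
                raise ValueError("each sequence must match the schedule length")

    def __len__(self) -> int:
        return len(self.sequences)

    @classmethod
    def generate(
        cls,
        n_sequences: int,
        schedule: Optional[BlockSchedule] = None,
        seed: int = 0,
        epsilon_dist: tuple[float, float] = (-1.7, 0.5),
    ) -> "ReplayBank":
        """AA sequences harvested from lapsing WSLS agents vs the live AA."""
        if schedule is None:
            schedule = build_schedule()
        wsls = get_model("WSLS")
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xBA4C])
        seqs = []
        for i in range(n_sequences):
            eps = float(1.0 / (1.0 + np.exp(-rng.normal(*epsilon_dist))))
            s = play_session(
                wsls, {"epsilon": eps}, schedule, seed=seed,
                subject_id=f"bank_{i + 1:04d}",
            )
            seqs.append(tuple(r.aa_choice for r in s.records))
        return cls(tuple(seqs), schedule)


def replay_model(
    model,
    params: dict[str, float],
    aa_sequence: Sequence[int],
    schedule: Optional[BlockSchedule] = None,
    seed: int = 0,
    subject_id: str = "replay",
) -> SessionData:
    """Play a model trial-by-trial against a fixed AA choice sequence."""
    if schedule is None:
        schedule = build_schedule(n_trials=len(aa_sequence))
    if len(aa_sequence) != len(schedule):
        raise ValueError("AA sequence length must match the schedule")
    rng = session_rng(subject_id, seed)
    state = model.start(params)
    records = []
    prev_pc = prev_aa = None
    for entry, aa_card in zip(schedule.entries, aa_sequence):
        p1 = model.act(state)
        pc = int(rng.random() < p1)
        outcome = int(pc == aa_card)
        records.append(
            TrialRecord(
                trial=entry.trial,
                mode=entry.mode,
                participant_choice=pc,
                aa_choice=int(aa_card),
                outcome=outcome,
                participant_stay=None if prev_pc is None else int(prev_pc == pc),
                aa_stay=None if prev_aa is None else int(prev_aa == aa_card),
            )
        )
        model.update(state, pc, int(aa_card), outcome)
        prev_pc, prev_aa = pc, int(aa_card)
    return SessionData(
        subject_id=subject_id, records=tuple(records), schedule=schedule, seed=seed
    )


# ---------------------------------------------------------------------------
# recovery analyses


def fit_population(
    sessions: Sequence[SessionData],
    model_names: Sequence[str],
    n_restarts: int = 8,
    seed: int = 0,
) -> tuple[np.ndarray, list[list[FitResult]]]:
    """Fit every model to every session; returns (F matrix, fits)."""
    F = np.empty((len(sessions), len(model_names)))
    fits: list[list[FitResult]] = []
    for i, session in enumerate(sessions):
        row = []
        for j, name in enumerate(model_names):
            fr = fit_map(
                get_model(name), session, n_restarts=n_restarts, seed=seed + i
            )
            F[i, j] = fr.free_energy
            row.append(fr)
        fits.append(row)
    return F, fits


def parameter_recovery(
    model_name: str = "INF_MIXED",
    n_rep: int = 50,
    n_trials: int = 163,
    seed: int = 0,
    n_restarts: int = 8,
    param_dists: Optional[dict[str, tuple[float, float]]] = None,
) -> pd.DataFrame:
    """Simulate-and-refit: one row per replicate with true and recovered values.

    The returned frame carries a ``rank_correlations`` attribute: the
    Spearman correlation between true and recovered values per parameter.
    """
    if n_trials < 1:
        raise ValueError("cannot recover parameters from empty sessions")
    spec = default_spec(
        model_name, n_subjects=n_rep, n_trials=n_trials, seed=seed
    )
    if param_dists is not None:
        spec = replace(spec, param_dists=dict(param_dists))
    for name, (_, sd) in spec.param_dists.items():
        if sd == 0:
            raise ValueError(
                f"parameter {name!r} is fixed in the generator; "
                "its recovery is undefined"
            )
    model = get_model(model_name)
    sessions, truths = simulate_population(spec)
    rows = []
    for i, (session, truth) in enumerate(zip(sessions, truths)):
        fr = fit_map(model, session, n_restarts=n_restarts, seed=seed + i)
        row = {"rep": i + 1}
        for name in model.param_names:
            row[f"true_{name}"] = truth[name]
            row[f"fit_{name}"] = fr.params[name]
        rows.append(row)
    df = pd.DataFrame(rows)
    corr = {}
    for name in model.param_names:
        rho = spearmanr(df[f"true_{name}"], df[f"fit_{name}"]).statistic
        corr[name] = float(rho)
    df.attrs["rank_correlations"] = corr
    return df


def expert_signature_analysis(
    n_datasets: int = 310,
    n_subjects: int = 31,
    seed: int = 0,
    n_restarts: int = 8,
) -> dict[str, float]:
    """Generative signature of the single cooperative vs competitive experts.

    Mirrors the study's replay design: a study-shaped population is simulated
    from the mixed-intentions model (the stand-in for the real participants),
    its AA choice sequences are stored as non-contingent opponents, each
    single-expert influence model is fitted to the population, ``n_datasets``
    parameter sets are drawn from normal distributions with the fitted
    population mean and SD (unconstrained scale), and each draw is replayed
    against the stored sequences.  Returns the mean stay probability per
    expert (plus the population win rates by block for reference).
    """
    spec = default_spec("INF_MIXED", n_subjects=n_subjects, seed=seed)
    sessions, _ = simulate_population(spec)
    schedule = spec.schedule()
    bank = [tuple(r.aa_choice for r in s.records) for s in sessions]
    out: dict[str, float] = {}
    for name in ("INF_COOP", "INF_COMP"):
        model = get_model(name)
        thetas = np.array(
            [
                fit_map(model, s, n_restarts=n_restarts, seed=seed + i).theta_map
                for i, s in enumerate(sessions)
            ]
        )
        mu, sd = thetas.mean(axis=0), thetas.std(axis=0)
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x516])
        stays = []
        for i in range(n_datasets):
            params = to_natural(model.param_defs, rng.normal(mu, sd))
            replay = replay_model(
                model, params, bank[i % len(bank)], schedule,
                seed=seed, subject_id=f"{name}_r{i:04d}",
            )
            pcs = [r.participant_choice for r in replay.records]
            stays.append(
                float(np.mean([pcs[t] == pcs[t - 1] for t in range(1, len(pcs))]))
            )
        out[f"stay_{name}"] = float(np.mean(stays))
    out["win_rate_coop"] = float(
        np.mean([s.win_rate_by_mode()[Mode.COOPERATIVE] for s in sessions])
    )
    out["win_rate_comp"] = float(
        np.mean([s.win_rate_by_mode()[Mode.COMPETITIVE] for s in sessions])
    )
    return out


def generative_signature_analysis(
    n_datasets: int = 310,
    n_subjects: int = 31,
    seed: int = 0,
    n_restarts: int = 4,
) -> "pd.DataFrame":
    """Generative analysis of the mixed-intentions model's behavioral signature.

    A study-shaped population is simulated, the mixed-intentions model is
    fitted to it, and ``n_datasets`` new datasets are generated by replaying
    the model (parameters drawn from the population-fitted normal on the
    unconstrained scale) against the stored AA choice sequences.  Returns the
    stacked analysis-ready covariate table (clustered by simulation id) with
    the generating model's own latents attached — the input to the stay/switch
    and valence x prediction-error panel regressions.
    """
    from .stats import covariates_table  # local import to avoid a cycle

    model = get_model("INF_MIXED")
    spec = default_spec("INF_MIXED", n_subjects=n_subjects, seed=seed)
    sessions, _ = simulate_population(spec)
    schedule = spec.schedule()
    bank = [tuple(r.aa_choice for r in s.records) for s in sessions]
    thetas = np.array(
        [
            fit_map(model, s, n_restarts=n_restarts, seed=seed + i).theta_map
            for i, s in enumerate(sessions)
        ]
    )
    mu, sd = thetas.mean(axis=0), thetas.std(axis=0)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x66E])
    replays, traces = [], []
    for i in range(n_datasets):
        params = to_natural(model.param_defs, rng.normal(mu, sd))
        r = replay_model(
            model, params, bank[i % len(bank)], schedule,
            seed=seed, subject_id=f"gen{i:04d}",
        )
        replays.append(r)
        traces.append(model.run(params, r))
    return covariates_table(replays, traces)


def model_recovery(
    generators: Sequence[str],
    fit_models: Optional[Sequence[str]] = None,
    n_subjects: int = 20,
    seed: int = 0,
    n_restarts: int = 8,
    n_trials: int = 163,
    ep_draws: int = 1_000_000,
) -> pd.DataFrame:
    """Confusion matrix of BMS outcomes: generators x candidate models (pEP).

    Each row is one generating model: a population is simulated from it, all
    candidate models are fitted to every subject, and the row holds the
    protected exceedance probabilities.  The BMS winner per row sits in
    ``attrs['winners']``.
    """
    if len(generators) < 2 and (fit_models is None or len(fit_models) < 2):
        raise ValueError("need at least two models to compare")
    if fit_models is None:
        fit_models = list(generators)
    rows, winners = [], {}
    for g, gen in enumerate(generators):
        spec = default_spec(gen, n_subjects=n_subjects, n_trials=n_trials,
                            seed=seed + 1000 * g)
        sessions, _ = simulate_population(spec)
        F, _ = fit_population(sessions, fit_models, n_restarts=n_restarts,
                              seed=seed + 1000 * g)
        result = bms(F, tuple(fit_models), n_draws=ep_draws, seed=seed)
        rows.append(dict(zip(fit_models, result.pep)))
        winners[gen] = result.winner
    df = pd.DataFrame(rows, index=list(generators))
    df.index.name = "generator"
    df.attrs["winners"] = winners
    return df
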