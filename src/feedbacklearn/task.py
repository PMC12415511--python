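"""Simulator for the active/observational probabilistic selection task.

The task presents three stimulus pairs with reciprocal reward contingencies
(A/B = 80/20, C/D = 70/30, E/F = 60/40).  A session comprises four learning
blocks of 60 trials alternating with four test blocks of 30 trials, followed
by a 40-trial transfer phase in which A and B are re-paired with every
stimulus they have not been seen with before.  Feedback (win/loss) is shown
only on learning trials; test and transfer trials end with the choice.

Active agents choose via a softmax over running Q-values and learn by a
dual-learning-rate delta rule; in feedback-free phases their values evolve
by a choice-induced preference change (CIPC).  Observational agents watch a
yoked active learner's learning-phase choices and outcomes and learn
vicariously, then choose for themselves in test and transfer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "StimulusPair",
    "TaskDesign",
    "AgentParams",
    "GroupParams",
    "CohortSpec",
    "build_design",
    "simulate_active_session",
    "simulate_observer_session",
    "simulate_cohort",
]


class ConfigError(ValueError):
    """Raised when a task configuration violates a design invariant."""


#: Per-stimulus probability of win feedback when that stimulus is chosen.
DEFAULT_CONTINGENCIES = {
    "A": 0.8,
    "B": 0.2,
    "C": 0.7,
    "D": 0.3,
    "E": 0.6,
    "F": 0.4,
}

STIMULI = tuple(DEFAULT_CONTINGENCIES)
STIM_INDEX = {s: i for i, s in enumerate(STIMULI)}


@dataclass(frozen=True)
class StimulusPair:
    """A two-stimulus choice pattern and the phases in which it appears."""

    label: str
    stimuli: tuple[str, str]
    phases: tuple[str, ...]

    def other(self, chosen: str) -> str:
        a, b = self.stimuli
        return b if chosen == a else a


def _learning_pairs() -> tuple[StimulusPair, ...]:
    return tuple(
        StimulusPair(f"{a}/{b}", (a, b), ("learning", "test"))
        for a, b in (("A", "B"), ("C", "D"), ("E", "F"))
    )


def _transfer_pairs() -> tuple[StimulusPair, ...]:
    # A and B each combined with the four stimuli they were never paired with.
    pairs = []
    for anchor in ("A", "B"):
        for other in ("C", "D", "E", "F"):
            pairs.append(StimulusPair(f"{anchor}/{other}", (anchor, other), ("transfer",)))
    return tuple(pairs)


@dataclass(frozen=True)
class TaskDesign:
    """Block structure, stimulus pairs and reward contingencies of a session."""

    n_learning_blocks: int = 4
    learning_block_len: int = 60
    n_test_blocks: int = 4
    test_block_len: int = 30
    transfer_len: int = 40
    win_points: int = 20
    loss_points: int = -10
    catch_rate: float = 0.2
    contingencies: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONTINGENCIES))
    pairs: tuple[StimulusPair, ...] = field(default_factory=_learning_pairs)
    transfer_pairs: tuple[StimulusPair, ...] = field(default_factory=_transfer_pairs)

    @property
    def n_trials(self) -> int:
        return (
            self.n_learning_blocks * self.learning_block_len
            + self.n_test_blocks * self.test_block_len
            + self.transfer_len
        )

    def p_win(self, stimulus: str) -> float:
        return self.contingencies[stimulus]

    def correct_stimulus(self, pair: StimulusPair) -> str:
        a, b = pair.stimuli
        return a if self.p_win(a) >= self.p_win(b) else b

    def validate(self) -> None:
        n_pairs = len(self.pairs)
        if self.learning_block_len % n_pairs:
            raise ConfigError(
                f"learning_block_len={self.learning_block_len} not divisible by "
                f"{n_pairs} learning pairs"
            )
        if self.test_block_len % n_pairs:
            raise ConfigError(
                f"test_block_len={self.test_block_len} not divisible by "
                f"{n_pairs} test pairs"
            )
        if self.transfer_len and self.transfer_len % len(self.transfer_pairs):
            raise ConfigError(
                f"transfer_len={self.transfer_len} not divisible by "
                f"{len(self.transfer_pairs)} transfer pairs"
            )
        for pair in self.pairs:
            a, b = pair.stimuli
            if not math.isclose(self.p_win(a) + self.p_win(b), 1.0):
                raise ConfigError(f"pair {pair.label}: contingencies not reciprocal")
        if not 0.0 <= self.catch_rate <= 1.0:
            raise ConfigError("catch_rate must be a probability")


def build_design(design: TaskDesign | None = None, seed: int = 0, **overrides) -> pd.DataFrame:
    """Enumerate the full trial schedule of one session.

    Returns a frame with one row per trial: global ``trial`` index (1-based),
    ``phase`` in {learning, test, transfer}, ``block`` (1-based within phase
    type), ``pair`` label and the seeded left/right side assignment.
    Learning and test blocks alternate L1,T1,...,L4,T4 and the transfer
    phase comes last; within a block every eligible pair appears equally
    often in shuffled order.
    """
    if design is None:
        design = TaskDesign(**overrides)
    elif overrides:
        design = replace(design, **overrides)
    design.validate()
    rng = np.random.default_rng(seed)

    rows: list[dict] = []

    def add_block(phase: str, block: int, pairs: tuple[StimulusPair, ...], length: int) -> None:
        reps = length // len(pairs)
        block_pairs = [p for p in pairs for _ in range(reps)]
        rng.shuffle(block_pairs)
        for p in block_pairs:
            a, b = p.stimuli
            flip = bool(rng.integers(2))
            rows.append(
                {
                    "phase": phase,
                    "block": block,
                    "pair": p.label,
                    "stim_left": b if flip else a,
                    "stim_right": a if flip else b,
                }
            )

    for b in range(1, design.n_learning_blocks + 1):
        add_block("learning", b, design.pairs, design.learning_block_len)
        if b <= design.n_test_blocks:
            add_block("test", b, design.pairs, design.test_block_len)
    if design.transfer_len:
        add_block("transfer", 1, design.transfer_pairs, design.transfer_len)

    schedule = pd.DataFrame(rows)
    schedule.insert(0, "trial", np.arange(1, len(schedule) + 1))
    return schedule


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of a simulated learner.

    ``alpha_pos``/``alpha_neg`` are delta-rule learning rates for win and
    loss feedback; ``beta`` is the softmax inverse temperature; ``epsilon``
    is the CIPC rate applied after every feedback-free choice (``epsilon=0``
    gives static values; ``dynamics='decay'`` instead relaxes values toward
    their initial level at rate ``gamma``).  Reaction times are drawn from a
    normal distribution clipped at 50 ms, so a small fraction of responses
    falls below the 200-ms validity cutoff; no-response trials occur at
    ``p_no_response``.
    """

    alpha_pos: float = 0.35
    alpha_neg: float = 0.30
    beta: float = 5.0
    epsilon: float = 0.15
    dynamics: str = "cipc"
    gamma: float = 0.0
    q0: float | tuple = 0.5  # scalar, or ((stimulus, value), ...) for informed starts
    rt_mean: float = 470.0
    rt_sd: float = 120.0
    p_no_response: float = 0.005

    def validate(self) -> None:
        for name in ("alpha_pos", "alpha_neg", "epsilon", "gamma", "p_no_response"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.beta < 0:
            raise ConfigError(f"beta={self.beta} must be >= 0")
        if self.rt_mean <= 0:
            raise ConfigError("rt_mean must be positive")
        if self.dynamics not in ("static", "decay", "cipc"):
            raise ConfigError(f"unknown dynamics {self.dynamics!r}")


def _softmax_left(q_left: float, q_right: float, beta: float) -> float:
    x = -beta * (q_left - q_right)
    return 1.0 / (1.0 + math.exp(min(700.0, max(-700.0, x))))


def _init_q(design: TaskDesign, agent: AgentParams) -> dict:
    if isinstance(agent.q0, tuple):
        informed = dict(agent.q0)
        return {s: float(informed.get(s, 0.5)) for s in design.contingencies}
    return {s: float(agent.q0) for s in design.contingencies}


def _feedbackfree(q: dict, q_init: dict, chosen: str, unchosen: str, agent: AgentParams) -> None:
    if agent.dynamics == "cipc":
        q[chosen] += agent.epsilon * (1.0 - q[chosen])
        q[unchosen] -= agent.epsilon * q[unchosen]
    elif agent.dynamics == "decay":
        q[chosen] += agent.gamma * (q_init[chosen] - q[chosen])
        q[unchosen] += agent.gamma * (q_init[unchosen] - q[unchosen])


def _draw_rt(rng: np.random.Generator, agent: AgentParams) -> float:
    return max(50.0, rng.normal(agent.rt_mean, agent.rt_sd))


def _base_record(row, participant_id, group, agency, session) -> dict:
    return {
        "participant_id": participant_id,
        "group": group,
        "session": session,
        "agency": agency,
        "phase": row.phase,
        "block": row.block,
        "trial": row.trial,
        "pair": row.pair,
        "stim_left": row.stim_left,
        "stim_right": row.stim_right,
        "side_of_choice": None,
        "chosen_stimulus": None,
        "feedback": "none",
        "rt": np.nan,
        "points_delta": 0,
        "catch": False,
    }


def simulate_active_session(
    schedule: pd.DataFrame,
    agent: AgentParams,
    seed: int,
    design: TaskDesign | None = None,
    participant_id: str = "P000",
    group: str = "HC",
    session: int = 1,
) -> pd.DataFrame:
    """Simulate one active learner playing a scheduled session.

    The agent chooses by softmax on its running Q-values (initialised at
    ``q0``), receives Bernoulli feedback per the chosen stimulus's
    contingency on learning trials, updates by the dual-rate delta rule, and
    applies its feedback-free dynamics after every test/transfer choice.
    """
    design = design or TaskDesign()
    agent.validate()
    rng = np.random.default_rng(seed)
    q = _init_q(design, agent)
    q_init = dict(q)
    records = []
    for row in schedule.itertuples(index=False):
        rec = _base_record(row, participant_id, group, "active", session)
        if rng.random() < agent.p_no_response:
            records.append(rec)
            continue
        p_left = _softmax_left(q[row.stim_left], q[row.stim_right], agent.beta)
        go_left = rng.random() < p_left
        chosen = row.stim_left if go_left else row.stim_right
        unchosen = row.stim_right if go_left else row.stim_left
        rec["side_of_choice"] = "left" if go_left else "right"
        rec["chosen_stimulus"] = chosen
        rec["rt"] = _draw_rt(rng, agent)
        if row.phase == "learning":
            win = rng.random() < design.p_win(chosen)
            rec["feedback"] = "win" if win else "loss"
            rec["points_delta"] = design.win_points if win else design.loss_points
            alpha = agent.alpha_pos if win else agent.alpha_neg
            q[chosen] += alpha * ((1.0 if win else 0.0) - q[chosen])
        else:
            _feedbackfree(q, q_init, chosen, unchosen, agent)
        records.append(rec)
    return pd.DataFrame(records)


def simulate_observer_session(
    schedule: pd.DataFrame,
    observed: pd.DataFrame,
    agent: AgentParams,
    seed: int,
    design: TaskDesign | None = None,
    participant_id: str = "P000",
    group: str = "HC",
    session: int = 1,
) -> pd.DataFrame:
    """Simulate an observational learner yoked to a completed active session.

    Learning-phase choices and feedback are copied verbatim from the yoked
    source; the observer updates its own Q-values from the observed
    outcomes.  Catch prompts are flagged after randomly selected learning
    trials at the design's ``catch_rate``.  Test and transfer choices are
    the observer's own.
    """
    design = design or TaskDesign()
    agent.validate()
    if len(observed) != len(schedule):
        raise ConfigError(
            f"yoked session has {len(observed)} trials but schedule has {len(schedule)}"
        )
    obs_learning = observed[observed["phase"] == "learning"].reset_index(drop=True)
    sched_learning = schedule[schedule["phase"] == "learning"].reset_index(drop=True)
    if not obs_learning["pair"].equals(sched_learning["pair"]):
        raise ConfigError("yoked session's learning-phase pair sequence does not match schedule")

    rng = np.random.default_rng(seed)
    q = _init_q(design, agent)
    q_init = dict(q)
    records = []
    it_obs = iter(obs_learning.itertuples(index=False))
    for row in schedule.itertuples(index=False):
        rec = _base_record(row, participant_id, group, "observational", session)
        if row.phase == "learning":
            src = next(it_obs)
            rec.update(
                stim_left=src.stim_left,
                stim_right=src.stim_right,
                side_of_choice=src.side_of_choice,
                chosen_stimulus=src.chosen_stimulus,
                feedback=src.feedback,
                points_delta=src.points_delta,
                catch=bool(rng.random() < design.catch_rate),
            )
            if src.feedback in ("win", "loss"):
                win = src.feedback == "win"
                alpha = agent.alpha_pos if win else agent.alpha_neg
                q[src.chosen_stimulus] += alpha * ((1.0 if win else 0.0) - q[src.chosen_stimulus])
        else:
            if rng.random() < agent.p_no_response:
                records.append(rec)
                continue
            p_left = _softmax_left(q[row.stim_left], q[row.stim_right], agent.beta)
            go_left = rng.random() < p_left
            chosen = row.stim_left if go_left else row.stim_right
            unchosen = row.stim_right if go_left else row.stim_left
            rec["side_of_choice"] = "left" if go_left else "right"
            rec["chosen_stimulus"] = chosen
            rec["rt"] = _draw_rt(rng, agent)
            _feedbackfree(q, q_init, chosen, unchosen, agent)
        records.append(rec)
    return pd.DataFrame(records)


@dataclass(frozen=True)
class GroupParams:
    """Population distribution (mean, sd) of agent parameters in one group."""

    alpha_pos: tuple[float, float] = (0.35, 0.12)
    alpha_neg: tuple[float, float] = (0.30, 0.12)
    beta: tuple[float, float] = (5.0, 2.0)
    epsilon: tuple[float, float] = (0.15, 0.08)

    def draw(self, rng: np.random.Generator) -> AgentParams:
        def trunc(mu_sd, lo, hi):
            return float(np.clip(rng.normal(*mu_sd), lo, hi))

        return AgentParams(
            alpha_pos=trunc(self.alpha_pos, 0.02, 0.98),
            alpha_neg=trunc(self.alpha_neg, 0.02, 0.98),
            beta=trunc(self.beta, 0.2, 20.0),
            epsilon=trunc(self.epsilon, 0.0, 0.9),
        )


def _default_group_params() -> dict[str, GroupParams]:
    # The clinical group is given a mildly reduced positive learning rate so
    # that a group effect exists for downstream recovery checks.
    return {
        "OCD": GroupParams(alpha_pos=(0.26, 0.12)),
        "HC": GroupParams(),
        "SAD": GroupParams(),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition: 27 OCD, 27 HC and 29 SAD participants by default."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"OCD": 27, "HC": 27, "SAD": 29}
    )
    group_params: dict[str, GroupParams] = field(default_factory=_default_group_params)
    seed: int = 0

    @property
    def n_participants(self) -> int:
        return sum(self.group_sizes.values())


def simulate_cohort(spec: CohortSpec, design: TaskDesign | None = None) -> pd.DataFrame:
    """Simulate a full cohort: two sessions (active + observational) each.

    Session order is counterbalanced across the roster; each observational
    session is yoked to the previous participant's active session (the first
    participant observes the last), mirroring the yoking of observers to
    previous active learners.  Fully reproducible from ``spec.seed``.
    """
    design = design or TaskDesign()
    master = np.random.SeedSequence(spec.seed)
    roster = [
        (f"{g}{i + 1:02d}", g)
        for g in sorted(spec.group_sizes)
        for i in range(spec.group_sizes[g])
    ]
    seeds = master.spawn(len(roster))

    actives: list[pd.DataFrame] = []
    agents: list[AgentParams] = []
    schedules: list[pd.DataFrame] = []
    for (pid, grp), ss in zip(roster, seeds):
        child = np.random.default_rng(ss)
        agent = spec.group_params[grp].draw(child)
        sched_seed, act_seed, obs_seed = child.integers(2**31, size=3)
        schedule = build_design(design, seed=int(sched_seed))
        active = simulate_active_session(
            schedule, agent, int(act_seed), design, pid, grp, session=1
        )
        agents.append(agent)
        schedules.append(schedule)
        actives.append(active)

    frames: list[pd.DataFrame] = []
    for i, ((pid, grp), ss) in enumerate(zip(roster, seeds)):
        obs_seed = int(np.random.default_rng(ss).integers(2**31, size=4)[3])
        yoked = i - 1  # first participant observes the last active learner
        observer = simulate_observer_session(
            schedules[yoked], actives[yoked], agents[i], obs_seed, design, pid, grp, session=2
        )
        active = actives[i]
        if i % 2:  # counterbalance: odd roster positions start observational
            active = active.assign(session=2)
            observer = observer.assign(session=1)
        frames.extend([active, observer])
    return pd.concat(frames, ignore_index=True)
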