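"""Synthetic participants for the reference game.

Each simulated participant follows one fixed strategy for the whole
session:

* ``rsa_L0`` / ``rsa_L1`` / ``rsa_L2`` -- sample from the corresponding
  quantal-response listener at the participant's rationality ``lam``.
* ``guess`` -- uniform among the referents the message is true of.
* ``visual_resemblance`` / ``odd_one_out`` / ``salience`` / ``preference``
  -- stimulus-driven strategies.  Their behavior on critical trials is
  parameterized by the design's ``bias_alignment``: the probability that
  the strategy's choice lands on the target in each condition (else the
  choice is uniform among the other two referents).  On unambiguous trials
  every strategy picks the message-matching target (attention-check
  semantics); on fully ambiguous trials the two identical referents are
  chosen between uniformly.

Two nuisance processes overlay every strategy: a small lapse rate (the
trial is answered with the distractor, emulating attention slips -- about
2% of trials in the data the simulator emulates) and an additive log-odds
position bias toward the center and right screen slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .design import (
    BIAS_STRATEGIES,
    ExperimentDesign,
    RefgameError,
    Session,
    Trial,
    generate_session,
    get_design,
    truth_of,
)
from .rsa import ROLES, listener_level

RSA_STRATEGIES = ("rsa_L0", "rsa_L1", "rsa_L2")
STRATEGIES = RSA_STRATEGIES + ("guess",) + BIAS_STRATEGIES

#: mixture emulating the annotated strategy breakdown of the original
#: stimuli: about half correct reasoners, a quarter guessers, and a quarter
#: stimulus-driven strategies dominated by visual resemblance.
DEFAULT_MIXTURE: dict[str, float] = {
    "rsa_L2": 0.28,
    "rsa_L1": 0.20,
    "rsa_L0": 0.07,
    "guess": 0.22,
    "visual_resemblance": 0.13,
    "odd_one_out": 0.03,
    "salience": 0.04,
    "preference": 0.03,
}

RESPONSE_COLUMNS = (
    "participant_id",
    "trial_index",
    "condition",
    "chosen_role",
    "chosen_position",
    "message_dimension",
    "correct",
)


@dataclass(frozen=True)
class ParticipantSpec:
    """Strategy profile of one simulated subject."""

    participant_id: str
    strategy: str
    lam: float = 5.0
    lapse_rate: float = 0.02
    position_bias: tuple[float, float] = (0.0, 0.0)  # (center, right) vs left

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise RefgameError(f"unknown strategy {self.strategy!r}")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise RefgameError("lapse_rate must lie in [0, 0.1]")


@dataclass(frozen=True)
class PopulationSpec:
    """A population of participants to simulate under one design."""

    n_participants: int
    mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    design_id: str = "exp1"
    lam: float = 5.0
    lapse_rate: float = 0.02
    position_bias: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise RefgameError("need at least one participant")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise RefgameError(f"mixture weights sum to {total}, not 1")
        for s in self.mixture:
            if s not in STRATEGIES:
                raise RefgameError(f"unknown strategy {s!r} in mixture")

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "mixture": dict(self.mixture),
            "design_id": self.design_id,
            "lam": self.lam,
            "lapse_rate": self.lapse_rate,
            "position_bias": list(self.position_bias),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationSpec":
        d = dict(d)
        if "position_bias" in d:
            d["position_bias"] = tuple(d["position_bias"])
        return cls(**d)


def _position_weights(trial: Trial, bias: tuple[float, float]) -> np.ndarray:
    """exp(log-odds boost) for each role, from the slot it occupies."""
    boost = {"left": 0.0, "center": bias[0], "right": bias[1]}
    return np.exp([boost[trial.positions[r]] for r in ROLES])


def _strategy_distribution(
    spec: ParticipantSpec, trial: Trial, design: ExperimentDesign
) -> np.ndarray:
    """Pre-lapse choice distribution over (target, competitor, distractor)."""
    # filler trials are handled structurally for every strategy: the
    # unambiguous fillers are attention checks (the message names the
    # target alone), and on the fully ambiguous fillers the two identical
    # referents carry no distinguishing information, so choice between
    # them is uniform.  Strategies differ only on the critical trials.
    if trial.condition == "unambiguous":
        return np.array([1.0, 0.0, 0.0])
    if trial.condition == "ambiguous":
        return np.array([0.5, 0.5, 0.0])

    if spec.strategy in RSA_STRATEGIES:
        n = int(spec.strategy[-1])
        return listener_level(n, trial, design, spec.lam).as_array()

    truth = np.array([truth_of(trial.message, r) for r in trial.referents], float)
    if spec.strategy == "guess":
        # uniform among message-true referents
        if truth.sum() == 0:
            return np.full(3, 1 / 3)
        return truth / truth.sum()
    # bias strategy on a critical trial: the residual mass lands on the
    # other message-matching referent (the competitor) -- stimulus-driven
    # choices are observed almost exclusively among the two matching
    # referents -- except for odd_one_out, which often singles out the
    # distractor (the only creature with an unshared feature).
    try:
        p_target = design.bias_alignment[spec.strategy][trial.condition]
    except KeyError:
        raise RefgameError(
            f"design {design.design_id!r} defines no bias alignment for "
            f"{spec.strategy!r} in condition {trial.condition!r}"
        ) from None
    residual = 1 - p_target
    if spec.strategy == "odd_one_out":
        return np.array([p_target, residual / 2, residual / 2])
    return np.array([p_target, residual, 0.0])


def simulate_participant(
    spec: ParticipantSpec,
    session: Session,
    design: ExperimentDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One response row per trial of the session.

    Correctness is coded immediately for non-ambiguous trials (target
    chosen); ambiguous trials are left unset (NaN) for the baseline-coding
    step downstream, mirroring the fact that with two identical referents
    "the target" is not observable.
    """
    rows = []
    for trial in session.trials:
        if rng.random() < spec.lapse_rate:
            role = "distractor"
        else:
            p = _strategy_distribution(spec, trial, design)
            w = p * _position_weights(trial, spec.position_bias)
            if w.sum() == 0:  # position bias cannot resurrect a zero dist.
                w = p
            role = ROLES[int(rng.choice(3, p=w / w.sum()))]
        correct: float = float(role == "target")
        if trial.condition == "ambiguous":
            correct = np.nan
        rows.append(
            {
                "participant_id": spec.participant_id,
                "trial_index": trial.trial_index,
                "condition": trial.condition,
                "chosen_role": role,
                "chosen_position": trial.positions[role],
                "message_dimension": trial.message.dimension,
                "correct": correct,
                "strategy": spec.strategy,
                "design_id": session.design_id,
                "target_position": trial.positions["target"],
            }
        )
    return pd.DataFrame(rows)


def simulate_dataset(pop: PopulationSpec) -> pd.DataFrame:
    """Simulate a full response table: one fresh session per participant.

    Per-participant session and response seeds are derived from the
    population seed, so the table is reproducible bit-for-bit.
    """
    design = get_design(pop.design_id)
    rng = np.random.default_rng(pop.seed)
    strategies = list(pop.mixture)
    weights = np.array([pop.mixture[s] for s in strategies])
    frames = []
    for i in range(pop.n_participants):
        strategy = strategies[int(rng.choice(len(strategies), p=weights))]
        spec = ParticipantSpec(
            participant_id=f"p{i:03d}",
            strategy=strategy,
            lam=pop.lam,
            lapse_rate=pop.lapse_rate,
            position_bias=pop.position_bias,
        )
        session_seed = int(rng.integers(2**31 - 1))
        session = generate_session(design, spec.participant_id, session_seed)
        frames.append(simulate_participant(spec, session, design, rng))
    return pd.concat(frames, ignore_index=True)
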