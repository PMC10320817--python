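"""Iterated quantal-response (softmax RSA) listener/speaker hierarchy.

All agents choose by a softmax rule: an option with utility ``u`` receives
weight ``exp(lambda * u)``, where the rationality parameter ``lambda > 0``
interpolates between uniform random choice (``lambda -> 0``) and strict
utility maximization (``lambda -> inf``).

The literal listener L0 scores each referent by the uniform
truth-conditional utility ``1/|truth set|`` (0 for referents the message is
false of); the literal speaker S0 scores each expressible message the same
way over the referent's true messages.  Higher levels iterate the rule: each
level's utility for an option is the previous level's choice probability
(L1 exponentiates S0's message probability, S1 exponentiates L0's referent
probability, L2 exponentiates S1's).  A ``logprob`` utility variant, which
exponentiates log-probabilities instead, is available as a configuration
option; both variants make the same qualitative predictions on every trial
type.

Predictions per design:

* L0 is at chance on both critical conditions.
* L1 solves simple trials (the competitor's speaker probability is split
  over two messages) but not complex ones.
* L2 solves both: S1 avoids the ambiguous message for the competitor, and
  L2 exploits that asymmetry.
* Under the all-messages design, simple-template trials become fully
  symmetric between target and competitor for every level, while the
  complex asymmetry survives and only L2 resolves it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Mapping

import numpy as np

from .design import (
    ExperimentDesign,
    FeatureValue,
    Referent,
    RefgameError,
    Trial,
    generate_trial,
    truth_of,
)

ROLES = ("target", "competitor", "distractor")

Utility = Literal["prob", "logprob"]


@dataclass(frozen=True)
class ListenerPrediction:
    """Choice distribution over the three referent roles."""

    level: int
    lam: float
    probs: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = np.array([self.probs[r] for r in ROLES])
        if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-12:
            raise RefgameError("listener probabilities must be a distribution")

    def as_array(self) -> np.ndarray:
        return np.array([self.probs[r] for r in ROLES])


@dataclass(frozen=True)
class SpeakerPrediction:
    """Choice distribution over the design's expressible messages."""

    level: int
    lam: float
    probs: Mapping[FeatureValue, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.probs.values()))
        if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
            raise RefgameError("speaker probabilities must be a distribution")


def _softmax(utilities: np.ndarray, lam: float) -> np.ndarray:
    w = np.exp(lam * (utilities - utilities.max()))
    return w / w.sum()


def _check_lambda(lam: float) -> None:
    if not lam > 0:
        raise RefgameError(f"rationality lambda must be positive, got {lam}")


def _listener_utilities_literal(trial: Trial) -> np.ndarray:
    truth = np.array([truth_of(trial.message, r) for r in trial.referents], float)
    n_true = truth.sum()
    return truth / n_true if n_true else truth


def literal_listener(trial: Trial, design: ExperimentDesign, lam: float) -> ListenerPrediction:
    """L0: softmax over the uniform truth-conditional utility.

    A message true of no referent yields zero utility everywhere, hence the
    uniform (1/3, 1/3, 1/3) distribution.
    """
    _check_lambda(lam)
    p = _softmax(_listener_utilities_literal(trial), lam)
    return ListenerPrediction(0, lam, dict(zip(ROLES, p)))


def _speaker_utilities_literal(
    referent: Referent, messages: tuple[FeatureValue, ...]
) -> np.ndarray:
    truth = np.array([truth_of(m, referent) for m in messages], float)
    n_true = truth.sum()
    return truth / n_true if n_true else truth


def literal_speaker(
    referent: Referent, design: ExperimentDesign, lam: float
) -> SpeakerPrediction:
    """S0: softmax over the uniform truth utility on expressible messages.

    A referent with no true expressible message gets a uniform distribution.
    """
    _check_lambda(lam)
    messages = design.messages()
    p = _softmax(_speaker_utilities_literal(referent, messages), lam)
    return SpeakerPrediction(0, lam, dict(zip(messages, p)))


def _as_utility(p: np.ndarray, utility: Utility) -> np.ndarray:
    if utility == "prob":
        return p
    with np.errstate(divide="ignore"):
        return np.log(p)


def _speaker_matrix(
    level: int,
    trial: Trial,
    design: ExperimentDesign,
    lam: float,
    utility: Utility,
) -> np.ndarray:
    """S_level(m | o) as a (3 referents x M messages) row-stochastic matrix."""
    messages = design.messages()
    if level == 0:
        rows = [_speaker_utilities_literal(r, messages) for r in trial.referents]
        u = np.array(rows)
    else:  # S1 reasons about the literal listener
        l0 = np.array(
            [
                literal_listener(replace(trial, message=m), design, lam).as_array()
                for m in messages
            ]
        ).T  # (3 referents x M messages)
        u = _as_utility(l0, utility)
    w = np.exp(lam * u)
    return w / w.sum(axis=1, keepdims=True)


def speaker_level(
    level: int,
    referent_role: str,
    trial: Trial,
    design: ExperimentDesign,
    lam: float,
    utility: Utility = "prob",
) -> SpeakerPrediction:
    """S0 or S1 message distribution for one referent of a trial."""
    _check_lambda(lam)
    if level not in (0, 1):
        raise RefgameError(f"speaker level must be 0 or 1, got {level}")
    mat = _speaker_matrix(level, trial, design, lam, utility)
    i = ROLES.index(referent_role)
    return SpeakerPrediction(level, lam, dict(zip(design.messages(), mat[i])))


def listener_level(
    n: int,
    trial: Trial,
    design: ExperimentDesign,
    lam: float,
    utility: Utility = "prob",
) -> ListenerPrediction:
    """Listener prediction at recursion depth ``n`` in {0, 1, 2}."""
    _check_lambda(lam)
    if n == 0:
        return literal_listener(trial, design, lam)
    if n not in (1, 2):
        raise RefgameError(f"listener level must be in {{0, 1, 2}}, got {n}")
    messages = design.messages()
    try:
        j = messages.index(trial.message)
    except ValueError:
        raise RefgameError(
            f"message {trial.message} not expressible under {design.design_id}"
        ) from None
    s = _speaker_matrix(n - 1, trial, design, lam, utility)[:, j]
    p = _softmax(_as_utility(s, utility), lam)
    return ListenerPrediction(n, lam, dict(zip(ROLES, p)))


def predicted_accuracy_profile(
    n: int,
    design: ExperimentDesign,
    lam: float,
    n_trials: int = 200,
    seed: int = 0,
    utility: Utility = "prob",
) -> tuple[float, float]:
    """Mean P(target) on simple and complex trials for listener level ``n``.

    Averaged over freshly generated trials per condition; with symbolic
    stimuli the prediction is constant across instantiations of a given
    geometry, so a couple hundred trials is ample.
    """
    rng = np.random.default_rng(seed)
    out = []
    for condition in ("simple", "complex"):
        ps = [
            listener_level(
                n, generate_trial(condition, design, rng), design, lam, utility
            ).probs["target"]
            for _ in range(n_trials)
        ]
        out.append(float(np.mean(ps)))
    return out[0], out[1]
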