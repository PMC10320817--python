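"""Symbolic reference-game designs: features, referents, trials, sessions.

The game shows three objects, each combining one value from each of two
feature dimensions (creatures wearing accessories in the original stimuli,
shapes with colors in the abstract variant).  A message names a single
feature value; only *expressible* values are available as messages.  Trials
come in four conditions:

* ``unambiguous`` -- only the target carries the message feature (attention
  check).
* ``ambiguous``   -- target and competitor are identical objects; a random
  baseline.
* ``simple``      -- target and competitor both match the message, but the
  competitor's other feature is expressible (it has an unambiguous
  alternative message) while the target's other feature is inexpressible.
  One step of alternative-based reasoning identifies the target.
* ``complex``     -- as simple, except the target's other feature is
  expressible but shared with the distractor, so no unambiguous message for
  the target exists.  Two reasoning steps are required.

Four designs are provided: the original expressibility assignment
(``exp1``), the remapped assignment in which expressible and inexpressible
values are swapped within each dimension (``exp2_remapped``), a variant with
all six values expressible (``exp3_all_messages``), and a structurally
identical abstract-stimulus variant (``exp4_abstract``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("simple", "complex", "ambiguous", "unambiguous")
ROLES = ("target", "competitor", "distractor")
SLOTS = ("left", "center", "right")

#: session composition: 24 critical trials (12 simple, 12 complex) plus
#: 42 fillers (33 unambiguous, 9 ambiguous) = 66 trials.
SESSION_COUNTS = {"simple": 12, "complex": 12, "unambiguous": 33, "ambiguous": 9}

BIAS_STRATEGIES = ("visual_resemblance", "odd_one_out", "salience", "preference")


class RefgameError(Exception):
    """Base class for reference-game structural errors."""


class IllFormedTrialError(RefgameError):
    """Raised when a trial matches none of the four condition geometries."""


@dataclass(frozen=True)
class FeatureValue:
    """One value on one feature dimension (e.g. the red hat)."""

    dimension: str
    value: str

    def __str__(self) -> str:  # compact repr for logs and tables
        return f"{self.dimension}:{self.value}"


@dataclass(frozen=True)
class Referent:
    """An object on screen: one value from each of the two dimensions.

    Features are stored in lexicographic dimension order regardless of
    constructor-argument order, so referents compare by content.
    """

    feature_a: FeatureValue
    feature_b: FeatureValue

    def __post_init__(self) -> None:
        if self.feature_a.dimension == self.feature_b.dimension:
            raise RefgameError("referent needs one value from each dimension")
        if self.feature_a.dimension > self.feature_b.dimension:
            a, b = self.feature_a, self.feature_b
            object.__setattr__(self, "feature_a", b)
            object.__setattr__(self, "feature_b", a)

    def feature_on(self, dimension: str) -> FeatureValue:
        if self.feature_a.dimension == dimension:
            return self.feature_a
        if self.feature_b.dimension == dimension:
            return self.feature_b
        raise RefgameError(f"referent has no dimension {dimension!r}")

    @property
    def dimensions(self) -> tuple[str, str]:
        return (self.feature_a.dimension, self.feature_b.dimension)


def truth_of(message: FeatureValue, referent: Referent) -> bool:
    """Whether ``message`` is literally true of ``referent``.

    Raises :class:`RefgameError` when message and referent come from
    different inventories (no matching dimension).
    """
    return referent.feature_on(message.dimension) == message


@dataclass(frozen=True)
class ExperimentDesign:
    """Feature inventory, expressibility map and bias-alignment parameters.

    ``bias_alignment[strategy][condition]`` is the probability that the
    named non-pragmatic strategy's choice lands on the target in that
    condition.  ``template_id`` names the design whose expressibility
    defines the *trial geometry*; it differs from ``design_id`` only for
    the all-messages design, whose trials are built (and labeled) from the
    original template even though every value is expressible at test time.
    """

    design_id: str
    dimensions: tuple[str, str]
    inventory: Mapping[str, tuple[str, ...]]
    expressible: frozenset[FeatureValue]
    bias_alignment: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    template_id: str | None = None

    def __post_init__(self) -> None:
        for dim in self.dimensions:
            if len(self.inventory[dim]) != 3:
                raise RefgameError(f"dimension {dim!r} must have exactly 3 values")
            if len(set(self.inventory[dim])) != 3:
                raise RefgameError(f"duplicate value ids on dimension {dim!r}")
        for fv in self.expressible:
            if fv.value not in self.inventory[fv.dimension]:
                raise RefgameError(f"expressible value {fv} not in inventory")
        for strat, by_cond in self.bias_alignment.items():
            for cond, p in by_cond.items():
                if not 0.0 <= p <= 1.0:
                    raise RefgameError(
                        f"bias_alignment[{strat}][{cond}]={p} outside [0, 1]"
                    )

    # -- inventory helpers -------------------------------------------------
    def values(self, dimension: str) -> tuple[FeatureValue, ...]:
        return tuple(FeatureValue(dimension, v) for v in self.inventory[dimension])

    def all_values(self) -> tuple[FeatureValue, ...]:
        return self.values(self.dimensions[0]) + self.values(self.dimensions[1])

    def is_expressible(self, fv: FeatureValue) -> bool:
        return fv in self.expressible

    def expressible_on(self, dimension: str) -> tuple[FeatureValue, ...]:
        return tuple(fv for fv in self.values(dimension) if self.is_expressible(fv))

    def inexpressible_on(self, dimension: str) -> tuple[FeatureValue, ...]:
        return tuple(
            fv for fv in self.values(dimension) if not self.is_expressible(fv)
        )

    def messages(self) -> tuple[FeatureValue, ...]:
        """Expressible messages in a stable order."""
        return tuple(fv for fv in self.all_values() if self.is_expressible(fv))

    def other_dimension(self, dimension: str) -> str:
        a, b = self.dimensions
        return b if dimension == a else a

    @property
    def template(self) -> "ExperimentDesign":
        """Design whose expressibility defines the trial geometry."""
        if self.template_id is None or self.template_id == self.design_id:
            return self
        return get_design(self.template_id)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "design_id": self.design_id,
            "dimensions": list(self.dimensions),
            "inventory": {d: list(v) for d, v in self.inventory.items()},
            "expressible": sorted([fv.dimension, fv.value] for fv in self.expressible),
            "bias_alignment": {
                s: dict(c) for s, c in self.bias_alignment.items()
            },
            "template_id": self.template_id,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentDesign":
        return cls(
            design_id=d["design_id"],
            dimensions=tuple(d["dimensions"]),
            inventory={k: tuple(v) for k, v in d["inventory"].items()},
            expressible=frozenset(
                FeatureValue(dim, val) for dim, val in d["expressible"]
            ),
            bias_alignment={s: dict(c) for s, c in d.get("bias_alignment", {}).items()},
            template_id=d.get("template_id"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ExperimentDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class Trial:
    """One display: a message plus three role-labeled referents on slots."""

    message: FeatureValue
    target: Referent
    competitor: Referent
    distractor: Referent
    positions: Mapping[str, str]  # role -> slot
    condition: str
    trial_index: int = 1

    def __post_init__(self) -> None:
        if set(self.positions) != set(ROLES) or set(self.positions.values()) != set(
            SLOTS
        ):
            raise RefgameError("positions must be a bijection roles -> slots")
        if self.condition not in CONDITIONS:
            raise RefgameError(f"unknown condition {self.condition!r}")

    def referent(self, role: str) -> Referent:
        return {"target": self.target, "competitor": self.competitor,
                "distractor": self.distractor}[role]

    @property
    def referents(self) -> tuple[Referent, Referent, Referent]:
        return (self.target, self.competitor, self.distractor)

    def role_at(self, slot: str) -> str:
        for role, s in self.positions.items():
            if s == slot:
                return role
        raise RefgameError(f"unknown slot {slot!r}")


@dataclass(frozen=True)
class Session:
    """An ordered 66-trial session for one participant."""

    design_id: str
    participant_id: str
    seed: int
    trials: tuple[Trial, ...]

    def condition_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CONDITIONS}
        for t in self.trials:
            counts[t.condition] += 1
        return counts


# ---------------------------------------------------------------------------
# condition classification
# ---------------------------------------------------------------------------

def classify_condition(trial: Trial, design: ExperimentDesign) -> str:
    """Label a trial's condition from its geometry under ``design``.

    The classification is purely structural: it asks which referents the
    message is true of, whether target and competitor are identical, and
    whether the non-message features leave an unambiguous alternative
    message for the competitor but not for the target.
    """
    design = design.template
    m = trial.message
    if not design.is_expressible(m):
        raise IllFormedTrialError(f"message {m} is not expressible under {design.design_id}")
    t, c, d = trial.target, trial.competitor, trial.distractor
    matches = [truth_of(m, r) for r in (t, c, d)]
    if not matches[0]:
        raise IllFormedTrialError("message is not true of the target")
    if sum(matches) == 1:
        return "unambiguous"
    if matches[2] and sum(matches) == 3:
        raise IllFormedTrialError("message true of all three referents")
    if matches[2]:
        raise IllFormedTrialError("message true of target and distractor only")
    # target and competitor both match
    if t == c:
        return "ambiguous"
    other_dim = design.other_dimension(m.dimension)
    t_other = t.feature_on(other_dim)
    c_other = c.feature_on(other_dim)
    competitor_unambiguous = (
        design.is_expressible(c_other)
        and t.feature_on(other_dim) != c_other
        and d.feature_on(other_dim) != c_other
    )
    if not competitor_unambiguous:
        raise IllFormedTrialError("competitor lacks an unambiguous alternative message")
    if not design.is_expressible(t_other):
        return "simple"
    if d.feature_on(other_dim) == t_other:
        return "complex"
    raise IllFormedTrialError(
        "target has an unambiguous alternative message; not a critical geometry"
    )


# ---------------------------------------------------------------------------
# trial and session generation
# ---------------------------------------------------------------------------

def _random_positions(rng: np.random.Generator) -> dict[str, str]:
    slots = list(SLOTS)
    rng.shuffle(slots)
    return dict(zip(ROLES, slots))


def _choice(rng: np.random.Generator, items: Sequence):
    return items[int(rng.integers(len(items)))]


def generate_trial(
    condition: str,
    design: ExperimentDesign,
    rng: np.random.Generator,
    message_dimension: str | None = None,
    trial_index: int = 1,
) -> Trial:
    """Sample a concrete trial realizing ``condition`` under ``design``.

    Feature assignments consistent with the condition geometry are sampled
    uniformly; the constructive inverse of :func:`classify_condition`.  For
    the all-messages design the geometry (and the returned condition label)
    follow the original template.
    """
    geom = design.template
    if condition not in CONDITIONS:
        raise RefgameError(f"unknown condition {condition!r}")
    dim = message_dimension or _choice(rng, geom.dimensions)
    other = geom.other_dimension(dim)
    o_vals = geom.values(other)

    if condition in ("simple", "complex"):
        if not (geom.inexpressible_on(other) and len(geom.expressible_on(other)) >= 2):
            raise RefgameError(
                f"condition {condition!r} not realizable under {geom.design_id}"
            )
        m = _choice(rng, geom.expressible_on(dim))
        e_pair = list(geom.expressible_on(other))
        rng.shuffle(e_pair)
        if condition == "simple":
            t_other = geom.inexpressible_on(other)[0]
            c_other, d_other = e_pair
        else:  # complex: target's other feature shared with the distractor
            t_other, c_other = e_pair
            d_other = t_other
        d_msg = _choice(rng, [v for v in geom.values(dim) if v != m])
        target = Referent(m, t_other)
        competitor = Referent(m, c_other)
        distractor = Referent(d_msg, d_other)
    elif condition == "ambiguous":
        m = _choice(rng, geom.expressible_on(dim))
        shared_other = _choice(rng, o_vals)
        target = competitor = Referent(m, shared_other)
        d_msg = _choice(rng, [v for v in geom.values(dim) if v != m])
        d_other = _choice(rng, o_vals)
        distractor = Referent(d_msg, d_other)
    else:  # unambiguous: only the target carries the message feature
        m = _choice(rng, geom.expressible_on(dim))
        non_m = [v for v in geom.values(dim) if v != m]
        target = Referent(m, _choice(rng, o_vals))
        competitor = Referent(_choice(rng, non_m), _choice(rng, o_vals))
        distractor = Referent(_choice(rng, non_m), _choice(rng, o_vals))

    trial = Trial(
        message=m,
        target=target,
        competitor=competitor,
        distractor=distractor,
        positions=_random_positions(rng),
        condition=condition,
        trial_index=trial_index,
    )
    assert classify_condition(trial, geom) == condition
    return trial


def generate_session(
    design: ExperimentDesign, participant_id: str = "p0", seed: int = 0
) -> Session:
    """Generate one 66-trial session: 12 simple, 12 complex, 33 unambiguous
    and 9 ambiguous trials in seeded-random order.

    Message dimensions are balanced within each condition (6/6 for the
    critical conditions; as close to even as the filler counts allow), and
    role-to-slot assignment is uniform per trial.
    """
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    for condition, n in SESSION_COUNTS.items():
        dims = [design.dimensions[i % 2] for i in range(n)]
        for d in dims:
            trials.append(generate_trial(condition, design, rng, message_dimension=d))
    order = rng.permutation(len(trials))
    ordered = tuple(
        replace(trials[j], trial_index=i + 1) for i, j in enumerate(order)
    )
    return Session(
        design_id=design.design_id,
        participant_id=participant_id,
        seed=seed,
        trials=ordered,
    )


# ---------------------------------------------------------------------------
# remapping (expressibility swap)
# ---------------------------------------------------------------------------

def _check_swap(design: ExperimentDesign, swap: Mapping[FeatureValue, FeatureValue]):
    by_dim: dict[str, dict] = {d: {} for d in design.dimensions}
    for src, dst in swap.items():
        if src.dimension != dst.dimension:
            raise RefgameError("swap must stay within a dimension")
        by_dim[src.dimension][src] = dst
    full: dict[FeatureValue, FeatureValue] = {}
    for dim in design.dimensions:
        mapping = dict(by_dim[dim])
        for fv in design.values(dim):
            mapping.setdefault(fv, fv)
        if set(mapping.values()) != set(design.values(dim)):
            raise RefgameError(f"swap is not a bijection on dimension {dim!r}")
        full.update(mapping)
    return full


def remap_design(
    design: ExperimentDesign,
    swap: Mapping[FeatureValue, FeatureValue],
    design_id: str | None = None,
) -> ExperimentDesign:
    """Transport expressibility through a within-dimension bijection.

    A value is expressible in the remapped design iff its swap pre-image was
    expressible in the original, so the remapped design is isomorphic to the
    original: condition labels and message-truth matrices are preserved under
    the joint remap of design and trial.
    """
    full = _check_swap(design, swap)
    new_expr = frozenset(full[fv] for fv in design.expressible)
    return replace(
        design,
        design_id=design_id or f"{design.design_id}_remapped",
        expressible=new_expr,
        template_id=None,
    )


def remap_trial(trial: Trial, design: ExperimentDesign,
                swap: Mapping[FeatureValue, FeatureValue]) -> Trial:
    """Apply the swap to a trial's message and every referent's features."""
    full = _check_swap(design, swap)

    def _ref(r: Referent) -> Referent:
        return Referent(full[r.feature_a], full[r.feature_b])

    return replace(
        trial,
        message=full[trial.message],
        target=_ref(trial.target),
        competitor=_ref(trial.competitor),
        distractor=_ref(trial.distractor),
    )


# ---------------------------------------------------------------------------
# built-in designs
# ---------------------------------------------------------------------------

_CREATURE = "creature"
_ACCESSORY = "accessory"
_INV_ORIG = {
    _CREATURE: ("green_monster", "purple_monster", "robot"),
    _ACCESSORY: ("red_hat", "blue_hat", "scarf"),
}

#: Bias-alignment defaults: P(strategy lands on the target | condition).
#: Only visual_resemblance is quantified by annotation data (≈0.87 on the
#: original stimuli in the simple condition, deflated to ≈0.25 on the
#: remapped stimuli); the rest are configurable mild defaults, with the
#: odd-one-out strategy pointing away from the target (it typically selects
#: the distractor on the original stimuli) and everything neutral (0.5) on
#: the abstract stimuli.
_BIAS_ORIG = {
    "visual_resemblance": {"simple": 0.87, "complex": 0.55},
    "odd_one_out": {"simple": 0.30, "complex": 0.35},
    "salience": {"simple": 0.80, "complex": 0.50},
    "preference": {"simple": 0.50, "complex": 0.50},
}
_BIAS_REMAPPED = {
    "visual_resemblance": {"simple": 0.25, "complex": 0.40},
    "odd_one_out": {"simple": 0.25, "complex": 0.35},
    "salience": {"simple": 0.30, "complex": 0.50},
    "preference": {"simple": 0.50, "complex": 0.50},
}
_BIAS_NEUTRAL = {
    s: {"simple": 0.50, "complex": 0.50} for s in BIAS_STRATEGIES
}


def _fv(dim: str, val: str) -> FeatureValue:
    return FeatureValue(dim, val)


EXP1 = ExperimentDesign(
    design_id="exp1",
    dimensions=(_CREATURE, _ACCESSORY),
    inventory=_INV_ORIG,
    expressible=frozenset(
        {
            _fv(_CREATURE, "green_monster"),
            _fv(_CREATURE, "purple_monster"),
            _fv(_ACCESSORY, "red_hat"),
            _fv(_ACCESSORY, "blue_hat"),
        }
    ),
    bias_alignment=_BIAS_ORIG,
)

#: swap used by the remapped design: robot <-> purple monster,
#: scarf <-> blue hat (the expressible/inexpressible exchange).
EXP2_SWAP = {
    _fv(_CREATURE, "robot"): _fv(_CREATURE, "purple_monster"),
    _fv(_CREATURE, "purple_monster"): _fv(_CREATURE, "robot"),
    _fv(_ACCESSORY, "scarf"): _fv(_ACCESSORY, "blue_hat"),
    _fv(_ACCESSORY, "blue_hat"): _fv(_ACCESSORY, "scarf"),
}

EXP2 = replace(
    remap_design(EXP1, EXP2_SWAP, design_id="exp2_remapped"),
    bias_alignment=_BIAS_REMAPPED,
)

EXP3 = ExperimentDesign(
    design_id="exp3_all_messages",
    dimensions=(_CREATURE, _ACCESSORY),
    inventory=_INV_ORIG,
    expressible=frozenset(
        _fv(d, v) for d, vs in _INV_ORIG.items() for v in vs
    ),
    bias_alignment=_BIAS_ORIG,
    template_id="exp1",
)

EXP4 = ExperimentDesign(
    design_id="exp4_abstract",
    dimensions=("shape", "color"),
    inventory={
        # square/triangle/circle stand in for robot/green/purple monster,
        # blue/green/red for scarf/red hat/blue hat.
        "shape": ("triangle", "circle", "square"),
        "color": ("green", "red", "blue"),
    },
    expressible=frozenset(
        {
            _fv("shape", "triangle"),
            _fv("shape", "circle"),
            _fv("color", "green"),
            _fv("color", "red"),
        }
    ),
    bias_alignment=_BIAS_NEUTRAL,
)

DESIGNS: dict[str, ExperimentDesign] = {
    d.design_id: d for d in (EXP1, EXP2, EXP3, EXP4)
}


def get_design(design_id: str) -> ExperimentDesign:
    try:
        return DESIGNS[design_id]
    except KeyError:
        raise RefgameError(
            f"unknown design {design_id!r}; available: {sorted(DESIGNS)}"
        ) from None


# ---------------------------------------------------------------------------
# trial-table I/O (long format, 3 rows per trial)
# ---------------------------------------------------------------------------

def session_to_frame(session: Session) -> pd.DataFrame:
    rows = []
    for t in session.trials:
        for role in ROLES:
            r = t.referent(role)
            rows.append(
                {
                    "session_id": session.participant_id,
                    "trial_index": t.trial_index,
                    "condition": t.condition,
                    "message_dimension": t.message.dimension,
                    "message_value": t.message.value,
                    "role": role,
                    "feature_a": r.feature_a.value,
                    "feature_b": r.feature_b.value,
                    "position": t.positions[role],
                }
            )
    return pd.DataFrame(rows)


def frame_to_trials(frame: pd.DataFrame, design: ExperimentDesign) -> list[Trial]:
    """Rebuild trials from a long-format trial table."""
    dim_a, dim_b = sorted(design.dimensions)
    trials = []
    for (_, idx), grp in frame.groupby(["session_id", "trial_index"], sort=True):
        by_role = {row["role"]: row for _, row in grp.iterrows()}
        refs = {
            role: Referent(
                FeatureValue(dim_a, by_role[role]["feature_a"]),
                FeatureValue(dim_b, by_role[role]["feature_b"]),
            )
            for role in ROLES
        }
        first = grp.iloc[0]
        trials.append(
            Trial(
                message=FeatureValue(
                    first["message_dimension"], first["message_value"]
                ),
                target=refs["target"],
                competitor=refs["competitor"],
                distractor=refs["distractor"],
                positions={role: by_role[role]["position"] for role in ROLES},
                condition=first["condition"],
                trial_index=int(idx),
            )
        )
    return trials
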