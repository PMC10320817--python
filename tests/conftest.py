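import numpy as np
import pytest

from refgame.design import FeatureValue, Referent, Trial, get_design

C, A = "creature", "accessory"
RED = FeatureValue(A, "red_hat")
_POS = {"target": "left", "competitor": "center", "distractor": "right"}


def make_trial(message, target, competitor, distractor, condition,
               positions=None):
    """Build a trial from ((creature, accessory), ...) tuples."""

    def ref(pair):
        return Referent(FeatureValue(C, pair[0]), FeatureValue(A, pair[1]))

    return Trial(
        message=message,
        target=ref(target),
        competitor=ref(competitor),
        distractor=ref(distractor),
        positions=positions or dict(_POS),
        condition=condition,
    )


@pytest.fixture(scope="session")
def exp1():
    return get_design("exp1")


@pytest.fixture(scope="session")
def exp2():
    return get_design("exp2_remapped")


@pytest.fixture(scope="session")
def exp3():
    return get_design("exp3_all_messages")


@pytest.fixture(scope="session")
def exp4():
    return get_design("exp4_abstract")


@pytest.fixture
def simple_trial():
    """The canonical simple item: robot and green monster share the red
    hat; the robot (inexpressible creature) is the target."""
    return make_trial(
        RED, ("robot", "red_hat"), ("green_monster", "red_hat"),
        ("purple_monster", "scarf"), "simple",
    )


@pytest.fixture
def complex_trial():
    """The canonical complex item: the purple-monster target shares its
    creature with the distractor, so it has no unambiguous message."""
    return make_trial(
        RED, ("purple_monster", "red_hat"), ("green_monster", "red_hat"),
        ("purple_monster", "scarf"), "complex",
    )


@pytest.fixture
def ambiguous_trial():
    return make_trial(
        FeatureValue(C, "purple_monster"),
        ("purple_monster", "blue_hat"), ("purple_monster", "blue_hat"),
        ("robot", "red_hat"), "ambiguous",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
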