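"""Independent brute-force oracle for the quantal-response listener recursion.

Deliberately written with plain Python floats, dicts and lists -- no shared
code with the package -- so it can serve as an independent cross-check of
the vectorized implementation.  Referents are (value, value) tuples and
messages are bare value strings; truth is set membership.
"""

import math


def _norm(weights):
    z = sum(weights)
    return [w / z for w in weights]


def oracle_L0(message, referents, lam):
    true_idx = [i for i, r in enumerate(referents) if message in r]
    n = len(true_idx)
    utils = [(1.0 / n if i in true_idx else 0.0) if n else 0.0
             for i in range(len(referents))]
    return _norm([math.exp(lam * u) for u in utils])


def oracle_S0(referent, messages, lam):
    true_msgs = [m for m in messages if m in referent]
    n = len(true_msgs)
    utils = {m: ((1.0 / n) if m in true_msgs else 0.0) if n else 0.0
             for m in messages}
    weights = {m: math.exp(lam * utils[m]) for m in messages}
    z = sum(weights.values())
    return {m: w / z for m, w in weights.items()}


def oracle_S1(ref_index, referents, messages, lam):
    utils = {m: oracle_L0(m, referents, lam)[ref_index] for m in messages}
    weights = {m: math.exp(lam * utils[m]) for m in messages}
    z = sum(weights.values())
    return {m: w / z for m, w in weights.items()}


def oracle_listener(level, message, referents, messages, lam):
    """Listener distribution over referents at recursion depth 0, 1 or 2."""
    if level == 0:
        return oracle_L0(message, referents, lam)
    if level == 1:
        utils = [oracle_S0(r, messages, lam)[message] for r in referents]
    elif level == 2:
        utils = [oracle_S1(i, referents, messages, lam)[message]
                 for i in range(len(referents))]
    else:
        raise ValueError(level)
    return _norm([math.exp(lam * u) for u in utils])
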