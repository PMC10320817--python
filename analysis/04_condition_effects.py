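"""Condition effects and the ambiguous-baseline randomization study.

For each design's simulated population: code the ambiguous baseline with
the forced-even split, estimate the dummy-coded condition effects (complex
as reference), and run the 100-recoding variance study comparing coin-flip
against forced-even coding.  The coin-flip method always shows at least as
much dispersion in the ambiguous-vs-complex effect; the forced-even
estimate is constant across recodings.  Expects the response tables under
scratch/ from 03_simulate_population.py; writes
results/condition_effects.csv and results/variance_study.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from refgame.analysis import (
    code_ambiguous,
    estimate_condition_effects,
    randomization_variance_study,
)
from refgame.io import read_responses

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

effect_rows, variance_rows = [], []
for path in sorted((ROOT / "scratch").glob("responses_*.csv")):
    design_id = path.stem.removeprefix("responses_")
    responses = read_responses(path)
    rng = np.random.default_rng(1)
    coded = code_ambiguous(responses, "forced_even", rng)
    eff = estimate_condition_effects(coded)
    for term in ("simple_vs_complex", "ambiguous_vs_complex"):
        effect_rows.append({
            "design": design_id, "term": term,
            "beta": round(eff.beta[term], 3), "se": round(eff.se[term], 3),
            "ci_low": round(eff.ci_low[term], 3),
            "ci_high": round(eff.ci_high[term], 3),
            "significant": eff.significant(term),
        })
    vs = randomization_variance_study(responses, n_runs=100, rng=rng)
    vs.insert(0, "design", design_id)
    variance_rows.append(vs)

effects = pd.DataFrame(effect_rows)
variance = pd.concat(variance_rows, ignore_index=True)
effects.to_csv(OUT / "condition_effects.csv", index=False)
variance.to_csv(OUT / "variance_study.csv", index=False)
print(effects.to_string(index=False))
print()
print(variance.to_string(index=False))
ok = (variance.pivot(index="design", columns="method", values="sd_beta")
      .eval("coinflip >= forced_even").all())
print(f"\ncoin-flip dispersion >= forced-even on every design: {ok}")
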