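"""I/O and pipeline glue: response tables, run configs, artifact bundles.

CSV tables are comma-separated UTF-8 with a header row and no index
column.  Every pipeline run writes its resolved configuration next to its
outputs so results are reproducible from the config and seeds alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import analysis
from .design import RefgameError, get_design
from .simulate import PopulationSpec, RESPONSE_COLUMNS, simulate_dataset

log = logging.getLogger("refgame")


def read_responses(path) -> pd.DataFrame:
    """Read a response table, validating the documented header.

    Unknown columns are preserved.  A missing required column raises an
    error naming it; a malformed row raises with its line number.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise RefgameError(f"malformed response CSV {path}: {exc}") from exc
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise RefgameError(
            f"response table {path} is missing required column(s): "
            + ", ".join(missing)
        )
    for i, (_, row) in enumerate(df.iterrows(), start=2):
        if row["chosen_role"] not in ("target", "competitor", "distractor"):
            raise RefgameError(
                f"{path} line {i}: bad chosen_role {row['chosen_role']!r}"
            )
    log.info("read %d response rows from %s", len(df), path)
    return df


def write_responses(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one end-to-end pipeline run."""

    design_id: str = "exp1"
    n_participants: int = 60
    mixture: Mapping[str, float] | None = None
    lam: float = 5.0
    lapse_rate: float = 0.02
    position_bias: tuple[float, float] = (0.5, 0.5)
    coding: str = "forced_even"
    seed: int = 0
    out_dir: str = "results/run"

    def population(self) -> PopulationSpec:
        kwargs = dict(
            n_participants=self.n_participants,
            design_id=self.design_id,
            lam=self.lam,
            lapse_rate=self.lapse_rate,
            position_bias=self.position_bias,
            seed=self.seed,
        )
        if self.mixture is not None:
            kwargs["mixture"] = dict(self.mixture)
        return PopulationSpec(**kwargs)

    def to_dict(self) -> dict:
        d = {
            "design_id": self.design_id,
            "n_participants": self.n_participants,
            "mixture": dict(self.mixture) if self.mixture is not None else None,
            "lam": self.lam,
            "lapse_rate": self.lapse_rate,
            "position_bias": list(self.position_bias),
            "coding": self.coding,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "position_bias" in d:
            d["position_bias"] = tuple(d["position_bias"])
        return cls(**d)


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """generate -> simulate -> code -> analyze, in order.

    Returns the artifact bundle as a dict (response table, accuracies,
    condition effects, variance study, class assignments, metrics) and,
    when ``write`` is set, saves the tables plus a ``metrics.json`` and the
    resolved config under ``config.out_dir``.
    """
    stage = "configure"
    try:
        design = get_design(config.design_id)
        pop = config.population()
        rng = np.random.default_rng(config.seed)

        stage = "simulate"
        log.info("simulating %d participants under %s (seed=%d)",
                 pop.n_participants, design.design_id, config.seed)
        responses = simulate_dataset(pop)

        stage = "code"
        coded = analysis.code_ambiguous(responses, config.coding, rng)

        stage = "analyze"
        acc = analysis.accuracy_by_condition(coded)
        effects = analysis.estimate_condition_effects(coded)
        variance = analysis.randomization_variance_study(responses, rng=rng)
        truth = responses.groupby("participant_id")["strategy"].first()
        acc = acc.assign(strategy=truth.reindex(acc["participant_id"]).to_numpy())
        acc["class_nearest"] = [
            analysis.classify_nearest_profile(s, c)
            for s, c in zip(acc["acc_simple"], acc["acc_complex"])
        ]
        acc["class_strategy"] = acc["strategy"].map(analysis.STRATEGY_CLASS)
        h, c = analysis.homogeneity_completeness(
            acc["class_strategy"], acc["class_nearest"]
        )
        metrics = {
            "design_id": config.design_id,
            "seed": config.seed,
            "n_participants": int(acc.shape[0]),
            "n_excluded": int(acc["exclude"].sum()),
            "distractor_rate": float((responses["chosen_role"] == "distractor").mean()),
            "effects": {
                "beta": dict(effects.beta),
                "se": dict(effects.se),
                "ci_low": dict(effects.ci_low),
                "ci_high": dict(effects.ci_high),
            },
            "variance_study": variance.to_dict(orient="records"),
            "homogeneity": h,
            "completeness": c,
        }
    except Exception as exc:
        raise RefgameError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    bundle = {
        "responses": coded,
        "accuracies": acc,
        "effects": effects,
        "variance_study": variance,
        "metrics": metrics,
    }
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_responses(coded, out / "responses.csv")
        acc.to_csv(out / "participants.csv", index=False)
        variance.to_csv(out / "variance_study.csv", index=False)
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2)
        with open(out / "config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2)
        log.info("wrote bundle to %s", out)
    return bundle
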