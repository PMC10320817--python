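"""Analysis pipeline: baseline coding, condition effects, contingency and
agreement statistics, latent-profile clustering, and type recovery.

The pipeline mirrors a standard reference-game analysis.  Correctness on
fully ambiguous trials (two identical referents) is not observable and must
be *assigned*; two randomization methods are provided -- independent
coin-flips per trial versus forcing an exactly even split -- together with a
variance study quantifying how the choice of method propagates into the
ambiguous-vs-complex condition effect.  Condition effects are estimated by
maximum-likelihood logistic regression with dummy-coded conditions (complex
as reference level); with no covariates the estimates reduce to closed-form
logit differences of pooled condition accuracies.  Individual-level
structure is recovered by latent profile analysis (a diagonal-covariance
Gaussian mixture on per-participant simple/complex accuracies) and by a
nearest-profile classifier against the canonical listener profiles
L0 = (0.5, 0.5), L1 = (1, 0.5), L2 = (1, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score, completeness_score, homogeneity_score
from sklearn.mixture import GaussianMixture

from .design import RefgameError
from .simulate import PopulationSpec, RSA_STRATEGIES, simulate_dataset

CLASSES = ("L0", "L1", "L2", "other")
#: canonical accuracy profiles (simple, complex) of the three listener types
PROFILES = {"L0": (0.5, 0.5), "L1": (1.0, 0.5), "L2": (1.0, 1.0)}

#: expected performance class for each simulated strategy
STRATEGY_CLASS = {
    "rsa_L0": "L0",
    "rsa_L1": "L1",
    "rsa_L2": "L2",
    "guess": "L0",
    "visual_resemblance": "other",
    "odd_one_out": "other",
    "salience": "other",
    "preference": "other",
}

Z95 = float(stats.norm.ppf(0.975))


# ---------------------------------------------------------------------------
# ambiguous-baseline coding
# ---------------------------------------------------------------------------

def code_ambiguous(
    responses: pd.DataFrame, method: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill in correctness for ambiguous trials.

    ``coinflip`` codes each ambiguous non-distractor response correct
    independently with probability 1/2; ``forced_even`` codes exactly
    ``floor(k/2)`` of the ``k`` ambiguous non-distractor responses correct
    (a uniformly random subset).  Distractor responses are coded incorrect
    under both methods.  Returns a copy; non-ambiguous rows are untouched.
    """
    if method not in ("coinflip", "forced_even"):
        raise RefgameError(f"unknown coding method {method!r}")
    out = responses.copy()
    ambig = out["condition"] == "ambiguous"
    distractor = out["chosen_role"] == "distractor"
    out.loc[ambig & distractor, "correct"] = 0.0
    idx = out.index[ambig & ~distractor]
    k = len(idx)
    if k == 0:
        return out
    if method == "coinflip":
        out.loc[idx, "correct"] = (rng.random(k) < 0.5).astype(float)
    else:
        correct = np.zeros(k)
        correct[: k // 2] = 1.0
        rng.shuffle(correct)
        out.loc[idx, "correct"] = correct
    return out


# ---------------------------------------------------------------------------
# accuracies and exclusion flags
# ---------------------------------------------------------------------------

def accuracy_by_condition(
    responses: pd.DataFrame,
    exclude_distractors: bool = True,
    attention_threshold: float = 0.8,
) -> pd.DataFrame:
    """Per-participant mean accuracy in each condition.

    Distractor-chosen trials are dropped before averaging when
    ``exclude_distractors`` is set.  A participant with no retained trial in
    some condition gets NaN there (flagged, never silently zero), and
    participants whose unambiguous accuracy falls below the attention
    threshold are marked for exclusion.
    """
    df = responses
    if exclude_distractors:
        df = df[df["chosen_role"] != "distractor"]
    acc = (
        df.pivot_table(
            index="participant_id",
            columns="condition",
            values="correct",
            aggfunc="mean",
        )
        .reindex(columns=["simple", "complex", "ambiguous", "unambiguous"])
        .add_prefix("acc_")
    )
    # participants who vanished entirely (e.g. all-distractor responders)
    everyone = responses["participant_id"].unique()
    acc = acc.reindex(everyone)
    acc["exclude"] = ~(acc["acc_unambiguous"] >= attention_threshold)
    return acc.reset_index().rename(columns={"index": "participant_id"})


# ---------------------------------------------------------------------------
# condition effects (dummy-coded logistic regression)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectEstimates:
    """Log-odds condition effects with complex as the reference level."""

    beta: Mapping[str, float]
    se: Mapping[str, float]
    ci_low: Mapping[str, float]
    ci_high: Mapping[str, float]
    n: int

    def significant(self, term: str) -> bool:
        """95% Wald interval excludes zero."""
        return self.ci_low[term] > 0 or self.ci_high[term] < 0


def _logit(p: float) -> float:
    return float(np.log(p) - np.log1p(-p))


def estimate_condition_effects(
    responses: pd.DataFrame,
    conditions: Sequence[str] = ("simple", "complex", "ambiguous"),
    reference: str = "complex",
) -> EffectEstimates:
    """ML logistic regression of correctness on dummy-coded condition.

    With condition dummies as the only predictors the MLE has the closed
    form ``beta_c = logit(p_c) - logit(p_reference)`` with Wald standard
    error ``sqrt(sum of reciprocal success/failure counts)``; that identity
    is used directly.  Distractor trials are excluded; a condition pooled at
    0 or 1 produces an infinite estimate and a warning (separation).
    """
    df = responses[responses["chosen_role"] != "distractor"]
    df = df[df["condition"].isin(conditions)].dropna(subset=["correct"])
    succ: dict[str, float] = {}
    fail: dict[str, float] = {}
    for cond in conditions:
        sub = df[df["condition"] == cond]
        if len(sub) == 0:
            raise RefgameError(f"no retained trials in condition {cond!r}")
        succ[cond] = float(sub["correct"].sum())
        fail[cond] = float(len(sub) - sub["correct"].sum())
        if succ[cond] == 0 or fail[cond] == 0:
            warnings.warn(
                f"separation: condition {cond!r} pooled at "
                f"{succ[cond] / len(sub):.0%}; estimate is infinite",
                RuntimeWarning,
                stacklevel=2,
            )

    def logit_counts(cond: str) -> float:
        if succ[cond] == 0:
            return -np.inf
        if fail[cond] == 0:
            return np.inf
        return float(np.log(succ[cond] / fail[cond]))

    beta = {"intercept": logit_counts(reference)}
    se = {
        "intercept": float(np.sqrt(1 / succ[reference] + 1 / fail[reference]))
        if np.isfinite(beta["intercept"])
        else np.inf
    }
    for cond in conditions:
        if cond == reference:
            continue
        term = f"{cond}_vs_{reference}"
        beta[term] = logit_counts(cond) - logit_counts(reference)
        if np.isfinite(beta[term]):
            se[term] = float(
                np.sqrt(
                    1 / succ[cond]
                    + 1 / fail[cond]
                    + 1 / succ[reference]
                    + 1 / fail[reference]
                )
            )
        else:
            se[term] = np.inf
    ci_low = {t: beta[t] - Z95 * se[t] for t in beta}
    ci_high = {t: beta[t] + Z95 * se[t] for t in beta}
    return EffectEstimates(beta=beta, se=se, ci_low=ci_low, ci_high=ci_high, n=len(df))


def randomization_variance_study(
    responses: pd.DataFrame,
    n_runs: int = 100,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Re-code the ambiguous baseline ``n_runs`` times per method and refit.

    Returns one row per method with the SD of the ambiguous-vs-complex
    effect across runs and the fraction of runs in which its 95% Wald
    interval excluded zero.  The coin-flip method lets the pooled ambiguous
    accuracy fluctuate binomially, so its dispersion is at least that of the
    forced-even split (which pins the pooled accuracy at floor(k/2)/k).
    """
    if n_runs < 2:
        raise RefgameError("variance study needs at least 2 runs")
    if not (responses["condition"] == "ambiguous").any():
        raise RefgameError("responses contain no ambiguous trials")
    rng = np.random.default_rng(0) if rng is None else rng
    term = "ambiguous_vs_complex"
    rows = []
    for method in ("coinflip", "forced_even"):
        betas, sig = [], []
        for _ in range(n_runs):
            coded = code_ambiguous(responses, method, rng)
            eff = estimate_condition_effects(coded)
            betas.append(eff.beta[term])
            sig.append(eff.significant(term))
        rows.append(
            {
                "method": method,
                "sd_beta": float(np.std(betas, ddof=1)),
                "mean_beta": float(np.mean(betas)),
                "significance_rate": float(np.mean(sig)),
                "n_runs": n_runs,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contingency and agreement statistics
# ---------------------------------------------------------------------------

def chisq_independence(table) -> tuple[float, int]:
    """Pearson chi-square of independence, no continuity correction.

    Returns ``(statistic, dof)`` with ``dof = (r - 1)(c - 1)``.
    """
    counts = np.asarray(table, dtype=float)
    if (counts < 0).any():
        raise RefgameError("contingency counts must be nonnegative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise RefgameError("zero marginal in contingency table")
    stat, _, dof, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(dof)


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> tuple[float, tuple[float, float]]:
    """Cohen's kappa with an asymptotic 95% confidence interval.

    ``kappa = (p_o - p_e) / (1 - p_e)``; the CI uses the large-sample
    standard error ``sqrt(p_o (1 - p_o) / (n (1 - p_e)^2))``.  Chance
    agreement of 1 leaves kappa undefined (NaN).
    """
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise RefgameError("label sequences must have equal length")
    n = len(a)
    conf = pd.crosstab(a, b).reindex(
        index=sorted(set(a) | set(b)), columns=sorted(set(a) | set(b)), fill_value=0
    ).to_numpy(dtype=float)
    p_o = np.trace(conf) / n
    p_e = float((conf.sum(axis=1) * conf.sum(axis=0)).sum()) / n**2
    if p_e == 1.0:
        warnings.warn("chance agreement is 1; kappa undefined", RuntimeWarning)
        return float("nan"), (float("nan"), float("nan"))
    kappa = (p_o - p_e) / (1 - p_e)
    se = np.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2))
    return float(kappa), (float(kappa - Z95 * se), float(kappa + Z95 * se))


# ---------------------------------------------------------------------------
# latent profile analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureFit:
    """A fitted K-component diagonal Gaussian mixture on accuracy profiles."""

    K: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    aic: float
    bic: float
    responsibilities: np.ndarray = field(repr=False)

    @property
    def n_parameters(self) -> int:
        d = self.means.shape[1]
        return self.K * 2 * d + (self.K - 1)


def fit_latent_profiles(
    accuracies: pd.DataFrame,
    K_range: Iterable[int] = range(1, 7),
    n_init: int = 20,
    variance_floor: float = 1e-4,
    seed: int = 0,
) -> tuple[dict[int, MixtureFit], int, int]:
    """Latent profile analysis on (acc_simple, acc_complex).

    Fits a diagonal-covariance Gaussian mixture by EM with ``n_init`` seeded
    restarts for each K, computes AIC and BIC, and returns
    ``(fits, K_bic, K_aic)`` -- model selection is by BIC, with the
    AIC-selected K reported alongside since the two can disagree.
    """
    X = accuracies[["acc_simple", "acc_complex"]].dropna().to_numpy()
    K_range = list(K_range)
    if len(X) < max(K_range) * 2:
        raise RefgameError(
            f"need at least {max(K_range) * 2} participants for K={max(K_range)}"
        )
    fits: dict[int, MixtureFit] = {}
    for K in K_range:
        gm = GaussianMixture(
            n_components=K,
            covariance_type="diag",
            n_init=n_init,
            reg_covar=variance_floor,
            random_state=seed,
        ).fit(X)
        ll = float(gm.score(X) * len(X))
        fits[K] = MixtureFit(
            K=K,
            means=gm.means_,
            variances=gm.covariances_,
            weights=gm.weights_,
            log_likelihood=ll,
            aic=float(gm.aic(X)),
            bic=float(gm.bic(X)),
            responsibilities=gm.predict_proba(X),
        )
    K_bic = min(fits, key=lambda K: fits[K].bic)
    K_aic = min(fits, key=lambda K: fits[K].aic)
    return fits, K_bic, K_aic


def classify_nearest_profile(
    acc_simple: float, acc_complex: float, margin: float = 0.25
) -> str:
    """Assign the nearest canonical listener profile, or ``other``.

    Participants whose simple-condition accuracy falls below ``0.5 -
    margin`` form the below-chance ``other`` class.  Otherwise the closest
    (Euclidean) of the L0/L1/L2 profiles wins, ties broken in the order
    L0 < L1 < L2.  With sessions of 12 trials per condition the default
    margin sits about 2.8 binomial standard deviations below chance, so a
    true chance-level responder is rarely swept into ``other``.
    """
    if np.isnan(acc_simple) or np.isnan(acc_complex):
        return "other"
    if acc_simple < 0.5 - margin:
        return "other"
    point = np.array([acc_simple, acc_complex])
    best, best_d = None, np.inf
    for name in ("L0", "L1", "L2"):
        d = float(np.sum((point - np.array(PROFILES[name])) ** 2))
        if d < best_d - 1e-15:
            best, best_d = name, d
    return best


def assign_mixture_classes(
    fit: MixtureFit, accuracies: pd.DataFrame, margin: float = 0.25
) -> pd.Series:
    """Map mixture components to listener classes via their means.

    Each participant is assigned the class of the component with maximal
    responsibility, where a component's class is the nearest-profile label
    of its mean.
    """
    comp_class = [
        classify_nearest_profile(m[0], m[1], margin=margin) for m in fit.means
    ]
    keep = accuracies[["acc_simple", "acc_complex"]].notna().all(axis=1)
    hard = fit.responsibilities.argmax(axis=1)
    out = pd.Series("other", index=accuracies.index, dtype=object)
    out.loc[accuracies.index[keep]] = [comp_class[i] for i in hard]
    return out


def homogeneity_completeness(
    predicted_classes: Sequence, reference_classes: Sequence
) -> tuple[float, float]:
    """Entropy-based homogeneity and completeness of a partition.

    ``h = 1 - H(ref|pred)/H(ref)`` and ``c = 1 - H(pred|ref)/H(pred)``;
    both lie in [0, 1], are invariant under label permutation, and equal 1
    by convention when the corresponding denominator entropy is zero.
    """
    if len(predicted_classes) != len(reference_classes):
        raise RefgameError("label sequences must have equal length")
    h = float(homogeneity_score(list(reference_classes), list(predicted_classes)))
    c = float(completeness_score(list(reference_classes), list(predicted_classes)))
    return h, c


# ---------------------------------------------------------------------------
# type-recovery experiment
# ---------------------------------------------------------------------------

def strategy_to_class(strategy: str) -> str:
    """Performance class a strategy is expected to land in."""
    return STRATEGY_CLASS[strategy]


def recovery_experiment(
    pop: PopulationSpec,
    coding: str = "forced_even",
    margin: float = 0.25,
    K_range: Iterable[int] = range(1, 7),
    seed: int | None = None,
) -> dict:
    """Simulate a population, classify everyone, and tabulate recovery.

    Runs the full loop -- simulate responses, code the ambiguous baseline,
    compute per-participant accuracies, classify with the nearest-profile
    rule and with the mixture model -- and returns the confusion matrix of
    true strategy versus assigned class plus per-class recovery rates for
    the nearest-profile classifier.
    """
    seed = pop.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    responses = simulate_dataset(pop)
    coded = code_ambiguous(responses, coding, rng)
    acc = accuracy_by_condition(coded)
    truth = (
        responses.groupby("participant_id")["strategy"].first().reindex(
            acc["participant_id"]
        )
    )
    acc = acc.assign(strategy=truth.to_numpy())
    acc["true_class"] = acc["strategy"].map(STRATEGY_CLASS)
    acc["nearest_class"] = [
        classify_nearest_profile(s, c, margin=margin)
        for s, c in zip(acc["acc_simple"], acc["acc_complex"])
    ]
    fits, K_bic, _ = fit_latent_profiles(acc, K_range=K_range, seed=seed)
    acc["mixture_class"] = assign_mixture_classes(
        fits[K_bic], acc, margin=margin
    ).to_numpy()
    confusion = pd.crosstab(acc["strategy"], acc["nearest_class"])
    rsa_mask = acc["strategy"].isin(RSA_STRATEGIES)
    recovery = {}
    for cls in CLASSES:
        members = acc[acc["true_class"] == cls]
        if len(members):
            recovery[cls] = float((members["nearest_class"] == cls).mean())
    result = {
        "assignments": acc,
        "confusion": confusion,
        "recovery_by_class": recovery,
        "selected_K": K_bic,
        "rsa_recovery": float(
            (acc.loc[rsa_mask, "nearest_class"] == acc.loc[rsa_mask, "true_class"]).mean()
        )
        if rsa_mask.any()
        else float("nan"),
        "overall_recovery": float((acc["nearest_class"] == acc["true_class"]).mean()),
    }
    return result
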