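"""Linking dPC similarity to trial outcomes and individual-difference traits.

dPC similarity is the Pearson correlation between one trial's dPC expression
time course and the mean time course of all imagined-support trials -- a
single number per trial summarizing how much its neural dynamics resemble the
canonical imagined-support response.  Trial-level effects are tested with a
random-intercept mixed model, individual-level trait associations with OLS
controlling for recruitment wave and age, and the behavioral condition
contrast with a Welch two-sample t-test.  BH-FDR is applied per declared test
family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dpca import DpcaModel, TrialFeatures, project_trials
from .parcels import fdr_adjust
from .synthetic import CONDITION_SELF, CONDITION_SUPPORT, TrialRecord

__all__ = [
    "LinkingError",
    "LinkResult",
    "reference_timecourse",
    "dpc_similarity",
    "similarity_table",
    "mean_similarity_by_participant",
    "trial_level_test",
    "individual_level_fit",
    "condition_contrast",
    "adjust_family",
]

OUTCOME_LESS = "less_negative"
OUTCOME_MORE = "more_negative"


class LinkingError(ValueError):
    pass


@dataclass
class LinkResult:
    """One fitted link model: estimate, uncertainty, and test family bookkeeping."""

    model: str
    estimate: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float
    p_adjusted: Optional[float] = None
    r_squared: Optional[float] = None
    covariates: Tuple[str, ...] = ()
    extras: Dict[str, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.extras is None:
            self.extras = {}


def reference_timecourse(features: Sequence[TrialFeatures],
                         condition: Optional[str] = CONDITION_SUPPORT) -> np.ndarray:
    """Element-wise mean dPC time course over trials matching ``condition``."""
    if condition is None:
        selected = list(features)
    else:
        selected = [f for f in features if f.condition == condition]
    if not selected:
        raise LinkingError(f"no trials match condition filter {condition!r}")
    return np.mean([f.z for f in selected], axis=0)


def dpc_similarity(trial_z: np.ndarray, reference: np.ndarray) -> float:
    """Pearson correlation between a trial's dPC time course and the reference."""
    trial_z = np.asarray(trial_z, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if trial_z.shape != reference.shape or trial_z.ndim != 1:
        raise LinkingError(
            f"shape mismatch: trial {trial_z.shape} vs reference {reference.shape}")
    if trial_z.size < 3:
        raise LinkingError(f"need at least 3 timepoints, got {trial_z.size}")
    if np.ptp(trial_z) == 0 or np.ptp(reference) == 0:
        raise LinkingError("correlation undefined: an input vector is constant")
    return float(stats.pearsonr(trial_z, reference)[0])


def similarity_table(trials: Sequence[TrialRecord], model: DpcaModel,
                     outcome_rule: str = "baseline",
                     leave_one_out: bool = False) -> pd.DataFrame:
    """Per-trial dPC similarity joined to outcomes.

    ``outcome_rule='baseline'`` labels a trial less_negative when its
    post-trial negativity rating falls below the memory's pre-scan baseline
    rating; ``'median'`` splits at the cohort median rating instead.  With
    ``leave_one_out`` an imagined-support trial is excluded from its own
    reference (removes the in-sample self-similarity bias).
    """
    if outcome_rule not in ("baseline", "median"):
        raise LinkingError(f"outcome_rule must be 'baseline' or 'median', got {outcome_rule!r}")
    z = project_trials(model, trials)
    conditions = np.array([t.condition for t in trials])
    support = conditions == CONDITION_SUPPORT
    if not support.any():
        raise LinkingError("no imagined-support trials to define the reference")
    ref_sum = z[support].sum(axis=0)
    n_support = int(support.sum())

    similarities = np.empty(len(trials))
    for i in range(len(trials)):
        if leave_one_out and support[i]:
            if n_support < 2:
                raise LinkingError("leave-one-out reference needs >= 2 support trials")
            ref = (ref_sum - z[i]) / (n_support - 1)
        else:
            ref = ref_sum / n_support
        similarities[i] = dpc_similarity(z[i], ref)

    ratings = np.array([t.negativity_rating for t in trials])
    baselines = np.array([t.baseline_negativity for t in trials])
    if outcome_rule == "baseline":
        less = ratings < baselines
    else:
        less = ratings < np.median(ratings)
    return pd.DataFrame({
        "participant_id": [t.participant_id for t in trials],
        "memory_id": [t.memory_id for t in trials],
        "condition": conditions,
        "similarity": similarities,
        "negativity_rating": ratings,
        "baseline_negativity": baselines,
        "outcome_group": np.where(less, OUTCOME_LESS, OUTCOME_MORE),
    })


def mean_similarity_by_participant(table: pd.DataFrame,
                                   condition: str = CONDITION_SUPPORT) -> pd.DataFrame:
    """Participant-level mean similarity, restricted to one condition."""
    subset = table[table["condition"] == condition]
    if subset.empty:
        raise LinkingError(f"no trials in condition {condition!r}")
    agg = subset.groupby("participant_id", sort=True)["similarity"].mean()
    return agg.rename("mean_similarity").reset_index()


def trial_level_test(table: pd.DataFrame, scope: str = "all") -> LinkResult:
    """Mixed model: similarity ~ outcome group with a participant random intercept.

    The estimate is the less_negative minus more_negative similarity
    difference.  The t reference uses a containment-style df
    (n_obs - n_participants - 1).
    """
    if scope == "all":
        data = table
    elif scope in (CONDITION_SELF, CONDITION_SUPPORT):
        data = table[table["condition"] == scope]
    else:
        raise LinkingError(
            f"scope must be 'all', {CONDITION_SELF!r} or {CONDITION_SUPPORT!r}, "
            f"got {scope!r}")
    groups_present = set(data["outcome_group"])
    if groups_present != {OUTCOME_LESS, OUTCOME_MORE}:
        raise LinkingError(
            f"both outcome groups must be present in scope {scope!r}; "
            f"found {sorted(groups_present)}")
    if data["participant_id"].nunique() < 2:
        raise LinkingError("need at least 2 participants for the mixed model")

    endog = data["similarity"].to_numpy()
    less = (data["outcome_group"] == OUTCOME_LESS).astype(float).to_numpy()
    exog = sm.add_constant(pd.DataFrame({"less_negative": less}))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MixedLM(endog, exog, groups=data["participant_id"]).fit(reml=True)
    b = float(fit.params["less_negative"])
    se = float(fit.bse["less_negative"])
    df = max(len(data) - data["participant_id"].nunique() - 1, 1)
    t = b / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    crit = stats.t.ppf(0.975, df)
    return LinkResult(
        model=f"mixed: similarity ~ outcome_group + (1 | participant), scope={scope}",
        estimate=b, ci_low=b - crit * se, ci_high=b + crit * se,
        t=t, df=float(df), p=p,
        extras={"n_trials": float(len(data)),
                "n_participants": float(data["participant_id"].nunique())})


def individual_level_fit(traits: pd.DataFrame, mean_similarity: pd.DataFrame,
                         trait: str) -> LinkResult:
    """OLS: trait ~ mean dPC similarity (support trials) + wave + age."""
    if trait not in traits.columns:
        raise LinkingError(f"trait {trait!r} not present in the trait table")
    merged = traits.merge(mean_similarity, on="participant_id", how="inner")
    if len(merged) < 10:
        raise LinkingError(f"need >= 10 participants, got {len(merged)}")

    covariates: List[str] = []
    for cov in ("wave", "age"):
        if cov in merged.columns:
            if merged[cov].nunique() <= 1:
                warnings.warn(f"covariate {cov!r} is constant and was dropped",
                              RuntimeWarning, stacklevel=2)
            else:
                covariates.append(cov)
    design = merged[["mean_similarity"] + covariates].astype(float)
    exog = sm.add_constant(design)
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        culprits = [c for c in design.columns
                    if np.linalg.matrix_rank(exog.drop(columns=c).to_numpy()) == rank]
        raise LinkingError(f"rank-deficient design; collinear columns: {culprits}")
    fit = sm.OLS(merged[trait].astype(float), exog).fit()
    b = float(fit.params["mean_similarity"])
    ci = fit.conf_int().loc["mean_similarity"]
    return LinkResult(
        model=f"ols: {trait} ~ mean_similarity + {' + '.join(covariates) or '1'}",
        estimate=b, ci_low=float(ci[0]), ci_high=float(ci[1]),
        t=float(fit.tvalues["mean_similarity"]), df=float(fit.df_resid),
        p=float(fit.pvalues["mean_similarity"]), r_squared=float(fit.rsquared),
        covariates=tuple(covariates),
        extras={"n_participants": float(len(merged))})


def condition_contrast(trials: Sequence[TrialRecord]) -> LinkResult:
    """Welch two-sample t-test on negativity ratings (support minus self-feel)."""
    support = np.array([t.negativity_rating for t in trials
                        if t.condition == CONDITION_SUPPORT], dtype=float)
    selfr = np.array([t.negativity_rating for t in trials
                      if t.condition == CONDITION_SELF], dtype=float)
    if support.size == 0 or selfr.size == 0:
        raise LinkingError("both conditions must have rated trials")
    res = stats.ttest_ind(support, selfr, equal_var=False)
    t = float(res.statistic)
    df = float(res.df)
    p = float(res.pvalue)
    if not np.isfinite(t):  # both groups constant
        t, p, df = 0.0, 1.0, float(support.size + selfr.size - 2)
    estimate = float(support.mean() - selfr.mean())
    se_sq = support.var(ddof=1) / support.size + selfr.var(ddof=1) / selfr.size
    se = float(np.sqrt(se_sq)) if se_sq > 0 else 0.0
    crit = stats.t.ppf(0.975, df) if df > 0 else 0.0
    return LinkResult(
        model="welch-t: negativity_rating ~ condition",
        estimate=estimate, ci_low=estimate - crit * se, ci_high=estimate + crit * se,
        t=t, df=df, p=p,
        extras={"mean_support": float(support.mean()), "sd_support": float(support.std(ddof=1)) if support.size > 1 else 0.0,
                "mean_self": float(selfr.mean()), "sd_self": float(selfr.std(ddof=1)) if selfr.size > 1 else 0.0,
                "n_support": float(support.size), "n_self": float(selfr.size)})


def adjust_family(results: Sequence[LinkResult]) -> List[LinkResult]:
    """BH-adjust raw p-values across one declared family of link tests."""
    adjusted = fdr_adjust([r.p for r in results])
    return [dc_replace(r, p_adjusted=float(a)) for r, a in zip(results, adjusted)]
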