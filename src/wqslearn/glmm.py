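"""Stage 1 (continuous outcomes): covariate-adjusted random-slope mixed models.

Each subject's learning curve for a continuous maze outcome (completion time,
distance traveled) is modelled as a Gaussian linear mixed model with a fixed
trial effect, covariate adjustment (age, SES, video-game use, IQ) and a
correlated random intercept + random trial slope per subject.  The
per-subject learning slope is the fixed trial coefficient plus the subject's
empirical-Bayes (BLUP) slope deviation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import FitError, ValidationError

OUTCOME_COLUMNS = {"time": "time_s", "distance": "distance",
                   "wm_errors": "wm_errors", "rm_errors": "rm_errors"}

#: covariate adjustment shared by every stage-1 model
COVARIATE_TERMS = ("age + C(ses, Treatment('low')) "
                   "+ C(videogames, Treatment('do_not_play')) + iq")


def merge_trials(trials: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    data = trials.merge(subjects, on="subject_id", how="left", validate="m:1")
    if data[["sex", "age", "ses", "videogames", "iq"]].isna().any().any():
        raise ValidationError("trials reference subjects missing from the subjects table")
    return data


def _check_panel(data: pd.DataFrame) -> None:
    per_subject = data.groupby("subject_id")["trial"].size()
    if (per_subject >= 2).mean() < 0.9:
        raise ValidationError("fewer than 90% of subjects have >= 2 trials")


@dataclass
class LearningCurveResults:
    """Fitted Gaussian random-slope model for one outcome.

    ``fixed_effects`` holds coefficient, SE and 95% CI per term;
    ``random_effect_sds`` holds the intercept SD, slope SD and their
    correlation; ``random_effects`` the per-subject BLUP deviations.
    """

    outcome: str
    fixed_effects: pd.DataFrame
    random_effect_sds: dict
    residual_sd: float
    loglik: float
    n_subjects: int
    n_obs: int
    converged: bool
    reml: bool
    random_effects: pd.DataFrame = field(repr=False, default=None)
    #: conditional SD of each subject's slope deviation
    slope_cond_sd: float = np.nan

    @property
    def trial_effect(self) -> float:
        return float(self.fixed_effects.loc["trial", "coef"])

    @property
    def trial_ci(self) -> tuple:
        row = self.fixed_effects.loc["trial"]
        return float(row["ci_low"]), float(row["ci_high"])

    def learning_curves(self) -> pd.DataFrame:
        """One row per subject: slope = fixed trial effect + BLUP deviation."""
        re = self.random_effects
        return pd.DataFrame({
            "subject_id": re.index,
            "outcome": self.outcome,
            "slope": self.trial_effect + re["trial"].to_numpy(),
            "slope_se": self.slope_cond_sd,
        }).reset_index(drop=True)

    def summary(self) -> str:
        sds = self.random_effect_sds
        lines = [f"Gaussian random-slope model: {self.outcome} "
                 f"({'REML' if self.reml else 'ML'}, "
                 f"{'converged' if self.converged else 'NOT converged'})",
                 f"  n = {self.n_subjects} subjects, {self.n_obs} observations, "
                 f"loglik = {self.loglik:.2f}",
                 f"  random effects: intercept SD {sds['intercept']:.3g}, "
                 f"slope SD {sds['slope']:.3g}, corr {sds['corr']:.2f}; "
                 f"residual SD {self.residual_sd:.3g}",
                 self.fixed_effects.round(4).to_string()]
        return "\n".join(lines)


class LearningCurveModel:
    """Random-slope mixed model for a continuous maze outcome.

    Parameters
    ----------
    trials, subjects : DataFrame
        Trial-level outcomes and the subject covariate table.
    outcome : {'time', 'distance'}
    random : {'both', 'intercept', 'slope'}
        Random-effect structure; the default is a correlated random
        intercept + trial slope per subject.
    """

    def __init__(self, trials: pd.DataFrame, subjects: pd.DataFrame,
                 outcome: str, random: str = "both"):
        if outcome not in ("time", "distance"):
            raise ValidationError("continuous outcomes are 'time' and 'distance'")
        self.outcome = outcome
        self.column = OUTCOME_COLUMNS[outcome]
        self.data = merge_trials(trials, subjects)
        _check_panel(self.data)
        if self.data[self.column].isna().any():
            raise ValidationError(f"missing values in {self.column}")
        if random not in ("both", "intercept", "slope"):
            raise ValidationError("random must be 'both', 'intercept' or 'slope'")
        self.random = random

    def fit(self, reml: bool = True, maxiter: int = 200) -> LearningCurveResults:
        formula = f"{self.column} ~ trial + {COVARIATE_TERMS}"
        re_formula = {"both": "~trial", "intercept": "~1", "slope": "~0 + trial"}[self.random]
        model = smf.mixedlm(formula, self.data, groups=self.data["subject_id"],
                            re_formula=re_formula)
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                res = model.fit(reml=reml, maxiter=maxiter)
            except ConvergenceWarning:
                converged = False
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit(reml=reml, maxiter=maxiter)
            except Exception as exc:
                raise FitError(f"mixed-model fit failed for {self.outcome}: {exc}") from exc
        if res.params.isna().any():
            raise FitError(f"mixed-model fit returned NaN for {self.outcome}")
        converged = converged and bool(res.converged)

        fe_names = res.fe_params.index
        ci = res.conf_int().loc[fe_names]
        fixed = pd.DataFrame({
            "coef": res.fe_params,
            "se": res.bse.loc[fe_names],
            "ci_low": ci[0], "ci_high": ci[1],
            "p": res.pvalues.loc[fe_names],
        })
        fixed = fixed.rename(index={"Intercept": "intercept"})

        scale = float(res.scale)
        cov_re = np.atleast_2d(np.asarray(res.cov_re))
        if self.random == "both":
            sd0 = float(np.sqrt(cov_re[0, 0]))
            sd1 = float(np.sqrt(cov_re[1, 1]))
            corr = float(cov_re[0, 1] / (sd0 * sd1)) if sd0 * sd1 > 0 else 0.0
        elif self.random == "intercept":
            sd0, sd1, corr = float(np.sqrt(cov_re[0, 0])), 0.0, 0.0
        else:
            sd0, sd1, corr = 0.0, float(np.sqrt(cov_re[0, 0])), 0.0

        re_rows = {}
        for gid, series in res.random_effects.items():
            b0 = float(series.get("Group", series.get("Intercept", 0.0)))
            b1 = float(series.get("trial", 0.0))
            re_rows[gid] = (b0, b1)
        random_effects = pd.DataFrame.from_dict(re_rows, orient="index",
                                                columns=["intercept", "trial"])
        random_effects = random_effects.loc[
            self.data["subject_id"].drop_duplicates().to_numpy()]

        # conditional covariance of the random effects under balanced trials
        # (Z'Z/sigma2 + G^-1)^-1; used as the reported slope_se
        slope_cond_sd = 0.0
        if self.random in ("both", "slope"):
            t = np.sort(self.data["trial"].unique()).astype(float)
            Z = np.column_stack([np.ones_like(t), t]) if self.random == "both" \
                else t[:, None]
            G = cov_re if self.random == "both" else cov_re
            try:
                V = np.linalg.inv(Z.T @ Z / scale + np.linalg.inv(G))
                slope_cond_sd = float(np.sqrt(V[-1, -1]))
            except np.linalg.LinAlgError:
                slope_cond_sd = float("nan")

        return LearningCurveResults(
            outcome=self.outcome,
            fixed_effects=fixed,
            random_effect_sds={"intercept": sd0, "slope": sd1, "corr": corr},
            residual_sd=float(np.sqrt(scale)),
            loglik=float(res.llf),
            n_subjects=int(random_effects.shape[0]),
            n_obs=int(len(self.data)),
            converged=converged,
            reml=reml,
            random_effects=random_effects,
            slope_cond_sd=slope_cond_sd,
        )


def fit_lmm(trials: pd.DataFrame, subjects: pd.DataFrame, outcome: str,
            reml: bool = True, random: str = "both") -> LearningCurveResults:
    """Fit the covariate-adjusted Gaussian random-slope model for one outcome."""
    return LearningCurveModel(trials, subjects, outcome, random=random).fit(reml=reml)
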