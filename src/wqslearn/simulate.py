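"""Synthetic cohort generator.

Emulates a 188-adolescent metal-exposure study: demographic and covariate
marginals by sex, correlated log-normal concentrations of four metals in five
biological matrices, and eight-trial virtual radial-arm-maze outcomes with
subject-specific learning slopes.  A mixture-index effect on the learning
slope is planted per sex (via that sex's true simplex weights), so the
downstream two-stage analysis can be validated against known truth.

All functions are deterministic given the configuration seed: demographics,
exposures and trials are drawn from independent child streams of one seed
sequence, so each stage is individually reproducible.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (BOY, COMPONENTS, COUNT_OUTCOMES, GAUSSIAN_OUTCOMES, GIRL,
                     METALS, SES_LEVELS, SEXES, VIDEOGAME_LEVELS,
                     GeneratorConfig)
from .errors import ConfigurationError, ValidationError
from .quantiles import decile_transform

_STAGE_COHORT, _STAGE_EXPOSURES, _STAGE_TRIALS = 0, 1, 2


def _stage_rng(config: GeneratorConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[stage])


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Draw by resampling out-of-range values; fine for mild truncation."""
    x = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, bad.sum()) if np.isscalar(mean) else \
            rng.normal(np.asarray(mean)[bad], np.asarray(sd)[bad])
    return np.clip(x, lo, hi)


def generate_cohort(config: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the subjects table: subject_id, sex, age, ses, videogames, iq.

    Sex is assigned by exact quota by default (round(n * p_girl) girls);
    categorical covariates are drawn from sex-specific marginals, age and IQ
    from sex-specific normals (age truncated to the configured range).
    """
    config.validate()
    rng = rng or _stage_rng(config, _STAGE_COHORT)
    n = config.n_subjects
    if config.sex_quota:
        n_girls = int(round(n * config.p_girl))
        sex = np.array([GIRL] * n_girls + [BOY] * (n - n_girls))
        rng.shuffle(sex)
    else:
        sex = np.where(rng.random(n) < config.p_girl, GIRL, BOY)

    age = np.empty(n)
    iq = np.empty(n)
    ses = np.empty(n, dtype=object)
    vg = np.empty(n, dtype=object)
    for s in SEXES:
        m = sex == s
        k = int(m.sum())
        if k == 0:
            continue
        age[m] = _truncated_normal(rng, config.age_mean[s], config.age_sd[s],
                                   *config.age_range, size=k)
        iq[m] = np.maximum(rng.normal(config.iq_mean[s], config.iq_sd[s], k), 40.0)
        ses[m] = rng.choice(SES_LEVELS, size=k, p=config.ses_probs[s])
        vg[m] = rng.choice(VIDEOGAME_LEVELS, size=k, p=config.videogame_probs[s])

    return pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(1, n + 1)],
        "sex": sex,
        "age": np.round(age, 3),
        "ses": ses,
        "videogames": vg,
        "iq": np.round(iq, 2),
    })


def exposure_log_correlation(config: GeneratorConfig) -> np.ndarray:
    """20x20 log-scale correlation: same metal across matrices vs. different
    metals, a simple shared-source structure."""
    c = len(COMPONENTS)
    metal_of = np.array([comp.split("_")[1] for comp in COMPONENTS])
    R = np.full((c, c), config.corr_other_metal)
    same = metal_of[:, None] == metal_of[None, :]
    R[same] = config.corr_same_metal
    np.fill_diagonal(R, 1.0)
    return R


def generate_exposures(subjects: pd.DataFrame, config: GeneratorConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the n x 20 exposure table (plus subject_id column).

    Each component is log-normal with the configured GM/GSD (sex-specific
    where configured); log-concentrations share the configured correlation
    structure across components.
    """
    config.validate()
    rng = rng or _stage_rng(config, _STAGE_EXPOSURES)
    n = len(subjects)
    R = exposure_log_correlation(config)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ConfigurationError("exposure correlation matrix is not PD") from exc
    Z = rng.standard_normal((n, len(COMPONENTS))) @ L.T

    mu = np.empty((n, len(COMPONENTS)))
    sigma = np.empty_like(mu)
    sex = subjects["sex"].to_numpy()
    for j, comp in enumerate(COMPONENTS):
        dist = config.exposure_gm_gsd[comp]
        for s in SEXES:
            m = sex == s
            gm, gsd = dist.params_for(s)
            mu[m, j] = np.log(gm)
            sigma[m, j] = np.log(gsd)
    X = np.exp(mu + sigma * Z)
    out = pd.DataFrame(X, columns=list(COMPONENTS))
    out.insert(0, "subject_id", subjects["subject_id"].to_numpy())
    return out


def _weights_vector(weights) -> np.ndarray:
    if isinstance(weights, dict):
        w = np.array([weights[c] for c in COMPONENTS], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-6:
        raise ValidationError("weights must be a nonnegative vector summing to 1")
    return np.clip(w, 0.0, None)


def compute_true_index(exposures: pd.DataFrame, weights,
                       direction: str = "pos") -> np.ndarray:
    """Weighted quantile sum index sum_i w_i q_ij from raw exposures.

    Exposures are deciled internally (scores 0-9), so the index always lies
    in [0, 9].  ``direction`` is accepted for interface symmetry with the
    estimation stage; the formula itself does not depend on it.
    """
    if direction not in ("pos", "neg"):
        raise ValidationError("direction must be 'pos' or 'neg'")
    X = exposures[[c for c in COMPONENTS if c in exposures.columns]]
    if X.shape[1] != len(COMPONENTS):
        X = exposures.drop(columns=["subject_id"], errors="ignore")
    w = _weights_vector(weights)
    if X.shape[1] != w.size:
        raise ValidationError("weights length does not match component count")
    q = decile_transform(X)
    return q.to_numpy() @ w


def _covariate_shift(subjects: pd.DataFrame, effects: dict) -> np.ndarray:
    """Linear covariate contribution to an outcome's intercept.

    Age and IQ enter centred at the cohort's configured means so the outcome
    intercept calibration is unaffected; videogame use enters as a linear
    trend over its six ordered levels.
    """
    shift = np.zeros(len(subjects))
    if "age" in effects:
        shift += effects["age"] * (subjects["age"].to_numpy() - 12.1)
    if "iq" in effects:
        shift += effects["iq"] * (subjects["iq"].to_numpy() - 107.2)
    ses = subjects["ses"].to_numpy()
    shift += effects.get("ses_medium", 0.0) * (ses == "medium")
    shift += effects.get("ses_high", 0.0) * (ses == "high")
    if "videogames" in effects:
        level = subjects["videogames"].map(
            {lv: i for i, lv in enumerate(VIDEOGAME_LEVELS)}).to_numpy()
        shift += effects["videogames"] * level
    return shift


def generate_vram_trials(subjects: pd.DataFrame, true_index: np.ndarray,
                         config: GeneratorConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the trial-level table: 8 rows per subject, four outcomes.

    ``true_index`` holds each subject's own-sex mixture index (in [0, 9]);
    its centred value scales the planted slope effect with the sex-specific
    sign.  Continuous outcomes follow a linear mixed model with correlated
    random intercept and slope, censored at the configured bounds; counts are
    zero-inflated Poisson with a log-rate linear in trial.
    """
    config.validate()
    rng = rng or _stage_rng(config, _STAGE_TRIALS)
    n = len(subjects)
    true_index = np.asarray(true_index, dtype=float)
    if true_index.shape != (n,):
        raise ValidationError("need exactly one index value per subject")
    for name in config.outcomes:
        if name not in GAUSSIAN_OUTCOMES + COUNT_OUTCOMES:
            raise ConfigurationError(f"index effect configured for unknown outcome {name!r}")

    trials = np.arange(1, config.n_trials + 1)
    t_mat = np.tile(trials, (n, 1))
    is_girl = (subjects["sex"] == GIRL).to_numpy()
    z = true_index - config.index_center

    cols = {
        "subject_id": np.repeat(subjects["subject_id"].to_numpy(), config.n_trials),
        "trial": np.tile(trials, n),
    }
    for name in ("time", "distance", "wm_errors", "rm_errors"):
        par = config.outcomes[name]
        cov = np.array([[par.sd_intercept ** 2,
                         par.re_corr * par.sd_intercept * par.sd_slope],
                        [par.re_corr * par.sd_intercept * par.sd_slope,
                         par.sd_slope ** 2]])
        b = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
        effect = np.where(is_girl, par.index_effect_girl, par.index_effect_boy)
        slope = par.trial_slope + effect * z + b[:, 1]
        level = par.intercept + _covariate_shift(subjects, par.covariate_effects) + b[:, 0]
        eta = level[:, None] + slope[:, None] * t_mat
        if name in GAUSSIAN_OUTCOMES:
            y = eta + rng.normal(0.0, par.sd_resid, size=eta.shape)
            if par.lower is not None:
                y = np.maximum(y, par.lower)
            if par.upper is not None:
                y = np.minimum(y, par.upper)
            key = "time_s" if name == "time" else "distance"
            cols[key] = np.round(y, 3).ravel()
        else:
            lam = np.exp(np.clip(eta, -20.0, 6.0))
            counts = rng.poisson(lam)
            structural_zero = rng.random(eta.shape) < par.zero_inflation_prob
            cols[name] = np.where(structural_zero, 0, counts).ravel()
    return pd.DataFrame(cols)[["subject_id", "trial", "time_s", "distance",
                               "wm_errors", "rm_errors"]]


def own_sex_index(subjects: pd.DataFrame, exposures: pd.DataFrame,
                  config: GeneratorConfig) -> np.ndarray:
    """Each subject's true index under their own sex's planted weights."""
    idx_girl = compute_true_index(exposures, config.true_weights[GIRL])
    idx_boy = compute_true_index(exposures, config.true_weights[BOY])
    return np.where(subjects["sex"].to_numpy() == GIRL, idx_girl, idx_boy)


def simulate_cohort(config: GeneratorConfig | None = None, seed: int | None = None
                    ) -> dict[str, pd.DataFrame]:
    """Generate the three linked tables (subjects, exposures, trials).

    Returns a dict with keys 'subjects', 'exposures', 'trials'.  ``seed``
    overrides ``config.seed`` when given.
    """
    config = config or GeneratorConfig()
    if seed is not None:
        config = GeneratorConfig.from_dict({**config.to_dict(), "seed": int(seed)})
    subjects = generate_cohort(config)
    exposures = generate_exposures(subjects, config)
    trials = generate_vram_trials(subjects, own_sex_index(subjects, exposures, config),
                                  config)
    return {"subjects": subjects, "exposures": exposures, "trials": trials}
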