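"""Cohort generator configuration and its default calibration.

The defaults emulate an adolescent cohort of 188 participants (88 girls,
100 boys, ages 10-14) living near ferroalloy emission sources: demographic
marginals, log-normal concentrations of Mn, Pb, Cr and Cu in five biological
matrices (blood, urine, hair, nails, saliva; 20 mixture components), and an
eight-trial virtual radial-arm-maze session per subject with four performance
outcomes.  A weighted-quantile-sum index effect on the per-subject learning
slope is planted with opposite signs in girls and boys, driven by Mn and Cu
in girls and by Cr in boys.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigurationError

METALS = ("Mn", "Pb", "Cr", "Cu")
MATRICES = ("blood", "urine", "hair", "nails", "saliva")
#: the 20 mixture components, named <matrix>_<metal>
COMPONENTS = tuple(f"{mat}_{met}" for mat in MATRICES for met in METALS)

SES_LEVELS = ("low", "medium", "high")
VIDEOGAME_LEVELS = ("do_not_play", "rarely", "lt1h", "lt2h", "lt3h", "gt3h")
OUTCOMES = ("time", "distance", "wm_errors", "rm_errors")
#: outcomes modelled with a Gaussian mixed model vs. a zero-inflated Poisson one
GAUSSIAN_OUTCOMES = ("time", "distance")
COUNT_OUTCOMES = ("wm_errors", "rm_errors")

GIRL, BOY = "girl", "boy"
SEXES = (GIRL, BOY)

#: regression leakage between the girls' (Mn/Cu) and boys' (Cr) true indices
#: induced by the default cross-metal exposure correlation; measured once from
#: the default correlation structure at large n and frozen.  Per-sex planted
#: effects are scaled by 1/(1+lambda) so the population-level sex-by-index
#: contrast equals the configured target.
INDEX_CROSS_LEAKAGE = 0.52


@dataclass
class ComponentDist:
    """Log-normal marginal for one mixture component.

    gm/gsd are geometric mean and geometric SD for the whole cohort; optional
    per-sex values override them (used for the four components whose
    concentrations differ by sex).
    """

    gm: float
    gsd: float
    gm_girl: Optional[float] = None
    gsd_girl: Optional[float] = None
    gm_boy: Optional[float] = None
    gsd_boy: Optional[float] = None

    def params_for(self, sex: str) -> tuple[float, float]:
        if sex == GIRL and self.gm_girl is not None:
            return self.gm_girl, self.gsd_girl or self.gsd
        if sex == BOY and self.gm_boy is not None:
            return self.gm_boy, self.gsd_boy or self.gsd
        return self.gm, self.gsd

    def validate(self, name: str) -> None:
        for gm in (self.gm, self.gm_girl, self.gm_boy):
            if gm is not None and gm <= 0:
                raise ConfigurationError(f"{name}: geometric mean must be > 0")
        for gsd in (self.gsd, self.gsd_girl, self.gsd_boy):
            if gsd is not None and gsd < 1:
                raise ConfigurationError(f"{name}: geometric SD must be >= 1")


@dataclass
class OutcomeParams:
    """Generative parameters for one trial-level outcome.

    For Gaussian outcomes all quantities are on the response scale; for count
    outcomes intercept/slopes/random effects live on the log-rate scale and
    ``sd_resid`` is unused.  ``index_effect_girl``/``index_effect_boy``
    multiply the centred true mixture index of the subject's own sex and are
    added to that subject's trial slope.
    """

    intercept: float
    trial_slope: float
    sd_intercept: float
    sd_slope: float
    re_corr: float = 0.0
    sd_resid: float = 0.0
    zero_inflation_prob: float = 0.0
    index_effect_girl: float = 0.0
    index_effect_boy: float = 0.0
    covariate_effects: dict = field(default_factory=dict)
    lower: Optional[float] = None
    upper: Optional[float] = None

    def validate(self, name: str) -> None:
        if not (0.0 <= self.zero_inflation_prob < 1.0):
            raise ConfigurationError(f"{name}: zero_inflation_prob must be in [0, 1)")
        if min(self.sd_intercept, self.sd_slope, self.sd_resid) < 0:
            raise ConfigurationError(f"{name}: random-effect/residual SDs must be >= 0")
        if abs(self.re_corr) > 1:
            raise ConfigurationError(f"{name}: |re_corr| must be <= 1")


def _table2_marginals() -> dict:
    """GM/GSD per component, with per-sex values for the four components whose
    distributions differ between girls and boys."""
    vals = {
        "blood_Mn": (10.92, 1.36), "blood_Pb": (14.48, 1.80),
        "blood_Cr": (0.74, 2.04), "blood_Cu": (845.17, 1.16),
        "urine_Mn": (0.23, 3.26), "urine_Pb": (0.69, 1.81),
        "urine_Cr": (0.19, 1.86), "urine_Cu": (8.46, 1.68),
        "hair_Mn": (0.07, 2.17), "hair_Pb": (0.10, 3.54),
        "hair_Cr": (0.04, 2.12), "hair_Cu": (12.16, 1.70),
        "nails_Mn": (0.27, 3.81), "nails_Pb": (0.24, 4.54),
        "nails_Cr": (0.17, 2.33), "nails_Cu": (2.51, 1.73),
        "saliva_Mn": (3.26, 2.95), "saliva_Pb": (0.32, 3.84),
        "saliva_Cr": (0.30, 2.60), "saliva_Cu": (16.63, 2.90),
    }
    sex_specific = {
        "blood_Pb": ((12.53, 1.71), (16.45, 1.82)),
        "blood_Cu": ((827.88, 1.16), (860.68, 1.15)),
        "hair_Mn": ((0.05, 1.97), (0.09, 2.22)),
        "hair_Cu": ((13.73, 1.73), (10.93, 1.64)),
    }
    out = {}
    for comp, (gm, gsd) in vals.items():
        if comp in sex_specific:
            (gmg, gsdg), (gmb, gsdb) = sex_specific[comp]
            out[comp] = ComponentDist(gm, gsd, gmg, gsdg, gmb, gsdb)
        else:
            out[comp] = ComponentDist(gm, gsd)
    return out


def _default_true_weights() -> dict:
    """Planted simplex weights: girls driven by Mn and Cu, boys by Cr."""
    girls = {c: 0.01 for c in COMPONENTS}  # Pb and Cr background, 0.01 each
    girls.update({
        "blood_Mn": 0.17, "hair_Mn": 0.13, "urine_Mn": 0.08,
        "nails_Mn": 0.07, "saliva_Mn": 0.05,              # Mn: 0.50
        "hair_Cu": 0.13, "blood_Cu": 0.11, "saliva_Cu": 0.06,
        "urine_Cu": 0.05, "nails_Cu": 0.05,               # Cu: 0.40
    })
    boys = {c: 0.25 / 15 for c in COMPONENTS}  # non-Cr background
    boys.update({
        "blood_Cr": 0.20, "urine_Cr": 0.16, "hair_Cr": 0.14,
        "nails_Cr": 0.125, "saliva_Cr": 0.125,            # Cr: 0.75
    })
    return {GIRL: girls, BOY: boys}


#: population sex-by-index contrasts targeted by the default calibration
DEFAULT_INTERACTION_TARGETS = {
    "time": 0.87, "distance": 222.0, "wm_errors": 0.06, "rm_errors": 0.06,
}


def _default_outcomes(interaction_targets: dict | None = None,
                      leakage: float = INDEX_CROSS_LEAKAGE) -> dict:
    targets = dict(DEFAULT_INTERACTION_TARGETS)
    if interaction_targets:
        targets.update(interaction_targets)
    # per-sex planted effect magnitude; the +/-c pair on correlated per-sex
    # indices yields a population interaction contrast of c*(1+leakage)
    c = {k: v / (1.0 + leakage) for k, v in targets.items()}
    return {
        "time": OutcomeParams(
            intercept=140.0, trial_slope=-6.7,
            sd_intercept=15.0, sd_slope=3.5, sd_resid=5.0,
            index_effect_girl=+c["time"], index_effect_boy=-c["time"],
            covariate_effects={"age": -1.0, "iq": -0.05, "ses_medium": -1.5,
                               "ses_high": -2.5, "videogames": -0.8},
            lower=1.0, upper=180.0,
        ),
        "distance": OutcomeParams(
            intercept=17000.0, trial_slope=-844.0,
            sd_intercept=1800.0, sd_slope=500.0, sd_resid=600.0,
            index_effect_girl=+c["distance"], index_effect_boy=-c["distance"],
            covariate_effects={"age": -120.0, "iq": -6.0, "ses_medium": -150.0,
                               "ses_high": -250.0, "videogames": -90.0},
            lower=1.0, upper=None,
        ),
        "wm_errors": OutcomeParams(
            intercept=1.3, trial_slope=-0.17,
            sd_intercept=0.5, sd_slope=0.20, zero_inflation_prob=0.15,
            index_effect_girl=+c["wm_errors"], index_effect_boy=-c["wm_errors"],
            covariate_effects={"age": -0.02, "iq": -0.002, "ses_medium": -0.03,
                               "ses_high": -0.05, "videogames": -0.02},
        ),
        "rm_errors": OutcomeParams(
            intercept=1.0, trial_slope=-0.14,
            sd_intercept=0.5, sd_slope=0.20, zero_inflation_prob=0.15,
            index_effect_girl=+c["rm_errors"], index_effect_boy=-c["rm_errors"],
            covariate_effects={"age": -0.02, "iq": -0.002, "ses_medium": -0.03,
                               "ses_high": -0.05, "videogames": -0.02},
        ),
    }


@dataclass
class GeneratorConfig:
    """Full configuration of the synthetic-cohort generator."""

    n_subjects: int = 188
    seed: int = 0
    p_girl: float = 88.0 / 188.0
    #: assign sexes by exact quota (round(n*p_girl) girls) rather than i.i.d.
    sex_quota: bool = True
    n_trials: int = 8

    age_mean: dict = field(default_factory=lambda: {GIRL: 12.1, BOY: 12.1})
    age_sd: dict = field(default_factory=lambda: {GIRL: 0.9, BOY: 0.8})
    age_range: tuple = (10.0, 14.0)
    ses_probs: dict = field(default_factory=lambda: {
        GIRL: (0.466, 0.273, 0.261), BOY: (0.62, 0.16, 0.22)})
    videogame_probs: dict = field(default_factory=lambda: {
        GIRL: (0.125, 0.261, 0.443, 0.125, 0.035, 0.011),
        BOY: (0.02, 0.20, 0.50, 0.21, 0.06, 0.01)})
    iq_mean: dict = field(default_factory=lambda: {GIRL: 107.4, BOY: 107.1})
    iq_sd: dict = field(default_factory=lambda: {GIRL: 13.6, BOY: 12.6})

    exposure_gm_gsd: dict = field(default_factory=_table2_marginals)
    #: log-scale correlation of the same metal across matrices / across metals
    corr_same_metal: float = 0.4
    corr_other_metal: float = 0.1

    true_weights: dict = field(default_factory=_default_true_weights)
    outcomes: dict = field(default_factory=_default_outcomes)
    #: deciles are coded 0..9, so the population index centre is 4.5
    index_center: float = 4.5

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if not (0.0 <= self.p_girl <= 1.0):
            raise ConfigurationError("p_girl must be in [0, 1]")
        for sex in SEXES:
            for name, probs, levels in (("ses_probs", self.ses_probs[sex], SES_LEVELS),
                                        ("videogame_probs", self.videogame_probs[sex],
                                         VIDEOGAME_LEVELS)):
                if len(probs) != len(levels):
                    raise ConfigurationError(f"{name}[{sex}]: need {len(levels)} values")
                if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-6:
                    raise ConfigurationError(f"{name}[{sex}]: probabilities must sum to 1")
            w = self.true_weights[sex]
            if set(w) != set(COMPONENTS):
                raise ConfigurationError(f"true_weights[{sex}]: must cover all 20 components")
            wv = np.array([w[c] for c in COMPONENTS])
            if np.any(wv < 0) or abs(wv.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"true_weights[{sex}]: not on the simplex")
        if set(self.exposure_gm_gsd) != set(COMPONENTS):
            raise ConfigurationError("exposure_gm_gsd must cover all 20 components")
        for name, dist in self.exposure_gm_gsd.items():
            dist.validate(name)
        for name in self.outcomes:
            if name not in OUTCOMES:
                raise ConfigurationError(f"unknown outcome {name!r}")
        for name, par in self.outcomes.items():
            par.validate(name)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exposure_gm_gsd"] = {k: asdict(v) for k, v in self.exposure_gm_gsd.items()}
        d["outcomes"] = {k: asdict(v) for k, v in self.outcomes.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "exposure_gm_gsd" in d:
            d["exposure_gm_gsd"] = {k: ComponentDist(**v) if isinstance(v, dict) else v
                                    for k, v in d["exposure_gm_gsd"].items()}
        if "outcomes" in d:
            d["outcomes"] = {k: OutcomeParams(**v) if isinstance(v, dict) else v
                             for k, v in d["outcomes"].items()}
        for key in ("age_range",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        for key in ("ses_probs", "videogame_probs"):
            if key in d:
                d[key] = {sex: tuple(v) for sex, v in d[key].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def null_config(**overrides) -> GeneratorConfig:
    """Default configuration with all planted mixture effects set to zero."""
    cfg = GeneratorConfig(**overrides)
    for par in cfg.outcomes.values():
        par.index_effect_girl = 0.0
        par.index_effect_boy = 0.0
    return cfg
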