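import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, gammaln

from conftest import make_config
from wqslearn import fit_zip_mm, simulate_cohort
from wqslearn.errors import FitError, ValidationError
from wqslearn.zipmm import ZIPMixedModel


@pytest.fixture(scope="module")
def models(small_cohort):
    zip_m = ZIPMixedModel(small_cohort["trials"], small_cohort["subjects"],
                          "wm_errors", zero_inflated=True)
    pois_m = ZIPMixedModel(small_cohort["trials"], small_cohort["subjects"],
                           "wm_errors", zero_inflated=False)
    return zip_m, pois_m


def _manual_zip_loglik(model, gamma, pi):
    """Closed-form fixed-effects ZIP log-likelihood (no random effects)."""
    eta = model.Xs @ gamma
    lam = np.exp(eta)
    Y, M = model.Y, model.mask
    pm = np.where(Y == 0,
                  np.log(pi + (1.0 - pi) * np.exp(-lam)),
                  np.log1p(-pi) + Y * eta - lam - gammaln(Y + 1))
    return float(pm[M].sum())


def test_quadrature_matches_closed_form_without_random_effects(models):
    zip_m, _ = models
    rng = np.random.default_rng(3)
    gamma = rng.normal(0, 0.1, zip_m.p)
    gamma[0] = 0.3
    # random-effect SDs of e^-10: the integral collapses to the fixed part
    theta = np.r_[gamma, -1.0, -10.0, -10.0, 0.0]
    ll = zip_m.loglik(theta, order=7)
    manual = _manual_zip_loglik(zip_m, gamma, expit(-1.0))
    assert ll == pytest.approx(manual, rel=1e-5)


def test_zip_nests_poisson_when_pi_is_zero(models):
    zip_m, pois_m = models
    rng = np.random.default_rng(4)
    gamma = rng.normal(0, 0.1, zip_m.p)
    gamma[0] = 0.2
    theta = np.r_[gamma, -40.0, np.log(0.4), np.log(0.15), 0.1]
    assert zip_m.loglik(theta, order=7) == pytest.approx(
        pois_m.loglik(theta, order=7), rel=1e-9, abs=1e-5)


def test_fit_recovers_planted_parameters():
    """Default-calibration wm_errors: trial effect -0.17, pi 0.15 planted."""
    cohort = simulate_cohort(make_config(n_subjects=150, seed=21))
    res = fit_zip_mm(cohort["trials"], cohort["subjects"], "wm_errors")
    assert res.converged
    lo, hi = res.trial_ci
    assert lo < res.trial_effect < hi < 0  # learning on the log-rate scale
    se = float(res.fixed_effects.loc["trial", "se"])
    assert abs(res.trial_effect - (-0.17)) < 4 * se
    assert 0.05 < res.zero_inflation_prob < 0.30
    curves = res.learning_curves()
    assert len(curves) == 150
    assert (curves["slope_se"] > 0).all()
    assert "zip mixed model" in res.summary().lower()


def test_laplace_order_one_close_to_agq(small_cohort, models):
    zip_m, _ = models
    rng = np.random.default_rng(5)
    gamma = rng.normal(0, 0.1, zip_m.p)
    theta = np.r_[gamma, -1.5, np.log(0.5), np.log(0.2), 0.0]
    ll1 = zip_m.loglik(theta, order=1)
    ll7 = zip_m.loglik(theta, order=7)
    assert ll1 == pytest.approx(ll7, rel=5e-3)


def test_input_validation(small_cohort):
    with pytest.raises(ValidationError):
        ZIPMixedModel(small_cohort["trials"], small_cohort["subjects"], "time")
    bad = small_cohort["trials"].copy()
    bad.loc[bad.index[0], "wm_errors"] = -1
    with pytest.raises(ValidationError):
        ZIPMixedModel(bad, small_cohort["subjects"], "wm_errors")
    allzero = small_cohort["trials"].copy()
    allzero["wm_errors"] = 0
    with pytest.raises(FitError):
        ZIPMixedModel(allzero, small_cohort["subjects"], "wm_errors")


def test_against_glmmtmb_oracle(small_cohort, tmp_path):
    """Independent oracle: glmmTMB's ZIP random-slope fit on the same data
    should agree on the trial coefficient within a small margin (the two
    integrators differ: adaptive GH here vs. Laplace there)."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript is required for the glmmTMB oracle test")
    res = fit_zip_mm(small_cohort["trials"], small_cohort["subjects"],
                     "wm_errors")
    data = small_cohort["trials"].merge(small_cohort["subjects"],
                                        on="subject_id")
    csv = tmp_path / "panel.csv"
    data.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(glmmTMB))
        d <- read.csv("{csv}")
        d$ses <- relevel(factor(d$ses), ref = "low")
        d$videogames <- relevel(factor(d$videogames), ref = "do_not_play")
        m <- glmmTMB(wm_errors ~ trial + age + ses + videogames + iq
                     + (trial | subject_id),
                     ziformula = ~1, family = poisson, data = d)
        co <- fixef(m)$cond
        cat(co[["trial"]], plogis(fixef(m)$zi[[1]]), sep = "\\n")
    """))
    out = subprocess.run(["Rscript", "--vanilla", str(script)],
                         capture_output=True, text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    trial_r, pi_r = [float(v) for v in out.stdout.strip().splitlines()[-2:]]
    assert res.trial_effect == pytest.approx(trial_r, abs=0.02)
    assert res.zero_inflation_prob == pytest.approx(pi_r, abs=0.05)
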