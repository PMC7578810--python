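import numpy as np
import pandas as pd
import pytest

from conftest import make_config
from wqslearn import (compute_true_index, generate_exposures, own_sex_index,
                      simulate_cohort, wqs_index)
from wqslearn.config import COMPONENTS, GeneratorConfig
from wqslearn.errors import ValidationError
from wqslearn.quantiles import decile_transform


def test_same_seed_is_bit_identical():
    a = simulate_cohort(make_config(n_subjects=50, seed=11))
    b = simulate_cohort(make_config(n_subjects=50, seed=11))
    for name in ("subjects", "exposures", "trials"):
        pd.testing.assert_frame_equal(a[name], b[name])


def test_different_seeds_differ():
    a = simulate_cohort(make_config(n_subjects=50, seed=11))
    b = simulate_cohort(make_config(n_subjects=50, seed=12))
    assert not a["exposures"].equals(b["exposures"])


def test_default_cohort_sex_quota(default_cohort):
    counts = default_cohort["subjects"]["sex"].value_counts()
    assert counts["girl"] == 88
    assert counts["boy"] == 100


def test_table_ranges(default_cohort):
    subj = default_cohort["subjects"]
    assert subj["age"].between(10, 14).all()
    trials = default_cohort["trials"]
    assert trials["trial"].between(1, 8).all()
    assert len(trials) == 8 * len(subj)
    assert (trials["time_s"] > 0).all() and (trials["time_s"] <= 180).all()
    assert (trials["distance"] > 0).all()
    for c in ("wm_errors", "rm_errors"):
        assert (trials[c] >= 0).all()
    assert (default_cohort["exposures"][list(COMPONENTS)] > 0).to_numpy().all()


def test_counts_have_excess_zeros(default_cohort):
    # the planted structural-zero share should leave clearly more zeros than
    # a pure Poisson with the same mean would produce
    y = default_cohort["trials"]["wm_errors"].to_numpy()
    poisson_zero = np.exp(-y.mean())
    assert (y == 0).mean() > poisson_zero


def test_performance_improves_over_trials(default_cohort):
    trials = default_cohort["trials"]
    g = trials.groupby("trial")
    for col in ("time_s", "distance"):
        m = g[col].mean()
        assert m.iloc[-1] < m.iloc[0]
    # counts: the typical subject improves (the arithmetic mean is dominated
    # by the heavy upper tail of the lognormal random slopes)
    for col in ("wm_errors", "rm_errors"):
        med = g[col].median()
        assert med.iloc[-1] <= med.iloc[0]
        slopes = trials.groupby("subject_id")[["trial", col]].apply(
            lambda d: np.polyfit(d["trial"], d[col], 1)[0])
        assert np.median(slopes) < 0


def test_true_index_is_weighted_decile_sum(default_cohort, rng):
    w = rng.dirichlet(np.ones(20))
    exposures = default_cohort["exposures"]
    idx = compute_true_index(exposures, w)
    Q = decile_transform(exposures[list(COMPONENTS)])
    np.testing.assert_allclose(idx, Q.to_numpy() @ w, atol=1e-12)
    assert idx.min() >= 0 and idx.max() <= 9
    uniform = compute_true_index(exposures, np.full(20, 0.05))
    np.testing.assert_allclose(uniform, Q.mean(axis=1), atol=1e-12)


def test_true_index_rejects_bad_weights(default_cohort):
    with pytest.raises(ValidationError):
        compute_true_index(default_cohort["exposures"], np.full(20, 0.1))


def test_own_sex_index_uses_each_sexs_weights(default_cohort):
    cfg = make_config(seed=1)
    subj, exp = default_cohort["subjects"], default_cohort["exposures"]
    idx = own_sex_index(subj, exp, cfg)
    girls = subj["sex"].to_numpy() == "girl"
    idx_girl = compute_true_index(exp, cfg.true_weights["girl"])
    idx_boy = compute_true_index(exp, cfg.true_weights["boy"])
    np.testing.assert_allclose(idx[girls], idx_girl[girls])
    np.testing.assert_allclose(idx[~girls], idx_boy[~girls])


def test_marginal_fidelity_at_large_n():
    """Empirical GM/GSD of generated exposures match the configuration within
    a Monte-Carlo tolerance derived from the log-scale standard error."""
    cfg = make_config(n_subjects=10000, seed=99)
    cohort = simulate_cohort(cfg)
    exp, subj = cohort["exposures"], cohort["subjects"]
    for comp in ("blood_Mn", "urine_Cr", "saliva_Cu", "nails_Pb"):
        dist = cfg.exposure_gm_gsd[comp]
        logs = np.log(exp[comp].to_numpy())
        n = logs.size
        mu, sig = np.log(dist.gm), np.log(dist.gsd)
        se_mu = sig / np.sqrt(n)
        assert abs(logs.mean() - mu) < 4 * se_mu
        se_sig = sig / np.sqrt(2 * (n - 1))
        assert abs(logs.std(ddof=1) - sig) < 4 * se_sig
    # a sex-specific component reproduces its per-sex geometric means
    girls = subj["sex"].to_numpy() == "girl"
    dist = cfg.exposure_gm_gsd["hair_Mn"]
    assert dist.gm_girl != dist.gm_boy
    for mask, gm, gsd in ((girls, dist.gm_girl, dist.gsd_girl or dist.gsd),
                          (~girls, dist.gm_boy, dist.gsd_boy or dist.gsd)):
        logs = np.log(exp["hair_Mn"].to_numpy()[mask])
        se = np.log(gsd) / np.sqrt(mask.sum())
        assert abs(logs.mean() - np.log(gm)) < 4 * se


def test_same_metal_correlation_exceeds_cross_metal():
    cfg = make_config(n_subjects=10000, seed=99)
    exp = generate_exposures(simulate_cohort(cfg)["subjects"], cfg)
    logs = np.log(exp[list(COMPONENTS)].to_numpy())
    corr = np.corrcoef(logs.T)
    names = list(COMPONENTS)
    i, j = names.index("blood_Mn"), names.index("hair_Mn")
    k = names.index("blood_Cu")
    assert corr[i, j] > corr[i, k] > 0.0
    assert corr[i, j] == pytest.approx(cfg.corr_same_metal, abs=0.05)
    assert corr[i, k] == pytest.approx(cfg.corr_other_metal, abs=0.05)
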