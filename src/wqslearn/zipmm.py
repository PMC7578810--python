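"""Stage 1 (count outcomes): zero-inflated Poisson mixed models.

Working- and reference-memory error counts mix a structural-zero process
(probability pi, intercept-only on the logit scale) with a Poisson process
whose log rate is linear in trial and the covariates, with a correlated
random intercept + random trial slope per subject:

    P(y=0) = pi + (1-pi) exp(-lam),   P(y=k) = (1-pi) exp(-lam) lam^k / k!
    log lam_jt = x_jt' gamma + b0_j + b1_j * trial_jt,  (b0,b1) ~ N(0, Sigma)

The random effects are integrated out by adaptive Gauss-Hermite quadrature:
per-subject posterior modes and curvatures are found by Newton steps
(vectorised across subjects) and the product-rule grid is centred and scaled
there.  Order 1 reduces to the Laplace approximation, which is used as a
fast first optimisation phase.  Per-subject learning slopes are the fixed
trial coefficient plus the conditional mode of b1 (log-rate scale).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from patsy import dmatrix
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import norm

from .errors import FitError, ValidationError
from .glmm import OUTCOME_COLUMNS, _check_panel, merge_trials

_FORMULA = ("1 + trial + age + C(ses, Treatment('low')) "
            "+ C(videogames, Treatment('do_not_play')) + iq")

_LOG2PI = np.log(2.0 * np.pi)


def _zip_terms(y, eta, log1m_pi, pi, need_derivs=False):
    """Per-observation ZIP log-pmf (and optionally d/d eta derivatives).

    Shapes broadcast; ``y`` are nonnegative integers, ``eta`` = log lambda.
    """
    eta = np.minimum(eta, 50.0)  # guard exp overflow in line searches
    lam = np.exp(eta)
    pos = y > 0
    # y > 0 branch
    lp_pos = log1m_pi - lam + y * eta - gammaln(y + 1.0)
    # y = 0 branch: log(pi + (1-pi) e^-lam), stable via logaddexp
    if pi > 0:
        lp_zero = np.logaddexp(np.log(pi), log1m_pi - lam)
    else:
        lp_zero = log1m_pi - lam
    lp = np.where(pos, lp_pos, lp_zero)
    if not need_derivs:
        return lp, None, None
    u_over_A = np.exp(log1m_pi - lam - lp_zero)  # (1-pi)e^-lam / A
    d1 = np.where(pos, y - lam, -u_over_A * lam)
    d2_zero = (lam ** 2 - lam) * u_over_A - (u_over_A * lam) ** 2
    d2 = np.where(pos, -lam, d2_zero)
    return lp, d1, d2


class ZIPMixedModel:
    """Zero-inflated Poisson mixed model for one count outcome.

    Parameters
    ----------
    trials, subjects : DataFrame
        Trial-level counts and the subject covariate table.
    outcome : {'wm_errors', 'rm_errors'}
    zero_inflated : bool
        When False, pi is fixed at 0 (plain Poisson mixed model); used for
        the nested-model comparison.
    """

    def __init__(self, trials: pd.DataFrame, subjects: pd.DataFrame,
                 outcome: str, zero_inflated: bool = True):
        if outcome not in ("wm_errors", "rm_errors"):
            raise ValidationError("count outcomes are 'wm_errors' and 'rm_errors'")
        self.outcome = outcome
        self.zero_inflated = zero_inflated
        data = merge_trials(trials, subjects).sort_values(
            ["subject_id", "trial"], kind="stable").reset_index(drop=True)
        _check_panel(data)
        yv = data[OUTCOME_COLUMNS[outcome]].to_numpy()
        if np.any(yv < 0) or np.any(yv != np.round(yv)):
            raise ValidationError(f"{outcome} must be nonnegative integers")
        if np.all(yv == 0):
            raise FitError(f"{outcome} is identically zero; nothing to model")
        self.data = data

        X = dmatrix(_FORMULA, data, return_type="dataframe")
        self.term_names = [c.replace("Intercept", "intercept") for c in X.columns]
        Xm = X.to_numpy(dtype=float)
        # standardise non-intercept columns for optimisation; coefficients
        # are mapped back to the raw scale in the results
        self._x_mean = Xm.mean(axis=0)
        self._x_sd = Xm.std(axis=0)
        self._x_mean[0], self._x_sd[0] = 0.0, 1.0
        self._x_sd[self._x_sd == 0] = 1.0
        Xs = (Xm - self._x_mean) / self._x_sd

        # pad to a (n_subjects, T_max) panel
        ids = data["subject_id"].to_numpy()
        self.subject_ids = pd.unique(ids)
        sub_index = pd.Series(np.arange(len(self.subject_ids)),
                              index=self.subject_ids)
        row_sub = sub_index[ids].to_numpy()
        counts = np.bincount(row_sub)
        T = counts.max()
        n = len(self.subject_ids)
        self.Y = np.zeros((n, T))
        self.Tr = np.zeros((n, T))
        self.mask = np.zeros((n, T), dtype=bool)
        self.Xs = np.zeros((n, T, Xs.shape[1]))
        pos = np.zeros(n, dtype=int)
        for r in range(len(ids)):
            j = row_sub[r]
            k = pos[j]
            self.Y[j, k] = yv[r]
            self.Tr[j, k] = data["trial"].iloc[r]
            self.Xs[j, k] = Xs[r]
            self.mask[j, k] = True
            pos[j] += 1
        self.p = Xs.shape[1]

    # -- likelihood ---------------------------------------------------------

    def _unpack(self, theta):
        p = self.p
        gamma = theta[:p]
        psi = theta[p]
        sd0, sd1 = np.exp(theta[p + 1]), np.exp(theta[p + 2])
        rho = np.tanh(theta[p + 3])
        cov = np.array([[sd0 ** 2, rho * sd0 * sd1],
                        [rho * sd0 * sd1, sd1 ** 2]])
        pi = expit(psi) if self.zero_inflated else 0.0
        return gamma, psi, pi, cov

    def _modes(self, eta0, pi, cov, b_start=None, n_iter=25, tol=1e-8):
        """Posterior modes and curvatures of (b0, b1), Newton with halving."""
        n = eta0.shape[0]
        b = np.zeros((n, 2)) if b_start is None else b_start.copy()
        prec = np.linalg.inv(cov + 1e-12 * np.eye(2))
        log1m_pi = np.log1p(-pi)
        m = self.mask

        def hval(bb):
            eta = eta0 + bb[:, :1] + bb[:, 1:2] * self.Tr
            lp, _, _ = _zip_terms(self.Y, eta, log1m_pi, pi)
            quad = np.einsum("ni,ij,nj->n", bb, prec, bb)
            return (lp * m).sum(axis=1) - 0.5 * quad

        h = hval(b)
        for _ in range(n_iter):
            eta = eta0 + b[:, :1] + b[:, 1:2] * self.Tr
            lp, d1, d2 = _zip_terms(self.Y, eta, log1m_pi, pi, need_derivs=True)
            d1, d2 = d1 * m, d2 * m
            g0 = d1.sum(axis=1) - (prec[0, 0] * b[:, 0] + prec[0, 1] * b[:, 1])
            g1 = (d1 * self.Tr).sum(axis=1) - (prec[1, 0] * b[:, 0] + prec[1, 1] * b[:, 1])
            H00 = d2.sum(axis=1) - prec[0, 0]
            H01 = (d2 * self.Tr).sum(axis=1) - prec[0, 1]
            H11 = (d2 * self.Tr ** 2).sum(axis=1) - prec[1, 1]
            det = H00 * H11 - H01 ** 2
            det = np.where(np.abs(det) < 1e-12, 1e-12, det)
            s0 = -(H11 * g0 - H01 * g1) / det
            s1 = -(-H01 * g0 + H00 * g1) / det
            step = np.column_stack([s0, s1])
            # backtracking: halve steps that decrease h
            new_b = b + step
            new_h = hval(new_b)
            for _ in range(10):
                worse = new_h < h - 1e-12
                if not worse.any():
                    break
                step[worse] *= 0.5
                new_b = b + step
                new_h = hval(new_b)
            moved = np.max(np.abs(step), axis=1)
            b, h = new_b, new_h
            if moved.max() < tol:
                break
        # curvature at the mode
        eta = eta0 + b[:, :1] + b[:, 1:2] * self.Tr
        _, _, d2 = _zip_terms(self.Y, eta, np.log1p(-pi), pi, need_derivs=True)
        d2 = d2 * m
        H00 = -(d2.sum(axis=1) - prec[0, 0])
        H01 = -((d2 * self.Tr).sum(axis=1) - prec[0, 1])
        H11 = -((d2 * self.Tr ** 2).sum(axis=1) - prec[1, 1])
        # the zero-branch curvature can turn positive at extreme trial
        # parameters; fall back to the prior precision to keep H PD
        bad = (H00 <= 1e-10) | (H11 <= 1e-10) | (H00 * H11 - H01 ** 2 <= 1e-10)
        if bad.any():
            H00 = np.where(bad, np.maximum(H00, prec[0, 0]), H00)
            H11 = np.where(bad, np.maximum(H11, prec[1, 1]), H11)
            H01 = np.where(bad, 0.0, H01)
        return b, h, (H00, H01, H11)

    def loglik(self, theta, order: int = 7, b_start=None, return_modes=False):
        """Marginal log-likelihood by adaptive Gauss-Hermite quadrature."""
        gamma, _, pi, cov = self._unpack(theta)
        eta0 = self.Xs @ gamma
        sign, logdet_cov = np.linalg.slogdet(cov + 1e-12 * np.eye(2))
        if sign <= 0:
            return (-np.inf, None) if return_modes else -np.inf
        b, h, (H00, H01, H11) = self._modes(eta0, pi, cov, b_start=b_start)
        # h above excludes the normal constant; add it here
        h_const = -_LOG2PI - 0.5 * logdet_cov
        detH = H00 * H11 - H01 ** 2
        detH = np.maximum(detH, 1e-12)
        if order <= 1:  # Laplace
            ll = (h + h_const) + _LOG2PI - 0.5 * np.log(detH)
            total = float(ll.sum())
            return (total, b) if return_modes else total

        # cholesky of Sigma_post = H^-1 per subject (2x2, closed form)
        # L such that L L' = H^-1
        l11 = np.sqrt(H11 / detH)
        l21 = -H01 / np.sqrt(H11 * detH)
        l22 = 1.0 / np.sqrt(H11)
        nodes, wts = hermegauss(order)  # weight exp(-u^2/2)
        U0, U1 = np.meshgrid(nodes, nodes, indexing="ij")
        u0, u1 = U0.ravel(), U1.ravel()
        logw = np.log(np.outer(wts, wts).ravel())
        # b_k = mode + L u  (probabilists' nodes; posterior ~ N(mode, H^-1))
        B0 = b[:, 0:1] + l11[:, None] * u0[None, :] + 0.0 * u1[None, :]
        B1 = b[:, 1:2] + l21[:, None] * u0[None, :] + l22[:, None] * u1[None, :]
        eta = (eta0[:, None, :] + B0[:, :, None] + B1[:, :, None] * self.Tr[:, None, :])
        lp, _, _ = _zip_terms(self.Y[:, None, :], eta, np.log1p(-pi), pi)
        lp = (lp * self.mask[:, None, :]).sum(axis=2)
        prec = np.linalg.inv(cov + 1e-12 * np.eye(2))
        quad = (prec[0, 0] * B0 ** 2 + 2 * prec[0, 1] * B0 * B1 + prec[1, 1] * B1 ** 2)
        hk = lp - 0.5 * quad + h_const
        # adaptive GHE: integral = |L| sum_k w_k exp(h(b_k) + |u_k|^2/2)
        arg = hk + 0.5 * (u0 ** 2 + u1 ** 2)[None, :] + logw[None, :]
        ll = logsumexp(arg, axis=1) - 0.5 * np.log(detH)
        total = float(ll.sum())
        return (total, b) if return_modes else total

    # -- fitting ------------------------------------------------------------

    def _start(self):
        y = self.Y[self.mask]
        X = self.Xs[self.mask]
        # Poisson GLM start via a few IRLS steps
        gamma = np.zeros(self.p)
        gamma[0] = np.log(max(y.mean(), 1e-3))
        for _ in range(25):
            lam = np.exp(np.clip(X @ gamma, -20, 20))
            W = lam
            z = X @ gamma + (y - lam) / np.maximum(lam, 1e-8)
            XtW = X.T * W
            try:
                new = np.linalg.solve(XtW @ X + 1e-8 * np.eye(self.p), XtW @ z)
            except np.linalg.LinAlgError:
                break
            if np.max(np.abs(new - gamma)) < 1e-8:
                gamma = new
                break
            gamma = new
        lam = np.exp(np.clip(X @ gamma, -20, 20))
        p0_obs = float((y == 0).mean())
        p0_pois = float(np.exp(-lam).mean())
        pi0 = np.clip((p0_obs - p0_pois) / max(1 - p0_pois, 1e-6), 0.02, 0.9)
        psi0 = float(np.log(pi0 / (1 - pi0))) if self.zero_inflated else -10.0
        return np.concatenate([gamma, [psi0, np.log(0.4), np.log(0.15),
                                       np.arctanh(0.0)]])

    def fit(self, order: int = 7, maxiter: int = 200) -> "ZIPMixedResults":
        theta0 = self._start()
        cache = {"b": None}

        def make_nll(ord_):
            def nll(theta):
                ll, modes = self.loglik(theta, order=ord_,
                                        b_start=cache["b"], return_modes=True)
                cache["b"] = modes
                return -ll if np.isfinite(ll) else 1e12
            return nll

        # phase 1: Laplace; phase 2: adaptive quadrature refinement
        res1 = minimize(make_nll(1), theta0, method="L-BFGS-B",
                        options={"maxiter": maxiter, "ftol": 1e-9})
        start2 = res1.x
        if order > 1:
            res = minimize(make_nll(order), start2, method="L-BFGS-B",
                           options={"maxiter": maxiter, "ftol": 1e-10})
        else:
            res = res1
        if not np.isfinite(res.fun):
            raise FitError(f"ZIP mixed model failed for {self.outcome}")
        theta = res.x
        ll_start = self.loglik(theta0, order=order)
        ll_final = -float(res.fun)
        if ll_final + 1e-6 < ll_start:
            raise FitError("optimizer ended below its starting log-likelihood")

        se = self._wald_se(theta, order)
        return self._build_results(theta, se, ll_final, order,
                                   converged=bool(res.success))

    def _wald_se(self, theta, order):
        """SEs from a central finite-difference Hessian of the marginal
        log-likelihood (observed information)."""
        k = len(theta)
        eps = 1e-4 * np.maximum(np.abs(theta), 1.0)
        H = np.zeros((k, k))
        f0 = self.loglik(theta, order=order)

        def f(th):
            return self.loglik(th, order=order)

        for i in range(k):
            ei = np.zeros(k); ei[i] = eps[i]
            fpp = f(theta + ei); fmm = f(theta - ei)
            H[i, i] = (fpp - 2 * f0 + fmm) / eps[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k); ej[j] = eps[j]
                fpq = f(theta + ei + ej); fmq = f(theta - ei + ej)
                fqp = f(theta + ei - ej); fqq = f(theta - ei - ej)
                H[i, j] = H[j, i] = (fpq - fmq - fqp + fqq) / (4 * eps[i] * eps[j])
        try:
            cov = np.linalg.inv(-H)
            d = np.diag(cov).copy()
            d[d < 0] = np.nan
            return np.sqrt(d)
        except np.linalg.LinAlgError:
            return np.full(k, np.nan)

    def _build_results(self, theta, se, loglik, order, converged):
        gamma_s, psi, pi, cov = self._unpack(theta)
        # back-transform coefficients to the raw covariate scale
        coef = gamma_s / self._x_sd
        coef[0] = gamma_s[0] - np.sum(gamma_s[1:] * self._x_mean[1:] / self._x_sd[1:])
        se_raw = se[:self.p] / self._x_sd
        se_raw[0] = np.nan  # intercept SE not back-transformed (not reported)
        zcrit = norm.ppf(0.975)
        fixed = pd.DataFrame({
            "coef": coef,
            "se": se_raw,
            "ci_low": coef - zcrit * se_raw,
            "ci_high": coef + zcrit * se_raw,
        }, index=self.term_names)

        # conditional modes and slope SD at the optimum
        eta0 = self.Xs @ gamma_s
        b, _, (H00, H01, H11) = self._modes(eta0, pi, cov)
        detH = np.maximum(H00 * H11 - H01 ** 2, 1e-12)
        slope_cond_sd = np.sqrt(H00 / detH)

        random_effects = pd.DataFrame(b, columns=["intercept", "trial"],
                                      index=self.subject_ids)
        sd0, sd1 = np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1])
        corr = cov[0, 1] / (sd0 * sd1) if sd0 * sd1 > 0 else 0.0
        boundary = self.zero_inflated and (pi < 1e-4 or pi > 1 - 1e-4)
        return ZIPMixedResults(
            outcome=self.outcome,
            fixed_effects=fixed,
            zero_inflation_logit=float(psi),
            zero_inflation_prob=float(pi),
            random_effect_sds={"intercept": float(sd0), "slope": float(sd1),
                               "corr": float(corr)},
            marginal_loglik=float(loglik),
            quadrature_order=int(order),
            n_subjects=len(self.subject_ids),
            n_obs=int(self.mask.sum()),
            converged=converged,
            boundary_pi=bool(boundary),
            random_effects=random_effects,
            slope_cond_sd=slope_cond_sd,
            zero_inflated=self.zero_inflated,
        )


@dataclass
class ZIPMixedResults:
    """Fitted zero-inflated Poisson mixed model for one count outcome.

    Count coefficients live on the log-rate scale; per-subject learning
    slopes are therefore log-rate slopes (a constant errors-per-trial change
    on the response scale is not well defined across subjects).
    """

    outcome: str
    fixed_effects: pd.DataFrame
    zero_inflation_logit: float
    zero_inflation_prob: float
    random_effect_sds: dict
    marginal_loglik: float
    quadrature_order: int
    n_subjects: int
    n_obs: int
    converged: bool
    boundary_pi: bool
    random_effects: pd.DataFrame = field(repr=False, default=None)
    slope_cond_sd: np.ndarray = field(repr=False, default=None)
    zero_inflated: bool = True

    @property
    def loglik(self) -> float:
        return self.marginal_loglik

    @property
    def trial_effect(self) -> float:
        return float(self.fixed_effects.loc["trial", "coef"])

    @property
    def trial_ci(self) -> tuple:
        row = self.fixed_effects.loc["trial"]
        return float(row["ci_low"]), float(row["ci_high"])

    def learning_curves(self) -> pd.DataFrame:
        re = self.random_effects
        return pd.DataFrame({
            "subject_id": re.index,
            "outcome": self.outcome,
            "slope": self.trial_effect + re["trial"].to_numpy(),
            "slope_se": self.slope_cond_sd,
        }).reset_index(drop=True)

    def summary(self) -> str:
        sds = self.random_effect_sds
        return "\n".join([
            f"ZIP mixed model: {self.outcome} (AGQ order {self.quadrature_order}, "
            f"{'converged' if self.converged else 'NOT converged'}"
            + (", pi at boundary" if self.boundary_pi else "") + ")",
            f"  n = {self.n_subjects} subjects, {self.n_obs} observations, "
            f"marginal loglik = {self.marginal_loglik:.2f}",
            f"  zero inflation pi = {self.zero_inflation_prob:.3f}; "
            f"random effects: intercept SD {sds['intercept']:.3g}, "
            f"slope SD {sds['slope']:.3g}, corr {sds['corr']:.2f}",
            self.fixed_effects.round(4).to_string(),
        ])


def fit_zip_mm(trials: pd.DataFrame, subjects: pd.DataFrame, outcome: str,
               order: int = 7, zero_inflated: bool = True) -> ZIPMixedResults:
    """Fit the covariate-adjusted ZIP random-slope model for one count outcome."""
    return ZIPMixedModel(trials, subjects, outcome,
                         zero_inflated=zero_inflated).fit(order=order)


def extract_learning_curves(fit, trials: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-subject learning curves from a fitted stage-1 model.

    slope = fixed trial coefficient + conditional mode of the subject's slope
    deviation; response scale for Gaussian outcomes, log-rate scale for
    counts.  When ``trials`` is given, every subject present there must be
    covered by the fit.
    """
    curves = fit.learning_curves()
    if trials is not None:
        missing = set(trials["subject_id"]) - set(curves["subject_id"])
        if missing:
            raise ValidationError(
                f"subjects absent from the fit: {sorted(missing)[:5]}...")
    return curves
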