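"""Generalized weighted quantile sum (WQS) regression.

The mixture index WQS_j = sum_i w_i q_ij combines decile-scored exposure
components with nonnegative weights that sum to one.  Weights are estimated
as an ensemble across bootstrap resamples under a sign constraint on the
index coefficient, then the fixed-weight index is tested in a final linear
model, optionally with a sex interaction or within sex strata.  A quadratic
sensitivity check and per-matrix/per-metal sub-mixture scans complete the
analysis surface.

Weight estimation and the final test deliberately reuse the full sample (no
training/validation split); an optional split is available for larger
samples.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2
import statsmodels.api as sm

from .errors import FitError, ValidationError
from .quantiles import decile_transform

SIMPLEX_TOL = 1e-9


def _check_direction(direction: str) -> int:
    if direction == "pos":
        return 1
    if direction == "neg":
        return -1
    raise ValidationError("direction must be 'pos' or 'neg'")


def _as_sex01(sex) -> np.ndarray:
    """Coerce a sex vector to the package convention girl=1, boy=0."""
    s = np.asarray(sex)
    if s.dtype.kind in "OUS":
        vals = set(np.unique(s).tolist())
        if not vals <= {"girl", "boy"}:
            raise ValidationError(f"unknown sex labels {vals - {'girl', 'boy'}}")
        return (s == "girl").astype(float)
    s = s.astype(float)
    if not set(np.unique(s)) <= {0.0, 1.0}:
        raise ValidationError("interaction vector must be binary (girl=1, boy=0)")
    return s


@dataclass
class WeightVector:
    """Simplex weights over the mixture components."""

    w: np.ndarray
    components: tuple
    n_bootstrap_used: int = 0

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        self.components = tuple(self.components)
        if self.w.shape != (len(self.components),):
            raise ValidationError("weight/component length mismatch")
        if np.any(self.w < -SIMPLEX_TOL) or abs(self.w.sum() - 1.0) > 1e-6:
            raise ValidationError("weights are off the simplex")

    def as_series(self) -> pd.Series:
        return pd.Series(self.w, index=list(self.components), name="weight")


@dataclass
class SingleFit:
    """One sign-constrained WQS fit on one (re)sample."""

    weights: np.ndarray
    beta0: float
    beta1: float
    t_beta1: float
    converged: bool
    objective: float


def fit_wqs_single(Q: pd.DataFrame, y, direction: str = "pos",
                   w0: np.ndarray | None = None) -> SingleFit:
    """Estimate simplex weights and the index coefficient on one sample.

    Minimises the residual sum of squares of y ~ b0 + b1 * (Q @ w) over
    (b0, b1, w) with w on the simplex and sign(b1) fixed by ``direction``.
    Deterministic given the data and the starting point (uniform weights by
    default).
    """
    sign = _check_direction(direction)
    Qm = np.asarray(Q, dtype=float)
    y = np.asarray(y, dtype=float)
    n, c = Qm.shape
    if c < 1:
        raise ValidationError("need at least one mixture component")
    if y.shape != (n,):
        raise ValidationError("response length does not match Q")
    if np.any(~np.isfinite(y)):
        raise ValidationError("missing values in the response")

    # optimise on the standardised response so convergence tolerances are
    # scale-free; coefficients are mapped back afterwards
    ysd = float(y.std()) or 1.0
    ys = y / ysd
    if w0 is None:
        w0 = np.full(c, 1.0 / c)
    s0 = Qm @ w0
    v = s0.var()
    b1_start = 0.0 if v == 0 else np.cov(s0, ys, bias=True)[0, 1] / v
    b1_start = sign * max(sign * b1_start, 1e-3)
    x0 = np.concatenate([[ys.mean(), b1_start], w0])

    def objective(theta):
        b0, b1, w = theta[0], theta[1], theta[2:]
        s = Qm @ w
        r = ys - b0 - b1 * s
        f = 0.5 * float(r @ r) / n
        g = np.empty_like(theta)
        g[0] = -r.sum() / n
        g[1] = -float(r @ s) / n
        g[2:] = -b1 * (Qm.T @ r) / n
        return f, g

    bounds = [(None, None),
              (0.0, None) if sign > 0 else (None, 0.0)] + [(0.0, 1.0)] * c
    constraints = [{"type": "eq",
                    "fun": lambda th: th[2:].sum() - 1.0,
                    "jac": lambda th: np.concatenate([[0.0, 0.0], np.ones(c)])}]
    res = minimize(objective, x0, jac=True, method="SLSQP", bounds=bounds,
                   constraints=constraints,
                   options={"maxiter": 200, "ftol": 1e-10})
    w = np.clip(res.x[2:], 0.0, None)
    tot = w.sum()
    converged = bool(res.success) and tot > 0
    w = w / tot if tot > 0 else np.full(c, 1.0 / c)
    b0, b1 = float(res.x[0]) * ysd, float(res.x[1]) * ysd

    # Wald t of b1 from the fixed-weight OLS (used by the significance-
    # weighted aggregation option)
    s = Qm @ w
    X = np.column_stack([np.ones(n), s])
    beta, sse, *_ = np.linalg.lstsq(X, y, rcond=None)
    dof = max(n - 2, 1)
    sig2 = float(y @ y - beta @ (X.T @ y)) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se_b1 = np.sqrt(max(sig2 * xtx_inv[1, 1], 1e-300))
    t1 = b1 / se_b1
    return SingleFit(w, b0, b1, float(t1), converged, float(res.fun))


def bootstrap_weights(Q: pd.DataFrame, y, direction: str = "pos",
                      B: int = 100, seed: int = 0,
                      aggregation: str = "mean",
                      sampler=None) -> WeightVector:
    """Ensemble weight estimation across ``B`` bootstrap resamples.

    Subjects are resampled with replacement; each resample gets its own
    sign-constrained fit, and per-component weights are aggregated across
    converged replicates — by plain mean (default) or by a mean weighted
    with |t| of the index coefficient (``aggregation='signif'``).  Replicate
    b draws from the spawned child b of the master seed, so results do not
    depend on B or on execution order.
    """
    if B < 1:
        raise ValidationError("need at least one bootstrap replicate")
    if aggregation not in ("mean", "signif"):
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    Qm = np.asarray(Q, dtype=float)
    components = tuple(Q.columns) if hasattr(Q, "columns") else tuple(range(Qm.shape[1]))
    y = np.asarray(y, dtype=float)
    n = len(y)
    master = np.random.SeedSequence(seed)

    weights, tstats = [], []
    dropped = 0
    for b in range(B):
        if sampler is not None:
            idx = np.asarray(sampler(b, n))
        else:
            rng = np.random.default_rng(master.spawn(b + 1)[-1])
            idx = rng.integers(0, n, n)
        fit = fit_wqs_single(Qm[idx], y[idx], direction)
        if fit.converged:
            weights.append(fit.weights)
            tstats.append(abs(fit.t_beta1))
        else:
            dropped += 1
    if dropped > 0.2 * B:
        raise FitError(f"{dropped}/{B} bootstrap replicates failed to converge")
    W = np.asarray(weights)
    if aggregation == "signif":
        t = np.asarray(tstats)
        t = t if t.sum() > 0 else np.ones_like(t)
        w = (W * t[:, None]).sum(axis=0) / t.sum()
    else:
        w = W.mean(axis=0)
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    return WeightVector(w, components, n_bootstrap_used=len(weights))


@dataclass
class WqsFit:
    """Final-model results for a fixed-weight WQS index."""

    direction: str
    weights: WeightVector
    beta_index: float
    se_index: float
    ci_index: tuple
    p_index: float
    beta_interaction: Optional[float] = None
    se_interaction: Optional[float] = None
    ci_interaction: Optional[tuple] = None
    p_interaction: Optional[float] = None
    beta_sex: Optional[float] = None
    intercept: float = np.nan
    aic: float = np.nan
    loglik: float = np.nan
    n: int = 0
    params: dict = field(default_factory=dict)
    stratum: Optional[str] = None

    def attribution(self, grouping: str) -> "WeightAttribution":
        return attribute_weights(self, grouping)

    def summary(self) -> str:
        lines = [f"WQS final model (direction={self.direction}"
                 + (f", stratum={self.stratum}" if self.stratum else "") + ")",
                 f"  n = {self.n}, AIC = {self.aic:.2f}, loglik = {self.loglik:.2f}",
                 f"  index:       beta = {self.beta_index:+.4g} "
                 f"(SE {self.se_index:.3g}, p = {self.p_index:.3g})"]
        if self.beta_interaction is not None:
            lines.append(f"  sex x index: beta = {self.beta_interaction:+.4g} "
                         f"(SE {self.se_interaction:.3g}, p = {self.p_interaction:.3g})")
        top = self.weights.as_series().sort_values(ascending=False).head(5)
        lines.append("  top weights: " +
                     ", ".join(f"{k}={v:.3f}" for k, v in top.items()))
        return "\n".join(lines)


def wqs_index(Q, weights: WeightVector | np.ndarray) -> np.ndarray:
    w = weights.w if isinstance(weights, WeightVector) else np.asarray(weights)
    return np.asarray(Q, dtype=float) @ w


def fit_wqs_final(Q, y, weights: WeightVector, direction: str = "pos",
                  interaction=None, stratum: str | None = None) -> WqsFit:
    """Test the fixed-weight index in an ordinary linear model.

    y ~ WQS, plus sex main effect and WQS x sex product when ``interaction``
    is given (girl=1, boy=0).  The stage-1 learning-curve responses are
    already covariate-adjusted, so no further adjustment is applied.
    """
    _check_direction(direction)
    y = np.asarray(y, dtype=float)
    idx = wqs_index(Q, weights)
    data = {"wqs": idx}
    if interaction is not None:
        sex01 = _as_sex01(interaction)
        data["sex"] = sex01
        data["wqs_x_sex"] = idx * sex01
    X = sm.add_constant(pd.DataFrame(data), has_constant="add")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int()
    fit = WqsFit(
        direction=direction, weights=weights,
        beta_index=float(res.params["wqs"]), se_index=float(res.bse["wqs"]),
        ci_index=(float(ci.loc["wqs", 0]), float(ci.loc["wqs", 1])),
        p_index=float(res.pvalues["wqs"]),
        intercept=float(res.params["const"]),
        aic=float(res.aic), loglik=float(res.llf), n=int(res.nobs),
        params={k: float(v) for k, v in res.params.items()},
        stratum=stratum,
    )
    if interaction is not None:
        fit.beta_interaction = float(res.params["wqs_x_sex"])
        fit.se_interaction = float(res.bse["wqs_x_sex"])
        fit.ci_interaction = (float(ci.loc["wqs_x_sex", 0]),
                              float(ci.loc["wqs_x_sex", 1]))
        fit.p_interaction = float(res.pvalues["wqs_x_sex"])
        fit.beta_sex = float(res.params["sex"])
    return fit


@dataclass
class WeightAttribution:
    """Weight shares summed within metal or matrix groups, in percent."""

    grouping: str
    shares: dict

    def top(self, k: int = 2) -> list:
        return sorted(self.shares, key=self.shares.get, reverse=True)[:k]


def attribute_weights(fit: WqsFit | WeightVector, grouping: str) -> WeightAttribution:
    """Sum component weights by metal or by matrix; shares reported in %."""
    if grouping not in ("by_metal", "by_matrix"):
        raise ValidationError(f"unknown grouping {grouping!r}")
    wv = fit.weights if isinstance(fit, WqsFit) else fit
    part = 1 if grouping == "by_metal" else 0
    shares: dict = {}
    for comp, w in zip(wv.components, wv.w):
        key = str(comp).split("_")[part]
        shares[key] = shares.get(key, 0.0) + 100.0 * float(w)
    return WeightAttribution(grouping, shares)


class WQSModel:
    """Generalized WQS regression model.

    Parameters
    ----------
    exposures : DataFrame
        Raw concentrations (one column per mixture component; a subject_id
        column is ignored), or pre-scored deciles with ``deciled=True``.
    y : array-like
        Response vector, here a stage-1 learning-curve slope per subject.
    direction : 'pos' or 'neg'
        Sign constraint on the index coefficient during weight estimation.
    sex : array-like, optional
        Binary effect modifier (girl=1/boy=0 or 'girl'/'boy' labels); when
        given, ``fit`` tests the sex x index interaction.
    """

    def __init__(self, exposures: pd.DataFrame, y, direction: str = "pos",
                 sex=None, n_quantiles: int = 10, deciled: bool = False):
        _check_direction(direction)
        X = exposures.drop(columns=["subject_id"], errors="ignore")
        self.Q = X.astype(int) if deciled else decile_transform(X, n_quantiles)
        self.y = np.asarray(y, dtype=float)
        if len(self.y) != len(self.Q):
            raise ValidationError("response length does not match exposures")
        self.direction = direction
        self.sex = None if sex is None else _as_sex01(sex)

    def fit(self, n_boot: int = 100, seed: int = 0,
            aggregation: str = "mean") -> WqsFit:
        weights = bootstrap_weights(self.Q, self.y, self.direction,
                                    B=n_boot, seed=seed, aggregation=aggregation)
        return fit_wqs_final(self.Q, self.y, weights, self.direction,
                             interaction=self.sex)


def fit_wqs_stratified(Q, y, sex, direction: str = "pos", B: int = 100,
                       seed: int = 0, min_stratum: int = 30,
                       aggregation: str = "mean") -> dict:
    """Run the full weight-estimation + final-test pipeline within each sex.

    Weights are re-estimated inside each stratum, so per-sex attributions
    reflect that sex's own drivers.  Strata get independent child seeds of
    the master seed (girl first), so results do not depend on stratum order.
    """
    _check_direction(direction)
    sex01 = _as_sex01(sex)
    y = np.asarray(y, dtype=float)
    Qdf = pd.DataFrame(Q)
    out = {}
    for code, label in ((1.0, "girl"), (0.0, "boy")):
        mask = sex01 == code
        n_s = int(mask.sum())
        if n_s < min_stratum:
            raise ValidationError(f"stratum {label!r} has n={n_s} < {min_stratum}")
        # deterministic per-stratum seed: 2*seed for girls, 2*seed+1 for boys
        sub_seed = (2 * seed + (1 - int(code))) % (2 ** 31)
        w = bootstrap_weights(Qdf[mask], y[mask], direction, B=B,
                              seed=sub_seed, aggregation=aggregation)
        out[label] = fit_wqs_final(Qdf[mask], y[mask], w, direction,
                                   stratum=label)
    return out


@dataclass
class SensitivityResult:
    linear: WqsFit
    quadratic: WqsFit
    lrt: float
    df: int
    p: float
    delta_aic: float

    @property
    def quadratic_preferred(self) -> bool:
        return self.p < 0.05 and self.delta_aic < 0


def sensitivity_quadratic(Q, y, weights: WeightVector, direction: str = "pos",
                          interaction=None) -> SensitivityResult:
    """Likelihood-ratio comparison of the linear index model against one with
    an added WQS^2 term (plus sex x WQS^2 when the interaction is present)."""
    y = np.asarray(y, dtype=float)
    idx = wqs_index(Q, weights)
    linear = fit_wqs_final(Q, y, weights, direction, interaction=interaction)

    data = {"wqs": idx, "wqs2": idx ** 2}
    df = 1
    if interaction is not None:
        sex01 = _as_sex01(interaction)
        data.update({"sex": sex01, "wqs_x_sex": idx * sex01,
                     "wqs2_x_sex": idx ** 2 * sex01})
        df = 2
    X = sm.add_constant(pd.DataFrame(data), has_constant="add")
    quad_res = sm.OLS(y, X).fit()
    quadratic = WqsFit(
        direction=direction, weights=weights,
        beta_index=float(quad_res.params["wqs"]),
        se_index=float(quad_res.bse["wqs"]),
        ci_index=(float(quad_res.conf_int().loc["wqs", 0]),
                  float(quad_res.conf_int().loc["wqs", 1])),
        p_index=float(quad_res.pvalues["wqs"]),
        intercept=float(quad_res.params["const"]),
        aic=float(quad_res.aic), loglik=float(quad_res.llf),
        n=int(quad_res.nobs),
        params={k: float(v) for k, v in quad_res.params.items()},
    )
    lrt = max(2.0 * (quadratic.loglik - linear.loglik), 0.0)
    p = float(chi2.sf(lrt, df))
    return SensitivityResult(linear, quadratic, float(lrt), df, p,
                             float(quadratic.aic - linear.aic))


def _submixture_columns(components: Sequence[str]) -> dict:
    """The nine sub-mixtures: one per matrix (its four metals) and one per
    metal (its five matrices)."""
    subsets: dict = {}
    matrices = sorted({c.split("_")[0] for c in components})
    metals = sorted({c.split("_")[1] for c in components})
    for mat in matrices:
        subsets[f"matrix:{mat}"] = [c for c in components if c.startswith(mat + "_")]
    for met in metals:
        subsets[f"metal:{met}"] = [c for c in components if c.endswith("_" + met)]
    return subsets


def submixture_scan(exposures: pd.DataFrame, y, sex, B: int = 100,
                    seed: int = 0, directions: Sequence[str] = ("pos", "neg"),
                    alpha: float = 0.05) -> pd.DataFrame:
    """Sign-constrained WQS fits for each of the nine sub-mixtures, within
    each sex stratum, with Bonferroni adjustment across the nine subsets
    inside each sex x direction family."""
    X = exposures.drop(columns=["subject_id"], errors="ignore")
    Q = decile_transform(X)
    y = np.asarray(y, dtype=float)
    sex01 = _as_sex01(sex)
    subsets = _submixture_columns(list(X.columns))

    rows = []
    for direction in directions:
        for code, label in ((1.0, "girl"), (0.0, "boy")):
            mask = sex01 == code
            for k, (name, cols) in enumerate(sorted(subsets.items())):
                sub_seed = (seed * 1000003 + k) % (2 ** 31)
                w = bootstrap_weights(Q.loc[mask, cols], y[mask], direction,
                                      B=B, seed=sub_seed)
                fit = fit_wqs_final(Q.loc[mask, cols], y[mask], w, direction,
                                    stratum=label)
                rows.append({"subset": name, "sex": label, "direction": direction,
                             "beta": fit.beta_index, "se": fit.se_index,
                             "p": fit.p_index, "n": fit.n,
                             "top_component": fit.weights.as_series().idxmax()})
    out = pd.DataFrame(rows)
    m = len(subsets)
    out["p_adjusted"] = np.minimum(out["p"] * m, 1.0)
    out["significant"] = out["p_adjusted"] < alpha
    return out
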