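"""End-to-end orchestration: simulate -> learning curves -> WQS -> report.

Reproduces the full analysis graph on a synthetic or user-supplied cohort:
four outcomes, sex-interaction and sex-stratified WQS models in both index
directions, quadratic sensitivity comparisons and per-matrix/per-metal
sub-mixture scans.  Every artefact is written with a content digest into a
run manifest, and a fixed master seed reproduces every output byte for byte.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import __version__
from .config import COMPONENTS, GAUSSIAN_OUTCOMES, OUTCOMES, GeneratorConfig
from .errors import ValidationError
from .glmm import fit_lmm
from .io import validate_cohort, write_results, write_tables
from .quantiles import decile_transform
from .simulate import simulate_cohort
from .wqs import (WqsFit, attribute_weights, bootstrap_weights, fit_wqs_final,
                  fit_wqs_stratified, sensitivity_quadratic, submixture_scan)
from .zipmm import fit_zip_mm

ALL_ANALYSES = ("glmm", "interaction", "stratified", "sensitivity", "submixture")
DIRECTIONS = ("pos", "neg")


def _derived_seed(master: int, outcome: str, direction: str, analysis: str) -> int:
    """Deterministic per-model seed: a fixed counter offset per
    outcome x direction x analysis slot, independent of execution order."""
    o = OUTCOMES.index(outcome)
    d = DIRECTIONS.index(direction)
    a = ALL_ANALYSES.index(analysis)
    return (master * 1000003 + o * 64 + d * 8 + a) % (2 ** 31)


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    seed: int
    version: str
    config: dict
    analyses: tuple
    n_boot: int
    file_digests: dict = field(default_factory=dict)
    convergence: dict = field(default_factory=dict)
    model_counts: dict = field(default_factory=dict)

    def register(self, path: Path) -> None:
        self.file_digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class ResultsSummary:
    """Per-outcome headline numbers mirroring the analysis narrative."""

    outcomes: dict = field(default_factory=dict)

    def to_markdown(self) -> str:
        lines = ["| outcome | learning slope [95% CI] | interaction beta (p) | "
                 "girls beta (p) | boys beta (p) | top components | quadratic? |",
                 "|---|---|---|---|---|---|---|"]
        for name, o in self.outcomes.items():
            sl = o.get("slope", {})
            it = o.get("interaction", {})
            g = o.get("girls", {})
            b = o.get("boys", {})
            top = ", ".join(o.get("top_components", [])[:3])
            lines.append(
                f"| {name} | {sl.get('estimate', float('nan')):.3g} "
                f"[{sl.get('ci_low', float('nan')):.3g}, {sl.get('ci_high', float('nan')):.3g}] "
                f"| {it.get('beta', float('nan')):.3g} ({it.get('p', float('nan')):.2g}) "
                f"| {g.get('beta', float('nan')):.3g} ({g.get('p', float('nan')):.2g}) "
                f"| {b.get('beta', float('nan')):.3g} ({b.get('p', float('nan')):.2g}) "
                f"| {top} | {o.get('quadratic_preferred', '')} |")
        return "\n".join(lines)


@dataclass
class PipelineResult:
    manifest: RunManifest
    summary: ResultsSummary
    curves: pd.DataFrame
    stage1: dict
    wqs_fits: dict
    submixtures: dict = field(default_factory=dict)


def _fit_record(fit: WqsFit) -> dict:
    rec = {
        "direction": fit.direction, "stratum": fit.stratum,
        "beta_index": fit.beta_index, "se_index": fit.se_index,
        "ci_index": list(fit.ci_index), "p_index": fit.p_index,
        "aic": fit.aic, "loglik": fit.loglik, "n": fit.n,
        "weights": {c: w for c, w in zip(fit.weights.components, fit.weights.w)},
        "n_bootstrap_used": fit.weights.n_bootstrap_used,
        "metal_shares": attribute_weights(fit, "by_metal").shares,
        "matrix_shares": attribute_weights(fit, "by_matrix").shares,
    }
    if fit.beta_interaction is not None:
        rec.update({"beta_interaction": fit.beta_interaction,
                    "se_interaction": fit.se_interaction,
                    "ci_interaction": list(fit.ci_interaction),
                    "p_interaction": fit.p_interaction,
                    "beta_sex": fit.beta_sex})
    return rec


def run_all(config: GeneratorConfig | None = None, seed: int = 0,
            out_dir=None, analyses=ALL_ANALYSES, n_boot: int = 100,
            tables: dict | None = None) -> PipelineResult:
    """Execute the analysis graph in dependency order.

    Parameters
    ----------
    config : GeneratorConfig, optional
        Generator settings used when ``tables`` is not supplied.
    seed : int
        Master seed; every stage derives its own child seed from it.
    out_dir : path, optional
        When given, all result files plus ``manifest.json``/``summary.json``
        are written there.
    analyses : sequence
        Subset of {'glmm','interaction','stratified','sensitivity',
        'submixture'} to run; stage 1 ('glmm') is always required and
        implied.
    tables : dict, optional
        Pre-built {'subjects','exposures','trials'} tables; bypasses
        simulation.
    """
    unknown = set(analyses) - set(ALL_ANALYSES)
    if unknown:
        raise ValidationError(f"unknown analyses {sorted(unknown)}")
    config = config or GeneratorConfig()
    if tables is None:
        tables = simulate_cohort(config, seed=seed)
    validate_cohort(tables["subjects"], tables["exposures"], tables["trials"])
    subjects, exposures, trials = (tables["subjects"], tables["exposures"],
                                   tables["trials"])

    manifest = RunManifest(seed=seed, version=__version__,
                           config=config.to_dict(), analyses=tuple(analyses),
                           n_boot=n_boot)
    summary = ResultsSummary()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        for name, p in write_tables(tables, out_path).items():
            manifest.register(p)

    # ---- stage 1: learning curves ----------------------------------------
    stage1 = {}
    curve_rows = []
    for outcome in OUTCOMES:
        if outcome in GAUSSIAN_OUTCOMES:
            res = fit_lmm(trials, subjects, outcome)
        else:
            res = fit_zip_mm(trials, subjects, outcome)
        stage1[outcome] = res
        manifest.convergence[f"glmm_{outcome}"] = bool(res.converged)
        curve_rows.append(res.learning_curves())
        ci = res.trial_ci
        summary.outcomes[outcome] = {
            "slope": {"estimate": res.trial_effect, "ci_low": ci[0],
                      "ci_high": ci[1]},
        }
    manifest.model_counts["glmm"] = len(stage1)
    curves = pd.concat(curve_rows, ignore_index=True)
    if out_path is not None:
        p = out_path / "curves.csv"
        curves.to_csv(p, index=False)
        manifest.register(p)
        for outcome, res in stage1.items():
            fp = out_path / f"fit_{outcome}.json"
            write_results({
                "outcome": outcome,
                "fixed_effects": res.fixed_effects.reset_index()
                .rename(columns={"index": "term"}),
                "random_effect_sds": res.random_effect_sds,
                "loglik": res.loglik,
                "converged": res.converged,
            }, fp)
            manifest.register(fp)

    # ---- stage 2: WQS --------------------------------------------------
    sex = subjects["sex"].to_numpy()
    Q = decile_transform(exposures[list(COMPONENTS)])
    wqs_fits: dict = {}
    submixtures: dict = {}
    order = {sid: i for i, sid in enumerate(subjects["subject_id"])}
    n_int, n_strat, n_sens, n_sub = 0, 0, 0, 0
    for outcome in OUTCOMES:
        yc = curves[curves["outcome"] == outcome]
        y = yc.set_index("subject_id")["slope"].reindex(subjects["subject_id"]).to_numpy()
        per_outcome: dict = {}

        if "interaction" in analyses:
            for direction in DIRECTIONS:
                s = _derived_seed(seed, outcome, direction, "interaction")
                w = bootstrap_weights(Q, y, direction, B=n_boot, seed=s)
                fit = fit_wqs_final(Q, y, w, direction, interaction=sex)
                per_outcome[f"interaction_{direction}"] = fit
                n_int += 1
            it = per_outcome["interaction_pos"]
            summary.outcomes[outcome]["interaction"] = {
                "beta": it.beta_interaction, "p": it.p_interaction}
            summary.outcomes[outcome]["top_components"] = list(
                it.weights.as_series().sort_values(ascending=False).head(3).index)
            summary.outcomes[outcome]["metal_shares"] = attribute_weights(
                it, "by_metal").shares
            summary.outcomes[outcome]["matrix_shares"] = attribute_weights(
                it, "by_matrix").shares

        if "stratified" in analyses:
            for direction in DIRECTIONS:
                s = _derived_seed(seed, outcome, direction, "stratified")
                strat = fit_wqs_stratified(Q, y, sex, direction, B=n_boot, seed=s)
                for label, fit in strat.items():
                    per_outcome[f"stratified_{label}_{direction}"] = fit
                    n_strat += 1
            # per-sex headline: the direction matching that sex's planted sign
            g = per_outcome["stratified_girl_pos"]
            b = per_outcome["stratified_boy_neg"]
            summary.outcomes[outcome]["girls"] = {"beta": g.beta_index,
                                                  "p": g.p_index}
            summary.outcomes[outcome]["boys"] = {"beta": b.beta_index,
                                                 "p": b.p_index}

        if "sensitivity" in analyses:
            base = per_outcome.get("interaction_pos")
            if base is None:
                s = _derived_seed(seed, outcome, "pos", "sensitivity")
                w = bootstrap_weights(Q, y, "pos", B=n_boot, seed=s)
            else:
                w = base.weights
            sens = sensitivity_quadratic(Q, y, w, "pos", interaction=sex)
            per_outcome["sensitivity"] = sens
            summary.outcomes[outcome]["quadratic_preferred"] = sens.quadratic_preferred
            summary.outcomes[outcome]["lrt"] = {"stat": sens.lrt, "p": sens.p,
                                                "delta_aic": sens.delta_aic}
            n_sens += 1

        if "submixture" in analyses:
            s = _derived_seed(seed, outcome, "pos", "submixture")
            scan = submixture_scan(exposures, y, sex, B=n_boot, seed=s)
            submixtures[outcome] = scan
            n_sub += len(scan)
            summary.outcomes[outcome]["significant_submixtures"] = (
                scan.loc[scan["significant"],
                         ["subset", "sex", "direction"]].to_dict(orient="records"))

        wqs_fits[outcome] = per_outcome
        if out_path is not None:
            for key, fit in per_outcome.items():
                if key == "sensitivity":
                    rec = {"lrt": fit.lrt, "df": fit.df, "p": fit.p,
                           "delta_aic": fit.delta_aic,
                           "linear": _fit_record(fit.linear),
                           "quadratic": _fit_record(fit.quadratic)}
                else:
                    rec = _fit_record(fit)
                fp = out_path / f"wqs_{outcome}_{key}.json"
                write_results(rec, fp)
                manifest.register(fp)
            if outcome in submixtures:
                fp = out_path / f"submixture_{outcome}.csv"
                submixtures[outcome].to_csv(fp, index=False)
                manifest.register(fp)

    manifest.model_counts.update({
        "wqs_interaction": n_int, "wqs_stratified": n_strat,
        "sensitivity": n_sens, "submixture": n_sub})

    if out_path is not None:
        fp = out_path / "summary.json"
        write_results(summary.outcomes, fp)
        manifest.register(fp)
        fp = out_path / "summary.md"
        fp.write_text(summary.to_markdown() + "\n")
        manifest.register(fp)
        write_results({k: getattr(manifest, k) for k in
                       ("seed", "version", "config", "analyses", "n_boot",
                        "file_digests", "convergence", "model_counts")},
                      out_path / "manifest.json")

    return PipelineResult(manifest=manifest, summary=summary, curves=curves,
                          stage1=stage1, wqs_fits=wqs_fits,
                          submixtures=submixtures)


@dataclass
class ModelComparison:
    lrt: float
    df: int
    p: float
    delta_aic: float
    interaction_preferred: bool


def compare_models(fit_with: WqsFit, fit_without: WqsFit) -> ModelComparison:
    """Likelihood-ratio and AIC comparison of nested final WQS models.

    ``fit_with`` must extend ``fit_without`` (same data, extra terms, e.g.
    sex main effect + sex x index).  Flags 'interaction preferred' when the
    LRT rejects at 0.05 and the AIC agrees.
    """
    if fit_with.n != fit_without.n:
        raise ValidationError("model comparison requires identical data")
    k_with, k_without = len(fit_with.params), len(fit_without.params)
    if k_with < k_without or not set(fit_without.params) <= set(fit_with.params):
        raise ValidationError("models are not nested")
    df = k_with - k_without
    lrt = max(2.0 * (fit_with.loglik - fit_without.loglik), 0.0)
    p = float(chi2.sf(lrt, df)) if df > 0 else 1.0
    delta_aic = fit_with.aic - fit_without.aic
    return ModelComparison(float(lrt), df, p, float(delta_aic),
                           bool(p < 0.05 and delta_aic < 0))


def cohort_accounting(counts) -> pd.DataFrame:
    """Completion percentages along an enrollment funnel.

    ``counts``: ordered mapping or list of (stage, count) with nonnegative,
    non-increasing counts.  Percentages are relative to the first stage and
    rounded to integer percent.
    """
    if isinstance(counts, dict):
        items = list(counts.items())
    else:
        items = list(counts)
    if not items:
        raise ValidationError("empty funnel")
    values = [int(v) for _, v in items]
    if any(v < 0 for v in values):
        raise ValidationError("funnel counts must be nonnegative")
    if any(b > a for a, b in zip(values, values[1:])):
        raise ValidationError("funnel counts must be non-increasing")
    base = values[0]
    pct = [int(round(100.0 * v / base)) if base else 0 for v in values]
    return pd.DataFrame({"stage": [k for k, _ in items], "count": values,
                         "percent": pct})
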