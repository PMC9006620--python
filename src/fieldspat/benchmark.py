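"""Monte-Carlo study runner.

Reproduces the simulation studies at configurable scale: univariate
observational and checkerboard hypothesis-testing studies (type I
error, power, coefficient MSE), the low-dimensional prediction study
(three R-squared measures, adjusted Moran's I diagnostics) and the
high-dimensional feature-selection study (sensitivity, TDP, red-shift).

Every replicate draws its random stream from (master_seed, stream
index), so results are independent of execution order. Results come
back as tidy tables with one row per (replicate, method, scenario,
metric, value); failed fits are logged and score R^2 = 0 by the
failed-fit rule.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation as ev
from .datasets import simulate_checkerboard, simulate_observational, simulate_test_set
from .gls import add_row_col_dummies, fit_gls, fit_ols
from .pengls import fit_en, fit_en_eigen, fit_pengls, tune_lambda
from .scenarios import STRUCTURES, ScenarioSpec

__all__ = [
    "StudyConfig",
    "StudyResult",
    "run_univariate_observational",
    "run_univariate_checkerboard",
    "run_lowdim",
    "run_highdim",
    "summarize",
]

logger = logging.getLogger(__name__)

ALPHA_LEVEL = 0.05  # significance level of the univariate tests
#: standard deviation of the univariate alternative effect (variance 0.25)
UNIVARIATE_BETA_SD = 0.5


def scenario_spec(structure: str, sigma2: float = 1.0) -> ScenarioSpec:
    """ScenarioSpec for a structure label with the study's parameters."""
    if structure == "gaussCor":
        return ScenarioSpec.gauss_cor(sigma2=sigma2)
    return ScenarioSpec(structure, sigma2=sigma2)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one Monte-Carlo study."""

    study: str
    n_reps: int = 100
    methods: Sequence[str] = ("ols", "gls")
    outcome_structures: Sequence[str] = STRUCTURES
    regressor_structures: Sequence[str] = STRUCTURES
    n: int = 100
    p: int = 1
    grid_size: int = 15
    beta_sd: float = 1.0
    beta_setting: str = "null"  # univariate studies: 'null' or 'alternative'
    subplot_sizes: Sequence[int] = (9, 6, 3)
    row_col_correction: Sequence[bool] = (False, True)
    folds: int = 10
    cv_schemes: Sequence[str] = ("random", "blocked")
    alpha: float = 0.5
    master_seed: int = 0

    def rep_seed(self, *stream) -> np.random.SeedSequence:
        """Seed sequence for one replicate stream, order-independent.

        String stream components are hashed with crc32 (stable across
        processes, unlike the built-in hash).
        """
        parts = [zlib.crc32(s.encode()) if isinstance(s, str) else int(s)
                 for s in stream]
        return np.random.SeedSequence([self.master_seed, *parts])


@dataclass
class StudyResult:
    """Tidy metric table plus the per-replicate failure log."""

    table: pd.DataFrame
    failures: list = dc_field(default_factory=list)

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def _rows(rep, method, out_s, reg_s, metrics: dict, **extra):
    base = {"replicate": rep, "method": method, "scenario_outcome": out_s,
            "scenario_regressor": reg_s, **extra}
    return [{**base, "metric": k, "value": v} for k, v in metrics.items()]


# ------------------------------------------------- univariate studies

def _fit_univariate(method, A, B, design):
    if method == "ols":
        return fit_ols(A, B)
    if method == "gls":
        return fit_gls(A, B, design)
    raise ValueError(f"univariate study supports ols/gls, not {method!r}")


def run_univariate_observational(config: StudyConfig) -> StudyResult:
    """Type I error / power / MSE of the univariate observational study.

    One continuous regressor per dataset; under the null beta = 0, under
    the alternative beta ~ N(0, 0.25) per replicate.
    """
    if not config.methods:
        raise ValueError("no methods requested")
    rows, failures = [], []
    for out_s in config.outcome_structures:
        for reg_s in config.regressor_structures:
            for rep in range(config.n_reps):
                ss = config.rep_seed("uni_obs", out_s, reg_s, rep)
                rng = np.random.default_rng(ss)
                beta = (0.0 if config.beta_setting == "null"
                        else rng.normal(0.0, UNIVARIATE_BETA_SD))
                ds = simulate_observational(
                    p=1, n=config.n, G=config.grid_size,
                    outcome_spec=scenario_spec(out_s),
                    regressor_spec=scenario_spec(reg_s),
                    spatial_fraction=1.0 if reg_s != "none" else 0.0,
                    seed=rng, beta=beta,
                )
                for method in config.methods:
                    try:
                        fit = _fit_univariate(method, ds.A, ds.B, ds.design)
                    except Exception as e:  # noqa: BLE001
                        failures.append((out_s, reg_s, rep, method, str(e)))
                        continue
                    metrics = {
                        "reject": float(fit.wald_test(0) < ALPHA_LEVEL),
                        "beta_mse": ev.beta_mse(fit.params[1:], ds.truth.beta),
                        "cov_failed": float(getattr(fit, "cov_failed", False)),
                    }
                    rows.extend(_rows(rep, method, out_s, reg_s, metrics))
    return StudyResult(pd.DataFrame(rows), failures)


def run_univariate_checkerboard(config: StudyConfig) -> StudyResult:
    """Checkerboard-design study: rejection rates by subplot size.

    For each outcome structure and subplot size the treatment test runs
    with and without row/column dummy correction.
    """
    if not config.methods:
        raise ValueError("no methods requested")
    rows, failures = [], []
    for out_s in config.outcome_structures:
        for s in config.subplot_sizes:
            for rep in range(config.n_reps):
                ss = config.rep_seed("uni_chk", out_s, s, rep)
                rng = np.random.default_rng(ss)
                beta = (0.0 if config.beta_setting == "null"
                        else rng.normal(0.0, UNIVARIATE_BETA_SD))
                ds = simulate_checkerboard(s, scenario_spec(out_s), beta=beta,
                                           n=config.n, seed=rng)
                for correct in config.row_col_correction:
                    B = ds.B
                    if correct:
                        B, _ = add_row_col_dummies(ds.B, ds.design)
                    for method in config.methods:
                        try:
                            fit = _fit_univariate(method, ds.A, B, ds.design)
                        except Exception as e:  # noqa: BLE001
                            failures.append((out_s, s, correct, rep, method, str(e)))
                            continue
                        metrics = {
                            "reject": float(fit.wald_test(0) < ALPHA_LEVEL),
                            "beta_mse": ev.beta_mse(fit.params[1:2], ds.truth.beta),
                        }
                        rows.extend(_rows(rep, method, out_s, "checkerboard",
                                          metrics, subplot_size=s,
                                          row_col_correction=correct))
    return StudyResult(pd.DataFrame(rows), failures)


# ------------------------------------------------- low-dimensional study

def run_lowdim(config: StudyConfig) -> StudyResult:
    """Prediction study: three R-squared measures and Moran diagnostics.

    For each method, computes cross-validated R-squared under random and
    blocked folds, R-squared on matched spatial and structure-free test
    sets (trained on the data minus one fold so training sizes match the
    CV), plus expectation-adjusted Moran's I of the training, CV and
    test residuals, and the MSE of beta.
    """
    rows, failures = [], []
    p = config.p if config.p > 1 else 50
    for out_s in config.outcome_structures:
        for reg_s in config.regressor_structures:
            for rep in range(config.n_reps):
                ss = config.rep_seed("lowdim", out_s, reg_s, rep)
                rng = np.random.default_rng(ss)
                ds = simulate_observational(
                    p=p, n=config.n, G=config.grid_size,
                    outcome_spec=scenario_spec(out_s),
                    regressor_spec=scenario_spec(reg_s),
                    beta_sd=config.beta_sd, seed=rng,
                )
                test_seed = rng.integers(2**31)
                ts_spatial = simulate_test_set(ds.truth, "spatial", seed=test_seed)
                ts_none = simulate_test_set(ds.truth, "none", seed=test_seed + 1)
                fold_seed = int(rng.integers(2**31))
                folds = {
                    "random": ev.random_folds(config.n, config.folds, fold_seed),
                    "blocked": ev.blocked_folds(ds.design, config.folds, fold_seed),
                }
                for method in config.methods:
                    fit_fn = (lambda A, B, d: fit_ols(A, B)) if method == "ols" \
                        else (lambda A, B, d: fit_gls(A, B, d))
                    try:
                        full_fit = fit_fn(ds.A, ds.B, ds.design)
                        metrics = {"beta_mse": ev.beta_mse(full_fit.params[1:],
                                                           ds.truth.beta)}
                        metrics["morans_i_train"] = ev.adjusted_morans_i(
                            ds.A, ds.design, "conditional",
                            full_fit.predict(ds.B))
                        for scheme in config.cv_schemes:
                            fa = folds[scheme]
                            metrics[f"cv_r2_{scheme}"] = ev.cv_r_squared(
                                fit_fn, ds, fa)
                            # CV Moran's I: residuals of the left-out folds
                            morans = []
                            for train, test in fa.split():
                                sub = ds.subset(train)
                                f = fit_fn(sub.A, sub.B, sub.design)
                                if len(test) >= 3:
                                    morans.append(ev.adjusted_morans_i(
                                        ds.A[test], ds.design.subset(test),
                                        "conditional", f.predict(ds.B[test])))
                            metrics[f"morans_i_cv_{scheme}"] = float(np.mean(morans))
                        # test-set evaluation: train on data minus one fold
                        train, _ = next(folds["random"].split())
                        sub = ds.subset(train)
                        sub_fit = fit_fn(sub.A, sub.B, sub.design)
                        for label, ts in (("spatial", ts_spatial), ("none", ts_none)):
                            pred = sub_fit.predict(ts.B)
                            metrics[f"test_r2_{label}"] = ev.r_squared_centered(
                                ts.A, pred)
                            if label == "spatial":
                                metrics["morans_i_test"] = ev.adjusted_morans_i(
                                    ts.A, ts.design, "conditional", pred)
                    except Exception as e:  # noqa: BLE001
                        failures.append((out_s, reg_s, rep, method, str(e)))
                        metrics = {"cv_r2_random": 0.0, "cv_r2_blocked": 0.0,
                                   "test_r2_spatial": 0.0, "test_r2_none": 0.0}
                    rows.extend(_rows(rep, method, out_s, reg_s, metrics))
    return StudyResult(pd.DataFrame(rows), failures)


# ------------------------------------------------- high-dimensional study

def _fit_highdim(method, A, B, design, lam, alpha):
    if method == "en":
        return fit_en(A, B, design, lam=lam, alpha=alpha)
    if method == "pengls":
        return fit_pengls(A, B, design, lam, alpha=alpha)
    if method == "en_eigen":
        return fit_en_eigen(A, B, design, lam, alpha=alpha)
    raise ValueError(f"high-dimensional study supports en/pengls/en_eigen, not {method!r}")


def run_highdim(config: StudyConfig) -> StudyResult:
    """Feature-selection study for the elastic-net variants.

    Per replicate and CV paradigm: tune lambda by the one-SE rule, fit
    on the full data, record selection metrics (sensitivity, TDP,
    spatial share of the selections) and the R-squared on a
    structure-free test set of a model trained on the data minus one
    fold at the tuned lambda.
    """
    rows, failures = [], []
    for out_s in config.outcome_structures:
        for reg_s in config.regressor_structures:
            for rep in range(config.n_reps):
                ss = config.rep_seed("highdim", out_s, reg_s, rep)
                rng = np.random.default_rng(ss)
                ds = simulate_observational(
                    p=config.p, n=config.n, G=config.grid_size,
                    outcome_spec=scenario_spec(out_s),
                    regressor_spec=scenario_spec(reg_s),
                    beta_sd=config.beta_sd, seed=rng,
                )
                test_seed = int(rng.integers(2**31))
                ts_none = simulate_test_set(ds.truth, "none", seed=test_seed)
                fold_seed = int(rng.integers(2**31))
                for scheme in config.cv_schemes:
                    fa = (ev.random_folds(config.n, config.folds, fold_seed)
                          if scheme == "random"
                          else ev.blocked_folds(ds.design, config.folds, fold_seed))
                    for method in config.methods:
                        try:
                            lam = tune_lambda(ds.A, ds.B, ds.design, fa,
                                              alpha=config.alpha, method=method)
                            fit = _fit_highdim(method, ds.A, ds.B, ds.design, lam,
                                               config.alpha)
                            sens, tdp, sprop = ev.selection_metrics(
                                fit.selected, ds.truth)
                            train, _ = next(fa.split())
                            sub = ds.subset(train)
                            sub_fit = _fit_highdim(method, sub.A, sub.B, sub.design,
                                                   lam, config.alpha)
                            test_r2 = ev.r_squared_centered(
                                ts_none.A, sub_fit.predict(ts_none.B))
                            metrics = {
                                "sensitivity": sens, "tdp": tdp,
                                "spatial_selected_prop": sprop,
                                "test_r2_none": test_r2,
                                "n_selected": float(fit.selected.size),
                                "lambda": lam,
                            }
                        except Exception as e:  # noqa: BLE001
                            failures.append((out_s, reg_s, rep, scheme, method,
                                             str(e)))
                            metrics = {"test_r2_none": 0.0}
                        rows.extend(_rows(rep, method, out_s, reg_s, metrics,
                                          cv_scheme=scheme))
    return StudyResult(pd.DataFrame(rows), failures)


# ------------------------------------------------- aggregation

def summarize(result: StudyResult) -> pd.DataFrame:
    """Per-cell means with Monte-Carlo standard errors.

    Groups the tidy table over everything except replicate and value;
    NaN metric values (undefined ratios) are dropped per cell, the count
    of dropped values reported alongside.
    """
    df = result.table
    if df.empty:
        raise ValueError("empty study result")
    keys = [c for c in df.columns if c not in ("replicate", "value")]

    def agg(g: pd.DataFrame) -> pd.Series:
        vals = g["value"].dropna()
        n = len(vals)
        return pd.Series({
            "mean": vals.mean() if n else np.nan,
            "mc_se": vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "n": n,
            "n_undefined": int(g["value"].isna().sum()),
        })

    out = df.groupby(keys, dropna=False).apply(agg, include_groups=False)
    return out.reset_index()
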