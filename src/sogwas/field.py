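"""Within-trial correction of plot phenotypes and heritability.

Per environment and trait, the row-column model

    Y_htfrc = mu + lambda_t + delta_f + R_r + C_c + G_h + E_htfrc

is fitted with fixed check effects lambda_t (4 checks + experimental),
an optional fixed precocity-block effect delta_f, and independent
random row, column and genotype effects (variances sigma2_R, sigma2_C,
sigma2_G) plus iid error.  Row and column effects are predicted by BLUP
and subtracted from the raw plot values; the genetic effect is left in
the corrected value.

Panel networks evaluated in different trials are put on a common scale
by shifting one panel by the difference of the mean corrected check
phenotypes.  Broad-sense heritabilities are entry-mean H2:

    single-env:  H2 = s2_G / (s2_G + s2_e / rbar)
    multi-env:   H2 = s2_G / (s2_G + s2_GxE / n_env + s2_e / (n_env rbar))

with rbar the harmonic-mean replicate count per genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import logger
from .reml import RemlResult, incidence, reml

MANDATORY_PLOT_COLUMNS = ("hybrid", "check", "row", "col", "env", "nplants")


def filter_density(plots: pd.DataFrame, offset: int = 15) -> pd.DataFrame:
    """Discard low-density plots.

    Keeps plots whose plant count is *not lower than* the per-environment
    median minus ``offset`` plants (strict "lower than" boundary: a plot
    exactly at median - offset is retained).
    """
    if plots["nplants"].isna().all():
        raise ValueError("all plant counts missing")
    out = []
    for env, grp in plots.groupby("env", sort=False):
        med = grp["nplants"].median()
        keep = grp[~(grp["nplants"] < med - offset)]
        dropped = len(grp) - len(keep)
        if dropped:
            logger.info("density filter: %s dropped %d of %d plots", env, dropped, len(grp))
        out.append(keep)
    return pd.concat(out, ignore_index=True)


def filter_outliers(
    plots: pd.DataFrame, trait: str, k: float = 3.0
) -> pd.DataFrame:
    """Optional robust outlier filter: drop |value - median| > k IQR per env."""
    out = []
    for env, grp in plots.groupby("env", sort=False):
        v = grp[trait]
        iqr = v.quantile(0.75) - v.quantile(0.25)
        if iqr <= 0:
            out.append(grp)
            continue
        keep = grp[(v - v.median()).abs() <= k * iqr]
        out.append(keep)
    return pd.concat(out, ignore_index=True)


@dataclass
class FieldModelFit:
    env: str
    trait: str
    intercept: float
    check_effects: dict[str, float]
    block_effects: dict[str, float]
    row_blup: dict[int, float]
    col_blup: dict[int, float]
    sigma2: dict[str, float]  # row, col, genetic, error
    loglik: float
    aic: float
    bic: float
    reml: RemlResult


def _field_design(
    grp: pd.DataFrame, with_block: bool
) -> tuple[np.ndarray, list[str]]:
    n = len(grp)
    cols = [np.ones(n)]
    names = ["mu"]
    checks = [c for c in pd.unique(grp["check"]) if c != "experimental"]
    for c in checks:
        cols.append((grp["check"] == c).to_numpy(dtype=float))
        names.append(f"check:{c}")
    if with_block and "block" in grp.columns:
        blocks = list(pd.unique(grp["block"]))
        for b in blocks[1:]:
            cols.append((grp["block"] == b).to_numpy(dtype=float))
            names.append(f"block:{b}")
    return np.column_stack(cols), names


def fit_field_model(
    plots: pd.DataFrame,
    env: str,
    trait: str,
    with_block: bool = True,
    include_row: bool = True,
    include_col: bool = True,
) -> FieldModelFit:
    """REML fit of the row-column correction model for one environment."""
    grp = plots[plots["env"] == env]
    if grp.empty:
        raise ValueError(f"no plots for environment {env!r}")
    if include_row and grp["row"].nunique() < 2:
        raise ValueError("need at least 2 rows")
    if include_col and grp["col"].nunique() < 2:
        raise ValueError("need at least 2 columns")
    y = grp[trait].to_numpy(dtype=float)
    X, fixed_names = _field_design(grp, with_block)
    terms: dict[str, np.ndarray] = {}
    zr, row_levels = incidence(grp["row"])
    zc, col_levels = incidence(grp["col"])
    zg, gen_levels = incidence(grp["hybrid"])
    if include_row:
        terms["row"] = zr @ zr.T
    if include_col:
        terms["col"] = zc @ zc.T
    terms["genetic"] = zg @ zg.T
    terms["error"] = np.eye(len(y))
    fit = reml(y, X, terms)
    # BLUPs: u_hat = sigma2 Z' P y
    row_blup = (
        dict(zip(row_levels, fit.sigma2["row"] * (zr.T @ fit.py)))
        if include_row
        else {lv: 0.0 for lv in row_levels}
    )
    col_blup = (
        dict(zip(col_levels, fit.sigma2["col"] * (zc.T @ fit.py)))
        if include_col
        else {lv: 0.0 for lv in col_levels}
    )
    effects = dict(zip(fixed_names, fit.beta))
    return FieldModelFit(
        env=env,
        trait=trait,
        intercept=float(effects.pop("mu")),
        check_effects={k.split(":", 1)[1]: float(v) for k, v in effects.items() if k.startswith("check:")},
        block_effects={k.split(":", 1)[1]: float(v) for k, v in effects.items() if k.startswith("block:")},
        row_blup={k: float(v) for k, v in row_blup.items()},
        col_blup={k: float(v) for k, v in col_blup.items()},
        sigma2={k: fit.sigma2.get(k, 0.0) for k in ("row", "col", "genetic", "error")},
        loglik=fit.loglik,
        aic=fit.aic(),
        bic=fit.bic(len(y)),
        reml=fit,
    )


def select_field_model(
    plots: pd.DataFrame, env: str, trait: str, with_block: bool = True
) -> tuple[FieldModelFit, pd.DataFrame]:
    """Fit row/column model variants and pick the best by AIC.

    Reports AIC/BIC for the four spatial variants (row+col, row, col,
    none); ties go to the simpler model (fewer variance parameters).
    """
    variants = [
        ("row+col", True, True),
        ("row", True, False),
        ("col", False, True),
        ("none", False, False),
    ]
    fits = []
    rows = []
    for name, use_r, use_c in variants:
        f = fit_field_model(plots, env, trait, with_block, use_r, use_c)
        fits.append((name, f))
        rows.append({"model": name, "aic": f.aic, "bic": f.bic,
                     "n_varparams": f.reml.n_varparams})
    report = pd.DataFrame(rows)
    best = min(fits, key=lambda nf: (round(nf[1].aic, 6), nf[1].reml.n_varparams))
    return best[1], report


def correct_phenotypes(
    plots: pd.DataFrame, fit: FieldModelFit
) -> pd.DataFrame:
    """Subtract predicted row and column BLUPs from the raw plot values.

    Check/block fixed effects and the genetic effect stay in the value.
    """
    grp = plots[plots["env"] == fit.env].copy()
    missing_rows = set(grp["row"]) - set(fit.row_blup)
    if missing_rows:
        raise ValueError(f"plots reference rows absent from fit: {sorted(missing_rows)[:5]}")
    missing_cols = set(grp["col"]) - set(fit.col_blup)
    if missing_cols:
        raise ValueError(f"plots reference columns absent from fit: {sorted(missing_cols)[:5]}")
    corr = (
        grp[fit.trait].to_numpy(dtype=float)
        - grp["row"].map(fit.row_blup).to_numpy(dtype=float)
        - grp["col"].map(fit.col_blup).to_numpy(dtype=float)
    )
    grp[fit.trait] = corr
    return grp


def correct_all(
    plots: pd.DataFrame, trait: str, with_block: bool = True
) -> tuple[pd.DataFrame, dict[str, FieldModelFit]]:
    """Row-column correction of every environment of a trial network."""
    fits = {}
    parts = []
    for env in pd.unique(plots["env"]):
        f = fit_field_model(plots, env, trait, with_block)
        fits[env] = f
        parts.append(correct_phenotypes(plots, f))
    return pd.concat(parts, ignore_index=True), fits


def adjust_panel_means(
    checks_a: pd.DataFrame,
    checks_b: pd.DataFrame,
    values_b: pd.Series,
    trait: str,
) -> pd.Series:
    """Shift panel B onto panel A's scale using shared checks.

    The shift is the mean over common checks of (mean corrected check
    phenotype in network A - same in network B).
    """
    ma = checks_a.groupby("check")[trait].mean()
    mb = checks_b.groupby("check")[trait].mean()
    common = sorted(set(ma.index) & set(mb.index) - {"experimental"})
    if not common:
        raise ValueError("no common check between the two trial networks")
    shift = float((ma[common] - mb[common]).mean())
    return values_b + shift


def _harmonic_mean_reps(data: pd.DataFrame) -> float:
    counts = data.groupby("hybrid").size().to_numpy(dtype=float)
    return len(counts) / np.sum(1.0 / counts)


def heritability(
    data: pd.DataFrame,
    scope: str = "single",
    value_col: str = "value",
) -> float:
    """Entry-mean broad-sense heritability of corrected hybrid phenotypes.

    ``data`` holds one row per plot with columns ``hybrid``, ``value_col``
    and, for ``scope='multi'``, ``env``.
    """
    if data["hybrid"].nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    y = data[value_col].to_numpy(dtype=float)
    zg, _ = incidence(data["hybrid"])
    rbar = _harmonic_mean_reps(data)
    if scope == "single":
        terms = {"genetic": zg @ zg.T, "error": np.eye(len(y))}
        fit = reml(y, np.ones((len(y), 1)), terms)
        s2g, s2e = fit.sigma2["genetic"], fit.sigma2["error"]
        denom = s2g + s2e / rbar
    elif scope == "multi":
        envs = list(pd.unique(data["env"]))
        if len(envs) < 2:
            raise ValueError("multi-environment heritability needs >= 2 environments")
        n_env = len(envs)
        env_arr = data["env"].to_numpy()
        X = np.column_stack(
            [np.ones(len(y))] + [(env_arr == e).astype(float) for e in envs[1:]]
        )
        zge, _ = incidence(list(zip(data["hybrid"], data["env"])))
        rbar = _harmonic_mean_reps(
            data.assign(hybrid=list(zip(data["hybrid"], data["env"])))
        )
        terms = {
            "genetic": zg @ zg.T,
            "gxe": zge @ zge.T,
            "error": np.eye(len(y)),
        }
        fit = reml(y, X, terms)
        s2g, s2ge, s2e = fit.sigma2["genetic"], fit.sigma2["gxe"], fit.sigma2["error"]
        denom = s2g + s2ge / n_env + s2e / (n_env * rbar)
    else:
        raise ValueError(f"scope must be 'single' or 'multi', got {scope!r}")
    if denom <= 0:
        raise ValueError("zero total variance: heritability undefined")
    return float(s2g / denom)
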