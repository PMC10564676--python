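"""MONO / MULTI variance-component models for hybrid panels.

MONO (one environment):

    y_hr = mu + A_h + D_h + Iaa_h + Iad_h + Idd_h + e_hr

with cov(A) = K_a sigma2_a, ..., cov(Idd) = K_dd sigma2_dd and iid
errors; the six random terms are independent.  Replicated plots enter
every random term through the plot-to-hybrid incidence Z as Z K Z'.

MULTI (all environments jointly) adds environment fixed effects, one
additive-by-environment and one dominance-by-environment component per
environment (kernels K_a and K_d, independent across environments) and
per-environment error variances.  Epistasis-by-environment terms are
not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinship import KinshipSet
from .reml import RemlResult, incidence, reml

GENETIC_COMPONENTS = ("a", "d", "aa", "ad", "dd")


@dataclass
class VarCompResult:
    """REML variance partition.

    ``sigma2`` holds the five main genetic components plus either
    ``error`` (MONO) or per-environment ``axe:<env>``, ``dxe:<env>`` and
    ``error:<env>`` entries (MULTI).
    """

    mode: str  # "mono" | "multi"
    sigma2: dict[str, float]
    loglik: float
    n_iter: int
    converged: bool
    envs: list[str]
    env_effects: dict[str, float]
    reml: RemlResult

    def main_genetic_variance(self) -> float:
        return sum(self.sigma2[c] for c in GENETIC_COMPONENTS)


def _genetic_terms(Z: np.ndarray, kin: KinshipSet) -> dict[str, np.ndarray]:
    return {name: Z @ K @ Z.T for name, K in kin.as_dict().items()}


def _check_coverage(hybrids, hybrid_order) -> None:
    missing = set(hybrids) - set(hybrid_order)
    if missing:
        raise ValueError(
            f"kinships do not cover hybrids: {sorted(missing)[:5]}"
        )


def fit_mono(
    data: pd.DataFrame,
    kin: KinshipSet,
    hybrid_order: list[str],
    value_col: str = "value",
) -> VarCompResult:
    """Single-environment variance partition.

    ``data`` needs columns ``hybrid`` and ``value_col``; replicates are
    allowed (one row per plot).
    """
    _check_coverage(data["hybrid"], hybrid_order)
    y = data[value_col].to_numpy(dtype=float)
    Z, _ = incidence(data["hybrid"], hybrid_order)
    terms = _genetic_terms(Z, kin)
    terms["error"] = np.eye(len(y))
    X = np.ones((len(y), 1))
    fit = reml(y, X, terms)
    return VarCompResult(
        mode="mono",
        sigma2=fit.sigma2,
        loglik=fit.loglik,
        n_iter=fit.n_iter,
        converged=fit.converged,
        envs=[],
        env_effects={},
        reml=fit,
    )


def multi_terms_and_design(
    data: pd.DataFrame,
    kin: KinshipSet,
    hybrid_order: list[str],
) -> tuple[np.ndarray, list[str], dict[str, np.ndarray], list[str]]:
    """Assemble the MULTI fixed design and covariance terms.

    Returns (X, fixed_names, terms, envs).  Environment fixed effects
    use reference coding on the first environment.
    """
    _check_coverage(data["hybrid"], hybrid_order)
    envs = list(pd.unique(data["env"]))
    if len(envs) < 2:
        raise ValueError("MULTI model needs at least 2 environments")
    n = len(data)
    Z, _ = incidence(data["hybrid"], hybrid_order)
    env_arr = data["env"].to_numpy()
    X_cols = [np.ones(n)]
    fixed_names = ["mu"]
    for e in envs[1:]:
        X_cols.append((env_arr == e).astype(float))
        fixed_names.append(f"env:{e}")
    X = np.column_stack(X_cols)
    terms = _genetic_terms(Z, kin)
    vka = terms["a"]
    vkd = terms["d"]
    for e in envs:
        mask = (env_arr == e).astype(float)
        if mask.sum() < 2:
            raise ValueError(
                f"environment {e!r} has a single observation; its error "
                "variance is not identifiable"
            )
        outer = np.outer(mask, mask)
        terms[f"axe:{e}"] = vka * outer
        terms[f"dxe:{e}"] = vkd * outer
        terms[f"error:{e}"] = np.diag(mask)
    return X, fixed_names, terms, envs


def fit_multi(
    data: pd.DataFrame,
    kin: KinshipSet,
    hybrid_order: list[str],
    value_col: str = "value",
) -> VarCompResult:
    """Multi-environment variance partition with GxE and per-env errors."""
    d = data.rename(columns={value_col: "value"})
    X, fixed_names, terms, envs = multi_terms_and_design(d, kin, hybrid_order)
    y = d["value"].to_numpy(dtype=float)
    fit = reml(y, X, terms)
    env_effects = {
        nm.split(":", 1)[1]: float(b)
        for nm, b in zip(fixed_names, fit.beta)
        if nm.startswith("env:")
    }
    return VarCompResult(
        mode="multi",
        sigma2=fit.sigma2,
        loglik=fit.loglik,
        n_iter=fit.n_iter,
        converged=fit.converged,
        envs=envs,
        env_effects=env_effects,
        reml=fit,
    )


def variance_report(result: VarCompResult) -> pd.DataFrame:
    """Partition table: absolute variances and shares of the main genetic
    variance (sum of additive, dominance and the three epistatic terms);
    for MULTI, AxE / DxE / error rows report the mean over environments.
    """
    if not result.converged:
        raise ValueError("variance_report requires a converged fit")
    main = result.main_genetic_variance()
    rows = []
    for c in GENETIC_COMPONENTS:
        v = result.sigma2[c]
        rows.append(
            {
                "component": c,
                "variance": v,
                "pct_main_genetic": 100.0 * v / main if main > 0 else np.nan,
            }
        )
    if result.mode == "mono":
        rows.append(
            {"component": "error", "variance": result.sigma2["error"],
             "pct_main_genetic": np.nan}
        )
    else:
        for kind in ("axe", "dxe", "error"):
            vals = [result.sigma2[f"{kind}:{e}"] for e in result.envs]
            rows.append(
                {"component": f"mean_{kind}", "variance": float(np.mean(vals)),
                 "pct_main_genetic": np.nan}
            )
    return pd.DataFrame(rows)
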