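"""Per-marker association tests under the Gso and Gad models.

The SNP-Origin model (Gso) fits one effect per observed SO genotype
class (cell means, no separate marker intercept, so every listed
contrast is estimable) on top of the polygenic covariance structure of
the no-marker null model.  Named effects are linear contrasts of the
class effects:

    a_DD = (b_1D1D - b_0D0D)/2           d_DD = b_1D0D - (b_1D1D + b_0D0D)/2
    a_FF = (b_1F1F - b_0F0F)/2           d_FF = b_1F0F - (b_1F1F + b_0F0F)/2
    a_DF = (b_1D1F - b_0D0F)/2           d_DF = (b_0D1F + b_1D0F)/2 - (b_1D1F + b_0D0F)/2
    a = (a_DD + a_FF + a_DF)/3           d likewise
    s_a = a_DD - a_FF                    t_a = a_DF - (a_DD + a_FF)/2   (and d twins)
    o_a00 = (b_0D0D - b_0F0F)/2          o_d00 = b_0D0F - (b_0F0F + b_0D0D)/2
    o_a11 = (b_1D1D - b_1F1F)/2          o_d11 = b_1D1F - (b_1F1F + b_1D1D)/2
    o_a = (o_a00 + o_a11)/2              o_d = (o_d00 + o_d11)/2
    Delta_LD = b_0D1F - b_1D0F
    g_shared / g_all: joint test that all participating classes are equal

The benchmark Gad model regresses on SNP allele-1 dosage (alpha) and a
heterozygosity indicator (delta).

Covariance handling follows the population-parameters-previously-
determined (P3D) scheme: variance components come from the H0
(no-marker) fit with leave-one-chromosome-out kinships; per marker,
the variance ratios stay fixed and one global scale is re-estimated
from the residual quadratic form.  Contrasts are tested with Wald
statistics against a chi-square reference (df = contrast rank).

Markers enter a contrast only if panel MAF >= the threshold and every
SO class with a nonzero coefficient in that contrast has at least
``min_class`` carriers.  BH false-discovery control is applied jointly
over all environments within each (contrast, panel, model, trait)
family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from statsmodels.stats.multitest import multipletests

from .config import RunConfig, logger
from .kinship import KinshipSet
from .panel import SO_CLASSES, SO_INDEX, GeneticMap, PanelGenotypes
from .reml import incidence
from .varcomp import fit_mono, fit_multi, multi_terms_and_design, VarCompResult

# ---------------------------------------------------------------------------
# Contrast registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastSpec:
    """A named linear contrast over the ten SO class effects."""

    name: str
    matrix: np.ndarray  # (rows, 10); rows each sum to 0
    family: str  # additive | dominance | origin | ld | global
    panels: tuple[str, ...]  # design kinds the contrast applies to

    @property
    def df(self) -> int:
        return self.matrix.shape[0]

    @property
    def classes(self) -> np.ndarray:
        """Indices of SO classes with a nonzero coefficient."""
        return np.flatnonzero(np.any(self.matrix != 0, axis=0))


def _e(*pairs) -> np.ndarray:
    v = np.zeros(len(SO_CLASSES))
    for name, w in pairs:
        v[SO_INDEX[name]] += w
    return v


_A_DD = _e(("1D1D", 0.5), ("0D0D", -0.5))
_A_FF = _e(("1F1F", 0.5), ("0F0F", -0.5))
_A_DF = _e(("1D1F", 0.5), ("0D0F", -0.5))
_D_DD = _e(("1D0D", 1.0), ("1D1D", -0.5), ("0D0D", -0.5))
_D_FF = _e(("1F0F", 1.0), ("1F1F", -0.5), ("0F0F", -0.5))
_D_DF = _e(("0D1F", 0.5), ("1D0F", 0.5), ("1D1F", -0.5), ("0D0F", -0.5))
_O_A00 = _e(("0D0D", 0.5), ("0F0F", -0.5))
_O_A11 = _e(("1D1D", 0.5), ("1F1F", -0.5))
_O_D00 = _e(("0D0F", 1.0), ("0F0F", -0.5), ("0D0D", -0.5))
_O_D11 = _e(("1D1F", 1.0), ("1F1F", -0.5), ("1D1D", -0.5))

_SHARED4 = [SO_INDEX[c] for c in ("0D0F", "0D1F", "1D0F", "1D1F")]


def _joint(classes: list[int]) -> np.ndarray:
    ref = classes[0]
    rows = []
    for c in classes[1:]:
        v = np.zeros(len(SO_CLASSES))
        v[c] = 1.0
        v[ref] = -1.0
        rows.append(v)
    return np.vstack(rows)


def _scalar(name, vec, family, panels=("diallel",)) -> ContrastSpec:
    return ContrastSpec(name=name, matrix=vec[None, :], family=family, panels=panels)


CONTRASTS: dict[str, ContrastSpec] = {
    c.name: c
    for c in [
        _scalar("a_DD", _A_DD, "additive"),
        _scalar("a_FF", _A_FF, "additive"),
        _scalar("a_DF", _A_DF, "additive", ("factorial", "diallel")),
        _scalar("a", (_A_DD + _A_FF + _A_DF) / 3.0, "additive"),
        _scalar("s_a", _A_DD - _A_FF, "additive"),
        _scalar("t_a", _A_DF - 0.5 * (_A_DD + _A_FF), "additive"),
        _scalar("d_DD", _D_DD, "dominance"),
        _scalar("d_FF", _D_FF, "dominance"),
        _scalar("d_DF", _D_DF, "dominance", ("factorial", "diallel")),
        _scalar("d", (_D_DD + _D_FF + _D_DF) / 3.0, "dominance"),
        _scalar("s_d", _D_DD - _D_FF, "dominance"),
        _scalar("t_d", _D_DF - 0.5 * (_D_DD + _D_FF), "dominance"),
        _scalar("o_a00", _O_A00, "origin"),
        _scalar("o_a11", _O_A11, "origin"),
        _scalar("o_a", 0.5 * (_O_A00 + _O_A11), "origin"),
        _scalar("o_d00", _O_D00, "origin"),
        _scalar("o_d11", _O_D11, "origin"),
        _scalar("o_d", 0.5 * (_O_D00 + _O_D11), "origin"),
        _scalar("delta_ld", _e(("0D1F", 1.0), ("1D0F", -1.0)), "ld",
                ("factorial", "diallel")),
        ContrastSpec("g_shared", _joint(_SHARED4), "global", ("factorial", "diallel")),
        ContrastSpec("g_all", _joint(list(range(10))), "global", ("diallel",)),
    ]
}


def contrasts_for_panel(kind: str) -> list[str]:
    return [c.name for c in CONTRASTS.values() if kind in c.panels]


def evaluate_contrasts(class_effects: np.ndarray) -> dict[str, float]:
    """Named scalar effect values from a full vector of ten class effects.

    Entries that reference a class with a NaN effect are skipped.
    """
    beta = np.asarray(class_effects, dtype=float)
    out = {}
    for spec in CONTRASTS.values():
        if spec.df != 1:
            continue
        if np.isnan(beta[spec.classes]).any():
            continue
        out[spec.name] = float(spec.matrix[0] @ np.nan_to_num(beta))
    return out


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_markers(
    panel: PanelGenotypes,
    contrast: ContrastSpec,
    maf_threshold: float = 0.05,
    min_class: int = 5,
) -> np.ndarray:
    """Boolean mask of markers eligible for ``contrast``.

    A marker qualifies when its panel MAF reaches the threshold and
    every SO class carrying a nonzero coefficient in the contrast has at
    least ``min_class`` carriers.
    """
    if maf_threshold < 0 or min_class < 0:
        raise ValueError("thresholds must be >= 0")
    ok = panel.maf() >= maf_threshold
    counts = panel.class_counts()
    for c in contrast.classes:
        ok &= counts[:, c] >= min_class
    logger.info(
        "filter_markers: contrast %s -> %d of %d markers eligible",
        contrast.name, int(ok.sum()), panel.n_markers,
    )
    return ok


def minor_class_filter(
    panel: PanelGenotypes, min_class: int = 5
) -> np.ndarray:
    """Mask of markers whose minor *observed* SO class has >= min_class carriers."""
    counts = panel.class_counts()
    observed_min = np.where(counts > 0, counts, np.iinfo(np.int64).max).min(axis=1)
    return observed_min >= min_class


# ---------------------------------------------------------------------------
# Null model (P3D)
# ---------------------------------------------------------------------------


@dataclass
class NullModel:
    """H0 (no-marker) covariance structure for marker-by-marker GLS."""

    layer: str  # environment id, or "MULTI"
    y: np.ndarray
    hybrid_idx: np.ndarray  # per observation, index into panel.hybrids
    x_extra: np.ndarray  # fixed covariates beyond the marker term (n, q)
    vi: np.ndarray  # inverse of the H0 covariance
    varcomp: VarCompResult
    excluded_chrom: object


def _hybrid_indices(hybrids, hybrid_order) -> np.ndarray:
    pos = {h: i for i, h in enumerate(hybrid_order)}
    try:
        return np.array([pos[h] for h in hybrids], dtype=np.intp)
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"hybrid {exc.args[0]!r} not covered by the panel") from exc


def fit_null_model(
    data: pd.DataFrame,
    kin: KinshipSet,
    hybrid_order: list[str],
    layer: str,
    value_col: str = "value",
) -> NullModel:
    """Fit the no-marker mixed model and freeze its covariance.

    ``layer`` is an environment id for the single-environment (MONO)
    model or ``"MULTI"`` for the joint model with AxE / DxE components
    and per-environment error variances.
    """
    d = data.rename(columns={value_col: "value"})
    if layer == "MULTI":
        vc = fit_multi(d, kin, hybrid_order)
        X, _, terms, envs = multi_terms_and_design(d, kin, hybrid_order)
        x_extra = X[:, 1:]  # env dummies; intercept absorbed by cell means
    else:
        d = d[d["env"] == layer] if "env" in d.columns else d
        if d.empty:
            raise ValueError(f"no observations for environment {layer!r}")
        vc = fit_mono(d, kin, hybrid_order)
        Z, _ = incidence(d["hybrid"], hybrid_order)
        terms = {name: Z @ K @ Z.T for name, K in kin.as_dict().items()}
        terms["error"] = np.eye(len(d))
        x_extra = np.empty((len(d), 0))
    V = np.zeros((len(d), len(d)))
    for name, M in terms.items():
        s = vc.sigma2[name]
        if s > 0:
            V += s * M
    V[np.diag_indices_from(V)] += 1e-10 * max(float(np.var(d["value"])), 1.0)
    vi = cho_solve(cho_factor(V, lower=True), np.eye(len(d)))
    return NullModel(
        layer=layer,
        y=d["value"].to_numpy(dtype=float),
        hybrid_idx=_hybrid_indices(d["hybrid"], hybrid_order),
        x_extra=x_extra,
        vi=vi,
        varcomp=vc,
        excluded_chrom=kin.excluded_chrom,
    )


# ---------------------------------------------------------------------------
# Marker tests
# ---------------------------------------------------------------------------


def _gls(null: NullModel, x_marker: np.ndarray):
    """GLS under the frozen null covariance with per-marker scale re-estimation.

    Returns (beta, cov, s2): estimates for [marker columns | extra
    covariates], their covariance on the re-scaled covariance, and the
    residual scale.
    """
    X = np.column_stack([x_marker, null.x_extra]) if null.x_extra.size else x_marker
    n, p = X.shape
    w = null.vi @ X
    xtvx = X.T @ w
    try:
        cx = cho_factor(xtvx, lower=True)
    except np.linalg.LinAlgError:
        return None
    beta = cho_solve(cx, w.T @ null.y)
    r = null.y - X @ beta
    s2 = float(r @ (null.vi @ r)) / max(n - p, 1)
    cov = s2 * cho_solve(cx, np.eye(p))
    return beta, cov, s2


def test_marker_gso(
    null: NullModel,
    so_col: np.ndarray,
    contrasts: list[str],
) -> list[dict]:
    """Wald tests of the requested contrasts at one marker.

    ``so_col`` holds the SO class code of every hybrid in panel order;
    class effects are fitted as cell means over the observed classes.
    Contrasts referencing an unobserved class are skipped with a reason.
    """
    classes_obs = so_col[null.hybrid_idx]
    present = np.unique(classes_obs)
    C = (classes_obs[:, None] == present[None, :]).astype(float)
    out = _gls(null, C)
    results = []
    if out is None:
        for name in contrasts:
            results.append(_skip(name, "singular class design"))
        return results
    beta, cov, s2 = out
    counts = {int(c): int(k) for c, k in zip(present, np.bincount(
        np.searchsorted(present, classes_obs), minlength=len(present)))}
    pos = {int(c): j for j, c in enumerate(present)}
    for name in contrasts:
        spec = CONTRASTS[name]
        if any(int(c) not in pos for c in spec.classes):
            results.append(_skip(name, "missing SO class"))
            continue
        L = np.zeros((spec.df, len(beta)))
        for r_i in range(spec.df):
            for c in spec.classes:
                L[r_i, pos[int(c)]] = spec.matrix[r_i, c]
        est = L @ beta
        vmat = L @ cov @ L.T
        if spec.df == 1:
            se = float(np.sqrt(vmat[0, 0]))
            wald = float(est[0] ** 2 / vmat[0, 0]) if vmat[0, 0] > 0 else np.nan
            df = 1
            estimate = float(est[0])
        else:
            try:
                wald = float(est @ np.linalg.solve(vmat, est))
            except np.linalg.LinAlgError:
                results.append(_skip(name, "singular contrast covariance"))
                continue
            df = int(np.linalg.matrix_rank(vmat))
            se = np.nan
            estimate = np.nan
        p = float(stats.chi2.sf(wald, df)) if np.isfinite(wald) else np.nan
        results.append(
            {
                "contrast": name,
                "estimate": estimate,
                "se": se,
                "wald": wald,
                "df": df,
                "p": p,
                "skipped": "",
                "n_min_class": int(min(counts[int(c)] for c in spec.classes)),
            }
        )
    return results


def _skip(name: str, reason: str) -> dict:
    return {
        "contrast": name, "estimate": np.nan, "se": np.nan, "wald": np.nan,
        "df": 0, "p": np.nan, "skipped": reason, "n_min_class": 0,
    }


def test_marker_gad(
    null: NullModel,
    dosage_col: np.ndarray,
    het_col: np.ndarray,
) -> list[dict]:
    """Wald tests of the additive (alpha) and dominance (delta) regressions."""
    dose = dosage_col[null.hybrid_idx].astype(float)
    het = het_col[null.hybrid_idx].astype(float)
    if np.ptp(dose) == 0:
        return [_skip("alpha", "monomorphic"), _skip("delta", "monomorphic")]
    cols = [np.ones(len(dose)), dose]
    names = ["alpha"]
    if np.ptp(het) > 0:
        cols.append(het)
        names.append("delta")
    X = np.column_stack(cols)
    out = _gls(null, X)
    if out is None:
        return [_skip(nm, "singular design") for nm in ("alpha", "delta")]
    beta, cov, s2 = out
    results = []
    for j, nm in enumerate(names, start=1):
        se = float(np.sqrt(cov[j, j]))
        wald = float(beta[j] ** 2 / cov[j, j]) if cov[j, j] > 0 else np.nan
        results.append(
            {
                "contrast": nm,
                "estimate": float(beta[j]),
                "se": se,
                "wald": wald,
                "df": 1,
                "p": float(stats.chi2.sf(wald, 1)) if np.isfinite(wald) else np.nan,
                "skipped": "",
                "n_min_class": int(min(np.bincount(dose.astype(int), minlength=3)[
                    np.unique(dose.astype(int))])),
            }
        )
    if "delta" not in names:
        results.append(_skip("delta", "no heterozygotes"))
    return results


# ---------------------------------------------------------------------------
# Genome scan driver
# ---------------------------------------------------------------------------


def run_gwas(
    panel: PanelGenotypes,
    gmap: GeneticMap,
    data: pd.DataFrame,
    loco: dict,
    model: str = "gso",
    layers: list[str] | None = None,
    contrasts: list[str] | None = None,
    config: RunConfig | None = None,
    trait: str = "trait",
) -> pd.DataFrame:
    """Genome scan: per chromosome, fit the LOCO null then test markers.

    ``loco`` maps chromosome -> KinshipSet built without that
    chromosome.  ``layers`` is a list of environment ids and/or
    ``"MULTI"``; defaults to every environment in ``data``.
    """
    cfg = config or RunConfig()
    if model not in ("gso", "gad"):
        raise ValueError("model must be 'gso' or 'gad'")
    kind = panel.design.kind if panel.design is not None else "diallel"
    if contrasts is None:
        wanted = contrasts_for_panel(kind) if model == "gso" else ["alpha", "delta"]
    else:
        wanted = list(contrasts)
    if layers is None:
        layers = list(pd.unique(data["env"]))
    chrom_arr = gmap.chrom_of()
    dosage = panel.dosage()
    het = panel.het()
    maf_ok = panel.maf() >= cfg.maf_threshold
    if model == "gso":
        elig = {
            nm: filter_markers(panel, CONTRASTS[nm], cfg.maf_threshold, cfg.min_so_class)
            for nm in wanted
        }
    else:
        elig = None
        gad_ok = maf_ok & minor_class_filter_gad(dosage, cfg.min_so_class)
    rows = []
    for layer in layers:
        for chrom in gmap.chromosomes:
            kin = loco[chrom]
            if kin.excluded_chrom != chrom:
                raise ValueError(
                    f"LOCO key mismatch: kinship excludes {kin.excluded_chrom!r} "
                    f"but chromosome {chrom!r} is being tested"
                )
            null = fit_null_model(data, kin, panel.hybrids, layer)
            for m in gmap.chrom_indices(chrom):
                if model == "gso":
                    todo = [nm for nm in wanted if elig[nm][m]]
                    if not todo:
                        continue
                    res = test_marker_gso(null, panel.so[:, m], todo)
                else:
                    if not gad_ok[m]:
                        continue
                    res = test_marker_gad(null, dosage[:, m], het[:, m])
                    res = [r for r in res if r["contrast"] in wanted]
                for r in res:
                    r.update(
                        marker=panel.markers[m], chrom=chrom, layer=layer,
                        model=model, trait=trait, panel=kind,
                    )
                    rows.append(r)
    out = pd.DataFrame(rows)
    if not out.empty:
        out = bh_fdr(out)
    return out


def minor_class_filter_gad(dosage: np.ndarray, min_class: int = 5) -> np.ndarray:
    """Gad analogue of the minor-SO-class rule on dosage classes."""
    ok = np.empty(dosage.shape[1], dtype=bool)
    for m in range(dosage.shape[1]):
        counts = np.bincount(dosage[:, m].astype(int), minlength=3)
        observed = counts[counts > 0]
        ok[m] = observed.min() >= min_class
    return ok


# ---------------------------------------------------------------------------
# Multiple testing and effect classification
# ---------------------------------------------------------------------------


def bh_fdr(
    results: pd.DataFrame,
    family_cols: tuple[str, ...] = ("contrast", "panel", "model", "trait"),
) -> pd.DataFrame:
    """Benjamini-Hochberg q-values within each family, pooling all layers."""
    out = results.copy()
    out["q"] = np.nan
    for _, idx in out.groupby(list(family_cols)).groups.items():
        sub = out.loc[idx]
        valid = sub["p"].notna()
        if valid.sum() == 0:
            continue
        q = multipletests(sub.loc[valid, "p"].to_numpy(), method="fdr_bh")[1]
        out.loc[sub.index[valid], "q"] = q
    return out


def classify_dominance(a: float, d: float) -> str:
    """Dominance category from the |d/a| ratio.

    ``|d/a| > 1`` is overdominant, ``0 < |d/a| <= 1`` (partial)
    dominance, ``d == 0`` additive.  A zero additive effect with nonzero
    dominance has an undefined ratio and is reported as overdominant
    with an explicit annotation.
    """
    if d == 0:
        return "additive"
    if a == 0:
        return "overdominant (a=0)"
    return "overdominant" if abs(d / a) > 1 else "partial dominance"
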