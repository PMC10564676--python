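"""LD-extent windows around significant markers and QTL clustering.

For each significant marker and each side, an LD window is grown
iteratively: start at 0.5 cM; regress observed r-squared (computed on
SNP hybrid dosages, origins ignored) on genetic distance with the
drift-recombination expectation of Hill & Weir (1988),

    E[r2] = (10 + C) / ((2 + C)(11 + C))
            * (1 + ((3 + C)(12 + 12 C + C^2)) / (n (2 + C)(11 + C)))

where n is the sample size and C = rho * c(d), with c(d) the Haldane
recombination fraction of a distance d cM and rho >= 0 the single
fitted parameter; the LD extent is the distance where the fitted curve
crosses r2 = 0.1.  While the extent exceeds the current window the
window grows by 0.1 cM and the fit is repeated; the final extent
defines the window length.  Fewer than 5 informative pairs, or a
degenerate fit, fall back to the current window (conservative).

Significant markers with overlapping LD windows (closed intervals;
touching endpoints count as overlapping) are clustered into one QTL
whose interval is the union span of the member windows.  QTLs from
different environments, layers or models are merged into meta-QTLs when
their intervals overlap, separately within each effect family
(additive, dominance, origin, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .config import RunConfig, logger
from .panel import GeneticMap, PanelGenotypes

# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------


def pairwise_r2(
    panel: PanelGenotypes,
    focal: int,
    candidates: np.ndarray,
    dose: np.ndarray | None = None,
) -> np.ndarray:
    """Squared dosage correlation between a focal marker and candidates.

    Zero-variance candidates yield NaN (excluded downstream).  ``dose``
    may carry a precomputed dosage matrix to avoid rebuilding it.
    """
    if dose is None:
        dose = panel.dosage().astype(float)
    x = dose[:, focal]
    if x.var() == 0:
        raise ValueError("focal marker has zero dosage variance")
    Y = dose[:, np.asarray(candidates, dtype=np.intp)]
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((xc @ xc) * (Yc * Yc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ Yc) / denom
    bad = ~np.isfinite(r)
    if bad.any():
        logger.debug("pairwise_r2: %d zero-variance candidates excluded", int(bad.sum()))
    return r**2


def haldane_c(d_cm: np.ndarray) -> np.ndarray:
    """Haldane recombination fraction of a genetic distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def hill_weir_expected_r2(d_cm: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Expected r-squared under drift-recombination with sampling correction."""
    C = rho * haldane_c(d_cm)
    t1 = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    t2 = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    return t1 * t2


def fit_ld_decay(
    r2: np.ndarray,
    dist_cm: np.ndarray,
    n: int,
    threshold: float = 0.1,
    min_pairs: int = 5,
) -> tuple[float | None, float | None]:
    """Fit the decay curve and locate the threshold crossing.

    Returns ``(rho, extent_cm)``.  ``extent_cm`` is 0.0 when even the
    origin of the fitted curve sits below the threshold, ``inf`` when
    the curve never crosses it, and ``None`` (with ``rho=None``) when
    the fit is degenerate or under-supported.
    """
    keep = np.isfinite(r2) & np.isfinite(dist_cm) & (dist_cm > 0)
    r2 = np.asarray(r2, dtype=float)[keep]
    d = np.asarray(dist_cm, dtype=float)[keep]
    if len(r2) < min_pairs:
        return None, None
    if np.ptp(r2) == 0:
        # flat data: below the threshold everywhere means no local LD
        # (extent 0); flat at a high value is a degenerate fit
        if r2[0] < threshold:
            return None, 0.0
        return None, None
    try:
        sol = least_squares(
            lambda p: hill_weir_expected_r2(d, p[0], n) - r2,
            x0=[10.0],
            bounds=([0.0], [np.inf]),
        )
    except Exception:
        return None, None
    rho = float(sol.x[0])

    def f(x):
        return float(hill_weir_expected_r2(np.array([x]), rho, n)[0]) - threshold

    if f(1e-9) <= 0:
        return rho, 0.0
    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e5:
            return rho, np.inf
    return rho, float(brentq(f, 1e-9, hi))


@dataclass
class LDWindow:
    """Per-side LD extents (cM) around a focal marker."""

    marker: str
    chrom: object
    cm: float
    left_extent: float
    right_extent: float
    left_window: float
    right_window: float
    n_pairs_left: int
    n_pairs_right: int

    @property
    def start_cm(self) -> float:
        return self.cm - self.left_extent

    @property
    def end_cm(self) -> float:
        return self.cm + self.right_extent


def _side_extent(
    panel: PanelGenotypes,
    focal: int,
    chrom_global: np.ndarray,
    chrom_pos: np.ndarray,
    focal_pos: float,
    side: int,
    cfg: RunConfig,
    dose: np.ndarray,
) -> tuple[float, float, int]:
    """Iteratively grown LD extent on one side (side=-1 left, +1 right)."""
    n = panel.n_hybrids
    boundary = (focal_pos - chrom_pos.min()) if side < 0 else (chrom_pos.max() - focal_pos)
    w = cfg.ld_init_window_cm
    while True:
        if side < 0:
            sel = (chrom_pos < focal_pos) & (chrom_pos >= focal_pos - w)
        else:
            sel = (chrom_pos > focal_pos) & (chrom_pos <= focal_pos + w)
        cand = chrom_global[sel]
        dist = np.abs(chrom_pos[sel] - focal_pos)
        r2 = pairwise_r2(panel, focal, cand, dose=dose) if len(cand) else np.empty(0)
        rho, extent = fit_ld_decay(
            r2, dist, n, threshold=cfg.ld_r2_threshold, min_pairs=5
        )
        n_pairs = int(np.isfinite(r2).sum())
        if extent is None:
            # under-supported or flat: conservative fallback to the window
            return min(w, boundary), w, n_pairs
        if extent <= w or w >= boundary:
            return min(extent, boundary), w, n_pairs
        w += cfg.ld_step_cm


def ld_window(
    panel: PanelGenotypes,
    gmap: GeneticMap,
    marker: str,
    config: RunConfig | None = None,
    dose: np.ndarray | None = None,
) -> LDWindow:
    """LD window (both sides) of one mapped marker."""
    cfg = config or RunConfig()
    if panel.markers != gmap.markers:
        raise ValueError("panel markers do not match map markers")
    try:
        row = gmap.marker_row(marker)
    except KeyError:
        raise ValueError(f"marker {marker!r} is not mapped") from None
    if dose is None:
        dose = panel.dosage().astype(float)
    chrom = row["chrom"]
    chrom_global = gmap.chrom_indices(chrom)
    chrom_pos = gmap.cm_of()[chrom_global]
    focal = int(gmap.table.index[gmap.table["marker"] == marker][0])
    focal_pos = float(row["cm"])
    left, lw, npl = _side_extent(
        panel, focal, chrom_global, chrom_pos, focal_pos, -1, cfg, dose
    )
    right, rw, npr = _side_extent(
        panel, focal, chrom_global, chrom_pos, focal_pos, +1, cfg, dose
    )
    return LDWindow(
        marker=marker,
        chrom=chrom,
        cm=float(row["cm"]),
        left_extent=float(left),
        right_extent=float(right),
        left_window=float(lw),
        right_window=float(rw),
        n_pairs_left=npl,
        n_pairs_right=npr,
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class Qtl:
    """A cluster of significant markers with overlapping LD windows."""

    chrom: object
    start_cm: float
    end_cm: float
    start_bp: int
    end_bp: int
    members: list[str]
    contrast: str
    family: str
    layers: list[str]
    peak_marker: str
    peak_p: float
    peak_estimate: float
    trait: str = "trait"

    def overlaps(self, other: "Qtl") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_cm <= other.end_cm
            and other.start_cm <= self.end_cm
        )


def _cm_to_bp(gmap: GeneticMap, chrom, cm_values: np.ndarray) -> np.ndarray:
    idx = gmap.chrom_indices(chrom)
    cm = gmap.cm_of()[idx]
    bp = gmap.bp_of()[idx].astype(float)
    return np.interp(cm_values, cm, bp).round().astype(np.int64)


def cluster_qtls(
    hits: pd.DataFrame,
    windows: dict[str, LDWindow],
    gmap: GeneticMap,
) -> list[Qtl]:
    """Cluster significant markers of one (contrast, layer) family.

    ``hits`` needs columns marker, chrom, contrast, layer, p, estimate,
    trait; every marker must have a window.  Markers whose closed
    [start, end] cM windows overlap (transitively) on the same
    chromosome form one QTL spanning the union of their windows.
    """
    missing = set(hits["marker"]) - set(windows)
    if missing:
        raise ValueError(f"no LD window for markers: {sorted(missing)[:5]}")
    qtls: list[Qtl] = []
    for (chrom, contrast, trait), grp in hits.groupby(
        ["chrom", "contrast", "trait"], sort=False
    ):
        ivals = sorted(
            (windows[mk].start_cm, windows[mk].end_cm, mk)
            for mk in grp["marker"]
        )
        clusters: list[list[tuple[float, float, str]]] = []
        cur = [ivals[0]]
        cur_end = ivals[0][1]
        for iv in ivals[1:]:
            if iv[0] <= cur_end:  # touching counts as overlapping
                cur.append(iv)
                cur_end = max(cur_end, iv[1])
            else:
                clusters.append(cur)
                cur = [iv]
                cur_end = iv[1]
        clusters.append(cur)
        fam = CONTRAST_FAMILY.get(contrast, "other")
        for cl in clusters:
            members = [mk for _, _, mk in cl]
            sub = grp[grp["marker"].isin(members)]
            peak = sub.loc[sub["p"].idxmin()]
            start = min(s for s, _, _ in cl)
            end = max(e for _, e, _ in cl)
            bp = _cm_to_bp(gmap, chrom, np.array([start, end]))
            qtls.append(
                Qtl(
                    chrom=chrom,
                    start_cm=float(start),
                    end_cm=float(end),
                    start_bp=int(bp[0]),
                    end_bp=int(bp[1]),
                    members=sorted(members),
                    contrast=contrast,
                    family=fam,
                    layers=sorted(set(grp["layer"].astype(str))),
                    peak_marker=str(peak["marker"]),
                    peak_p=float(peak["p"]),
                    peak_estimate=float(peak["estimate"]),
                    trait=str(trait),
                )
            )
    return qtls


#: Effect family of every testable contrast (Gso and Gad), used to keep
#: additive, dominance and origin QTLs in separate merging families.
from .gwas import CONTRASTS as _CONTRASTS  # noqa: E402

CONTRAST_FAMILY = {name: spec.family for name, spec in _CONTRASTS.items()}
CONTRAST_FAMILY["alpha"] = "additive"
CONTRAST_FAMILY["delta"] = "dominance"


def merge_meta_qtls(qtls: list[Qtl]) -> list[Qtl]:
    """Merge overlapping QTL intervals across layers/models into meta-QTLs.

    Merging happens within each (trait, family, chromosome) group only:
    additive, dominance and origin QTLs are never merged together even
    when their intervals overlap.
    """
    groups: dict[tuple, list[Qtl]] = {}
    for q in qtls:
        groups.setdefault((q.trait, q.family, q.chrom), []).append(q)
    merged: list[Qtl] = []
    for key, grp in sorted(groups.items(), key=lambda kv: (str(kv[0]))):
        grp = sorted(grp, key=lambda q: (q.start_cm, q.end_cm))
        cur = grp[0]
        acc = [cur]
        out: list[list[Qtl]] = []
        cur_end = cur.end_cm
        for q in grp[1:]:
            if q.start_cm <= cur_end:
                acc.append(q)
                cur_end = max(cur_end, q.end_cm)
            else:
                out.append(acc)
                acc = [q]
                cur_end = q.end_cm
        out.append(acc)
        for cluster in out:
            peak = min(cluster, key=lambda q: q.peak_p)
            merged.append(
                Qtl(
                    chrom=key[2],
                    start_cm=min(q.start_cm for q in cluster),
                    end_cm=max(q.end_cm for q in cluster),
                    start_bp=min(q.start_bp for q in cluster),
                    end_bp=max(q.end_bp for q in cluster),
                    members=sorted({m for q in cluster for m in q.members}),
                    contrast="+".join(sorted({q.contrast for q in cluster})),
                    family=key[1],
                    layers=sorted({lay for q in cluster for lay in q.layers}),
                    peak_marker=peak.peak_marker,
                    peak_p=peak.peak_p,
                    peak_estimate=peak.peak_estimate,
                    trait=key[0],
                )
            )
    return merged
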