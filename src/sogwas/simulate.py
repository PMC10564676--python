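"""Synthetic two-group breeding panel generator.

Emulates the construction of hybrid maize panels from two divergent
heterotic groups (Dent, Flint):

1. two founder inbred-line pools whose allele frequencies diverge from a
   common ancestral frequency (Balding-Nichols spread controlled by an
   Fst-like parameter);
2. an incomplete factorial of inter-group F1 hybrids (one D and one F
   gamete at every locus);
3. origin-tracked doubled-haploid (DH) lines derived from the F1s, each
   being a single recombinant gamete doubled, with crossovers placed by
   a Haldane (no-interference) model: Poisson count with mean L_cM/100
   per chromosome;
4. a sparse diallel of admixed hybrids between DH lines, realizing all
   ten SO genotype classes;
5. plot-level phenotypes driven by a known architecture: SO-class QTL
   effects, polygenic additive/dominance/epistatic draws with NOIA
   kinship covariances, per-environment GxE, row/column field effects,
   replicated checks and an error term.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import logger
from .panel import (
    ORIGIN_D,
    ORIGIN_F,
    SO_CLASSES,
    CrossDesign,
    GeneticMap,
    PanelGenotypes,
)

# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


def simulate_map(
    n_markers: int,
    n_chrom: int = 2,
    chrom_len_cm: float = 100.0,
    bp_per_cm: float = 1_000_000.0,
    seed: int = 0,
) -> GeneticMap:
    """Evenly distribute markers over chromosomes, uniform cM positions."""
    rng = np.random.default_rng(seed)
    per = np.full(n_chrom, n_markers // n_chrom, dtype=int)
    per[: n_markers % n_chrom] += 1
    width = len(str(n_chrom))
    rows = []
    k = 0
    for c in range(n_chrom):
        pos = np.sort(rng.uniform(0.0, chrom_len_cm, size=per[c]))
        # zero-padded chromosome names keep lexicographic sort consistent
        # with the positional marker convention (column j <-> map row j)
        for p in pos:
            rows.append(
                (f"m{k:05d}", f"chr{c + 1:0{width}d}", float(p), int(round(p * bp_per_cm)) + 1)
            )
            k += 1
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "cm", "bp"]))


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------


@dataclass
class FounderSet:
    """Two pools of fully homozygous inbred lines sharing one marker set."""

    names: list[str]
    groups: np.ndarray  # (n_lines,) 0=D, 1=F
    haplotypes: np.ndarray  # (n_lines, m) alleles in {0,1}; lines are inbred
    freq_dent: np.ndarray  # (m,) allele-1 frequency in the Dent pool
    freq_flint: np.ndarray

    def __post_init__(self) -> None:
        for f in (self.freq_dent, self.freq_flint):
            if ((f < 0) | (f > 1)).any():
                raise ValueError("founder frequencies must lie in [0, 1]")

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def lines_of(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.groups == group)


def simulate_founders(
    n_dent: int,
    n_flint: int,
    n_markers: int,
    divergence: float = 0.15,
    seed: int = 0,
) -> FounderSet:
    """Draw two divergent founder pools.

    Per-marker ancestral frequencies are uniform on [0.1, 0.9]; each
    group's frequency is a Beta(p(1-F)/F, (1-p)(1-F)/F) draw around the
    ancestral value (Balding-Nichols), so ``divergence`` acts like Fst:
    0 keeps the groups identical in expectation, 1 fixes most markers
    for opposite alleles.
    """
    if n_dent < 2 or n_flint < 2:
        raise ValueError("need at least 2 lines per group")
    if not np.isfinite(divergence) or not (0.0 <= divergence <= 1.0):
        raise ValueError(f"divergence must be a finite value in [0, 1], got {divergence}")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, size=n_markers)
    if divergence == 0.0:
        p_d = p_anc.copy()
        p_f = p_anc.copy()
    elif divergence == 1.0:
        p_d = rng.binomial(1, p_anc).astype(float)
        p_f = rng.binomial(1, p_anc).astype(float)
    else:
        a = p_anc * (1.0 - divergence) / divergence
        b = (1.0 - p_anc) * (1.0 - divergence) / divergence
        p_d = rng.beta(a, b)
        p_f = rng.beta(a, b)
    hap_d = (rng.random((n_dent, n_markers)) < p_d).astype(np.uint8)
    hap_f = (rng.random((n_flint, n_markers)) < p_f).astype(np.uint8)
    names = [f"D{i:03d}" for i in range(n_dent)] + [f"F{i:03d}" for i in range(n_flint)]
    groups = np.concatenate([np.zeros(n_dent, dtype=np.uint8), np.ones(n_flint, dtype=np.uint8)])
    return FounderSet(
        names=names,
        groups=groups,
        haplotypes=np.vstack([hap_d, hap_f]),
        freq_dent=p_d,
        freq_flint=p_f,
    )


# ---------------------------------------------------------------------------
# Sparse mating designs
# ---------------------------------------------------------------------------


def _sample_pairs(
    candidates: list[tuple[str, str]],
    n: int,
    max_per_parent: int,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Sample n distinct pairs uniformly, capping per-parent contributions."""
    order = rng.permutation(len(candidates))
    counts: dict[str, int] = {}
    chosen: list[tuple[str, str]] = []
    for k in order:
        p1, p2 = candidates[k]
        if counts.get(p1, 0) >= max_per_parent or counts.get(p2, 0) >= max_per_parent:
            continue
        chosen.append((p1, p2))
        counts[p1] = counts.get(p1, 0) + 1
        counts[p2] = counts.get(p2, 0) + 1
        if len(chosen) == n:
            return chosen
    raise ValueError(
        f"cannot draw {n} crosses from {len(candidates)} admissible pairs "
        f"with a per-parent cap of {max_per_parent}"
    )


def simulate_factorial(
    founders: FounderSet,
    n_hybrids: int,
    seed: int = 0,
    max_per_parent: int = 5,
) -> PanelGenotypes:
    """Incomplete factorial of D x F single-cross hybrids.

    Every hybrid carries exactly one Dent-origin and one Flint-origin
    gamete at every marker (gamete slot 0 = Dent parent), so only the
    four mixed-background SO classes can occur.
    """
    dent = founders.lines_of(0)
    flint = founders.lines_of(1)
    if len(dent) == 0 or len(flint) == 0:
        raise ValueError("need at least one line per group")
    candidates = [
        (founders.names[i], founders.names[j]) for i in dent for j in flint
    ]
    rng = np.random.default_rng(seed)
    pairs = _sample_pairs(candidates, n_hybrids, max_per_parent, rng)
    name_idx = {nm: i for i, nm in enumerate(founders.names)}
    m = founders.n_markers
    alleles = np.empty((n_hybrids, m, 2), dtype=np.uint8)
    origins = np.empty((n_hybrids, m, 2), dtype=np.uint8)
    for h, (pd_name, pf_name) in enumerate(pairs):
        alleles[h, :, 0] = founders.haplotypes[name_idx[pd_name]]
        alleles[h, :, 1] = founders.haplotypes[name_idx[pf_name]]
    origins[:, :, 0] = ORIGIN_D
    origins[:, :, 1] = ORIGIN_F
    hybrids = [f"{p1}x{p2}" for p1, p2 in pairs]
    return PanelGenotypes(
        hybrids=hybrids,
        markers=[f"m{k:05d}" for k in range(m)],
        alleles=alleles,
        origins=origins,
        design=CrossDesign(kind="factorial", pairs=pairs),
    )


# ---------------------------------------------------------------------------
# Doubled haploids
# ---------------------------------------------------------------------------


@dataclass
class DHLines:
    """Admixed doubled-haploid lines with origin-tracked segments.

    Each line is a single recombinant F1 gamete doubled: fully
    homozygous at the allele level, every locus labeled with the
    heterotic-group origin of the contributing F1 haplotype.
    """

    names: list[str]
    alleles: np.ndarray  # (n_dh, m)
    origins: np.ndarray  # (n_dh, m)
    parents: list[str]  # contributing F1 hybrid per line

    @property
    def n_lines(self) -> int:
        return self.alleles.shape[0]


def _recombinant_gamete(
    chrom_starts: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Haplotype index (0/1) per marker under Haldane recombination.

    ``chrom_starts`` holds the cM positions of the markers of each
    chromosome.  Crossover counts are Poisson with mean span/100 cM (no
    interference); crossover positions are uniform on the span.
    """
    out = []
    for pos in chrom_starts:
        span = float(pos[-1] - pos[0]) if len(pos) else 0.0
        n_xo = rng.poisson(span / 100.0) if span > 0 else 0
        start = rng.integers(0, 2)
        if n_xo == 0:
            out.append(np.full(len(pos), start, dtype=np.uint8))
            continue
        xo = np.sort(rng.uniform(pos[0], pos[-1], size=n_xo))
        hap = (start + np.searchsorted(xo, pos, side="right")) % 2
        out.append(hap.astype(np.uint8))
    return np.concatenate(out) if out else np.empty(0, dtype=np.uint8)


def simulate_dh(
    f1_panel: PanelGenotypes,
    gmap: GeneticMap,
    n_dh: int,
    seed: int = 0,
) -> DHLines:
    """Derive admixed DH lines from inter-group F1 hybrids."""
    if f1_panel.markers != gmap.markers:
        raise ValueError("panel markers do not match map markers (order and identity)")
    # F1 parents must be inter-group hybrids at every locus
    if not ((f1_panel.origins.sum(axis=2) == 1).all()):
        raise ValueError("F1 parents must carry one D and one F gamete at every marker")
    rng = np.random.default_rng(seed)
    chrom_pos = [gmap.cm_of()[gmap.chrom_indices(c)] for c in gmap.chromosomes]
    m = f1_panel.n_markers
    alleles = np.empty((n_dh, m), dtype=np.uint8)
    origins = np.empty((n_dh, m), dtype=np.uint8)
    parent_idx = rng.integers(0, f1_panel.n_hybrids, size=n_dh)
    rows = np.arange(m)
    for k in range(n_dh):
        h = parent_idx[k]
        hap = _recombinant_gamete(chrom_pos, rng)
        alleles[k] = f1_panel.alleles[h, rows, hap]
        origins[k] = f1_panel.origins[h, rows, hap]
    names = [f"DH{k:03d}" for k in range(n_dh)]
    parents = [f1_panel.hybrids[h] for h in parent_idx]
    return DHLines(names=names, alleles=alleles, origins=origins, parents=parents)


def simulate_diallel(
    dh: DHLines,
    n_hybrids: int,
    seed: int = 0,
    max_per_parent: int = 4,
) -> PanelGenotypes:
    """Sparse diallel between admixed DH lines.

    Since a DH line is fully homozygous, each parent transmits its single
    haplotype (with its origin labels) unchanged; the hybrid is the
    unordered union of the two parental haplotypes and can realize all
    ten SO classes.
    """
    if dh.n_lines < 2:
        raise ValueError("need at least 2 DH lines for a diallel")
    candidates = [
        (dh.names[i], dh.names[j])
        for i, j in itertools.combinations(range(dh.n_lines), 2)
    ]
    rng = np.random.default_rng(seed)
    pairs = _sample_pairs(candidates, n_hybrids, max_per_parent, rng)
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate cross requested")
    name_idx = {nm: i for i, nm in enumerate(dh.names)}
    m = dh.alleles.shape[1]
    alleles = np.empty((n_hybrids, m, 2), dtype=np.uint8)
    origins = np.empty((n_hybrids, m, 2), dtype=np.uint8)
    for h, (p1, p2) in enumerate(pairs):
        i, j = name_idx[p1], name_idx[p2]
        alleles[h, :, 0] = dh.alleles[i]
        origins[h, :, 0] = dh.origins[i]
        alleles[h, :, 1] = dh.alleles[j]
        origins[h, :, 1] = dh.origins[j]
    hybrids = [f"{p1}x{p2}" for p1, p2 in pairs]
    return PanelGenotypes(
        hybrids=hybrids,
        markers=[f"m{k:05d}" for k in range(m)],
        alleles=alleles,
        origins=origins,
        design=CrossDesign(kind="diallel", pairs=pairs),
    )


def apply_maf_filter(
    panel: PanelGenotypes, gmap: GeneticMap, threshold: float = 0.05
) -> tuple[PanelGenotypes, GeneticMap]:
    """Drop markers with panel MAF below ``threshold`` from panel and map."""
    keep = panel.maf() >= threshold
    dropped = int((~keep).sum())
    if dropped:
        logger.info("MAF filter: dropped %d of %d markers", dropped, panel.n_markers)
    kept_names = set(np.array(panel.markers)[keep])
    new_map = GeneticMap(gmap.table[gmap.table["marker"].isin(kept_names)].copy())
    return panel.subset_markers(np.flatnonzero(keep)), new_map


# ---------------------------------------------------------------------------
# True architecture and phenotypes
# ---------------------------------------------------------------------------


@dataclass
class QtlEffect:
    """Background-specific biological effects of one QTL, in trait units.

    ``a_bg`` is half the difference between the two SNP homozygotes
    within background ``bg``; ``d_bg`` the heterozygote deviation from
    their mean; ``o_a`` an additive effect of the count of Dent-origin
    alleles; ``o_d`` a deviation specific to the mixed DF background;
    ``delta_ld`` the difference between the two mixed-phase double
    heterozygotes (0D1F minus 1D0F).
    """

    marker: int  # index into the panel marker list
    a_dd: float = 0.0
    a_df: float = 0.0
    a_ff: float = 0.0
    d_dd: float = 0.0
    d_df: float = 0.0
    d_ff: float = 0.0
    o_a: float = 0.0
    o_d: float = 0.0
    delta_ld: float = 0.0

    def class_means(self) -> np.ndarray:
        """Genetic value of each of the ten SO classes, SO_CLASSES order."""
        return np.array(
            [
                -self.a_dd + self.o_a,                      # 0D0D
                self.d_dd + self.o_a,                       # 1D0D
                self.a_dd + self.o_a,                       # 1D1D
                -self.a_ff - self.o_a,                      # 0F0F
                self.d_ff - self.o_a,                       # 1F0F
                self.a_ff - self.o_a,                       # 1F1F
                -self.a_df + self.o_d,                      # 0D0F
                self.d_df + self.o_d + self.delta_ld / 2.0,  # 0D1F
                self.d_df + self.o_d - self.delta_ld / 2.0,  # 1D0F
                self.a_df + self.o_d,                       # 1D1F
            ]
        )


def _per_env(value, n_env: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n_env, float(arr))
    if arr.shape != (n_env,):
        raise ValueError(f"expected scalar or length-{n_env} sequence, got shape {arr.shape}")
    return arr


@dataclass
class TrueArchitecture:
    """Generative truth for phenotype simulation.

    Variances are in squared trait units.  Defaults describe a highly
    heritable, additivity-dominated trait on a panel of a few hundred
    hybrids: polygenic additive variance 1.0, dominance 0.15, weak
    epistasis, GxE variances smaller than their main effects except for
    dominance (DxE > dominance), moderate spatial field trends and an
    error variance of 0.5 per plot.
    """

    mean: float = 100.0
    qtls: list[QtlEffect] = field(default_factory=list)
    var_a: float = 1.0
    var_d: float = 0.15
    var_aa: float = 0.05
    var_ad: float = 0.05
    var_dd: float = 0.05
    var_axe: float | Sequence[float] = 0.15
    var_dxe: float | Sequence[float] = 0.25
    var_error: float | Sequence[float] = 0.5
    var_row: float = 0.2
    var_col: float = 0.2
    check_effects: tuple[float, ...] = (0.8, -0.8, 1.5, -1.5)
    block_effect: float = 0.5

    def validate(self, n_markers: int) -> None:
        for name in ("var_a", "var_d", "var_aa", "var_ad", "var_dd", "var_row", "var_col"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("var_axe", "var_dxe", "var_error"):
            if np.any(np.asarray(getattr(self, name), dtype=float) < 0):
                raise ValueError(f"{name} must be >= 0")
        for q in self.qtls:
            if not (0 <= q.marker < n_markers):
                raise ValueError(f"QTL marker index {q.marker} out of range")


@dataclass
class FieldLayout:
    """Rectangular trial grid."""

    n_rows: int = 16
    n_cols: int = 32


CHECK_NAMES = ("check1", "check2", "check3", "check4")


def _mvn_draw(rng: np.random.Generator, K: np.ndarray, var: float) -> np.ndarray:
    n = K.shape[0]
    if var <= 0:
        return np.zeros(n)
    # jittered Cholesky for PSD kinships
    jitter = 1e-8 * np.trace(K) / n
    L = np.linalg.cholesky(K + jitter * np.eye(n))
    return L @ rng.standard_normal(n) * np.sqrt(var)


def simulate_phenotypes(
    panel: PanelGenotypes,
    arch: TrueArchitecture,
    layout: FieldLayout | None = None,
    n_env: int = 1,
    seed: int = 0,
    check_reps: int = 4,
    exp_reps: int = 1,
    trait: str = "trait",
    with_blocks: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a plot table over ``n_env`` single-trial environments.

    Each experimental hybrid is planted ``exp_reps`` times per
    environment (1 mirrors a sparse trial; >1 makes the within-trial
    genetic variance separable from the plot error); the four checks
    are replicated ``check_reps`` times per environment.  Returns the
    plot table (formats_io PlotTable layout) and a truth dictionary
    with the per-hybrid genetic values and every variance draw, for
    recovery tests.
    """
    if layout is None:
        layout = FieldLayout()
    arch.validate(panel.n_markers)
    n = panel.n_hybrids
    rng = np.random.default_rng(seed)

    # --- genetic values -----------------------------------------------------
    from .kinship import build_kinships, noia_codings  # deferred: avoids import cycle at doc build

    g_qtl = np.zeros(n)
    for q in arch.qtls:
        g_qtl += q.class_means()[panel.so[:, q.marker]]

    any_polygenic = max(arch.var_a, arch.var_d, arch.var_aa, arch.var_ad, arch.var_dd) > 0
    axe_vars = _per_env(arch.var_axe, n_env)
    dxe_vars = _per_env(arch.var_dxe, n_env)
    err_vars = _per_env(arch.var_error, n_env)
    if any_polygenic or axe_vars.max() > 0 or dxe_vars.max() > 0:
        coding = noia_codings(panel.dosage())
        kin = build_kinships(coding)
        A = _mvn_draw(rng, kin.ka, arch.var_a)
        D = _mvn_draw(rng, kin.kd, arch.var_d)
        Iaa = _mvn_draw(rng, kin.kaa, arch.var_aa)
        Iad = _mvn_draw(rng, kin.kad, arch.var_ad)
        Idd = _mvn_draw(rng, kin.kdd, arch.var_dd)
        AE = np.stack([_mvn_draw(rng, kin.ka, axe_vars[e]) for e in range(n_env)])
        DE = np.stack([_mvn_draw(rng, kin.kd, dxe_vars[e]) for e in range(n_env)])
    else:
        A = D = Iaa = Iad = Idd = np.zeros(n)
        AE = np.zeros((n_env, n))
        DE = np.zeros((n_env, n))
    g_main = g_qtl + A + D + Iaa + Iad + Idd

    # precocity blocks: median split on the main genetic value (mirrors
    # grouping genotypes by earliness to avoid competition)
    if with_blocks:
        block_of = (g_main > np.median(g_main)).astype(int)
    else:
        block_of = np.zeros(n, dtype=int)

    env_effects = rng.normal(0.0, 1.0, size=n_env) if n_env > 1 else np.zeros(1)

    rows_out = []
    truth_rowcol = {}
    plot_id = 0
    for e in range(n_env):
        env = f"env{e + 1}"
        entries = [("experimental", h) for h in range(n) for _ in range(exp_reps)]
        for t, chk in enumerate(CHECK_NAMES):
            entries.extend([(chk, -1 - t)] * check_reps)
        n_plots = len(entries)
        if layout.n_rows * layout.n_cols < n_plots:
            raise ValueError(
                f"layout {layout.n_rows}x{layout.n_cols} too small for {n_plots} plots"
            )
        # contiguous row bands per precocity block, random within band
        order = sorted(
            range(len(entries)),
            key=lambda k: (
                block_of[entries[k][1]] if entries[k][0] == "experimental" else rng.integers(0, 2),
                rng.random(),
            ),
        )
        row_eff = rng.normal(0.0, np.sqrt(arch.var_row), size=layout.n_rows)
        col_eff = rng.normal(0.0, np.sqrt(arch.var_col), size=layout.n_cols)
        truth_rowcol[env] = {"row": row_eff, "col": col_eff}
        for slot, k in enumerate(order):
            status, h = entries[k]
            r, c = divmod(slot, layout.n_cols)
            err = rng.normal(0.0, np.sqrt(err_vars[e])) if err_vars[e] > 0 else 0.0
            if status == "experimental":
                value = (
                    arch.mean
                    + env_effects[e]
                    + arch.block_effect * block_of[h]
                    + g_main[h]
                    + AE[e, h]
                    + DE[e, h]
                    + row_eff[r]
                    + col_eff[c]
                    + err
                )
                hybrid = panel.hybrids[h]
                block = f"block{block_of[h] + 1}"
            else:
                t = -h - 1
                value = (
                    arch.mean
                    + env_effects[e]
                    + arch.check_effects[t]
                    + row_eff[r]
                    + col_eff[c]
                    + err
                )
                hybrid = status
                block = f"block{1 + (r >= layout.n_rows // 2)}"
            rows_out.append(
                {
                    "plot": f"p{plot_id:05d}",
                    "hybrid": hybrid,
                    "check": status,
                    "block": block,
                    "row": r,
                    "col": c,
                    "env": env,
                    "nplants": int(rng.poisson(50)),
                    trait: value,
                }
            )
            plot_id += 1

    plots = pd.DataFrame(rows_out)
    truth = {
        "g_qtl": g_qtl,
        "A": A,
        "D": D,
        "Iaa": Iaa,
        "Iad": Iad,
        "Idd": Idd,
        "AE": AE,
        "DE": DE,
        "g_main": g_main,
        "block_of": block_of,
        "env_effects": env_effects,
        "rowcol": truth_rowcol,
        "class_means": {q.marker: q.class_means() for q in arch.qtls},
    }
    return plots, truth
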