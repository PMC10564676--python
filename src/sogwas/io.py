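"""Readers and writers for the project's tabular formats.

Genotypes travel as a long TSV with one row per hybrid x marker:
``hybrid  marker  gamete1_allele  gamete1_origin  gamete2_allele
gamete2_origin  so_class``; the SO class column is derived on write and
re-derived (and cross-checked) on read.  Maps are TSV (marker, chrom,
cm, bp), plot tables CSV.  Readers reject inconsistent marker universes
instead of silently intersecting unless ``allow_intersect`` is set.
Kinship sets persist as a labeled ``.npz`` container.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import logger
from .kinship import KinshipSet
from .panel import (
    ORIGIN_LABELS,
    SO_CLASSES,
    GeneticMap,
    PanelGenotypes,
    order_panel_by_map,
)
from .qtl import Qtl

_ORIGIN_CODE = {"D": 0, "F": 1}


# ---------------------------------------------------------------------------
# Genotypes + map
# ---------------------------------------------------------------------------


def write_panel(panel: PanelGenotypes, path: str | Path) -> None:
    n, m = panel.n_hybrids, panel.n_markers
    hyb = np.repeat(panel.hybrids, m)
    mk = np.tile(panel.markers, n)
    a = panel.alleles.reshape(n * m, 2)
    o = panel.origins.reshape(n * m, 2)
    df = pd.DataFrame(
        {
            "hybrid": hyb,
            "marker": mk,
            "gamete1_allele": a[:, 0],
            "gamete1_origin": np.array(ORIGIN_LABELS)[o[:, 0]],
            "gamete2_allele": a[:, 1],
            "gamete2_origin": np.array(ORIGIN_LABELS)[o[:, 1]],
            "so_class": np.array(SO_CLASSES)[panel.so.reshape(n * m)],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_map(path: str | Path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, sep="\t"))


def read_panel(
    genotype_path: str | Path,
    map_path: str | Path,
    allow_intersect: bool = False,
) -> tuple[PanelGenotypes, GeneticMap]:
    """Parse a genotype TSV and its map; markers end up in map order."""
    gmap = read_map(map_path)
    df = pd.read_csv(genotype_path, sep="\t", dtype={"hybrid": str, "marker": str})
    required = [
        "hybrid", "marker",
        "gamete1_allele", "gamete1_origin", "gamete2_allele", "gamete2_origin",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"genotype file missing columns: {missing}")
    for col in ("gamete1_origin", "gamete2_origin"):
        bad = ~df[col].isin(_ORIGIN_CODE)
        if bad.any():
            row = df.loc[bad].iloc[0]
            raise ValueError(
                f"unknown origin code {row[col]!r} at marker {row['marker']!r}"
            )
    for col in ("gamete1_allele", "gamete2_allele"):
        bad = ~df[col].isin((0, 1))
        if bad.any():
            row = df.loc[bad].iloc[0]
            raise ValueError(
                f"allele outside {{0,1}} ({row[col]!r}) at marker {row['marker']!r}"
            )
    hybrids = list(dict.fromkeys(df["hybrid"]))
    markers = list(dict.fromkeys(df["marker"]))
    if allow_intersect:
        common = [mk for mk in markers if mk in set(gmap.markers)]
        df = df[df["marker"].isin(set(common))]
        gmap = GeneticMap(gmap.table[gmap.table["marker"].isin(set(common))].copy())
        markers = common
    hidx = {h: i for i, h in enumerate(hybrids)}
    midx = {mk: j for j, mk in enumerate(markers)}
    n, m = len(hybrids), len(markers)
    alleles = np.zeros((n, m, 2), dtype=np.uint8)
    origins = np.zeros((n, m, 2), dtype=np.uint8)
    rows = df["hybrid"].map(hidx).to_numpy()
    cols = df["marker"].map(midx).to_numpy()
    alleles[rows, cols, 0] = df["gamete1_allele"]
    alleles[rows, cols, 1] = df["gamete2_allele"]
    origins[rows, cols, 0] = df["gamete1_origin"].map(_ORIGIN_CODE)
    origins[rows, cols, 1] = df["gamete2_origin"].map(_ORIGIN_CODE)
    panel = PanelGenotypes(hybrids=hybrids, markers=markers, alleles=alleles, origins=origins)
    panel = order_panel_by_map(panel, gmap)
    logger.info("read_panel: %d hybrids x %d markers", n, panel.n_markers)
    return panel, gmap


def read_panel_vcf(
    vcf_path: str | Path,
    map_path: str | Path,
    origin_format_tag: str = "SO",
) -> tuple[PanelGenotypes, GeneticMap]:
    """Import phased hybrid genotypes from a VCF.

    Haplotype origins are read from a per-sample FORMAT string tag
    holding two comma-separated codes (one per allele), e.g. ``D,F``.
    Requires the optional ``cyvcf2`` dependency.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    hybrids = list(vcf.samples)
    markers, rows_a, rows_o = [], [], []
    for var in vcf:
        mid = var.ID or f"{var.CHROM}_{var.POS}"
        markers.append(mid)
        gt = np.array(var.genotypes)[:, :2]
        if ((gt < 0) | (gt > 1)).any():
            raise ValueError(f"allele outside {{0,1}} at marker {mid!r}")
        tags = var.format(origin_format_tag)
        if tags is None:
            raise ValueError(f"missing FORMAT tag {origin_format_tag!r} at marker {mid!r}")
        o = np.empty((len(hybrids), 2), dtype=np.uint8)
        for i, t in enumerate(tags):
            t = t if isinstance(t, str) else t.decode()
            parts = t.split(",")
            if len(parts) != 2 or any(p not in _ORIGIN_CODE for p in parts):
                raise ValueError(f"unknown origin code {t!r} at marker {mid!r}")
            o[i] = [_ORIGIN_CODE[parts[0]], _ORIGIN_CODE[parts[1]]]
        rows_a.append(gt.astype(np.uint8))
        rows_o.append(o)
    gmap = read_map(map_path)
    panel = PanelGenotypes(
        hybrids=hybrids,
        markers=markers,
        alleles=np.stack(rows_a, axis=1),
        origins=np.stack(rows_o, axis=1),
    )
    return order_panel_by_map(panel, gmap), gmap


# ---------------------------------------------------------------------------
# Plot tables
# ---------------------------------------------------------------------------


def write_plots(plots: pd.DataFrame, path: str | Path) -> None:
    plots.to_csv(path, index=False)


def read_plots(
    csv_path: str | Path, traits: list[str] | None = None
) -> pd.DataFrame:
    """Read and validate a plot-level phenotype table."""
    df = pd.read_csv(csv_path)
    mandatory = ["hybrid", "check", "row", "col", "env", "nplants"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"plot table missing mandatory columns: {missing}")
    for t in traits or []:
        if t not in df.columns:
            raise ValueError(f"plot table missing trait column {t!r}")
    dup = df.duplicated(subset=["row", "col", "env"])
    if dup.any():
        r = df.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate plot coordinates (row={r['row']}, col={r['col']}, env={r['env']})"
        )
    if (df["nplants"] < 0).any():
        raise ValueError("plant counts must be >= 0")
    return df


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


def write_gwas_table(results: pd.DataFrame, path: str | Path, allow_empty: bool = False) -> None:
    if results.empty and not allow_empty:
        raise ValueError("refusing to write an empty GWAS table (pass allow_empty=True)")
    results.to_csv(path, sep="\t", index=False)


def read_gwas_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_qtl_table(qtls: list[Qtl], path: str | Path, allow_empty: bool = False) -> None:
    """BED-like QTL table: chrom, bp interval, cM interval, provenance."""
    if not qtls and not allow_empty:
        raise ValueError("refusing to write an empty QTL table (pass allow_empty=True)")
    rows = [
        {
            "chrom": q.chrom,
            "start_bp": q.start_bp,
            "end_bp": q.end_bp,
            "start_cm": q.start_cm,
            "end_cm": q.end_cm,
            "trait": q.trait,
            "contrast": q.contrast,
            "family": q.family,
            "layers": ";".join(q.layers),
            "peak_marker": q.peak_marker,
            "peak_p": q.peak_p,
            "peak_estimate": q.peak_estimate,
            "members": ";".join(q.members),
        }
        for q in qtls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def save_kinships(kinsets: dict, path: str | Path, hybrids: list[str]) -> None:
    """Persist kinship sets keyed by excluded chromosome ('none' = whole genome)."""
    arrays = {"hybrids": np.array(hybrids)}
    for key, kin in kinsets.items():
        for name, M in kin.as_dict().items():
            arrays[f"{key}__{name}"] = M
    np.savez_compressed(path, **arrays)


def load_kinships(path: str | Path) -> tuple[dict, list[str]]:
    data = np.load(path, allow_pickle=False)
    hybrids = [str(h) for h in data["hybrids"]]
    keys = sorted({k.rsplit("__", 1)[0] for k in data.files if "__" in k})
    out = {}
    for key in keys:
        out[key] = KinshipSet(
            ka=data[f"{key}__a"],
            kd=data[f"{key}__d"],
            kaa=data[f"{key}__aa"],
            kad=data[f"{key}__ad"],
            kdd=data[f"{key}__dd"],
            excluded_chrom=key if key != "none" else "none",
        )
    return out, hybrids


def write_truth(truth: dict, path: str | Path) -> None:
    """JSON dump of the generative truth (arrays become lists)."""

    def conv(x):
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, dict):
            return {str(k): conv(v) for k, v in x.items()}
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        return x

    with open(path, "w") as fh:
        json.dump(conv(truth), fh)
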