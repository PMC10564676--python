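"""Core containers for two-group hybrid panels.

A hybrid is stored as two gametes per marker, each gamete carrying an
allele in {0, 1} and the heterotic-group origin of the local genetic
background it came from (Dent ``D`` or Flint ``F``).  Combining both
pieces of information yields four SNP-Origin (SO) *alleles* -- 0D, 1D,
0F and 1F -- and, at the genotype level, ten distinct unordered pairs
(SO classes).  An inter-group factorial panel carries one D and one F
gamete everywhere and therefore only realizes the four mixed-background
classes; a diallel between admixed lines can realize all ten.

The two double heterozygotes 0D1F and 1D0F are distinct classes: they
differ in which origin carries allele 1, which is exactly the phase
information the Delta_LD contrast exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ORIGIN_D = 0
ORIGIN_F = 1
ORIGIN_LABELS = ("D", "F")

#: Canonical order of the ten SO genotype classes.  The first six are the
#: intra-group backgrounds (DD then FF), the last four the inter-group
#: (DF) classes shared by factorial and diallel panels.
SO_CLASSES = (
    "0D0D", "1D0D", "1D1D",
    "0F0F", "1F0F", "1F1F",
    "0D0F", "0D1F", "1D0F", "1D1F",
)
SO_INDEX = {name: i for i, name in enumerate(SO_CLASSES)}

#: The four classes observable in an inter-group factorial panel.
FACTORIAL_CLASSES = ("0D0F", "0D1F", "1D0F", "1D1F")

#: Genetic background (origin pair) of each SO class, in SO_CLASSES order.
SO_BACKGROUND = ("DD", "DD", "DD", "FF", "FF", "FF", "DF", "DF", "DF", "DF")

#: SNP allele dosage (count of allele 1) of each SO class.
SO_DOSAGE = np.array([0, 1, 2, 0, 1, 2, 0, 1, 1, 2], dtype=np.int8)

#: Count of Dent-origin alleles of each SO class.
SO_N_DENT = np.array([2, 2, 2, 0, 0, 0, 1, 1, 1, 1], dtype=np.int8)


def so_class_name(allele1: int, origin1: int, allele2: int, origin2: int) -> str:
    """Canonical SO class name of an unordered pair of (allele, origin) gametes.

    Gametes are ordered D before F; within the same origin the allele-1
    gamete comes first (matching the 1D0D / 1F0F naming convention).
    """
    g1 = (int(allele1), int(origin1))
    g2 = (int(allele2), int(origin2))
    for a, o in (g1, g2):
        if a not in (0, 1):
            raise ValueError(f"allele must be 0 or 1, got {a}")
        if o not in (ORIGIN_D, ORIGIN_F):
            raise ValueError(f"origin must be 0 (D) or 1 (F), got {o}")
    # sort by (origin asc, allele desc)
    g1, g2 = sorted((g1, g2), key=lambda g: (g[1], -g[0]))
    return "{}{}{}{}".format(
        g1[0], ORIGIN_LABELS[g1[1]], g2[0], ORIGIN_LABELS[g2[1]]
    )


def _build_lut() -> np.ndarray:
    lut = np.empty(16, dtype=np.uint8)
    for a1 in (0, 1):
        for o1 in (0, 1):
            for a2 in (0, 1):
                for o2 in (0, 1):
                    lut[a1 * 8 + o1 * 4 + a2 * 2 + o2] = SO_INDEX[
                        so_class_name(a1, o1, a2, o2)
                    ]
    return lut


_SO_LUT = _build_lut()


def assign_so_classes(alleles: np.ndarray, origins: np.ndarray) -> np.ndarray:
    """Vectorized SO class codes (indices into :data:`SO_CLASSES`).

    Parameters
    ----------
    alleles, origins
        Arrays of shape ``(..., 2)`` holding the two gametes.
    """
    a = np.asarray(alleles, dtype=np.int64)
    o = np.asarray(origins, dtype=np.int64)
    if a.shape != o.shape or a.shape[-1] != 2:
        raise ValueError("alleles and origins must both have trailing dim 2")
    if ((a < 0) | (a > 1)).any():
        raise ValueError("alleles must be in {0, 1}")
    if ((o < 0) | (o > 1)).any():
        raise ValueError("origins must be 0 (D) or 1 (F)")
    key = a[..., 0] * 8 + o[..., 0] * 4 + a[..., 1] * 2 + o[..., 1]
    return _SO_LUT[key]


@dataclass
class CrossDesign:
    """Record of which parental pairs produced each hybrid."""

    kind: str  # "factorial" | "diallel"
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.kind not in ("factorial", "diallel"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        for p1, p2 in self.pairs:
            if p1 == p2:
                raise ValueError(f"self-cross {p1} x {p2} not allowed")

    def contributions(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p1, p2 in self.pairs:
            counts[p1] = counts.get(p1, 0) + 1
            counts[p2] = counts.get(p2, 0) + 1
        return counts


@dataclass
class PanelGenotypes:
    """Hybrid genotypes as (allele, origin) gamete pairs per marker.

    Attributes
    ----------
    hybrids : list of str
        Hybrid identifiers, length n.
    markers : list of str
        Marker identifiers, length m, in map order.
    alleles : ndarray of shape (n, m, 2)
        Allele (0/1) of each gamete.
    origins : ndarray of shape (n, m, 2)
        Group origin of each gamete (0 = Dent, 1 = Flint).
    """

    hybrids: list[str]
    markers: list[str]
    alleles: np.ndarray
    origins: np.ndarray
    design: CrossDesign | None = None
    so: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n, m = len(self.hybrids), len(self.markers)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.origins = np.asarray(self.origins, dtype=np.uint8)
        expect = (n, m, 2)
        if self.alleles.shape != expect or self.origins.shape != expect:
            raise ValueError(
                f"alleles/origins must have shape {expect}, got "
                f"{self.alleles.shape} / {self.origins.shape}"
            )
        if len(set(self.hybrids)) != n:
            raise ValueError("duplicate hybrid ids")
        if len(set(self.markers)) != m:
            raise ValueError("duplicate marker ids")
        self.so = assign_so_classes(self.alleles, self.origins)

    @property
    def n_hybrids(self) -> int:
        return len(self.hybrids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def dosage(self) -> np.ndarray:
        """Count of allele 1 per hybrid x marker (0, 1 or 2)."""
        return self.alleles.sum(axis=2).astype(np.int8)

    def het(self) -> np.ndarray:
        """SNP-heterozygosity indicator per hybrid x marker."""
        return (self.alleles[..., 0] != self.alleles[..., 1]).astype(np.int8)

    def maf(self) -> np.ndarray:
        """Panel minor allele frequency per marker."""
        p = self.dosage().mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def background_fractions(self) -> pd.DataFrame:
        """Per-hybrid fractions of DD / DF / FF loci."""
        n_dent = self.origins.shape[-1] - self.origins.sum(axis=2)  # 0,1,2
        out = pd.DataFrame(
            {
                "DD": (n_dent == 2).mean(axis=1),
                "DF": (n_dent == 1).mean(axis=1),
                "FF": (n_dent == 0).mean(axis=1),
            },
            index=pd.Index(self.hybrids, name="hybrid"),
        )
        return out

    def class_counts(self) -> np.ndarray:
        """(m, 10) array of SO class carrier counts per marker."""
        counts = np.zeros((self.n_markers, len(SO_CLASSES)), dtype=np.int64)
        for c in range(len(SO_CLASSES)):
            counts[:, c] = (self.so == c).sum(axis=0)
        return counts

    def subset_markers(self, idx: Sequence[int]) -> "PanelGenotypes":
        idx = np.asarray(idx)
        return PanelGenotypes(
            hybrids=list(self.hybrids),
            markers=[self.markers[i] for i in idx],
            alleles=self.alleles[:, idx, :],
            origins=self.origins[:, idx, :],
            design=self.design,
        )


@dataclass
class GeneticMap:
    """Marker coordinates: chromosome, genetic (cM) and physical (bp) position.

    Markers are sorted by (chromosome, cM, bp) on construction; positions
    must be non-negative and bp 1-based.
    """

    table: pd.DataFrame  # columns: marker, chrom, cm, bp

    REQUIRED = ("marker", "chrom", "cm", "bp")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"genetic map missing columns: {missing}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker id in map: {dup}")
        if (t["cm"] < 0).any():
            raise ValueError("cM positions must be non-negative")
        if (t["bp"] < 1).any():
            raise ValueError("bp positions must be 1-based (>= 1)")
        self.table = (
            t.sort_values(["chrom", "cm", "bp"], kind="stable")
            .reset_index(drop=True)
        )

    @property
    def markers(self) -> list[str]:
        return list(self.table["marker"])

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.table["chrom"]))

    def chrom_of(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    def cm_of(self) -> np.ndarray:
        return self.table["cm"].to_numpy(dtype=float)

    def bp_of(self) -> np.ndarray:
        return self.table["bp"].to_numpy(dtype=np.int64)

    def marker_row(self, marker: str) -> pd.Series:
        rows = self.table.index[self.table["marker"] == marker]
        if len(rows) == 0:
            raise KeyError(f"marker {marker!r} not in map")
        return self.table.loc[rows[0]]

    def chrom_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero(self.table["chrom"].to_numpy() == chrom)


def order_panel_by_map(panel: PanelGenotypes, gmap: GeneticMap) -> PanelGenotypes:
    """Reorder panel markers to map order, rejecting inconsistent marker sets."""
    panel_set = set(panel.markers)
    map_set = set(gmap.markers)
    only_panel = panel_set - map_set
    if only_panel:
        name = sorted(only_panel)[0]
        raise ValueError(f"marker {name!r} present in genotypes but absent from map")
    only_map = map_set - panel_set
    if only_map:
        name = sorted(only_map)[0]
        raise ValueError(f"marker {name!r} present in map but absent from genotypes")
    pos = {mk: i for i, mk in enumerate(panel.markers)}
    idx = [pos[mk] for mk in gmap.markers]
    return panel.subset_markers(idx)
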