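"""NOIA marker codings and the five genomic relationship matrices.

The Natural and Orthogonal Interactions (NOIA) parametrization builds
additive and dominance marker codings that are orthogonal under the
*observed* genotype frequencies of the analyzed panel: for every marker
the frequency-weighted means of both codings and their cross-product
are zero.  With B the allele counted (here allele 1) and genotype
frequencies (p_BB, p_Bb, p_bb):

    h_a:  BB -> p_Bb + 2 p_bb
          Bb -> p_Bb + 2 p_bb - 1
          bb -> p_Bb + 2 p_bb - 2

    h_d:  BB -> -2 p_Bb p_bb / den
          Bb ->  4 p_BB p_bb / den
          bb -> -2 p_BB p_Bb / den,   den = p_BB + p_bb - (p_BB - p_bb)^2

Relationship matrices are cross-products normalized to mean diagonal 1,
K = H H' / (tr[H H']/n); the three epistatic kinships are Hadamard
products of K_a and K_d with the same normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import logger
from .panel import GeneticMap, PanelGenotypes


def genotype_frequencies(dosage: np.ndarray) -> np.ndarray:
    """Observed genotype frequencies per marker.

    Returns an (m, 3) array of (p_BB, p_Bb, p_bb) where B is allele 1,
    so BB corresponds to dosage 2 and bb to dosage 0.
    """
    d = np.asarray(dosage)
    n = d.shape[0]
    p_bb = (d == 0).sum(axis=0) / n
    p_het = (d == 1).sum(axis=0) / n
    p_BB = (d == 2).sum(axis=0) / n
    return np.stack([p_BB, p_het, p_bb], axis=1)


def code_additive(dosage_col: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """NOIA additive coding of one marker.

    ``freqs`` is the (p_BB, p_Bb, p_bb) triple; coding depends on the
    genotype class only.  Frequency-weighted mean is 0 by construction.
    """
    p_BB, p_Bb, p_bb = (float(x) for x in freqs)
    if abs(p_BB + p_Bb + p_bb - 1.0) > 1e-8:
        raise ValueError("genotype frequencies must sum to 1")
    base = p_Bb + 2.0 * p_bb
    # dosage 2 = BB, 1 = Bb, 0 = bb
    codes = np.array([base - 2.0, base - 1.0, base])  # index by dosage
    return codes[np.asarray(dosage_col, dtype=np.intp)]


def dominance_denominator(freqs: np.ndarray) -> float:
    p_BB, p_Bb, p_bb = (float(x) for x in freqs)
    return p_BB + p_bb - (p_BB - p_bb) ** 2


def code_dominance(dosage_col: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """NOIA dominance coding of one marker.

    Raises ``ValueError`` when the denominator is not positive (the
    marker is then excluded from H_d by :func:`noia_codings`).
    """
    p_BB, p_Bb, p_bb = (float(x) for x in freqs)
    if abs(p_BB + p_Bb + p_bb - 1.0) > 1e-8:
        raise ValueError("genotype frequencies must sum to 1")
    den = dominance_denominator(freqs)
    if den <= 0:
        raise ValueError("dominance coding undefined: zero denominator")
    codes = np.array(
        [
            -2.0 * p_BB * p_Bb / den,  # dosage 0 = bb
            4.0 * p_BB * p_bb / den,   # dosage 1 = Bb
            -2.0 * p_Bb * p_bb / den,  # dosage 2 = BB
        ]
    )
    return codes[np.asarray(dosage_col, dtype=np.intp)]


@dataclass
class NoiaCoding:
    """Panel-wide NOIA codings.

    ``ha`` has one column per marker; ``hd`` only covers markers whose
    dominance denominator is positive (``hd_markers`` indexes them).
    """

    ha: np.ndarray  # (n, m)
    hd: np.ndarray  # (n, m_d)
    freqs: np.ndarray  # (m, 3)
    hd_markers: np.ndarray  # indices of markers retained in hd


def noia_codings(dosage: np.ndarray) -> NoiaCoding:
    """Build H_a and H_d for all markers from observed frequencies."""
    d = np.asarray(dosage, dtype=np.intp)
    freqs = genotype_frequencies(d)
    p_BB, p_Bb, p_bb = freqs[:, 0], freqs[:, 1], freqs[:, 2]
    base = p_Bb + 2.0 * p_bb
    ha = base[None, :] - (2 - d)
    den = p_BB + p_bb - (p_BB - p_bb) ** 2
    ok = den > 1e-12
    if not ok.all():
        logger.info(
            "dominance coding: excluded %d of %d markers (zero denominator)",
            int((~ok).sum()), len(ok),
        )
    idx = np.flatnonzero(ok)
    codes = np.zeros((3, len(idx)))
    codes[0] = -2.0 * p_BB[idx] * p_Bb[idx] / den[idx]
    codes[1] = 4.0 * p_BB[idx] * p_bb[idx] / den[idx]
    codes[2] = -2.0 * p_Bb[idx] * p_bb[idx] / den[idx]
    hd = codes[d[:, idx], np.arange(len(idx))[None, :]]
    return NoiaCoding(ha=ha, hd=hd, freqs=freqs, hd_markers=idx)


@dataclass
class KinshipSet:
    """The five normalized relationship matrices (tr(K)/n = 1 each)."""

    ka: np.ndarray
    kd: np.ndarray
    kaa: np.ndarray
    kad: np.ndarray
    kdd: np.ndarray
    excluded_chrom: object = "none"

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"a": self.ka, "d": self.kd, "aa": self.kaa, "ad": self.kad, "dd": self.kdd}


def _normalize(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    tr = np.trace(M)
    if tr <= 0:
        raise ValueError("cannot normalize a matrix with non-positive trace")
    return M * (n / tr)


def build_kinships(coding: NoiaCoding, excluded_chrom: object = "none") -> KinshipSet:
    """K_a, K_d from cross-products; epistatic kinships from Hadamard products."""
    if coding.ha.shape[1] == 0:
        raise ValueError("no markers retained in the additive coding")
    if coding.hd.shape[1] == 0:
        raise ValueError("no markers retained in the dominance coding")
    ka = _normalize(coding.ha @ coding.ha.T)
    kd = _normalize(coding.hd @ coding.hd.T)
    kaa = _normalize(ka * ka)
    kad = _normalize(ka * kd)
    kdd = _normalize(kd * kd)
    return KinshipSet(ka=ka, kd=kd, kaa=kaa, kad=kad, kdd=kdd, excluded_chrom=excluded_chrom)


def panel_kinships(panel: PanelGenotypes) -> KinshipSet:
    """Whole-genome kinships from the panel's observed genotype frequencies."""
    return build_kinships(noia_codings(panel.dosage()))


def loco_kinships(panel: PanelGenotypes, gmap: GeneticMap) -> dict:
    """Leave-one-chromosome-out kinship sets.

    For every chromosome c, all five matrices (including the epistatic
    ones) are rebuilt from the markers *not* on c, so the Hadamard
    products use the LOCO K_a / K_d rather than masked whole-genome
    versions.
    """
    if panel.markers != gmap.markers:
        raise ValueError("panel markers do not match map markers")
    chroms = gmap.chromosomes
    if len(chroms) < 2:
        raise ValueError(
            "single-chromosome map: leave-one-chromosome-out kinships are "
            "undefined; use whole-genome kinships instead"
        )
    chrom_arr = gmap.chrom_of()
    dosage = panel.dosage()
    out = {}
    for c in chroms:
        keep = np.flatnonzero(chrom_arr != c)
        coding = noia_codings(dosage[:, keep])
        out[c] = build_kinships(coding, excluded_chrom=c)
    return out
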