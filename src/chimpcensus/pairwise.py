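"""Pairwise identity-by-state, relatedness, and identity-by-descent.

All statistics are computed over sites non-missing in both members of a
pair (complete-pairs policy), which is how sparse RNA-seq-derived genotype
matrices have to be handled.  The three estimators are:

* IBS sharing — allele-sharing fraction ``(2*ibs2 + ibs1) / (2*n)``, with
  the distance defined as one minus the sharing.
* The relatedness coefficient
  ``(shared_hets - 2*ibs0) / min(hets_a, hets_b)`` used for identifying
  identical samples; values near 1 indicate the same donor, strongly
  negative values indicate unrelated samples (opposite homozygotes are
  penalized).  The raw value is deliberately not truncated.
* Method-of-moments IBD: expected IBS-class counts given 0/1/2 alleles
  shared identical-by-descent are computed from cohort allele frequencies
  with small-sample bias corrections, and the observed IBS0/1/2 counts are
  inverted to the Z = (Z0, Z1, Z2) triplet, truncated to [0, 1] and
  renormalized.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix
from .popsim import MISSING

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["sample_a", "sample_b", "n", "ibs0", "ibs1", "ibs2",
                "shared_hets", "hets_a", "hets_b", "relatedness",
                "z0", "z1", "z2", "pi_hat"]


@dataclass(frozen=True)
class IBDEstimate:
    """Genome-wide probabilities of sharing 0/1/2 alleles IBD."""

    z0: float
    z1: float
    z2: float

    @property
    def pi_hat(self) -> float:
        return self.z1 / 2 + self.z2

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.z0, self.z1, self.z2)


def _indicator_products(dosages: np.ndarray) -> dict:
    """All 3x3 joint dosage-count matrices via BLAS matmuls."""
    ind = [(dosages == k).astype(np.float32) for k in (0, 1, 2)]
    return {(x, y): ind[x] @ ind[y].T for x in range(3) for y in range(3)}


def pair_counts(g: GenotypeMatrix) -> dict[str, np.ndarray]:
    """Square matrices of IBS and heterozygosity counts for all pairs.

    Returns n_informative, ibs0, ibs1, ibs2, shared_hets, hets_a (rows'
    heterozygote count over the pair's informative sites; ``hets_b`` is its
    transpose).
    """
    d = g.dosages
    m = _indicator_products(d)
    valid = (d != MISSING).astype(np.float32)
    het = (d == 1).astype(np.float32)
    counts = {
        "ibs0": m[(0, 2)] + m[(2, 0)],
        "ibs2": m[(0, 0)] + m[(1, 1)] + m[(2, 2)],
        "shared_hets": m[(1, 1)],
        "n": valid @ valid.T,
        "hets_a": het @ valid.T,
    }
    counts["ibs1"] = counts["n"] - counts["ibs0"] - counts["ibs2"]
    return {k: np.asarray(v, dtype=np.float64) for k, v in counts.items()}


def ibs_distance_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """1 - allele-sharing fraction for every sample pair.

    Sharing is (2*ibs2 + ibs1)/(2*n_informative); diagonal is 0.  Pairs with
    no jointly genotyped site are NaN with a warning.
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    c = pair_counts(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (2 * c["ibs2"] + c["ibs1"]) / (2 * c["n"])
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    if np.isnan(dist).any():
        logger.warning("ibs_distance_matrix: %d pairs share no informative site",
                       int(np.isnan(dist).sum() // 2))
    return pd.DataFrame(dist, index=g.samples, columns=g.samples)


def relatedness_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """Relatedness coefficient (shared_hets - 2*ibs0)/min(hets) per pair.

    The caller is expected to pre-filter to well-informative sites
    (MAF >= 0.25 in the published protocol).  Pairs where either member has
    zero heterozygous informative sites are NaN.
    """
    c = pair_counts(g)
    min_hets = np.minimum(c["hets_a"], c["hets_a"].T)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = (c["shared_hets"] - 2 * c["ibs0"]) / min_hets
    rel[min_hets == 0] = np.nan
    return pd.DataFrame(rel, index=g.samples, columns=g.samples)


def relatedness(a: np.ndarray, b: np.ndarray) -> float:
    """Relatedness coefficient for a single pair of dosage vectors."""
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    shared_hets = int(((a == 1) & (b == 1)).sum())
    ibs0 = int((np.abs(a - b) == 2).sum())
    hets_a = int((a == 1).sum())
    hets_b = int((b == 1).sum())
    m = min(hets_a, hets_b)
    if m == 0:
        return float("nan")
    return (shared_hets - 2 * ibs0) / m


def _expected_ibs_given_ibd(freq: np.ndarray, allele_n: np.ndarray,
                            ) -> dict[str, np.ndarray]:
    """Per-site expected IBS-class probabilities given IBD state.

    Classical method-of-moments expectations with the allele-count bias
    corrections (``allele_n`` is the per-site count of alleles behind the
    frequency estimate).  Returns vectors e00, e10, e20, e11, e21 where
    ``eXY`` is P(IBS=X | IBD=Y); P(IBS=2|IBD=2) = 1.
    """
    x, na = freq, allele_n
    y = 1 - x
    t2 = (na / (na - 1)) * (na / (na - 2))
    t3 = t2 * (na / (na - 3))
    cx1 = (x * na - 1) / (x * na)
    cx2 = (x * na - 2) / (x * na)
    cx3 = (x * na - 3) / (x * na)
    cy1 = (y * na - 1) / (y * na)
    cy2 = (y * na - 2) / (y * na)
    cy3 = (y * na - 3) / (y * na)
    return {
        "e00": 2 * x**2 * y**2 * cx1 * cy1 * t3,
        "e10": 4 * x**3 * y * cx1 * cx2 * t3 + 4 * x * y**3 * cy1 * cy2 * t3,
        "e20": (x**4 * cx1 * cx2 * cx3 * t3 + y**4 * cy1 * cy2 * cy3 * t3
                + 4 * x**2 * y**2 * cx1 * cy1 * t3),
        "e11": 2 * x**2 * y * cx1 * t2 + 2 * x * y**2 * cy1 * t2,
        "e21": (x**3 * cx1 * cx2 * t2 + y**3 * cy1 * cy2 * t2
                + x**2 * y * cx1 * t2 + x * y**2 * cy1 * t2),
    }


def _solve_z(n0, n1, n2, e, n_sites):
    z0 = n0 / e["e00"] if e["e00"] > 0 else 0.0
    z1 = (n1 - z0 * e["e10"]) / e["e11"] if e["e11"] > 0 else 0.0
    z2 = (n2 - z0 * e["e20"] - z1 * e["e21"]) / n_sites
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    s = z.sum()
    if s == 0:
        return IBDEstimate(1.0, 0.0, 0.0)
    z = z / s
    return IBDEstimate(*map(float, z))


def estimate_ibd(a: np.ndarray, b: np.ndarray, freq: np.ndarray,
                 allele_n: np.ndarray | float, min_sites: int = 200,
                 ) -> IBDEstimate:
    """Method-of-moments IBD Z-triplet for one pair.

    ``freq`` are cohort (or panel) alternate-allele frequencies; ``allele_n``
    the allele counts behind them (scalar or per-site).  Sites that are
    degenerate (freq 0/1, too few alleles) or missing in either sample are
    skipped; fewer than ``min_sites`` usable sites triggers a warning.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    freq = np.asarray(freq, dtype=float)
    na = np.broadcast_to(np.asarray(allele_n, dtype=float), freq.shape)
    ok = ((a != MISSING) & (b != MISSING)
          & (freq * na > 1) & ((1 - freq) * na > 1) & (na > 3))
    n_sites = int(ok.sum())
    if n_sites < min_sites:
        logger.warning("estimate_ibd: only %d usable sites (< %d)",
                       n_sites, min_sites)
    if n_sites == 0:
        return IBDEstimate(float("nan"), float("nan"), float("nan"))
    e = {k: float(v.sum())
         for k, v in _expected_ibs_given_ibd(freq[ok], na[ok]).items()}
    diff = np.abs(a[ok] - b[ok])
    n0, n1, n2 = int((diff == 2).sum()), int((diff == 1).sum()), int((diff == 0).sum())
    return _solve_z(n0, n1, n2, e, n_sites)


def ibd_matrix(g: GenotypeMatrix, freq: np.ndarray | None = None,
               allele_n: np.ndarray | float | None = None,
               min_sites: int = 200) -> pd.DataFrame:
    """IBD Z-triplets for all unordered pairs (long format).

    By default frequencies come from the analysis cohort itself, the
    standard choice when no external panel is supplied.
    """
    if freq is None:
        alt, tot = g.allele_counts()
        freq = alt / np.maximum(tot, 1)
        allele_n = tot
    rows = []
    for i, j in itertools.combinations(range(g.n_samples), 2):
        z = estimate_ibd(g.dosages[i], g.dosages[j], freq, allele_n,
                         min_sites=min_sites)
        rows.append((g.samples[i], g.samples[j], z.z0, z.z1, z.z2, z.pi_hat))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b",
                                       "z0", "z1", "z2", "pi_hat"])


def pairwise_table(g: GenotypeMatrix, maf_min_for_relatedness: float = 0.25,
                   min_sites: int = 200) -> pd.DataFrame:
    """Long-format table of all pairwise statistics.

    IBS counts and IBD use every site of ``g``; the relatedness coefficient
    is computed on the MAF-filtered subset (default >= 0.25), matching the
    published protocol of restricting to common sites.
    """
    from .genio import filter_maf

    c = pair_counts(g)
    rel = relatedness_matrix(filter_maf(g, maf_min_for_relatedness))
    ibd = ibd_matrix(g, min_sites=min_sites)
    ibd = ibd.set_index(["sample_a", "sample_b"])
    rows = []
    for i, j in itertools.combinations(range(g.n_samples), 2):
        sa, sb = g.samples[i], g.samples[j]
        z = ibd.loc[(sa, sb)]
        rows.append((sa, sb, c["n"][i, j], c["ibs0"][i, j], c["ibs1"][i, j],
                     c["ibs2"][i, j], c["shared_hets"][i, j],
                     c["hets_a"][i, j], c["hets_a"].T[i, j],
                     rel.iloc[i, j], z["z0"], z["z1"], z["z2"], z["pi_hat"]))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)
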