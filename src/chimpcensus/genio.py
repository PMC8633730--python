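"""Genotype matrix I/O, filtering, and merging.

The in-memory container is :class:`GenotypeMatrix`: a samples x sites array
of alternate-allele dosages (0/1/2, ``-1`` for missing) plus site and sample
registries.  Sites are keyed by (chrom, pos, ref, alt), 1-based as in VCF;
only biallelic SNPs are represented.  Reading goes through cyvcf2; writing
emits minimal VCF 4.2 with a GT-only FORMAT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .popsim import MISSING

logger = logging.getLogger(__name__)

SITE_COLS = ["chrom", "pos", "ref", "alt"]
TISSUE_CATEGORIES = ("brain", "heart", "blood", "skin", "ipsc",
                     "kidney", "liver", "testis", "colon")
META_COLS = ["sample_id", "study_id", "donor_label", "sex", "age", "tissue"]


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix with registries."""

    dosages: np.ndarray          # (n_samples, n_sites), int8, -1 missing
    samples: list[str]
    sites: pd.DataFrame          # columns chrom, pos, ref, alt

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.sites = self.sites.reset_index(drop=True)
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError("registry lengths must match array dimensions")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        if self.sites.duplicated(["chrom", "pos"]).any():
            raise ValueError("positions must be unique per chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_keys(self) -> pd.Index:
        return pd.MultiIndex.from_frame(self.sites[SITE_COLS])

    def take_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypeMatrix(self.dosages[:, idx], list(self.samples),
                              self.sites.iloc[idx])

    def take_samples(self, names: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in names]
        return GenotypeMatrix(self.dosages[idx, :], list(names), self.sites)

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing genotypes."""
        return (self.dosages == MISSING).mean(axis=0)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, total non-missing allele count)."""
        valid = self.dosages != MISSING
        alt = np.where(valid, self.dosages, 0).sum(axis=0)
        return alt, 2 * valid.sum(axis=0)

    def alt_freq(self) -> np.ndarray:
        alt, tot = self.allele_counts()
        return alt / np.maximum(tot, 1)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency among non-missing genotypes."""
        f = self.alt_freq()
        return np.minimum(f, 1 - f)


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a GenotypeMatrix.

    Indels and multiallelic records are skipped (count logged); half-calls
    and ``./.`` become the missing sentinel.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, sites, skipped = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        dos = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            dos[i] = MISSING if (a < 0 or b < 0) else a + b
        rows.append(dos)
        sites.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    vcf.close()
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    dosages = (np.vstack(rows).T if rows
               else np.empty((len(samples), 0), dtype=np.int8))
    frame = pd.DataFrame(sites, columns=SITE_COLS)
    return GenotypeMatrix(dosages, samples, frame)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as minimal uncompressed VCF 4.2."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        chroms = g.sites["chrom"].to_numpy()
        poss = g.sites["pos"].to_numpy()
        refs = g.sites["ref"].to_numpy()
        alts = g.sites["alt"].to_numpy()
        for j in range(g.n_sites):
            gts = "\t".join(gt_str[int(d)] for d in g.dosages[:, j])
            fh.write(f"{chroms[j]}\t{poss[j]}\t.\t{refs[j]}\t{alts[j]}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV and validate its closed vocabularies."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing_cols = set(META_COLS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("metadata sample IDs must be unique")
    known = meta["tissue"].dropna()
    bad = set(known) - set(TISSUE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown tissue categories: {sorted(bad)}")
    return meta


def filter_missingness(g: GenotypeMatrix, max_missing: float) -> GenotypeMatrix:
    """Keep sites whose missing-genotype fraction is <= ``max_missing``.

    The boundary is an inclusive keep (a site at exactly the threshold
    survives); the complementary exclusive-drop reading is obtained by
    nudging the threshold.
    """
    if not (0 <= max_missing < 1):
        raise ValueError("max_missing must be in [0, 1)")
    keep = g.missing_fraction() <= max_missing
    out = g.take_sites(keep)
    logger.info("filter_missingness(%.3g): %d -> %d sites",
                max_missing, g.n_sites, out.n_sites)
    if out.n_sites == 0:
        logger.warning("filter_missingness removed every site")
    return out


def drop_singletons(g: GenotypeMatrix) -> GenotypeMatrix:
    """Remove sites whose minor allele is observed exactly once.

    Counts are over non-missing genotypes; monomorphic sites (count 0) are
    untouched by this filter.
    """
    alt, tot = g.allele_counts()
    minor = np.minimum(alt, tot - alt)
    out = g.take_sites(minor != 1)
    logger.info("drop_singletons: %d -> %d sites", g.n_sites, out.n_sites)
    return out


def filter_maf(g: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Keep sites with minor-allele frequency >= ``min_maf`` (inclusive)."""
    if not (0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    out = g.take_sites(g.maf() >= min_maf)
    logger.info("filter_maf(%.3g): %d -> %d sites", min_maf, g.n_sites, out.n_sites)
    return out


def merge(a: GenotypeMatrix, b: GenotypeMatrix, mode: str = "intersect",
          ) -> GenotypeMatrix:
    """Merge two cohorts on shared site keys.

    Samples are stacked (duplicate IDs are an error).  ``mode='intersect'``
    keeps sites present in both inputs; ``mode='union'`` keeps all sites,
    with absent sites becoming missing for the other cohort.  A site present
    at the same (chrom, pos) with swapped ref/alt is reconciled by flipping
    dosages 0<->2 in ``b``; any other allele mismatch at a shared position is
    dropped with a logged count.
    """
    if mode not in ("intersect", "union"):
        raise ValueError("mode must be 'intersect' or 'union'")
    clash = set(a.samples) & set(b.samples)
    if clash:
        raise ValueError(f"duplicate sample IDs across inputs: {sorted(clash)}")

    a_keys = a.site_keys()
    b_sites = b.sites.copy()
    b_dos = b.dosages.copy()
    # reconcile swapped ref/alt in b against a's orientation
    a_by_pos = {(c, p): (r, t) for c, p, r, t in a.sites[SITE_COLS].itertuples(index=False)}
    flipped = dropped = 0
    keep_b = np.ones(len(b_sites), dtype=bool)
    for j, (c, p, r, t) in enumerate(b_sites[SITE_COLS].itertuples(index=False)):
        ra = a_by_pos.get((c, p))
        if ra is None or ra == (r, t):
            continue
        if ra == (t, r):
            valid = b_dos[:, j] != MISSING
            b_dos[valid, j] = 2 - b_dos[valid, j]
            b_sites.iloc[j, b_sites.columns.get_loc("ref")] = ra[0]
            b_sites.iloc[j, b_sites.columns.get_loc("alt")] = ra[1]
            flipped += 1
        else:
            keep_b[j] = False
            dropped += 1
    if flipped or dropped:
        logger.info("merge: flipped %d swapped-allele sites, dropped %d mismatches",
                    flipped, dropped)
    b_sites = b_sites.loc[keep_b].reset_index(drop=True)
    b_dos = b_dos[:, keep_b]
    b_keys = pd.MultiIndex.from_frame(b_sites[SITE_COLS])

    if mode == "intersect":
        keys = a_keys.intersection(b_keys, sort=False)
        sites = keys.to_frame(index=False)
        sites.columns = SITE_COLS
    else:
        keys = a_keys.union(b_keys, sort=False)
        sites = keys.to_frame(index=False)
        sites.columns = SITE_COLS
    # stable deterministic order
    sites = sites.sort_values(["chrom", "pos"]).reset_index(drop=True)
    keys = pd.MultiIndex.from_frame(sites[SITE_COLS])

    def align(dos: np.ndarray, src_keys: pd.Index) -> np.ndarray:
        idx = src_keys.get_indexer(keys)
        out = np.full((dos.shape[0], len(keys)), MISSING, dtype=np.int8)
        present = idx >= 0
        out[:, present] = dos[:, idx[present]]
        return out

    merged = np.vstack([align(a.dosages, a_keys), align(b_dos, b_keys)])
    return GenotypeMatrix(merged, list(a.samples) + list(b.samples), sites)


def matrix_from_arrays(vectors: dict[str, np.ndarray],
                       chrom: str = "chr1") -> GenotypeMatrix:
    """Build a GenotypeMatrix from named dosage vectors (test/sim helper)."""
    samples = list(vectors)
    dosages = np.vstack([vectors[s] for s in samples]).astype(np.int8)
    n = dosages.shape[1]
    sites = pd.DataFrame({"chrom": chrom, "pos": np.arange(1, n + 1),
                          "ref": "A", "alt": "G"})
    return GenotypeMatrix(dosages, samples, sites)
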