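"""Synthetic structured populations with known truth.

Generates chimpanzee-like cohorts under the Balding–Nichols model: per-site
ancestral allele frequencies are drawn once, and each subspecies drifts away
from them with a Beta-distributed deviation parameterized by ``F``, which
equals the expected pairwise Hudson F_ST between a drifted population and the
ancestor (and ``(F_A + F_B)/2`` between two drifted populations).  On top of
the structured populations the module plants admixed individuals, Mendelian
pedigrees (parent/offspring, full siblings, grandparent–grandchild),
replicate samples of one donor with RNA-seq-style missingness and genotype
error, and contaminant samples drawn from an alien frequency spectrum.

All randomness flows through a single integer seed; identical configuration
and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

RELATIONSHIPS = ("identical", "parent_offspring", "full_sibling",
                 "second_degree", "unrelated")

#: Drift parameters reproducing the published pairwise F_ST between
#: subspecies pairs (Western–Central 0.29, Western–Eastern 0.32,
#: Central–Eastern 0.09) via F_ST(A, B) ~= (F_A + F_B) / 2.  The
#: Nigeria–Cameroon value is not published; 0.10 is a conventional
#: same-clade choice.
DEFAULT_DRIFT = {
    "western": 0.52,
    "central": 0.06,
    "eastern": 0.12,
    "nigeria_cameroon": 0.10,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is out of range."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the cohort simulator.

    Parameters
    ----------
    n_sites
        Number of unlinked biallelic SNPs.
    ancestral_maf_range
        Interval on (0, 0.5] from which ancestral alternate-allele
        frequencies are drawn uniformly.
    drift
        Mapping subspecies name -> Balding–Nichols ``F`` in (0, 1).
    seed
        Integer RNG seed; the whole simulation is a pure function of
        (config, seed).
    missing_rate
        Per-genotype missingness probability applied to replicate samples.
    genotype_error_rate
        Per-genotype probability of resampling a uniform random dosage.
    contaminant_divergence
        ``F`` of the outgroup population used for contaminant genotypes.
    """

    n_sites: int = 20_000
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    drift: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRIFT))
    seed: int = 0
    missing_rate: float = 0.05
    genotype_error_rate: float = 0.01
    contaminant_divergence: float = 0.9

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("ancestral_maf_range must lie in (0, 0.5]")
        for name, f in self.drift.items():
            if not (0 < f < 1):
                raise ConfigurationError(
                    f"drift F for {name!r} must be in (0, 1), got {f}")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not (0 <= self.genotype_error_rate < 1):
            raise ConfigurationError("genotype_error_rate must be in [0, 1)")
        if not (0 < self.contaminant_divergence < 1):
            raise ConfigurationError("contaminant_divergence must be in (0, 1)")


@dataclass
class ReferencePanel:
    """Per-subspecies allele frequencies plus labeled panel genotypes.

    ``pop_freqs`` maps subspecies name to a length-``n_sites`` vector of
    alternate-allele frequencies; ``genotypes`` is a samples x sites dosage
    array aligned with ``samples`` and ``labels``.
    """

    pop_freqs: dict[str, np.ndarray]
    ancestral_freqs: np.ndarray
    genotypes: np.ndarray            # (n_panel, n_sites), dosages 0/1/2
    samples: list[str]
    labels: dict[str, str]           # sample -> subspecies

    @property
    def populations(self) -> list[str]:
        return list(self.pop_freqs)

    @property
    def n_sites(self) -> int:
        return self.ancestral_freqs.shape[0]

    def __post_init__(self) -> None:
        n = {len(v) for v in self.pop_freqs.values()}
        if n != {self.n_sites}:
            raise ValueError("frequency vectors must share one site registry")
        for s in self.samples:
            if s not in self.labels:
                raise ValueError(f"panel sample {s!r} has no subspecies label")


@dataclass
class PedigreeTruth:
    """Ground-truth tables for a simulated cohort.

    ``individuals`` has one row per individual (id, admixture proportions,
    contaminant flag); ``pairs`` lists known relationships symmetrically
    stored once per unordered pair; ``replicate_map`` maps every emitted
    sample ID to its donor individual.
    """

    individuals: pd.DataFrame        # columns: individual_id, q_<pop>..., is_contaminant
    pairs: pd.DataFrame              # columns: id_a, id_b, relationship
    replicate_map: pd.DataFrame      # columns: sample_id, individual_id

    def __post_init__(self) -> None:
        bad = set(self.pairs["relationship"]) - set(RELATIONSHIPS)
        if bad:
            raise ValueError(f"unknown relationship labels: {sorted(bad)}")
        if self.replicate_map["sample_id"].duplicated().any():
            raise ValueError("every sample must map to exactly one individual")


def _balding_nichols(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return rng.beta(a, b)


def draw_reference_freqs(cfg: SimConfig, panel_sizes: dict[str, int] | None = None,
                         ) -> ReferencePanel:
    """Draw ancestral and per-subspecies frequencies, then panel genotypes.

    Ancestral frequencies are uniform on ``cfg.ancestral_maf_range``; each
    subspecies frequency vector is Beta(p(1-F)/F, (1-p)(1-F)/F); panel
    genotypes are Binomial(2, freq).  ``panel_sizes`` defaults to 15 per
    subspecies.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_maf_range
    p = rng.uniform(lo, hi, cfg.n_sites)
    pop_freqs = {name: _balding_nichols(p, f, rng)
                 for name, f in cfg.drift.items()}
    if panel_sizes is None:
        panel_sizes = {name: 15 for name in cfg.drift}
    samples, labels, blocks = [], {}, []
    for name in cfg.drift:
        n = panel_sizes.get(name, 0)
        if n == 0:
            continue
        blocks.append(rng.binomial(2, pop_freqs[name][None, :].repeat(n, 0)))
        for i in range(n):
            sid = f"{name}_{i + 1:02d}"
            samples.append(sid)
            labels[sid] = name
    genotypes = (np.vstack(blocks) if blocks
                 else np.empty((0, cfg.n_sites), dtype=np.int64))
    return ReferencePanel(pop_freqs=pop_freqs, ancestral_freqs=p,
                          genotypes=genotypes.astype(np.int8),
                          samples=samples, labels=labels)


def simulate_individual(panel: ReferencePanel, q: dict[str, float],
                        seed: int) -> np.ndarray:
    """Draw one admixed diploid: genotype ~ Binomial(2, sum_k q_k p_k)."""
    qv = np.array([q.get(k, 0.0) for k in panel.populations], dtype=float)
    if (qv < 0).any() or abs(qv.sum() - 1.0) > 1e-9:
        raise ValueError("admixture proportions must be nonnegative and sum to 1")
    unknown = set(q) - set(panel.populations)
    if unknown:
        raise ValueError(f"q keyed by unknown subspecies: {sorted(unknown)}")
    freqs = np.vstack([panel.pop_freqs[k] for k in panel.populations])
    eff = qv @ freqs
    rng = np.random.default_rng(seed)
    return rng.binomial(2, eff).astype(np.int8)


def drop_offspring(parent_a: np.ndarray, parent_b: np.ndarray,
                   seed: int) -> np.ndarray:
    """Mendelian gamete dropping: one uniformly chosen allele per parent.

    Chaining produces grandparent/half-sib (second-degree) pairs.
    """
    if parent_a.shape != parent_b.shape:
        raise ValueError("parent genotype vectors must have equal length")
    if (parent_a == MISSING).any() or (parent_b == MISSING).any():
        raise ValueError("parents must have no missing genotypes")
    rng = np.random.default_rng(seed)

    def gamete(g: np.ndarray) -> np.ndarray:
        # hom contributes its allele; het contributes 0 or 1 with prob 1/2
        return np.where(g == 1, rng.integers(0, 2, g.shape), g // 2)

    return (gamete(parent_a) + gamete(parent_b)).astype(np.int8)


def make_replicates(individual: np.ndarray, n: int, cfg: SimConfig,
                    seed: int) -> list[np.ndarray]:
    """Derive ``n`` replicate samples with independent missingness and error.

    Each replicate resamples a uniform random dosage at
    ``cfg.genotype_error_rate`` of sites and masks ``cfg.missing_rate`` of
    genotypes to the missing sentinel.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        rep = individual.astype(np.int8).copy()
        if cfg.genotype_error_rate > 0:
            err = rng.random(rep.shape) < cfg.genotype_error_rate
            rep[err] = rng.integers(0, 3, int(err.sum()), dtype=np.int8)
        if cfg.missing_rate > 0:
            rep[rng.random(rep.shape) < cfg.missing_rate] = MISSING
        out.append(rep)
    return out


def make_contaminant(cfg: SimConfig, n_sites: int, seed: int) -> np.ndarray:
    """Draw a contaminant genotype vector from an alien frequency spectrum.

    Contamination in the emulated setting comes from another species, so the
    contaminant population has its own ancestral frequencies (uniform on
    0.05–0.95, i.e. random allele orientation) drifted by
    ``cfg.contaminant_divergence``.  Its IBS distance to any in-group sample
    concentrates near 0.5, well past the flagging threshold, whereas a
    population drifted from the *shared* ancestor can never exceed the
    in-group's own cross-subspecies distances once one subspecies is as
    drifted as Western chimpanzees.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, n_sites)
    freq = _balding_nichols(p, cfg.contaminant_divergence, rng)
    return rng.binomial(2, freq).astype(np.int8)


def hudson_fst(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Hudson's F_ST estimator (ratio of sums) from two dosage matrices.

    Per site: numerator (p_a - p_b)^2 - p_a(1-p_a)/(n_a-1) - p_b(1-p_b)/(n_b-1),
    denominator p_a(1-p_b) + p_b(1-p_a); the estimate is the ratio of the
    site sums.  Missing genotypes (sentinel) are excluded per site.
    """
    def freqs(g):
        valid = g != MISSING
        alt = np.where(valid, g, 0).sum(0)
        n = 2 * valid.sum(0)
        return alt / np.maximum(n, 1), n

    pa, na = freqs(np.asarray(geno_a))
    pb, nb = freqs(np.asarray(geno_b))
    ok = (na > 2) & (nb > 2)
    pa, pb, na, nb = pa[ok], pb[ok], na[ok], nb[ok]
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    return float(num.sum() / den.sum())


def write_truth_tables(truth: PedigreeTruth, prefix) -> dict[str, str]:
    """Write the three truth tables as TSV; returns the paths written."""
    import os

    paths = {}
    for name, frame in (("individuals", truth.individuals),
                        ("pairs", truth.pairs),
                        ("replicates", truth.replicate_map)):
        path = os.fspath(prefix) + f".{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths


def read_truth_tables(prefix) -> PedigreeTruth:
    import os

    def rd(name):
        return pd.read_csv(os.fspath(prefix) + f".{name}.tsv", sep="\t")

    return PedigreeTruth(individuals=rd("individuals"), pairs=rd("pairs"),
                         replicate_map=rd("replicates"))


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Return a copy of ``cfg`` with a different seed."""
    return replace(cfg, seed=seed)
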