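"""Simulation-based calibration experiments.

Self-contained routines that measure, under the simulator's study
conditions, the quantities the analysis thresholds rest on: F_ST recovery
of the Balding–Nichols drift parameter, the IBD Z1 signature of
parent/offspring and second-degree pairs, replicate-sample relatedness
against the identity threshold, and supervised-admixture recovery error.
Every routine is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

from . import ancestry as anc
from . import pairwise, popsim
from .popsim import SimConfig


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


def fst_between_simulated_pair(target_fst: float, n_sites: int = 50_000,
                               n_per_pop: int = 20, seed: int = 0) -> float:
    """Hudson F_ST between two populations drifted by F = ``target_fst``.

    Under Balding–Nichols from a shared ancestor, pairwise F_ST between two
    populations with drift F_A and F_B is (F_A+F_B)/2, so equal drift at the
    target reproduces it directly.
    """
    cfg = SimConfig(n_sites=n_sites, seed=seed,
                    drift={"pop_a": target_fst, "pop_b": target_fst})
    panel = popsim.draw_reference_freqs(cfg, {"pop_a": n_per_pop,
                                              "pop_b": n_per_pop})
    labels = np.array([panel.labels[s] for s in panel.samples])
    ga = panel.genotypes[labels == "pop_a"]
    gb = panel.genotypes[labels == "pop_b"]
    return popsim.hudson_fst(ga, gb)


def _founder_population(n: int, n_sites: int, seed: int) -> np.ndarray:
    """Diploid founders from one population (modest drift off the ancestor)."""
    cfg = SimConfig(n_sites=n_sites, seed=seed, drift={"pop": 0.1})
    panel = popsim.draw_reference_freqs(cfg, {"pop": n})
    return panel.genotypes


def mean_z1(relationship: str, n_pairs: int = 50, n_sites: int = 20_000,
            seed: int = 0) -> float:
    """Mean method-of-moments Z1 over simulated pairs of one class.

    ``parent_offspring`` pairs come from one round of gamete dropping,
    ``second_degree`` pairs are grandparent–grandchild via two rounds.
    Allele frequencies for the inversion come from the whole simulated
    cohort (founders plus descendants), as in a real analysis.
    """
    seeds = iter(_spawn_seeds(seed, 4 * n_pairs + 1))
    founders = _founder_population(3 * n_pairs, n_sites, next(seeds))
    members_a, members_b, extra = [], [], []
    for i in range(n_pairs):
        f1, f2, f3 = founders[3 * i], founders[3 * i + 1], founders[3 * i + 2]
        if relationship == "parent_offspring":
            child = popsim.drop_offspring(f1, f2, next(seeds))
            members_a.append(f1)
            members_b.append(child)
            extra.append(child)
        elif relationship == "second_degree":
            parent = popsim.drop_offspring(f1, f2, next(seeds))
            grandchild = popsim.drop_offspring(parent, f3, next(seeds))
            members_a.append(f1)
            members_b.append(grandchild)
            extra.append(grandchild)
        else:
            raise ValueError(f"unknown relationship {relationship!r}")
    cohort = np.vstack([founders] + [np.vstack(extra)])
    valid = cohort != popsim.MISSING
    freq = np.where(valid, cohort, 0).sum(0) / (2 * valid.sum(0))
    allele_n = 2 * valid.sum(0)
    z1s = [pairwise.estimate_ibd(a, b, freq, allele_n).z1
           for a, b in zip(members_a, members_b)]
    return float(np.mean(z1s))


def replicate_relatedness_trials(n_trials: int = 100, n_sites: int = 20_000,
                                 cohort_n: int = 30, seed: int = 0,
                                 missing_rate: float = 0.05,
                                 genotype_error_rate: float = 0.01,
                                 maf_min: float = 0.25) -> np.ndarray:
    """Relatedness between two replicates of one donor, per trial.

    Each trial simulates a cohort, derives two replicate samples of one
    donor with independent missingness and genotype error, restricts to
    sites at cohort MAF >= ``maf_min``, and computes the relatedness
    coefficient.  Returns the per-trial values.
    """
    seeds = _spawn_seeds(seed, 2 * n_trials)
    vals = np.empty(n_trials)
    for t in range(n_trials):
        cfg = SimConfig(n_sites=n_sites, seed=seeds[2 * t], drift={"pop": 0.1},
                        missing_rate=missing_rate,
                        genotype_error_rate=genotype_error_rate)
        panel = popsim.draw_reference_freqs(cfg, {"pop": cohort_n})
        cohort = panel.genotypes
        freq = cohort.mean(0) / 2
        maf = np.minimum(freq, 1 - freq)
        donor = cohort[0]
        r1, r2 = popsim.make_replicates(donor, 2, cfg, seeds[2 * t + 1])
        sel = maf >= maf_min
        vals[t] = pairwise.relatedness(r1[sel], r2[sel])
    return vals


def admixture_recovery_mae(n_samples: int = 100, n_sites: int = 10_000,
                           seed: int = 0) -> tuple[float, np.ndarray]:
    """Supervised-admixture recovery error under Dirichlet-random ancestry.

    Simulates individuals with Dirichlet(1,1,1,1) ancestry over the four
    subspecies at published-level F_ST, estimates q against the panel's
    frequency vectors, and returns (overall MAE, per-component MAE).
    """
    s1, s2, s3 = _spawn_seeds(seed, 3)
    cfg = SimConfig(n_sites=n_sites, seed=s1)
    panel = popsim.draw_reference_freqs(cfg)
    pops = panel.populations
    rng = np.random.default_rng(s2)
    q_true = rng.dirichlet(np.ones(len(pops)), n_samples)
    geno_seeds = _spawn_seeds(s3, n_samples)
    X = np.vstack([
        popsim.simulate_individual(panel, dict(zip(pops, q)), gs)
        for q, gs in zip(q_true, geno_seeds)
    ]).astype(float)
    Q, est_pops, _ = anc.supervised_admixture(panel, X)
    order = [est_pops.index(p) for p in pops]
    err = np.abs(Q[:, order] - q_true)
    return float(err.mean()), err.mean(axis=0)
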