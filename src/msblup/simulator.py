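"""Desk-scale gene-drop simulator for linked QTL and SNP panels.

The simulator emulates a standard forward-in-time quantitative-trait design:

1. a *historical* random-mating population of effective size N_e evolves for
   a number of discrete generations so that linkage disequilibrium builds up
   between SNP and QTL on a genetic map;
2. a small *study pedigree* (base cohort plus discrete offspring cohorts) is
   drawn from the final historical generation and genotypes are gene-dropped
   through it with recombination;
3. biallelic QTL receive additive effects rescaled so the realized QTL
   variance in the base cohort hits its target; an infinitesimal polygenic
   value is simulated down the pedigree; phenotypes add normal residuals.

Recombination uses the Haldane (no-interference) map function.  Transmission
is simulated per inter-locus interval: an odd number of crossovers between
adjacent loci at map distance d occurs with probability (1 - exp(-2d))/2,
and loci on different chromosomes segregate independently (switch
probability 1/2), which is distributionally identical to dropping
Poisson-distributed crossover positions and reading off the loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .marker_data import MarkerMatrix
from .pedigree_algebra import Pedigree, inbreeding_coefficients, parse_pedigree

__all__ = [
    "SimScenario",
    "TruthSet",
    "GenomeMap",
    "make_genome_map",
    "simulate_gametes",
    "simulate_historical",
    "simulate_pedigree",
    "gene_drop",
    "assign_qtl_effects",
    "simulate_polygenic",
    "simulate_phenotypes",
    "run_scenario",
]


@dataclass(frozen=True)
class SimScenario:
    """Configuration of one simulation scenario.

    Defaults correspond to the replicated comparison design: 2 chromosomes of
    1 Morgan, 10 QTL per chromosome, a 25-individual base cohort followed by
    three 40-individual training cohorts and a 40-individual target cohort,
    random mating with family size 1, phenotypic variance 1 and overall
    heritability 0.4.  ``qtl_variance_fraction`` sets the share of genetic
    variance carried by the QTL (the rest is infinitesimal).
    """

    qtl_variance_fraction: float = 0.5
    n_snp_per_chrom: int = 2000
    n_chrom: int = 2
    chrom_length_morgan: float = 1.0
    n_qtl_per_chrom: int = 10
    h2: float = 0.4
    pheno_var: float = 1.0
    cohorts: tuple = (25, 40, 40, 40, 40)
    family_size: int = 1
    historical_ne: int = 100
    historical_generations: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.qtl_variance_fraction <= 1.0:
            raise ValueError("qtl_variance_fraction must be in [0, 1]")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must be in (0, 1]")
        if any(c <= 0 for c in self.cohorts) or len(self.cohorts) < 2:
            raise ValueError("need at least two positive cohort sizes")

    @property
    def sigma_qtl2(self) -> float:
        return self.qtl_variance_fraction * self.h2 * self.pheno_var

    @property
    def sigma_poly2(self) -> float:
        return (1.0 - self.qtl_variance_fraction) * self.h2 * self.pheno_var

    @property
    def sigma_e2(self) -> float:
        return (1.0 - self.h2) * self.pheno_var


@dataclass(frozen=True)
class GenomeMap:
    """Loci on a multi-chromosome genetic map (positions in Morgans).

    ``recomb[j]`` is the probability that gamete phase switches between locus
    j and locus j+1 (Haldane within a chromosome, 1/2 across chromosomes).
    ``is_qtl`` flags causal loci; the SNP panel is its complement.
    """

    chrom: np.ndarray
    pos: np.ndarray
    recomb: np.ndarray
    is_qtl: np.ndarray

    @property
    def n_loci(self) -> int:
        return self.pos.size


@dataclass
class TruthSet:
    """One simulated replicate with full truth for scoring."""

    scenario: SimScenario
    ped: Pedigree
    markers: MarkerMatrix            # SNP panel only (QTL excluded)
    qtl_dosages: np.ndarray          # N_i x N_qtl
    qtl_effects: np.ndarray
    genome: GenomeMap
    u_qtl: np.ndarray
    u_poly: np.ndarray
    y: np.ndarray
    cohort: np.ndarray               # cohort index per individual (0 = base)
    use_in_training: np.ndarray      # phenotype enters model fitting

    @property
    def u_total(self) -> np.ndarray:
        return self.u_qtl + self.u_poly

    @property
    def is_target(self) -> np.ndarray:
        return self.cohort == self.cohort.max()

    @property
    def training_ids(self):
        return tuple(np.array(self.ped.ids)[self.use_in_training])

    @property
    def target_ids(self):
        return tuple(np.array(self.ped.ids)[self.is_target])


def make_genome_map(n_chrom, chrom_length, n_qtl_per_chrom, n_snp_per_chrom,
                    rng) -> GenomeMap:
    """Place QTL and SNP uniformly at random on each chromosome."""
    chroms, positions, qtl_flags = [], [], []
    per_chrom = n_qtl_per_chrom + n_snp_per_chrom
    for c in range(n_chrom):
        pos = np.sort(rng.uniform(0.0, chrom_length, size=per_chrom))
        qtl_idx = rng.choice(per_chrom, size=n_qtl_per_chrom, replace=False)
        flag = np.zeros(per_chrom, dtype=bool)
        flag[qtl_idx] = True
        chroms.append(np.full(per_chrom, c))
        positions.append(pos)
        qtl_flags.append(flag)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    is_qtl = np.concatenate(qtl_flags)
    d = np.diff(pos)
    same_chrom = np.diff(chrom) == 0
    recomb = np.where(same_chrom, 0.5 * (1.0 - np.exp(-2.0 * np.maximum(d, 0.0))), 0.5)
    return GenomeMap(chrom=chrom, pos=pos, recomb=recomb, is_qtl=is_qtl)


def simulate_gametes(hap_a: np.ndarray, hap_b: np.ndarray, recomb: np.ndarray,
                     rng) -> np.ndarray:
    """Recombinant gametes from paired parental haplotypes.

    ``hap_a``/``hap_b`` have shape (n_meioses, n_loci); ``recomb`` gives the
    per-interval phase-switch probabilities.  Returns (n_meioses, n_loci).
    """
    n, L = hap_a.shape
    phase = np.empty((n, L), dtype=np.int64)
    phase[:, 0] = rng.integers(0, 2, size=n)
    if L > 1:
        switches = rng.random((n, L - 1)) < recomb
        phase[:, 1:] = switches
        np.cumsum(phase, axis=1, out=phase)
        phase &= 1
    return np.where(phase == 0, hap_a, hap_b)


def simulate_historical(n_e: int, n_gen: int, recomb: np.ndarray, n_loci: int,
                        rng) -> np.ndarray:
    """Random-mating historical population; returns 2*n_e founder haplotypes.

    Initial allele frequencies are Uniform(0.1, 0.9) with haplotypes in
    linkage equilibrium; each generation draws two distinct parents per
    offspring and one recombinant gamete per parent, so LD accumulates by
    drift and linkage over ``n_gen`` generations.  Loci that drift to
    fixation stay in the panel (they are monomorphic markers downstream).
    """
    if n_e < 4:
        raise ValueError("historical effective size must be at least 4")
    p0 = rng.uniform(0.1, 0.9, size=n_loci)
    pool = (rng.random((2 * n_e, n_loci)) < p0).astype(np.int8)
    for _ in range(n_gen):
        sires = rng.integers(0, n_e, size=n_e)
        offset = 1 + rng.integers(0, n_e - 1, size=n_e)
        dams = (sires + offset) % n_e  # distinct from sires
        new_pool = np.empty_like(pool)
        new_pool[0::2] = simulate_gametes(pool[2 * sires], pool[2 * sires + 1],
                                          recomb, rng)
        new_pool[1::2] = simulate_gametes(pool[2 * dams], pool[2 * dams + 1],
                                          recomb, rng)
        pool = new_pool
    return pool


def simulate_pedigree(cohorts, family_size: int, rng) -> Pedigree:
    """Discrete-cohort pedigree with random mating.

    Each post-base cohort is produced by distinct (sire, dam) pairs drawn
    without replacement from the previous cohort (sexes assigned at random
    in equal ratio), each pair contributing ``family_size`` offspring, so
    with family size 1 there are no full sibs.
    """
    records = []
    prev = [f"G0_{i + 1:03d}" for i in range(cohorts[0])]
    records += [(i, None, None) for i in prev]
    for g, size in enumerate(cohorts[1:], start=1):
        if len(prev) < 2:
            raise ValueError(f"cohort {g - 1} too small to supply two parents")
        perm = rng.permutation(len(prev))
        half = len(prev) // 2
        males = [prev[i] for i in perm[:half]]
        females = [prev[i] for i in perm[half:]]
        n_matings = -(-size // family_size)  # ceil
        if n_matings > len(males) * len(females):
            raise ValueError(
                f"cohort {g - 1} cannot supply {n_matings} distinct mating pairs"
            )
        pair_idx = rng.choice(len(males) * len(females), size=n_matings,
                              replace=False)
        ids = [f"G{g}_{i + 1:03d}" for i in range(size)]
        for k, iid in enumerate(ids):
            pair = pair_idx[k // family_size]
            records.append((iid, males[pair // len(females)],
                            females[pair % len(females)]))
        prev = ids
    return parse_pedigree(records)


def gene_drop(founder_haplotypes: np.ndarray, ped: Pedigree, recomb: np.ndarray,
              rng) -> np.ndarray:
    """Drop haplotypes through a pedigree; returns (N_i, 2, n_loci) int8.

    Base individuals take consecutive haplotype pairs from
    ``founder_haplotypes`` (which must supply at least 2*N_b rows); each
    descendant receives one recombinant gamete from each parent.
    """
    n_loci = founder_haplotypes.shape[1]
    if founder_haplotypes.shape[0] < 2 * ped.n_base:
        raise ValueError("founder haplotype pool exhausted")
    haplo = np.empty((ped.n, 2, n_loci), dtype=np.int8)
    nb = ped.n_base
    haplo[:nb, 0] = founder_haplotypes[0:2 * nb:2]
    haplo[:nb, 1] = founder_haplotypes[1:2 * nb:2]
    for i in range(nb, ped.n):
        s, d = ped.sire[i], ped.dam[i]
        gam = simulate_gametes(
            np.vstack([haplo[s, 0], haplo[d, 0]]),
            np.vstack([haplo[s, 1], haplo[d, 1]]),
            recomb, rng,
        )
        haplo[i] = gam
    return haplo


def assign_qtl_effects(qtl_dosages_base: np.ndarray, target_variance: float,
                       rng) -> np.ndarray:
    """Additive QTL effects rescaled to a realized base-cohort variance.

    Effects are drawn standard normal and multiplied by one common factor so
    that the sample variance (ddof=1) of the base cohort's summed QTL values
    equals ``target_variance`` exactly.
    """
    n_qtl = qtl_dosages_base.shape[1]
    if target_variance == 0.0:
        return np.zeros(n_qtl)
    if not (qtl_dosages_base.std(axis=0) > 0).any():
        raise ValueError("all QTL monomorphic in the base cohort")
    effects = rng.standard_normal(n_qtl)
    g = qtl_dosages_base @ effects
    realized = g.var(ddof=1)
    return effects * np.sqrt(target_variance / realized)


def simulate_polygenic(ped: Pedigree, sigma_poly2: float, rng) -> np.ndarray:
    """Infinitesimal genetic values down the pedigree.

    Base values are N(0, sigma2); each descendant adds a Mendelian-sampling
    deviation N(0, sigma2 * (1/2 - (F_sire + F_dam)/4)) to its parental mean.
    """
    if sigma_poly2 == 0.0:
        return np.zeros(ped.n)
    F = inbreeding_coefficients(ped)
    u = np.empty(ped.n)
    nb = ped.n_base
    u[:nb] = rng.normal(0.0, np.sqrt(sigma_poly2), size=nb)
    for i in range(nb, ped.n):
        s, d = ped.sire[i], ped.dam[i]
        var_phi = sigma_poly2 * (0.5 - 0.25 * (F[s] + F[d]))
        u[i] = 0.5 * (u[s] + u[d]) + rng.normal(0.0, np.sqrt(max(var_phi, 0.0)))
    return u


def simulate_phenotypes(u_total: np.ndarray, h2: float, pheno_var: float,
                        rng) -> np.ndarray:
    """y = u + e with Var(e) = (1 - h2) * pheno_var (mean zero)."""
    sigma_e2 = (1.0 - h2) * pheno_var
    if sigma_e2 == 0.0:
        return u_total.copy()
    return u_total + rng.normal(0.0, np.sqrt(sigma_e2), size=u_total.shape)


def run_scenario(scenario: SimScenario) -> TruthSet:
    """Simulate one full replicate of a scenario (deterministic per seed)."""
    rng = np.random.default_rng(scenario.seed)
    genome = make_genome_map(scenario.n_chrom, scenario.chrom_length_morgan,
                             scenario.n_qtl_per_chrom, scenario.n_snp_per_chrom,
                             rng)
    pool = simulate_historical(scenario.historical_ne,
                               scenario.historical_generations,
                               genome.recomb, genome.n_loci, rng)
    ped = simulate_pedigree(scenario.cohorts, scenario.family_size, rng)
    founder_rows = rng.choice(pool.shape[0], size=2 * ped.n_base, replace=False)
    haplo = gene_drop(pool[founder_rows], ped, genome.recomb, rng)
    dosage = haplo.sum(axis=1)
    qtl_dosages = dosage[:, genome.is_qtl].astype(float)
    snp = dosage[:, ~genome.is_qtl].astype(float)
    snp_ids = tuple(
        f"snp_c{int(c) + 1}_{k + 1:04d}"
        for k, c in enumerate(genome.chrom[~genome.is_qtl])
    )
    markers = MarkerMatrix(W=snp, marker_ids=snp_ids, ped=ped)

    qtl_effects = assign_qtl_effects(qtl_dosages[:ped.n_base],
                                     scenario.sigma_qtl2, rng)
    u_qtl = qtl_dosages @ qtl_effects
    u_qtl -= u_qtl[:ped.n_base].mean()  # centre on the base cohort
    u_poly = simulate_polygenic(ped, scenario.sigma_poly2, rng)
    y = simulate_phenotypes(u_qtl + u_poly, scenario.h2, scenario.pheno_var, rng)

    cohort = np.empty(ped.n, dtype=np.int64)
    for i, iid in enumerate(ped.ids):
        cohort[i] = int(iid.split("_")[0][1:])
    last = cohort.max()
    use_in_training = (cohort > 0) & (cohort < last)
    return TruthSet(
        scenario=scenario, ped=ped, markers=markers, qtl_dosages=qtl_dosages,
        qtl_effects=qtl_effects, genome=genome, u_qtl=u_qtl, u_poly=u_poly,
        y=y, cohort=cohort, use_in_training=use_in_training,
    )


def scenario_with(scenario: SimScenario, **kwargs) -> SimScenario:
    """Functional update of a frozen scenario."""
    return replace(scenario, **kwargs)
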