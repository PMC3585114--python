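"""Forward-time stochastic simulation of diploid populations under selection.

Each individual carries two gametes (haplotypes over the two loci); its
genetic value is the G-P map cell for its two-locus genotype, and its
phenotype adds independent Gaussian noise with variance VE fixed at
generation 0 from the configured broad-sense heritability.  Selection is
phenotype-proportional: each generation 500 parent draws are made with
replacement with probability proportional to the (clamped non-negative)
phenotype, paired at random into 250 pairs, and each pair produces 4
offspring; every offspring receives one gamete from each parent, formed
with recombination fraction c.  Replicates run until an allele is lost or
fixed (exact count 0 or 2N) or the generation horizon is reached.

Sampling parent slots with replacement makes the expected gamete
contribution of a genotype exactly proportional to its expected selection
weight, so the infinite-population mean of the process is the two-locus
selection recursion run on the *effective* fitness map
E[max(g + e, 0)] (see :func:`effective_fitness_map`); at VE = 0 this is
the G-P map itself.  The test suite verifies this mean-field consistency.

Populations are stored columnarly as integer gamete indices (0 = AB,
1 = Ab, 2 = aB, 3 = ab), which keeps a 1000-individual generation to a few
vectorised numpy operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import _A_COUNT, _B_COUNT, HaplotypeState
from .gpmaps import GPMap
from .power import StudyDesign, TestSpec, detect, environmental_variance
from .varcomp import variance_components

__all__ = [
    "PopSimConfig",
    "Population",
    "effective_fitness_map",
    "init_population",
    "assign_phenotypes",
    "select_and_reproduce",
    "run_population",
    "stochastic_power",
]


@dataclass(frozen=True)
class PopSimConfig:
    """Configuration of the stochastic breeding design (500 -> 250 -> 1000)."""

    N: int = 1000
    n_parents: int = 500
    n_pairs: int = 250
    offspring_per_pair: int = 4
    max_gen: int = 200
    H2_0: float = 0.5
    init_freq: float = 0.5
    c: float = 0.5
    n_reps: int = 300

    def __post_init__(self) -> None:
        if self.n_parents > self.N:
            raise ValueError("cannot sample more parents than individuals")
        if 2 * self.n_pairs != self.n_parents:
            raise ValueError("pairs must use every sampled parent exactly once")
        if self.n_pairs * self.offspring_per_pair != self.N:
            raise ValueError("offspring must restore the population size")


@dataclass
class Population:
    """Gamete indices (N x 2) plus the map and fixed environmental variance."""

    gametes: np.ndarray  # shape (N, 2), values in {0, 1, 2, 3}
    m: GPMap
    VE: float
    phenotypes: np.ndarray | None = None

    @property
    def N(self) -> int:
        return self.gametes.shape[0]

    @property
    def genotype_rows(self) -> np.ndarray:
        return _A_COUNT[self.gametes].sum(axis=1)

    @property
    def genotype_cols(self) -> np.ndarray:
        return _B_COUNT[self.gametes].sum(axis=1)

    @property
    def genetic_values(self) -> np.ndarray:
        return self.m.values[self.genotype_rows, self.genotype_cols]

    def allele_freqs(self) -> tuple[float, float]:
        """Frequencies of the reference alleles A and B."""
        pA = 1.0 - _A_COUNT[self.gametes].mean()
        pB = 1.0 - _B_COUNT[self.gametes].mean()
        return float(pA), float(pB)

    def haplotype_freqs(self) -> np.ndarray:
        return np.bincount(self.gametes.flatten(), minlength=4) / (2 * self.N)

    def is_fixed(self) -> bool:
        pA, pB = self.allele_freqs()
        return pA in (0.0, 1.0) or pB in (0.0, 1.0)

    def realised_VG(self) -> float:
        return float(np.var(self.genetic_values))


def _deterministic_VG0(m: GPMap, init_freq: float, c: float) -> float:
    """Expected genetic variance at the initial frequencies (HWE, LE)."""
    state = HaplotypeState(
        np.array(
            [
                init_freq * init_freq,
                init_freq * (1 - init_freq),
                (1 - init_freq) * init_freq,
                (1 - init_freq) * (1 - init_freq),
            ]
        ),
        c=c,
    )
    return variance_components(m, state).VG


def init_population(m: GPMap, config: PopSimConfig, rng: np.random.Generator) -> Population:
    """Random HWE/LE population at the configured initial allele frequency.

    VE is derived once from the expected genetic variance at the initial
    frequencies (so every replicate shares the same VE) and held fixed.
    """
    p = config.init_freq
    a = rng.random((config.N, 2)) >= p  # True -> alternative allele a
    b = rng.random((config.N, 2)) >= p
    gametes = (2 * a + b).astype(np.int64)  # index = 2*a_count + b_count
    VG0 = _deterministic_VG0(m, p, config.c)
    VE = environmental_variance(VG0, config.H2_0)
    return Population(gametes=gametes, m=m, VE=VE)


def assign_phenotypes(pop: Population, rng: np.random.Generator) -> Population:
    """P_i = g_i + e_i with e_i ~ Normal(0, VE)."""
    e = rng.normal(0.0, np.sqrt(pop.VE), size=pop.N) if pop.VE > 0 else np.zeros(pop.N)
    pop.phenotypes = pop.genetic_values + e
    return pop


def _transmit(gametes: np.ndarray, c: float, rng: np.random.Generator) -> np.ndarray:
    """One transmitted gamete per parent row, with recombination fraction c."""
    n = gametes.shape[0]
    first = rng.integers(0, 2, size=n)  # gamete supplying the locus-A allele
    recomb = rng.random(n) < c
    second = np.where(recomb, 1 - first, first)
    gA = gametes[np.arange(n), first]
    gB = gametes[np.arange(n), second]
    return (2 * _A_COUNT[gA] + _B_COUNT[gB]).astype(np.int64)


def effective_fitness_map(m: GPMap, VE: float) -> GPMap:
    """Expected selection weight per genotype class under phenotype noise.

    With phenotype P = g + e, e ~ Normal(0, VE), and sampling weight
    max(P, 0), the expected weight of a genotype with value g is
    g Phi(g/s) + s phi(g/s) with s = sqrt(VE).  Running the deterministic
    recursion on this map gives the exact infinite-population mean of the
    stochastic engine.  Identity when VE = 0.
    """
    if VE < 0:
        raise ValueError("VE must be non-negative")
    if VE == 0:
        return m
    s = float(np.sqrt(VE))
    g = m.values
    vals = g * stats.norm.cdf(g / s) + s * stats.norm.pdf(g / s)
    return GPMap(vals, label=f"{m.label} (effective, VE={VE:g})", id=m.id)


def select_and_reproduce(pop: Population, config: PopSimConfig, rng: np.random.Generator) -> Population:
    """Phenotype-proportional parent sampling, pairing and reproduction."""
    if pop.phenotypes is None:
        raise ValueError("assign phenotypes before selection")
    w = np.clip(pop.phenotypes, 0.0, None)
    if w.sum() <= 0:
        raise ValueError("all selection weights are zero: degenerate population")
    parents = rng.choice(pop.N, size=config.n_parents, replace=True, p=w / w.sum())
    parents = rng.permutation(parents)
    mothers = parents[: config.n_pairs]
    fathers = parents[config.n_pairs :]
    k = config.offspring_per_pair
    mother_rows = np.repeat(mothers, k)
    father_rows = np.repeat(fathers, k)
    g1 = _transmit(pop.gametes[mother_rows], config.c, rng)
    g2 = _transmit(pop.gametes[father_rows], config.c, rng)
    return Population(
        gametes=np.column_stack([g1, g2]), m=pop.m, VE=pop.VE
    )


def run_population(
    m: GPMap,
    config: PopSimConfig,
    seed: int | np.random.Generator = 0,
    record_populations: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[list[Population]]]:
    """Run replicate populations; long-format per-generation records.

    Columns: rep, gen, pA, pB, VG, fixed.  A replicate stops at the first
    generation in which an allele is lost or fixed, or at max_gen.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    kept: list[list[Population]] = []
    for rep in range(config.n_reps):
        pop = init_population(m, config, rng)
        snapshots = []
        for gen in range(config.max_gen + 1):
            pA, pB = pop.allele_freqs()
            fixed = pop.is_fixed()
            rows.append(
                {
                    "rep": rep,
                    "gen": gen,
                    "pA": pA,
                    "pB": pB,
                    "VG": pop.realised_VG(),
                    "fixed": fixed,
                }
            )
            if record_populations:
                snapshots.append(pop)
            if fixed or gen == config.max_gen:
                break
            pop = assign_phenotypes(pop, rng)
            pop = select_and_reproduce(pop, config, rng)
        kept.append(snapshots)
    df = pd.DataFrame(rows)
    if record_populations:
        return df, kept
    return df


def stochastic_power(
    m: GPMap,
    config: PopSimConfig,
    design: StudyDesign,
    tests: list[TestSpec],
    seed: int | np.random.Generator = 0,
    n_populations: int = 50,
) -> pd.DataFrame:
    """Per-generation detected additive variance across replicate populations.

    At each generation the realised haplotype frequencies of every
    population define a two-locus system whose variance components are
    decomposed and fed to the expected-F detection rules; detected and
    available joint additive variance are summed across populations and
    reported as a percentage per generation and test.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    detected = {t.name: np.zeros(config.max_gen + 1) for t in tests}
    available = np.zeros(config.max_gen + 1)
    counts = np.zeros(config.max_gen + 1, dtype=int)
    for _ in range(n_populations):
        pop = init_population(m, config, rng)
        VE = pop.VE
        for gen in range(config.max_gen + 1):
            pA, pB = pop.allele_freqs()
            if pop.is_fixed():
                break
            hap = pop.haplotype_freqs()
            state = HaplotypeState(hap, c=config.c)
            if 0 < state.pA < 1 and 0 < state.pB < 1:
                vc = variance_components(m, state)
                available[gen] += vc.VA_joint
                counts[gen] += 1
                for t in tests:
                    res = detect(vc, design, t, VE=VE)
                    detected[t.name][gen] += res.detected_VA
            if gen == config.max_gen:
                break
            pop = assign_phenotypes(pop, rng)
            pop = select_and_reproduce(pop, config, rng)
    rows = []
    for gen in range(config.max_gen + 1):
        for t in tests:
            pct = 100.0 * detected[t.name][gen] / available[gen] if available[gen] > 0 else 0.0
            rows.append(
                {
                    "gen": gen,
                    "test": t.name,
                    "pct_VA_detected": pct,
                    "n_segregating": counts[gen],
                }
            )
    return pd.DataFrame(rows)
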