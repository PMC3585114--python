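"""Deterministic two-locus haplotype-frequency dynamics under selection.

The state of the system is the vector of four gamete frequencies
x = (x_AB, x_Ab, x_aB, x_ab) together with the recombination fraction c.
One generation of viability selection followed by random mating updates

    x1' = (x1 w1 - c wH D) / wbar
    x2' = (x2 w2 + c wH D) / wbar
    x3' = (x3 w3 + c wH D) / wbar
    x4' = (x4 w4 - c wH D) / wbar

where wi = sum_j w(i,j) x_j are marginal gamete fitnesses under random
union of gametes, wH is the fitness of the double heterozygote (cis and
trans assumed equal), D = x1 x4 - x2 x3 is the gametic disequilibrium and
wbar is mean fitness.  This is the classical two-locus selection recursion;
it is verified in the test suite against a brute-force mating-table
enumeration.

Trajectories run for a fixed horizon (default 200 generations) or until a
locus is deterministically "fixed", i.e. its minor-allele frequency falls
below 1/(2N) for a nominal population size N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gpmaps import GPMap

__all__ = [
    "HaplotypeState",
    "FixationRule",
    "Trajectory",
    "GAMETES",
    "gamete_genotype_index",
    "genotype_value",
    "fitness_matrix",
    "marginal_fitness_and_mean",
    "step",
    "is_fixed",
    "quasi_ld",
    "state_from_allele_freqs",
    "run_deterministic",
    "DEFAULT_FREQ_GRID",
    "initial_frequency_grid",
]

#: gamete order used throughout: index 0..3
GAMETES = ("AB", "Ab", "aB", "ab")

# number of alternative alleles carried by each gamete at locus A / locus B
_A_COUNT = np.array([0, 0, 1, 1])  # 'a' copies: AB, Ab carry A; aB, ab carry a
_B_COUNT = np.array([0, 1, 0, 1])  # 'b' copies

DEFAULT_FREQ_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class HaplotypeState:
    """Four gamete frequencies plus the recombination fraction."""

    x: np.ndarray
    c: float = 0.5

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.shape != (4,):
            raise ValueError("haplotype state needs 4 gamete frequencies")
        if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
            raise ValueError(f"gamete frequencies out of [0,1]: {x}")
        if abs(x.sum() - 1.0) > 1e-9:
            raise ValueError(f"gamete frequencies must sum to 1, got {x.sum()}")
        if not 0.0 <= self.c <= 0.5:
            raise ValueError("recombination fraction must lie in [0, 0.5]")
        x = np.clip(x, 0.0, 1.0)
        x = x / x.sum()
        x.flags.writeable = False
        object.__setattr__(self, "x", x)

    @property
    def pA(self) -> float:
        """Frequency of the reference allele A."""
        return float(self.x[0] + self.x[1])

    @property
    def pB(self) -> float:
        return float(self.x[0] + self.x[2])

    @property
    def qA(self) -> float:
        """Minor-allele frequency at locus A."""
        p = self.pA
        return min(p, 1.0 - p)

    @property
    def qB(self) -> float:
        p = self.pB
        return min(p, 1.0 - p)

    @property
    def D(self) -> float:
        x = self.x
        return float(x[0] * x[3] - x[1] * x[2])


@dataclass(frozen=True)
class FixationRule:
    """Deterministic fixation cutoff: minor-allele frequency < 1/(2N)."""

    N: int = 1000

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size must be at least 2")

    @property
    def threshold(self) -> float:
        return 1.0 / (2 * self.N)


def gamete_genotype_index(hapi: int, hapj: int) -> tuple[int, int]:
    """Genotype grid indices (row, col) for an ordered gamete pair.

    Row = number of 'a' alleles (0 = AA, 1 = Aa, 2 = aa); column likewise
    for locus B.  Cis and trans double heterozygotes map to the same cell.
    """
    return (
        int(_A_COUNT[hapi] + _A_COUNT[hapj]),
        int(_B_COUNT[hapi] + _B_COUNT[hapj]),
    )


def genotype_value(m: GPMap, hapi: int, hapj: int) -> float:
    row, col = gamete_genotype_index(hapi, hapj)
    return float(m.values[row, col])


def fitness_matrix(m: GPMap) -> np.ndarray:
    """4x4 matrix of genotype values for ordered gamete pairs."""
    w = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            w[i, j] = genotype_value(m, i, j)
    return w


def marginal_fitness_and_mean(state: HaplotypeState, m: GPMap) -> tuple[np.ndarray, float]:
    """Marginal gamete fitnesses w_i = sum_j w(i,j) x_j and mean fitness."""
    w = fitness_matrix(m)
    wi = w @ state.x
    wbar = float(state.x @ wi)
    return wi, wbar


def step(state: HaplotypeState, m: GPMap) -> HaplotypeState:
    """One generation of selection and recombination."""
    wi, wbar = marginal_fitness_and_mean(state, m)
    if wbar <= 0:
        raise ZeroDivisionError("mean fitness is zero: selection undefined")
    x = state.x
    D = x[0] * x[3] - x[1] * x[2]
    wH = float(m.values[1, 1])
    cwd = state.c * wH * D
    sign = np.array([-1.0, 1.0, 1.0, -1.0])
    x_new = (x * wi + sign * cwd) / wbar
    x_new = np.clip(x_new, 0.0, None)
    x_new = x_new / x_new.sum()
    return HaplotypeState(x_new, c=state.c)


def is_fixed(state: HaplotypeState, rule: FixationRule) -> bool:
    t = rule.threshold
    return state.qA < t or state.qB < t


def quasi_ld(state: HaplotypeState) -> tuple[float, float]:
    """Gametic disequilibrium D and squared correlation r2.

    r2 is defined as 0 when either locus is monomorphic.
    """
    D = state.D
    denom = state.pA * (1 - state.pA) * state.pB * (1 - state.pB)
    r2 = 0.0 if denom == 0 else D * D / denom
    return D, r2


def state_from_allele_freqs(pA: float, pB: float, D: float = 0.0, c: float = 0.5) -> HaplotypeState:
    """Build a haplotype state from allele frequencies and disequilibrium."""
    x = np.array(
        [
            pA * pB + D,
            pA * (1 - pB) - D,
            (1 - pA) * pB - D,
            (1 - pA) * (1 - pB) + D,
        ]
    )
    if np.any(x < -1e-12):
        raise ValueError(f"infeasible (pA={pA}, pB={pB}, D={D})")
    return HaplotypeState(np.clip(x, 0.0, 1.0), c=c)


@dataclass
class Trajectory:
    """Per-generation record of a deterministic simulation."""

    states: list[HaplotypeState]
    fixed: bool
    m: GPMap
    rule: FixationRule
    wbar: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def generations(self) -> int:
        return len(self.states)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gen, (s, wb) in enumerate(zip(self.states, self.wbar)):
            D, r2 = quasi_ld(s)
            last = gen == len(self.states) - 1
            rows.append(
                {
                    "gen": gen,
                    "x1": s.x[0],
                    "x2": s.x[1],
                    "x3": s.x[2],
                    "x4": s.x[3],
                    "pA": s.pA,
                    "pB": s.pB,
                    "D": D,
                    "r2": r2,
                    "wbar": wb,
                    "fixed": self.fixed and last,
                }
            )
        return pd.DataFrame(rows)


def run_deterministic(
    m: GPMap,
    init: tuple[float, float, float] | HaplotypeState,
    c: float = 0.5,
    max_gen: int = 200,
    rule: FixationRule | None = None,
) -> Trajectory:
    """Iterate the selection recursion until fixation or ``max_gen``.

    ``init`` is either a HaplotypeState or a tuple (pA0, pB0, D0); initial
    frequencies must be strictly polymorphic.  Generation 0 (the initial
    state) is recorded; the trajectory ends at the first generation whose
    state is fixed, or at max_gen.
    """
    rule = rule or FixationRule()
    if isinstance(init, HaplotypeState):
        state = init
    else:
        pA0, pB0, D0 = init
        if not (0 < pA0 < 1 and 0 < pB0 < 1):
            raise ValueError("initial allele frequencies must lie in (0, 1)")
        state = state_from_allele_freqs(pA0, pB0, D0, c=c)
    states = [state]
    wbars = [marginal_fitness_and_mean(state, m)[1]]
    fixed = is_fixed(state, rule)
    while not fixed and len(states) <= max_gen:
        state = step(state, m)
        states.append(state)
        wbars.append(marginal_fitness_and_mean(state, m)[1])
        fixed = is_fixed(state, rule)
        if len(states) == max_gen + 1:
            break
    return Trajectory(states=states, fixed=fixed, m=m, rule=rule, wbar=wbars)


def initial_frequency_grid(freqs=DEFAULT_FREQ_GRID) -> list[tuple[float, float]]:
    """The standard 25-point initial-frequency grid: freqs x freqs."""
    return [(pA, pB) for pA in freqs for pB in freqs]
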