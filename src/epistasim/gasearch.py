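"""Genetic algorithm over G-P map space.

Searches for two-locus fitness patterns that simultaneously maximise the
additive genetic variance maintained under selection and avoid fixation.
A candidate is a 3x3 map scaled to [0, 1]; its score is the joint additive
variance summed over 25 deterministic inner simulations (initial allele
frequencies enumerating a 5-point set at both loci) and over generations
after a burn-in, provided that at least a configured fraction of the inner
simulations remain unfixed at the end of the horizon — otherwise the
candidate scores zero.  Each round keeps the top s candidates (elitism, so
the best score never decreases), adds m Gaussian mutants per survivor
(rescaled to [0, 1]) and tops the pool back up with fresh random maps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dynamics import FixationRule, run_deterministic
from .gpmaps import GPMap, scale_map
from .varcomp import joint_additive_variance

__all__ = [
    "GAConfig",
    "Candidate",
    "ga_initialise",
    "ga_score",
    "ga_select",
    "ga_mutate",
    "ga_run",
]


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the map-space genetic algorithm.

    The candidate pool of size C is composed each round of the s selected
    survivors, s*m of their mutants and C - s - s*m fresh random maps.
    """

    C: int = 100
    s: int = 5
    m: int = 10
    G: int = 100
    g0: int = 10
    R: int = 50
    survival_frac: float = 0.8
    sigma_m: float = 0.05
    freqs: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    N: int = 1000
    c: float = 0.5

    def __post_init__(self) -> None:
        if self.C < self.s * (1 + self.m):
            raise ValueError("pool size C must fit s survivors plus s*m mutants")
        if not 0 < self.survival_frac <= 1:
            raise ValueError("survival_frac must lie in (0, 1]")
        if not 0 <= self.g0 < self.G:
            raise ValueError("burn-in g0 must lie in [0, G)")

    @property
    def n_fresh(self) -> int:
        return self.C - self.s - self.s * self.m

    @property
    def n_inner(self) -> int:
        return len(self.freqs) ** 2


@dataclass(frozen=True)
class Candidate:
    gpmap: GPMap
    score: float = float("nan")
    n_unfixed: int = -1

    @property
    def scored(self) -> bool:
        return not np.isnan(self.score)


def _random_map(rng: np.random.Generator) -> GPMap:
    vals = rng.uniform(0.0, 1.0, size=(3, 3))
    return scale_map(GPMap(vals, label="random"))


def ga_initialise(config: GAConfig, rng: np.random.Generator) -> list[Candidate]:
    """C random candidates, each min-max scaled to [0, 1]."""
    return [Candidate(_random_map(rng)) for _ in range(config.C)]


def ga_score(cand: Candidate, config: GAConfig) -> Candidate:
    """Score a candidate by summed joint additive variance.

    Runs the deterministic inner simulations over the 25 initial
    frequencies.  If fewer than survival_frac of them remain unfixed after
    G generations the candidate fails selection and scores 0; otherwise
    the score sums VA_joint over generations g0+1 .. min(fixation, G) of
    every simulation.
    """
    rule = FixationRule(config.N)
    total = 0.0
    n_unfixed = 0
    per_sim_scores = []
    for pA0 in config.freqs:
        for pB0 in config.freqs:
            traj = run_deterministic(
                cand.gpmap, (pA0, pB0, 0.0), c=config.c, max_gen=config.G, rule=rule
            )
            if not traj.fixed:
                n_unfixed += 1
            s = 0.0
            for gen, state in enumerate(traj.states):
                if gen <= config.g0:
                    continue
                if traj.fixed and gen == len(traj.states) - 1:
                    break
                if 0 < state.pA < 1 and 0 < state.pB < 1:
                    s += joint_additive_variance(cand.gpmap, state)
            per_sim_scores.append(s)
    if n_unfixed < config.survival_frac * config.n_inner:
        return replace(cand, score=0.0, n_unfixed=n_unfixed)
    return replace(cand, score=float(sum(per_sim_scores)), n_unfixed=n_unfixed)


def ga_select(pool: list[Candidate], config: GAConfig) -> list[Candidate]:
    """Top s candidates by score; empty list signals full reinitialisation.

    Ties are broken by pool order then by lexicographic map comparison,
    making selection invariant to input ordering of equal candidates.
    """
    if all(c.score <= 0 for c in pool):
        return []
    ranked = sorted(
        enumerate(pool),
        key=lambda ic: (-ic[1].score, tuple(ic[1].gpmap.values.flatten()), ic[0]),
    )
    return [c for _, c in ranked[: config.s]]


def ga_mutate(cand: Candidate, config: GAConfig, rng: np.random.Generator) -> Candidate:
    """Gaussian perturbation of every cell followed by min-max rescaling."""
    vals = cand.gpmap.values + rng.normal(0.0, config.sigma_m, size=(3, 3))
    return Candidate(scale_map(GPMap(vals, label="mutant")))


def ga_run(
    config: GAConfig,
    seed: int | np.random.Generator = 0,
    progress: bool = False,
) -> tuple[Candidate, list[float]]:
    """Run the full search; returns the best candidate and score history.

    The best score history is non-decreasing because the selected set is
    carried into every following round unchanged (elitism).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = ga_initialise(config, rng)
    history: list[float] = []
    best: Candidate | None = None
    for rnd in range(config.R):
        pool = [c if c.scored else ga_score(c, config) for c in pool]
        selected = ga_select(pool, config)
        round_best = max((c.score for c in pool), default=0.0)
        if best is None or round_best > best.score:
            best = max(pool, key=lambda c: c.score)
        history.append(best.score if best else 0.0)
        if progress:
            print(f"round {rnd + 1}/{config.R}: best score {history[-1]:.4f}")
        if rnd == config.R - 1:
            break
        if not selected:
            pool = ga_initialise(config, rng)
            continue
        next_pool = list(selected)
        for parent in selected:
            for _ in range(config.m):
                next_pool.append(ga_mutate(parent, config, rng))
        while len(next_pool) < config.C:
            next_pool.append(Candidate(_random_map(rng)))
        pool = next_pool
    assert best is not None
    return best, history
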