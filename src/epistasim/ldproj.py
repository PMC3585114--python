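"""Projection of causal two-locus effects onto observed SNPs in incomplete LD.

Each causal locus has a linked observed SNP with the *same* allele
frequency and a signed gametic correlation r (reported as r^2).  The
observed genotype at a SNP carries only probabilistic information about
the causal genotype, so the G-P map "seen" at the observed SNP pair is a
convex blur of the causal map:

    M_O(i, j) = sum_k sum_l P_A(k | i) P_B(l | j) M_C(k, l)

with per-locus conditional genotype matrices P built from the gamete-pair
model (HWE, independent transmission of the two gametes).  Only the causal
variants are inherited across generations; the observed SNPs are composed
afresh at each generation at the configured LD.

Quasi-LD between the two causal loci attenuates through both links: the
observed SNP pair carries gametic disequilibrium D_obs = rA rB D_causal,
so at |rA| = |rB| = 1 the observed system reproduces the causal system
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import HaplotypeState, state_from_allele_freqs
from .gpmaps import GPMap

__all__ = [
    "LDLink",
    "ObservedSystem",
    "causal_observed_gamete_freqs",
    "conditional_genotype_matrix",
    "project_map",
    "DEFAULT_R2_GRID",
]

DEFAULT_R2_GRID = (1.0, 0.8, 0.6, 0.4, 0.2)


@dataclass(frozen=True)
class LDLink:
    """LD between one causal locus and its observed SNP."""

    r: float
    p: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("gametic correlation must lie in [-1, 1]")
        if not 0.0 < self.p < 1.0:
            raise ValueError("shared allele frequency must lie in (0, 1)")

    @property
    def r2(self) -> float:
        return self.r * self.r

    @property
    def D_link(self) -> float:
        return self.r * self.p * (1.0 - self.p)


@dataclass(frozen=True)
class ObservedSystem:
    """The observed SNP pair induced by LD links from a causal system."""

    map: GPMap
    state: HaplotypeState
    cond_A: np.ndarray  # P(causal genotype | observed genotype) at locus A
    cond_B: np.ndarray


def causal_observed_gamete_freqs(p: float, r: float) -> np.ndarray:
    """Gamete frequencies of a (causal, observed) locus pair.

    Order (CM, Cm, cM, cm) where C/c are causal alleles and M/m observed;
    both loci share allele frequency p and D_link = r p (1-p).
    """
    link = LDLink(r=r, p=p)
    D = link.D_link
    f = np.array(
        [
            p * p + D,
            p * (1 - p) - D,
            p * (1 - p) - D,
            (1 - p) * (1 - p) + D,
        ]
    )
    if np.any(f < -1e-12):
        raise ValueError(f"infeasible LD link (p={p}, r={r})")
    return np.clip(f, 0.0, 1.0)


def conditional_genotype_matrix(p: float, r: float) -> np.ndarray:
    """P(causal genotype | observed genotype) under the gamete-pair model.

    Rows index the observed genotype (MM, Mm, mm), columns the causal
    genotype (CC, Cc, cc).  The two gametes of an individual are
    transmitted independently (HWE), so each row is a convolution of
    per-gamete conditionals.  Every row sums to 1.
    """
    f = causal_observed_gamete_freqs(p, r)
    # per-gamete conditionals P(causal allele | observed allele)
    pC_given_M = np.array([f[0], f[2]]) / p  # (C, c) given M
    pC_given_m = np.array([f[1], f[3]]) / (1 - p)

    def conv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # a, b are (P(C), P(c)) for the two gametes; combine into genotype
        # classes indexed by number of c alleles: CC, Cc, cc
        return np.array(
            [a[0] * b[0], a[0] * b[1] + a[1] * b[0], a[1] * b[1]]
        )

    return np.vstack(
        [
            conv(pC_given_M, pC_given_M),
            conv(pC_given_M, pC_given_m),
            conv(pC_given_m, pC_given_m),
        ]
    )


def project_map(
    m_c: GPMap,
    state: HaplotypeState,
    rA: float,
    rB: float,
) -> ObservedSystem:
    """Blur a causal map onto the observed SNP pair.

    ``state`` is the causal haplotype state; rA, rB the signed gametic
    correlations of the two LD links.  Returns the observed map, the
    observed haplotype state (same allele frequencies, D attenuated by
    rA rB) and the conditional matrices.
    """
    pA, pB = state.pA, state.pB
    if not (0 < pA < 1 and 0 < pB < 1):
        raise ValueError("both causal loci must be polymorphic")
    PA = conditional_genotype_matrix(pA, rA)
    PB = conditional_genotype_matrix(pB, rB)
    M_O = PA @ m_c.values @ PB.T
    D_obs = rA * rB * state.D
    obs_state = state_from_allele_freqs(pA, pB, D_obs, c=state.c)
    return ObservedSystem(
        map=GPMap(M_O, label=f"{m_c.label} (observed, rA={rA:g}, rB={rB:g})", id=m_c.id),
        state=obs_state,
        cond_A=PA,
        cond_B=PB,
    )
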