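"""Variance decomposition of two-locus G-P maps.

Two complementary decompositions are provided:

* the classical marginal/average-effect algebra: per-locus average effects
  alpha from the marginal genotype values, marginal additive variances
  2pq alpha^2, and a *joint* additive variance for the two-locus system
  that includes the LD covariance term,

      VA_joint = 2 pA qA alphaA^2 + 4 D alphaA alphaB + 2 pB qB alphaB^2,

  where the alphas are the (partial) average effects obtained from the
  least-squares regression of genotypic value on the two allele dosages.
  When D = 0 they reduce to the familiar marginal average effects.

* the NOIA statistical decomposition into 8 orthogonal components (VA1,
  VD1, VA2, VD2, VAA, VAD, VDA, VDD) built from each locus's own genotype
  frequencies, treating the loci as independent.  Under independence the
  components are orthogonal at arbitrary (non-HWE) genotype frequencies
  and sum to the total genetic variance; under linkage disequilibrium the
  decomposition is no longer orthogonal — that failure is an intrinsic
  property of all extant two-locus decompositions and is deliberately
  retained, since it is exactly what association-testing practice does.

A weighted-regression oracle (``regression_oracle``) provides an
independent route to the additive variance and is used throughout the test
suite as the arbiter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import HaplotypeState, _A_COUNT, _B_COUNT
from .gpmaps import GPMap

__all__ = [
    "GenotypeDistribution",
    "VarianceComponents",
    "genotype_distribution",
    "marginal_genotype_values",
    "marginal_additive_variance",
    "average_effects",
    "joint_additive_variance",
    "regression_oracle",
    "noia_decomposition",
    "variance_components",
]

_NEG_TOL = 1e-12

COMPONENT_NAMES = ("VA1", "VD1", "VA2", "VD2", "VAA", "VAD", "VDA", "VDD")


@dataclass(frozen=True)
class GenotypeDistribution:
    """3x3 two-locus genotype frequencies (rows = locus A: AA, Aa, aa)."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (3, 3):
            raise ValueError("genotype distribution must be 3x3")
        if np.any(f < -1e-12):
            raise ValueError("negative genotype frequency")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("genotype frequencies must sum to 1")
        f = np.clip(f, 0.0, None)
        f = f / f.sum()
        f.flags.writeable = False
        object.__setattr__(self, "freqs", f)

    @property
    def marginal_A(self) -> np.ndarray:
        return self.freqs.sum(axis=1)

    @property
    def marginal_B(self) -> np.ndarray:
        return self.freqs.sum(axis=0)

    @property
    def pA(self) -> float:
        gA = self.marginal_A
        return float(gA[0] + 0.5 * gA[1])

    @property
    def pB(self) -> float:
        gB = self.marginal_B
        return float(gB[0] + 0.5 * gB[1])


@dataclass(frozen=True)
class VarianceComponents:
    VA1: float
    VD1: float
    VA2: float
    VD2: float
    VAA: float
    VAD: float
    VDA: float
    VDD: float
    VG: float
    VA_joint: float
    alphaA: float
    alphaB: float

    @property
    def component_sum(self) -> float:
        return (
            self.VA1 + self.VD1 + self.VA2 + self.VD2
            + self.VAA + self.VAD + self.VDA + self.VDD
        )

    @property
    def marginal(self) -> float:
        """Sum of the four single-locus components."""
        return self.VA1 + self.VD1 + self.VA2 + self.VD2

    @property
    def epistatic(self) -> float:
        """Sum of the four interaction components."""
        return self.VAA + self.VAD + self.VDA + self.VDD

    def as_dict(self) -> dict[str, float]:
        return {
            "VA1": self.VA1, "VD1": self.VD1, "VA2": self.VA2, "VD2": self.VD2,
            "VAA": self.VAA, "VAD": self.VAD, "VDA": self.VDA, "VDD": self.VDD,
            "VG": self.VG, "VA_joint": self.VA_joint,
            "alphaA": self.alphaA, "alphaB": self.alphaB,
        }


def genotype_distribution(state: HaplotypeState) -> GenotypeDistribution:
    """Two-locus genotype frequencies from random union of gametes."""
    f = np.zeros((3, 3))
    x = state.x
    for i in range(4):
        for j in range(4):
            f[_A_COUNT[i] + _A_COUNT[j], _B_COUNT[i] + _B_COUNT[j]] += x[i] * x[j]
    return GenotypeDistribution(f)


def marginal_genotype_values(m: GPMap, state: HaplotypeState) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus genotype values: conditional means of the map.

    Value of genotype g at locus A = E[m | locus-A genotype = g] under the
    random-union genotype distribution; likewise for locus B.  Raises if a
    locus is monomorphic (conditional means undefined for absent classes).
    """
    if not (0 < state.pA < 1):
        raise ValueError("locus A is monomorphic")
    if not (0 < state.pB < 1):
        raise ValueError("locus B is monomorphic")
    dist = genotype_distribution(state)
    f = dist.freqs
    gA = dist.marginal_A
    gB = dist.marginal_B
    condA = f / gA[:, None]  # P(B genotype | A genotype)
    condB = f / gB[None, :]
    valsA = (condA * m.values).sum(axis=1)
    valsB = (condB * m.values).sum(axis=0)
    return valsA, valsB


def marginal_additive_variance(values: np.ndarray, p: float) -> tuple[float, float]:
    """Additive variance and average effect at one locus.

    ``values`` = genotype values (m2, m1, m0) for (AA, Aa, aa) and ``p`` =
    frequency of the reference allele A.  alpha = p(m2-m1) + (1-p)(m1-m0);
    VA = 2p(1-p) alpha^2.
    """
    if not 0 < p < 1:
        raise ValueError("allele frequency must lie in (0, 1)")
    m2, m1, m0 = (float(v) for v in values)
    alpha = p * (m2 - m1) + (1 - p) * (m1 - m0)
    VA = 2 * p * (1 - p) * alpha * alpha
    return VA, alpha


def average_effects(m: GPMap, state: HaplotypeState) -> tuple[float, float]:
    """Partial average effects (alphaA, alphaB) of the two-locus system.

    Solves the 2x2 least-squares normal equations for the regression of
    genotypic value on the two reference-allele dosages, with genotype
    frequencies from random union of gametes: Var(dosage) = 2pq per locus
    and Cov(dosageA, dosageB) = 2D.  At linkage equilibrium these equal
    the marginal average effects.
    """
    pA, pB, D = state.pA, state.pB, state.D
    if not (0 < pA < 1 and 0 < pB < 1):
        raise ValueError("both loci must be polymorphic")
    dist = genotype_distribution(state)
    f = dist.freqs
    dosA = np.array([2.0, 1.0, 0.0])  # reference-allele count per row
    v = m.values
    mean_v = float((f * v).sum())
    covA = float((f * v * dosA[:, None]).sum()) - mean_v * (2 * pA)
    covB = float((f * v * dosA[None, :]).sum()) - mean_v * (2 * pB)
    C = np.array(
        [
            [2 * pA * (1 - pA), 2 * D],
            [2 * D, 2 * pB * (1 - pB)],
        ]
    )
    # pseudo-inverse: at complete gametic coupling (|r| = 1 between the
    # causal loci) the dosages are collinear and the individual effects are
    # unidentifiable, but the fitted additive variance alpha . cov remains
    # well defined (minimum-norm solution)
    alphaA, alphaB = np.linalg.pinv(C, rcond=1e-12) @ np.array([covA, covB])
    return float(alphaA), float(alphaB)


def joint_additive_variance(m: GPMap, state: HaplotypeState) -> float:
    """Total additive variance of the two-locus system, LD included.

    VA_joint = 2 pA qA alphaA^2 + 4 D alphaA alphaB + 2 pB qB alphaB^2,
    with the partial average effects of :func:`average_effects`.  Equals
    the variance of fitted values of the dosage regression
    (:func:`regression_oracle`) on the random-union genotype distribution.
    """
    alphaA, alphaB = average_effects(m, state)
    pA, pB, D = state.pA, state.pB, state.D
    VA = (
        2 * pA * (1 - pA) * alphaA**2
        + 4 * D * alphaA * alphaB
        + 2 * pB * (1 - pB) * alphaB**2
    )
    return float(max(VA, 0.0))


def regression_oracle(m: GPMap, dist: GenotypeDistribution) -> tuple[float, float]:
    """Weighted least-squares additive variance: the independent arbiter.

    Regresses genotype value on the two reference-allele dosages with
    genotype frequencies as weights.  Returns (VA = variance of fitted
    values, VG = variance of genotype values).
    """
    f = dist.freqs.flatten()
    rows, cols = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    dosA = (2 - rows).flatten().astype(float)
    dosB = (2 - cols).flatten().astype(float)
    v = m.values.flatten()
    X = np.column_stack([np.ones(9), dosA, dosB])
    W = np.diag(f)
    XtW = X.T @ W
    beta, *_ = np.linalg.lstsq(XtW @ X, XtW @ v, rcond=None)
    fitted = X @ beta
    mean_fit = float(f @ fitted)
    VA = float(f @ (fitted - mean_fit) ** 2)
    mean_v = float(f @ v)
    VG = float(f @ (v - mean_v) ** 2)
    return VA, VG


def _locus_basis(geno_freqs: np.ndarray) -> np.ndarray:
    """Orthogonal per-locus basis (mean, additive, dominance) columns.

    Columns are evaluated at the three genotypes (AA, Aa, aa) and are
    orthogonal under the genotype-frequency inner product.  The additive
    column is the centred reference-allele dosage, so its effect is the
    average effect alpha; the dominance column is the heterozygosity
    indicator orthogonalised against mean and dosage.  This reproduces the
    NOIA statistical scaling at arbitrary genotype frequencies.
    """
    w = np.asarray(geno_freqs, dtype=float)
    if w.shape != (3,) or abs(w.sum() - 1.0) > 1e-9 or np.any(w < -1e-12):
        raise ValueError("invalid genotype frequency vector")
    dos = np.array([2.0, 1.0, 0.0])
    b0 = np.ones(3)
    b1 = dos - float(w @ dos)
    var1 = float(w @ b1**2)
    het = np.array([0.0, 1.0, 0.0])
    if var1 <= 1e-14:
        raise ValueError("monomorphic locus: additive contrast degenerate")
    b2 = het - float(w @ het) - (float(w @ (het * b1)) / var1) * b1
    return np.column_stack([b0, b1, b2])


def noia_decomposition(
    m: GPMap,
    pA_geno: np.ndarray,
    pB_geno: np.ndarray,
) -> VarianceComponents:
    """NOIA statistical decomposition from per-locus genotype frequencies.

    Builds each locus's orthogonal (mean, additive, dominance) basis from
    its own genotype frequencies, forms the two-locus design as the
    Kronecker product, solves exactly for the 9 effects, and returns the
    variance contributed by each of the 8 non-mean effects plus the total
    genetic variance under the product (independence) distribution.
    """
    SA = _locus_basis(np.asarray(pA_geno, dtype=float))
    SB = _locus_basis(np.asarray(pB_geno, dtype=float))
    wA = np.asarray(pA_geno, dtype=float)
    wB = np.asarray(pB_geno, dtype=float)
    # joint design over the 9 genotypes, row-major (A genotype, B genotype)
    S = np.kron(SA, SB)  # rows: (gA, gB); cols: (termA, termB)
    v = m.values.flatten()
    effects = np.linalg.solve(S, v)
    w_joint = np.kron(wA, wB)
    # E[basis^2] per column; orthogonality makes variances separable
    col_sq = S**2
    basis_var = w_joint @ col_sq  # E[b^2]; mean column has E=1
    var_per_effect = effects**2 * basis_var
    # column order of kron: (A-term-major): [(0,0),(0,1),(0,2),(1,0),...]
    # term indices: 0 = mean, 1 = additive, 2 = dominance
    def comp(a_term: int, b_term: int) -> float:
        val = float(var_per_effect[a_term * 3 + b_term])
        if val < -_NEG_TOL:
            raise ValueError(f"negative variance component: {val}")
        return max(val, 0.0)

    VA1, VD1 = comp(1, 0), comp(2, 0)
    VA2, VD2 = comp(0, 1), comp(0, 2)
    VAA, VAD = comp(1, 1), comp(1, 2)
    VDA, VDD = comp(2, 1), comp(2, 2)
    mean_v = float(w_joint @ v)
    VG = float(w_joint @ (v - mean_v) ** 2)
    # marginal alphas for reference; VA_joint defaults to the LE sum
    alphaA = float(effects[3])  # (A additive, B mean) term
    alphaB = float(effects[1])
    return VarianceComponents(
        VA1=VA1, VD1=VD1, VA2=VA2, VD2=VD2,
        VAA=VAA, VAD=VAD, VDA=VDA, VDD=VDD,
        VG=VG, VA_joint=VA1 + VA2, alphaA=alphaA, alphaB=alphaB,
    )


def variance_components(m: GPMap, state: HaplotypeState) -> VarianceComponents:
    """Full decomposition of a map at a haplotype state.

    NOIA components from each locus's marginal genotype frequencies
    (loci treated as independent, mirroring association-testing practice),
    with VA_joint and the average effects replaced by the LD-aware joint
    quantities from the dosage regression.
    """
    dist = genotype_distribution(state)
    vc = noia_decomposition(m, dist.marginal_A, dist.marginal_B)
    alphaA, alphaB = average_effects(m, state)
    VA_joint = joint_additive_variance(m, state)
    return VarianceComponents(
        VA1=vc.VA1, VD1=vc.VD1, VA2=vc.VA2, VD2=vc.VD2,
        VAA=vc.VAA, VAD=vc.VAD, VDA=vc.VDA, VDD=vc.VDD,
        VG=vc.VG, VA_joint=VA_joint, alphaA=alphaA, alphaB=alphaB,
    )
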