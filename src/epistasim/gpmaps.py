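"""Two-locus genotype-phenotype maps: construction, scaling, classification.

A G-P map is a 3x3 grid of genotype class means for a biallelic two-locus
system.  Rows index the genotype at locus A (AA, Aa, aa), columns the
genotype at locus B (BB, Bb, bb).  Values are unitless fitness / phenotype
class means; maps used in selection simulations are min-max scaled to [0, 1].

The module also enumerates the catalogue of binary (0/1) trait patterns
unique up to allele relabelling at either locus, locus exchange and trait
polarity inversion, and assembles the standard 56-map study catalogue:
the neutral map, the 50 binary symmetry classes, and five classical
parametric patterns.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "GPMap",
    "CatalogueEntry",
    "MapFamily",
    "ParametricKind",
    "symmetry_group",
    "canonical_binary",
    "enumerate_binary_patterns",
    "make_parametric_map",
    "scale_map",
    "classify_epistatic",
    "interaction_ss",
    "build_catalogue",
    "catalogue_to_json",
    "catalogue_from_json",
]

EPISTASIS_TOL = 1e-9


@dataclass(frozen=True)
class GPMap:
    """A 3x3 genotype-phenotype map.

    Parameters
    ----------
    values
        3x3 array of genotype class means.  Row index counts copies of the
        alternative allele ``a`` at locus A (0 = AA, 1 = Aa, 2 = aa);
        column index likewise for locus B.
    label
        Free-text description.
    id
        Optional catalogue index (1-56).
    """

    values: np.ndarray
    label: str = ""
    id: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (3, 3):
            raise ValueError(f"G-P map must be 3x3, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("G-P map values must be finite")
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    @property
    def is_constant(self) -> bool:
        return bool(np.ptp(self.values) == 0.0)

    def scaled(self) -> "GPMap":
        return scale_map(self)

    def __eq__(self, other: object) -> bool:  # value equality, label-blind
        if not isinstance(other, GPMap):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    def __hash__(self) -> int:
        return hash(self.values.tobytes())


class MapFamily(str, Enum):
    NEUTRAL = "neutral"
    BINARY = "binary"
    PARAMETRIC = "parametric"


class ParametricKind(str, Enum):
    NEUTRAL = "neutral"
    ADDITIVE = "additive"
    DOMINANCE_CANALISATION_DOM = "dominance_canalisation_dom"
    DOMINANCE_CANALISATION_REC = "dominance_canalisation_rec"
    AXA = "axa"
    AXD = "axd"
    DXD = "dxd"
    OVERDOMINANCE = "overdominance"


@dataclass(frozen=True)
class CatalogueEntry:
    gpmap: GPMap
    index: int
    family: MapFamily
    is_epistatic: bool


# ---------------------------------------------------------------------------
# Symmetry group and binary-pattern enumeration
# ---------------------------------------------------------------------------

def _closure(generators):
    ident = (tuple(range(9)), False)
    group = {ident}
    frontier = [ident]
    while frontier:
        new = []
        for perm_a, inv_a in frontier:
            for perm_b, inv_b in generators:
                g = (tuple(perm_a[i] for i in perm_b), inv_a ^ inv_b)
                if g not in group:
                    group.add(g)
                    new.append(g)
        frontier = new
    return sorted(group)


def _perm_from(fn) -> tuple[int, ...]:
    idx = np.arange(9).reshape(3, 3)
    return tuple(fn(idx).flatten().tolist())


def symmetry_group() -> list[tuple[tuple[int, ...], bool]]:
    """The 16-element group acting on 3x3 maps.

    Generated by row reversal (allele swap at locus A), column reversal
    (allele swap at locus B), transposition (locus exchange) and value
    inversion (trait polarity).  Each element is a (cell permutation,
    invert-values flag) pair.
    """
    gens = [
        (_perm_from(lambda m: m[::-1, :]), False),
        (_perm_from(lambda m: m[:, ::-1]), False),
        (_perm_from(lambda m: m.T), False),
        (tuple(range(9)), True),
    ]
    return _closure(gens)


_GROUP = symmetry_group()


def apply_symmetry(values: np.ndarray, element: tuple[tuple[int, ...], bool]) -> np.ndarray:
    """Apply one symmetry-group element to a 3x3 value grid.

    For value inversion on a binary map this is 1 - v; for general maps
    inversion reflects values about the (min + max) midpoint so that the
    scaled range is preserved.
    """
    perm, inv = element
    flat = np.asarray(values, dtype=float).flatten()
    out = flat[list(perm)]
    if inv:
        out = (flat.min() + flat.max()) - out
    return out.reshape(3, 3)


def canonical_binary(values: np.ndarray) -> bytes:
    """Canonical representative of a binary map's symmetry orbit.

    Returns the lexicographically smallest row-major 0/1 tuple over the
    16-element orbit, as bytes (9 values).
    """
    flat = np.asarray(values).astype(int).flatten()
    best = None
    for perm, inv in _GROUP:
        cand = flat[list(perm)]
        if inv:
            cand = 1 - cand
        b = bytes(cand.tolist())
        if best is None or b < best:
            best = b
    return best


def enumerate_binary_patterns() -> list[GPMap]:
    """All non-constant binary 3x3 patterns unique up to symmetry.

    Collapses the 512 binary matrices into orbits under the 16-element
    group (row/column reversal, transposition, value inversion), drops the
    single constant orbit, and returns one canonical (lexicographically
    smallest) representative per orbit, ordered by that representative.
    """
    reps: set[bytes] = set()
    for bits in itertools.product((0, 1), repeat=9):
        if len(set(bits)) == 1:
            continue
        reps.add(canonical_binary(np.array(bits)))
    maps = []
    for b in sorted(reps):
        vals = np.frombuffer(b, dtype=np.uint8).astype(float).reshape(3, 3)
        maps.append(GPMap(vals, label="binary"))
    return maps


# ---------------------------------------------------------------------------
# Parametric maps
# ---------------------------------------------------------------------------

def _dosage_score() -> np.ndarray:
    # signed half-dosage per genotype: AA -> +1/2, Aa -> 0, aa -> -1/2
    return np.array([0.5, 0.0, -0.5])


def make_parametric_map(kind: ParametricKind | str, **params: float) -> GPMap:
    """Construct one of the classical two-locus patterns, scaled to [0, 1].

    Kinds
    -----
    neutral
        All cells equal (0.5).
    additive
        0.5 + aA*sA + aB*sB with s in {+1/2, 0, -1/2}; params aA, aB
        (default 0.25 each).
    dominance_canalisation_dom / dominance_canalisation_rec
        Canalisation in which the dominant (resp. recessive) genotype at
        either locus masks the other locus: the double canalised class is
        the only one differing from baseline.
    axa, axd, dxd
        Pure additive-by-additive, additive-by-dominance and
        dominance-by-dominance interaction terms; param c (default 0.5).
    overdominance
        Single-locus heterozygote advantage at locus A, neutral at locus B.
    """
    kind = ParametricKind(kind)
    s = _dosage_score()
    if kind is ParametricKind.NEUTRAL:
        vals = np.full((3, 3), 0.5)
        return GPMap(vals, label="neutral")
    if kind is ParametricKind.ADDITIVE:
        aA = params.get("aA", 0.25)
        aB = params.get("aB", 0.25)
        vals = 0.5 + aA * s[:, None] + aB * s[None, :]
        return scale_map(GPMap(vals, label="additive"))
    if kind is ParametricKind.AXA:
        c = params.get("c", 0.5)
        sa = 2 * s  # {+1, 0, -1}
        vals = 0.5 + c * sa[:, None] * sa[None, :]
        return scale_map(GPMap(vals, label="axa"))
    if kind is ParametricKind.AXD:
        c = params.get("c", 0.5)
        sa = 2 * s
        d = np.array([-0.5, 0.5, -0.5])  # heterozygosity contrast at locus B
        vals = 0.5 + c * sa[:, None] * d[None, :]
        return scale_map(GPMap(vals, label="axd"))
    if kind is ParametricKind.DXD:
        c = params.get("c", 0.5)
        d = np.array([-0.5, 0.5, -0.5])
        vals = 0.5 + c * d[:, None] * d[None, :]
        return scale_map(GPMap(vals, label="dxd"))
    if kind is ParametricKind.OVERDOMINANCE:
        vals = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0], [0.0, 0.0, 0.0]])
        return GPMap(vals, label="overdominance")
    if kind is ParametricKind.DOMINANCE_CANALISATION_DOM:
        # the deleterious aa knockout is masked by any copy of B
        # (dominant masking): only aa x bb departs from baseline
        vals = np.ones((3, 3))
        vals[2, 2] = 0.0
        return GPMap(vals, label="canalisation (dominant masking)")
    if kind is ParametricKind.DOMINANCE_CANALISATION_REC:
        # masking only when homozygous BB (recessive masking): the aa
        # knockout is expressed in both Bb and bb backgrounds
        vals = np.ones((3, 3))
        vals[2, 1] = 0.0
        vals[2, 2] = 0.0
        return GPMap(vals, label="canalisation (recessive masking)")
    raise ValueError(f"unknown parametric kind: {kind}")  # pragma: no cover


def scale_map(m: GPMap) -> GPMap:
    """Affine min-max rescale so that min = 0 and max = 1.

    Constant maps cannot be rescaled; they are returned unchanged with a
    warning.
    """
    lo = float(m.values.min())
    hi = float(m.values.max())
    if hi == lo:
        warnings.warn("constant G-P map cannot be min-max scaled; returned unchanged")
        return m
    return replace(m, values=(m.values - lo) / (hi - lo))


# ---------------------------------------------------------------------------
# Epistasis classification
# ---------------------------------------------------------------------------

def interaction_ss(m: GPMap) -> float:
    """Interaction sum of squares of the equally-weighted two-way layout.

    Treats the 3x3 grid as a saturated two-way table with equal cell
    weights, removes the grand mean and both sets of marginal (row/column)
    effects, and returns the sum of squared residuals.  Zero iff the map is
    separable into per-locus effects.
    """
    v = m.values
    grand = v.mean()
    rows = v.mean(axis=1, keepdims=True) - grand
    cols = v.mean(axis=0, keepdims=True) - grand
    resid = v - grand - rows - cols
    return float(np.sum(resid**2))


def classify_epistatic(m: GPMap, tol: float = EPISTASIS_TOL) -> bool:
    """True iff the map is not expressible as mu + f_A(g_A) + f_B(g_B)."""
    return interaction_ss(m) > tol


# ---------------------------------------------------------------------------
# Catalogue
# ---------------------------------------------------------------------------

def build_catalogue() -> list[CatalogueEntry]:
    """Assemble the standard 56-map study catalogue.

    Entry 1 is the neutral map, entries 2-51 the binary symmetry classes in
    canonical order, entries 52-56 the parametric patterns AxA, AxD, DxD,
    overdominance and additive.  Deterministic: repeated calls are
    identical.
    """
    entries: list[CatalogueEntry] = []

    def add(gpmap: GPMap, family: MapFamily) -> None:
        index = len(entries) + 1
        gp = replace(gpmap, id=index)
        entries.append(
            CatalogueEntry(
                gpmap=gp,
                index=index,
                family=family,
                is_epistatic=classify_epistatic(gp),
            )
        )

    add(make_parametric_map(ParametricKind.NEUTRAL), MapFamily.NEUTRAL)
    for m in enumerate_binary_patterns():
        add(m, MapFamily.BINARY)
    for kind in (
        ParametricKind.AXA,
        ParametricKind.AXD,
        ParametricKind.DXD,
        ParametricKind.OVERDOMINANCE,
        ParametricKind.ADDITIVE,
    ):
        add(make_parametric_map(kind), MapFamily.PARAMETRIC)
    return entries


def catalogue_to_json(entries: Sequence[CatalogueEntry]) -> str:
    payload = [
        {
            "index": e.index,
            "label": e.gpmap.label,
            "family": e.family.value,
            "is_epistatic": e.is_epistatic,
            "values": [float(x) for x in e.gpmap.values.flatten()],
        }
        for e in entries
    ]
    return json.dumps(payload, indent=1)


def catalogue_from_json(text: str) -> list[CatalogueEntry]:
    entries = []
    for obj in json.loads(text):
        gp = GPMap(
            np.array(obj["values"], dtype=float).reshape(3, 3),
            label=obj.get("label", ""),
            id=obj["index"],
        )
        entries.append(
            CatalogueEntry(
                gpmap=gp,
                index=obj["index"],
                family=MapFamily(obj["family"]),
                is_epistatic=bool(obj["is_epistatic"]),
            )
        )
    return entries
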