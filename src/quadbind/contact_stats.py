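"""Statistics over Hirshfeld contact-surface percentage tables.

A crystal's Hirshfeld surface can be decomposed into percentage
contributions C_XY of contacts between element types X and Y (unordered
pairs summing to ≈ 100%).  From these the module derives:

* per-element surface fractions  S_X = C_XX + ½ Σ_{Y≠X} C_XY (renormalized),
* the random-contact model       R_XX = s_x²·100, R_XY = 2 s_x s_y·100,
* enrichment ratios              E_XY = C_XY / R_XY,

where s_x = S_X/100.  E_XY > 1 marks a privileged contact, E_XY = 1
neutral, E_XY < 1 disfavored.  Pairs whose random proportion falls below a
sparsity threshold are flagged rather than reported, since the ratio blows
up on tiny denominators.

The module also measures distances between named percentage-contribution
vectors (e.g. the N···X channels of a nitrogen-localized surface):
root-mean-square deviation with channels absent from one vector
zero-filled and n equal to the channel-union size, and the Euclidean
distance ED = RMSD·√n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nqr import ValidationError

__all__ = [
    "ContactMatrix",
    "SurfaceFractions",
    "EnrichmentTable",
    "ContributionVector",
    "surface_fractions",
    "random_contacts",
    "enrichment",
    "contribution_rmsd",
    "contribution_euclidean",
]

#: |Σ C_XY − 100| allowed, absolute percent (tables round to 0.05–0.1).
DEFAULT_CLOSURE_TOLERANCE = 1.5

#: R_XY below this (percent) flags the pair "sparse" in enrichment output.
DEFAULT_SPARSITY_THRESHOLD = 0.5


@dataclass(frozen=True)
class ContactMatrix:
    """Symmetric element-pair contact percentages for one structure.

    ``contact_pct[(X, Y)]`` is the percentage of the Hirshfeld surface made
    of X···Y contacts; keys are stored with elements sorted alphabetically.
    """

    elements: tuple[str, ...]
    contact_pct: dict
    structure_id: str = ""
    closure_tolerance: float = DEFAULT_CLOSURE_TOLERANCE

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValidationError("contact matrix needs at least one element")
        norm = {}
        for (x, y), v in self.contact_pct.items():
            if x not in self.elements or y not in self.elements:
                raise ValidationError(f"contact pair ({x}, {y}) uses unknown element")
            if v < 0:
                raise ValidationError(f"negative contact percentage for ({x}, {y})")
            key = tuple(sorted((x, y)))
            norm[key] = norm.get(key, 0.0) + float(v)
        total = sum(norm.values())
        if abs(total - 100.0) > self.closure_tolerance:
            raise ValidationError(
                f"contact percentages sum to {total:.2f}, outside "
                f"100 ± {self.closure_tolerance}"
            )
        object.__setattr__(self, "contact_pct", norm)

    def get(self, x: str, y: str) -> float:
        return self.contact_pct.get(tuple(sorted((x, y))), 0.0)


@dataclass(frozen=True)
class SurfaceFractions:
    """Per-element molecular-surface percentages, summing to 100."""

    fractions: dict
    closure_tolerance: float = DEFAULT_CLOSURE_TOLERANCE

    def __post_init__(self) -> None:
        for el, v in self.fractions.items():
            if v < 0:
                raise ValidationError(f"negative surface fraction for {el}")
        total = sum(self.fractions.values())
        if abs(total - 100.0) > self.closure_tolerance:
            raise ValidationError(
                f"surface fractions sum to {total:.2f}, outside "
                f"100 ± {self.closure_tolerance}"
            )


@dataclass(frozen=True)
class EnrichmentTable:
    """E_XY per unordered pair, with sparse pairs flagged instead of valued."""

    ratios: dict
    sparse_pairs: frozenset = field(default_factory=frozenset)

    def classification(self, x: str, y: str) -> str:
        e = self.ratios[tuple(sorted((x, y)))]
        if e > 1.0:
            return "privileged"
        if e < 1.0:
            return "disfavored"
        return "neutral"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pair": f"{x}...{y}", "E": e,
             "sparse": tuple(sorted((x, y))) in self.sparse_pairs}
            for (x, y), e in sorted(self.ratios.items())
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContributionVector:
    """Named contact channels with percentage values (absent ≠ zero only
    in provenance; distances zero-fill absent channels)."""

    channels: dict
    structure_id: str = ""

    def __post_init__(self) -> None:
        for name, v in self.channels.items():
            if v < 0:
                raise ValidationError(f"negative contribution for channel {name}")


def surface_fractions(cm: ContactMatrix) -> SurfaceFractions:
    """S_X = C_XX + ½ Σ_{Y≠X} C_XY, renormalized to sum exactly 100."""
    raw = {}
    for x in cm.elements:
        s = cm.get(x, x)
        for y in cm.elements:
            if y != x:
                s += 0.5 * cm.get(x, y)
        raw[x] = s
    total = sum(raw.values())
    if total == 0:
        raise ValidationError("all contact percentages are zero")
    return SurfaceFractions(
        fractions={x: 100.0 * v / total for x, v in raw.items()}
    )


def random_contacts(sf: SurfaceFractions) -> dict:
    """Random-mixing contact proportions R_XY from surface fractions.

    R_XX = s_x²·100 and R_XY = 2 s_x s_y·100 (X ≠ Y) with s_x = S_X/100;
    the result sums to 100 exactly because (Σ s_x)² = 1.
    """
    elements = sorted(sf.fractions)
    s = {x: sf.fractions[x] / 100.0 for x in elements}
    out = {}
    for i, x in enumerate(elements):
        for y in elements[i:]:
            out[(x, y)] = (100.0 * s[x] * s[y] if x == y
                           else 200.0 * s[x] * s[y])
    return out


def enrichment(
    cm: ContactMatrix,
    sparsity_threshold: float = DEFAULT_SPARSITY_THRESHOLD,
) -> EnrichmentTable:
    """E_XY = C_XY / R_XY with division-blow-up guarding.

    Pairs with R_XY < ``sparsity_threshold`` percent are flagged sparse;
    their ratio is still reported when finite, NaN when R_XY = 0.
    """
    r = random_contacts(surface_fractions(cm))
    ratios = {}
    sparse = set()
    for pair, r_xy in r.items():
        c_xy = cm.get(*pair)
        if r_xy < sparsity_threshold:
            sparse.add(pair)
        ratios[pair] = c_xy / r_xy if r_xy > 0 else math.nan
    return EnrichmentTable(ratios=ratios, sparse_pairs=frozenset(sparse))


def _channel_arrays(a: ContributionVector, b: ContributionVector):
    union = sorted(set(a.channels) | set(b.channels))
    if not union:
        raise ValidationError("both contribution vectors are empty")
    va = np.array([a.channels.get(c, 0.0) for c in union])
    vb = np.array([b.channels.get(c, 0.0) for c in union])
    return union, va, vb


def contribution_rmsd(a: ContributionVector, b: ContributionVector) -> float:
    """RMSD over the channel union, absent channels zero-filled."""
    union, va, vb = _channel_arrays(a, b)
    return float(np.sqrt(np.mean((va - vb) ** 2)))


def contribution_euclidean(a: ContributionVector, b: ContributionVector) -> float:
    """Euclidean distance with the same zero-fill convention (= RMSD·√n)."""
    _, va, vb = _channel_arrays(a, b)
    return float(np.linalg.norm(va - vb))
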