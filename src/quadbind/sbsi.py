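"""Structure-binding strength indices (SBSI) for reference-based screening.

Each of the seven indices divides the difference of one docking energy term
between a reference ligand and a candidate by their structural
dissimilarity:

    index = (term_reference − term_ligand) / (1 − s),   0 ≤ s ≤ 1,

where s is a molecular similarity (fingerprint Tanimoto, atom-pair
Tanimoto, or maximum-common-substructure similarity).  The seven terms are
binding affinity (SBAI), hydrogen bonds (SHBI), steric (SSEI),
protein–ligand (SPLI), van der Waals (SVdWI), RNA template (SRNAI), and
metal coordination (SMEI), all in kJ/mol.

For a candidate identical to the reference (s = 1) the indices diverge; the
toolkit returns a signed infinity carrying the numerator's sign (+inf when
the numerator is zero, i.e. the reference against itself) rather than a
large float.  SBAI > 0 marks a candidate binding more strongly than the
reference (strongly binding / active); SBAI < 0 marks weak binders.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

from .nqr import ValidationError

__all__ = [
    "EnergyDecomposition",
    "SimilarityScores",
    "SBSIRecord",
    "SimilarityKind",
    "BindingClass",
    "TERM_INDEX_NAMES",
    "sbsi_index",
    "compute_all",
    "classify",
]


class SimilarityKind(str, enum.Enum):
    TANIMOTO = "tanimoto"
    ATOM_PAIR = "atom_pair"
    MCS = "mcs"


class BindingClass(str, enum.Enum):
    STRONGLY_BINDING = "strongly_binding"
    WEAKLY_BINDING = "weakly_binding"


#: docking term attribute -> SBSI index attribute
TERM_INDEX_NAMES = {
    "binding_affinity": "sbai",
    "hydrogen_bonds": "shbi",
    "steric": "ssei",
    "protein_ligand": "spli",
    "vdw": "svdwi",
    "rna_template": "srnai",
    "metal": "smei",
}


@dataclass(frozen=True)
class EnergyDecomposition:
    """Per-ligand docking energy terms, kJ/mol.

    ``binding_affinity`` comes from a separate affinity estimate and is kept
    distinct from the total of the decomposition terms. Terms may be None
    when a decomposition does not report them.
    """

    ligand_id: str
    binding_affinity: float | None = None
    total: float | None = None
    protein_ligand: float | None = None
    steric: float | None = None
    hydrogen_bonds: float | None = None
    vdw: float | None = None
    metal: float | None = None
    rna_template: float | None = None

    def __post_init__(self) -> None:
        for name in ("binding_affinity", "total", "protein_ligand", "steric",
                     "hydrogen_bonds", "vdw", "metal", "rna_template"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValidationError(f"{self.ligand_id}: {name} is not finite")


@dataclass(frozen=True)
class SimilarityScores:
    """Similarities of one ligand to the reference, each in [0, 1]."""

    ligand_id: str
    tanimoto: float
    atom_pair: float
    mcs: float

    def __post_init__(self) -> None:
        for name in ("tanimoto", "atom_pair", "mcs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"{self.ligand_id}: {name} similarity {v} outside [0, 1]"
                )

    def get(self, kind: SimilarityKind) -> float:
        return getattr(self, SimilarityKind(kind).value)


@dataclass(frozen=True)
class SBSIRecord:
    """All seven indices for one ligand under one similarity kind.

    Index values are kJ/mol; ±inf encodes the s = 1 sentinel; None marks a
    term absent from either decomposition.
    """

    ligand_id: str
    similarity_kind: SimilarityKind
    sbai: float | None = None
    shbi: float | None = None
    ssei: float | None = None
    spli: float | None = None
    svdwi: float | None = None
    srnai: float | None = None
    smei: float | None = None


def sbsi_index(reference_term: float, ligand_term: float,
               similarity: float) -> float:
    """(reference − ligand) / (1 − s); signed infinity at s = 1."""
    if not 0.0 <= similarity <= 1.0:
        raise ValidationError(f"similarity {similarity} outside [0, 1]")
    numerator = reference_term - ligand_term
    if similarity == 1.0:
        return math.copysign(math.inf, numerator) if numerator != 0 else math.inf
    return numerator / (1.0 - similarity)


def compute_all(
    reference: EnergyDecomposition,
    ligand: EnergyDecomposition,
    scores: SimilarityScores,
    similarity_kind: SimilarityKind | str = SimilarityKind.TANIMOTO,
) -> SBSIRecord:
    """Apply the common index form to each of the seven term pairs.

    A term missing from either decomposition yields an absent index with a
    warning, never a silent zero.
    """
    kind = SimilarityKind(similarity_kind)
    s = scores.get(kind)
    values: dict[str, float | None] = {}
    for term, index_name in TERM_INDEX_NAMES.items():
        ref_v = getattr(reference, term)
        lig_v = getattr(ligand, term)
        if ref_v is None or lig_v is None:
            warnings.warn(
                f"term {term!r} absent for "
                f"{reference.ligand_id if ref_v is None else ligand.ligand_id}; "
                f"{index_name} not computed",
                stacklevel=2,
            )
            values[index_name] = None
        else:
            values[index_name] = sbsi_index(ref_v, lig_v, s)
    return SBSIRecord(ligand_id=ligand.ligand_id, similarity_kind=kind, **values)


def classify(record: SBSIRecord) -> BindingClass:
    """Split candidates into strongly (SBAI > 0) vs weakly (SBAI < 0) binding.

    The s = 1 sentinel (+inf) classifies as strongly binding; an exact zero
    is classified strongly binding with a boundary warning.
    """
    sbai = record.sbai
    if sbai is None:
        raise ValidationError(
            f"{record.ligand_id}: SBAI absent, classification undefined"
        )
    if sbai == 0.0:
        warnings.warn(
            f"{record.ligand_id}: SBAI exactly 0, on the class boundary",
            stacklevel=2,
        )
        return BindingClass.STRONGLY_BINDING
    return (BindingClass.STRONGLY_BINDING if sbai > 0
            else BindingClass.WEAKLY_BINDING)
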