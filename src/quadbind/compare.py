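"""Binding-mode and structural-rigidity comparison metrics.

A binding mode is the vector of per-residue (and per-cofactor) interaction
energies describing how a ligand engages a protein pocket.  Two modes are
compared over the union of their residue identifiers, with residues
contacted by only one ligand contributing their full energy ("all bindings
included"; no interaction = zero energy):

    RMSD_BM(P, Q) = sqrt((1/n) Σ_i (p_i − q_i)²),  n = union size,

plus plain Manhattan (Σ|p_i − q_i|) and Euclidean distances.  Manhattan ≥
Euclidean holds for every input by the norm inequality.

Crystallographic rigidity is compared through normalized B-factors:
B′_i = (B_i − mean)/std per structure (population std), so that negative
B′ marks residues more rigid than the structure average.  ΔB′ is the
per-residue difference of two normalized profiles under a residue
alignment, summarized by windowed mean absolute deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nqr import ValidationError

__all__ = [
    "BindingMode",
    "BFactorProfile",
    "rmsd_bm",
    "mode_distance",
    "normalize_bfactors",
    "delta_bfactors",
    "mad_windows",
    "bfactors_from_pdb",
]


@dataclass(frozen=True)
class BindingMode:
    """Per-residue/cofactor interaction energies of one ligand, kJ/mol."""

    ligand_id: str
    entries: dict

    def __post_init__(self) -> None:
        for res, e in self.entries.items():
            if not math.isfinite(e):
                raise ValidationError(
                    f"{self.ligand_id}: non-finite energy for {res}"
                )


@dataclass(frozen=True)
class BFactorProfile:
    """Per-residue displacement parameters (Å²) of one structure."""

    structure_id: str
    bfactors: dict

    def __post_init__(self) -> None:
        if len(self.bfactors) < 2:
            raise ValidationError(
                f"{self.structure_id}: need at least 2 residues to normalize"
            )


def _difference_vector(P: BindingMode, Q: BindingMode) -> np.ndarray:
    keys = sorted(set(P.entries) | set(Q.entries), key=str)
    if not keys:
        raise ValidationError("both binding modes are empty")
    p = np.array([P.entries.get(k, 0.0) for k in keys])
    q = np.array([Q.entries.get(k, 0.0) for k in keys])
    return p - q


def rmsd_bm(P: BindingMode, Q: BindingMode) -> float:
    """Root mean square deviation of binding modes over the identifier union."""
    d = _difference_vector(P, Q)
    return float(np.sqrt(np.mean(d**2)))


def mode_distance(P: BindingMode, Q: BindingMode, metric: str = "manhattan") -> float:
    """Manhattan or Euclidean distance between zero-filled mode vectors."""
    d = _difference_vector(P, Q)
    if metric == "manhattan":
        return float(np.sum(np.abs(d)))
    if metric == "euclidean":
        return float(np.linalg.norm(d))
    raise ValidationError(f"unknown metric {metric!r} (manhattan|euclidean)")


def normalize_bfactors(profile: BFactorProfile) -> dict:
    """Z-score the profile: B′ = (B − mean)/std with population std.

    The output has mean 0 and standard deviation 1 regardless of the raw
    scale, making profiles from structures refined at different resolutions
    comparable.  A constant profile has no variance to normalize and is
    rejected.
    """
    keys = list(profile.bfactors)
    values = np.array([profile.bfactors[k] for k in keys], dtype=float)
    std = float(np.std(values))  # population std
    if std == 0.0:
        raise ValidationError(
            f"{profile.structure_id}: constant B-factor profile (zero variance)"
        )
    mean = float(np.mean(values))
    return {k: (profile.bfactors[k] - mean) / std for k in keys}


def delta_bfactors(
    a: BFactorProfile,
    b: BFactorProfile,
    alignment: dict | None = None,
) -> dict:
    """ΔB′ = B′_a − B′_b over aligned residues.

    ``alignment`` maps residue ids of ``a`` to residue ids of ``b``; by
    default residues with identical identifiers are paired (appropriate for
    near-identical chains), and a mapping overrides.
    """
    na, nb = normalize_bfactors(a), normalize_bfactors(b)
    if alignment is None:
        alignment = {k: k for k in na if k in nb}
    if not alignment:
        raise ValidationError("empty residue alignment")
    missing = [
        (ka, kb) for ka, kb in alignment.items() if ka not in na or kb not in nb
    ]
    if missing:
        raise ValidationError(f"alignment references absent residues: {missing[:5]}")
    return {ka: na[ka] - nb[kb] for ka, kb in alignment.items()}


def mad_windows(delta: dict, window: int = 10) -> list[tuple]:
    """Mean absolute deviation of ΔB′ over consecutive residue windows."""
    if window < 1:
        raise ValidationError("window must be >= 1")
    keys = list(delta)
    out = []
    for start in range(0, len(keys), window):
        chunk = keys[start:start + window]
        mad = float(np.mean([abs(delta[k]) for k in chunk]))
        out.append(((chunk[0], chunk[-1]), mad))
    return out


def bfactors_from_pdb(path, structure_id: str = "",
                      chain: str | None = None) -> BFactorProfile:
    """Extract per-residue B-factors from a PDB file.

    Uses the Cα atom where present, otherwise the mean over the residue's
    atoms.  Waters and other heteroatoms are skipped.
    """
    from Bio.PDB import PDBParser  # deferred: optional heavyweight import

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(structure_id or "structure", str(path))
    model = next(structure.get_models())
    bfactors = {}
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for residue in ch:
            if residue.id[0] != " ":  # heteroatom/water
                continue
            key = f"{ch.id}:{residue.id[1]}"
            if "CA" in residue:
                bfactors[key] = float(residue["CA"].get_bfactor())
            else:
                atoms = [a.get_bfactor() for a in residue]
                if atoms:
                    bfactors[key] = float(np.mean(atoms))
    if len(bfactors) < 2:
        raise ValidationError(f"{path}: fewer than 2 polymer residues found")
    return BFactorProfile(structure_id=structure_id or str(path),
                          bfactors=bfactors)
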