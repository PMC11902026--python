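"""Readers/writers for the toolkit's tabular formats and run configuration.

CSV dialect: comma-separated, UTF-8, "." decimal separator, header row
required.  Unicode minus signs (common in tables pasted from papers) are
normalized to ASCII on read.  Readers reject rows with missing required
columns with line-numbered diagnostics; writers round-trip at full
precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compare import BFactorProfile, BindingMode
from .contact_stats import ContactMatrix, ContributionVector
from .nqr import (EFGTensor, FrequencyTriplet, NQRParams, SiteRecord,
                  ValidationError, params_from_frequencies)
from .quad_indices import ContextParams
from .sbsi import EnergyDecomposition, SimilarityScores

__all__ = [
    "RunConfig",
    "load_config",
    "read_frequency_table",
    "write_params_table",
    "read_efg_tensors",
    "read_context_params",
    "read_energy_decompositions",
    "read_similarities",
    "read_contact_matrix",
    "read_contribution_vector",
    "read_binding_mode",
    "read_bfactor_csv",
]

_MINUS_VARIANTS = {"−": "-", "–": "-", "—": "-"}


@dataclass
class RunConfig:
    """Toolkit-wide settings; CLI flags override config-file values."""

    triplet_tolerance: float = 0.01
    fingerprint_length: int = 2048
    fingerprint_max_path: int = 7
    mcs_timeout: float = 10.0
    reference_ligand: str = "RBV"
    sparsity_threshold: float = 0.5
    closure_tolerance: float = 1.5
    verbosity: int = 0

    def __post_init__(self) -> None:
        for name in ("triplet_tolerance", "mcs_timeout", "sparsity_threshold",
                     "closure_tolerance"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config: {name} must be positive")


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a key-value document")
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)


def _normalize_minus(text: str) -> str:
    for bad, good in _MINUS_VARIANTS.items():
        text = text.replace(bad, good)
    return text


def _read_csv(path) -> pd.DataFrame:
    raw = Path(path).read_text(encoding="utf-8")
    from io import StringIO

    return pd.read_csv(StringIO(_normalize_minus(raw)), skipinitialspace=True)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    for col in required:
        bad = df.index[df[col].isna()]
        if len(bad):
            # +2: header line plus 1-based indexing
            raise ValidationError(
                f"{path}: missing {col!r} on line {int(bad[0]) + 2}"
            )


def read_frequency_table(path) -> list[SiteRecord]:
    """Read site,nu_plus,nu_minus[,nu_zero] from CSV or JSON (MHz).

    A missing nu_zero column (or cell) is derived as nu_plus − nu_minus.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(_normalize_minus(path.read_text(encoding="utf-8")))
        df = pd.DataFrame(rows)
    else:
        df = _read_csv(path)
    _require_columns(df, ["site", "nu_plus", "nu_minus"], path)
    records = []
    for _, row in df.iterrows():
        nu_p, nu_m = float(row["nu_plus"]), float(row["nu_minus"])
        nu_0 = row.get("nu_zero")
        nu_0 = (nu_p - nu_m) if nu_0 is None or pd.isna(nu_0) else float(nu_0)
        triplet = FrequencyTriplet(nu_plus=nu_p, nu_minus=nu_m, nu_zero=nu_0)
        records.append(
            SiteRecord(site_label=str(row["site"]), triplet=triplet,
                       params=params_from_frequencies(nu_p, nu_m))
        )
    return records


def write_params_table(records: list[SiteRecord], path) -> None:
    df = pd.DataFrame(
        {
            "site": [r.site_label for r in records],
            "nu_plus": [r.triplet.nu_plus for r in records],
            "nu_minus": [r.triplet.nu_minus for r in records],
            "nu_zero": [r.triplet.nu_zero for r in records],
            "cqcc": [r.params.cqcc for r in records],
            "eta": [r.params.eta for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_efg_tensors(path) -> dict[str, EFGTensor]:
    """JSON mapping site label -> 3×3 nested array, units atomic (au)."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    out = {}
    for site, entry in data.items():
        matrix = entry["components"] if isinstance(entry, dict) else entry
        if isinstance(entry, dict) and entry.get("units", "au") != "au":
            raise ValidationError(
                f"{path}: site {site!r} has units {entry['units']!r}, expected 'au'"
            )
        out[site] = EFGTensor(components=np.asarray(matrix, dtype=float))
    return out


def read_context_params(path) -> dict[str, list[ContextParams]]:
    """CSV compound,site,context,cqcc,eta with context in single|solid|complex."""
    df = _read_csv(path)
    _require_columns(df, ["compound", "site", "context", "cqcc", "eta"], path)
    context_field = {"single": "single_molecule", "solid": "solid",
                     "complex": "complex"}
    grouped: dict[str, dict[str, dict]] = {}
    for i, row in df.iterrows():
        ctx = str(row["context"]).strip().lower()
        if ctx not in context_field:
            raise ValidationError(
                f"{path}: line {i + 2}: unknown context {row['context']!r} "
                "(expected single|solid|complex)"
            )
        params = NQRParams(cqcc=float(row["cqcc"]), eta=float(row["eta"]))
        site_map = grouped.setdefault(str(row["compound"]), {})
        fields = site_map.setdefault(str(row["site"]), {})
        if context_field[ctx] in fields:
            raise ValidationError(
                f"{path}: line {i + 2}: duplicate context {ctx!r} for "
                f"{row['compound']}/{row['site']}"
            )
        fields[context_field[ctx]] = params
    return {
        compound: [
            ContextParams(site_label=site, **fields)
            for site, fields in site_map.items()
        ]
        for compound, site_map in grouped.items()
    }


_TERM_ROWS = {
    "Total energy": "total",
    "Protein-ligand": "protein_ligand",
    "Steric": "steric",
    "Hydrogen bonds": "hydrogen_bonds",
    "VdW": "vdw",
    "Metal": "metal",
    "RNA template": "rna_template",
    "Binding affinity": "binding_affinity",
}


def read_energy_decompositions(path, affinities=None) -> dict[str, EnergyDecomposition]:
    """Wide CSV: first column 'parameter' (term name), one column per ligand.

    ``affinities``, if given, is a CSV with columns ligand,binding_affinity
    merged into the result (the affinity estimate is computed separately
    from the decomposition terms).
    """
    df = _read_csv(path)
    _require_columns(df, ["parameter"], path)
    ligands = [c for c in df.columns if c != "parameter"]
    if not ligands:
        raise ValidationError(f"{path}: no ligand columns")
    values: dict[str, dict[str, float]] = {lig: {} for lig in ligands}
    for i, row in df.iterrows():
        term = _TERM_ROWS.get(str(row["parameter"]).strip())
        if term is None:
            raise ValidationError(
                f"{path}: line {i + 2}: unknown energy term "
                f"{row['parameter']!r} (expected one of {list(_TERM_ROWS)})"
            )
        for lig in ligands:
            if not pd.isna(row[lig]):
                values[lig][term] = float(row[lig])
    if affinities is not None:
        adf = _read_csv(affinities)
        _require_columns(adf, ["ligand", "binding_affinity"], affinities)
        for _, row in adf.iterrows():
            lig = str(row["ligand"])
            if lig in values:
                values[lig]["binding_affinity"] = float(row["binding_affinity"])
    return {
        lig: EnergyDecomposition(ligand_id=lig, **terms)
        for lig, terms in values.items()
    }


def read_similarities(path) -> dict[str, SimilarityScores]:
    """CSV ligand,tanimoto,atom_pair,mcs."""
    df = _read_csv(path)
    _require_columns(df, ["ligand", "tanimoto", "atom_pair", "mcs"], path)
    return {
        str(row["ligand"]): SimilarityScores(
            ligand_id=str(row["ligand"]),
            tanimoto=float(row["tanimoto"]),
            atom_pair=float(row["atom_pair"]),
            mcs=float(row["mcs"]),
        )
        for _, row in df.iterrows()
    }


def read_contact_matrix(path, structure_id: str = "") -> ContactMatrix:
    """Element × element CSV; first column holds row element symbols."""
    df = _read_csv(path)
    first = df.columns[0]
    elements = tuple(str(e) for e in df[first])
    if tuple(df.columns[1:]) != elements:
        raise ValidationError(
            f"{path}: row labels {elements} do not match column labels "
            f"{tuple(df.columns[1:])}"
        )
    contact = {}
    for i, x in enumerate(elements):
        for j, y in enumerate(elements):
            if j < i:
                continue
            v = df.iloc[i, j + 1]
            if not pd.isna(v):
                contact[(x, y)] = float(v)
    return ContactMatrix(elements=elements, contact_pct=contact,
                         structure_id=structure_id or str(path))


def read_contribution_vector(path, structure_id: str = "") -> ContributionVector:
    df = _read_csv(path)
    _require_columns(df, ["channel", "value"], path)
    return ContributionVector(
        channels={str(r["channel"]): float(r["value"]) for _, r in df.iterrows()},
        structure_id=structure_id or str(path),
    )


def read_binding_mode(path, ligand_id: str = "") -> BindingMode:
    df = _read_csv(path)
    _require_columns(df, ["residue_id", "energy"], path)
    return BindingMode(
        ligand_id=ligand_id or str(path),
        entries={str(r["residue_id"]): float(r["energy"]) for _, r in df.iterrows()},
    )


def read_bfactor_csv(path, structure_id: str = "") -> BFactorProfile:
    df = _read_csv(path)
    _require_columns(df, ["residue_id", "B"], path)
    return BFactorProfile(
        structure_id=structure_id or str(path),
        bfactors={str(r["residue_id"]): float(r["B"]) for _, r in df.iterrows()},
    )
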