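"""Quadrupolar indices: per-site NQR parameter shifts between contexts.

A nitrogen site can be characterized in three contexts — the isolated single
molecule, the crystalline solid, and the protein–ligand complex.  The six
quadrupolar indices quantify how binding reshapes the electron density at
the site, as differences of the NQR parameters between pairs of contexts:

    Δs  = |e²qQ/h|_solid   − |e²qQ/h|_single     δs  = η_solid   − η_single
    Δc  = |e²qQ/h|_complex − |e²qQ/h|_single     δc  = η_complex − η_single
    ΔCS = |e²qQ/h|_complex − |e²qQ/h|_solid      δCS = η_complex − η_solid

Δ values are in MHz, δ values dimensionless.  When all three contexts share
the same single-molecule reference, ΔCS = Δc − Δs and δCS = δc − δs hold
identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .nqr import NQRParams, ValidationError

__all__ = [
    "ContextParams",
    "QuadIndexRecord",
    "MissingContextError",
    "solid_state_indices",
    "complexation_indices",
    "solid_vs_complex_indices",
    "tabulate_indices",
]


class MissingContextError(ValidationError):
    """An index was requested for a site lacking one of its two contexts."""


@dataclass(frozen=True)
class ContextParams:
    """NQR parameters of one site in up to three contexts."""

    site_label: str
    single_molecule: NQRParams | None = None
    solid: NQRParams | None = None
    complex: NQRParams | None = None

    def _require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise MissingContextError(
                f"site {self.site_label!r}: missing context(s) {', '.join(missing)}"
            )


@dataclass(frozen=True)
class QuadIndexRecord:
    """One output row: all computable indices for one site (absent = None)."""

    site_label: str
    delta_s: float | None = None
    small_delta_s: float | None = None
    delta_c: float | None = None
    small_delta_c: float | None = None
    delta_cs: float | None = None
    small_delta_cs: float | None = None


def solid_state_indices(ctx: ContextParams) -> tuple[float, float]:
    """(Δs, δs): solid-state effect relative to the single molecule."""
    ctx._require("solid", "single_molecule")
    return (
        ctx.solid.cqcc - ctx.single_molecule.cqcc,
        ctx.solid.eta - ctx.single_molecule.eta,
    )


def complexation_indices(ctx: ContextParams) -> tuple[float, float]:
    """(Δc, δc): complexation effect relative to the single molecule."""
    ctx._require("complex", "single_molecule")
    return (
        ctx.complex.cqcc - ctx.single_molecule.cqcc,
        ctx.complex.eta - ctx.single_molecule.eta,
    )


def solid_vs_complex_indices(ctx: ContextParams) -> tuple[float, float]:
    """(ΔCS, δCS): complex-vs-solid difference of the binding motifs."""
    ctx._require("complex", "solid")
    return (
        ctx.complex.cqcc - ctx.solid.cqcc,
        ctx.complex.eta - ctx.solid.eta,
    )


def tabulate_indices(records: list[ContextParams]) -> pd.DataFrame:
    """Compute every index each record's contexts allow, one row per site.

    Absent contexts yield absent (NaN) index columns, never silent zeros.
    Duplicate site labels are rejected: each site must appear once per table.
    """
    if not records:
        raise ValidationError("tabulate_indices requires a non-empty record list")
    labels = [r.site_label for r in records]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValidationError(f"duplicate site labels: {sorted(dupes)}")

    rows = []
    for ctx in records:
        rec = {"site": ctx.site_label}
        pairs = (
            ("delta_s", "small_delta_s", solid_state_indices),
            ("delta_c", "small_delta_c", complexation_indices),
            ("delta_cs", "small_delta_cs", solid_vs_complex_indices),
        )
        for big, small, fn in pairs:
            try:
                rec[big], rec[small] = fn(ctx)
            except MissingContextError:
                rec[big], rec[small] = math.nan, math.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("site")
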