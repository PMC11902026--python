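"""¹⁴N NQR parameter algebra and spectral-line assignment.

A spin-1 nucleus such as ¹⁴N in zero field has three NQR transition
frequencies (ν₊, ν₋, ν₀) per chemically distinct site, fully determined by
two parameters of the electric field gradient (EFG) at the nucleus: the
quadrupole coupling constant e²qQ/h (MHz) and the asymmetry parameter
η ∈ [0, 1]:

    ν₊ = (e²qQ/4h)(3 + η),   ν₋ = (e²qQ/4h)(3 − η),   ν₀ = ν₊ − ν₋

and inversely

    e²qQ/h = (2/3)(ν₊ + ν₋),   η = 3(ν₊ − ν₋)/(ν₊ + ν₋).

This module provides the conversions in both directions, the reduction of a
diagonalized EFG tensor to (e²qQ/h, η), a combinatorial grouping of a raw
multi-line spectrum into internally consistent triplets (each triplet obeys
ν₀ ≈ ν₊ − ν₋), and the assignment of experimental sites to calculated
candidates by exhaustive correlation maximization.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants

__all__ = [
    "FrequencyTriplet",
    "NQRParams",
    "EFGTensor",
    "SiteRecord",
    "Assignment",
    "TripletGrouping",
    "params_from_frequencies",
    "frequencies_from_params",
    "efg_to_params",
    "group_lines",
    "assign_sites",
    "N14_QUADRUPOLE_MOMENT_FM2",
    "EFG_AU_BARN_TO_MHZ",
]

#: Nuclear quadrupole moment of ¹⁴N in fm² (1 barn = 100 fm²).
N14_QUADRUPOLE_MOMENT_FM2 = 2.044

#: Conversion constant: e²qQ/h in MHz per (Q in barn × q_zz in atomic units).
#: Derived from e * (1 a.u. of EFG) * (1 barn) / h, expressed in MHz:
#: e[C] · 9.717…e21[V m⁻²] · 1e−28[m²] / h[J s] / 1e6 ≈ 234.96 MHz/(barn·a.u.)
_EFG_AU = constants.physical_constants["atomic unit of electric field gradient"][0]
EFG_AU_BARN_TO_MHZ = constants.e * _EFG_AU * 1e-28 / constants.h / 1e6

#: Default consistency tolerance |ν₀ − (ν₊ − ν₋)| for triplets, MHz.
DEFAULT_TRIPLET_TOLERANCE = 0.01


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class FrequencyTriplet:
    """The three NQR transition frequencies of one nitrogen site, in MHz."""

    nu_plus: float
    nu_minus: float
    nu_zero: float

    def __post_init__(self) -> None:
        if self.nu_plus < self.nu_minus:
            raise ValidationError(
                f"nu_plus ({self.nu_plus}) must be >= nu_minus ({self.nu_minus})"
            )
        if self.nu_minus < 0:
            raise ValidationError(f"nu_minus must be >= 0, got {self.nu_minus}")

    @property
    def consistency_residual(self) -> float:
        """|ν₀ − (ν₊ − ν₋)|; zero for an exact spin-1 triplet."""
        return abs(self.nu_zero - (self.nu_plus - self.nu_minus))

    def is_consistent(self, tolerance: float = DEFAULT_TRIPLET_TOLERANCE) -> bool:
        return self.consistency_residual <= tolerance


@dataclass(frozen=True)
class NQRParams:
    """Quadrupole coupling constant magnitude |e²qQ/h| (MHz) and asymmetry η."""

    cqcc: float
    eta: float

    def __post_init__(self) -> None:
        if self.cqcc < 0:
            raise ValidationError(f"cqcc must be >= 0, got {self.cqcc}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValidationError(f"eta must lie in [0, 1], got {self.eta}")


@dataclass(frozen=True)
class EFGTensor:
    """A 3×3 real symmetric, traceless electric-field-gradient tensor (a.u.)."""

    components: np.ndarray
    symmetry_tolerance: float = 1e-8
    trace_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        m = np.asarray(self.components, dtype=float)
        if m.shape != (3, 3):
            raise ValidationError(f"EFG tensor must be 3x3, got shape {m.shape}")
        scale = max(1.0, float(np.abs(m).max()))
        if not np.allclose(m, m.T, atol=self.symmetry_tolerance * scale):
            raise ValidationError("EFG tensor is not symmetric within tolerance")
        if abs(float(np.trace(m))) > self.trace_tolerance * scale:
            raise ValidationError(
                f"EFG tensor trace {np.trace(m):.3e} violates the Laplace condition"
            )
        object.__setattr__(self, "components", m)

    def principal_values(self) -> np.ndarray:
        """Eigenvalues sorted by increasing magnitude: |q_xx| ≤ |q_yy| ≤ |q_zz|."""
        vals = np.linalg.eigvalsh(self.components)
        return vals[np.argsort(np.abs(vals), kind="stable")]


@dataclass(frozen=True)
class SiteRecord:
    """One nitrogen site: label, measured triplet, and derived parameters."""

    site_label: str
    triplet: FrequencyTriplet
    params: NQRParams


@dataclass(frozen=True)
class Assignment:
    """A bijection experimental-index → candidate-index with its fit quality."""

    pairs: dict[int, int]
    pearson_r: float
    fit_sd: float


@dataclass(frozen=True)
class TripletGrouping:
    """One way of grouping spectrum lines into consistent triplets.

    ``triplets`` hold the grouped lines (descending within each triplet);
    ``leftover`` lists input lines not absorbed into any triplet (only
    populated when grouping ran in leftover mode).
    """

    triplets: tuple[FrequencyTriplet, ...]
    leftover: tuple[float, ...] = field(default_factory=tuple)

    @property
    def total_residual(self) -> float:
        return sum(t.consistency_residual for t in self.triplets)


# ---------------------------------------------------------------------------
# parameter <-> frequency conversions
# ---------------------------------------------------------------------------

def params_from_frequencies(nu_plus: float, nu_minus: float) -> NQRParams:
    """Convert the two upper transition frequencies to (|e²qQ/h|, η).

    e²qQ/h = (2/3)(ν₊ + ν₋) and η = 3(ν₊ − ν₋)/(ν₊ + ν₋).  The precondition
    ν₊ ≥ ν₋ > 0 guarantees η ∈ [0, 1] because ν₊ ≤ 2ν₋ never needs to hold:
    η ≤ 1 ⟺ ν₊ ≤ 2ν₋, which is implied by the physics (ν₀ = ν₊ − ν₋ ≤ ν₋).
    """
    if nu_minus <= 0:
        raise ValidationError(f"nu_minus must be positive, got {nu_minus}")
    if nu_plus < nu_minus:
        raise ValidationError(
            f"nu_plus ({nu_plus}) must be >= nu_minus ({nu_minus})"
        )
    cqcc = (2.0 / 3.0) * (nu_plus + nu_minus)
    eta = 3.0 * (nu_plus - nu_minus) / (nu_plus + nu_minus)
    if eta > 1.0:
        raise ValidationError(
            f"frequencies ({nu_plus}, {nu_minus}) imply eta = {eta:.4f} > 1; "
            "not a valid spin-1 triplet (requires nu_plus <= 2 nu_minus)"
        )
    return NQRParams(cqcc=cqcc, eta=eta)


def frequencies_from_params(params: NQRParams) -> FrequencyTriplet:
    """Expand (|e²qQ/h|, η) into the transition triplet (ν₊, ν₋, ν₀)."""
    quarter = params.cqcc / 4.0
    nu_plus = quarter * (3.0 + params.eta)
    nu_minus = quarter * (3.0 - params.eta)
    return FrequencyTriplet(nu_plus=nu_plus, nu_minus=nu_minus,
                            nu_zero=nu_plus - nu_minus)


def efg_to_params(
    tensor: EFGTensor,
    quadrupole_moment: float = N14_QUADRUPOLE_MOMENT_FM2,
) -> tuple[NQRParams, dict]:
    """Reduce a diagonalizable EFG tensor to NQR parameters.

    Parameters
    ----------
    tensor
        Symmetric traceless EFG tensor in atomic units.
    quadrupole_moment
        Nuclear quadrupole moment in fm² (default: ¹⁴N, 2.044 fm²).

    Returns
    -------
    (params, meta)
        ``params`` holds |e²qQ/h| in MHz and η = |q_xx − q_yy| / |q_zz| with
        principal values ordered by magnitude |q_xx| ≤ |q_yy| ≤ |q_zz|.
        ``meta`` retains the signed principal values and the signed coupling
        constant, since only magnitudes enter the reported parameters.
    """
    if quadrupole_moment <= 0:
        raise ValidationError(
            f"quadrupole_moment must be positive, got {quadrupole_moment}"
        )
    q_xx, q_yy, q_zz = tensor.principal_values()
    if abs(q_zz) == 0.0:
        raise ValidationError(
            "degenerate EFG tensor: q_zz = 0, asymmetry parameter undefined"
        )
    eta = abs(q_xx - q_yy) / abs(q_zz)
    eta = min(eta, 1.0)  # clamp ulp-level overshoot for near-axial tensors
    q_barn = quadrupole_moment / 100.0  # 1 barn = 100 fm²
    cqcc_signed = EFG_AU_BARN_TO_MHZ * q_barn * q_zz
    params = NQRParams(cqcc=abs(cqcc_signed), eta=eta)
    meta = {
        "principal_values_au": (float(q_xx), float(q_yy), float(q_zz)),
        "cqcc_signed_mhz": float(cqcc_signed),
    }
    return params, meta


# ---------------------------------------------------------------------------
# spectral grouping and site assignment
# ---------------------------------------------------------------------------

def _triplet_from_lines(lines: tuple[float, float, float]) -> FrequencyTriplet:
    hi, mid, lo = sorted(lines, reverse=True)
    return FrequencyTriplet(nu_plus=hi, nu_minus=mid, nu_zero=lo)


def _consistent_triplets(
    lines: list[float], tolerance: float
) -> list[tuple[int, int, int]]:
    """Index triples whose sorted lines satisfy the ν₀ ≈ ν₊ − ν₋ constraint."""
    out = []
    for combo in itertools.combinations(range(len(lines)), 3):
        t = _triplet_from_lines(tuple(lines[i] for i in combo))
        if t.nu_minus <= 0:
            continue
        if t.is_consistent(tolerance):
            try:
                params_from_frequencies(t.nu_plus, t.nu_minus)
            except ValidationError:
                continue
            out.append(combo)
    return out


def group_lines(
    frequencies: list[float],
    tolerance: float = DEFAULT_TRIPLET_TOLERANCE,
    allow_leftover: bool = False,
) -> list[TripletGrouping]:
    """Partition a raw spectrum into consistent spin-1 triplets.

    Exhaustively searches partitions of the line list into disjoint triplets
    such that every triplet satisfies |ν₀ − (ν₊ − ν₋)| ≤ ``tolerance`` and
    yields a valid η ∈ [0, 1].  Results are sorted by total consistency
    residual, best first.

    With ``allow_leftover=True`` (for spectra containing spurious peaks from
    molecular motions), the search instead returns the groupings with the
    maximum number of disjoint consistent triplets, reporting unused lines.
    Otherwise the line count must be divisible by 3.
    """
    if tolerance <= 0:
        raise ValidationError(f"tolerance must be positive, got {tolerance}")
    if len(frequencies) < 3:
        raise ValidationError(
            f"need at least 3 lines to form a triplet, got {len(frequencies)}"
        )
    lines = [float(f) for f in frequencies]
    if not allow_leftover and len(lines) % 3 != 0:
        raise ValidationError(
            f"line count {len(lines)} is not divisible by 3; "
            "use allow_leftover=True for spectra with spurious lines"
        )

    candidates = _consistent_triplets(lines, tolerance)
    by_first: dict[int, list[tuple[int, int, int]]] = {}
    for combo in candidates:
        by_first.setdefault(combo[0], []).append(combo)

    results: list[tuple[tuple[tuple[int, int, int], ...], frozenset[int]]] = []
    n = len(lines)

    def extend(used: frozenset[int], chosen: tuple) -> None:
        remaining = [i for i in range(n) if i not in used]
        if not allow_leftover:
            if not remaining:
                results.append((chosen, used))
                return
            anchor = remaining[0]
            for combo in by_first.get(anchor, []):
                if used.isdisjoint(combo):
                    extend(used | frozenset(combo), chosen + (combo,))
        else:
            # every line is either the anchor of a later triplet or leftover;
            # enumerate maximal disjoint families by anchoring on the smallest
            # unused line that can still start a triplet
            extended = False
            for combo in candidates:
                if combo[0] in used or not used.isdisjoint(combo):
                    continue
                if chosen and combo < chosen[-1]:
                    continue  # enforce lexicographic order to avoid duplicates
                extended = True
                extend(used | frozenset(combo), chosen + (combo,))
            if not extended:
                results.append((chosen, used))

    extend(frozenset(), ())

    if allow_leftover and results:
        best = max(len(chosen) for chosen, _ in results)
        results = [r for r in results if len(r[0]) == best]

    seen: set[frozenset[frozenset[int]]] = set()
    groupings: list[TripletGrouping] = []
    for chosen, used in results:
        key = frozenset(frozenset(c) for c in chosen)
        if key in seen or not chosen:
            continue
        seen.add(key)
        triplets = tuple(
            _triplet_from_lines(tuple(lines[i] for i in combo)) for combo in chosen
        )
        leftover = tuple(lines[i] for i in range(n) if i not in used)
        groupings.append(TripletGrouping(triplets=triplets, leftover=leftover))

    groupings.sort(key=lambda g: g.total_residual)
    return groupings


def _frequencies_vector(params_list: list[NQRParams]) -> np.ndarray:
    out = []
    for p in params_list:
        t = frequencies_from_params(p)
        out.extend((t.nu_plus, t.nu_minus, t.nu_zero))
    return np.array(out)


def assign_sites(
    experimental: list[NQRParams],
    calculated: list[NQRParams],
) -> Assignment:
    """Match experimental sites to calculated candidates.

    Evaluates every bijection between the two equally sized lists.  For each
    bijection the three transition frequencies per site are regenerated from
    the parameters and the Pearson correlation between the 3n experimental
    and calculated frequencies is computed, together with the standard
    deviation of residuals about the identity line (fit_sd, MHz).  The
    bijection maximizing the correlation wins; ties break on smaller fit_sd,
    then on lexicographic assignment order — deterministic by construction.
    """
    if len(experimental) != len(calculated):
        raise ValidationError(
            f"site count mismatch: {len(experimental)} experimental vs "
            f"{len(calculated)} calculated"
        )
    n = len(experimental)
    if n < 2:
        raise ValidationError("at least 2 sites required (correlation undefined)")

    exp_freqs = np.array([
        _frequencies_vector([p]) for p in experimental
    ])  # shape (n, 3)
    calc_freqs = np.array([_frequencies_vector([p]) for p in calculated])

    best: tuple[float, float, tuple[int, ...]] | None = None
    for perm in itertools.permutations(range(n)):
        x = exp_freqs.reshape(-1)
        y = calc_freqs[list(perm)].reshape(-1)
        sx = float(np.std(x))
        sy = float(np.std(y))
        if sx == 0.0 or sy == 0.0:
            r = 1.0 if np.allclose(x, y) else 0.0
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        sd = float(np.sqrt(np.mean((x - y) ** 2)))
        key = (-r, sd, perm)
        if best is None or key < best:
            best = key
    neg_r, sd, perm = best
    return Assignment(
        pairs={i: perm[i] for i in range(n)},
        pearson_r=-neg_r,
        fit_sd=sd,
    )
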