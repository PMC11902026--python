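"""Binding-mode metrics and normalized B-factor differencing."""

import math

import numpy as np
import pytest

from quadbind import (
    BFactorProfile,
    BindingMode,
    ValidationError,
    delta_bfactors,
    mode_distance,
    normalize_bfactors,
    rmsd_bm,
)
from quadbind.compare import bfactors_from_pdb, mad_windows


def _mode(name, **entries):
    return BindingMode(ligand_id=name, entries=entries)


class TestRmsdBM:
    def test_identical_modes(self):
        p = _mode("p", r1=-4.0, r2=2.0)
        assert rmsd_bm(p, p) == 0.0

    def test_arithmetic_example(self):
        p = _mode("p", r1=-4.0, r2=0.0)
        q = _mode("q", r1=0.0, r2=3.0)
        assert rmsd_bm(p, q) == pytest.approx(math.sqrt((16 + 9) / 2))

    def test_union_zero_fill_semantics(self):
        # residues contacted by only one ligand contribute fully
        p = _mode("p", r1=-1.0)
        q = _mode("q", r2=-1.0)
        assert rmsd_bm(p, q) == pytest.approx(1.0)

    def test_empty_modes_rejected(self):
        with pytest.raises(ValidationError):
            rmsd_bm(_mode("p"), _mode("q"))


class TestModeDistance:
    def test_single_entry_difference(self):
        p = _mode("p", r1=5.0)
        q = _mode("q", r1=2.0)
        assert mode_distance(p, q, "manhattan") == 3.0
        assert mode_distance(p, q, "euclidean") == 3.0

    def test_three_four_five(self):
        p = _mode("p", r1=3.0, r2=4.0)
        q = _mode("q", r1=0.0, r2=0.0)
        assert mode_distance(p, q, "manhattan") == 7.0
        assert mode_distance(p, q, "euclidean") == 5.0

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValidationError, match="metric"):
            mode_distance(_mode("p", r1=1.0), _mode("q", r1=2.0), "cosine")

    def test_metric_axioms_and_norm_inequality(self, rng):
        """Non-negativity, symmetry, triangle inequality, and
        Manhattan ≥ Euclidean ≥ RMSD on random binding-mode triples."""
        residues = [f"r{i}" for i in range(12)]
        for _ in range(300):
            def draw():
                k = int(rng.integers(1, len(residues)))
                chosen = rng.choice(residues, size=k, replace=False)
                return BindingMode(
                    "x", {r: float(rng.normal(0, 20)) for r in chosen}
                )

            p, q, s = draw(), draw(), draw()
            for metric in ("manhattan", "euclidean"):
                d_pq = mode_distance(p, q, metric)
                assert d_pq >= 0.0
                assert d_pq == pytest.approx(mode_distance(q, p, metric))
                assert d_pq <= (mode_distance(p, s, metric)
                                + mode_distance(s, q, metric) + 1e-9)
            man = mode_distance(p, q, "manhattan")
            euc = mode_distance(p, q, "euclidean")
            assert man >= euc - 1e-12
            assert rmsd_bm(p, q) <= euc + 1e-12


class TestNormalizeBFactors:
    def test_three_residue_zscores(self):
        prof = BFactorProfile("s", {"1": 10.0, "2": 20.0, "3": 30.0})
        out = normalize_bfactors(prof)
        assert out["1"] == pytest.approx(-1.2247, abs=1e-4)
        assert out["2"] == pytest.approx(0.0, abs=1e-12)
        assert out["3"] == pytest.approx(1.2247, abs=1e-4)

    def test_output_is_standardized(self, rng):
        prof = BFactorProfile(
            "s", {str(i): float(v) for i, v in enumerate(rng.uniform(5, 80, 50))}
        )
        out = np.array(list(normalize_bfactors(prof).values()))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0, abs=1e-12)

    def test_two_residue_profile_is_unit(self):
        out = normalize_bfactors(BFactorProfile("s", {"a": 3.0, "b": 9.0}))
        assert out["a"] == pytest.approx(-1.0)
        assert out["b"] == pytest.approx(1.0)

    def test_translation_and_scale_invariance(self, rng):
        values = rng.uniform(10, 60, 20)
        p1 = BFactorProfile("a", {str(i): float(v) for i, v in enumerate(values)})
        p2 = BFactorProfile(
            "b", {str(i): float(3.5 * v + 11.0) for i, v in enumerate(values)}
        )
        n1, n2 = normalize_bfactors(p1), normalize_bfactors(p2)
        for k in n1:
            assert n1[k] == pytest.approx(n2[k], abs=1e-10)

    def test_constant_profile_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            normalize_bfactors(BFactorProfile("s", {"a": 5.0, "b": 5.0}))


class TestDeltaBFactors:
    def test_identical_profiles_zero_delta_and_mad(self):
        prof = BFactorProfile("s", {str(i): float(10 + i) for i in range(5)})
        delta = delta_bfactors(prof, prof)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in delta.values())
        assert mad_windows(delta, window=2)[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self):
        a = BFactorProfile("a", {str(i): float(v) for i, v in
                                 enumerate((12.0, 18.0, 25.0, 31.0, 44.0))})
        b = BFactorProfile("b", {str(i): float(v) for i, v in
                                 enumerate((44.0, 31.0, 25.0, 18.0, 12.0))})
        ab, ba = delta_bfactors(a, b), delta_bfactors(b, a)
        for k in ab:
            assert ab[k] == pytest.approx(-ba[k], abs=1e-12)

    def test_single_residue_shift_localized(self):
        base = {"1": 10.0, "2": 20.0, "3": 30.0, "4": 40.0, "5": 50.0}
        shifted = dict(base, **{"3": 35.0})
        delta = delta_bfactors(
            BFactorProfile("a", base), BFactorProfile("b", shifted)
        )
        # renormalization spreads a small residual everywhere; the shifted
        # residue must still dominate
        assert abs(delta["3"]) == max(abs(v) for v in delta.values())

    def test_explicit_alignment_override(self):
        a = BFactorProfile("a", {"x1": 10.0, "x2": 20.0})
        b = BFactorProfile("b", {"y1": 10.0, "y2": 20.0})
        delta = delta_bfactors(a, b, alignment={"x1": "y1", "x2": "y2"})
        assert delta == pytest.approx({"x1": 0.0, "x2": 0.0}, abs=1e-12)

    def test_empty_alignment_rejected(self):
        a = BFactorProfile("a", {"x1": 10.0, "x2": 20.0})
        b = BFactorProfile("b", {"y1": 10.0, "y2": 20.0})
        with pytest.raises(ValidationError, match="alignment"):
            delta_bfactors(a, b)


PDB_SNIPPET = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 20.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 25.00           C
ATOM      3  C   ALA A   1      12.428   7.340  -4.804  1.00 22.00           C
ATOM      4  N   GLY A   2      12.424   7.745  -3.531  1.00 30.00           N
ATOM      5  CA  GLY A   2      13.155   8.931  -3.100  1.00 35.00           C
ATOM      6  N   SER A   3      13.012   9.192  -1.775  1.00 41.00           N
ATOM      7  CA  SER A   3      13.622  10.360  -1.145  1.00 45.00           C
HETATM    8  O   HOH A 101      15.000  15.000  15.000  1.00 60.00           O
END
"""


def test_bfactor_extraction_from_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(PDB_SNIPPET)
    prof = bfactors_from_pdb(path, structure_id="toy")
    # Cα B-factors per residue; the water is skipped
    assert prof.bfactors == {"A:1": 25.0, "A:2": 35.0, "A:3": 45.0}
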