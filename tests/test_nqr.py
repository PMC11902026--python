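"""NQR parameter algebra, spectral grouping, and site assignment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadbind import (
    EFGTensor,
    FrequencyTriplet,
    NQRParams,
    ValidationError,
    assign_sites,
    efg_to_params,
    frequencies_from_params,
    group_lines,
    params_from_frequencies,
)
from quadbind.nqr import EFG_AU_BARN_TO_MHZ


class TestParamsFromFrequencies:
    @pytest.mark.parametrize(
        "nu_plus, nu_minus, cqcc, eta",
        [
            # experimental ribavirin sites (amide, two ring N, sugar N)
            (2.340, 1.700, 2.693, 0.475),
            (3.980, 2.650, 4.420, 0.602),
            (2.600, 2.280, 3.253, 0.197),
            (2.400, 1.480, 2.587, 0.711),
        ],
    )
    def test_reference_sites(self, nu_plus, nu_minus, cqcc, eta):
        p = params_from_frequencies(nu_plus, nu_minus)
        assert p.cqcc == pytest.approx(cqcc, abs=5e-4)
        assert p.eta == pytest.approx(eta, abs=5e-4)

    def test_degenerate_frequencies_force_zero_eta(self):
        p = params_from_frequencies(1.5, 1.5)
        assert p.eta == 0.0
        assert p.cqcc == pytest.approx(4 * 1.5 / 3)

    @pytest.mark.parametrize("nu_plus, nu_minus", [(1.0, -0.5), (1.0, 0.0), (1.0, 2.0)])
    def test_invalid_frequencies_rejected(self, nu_plus, nu_minus):
        with pytest.raises(ValidationError):
            params_from_frequencies(nu_plus, nu_minus)

    def test_unphysical_ratio_rejected(self):
        # nu_plus > 2 nu_minus implies eta > 1
        with pytest.raises(ValidationError, match="eta"):
            params_from_frequencies(3.0, 1.0)


class TestFrequenciesFromParams:
    def test_inverse_of_reference_site(self):
        t = frequencies_from_params(NQRParams(2.693, 0.475))
        assert t.nu_plus == pytest.approx(2.340, abs=2e-3)
        assert t.nu_minus == pytest.approx(1.700, abs=2e-3)
        assert t.nu_zero == pytest.approx(0.640, abs=2e-3)

    def test_axially_symmetric_site_collapses_to_doublet(self):
        t = frequencies_from_params(NQRParams(4.0, 0.0))
        assert t.nu_plus == t.nu_minus == pytest.approx(3.0)
        assert t.nu_zero == 0.0

    @given(
        cqcc=st.floats(0.1, 10.0),
        eta=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_roundtrip_is_identity(self, cqcc, eta):
        t = frequencies_from_params(NQRParams(cqcc, eta))
        p = params_from_frequencies(t.nu_plus, t.nu_minus)
        assert p.cqcc == pytest.approx(cqcc, rel=1e-9)
        assert p.eta == pytest.approx(eta, rel=1e-9, abs=1e-9)
        assert t.nu_zero == pytest.approx(t.nu_plus - t.nu_minus, rel=1e-9)


class TestEFGToParams:
    def test_axial_tensor_arithmetic(self):
        # independent arithmetic: cqcc = conv * Q[barn] * |q_zz|
        params, meta = efg_to_params(EFGTensor(np.diag([1.0, 1.0, -2.0])))
        assert params.eta == 0.0
        assert params.cqcc == pytest.approx(EFG_AU_BARN_TO_MHZ * 0.02044 * 2.0)
        assert meta["cqcc_signed_mhz"] < 0  # sign of q_zz retained

    def test_zero_tensor_is_degenerate(self):
        with pytest.raises(ValidationError, match="degenerate"):
            efg_to_params(EFGTensor(np.zeros((3, 3))))

    def test_asymmetric_matrix_rejected(self):
        m = np.diag([1.0, 1.0, -2.0])
        m[0, 1] = 0.5
        with pytest.raises(ValidationError, match="symmetric"):
            efg_to_params(EFGTensor(m))

    def test_traced_matrix_rejected(self):
        with pytest.raises(ValidationError, match="trace"):
            EFGTensor(np.diag([1.0, 1.0, 1.0]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, derandomize=True)
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(-3, 3, size=2)
        tensor = np.diag([vals[0], vals[1], -vals.sum()])
        if abs(tensor).max() < 1e-6:
            return
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = q @ tensor @ q.T
        rotated = 0.5 * (rotated + rotated.T)  # scrub fp asymmetry
        p1, _ = efg_to_params(EFGTensor(tensor))
        p2, _ = efg_to_params(EFGTensor(rotated))
        assert p2.cqcc == pytest.approx(p1.cqcc, rel=1e-9)
        assert p2.eta == pytest.approx(p1.eta, rel=1e-7, abs=1e-9)


from _oracles import brute_force_partitions


class TestGroupLines:
    def test_single_consistent_triplet(self):
        (g,) = group_lines([3.0, 2.0, 1.0])
        assert g.triplets[0] == FrequencyTriplet(3.0, 2.0, 1.0)

    def test_inconsistent_lines_yield_nothing(self):
        assert group_lines([3.0, 2.0, 0.5], tolerance=0.01) == []

    def test_count_not_divisible_by_three(self):
        with pytest.raises(ValidationError, match="divisible by 3"):
            group_lines([3.0, 2.0, 1.0, 0.5])

    def test_leftover_mode_absorbs_spurious_line(self):
        gs = group_lines([3.0, 2.0, 1.0, 0.123], tolerance=0.01,
                         allow_leftover=True)
        assert gs and gs[0].leftover == (0.123,)

    def test_ribavirin_spectrum_unique_partition(self, ribavirin_lines):
        shuffled = sorted(ribavirin_lines)  # any fixed order works
        gs = group_lines(shuffled, tolerance=0.005)
        assert len(gs) == 1
        got = {
            (t.nu_plus, t.nu_minus, t.nu_zero) for t in gs[0].triplets
        }
        assert got == {
            (2.340, 1.700, 0.640),
            (3.980, 2.650, 1.330),
            (2.600, 2.280, 0.320),
            (2.400, 1.480, 0.920),
        }

    @pytest.mark.parametrize("seed", [0, 1, 7, 42])
    def test_matches_brute_force_enumeration(self, seed):
        from quadbind import SyntheticSpectrumSpec, generate_spectrum

        lines, _ = generate_spectrum(
            SyntheticSpectrumSpec(n_sites=3, noise_sd=0.001, seed=seed)
        )
        tolerance = 0.01
        expected = brute_force_partitions(lines, tolerance)
        got = {
            frozenset(
                frozenset(
                    round(v, 9)
                    for v in (t.nu_plus, t.nu_minus, t.nu_zero)
                )
                for t in g.triplets
            )
            for g in group_lines(lines, tolerance=tolerance)
        }
        assert got == expected

    def test_all_emitted_triplets_have_valid_eta(self, ribavirin_lines):
        for g in group_lines(ribavirin_lines, tolerance=0.05):
            for t in g.triplets:
                p = params_from_frequencies(t.nu_plus, t.nu_minus)
                assert 0.0 <= p.eta <= 1.0


class TestAssignSites:
    def _table_params(self):
        return [
            params_from_frequencies(2.340, 1.700),
            params_from_frequencies(3.980, 2.650),
            params_from_frequencies(2.600, 2.280),
            params_from_frequencies(2.400, 1.480),
        ]

    def test_shuffled_identity_recovered(self):
        exp = self._table_params()
        order = [2, 0, 3, 1]
        calc = [exp[i] for i in order]
        a = assign_sites(exp, calc)
        assert [calc[a.pairs[i]] for i in range(4)] == exp
        assert a.pearson_r == pytest.approx(1.0)
        assert a.fit_sd == pytest.approx(0.0, abs=1e-12)

    def test_perturbed_candidates_keep_identity_assignment(self):
        exp = self._table_params()
        calc = [NQRParams(p.cqcc + 0.1, p.eta) for p in exp]
        a = assign_sites(exp, calc)
        assert a.pairs == {i: i for i in range(4)}
        assert a.pearson_r > 0.99

    def test_noisy_two_site_recovery(self, rng):
        exp = [NQRParams(2.7, 0.45), NQRParams(4.4, 0.60)]
        calc = [
            NQRParams(p.cqcc + rng.normal(0, 0.01), p.eta + rng.normal(0, 0.002))
            for p in exp
        ]
        a = assign_sites(exp, calc)
        assert a.pairs == {0: 0, 1: 1}

    def test_size_mismatch_and_small_input_rejected(self):
        p = NQRParams(2.7, 0.45)
        with pytest.raises(ValidationError, match="mismatch"):
            assign_sites([p, p], [p])
        with pytest.raises(ValidationError, match="at least 2"):
            assign_sites([p], [p])

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_attains_exhaustive_maximum(self, n, rng):
        """The returned bijection maximizes r over all n! bijections."""
        from scipy.stats import pearsonr

        exp = [
            NQRParams(float(rng.uniform(2, 5)), float(rng.uniform(0.05, 0.9)))
            for _ in range(n)
        ]
        calc = [
            NQRParams(p.cqcc * float(rng.uniform(0.9, 1.1)),
                      min(1.0, p.eta * float(rng.uniform(0.9, 1.1))))
            for p in exp
        ]
        a = assign_sites(exp, calc)

        def freqs(params_list):
            out = []
            for p in params_list:
                t = frequencies_from_params(p)
                out.extend((t.nu_plus, t.nu_minus, t.nu_zero))
            return out

        x = freqs(exp)
        best_r = max(
            pearsonr(x, freqs([calc[i] for i in perm])).statistic
            for perm in itertools.permutations(range(n))
        )
        assert a.pearson_r == pytest.approx(best_r, abs=1e-12)
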