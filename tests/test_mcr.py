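import itertools
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from chromspect.elution import fit_shared_rt, flank_spectra
from chromspect.io import ValidationError
from chromspect.mcr import (
    compare_spectra,
    discrete_frechet,
    mcr_ar,
    r_squared,
    unimodality_constraint,
)


def brute_force_frechet(P, Q):
    """Independent recursive-DP oracle over all monotone couplings."""
    P = [tuple(p) for p in np.atleast_2d(P)]
    Q = [tuple(q) for q in np.atleast_2d(Q)]

    @lru_cache(maxsize=None)
    def c(i, j):
        d = float(np.hypot(P[i][0] - Q[j][0], P[i][1] - Q[j][1]))
        if i == 0 and j == 0:
            return d
        if i == 0:
            return max(c(0, j - 1), d)
        if j == 0:
            return max(c(i - 1, 0), d)
        return max(min(c(i - 1, j), c(i - 1, j - 1), c(i, j - 1)), d)

    return c(len(P) - 1, len(Q) - 1)


class TestDiscreteFrechet:
    def test_equals_brute_force_on_short_random_curves(self, rng):
        for _ in range(25):
            n, m = rng.integers(2, 10, size=2)
            P = rng.normal(size=(n, 2))
            Q = rng.normal(size=(m, 2))
            assert discrete_frechet(P, Q) == pytest.approx(
                brute_force_frechet(P, Q), abs=1e-12
            )

    def test_hand_case_three_points(self):
        P = np.array([[0, 0], [0.5, 1.0], [1, 0]])
        Q = np.array([[0, 0], [0.5, 0.8], [1, 0]])
        assert discrete_frechet(P, Q) == pytest.approx(0.2)
        assert brute_force_frechet(P, Q) == pytest.approx(0.2)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(20):
            A, B, C = (rng.normal(size=(6, 2)) for _ in range(3))
            dab = discrete_frechet(A, B)
            dba = discrete_frechet(B, A)
            assert dab == pytest.approx(dba, abs=1e-12)          # symmetry
            assert discrete_frechet(A, A) == 0.0                 # identity
            dac = discrete_frechet(A, C)
            dcb = discrete_frechet(C, B)
            assert dab <= dac + dcb + 1e-12                      # triangle

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        P=arrays(float, (5, 2), elements=st.floats(-5, 5)),
        Q=arrays(float, (4, 2), elements=st.floats(-5, 5)),
    )
    def test_symmetry_and_oracle_agreement_property(self, P, Q):
        d = discrete_frechet(P, Q)
        assert d == pytest.approx(discrete_frechet(Q, P), abs=1e-12)
        assert d == pytest.approx(brute_force_frechet(P, Q), abs=1e-12)

    def test_zero_iff_identical(self, rng):
        A = rng.normal(size=(7, 2))
        B = A.copy()
        B[3] += 0.01
        assert discrete_frechet(A, A) == 0.0
        assert discrete_frechet(A, B) > 0.0


class TestCompareSpectra:
    def grid(self):
        return np.linspace(200, 400, 201)

    def test_identical_spectra(self):
        wl = self.grid()
        a = np.exp(-0.5 * ((wl - 300) / 20) ** 2)
        out = compare_spectra(wl, a, wl, a)
        assert out["r2"] == pytest.approx(1.0)
        assert out["frechet"] == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_versus_offset(self):
        wl = self.grid()
        a = np.exp(-0.5 * ((wl - 300) / 20) ** 2)  # baseline is 0
        scaled = compare_spectra(wl, a, wl, 2 * a)
        assert scaled["r2"] == pytest.approx(1.0)
        assert scaled["frechet"] == pytest.approx(0.0, abs=1e-12)
        offset = compare_spectra(wl, a, wl, 2 * a + 0.1)
        assert offset["r2"] == pytest.approx(1.0)
        assert offset["frechet"] > 0.01  # unit-max scaling does not remove offsets

    def test_insufficient_overlap_rejected(self):
        wl = self.grid()
        a = np.ones_like(wl)
        with pytest.raises(ValidationError):
            compare_spectra(wl, a, wl + 195, a)


class TestUnimodality:
    def test_two_bump_clipped_to_monotone_envelope(self):
        v = np.array([0.0, 2.0, 1.0, 3.0, 1.0, 2.0, 0.0])
        out = unimodality_constraint(v)
        m = int(np.argmax(out))
        assert np.all(np.diff(out[: m + 1]) >= 0)
        assert np.all(np.diff(out[m:]) <= 0)
        np.testing.assert_array_equal(out, [0, 1, 1, 3, 1, 1, 0])

    def test_already_unimodal_unchanged(self):
        v = np.array([0.0, 1.0, 4.0, 2.0, 0.5])
        np.testing.assert_array_equal(unimodality_constraint(v), v)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(v=arrays(float, 12, elements=st.floats(0, 10)))
    def test_idempotent_and_dominated(self, v):
        once = unimodality_constraint(v)
        np.testing.assert_array_equal(unimodality_constraint(once), once)
        assert np.all(once <= v + 1e-12)


def random_factors(rng, n_t=60, n_wl=40, k=3):
    t = np.linspace(0, 1, n_t)
    C = np.column_stack(
        [np.exp(-0.5 * ((t - mu) / 0.08) ** 2) for mu in (0.3, 0.5, 0.7)[:k]]
    )
    S = rng.random((n_wl, k))
    S /= S.max(axis=0, keepdims=True)
    return C, S


class TestMcrAr:
    def test_fixed_point_of_true_factors(self, rng):
        C, S = random_factors(rng)
        D = C @ S.T
        res = mcr_ar(D, S)
        assert res.iterations <= 3
        assert res.lack_of_fit < 1e-6

    def test_lack_of_fit_monotone_non_increasing(self, rng):
        C, S = random_factors(rng)
        D = C @ S.T + rng.normal(0, 0.02, (C.shape[0], S.shape[0]))
        D = np.clip(D, 0, None)
        S0 = np.clip(S + rng.normal(0, 0.15, S.shape), 0, None)
        res = mcr_ar(D, S0)
        assert np.all(np.diff(res.residual_history) <= 1e-9)

    def test_factors_non_negative_and_unit_max(self, rng):
        C, S = random_factors(rng)
        D = C @ S.T + rng.normal(0, 0.01, (C.shape[0], S.shape[0]))
        res = mcr_ar(np.clip(D, 0, None), np.clip(S + 0.1 * rng.random(S.shape), 0, None))
        assert (res.C >= 0).all() and (res.S >= 0).all()
        np.testing.assert_allclose(res.S.max(axis=0), 1.0)

    def test_permuting_s0_permutes_output(self, rng):
        C, S = random_factors(rng)
        D = C @ S.T
        perm = [2, 0, 1]
        a = mcr_ar(D, S)
        b = mcr_ar(D, S[:, perm])
        np.testing.assert_allclose(a.S[:, perm], b.S, atol=1e-8)

    def test_k_above_rank_bound_rejected(self, rng):
        D = rng.random((5, 40))
        with pytest.raises(ValidationError):
            mcr_ar(D, rng.random((40, 6)))


@pytest.fixture(scope="module")
def recoveries():
    """Deconvolved middle-species spectra for 3 replicate runs."""
    from chromspect.synthetic import hidden_peak_scenario

    out = []
    for seed in (11, 12, 13):
        chrom, truth = hidden_peak_scenario(seed)
        fit = fit_shared_rt(chrom, truth["window"], 3, rt_init=truth["rt"] + 0.02)
        S0, _ = flank_spectra(chrom, fit, truth["window"])
        sub = chrom.crop_time(*truth["window"])
        res = mcr_ar(sub.absorbance, S0)
        out.append((res.S[:, 1], truth))
    return out


class TestHiddenPeakRecovery:
    def test_middle_species_recovered(self, recoveries):
        for s_mid, truth in recoveries:
            assert r_squared(s_mid, truth["S"][:, 1]) >= 0.96

    def test_deconvolution_beats_convolved_apex_spectrum(self, recoveries):
        for s_mid, truth in recoveries:
            chrom_row = (truth["C"] @ truth["S"].T)[
                int(np.argmin(np.abs(truth["config"].time_grid - truth["rt"][1])))
            ]
            convolved_r2 = r_squared(chrom_row, truth["S"][:, 1])
            assert r_squared(s_mid, truth["S"][:, 1]) > convolved_r2

    def test_replicate_recoveries_agree(self, recoveries):
        specs = [s for s, _ in recoveries]
        for a, b in itertools.combinations(specs, 2):
            assert r_squared(a, b) >= 0.97
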