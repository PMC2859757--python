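import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lode.ld import (
    DegenerateLocusError,
    HaplotypeFreqs,
    _em_kernel,
    _em_scalar_trace,
    em_haplotype_freqs,
    genotype_table,
    ld_significance,
    pairwise_ld,
    r2_from_hapfreqs,
)
from lode.panel import SnpRecord

from .conftest import grid_search_r2, random_tables, tiny_panel


class TestEmHaplotypeFreqs:
    def test_phase_unambiguous_coupling_table(self):
        # only 0/0, 1/1, 2/2 genotype pairs: haplotypes must be 11 and 22
        t = np.array([[10, 0, 0], [0, 12, 0], [0, 0, 8]])
        h = em_haplotype_freqs(t)
        assert h.f11 + h.f22 == pytest.approx(1.0, abs=1e-12)
        assert r2_from_hapfreqs(h) == pytest.approx(1.0, abs=1e-9)

    def test_equilibrium_fixed_point(self):
        # Hardy-Weinberg products at p = q = 0.5, n = 64
        t = 64 * np.outer([0.25, 0.5, 0.25], [0.25, 0.5, 0.25])
        h = em_haplotype_freqs(t)
        for f in (h.f11, h.f12, h.f21, h.f22):
            assert f == pytest.approx(0.25, abs=1e-6)

    def test_matches_brute_force_likelihood_oracle(self):
        rng = np.random.default_rng(1234)
        for t in random_tables(25, rng, max_n=50):
            h = em_haplotype_freqs(t)
            assert r2_from_hapfreqs(h) == pytest.approx(grid_search_r2(t), abs=1e-3)

    def test_marginals_match_observed_allele_frequencies(self):
        rng = np.random.default_rng(5)
        for t in random_tables(10, rng):
            h = em_haplotype_freqs(t)
            n = t.sum()
            idx = np.arange(3.0)
            assert h.p_a == pytest.approx((t * idx[:, None]).sum() / (2 * n), abs=1e-9)
            assert h.p_b == pytest.approx((t * idx[None, :]).sum() / (2 * n), abs=1e-9)

    def test_monomorphic_locus_is_degenerate(self):
        with pytest.raises(DegenerateLocusError):
            em_haplotype_freqs(np.array([[5, 3, 1], [0, 0, 0], [0, 0, 0]]))

    def test_loglik_is_nondecreasing_along_iterations(self):
        rng = np.random.default_rng(99)
        for t in random_tables(20, rng):
            trace = _em_scalar_trace(t)
            diffs = np.diff(trace)
            assert (diffs >= -1e-9).all()


class TestR2FromHapfreqs:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ((0.5, 0.0, 0.0, 0.5), 1.0),  # perfect coupling
            ((0.25, 0.25, 0.25, 0.25), 0.0),  # equilibrium
            ((0.4, 0.1, 0.1, 0.4), 0.36),  # hand evaluation: D=0.15, denom=0.0625
        ],
    )
    def test_known_values(self, freqs, expected):
        h = HaplotypeFreqs(*freqs, loglik=0.0)
        assert r2_from_hapfreqs(h) == pytest.approx(expected)

    def test_degenerate_marginals_error(self):
        with pytest.raises(DegenerateLocusError):
            r2_from_hapfreqs(HaplotypeFreqs(0.5, 0.5, 0.0, 0.0, loglik=0.0))


class TestLdSignificance:
    def test_null_statistic_gives_p_one(self):
        assert ld_significance(0.0, 500) == 1.0

    def test_extreme_statistic(self):
        assert ld_significance(1.0, 100) < 1e-20

    def test_chi2_boundary_value(self):
        # chi2 = 6.64 on 1 df sits just inside the 0.01 level
        assert ld_significance(0.0664, 100) == pytest.approx(0.00997, abs=2e-5)

    def test_requires_two_observations(self):
        with pytest.raises(ValueError):
            ld_significance(0.5, 1)


class TestPairwiseLd:
    def test_duplicate_column_has_r2_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=150).tolist()
        other = rng.integers(0, 3, size=150).tolist()
        m = tiny_panel([col, col, other])
        ests = pairwise_ld(m.snps[0], [m.snps[1], m.snps[2]], m, min_obs=100)
        by = {e.snp_b: e for e in ests}
        assert by["s1"].r2 == pytest.approx(1.0)
        assert by["s1"].p_value < 1e-10 and by["s1"].passes_quality

    @pytest.mark.filterwarnings("ignore:panel has")
    def test_pair_with_too_few_shared_calls_is_skipped(self):
        col = [0, 1, 2, 1]
        anchor = [1, 0, 2, 1]
        missing = np.array(
            [[False, True], [False, True], [False, True], [False, False]]
        )
        m = tiny_panel([col, anchor], missing=missing)
        assert pairwise_ld(m.snps[0], [m.snps[1]], m, min_obs=2) == []

    def test_empty_anchor_list_is_an_error(self):
        m = tiny_panel([[0, 1, 2]])
        with pytest.raises(ValueError, match="empty anchor"):
            pairwise_ld(m.snps[0], [], m)

    def test_small_panel_emits_warning(self):
        rng = np.random.default_rng(3)
        m = tiny_panel([rng.integers(0, 3, 20).tolist(), rng.integers(0, 3, 20).tolist()])
        with pytest.warns(UserWarning, match="75 unrelated"):
            pairwise_ld(m.snps[0], [m.snps[1]], m, min_obs=2)

    def test_recovers_generating_r2_from_simulated_pair(self):
        # draw 500 diploids from known haplotype frequencies and re-estimate
        rng = np.random.default_rng(42)
        freqs = np.array([0.45, 0.05, 0.1, 0.4])  # r2 of the generator:
        pA, pB = 0.5, 0.55
        d = freqs[0] - pA * pB
        r2_true = d * d / (pA * (1 - pA) * pB * (1 - pB))
        haps = rng.choice(4, size=(500, 2), p=freqs)
        allele_a = (haps < 2).sum(axis=1)
        allele_b = np.isin(haps, (0, 2)).sum(axis=1)
        m = tiny_panel([allele_a.tolist(), allele_b.tolist()])
        est = pairwise_ld(m.snps[0], [m.snps[1]], m, min_obs=100)[0]
        assert est.r2 == pytest.approx(r2_true, abs=0.07)


class TestKernelProperties:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_r2_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        t = random_tables(1, rng)[0]
        r = _em_kernel(t.astype(float))
        rt = _em_kernel(t.T.astype(float))
        assert 0.0 <= r["r2"][0] <= 1.0
        assert r["r2"][0] == pytest.approx(rt["r2"][0], abs=1e-9)

    def test_em_equals_counting_when_double_het_empty(self):
        rng = np.random.default_rng(77)
        checked = 0
        for t in random_tables(40, rng):
            t = t.copy()
            t[1, 1] = 0
            res = _em_kernel(t.astype(float))
            if not res["valid"][0]:
                continue
            n = t.sum()
            kAB = 2 * t[2, 2] + t[2, 1] + t[1, 2]
            assert res["pAB"][0] == pytest.approx(kAB / (2 * n), abs=1e-12)
            checked += 1
        assert checked > 20

    def test_genotype_table_counts(self):
        a = np.array([0, 1, 2, 1, 0])
        b = np.array([0, 1, 2, 2, 1])
        t = genotype_table(a, b, missing_a=[False] * 5, missing_b=[False, False, False, False, True])
        assert t[0, 0] == 1 and t[1, 1] == 1 and t[2, 2] == 1 and t[1, 2] == 1
        assert t.sum() == 4
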