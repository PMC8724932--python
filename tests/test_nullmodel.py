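import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats as st

from lncpep.nullmodel import (
    DecoyConfig,
    NullModelParams,
    binomial_tail,
    decoy_match_count,
    empirical_pvalue,
    generate_decoy_segments,
    p_chance,
    segment_sequences,
)


def exact_upper_tail(k, n, p_frac):
    """Enumeration oracle: exact rational sum of C(n,j) p^j (1-p)^(n-j)."""
    total = Fraction(0)
    for j in range(k, n + 1):
        total += math.comb(n, j) * p_frac**j * (1 - p_frac) ** (n - j)
    return float(total)


class TestPChance:
    def test_study_parameters(self):
        assert p_chance(66, 50_000, 6, 2_000, 33) == pytest.approx(3.63e-6, rel=1e-3)

    def test_zero_matches(self):
        assert p_chance(0, 50_000, 6, 2_000, 33) == 0.0

    def test_single_slot(self):
        assert p_chance(1, 1, 1, 33, 33) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            p_chance(-1, 10)
        with pytest.raises(ValueError):
            p_chance(5, 0)
        with pytest.raises(ValueError):
            p_chance(100, 1, 1, 33, 33)  # m exceeds candidate slots


class TestBinomialTail:
    def test_k_zero_is_one(self):
        assert binomial_tail(0, 100, 0.3) == 1.0

    def test_exact_small_case(self):
        assert binomial_tail(5, 10, 0.5) == pytest.approx(638 / 1024, abs=1e-14)

    def test_matches_enumeration_small_n(self):
        for n in (1, 2, 5, 11, 23, 30):
            for p_frac in (Fraction(1, 10), Fraction(1, 2), Fraction(9, 10)):
                for k in range(n + 1):
                    expected = exact_upper_tail(k, n, p_frac)
                    assert binomial_tail(k, n, float(p_frac)) == pytest.approx(
                        expected, abs=1e-12
                    )

    def test_matches_scipy_large_n_small_p(self):
        for n, p, k in [
            (10**6, 1e-4, 150),
            (38_923_273, 3.63e-6, 195),
            (10**7, 5e-6, 30),
        ]:
            assert binomial_tail(k, n, p) == pytest.approx(
                st.binom.sf(k - 1, n, p), rel=1e-6
            )

    def test_monotone_nonincreasing_in_k(self):
        vals = [binomial_tail(k, 500, 0.02) for k in range(0, 60, 3)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_monotone_nondecreasing_in_p(self):
        vals = [binomial_tail(12, 500, p) for p in (0.005, 0.01, 0.02, 0.05, 0.1)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_poisson_limit_agreement(self):
        n = 10**6
        for lam in (50, 200, 500):
            p = lam / n
            k = lam + int(3 * math.sqrt(lam))
            assert binomial_tail(k, n, p) == pytest.approx(
                st.poisson.sf(k - 1, lam), rel=0.02
            )

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            binomial_tail(5, 3, 0.5)
        with pytest.raises(ValueError):
            binomial_tail(1, 3, 1.5)
        with pytest.raises(TypeError):
            binomial_tail(1.5, 3, 0.5)

    def test_degenerate_p(self):
        assert binomial_tail(1, 10, 0.0) == 0.0
        assert binomial_tail(10, 10, 1.0) == 1.0


class TestEmpiricalPvalue:
    def test_study_parameters_reproduce_reported_pvalue(self):
        params = NullModelParams(m_decoy_matches=66, k_observed=195)
        p_ch, p_val = empirical_pvalue(params)
        assert p_ch == pytest.approx(3.63e-6, rel=1e-3)
        assert p_val == pytest.approx(1.1e-5, rel=0.2)

    def test_k_zero_gives_one(self):
        params = NullModelParams(m_decoy_matches=66, k_observed=0)
        assert empirical_pvalue(params)[1] == 1.0

    def test_doubling_decoy_matches_increases_pvalue(self):
        base = empirical_pvalue(NullModelParams(m_decoy_matches=66, k_observed=195))[1]
        doubled = empirical_pvalue(NullModelParams(m_decoy_matches=132, k_observed=195))[1]
        assert doubled > base


class TestDecoyGeneration:
    def _toy_genome(self, seed=0, length=10_000, with_n=False):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if with_n:
            seq = seq[:4000] + "N" * 500 + seq[4500:]
        return [("chr1", seq)]

    def test_disjoint_and_reproducible(self):
        genome = self._toy_genome()
        config = DecoyConfig(n_segments=3, segment_len_nt=2_000, seed=1)
        segs = generate_decoy_segments(genome, config)
        assert len(segs) == 3
        ordered = sorted(segs)
        for (c1, s1, e1), (c2, s2, e2) in zip(ordered, ordered[1:]):
            assert c1 != c2 or e1 <= s2
        assert segs == generate_decoy_segments(genome, config)

    def test_capacity_error_states_requirement(self):
        genome = self._toy_genome(length=3_000)
        with pytest.raises(ValueError, match="6000"):
            generate_decoy_segments(genome, DecoyConfig(n_segments=3, segment_len_nt=2_000))

    def test_same_seed_identical_different_seed_not(self):
        genome = self._toy_genome(seed=3, length=50_000)
        a = generate_decoy_segments(genome, DecoyConfig(10, 1_000, seed=7))
        b = generate_decoy_segments(genome, DecoyConfig(10, 1_000, seed=7))
        c = generate_decoy_segments(genome, DecoyConfig(10, 1_000, seed=8))
        assert a == b
        assert a != c

    def test_n_segments_resampled(self):
        genome = self._toy_genome(with_n=True)
        config = DecoyConfig(n_segments=4, segment_len_nt=1_000, seed=2)
        for chrom, s, e in generate_decoy_segments(genome, config):
            assert "N" not in genome[0][1][s:e]

    def test_segments_within_chromosomes(self):
        genome = [("chr1", "ACGT" * 1_000), ("chr2", "TTAA" * 500)]
        config = DecoyConfig(n_segments=5, segment_len_nt=500, seed=4)
        for chrom, s, e in generate_decoy_segments(genome, config):
            assert 0 <= s < e <= len(dict(genome)[chrom])
            assert e - s == 500

    def test_decoy_match_count_counts_distinct_peptides(self):
        # decoy translated in frame +1 contains MKWWH; decoy peptide absent
        records = [("d1", "ATGAAATGGTGGCATTAA")]
        assert decoy_match_count(["MKWWH", "YYYYYYYY"], records) == 1

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DecoyConfig(n_segments=0)
        with pytest.raises(ValueError):
            DecoyConfig(segment_len_nt=10)
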