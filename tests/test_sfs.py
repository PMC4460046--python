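"""SFS neutrality statistics: worked examples, oracles and invariants."""
import math

import numpy as np
import pytest

from conftest import block_from_strings, random_block
from ncselect.sfs import (
    fay_wu_h,
    fu_li_star,
    nucleotide_diversity,
    observed_heterozygosity,
    sfs_constants,
    sfs_summary,
    site_counts,
    tajimas_d,
    watterson_theta,
)


def brute_pi_total(block):
    """Mean pairwise differences by explicit enumeration of all pairs."""
    n = block.n_haplotypes
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(block.alleles[i] != block.alleles[j]))
            pairs += 1
    return total / pairs


class TestDiversity:
    def test_identical_haplotypes_zero(self):
        b = block_from_strings(["0000", "0000"])
        assert nucleotide_diversity(b, L=4) == 0.0

    def test_hand_enumeration_three_haplotypes(self):
        # pairs: (00,01)=1, (00,11)=2, (01,11)=1 -> mean 4/3; per site 2/3
        b = block_from_strings(["00", "01", "11"])
        assert nucleotide_diversity(b) == pytest.approx(4 / 3)
        assert nucleotide_diversity(b, L=2) == pytest.approx(2 / 3)

    def test_frequency_identity_matches_pairwise(self, rng):
        for _ in range(20):
            b = random_block(rng, n_hap=int(rng.integers(2, 9)), n_sites=int(rng.integers(1, 15)))
            assert nucleotide_diversity(b) == pytest.approx(brute_pi_total(b), abs=1e-12)

    def test_rejects_nonpositive_length(self):
        b = block_from_strings(["00", "01"])
        with pytest.raises(ValueError):
            nucleotide_diversity(b, L=0)


class TestTajimasD:
    def test_worked_example_n4(self):
        # S=3, pi_total=10/6, theta_W=3/(11/6)=18/11, numerator=1/33
        b = block_from_strings(["000", "001", "011", "111"])
        k = sfs_constants(4)
        assert k.a1 == pytest.approx(11 / 6)
        num = 5 / 3 - 18 / 11
        expected = num / math.sqrt(k.e1 * 3 + k.e2 * 3 * 2)
        assert tajimas_d(b) == pytest.approx(expected, abs=1e-12)
        assert num == pytest.approx(1 / 33)

    def test_undefined_when_no_segregating_sites(self):
        b = block_from_strings(["0000", "0000", "0000", "0000"])
        assert math.isnan(tajimas_d(b))

    def test_numerator_sign_matches_pi_minus_theta(self, rng):
        for _ in range(20):
            b = random_block(rng, n_hap=8, n_sites=12)
            d = tajimas_d(b)
            diff = nucleotide_diversity(b) - watterson_theta(b)
            assert math.copysign(1, d) == math.copysign(1, diff) or diff == 0

    def test_matches_tskit_on_msprime_data(self):
        """Independent oracle: tskit's Tajima's D on msprime genotypes."""
        msprime = pytest.importorskip("msprime")
        from ncselect.datamodel import HaplotypeBlock

        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(10):
            ts = msprime.sim_ancestry(
                samples=10, ploidy=2, sequence_length=10_000,
                random_seed=int(rng.integers(1, 2**31)),
            )
            mts = msprime.sim_mutations(
                ts, rate=2.5e-4, random_seed=int(rng.integers(1, 2**31)),
                discrete_genome=False,
            )
            G = mts.genotype_matrix()
            if G.shape[0] == 0:
                continue
            blk = HaplotypeBlock(
                "c", np.arange(G.shape[0]), (G.T > 0).astype(np.uint8),
                np.ones(G.shape[0], bool),
            )
            assert tajimas_d(blk) == pytest.approx(mts.Tajimas_D(), abs=1e-10)
            checked += 1
        assert checked >= 5


class TestFuLiStar:
    def test_no_singletons_positive_numerator_sign(self):
        # every variant at count 2 of n=4: eta_s=0 -> D* numerator (n/(n-1))S > 0
        b = block_from_strings(["0011", "0011", "1100", "1100"]).take_haplotypes(np.arange(4))
        d_star, _ = fu_li_star(b)
        assert d_star > 0

    def test_constants_match_closed_form_dstar(self):
        """Covariance-derived D* constants equal the published closed form."""
        for n in (6, 20, 50):
            k = sfs_constants(n)
            v = (
                (n / (n - 1)) ** 2 * k.a2
                + k.a1**2 * k.dn
                - 2 * n * k.a1 * (k.a1 + 1) / ((n - 1) ** 2)
            ) / (k.a1**2 + k.a2)
            u = (n / (n - 1)) * (k.a1 - n / (n - 1)) - v
            assert k.v_dstar == pytest.approx(v, abs=1e-12)
            assert k.u_dstar == pytest.approx(u, abs=1e-12)

    def test_variance_constants_match_coalescent_monte_carlo(self):
        """Var(numerator) from simulation vs the (u,v)-implied variance."""
        from ncselect.simulate import SimConfig, simulate_neutral
        from ncselect.sfs import _minor_singletons, _pi_total

        n, theta = 6, 2.0
        rng = np.random.default_rng(7)
        cfg = SimConfig(n_haplotypes=n, theta=theta)
        num_d, num_f = [], []
        for _ in range(30_000):
            b = simulate_neutral(cfg, rng)
            c = site_counts(b)
            S, eta = c.size, _minor_singletons(c, n)
            num_d.append((n / (n - 1)) * S - sfs_constants(n).a1 * eta)
            num_f.append(_pi_total(c, n) - ((n - 1) / n) * eta)
        k = sfs_constants(n)
        ab = k.a1**2 + k.a2
        theo_d = (k.u_dstar + k.v_dstar) * k.a1 * theta + k.v_dstar * ab * theta**2
        theo_f = (k.u_fstar + k.v_fstar) * k.a1 * theta + k.v_fstar * ab * theta**2
        assert np.var(num_d) == pytest.approx(theo_d, rel=0.1)
        assert np.var(num_f) == pytest.approx(theo_f, rel=0.1)

    def test_undefined_for_small_samples(self):
        b = block_from_strings(["01", "10", "00"])
        d_star, f_star = fu_li_star(b)
        assert math.isnan(d_star) and math.isnan(f_star)


class TestFayWuH:
    def test_high_frequency_derived_worked_example(self):
        # one site at derived count 3 of n=4: theta_H=1.5, pi=0.5, H=-1
        b = block_from_strings(["0", "1", "1", "1"])
        assert fay_wu_h(b) == pytest.approx(-1.0)

    def test_n2_identity_zero(self):
        # at n=2 every polymorphism is a singleton: pi_total == theta_H
        b = block_from_strings(["010", "101"])
        assert fay_wu_h(b) == pytest.approx(0.0)

    def test_unknown_ancestral_sites_excluded(self):
        b = block_from_strings(
            ["01", "11", "11", "10"], ancestral_known=[False, True]
        )
        only_second = block_from_strings(["1", "1", "1", "0"])
        assert fay_wu_h(b) == pytest.approx(fay_wu_h(only_second))

    def test_all_unpolarized_undefined(self):
        b = block_from_strings(["01", "10"], ancestral_known=[False, False])
        assert math.isnan(fay_wu_h(b))


class TestObservedHeterozygosity:
    def test_all_homozygous(self):
        b = block_from_strings(["11", "11", "00", "00"])
        assert observed_heterozygosity(b) == 0.0

    def test_half_heterozygous_single_site(self):
        b = block_from_strings(["1", "0", "1", "1"])
        assert observed_heterozygosity(b) == 0.5

    def test_matches_brute_force(self, rng):
        b = random_block(rng, n_hap=8, n_sites=20)
        expected = np.mean(
            [
                np.mean([b.alleles[2 * i, j] != b.alleles[2 * i + 1, j] for i in range(4)])
                for j in range(20)
            ]
        )
        assert observed_heterozygosity(b) == pytest.approx(expected)

    def test_odd_haplotype_count_rejected(self):
        b = block_from_strings(["0", "1", "1"])
        with pytest.raises(ValueError):
            observed_heterozygosity(b)


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.lists(st.integers(0, 1), min_size=4, max_size=8),
            min_size=2,
            max_size=12,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_pi_identity_property(data):
        """π frequency form equals all-pairs enumeration on any matrix."""
        b = block_from_strings(["".join(map(str, r)) for r in data])
        assert nucleotide_diversity(b) == pytest.approx(brute_pi_total(b), abs=1e-12)

except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


class TestInvariances:
    def test_statistics_invariant_to_reordering(self, rng):
        b = random_block(rng, n_hap=8, n_sites=12)
        hap_perm = rng.permutation(8)
        b2 = b.take_haplotypes(hap_perm)
        for f in (tajimas_d, fay_wu_h, nucleotide_diversity):
            assert f(b) == pytest.approx(f(b2), abs=1e-12)
        assert fu_li_star(b) == pytest.approx(fu_li_star(b2), abs=1e-12)

    def test_summary_flags_empty_window(self):
        b = block_from_strings(["000", "000", "000", "000"])
        s = sfs_summary(b, L=1000)
        assert not s.defined
        assert s.S == 0
        assert math.isnan(s.tajima_d)
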