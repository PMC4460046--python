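"""Allele frequencies, Weir-Cockerham F_ST, binning, conservation classes."""
import numpy as np
import pandas as pd
import pytest

from conftest import block_from_strings
from ncselect.datamodel import ConservationTrack, ElementTrack, HaplotypeBlock, PopulationPanel
from ncselect.freq import (
    bin_spectrum,
    classify_conservation,
    element_conserved_fraction,
    fraction_low_daf,
    global_and_pairwise_fst,
    maf_daf,
    weir_cockerham_fst,
)


def two_pop_block(rng, n1=10, n2=12, n_sites=25):
    """Random block whose haplotypes split into two labelled populations."""
    alleles = rng.integers(0, 2, size=(n1 + n2, n_sites)).astype(np.uint8)
    ids = [f"a{i}_{h}" for i in range(n1 // 2) for h in (1, 2)]
    ids += [f"b{i}_{h}" for i in range(n2 // 2) for h in (1, 2)]
    block = HaplotypeBlock(
        chrom="chr1",
        positions=np.arange(n_sites),
        alleles=alleles,
        ancestral_known=np.ones(n_sites, bool),
        sample_ids=ids,
    )
    panel = PopulationPanel(
        pd.DataFrame(
            [(f"a{i}", "P1", "S1") for i in range(n1 // 2)]
            + [(f"b{i}", "P2", "S2") for i in range(n2 // 2)],
            columns=["sample", "pop", "superpop"],
        )
    )
    return block, panel


def anova_theta(p, n):
    """Independent mean-squares route to the haploid W&C estimator."""
    r = len(n)
    nbar = np.mean(n)
    nc = (r * nbar - np.sum(np.square(n)) / (r * nbar)) / (r - 1)
    pbar = np.sum(n[:, None] * p, axis=0) / n.sum()
    msp = np.sum(n[:, None] * (p - pbar) ** 2, axis=0) / (r - 1)
    msg = np.sum(n[:, None] * p * (1 - p), axis=0) / np.sum(n - 1)
    return (msp - msg) / (msp + (nc - 1) * msg)


class TestWeirCockerham:
    def test_matches_anova_route_exactly(self, rng):
        block, panel = two_pop_block(rng)
        res = weir_cockerham_fst(block, panel, ["P1", "P2"])
        idx1 = panel.haplotype_indices(block, "P1")
        idx2 = panel.haplotype_indices(block, "P2")
        p = np.stack([block.alleles[idx1].mean(0), block.alleles[idx2].mean(0)])
        n = np.array([idx1.size, idx2.size], dtype=float)
        expected = anova_theta(p, n)
        d = res.defined
        assert np.allclose(res.theta[d], expected[d], atol=1e-10)

    def test_no_differentiation_small_or_negative(self):
        # p1 == p2 with equal n: s2=0 so theta <= 0
        b = block_from_strings(["01", "10", "01", "10"])
        b.sample_ids = ["a0_1", "a0_2", "b0_1", "b0_2"]
        panel = PopulationPanel(
            pd.DataFrame([("a0", "P1", "S1"), ("b0", "P2", "S2")],
                         columns=["sample", "pop", "superpop"])
        )
        res = weir_cockerham_fst(b, panel, ["P1", "P2"])
        assert np.all(res.theta[res.defined] <= 0)

    def test_fixed_difference_approaches_one(self, rng):
        n = 100
        alleles = np.zeros((2 * n, 1), dtype=np.uint8)
        alleles[:n] = 1
        ids = [f"a{i}_{h}" for i in range(n // 2) for h in (1, 2)]
        ids += [f"b{i}_{h}" for i in range(n // 2) for h in (1, 2)]
        b = HaplotypeBlock("c", np.array([0]), alleles, np.array([True]), ids)
        panel = PopulationPanel(
            pd.DataFrame(
                [(f"a{i}", "P1", "S1") for i in range(n // 2)]
                + [(f"b{i}", "P2", "S2") for i in range(n // 2)],
                columns=["sample", "pop", "superpop"],
            )
        )
        res = weir_cockerham_fst(b, panel, ["P1", "P2"])
        assert res.theta[0] > 0.98

    def test_allele_label_swap_invariant(self, rng):
        block, panel = two_pop_block(rng)
        res1 = weir_cockerham_fst(block, panel, ["P1", "P2"])
        flipped = HaplotypeBlock(
            block.chrom, block.positions, 1 - block.alleles,
            block.ancestral_known, block.sample_ids,
        )
        res2 = weir_cockerham_fst(flipped, panel, ["P1", "P2"])
        assert np.allclose(res1.a, res2.a, atol=1e-12)
        assert np.allclose(res1.b, res2.b, atol=1e-12)

    def test_monomorphic_site_undefined(self):
        b = block_from_strings(["00", "01", "00", "01"])
        b.sample_ids = ["a0_1", "a0_2", "b0_1", "b0_2"]
        panel = PopulationPanel(
            pd.DataFrame([("a0", "P1", "S1"), ("b0", "P2", "S2")],
                         columns=["sample", "pop", "superpop"])
        )
        res = weir_cockerham_fst(b, panel, ["P1", "P2"])
        assert not res.defined[0]   # first site monomorphic
        assert res.defined[1]


class TestGlobalPairwise:
    def test_identical_populations_global_nonpositive(self, rng):
        base = rng.integers(0, 2, size=(2, 10)).astype(np.uint8)
        alleles = np.concatenate([np.tile(base, (3, 1))])
        ids = [f"{p}{0}_{h}" for p in "abc" for h in (1, 2)]
        b = HaplotypeBlock("c", np.arange(10), alleles, np.ones(10, bool), ids)
        panel = PopulationPanel(
            pd.DataFrame(
                [("a0", "P1", "S1"), ("b0", "P2", "S2"), ("c0", "P3", "S3")],
                columns=["sample", "pop", "superpop"],
            )
        )
        out = global_and_pairwise_fst(b, panel, global_pops=["P1", "P2", "P3"])
        vals = out["fst_global"].dropna()
        assert (vals <= 1e-12).all()

    def test_pairwise_columns_cover_superpop_pairs(self, rng):
        block, panel = two_pop_block(rng)
        out = global_and_pairwise_fst(block, panel, global_pops=["P1", "P2"])
        assert "fst_S1_S2" in out.columns


class TestMafDaf:
    def test_basic_and_unknown_ancestral(self):
        b = block_from_strings(
            ["11", "11", "11", "10", "00", "00", "00", "00", "00", "00"],
            ancestral_known=[True, False],
        )
        out = maf_daf(b)
        assert out["daf"][0] == pytest.approx(0.4)
        assert out["maf"][0] == pytest.approx(0.4)
        assert np.isnan(out["daf"][1])
        assert out["maf"][1] == pytest.approx(0.3)

    def test_neutral_spectrum_shape(self):
        """Mean neutral SFS class counts match E[ξ_i] = θ/i within MC error.

        A pooled χ² goodness-of-fit would over-reject here because sites
        within one replicate share a genealogy; per-class replicate means
        with empirical SEs are the sound comparison.
        """
        from ncselect.simulate import SimConfig, simulate_neutral

        rng = np.random.default_rng(31)
        n, theta, reps = 10, 5.0, 600
        cfg = SimConfig(n_haplotypes=n, theta=theta)
        per_rep = np.zeros((reps, n - 1))
        for r in range(reps):
            b = simulate_neutral(cfg, rng)
            per_rep[r] = np.bincount(b.derived_counts(), minlength=n)[1:n]
        means = per_rep.mean(axis=0)
        ses = per_rep.std(axis=0) / np.sqrt(reps)
        expected = theta / np.arange(1, n)
        assert np.all(np.abs(means - expected) < 4 * ses)


class TestBinSpectrum:
    def test_edge_value_goes_right(self):
        counts, _ = bin_spectrum(np.array([0.05]), np.array([0.0, 0.05, 0.1]))
        assert list(counts) == [0, 1]

    def test_counts_sum_and_undefined(self, rng):
        v = rng.random(100)
        v[:7] = np.nan
        counts, n_undef = bin_spectrum(v, np.linspace(0, 1.0001, 11))
        assert counts.sum() == 93
        assert n_undef == 7

    def test_matches_brute_force(self, rng):
        v = rng.random(200)
        edges = np.array([0.0, 0.1, 0.5, 0.9, 1.0001])
        counts, _ = bin_spectrum(v, edges)
        brute = [np.sum((v >= lo) & (v < hi)) for lo, hi in zip(edges[:-1], edges[1:])]
        assert list(counts) == brute

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_spectrum(np.array([1.5]), np.array([0.0, 1.0]))


class TestConservation:
    def _setup(self):
        b = block_from_strings(["01", "10"], positions=[5, 50])
        track = ConservationTrack(
            pd.DataFrame(
                [("chr1", 0, 10, 2.0), ("chr1", 40, 60, 3.5)],
                columns=["chrom", "start", "end", "score"],
            )
        )
        return b, track

    def test_inclusive_threshold_boundary(self):
        b, track = self._setup()
        out = classify_conservation(b, track)
        assert bool(out["conserved_ge2"][0])      # score exactly 2.0
        assert not bool(out["conserved_ge3"][0])
        assert bool(out["conserved_ge3"][1])

    def test_threshold_monotonicity(self, rng):
        b, track = self._setup()
        out = classify_conservation(b, track)
        assert np.all(~out["conserved_ge3"] | out["conserved_ge2"])

    def test_missing_score_nonconserved(self):
        b = block_from_strings(["01", "10"], positions=[100, 200])
        track = ConservationTrack(
            pd.DataFrame([("chr1", 0, 10, 5.0)], columns=["chrom", "start", "end", "score"])
        )
        out = classify_conservation(b, track)
        assert not out["conserved_ge2"].any()

    def test_element_fraction_by_construction(self):
        els = ElementTrack(
            pd.DataFrame([("chr1", 0, 100, "CNC")], columns=["chrom", "start", "end", "element_class"])
        )
        track = ConservationTrack(
            pd.DataFrame([("chr1", 0, 40, 3.0), ("chr1", 40, 100, 0.0)],
                         columns=["chrom", "start", "end", "score"])
        )
        out = element_conserved_fraction(els, track, 2.0)
        assert out.loc[0, "fraction"] == pytest.approx(0.4)

    def test_fraction_matches_per_base_scan(self, rng):
        size = 5_000
        runs = []
        cursor = 0
        while cursor < size:
            ln = int(rng.integers(50, 400))
            runs.append(("chr1", cursor, min(cursor + ln, size), float(rng.normal())))
            cursor += ln
        track = ConservationTrack(pd.DataFrame(runs, columns=["chrom", "start", "end", "score"]))
        els = ElementTrack(
            pd.DataFrame([("chr1", 500, 2_500, "x"), ("chr1", 3_000, 4_200, "x")],
                         columns=["chrom", "start", "end", "element_class"])
        )
        out = element_conserved_fraction(els, track, 0.0)
        per_base = np.full(size, -np.inf)
        for _, s, e, sc in runs:
            per_base[s:e] = sc
        mask = np.zeros(size, bool)
        mask[500:2_500] = True
        mask[3_000:4_200] = True
        expected = np.mean(per_base[mask] >= 0.0)
        assert out.loc[0, "fraction"] == pytest.approx(expected)

    def test_fraction_low_daf(self):
        assert fraction_low_daf(np.array([0.01, 0.05, 0.5, np.nan])) == pytest.approx(2 / 3)
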