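import numpy as np
import pytest

from ncselect.datamodel import HaplotypeBlock


def block_from_strings(haps, positions=None, ancestral_known=None, chrom="chr1"):
    """Build a HaplotypeBlock from '0101'-style haplotype strings."""
    alleles = np.array([[int(c) for c in h] for h in haps], dtype=np.uint8)
    n_sites = alleles.shape[1]
    if positions is None:
        positions = np.arange(n_sites)
    if ancestral_known is None:
        ancestral_known = np.ones(n_sites, dtype=bool)
    return HaplotypeBlock(
        chrom=chrom,
        positions=np.asarray(positions),
        alleles=alleles,
        ancestral_known=np.asarray(ancestral_known),
    )


def random_block(rng, n_hap=6, n_sites=10, chrom="chr1"):
    """Random segregating-site matrix (no fixed columns)."""
    cols = []
    while len(cols) < n_sites:
        c = rng.integers(0, 2, size=n_hap).astype(np.uint8)
        if 0 < c.sum() < n_hap:
            cols.append(c)
    alleles = np.stack(cols, axis=1)
    positions = np.sort(rng.choice(100_000, size=n_sites, replace=False))
    return HaplotypeBlock(
        chrom=chrom,
        positions=positions,
        alleles=alleles,
        ancestral_known=np.ones(n_sites, dtype=bool),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
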