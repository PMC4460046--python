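"""Coalescent synthetic-data generator.

Produces phased haplotype data with the statistical structure the
downstream scan assumes: a neutral panmictic baseline, island-model
population differentiation, selective-sweep haplotype structure around a
core SNP (founder copying), a purifying-selection SFS skew inside
designated constrained elements, and matching element / conservation /
gene tracks.

Loci are simulated under the standard Kingman coalescent with infinite
sites and no intra-locus recombination (windows are short); recombination
enters only through the sweep founder-copy breakpoints.  Time is in units
of 2N generations, so pairwise coalescence happens at rate 1 and mutations
fall on a branch of length t as Poisson(θ/2 · t) with θ = 4Nμ per locus.

Everything is a pure function of (config, seed): a fixed seed gives a
byte-identical result.  Replicate streams are derived from the master seed
with ``numpy.random.SeedSequence(seed).spawn``.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datamodel import (
    ConservationTrack,
    ElementTrack,
    GeneTrack,
    HaplotypeBlock,
    PopulationPanel,
)

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Parameters of the generator.

    n_haplotypes  haplotypes per deme (an even count pairs into diploids)
    theta         4Nμ per locus
    locus_length  locus size in bp
    n_demes / migration   island model; migration M = 4Nm (per-lineage
                  migration rate M/2 in coalescent time units)
    sweep_*       core position (default locus midpoint), final derived
                  frequency at the core, per-bp crossover probability for
                  the founder-copy breakpoints, and copy fidelity
    beta          SFS skew exponent for constrained elements (f(i) ∝ i^−β;
                  β=1 is the neutral spectrum)
    """

    n_haplotypes: int = 50
    theta: float = 10.0
    locus_length: int = 10_000
    n_demes: int = 1
    migration: float = 1.0
    sweep_pos: int | None = None
    sweep_freq: float = 0.7
    crossover_prob: float = 5e-6
    sweep_fidelity: float = 1.0
    beta: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.sweep_freq < 1:
            raise ValueError("sweep_freq must lie in (0, 1)")
        if self.locus_length <= 0:
            raise ValueError("locus_length must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _coalesce_panmictic(n: int, rng: np.random.Generator) -> list[tuple[np.ndarray, float]]:
    """Single-deme Kingman coalescent (fast path for the neutral generator)."""
    k = np.arange(n, 1, -1)
    waits = rng.exponential(2.0 / (k * (k - 1.0)))  # T_k for k = n..2
    lineages: list[np.ndarray] = [np.array([i], dtype=np.int64) for i in range(n)]
    birth = [0.0] * n
    branches: list[tuple[np.ndarray, float]] = []
    t = 0.0
    for w in waits:
        t += w
        m = len(lineages)
        i = int(rng.integers(m))
        j = int(rng.integers(m - 1))
        if j >= i:
            j += 1
        branches.append((lineages[i], t - birth[i]))
        branches.append((lineages[j], t - birth[j]))
        merged = np.concatenate([lineages[i], lineages[j]])
        if i < j:
            i, j = j, i
        lineages[i] = lineages[-1] if i != m - 1 else lineages[i]
        birth[i] = birth[-1]
        lineages[j] = merged
        birth[j] = t
        lineages.pop()
        birth.pop()
    return branches


def _coalesce(
    n_per_deme: list[int], migration: float, rng: np.random.Generator
) -> list[tuple[np.ndarray, float]]:
    """Structured Kingman coalescent; returns (descendant-leaf-set, length) branches."""
    demes = len(n_per_deme)
    if demes == 1:
        return _coalesce_panmictic(n_per_deme[0], rng)
    leaves: list[np.ndarray] = []
    deme_of: list[int] = []
    offset = 0
    for d, nd in enumerate(n_per_deme):
        for i in range(nd):
            leaves.append(np.array([offset + i], dtype=np.int64))
            deme_of.append(d)
        offset += nd
    birth = [0.0] * len(leaves)
    branches: list[tuple[np.ndarray, float]] = []
    t = 0.0
    while len(leaves) > 1:
        k_d = np.bincount(deme_of, minlength=demes)
        coal_rates = k_d * (k_d - 1) / 2.0
        mig_rate = len(leaves) * migration / 2.0 if demes > 1 else 0.0
        total = coal_rates.sum() + mig_rate
        if total <= 0:
            raise ValueError(
                "no possible event: lineages isolated in different demes "
                "with migration <= 0"
            )
        t += rng.exponential(1.0 / total)
        if rng.random() * total < coal_rates.sum():
            d = rng.choice(demes, p=coal_rates / coal_rates.sum())
            members = [i for i, dd in enumerate(deme_of) if dd == d]
            i, j = rng.choice(len(members), size=2, replace=False)
            ii, jj = members[i], members[j]
            for idx in (ii, jj):
                branches.append((leaves[idx], t - birth[idx]))
            merged = np.concatenate([leaves[ii], leaves[jj]])
            keep = [x for x in range(len(leaves)) if x not in (ii, jj)]
            leaves = [leaves[x] for x in keep] + [merged]
            birth = [birth[x] for x in keep] + [t]
            deme_of = [deme_of[x] for x in keep] + [d]
        else:
            i = int(rng.integers(len(leaves)))
            others = [d for d in range(demes) if d != deme_of[i]]
            deme_of[i] = int(rng.choice(others))
    return branches


def _drop_mutations(
    branches: list[tuple[np.ndarray, float]],
    n: int,
    theta: float,
    L: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson mutations on branches under infinite sites; distinct bp positions."""
    lengths = np.array([b[1] for b in branches])
    total = lengths.sum()
    n_mut = rng.poisson(theta / 2.0 * total)
    n_mut = min(n_mut, L)  # infinite sites capped by finite bp grid
    if n_mut == 0:
        return np.zeros(0, dtype=np.int64), np.zeros((n, 0), dtype=np.uint8)
    which = rng.choice(len(branches), size=n_mut, p=lengths / total)
    positions = rng.choice(L, size=n_mut, replace=False)
    order = np.argsort(positions)
    positions = positions[order]
    which = which[order]
    alleles = np.zeros((n, n_mut), dtype=np.uint8)
    for j, b in enumerate(which):
        alleles[branches[b][0], j] = 1
    return positions.astype(np.int64), alleles


def _sample_ids(n: int, prefix: str = "s") -> list[str]:
    if n % 2:
        return [f"{prefix}{i}" for i in range(n)]
    return [f"{prefix}{i}_{h}" for i in range(n // 2) for h in (1, 2)]


def simulate_neutral(config: SimConfig, rng: np.random.Generator | None = None) -> HaplotypeBlock:
    """One neutral panmictic locus under the standard coalescent."""
    n = config.n_haplotypes
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    rng = config.rng() if rng is None else rng
    branches = _coalesce([n], 0.0, rng)
    positions, alleles = _drop_mutations(branches, n, config.theta, config.locus_length, rng)
    return HaplotypeBlock(
        chrom="chrS",
        positions=positions,
        alleles=alleles,
        ancestral_known=np.ones(positions.size, dtype=bool),
        sample_ids=_sample_ids(n),
    )


_DEME_CODES = ["POP1", "POP2", "POP3", "POP4", "POP5"]
_SUPER_CODES = ["SP1", "SP2", "SP3", "SP4", "SP5"]


def simulate_island(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[HaplotypeBlock, PopulationPanel]:
    """Island-model locus: d demes, symmetric migration M = 4Nm."""
    d = config.n_demes
    if d < 2:
        raise ValueError("island model needs >= 2 demes")
    if config.migration <= 0:
        raise ValueError("migration must be > 0 (pure isolation has no common ancestor)")
    n = config.n_haplotypes
    rng = config.rng() if rng is None else rng
    branches = _coalesce([n] * d, config.migration, rng)
    total_n = n * d
    positions, alleles = _drop_mutations(branches, total_n, config.theta, config.locus_length, rng)
    ids = []
    panel_rows = []
    for dd in range(d):
        pop = _DEME_CODES[dd % len(_DEME_CODES)]
        sup = _SUPER_CODES[dd % len(_SUPER_CODES)]
        for i in range(n // 2):
            sample = f"{pop.lower()}_{i}"
            ids.extend([f"{sample}_1", f"{sample}_2"])
            panel_rows.append((sample, pop, sup))
        if n % 2:
            sample = f"{pop.lower()}_x"
            ids.append(sample)
            panel_rows.append((sample, pop, sup))
    block = HaplotypeBlock(
        chrom="chrS",
        positions=positions,
        alleles=alleles,
        ancestral_known=np.ones(positions.size, dtype=bool),
        sample_ids=ids,
    )
    panel = PopulationPanel(pd.DataFrame(panel_rows, columns=["sample", "pop", "superpop"]))
    return block, panel


def simulate_sweep(config: SimConfig, rng: np.random.Generator | None = None) -> HaplotypeBlock:
    """Neutral locus with founder-copy sweep structure around a core SNP.

    A core site is inserted at ``sweep_pos`` (locus midpoint by default) at
    the configured derived frequency.  Every derived-core carrier replaces
    its flanking sequence with the founder carrier's haplotype out to
    independent left/right breakpoints drawn geometric per bp with rate
    ``crossover_prob``, producing long shared homozygosity on the derived
    background only.  ``sweep_fidelity`` < 1 lets each copied allele revert
    to the carrier's own with probability 1 − fidelity.
    """
    rng = config.rng() if rng is None else rng
    block = simulate_neutral(config, rng)
    n = config.n_haplotypes
    L = config.locus_length
    core_pos = config.sweep_pos if config.sweep_pos is not None else L // 2
    n_carriers = round(config.sweep_freq * n)
    if not math.isclose(config.sweep_freq * n, n_carriers):
        logger.info(
            "sweep frequency %.3f x n=%d rounded to %d carriers",
            config.sweep_freq, n, n_carriers,
        )
    n_carriers = min(max(n_carriers, 2), n - 1)
    carriers = rng.choice(n, size=n_carriers, replace=False)
    founder = carriers[0]
    alleles = block.alleles.copy()
    for h in carriers[1:]:
        left = int(rng.geometric(config.crossover_prob)) if config.crossover_prob > 0 else L
        right = int(rng.geometric(config.crossover_prob)) if config.crossover_prob > 0 else L
        span = (block.positions > core_pos - left) & (block.positions < core_pos + right)
        idx = np.flatnonzero(span)
        if config.sweep_fidelity < 1.0:
            copy = rng.random(idx.size) < config.sweep_fidelity
            idx = idx[copy]
        alleles[h, idx] = block.alleles[founder, idx]
    core_col = np.zeros((n, 1), dtype=np.uint8)
    core_col[carriers, 0] = 1
    # splice the core column into position order (replace any colliding site)
    keep = block.positions != core_pos
    positions = np.concatenate([block.positions[keep], [core_pos]])
    alleles = np.concatenate([alleles[:, keep], core_col], axis=1)
    order = np.argsort(positions)
    return HaplotypeBlock(
        chrom=block.chrom,
        positions=positions[order],
        alleles=alleles[:, order],
        ancestral_known=np.ones(positions.size, dtype=bool),
        sample_ids=block.sample_ids,
    )


def skew_sfs(
    block: HaplotypeBlock,
    elements: ElementTrack,
    beta: float,
    constrained_classes: set[str] | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> HaplotypeBlock:
    """Purifying-selection skew: thin sites inside constrained elements.

    Inside the designated element classes a segregating site with derived
    count i is retained with probability i^(1−β), so the retained
    derived-count distribution follows f(i) ∝ 1/i^β (the neutral spectrum
    is ∝ 1/i; β = 1 is an exact no-op in distribution).  Sites outside the
    elements are untouched.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    classes = constrained_classes or set(elements.classes)
    inside = np.zeros(block.n_sites, dtype=bool)
    sub = elements.df[elements.df["element_class"].isin(classes)]
    for _, row in sub.iterrows():
        if str(row["chrom"]) != block.chrom:
            continue
        inside |= (block.positions >= row["start"]) & (block.positions < row["end"])
    if not inside.any():
        logger.info("skew_sfs: no sites inside constrained elements; no-op")
        return block
    counts = block.derived_counts().astype(float)
    with np.errstate(divide="ignore"):
        accept_p = np.where(counts > 0, counts ** (1.0 - beta), 1.0)
    accept = rng.random(block.n_sites) < accept_p
    keep = ~inside | accept
    return block.take_sites(np.flatnonzero(keep))


def make_tracks(
    chrom: str,
    chrom_size: int,
    class_layout: dict[str, tuple[int, int]],
    constrained_classes: set[str],
    cons_prob: float = 0.9,
    cons_high: float = 3.5,
    cons_low: float = -1.0,
    n_genes: int = 10,
    gene_length: int = 2_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ElementTrack, ConservationTrack, GeneTrack]:
    """Element, conservation and gene tracks over one synthetic chromosome.

    ``class_layout`` maps element class -> (n_intervals, interval_length);
    intervals are placed non-overlapping in random order along the
    chromosome with random gaps.  Bases of constrained classes score
    ``cons_high`` with probability ``cons_prob`` (per interval), all other
    bases ``cons_low``.  Genes are dropped uniformly at random, so calls
    land inside genes, within 5 kb, and beyond.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    need = sum(n * ln for n, ln in class_layout.values())
    if need > chrom_size:
        raise ValueError("requested element lengths exceed chromosome size")
    pieces = [(cls, ln) for cls, (n, ln) in class_layout.items() for _ in range(n)]
    order = rng.permutation(len(pieces))
    slack = chrom_size - need
    gaps = rng.multinomial(slack, np.ones(len(pieces) + 1) / (len(pieces) + 1))
    rows, cons_rows = [], []
    cursor = 0
    for k, oi in enumerate(order):
        cls, ln = pieces[oi]
        cursor += int(gaps[k])
        start, end = cursor, cursor + ln
        rows.append((chrom, start, end, cls))
        if cls in constrained_classes and rng.random() < cons_prob:
            cons_rows.append((chrom, start, end, cons_high))
        else:
            cons_rows.append((chrom, start, end, cons_low))
        cursor = end
    elements = ElementTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "element_class"]))
    cons = ConservationTrack(
        pd.DataFrame(cons_rows, columns=["chrom", "start", "end", "score"]).sort_values("start")
    )
    g_starts = np.sort(rng.choice(max(chrom_size - gene_length, 1), size=n_genes, replace=False))
    genes = GeneTrack(
        pd.DataFrame(
            [(chrom, int(s), int(s) + gene_length, f"GENE{i}") for i, s in enumerate(g_starts)],
            columns=["chrom", "start", "end", "gene"],
        )
    )
    return elements, cons, genes


@dataclass
class GenomeConfig:
    """Layout of the full synthetic genome used by the end-to-end pipeline.

    The chromosome is tiled with consecutive independent loci (a crude
    stand-in for free recombination between windows); each locus is an
    island-model coalescent over the configured demes.  Sites falling in
    ``constrained_classes`` elements get the β-skewed spectrum; one locus
    inside ``sweep_class`` carries a founder-copy sweep.
    """

    n_loci: int = 60
    locus_length: int = 10_000
    theta: float = 10.0
    n_haplotypes: int = 20  # per deme
    n_demes: int = 3
    migration: float = 2.0
    beta: float = 2.0
    constrained_classes: tuple[str, ...] = ("CNC", "tRNA", "CDS")
    sweep_class: str = "lincRNA"
    sweep_freq: float = 0.7
    crossover_prob: float = 2e-4
    seed: int = 0


def simulate_genome(
    cfg: GenomeConfig,
) -> tuple[HaplotypeBlock, PopulationPanel, ElementTrack, ConservationTrack, GeneTrack]:
    """Full synthetic chromosome: island structure + constraint + one sweep."""
    master = np.random.SeedSequence(cfg.seed)
    seqs = master.spawn(cfg.n_loci + 2)
    L = cfg.locus_length
    chrom_size = cfg.n_loci * L
    chrom = "chr1"
    layout = {
        "CDS": (max(cfg.n_loci // 12, 1), L // 2),
        "intron": (max(cfg.n_loci // 8, 2), L),
        "CNC": (max(cfg.n_loci // 12, 1), L // 2),
        "tRNA": (max(cfg.n_loci // 20, 1), L // 10),
        "lincRNA": (max(cfg.n_loci // 12, 1), L),
    }
    track_rng = np.random.default_rng(seqs[-1])
    elements, cons, genes = make_tracks(
        chrom,
        chrom_size,
        layout,
        set(cfg.constrained_classes),
        rng=track_rng,
    )
    sweep_iv = elements.intervals(cfg.sweep_class).iloc[0]
    blocks: list[HaplotypeBlock] = []
    panel = None
    skew_rng = np.random.default_rng(seqs[-2])
    for k in range(cfg.n_loci):
        rng = np.random.default_rng(seqs[k])
        lo, hi = k * L, (k + 1) * L
        covers_sweep = lo <= (sweep_iv["start"] + sweep_iv["end"]) // 2 < hi
        conf = replace_config(cfg, L)
        if covers_sweep:
            # sweep applied on a panmictic tree so the swept haplotype is
            # shared across demes, then labelled by deme order
            sweep_conf = conf_with(conf, n_haplotypes=cfg.n_haplotypes * cfg.n_demes,
                                   sweep_pos=int((sweep_iv["start"] + sweep_iv["end"]) // 2 - lo))
            loc = simulate_sweep(sweep_conf, rng)
        else:
            loc, pnl = simulate_island(conf, rng)
            panel = panel or pnl
        loc = HaplotypeBlock(
            chrom=chrom,
            positions=loc.positions + lo,
            alleles=loc.alleles,
            ancestral_known=loc.ancestral_known,
            sample_ids=loc.sample_ids,
        )
        blocks.append(loc)
    if panel is None:
        raise RuntimeError("genome must contain at least one non-sweep locus")
    # one consistent deme-labelled haplotype ordering across all loci
    ids = [
        f"{s}_{h}"
        for s in panel.df["sample"]
        for h in (1, 2)
    ][: cfg.n_haplotypes * cfg.n_demes]
    positions = np.concatenate([b.positions for b in blocks])
    alleles = np.concatenate([b.alleles for b in blocks], axis=1)
    known = np.concatenate([b.ancestral_known for b in blocks])
    block = HaplotypeBlock(
        chrom=chrom,
        positions=positions,
        alleles=alleles,
        ancestral_known=known,
        sample_ids=ids,
    )
    block = skew_sfs(block, elements, cfg.beta, set(cfg.constrained_classes), rng=skew_rng)
    return block, panel, elements, cons, genes


def replace_config(cfg: GenomeConfig, L: int) -> SimConfig:
    return SimConfig(
        n_haplotypes=cfg.n_haplotypes,
        theta=cfg.theta,
        locus_length=L,
        n_demes=cfg.n_demes,
        migration=cfg.migration,
        sweep_freq=cfg.sweep_freq,
        crossover_prob=cfg.crossover_prob,
    )


def conf_with(conf: SimConfig, **kw) -> SimConfig:
    return replace(conf, **kw)
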