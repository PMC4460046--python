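"""Per-SNP allele-frequency quantities, Weir–Cockerham F_ST, spectrum
binning and conservation-threshold classification.

The F_ST estimator is the Weir & Cockerham (1984) method-of-moments θ̂ in
its haploid reduction (phased haplotypes are the sampling units, so the
heterozygosity component vanishes).  Per-site variance components a
(among populations) and b (within) are reported alongside θ̂ = a/(a+b);
negative per-site values are retained, not clamped, so threshold counts
such as F_ST < 0.05 stay well defined.  Two multi-locus aggregates are
emitted: the mean of per-site θ̂ and the ratio of sums Σa/Σ(a+b).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import ConservationTrack, ElementTrack, HaplotypeBlock, PopulationPanel

__all__ = [
    "FstResult",
    "weir_cockerham_fst",
    "hudson_fst",
    "global_and_pairwise_fst",
    "maf_daf",
    "bin_spectrum",
    "classify_conservation",
    "element_conserved_fraction",
    "fraction_low_daf",
]


@dataclass
class FstResult:
    """Per-site Weir–Cockerham components and aggregates."""

    a: np.ndarray        # among-population variance component per site
    b: np.ndarray        # within-population component per site
    theta: np.ndarray    # per-site a/(a+b); NaN where monomorphic overall
    defined: np.ndarray  # bool per site

    @property
    def mean_theta(self) -> float:
        return float(np.nanmean(np.where(self.defined, self.theta, np.nan)))

    @property
    def ratio_of_sums(self) -> float:
        d = self.defined
        return float(self.a[d].sum() / (self.a[d] + self.b[d]).sum())


def _group_freqs(
    block: HaplotypeBlock, panel: PopulationPanel, groups: Sequence[str | Sequence[str]], level: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group derived-allele frequencies and haploid sample sizes."""
    freqs, sizes = [], []
    for g in groups:
        idx = panel.haplotype_indices(block, g, level=level)
        sub = block.alleles[idx, :]
        freqs.append(sub.mean(axis=0))
        sizes.append(idx.size)
    return np.asarray(freqs, dtype=float), np.asarray(sizes, dtype=float)


def weir_cockerham_fst(
    block: HaplotypeBlock,
    panel: PopulationPanel,
    groups: Sequence[str | Sequence[str]],
    level: str = "pop",
) -> FstResult:
    """Haploid Weir–Cockerham θ̂ per site across the given population groups.

    With r groups of haploid sizes n_i and derived frequencies p_i:
    n̄ = Σn_i/r,  n_c = (r·n̄ − Σn_i²/(r·n̄))/(r−1),  p̄ = Σn_i p_i/(r·n̄),
    s² = Σn_i(p_i−p̄)²/((r−1)n̄), and
    a = (n̄/n_c)[s² − (p̄(1−p̄) − (r−1)s²/r)/(n̄−1)],
    b = (n̄/(n̄−1))[p̄(1−p̄) − (r−1)s²/r],  θ̂ = a/(a+b).
    Sites monomorphic in the pooled sample are flagged undefined.
    """
    r = len(groups)
    if r < 2:
        raise ValueError("need at least 2 population groups")
    p, n = _group_freqs(block, panel, groups, level)
    nbar = n.mean()
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (p - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1) * nbar)
    pq = pbar * (1.0 - pbar)
    b = (nbar / (nbar - 1.0)) * (pq - (r - 1.0) / r * s2)
    a = (nbar / nc) * (s2 - (pq - (r - 1.0) / r * s2) / (nbar - 1.0))
    denom = a + b
    defined = denom != 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(defined, a / np.where(defined, denom, 1.0), np.nan)
    return FstResult(a=a, b=b, theta=theta, defined=defined)


def hudson_fst(
    block: HaplotypeBlock,
    panel: PopulationPanel,
    groups: Sequence[str | Sequence[str]],
    level: str = "pop",
) -> float:
    """Hudson's multi-locus F_ST = 1 − π_within / π_between.

    π_within is the mean pairwise diversity inside groups (pooled over
    group pair counts); π_between averages pairs drawn from different
    groups.  An independent allele-count route used to cross-check the
    variance-component θ̂ on island simulations.
    """
    within_pairs = 0.0
    within_diff = 0.0
    sizes, counts = [], []
    for g in groups:
        idx = panel.haplotype_indices(block, g, level=level)
        ni = idx.size
        c = block.alleles[idx, :].sum(axis=0, dtype=np.int64)
        within_diff += float(np.sum(c * (ni - c)))
        within_pairs += ni * (ni - 1) / 2.0
        sizes.append(ni)
        counts.append(c)
    between_diff = 0.0
    between_pairs = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            between_diff += float(
                np.sum(counts[i] * (sizes[j] - counts[j]) + counts[j] * (sizes[i] - counts[i]))
            )
            between_pairs += sizes[i] * sizes[j]
    pi_w = within_diff / within_pairs
    pi_b = between_diff / between_pairs
    return 1.0 - pi_w / pi_b


def global_and_pairwise_fst(
    block: HaplotypeBlock,
    panel: PopulationPanel,
    global_pops: Sequence[str] | None = None,
    pooled: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-site global θ̂ over a population triple and pairwise pooled θ̂.

    ``global_pops`` defaults to the panel's first three populations; the
    global value is the r=3 W&C estimator over them taken together.
    ``pooled`` maps superpopulation-style labels to unions of populations
    (defaults to the panel's superpopulation column); pairwise θ̂ is the
    two-group estimator for each pooled pair.
    """
    if global_pops is None:
        global_pops = panel.populations[:3]
    if len(global_pops) < 2:
        raise ValueError("global F_ST needs at least 2 populations")
    out = pd.DataFrame({"chrom": block.chrom, "pos": block.positions})
    res = weir_cockerham_fst(block, panel, list(global_pops), level="pop")
    out["fst_global"] = res.theta
    if pooled is None:
        pooled = {
            sup: sorted(grp["pop"].unique())
            for sup, grp in panel.df.groupby("superpop")
        }
    names = sorted(pooled)
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            res = weir_cockerham_fst(block, panel, [list(pooled[gi]), list(pooled[gj])], level="pop")
            out[f"fst_{gi}_{gj}"] = res.theta
    return out


def maf_daf(
    block: HaplotypeBlock,
    panel: PopulationPanel | None = None,
    group: str | Sequence[str] | None = None,
    level: str = "pop",
) -> pd.DataFrame:
    """Per-site MAF and DAF, pooled or within one population group.

    MAF = min(p, 1−p) is defined at every site; DAF is NaN where the
    ancestral state is unknown.
    """
    if group is not None:
        if panel is None:
            raise ValueError("panel required for per-population frequencies")
        idx = panel.haplotype_indices(block, group, level=level)
        p = block.alleles[idx, :].mean(axis=0)
    else:
        p = block.alleles.mean(axis=0)
    daf = p.astype(float).copy()
    daf[~block.ancestral_known] = np.nan
    return pd.DataFrame(
        {
            "chrom": block.chrom,
            "pos": block.positions,
            "maf": np.minimum(p, 1.0 - p),
            "daf": daf,
            "ancestral_known": block.ancestral_known,
        }
    )


def bin_spectrum(values: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, int]:
    """Histogram over half-open, left-closed bins [e_k, e_{k+1}).

    NaN values are excluded and returned as a separate count.  Values
    outside [0, 1] raise.
    """
    values = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    defined = ~np.isnan(values)
    v = values[defined]
    if v.size and (v.min() < 0 or v.max() > 1):
        raise ValueError("values must lie in [0, 1]")
    idx = np.searchsorted(edges, v, side="right") - 1
    counts = np.bincount(idx[(idx >= 0) & (idx < len(edges) - 1)], minlength=len(edges) - 1)
    return counts, int(np.sum(~defined))


def classify_conservation(
    block: HaplotypeBlock,
    track: ConservationTrack,
    thresholds: Sequence[float] = (2.0, 3.0),
) -> pd.DataFrame:
    """Per-site conserved/non-conserved class at each score threshold.

    Conserved means score ≥ threshold (inclusive); a base with no score
    run is non-conserved at every threshold.
    """
    scores = track.score_at(block.chrom, block.positions)
    out = pd.DataFrame({"chrom": block.chrom, "pos": block.positions, "score": scores})
    for t in thresholds:
        out[f"conserved_ge{t:g}"] = ~np.isnan(scores) & (scores >= t)
    return out


def element_conserved_fraction(
    elements: ElementTrack, track: ConservationTrack, threshold: float
) -> pd.DataFrame:
    """Fraction of each element class's length with score ≥ threshold."""
    rows = []
    for cls in elements.classes:
        total = 0
        conserved = 0
        for _, iv in elements.intervals(cls).iterrows():
            length = iv["end"] - iv["start"]
            total += length
            runs = track.df[
                (track.df["chrom"] == iv["chrom"])
                & (track.df["end"] > iv["start"])
                & (track.df["start"] < iv["end"])
                & (track.df["score"] >= threshold)
            ]
            for _, r in runs.iterrows():
                conserved += min(r["end"], iv["end"]) - max(r["start"], iv["start"])
        rows.append((cls, total, conserved, conserved / total if total else np.nan))
    return pd.DataFrame(rows, columns=["element_class", "length", "conserved_length", "fraction"])


def fraction_low_daf(daf: np.ndarray, cutoff: float = 0.05) -> float:
    """Fraction of defined DAF values ≤ cutoff (rare-variant load)."""
    daf = np.asarray(daf, dtype=float)
    defined = ~np.isnan(daf)
    if not defined.any():
        return float("nan")
    return float(np.mean(daf[defined] <= cutoff))
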