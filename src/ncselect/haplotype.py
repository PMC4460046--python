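"""Extended haplotype homozygosity (EHH), integrated EHH, and iHS.

For a core SNP, EHH at a marker x is the probability that two randomly
drawn carriers of the core allele are identical at every polymorphic site
from the core through x.  iHH integrates the EHH curve over physical
distance (bp) on both sides of the core, truncated where the curve decays
below a cutoff (0.05 by default, the cited scan's convention); iHS is
ln(iHH_ancestral / iHH_derived), standardized to zero mean and unit SD
within derived-allele-frequency bins so that scores are comparable across
frequencies.  |iHS| > 2 is the conventional outlier flag.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import HaplotypeBlock

__all__ = ["IhsRecord", "ehh", "ihh", "ihs_at", "ihs_scan", "standardize_ihs", "BinReference"]

MAX_GAP = 200_000  # bp; larger inter-marker gaps truncate the EHH extension


def ehh(
    block: HaplotypeBlock,
    core_index: int,
    allele: int,
    direction: int,
    max_gap: int = MAX_GAP,
    stop_below: float | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """EHH curve from the core outward in one direction (+1 right, −1 left).

    Returns (positions, ehh, gap_truncated); the first entry is the core
    itself with EHH = 1.  The curve is non-increasing: haplotype groups
    only split as markers accumulate.  ``stop_below`` ends the walk once
    the curve first drops under the given value (one sub-threshold point
    is kept so the integrator can interpolate the crossing).
    """
    if allele not in (0, 1):
        raise ValueError("allele must be 0 (ancestral) or 1 (derived)")
    carriers = np.flatnonzero(block.alleles[:, core_index] == allele)
    if carriers.size < 2:
        raise ValueError("need at least 2 carriers of the core allele")
    c = carriers.size
    pair_norm = c * (c - 1)
    positions = [int(block.positions[core_index])]
    values = [1.0]
    group = np.zeros(c, dtype=np.int64)
    n_groups = 1
    j = core_index
    gap_truncated = False
    while True:
        j_next = j + direction
        if j_next < 0 or j_next >= block.n_sites:
            break
        if abs(int(block.positions[j_next]) - int(block.positions[j])) > max_gap:
            gap_truncated = True
            break
        col = block.alleles[carriers, j_next].astype(np.int64)
        combined = group * 2 + col
        _, group, counts = np.unique(combined, return_inverse=True, return_counts=True)
        n_groups = counts.size
        positions.append(int(block.positions[j_next]))
        values.append(float(np.sum(counts * (counts - 1)) / pair_norm))
        j = j_next
        if n_groups == c:  # fully split; EHH stays 0
            break
        if stop_below is not None and values[-1] < stop_below:
            break
    return np.asarray(positions, dtype=np.int64), np.asarray(values), gap_truncated


def ihh(
    positions: np.ndarray, ehh_values: np.ndarray, cutoff: float = 0.05
) -> tuple[float, bool]:
    """Trapezoid integral of one EHH arm over bp, truncated at the cutoff.

    Integration runs from the core to the linearly interpolated point
    where EHH first reaches the cutoff; if the curve never falls below the
    cutoff before the last marker, the arm is flagged edge-truncated and
    integrated to the end.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(ehh_values, dtype=float)
    if values[0] != 1.0:
        raise ValueError("EHH curve must start at 1 at the core")
    if values[0] <= cutoff:
        return 0.0, False
    area = 0.0
    for k in range(1, len(values)):
        d = abs(positions[k] - positions[k - 1])
        if values[k] >= cutoff:
            area += 0.5 * (values[k] + values[k - 1]) * d
        else:
            # interpolate the crossing, integrate the wedge above it
            frac = (values[k - 1] - cutoff) / (values[k - 1] - values[k])
            area += 0.5 * (values[k - 1] + cutoff) * d * frac
            return area, False
    return area, True  # never fell below cutoff before the last marker


@dataclass
class IhsRecord:
    chrom: str
    pos: int
    daf: float
    ihh_a: float
    ihh_d: float
    ihs_unstd: float
    ihs_std: float = math.nan
    edge_truncated: bool = False
    gap_truncated: bool = False
    bin_unstandardized: bool = False


def ihs_at(
    block: HaplotypeBlock, core_index: int, cutoff: float = 0.05, max_gap: int = MAX_GAP
) -> IhsRecord | None:
    """Unstandardized iHS for one core site; None when undefined.

    Undefined cases: fewer than 2 carriers of either core allele, or a
    zero iHH on either background.
    """
    col = block.alleles[:, core_index]
    if (col == 0).sum() < 2 or (col == 1).sum() < 2:
        return None
    edge = False
    gap = False
    ihhs = {}
    for allele in (0, 1):
        total = 0.0
        for direction in (-1, 1):
            pos, vals, g = ehh(block, core_index, allele, direction, max_gap, stop_below=cutoff)
            arm, e = ihh(pos, vals, cutoff)
            total += arm
            edge |= e
            gap |= g
        ihhs[allele] = total
    if ihhs[0] <= 0 or ihhs[1] <= 0:
        return None
    daf = float(block.alleles[:, core_index].mean())
    return IhsRecord(
        chrom=block.chrom,
        pos=int(block.positions[core_index]),
        daf=daf,
        ihh_a=ihhs[0],
        ihh_d=ihhs[1],
        ihs_unstd=math.log(ihhs[0] / ihhs[1]),
        edge_truncated=edge,
        gap_truncated=gap,
    )


@dataclass
class BinReference:
    """Frequency-bin means/SDs used to standardize iHS against a reference."""

    edges: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def from_scores(cls, daf: np.ndarray, scores: np.ndarray, n_bins: int = 20) -> "BinReference":
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        idx = np.clip(np.searchsorted(edges, daf, side="right") - 1, 0, n_bins - 1)
        means = np.full(n_bins, np.nan)
        sds = np.full(n_bins, np.nan)
        for b in range(n_bins):
            s = scores[idx == b]
            if s.size >= 2:
                means[b] = s.mean()
                sds[b] = s.std(ddof=0)
        return cls(edges=edges, means=means, sds=sds)

    def standardize(self, daf: float, score: float) -> tuple[float, bool]:
        n_bins = len(self.means)
        b = min(max(int(np.searchsorted(self.edges, daf, side="right") - 1), 0), n_bins - 1)
        if np.isnan(self.means[b]) or self.sds[b] == 0:
            return score, True  # left unstandardized, flagged
        return (score - self.means[b]) / self.sds[b], False


def ihs_scan(
    block: HaplotypeBlock,
    min_maf: float = 0.05,
    cutoff: float = 0.05,
    n_bins: int = 20,
    max_gap: int = MAX_GAP,
    reference: BinReference | None = None,
) -> pd.DataFrame:
    """iHS over every eligible core SNP of a block.

    Cores need MAF ≥ min_maf and a known ancestral state.  Standardization
    subtracts the derived-frequency-bin mean and divides by the bin SD,
    either within the scanned set itself or against a supplied reference
    (e.g. a genome-wide or neutral-background scan); bins with fewer than
    two scores leave their scores unstandardized and flagged.
    """
    freqs = block.alleles.mean(axis=0)
    maf = np.minimum(freqs, 1 - freqs)
    eligible = np.flatnonzero((maf >= min_maf) & block.ancestral_known)
    records: list[IhsRecord] = []
    for j in eligible:
        rec = ihs_at(block, int(j), cutoff=cutoff, max_gap=max_gap)
        if rec is not None:
            records.append(rec)
    if not records:
        return pd.DataFrame(
            columns=[
                "chrom", "pos", "daf", "ihh_a", "ihh_d", "ihs_unstd", "ihs_std",
                "edge_truncated", "gap_truncated", "bin_unstandardized",
            ]
        )
    daf = np.array([r.daf for r in records])
    raw = np.array([r.ihs_unstd for r in records])
    ref = reference or BinReference.from_scores(daf, raw, n_bins=n_bins)
    for r in records:
        r.ihs_std, r.bin_unstandardized = ref.standardize(r.daf, r.ihs_unstd)
    return pd.DataFrame([r.__dict__ for r in records])


def standardize_ihs(daf: np.ndarray, scores: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Standalone frequency-bin z-scoring of unstandardized iHS values."""
    ref = BinReference.from_scores(np.asarray(daf), np.asarray(scores), n_bins=n_bins)
    out = np.empty(len(scores))
    for k, (d, s) in enumerate(zip(daf, scores)):
        out[k], _ = ref.standardize(float(d), float(s))
    return out
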