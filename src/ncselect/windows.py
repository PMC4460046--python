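"""Concatenation, sliding windows, bootstrap and permutation machinery.

Each element class is analysed on a gapless concatenated coordinate axis
(its intervals re-addressed end to end, preserving order), cut into 10 kb
windows advanced by 5 kb.  Window means of a statistic are compared to the
genome-wide background by a label-permutation test; the bootstrap gives a
mean and resampling SE over windows.

Terminal partial windows (shorter than the window size) are dropped so
per-window L is constant; windows with S = 0 carry NaN statistics and are
excluded from means symmetrically on both sides of every comparison.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ElementTrack, HaplotypeBlock
from .sfs import SfsSummary, sfs_summary

__all__ = [
    "ConcatMap",
    "PermutationResult",
    "concatenate_element",
    "sliding_windows",
    "windows_to_frame",
    "bootstrap_mean",
    "permutation_test",
]


@dataclass
class ConcatMap:
    """Mapping between original and concatenated coordinates for one class."""

    chrom: str
    starts: np.ndarray   # original interval starts
    ends: np.ndarray
    offsets: np.ndarray  # concatenated-axis start of each interval
    length: int          # total concatenated length

    def to_concat(self, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=np.int64)
        idx = np.searchsorted(self.starts, positions, side="right") - 1
        if (idx < 0).any() or (positions >= self.ends[np.clip(idx, 0, None)]).any():
            raise ValueError("position outside the concatenated intervals")
        return self.offsets[idx] + (positions - self.starts[idx])

    def to_original(self, concat_positions: np.ndarray) -> np.ndarray:
        concat_positions = np.asarray(concat_positions, dtype=np.int64)
        idx = np.searchsorted(self.offsets, concat_positions, side="right") - 1
        return self.starts[idx] + (concat_positions - self.offsets[idx])


def concatenate_element(
    block: HaplotypeBlock, elements: ElementTrack, element_class: str
) -> tuple[HaplotypeBlock, ConcatMap]:
    """Restrict a block to one element class on a gapless concatenated axis."""
    ivs = elements.intervals(element_class)
    ivs = ivs[ivs["chrom"] == block.chrom].reset_index(drop=True)
    total = int((ivs["end"] - ivs["start"]).sum()) if len(ivs) else 0
    if total == 0:
        raise ValueError(f"element class {element_class!r} has zero length on {block.chrom}")
    starts = ivs["start"].to_numpy(dtype=np.int64)
    ends = ivs["end"].to_numpy(dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(ends - starts)[:-1]]).astype(np.int64)
    cmap = ConcatMap(block.chrom, starts, ends, offsets, total)
    sub, _ = block.restrict(ivs)
    remapped = HaplotypeBlock(
        chrom=block.chrom,
        positions=cmap.to_concat(sub.positions),
        alleles=sub.alleles,
        ancestral_known=sub.ancestral_known,
        sample_ids=sub.sample_ids,
    )
    return remapped, cmap


def sliding_windows(
    block: HaplotypeBlock,
    axis_length: int,
    size: int = 10_000,
    step: int = 5_000,
) -> list[tuple[int, int, SfsSummary]]:
    """SFS summaries in [k·step, k·step+size) windows on the given axis.

    Only full-size windows are emitted (terminal remainders are dropped);
    empty windows produce S=0 summaries flagged undefined.
    """
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    out = []
    start = 0
    while start + size <= axis_length:
        idx = np.flatnonzero((block.positions >= start) & (block.positions < start + size))
        out.append((start, start + size, sfs_summary(block.take_sites(idx), L=size)))
        start += step
    return out


def windows_to_frame(
    windows: list[tuple[int, int, SfsSummary]],
    element_class: str = "",
    population: str = "",
) -> pd.DataFrame:
    columns = [
        "element_class", "population", "window", "start", "end", "n", "S",
        "pi_per_site", "theta_w", "tajima_d", "fu_li_d_star", "fu_li_f_star",
        "fay_wu_h", "defined",
    ]
    if not windows:
        return pd.DataFrame(columns=columns)
    rows = []
    for k, (s, e, summ) in enumerate(windows):
        rows.append(
            {
                "element_class": element_class,
                "population": population,
                "window": k,
                "start": s,
                "end": e,
                "n": summ.n,
                "S": summ.S,
                "pi_per_site": summ.pi_per_site,
                "theta_w": summ.theta_w,
                "tajima_d": summ.tajima_d,
                "fu_li_d_star": summ.fu_li_d_star,
                "fu_li_f_star": summ.fu_li_f_star,
                "fay_wu_h": summ.fay_wu_h,
                "defined": summ.defined,
            }
        )
    return pd.DataFrame(rows)


def bootstrap_mean(
    values: np.ndarray, n_boot: int = 1000, seed: int | None = None
) -> tuple[float, float]:
    """Mean of n_boot with-replacement resample means, and their SD.

    NaN (undefined-window) values are dropped first; an all-NaN input
    raises.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("no defined values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    return float(means.mean()), float(means.std())


@dataclass
class PermutationResult:
    element_class: str
    statistic: str
    element_mean: float
    background_mean: float
    delta_obs: float
    p_value: float
    n_perm: int
    two_sided: bool


def permutation_test(
    element_values: np.ndarray,
    background_values: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    two_sided: bool = True,
    element_class: str = "",
    statistic: str = "",
) -> PermutationResult:
    """Label-permutation test on the difference of group means.

    Pools both groups, reshuffles labels preserving group sizes, and
    counts permuted |Δ| ≥ |Δ_obs| (signed Δ ≥ Δ_obs when one-sided).
    P uses the +1 finite-resampling correction, so P ∈ (0, 1].
    NaN values are dropped from both groups symmetrically.
    """
    ev = np.asarray(element_values, dtype=float)
    bv = np.asarray(background_values, dtype=float)
    ev = ev[~np.isnan(ev)]
    bv = bv[~np.isnan(bv)]
    if ev.size == 0 or bv.size == 0:
        raise ValueError("both groups must contain defined values")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([ev, bv])
    ne = ev.size
    delta_obs = ev.mean() - bv.mean()
    obs = abs(delta_obs) if two_sided else delta_obs
    # vectorized label shuffles: each row an independent permutation
    n_tot = pooled.size
    count = 0
    chunk = max(1, min(n_perm, int(2e7) // max(n_tot, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.tile(pooled, (m, 1)), axis=1)
        d = perm[:, :ne].mean(axis=1) - perm[:, ne:].mean(axis=1)
        stat = np.abs(d) if two_sided else d
        count += int(np.sum(stat >= obs))
        done += m
    p = (1.0 + count) / (n_perm + 1.0)
    return PermutationResult(
        element_class=element_class,
        statistic=statistic,
        element_mean=float(ev.mean()),
        background_mean=float(bv.mean()),
        delta_obs=float(delta_obs),
        p_value=float(p),
        n_perm=n_perm,
        two_sided=two_sided,
    )
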