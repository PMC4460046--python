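"""Core in-memory containers for the selection scan.

All genomic coordinates are 0-based, half-open throughout the package;
1-based VCF positions are converted on ingest.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class HaplotypeBlock:
    """Phased biallelic haplotypes over one chromosome.

    ``alleles`` is an (n_haplotypes, n_sites) matrix coded 0 = ancestral,
    1 = derived at sites where the ancestral state is known.  Where
    ``ancestral_known`` is False the codes are REF/ALT counts (0 = REF,
    1 = ALT) and derived-allele quantities are undefined at that site.
    Two consecutive haplotypes belong to one diploid sample when the
    ``sample_ids`` labels share a sample stem (``<sample>_1``/``<sample>_2``).
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    ancestral_known: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.ancestral_known = np.asarray(self.ancestral_known, dtype=bool)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (haplotypes x sites) matrix")
        n_hap, n_sites = self.alleles.shape
        if self.positions.shape != (n_sites,):
            raise ValueError("positions length must equal number of sites")
        if self.ancestral_known.shape != (n_sites,):
            raise ValueError("ancestral_known length must equal number of sites")
        if n_sites > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("allele codes must be 0 or 1")
        if not self.sample_ids:
            self.sample_ids = [f"hap{i}" for i in range(n_hap)]
        if len(self.sample_ids) != n_hap:
            raise ValueError("sample_ids length must equal number of haplotypes")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def derived_counts(self) -> np.ndarray:
        """Per-site count of the derived (or ALT, where unpolarized) allele."""
        return self.alleles.sum(axis=0, dtype=np.int64)

    def derived_freq(self) -> np.ndarray:
        """Per-site derived-allele frequency; NaN where ancestral state unknown."""
        with np.errstate(invalid="ignore"):
            f = self.derived_counts() / float(self.n_haplotypes)
        f = f.astype(float)
        f[~self.ancestral_known] = np.nan
        return f

    def take_sites(self, index: np.ndarray) -> "HaplotypeBlock":
        index = np.asarray(index)
        return replace(
            self,
            positions=self.positions[index],
            alleles=self.alleles[:, index],
            ancestral_known=self.ancestral_known[index],
        )

    def take_haplotypes(self, index: np.ndarray) -> "HaplotypeBlock":
        index = np.asarray(index)
        return replace(
            self,
            alleles=self.alleles[index, :],
            sample_ids=[self.sample_ids[i] for i in index],
        )

    def sample_stems(self) -> list[str]:
        """Sample of origin per haplotype (label without trailing _1/_2)."""
        stems = []
        for s in self.sample_ids:
            stem, _, tail = s.rpartition("_")
            stems.append(stem if stem and tail in ("1", "2") else s)
        return stems

    def restrict(self, intervals: pd.DataFrame) -> tuple["HaplotypeBlock", np.ndarray]:
        """Subset to sites falling inside any half-open (start, end) interval.

        Returns the restricted block and the index of the kept sites.
        """
        keep = np.zeros(self.n_sites, dtype=bool)
        for _, row in intervals.iterrows():
            if str(row.get("chrom", self.chrom)) != self.chrom:
                continue
            keep |= (self.positions >= row["start"]) & (self.positions < row["end"])
        idx = np.flatnonzero(keep)
        return self.take_sites(idx), idx


def _normalize_intervals(df: pd.DataFrame, label_col: str) -> pd.DataFrame:
    """Sort and merge overlapping or touching intervals within one label."""
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(f"empty or inverted interval {bad['chrom']}:{bad['start']}-{bad['end']}")
    out = []
    for (chrom, label), grp in df.groupby(["chrom", label_col], sort=True):
        grp = grp.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e, label))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e, label))
    res = pd.DataFrame(out, columns=["chrom", "start", "end", label_col])
    return res.sort_values(["chrom", "start"]).reset_index(drop=True)


@dataclass
class ElementTrack:
    """Labelled genomic intervals partitioning the analysis (half-open)."""

    df: pd.DataFrame  # chrom, start, end, element_class

    def __post_init__(self) -> None:
        self.df = _normalize_intervals(
            self.df[["chrom", "start", "end", "element_class"]].copy(), "element_class"
        )

    @property
    def classes(self) -> list[str]:
        return sorted(self.df["element_class"].unique())

    def intervals(self, element_class: str) -> pd.DataFrame:
        sub = self.df[self.df["element_class"] == element_class]
        if sub.empty:
            raise KeyError(f"element class {element_class!r} not present in track")
        return sub.reset_index(drop=True)

    def total_length(self, element_class: str) -> int:
        sub = self.intervals(element_class)
        return int((sub["end"] - sub["start"]).sum())


@dataclass
class GeneTrack:
    """Gene intervals (half-open) used for call annotation."""

    df: pd.DataFrame  # chrom, start, end, gene

    def __post_init__(self) -> None:
        self.df = (
            self.df[["chrom", "start", "end", "gene"]]
            .sort_values(["chrom", "start"])
            .reset_index(drop=True)
        )
        if (self.df["start"] >= self.df["end"]).any():
            raise ValueError("gene intervals must satisfy start < end")


@dataclass
class ConservationTrack:
    """Per-base conservation scores as non-overlapping half-open runs."""

    df: pd.DataFrame  # chrom, start, end, score

    def __post_init__(self) -> None:
        df = self.df[["chrom", "start", "end", "score"]].sort_values(["chrom", "start"])
        for chrom, grp in df.groupby("chrom"):
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise ValueError(f"overlapping score runs on {chrom}")
        if not np.isfinite(df["score"]).all():
            raise ValueError("scores must be finite")
        self.df = df.reset_index(drop=True)

    def score_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Score per base; NaN where no run covers the base."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, np.nan)
        grp = self.df[self.df["chrom"] == chrom]
        if grp.empty:
            return out
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        scores = grp["score"].to_numpy()
        idx = np.searchsorted(starts, positions, side="right") - 1
        valid = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        out[valid] = scores[idx[valid]]
        return out


@dataclass
class PopulationPanel:
    """sample -> (population, superpopulation) grouping."""

    df: pd.DataFrame  # sample, pop, superpop

    def __post_init__(self) -> None:
        self.df = self.df[["sample", "pop", "superpop"]].reset_index(drop=True)
        if self.df["sample"].duplicated().any():
            raise ValueError("duplicate sample in panel")

    @property
    def populations(self) -> list[str]:
        return sorted(self.df["pop"].unique())

    @property
    def superpopulations(self) -> list[str]:
        return sorted(self.df["superpop"].unique())

    def samples_in(self, group: str | Sequence[str], level: str = "pop") -> list[str]:
        """Samples in one population or in a pooled union of populations."""
        groups = [group] if isinstance(group, str) else list(group)
        col = {"pop": "pop", "superpop": "superpop"}[level]
        known = set(self.df[col])
        missing = [g for g in groups if g not in known]
        if missing:
            raise KeyError(f"population(s) {missing} not in panel")
        return self.df.loc[self.df[col].isin(groups), "sample"].tolist()

    def haplotype_indices(
        self, block: HaplotypeBlock, group: str | Sequence[str], level: str = "pop"
    ) -> np.ndarray:
        """Indices of the block's haplotypes carried by samples of a group."""
        wanted = set(self.samples_in(group, level))
        stems = block.sample_stems()
        idx = np.array([i for i, s in enumerate(stems) if s in wanted], dtype=np.int64)
        if idx.size == 0:
            raise KeyError(f"no haplotypes for group {group!r} in block")
        return idx
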